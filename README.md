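# colocmap

Genome-wide **feature co-localization analysis** in fixed-size windows.

Genomic features — repeat families (Alu, L1, L2, MIR), genes, regulatory
elements, methylation marks, SNPs, CNV breakpoints, recombination rates —
are not placed independently along chromosomes. Quantifying how strongly
any two feature tracks co-occur across the genome reveals large-scale
architecture (gene-rich vs gene-poor zones) and flags windows where several
variant classes pile up at once, which are natural targets for
disease-association searches. `colocmap` is a library + CLI for exactly
this analysis, aimed at statistical geneticists and genome-annotation
analysts working from BED-style interval tracks.

## What it computes

1. **Windowed quantitation.** Each chromosome is tiled into non-overlapping
   windows of W bp (floor(L/W) windows; windows overlapping assembly gaps
   are removed). Each feature's level in a window is one of
   - *Density* = (bases covered by merged intervals) / W,
   - *Intensity* = Σ (covered bases × element score) / W,
   - *count* = number of elements whose start lies in the window.
2. **Co-localization coefficients.** For every unordered pair of the k
   features (k = 42 gives 861 pairs), Pearson *r* and Spearman *ρ* of their
   per-window levels across the n kept windows, with the asymptotic
   two-tailed p-value from *t* = *r*·√((n−2)/(1−*r*²)) on n−2 df.
   Robustness concordances: *R_C* = corr(ρ-vector, r-vector), *R_W* =
   corr(r-vectors at two window sizes).
3. **Zonal classification (feature-ratios method).** Windows are labelled
   Genic / Proximal / Distal: score(w, z) = mean over zone-z features f of
   level(w, f)/mean(level(·, f)); label = argmax. The shipped model groups
   31 non-Marker features (24 Genic, 4 Proximal: L2, MIR, CID, TFBS,
   3 Distal: NAS−, L1, ATrich).
4. **SNP/CNV hotspots.** Per feature, the top-5% (ceil(q·n) by rank) windows;
   double/triple hotspots are windows hot in 2/3 marker features; their
   recombination rates are compared to the genome background with Welch's
   two-tailed t-test, and their gene content is tested for gene-set
   over-representation (hypergeometric p with Bonferroni, Benjamini–Hochberg
   and FDR-q control; significance requires all three < 0.05).
5. **Synthetic genomes.** A generator plants zone segments, pairwise
   correlations (Gaussian copula over Poisson rates) and joint hotspot
   windows with elevated recombination, and writes the same file formats
   the readers consume plus a ground-truth JSON — so the whole pipeline is
   testable without any downloads.

## Worked example

```sh
colocmap simulate --seed 7 --outdir demo/data --n-windows 1000
colocmap zones --layout demo/data/genome.chrom.sizes \
    --gaps demo/data/gaps.bed --manifest demo/data/tracks_manifest.tsv \
    -w 500000 --out demo/zones.bed
```

prints

```
Genic: 443 (45.2%)  Proximal: 301 (30.7%)  Distal: 236 (24.1%)
```

i.e. of the 980 gap-free 500-kb windows, 45.2% classify as Genic, 30.7% as
Proximal and 24.1% as Distal — recovering the simulated 45/31/24 zone mix.
The same objects are available from Python:

```python
import colocmap as cm
from colocmap.simulate import default_config, simulate_dataset

data = simulate_dataset(default_config(seed=7, n_windows=1000))
grid = cm.filter_gap_windows(cm.make_windows(data.layout, 500_000), data.gaps)
matrix = cm.build_matrix(grid, data.tracks)          # 980 windows x 35 features
pairs  = cm.build_coloc_matrix(matrix).pairs          # 595 rows: r, rho, p_asym
hot    = [cm.call_hotspots(matrix, f) for f in ("SNPdb", "SNP1K", "CNVG")]
triple = cm.overlap_hotspots(hot).triple              # joint SNP-CNV hotspot windows
rec    = matrix["RecH"]
print(cm.rate_test(rec, rec[sorted(triple)]).p)       # 9.97e-05
```

The SNPdb–SNP1K pair comes out at r = 0.81: the planted baseline
correlation of 0.7 plus the extra covariance contributed by the jointly
planted hotspot windows — exactly the kind of hotspot-driven inflation the
analysis is meant to surface. The triple-hotspot windows show
significantly elevated recombination intensity (p ≈ 1.0 × 10⁻⁴ above).

A full multi-window-size run (`colocmap run-all --config run.yaml`) writes,
per window size: the window grid BED, level-matrix TSV, co-localization
long TSV, zone BED + proportions, hotspot BEDs + per-zone Venn TSV, the
rate-test report and the enrichment TSV, plus R_C/R_W concordances and a
checksummed run manifest.

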