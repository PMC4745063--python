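# Methods

## Windowing and quantitation

Chromosomes are tiled from coordinate 0 into non-overlapping windows of
exactly W bp; a chromosome of length L yields floor(L/W) windows and the
trailing partial segment is discarded, so every window carries the same
denominator (a 249-Mb chromosome at W = 500 kb gives 498 windows). All
coordinates are 0-based half-open. Windows sharing at least 1 bp with any
assembly-gap interval are excluded from every downstream statistic; the
minimum-overlap threshold is configurable (default 1 bp, the strictest
reading of "overlaps a gap").

Feature levels per window:

* **Density** — covered bases / W, with overlapping intervals of the same
  track merged first so density ∈ [0, 1]. Used for sequence-class and
  repeat tracks.
* **Intensity** — Σ over elements of (bases inside the window × element
  score) / W, *without* merging: each scored element contributes
  independently. Used for scored tracks (binding-site, chromatin,
  methylation, expression, recombination-rate signals). Scores are used
  as supplied; no renormalisation is applied.
* **count** — number of elements whose start coordinate lies in the
  window. A boundary-straddling element therefore belongs to exactly one
  window and is never double-counted. Used for point-like elements (SNP
  sites, indels, CNV breakpoints, microsatellites).

Which mode a track uses is declared per track in the manifest; the
simulator's default roster uses count for element tracks and intensity for
the recombination track.

## Co-localization statistics

For each unordered feature pair, Pearson r of the paired per-window levels
and Spearman ρ (Pearson on mid-ranks, ties averaged). Both coefficients
get an asymptotic two-tailed p-value via t = r·√((n−2)/(1−r²)) on n−2 df —
the same transform for ρ, matching the convention of R's `Hmisc::rcorr`.
Exact Spearman null tables are not implemented. p-values below double
precision are reported as 0 (printed "<1e-16"). Constant feature columns
make the correlation undefined and raise an error naming the feature.

Robustness concordances are plain Pearson correlations of coefficient
vectors aligned in canonical (lexicographic) pair order: R_C between the
Spearman and Pearson vectors at one window size; R_W between Pearson
vectors at two window sizes. Pairs, not windows, are aligned — the kept
window set may legitimately differ between sizes because gap filtering is
size-dependent.

The asymptotic p is an approximation: against an exact permutation test at
n = 10 its bias is ≈ 2 × 10⁻³ in the distribution bulk, larger than the
Monte-Carlo error of a 10⁶-replicate permutation estimate (≈ 3 × 10⁻⁴), so
the oracle-equivalence tests assert agreement to 5 × 10⁻³ absolute — the
accuracy the t-approximation actually supports at that n. At the
thousands of windows used in real analyses the approximation error is
negligible relative to the p-values of interest.

## Zonal classification (feature-ratios method)

Given a zone model mapping zone → defining feature set (default: 24 Genic,
4 Proximal, 3 Distal features; Marker features excluded), the score of
window w for zone z is the mean over z's features of
level(w, f) / mean_windows(level(·, f)), and the window takes the argmax
zone. The score is parameter-free and scale-invariant per feature
(rescaling any feature column by a positive constant changes no label).
Exact score ties break deterministically by model zone order
(Genic > Proximal > Distal). A defining feature with zero genome-wide mean
is an error rather than a silent division by zero.

The designation-match check inverts the logic: for each model feature,
the fraction of its genome-wide summed level falling in each zone's
windows; a feature "matches" when its largest fraction sits in its own
designated zone. On synthetic genomes with a 4-fold in-zone mean elevation
all 31 default features match and ≥ 90% of planted window labels are
recovered.

## Hotspots, rate test and enrichment

A feature's hotspots are its top-q fraction of kept windows **by rank**:
exactly ceil(q·n) members, boundary ties broken by genomic order, so the
set size is deterministic and the reported threshold (minimum member
level) is a data realisation, not an input. q defaults to 0.05 (top-5%).
Double/triple hotspots are windows hot in ≥ 2 / all 3 marker features;
Venn segments are decomposed per zone by exact membership enumeration.

Gene content of a window set uses the any-overlap rule (≥ 1 bp of the gene
inside ≥ 1 selected window), each gene counted once.

The recombination comparison is **Welch's** unequal-variance two-tailed
t-test with Welch–Satterthwaite df, accepting either raw level vectors or
printed (mean, sd, n) summaries. The pooled-variance form is grossly
inconsistent with published summary-statistics examples given their very
unequal group sizes and variances, which is why the unequal-variance form
is the only one offered.

Over-representation uses the one-sided upper-tail hypergeometric p per
gene set, Bonferroni (min(1, m·p)), Benjamini–Hochberg step-up, and an FDR
q reported as the BH value (tools in this space often print BH and an
empirically resampled FDR as separate columns; here they coincide by
construction and the documentation says so). A set is significant only
when all three corrected values are < 0.05; output is ordered by ascending
Bonferroni p. Set members outside the universe are intersected away;
query genes outside the universe are an error.

## Synthetic-data generator

The generator emulates the statistical structure the pipeline is designed
to detect, not real genome sequence (no base composition, repeat sequence
content or LD structure):

* **Zones** — whole-window segments (default 5 windows per segment) whose
  per-zone totals follow the configured mix (default 45/31/24
  Genic/Proximal/Distal) via largest-remainder rounding, shuffled
  deterministically. Gap windows (default 2%) receive a mid-window gap
  interval and no elements.
* **Levels** — element counts per window are Poisson with rate
  λ_wf = μ_f · fold_f(zone_w) · max(1 + c·Z_wf, 0.02), Z a latent
  standard-normal matrix carrying the planted pairwise correlations via
  the Cholesky factor of the implied correlation matrix (non-PSD plans are
  rejected). The clipped **linear** link keeps the rates' Pearson
  correlation equal to the planted value — a log-normal link would
  attenuate and distort negative correlations — so the realised count
  correlation is the target shrunk only by the Poisson factor
  1/(1 + 1/(c²μ)) ≈ 0.98 at the default μ = 200, c = 0.5. Features whose
  extreme-value behaviour matters more than their correlation (hotspot
  markers) can set a smaller per-feature latent CV (0.2 in the recovery
  configurations) so that a 10-fold planted elevation strictly dominates
  the basal maximum.
* **Intervals** — lengths log-normal (points of length 1 for count
  tracks), scores gamma, positions uniform *within* the window, so no
  element crosses a window boundary, leaves its chromosome or touches a
  gap.
* **Hotspots** — planted by multiplying a window's realised element count
  by the elevation fold (extra elements drawn fresh); triple-hotspot
  windows also get their recombination scores multiplied by the
  recombination fold (default 2×). Membership sets are drawn disjointly
  (triples, then doubles, then singles), so overlapping plans cannot
  double-plant.
* **Determinism** — every stage draws from `default_rng([seed, stage])`;
  identical configs give byte-identical emitted files.

Passing tests on these genomes demonstrate correct recovery of planted
correlation, zonal and hotspot structure under Poisson noise; they do not
demonstrate robustness to features real tracks may add (spatial
autocorrelation between neighbouring windows, heavy-tailed scores,
chromosome-scale trends).

Default study sizes: 1,000 windows of 500 kb for zone/hotspot recovery and
5,000 windows for correlation recovery — large enough that estimator noise
(se(r) ≈ 0.014 at n = 5,000) is well inside the ±0.05 recovery band. The
demo configuration plants 5% triple hotspots plus additional double/single
hotspots, intentionally exceeding top-5% capacity the way real overlapping
hotspot classes would; the exact-recovery configurations plant triples
only.

## Numerical and design notes

* Sample median of an even-length set is the mean of the two central order
  statistics; sd uses the n−1 denominator.
* The normality-deviation scalar for interval-length distributions is the
  Jarque–Bera statistic n·(S²/6 + K²/24) (0 for a perfect normal sample,
  asymptotically χ²₂), computed via `scipy.stats.jarque_bera`.
* TSV outputs print floats at 6 significant digits and round-trip
  bit-identically at that precision; the run manifest records a config
  hash (excluding the output directory) and per-file SHA-256 checksums.
* Interval overlap arithmetic uses closed-form index arithmetic on the
  uniform window grid (numpy sweeps / searchsorted) rather than a general
  interval-tree library; the per-base brute-force scans in the test suite
  are the independent checks of that arithmetic.
* p-value census bins are ``P > c0``, ``c_i < P ≤ c_{i-1}``, ``P ≤ c_k``
  for cutoffs c0 > … > ck, a partition of all pairs.

## Known limitations

* No correction for spatial autocorrelation between neighbouring windows;
  asymptotic p-values treat windows as independent observations.
* Hard zone labels only; no probabilistic membership.
* Exact Spearman small-n null distributions are not implemented.
* The enrichment stage is a generic over-representation test over
  user-supplied gene sets; it does not bundle any annotation database or
  reproduce annotation-clustering heuristics of web tools.
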