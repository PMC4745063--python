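"""Synthetic genomes with planted zonal structure, correlations and hotspots.

The generator emits the exact artifacts the readers consume — a chromosome
layout, a gap BED, BED3/BED5 feature tracks, a named gene BED and gene-set
TSV — together with a ground-truth record, so every pipeline stage can be
validated against planted truth.

Generative model
----------------
Windows are tiled over the configured chromosomes and laid out as contiguous
zone segments (whole-window multiples) whose per-zone totals follow the
configured mix via largest-remainder rounding, then shuffled.  For each
feature, the expected element count per window is

    λ_wf = μ_f · fold_f(zone_w) · max(1 + c·Z_wf, 0.02)

where Z is a latent standard-normal matrix with the planted pairwise
correlations (Gaussian copula over features, Cholesky factor of the implied
correlation matrix), and c is a latent coefficient of variation.  Element
counts are Poisson(λ); the clipped *linear* link keeps the Pearson
correlation of the rates equal to the planted value, attenuated only by the
Poisson noise factor 1/(1 + 1/(c²μ)).  Interval lengths are log-normal,
scores gamma, and positions uniform within their window, so no interval
crosses a window boundary, leaves its chromosome, or touches a gap (gap
windows receive no elements).

Hotspots are planted afterwards by multiplying a window's element count by
an elevation fold; triple-hotspot windows additionally get their
recombination scores elevated.
"""

from __future__ import annotations

import json
from collections import namedtuple
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .tracks import FeatureTrack, GapTrack, GenomeLayout
from .zones import DISTAL_FEATURES, GENIC_FEATURES, PROXIMAL_FEATURES

__all__ = [
    "FeatureSpec",
    "HotspotPlan",
    "SimConfig",
    "SimTruth",
    "SimData",
    "simulate_genome",
    "simulate_tracks",
    "plant_hotspots",
    "simulate_genes",
    "simulate_gene_sets",
    "simulate_dataset",
    "write_dataset",
    "default_features",
    "default_config",
]

DEFAULT_ZONE_FRACTIONS = (("Genic", 0.45), ("Proximal", 0.31), ("Distal", 0.24))


@dataclass(frozen=True)
class FeatureSpec:
    """One synthetic feature track.

    ``mean_per_window`` is the basal expected element count per window;
    ``zone_folds`` multiplies it inside the named zones (fold ≥ 1 plants the
    zone-dependent means the classifier must recover).  ``length_*`` set the
    log-normal interval-length distribution (bp); ``score_*`` the gamma score
    distribution used by intensity-mode tracks.
    """

    name: str
    mode: str = "count"
    mean_per_window: float = 100.0
    zone_folds: tuple[tuple[str, float], ...] = ()
    length_mean_bp: float = 300.0
    length_sigma: float = 0.6
    score_shape: float = 2.0
    score_scale: float = 1.0
    latent_cv: float | None = None  # None -> SimConfig.latent_cv

    def fold(self, zone: str) -> float:
        return dict(self.zone_folds).get(zone, 1.0)


@dataclass(frozen=True)
class HotspotPlan:
    """Joint SNP/CNV hotspot plan over three marker features.

    ``n_triple`` windows are elevated ``fold``-fold in all three features,
    ``n_double`` in a rotating pair, ``n_single`` (per feature) in one;
    triple windows additionally get ``recomb_fold``-elevated scores on the
    recombination track.
    """

    features: tuple[str, str, str] = ("SNPdb", "SNP1K", "CNVG")
    n_single: int = 5
    n_double: int = 6
    n_triple: int = 50
    fold: float = 10.0
    recomb_feature: str | None = "RecH"
    recomb_fold: float = 2.0


@dataclass(frozen=True)
class SimConfig:
    """Full description of one synthetic study."""

    seed: int
    chromosome_lengths: tuple[int, ...] = (250_000_000, 250_000_000)
    W: int = 500_000
    zone_fractions: tuple[tuple[str, float], ...] = DEFAULT_ZONE_FRACTIONS
    segment_windows: int = 5
    n_gap_windows: int = 0
    features: tuple[FeatureSpec, ...] = ()
    correlations: tuple[tuple[str, str, float], ...] = ()
    hotspots: HotspotPlan | None = None
    latent_cv: float = 0.5
    n_genes: int = 0
    gene_length_bp: int = 30_000

    def __post_init__(self) -> None:
        total = sum(f for _, f in self.zone_fractions)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"zone fractions must sum to 1, got {total}")
        if self.segment_windows < 1:
            raise ValueError("segment_windows must be >= 1")
        for a, b, r in self.correlations:
            if not abs(r) < 1:
                raise ValueError(f"planted |r| must be < 1 for pair ({a}, {b})")


class SimTruth:
    """Planted ground truth: per-window zones, hotspot windows, correlations.

    ``zone`` labels every grid window; ``kept`` flags non-gap windows;
    hotspot ids index rows of the kept-window matrix.
    """

    def __init__(
        self,
        windows: pd.DataFrame,
        zone: np.ndarray,
        kept: np.ndarray,
        correlations: tuple[tuple[str, str, float], ...] = (),
    ) -> None:
        self.windows = windows.reset_index(drop=True)
        self.zone = np.asarray(zone)
        self.kept = np.asarray(kept, dtype=bool)
        self.correlations = tuple(correlations)
        self.hotspots: dict[str, set[int]] = {}
        self.triple_hotspots: set[int] = set()

    @property
    def kept_zone(self) -> np.ndarray:
        """Zone labels restricted to kept windows (matrix row order)."""
        return self.zone[self.kept]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "zone": self.zone.tolist(),
            "kept": self.kept.astype(int).tolist(),
            "correlations": [list(c) for c in self.correlations],
            "hotspots": {k: sorted(v) for k, v in self.hotspots.items()},
            "triple_hotspots": sorted(self.triple_hotspots),
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1)


def _window_table(cfg: SimConfig) -> tuple[GenomeLayout, pd.DataFrame]:
    layout = GenomeLayout(
        tuple((f"chrS{i + 1}", int(L)) for i, L in enumerate(cfg.chromosome_lengths))
    )
    frames = []
    for chrom, L in layout.chromosomes:
        n = L // cfg.W
        idx = np.arange(n, dtype=np.int64)
        frames.append(
            pd.DataFrame({"chrom": chrom, "start": idx * cfg.W, "end": (idx + 1) * cfg.W})
        )
    return layout, pd.concat(frames, ignore_index=True)


def _largest_remainder(fractions: Sequence[float], total: int) -> list[int]:
    raw = [f * total for f in fractions]
    counts = [int(np.floor(x)) for x in raw]
    short = total - sum(counts)
    order = np.argsort([-(x - np.floor(x)) for x in raw], kind="stable")
    for i in range(short):
        counts[order[i]] += 1
    return counts


def simulate_genome(cfg: SimConfig) -> tuple[GenomeLayout, GapTrack, SimTruth]:
    """Lay down chromosomes, zone segments and gap windows; deterministic per seed."""
    rng = np.random.default_rng([cfg.seed, 0])
    layout, windows = _window_table(cfg)
    N = len(windows)
    if N == 0:
        raise ValueError("no full windows; chromosomes shorter than W")
    zone_names = [z for z, _ in cfg.zone_fractions]
    counts = _largest_remainder([f for _, f in cfg.zone_fractions], N)
    segments: list[tuple[str, int]] = []
    for zone, c in zip(zone_names, counts):
        while c > 0:
            take = min(cfg.segment_windows, c)
            segments.append((zone, take))
            c -= take
    rng.shuffle(segments)
    zone = np.empty(N, dtype=object)
    pos = 0
    for z, length in segments:
        zone[pos : pos + length] = z
        pos += length
    kept = np.ones(N, dtype=bool)
    gap_rows: list[tuple[str, int, int]] = []
    if cfg.n_gap_windows > 0:
        if cfg.n_gap_windows >= N:
            raise ValueError("n_gap_windows must leave at least one kept window")
        gap_ids = rng.choice(N, size=cfg.n_gap_windows, replace=False)
        for g in sorted(int(i) for i in gap_ids):
            kept[g] = False
            row = windows.iloc[g]
            gap_rows.append((row["chrom"], int(row["start"] + cfg.W // 4), int(row["start"] + 3 * cfg.W // 4)))
    gaps = (
        GapTrack(pd.DataFrame(gap_rows, columns=["chrom", "start", "end"]), layout=layout)
        if gap_rows
        else GapTrack.empty()
    )
    truth = SimTruth(windows, zone, kept, cfg.correlations)
    return layout, gaps, truth


def _latent_matrix(cfg: SimConfig, truth: SimTruth, rng: np.random.Generator) -> np.ndarray:
    names = [f.name for f in cfg.features]
    idx = {n: i for i, n in enumerate(names)}
    F = len(names)
    sigma = np.eye(F)
    for a, b, r in cfg.correlations:
        if a not in idx or b not in idx:
            raise ValueError(f"planted correlation names unknown feature: ({a}, {b})")
        sigma[idx[a], idx[b]] = sigma[idx[b], idx[a]] = r
    eigmin = float(np.linalg.eigvalsh(sigma).min())
    if eigmin < -1e-9:
        raise ValueError(
            f"infeasible correlation plan: implied latent covariance not PSD (min eig {eigmin:.3g})"
        )
    L = np.linalg.cholesky(sigma + 1e-12 * np.eye(F))
    N = len(truth.zone)
    return rng.standard_normal((N, F)) @ L.T


def simulate_tracks(cfg: SimConfig, truth: SimTruth) -> list[FeatureTrack]:
    """Realize every configured feature as a BED-style interval track."""
    if not cfg.features:
        raise ValueError("no features configured")
    rng = np.random.default_rng([cfg.seed, 1])
    Z = _latent_matrix(cfg, truth, rng)
    W = cfg.W
    windows = truth.windows
    wstart = windows["start"].to_numpy()
    wchrom = windows["chrom"].to_numpy()
    tracks: list[FeatureTrack] = []
    for j, spec in enumerate(cfg.features):
        folds = np.array([spec.fold(z) for z in truth.zone], dtype=float)
        cv = cfg.latent_cv if spec.latent_cv is None else spec.latent_cv
        lam = spec.mean_per_window * folds * np.clip(1.0 + cv * Z[:, j], 0.02, None)
        lam[~truth.kept] = 0.0
        counts = rng.poisson(lam)
        widx = np.repeat(np.arange(len(counts)), counts)
        K = len(widx)
        if spec.mode == "count":
            lengths = np.ones(K, dtype=np.int64)
        else:
            mu_log = np.log(max(spec.length_mean_bp, 1.0)) - spec.length_sigma**2 / 2
            lengths = np.clip(
                np.round(rng.lognormal(mu_log, spec.length_sigma, size=K)), 1, W - 1
            ).astype(np.int64)
        offsets = rng.integers(0, W - lengths + 1, size=K) if K else np.zeros(0, dtype=np.int64)
        starts = wstart[widx] + offsets
        df = pd.DataFrame(
            {"chrom": wchrom[widx], "start": starts, "end": starts + lengths}
        )
        if spec.mode == "intensity":
            df["score"] = rng.gamma(spec.score_shape, spec.score_scale, size=K)
        tracks.append(FeatureTrack(spec.name, spec.mode, df))
    return tracks


def _kept_row_of(truth: SimTruth) -> np.ndarray:
    """Map grid window index → kept-window (matrix) row, -1 for gap windows."""
    row = np.full(len(truth.kept), -1, dtype=np.int64)
    row[truth.kept] = np.arange(int(truth.kept.sum()))
    return row


def plant_hotspots(
    cfg: SimConfig, tracks: Sequence[FeatureTrack], truth: SimTruth
) -> tuple[list[FeatureTrack], SimTruth]:
    """Elevate planted windows' element counts; record truth memberships.

    Windows are drawn from kept windows without replacement: first the
    triple set, then doubles over rotating pairs, then singles per feature,
    so overlapping plans cannot double-plant a window.  Hotspot ids in the
    returned truth are kept-window row positions (fold 1 leaves tracks
    unchanged but still records memberships).
    """
    plan = cfg.hotspots
    if plan is None:
        return list(tracks), truth
    rng = np.random.default_rng([cfg.seed, 2])
    kept_ids = np.flatnonzero(truth.kept)
    needed = plan.n_triple + plan.n_double + 3 * plan.n_single
    if needed > len(kept_ids):
        raise ValueError(f"hotspot plan needs {needed} windows, only {len(kept_ids)} kept")
    picked = rng.choice(kept_ids, size=needed, replace=False)
    pos = 0
    triple = set(int(i) for i in picked[: plan.n_triple])
    pos += plan.n_triple
    feats = plan.features
    pair_cycle = [(feats[0], feats[1]), (feats[0], feats[2]), (feats[1], feats[2])]
    membership: dict[str, set[int]] = {f: set(triple) for f in feats}
    for k in range(plan.n_double):
        w = int(picked[pos + k])
        a, b = pair_cycle[k % 3]
        membership[a].add(w)
        membership[b].add(w)
    pos += plan.n_double
    for f in feats:
        for k in range(plan.n_single):
            membership[f].add(int(picked[pos + k]))
        pos += plan.n_single

    W = cfg.W
    windows = truth.windows
    chrom_off: dict[str, int] = {}
    acc = 0
    for chrom, sub in windows.groupby("chrom", sort=False):
        chrom_off[chrom] = acc
        acc += len(sub)

    def grid_index(df: pd.DataFrame) -> np.ndarray:
        base = df["chrom"].map(chrom_off).to_numpy()
        return base + (df["start"].to_numpy() // W)

    out_tracks: list[FeatureTrack] = []
    for track in tracks:
        name = track.feature_name
        if name in membership and plan.fold != 1.0:
            df = track.intervals
            gidx = grid_index(df)
            sel_windows = np.array(sorted(membership[name]))
            hot = np.isin(gidx, sel_windows)
            extra_frames = [df]
            sub = df[hot]
            sub_idx = gidx[hot]
            # per hot window, add round(count·(fold−1)) fresh elements
            for w in sel_windows:
                cur = sub[sub_idx == w]
                extra_n = int(round(len(cur) * (plan.fold - 1.0)))
                if extra_n <= 0:
                    continue
                row = windows.iloc[int(w)]
                if track.mode == "count":
                    lengths = np.ones(extra_n, dtype=np.int64)
                else:
                    lengths = (cur["end"] - cur["start"]).to_numpy()
                    lengths = lengths[rng.integers(0, len(lengths), size=extra_n)]
                starts = row["start"] + rng.integers(0, W - lengths + 1, size=extra_n)
                new = pd.DataFrame(
                    {"chrom": row["chrom"], "start": starts, "end": starts + lengths}
                )
                if "score" in df.columns:
                    new["score"] = rng.gamma(2.0, 1.0, size=extra_n)
                extra_frames.append(new)
            merged = pd.concat(extra_frames, ignore_index=True)
            out_tracks.append(FeatureTrack(name, track.mode, merged))
        elif name == plan.recomb_feature and plan.recomb_fold != 1.0 and triple:
            df = track.intervals.copy()
            gidx = grid_index(df)
            hot = np.isin(gidx, np.array(sorted(triple)))
            if "score" not in df.columns:
                raise ValueError(f"recombination track {name!r} has no scores to elevate")
            df.loc[hot, "score"] = df.loc[hot, "score"] * plan.recomb_fold
            out_tracks.append(FeatureTrack(name, track.mode, df))
        else:
            out_tracks.append(track)

    row_of = _kept_row_of(truth)
    truth.hotspots = {f: {int(row_of[w]) for w in s} for f, s in membership.items()}
    truth.triple_hotspots = {int(row_of[w]) for w in triple}
    return out_tracks, truth


def simulate_genes(cfg: SimConfig, truth: SimTruth) -> FeatureTrack:
    """Named gene intervals placed uniformly along the chromosomes."""
    rng = np.random.default_rng([cfg.seed, 3])
    rows = []
    lengths_cum = np.cumsum([L for L in cfg.chromosome_lengths])
    total = int(lengths_cum[-1])
    for i in range(cfg.n_genes):
        pos = int(rng.integers(0, total - cfg.gene_length_bp))
        c = int(np.searchsorted(lengths_cum, pos, side="right"))
        off = pos - (0 if c == 0 else int(lengths_cum[c - 1]))
        L = cfg.chromosome_lengths[c]
        off = min(off, L - cfg.gene_length_bp - 1)
        rows.append((f"chrS{c + 1}", off, off + cfg.gene_length_bp, f"GENE{i + 1:05d}"))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])
    return FeatureTrack("genes", "density", df)


def simulate_gene_sets(
    cfg: SimConfig,
    genes: FeatureTrack,
    truth: SimTruth,
    n_enriched: int = 3,
    n_null: int = 10,
    set_size: int = 30,
    enrichment: float = 0.7,
) -> dict[str, list[str]]:
    """Gene sets for the enrichment stage: some loaded with triple-hotspot genes.

    Enriched sets draw a fraction ``enrichment`` of their members from genes
    overlapping planted triple-hotspot windows; null sets are uniform draws.
    """
    from .hotspots import genes_in_windows

    rng = np.random.default_rng([cfg.seed, 4])
    universe = list(genes.intervals["name"])
    kept_windows = truth.windows[truth.kept].reset_index(drop=True)
    hot_windows = kept_windows.iloc[sorted(truth.triple_hotspots)]
    hot_genes = genes_in_windows(genes, hot_windows) if len(hot_windows) else []
    sets: dict[str, list[str]] = {}
    for i in range(n_enriched):
        n_hot = min(int(round(set_size * enrichment)), len(hot_genes))
        members = list(rng.choice(hot_genes, size=n_hot, replace=False)) if n_hot else []
        rest = [g for g in universe if g not in set(members)]
        members += list(rng.choice(rest, size=set_size - len(members), replace=False))
        sets[f"enriched_set_{i + 1}"] = sorted(members)
    for i in range(n_null):
        sets[f"null_set_{i + 1}"] = sorted(rng.choice(universe, size=set_size, replace=False))
    return sets


SimData = namedtuple(
    "SimData", ["config", "layout", "gaps", "truth", "tracks", "genes", "gene_sets"]
)


def simulate_dataset(cfg: SimConfig) -> SimData:
    """Run the full generator: genome → tracks → hotspots → genes → gene sets."""
    layout, gaps, truth = simulate_genome(cfg)
    tracks = simulate_tracks(cfg, truth)
    tracks, truth = plant_hotspots(cfg, tracks, truth)
    genes = simulate_genes(cfg, truth) if cfg.n_genes > 0 else None
    gene_sets = (
        simulate_gene_sets(cfg, genes, truth) if genes is not None and truth.triple_hotspots else None
    )
    return SimData(cfg, layout, gaps, truth, tracks, genes, gene_sets)


def write_dataset(data: SimData, outdir: str | Path) -> dict[str, Path]:
    """Emit chrom.sizes, gap BED, track BEDs + manifest, genes, gene sets, truth JSON."""
    outdir = Path(outdir)
    (outdir / "tracks").mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    layout_path = outdir / "genome.chrom.sizes"
    data.layout.to_file(layout_path)
    paths["layout"] = layout_path
    gaps_path = outdir / "gaps.bed"
    data.gaps.intervals.to_csv(gaps_path, sep="\t", header=False, index=False)
    paths["gaps"] = gaps_path
    manifest_rows = []
    for t in data.tracks:
        p = outdir / "tracks" / f"{t.feature_name.replace('+', 'p').replace('-', 'm')}.bed"
        t.to_bed(p)
        manifest_rows.append((t.feature_name, str(p), t.mode))
    manifest = outdir / "tracks_manifest.tsv"
    pd.DataFrame(manifest_rows, columns=["name", "path", "mode"]).to_csv(
        manifest, sep="\t", index=False
    )
    paths["manifest"] = manifest
    if data.genes is not None:
        genes_path = outdir / "genes.bed"
        data.genes.intervals[["chrom", "start", "end", "name"]].to_csv(
            genes_path, sep="\t", header=False, index=False
        )
        paths["genes"] = genes_path
    if data.gene_sets is not None:
        gs_path = outdir / "gene_sets.tsv"
        with open(gs_path, "w", encoding="utf-8") as fh:
            for name, members in data.gene_sets.items():
                fh.write(f"{name}\t{','.join(members)}\n")
        paths["gene_sets"] = gs_path
    truth_path = outdir / "truth.json"
    data.truth.to_json(truth_path)
    paths["truth"] = truth_path
    return paths


def default_features(
    zone_fold: float = 4.0,
    zone_mean: float = 20.0,
    marker_mean: float = 200.0,
) -> tuple[FeatureSpec, ...]:
    """The standard roster: 31 zone features plus SNP/CNV/recombination markers.

    Each zone feature has a ``zone_fold``-elevated mean in its home zone;
    markers (SNPdb, SNP1K, CNVG counts; RecH intensity) have flat means.
    """
    specs: list[FeatureSpec] = []
    for name in GENIC_FEATURES:
        specs.append(FeatureSpec(name, "count", zone_mean, (("Genic", zone_fold),)))
    for name in PROXIMAL_FEATURES:
        specs.append(FeatureSpec(name, "count", zone_mean, (("Proximal", zone_fold),)))
    for name in DISTAL_FEATURES:
        specs.append(FeatureSpec(name, "count", zone_mean, (("Distal", zone_fold),)))
    specs.append(FeatureSpec("SNPdb", "count", marker_mean))
    specs.append(FeatureSpec("SNP1K", "count", marker_mean))
    specs.append(FeatureSpec("CNVG", "count", marker_mean / 2))
    specs.append(
        FeatureSpec("RecH", "intensity", 50.0, length_mean_bp=2_000.0, score_shape=2.0, score_scale=0.5)
    )
    return tuple(specs)


def default_config(seed: int, n_windows: int = 1_000, W: int = 500_000) -> SimConfig:
    """A ready-to-run study: two chromosomes, the default roster, planted
    SNP-SNP/SNP-CNV correlations, 2% gap windows and a 50-window triple-hotspot
    plan with 2x recombination elevation."""
    per_chrom = (n_windows + 1) // 2
    lengths = (per_chrom * W + W // 3, (n_windows - per_chrom) * W + W // 3)
    # hotspot plan scales with genome size: ~5% of windows are triple hotspots
    plan = HotspotPlan(
        n_single=max(1, n_windows // 200),
        n_double=max(1, n_windows // 160),
        n_triple=max(2, n_windows // 20),
    )
    return SimConfig(
        seed=seed,
        chromosome_lengths=lengths,
        W=W,
        n_gap_windows=max(2, n_windows // 50),
        features=default_features(),
        correlations=(("SNPdb", "SNP1K", 0.7), ("SNPdb", "CNVG", 0.3)),
        hotspots=plan,
        n_genes=2_000,
    )
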