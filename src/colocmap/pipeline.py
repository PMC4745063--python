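"""End-to-end orchestration: windows → quantitation → co-localization →
zones → hotspots → enrichment, over one or more window sizes, with a run
manifest for deterministic re-runs."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from itertools import combinations
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .coloc import build_coloc_matrix, concordance
from .hotspots import call_hotspots, genes_in_windows, ora_enrichment, overlap_hotspots, rate_test
from .quantify import build_matrix
from .tracks import read_chrom_sizes, read_feature_track, read_gap_track, write_table
from .windows import filter_gap_windows, make_windows
from .zones import ZoneModel, classify_windows, default_zone_model, zone_proportions, zonal_feature_fractions

logger = logging.getLogger("colocmap")

__all__ = ["RunConfig", "run_full_analysis", "read_gene_sets"]


@dataclass
class RunConfig:
    """Declarative description of one full analysis run."""

    layout: str
    gaps: str | None
    tracks_manifest: str
    outdir: str
    genes: str | None = None
    gene_sets: str | None = None
    window_sizes: tuple[int, ...] = (500_000,)
    hotspot_q: float = 0.05
    method: str = "both"
    hotspot_features: tuple[str, ...] = ("SNPdb", "SNP1K", "CNVG")
    recomb_feature: str | None = "RecH"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        for key in ("window_sizes", "hotspot_features"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def validate_paths(self) -> None:
        for label in ("layout", "gaps", "tracks_manifest", "genes", "gene_sets"):
            p = getattr(self, label)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{label} path does not exist: {p}")


def read_gene_sets(path: str | Path) -> dict[str, list[str]]:
    """Parse a gene-set TSV: set_name<TAB>gene1,gene2,..."""
    sets: dict[str, list[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected set_name<TAB>gene,gene,...")
            sets[parts[0]] = [g for g in parts[1].split(",") if g]
    return sets


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_full_analysis(cfg: RunConfig) -> Path:
    """Run every stage for every window size and write all artifacts.

    Per window size W: window grid BED, level-matrix TSV, co-localization
    long TSV, zone assignment BED + proportions TSV, hotspot BEDs + Venn
    TSV, recombination rate-test TSV, enrichment TSV (when genes and gene
    sets are configured).  Across sizes: R_C per size and R_W per size pair.
    A manifest JSON records the config hash, seed and per-file checksums.
    Outputs are pure functions of (inputs, config): re-running with the same
    config reproduces them bit-identically.
    """
    cfg.validate_paths()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    layout = read_chrom_sizes(cfg.layout)
    gaps = read_gap_track(cfg.gaps, layout=layout) if cfg.gaps else None
    manifest = pd.read_csv(cfg.tracks_manifest, sep="\t")
    tracks = [
        read_feature_track(row["path"], row["name"], row["mode"], layout=layout)
        for _, row in manifest.iterrows()
    ]
    logger.info("loaded %d tracks over %d chromosomes", len(tracks), len(layout))
    genes = (
        read_feature_track(cfg.genes, "genes", "density", layout=layout) if cfg.genes else None
    )
    gene_sets = read_gene_sets(cfg.gene_sets) if cfg.gene_sets else None
    model = default_zone_model()
    available = {t.feature_name for t in tracks}
    model_feats = [f for f in model.features if f in available]
    use_zone_model = len(model_feats) == len(model.features)

    pearson_vectors: dict[int, np.ndarray] = {}
    outputs: list[Path] = []
    concord_rows: list[tuple[str, str, float]] = []
    for W in cfg.window_sizes:
        tag = f"W{W}"
        grid = make_windows(layout, W)
        if gaps is not None:
            grid = filter_gap_windows(grid, gaps)
        logger.info("%s: %d windows, %d kept", tag, grid.n_windows, grid.n_kept)
        grid_path = outdir / f"{tag}.windows.bed"
        grid.to_bed(grid_path)
        outputs.append(grid_path)
        matrix = build_matrix(grid, tracks)
        mat_path = outdir / f"{tag}.levels.tsv"
        matrix.to_tsv(mat_path)
        outputs.append(mat_path)
        cm = build_coloc_matrix(matrix, method=cfg.method)
        coloc_path = outdir / f"{tag}.coloc.tsv"
        cm.to_tsv(coloc_path)
        outputs.append(coloc_path)
        pearson_vectors[W] = cm.coefficient_vector("r")
        rc = concordance(cm.coefficient_vector("rho"), cm.coefficient_vector("r"), "R_C")
        concord_rows.append((f"R_C_{tag}", tag, rc.value))

        assign = None
        if use_zone_model:
            assign = classify_windows(matrix, model)
            zb = outdir / f"{tag}.zones.bed"
            assign.to_bed(zb)
            outputs.append(zb)
            props = zone_proportions(assign)
            zp = outdir / f"{tag}.zone_proportions.tsv"
            write_table(
                [(z, props.counts[z], props.fractions[z]) for z in assign.model.zone_names],
                zp,
                header=["zone", "count", "fraction"],
            )
            outputs.append(zp)
            fr = zonal_feature_fractions(matrix, assign)
            fp = outdir / f"{tag}.zonal_fractions.tsv"
            write_table(fr.reset_index(names="feature"), fp)
            outputs.append(fp)

        hot_feats = [f for f in cfg.hotspot_features if f in available]
        if len(hot_feats) >= 2:
            sets = [call_hotspots(matrix, f, q=cfg.hotspot_q) for f in hot_feats]
            kept = matrix.windows
            for s in sets:
                hb = outdir / f"{tag}.hotspots.{s.feature_name}.bed"
                rows = kept.iloc[sorted(s.window_ids)][["chrom", "start", "end"]].copy()
                rows["feature"] = s.feature_name
                rows.to_csv(hb, sep="\t", header=False, index=False)
                outputs.append(hb)
            ov = overlap_hotspots(sets, assign)
            if ov.venn is not None:
                vp = outdir / f"{tag}.hotspot_venn.tsv"
                write_table(ov.venn.reset_index(names="zone"), vp)
                outputs.append(vp)
            if cfg.recomb_feature in available and len(ov.triple) >= 2:
                rec = matrix[cfg.recomb_feature]
                triple_ids = sorted(ov.triple)
                rt = rate_test(rec, rec[triple_ids])
                rp = outdir / f"{tag}.rate_test.tsv"
                write_table(
                    [
                        (
                            cfg.recomb_feature, len(triple_ids), rt.mean_group, rt.sd_group,
                            rt.mean_background, rt.sd_background, rt.t, rt.df, rt.p,
                        )
                    ],
                    rp,
                    header=[
                        "feature", "n_triple", "mean_triple", "sd_triple",
                        "mean_all", "sd_all", "t", "df", "p",
                    ],
                )
                outputs.append(rp)
                if genes is not None and gene_sets:
                    hot_windows = kept.iloc[triple_ids]
                    gene_list = genes_in_windows(genes, hot_windows)
                    universe = sorted(set(genes.intervals["name"]))
                    if gene_list:
                        enr = ora_enrichment(gene_list, universe, gene_sets)
                        ep = outdir / f"{tag}.enrichment.tsv"
                        write_table(enr, ep)
                        outputs.append(ep)

    for a, b in combinations(cfg.window_sizes, 2):
        rw = concordance(pearson_vectors[a], pearson_vectors[b], "R_W")
        concord_rows.append((f"R_W_W{a}_W{b}", f"W{a}|W{b}", rw.value))
    cp = outdir / "concordance.tsv"
    write_table(concord_rows, cp, header=["label", "windows", "value"])
    outputs.append(cp)

    cfg_dict = asdict(cfg)
    cfg_dict.pop("outdir")  # the hash describes the analysis, not its destination
    cfg_text = yaml.safe_dump(cfg_dict, sort_keys=True)
    run_manifest = {
        "config_sha256": hashlib.sha256(cfg_text.encode()).hexdigest(),
        "seed": cfg.seed,
        "files": {p.name: _sha256(p) for p in sorted(outputs)},
    }
    with open(outdir / "run_manifest.json", "w", encoding="utf-8") as fh:
        json.dump(run_manifest, fh, indent=1, sort_keys=True)
    return outdir
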