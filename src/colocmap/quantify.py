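"""Per-window feature quantitation and the windows × features level matrix.

Three quantitation modes:

* ``density`` — fraction of window bases covered by at least one interval
  (overlapping intervals merged first, so density ∈ [0, 1]);
* ``intensity`` — Σ over intervals of (bases of the interval inside the
  window × interval score) / W, without merging (each scored element
  contributes);
* ``count`` — number of elements whose start coordinate lies in the window,
  so point-like elements (SNP sites, CNV breakpoints) are never
  double-counted across a window boundary.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .tracks import FeatureTrack, write_table
from .windows import WindowGrid

__all__ = ["FeatureWindowMatrix", "quantitate_window", "quantitate_track", "build_matrix"]


def _merge_intervals(starts: np.ndarray, ends: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Merge sorted, possibly overlapping intervals into disjoint ones."""
    if len(starts) == 0:
        return starts, ends
    order = np.argsort(starts, kind="mergesort")
    s, e = starts[order], ends[order]
    run_end = np.maximum.accumulate(e)
    new_run = np.empty(len(s), dtype=bool)
    new_run[0] = True
    new_run[1:] = s[1:] > run_end[:-1]
    idx = np.flatnonzero(new_run)
    ms = s[idx]
    me = np.empty(len(idx), dtype=e.dtype)
    me[:-1] = run_end[idx[1:] - 1]
    me[-1] = run_end[-1]
    return ms, me


def _spread_weighted(starts, ends, weights, W: int, n_windows: int) -> np.ndarray:
    """Distribute per-interval weight-per-bp across the windows each interval spans."""
    out = np.zeros(n_windows, dtype=float)
    if len(starts) == 0:
        return out
    starts = np.clip(starts, 0, n_windows * W)
    ends = np.clip(ends, 0, n_windows * W)
    valid = ends > starts
    starts, ends, weights = starts[valid], ends[valid], np.asarray(weights, dtype=float)[valid]
    i0 = starts // W
    i1 = (ends - 1) // W
    single = i0 == i1
    np.add.at(out, i0[single], (ends[single] - starts[single]) * weights[single])
    for s, e, w, a, b in zip(
        starts[~single], ends[~single], weights[~single], i0[~single], i1[~single]
    ):
        out[a] += ((a + 1) * W - s) * w
        out[b] += (e - b * W) * w
        if b > a + 1:
            out[a + 1 : b] += W * w
    return out


def _chrom_levels(track: FeatureTrack, chrom: str, W: int, n_windows: int) -> np.ndarray:
    """Full per-window level vector for one chromosome (all windows, kept or not)."""
    sub = track.intervals[track.intervals["chrom"] == chrom]
    starts = sub["start"].to_numpy()
    ends = sub["end"].to_numpy()
    if track.mode == "count":
        idx = starts // W
        inside = (idx >= 0) & (idx < n_windows)
        return np.bincount(idx[inside], minlength=n_windows).astype(float)
    if track.mode == "density":
        ms, me = _merge_intervals(starts, ends)
        cov = _spread_weighted(ms, me, np.ones(len(ms)), W, n_windows)
        return cov / W
    # intensity
    scores = sub["score"].to_numpy(dtype=float)
    if np.isnan(scores).any():
        raise ValueError(f"track {track.feature_name!r}: score required for intensity mode")
    return _spread_weighted(starts, ends, scores, W, n_windows) / W


def quantitate_window(track: FeatureTrack, window) -> float:
    """Level of one feature in one kept window.

    ``window`` is a mapping/row with ``chrom``, ``start``, ``end`` fields
    (``end - start`` = W).  See the module docstring for the three mode
    formulas.
    """
    chrom, start, end = window["chrom"], int(window["start"]), int(window["end"])
    W = end - start
    sub = track.intervals[track.intervals["chrom"] == chrom]
    starts = sub["start"].to_numpy()
    ends = sub["end"].to_numpy()
    if track.mode == "count":
        return float(np.sum((starts >= start) & (starts < end)))
    cs = np.clip(starts, start, end)
    ce = np.clip(ends, start, end)
    if track.mode == "density":
        keep = ce > cs
        ms, me = _merge_intervals(cs[keep], ce[keep])
        return float(np.sum(me - ms) / W)
    scores = sub["score"].to_numpy(dtype=float)
    if np.isnan(scores).any():
        raise ValueError(f"track {track.feature_name!r}: score required for intensity mode")
    return float(np.sum(np.maximum(ce - cs, 0) * scores) / W)


def quantitate_track(track: FeatureTrack, grid: WindowGrid) -> np.ndarray:
    """Level of ``track`` in every *kept* window of ``grid``, in grid order."""
    layout_names = set(grid.layout.names)
    for chrom in track.intervals["chrom"].unique():
        if chrom not in layout_names:
            raise ValueError(
                f"track {track.feature_name!r}: chromosome {chrom!r} absent from layout"
            )
    pieces = []
    for chrom, sub in grid.windows.groupby("chrom", sort=False):
        levels = _chrom_levels(track, chrom, grid.W, len(sub))
        pieces.append(levels[sub["kept"].to_numpy()])
    if not pieces:
        return np.zeros(0)
    return np.concatenate(pieces)


class FeatureWindowMatrix:
    """Kept-windows × features table of quantified levels.

    The central object all downstream statistics consume.  ``windows`` holds
    the kept windows' coordinates (chrom, start, end) aligned row-for-row
    with ``levels`` (one column per feature).
    """

    def __init__(self, grid: WindowGrid, windows: pd.DataFrame, levels: pd.DataFrame) -> None:
        if len(windows) != len(levels):
            raise ValueError("windows and levels row counts differ")
        vals = levels.to_numpy(dtype=float)
        if not np.isfinite(vals).all():
            raise ValueError("non-finite level encountered")
        self.grid = grid
        self.windows = windows.reset_index(drop=True)
        self.levels = levels.reset_index(drop=True)

    @property
    def feature_names(self) -> list[str]:
        return list(self.levels.columns)

    @property
    def n_windows(self) -> int:
        return len(self.levels)

    def __getitem__(self, feature: str) -> np.ndarray:
        return self.levels[feature].to_numpy()

    def to_tsv(self, path: str | Path) -> None:
        out = pd.concat([self.windows[["chrom", "start", "end"]], self.levels], axis=1)
        write_table(out, path)

    @classmethod
    def from_tsv(cls, path: str | Path, grid: WindowGrid | None = None) -> "FeatureWindowMatrix":
        df = pd.read_csv(path, sep="\t")
        windows = df[["chrom", "start", "end"]]
        levels = df.drop(columns=["chrom", "start", "end"])
        if grid is None:
            W = int((windows["end"] - windows["start"]).iloc[0]) if len(windows) else 0
            from .tracks import GenomeLayout

            chroms = tuple(
                (c, int(windows.loc[windows["chrom"] == c, "end"].max()))
                for c in windows["chrom"].unique()
            )
            layout = GenomeLayout(chroms) if chroms else GenomeLayout((("empty", 1),))
            gw = windows.copy()
            gw["index"] = gw["start"] // max(W, 1)
            gw["kept"] = True
            from .windows import WindowGrid as _WG

            grid = _WG(layout, W, gw[["chrom", "index", "start", "end", "kept"]])
        return cls(grid, windows, levels)


def build_matrix(grid: WindowGrid, tracks: Sequence[FeatureTrack]) -> FeatureWindowMatrix:
    """Quantify every track over every kept window.

    Deterministic given inputs; levels[i, j] equals
    ``quantitate_window(tracks[j], kept_window_i)``.
    """
    if grid.n_kept == 0:
        raise ValueError("grid has no kept windows")
    if not tracks:
        raise ValueError("no tracks supplied")
    names = [t.feature_name for t in tracks]
    if len(set(names)) != len(names):
        raise ValueError("duplicate feature names among tracks")
    kept = grid.kept_windows()[["chrom", "start", "end"]]
    levels = pd.DataFrame(
        {t.feature_name: quantitate_track(t, grid) for t in tracks}
    )
    return FeatureWindowMatrix(grid, kept, levels)
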