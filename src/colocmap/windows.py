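"""Fixed-size window grids over a genome layout.

Each chromosome is tiled from coordinate 0 with non-overlapping windows of
exactly ``W`` bp; the trailing partial segment (< W bp) is discarded, so a
chromosome of length L yields floor(L/W) windows.  Windows overlapping an
assembly gap are flagged ``kept=False`` and excluded from all downstream
statistics.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .tracks import GapTrack, GenomeLayout

__all__ = ["WindowGrid", "make_windows", "filter_gap_windows"]


class WindowGrid:
    """Tiling of a genome into fixed ``W``-bp windows.

    Attributes
    ----------
    W : int
        Window size in bp.
    windows : pandas.DataFrame
        One row per window: ``chrom, index, start, end, kept``, in layout
        order.  ``index`` is the ordinal within its chromosome.
    """

    def __init__(self, layout: GenomeLayout, W: int, windows: pd.DataFrame) -> None:
        self.layout = layout
        self.W = int(W)
        self.windows = windows.reset_index(drop=True)

    @property
    def n_windows(self) -> int:
        return len(self.windows)

    @property
    def n_kept(self) -> int:
        return int(self.windows["kept"].sum())

    def kept_windows(self) -> pd.DataFrame:
        """The kept windows, in genomic order, with their grid row positions as index."""
        return self.windows[self.windows["kept"]]

    def with_kept(self, kept: np.ndarray) -> "WindowGrid":
        df = self.windows.copy()
        df["kept"] = np.asarray(kept, dtype=bool)
        return WindowGrid(self.layout, self.W, df)

    def to_bed(self, path: str | Path) -> None:
        """Export as BED4: chrom, start, end, kept flag."""
        out = self.windows[["chrom", "start", "end"]].copy()
        out["kept"] = self.windows["kept"].map({True: "kept", False: "removed"})
        out.to_csv(path, sep="\t", header=False, index=False)


def make_windows(layout: GenomeLayout, W: int) -> WindowGrid:
    """Tile every chromosome into floor(L/W) full windows of W bp.

    All windows start ``kept=True``.  A 249,000,000-bp chromosome at
    W=500,000 yields 498 windows.  If no chromosome is at least W bp long the
    grid is empty and a warning is issued.
    """
    W = int(W)
    if W <= 0:
        raise ValueError(f"window size must be positive, got {W}")
    frames = []
    for chrom, length in layout.chromosomes:
        n = length // W
        if n == 0:
            continue
        idx = np.arange(n, dtype=np.int64)
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "index": idx,
                    "start": idx * W,
                    "end": (idx + 1) * W,
                    "kept": True,
                }
            )
        )
    if not frames:
        warnings.warn(
            f"window size {W} exceeds every chromosome length; grid is empty",
            stacklevel=2,
        )
        df = pd.DataFrame(
            {
                "chrom": pd.Series(dtype=str),
                "index": pd.Series(dtype=np.int64),
                "start": pd.Series(dtype=np.int64),
                "end": pd.Series(dtype=np.int64),
                "kept": pd.Series(dtype=bool),
            }
        )
        return WindowGrid(layout, W, df)
    return WindowGrid(layout, W, pd.concat(frames, ignore_index=True))


def filter_gap_windows(grid: WindowGrid, gaps: GapTrack, min_overlap: int = 1) -> WindowGrid:
    """Return a new grid with gap-overlapping windows flagged ``kept=False``.

    A window is removed when it shares at least ``min_overlap`` bp
    (default 1, the strictest any-overlap reading) with any gap interval.
    The input grid is not mutated; an empty gap track is a no-op.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    if len(gaps) == 0 or grid.n_windows == 0:
        return grid.with_kept(grid.windows["kept"].to_numpy())
    W = grid.W
    kept = grid.windows["kept"].to_numpy().copy()
    # row offset of each chromosome's first window in the grid
    offsets: dict[str, tuple[int, int]] = {}
    pos = 0
    for chrom, sub in grid.windows.groupby("chrom", sort=False):
        offsets[chrom] = (pos, len(sub))
        pos += len(sub)
    for chrom, sub in gaps.intervals.groupby("chrom", sort=False):
        if chrom not in offsets:
            continue
        off, n = offsets[chrom]
        for gs, ge in sub[["start", "end"]].itertuples(index=False):
            lo = max(0, (gs - W + min_overlap) // W)  # first window with >= min_overlap bp
            hi = min(n - 1, (ge - min_overlap) // W)  # last such window
            for i in range(int(lo), int(hi) + 1):
                if min(ge, (i + 1) * W) - max(gs, i * W) >= min_overlap:
                    kept[off + i] = False
    return grid.with_kept(kept)
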