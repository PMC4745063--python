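"""Reading and writing genomic track files, plus per-track length statistics.

All coordinates are 0-based half-open throughout the package: an interval
``[0, 100)`` has length 100 and covers bases 0..99.  Supported inputs are
chrom.sizes-style two-column TSVs, BED3/BED5/BED6 interval files, and plain
header-bearing TSV tables.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GenomeLayout",
    "FeatureTrack",
    "GapTrack",
    "LengthStats",
    "QUANTITATION_MODES",
    "read_chrom_sizes",
    "read_feature_track",
    "read_gap_track",
    "length_stats",
    "write_table",
    "read_table",
]

QUANTITATION_MODES = ("count", "density", "intensity")


@dataclass(frozen=True)
class GenomeLayout:
    """Named chromosomes with lengths — the coordinate universe.

    Parameters
    ----------
    chromosomes
        Ordered ``(name, length_bp)`` pairs.  Order is preserved and defines
        window ordering downstream.
    """

    chromosomes: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        names = [c[0] for c in self.chromosomes]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate chromosome name(s): {', '.join(dupes)}")
        for name, length in self.chromosomes:
            if int(length) <= 0:
                raise ValueError(f"non-positive length for chromosome {name!r}: {length}")
        object.__setattr__(
            self,
            "chromosomes",
            tuple((str(n), int(l)) for n, l in self.chromosomes),
        )

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(c[0] for c in self.chromosomes)

    @property
    def lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)

    def length(self, chrom: str) -> int:
        try:
            return self.lengths[chrom]
        except KeyError:
            raise KeyError(f"unknown chromosome {chrom!r}") from None

    def __len__(self) -> int:
        return len(self.chromosomes)

    def to_file(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for name, length in self.chromosomes:
                fh.write(f"{name}\t{length}\n")


def read_chrom_sizes(path: str | Path) -> GenomeLayout:
    """Parse a two-column (name, length) TSV into a :class:`GenomeLayout`.

    File order is preserved.  Malformed lines, duplicate names and
    non-positive lengths raise :class:`ValueError` naming the offending line.
    """
    chroms: list[tuple[str, int]] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 tab-separated columns, got {len(parts)}")
            name, length_s = parts
            try:
                length = int(length_s)
            except ValueError:
                raise ValueError(f"{path}:{lineno}: length {length_s!r} is not an integer") from None
            if length <= 0:
                raise ValueError(f"{path}:{lineno}: non-positive length {length} for {name!r}")
            if name in seen:
                raise ValueError(f"{path}:{lineno}: duplicate chromosome name {name!r}")
            seen.add(name)
            chroms.append((name, length))
    return GenomeLayout(tuple(chroms))


_BED_COLUMNS = ("chrom", "start", "end", "name", "score")


class FeatureTrack:
    """A named set of genomic intervals with a quantitation mode.

    Intervals are stored as a :class:`pandas.DataFrame` with columns
    ``chrom, start, end`` and optional ``score`` / ``name``, sorted by
    ``(chrom, start, end)``.  ``mode`` is one of ``count`` (point elements
    assigned to windows by start coordinate), ``density`` (merged coverage
    fraction) or ``intensity`` (score-weighted coverage per bp; requires a
    score on every interval).
    """

    def __init__(
        self,
        feature_name: str,
        mode: str,
        intervals: pd.DataFrame,
        layout: GenomeLayout | None = None,
    ) -> None:
        if mode not in QUANTITATION_MODES:
            raise ValueError(f"unknown quantitation mode {mode!r}; expected one of {QUANTITATION_MODES}")
        df = intervals.copy()
        for col in ("chrom", "start", "end"):
            if col not in df.columns:
                raise ValueError(f"track {feature_name!r}: missing column {col!r}")
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        bad = df["start"] >= df["end"]
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            row = df.iloc[i]
            raise ValueError(
                f"track {feature_name!r}: start >= end at row {i} "
                f"({row['chrom']}:{row['start']}-{row['end']})"
            )
        if (df["start"] < 0).any():
            raise ValueError(f"track {feature_name!r}: negative start coordinate")
        if mode == "intensity":
            if "score" not in df.columns or df["score"].isna().any():
                raise ValueError(f"track {feature_name!r}: score required for intensity mode")
        if "score" in df.columns:
            df["score"] = df["score"].astype(float)
        df = df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)
        self.feature_name = str(feature_name)
        self.mode = mode
        self.intervals = df
        if layout is not None:
            self.validate_against(layout)

    def validate_against(self, layout: GenomeLayout) -> None:
        """Raise if any interval falls on an unknown chromosome or runs past its end."""
        lengths = layout.lengths
        for chrom, sub in self.intervals.groupby("chrom", sort=False):
            if chrom not in lengths:
                raise ValueError(f"track {self.feature_name!r}: unknown chromosome {chrom!r}")
            over = sub["end"] > lengths[chrom]
            if over.any():
                row = sub[over].iloc[0]
                raise ValueError(
                    f"track {self.feature_name!r}: interval beyond chromosome end at "
                    f"{chrom}:{row['start']}-{row['end']} (length {lengths[chrom]})"
                )

    def __len__(self) -> int:
        return len(self.intervals)

    def lengths_bp(self) -> np.ndarray:
        return (self.intervals["end"] - self.intervals["start"]).to_numpy()

    def to_bed(self, path: str | Path) -> None:
        df = self.intervals
        cols = ["chrom", "start", "end"]
        if "score" in df.columns:
            out = df[cols].copy()
            out["name"] = df["name"] if "name" in df.columns else "."
            out["score"] = df["score"]
            out.to_csv(path, sep="\t", header=False, index=False)
        elif "name" in df.columns:
            df[cols + ["name"]].to_csv(path, sep="\t", header=False, index=False)
        else:
            df[cols].to_csv(path, sep="\t", header=False, index=False)


class GapTrack:
    """Assembly gap regions (unsequenced stretches, centromeres, telomeres).

    Windows overlapping any gap interval are excluded from analysis.
    """

    def __init__(self, intervals: pd.DataFrame, layout: GenomeLayout | None = None) -> None:
        track = FeatureTrack("gap", "density", intervals[["chrom", "start", "end"]], layout=layout)
        self.intervals = track.intervals

    def __len__(self) -> int:
        return len(self.intervals)

    @classmethod
    def empty(cls) -> "GapTrack":
        return cls(pd.DataFrame({"chrom": pd.Series(dtype=str),
                                 "start": pd.Series(dtype=np.int64),
                                 "end": pd.Series(dtype=np.int64)}))


def _read_bed(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    ncol = df.shape[1]
    if ncol < 3:
        raise ValueError(f"{path}: BED requires at least 3 columns, got {ncol}")
    df = df.iloc[:, : min(ncol, 5)]
    df.columns = list(_BED_COLUMNS[: df.shape[1]])
    return df


def read_feature_track(
    path: str | Path,
    feature_name: str,
    mode: str,
    layout: GenomeLayout | None = None,
) -> FeatureTrack:
    """Read a BED3/BED5/BED6 file into a :class:`FeatureTrack`.

    BED5+ score columns (column 5) become interval scores; ``mode="intensity"``
    rejects files without one.  Unsorted input is sorted on load.  If a
    ``layout`` is given, intervals beyond chromosome ends are a hard error.
    """
    df = _read_bed(path)
    if mode == "intensity" and "score" not in df.columns:
        raise ValueError(f"{path}: score required for intensity mode (BED file has no column 5)")
    return FeatureTrack(feature_name, mode, df, layout=layout)


def read_gap_track(path: str | Path, layout: GenomeLayout | None = None) -> GapTrack:
    """Read a BED3 gap file."""
    return GapTrack(_read_bed(path), layout=layout)


@dataclass(frozen=True)
class LengthStats:
    """Descriptive statistics of a track's interval lengths.

    ``normal_deviation`` is the Jarque–Bera statistic
    ``n·(S²/6 + K²/24)`` computed from sample skewness S and excess kurtosis
    K — a dimensionless measure of departure from normality (0 for a perfect
    normal sample, asymptotically χ²₂ under normality).
    """

    feature_name: str
    n: int
    mean: float
    median: float
    sd: float
    histogram: tuple[np.ndarray, np.ndarray]  # (bin edges bp, counts)
    normal_deviation: float


def length_stats(track: FeatureTrack, bins: int | str = 50) -> LengthStats:
    """Compute length statistics for a non-empty track.

    The median of an even-length sample is the average of the two central
    order statistics; sd uses the n−1 (sample) denominator.
    """
    if len(track) == 0:
        raise ValueError(f"track {track.feature_name!r} is empty")
    lengths = track.lengths_bp().astype(float)
    counts, edges = np.histogram(lengths, bins=bins)
    if lengths.std() == 0:
        jb = 0.0
    else:
        jb = float(stats.jarque_bera(lengths).statistic)
    return LengthStats(
        feature_name=track.feature_name,
        n=len(lengths),
        mean=float(lengths.mean()),
        median=float(np.median(lengths)),
        sd=float(lengths.std(ddof=1)) if len(lengths) > 1 else 0.0,
        histogram=(edges, counts),
        normal_deviation=jb,
    )


def write_table(rows, path: str | Path, header: Sequence[str] | None = None) -> None:
    """Write a rectangular table as UTF-8 TSV with floats at 6 significant digits.

    ``rows`` may be a DataFrame (header taken from columns) or a sequence of
    row sequences with ``header`` supplied.  Ragged rows are an error.
    """
    if isinstance(rows, pd.DataFrame):
        df = rows
        cols = list(df.columns)
        data = df.to_numpy(dtype=object).tolist()
    else:
        if header is None:
            raise ValueError("header required when rows is not a DataFrame")
        cols = list(header)
        data = [list(r) for r in rows]
    width = len(cols)
    for i, r in enumerate(data):
        if len(r) != width:
            raise ValueError(f"ragged row {i}: {len(r)} fields, header has {width}")

    def fmt(v) -> str:
        if isinstance(v, (float, np.floating)):
            return format(float(v), ".6g")
        return str(v)

    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(map(str, cols)) + "\n")
        for r in data:
            fh.write("\t".join(fmt(v) for v in r) + "\n")


def read_table(path: str | Path) -> pd.DataFrame:
    """Read back a :func:`write_table` TSV (header line required)."""
    return pd.read_csv(path, sep="\t")
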