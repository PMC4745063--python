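"""Top-q% hotspot windows, double/triple hotspot intersections, gene content,
the recombination-rate group test, and over-representation analysis.

A hotspot for a feature is a kept window whose level ranks in the top q
(default 5%) of all kept windows — membership by rank, |set| = ceil(q·n),
with boundary ties broken by genomic order for determinism.  Double/triple
hotspots are windows hot for 2/3 marker features simultaneously; the genes
they contain (any-overlap rule) feed a hypergeometric over-representation
test with Bonferroni and Benjamini–Hochberg control.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .quantify import FeatureWindowMatrix
from .tracks import FeatureTrack
from .zones import ZoneAssignment

__all__ = [
    "HotspotSet",
    "HotspotOverlap",
    "HotspotCaller",
    "RateTest",
    "call_hotspots",
    "overlap_hotspots",
    "genes_in_windows",
    "rate_test",
    "ora_enrichment",
]


@dataclass(frozen=True)
class HotspotSet:
    """Top-q% windows for one feature.

    ``window_ids`` are row positions into the kept-window matrix;
    ``threshold`` is the minimum member level (every member's level is >=
    every non-member's level).
    """

    feature_name: str
    q: float
    threshold: float
    window_ids: frozenset[int]

    def __len__(self) -> int:
        return len(self.window_ids)


class HotspotCaller(BaseEstimator):
    """Rank-rule top-q% caller over a windows × features level table.

    ``fit(X)`` records per-feature thresholds and memberships for every
    column; ``predict(X=None)`` returns the boolean membership matrix.

    Parameters
    ----------
    q : float
        Tail fraction in (0, 1); default 0.05 (top-5% windows).
    """

    def __init__(self, q: float = 0.05) -> None:
        self.q = q

    @staticmethod
    def _levels(X) -> pd.DataFrame:
        if isinstance(X, FeatureWindowMatrix):
            return X.levels
        return pd.DataFrame(X)

    def fit(self, X, y=None) -> "HotspotCaller":
        if not 0 < self.q < 1:
            raise ValueError(f"q must be in (0, 1), got {self.q}")
        levels = self._levels(X)
        n = len(levels)
        if n == 0:
            raise ValueError("no kept windows")
        k = int(np.ceil(self.q * n))
        members = {}
        thresholds = {}
        for col in levels.columns:
            v = levels[col].to_numpy(dtype=float)
            if v.std() == 0:
                raise ValueError(f"feature {col!r} is constant; hotspots undefined")
            # sort by (-level, genomic order); stable → boundary ties by (chrom, start)
            order = np.lexsort((np.arange(n), -v))
            ids = order[:k]
            members[col] = frozenset(int(i) for i in ids)
            thresholds[col] = float(v[ids].min())
        self.k_ = k
        self.n_windows_ = n
        self.members_ = members
        self.thresholds_ = thresholds
        return self

    def predict(self, X=None) -> pd.DataFrame:
        cols = list(self.members_)
        out = pd.DataFrame(
            {c: np.zeros(self.n_windows_, dtype=bool) for c in cols}
        )
        for c in cols:
            out.loc[list(self.members_[c]), c] = True
        return out

    def hotspot_set(self, feature: str) -> HotspotSet:
        return HotspotSet(
            feature_name=feature,
            q=self.q,
            threshold=self.thresholds_[feature],
            window_ids=self.members_[feature],
        )


def call_hotspots(matrix: FeatureWindowMatrix, feature: str, q: float = 0.05) -> HotspotSet:
    """The ceil(q·n) highest-level kept windows for one feature."""
    levels = matrix.levels[[feature]]
    caller = HotspotCaller(q=q).fit(levels)
    return caller.hotspot_set(feature)


class HotspotOverlap:
    """Set intersections of hotspot sets with a per-zone Venn decomposition.

    ``double`` — windows in ≥2 member sets; ``triple`` — windows in all
    member sets when there are exactly 3.  ``venn`` counts, per zone, the
    windows in each exclusive membership pattern; per zone the segment
    counts sum to the zone's union-of-hotspots count.
    """

    def __init__(self, sets: Sequence[HotspotSet], assign: ZoneAssignment | None = None) -> None:
        if not sets:
            raise ValueError("no hotspot sets supplied")
        self.sets = {s.feature_name: set(s.window_ids) for s in sets}
        names = list(self.sets)
        if len(set(names)) != len(names):
            raise ValueError("duplicate feature names among hotspot sets")
        universe = set().union(*self.sets.values())
        if assign is not None and universe and max(universe) >= len(assign):
            raise ValueError("hotspot window ids exceed assignment; mismatched grids")
        member_count = {
            w: sum(w in s for s in self.sets.values()) for w in universe
        }
        self.double = {w for w, c in member_count.items() if c >= 2}
        self.triple = (
            {w for w, c in member_count.items() if c == len(self.sets)}
            if len(self.sets) >= 3
            else set()
        )
        self.assign = assign
        self.venn = self._venn() if assign is not None else None

    def pair_intersection(self, a: str, b: str) -> set[int]:
        return self.sets[a] & self.sets[b]

    def _venn(self) -> pd.DataFrame:
        names = list(self.sets)
        zones = list(self.assign.model.zone_names)
        patterns = []
        for r in range(1, len(names) + 1):
            patterns.extend(combinations(names, r))
        rows = []
        labels = self.assign.labels
        for zone in zones:
            row = {}
            for pat in patterns:
                inside = set.intersection(*(self.sets[n] for n in pat))
                outside = set().union(*(self.sets[n] for n in names if n not in pat)) if len(pat) < len(names) else set()
                exclusive = inside - outside
                row["&".join(pat)] = sum(1 for w in exclusive if labels[w] == zone)
            rows.append(row)
        return pd.DataFrame(rows, index=zones)


def overlap_hotspots(
    sets: Sequence[HotspotSet], assign: ZoneAssignment | None = None
) -> HotspotOverlap:
    """Intersect hotspot sets and decompose the Venn segments by zone."""
    return HotspotOverlap(sets, assign)


def genes_in_windows(genes: FeatureTrack, windows: pd.DataFrame) -> list[str]:
    """Unique, sorted names of genes overlapping ≥1 bp of ≥1 selected window.

    A gene belongs to a window's content if any portion of its sequence falls
    within the window; a gene spanning several selected windows is counted
    once.  ``windows`` is a DataFrame with chrom/start/end rows.
    """
    if "name" not in genes.intervals.columns or genes.intervals["name"].isna().any():
        raise ValueError("gene track has unnamed interval(s)")
    found: set[str] = set()
    win_by_chrom = {c: sub.sort_values("start") for c, sub in windows.groupby("chrom")}
    for chrom, sub in genes.intervals.groupby("chrom", sort=False):
        if chrom not in win_by_chrom:
            continue
        ws = win_by_chrom[chrom]["start"].to_numpy()
        we = win_by_chrom[chrom]["end"].to_numpy()
        gs = sub["start"].to_numpy()
        ge = sub["end"].to_numpy()
        # windows are disjoint and sorted: first window whose end > gene start
        i = np.searchsorted(we, gs, side="right")
        hit = (i < len(ws)) & (np.where(i < len(ws), ws[np.minimum(i, len(ws) - 1)], 0) < ge)
        found.update(sub["name"].to_numpy()[hit])
    return sorted(found)


@dataclass(frozen=True)
class RateTest:
    """Welch's two-sample t-test summary (unequal variances)."""

    mean_group: float
    sd_group: float
    n_group: int
    mean_background: float
    sd_background: float
    n_background: int
    t: float
    df: float
    p: float


def _summarize(values) -> tuple[float, float, int]:
    if isinstance(values, tuple) and len(values) == 3 and np.isscalar(values[0]):
        mean, sd, n = values
        return float(mean), float(sd), int(n)
    arr = np.asarray(values, dtype=float)
    return float(arr.mean()), float(arr.std(ddof=1)), len(arr)


def rate_test(values_background, values_group) -> RateTest:
    """Welch's unequal-variance two-tailed t-test.

    Either argument may be a raw vector or a printed ``(mean, sd, n)``
    summary, so results reported only as summary statistics can be checked.
    Uses the Welch–Satterthwaite degrees of freedom; identical groups give
    t = 0, p = 1.
    """
    m1, s1, n1 = _summarize(values_group)
    m2, s2, n2 = _summarize(values_background)
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if s1 == 0 and s2 == 0:
        if m1 == m2:
            return RateTest(m1, s1, n1, m2, s2, n2, t=0.0, df=float(n1 + n2 - 2), p=1.0)
        raise ValueError("both groups have zero variance")
    v1, v2 = s1**2 / n1, s2**2 / n2
    se = np.sqrt(v1 + v2)
    t = (m1 - m2) / se
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    p = float(2 * stats.t.sf(abs(t), df=df))
    return RateTest(m1, s1, n1, m2, s2, n2, t=float(t), df=float(df), p=min(p, 1.0))


def ora_enrichment(
    gene_list: Sequence[str],
    universe: Sequence[str],
    gene_sets: Mapping[str, Sequence[str]],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``gene_list`` in each gene set.

    Per set: one-sided upper-tail hypergeometric p, Bonferroni-corrected p,
    Benjamini–Hochberg step-up adjusted p, and FDR q (reported as the BH
    value).  A set is ``significant`` only when all three corrected values
    are below ``alpha``.  Output rows are ordered by ascending Bonferroni p.

    Genes in a set but absent from the universe are ignored (intersected
    away); a query gene outside the universe is an error.
    """
    genes = set(gene_list)
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    if not genes:
        raise ValueError("empty gene list")
    stray = genes - uni
    if stray:
        raise ValueError(f"gene(s) not in universe: {sorted(stray)[:5]}")
    if not gene_sets:
        raise ValueError("no gene sets supplied")
    M, n = len(uni), len(genes)
    rows = []
    for set_name, members in gene_sets.items():
        s = set(members) & uni
        k = len(s & genes)
        # P(X >= k) for X ~ Hypergeom(M, |set|, |list|)
        p = float(stats.hypergeom.sf(k - 1, M, len(s), n)) if s else 1.0
        rows.append((set_name, k, len(s), min(p, 1.0)))
    df = pd.DataFrame(rows, columns=["gene_set", "overlap", "set_size", "p"])
    m = len(df)
    df["p_bonferroni"] = np.minimum(df["p"] * m, 1.0)
    df["p_benjamini"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1]
    df["q_fdr"] = df["p_benjamini"]
    df["significant"] = (
        (df["p_bonferroni"] < alpha) & (df["p_benjamini"] < alpha) & (df["q_fdr"] < alpha)
    )
    return df.sort_values(["p_bonferroni", "gene_set"], kind="mergesort").reset_index(drop=True)
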