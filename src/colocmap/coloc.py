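"""Pairwise feature co-localization: Pearson r, Spearman ρ, asymptotic P.

The co-localization coefficient of a feature pair is the correlation between
their per-window levels across all kept windows.  Asymptotic two-tailed
p-values use the t-transform with n−2 degrees of freedom,

    t = r · sqrt((n − 2) / (1 − r²)),   P = 2·SF_t(|t|, n − 2),

applied identically to ρ for its own p (the Hmisc::rcorr convention).
Concordances summarise methodological robustness: R_C is the plain Pearson
correlation between the Spearman and Pearson coefficient vectors over all
pairs; R_W between Pearson coefficient vectors from two window sizes.
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

from .quantify import FeatureWindowMatrix
from .tracks import write_table

__all__ = [
    "ColocPair",
    "ColocMatrix",
    "Concordance",
    "PairwiseColocalization",
    "correlate_pair",
    "build_coloc_matrix",
    "concordance",
    "p_value_census",
    "asymptotic_p",
]


def asymptotic_p(r: np.ndarray | float, n: int) -> np.ndarray | float:
    """Two-tailed p for a correlation coefficient via the t-transform, n−2 df.

    |r| = 1 maps to p = 0; values below float precision are reported as 0,
    printed downstream as "<1e-16".
    """
    if n < 3:
        raise ValueError("n >= 3 required for the asymptotic p-value")
    r = np.asarray(r, dtype=float)
    denom = 1.0 - r**2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(denom > 0, np.abs(r) * np.sqrt((n - 2) / np.maximum(denom, 1e-300)), np.inf)
    p = 2.0 * stats.t.sf(t, df=n - 2)
    p = np.minimum(p, 1.0)
    return float(p) if p.ndim == 0 else p


@dataclass(frozen=True)
class ColocPair:
    """One pairwise co-localization: symmetric in (feature_a, feature_b)."""

    feature_a: str
    feature_b: str
    r: float
    rho: float
    p_asym: float
    p_asym_rho: float
    n: int


def _check_finite_nonconstant(x: np.ndarray, name: str) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if not np.isfinite(x).all():
        raise ValueError(f"non-finite levels in {name!r}")
    if x.std() == 0:
        raise ValueError(f"feature {name!r} is constant; correlation undefined")
    return x


def correlate_pair(
    x: np.ndarray, y: np.ndarray, feature_a: str = "x", feature_b: str = "y"
) -> ColocPair:
    """Pearson r and Spearman ρ (mid-ranks for ties) with asymptotic p-values."""
    x = _check_finite_nonconstant(x, feature_a)
    y = _check_finite_nonconstant(y, feature_b)
    if len(x) != len(y):
        raise ValueError(f"length mismatch: {len(x)} vs {len(y)}")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 paired observations")
    r = float(np.corrcoef(x, y)[0, 1])
    rho = float(np.corrcoef(stats.rankdata(x), stats.rankdata(y))[0, 1])
    return ColocPair(
        feature_a=feature_a,
        feature_b=feature_b,
        r=r,
        rho=rho,
        p_asym=float(asymptotic_p(r, n)),
        p_asym_rho=float(asymptotic_p(rho, n)),
        n=n,
    )


class PairwiseColocalization(BaseEstimator):
    """All-pairs co-localization estimator over a windows × features table.

    Parameters
    ----------
    method : {"both", "pearson", "spearman"}
        Which coefficients to compute (both by default).

    After ``fit(X)`` (X a DataFrame or :class:`FeatureWindowMatrix`):

    Attributes
    ----------
    pairs_ : pandas.DataFrame
        One row per unordered pair, lexicographic by (feature_a, feature_b):
        columns feature_a, feature_b, r, rho, p_asym, p_asym_rho, n.
    feature_names_ : list of str
    n_windows_ : int
    """

    def __init__(self, method: str = "both") -> None:
        self.method = method

    def fit(self, X, y=None) -> "PairwiseColocalization":
        if self.method not in ("both", "pearson", "spearman"):
            raise ValueError(f"unknown method {self.method!r}")
        if isinstance(X, FeatureWindowMatrix):
            X = X.levels
        X = pd.DataFrame(X)
        if X.shape[1] < 2:
            raise ValueError("need at least 2 features")
        n = len(X)
        if n < 3:
            raise ValueError("need at least 3 kept windows")
        vals = X.to_numpy(dtype=float)
        if not np.isfinite(vals).all():
            raise ValueError("non-finite levels in matrix")
        sds = vals.std(axis=0)
        if (sds == 0).any():
            bad = [c for c, s in zip(X.columns, sds) if s == 0]
            raise ValueError(f"constant feature(s): {', '.join(map(str, bad))}")
        names = [str(c) for c in X.columns]
        R = np.corrcoef(vals, rowvar=False)
        ranks = np.apply_along_axis(stats.rankdata, 0, vals)
        RHO = np.corrcoef(ranks, rowvar=False)
        order = sorted(range(len(names)), key=lambda i: names[i])
        rows = []
        for ia, ib in combinations(order, 2):
            a, b = names[ia], names[ib]
            r = float(R[ia, ib])
            rho = float(RHO[ia, ib])
            rows.append(
                (a, b, r, rho, float(asymptotic_p(r, n)), float(asymptotic_p(rho, n)), n)
            )
        self.pairs_ = pd.DataFrame(
            rows, columns=["feature_a", "feature_b", "r", "rho", "p_asym", "p_asym_rho", "n"]
        )
        self.feature_names_ = names
        self.n_windows_ = n
        return self


class ColocMatrix:
    """All pairwise co-localization coefficients (long format).

    k features give k·(k−1)/2 unordered pairs — 861 for the 42-feature set.
    """

    def __init__(self, pairs: pd.DataFrame, feature_names: Sequence[str], n: int) -> None:
        self.pairs = pairs.reset_index(drop=True)
        self.feature_names = list(feature_names)
        self.n = int(n)

    def __len__(self) -> int:
        return len(self.pairs)

    def coefficient_vector(self, which: str = "r") -> np.ndarray:
        """Coefficients in the canonical (lexicographic) pair order."""
        return self.pairs[which].to_numpy()

    def to_square(self, which: str = "r") -> pd.DataFrame:
        names = sorted(self.feature_names)
        M = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
        for row in self.pairs.itertuples(index=False):
            v = getattr(row, which)
            M.loc[row.feature_a, row.feature_b] = v
            M.loc[row.feature_b, row.feature_a] = v
        return M

    def to_tsv(self, path: str | Path) -> None:
        write_table(self.pairs, path)


def build_coloc_matrix(matrix: FeatureWindowMatrix | pd.DataFrame, method: str = "both") -> ColocMatrix:
    """Correlate every unordered feature pair of the level matrix."""
    est = PairwiseColocalization(method=method).fit(matrix)
    return ColocMatrix(est.pairs_, est.feature_names_, est.n_windows_)


@dataclass(frozen=True)
class Concordance:
    """Linear correlation between two coefficient vectors (R_C or R_W)."""

    label: str
    value: float


def concordance(coeffs_a: np.ndarray, coeffs_b: np.ndarray, label: str = "R_C") -> Concordance:
    """Plain Pearson correlation of two aligned coefficient vectors."""
    a = np.asarray(coeffs_a, dtype=float)
    b = np.asarray(coeffs_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    value = float(np.corrcoef(a, b)[0, 1])
    return Concordance(label=label, value=value)


def p_value_census(
    cm: ColocMatrix, cutoffs: Sequence[float] = (0.05, 0.01, 0.001, 1e-16), which: str = "p_asym"
) -> dict[str, int]:
    """Count pairs per p-value bin.

    With cutoffs c0 > c1 > ... > ck the bins are ``P > c0``,
    ``c_{i} < P <= c_{i-1}`` for each interior cutoff, and ``P <= ck``;
    the bins partition all pairs.
    """
    cuts = sorted(set(float(c) for c in cutoffs), reverse=True)
    p = cm.pairs[which].to_numpy()
    out: dict[str, int] = {}
    out[f"P > {cuts[0]:g}"] = int((p > cuts[0]).sum())
    for hi, lo in zip(cuts[:-1], cuts[1:]):
        out[f"{lo:g} < P <= {hi:g}"] = int(((p > lo) & (p <= hi)).sum())
    out[f"P <= {cuts[-1]:g}"] = int((p <= cuts[-1]).sum())
    return out
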