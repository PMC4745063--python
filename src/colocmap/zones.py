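"""Tripartite zonal classification of genome windows by the feature-ratios method.

Windows are labelled Genic, Proximal or Distal.  For a window w and zone z
with defining feature set F_z, the zone score is the mean over f ∈ F_z of
level(w, f) / mean_all_windows(level(·, f)); the window is assigned the
argmax zone.  The score is scale-invariant per feature (multiplying a
feature column by a positive constant changes no label) and parameter-free.

The default zone model groups 31 non-Marker features: 24 gene-associated
("Genic") features including the Alu family, 4 gene-proximal features
(L2, MIR, CID, TFBS), and 3 gene-distal features (NAS-, L1, ATrich).
"""

from __future__ import annotations

from collections import namedtuple
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .quantify import FeatureWindowMatrix

__all__ = [
    "ZoneModel",
    "ZoneAssignment",
    "ZoneClassifier",
    "default_zone_model",
    "classify_windows",
    "zone_proportions",
    "zonal_feature_fractions",
    "designation_match_accuracy",
]

GENIC_FEATURES = (
    "GENE", "CLV", "CNVT", "REG", "H3K4", "DNase", "FAIRE", "EXPS", "NAS+",
    "GCrich", "MeMRE", "MeBS", "CpGi", "CpGe", "Me450", "FLAM", "AluJ",
    "AluS", "AluY", "LRNA+", "LRNA-", "LINC", "SRNA-", "SRNA+",
)
PROXIMAL_FEATURES = ("L2", "MIR", "CID", "TFBS")
DISTAL_FEATURES = ("NAS-", "L1", "ATrich")


@dataclass(frozen=True)
class ZoneModel:
    """Mapping of zone name → defining feature set.

    Zone insertion order doubles as the deterministic tie-break priority
    (first zone wins ties); the default order is Genic > Proximal > Distal.
    """

    zones: tuple[tuple[str, tuple[str, ...]], ...]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for zone, feats in self.zones:
            if not feats:
                raise ValueError(f"zone {zone!r} has no defining features")
            overlap = seen & set(feats)
            if overlap:
                raise ValueError(f"feature(s) in multiple zones: {sorted(overlap)}")
            seen |= set(feats)

    @property
    def zone_names(self) -> tuple[str, ...]:
        return tuple(z for z, _ in self.zones)

    @property
    def features(self) -> tuple[str, ...]:
        return tuple(f for _, feats in self.zones for f in feats)

    def zone_of(self, feature: str) -> str:
        for zone, feats in self.zones:
            if feature in feats:
                return zone
        raise KeyError(f"feature {feature!r} not in zone model")

    def feature_sets(self) -> dict[str, tuple[str, ...]]:
        return dict(self.zones)


def default_zone_model() -> ZoneModel:
    """The 31-feature Genic/Proximal/Distal model (Marker features excluded)."""
    return ZoneModel(
        (
            ("Genic", GENIC_FEATURES),
            ("Proximal", PROXIMAL_FEATURES),
            ("Distal", DISTAL_FEATURES),
        )
    )


class ZoneClassifier(BaseEstimator):
    """Feature-ratios window classifier (sklearn-style).

    ``fit`` learns the genome-wide mean level of each defining feature;
    ``predict`` labels windows by argmax mean-ratio score, with ties broken
    by the model's zone order.  ``fit_predict(X)`` is the one-shot path used
    by :func:`classify_windows`.

    Parameters
    ----------
    model : ZoneModel, optional
        Defaults to :func:`default_zone_model`.
    """

    def __init__(self, model: ZoneModel | None = None) -> None:
        self.model = model

    def _resolve_model(self) -> ZoneModel:
        return self.model if self.model is not None else default_zone_model()

    @staticmethod
    def _levels(X) -> pd.DataFrame:
        if isinstance(X, FeatureWindowMatrix):
            return X.levels
        return pd.DataFrame(X)

    def fit(self, X, y=None) -> "ZoneClassifier":
        model = self._resolve_model()
        levels = self._levels(X)
        missing = [f for f in model.features if f not in levels.columns]
        if missing:
            raise ValueError(f"model feature(s) absent from matrix: {', '.join(missing)}")
        means = levels[list(model.features)].mean(axis=0)
        zero = means[means <= 0]
        if len(zero):
            raise ValueError(
                f"zero genome-wide mean for defining feature(s): {', '.join(zero.index)}"
            )
        self.model_ = model
        self.means_ = means
        self.classes_ = np.asarray(model.zone_names)
        return self

    def decision_function(self, X) -> pd.DataFrame:
        """Per-window mean-ratio score for each zone (columns in zone order)."""
        levels = self._levels(X)
        ratios = levels[self.means_.index] / self.means_
        scores = {}
        for zone, feats in self.model_.zones:
            scores[zone] = ratios[list(feats)].mean(axis=1)
        return pd.DataFrame(scores)

    def predict(self, X) -> np.ndarray:
        scores = self.decision_function(X)
        # np.argmax takes the first maximum → zone-order tie-break
        idx = np.argmax(scores.to_numpy(), axis=1)
        return self.classes_[idx]

    def fit_predict(self, X, y=None) -> np.ndarray:
        return self.fit(X).predict(X)


class ZoneAssignment:
    """Per-window zone labels plus the per-zone ratio scores that produced them."""

    def __init__(
        self,
        windows: pd.DataFrame,
        labels: np.ndarray,
        scores: pd.DataFrame,
        model: ZoneModel,
    ) -> None:
        self.windows = windows.reset_index(drop=True)
        self.labels = np.asarray(labels)
        self.scores = scores.reset_index(drop=True)
        self.model = model

    def __len__(self) -> int:
        return len(self.labels)

    def to_bed(self, path: str | Path) -> None:
        out = self.windows[["chrom", "start", "end"]].copy()
        out["zone"] = self.labels
        out.to_csv(path, sep="\t", header=False, index=False)


def classify_windows(matrix: FeatureWindowMatrix, model: ZoneModel | None = None) -> ZoneAssignment:
    """Assign every kept window to its maximal-ratio zone."""
    clf = ZoneClassifier(model=model).fit(matrix)
    labels = clf.predict(matrix)
    scores = clf.decision_function(matrix)
    return ZoneAssignment(matrix.windows, labels, scores, clf.model_)


ZoneProportions = namedtuple("ZoneProportions", ["fractions", "counts"])


def zone_proportions(assign: ZoneAssignment) -> ZoneProportions:
    """Fraction and absolute count of kept windows per zone (fractions sum to 1)."""
    if len(assign) == 0:
        raise ValueError("no windows assigned")
    n = len(assign)
    counts = {z: int(np.sum(assign.labels == z)) for z in assign.model.zone_names}
    fractions = {z: c / n for z, c in counts.items()}
    return ZoneProportions(fractions=fractions, counts=counts)


def zonal_feature_fractions(
    matrix: FeatureWindowMatrix, assign: ZoneAssignment
) -> pd.DataFrame:
    """Per feature, the fraction of its genome-wide summed level in each zone.

    Rows (features) sum to 1.  An all-zero feature has no defined fractions
    and raises.
    """
    if len(assign) != matrix.n_windows:
        raise ValueError("assignment and matrix cover different windows")
    zones = assign.model.zone_names
    totals = matrix.levels.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"all-zero feature(s), fractions undefined: {', '.join(zero.index)}")
    rows = {}
    for z in zones:
        mask = assign.labels == z
        rows[z] = matrix.levels[mask].sum(axis=0) / totals
    return pd.DataFrame(rows)


MatchAccuracy = namedtuple("MatchAccuracy", ["matched", "total", "accuracy"])


def designation_match_accuracy(fractions: pd.DataFrame, model: ZoneModel) -> MatchAccuracy:
    """How many model features are most abundant in their own designated zone.

    A feature matches when the argmax of its zonal fraction row equals its
    zone in the model; accuracy = matched / total.
    """
    missing = [f for f in model.features if f not in fractions.index]
    if missing:
        raise ValueError(f"fraction row missing for feature(s): {', '.join(missing)}")
    matched = 0
    for f in model.features:
        if fractions.loc[f].idxmax() == model.zone_of(f):
            matched += 1
    total = len(model.features)
    return MatchAccuracy(matched=matched, total=total, accuracy=matched / total)
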