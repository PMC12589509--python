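"""Feature partition registry and per-feature eTIV residualization.

Morphometric features are partitioned into two disjoint classes, ``limbic``
and ``nonlimbic``; ``whole_brain`` is their union.  Head size is removed by
ordinary least squares of each feature on {1, eTIV}, keeping the residuals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tables import ETIV, feature_columns

LIMBIC = "limbic"
NONLIMBIC = "nonlimbic"
WHOLE_BRAIN = "whole_brain"
FEATURE_SETS = (LIMBIC, NONLIMBIC, WHOLE_BRAIN)

# Sizes of the default registry (placeholder names; real anatomical labels
# are segmentation-specific and out of scope).
DEFAULT_N_LIMBIC = 160
DEFAULT_N_NONLIMBIC = 333


@dataclass(frozen=True)
class FeaturePartition:
    """Disjoint assignment of feature names to limbic / non-limbic classes."""

    limbic: tuple[str, ...]
    nonlimbic: tuple[str, ...]

    def __post_init__(self) -> None:
        overlap = set(self.limbic) & set(self.nonlimbic)
        if overlap:
            raise ValueError(f"features in both classes: {sorted(overlap)[:5]}")
        names = list(self.limbic) + list(self.nonlimbic)
        if len(names) != len(set(names)):
            raise ValueError("duplicate feature names in partition")

    @property
    def whole_brain(self) -> tuple[str, ...]:
        return self.limbic + self.nonlimbic

    def set_names(self, set_id: str) -> tuple[str, ...]:
        if set_id == LIMBIC:
            return self.limbic
        if set_id == NONLIMBIC:
            return self.nonlimbic
        if set_id == WHOLE_BRAIN:
            return self.whole_brain
        raise ValueError(f"unknown feature set {set_id!r}; expected one of {FEATURE_SETS}")

    def class_of(self, feature: str) -> str:
        if feature in self.limbic:
            return LIMBIC
        if feature in self.nonlimbic:
            return NONLIMBIC
        raise KeyError(feature)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature": list(self.whole_brain),
                "class": [LIMBIC] * len(self.limbic) + [NONLIMBIC] * len(self.nonlimbic),
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FeaturePartition":
        limbic = tuple(df.loc[df["class"] == LIMBIC, "feature"])
        nonlimbic = tuple(df.loc[df["class"] == NONLIMBIC, "feature"])
        return cls(limbic=limbic, nonlimbic=nonlimbic)


def make_partition(n_limbic: int, n_nonlimbic: int) -> FeaturePartition:
    """Synthetic partition with generated placeholder names."""
    if n_limbic <= 0 or n_nonlimbic <= 0:
        raise ValueError("partition class sizes must be positive")
    width = max(3, len(str(max(n_limbic, n_nonlimbic))))
    limbic = tuple(f"limbic_{i:0{width}d}" for i in range(1, n_limbic + 1))
    nonlimbic = tuple(f"nonlimbic_{i:0{width}d}" for i in range(1, n_nonlimbic + 1))
    return FeaturePartition(limbic=limbic, nonlimbic=nonlimbic)


def default_partition() -> FeaturePartition:
    """The shipped 160 limbic / 333 non-limbic / 493 whole-brain registry."""
    return make_partition(DEFAULT_N_LIMBIC, DEFAULT_N_NONLIMBIC)


@dataclass
class ResidualizationModel:
    """Per-feature intercept and eTIV slope fitted by OLS."""

    features: list[str]
    intercepts: np.ndarray
    slopes: np.ndarray
    fit_cohort: str = ""

    def __post_init__(self) -> None:
        if len(self.features) != len(self.intercepts) or len(self.features) != len(self.slopes):
            raise ValueError("one coefficient pair required per feature")
        if not np.all(np.isfinite(self.slopes)):
            raise ValueError("non-finite eTIV slope")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"feature": self.features, "intercept": self.intercepts, "etiv_slope": self.slopes}
        )


def residualize_etiv(
    cohort: pd.DataFrame,
    features: list[str] | None = None,
    model: ResidualizationModel | None = None,
    fit_cohort: str = "",
) -> tuple[pd.DataFrame, ResidualizationModel]:
    """Replace feature columns by their residuals after regression on eTIV.

    By default coefficients are fit on `cohort` itself.  Passing a `model`
    applies previously fitted coefficients instead (transfer mode).
    """
    if ETIV not in cohort.columns:
        raise ValueError(f"cohort has no {ETIV!r} column")
    if features is None:
        features = feature_columns(cohort) if model is None else list(model.features)
    missing = [f for f in features if f not in cohort.columns]
    if missing:
        raise ValueError(f"features absent from cohort: {missing}")

    etiv = cohort[ETIV].to_numpy(dtype=float)
    Y = cohort[features].to_numpy(dtype=float)
    if model is None:
        if np.ptp(etiv) == 0:
            raise ValueError("eTIV has zero variance; slope undefined")
        X = np.column_stack([np.ones_like(etiv), etiv])
        coef, *_ = np.linalg.lstsq(X, Y, rcond=None)
        model = ResidualizationModel(
            features=list(features),
            intercepts=coef[0].copy(),
            slopes=coef[1].copy(),
            fit_cohort=fit_cohort,
        )
    elif list(model.features) != list(features):
        raise ValueError("model feature list does not match requested features")

    resid = Y - (model.intercepts[None, :] + np.outer(etiv, model.slopes))
    out = cohort.copy()
    out[features] = resid
    return out, model


def select_features(cohort: pd.DataFrame, partition: FeaturePartition, set_id: str) -> pd.DataFrame:
    """Restrict the table to metadata plus one named feature set."""
    names = partition.set_names(set_id)
    missing = [f for f in names if f not in cohort.columns]
    if missing:
        raise ValueError(f"feature set {set_id!r} members missing from cohort: {missing[:10]}")
    meta = [c for c in cohort.columns if c not in set(partition.whole_brain)]
    return cohort[meta + list(names)]
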