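"""Gradient-boosted sex classification with nested cross-validation.

The outer 5-fold loop yields out-of-fold class probabilities and the CV
AUC; within each outer training split an inner k-fold loop tracks the
validation log-loss at every boosting iteration, and the iteration
minimizing the mean inner curve gives that fold's optimal round count.
The final model is refit on all data for the median of the per-fold
optima.  Sex is coded males=0, females=1, so the predicted probability is
P(female): 0 = male-like, 1 = female-like.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.metrics import log_loss, roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .tables import SESSION, SEX, SUBJECT

LABEL_CODING = {"M": 0, "F": 1}


@dataclass(frozen=True)
class TrainingParams:
    learning_rate: float = 0.01
    initial_rounds: int = 1000
    outer_folds: int = 5
    inner_folds: int = 5
    max_depth: int = 3
    subsample: float = 1.0
    max_features: str | float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.learning_rate <= 1:
            raise ValueError("learning rate must lie in (0, 1]")
        if self.initial_rounds < 1:
            raise ValueError("initial_rounds must be >= 1")
        if self.outer_folds < 2 or self.inner_folds < 2:
            raise ValueError("folds must be >= 2")

    def backend_kwargs(self, n_estimators: int) -> dict:
        return dict(n_estimators=n_estimators, learning_rate=self.learning_rate,
                    max_depth=self.max_depth, subsample=self.subsample,
                    max_features=self.max_features, random_state=self.seed)


@dataclass
class TrainedSexModel:
    booster: GradientBoostingClassifier
    params: TrainingParams
    features: list[str]
    feature_set: str
    optimal_rounds: int
    fold_optimal_rounds: list[int]
    fold_assignment: np.ndarray        # outer-fold index per training row
    cv_auc: float
    label_coding: dict = field(default_factory=lambda: dict(LABEL_CODING))

    def __post_init__(self) -> None:
        if self.optimal_rounds > self.params.initial_rounds:
            raise ValueError("optimal_rounds cannot exceed initial_rounds")

    def save_metadata(self, path: str | Path) -> None:
        meta = {
            "feature_set": self.feature_set,
            "features": self.features,
            "optimal_rounds": self.optimal_rounds,
            "fold_optimal_rounds": self.fold_optimal_rounds,
            "cv_auc": self.cv_auc,
            "label_coding": self.label_coding,
            "params": asdict(self.params),
            "backend": "sklearn.ensemble.GradientBoostingClassifier",
        }
        Path(path).write_text(json.dumps(meta, indent=1))


def encode_labels(sex: pd.Series | np.ndarray) -> np.ndarray:
    arr = np.asarray(sex)
    bad = set(np.unique(arr)) - set(LABEL_CODING)
    if bad:
        raise ValueError(f"unknown sex labels: {sorted(bad)}")
    return np.array([LABEL_CODING[s] for s in arr])


def roc_auc(probs: np.ndarray, labels: np.ndarray) -> float:
    """AUC = Mann-Whitney concordance probability, ties counting 1/2."""
    labels = np.asarray(labels)
    probs = np.asarray(probs, dtype=float)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC undefined with a single class")
    return float(roc_auc_score(labels, probs))


def _matrix(cohort: pd.DataFrame, features: list[str]) -> np.ndarray:
    missing = [f for f in features if f not in cohort.columns]
    if missing:
        raise ValueError(f"cohort lacks model features: {missing[:10]}")
    return cohort[features].to_numpy(dtype=float)


def _inner_optimal_rounds(X: np.ndarray, y: np.ndarray, params: TrainingParams,
                          rng_seed: int) -> int:
    """Iteration minimizing mean inner-fold validation log-loss."""
    skf = StratifiedKFold(n_splits=params.inner_folds, shuffle=True, random_state=rng_seed)
    curves = np.zeros((params.inner_folds, params.initial_rounds))
    for i, (tr, va) in enumerate(skf.split(X, y)):
        gb = GradientBoostingClassifier(**params.backend_kwargs(params.initial_rounds))
        gb.fit(X[tr], y[tr])
        for it, proba in enumerate(gb.staged_predict_proba(X[va])):
            curves[i, it] = log_loss(y[va], proba[:, 1], labels=[0, 1])
    return int(np.argmin(curves.mean(axis=0))) + 1


def train_nested_cv(cohort: pd.DataFrame, features: list[str],
                    params: TrainingParams = TrainingParams(),
                    feature_set: str = "whole_brain") -> tuple[TrainedSexModel, pd.DataFrame]:
    """Nested stratified CV; returns the final model and out-of-fold probabilities."""
    X = _matrix(cohort, features)
    y = encode_labels(cohort[SEX])
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    if len(y) < params.outer_folds:
        raise ValueError("fewer rows than outer folds")

    outer = StratifiedKFold(n_splits=params.outer_folds, shuffle=True,
                            random_state=params.seed)
    oof = np.full(len(y), np.nan)
    fold_of = np.full(len(y), -1)
    fold_rounds = []
    for f_idx, (tr, te) in enumerate(outer.split(X, y)):
        best = _inner_optimal_rounds(X[tr], y[tr], params, params.seed + 100 + f_idx)
        fold_rounds.append(best)
        gb = GradientBoostingClassifier(**params.backend_kwargs(best))
        gb.fit(X[tr], y[tr])
        oof[te] = gb.predict_proba(X[te])[:, 1]
        fold_of[te] = f_idx

    optimal = int(np.median(fold_rounds))
    final = GradientBoostingClassifier(**params.backend_kwargs(optimal))
    final.fit(X, y)
    cv_auc = roc_auc(oof, y)

    model = TrainedSexModel(booster=final, params=params, features=list(features),
                            feature_set=feature_set, optimal_rounds=optimal,
                            fold_optimal_rounds=fold_rounds, fold_assignment=fold_of,
                            cv_auc=cv_auc)
    prob_cols = {c: cohort[c].to_numpy() for c in (SUBJECT, SESSION) if c in cohort.columns}
    probs = pd.DataFrame({**prob_cols, "feature_set": feature_set, "p_female": oof,
                          "outer_fold": fold_of})
    return model, probs


def predict(model: TrainedSexModel, cohort: pd.DataFrame) -> pd.DataFrame:
    """Score rows independently; returns a class-probability table."""
    extra = [c for c in cohort.columns
             if c not in model.features and c not in
             (SUBJECT, SESSION, SEX, "age_months", "etiv_mm3", "euler", "site_id", "family_id")]
    missing = [f for f in model.features if f not in cohort.columns]
    if missing:
        raise ValueError(f"missing model features: {missing[:10]}; unexpected extras: {extra[:10]}")
    X = _matrix(cohort, model.features)
    p = model.booster.predict_proba(X)[:, 1]
    cols = {c: cohort[c].to_numpy() for c in (SUBJECT, SESSION) if c in cohort.columns}
    return pd.DataFrame({**cols, "feature_set": model.feature_set, "p_female": p})


def feature_importance(model: TrainedSexModel) -> pd.DataFrame:
    """Gain-share feature contributions, descending, normalized to sum 1."""
    imp = np.asarray(model.booster.feature_importances_, dtype=float)
    total = imp.sum()
    share = imp / total if total > 0 else np.full_like(imp, 1.0 / len(imp))
    out = pd.DataFrame({"feature": model.features, "gain_share": share})
    return out.sort_values("gain_share", ascending=False, kind="mergesort").reset_index(drop=True)


def importance_overlap(rank_a: pd.DataFrame, rank_b: pd.DataFrame, k: int) -> float:
    """|top-k(a) & top-k(b)| / k over the shared feature universe."""
    if rank_a.empty or rank_b.empty:
        raise ValueError("rankings must be non-empty")
    shared = set(rank_a["feature"]) & set(rank_b["feature"])
    if k > len(shared):
        raise ValueError(f"k={k} exceeds shared feature universe of size {len(shared)}")
    top_a = list(rank_a.loc[rank_a["feature"].isin(shared), "feature"])[:k]
    top_b = list(rank_b.loc[rank_b["feature"].isin(shared), "feature"])[:k]
    return len(set(top_a) & set(top_b)) / k
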