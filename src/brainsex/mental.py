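"""General mental-health score via baseline PCA with loading projection.

The first principal component of the standardized baseline questionnaire
items serves as a general distress score.  Follow-up items are standardized
with the *baseline* moments and projected onto the stored baseline PC1
loadings -- the component is never refit at follow-up.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .tables import SESSION, SUBJECT, require_columns

logger = logging.getLogger(__name__)


@dataclass
class PcModel:
    items: list[str]
    means: np.ndarray
    sds: np.ndarray
    loadings: np.ndarray            # unit norm, oriented to correlate + with items
    explained_variance: float
    sign_flipped: bool
    standardized: bool = True

    def __post_init__(self) -> None:
        if not np.isclose(np.linalg.norm(self.loadings), 1.0):
            raise ValueError("loading vector must have unit norm")
        if not 0 < self.explained_variance <= 1:
            raise ValueError("explained variance must lie in (0, 1]")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "items": self.items,
            "means": self.means.tolist(),
            "sds": self.sds.tolist(),
            "loadings": self.loadings.tolist(),
            "explained_variance": self.explained_variance,
            "sign_flipped": self.sign_flipped,
            "standardized": self.standardized,
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def _item_columns(items: pd.DataFrame) -> list[str]:
    return [c for c in items.columns if c not in (SUBJECT, SESSION)]


def fit_pc1(items: pd.DataFrame, standardize: bool = True) -> tuple[PcModel, pd.DataFrame]:
    """PC1 of the (standardized) baseline items, sign-oriented positively.

    Returns the model and the baseline scores keyed by subject.
    """
    cols = _item_columns(items)
    if len(cols) < 2:
        raise ValueError("need at least 2 items")
    work = items.dropna(subset=cols)
    dropped = len(items) - len(work)
    if dropped:
        logger.info("PCA: listwise-deleted %d incomplete rows", dropped)
    if len(work) < 3:
        raise ValueError("need at least 3 complete subjects")

    X = work[cols].to_numpy(dtype=float)
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    zero = [c for c, s in zip(cols, sds) if s == 0]
    if zero:
        raise ValueError(f"zero-variance items: {zero}")
    Z = (X - means) / sds if standardize else X - means

    cov = np.cov(Z, rowvar=False, ddof=1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    v = evecs[:, 0]
    explained = float(evals[0] / evals.sum())

    scores = Z @ v
    item_corr = np.array([np.corrcoef(scores, Z[:, j])[0, 1] for j in range(Z.shape[1])])
    flipped = item_corr.sum() < 0
    if flipped:
        v, scores = -v, -scores

    model = PcModel(items=cols, means=means, sds=sds, loadings=v,
                    explained_variance=explained, sign_flipped=bool(flipped),
                    standardized=standardize)
    out = pd.DataFrame({SUBJECT: work[SUBJECT].to_numpy(), "mh_score": scores})
    return model, out


def project(model: PcModel, items: pd.DataFrame) -> pd.DataFrame:
    """Score any session's items with the baseline moments and loadings."""
    cols = _item_columns(items)
    if set(cols) != set(model.items):
        raise ValueError(f"item-set mismatch: expected {model.items}, got {cols}")
    work = items.dropna(subset=model.items)
    X = work[model.items].to_numpy(dtype=float)
    Z = (X - model.means) / model.sds if model.standardized else X - model.means
    scores = Z @ model.loadings
    keep = [c for c in (SUBJECT, SESSION) if c in work.columns]
    out = work[keep].copy()
    out["mh_score"] = scores
    return out.reset_index(drop=True)


def session_correlation(baseline: pd.DataFrame, followup: pd.DataFrame) -> dict:
    """Pearson correlation of paired baseline/follow-up scores."""
    require_columns(baseline, [SUBJECT, "mh_score"], "baseline scores")
    require_columns(followup, [SUBJECT, "mh_score"], "follow-up scores")
    merged = baseline.merge(followup, on=SUBJECT, suffixes=("_b", "_f"))
    n = len(merged)
    if n < 3:
        raise ValueError("need at least 3 paired scores")
    a = merged["mh_score_b"].to_numpy(dtype=float)
    b = merged["mh_score_f"].to_numpy(dtype=float)
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("zero variance in one of the score vectors")
    r = float(np.corrcoef(a, b)[0, 1])
    r_c = min(max(r, -1.0 + 1e-15), 1.0 - 1e-15)
    t = r_c * np.sqrt((n - 2) / (1 - r_c**2))
    p = float(2 * sps.t.sf(abs(t), n - 2))
    return {"r": r, "t": float(t), "p": p, "n": n}
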