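"""Quality control and covariate-constrained 1:1 female-male matching.

QC removes rows whose Euler number lies below ``mean - n_sd * SD`` of the
input cohort (one-sided: only the low-quality tail is excluded).  Matching
then pairs each reference-sex subject with one opposite-sex subject under
three constraints -- age within 12 months, relative eTIV difference within
3% of the reference subject's eTIV, Euler difference within one cohort SD --
greedily and without replacement, preferring the admissible candidate with
the smallest absolute eTIV difference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .tables import AGE, ETIV, EULER, SEX, SUBJECT, require_columns

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MatchSpec:
    max_age_diff_months: float = 12.0
    max_etiv_rel_diff: float = 0.03
    max_euler_diff_sd: float = 1.0
    reference_sex: str = "F"
    iteration_order: str = "by_id"   # or "random"
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.max_age_diff_months, self.max_etiv_rel_diff, self.max_euler_diff_sd) <= 0:
            raise ValueError("matching thresholds must be positive")
        if self.reference_sex not in ("F", "M"):
            raise ValueError("reference_sex must be 'F' or 'M'")
        if self.iteration_order not in ("by_id", "random"):
            raise ValueError("iteration_order must be 'by_id' or 'random'")


@dataclass
class MatchedSample:
    pairs: pd.DataFrame              # reference_subject_id, matched_subject_id, diffs
    cohort: pd.DataFrame             # matched subset, both sexes
    unmatched_reference: list[str]
    spec: MatchSpec
    euler_sd: float

    def validate(self) -> None:
        """Re-verify every pair against the spec constraints from the pair list."""
        p = self.pairs
        if p.empty:
            return
        ids = pd.concat([p["reference_subject_id"], p["matched_subject_id"]])
        if ids.duplicated().any():
            raise AssertionError("a subject appears in more than one pair")
        tol = 1e-12
        if (p["age_diff_months"].abs() > self.spec.max_age_diff_months + tol).any():
            raise AssertionError("age constraint violated")
        if (p["etiv_rel_diff"].abs() > self.spec.max_etiv_rel_diff + tol).any():
            raise AssertionError("eTIV constraint violated")
        if (p["euler_diff"].abs() > self.spec.max_euler_diff_sd * self.euler_sd + tol).any():
            raise AssertionError("Euler constraint violated")
        n_f = (self.cohort[SEX] == "F").sum()
        if n_f * 2 != len(self.cohort):
            raise AssertionError("matched cohort is not 50% female")


def euler_qc(cohort: pd.DataFrame, n_sd: float = 3.0) -> tuple[pd.DataFrame, list[str]]:
    """Drop rows with Euler number below ``mean - n_sd * SD`` of the input."""
    require_columns(cohort, [EULER], "cohort")
    if len(cohort) < 2:
        raise ValueError("need at least 2 observations for Euler QC")
    e = cohort[EULER].to_numpy(dtype=float)
    sd = e.std(ddof=1)
    if sd == 0:
        logger.info("all Euler values identical; nothing excluded")
        return cohort.copy(), []
    cut = e.mean() - n_sd * sd
    bad = e < cut
    excluded = cohort.loc[bad, SUBJECT].astype(str).unique().tolist() if SUBJECT in cohort \
        else cohort.index[bad].tolist()
    logger.info("Euler QC: excluded %d of %d rows (cutoff %.2f)", bad.sum(), len(cohort), cut)
    return cohort.loc[~bad].copy(), excluded


def match_pairs(cohort: pd.DataFrame, spec: MatchSpec = MatchSpec()) -> MatchedSample:
    """Greedy without-replacement 1:1 matching of reference-sex subjects."""
    require_columns(cohort, [SUBJECT, SEX, AGE, ETIV, EULER], "cohort")
    if cohort[SUBJECT].duplicated().any():
        raise ValueError("match_pairs expects one row per subject (cross-sectional)")

    euler_sd = float(cohort[EULER].to_numpy(dtype=float).std(ddof=1)) if len(cohort) > 1 else 0.0
    max_euler = spec.max_euler_diff_sd * euler_sd

    ref = cohort[cohort[SEX] == spec.reference_sex]
    other = cohort[cohort[SEX] != spec.reference_sex]

    if spec.iteration_order == "by_id":
        ref = ref.sort_values(SUBJECT)
    else:
        rng = np.random.default_rng(spec.seed)
        ref = ref.iloc[rng.permutation(len(ref))]

    cand_age = other[AGE].to_numpy(dtype=float)
    cand_etiv = other[ETIV].to_numpy(dtype=float)
    cand_euler = other[EULER].to_numpy(dtype=float)
    cand_ids = other[SUBJECT].to_numpy()
    available = np.ones(len(other), dtype=bool)

    pairs, unmatched = [], []
    for _, row in ref.iterrows():
        age_d = cand_age - float(row[AGE])
        etiv_d = cand_etiv - float(row[ETIV])
        euler_d = cand_euler - float(row[EULER])
        ok = (available
              & (np.abs(age_d) <= spec.max_age_diff_months)
              & (np.abs(etiv_d) / float(row[ETIV]) <= spec.max_etiv_rel_diff)
              & (np.abs(euler_d) <= max_euler))
        if not ok.any():
            unmatched.append(str(row[SUBJECT]))
            continue
        idx = np.where(ok)[0]
        best = idx[np.argmin(np.abs(etiv_d[idx]))]
        available[best] = False
        pairs.append({
            "reference_subject_id": str(row[SUBJECT]),
            "matched_subject_id": str(cand_ids[best]),
            "age_diff_months": float(age_d[best]),
            "etiv_rel_diff": float(etiv_d[best] / row[ETIV]),
            "euler_diff": float(euler_d[best]),
        })

    pair_df = pd.DataFrame(pairs, columns=["reference_subject_id", "matched_subject_id",
                                           "age_diff_months", "etiv_rel_diff", "euler_diff"])
    keep = set(pair_df["reference_subject_id"]) | set(pair_df["matched_subject_id"])
    matched = cohort[cohort[SUBJECT].astype(str).isin(keep)].copy()
    logger.info("matching: %d pairs, %d unmatched %s subjects",
                len(pair_df), len(unmatched), spec.reference_sex)
    return MatchedSample(pairs=pair_df, cohort=matched, unmatched_reference=unmatched,
                         spec=spec, euler_sd=euler_sd)


def balance_check(matched: MatchedSample) -> pd.DataFrame:
    """Welch two-sample tests on age, eTIV and Euler between sexes."""
    df = matched.cohort
    if df.empty:
        raise ValueError("empty matched sample")
    f = df[df[SEX] == "F"]
    m = df[df[SEX] == "M"]
    if len(f) < 2 or len(m) < 2:
        raise ValueError("need at least 2 subjects per sex for balance tests")
    rows = []
    for var in (AGE, ETIV, EULER):
        a, b = f[var].to_numpy(dtype=float), m[var].to_numpy(dtype=float)
        if np.ptp(a) == 0 and np.ptp(b) == 0 and a.mean() == b.mean():
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_ind(a, b, equal_var=False)
        rows.append({"variable": var, "mean_F": a.mean(), "mean_M": b.mean(),
                     "t": float(t), "p": float(p)})
    return pd.DataFrame(rows)
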