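"""Linear mixed-effects association models on class probabilities.

Four association analyses (age, pubertal stage, menarche onset, mental
health) are fit per sex and per feature set with a subject random
intercept, estimated by maximum likelihood.  Term F-tests come in two
flavours: sequential (type I, formula order) and marginal (type II, each
main effect after every other term that does not contain it, interactions
last).  Denominator degrees of freedom follow the containment convention
(between-subject vs within-subject terms).  P-values are adjusted by
Benjamini-Hochberg within a declared family.

The training-cohort age analysis is a plain linear model (no repeated
measures), handled by the same machinery with a zero random-effect
variance.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.stats.multitest import multipletests

from .tables import AGE, BASELINE, EULER, FOLLOWUP, SESSION, SEX, SITE, SUBJECT, \
    require_columns

logger = logging.getLogger(__name__)

MENARCHE_NO_NO = "no_no"
MENARCHE_ONSET = "onset"
MENARCHE_EXCLUDED = "excluded"


@dataclass(frozen=True)
class ModelSpec:
    """Fixed-effect term order and random structure of one analysis."""

    id: str
    terms: tuple[str, ...]          # formula order, site excluded
    random_intercept: bool = True
    site_position: int | None = None  # index at which a site term is inserted

    def with_site(self, include: bool) -> tuple[str, ...]:
        if not include:
            return self.terms
        pos = self.site_position if self.site_position is not None else len(self.terms)
        terms = list(self.terms)
        terms.insert(pos, "site")
        return tuple(terms)


# term order exactly as in the study formulas; site enters as a further
# covariate after euler, before the interactions
MODEL_SPECS: dict[str, ModelSpec] = {
    "age_lm_training": ModelSpec("age_lm_training", ("age_months", "euler"),
                                 random_intercept=False, site_position=2),
    "age_lme": ModelSpec("age_lme",
                         ("age_months", "session", "euler", "age_months:session"),
                         site_position=3),
    "pds_lme": ModelSpec("pds_lme",
                         ("pds_average", "age_months", "euler", "pds_average:age_months"),
                         site_position=3),
    "menarche_lme": ModelSpec("menarche_lme",
                              ("menarche_onset", "age_months", "session", "euler",
                               "menarche_onset:age_months", "menarche_onset:session"),
                              site_position=4),
    "mh_lme": ModelSpec("mh_lme",
                        ("mh_score", "age_months", "session", "euler",
                         "mh_score:age_months", "mh_score:session"),
                        site_position=4),
}

_VARIABLE_COLUMNS = {
    "age_months": AGE,
    "euler": EULER,
    "session": SESSION,
    "site": SITE,
    "pds_average": "pds_average",
    "menarche_onset": "menarche_group",
    "mh_score": "mh_score",
}
_CATEGORICAL = {"session", "site", "menarche_onset"}


@dataclass
class AssociationResult:
    spec_id: str
    anova_type: str                  # "I" or "II"
    stratum: dict
    table: pd.DataFrame              # term, F, num_df, den_df, p [, p_adj]

    def to_frame(self) -> pd.DataFrame:
        out = self.table.copy()
        out.insert(0, "spec_id", self.spec_id)
        out.insert(1, "anova_type", self.anova_type)
        for i, (k, v) in enumerate(self.stratum.items()):
            out.insert(2 + i, k, v)
        return out


def results_frame(results: list[AssociationResult]) -> pd.DataFrame:
    return pd.concat([r.to_frame() for r in results], ignore_index=True)


# ---------------------------------------------------------------- scoring ---

def pds_average(items) -> float:
    """Mean of the available PDS item scores (menarche coded No=1/Yes=4)."""
    vals = pd.Series(list(items), dtype=float)
    vals = vals.dropna()
    if vals.empty:
        raise ValueError("all PDS items missing")
    return float(vals.mean())


def menarche_groups(puberty: pd.DataFrame) -> pd.DataFrame:
    """Classify females with both sessions by their menstruation answers.

    (No, No) -> no_no; (No, Yes) -> onset; anything else -> excluded.
    """
    require_columns(puberty, [SUBJECT, SESSION, SEX, "menarche"], "puberty table")
    fem = puberty[puberty[SEX] == "F"]
    wide = fem.pivot_table(index=SUBJECT, columns=SESSION, values="menarche",
                           aggfunc="first")
    rows = []
    for sid, r in wide.iterrows():
        b = r.get(BASELINE)
        f = r.get(FOLLOWUP)
        if pd.isna(b) or pd.isna(f) or b == "" or f == "":
            group, reason = MENARCHE_EXCLUDED, "missing session"
        elif b == "no" and f == "no":
            group, reason = MENARCHE_NO_NO, ""
        elif b == "no" and f == "yes":
            group, reason = MENARCHE_ONSET, ""
        else:
            group, reason = MENARCHE_EXCLUDED, f"answers ({b}, {f})"
        rows.append({SUBJECT: sid, "menarche_group": group, "reason": reason})
    out = pd.DataFrame(rows)
    counts = out["menarche_group"].value_counts().to_dict()
    logger.info("menarche groups: %s", counts)
    return out


def site_filter(data: pd.DataFrame, min_n: int = 20) -> pd.DataFrame:
    """Drop rows belonging to sites with fewer than ``min_n`` observations."""
    require_columns(data, [SITE], "data")
    counts = data[SITE].value_counts()
    small = counts[counts < min_n].index.tolist()
    if small:
        logger.info("site filter: dropping %s (< %d observations)", small, min_n)
    out = data[~data[SITE].isin(small)]
    if out.empty:
        raise ValueError(f"all sites have fewer than {min_n} observations")
    return out.copy()


# ----------------------------------------------------------- design matrix ---

def _term_columns(df: pd.DataFrame, var: str) -> tuple[np.ndarray, list[str]]:
    col = _VARIABLE_COLUMNS[var]
    if col not in df.columns:
        raise ValueError(f"analysis variable {var!r} needs column {col!r}")
    if var in _CATEGORICAL:
        levels = sorted(df[col].astype(str).unique())
        mat = np.column_stack([(df[col].astype(str) == lev).astype(float)
                               for lev in levels[1:]]) if len(levels) > 1 else \
            np.empty((len(df), 0))
        names = [f"{var}[{lev}]" for lev in levels[1:]]
        return mat, names
    return df[col].to_numpy(dtype=float)[:, None], [var]


def _build_design(df: pd.DataFrame, terms: tuple[str, ...]) \
        -> tuple[np.ndarray, dict[str, slice]]:
    """Column-stacked design with intercept first; returns term -> slice."""
    blocks = [np.ones((len(df), 1))]
    slices: dict[str, slice] = {"Intercept": slice(0, 1)}
    pos = 1
    for term in terms:
        parts = term.split(":")
        mat, _ = _term_columns(df, parts[0])
        for p in parts[1:]:
            m2, _ = _term_columns(df, p)
            mat = np.concatenate([mat[:, i:i + 1] * m2
                                  for i in range(mat.shape[1])], axis=1)
        if mat.shape[1] == 0:
            raise ValueError(f"term {term!r} has no variation (single level)")
        blocks.append(mat)
        slices[term] = slice(pos, pos + mat.shape[1])
        pos += mat.shape[1]
    return np.concatenate(blocks, axis=1), slices


# ------------------------------------------------------------------ fitting ---

@dataclass
class LmeFit:
    spec: ModelSpec
    terms: tuple[str, ...]
    X: np.ndarray
    y: np.ndarray
    slices: dict[str, slice]
    groups: np.ndarray | None
    sigma2_u: float
    sigma2_e: float
    fe_params: np.ndarray
    fe_se: np.ndarray
    converged: bool
    singular: bool
    n_subjects: int

    def coef(self, name: str) -> tuple[float, float]:
        """(estimate, standard error) for one design column by term name."""
        sl = self.slices[name]
        if sl.stop - sl.start != 1:
            raise ValueError(f"term {name!r} spans multiple columns")
        return float(self.fe_params[sl.start]), float(self.fe_se[sl.start])


def fit_lme(spec: ModelSpec, data: pd.DataFrame, outcome: str = "p_female",
            include_site: bool = False) -> LmeFit:
    """Maximum-likelihood fit with a subject random intercept."""
    terms = spec.with_site(include_site)
    require_columns(data, [outcome], "analysis data")
    cols = {outcome} | {_VARIABLE_COLUMNS[p] for t in terms for p in t.split(":")}
    if spec.random_intercept:
        cols.add(SUBJECT)
    work = data.dropna(subset=[c for c in cols if c in data.columns])
    dropped = len(data) - len(work)
    if dropped:
        logger.info("%s: dropped %d rows with missing values", spec.id, dropped)
    if len(work) < 3:
        raise ValueError(f"{spec.id}: not enough complete rows ({len(work)})")

    X, slices = _build_design(work, terms)
    y = work[outcome].to_numpy(dtype=float)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        aliased = [t for t, sl in slices.items()
                   if np.linalg.matrix_rank(np.delete(X, range(sl.start, sl.stop), axis=1))
                   == np.linalg.matrix_rank(X)]
        raise ValueError(f"aliased terms in design: {aliased}")

    if not spec.random_intercept:
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        s2 = float(resid @ resid) / max(len(y) - X.shape[1], 1)
        se = np.sqrt(np.diag(np.linalg.pinv(X.T @ X)) * s2)
        return LmeFit(spec=spec, terms=terms, X=X, y=y, slices=slices, groups=None,
                      sigma2_u=0.0, sigma2_e=s2, fe_params=beta, fe_se=se,
                      converged=True, singular=False, n_subjects=len(y))

    groups = work[SUBJECT].to_numpy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = MixedLM(y, X, groups=groups).fit(reml=False)
        if not res.converged:
            res = MixedLM(y, X, groups=groups).fit(reml=False, method="powell")
        # variance components for the F-test denominators come from REML:
        # the ML plug-in is biased low and inflates between-subject F tests
        # when fixed effects are collinear at small n
        res_reml = MixedLM(y, X, groups=groups).fit(reml=True)
        if not res_reml.converged:
            res_reml = res
    sigma2_u = float(np.asarray(res_reml.cov_re)[0, 0])
    sigma2_e = float(res_reml.scale)
    # variance estimates at (or next to) the zero boundary are legitimate
    # singular fits, not convergence failures; optimizers stop slightly off
    # the boundary, so snap tiny ratios to exactly zero
    singular = sigma2_u < 0.02 * sigma2_e
    if singular:
        sigma2_u = 0.0
    if singular:
        warnings.warn(f"{spec.id}: random-intercept variance is near zero", UserWarning)
    if not res.converged and not singular:
        raise RuntimeError(f"{spec.id}: mixed model did not converge "
                           f"(llf={res.llf:.4g}, sigma2_u={sigma2_u:.4g})")
    return LmeFit(spec=spec, terms=terms, X=X, y=y, slices=slices, groups=groups,
                  sigma2_u=sigma2_u, sigma2_e=sigma2_e,
                  fe_params=np.asarray(res.fe_params),
                  fe_se=np.asarray(res.bse_fe), converged=True,
                  singular=singular, n_subjects=len(np.unique(groups)))


# ------------------------------------------------------------------- anova ---

def _whiten(fit: LmeFit) -> tuple[np.ndarray, np.ndarray]:
    """Transform so the error covariance becomes (a multiple of) identity.

    For a compound-symmetry block V = sigma_e^2 I + sigma_u^2 J the inverse
    square root shrinks each block mean by 1 - 1/sqrt(1 + n*theta).
    """
    if fit.groups is None or fit.sigma2_u == 0:
        return fit.X, fit.y
    theta = fit.sigma2_u / fit.sigma2_e
    Xw, yw = fit.X.astype(float).copy(), fit.y.astype(float).copy()
    for g in np.unique(fit.groups):
        m = fit.groups == g
        n_g = int(m.sum())
        c = 1.0 - 1.0 / np.sqrt(1.0 + n_g * theta)
        Xw[m] -= c * Xw[m].mean(axis=0, keepdims=True)
        yw[m] -= c * yw[m].mean()
    return Xw, yw


def _rss(X: np.ndarray, y: np.ndarray) -> float:
    if X.shape[1] == 0:
        return float(y @ y)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


def _is_between(fit: LmeFit, sl: slice) -> bool:
    """True if the term's columns are constant within every subject."""
    if fit.groups is None:
        return False
    block = fit.X[:, sl]
    for g in np.unique(fit.groups):
        sub = block[fit.groups == g]
        if not np.allclose(sub, sub[0], atol=1e-10):
            return False
    return True


def _containment_ddf(fit: LmeFit) -> dict[str, float]:
    """Denominator df per term: between terms against subjects, within
    terms against observations."""
    n, p = fit.X.shape
    if fit.groups is None:
        return {t: float(n - p) for t in fit.terms}
    between = {t: _is_between(fit, fit.slices[t]) for t in fit.terms}
    q_between = sum(fit.slices[t].stop - fit.slices[t].start
                    for t in fit.terms if between[t])
    q_within = sum(fit.slices[t].stop - fit.slices[t].start
                   for t in fit.terms if not between[t])
    n_subj = fit.n_subjects
    ddf_between = max(n_subj - q_between - 1, 1)
    ddf_within = max(n - n_subj - q_within, 1)
    return {t: float(ddf_between if between[t] else ddf_within) for t in fit.terms}


def _f_table(fit: LmeFit, ss: dict[str, float], df_num: dict[str, int]) -> pd.DataFrame:
    Xw, yw = _whiten(fit)
    n, p = Xw.shape
    mse = _rss(Xw, yw) / max(n - p, 1)
    ddf = _containment_ddf(fit)
    rows = []
    for t in fit.terms:
        F = (ss[t] / df_num[t]) / mse if mse > 0 else np.inf
        F = max(F, 0.0)
        pval = float(sps.f.sf(F, df_num[t], ddf[t]))
        rows.append({"term": t, "F": float(F), "num_df": int(df_num[t]),
                     "den_df": ddf[t], "p": pval})
    return pd.DataFrame(rows)


def _term_df(fit: LmeFit, t: str) -> int:
    sl = fit.slices[t]
    return sl.stop - sl.start


def anova_sequential(fit: LmeFit, stratum: dict | None = None) -> AssociationResult:
    """Type I: conditional F-tests in formula order."""
    Xw, yw = _whiten(fit)
    ss, df_num = {}, {}
    cols = list(range(1))          # intercept always first
    rss_prev = _rss(Xw[:, cols], yw)
    for t in fit.terms:
        sl = fit.slices[t]
        cols = cols + list(range(sl.start, sl.stop))
        rss_new = _rss(Xw[:, cols], yw)
        ss[t] = max(rss_prev - rss_new, 0.0)
        df_num[t] = _term_df(fit, t)
        rss_prev = rss_new
    table = _f_table(fit, ss, df_num)
    return AssociationResult(spec_id=fit.spec.id, anova_type="I",
                             stratum=stratum or {}, table=table)


def _contains(inner: str, outer: str) -> bool:
    """True if interaction `outer` contains every factor of `inner`."""
    return inner != outer and set(inner.split(":")) <= set(outer.split(":"))


def anova_marginal(fit: LmeFit, stratum: dict | None = None) -> AssociationResult:
    """Type II: each term tested after all others that do not contain it."""
    Xw, yw = _whiten(fit)
    ss, df_num = {}, {}
    for t in fit.terms:
        exclude = {t} | {o for o in fit.terms if _contains(t, o)}
        base_terms = [o for o in fit.terms if o not in exclude]
        base_cols = [0] + [i for o in base_terms
                           for i in range(fit.slices[o].start, fit.slices[o].stop)]
        with_cols = base_cols + list(range(fit.slices[t].start, fit.slices[t].stop))
        ss[t] = max(_rss(Xw[:, base_cols], yw) - _rss(Xw[:, with_cols], yw), 0.0)
        df_num[t] = _term_df(fit, t)
    table = _f_table(fit, ss, df_num)
    return AssociationResult(spec_id=fit.spec.id, anova_type="II",
                             stratum=stratum or {}, table=table)


def adjust_pvalues(results: list[AssociationResult],
                   alpha: float = 0.05) -> list[AssociationResult]:
    """Benjamini-Hochberg adjustment across all terms of the given family."""
    if not results:
        raise ValueError("empty result family")
    pvals = np.concatenate([r.table["p"].to_numpy() for r in results])
    if np.any((pvals < 0) | (pvals > 1)):
        raise ValueError("p-values outside [0, 1]")
    _, p_adj, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
    offset = 0
    for r in results:
        k = len(r.table)
        r.table = r.table.assign(p_adj=p_adj[offset:offset + k])
        offset += k
    return results


# ------------------------------------------------------------------ driver ---

def run_association(spec_id: str, probs: pd.DataFrame, meta: pd.DataFrame,
                    sex: str, min_site_n: int = 20,
                    include_site: bool | None = None,
                    adjust: bool = True) -> list[AssociationResult]:
    """Join probabilities with covariates, fit per feature set, run both
    ANOVA types and adjust p-values within the family.

    ``meta`` must carry one row per subject-session with the metadata and
    any analysis variable the spec needs; analyses never run on pooled
    sexes.
    """
    if sex not in ("F", "M"):
        raise ValueError("analyses are stratified by sex; pass sex='F' or 'M'")
    spec = MODEL_SPECS[spec_id]
    require_columns(meta, [SUBJECT, SEX], "meta")
    meta_sex = meta[meta[SEX] == sex]
    if meta_sex.empty:
        raise ValueError(f"no rows for sex={sex}")

    join_keys = [SUBJECT, SESSION] if SESSION in probs.columns and SESSION in meta.columns \
        else [SUBJECT]
    results: list[AssociationResult] = []
    for fs in sorted(probs["feature_set"].unique()):
        sub = probs[probs["feature_set"] == fs]
        data = sub.merge(meta_sex, on=join_keys, how="inner")
        lost = 1.0 - len(data) / max(len(meta_sex), 1)
        if lost > 0.5:
            warnings.warn(f"{spec_id}/{fs}: join lost {lost:.0%} of rows "
                          f"({len(data)} of {len(meta_sex)})", UserWarning)
        use_site = include_site
        if spec.id != "age_lm_training" or SITE in data.columns:
            if use_site is None:
                use_site = SITE in data.columns and data[SITE].nunique() > 1
        if use_site:
            data = site_filter(data, min_site_n)
            if data[SITE].nunique() < 2:
                use_site = False
        stratum = {"sex": sex, "feature_set": fs}
        fit = fit_lme(spec, data, include_site=bool(use_site))
        results.append(anova_sequential(fit, stratum))
        results.append(anova_marginal(fit, stratum))

    if adjust:
        for anova_type in ("I", "II"):
            fam = [r for r in results if r.anova_type == anova_type]
            adjust_pvalues(fam)
    return results
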