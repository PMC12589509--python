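"""Synthetic longitudinal morphometric cohorts with known injected effects.

The generator emits (i) a cohort table of per-feature volumes with the
metadata used downstream, (ii) a pubertal-development item table, (iii) a
questionnaire item table driven by a latent distress factor, and (iv) a
hidden-truth record of every injected effect so recovery tests can read the
ground truth.

Generative model for feature ``j`` of subject ``i`` at session ``s``::

    y_ijs = base_j + slope_etiv_j * (eTIV_i - eTIV_ref)
            + sigma_j * [ dir_j * (sex_effect_class + age_slope_sex * age_c
                                   + puberty_effect_class * L_is)
                          + u_ij + shift_site_j + scale_site_j * eps_ijs ]

where ``dir_j`` is a random +/-1 sex-difference direction, ``age_c`` is age
in years centred at the age-range midpoint, ``L_is`` is a latent pubertal
stage (logistic in age with earlier onset in girls), ``u_ij`` a subject
random intercept and ``eps`` i.i.d. noise.  Site shift/scale mimic
additive/multiplicative scanner effects.  eTIV is drawn per sex with a
configurable male/female mean ratio.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import tables as T
from .features import FeaturePartition, make_partition

__all__ = ["GenerativeConfig", "SyntheticTruth", "generate_cohort", "generate_puberty",
           "generate_questionnaire"]


@dataclass
class GenerativeConfig:
    """All knobs of the generative model.  ``seed`` fully determines output."""

    n_subjects: int = 600
    n_sessions: int = 2
    session_gap_months: float = 24.0
    age_range_months: tuple[float, float] = (108.0, 168.0)
    n_sites: int = 4
    site_prefix: str = "site"
    n_features_limbic: int = 20
    n_features_nonlimbic: int = 40
    etiv_male_female_ratio: float = 1.10
    etiv_female_mean_mm3: float = 1_450_000.0
    etiv_cv: float = 0.05
    # standardized (per-feature SD) effect sizes
    sex_effect_sd_units: dict = field(default_factory=lambda: {"limbic": 0.6, "nonlimbic": 0.4})
    age_slope_sd_units_per_year: dict = field(default_factory=lambda: {"F": 0.12, "M": 0.04})
    puberty_effect_sd_units: dict = field(default_factory=lambda: {"limbic": 0.5, "nonlimbic": 0.0})
    site_shift_sd_units: float = 0.3
    site_scale_range: tuple[float, float] = (0.85, 1.15)
    subject_re_sd: float = 0.5
    noise_sd: float = 1.0
    # pubertal timing (latent stage is logistic in age)
    puberty_onset_months: dict = field(default_factory=lambda: {"F": 138.0, "M": 156.0})
    puberty_width_months: float = 15.0
    puberty_onset_jitter_months: float = 12.0
    menarche_threshold: float = 0.6
    pds_item_noise_months: float = 8.0
    # Euler quality proxy: normal with heavy-tail contamination
    euler_mean: float = -50.0
    euler_sd: float = 15.0
    euler_outlier_frac: float = 0.02
    euler_outlier_shift: float = -200.0
    # questionnaire / latent distress
    n_items: int = 12
    item_loading: float = 0.7
    distress_limbic_coupling: float = 0.4
    distress_stability: float = 0.5
    seed: int = 0
    # feature identities (base volume, sex-difference direction, eTIV slope)
    # are drawn from this separate seed so that independently simulated
    # cohorts share the same generative meaning per feature name
    feature_seed: int = 42

    def __post_init__(self) -> None:
        for name in ("n_subjects", "n_sessions", "n_sites", "n_features_limbic",
                     "n_features_nonlimbic", "n_items"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.etiv_male_female_ratio <= 0:
            raise ValueError("etiv_male_female_ratio must be positive")
        lo, hi = self.age_range_months
        if not lo < hi:
            raise ValueError("age_range_months must satisfy min < max")
        for name in ("site_shift_sd_units", "subject_re_sd", "noise_sd",
                     "puberty_onset_jitter_months", "pds_item_noise_months"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not -1.0 <= self.distress_limbic_coupling <= 1.0:
            raise ValueError("distress_limbic_coupling must lie in [-1, 1]")

    @property
    def female_onset_shift_months(self) -> float:
        return self.puberty_onset_months["M"] - self.puberty_onset_months["F"]

    def partition(self) -> FeaturePartition:
        return make_partition(self.n_features_limbic, self.n_features_nonlimbic)


@dataclass
class SyntheticTruth:
    """Ground-truth record of everything the generator injected."""

    config: GenerativeConfig
    feature_names: list[str]
    feature_class: dict
    base: np.ndarray
    sigma: np.ndarray
    direction: np.ndarray          # +/-1 sex-difference direction per feature
    etiv_slope: np.ndarray
    sex_effect: np.ndarray         # per-feature standardized female shift
    puberty_effect: np.ndarray
    site_shift: np.ndarray         # (n_sites, n_features)
    site_scale: np.ndarray
    subject_re: np.ndarray         # (n_subjects, n_features)
    onset_jitter: pd.Series | None = None        # per-subject puberty-timing shift
    latent_puberty: pd.DataFrame | None = None   # subject_id, session, stage
    limbic_proxy: pd.DataFrame | None = None     # subject-level limbic female-likeness
    distress: pd.DataFrame | None = None
    item_loadings: np.ndarray | None = None

    def to_json(self, path: str | Path) -> None:
        def conv(x):
            if isinstance(x, np.ndarray):
                return x.tolist()
            if isinstance(x, pd.DataFrame):
                return x.to_dict(orient="list")
            if isinstance(x, pd.Series):
                return {str(k): float(v) for k, v in x.items()}
            if isinstance(x, GenerativeConfig):
                return asdict(x)
            return x
        payload = {k: conv(v) for k, v in self.__dict__.items()}
        Path(path).write_text(json.dumps(payload, indent=1, default=str))


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _latent_stage(age: np.ndarray, sex: np.ndarray, jitter: np.ndarray,
                  cfg: GenerativeConfig) -> np.ndarray:
    onset = np.where(sex == "F", cfg.puberty_onset_months["F"], cfg.puberty_onset_months["M"])
    return _logistic((age - onset - jitter) / cfg.puberty_width_months)


def generate_cohort(cfg: GenerativeConfig) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Draw a longitudinal cohort table plus the hidden-truth record."""
    rng = np.random.default_rng(cfg.seed)
    n, k = cfg.n_subjects, cfg.n_features_limbic + cfg.n_features_nonlimbic
    part = cfg.partition()
    names = list(part.whole_brain)
    klass = np.array([part.class_of(f) for f in names])

    # subject-level draws
    subj_ids = [f"S{i:05d}" for i in range(1, n + 1)]
    sex = np.array(["F", "M"])[rng.permutation(np.arange(n) % 2)]
    site = rng.integers(0, cfg.n_sites, size=n)
    family = np.array([f"FAM{(i // 2) + 1:05d}" for i in range(n)])
    lo, hi = cfg.age_range_months
    age0 = rng.uniform(lo, hi, size=n)
    etiv_mean = np.where(sex == "F", cfg.etiv_female_mean_mm3,
                         cfg.etiv_female_mean_mm3 * cfg.etiv_male_female_ratio)
    etiv = rng.normal(etiv_mean, cfg.etiv_cv * etiv_mean)
    onset_jitter = rng.normal(0.0, cfg.puberty_onset_jitter_months, size=n)

    euler = rng.normal(cfg.euler_mean, cfg.euler_sd, size=n)
    outl = rng.random(n) < cfg.euler_outlier_frac
    euler = np.where(outl, euler + cfg.euler_outlier_shift, euler)
    euler = np.round(euler).astype(int)

    # feature-level draws: separate seed so cohorts share feature identities
    frng = np.random.default_rng(cfg.feature_seed)
    base = frng.uniform(1500.0, 9000.0, size=k)
    sigma = 0.04 * base
    direction = frng.choice([-1.0, 1.0], size=k)
    etiv_slope = base / cfg.etiv_female_mean_mm3 * frng.uniform(0.5, 1.5, size=k)
    sex_eff = np.array([cfg.sex_effect_sd_units[c] for c in klass])
    pub_eff = np.array([cfg.puberty_effect_sd_units[c] for c in klass])
    site_shift = rng.normal(0.0, cfg.site_shift_sd_units, size=(cfg.n_sites, k))
    site_scale = rng.uniform(*cfg.site_scale_range, size=(cfg.n_sites, k))
    subject_re = rng.normal(0.0, cfg.subject_re_sd, size=(n, k))

    mid = 0.5 * (lo + hi)
    is_f = (sex == "F").astype(float)
    age_slope = np.where(sex == "F", cfg.age_slope_sd_units_per_year["F"],
                         cfg.age_slope_sd_units_per_year["M"])

    rows, stage_rows = [], []
    session_names = [T.BASELINE, T.FOLLOWUP] + [f"session{j}" for j in range(3, cfg.n_sessions + 1)]
    for s_idx in range(cfg.n_sessions):
        gap = s_idx * cfg.session_gap_months
        age = age0 + gap + (rng.uniform(-2.0, 2.0, size=n) if s_idx > 0 else 0.0)
        age = np.maximum(age, age0 + s_idx * 1.0)  # follow-up strictly after baseline
        stage = _latent_stage(age, sex, onset_jitter, cfg)
        age_c = (age - mid) / 12.0

        signal = (direction[None, :] * (sex_eff[None, :] * is_f[:, None]
                                        + age_slope[:, None] * age_c[:, None]
                                        + pub_eff[None, :] * stage[:, None]))
        eps = rng.normal(0.0, cfg.noise_sd, size=(n, k))
        std_part = signal + subject_re + site_shift[site] + site_scale[site] * eps
        Y = base[None, :] + etiv_slope[None, :] * (etiv - cfg.etiv_female_mean_mm3)[:, None] \
            + sigma[None, :] * std_part
        Y = np.maximum(Y, 1.0)  # volumes strictly positive

        df = pd.DataFrame(Y, columns=names)
        df.insert(0, T.SUBJECT, subj_ids)
        df.insert(1, T.SESSION, session_names[s_idx])
        df.insert(2, T.SEX, sex)
        df.insert(3, T.AGE, age)
        df.insert(4, T.ETIV, etiv)
        df.insert(5, T.EULER, euler)
        df.insert(6, T.SITE, [f"{cfg.site_prefix}{s + 1:02d}" for s in site])
        df.insert(7, T.FAMILY, family)
        rows.append(df)
        stage_rows.append(pd.DataFrame({T.SUBJECT: subj_ids, T.SESSION: session_names[s_idx],
                                        "stage": stage, T.AGE: age, T.SEX: sex}))

    cohort = pd.concat(rows, ignore_index=True)
    latent = pd.concat(stage_rows, ignore_index=True)

    # subject-level limbic female-likeness: projection of the stable
    # subject-specific part (random intercepts plus the subject's average
    # pubertal contribution) onto the limbic sex-difference direction
    limbic_idx = np.array([i for i, c in enumerate(klass) if c == "limbic"])
    re_part = (subject_re[:, limbic_idx] * direction[None, limbic_idx]).mean(axis=1)
    stage_mean = latent.groupby(T.SUBJECT, sort=False)["stage"].mean() \
        .reindex(subj_ids).to_numpy()
    pub_part = cfg.puberty_effect_sd_units["limbic"] * stage_mean
    proxy_df = pd.DataFrame({T.SUBJECT: subj_ids, T.SEX: sex,
                             "limbic_proxy": re_part + pub_part})

    truth = SyntheticTruth(
        config=cfg, feature_names=names,
        feature_class={f: c for f, c in zip(names, klass)},
        base=base, sigma=sigma, direction=direction, etiv_slope=etiv_slope,
        sex_effect=sex_eff * direction, puberty_effect=pub_eff * direction,
        site_shift=site_shift, site_scale=site_scale, subject_re=subject_re,
        onset_jitter=pd.Series(onset_jitter, index=subj_ids),
        latent_puberty=latent, limbic_proxy=proxy_df,
    )
    T.check_cohort(cohort)
    return cohort, truth


def generate_puberty(cohort: pd.DataFrame, cfg: GenerativeConfig,
                     truth: SyntheticTruth | None = None) -> pd.DataFrame:
    """Pubertal Development Scale items derived from the latent stage.

    Items 1-4 are 1..4 integers; item 5 is the menstruation question for
    females (No=1 / Yes=4) and an ordinary 1..4 item for males.  Menarche
    never reverts across sessions because the latent stage is monotone in
    age and the per-subject threshold is fixed.
    """
    T.require_columns(cohort, [T.SUBJECT, T.SESSION, T.SEX, T.AGE], "cohort")
    rng = np.random.default_rng(cfg.seed + 1)
    meta = cohort[[T.SUBJECT, T.SESSION, T.SEX, T.AGE]].drop_duplicates([T.SUBJECT, T.SESSION])

    subjects = meta[T.SUBJECT].unique()
    if truth is not None and truth.onset_jitter is not None:
        # reuse the timing shifts injected into the features so PDS shares
        # their variance beyond age
        jitter = truth.onset_jitter.reindex(subjects)
        if jitter.isna().any():
            raise ValueError("truth record does not cover all cohort subjects")
    else:
        jitter = pd.Series(rng.normal(0.0, cfg.puberty_onset_jitter_months, size=len(subjects)),
                           index=subjects)
    thresh = pd.Series(np.clip(rng.normal(cfg.menarche_threshold, 0.05, size=len(subjects)),
                               0.05, 0.95), index=subjects)

    age = meta[T.AGE].to_numpy(dtype=float)
    sex = meta[T.SEX].to_numpy()
    jit = jitter.loc[meta[T.SUBJECT]].to_numpy()

    out = meta[[T.SUBJECT, T.SESSION, T.SEX]].copy()
    n_rows = len(meta)
    item_stages = []
    for item in range(1, 5):
        eta = rng.normal(0.0, cfg.pds_item_noise_months, size=n_rows)
        stage_k = _logistic((age - np.where(sex == "F", cfg.puberty_onset_months["F"],
                                            cfg.puberty_onset_months["M"]) - jit + eta)
                            / cfg.puberty_width_months)
        out[f"p{item}"] = (1 + np.round(3 * stage_k)).astype(int)
        item_stages.append(stage_k)

    stage = _latent_stage(age, sex, jit, cfg)
    menarche = np.where(stage > thresh.loc[meta[T.SUBJECT]].to_numpy(), "yes", "no")
    # males: item 5 is a regular developmental item
    eta5 = rng.normal(0.0, cfg.pds_item_noise_months, size=n_rows)
    stage5 = _logistic((age - cfg.puberty_onset_months["M"] - jit + eta5)
                       / cfg.puberty_width_months)
    p5_m = (1 + np.round(3 * stage5)).astype(int)
    p5 = np.where(sex == "F", np.where(menarche == "yes", 4, 1), p5_m)
    out["p5"] = p5.astype(int)
    out["menarche"] = np.where(sex == "F", menarche, "")
    out["reporter"] = "self"

    items = out[["p1", "p2", "p3", "p4", "p5"]].to_numpy(dtype=float)
    out["average_score"] = items.mean(axis=1)
    return out.reset_index(drop=True)


def generate_questionnaire(cohort: pd.DataFrame, proxy: pd.DataFrame,
                           cfg: GenerativeConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Questionnaire items loading on a latent distress factor.

    ``proxy`` maps subject_id to a limbic female-likeness value (e.g. the
    hidden-truth proxy or a classifier probability).  In females, latent
    distress correlates with the standardized proxy at
    ``cfg.distress_limbic_coupling``; in males the coupling is zero.
    Returns (items table, hidden distress table).
    """
    T.require_columns(cohort, [T.SUBJECT, T.SESSION, T.SEX], "cohort")
    T.require_columns(proxy, [T.SUBJECT, "limbic_proxy"], "proxy")
    c = cfg.distress_limbic_coupling
    if not -1.0 <= c <= 1.0:
        raise ValueError("coupling must lie in [-1, 1]")
    rng = np.random.default_rng(cfg.seed + 2)

    subj = cohort[[T.SUBJECT, T.SEX]].drop_duplicates(T.SUBJECT).merge(
        proxy[[T.SUBJECT, "limbic_proxy"]], on=T.SUBJECT)
    z = np.zeros(len(subj))
    for s in ("F", "M"):
        m = (subj[T.SEX] == s).to_numpy()
        if m.sum() > 1:
            v = subj.loc[m, "limbic_proxy"].to_numpy(dtype=float)
            z[m] = (v - v.mean()) / (v.std() or 1.0)
    coupling = np.where(subj[T.SEX].to_numpy() == "F", c, 0.0)
    base_d = coupling * z + np.sqrt(1.0 - coupling**2) * rng.normal(size=len(subj))

    sessions = list(cohort[T.SESSION].drop_duplicates())
    st = cfg.distress_stability
    distress_by_session = {sessions[0]: base_d}
    prev = base_d
    for ses in sessions[1:]:
        nxt = st * prev + np.sqrt(1.0 - st**2) * rng.normal(size=len(subj))
        distress_by_session[ses] = nxt
        prev = nxt

    loadings = np.full(cfg.n_items, cfg.item_loading)
    item_sd = np.sqrt(np.clip(1.0 - cfg.item_loading**2, 1e-12, None))
    item_rows, truth_rows = [], []
    for ses in sessions:
        d = distress_by_session[ses]
        items = d[:, None] * loadings[None, :] + rng.normal(0.0, item_sd,
                                                            size=(len(subj), cfg.n_items))
        df = pd.DataFrame(items, columns=[f"item_{k + 1}" for k in range(cfg.n_items)])
        df.insert(0, T.SUBJECT, subj[T.SUBJECT].to_numpy())
        df.insert(1, T.SESSION, ses)
        item_rows.append(df)
        truth_rows.append(pd.DataFrame({T.SUBJECT: subj[T.SUBJECT], T.SESSION: ses,
                                        "latent_distress": d}))
    return (pd.concat(item_rows, ignore_index=True),
            pd.concat(truth_rows, ignore_index=True))
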