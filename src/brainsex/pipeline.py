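"""End-to-end study replica on synthetic cohorts.

simulate -> harmonize -> QC -> match -> residualize -> train three models
(limbic / non-limbic / whole brain) -> predict longitudinally -> run the
four association batteries -> mental-health scoring -> report.

The training cohort is cross-sectional and the validation cohort is an
independently simulated two-session cohort with its own sites and age
range, so external validation is genuinely out of distribution.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import tables as T
from .classifier import TrainedSexModel, TrainingParams, predict, roc_auc, \
    train_nested_cv, feature_importance
from .features import FEATURE_SETS, FeaturePartition, residualize_etiv, select_features
from .harmonization import CROSS_SECTIONAL, LONGITUDINAL, apply_combat, fit_combat
from .longitudinal import MENARCHE_EXCLUDED, MODEL_SPECS, AssociationResult, \
    menarche_groups, results_frame, run_association
from .mental import fit_pc1, project, session_correlation
from .prep import MatchSpec, MatchedSample, balance_check, euler_qc, match_pairs
from .synthetic import GenerativeConfig, generate_cohort, generate_puberty, \
    generate_questionnaire

logger = logging.getLogger(__name__)

_TUPLE_FIELDS = {"age_range_months", "site_scale_range"}


def _to_dict(obj) -> dict:
    d = dataclasses.asdict(obj)
    return {k: (list(v) if isinstance(v, tuple) else v) for k, v in d.items()}


def _from_dict(cls, d: dict):
    d = dict(d)
    for k in _TUPLE_FIELDS & set(d):
        d[k] = tuple(d[k])
    return cls(**d)


@dataclass
class RunConfig:
    """One seed and one config govern the whole run."""

    train: GenerativeConfig = field(default_factory=lambda: GenerativeConfig(
        n_subjects=800, n_sessions=1, age_range_months=(96.0, 264.0), n_sites=5,
        site_prefix="tsite"))
    validation: GenerativeConfig = field(default_factory=lambda: GenerativeConfig(
        n_subjects=600, n_sessions=2, age_range_months=(108.0, 168.0), n_sites=4,
        site_prefix="vsite"))
    match: MatchSpec = field(default_factory=MatchSpec)
    # desk-scale boosting settings; the full-scale defaults (eta=0.01,
    # 1000 rounds) live in TrainingParams itself
    training: TrainingParams = field(default_factory=lambda: TrainingParams(
        learning_rate=0.05, initial_rounds=150, inner_folds=3, max_depth=2,
        max_features="sqrt"))
    min_site_n: int = 20
    run_associations: bool = True
    run_mental_health: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.train.n_features_limbic != self.validation.n_features_limbic
                or self.train.n_features_nonlimbic != self.validation.n_features_nonlimbic):
            raise ValueError("training and validation cohorts must share the feature registry")

    def reseed(self, seed: int) -> "RunConfig":
        return dataclasses.replace(
            self, seed=seed,
            train=dataclasses.replace(self.train, seed=seed),
            validation=dataclasses.replace(self.validation, seed=seed + 10_000),
            training=dataclasses.replace(self.training, seed=seed),
            match=dataclasses.replace(self.match, seed=seed),
        )

    def to_yaml(self, path: str | Path) -> None:
        payload = {
            "train": _to_dict(self.train),
            "validation": _to_dict(self.validation),
            "match": _to_dict(self.match),
            "training": _to_dict(self.training),
            "min_site_n": self.min_site_n,
            "run_associations": self.run_associations,
            "run_mental_health": self.run_mental_health,
            "seed": self.seed,
        }
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text())
        return cls(
            train=_from_dict(GenerativeConfig, payload["train"]),
            validation=_from_dict(GenerativeConfig, payload["validation"]),
            match=_from_dict(MatchSpec, payload["match"]),
            training=_from_dict(TrainingParams, payload["training"]),
            min_site_n=payload.get("min_site_n", 20),
            run_associations=payload.get("run_associations", True),
            run_mental_health=payload.get("run_mental_health", True),
            seed=payload.get("seed", 0),
        )


@dataclass
class RunResult:
    out_dir: Path
    matched: MatchedSample
    models: dict[str, TrainedSexModel]
    cv_auc: dict[str, float]
    validation_auc: pd.DataFrame          # feature_set, session, auc
    training_probs: pd.DataFrame
    validation_probs: pd.DataFrame
    associations: pd.DataFrame | None
    mental_health: dict | None
    importances: dict[str, pd.DataFrame]


def _stage(name: str, t0: float, n_in: int, n_out: int) -> None:
    logger.info("stage=%s elapsed=%.1fs rows_in=%d rows_out=%d",
                name, time.time() - t0, n_in, n_out)


def run_full(config: RunConfig, out_dir: str | Path) -> RunResult:
    """Execute every stage and persist all intermediates under ``out_dir``."""
    out = Path(out_dir)
    for sub in ("tables", "models", "results"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    part = config.train.partition()

    stage = "simulate_training"
    try:
        t0 = time.time()
        train_raw, train_truth = generate_cohort(config.train)
        train_raw.to_csv(out / "tables" / "train_cohort.csv", index=False)
        train_truth.to_json(out / "tables" / "train_truth.json")
        _stage(stage, t0, 0, len(train_raw))

        stage = "harmonize_training"
        t0 = time.time()
        combat_train = fit_combat(train_raw, [T.SEX, T.AGE], CROSS_SECTIONAL)
        train_h = apply_combat(combat_train, train_raw)
        combat_train.to_json(out / "models" / "combat_training.json")
        _stage(stage, t0, len(train_raw), len(train_h))

        stage = "qc_match"
        t0 = time.time()
        train_qc, excluded = euler_qc(train_h)
        matched = match_pairs(train_qc, config.match)
        matched.validate()
        matched.pairs.to_csv(out / "tables" / "matched_pairs.csv", index=False)
        balance = balance_check(matched)
        balance.to_csv(out / "tables" / "balance.csv", index=False)
        _stage(stage, t0, len(train_h), len(matched.cohort))

        stage = "residualize_training"
        t0 = time.time()
        train_resid, resid_model = residualize_etiv(matched.cohort, fit_cohort="training")
        resid_model.to_frame().to_csv(out / "models" / "residualization_training.csv",
                                      index=False)
        _stage(stage, t0, len(matched.cohort), len(train_resid))

        stage = "train_models"
        t0 = time.time()
        models: dict[str, TrainedSexModel] = {}
        cv_auc: dict[str, float] = {}
        oof_tables = []
        importances: dict[str, pd.DataFrame] = {}
        for fs in FEATURE_SETS:
            feats = list(part.set_names(fs))
            model, oof = train_nested_cv(train_resid, feats, config.training, feature_set=fs)
            models[fs] = model
            cv_auc[fs] = model.cv_auc
            oof_tables.append(oof)
            model.save_metadata(out / "models" / f"sex_model_{fs}.json")
            imp = feature_importance(model)
            importances[fs] = imp
            imp.to_csv(out / "results" / f"importance_{fs}.csv", index=False)
        training_probs = pd.concat(oof_tables, ignore_index=True)
        training_probs.to_csv(out / "tables" / "probs_training_oof.csv", index=False)
        _stage(stage, t0, len(train_resid), len(training_probs))

        stage = "simulate_validation"
        t0 = time.time()
        val_raw, val_truth = generate_cohort(config.validation)
        val_raw.to_csv(out / "tables" / "validation_cohort.csv", index=False)
        val_truth.to_json(out / "tables" / "validation_truth.json")
        _stage(stage, t0, 0, len(val_raw))

        stage = "harmonize_validation"
        t0 = time.time()
        combat_val = fit_combat(val_raw, [T.SEX, T.AGE], LONGITUDINAL)
        val_h = apply_combat(combat_val, val_raw)
        combat_val.to_json(out / "models" / "combat_validation.json")
        val_qc, _ = euler_qc(val_h)
        # residualization refit per cohort on pooled sessions
        val_resid, _ = residualize_etiv(val_qc, fit_cohort="validation")
        _stage(stage, t0, len(val_raw), len(val_resid))

        stage = "predict_validation"
        t0 = time.time()
        val_prob_tables = []
        auc_rows = []
        for fs in FEATURE_SETS:
            probs = predict(models[fs], val_resid)
            probs = probs.merge(val_resid[[T.SUBJECT, T.SESSION, T.SEX]],
                                on=[T.SUBJECT, T.SESSION])
            val_prob_tables.append(probs)
            for ses in sorted(val_resid[T.SESSION].unique()):
                m = probs[T.SESSION] == ses
                auc_rows.append({"feature_set": fs, "session": ses,
                                 "auc": roc_auc(probs.loc[m, "p_female"],
                                                (probs.loc[m, T.SEX] == "F").astype(int))})
        validation_probs = pd.concat(val_prob_tables, ignore_index=True)
        validation_probs.to_csv(out / "tables" / "probs_validation.csv", index=False)
        validation_auc = pd.DataFrame(auc_rows)
        validation_auc.to_csv(out / "results" / "validation_auc.csv", index=False)
        _stage(stage, t0, len(val_resid), len(validation_probs))

        stage = "puberty_questionnaire"
        t0 = time.time()
        puberty = generate_puberty(val_raw, config.validation, val_truth)
        puberty.to_csv(out / "tables" / "puberty.csv", index=False)
        items, distress = generate_questionnaire(val_raw, val_truth.limbic_proxy,
                                                 config.validation)
        items.to_csv(out / "tables" / "questionnaire_items.csv", index=False)
        distress.to_csv(out / "tables" / "latent_distress.csv", index=False)
        _stage(stage, t0, len(val_raw), len(puberty))

        associations = None
        mh_summary = None
        if config.run_associations:
            stage = "associations"
            t0 = time.time()
            meta = val_resid[[T.SUBJECT, T.SESSION, T.SEX, T.AGE, T.EULER, T.SITE]].copy()
            meta = meta.merge(puberty[[T.SUBJECT, T.SESSION, "average_score"]]
                              .rename(columns={"average_score": "pds_average"}),
                              on=[T.SUBJECT, T.SESSION], how="left")
            groups = menarche_groups(puberty)
            meta = meta.merge(groups[[T.SUBJECT, "menarche_group"]], on=T.SUBJECT, how="left")
            meta.loc[meta["menarche_group"] == MENARCHE_EXCLUDED, "menarche_group"] = np.nan

            all_results: list[AssociationResult] = []
            probs = validation_probs
            for sex in ("F", "M"):
                all_results += run_association("age_lme", probs, meta, sex,
                                               min_site_n=config.min_site_n)
                all_results += run_association("pds_lme", probs, meta, sex,
                                               min_site_n=config.min_site_n)
            all_results += run_association("menarche_lme", probs, meta, "F",
                                           min_site_n=config.min_site_n)

            if config.run_mental_health:
                stage = "mental_health"
                base_items = items[items[T.SESSION] == T.BASELINE].drop(columns=[T.SESSION])
                pc_model, base_scores = fit_pc1(base_items)
                pc_model.to_json(out / "models" / "pc_model.json")
                fup_items = items[items[T.SESSION] == T.FOLLOWUP]
                fup_scores = project(pc_model, fup_items)
                corr = session_correlation(base_scores, fup_scores[[T.SUBJECT, "mh_score"]])
                mh_summary = {"explained_variance": pc_model.explained_variance, **corr}
                (out / "results" / "mental_health.json").write_text(
                    json.dumps(mh_summary, indent=1))
                scores = pd.concat([base_scores.assign(**{T.SESSION: T.BASELINE}),
                                    fup_scores], ignore_index=True)
                scores.to_csv(out / "tables" / "mh_scores.csv", index=False)
                meta = meta.merge(scores, on=[T.SUBJECT, T.SESSION], how="left")
                for sex in ("F", "M"):
                    all_results += run_association("mh_lme", probs, meta, sex,
                                                   min_site_n=config.min_site_n)

            associations = results_frame(all_results)
            associations.to_csv(out / "results" / "associations.csv", index=False)
            _stage("associations", t0, len(meta), len(associations))

        stage = "report"
        _write_report(out, cv_auc, validation_auc, associations, mh_summary, matched)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    return RunResult(out_dir=out, matched=matched, models=models, cv_auc=cv_auc,
                     validation_auc=validation_auc, training_probs=training_probs,
                     validation_probs=validation_probs, associations=associations,
                     mental_health=mh_summary, importances=importances)


def _write_report(out: Path, cv_auc: dict, validation_auc: pd.DataFrame,
                  associations: pd.DataFrame | None, mh: dict | None,
                  matched: MatchedSample) -> None:
    lines = ["# Brain-sex pipeline report", ""]
    lines.append(f"Matched training sample: {len(matched.cohort)} subjects "
                 f"({len(matched.pairs)} pairs, "
                 f"{len(matched.unmatched_reference)} unmatched reference subjects)")
    lines.append("")
    lines.append("## Cross-validated training AUC")
    for fs, a in cv_auc.items():
        lines.append(f"- {fs}: {a:.3f}")
    lines.append("")
    lines.append("## Validation AUC per session")
    lines.append(validation_auc.to_string(index=False))
    if associations is not None:
        lines.append("")
        lines.append("## Association F statistics (first term per model)")
        first = associations.groupby(["spec_id", "anova_type", "sex", "feature_set"],
                                     sort=True).head(1)
        lines.append(first.to_string(index=False))
    if mh is not None:
        lines.append("")
        lines.append("## Mental-health scoring")
        lines.append(f"PC1 explained variance: {mh['explained_variance']:.3f}; "
                     f"baseline-followup r = {mh['r']:.3f} "
                     f"(t = {mh['t']:.2f}, p = {mh['p']:.3g}, n = {mh['n']})")
    (out / "report.md").write_text("\n".join(lines) + "\n")
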