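"""Column conventions for cohort tables.

Every cohort table is a long-format :class:`pandas.DataFrame` with one row
per subject-session, a fixed set of metadata columns, and one numeric column
per named brain feature (volumes in mm^3, or residuals thereof).
"""

from __future__ import annotations

import pandas as pd

SUBJECT = "subject_id"
SESSION = "session"
SEX = "sex"
AGE = "age_months"
ETIV = "etiv_mm3"
EULER = "euler"
SITE = "site_id"
FAMILY = "family_id"

BASELINE = "baseline"
FOLLOWUP = "followup"

METADATA_COLS = [SUBJECT, SESSION, SEX, AGE, ETIV, EULER, SITE, FAMILY]


def feature_columns(df: pd.DataFrame) -> list[str]:
    """All non-metadata columns, in table order."""
    return [c for c in df.columns if c not in METADATA_COLS]


def require_columns(df: pd.DataFrame, cols: list[str], context: str = "") -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        where = f" in {context}" if context else ""
        raise ValueError(f"missing required columns{where}: {missing}")


def check_cohort(df: pd.DataFrame) -> None:
    """Validate the structural invariants of a cohort table."""
    require_columns(df, [SUBJECT, SESSION, SEX, AGE, ETIV, EULER, SITE], "cohort")
    dup = df.duplicated([SUBJECT, SESSION])
    if dup.any():
        raise ValueError(
            f"duplicate (subject_id, session) rows: "
            f"{df.loc[dup, [SUBJECT, SESSION]].values.tolist()[:5]}"
        )
    bad_sex = set(df[SEX].unique()) - {"F", "M"}
    if bad_sex:
        raise ValueError(f"sex column must be 'F' or 'M', got {sorted(bad_sex)}")
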