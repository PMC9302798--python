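"""ADA-based classification of glycemic records into resolved state histories.

Measurement bands (ADA):

=========  ==================  ==================
kind       prediabetes         diabetes
=========  ==================  ==================
FPG        [5.6, 7.0) mmol/L   >= 7.0 mmol/L
HbA1c      [39, 48) mmol/mol   >= 48 mmol/mol
OGTT2h     [7.8, 11.1) mmol/L  >= 11.1 mmol/L
RPG        never               never (on its own)
=========  ==================  ==================

Diabetes is additionally established by a clinician diagnosis code, a
prescription of a non-insulin glucose-lowering drug, or a continuous insulin
episode of at least 28 days. States never revert: once prediabetic (or
diabetic), always so; severity ties at the same age resolve to the more
severe state. Onsets are binned to the integer age containing them, matching
the one-year cycle of the downstream Markov chain.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .states import State

# ADA thresholds
FPG_PRE, FPG_DM = 5.6, 7.0            # mmol/L
HBA1C_PRE, HBA1C_DM = 39.0, 48.0      # mmol/mol
OGTT_PRE, OGTT_DM = 7.8, 11.1         # mmol/L
INSULIN_MIN_DAYS = 28
GESTATION_WINDOW = (24, 40)           # weeks; measurements inside are excluded

MEASUREMENT_KINDS = ("FPG", "HbA1c", "OGTT2h", "RPG")
FLAG_KINDS = ("dx_code", "noninsulin_drug", "insulin_episode", "death")

_THRESHOLDS = {"FPG": (FPG_PRE, FPG_DM), "HbA1c": (HBA1C_PRE, HBA1C_DM),
               "OGTT2h": (OGTT_PRE, OGTT_DM)}

PREDIABETES_DEFINITIONS = {
    "any": ("FPG", "HbA1c", "OGTT2h"),
    "fpg_only": ("FPG",),
    "hba1c_only": ("HbA1c",),
}

HISTORY_COLUMNS = [
    "person_id", "sex", "birth_year", "entry_age", "pre_onset_age",
    "dm_onset_age", "death_age", "censor_age", "linkage_end_age",
    "n_measurements", "followup_years",
]


def classify_measurement(kind: str, value: float) -> State:
    """Classify a single glycemic measurement into NORMO / PRE / DM.

    Random plasma glucose is accepted but never classifies beyond NORMO on
    its own. Raises ``ValueError`` for unknown kinds or invalid values.
    """
    if kind not in MEASUREMENT_KINDS:
        raise ValueError(f"unknown measurement kind: {kind!r}")
    value = float(value)
    if not np.isfinite(value) or value < 0:
        raise ValueError(f"invalid measurement value: {value!r}")
    if kind == "RPG":
        return State.NORMO
    pre, dm = _THRESHOLDS[kind]
    if value >= dm:
        return State.DM
    if value >= pre:
        return State.PRE
    return State.NORMO


def apply_exclusions(records: pd.DataFrame) -> pd.DataFrame:
    """Drop inpatient FPG records and any glycemic measurement taken in
    gestational weeks 24-40 (stress and gestational hyperglycemia guards).

    Other records pass through unchanged, order preserved; absent flags are
    treated as false/absent. Idempotent.
    """
    kind = records["record_kind"]
    inpatient = records.get("inpatient")
    inpatient = (inpatient.fillna(False).astype(bool)
                 if inpatient is not None else pd.Series(False, index=records.index))
    gest = records.get("gestational_week")
    gest = (pd.to_numeric(gest, errors="coerce")
            if gest is not None else pd.Series(np.nan, index=records.index))
    is_meas = kind.isin(MEASUREMENT_KINDS)
    drop = (is_meas & (kind == "FPG") & inpatient) | (
        is_meas & gest.between(*GESTATION_WINDOW)
    )
    return records.loc[~drop]


def _measurement_states(records: pd.DataFrame) -> np.ndarray:
    """Vectorized band classification; non-measurement rows get NORMO."""
    kind = records["record_kind"].to_numpy()
    if "value" in records.columns:
        value = pd.to_numeric(records["value"], errors="coerce").to_numpy(float)
    else:
        value = np.full(len(records), np.nan)
    out = np.zeros(len(records), dtype=np.int8)
    for k, (pre, dm) in _THRESHOLDS.items():
        mask = kind == k
        out[mask & (value >= pre)] = State.PRE
        out[mask & (value >= dm)] = State.DM
    return out


def resolve_state_histories(
    records: pd.DataFrame,
    prediabetes_definition: str = "any",
    linkage_end_year: int | None = None,
) -> pd.DataFrame:
    """Resolve raw (pre-filtered) records into one history row per person.

    ``linkage_end_year`` is the last calendar year with complete vital-status
    linkage (the registry's closing year). It yields a ``linkage_end_age``
    per person (``linkage_end_year - birth_year``, a conservative whole-years
    bound) through which survival is known even without further glycemic
    encounters; downstream mortality estimation is unbiased only when this is
    supplied. Left as NaN when unknown.

    Returns a DataFrame with :data:`HISTORY_COLUMNS`: entry age (first
    glycemic measurement), onset ages of prediabetes and diabetes (NaN if
    never), death age, censor age (last glycemic measurement), measurement
    count and follow-up span. Onset ages follow the right-endpoint
    convention: the age of the first qualifying record. A prediabetes onset
    at or after the diabetes onset is discarded (severity never reverts, so
    such evidence is moot). The choice of ``prediabetes_definition`` (``any``,
    ``fpg_only``, ``hba1c_only``) affects prediabetes onsets only, never the
    diabetes onset.

    Persons with no glycemic measurement after exclusions are dropped (the
    registry's inclusion criterion is at least one measurement).
    """
    if prediabetes_definition not in PREDIABETES_DEFINITIONS:
        raise ValueError(f"unknown prediabetes definition: {prediabetes_definition!r}")
    if len(records) == 0:
        raise ValueError("empty record set")
    pre_kinds = PREDIABETES_DEFINITIONS[prediabetes_definition]

    kind = records["record_kind"].to_numpy()
    age = pd.to_numeric(records["event_age"], errors="coerce").to_numpy(float)
    if np.any(~np.isfinite(age)) or np.any(age < 0):
        raise ValueError("event_age must be finite and non-negative")
    states = _measurement_states(records)

    if "insulin_days" in records.columns:
        insulin_days = pd.to_numeric(
            records["insulin_days"], errors="coerce"
        ).to_numpy(float)
    else:
        insulin_days = np.full(len(records), np.nan)

    is_meas = np.isin(kind, MEASUREMENT_KINDS)
    dm_evidence = (
        (states == State.DM)
        | (kind == "dx_code")
        | (kind == "noninsulin_drug")
        | ((kind == "insulin_episode") & (insulin_days >= INSULIN_MIN_DAYS))
    )
    pre_evidence = (states == State.PRE) & np.isin(kind, pre_kinds)
    is_death = kind == "death"

    df = pd.DataFrame(
        {
            "person_id": records["person_id"].to_numpy(),
            "age": age,
            "meas_age": np.where(is_meas, age, np.nan),
            # any living-state encounter (measurement or clinical flag) keeps
            # the person under observation; death records do not
            "alive_age": np.where(~is_death, age, np.nan),
            "dm_age": np.where(dm_evidence, age, np.nan),
            "pre_age": np.where(pre_evidence, age, np.nan),
            "death_age": np.where(is_death, age, np.nan),
        }
    )
    grouped = df.groupby("person_id", sort=True)
    hist = grouped.agg(
        entry_age=("meas_age", "min"),
        censor_age=("alive_age", "max"),
        n_measurements=("meas_age", "count"),
        dm_onset_age=("dm_age", "min"),
        pre_onset_age=("pre_age", "min"),
        death_age=("death_age", "min"),
        n_deaths=("death_age", "count"),
    )
    if (hist["n_deaths"] > 1).any():
        bad = hist.index[hist["n_deaths"] > 1][:5].tolist()
        raise ValueError(f"multiple death records for persons: {bad}")
    hist = hist.drop(columns="n_deaths")

    # prediabetes evidence at/after the diabetes onset never counts
    moot = hist["pre_onset_age"] >= hist["dm_onset_age"]
    hist.loc[moot.fillna(False), "pre_onset_age"] = np.nan

    hist = hist[hist["n_measurements"] > 0].copy()
    hist["followup_years"] = hist["censor_age"] - hist["entry_age"]

    meta_cols = [c for c in ("sex", "birth_year") if c in records.columns]
    if meta_cols:
        meta = records.drop_duplicates("person_id").set_index("person_id")[meta_cols]
        hist = hist.join(meta)
    else:
        hist["sex"] = "U"
        hist["birth_year"] = np.nan
    if linkage_end_year is not None:
        hist["linkage_end_age"] = float(linkage_end_year) - hist["birth_year"].astype(float)
    else:
        hist["linkage_end_age"] = np.nan
    hist = hist.reset_index()
    return hist[HISTORY_COLUMNS]


def resolve_state_history(
    records: pd.DataFrame, prediabetes_definition: str = "any"
) -> pd.Series:
    """Single-person variant of :func:`resolve_state_histories`."""
    if records["person_id"].nunique() > 1:
        raise ValueError("records belong to more than one person")
    out = resolve_state_histories(records, prediabetes_definition)
    return out.iloc[0]


def filter_cohort(
    histories: pd.DataFrame, min_followup: float = 0.0, min_entry_age: float = 0.0
) -> pd.DataFrame:
    """Keep histories with at least ``min_followup`` years of observation and
    entry at or after ``min_entry_age`` (the sensitivity-analysis filters)."""
    if min_followup < 0 or min_entry_age < 0:
        raise ValueError("thresholds must be non-negative")
    keep = (histories["followup_years"] >= min_followup) & (
        histories["entry_age"] >= min_entry_age
    )
    return histories.loc[keep]


def annual_states(history: pd.Series, max_age: int = 110) -> pd.DataFrame:
    """Expand one history into its annual state sequence.

    Ages run from ``floor(entry_age)`` to the last determinable age; the state
    at integer age ``a`` is the most severe state whose onset falls in an age
    year at or before ``a`` (death uses exact age: dead at ``a`` when
    ``a >= death_age``).
    """
    entry = int(np.floor(history["entry_age"]))
    death = history.get("death_age", np.nan)
    censor = history["censor_age"]
    last = int(np.ceil(death)) if np.isfinite(death) else int(np.floor(censor))
    ages = np.arange(entry, last + 1)
    return pd.DataFrame({
        "age": ages,
        "state": [State(s).name for s in _states_at(history, ages)],
    })


def _states_at(history: pd.Series, ages: np.ndarray) -> np.ndarray:
    pre = history.get("pre_onset_age", np.nan)
    dm = history.get("dm_onset_age", np.nan)
    death = history.get("death_age", np.nan)
    out = np.zeros(len(ages), dtype=np.int8)
    if np.isfinite(pre):
        out[ages >= np.floor(pre)] = State.PRE
    if np.isfinite(dm):
        out[ages >= np.floor(dm)] = State.DM
    if np.isfinite(death):
        out[ages >= death] = State.DEATH
    return out
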