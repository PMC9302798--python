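"""Synthetic EMR-style glycemic surveillance registry.

The generator separates a *latent* process from an *observation* process:

1. every person's annual trajectory through normoglycemia, prediabetes,
   diabetes and death is simulated exactly from a known ground-truth
   transition table (per sex), from age 0;
2. an opportunistic testing process overlays irregular glycemic measurements
   (FPG / HbA1c / 2h-OGTT / random glucose), clinical flags (diagnosis codes,
   glucose-lowering drugs, insulin episodes), inpatient and gestational
   records, administrative and random censoring, and death records.

Measurement values are drawn uniformly *within* the ADA band of the latent
state at the test age, so classification recovers the latent state without
misclassification and downstream estimators can be tested for parameter
recovery against the generating table. A ``dense_testing`` mode places one
measurement at every integer age under observation, removing detection delay
entirely; the default opportunistic mode reproduces registry features such as
a large fraction of persons with a single measurement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .states import MAX_AGE, State
from .transitions import TransitionTable

REGISTRY_COLUMNS = [
    "person_id", "sex", "birth_year", "event_age", "record_kind", "value",
    "inpatient", "gestational_week", "insulin_days",
]

#: value bands (uniform draws) per measurement kind and latent state
_VALUE_BANDS = {
    "FPG": {State.NORMO: (3.9, 5.6), State.PRE: (5.6, 7.0), State.DM: (7.0, 15.0)},
    "HbA1c": {State.NORMO: (25.0, 39.0), State.PRE: (39.0, 48.0), State.DM: (48.0, 110.0)},
    "OGTT2h": {State.NORMO: (4.0, 7.8), State.PRE: (7.8, 11.1), State.DM: (11.1, 25.0)},
    "RPG": {State.NORMO: (4.0, 7.5), State.PRE: (4.5, 10.0), State.DM: (6.0, 20.0)},
}

FERTILE_AGES = (15.0, 49.0)


def default_truth_table(sex: str = "pooled", max_age: int = MAX_AGE) -> TransitionTable:
    """A plausible urban East-Asian illness-death schedule, used as the
    default generating truth.

    Mortality is Gompertz-Makeham with a modest excess for prediabetes and a
    larger one for diabetes; progression hazards rise with age through midlife.
    Women face lower mortality than men with the same glycemic progression,
    which is what drives their higher lifetime risk downstream.
    """
    age = np.arange(max_age + 1, dtype=float)

    def logistic(x: np.ndarray) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-x))

    mult = {"F": 0.78, "M": 1.22, "pooled": 1.0}[sex]
    q_base = np.clip(mult * (3e-4 + 2e-5 * np.exp(0.09 * age)), 0.0, 0.7)
    normo_pre = 0.002 + 0.030 * logistic((age - 45.0) / 12.0)
    normo_dm = 0.002 + 0.004 * logistic((age - 50.0) / 10.0)
    pre_dm = 0.018 + 0.028 * logistic((age - 55.0) / 15.0)
    return TransitionTable.from_hazards(
        normo_pre=normo_pre,
        normo_dm=normo_dm,
        pre_dm=pre_dm,
        death_normo=q_base,
        death_pre=np.clip(1.1 * q_base, 0, 0.8),
        death_dm=np.clip(1.8 * q_base, 0, 0.9),
        sex=sex,
        max_age=max_age,
    )


@dataclass
class GeneratorConfig:
    """Study conditions for one synthetic registry draw.

    Defaults emulate the surveillance registry the pipeline is designed for:
    entry at arbitrary ages over a 2001-2019 window, 21.2% of persons with a
    single glycemic measurement, a measurement mix in which the 2-hour OGTT is
    rare (1.4%), inpatient and gestational contamination, right censoring, and
    death linkage.
    """

    n_persons: int = 50_000
    seed: int = 0
    max_age: int = MAX_AGE
    sex_ratio_female: float = 0.542
    entry_age_distribution: tuple = ("uniform", 0.0, 90.0)
    truth_transitions: Mapping[str, TransitionTable] | TransitionTable | None = None
    mean_tests_per_year: float = 0.9
    single_test_fraction: float = 0.212
    measurement_type_mix: Mapping[str, float] = field(
        default_factory=lambda: {"FPG": 0.62, "HbA1c": 0.316, "OGTT2h": 0.014, "RPG": 0.05}
    )
    inpatient_fraction: float = 0.03
    gestational_fraction: float = 0.02
    #: per-year probability of loss to follow-up beyond the administrative
    #: window. Default 0: death linkage in a territory-wide registry is
    #: complete and net migration is negligible; positive values are for
    #: sensitivity work only (they violate the estimator's complete-linkage
    #: assumption for the death column).
    censor_rate: float = 0.0
    period_range: tuple[int, int] = (2001, 2019)
    dense_testing: bool = False
    #: testing-intensity multiplier by latent state at entry (sicker people
    #: tested more); no empirical default is claimed, 1.0 = no dependence.
    testing_state_multiplier: Mapping[int, float] = field(
        default_factory=lambda: {int(s): 1.0 for s in (State.NORMO, State.PRE, State.DM)}
    )
    dx_code_fraction: float = 0.3
    noninsulin_drug_fraction: float = 0.3
    insulin_fraction: float = 0.10
    short_insulin_noise_fraction: float = 0.002

    def __post_init__(self) -> None:
        if self.n_persons < 1:
            raise ValueError("n_persons must be at least 1 (empty output requested)")
        if not 0 <= self.max_age <= MAX_AGE:
            raise ValueError(f"max_age must lie in [0, {MAX_AGE}]")
        for name in ("sex_ratio_female", "single_test_fraction", "inpatient_fraction",
                     "gestational_fraction", "dx_code_fraction",
                     "noninsulin_drug_fraction", "insulin_fraction",
                     "short_insulin_noise_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.mean_tests_per_year < 0 or self.censor_rate < 0:
            raise ValueError("rates must be non-negative")
        name = self.entry_age_distribution[0]
        if name != "uniform":
            raise ValueError(f"unknown entry age distribution: {name!r}")
        mix = dict(self.measurement_type_mix)
        if any(v < 0 for v in mix.values()) or sum(mix.values()) <= 0:
            raise ValueError("measurement_type_mix must be non-negative with positive sum")
        unknown = set(mix) - set(_VALUE_BANDS)
        if unknown:
            raise ValueError(f"unknown measurement kinds in mix: {sorted(unknown)}")

    def truth(self) -> dict[str, TransitionTable]:
        """The generating transition table per sex (defaults filled in)."""
        t = self.truth_transitions
        if t is None:
            return {"M": default_truth_table("M", self.max_age),
                    "F": default_truth_table("F", self.max_age)}
        if isinstance(t, TransitionTable):
            return {"M": t, "F": t}
        return {"M": t["M"], "F": t["F"]}


def export_truth(config: GeneratorConfig) -> dict[str, TransitionTable]:
    """Return the exact generating transition tables, for recovery tests."""
    truth = config.truth()
    for table in truth.values():
        table.validate()
    return truth


def _simulate_latent(
    truth: dict[str, TransitionTable], sex: np.ndarray, rng: np.random.Generator,
    max_age: int,
) -> np.ndarray:
    """Latent annual state path from age 0 for every person, shape (n, max_age+1)."""
    n = len(sex)
    paths = np.zeros((n, max_age + 1), dtype=np.int8)
    state = np.zeros(n, dtype=np.int64)
    idx_by_sex = {s: np.flatnonzero(sex == s) for s in ("M", "F")}
    cums = {s: np.cumsum(truth[s].probs, axis=2) for s in ("M", "F")}
    for a in range(max_age):
        u = rng.random(n)
        nxt = np.empty(n, dtype=np.int64)
        for s, idx in idx_by_sex.items():
            if idx.size == 0:
                continue
            c = cums[s][a]  # (4, 4)
            nxt[idx] = (u[idx, None] > c[state[idx]]).sum(axis=1)
        state = nxt
        paths[:, a + 1] = state
    return paths


def generate_registry(config: GeneratorConfig) -> pd.DataFrame:
    """Generate one synthetic registry as a tidy record table.

    Deterministic given ``config.seed``. Returns a DataFrame with
    :data:`REGISTRY_COLUMNS`, one row per measurement, clinical flag, or
    death record, sorted by person and age. The registry can contain fewer
    than ``n_persons`` distinct ids: persons whose latent death precedes
    their would-be entry never reach a health facility and are absent, as in
    a real surveillance database.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_persons
    max_age = config.max_age
    truth = config.truth()

    sex = np.where(rng.random(n) < config.sex_ratio_female, "F", "M")
    paths = _simulate_latent(truth, sex, rng, max_age)

    # death age: latent chain enters DEATH at an integer age d, the death
    # itself falls uniformly inside (d - 1, d]
    dead_any = paths[:, -1] == State.DEATH
    first_death = np.where(dead_any, np.argmax(paths == State.DEATH, axis=1), -1)
    death_age = np.where(dead_any, first_death - rng.random(n), np.inf)

    # entry age drawn independently of the latent trajectory; persons who die
    # before their would-be entry never appear in the registry (dropped at the
    # end), which keeps entry uninformative about survival
    _, lo, hi = config.entry_age_distribution
    hi = min(hi, float(max_age))
    entry_age = lo + rng.random(n) * (hi - lo)
    observed = entry_age < death_age

    # calendar placement and censoring
    p0, p1 = config.period_range
    entry_year = rng.uniform(p0, p1 + 1.0, n)
    birth_year = np.floor(entry_year - entry_age).astype(int)
    admin_years = (p1 + 1.0) - entry_year
    if config.censor_rate > 0:
        random_censor = rng.exponential(1.0 / config.censor_rate, n)
    else:
        random_censor = np.full(n, np.inf)
    obs_years = np.minimum(admin_years, random_censor)
    window_end = np.minimum(entry_age + obs_years, np.minimum(death_age, float(max_age)))
    window_end = np.maximum(window_end, entry_age)

    # ---- glycemic test times ----------------------------------------------
    pid_col: list[np.ndarray] = []
    age_col: list[np.ndarray] = []
    if config.dense_testing:
        first = np.ceil(entry_age)
        last = np.floor(window_end)
        counts = np.maximum(last - first + 1, 0).astype(int)
        pid = np.repeat(np.arange(n), counts)
        offsets = _ragged_arange(counts)
        ages = first[pid] + offsets
        pid_col += [np.arange(n), pid]
        age_col += [entry_age, ages]
    else:
        single = rng.random(n) < config.single_test_fraction
        mult = np.array([config.testing_state_multiplier.get(int(s), 1.0)
                         for s in paths[np.arange(n), np.floor(entry_age).astype(int)]])
        lam = config.mean_tests_per_year * mult * (window_end - entry_age)
        extra = np.where(single, 0, 1 + rng.poisson(lam))
        pid = np.repeat(np.arange(n), extra)
        ages = entry_age[pid] + rng.random(pid.size) * (window_end - entry_age)[pid]
        pid_col += [np.arange(n), pid]
        age_col += [entry_age, ages]
    test_pid = np.concatenate(pid_col)
    test_age = np.concatenate(age_col)

    # measurement kinds and in-band values from the latent state at the test age
    kinds_all = sorted(config.measurement_type_mix)
    mix = np.array([config.measurement_type_mix[k] for k in kinds_all], dtype=float)
    mix = mix / mix.sum()
    kind_idx = rng.choice(len(kinds_all), size=test_pid.size, p=mix)
    latent = paths[test_pid, np.floor(test_age).astype(int)]
    # tests are scheduled strictly while alive; guard the measure-zero case of
    # a test age landing exactly on the death age
    latent = np.minimum(latent, np.int8(State.DM))
    value = np.empty(test_pid.size)
    for ki, kname in enumerate(kinds_all):
        for s in (State.NORMO, State.PRE, State.DM):
            m = (kind_idx == ki) & (latent == s)
            lo_b, hi_b = _VALUE_BANDS[kname][s]
            value[m] = lo_b + rng.random(int(m.sum())) * (hi_b - lo_b)
    kind_arr = np.array(kinds_all, dtype=object)[kind_idx]

    # inpatient contamination: FPG during admissions can be stress-elevated
    inpatient = np.zeros(test_pid.size, dtype=bool)
    m = (kind_arr == "FPG") & (rng.random(test_pid.size) < config.inpatient_fraction)
    inpatient[m] = True
    value[m] = 3.9 + rng.random(int(m.sum())) * (20.0 - 3.9)

    # gestational contamination: measurements in weeks 24-40 for fertile women
    gest_week = np.full(test_pid.size, np.nan)
    fertile = (sex[test_pid] == "F") & (test_age >= FERTILE_AGES[0]) & (test_age <= FERTILE_AGES[1])
    m = fertile & (rng.random(test_pid.size) < config.gestational_fraction)
    gest_week[m] = rng.integers(24, 41, int(m.sum()))
    value[m] = 3.9 + rng.random(int(m.sum())) * (12.0 - 3.9)

    frames = [pd.DataFrame({
        "person_id": test_pid, "event_age": test_age, "record_kind": kind_arr,
        "value": value, "inpatient": inpatient, "gestational_week": gest_week,
        "insulin_days": np.nan,
    })]

    # ---- clinical flags for persons diabetic during observation ------------
    ever_dm = (paths == State.DM).any(axis=1)
    dm_onset = np.where(ever_dm, np.argmax(paths == State.DM, axis=1), np.inf)
    flag_from = np.maximum(dm_onset, entry_age)
    can_flag = ever_dm & (flag_from <= window_end)

    def _flag_frame(mask: np.ndarray, kind: str, days: np.ndarray | None = None) -> pd.DataFrame:
        idx = np.flatnonzero(mask)
        ages = flag_from[idx] + rng.random(idx.size) * (window_end[idx] - flag_from[idx])
        return pd.DataFrame({
            "person_id": idx, "event_age": ages, "record_kind": kind,
            "value": np.nan, "inpatient": False, "gestational_week": np.nan,
            "insulin_days": days if days is not None else np.nan,
        })

    frames.append(_flag_frame(can_flag & (rng.random(n) < config.dx_code_fraction), "dx_code"))
    frames.append(_flag_frame(
        can_flag & (rng.random(n) < config.noninsulin_drug_fraction), "noninsulin_drug"))
    m = can_flag & (rng.random(n) < config.insulin_fraction)
    frames.append(_flag_frame(m, "insulin_episode",
                              days=rng.integers(28, 366, int(m.sum())).astype(float)))
    # short insulin episodes (below the 28-day diabetes criterion) as noise
    m = (rng.random(n) < config.short_insulin_noise_fraction) & (entry_age < window_end)
    idx = np.flatnonzero(m)
    frames.append(pd.DataFrame({
        "person_id": idx,
        "event_age": entry_age[idx] + rng.random(idx.size) * (window_end[idx] - entry_age[idx]),
        "record_kind": "insulin_episode", "value": np.nan, "inpatient": False,
        "gestational_week": np.nan,
        "insulin_days": rng.integers(1, 28, idx.size).astype(float),
    }))

    # ---- death records (vital-status linkage within the observation window) -
    death_observed = observed & np.isfinite(death_age) & (
        death_age <= np.minimum(entry_age + admin_years, entry_age + random_censor)
    ) & (death_age <= float(max_age))
    idx = np.flatnonzero(death_observed)
    frames.append(pd.DataFrame({
        "person_id": idx, "event_age": death_age[idx], "record_kind": "death",
        "value": np.nan, "inpatient": False, "gestational_week": np.nan,
        "insulin_days": np.nan,
    }))

    records = pd.concat(frames, ignore_index=True)
    records = records[observed[records["person_id"].to_numpy()]]
    records["sex"] = sex[records["person_id"].to_numpy()]
    records["birth_year"] = birth_year[records["person_id"].to_numpy()]
    records = records[REGISTRY_COLUMNS]
    records = records.sort_values(
        ["person_id", "event_age", "record_kind"], kind="mergesort"
    ).reset_index(drop=True)
    return records


def latent_histories(config: GeneratorConfig) -> pd.DataFrame:
    """Ground-truth onset/death ages per person (for generator diagnostics).

    Deterministic companion of :func:`generate_registry` under the same seed:
    replays the latent simulation only, returning integer onset ages of
    prediabetes and diabetes and the fractional death age per person.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_persons
    sex = np.where(rng.random(n) < config.sex_ratio_female, "F", "M")
    paths = _simulate_latent(config.truth(), sex, rng, config.max_age)
    dead_any = paths[:, -1] == State.DEATH
    first_death = np.where(dead_any, np.argmax(paths == State.DEATH, axis=1), -1)
    death_age = np.where(dead_any, first_death - rng.random(n), np.nan)
    ever = {}
    for s, name in ((State.PRE, "pre_onset_age"), (State.DM, "dm_onset_age")):
        hit = (paths == s).any(axis=1)
        ever[name] = np.where(hit, np.argmax(paths == s, axis=1), np.nan)
    return pd.DataFrame({
        "person_id": np.arange(n), "sex": sex, **ever, "death_age": death_age,
    })


def _ragged_arange(counts: np.ndarray) -> np.ndarray:
    """[0..c0), [0..c1), ... concatenated."""
    total = int(counts.sum())
    if total == 0:
        return np.zeros(0)
    ends = np.cumsum(counts)
    starts = ends - counts
    return np.arange(total) - np.repeat(starts, counts)
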