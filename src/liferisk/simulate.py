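"""Monte Carlo cohort simulation of glycemic progression and lifetime risk.

A cohort of individuals is propagated through the annual-cycle Markov chain
defined by a :class:`~liferisk.transitions.TransitionTable` from a start age
to 110. From the simulated trajectories the module computes, at any index age
and origin state (normoglycemia or prediabetes):

* remaining lifetime risk of diabetes -- the proportion of the conditioning
  set that ever develops diabetes;
* expected remaining life-years without and with diabetes;
* the proportion of remaining life spent with diabetes, averaged over
  individual-level fractions (zeros for those who never progress).

Each simulated quantity has an exact matrix-propagation counterpart
(:func:`occupancy_grid`, :func:`lifetime_quantities_exact`) obtained by
iterating the chain's distribution vector on an expanded state space that
separates death with and without prior diabetes. The exact values serve as
oracles for the Monte Carlo estimates and as fast deterministic inputs for
life-table work.

Survivors at 110 are truncated there for year accounting; very few survive
that long under realistic schedules.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .states import State
from .transitions import TransitionTable


class SimulationError(RuntimeError):
    pass


@dataclass
class SimulatedCohort:
    """Compressed trajectories: onset ages (NaN when the event never happens)."""

    pre_onset: np.ndarray
    dm_onset: np.ndarray
    death_age: np.ndarray
    start_age: int
    start_state: State
    sex: str
    seed: int
    max_age: int = 110

    @property
    def n(self) -> int:
        return len(self.death_age)

    def end_age(self) -> np.ndarray:
        """Death age, or the truncation horizon for survivors."""
        return np.where(np.isfinite(self.death_age), self.death_age, float(self.max_age))

    def state_at(self, age: float) -> np.ndarray:
        """State of every individual at an integer age (int8 array)."""
        out = np.zeros(self.n, dtype=np.int8)
        out[self.pre_onset <= age] = State.PRE
        out[self.dm_onset <= age] = State.DM
        out[self.death_age <= age] = State.DEATH
        return out


@dataclass
class LifetimeEstimate:
    """Lifetime risk and life-year summary at one (index age, origin state)."""

    index_age: int
    origin_state: State
    lifetime_risk: float = np.nan
    years_with_dm: float = np.nan
    years_without_dm: float = np.nan
    prop_with_dm: float = np.nan
    ci95: dict = field(default_factory=dict)
    n_conditioning: int = 0
    unstable: bool = False

    def as_row(self) -> dict:
        row = {
            "index_age": self.index_age,
            "origin_state": State(self.origin_state).name,
            "lifetime_risk": self.lifetime_risk,
            "years_with_dm": self.years_with_dm,
            "years_without_dm": self.years_without_dm,
            "prop_with_dm": self.prop_with_dm,
            "n_conditioning": self.n_conditioning,
            "unstable": self.unstable,
        }
        for key, (lo, hi) in self.ci95.items():
            row[f"{key}_lo"] = lo
            row[f"{key}_hi"] = hi
        return row


def simulate_cohort(
    table: TransitionTable,
    n: int,
    seed: int,
    start_age: int = 0,
    start_state: State = State.NORMO,
) -> SimulatedCohort:
    """Simulate ``n`` individual trajectories from ``start_age`` to 110.

    Everyone starts in ``start_state`` at ``start_age``; each year the next
    state is a multinomial draw from the age- and state-specific row of
    ``table``. Reproducible under ``seed``.
    """
    table.validate()
    max_age = table.max_age
    if not 0 <= start_age < max_age:
        raise SimulationError(f"start_age must lie in [0, {max_age})")
    rng = np.random.default_rng(seed)
    cums = np.cumsum(table.probs, axis=2)
    state = np.full(n, int(start_state), dtype=np.int64)
    pre_onset = np.full(n, np.nan)
    dm_onset = np.full(n, np.nan)
    death_age = np.full(n, np.nan)
    if start_state == State.PRE:
        pre_onset[:] = start_age
    if start_state == State.DM:
        dm_onset[:] = start_age
    for a in range(start_age, max_age):
        u = rng.random(n)
        nxt = (u[:, None] > cums[a][state]).sum(axis=1)
        newly = np.isnan(pre_onset) & (nxt == State.PRE)
        pre_onset[newly] = a + 1
        newly = np.isnan(dm_onset) & (nxt == State.DM)
        dm_onset[newly] = a + 1
        newly = np.isnan(death_age) & (nxt == State.DEATH)
        death_age[newly] = a + 1
        state = nxt
    return SimulatedCohort(pre_onset=pre_onset, dm_onset=dm_onset,
                           death_age=death_age, start_age=start_age,
                           start_state=State(start_state), sex=table.sex,
                           seed=seed, max_age=max_age)


def _conditioning_mask(cohort: SimulatedCohort, index_age: int,
                       origin_state: State) -> np.ndarray:
    return cohort.state_at(index_age) == origin_state


def remaining_lifetime_risk(
    cohort: SimulatedCohort, index_age: int, origin_state: State
) -> LifetimeEstimate:
    """Proportion eventually developing diabetes among those in
    ``origin_state`` at ``index_age``."""
    cond = _conditioning_mask(cohort, index_age, origin_state)
    est = LifetimeEstimate(index_age=index_age, origin_state=State(origin_state))
    est.n_conditioning = int(cond.sum())
    if est.n_conditioning == 0:
        est.unstable = True
        return est
    dm = cohort.dm_onset[cond]
    est.lifetime_risk = float(np.mean(np.isfinite(dm) & (dm >= index_age)))
    return est


def life_years(
    cohort: SimulatedCohort, index_age: int, origin_state: State
) -> LifetimeEstimate:
    """Expected remaining years without and with diabetes from ``index_age``.

    Per individual, years without diabetes run from the index age to the
    earlier of diabetes onset and death (or the age-110 truncation); years
    with diabetes run from onset to death/truncation. The proportion of
    remaining life with diabetes is the mean of the per-individual fractions,
    with zeros for those who never progress -- *not* the ratio of the two mean
    durations, which differs in general.
    """
    cond = _conditioning_mask(cohort, index_age, origin_state)
    est = LifetimeEstimate(index_age=index_age, origin_state=State(origin_state))
    est.n_conditioning = int(cond.sum())
    if est.n_conditioning == 0:
        est.unstable = True
        return est
    dm = cohort.dm_onset[cond]
    end = cohort.end_age()[cond]
    dm_eff = np.where(np.isfinite(dm), dm, np.inf)
    without = np.minimum(dm_eff, end) - index_age
    with_dm = np.maximum(end - dm_eff, 0.0)
    with_dm[~np.isfinite(dm)] = 0.0
    total = without + with_dm
    frac = np.divide(with_dm, total, out=np.zeros_like(with_dm), where=total > 0)
    est.years_without_dm = float(without.mean())
    est.years_with_dm = float(with_dm.mean())
    est.prop_with_dm = float(frac.mean())
    est.lifetime_risk = float(np.mean(np.isfinite(dm) & (dm >= index_age)))
    return est


def lifetime_estimate(
    cohort: SimulatedCohort, index_age: int, origin_state: State
) -> LifetimeEstimate:
    """Risk and life-years in one pass."""
    return life_years(cohort, index_age, origin_state)


# ---------------------------------------------------------------------------
# exact matrix-propagation oracle
# ---------------------------------------------------------------------------

_N_EXP = 5  # NORMO, PRE, DM, DEATH (never DM), DEATH (after DM)


def _expanded_probs(table: TransitionTable) -> np.ndarray:
    """Per-age 5x5 matrices splitting death by whether diabetes came first."""
    p = table.probs
    n_ages = p.shape[0]
    q = np.zeros((n_ages, _N_EXP, _N_EXP))
    for s in (State.NORMO, State.PRE):
        q[:, s, State.NORMO:State.DM + 1] = p[:, s, State.NORMO:State.DM + 1]
        q[:, s, 3] = p[:, s, State.DEATH]
    q[:, State.DM, State.DM] = p[:, State.DM, State.DM]
    q[:, State.DM, 4] = p[:, State.DM, State.DEATH]
    q[:, 3, 3] = 1.0
    q[:, 4, 4] = 1.0
    return q


def occupancy_grid(
    table: TransitionTable, start_age: int, start_state: State
) -> np.ndarray:
    """Exact state-occupancy probabilities by age.

    Returns an array of shape ``(max_age + 1, 5)`` over the expanded states
    (normo, pre, dm, death without prior dm, death after dm); rows before
    ``start_age`` are zero.
    """
    q = _expanded_probs(table)
    occ = np.zeros((table.max_age + 1, _N_EXP))
    occ[start_age, int(start_state)] = 1.0
    for a in range(start_age, table.max_age):
        occ[a + 1] = occ[a] @ q[a]
    return occ


def lifetime_quantities_exact(
    table: TransitionTable, index_age: int, origin_state: State
) -> dict:
    """Closed-form (matrix-propagation) lifetime risk and mean life-years.

    Matches the Monte Carlo conventions exactly: whole-year occupancy at
    integer ages, truncation at 110. ``prop_with_dm`` is not included -- the
    per-individual-fraction mean has no occupancy-level closed form.
    """
    occ = occupancy_grid(table, index_age, origin_state)
    risk = occ[table.max_age, State.DM] + occ[table.max_age, 4]
    years_without = occ[index_age:table.max_age, [State.NORMO, State.PRE]].sum()
    years_with = occ[index_age:table.max_age, State.DM].sum()
    return {
        "lifetime_risk": float(risk),
        "years_without_dm": float(years_without),
        "years_with_dm": float(years_with),
    }


# ---------------------------------------------------------------------------
# uncertainty: bootstrap over the estimated transition counts
# ---------------------------------------------------------------------------

def bootstrap_lifetime(
    table: TransitionTable,
    index_ages: list[int],
    origin_states: list[State],
    n_boot: int = 200,
    n_sim: int = 100_000,
    seed: int = 0,
    start_age: int = 0,
    use_exact: bool = False,
) -> dict[tuple[int, State], dict[str, tuple[float, float]]]:
    """Percentile 95% intervals propagating transition-estimation uncertainty.

    Each replicate redraws every estimated row's transition counts from a
    multinomial with the observed at-risk size, rebuilds the table, and
    recomputes the lifetime quantities (by a reduced simulation of ``n_sim``
    trajectories, or exactly when ``use_exact``). Rows never observed keep
    their point-estimate values.
    """
    rng = np.random.default_rng(seed)
    reps: dict[tuple[int, State], dict[str, list[float]]] = {
        (a, State(s)): {"lifetime_risk": [], "years_with_dm": [],
                        "years_without_dm": [], "prop_with_dm": []}
        for a in index_ages for s in origin_states
    }
    for b in range(n_boot):
        bt = resample_table(table, rng)
        if use_exact:
            for (a, s), store in reps.items():
                ex = lifetime_quantities_exact(bt, a, s)
                for k in ("lifetime_risk", "years_with_dm", "years_without_dm"):
                    store[k].append(ex[k])
        else:
            cohort = simulate_cohort(bt, n_sim, seed=int(rng.integers(2**31)),
                                     start_age=start_age)
            for (a, s), store in reps.items():
                est = life_years(cohort, a, s)
                store["lifetime_risk"].append(est.lifetime_risk)
                store["years_with_dm"].append(est.years_with_dm)
                store["years_without_dm"].append(est.years_without_dm)
                store["prop_with_dm"].append(est.prop_with_dm)
    out: dict[tuple[int, State], dict[str, tuple[float, float]]] = {}
    for key, store in reps.items():
        out[key] = {}
        for quant, values in store.items():
            vals = np.asarray(values, dtype=float)
            vals = vals[np.isfinite(vals)]
            if vals.size:
                lo, hi = np.percentile(vals, [2.5, 97.5])
                out[key][quant] = (float(lo), float(hi))
    return out


def resample_table(table: TransitionTable, rng: np.random.Generator) -> TransitionTable:
    """One parametric-bootstrap replicate of an estimated table."""
    probs = table.probs.copy()
    risk = np.round(table.n_at_risk).astype(np.int64)
    for s in (State.NORMO, State.PRE, State.DM):
        ages = np.flatnonzero(risk[:, s] > 0)
        for a in ages:
            row = table.probs[a, s]
            draw = rng.multinomial(risk[a, s], row / row.sum())
            probs[a, s] = draw / draw.sum()
    return TransitionTable(probs=probs, n_transitions=table.n_transitions,
                           n_at_risk=table.n_at_risk, sex=table.sex,
                           max_age=table.max_age)


# ---------------------------------------------------------------------------
# validation against observed short-term risk
# ---------------------------------------------------------------------------

def cohort_to_histories(cohort: SimulatedCohort) -> pd.DataFrame:
    """Present simulated trajectories in the resolved-history schema so the
    observed-data survival machinery can run on them unchanged."""
    end = cohort.end_age()
    return pd.DataFrame({
        "person_id": np.arange(cohort.n),
        "sex": cohort.sex,
        "birth_year": 0,
        "entry_age": float(cohort.start_age),
        "pre_onset_age": cohort.pre_onset,
        "dm_onset_age": cohort.dm_onset,
        "death_age": cohort.death_age,
        "censor_age": end,
        "linkage_end_age": float(cohort.max_age + 1),
        "n_measurements": 0,
        "followup_years": end - cohort.start_age,
    })


def validate_against_observed(
    cohort: SimulatedCohort,
    histories: pd.DataFrame,
    onset_age_groups: list[tuple[float, float]] | None = None,
    horizon: float = 19.0,
    min_at_risk: int = 50,
) -> pd.DataFrame:
    """Predicted vs observed short-term risk of prediabetes-to-diabetes
    progression, stratified by onset age of prediabetes.

    Both sides are summarized as death-adjusted cumulative incidence curves
    (observed from the registry histories, predicted from the simulated
    cohort); the comparison statistic per stratum is the maximum vertical
    discrepancy over the horizon, restricted to times where both curves still
    have at least ``min_at_risk`` persons at risk. Strata empty on either side
    are skipped.
    """
    from .competing import discrete_cif

    if onset_age_groups is None:
        onset_age_groups = [(0, 20), (20, 40), (40, 60), (60, 200)]
    sim_hist = cohort_to_histories(cohort)
    rows = []
    for lo, hi in onset_age_groups:
        obs = discrete_cif(histories, State.PRE, (lo, hi), horizon=int(horizon))
        pred = discrete_cif(sim_hist, State.PRE, (lo, hi), horizon=int(horizon))
        if len(obs) == 0 or len(pred) == 0:
            continue
        merged = obs.merge(pred, on="time", suffixes=("_obs", "_pred"))
        ok = (merged["n_risk_obs"] >= min_at_risk) & (merged["n_risk_pred"] >= min_at_risk)
        if not ok.any():
            continue
        disc = (merged.loc[ok, "cif_obs"] - merged.loc[ok, "cif_pred"]).abs()
        rows.append({"onset_age_lo": lo, "onset_age_hi": hi,
                     "max_discrepancy": float(disc.max()),
                     "n_observed": int(merged["n_risk_obs"].max()),
                     "n_predicted": int(merged["n_risk_pred"].max())})
    return pd.DataFrame(rows)
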