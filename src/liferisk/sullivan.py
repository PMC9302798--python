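"""Sullivan life-table partition of remaining life expectancy by diabetes.

The Sullivan method combines an ordinary period life table (from age-specific
death probabilities) with age-specific diabetes prevalence: the person-years
lived in each age interval are split by the fraction of that age's person
time spent with diabetes, giving expected remaining years lived with and
without the disease at every age. The two partitions always sum to the total
remaining life expectancy.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .states import State
from .simulate import SimulatedCohort

LIFETABLE_COLUMNS = ["age", "q", "l", "d", "L", "prevalence", "e",
                     "e_with_dm", "e_without_dm"]


def build_life_table(
    death_probs: np.ndarray,
    prevalence: np.ndarray,
    radix: float = 100_000.0,
    max_age: int = 110,
    halfyear: float = 0.5,
) -> pd.DataFrame:
    """Sullivan life table on ages ``0..max_age``.

    Parameters
    ----------
    death_probs : array
        Annual death probability ``q(x)`` per age.
    prevalence : array
        Fraction of person-years at age ``x`` spent with diabetes; missing
        (NaN) values at sparse old ages are forward-filled from the last
        observed age (zero if never observed).
    halfyear : float
        Fraction of the year lived by those dying in the interval
        (``a(x) = 0.5`` for all ages by default). The closing interval uses
        ``L(max_age) = l(max_age) * halfyear``, survivorship there being
        negligible.
    """
    q = np.broadcast_to(np.asarray(death_probs, dtype=float), (max_age + 1,)).copy()
    prev = np.broadcast_to(np.asarray(prevalence, dtype=float), (max_age + 1,)).astype(float).copy()
    if np.any((q < 0) | (q > 1)):
        raise ValueError("death probabilities must lie in [0, 1]")
    if np.any((prev < 0) | (prev > 1) & np.isfinite(prev)):
        raise ValueError("prevalence must lie in [0, 1]")
    # forward-fill missing prevalence
    filled = 0.0
    for i in range(max_age + 1):
        if np.isfinite(prev[i]):
            filled = prev[i]
        else:
            prev[i] = filled

    l = np.zeros(max_age + 1)
    l[0] = radix
    for x in range(max_age):
        l[x + 1] = l[x] * (1.0 - q[x])
    d = np.empty(max_age + 1)
    d[:-1] = l[:-1] - l[1:]
    d[-1] = l[-1]
    L = np.empty(max_age + 1)
    L[:-1] = l[1:] + halfyear * d[:-1]
    L[-1] = l[-1] * halfyear

    T = np.cumsum(L[::-1])[::-1]
    T_dm = np.cumsum((prev * L)[::-1])[::-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        e = np.where(l > 0, T / l, 0.0)
        e_with = np.where(l > 0, T_dm / l, 0.0)
    e_without = e - e_with
    return pd.DataFrame({
        "age": np.arange(max_age + 1), "q": q, "l": l, "d": d, "L": L,
        "prevalence": prev, "e": e, "e_with_dm": e_with,
        "e_without_dm": e_without,
    })


def prevalence_from_cohort(cohort: SimulatedCohort) -> np.ndarray:
    """Diabetes prevalence per age among alive person-years of a simulated
    cohort; NaN where no one is alive (to be forward-filled by the table)."""
    if cohort.n == 0:
        raise ValueError("empty cohort")
    ages = np.arange(cohort.max_age + 1, dtype=float)
    alive = np.zeros(cohort.max_age + 1)
    with_dm = np.zeros(cohort.max_age + 1)
    dm = cohort.dm_onset
    death = np.where(np.isfinite(cohort.death_age), cohort.death_age, np.inf)
    for i, a in enumerate(ages):
        if a < cohort.start_age:
            alive[i] = np.nan
            continue
        is_alive = death > a
        alive[i] = is_alive.sum()
        with_dm[i] = (is_alive & (dm <= a)).sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        prev = np.where(alive > 0, with_dm / np.where(alive > 0, alive, 1.0), np.nan)
    return prev


def mortality_from_cohort(cohort: SimulatedCohort) -> np.ndarray:
    """Annual all-state death probability q(a) observed in a simulated cohort;
    NaN where no one is alive."""
    death = np.where(np.isfinite(cohort.death_age), cohort.death_age, np.inf)
    q = np.full(cohort.max_age + 1, np.nan)
    for a in range(cohort.start_age, cohort.max_age):
        alive = (death > a).sum()
        if alive > 0:
            q[a] = ((death > a) & (death <= a + 1)).sum() / alive
    return q


def sullivan_from_cohort(cohort: SimulatedCohort, index_age: int,
                         origin_state: State, halfyear: float = 0.5) -> pd.DataFrame:
    """Sullivan table for the sub-cohort in ``origin_state`` at ``index_age``,
    with mortality and prevalence read off the same simulated trajectories.

    This is the cross-method companion of the simulated life-years: both
    sides share the empirical survival, so the comparison isolates the
    life-table person-year convention (the half-year assumption) rather than
    Monte Carlo noise.
    """
    cond = cohort.state_at(index_age) == origin_state
    if not cond.any():
        raise ValueError("empty conditioning set")
    dm = cohort.dm_onset[cond]
    death = np.where(np.isfinite(cohort.death_age[cond]),
                     cohort.death_age[cond], np.inf)
    max_age = cohort.max_age
    n_ages = max_age - index_age + 1
    q = np.zeros(n_ages)
    prev = np.full(n_ages, np.nan)
    for i, a in enumerate(range(index_age, max_age + 1)):
        alive = death > a
        n_alive = int(alive.sum())
        if n_alive == 0:
            q[i] = 1.0
            continue
        prev[i] = float((alive & (dm <= a)).sum() / n_alive)
        if a < max_age:
            q[i] = float(((death > a) & (death <= a + 1)).sum() / n_alive)
    table = build_life_table(q, prev, max_age=max_age - index_age,
                             halfyear=halfyear)
    table["age"] = table["age"] + index_age
    return table


def sullivan_from_occupancy(occ: np.ndarray, index_age: int,
                            halfyear: float = 0.5) -> pd.DataFrame:
    """Sullivan table driven by exact chain occupancy (see
    :func:`liferisk.simulate.occupancy_grid`): mortality and prevalence are
    read off the occupancy distribution, giving a deterministic cross-method
    check against simulated life-years."""
    max_age = occ.shape[0] - 1
    alive = occ[:, :int(State.DM) + 1].sum(axis=1)
    q = np.full(max_age + 1, np.nan)
    for a in range(index_age, max_age):
        if alive[a] > 0:
            q[a] = (alive[a] - alive[a + 1]) / alive[a]
    q = np.clip(np.where(np.isfinite(q), q, 1.0), 0.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        prev = np.where(alive > 0, occ[:, State.DM] / np.where(alive > 0, alive, 1.0), np.nan)
    # life table conditioned at the index age: shift so age 0 is index_age
    q_cond = q[index_age:]
    prev_cond = prev[index_age:]
    table = build_life_table(q_cond, prev_cond, max_age=max_age - index_age,
                             halfyear=halfyear)
    table["age"] = table["age"] + index_age
    return table
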