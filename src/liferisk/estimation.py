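"""Discrete-time estimation of one-year transition probabilities.

The estimator uses age as the clock and a two-part occurrence/exposure
construction that respects how a surveillance registry actually observes
people:

* **Death part.** Vital status is known through each person's linkage end
  (the registry closing year), independently of how often they were tested.
  The annual death probability from state ``s`` at age ``a`` is the number of
  deaths in ``(a, a+1]`` among persons whose state at ``a`` is known to be
  ``s`` and whose vital linkage covers ``a + 1``.
* **Living part.** The split of survivors among living destinations needs the
  glycemic state at ``a + 1``, which is known only up to the last clinical
  encounter (diabetes, absorbing among the living, stays known until death).
  The conditional destination shares are estimated on that smaller exposure
  set and scaled by the survival probability ``1 - q``.

Using a single exposure set for both parts would condition inclusion of the
final person-year on the outcome (deaths after the last encounter would be
counted while the matching survivor time is not), biasing mortality upward;
the two-part split removes that asymmetry. Between the first and last
encounter the no-reversion convention makes every interior year's state
deducible from the surrounding measurements, with onsets dated at detection
(right-endpoint convention).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .states import MAX_AGE, N_STATES, State
from .transitions import TransitionTable, probs_from_two_part


class EstimationError(RuntimeError):
    pass


@dataclass
class PersonArrays:
    """Per-person quantities on the integer-age grid (NaN-free conventions:
    missing onsets are +inf, missing death is +inf)."""

    a0: np.ndarray          # first age with known state: floor(entry)
    k_glyc: np.ndarray      # glycemic state known through this age: floor(censor)
    pre_f: np.ndarray       # floor(prediabetes onset), +inf if never
    dm_f: np.ndarray        # floor(diabetes onset), +inf if never
    death_entry: np.ndarray  # first integer age in DEATH: ceil(death age), +inf
    linkage: np.ndarray     # vital status known through this integer age
    birth_year: np.ndarray

    def state_at(self, pid: np.ndarray, ages: np.ndarray) -> np.ndarray:
        out = np.zeros(len(ages), dtype=np.int8)
        out[ages >= self.pre_f[pid]] = State.PRE
        out[ages >= self.dm_f[pid]] = State.DM
        out[ages >= self.death_entry[pid]] = State.DEATH
        return out

    def known_living(self, pid: np.ndarray, ages: np.ndarray) -> np.ndarray:
        """State at ``ages`` known and living: within measurement coverage or
        deducible (diabetes absorbing), and before death."""
        within = ages <= self.k_glyc[pid]
        dm_deduced = ages >= self.dm_f[pid]
        return ((ages >= self.a0[pid]) & (within | dm_deduced)
                & (ages < self.death_entry[pid]))


def person_arrays(histories: pd.DataFrame) -> PersonArrays:
    def col(name: str) -> np.ndarray:
        if name in histories:
            return histories[name].to_numpy(float)
        return np.full(len(histories), np.nan)

    entry = col("entry_age")
    censor = col("censor_age")
    death = col("death_age")
    pre = col("pre_onset_age")
    dm = col("dm_onset_age")
    linkage = col("linkage_end_age")

    died = np.isfinite(death)
    death_entry = np.where(died, np.ceil(np.where(died, death, 0.0)), np.inf)
    k_glyc = np.floor(censor)
    # fallback when linkage is unknown: assume coverage through the last
    # encounter (and through an observed death) -- mortality from states other
    # than diabetes is then biased upward; supply linkage_end_age to avoid it
    fallback = np.where(died, death_entry, k_glyc)
    linkage = np.where(np.isfinite(linkage), np.floor(linkage), fallback)
    return PersonArrays(
        a0=np.floor(entry),
        k_glyc=k_glyc,
        pre_f=np.where(np.isfinite(pre), np.floor(pre), np.inf),
        dm_f=np.where(np.isfinite(dm), np.floor(dm), np.inf),
        death_entry=death_entry,
        linkage=linkage,
        birth_year=col("birth_year"),
    )


def transition_counts(
    histories: pd.DataFrame,
    period: tuple[int, int] | None = None,
    max_age: int = MAX_AGE,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Raw counting arrays for the two-part estimator.

    Returns ``(deaths, death_exposure, living_transitions)`` with shapes
    ``(max_age+1, 4)``, ``(max_age+1, 4)`` and ``(max_age+1, 4, 4)``; the
    living-destination exposure is the row sum of ``living_transitions``.
    """
    p = person_arrays(histories)
    n = len(histories)
    # candidate ages: from a0 through min(linkage, death_entry) - 1
    last = np.minimum(p.linkage, p.death_entry) - 1
    last = np.minimum(last, max_age - 1)
    first = p.a0
    counts = np.maximum(last - first + 1, 0)
    counts = np.where(np.isfinite(counts), counts, 0).astype(int)
    pid = np.repeat(np.arange(n), counts)
    ages = (first[pid] + _ragged_arange(counts)).astype(int)

    if period is not None:
        year = p.birth_year[pid] + ages
        inside = (year >= period[0]) & (year <= period[1])
        pid, ages = pid[inside], ages[inside]

    known = p.known_living(pid, ages)
    pid, ages = pid[known], ages[known]
    s_from = p.state_at(pid, ages)

    deaths = np.zeros((max_age + 1, N_STATES))
    death_expo = np.zeros((max_age + 1, N_STATES))
    living_trans = np.zeros((max_age + 1, N_STATES, N_STATES))

    # death part: vital status ascertainable through a+1 by construction
    # (ages run to linkage - 1; observed deaths lie within linkage)
    np.add.at(death_expo, (ages, s_from), 1.0)
    is_death = p.death_entry[pid] == ages + 1
    np.add.at(deaths, (ages[is_death], s_from[is_death]), 1.0)

    # living part: glycemic state at a+1 known (measured or deducible) and
    # the person survives the year
    alive_next = p.death_entry[pid] > ages + 1
    glyc_next = (ages + 1 <= p.k_glyc[pid]) | (ages + 1 >= p.dm_f[pid])
    m = alive_next & glyc_next
    s_to = p.state_at(pid[m], ages[m] + 1)
    np.add.at(living_trans, (ages[m], s_from[m], s_to), 1.0)
    return deaths, death_expo, living_trans


def estimate_transitions(
    histories: pd.DataFrame,
    sex: str = "pooled",
    period: tuple[int, int] | None = None,
    max_age: int = MAX_AGE,
) -> TransitionTable:
    """Estimate the age-specific transition table from resolved histories.

    Parameters
    ----------
    histories : DataFrame
        Output of :func:`liferisk.classify.resolve_state_histories`.
    sex : str
        ``"M"``, ``"F"`` or ``"pooled"`` (all persons).
    period : (int, int), optional
        Calendar window; the person-year at age ``a`` is attributed to the
        calendar year ``birth_year + a`` and only counted when that year falls
        inside the window (the period-split analyses).

    Ages with no observed exposure borrow the nearest populated age's row
    within the same origin state.
    """
    h = histories
    if sex != "pooled":
        h = h[h["sex"] == sex]
    if len(h) == 0:
        raise EstimationError(f"no histories in stratum sex={sex!r}")
    deaths, death_expo, living = transition_counts(h, period=period, max_age=max_age)
    if death_expo.sum() == 0:
        raise EstimationError(f"no observed person-time in stratum sex={sex!r}")
    probs = probs_from_two_part(deaths, death_expo, living, max_age)
    n_trans = living.copy()
    n_trans[:, :, State.DEATH] = deaths
    table = TransitionTable(probs=probs, n_transitions=n_trans,
                           n_at_risk=death_expo,
                           n_at_risk_living=living.sum(axis=2),
                           sex=sex, max_age=max_age)
    table.validate()
    return table


def incidence_rate(events: float, person_years: float) -> float:
    """Crude incidence per 1,000 person-years."""
    if person_years <= 0:
        raise EstimationError("undefined rate: zero person-years at risk")
    return 1000.0 * events / person_years


def crude_incidence(
    histories: pd.DataFrame,
    origin_state: State = State.PRE,
    event_state: State = State.DM,
) -> tuple[float, int, float]:
    """Crude incidence of progression, with exact (fractional) person-time.

    Person-time runs from entry into the origin state (registry entry for
    normoglycemia, prediabetes onset for prediabetes) until the event, death,
    or the last encounter, whichever comes first. Returns
    ``(rate per 1,000 PY, n_events, person_years)``.
    """
    if not origin_state < event_state:
        raise ValueError("origin must precede event in severity order")
    entry = histories["entry_age"].to_numpy(float)
    censor = histories["censor_age"].to_numpy(float)
    death = (histories["death_age"].to_numpy(float)
             if "death_age" in histories else np.full(len(histories), np.nan))
    pre = histories["pre_onset_age"].to_numpy(float)
    dm = histories["dm_onset_age"].to_numpy(float)

    event = {State.PRE: pre, State.DM: dm}[event_state]
    if origin_state == State.NORMO:
        in_origin = ~((pre <= entry) | (dm <= entry))
        start = entry
    elif origin_state == State.PRE:
        in_origin = np.isfinite(pre) & ~(dm <= pre)
        start = pre
    else:
        raise ValueError("origin must be a living, non-absorbing state")
    stop = np.fmin(np.fmin(event, death), censor)
    stop = np.fmax(stop, start)
    valid = in_origin & np.isfinite(start)
    py = float(np.sum(np.where(valid, stop - start, 0.0)))
    n_events = int(np.sum(valid & np.isfinite(event) & (event <= censor + 1e-9)))
    return incidence_rate(n_events, py), n_events, py


def _ragged_arange(counts: np.ndarray) -> np.ndarray:
    total = int(counts.sum())
    if total == 0:
        return np.zeros(0, dtype=int)
    ends = np.cumsum(counts)
    return np.arange(total) - np.repeat(ends - counts, counts)
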