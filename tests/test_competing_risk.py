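"""Aalen-Johansen cumulative incidence and the modified Kaplan-Meier
lifetime-risk estimator."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_histories
from liferisk.competing import (
    aalen_johansen,
    cumulative_incidence,
    discrete_cif,
    modified_km_lifetime_risk,
)
from liferisk.estimation import estimate_transitions
from liferisk.registry import default_truth_table
from liferisk.simulate import (
    cohort_to_histories,
    lifetime_quantities_exact,
    simulate_cohort,
)
from liferisk.states import State


def test_hand_fixture_matches_manual_aalen_johansen_sum():
    """Five subjects: events at t=1 and t=2, a competing death at t=1.5,
    censorings at t=3 and t=4. Worked by hand:
    CIF(1)=1/5=0.2, death CIF(1.5)=0.8*1/4=0.2, CIF(2)=0.2+0.6*1/3=0.4,
    flat afterwards."""
    curve = aalen_johansen(
        time=np.array([1.0, 2.0, 1.5, 3.0, 4.0]),
        status=np.array([1, 1, 2, 0, 0]),
    )
    np.testing.assert_allclose(curve["time"], [1.0, 1.5, 2.0])
    np.testing.assert_allclose(curve["cif"], [0.2, 0.2, 0.4])
    np.testing.assert_allclose(curve["cif_death"], [0.0, 0.2, 0.2])
    np.testing.assert_allclose(curve["surv"], [0.8, 0.6, 0.4])
    assert (curve["cif_lo"] <= curve["cif"]).all()
    assert (curve["cif"] <= curve["cif_hi"]).all()


def test_no_deaths_adjusted_equals_one_minus_km():
    rng = np.random.default_rng(0)
    t = rng.exponential(5, 200)
    status = np.where(rng.random(200) < 0.6, 1, 0)
    adj = aalen_johansen(t, status)
    unadj = aalen_johansen(t, status)  # no competing events present anyway
    np.testing.assert_allclose(adj["cif"], unadj["cif"])
    km = np.cumprod(1 - adj["d_event"] / adj["n_risk"])
    np.testing.assert_allclose(adj["cif"], 1 - km, atol=1e-12)


def test_cif_bounds_and_decomposition():
    """Cause-specific CIFs plus event-free survival sum to one, and the
    death-adjusted curve is bounded by the censor-deaths curve."""
    rng = np.random.default_rng(1)
    n = 500
    t = rng.exponential(5, n)
    status = rng.choice([0, 1, 2], n, p=[0.3, 0.4, 0.3])
    curve = aalen_johansen(t, status)
    total = curve["cif"] + curve["cif_death"] + curve["surv"]
    np.testing.assert_allclose(total, 1.0, atol=1e-9)
    st2 = status.copy()
    st2[st2 == 2] = 0
    unadj = aalen_johansen(t, st2)
    merged = pd.merge_asof(curve, unadj, on="time", suffixes=("_adj", "_unadj"))
    assert (merged["cif_unadj"] >= merged["cif_adj"] - 1e-12).all()


def test_against_lifelines_aalen_johansen():
    """Independent cross-check of the CIF point estimates."""
    from lifelines import AalenJohansenFitter

    rng = np.random.default_rng(2)
    n = 300
    t = rng.exponential(5, n) + 0.01  # continuous times: no ties to jitter
    status = rng.choice([0, 1, 2], n, p=[0.25, 0.5, 0.25])
    ours = aalen_johansen(t, status)
    ajf = AalenJohansenFitter(calculate_variance=False, seed=0)
    ajf.fit(t, status, event_of_interest=1)
    theirs = ajf.cumulative_density_.iloc[:, 0]
    grid = ours["time"].to_numpy()
    ref = theirs.reindex(theirs.index.union(grid)).ffill().fillna(0.0).loc[grid]
    np.testing.assert_allclose(ours["cif"].to_numpy(), ref.to_numpy(), atol=1e-10)


def test_left_truncation_late_entrants_do_not_change_earlier_curve():
    t = np.array([2.0, 3.0, 5.0, 9.0])
    status = np.array([1, 1, 2, 0])
    entry = np.zeros(4)
    base = aalen_johansen(t, status, entry)
    t2 = np.concatenate([t, [8.0]])
    status2 = np.concatenate([status, [0]])
    entry2 = np.concatenate([entry, [6.0]])  # enters after the last event
    with_late = aalen_johansen(t2, status2, entry2)
    np.testing.assert_allclose(base["cif"], with_late["cif"])
    with pytest.raises(ValueError):
        aalen_johansen(t, status, entry=t + 1.0)


def test_cumulative_incidence_strata_and_baselines():
    hist = make_histories([
        {"entry_age": 30.0, "pre_onset_age": 35.0, "dm_onset_age": 40.0,
         "censor_age": 45.0},
        {"entry_age": 50.0, "pre_onset_age": 52.0, "censor_age": 60.0},
        {"entry_age": 41.0, "pre_onset_age": 45.0, "death_age": 50.0,
         "censor_age": 49.0},
        {"entry_age": 20.0, "censor_age": 30.0},  # never prediabetic
    ])
    curves = cumulative_incidence(hist, State.PRE,
                                  age_groups=[(20, 40), (40, 60)])
    assert set(curves) == {(20, 40), (40, 60)}
    # person 1: onset 35, event 5 years later
    c = curves[(20, 40)]
    assert c["cif"].iloc[-1] == pytest.approx(1.0)
    # normo origin counts everyone from entry
    curves_n = cumulative_incidence(hist, State.NORMO, age_groups=[(20, 60)])
    assert curves_n[(20, 60)]["n_risk"].iloc[0] == 4


def test_modified_km_two_age_hand_sum():
    """Two ages with marginal hazards (dm .2, death .1) each: lifetime risk
    is .2 + (1 - .2 - .1) * .2 = .34, with the second-age risk set refreshed
    by late entrants (left truncation)."""
    rows = []
    # age 50 risk set: 10 prediabetic persons
    rows += [{"pre_onset_age": 50.0, "dm_onset_age": 51.0} for _ in range(2)]
    rows += [{"pre_onset_age": 50.0, "death_age": 50.5, "censor_age": 50.0}]
    rows += [{"pre_onset_age": 50.0} for _ in range(7)]
    # three late entrants at 51 keep n = 10 there
    rows += [{"pre_onset_age": 51.0} for _ in range(3)]
    hist = make_histories([
        {"entry_age": r.get("pre_onset_age", 50.0), "censor_age": 52.0,
         "linkage_end_age": 60.0, **r} for r in rows])
    # events at age 52: one stayer and one late entrant progress, one stayer dies
    hist.loc[3, "dm_onset_age"] = 52.0
    hist.loc[10, "dm_onset_age"] = 52.0
    hist.loc[4, "death_age"] = 51.5
    hist.loc[4, "censor_age"] = 51.0
    res = modified_km_lifetime_risk(hist, State.PRE, index_age=50, n_boot=10)
    assert res["risk"] == pytest.approx(0.34)
    assert res["n_at_entry"] == 10


def test_modified_km_zero_mortality_equals_discrete_cif():
    """Without deaths the age-timescale sum collapses to the plain
    cumulative incidence from the index age."""
    rng = np.random.default_rng(3)
    n = 400
    onset = np.full(n, 60.0)
    dm = np.where(rng.random(n) < 0.5, 60 + rng.integers(1, 20, n), np.nan)
    hist = make_histories([
        {"entry_age": 60.0, "pre_onset_age": 60.0, "dm_onset_age": dm[i],
         "censor_age": 85.0, "linkage_end_age": 111.0} for i in range(n)])
    res = modified_km_lifetime_risk(hist, State.PRE, 60, n_boot=10)
    curve = discrete_cif(hist, State.PRE, (55, 65), horizon=50)
    assert res["risk"] == pytest.approx(curve["cif"].iloc[-1])
    del onset


def test_modified_km_equals_chain_absorption_on_complete_trajectories():
    """Fed complete (uncensored) discrete trajectories, the modified KM
    reproduces the absorption probability of the chain estimated from the
    same trajectories -- exactly, for the prediabetes origin."""
    t = default_truth_table("pooled")
    cohort = simulate_cohort(t, 30_000, seed=4)
    hist = cohort_to_histories(cohort)
    est = estimate_transitions(hist)
    for age in (40, 60):
        mkm = modified_km_lifetime_risk(hist, State.PRE, age, n_boot=5)
        exact = lifetime_quantities_exact(est, age, State.PRE)["lifetime_risk"]
        assert mkm["risk"] == pytest.approx(exact, abs=1e-10)


def test_modified_km_unstable_flag():
    hist = make_histories([{"entry_age": 30.0, "censor_age": 40.0}])
    res = modified_km_lifetime_risk(hist, State.PRE, 20)
    assert res["unstable"]
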