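"""Monte Carlo cohort simulation against exact matrix-propagation oracles."""

import numpy as np
import pytest

from liferisk.registry import default_truth_table
from liferisk.simulate import (
    SimulationError,
    bootstrap_lifetime,
    cohort_to_histories,
    life_years,
    lifetime_quantities_exact,
    occupancy_grid,
    remaining_lifetime_risk,
    simulate_cohort,
    validate_against_observed,
)
from liferisk.states import State
from liferisk.transitions import TransitionTable


def constant_chain(p_pre_dm=0.2, p_pre_death=0.1, p_n_pre=0.05, p_n_dm=0.0,
                   p_n_death=0.05, p_dm_death=0.15):
    ones = np.ones(111)
    return TransitionTable.from_hazards(
        normo_pre=p_n_pre * ones, normo_dm=p_n_dm * ones, pre_dm=p_pre_dm * ones,
        death_normo=p_n_death * ones, death_pre=p_pre_death * ones,
        death_dm=p_dm_death * ones,
    )


def test_certain_death_chain():
    ones = np.ones(111)
    t = TransitionTable.from_hazards(0 * ones, 0 * ones, 0 * ones,
                                     ones, ones, ones)
    cohort = simulate_cohort(t, 1000, seed=0, start_age=30)
    assert (cohort.death_age == 31).all()
    est = remaining_lifetime_risk(cohort, 30, State.NORMO)
    assert est.lifetime_risk == 0.0


def test_geometric_competing_absorption():
    """From prediabetes with constant annual (stay .7, dm .2, death .1), the
    eventual-diabetes probability is 0.2/0.3 = 2/3."""
    t = constant_chain()
    cohort = simulate_cohort(t, 100_000, seed=1, start_age=20,
                             start_state=State.PRE)
    est = remaining_lifetime_risk(cohort, 20, State.PRE)
    p = 2.0 / 3.0
    se = np.sqrt(p * (1 - p) / cohort.n)
    assert abs(est.lifetime_risk - p) < 3 * se
    exact = lifetime_quantities_exact(t, 20, State.PRE)
    assert exact["lifetime_risk"] == pytest.approx(p, abs=1e-9)


def test_simulation_matches_matrix_propagation():
    """All reported quantities agree with iterating the chain's distribution
    vector, at Monte Carlo scale."""
    t = default_truth_table("pooled")
    cohort = simulate_cohort(t, 100_000, seed=2)
    for origin in (State.PRE, State.NORMO):
        for age in (20, 40, 60):
            est = life_years(cohort, age, origin)
            exact = lifetime_quantities_exact(t, age, origin)
            n = est.n_conditioning
            se_risk = np.sqrt(exact["lifetime_risk"] * (1 - exact["lifetime_risk"]) / n)
            assert abs(est.lifetime_risk - exact["lifetime_risk"]) < 3 * se_risk
            # life-years standard errors from per-person dispersion (< 30y sd)
            assert abs(est.years_with_dm - exact["years_with_dm"]) < 3 * 30 / np.sqrt(n)
            assert abs(est.years_without_dm - exact["years_without_dm"]) < 3 * 30 / np.sqrt(n)


def test_constant_hazard_life_years_closed_form():
    """Under constant hazards the expected years in each state are geometric
    sums of survival probabilities."""
    t = constant_chain()
    exact = lifetime_quantities_exact(t, 100, State.PRE)
    # from PRE at 100 with stay-prob .7 up to 110: sum_{k=0..9} 0.7^k years
    expect_without = (1 - 0.7 ** 10) / 0.3
    assert exact["years_without_dm"] == pytest.approx(expect_without, rel=1e-9)
    cohort = simulate_cohort(t, 100_000, seed=3, start_age=100, start_state=State.PRE)
    est = life_years(cohort, 100, State.PRE)
    assert abs(est.years_without_dm - expect_without) < 3 * 3 / np.sqrt(cohort.n)


def test_life_year_identity_and_truncation():
    """Years with + years without equal remaining expectancy (truncated at
    110) individual by individual, hence in means."""
    t = default_truth_table("M")
    cohort = simulate_cohort(t, 20_000, seed=4)
    for age in (20, 60):
        est = life_years(cohort, age, State.PRE)
        cond = cohort.state_at(age) == State.PRE
        expectancy = (np.minimum(cohort.end_age()[cond], 110) - age).mean()
        assert est.years_with_dm + est.years_without_dm == pytest.approx(expectancy)


def test_prop_with_dm_is_mean_of_individual_fractions():
    """The per-individual-fraction mean differs from the ratio of mean
    durations: a cohort of one late-onset and one never-onset person shows
    the gap."""
    from liferisk.simulate import SimulatedCohort

    cohort = SimulatedCohort(
        pre_onset=np.array([20.0, 20.0]),
        dm_onset=np.array([30.0, np.nan]),
        death_age=np.array([50.0, 40.0]),
        start_age=0, start_state=State.NORMO, sex="pooled", seed=0,
    )
    est = life_years(cohort, 20, State.PRE)
    # person 1: 10y without, 20y with (2/3); person 2: 20y without, 0y with
    assert est.prop_with_dm == pytest.approx((2 / 3 + 0) / 2)
    ratio = est.years_with_dm / (est.years_with_dm + est.years_without_dm)
    assert ratio == pytest.approx(20 / 50)
    assert abs(est.prop_with_dm - ratio) > 0.05


def test_risk_declines_with_index_age_and_origin_ordering():
    """On the default schedule the remaining lifetime risk falls with index
    age, and prediabetes always carries more risk than normoglycemia."""
    for sex in ("M", "F"):
        t = default_truth_table(sex)
        risks = {}
        for origin in (State.PRE, State.NORMO):
            r = [lifetime_quantities_exact(t, a, origin)["lifetime_risk"]
                 for a in (20, 40, 60)]
            assert r[0] > r[1] > r[2]
            risks[origin] = r
        assert all(p > n for p, n in zip(risks[State.PRE], risks[State.NORMO]))


def test_pre_risk_dominates_normo_under_hazard_ordering():
    """Coupling property: when the diabetes hazard from prediabetes weakly
    dominates the one from normoglycemia at every age (and mortality is
    shared), the lifetime risk from prediabetes dominates too."""
    rng = np.random.default_rng(5)
    for _ in range(5):
        base = rng.uniform(0.0, 0.1, 111)
        extra = rng.uniform(0.0, 0.1, 111)
        q = rng.uniform(0.0, 0.05, 111)
        t = TransitionTable.from_hazards(
            normo_pre=rng.uniform(0, 0.05, 111), normo_dm=base,
            pre_dm=np.clip(base + extra, 0, 1),
            death_normo=q, death_pre=q, death_dm=np.clip(2 * q, 0, 1))
        for age in (0, 30, 70):
            rp = lifetime_quantities_exact(t, age, State.PRE)["lifetime_risk"]
            rn = lifetime_quantities_exact(t, age, State.NORMO)["lifetime_risk"]
            assert rp >= rn - 1e-12


def test_simulation_reproducible_and_start_state():
    t = default_truth_table()
    a = simulate_cohort(t, 5_000, seed=9, start_age=20, start_state=State.PRE)
    b = simulate_cohort(t, 5_000, seed=9, start_age=20, start_state=State.PRE)
    np.testing.assert_array_equal(a.dm_onset, b.dm_onset)
    assert (a.pre_onset == 20).all()
    with pytest.raises(SimulationError):
        simulate_cohort(t, 10, seed=0, start_age=200)


def test_occupancy_rows_are_distributions():
    t = default_truth_table("F")
    occ = occupancy_grid(t, 20, State.PRE)
    np.testing.assert_allclose(occ[20:].sum(axis=1), 1.0, atol=1e-9)
    # ever-diabetes probability is non-decreasing in age
    ever = occ[:, 2] + occ[:, 4]
    assert (np.diff(ever[20:]) >= -1e-12).all()


def test_bootstrap_intervals_cover_point_estimate(dense_histories):
    from liferisk.estimation import estimate_transitions

    t = estimate_transitions(dense_histories[dense_histories["person_id"] < 20_000])
    cis = bootstrap_lifetime(t, [40], [State.PRE], n_boot=30, seed=6, use_exact=True)
    lo, hi = cis[(40, State.PRE)]["lifetime_risk"]
    point = lifetime_quantities_exact(t, 40, State.PRE)["lifetime_risk"]
    assert lo <= point <= hi
    assert hi - lo < 0.2


def test_validation_detects_perturbed_hazard():
    """Doubling the diabetes hazard in the simulated table shows up as a
    large observed-vs-predicted discrepancy; the matched table does not."""
    t = default_truth_table("pooled")
    cohort_true = simulate_cohort(t, 50_000, seed=7)
    reference = cohort_to_histories(simulate_cohort(t, 50_000, seed=8))
    # with two Monte Carlo curves of this size, the 0.02 noise budget needs a
    # few thousand at risk on both sides
    ok = validate_against_observed(cohort_true, reference, min_at_risk=5000)
    assert (ok["max_discrepancy"] < 0.02).all()

    boosted = t.probs.copy()
    boosted[:, State.PRE, State.DM] = np.minimum(
        2 * boosted[:, State.PRE, State.DM],
        1 - boosted[:, State.PRE, State.DEATH])
    boosted[:, State.PRE, State.PRE] = 1 - boosted[:, State.PRE, 2:].sum(axis=1)
    t2 = TransitionTable(probs=boosted)
    cohort_boosted = simulate_cohort(t2, 50_000, seed=9)
    bad = validate_against_observed(cohort_boosted, reference, min_at_risk=500)
    assert (bad["max_discrepancy"] > 0.05).any()


def test_identical_inputs_zero_discrepancy():
    t = default_truth_table("pooled")
    cohort = simulate_cohort(t, 20_000, seed=10)
    hist = cohort_to_histories(cohort)
    out = validate_against_observed(cohort, hist, min_at_risk=100)
    assert (out["max_discrepancy"] == 0.0).all()
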