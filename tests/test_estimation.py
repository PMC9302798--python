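"""Transition-table machinery and the discrete-time transition estimator."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import make_histories
from liferisk.estimation import (
    EstimationError,
    crude_incidence,
    estimate_transitions,
    incidence_rate,
)
from liferisk.registry import default_truth_table
from liferisk.states import State
from liferisk.transitions import TransitionTable


# -- TransitionTable ---------------------------------------------------------

def test_table_validation_catches_bad_rows():
    t = default_truth_table()
    bad = t.probs.copy()
    bad[50, 0, 0] += 0.5
    with pytest.raises(ValueError):
        TransitionTable(probs=bad).validate()
    rev = t.probs.copy()
    rev[50, State.DM, State.PRE] = rev[50, State.DM, State.DM]
    rev[50, State.DM, State.DM] = 0.0
    with pytest.raises(ValueError):
        TransitionTable(probs=rev).validate()


def test_table_csv_round_trip(tmp_path):
    t = default_truth_table("F")
    path = tmp_path / "t.csv"
    t.to_csv(path)
    back = TransitionTable.read_csv(path)
    assert back.sex == "F"
    np.testing.assert_allclose(back.probs, t.probs, atol=1e-12)


def test_substitute_mortality_hand_case():
    """Row (0, .6, .3, .1) with death probability raised to .4 rescales the
    surviving mass proportionally to (0, .4, .2, .4)."""
    probs = np.zeros((111, 4, 4))
    probs[:, State.NORMO] = [0.7, 0.2, 0.05, 0.05]
    probs[:, State.PRE] = [0.0, 0.6, 0.3, 0.1]
    probs[:, State.DM] = [0.0, 0.0, 0.9, 0.1]
    probs[:, State.DEATH, State.DEATH] = 1.0
    t = TransitionTable(probs=probs)
    q = np.full((111, 3), 0.4)
    q[:, State.NORMO] = 0.05
    q[:, State.DM] = 0.1
    out = t.substitute_mortality(q)
    np.testing.assert_allclose(out.probs[40, State.PRE], [0.0, 0.4, 0.2, 0.4])
    # untouched rows keep their death probability
    np.testing.assert_allclose(out.probs[40, State.NORMO], probs[40, State.NORMO])


def test_substitute_mortality_identity_and_validation():
    t = default_truth_table()
    same = t.substitute_mortality(t.death_probabilities())
    np.testing.assert_allclose(same.probs, t.probs, atol=1e-12)
    with pytest.raises(ValueError):
        t.substitute_mortality(np.full((111, 3), 1.5))


@settings(max_examples=30, derandomize=True)
@given(st.integers(0, 2**32 - 1))
def test_substitute_mortality_rows_remain_stochastic(seed):
    rng = np.random.default_rng(seed)
    t = default_truth_table()
    q = rng.random((111, 3))
    out = t.substitute_mortality(q)
    out.validate()
    np.testing.assert_allclose(out.probs[:, :3, State.DEATH], q, atol=1e-12)


# -- estimator ---------------------------------------------------------------

def _full_obs(rows):
    return make_histories([{"entry_age": 45.0, "censor_age": 60.0,
                            "linkage_end_age": 70.0, **r} for r in rows])


def test_estimator_hand_fixture_row():
    """10 persons prediabetic at 50 followed through 51: 3 progress, 1 dies,
    6 stay; the age-50 row is (0, .6, .3, .1)."""
    rows = []
    rows += [{"pre_onset_age": 50.0, "dm_onset_age": 51.0} for _ in range(3)]
    rows += [{"pre_onset_age": 50.0, "death_age": 50.5, "censor_age": 50.0}]
    rows += [{"pre_onset_age": 50.0} for _ in range(6)]
    hist = _full_obs(rows)
    t = estimate_transitions(hist)
    np.testing.assert_allclose(t.probs[50, State.PRE], [0.0, 0.6, 0.3, 0.1])
    assert t.n_at_risk[50, State.PRE] == 10


def test_estimator_no_events_gives_identity_rows():
    hist = _full_obs([{} for _ in range(5)])
    t = estimate_transitions(hist)
    for a in range(45, 59):
        np.testing.assert_allclose(t.probs[a, State.NORMO],
                                   [1.0, 0.0, 0.0, 0.0])


def test_estimator_empty_stratum_errors():
    hist = _full_obs([{}])
    with pytest.raises(EstimationError):
        estimate_transitions(hist, sex="M")  # fixture is all-female


def test_pooled_equals_count_recombination(dense_histories):
    """Pooling the sex-specific tables on their counts reproduces the pooled
    estimate exactly."""
    tm = estimate_transitions(dense_histories, sex="M")
    tf = estimate_transitions(dense_histories, sex="F")
    pooled = estimate_transitions(dense_histories, sex="pooled")
    recombined = TransitionTable.pool([tm, tf])
    np.testing.assert_allclose(recombined.probs, pooled.probs, atol=1e-12)
    np.testing.assert_allclose(recombined.n_at_risk, pooled.n_at_risk)


def test_period_split_partitions_person_time(dense_histories):
    early = estimate_transitions(dense_histories, period=(2001, 2009))
    late = estimate_transitions(dense_histories, period=(2010, 2019))
    full = estimate_transitions(dense_histories, period=(2001, 2019))
    assert early.n_at_risk.sum() + late.n_at_risk.sum() == full.n_at_risk.sum()


def test_parameter_recovery_small_n(dense_config, dense_histories):
    """Cellwise recovery of the generating probabilities at modest n: errors
    behave like binomial noise (checked in depth in the acceptance suite)."""
    truth = dense_config.truth()
    sub = dense_histories[dense_histories["person_id"] < 30_000]
    t = estimate_transitions(sub, sex="F")
    z = _recovery_z(t, truth["F"], min_exposure=500)
    assert z.size > 200
    assert (z > 3).mean() <= 0.005 + 2.0 / z.size
    assert z.max() < 4.5


def _recovery_z(est, truth, min_exposure=500):
    """Standardized cellwise errors, each scaled by the sampling SE of its
    part of the two-part estimator."""
    z = []
    for s in (State.NORMO, State.PRE, State.DM):
        n1 = est.n_at_risk[:, s]
        n2 = est.n_at_risk_living[:, s]
        for a in np.flatnonzero(n1 >= min_exposure):
            q = truth.probs[a, s, State.DEATH]
            se = np.sqrt(q * (1 - q) / n1[a])
            if se > 0:
                z.append(abs(est.probs[a, s, State.DEATH] - q) / se)
            if n2[a] < min_exposure or q >= 1:
                continue
            for d in range(s, State.DEATH):
                split = truth.probs[a, s, d] / (1 - q)
                var = (split * (1 - split) * (1 - q) ** 2 / n2[a]
                       + split ** 2 * q * (1 - q) / n1[a])
                if var > 0:
                    z.append(abs(est.probs[a, s, d] - truth.probs[a, s, d])
                             / np.sqrt(var))
    return np.asarray(z)


# -- crude incidence ---------------------------------------------------------

def test_incidence_rate_arithmetic():
    assert incidence_rate(250, 1000.0) == 250.0
    assert incidence_rate(0, 100.0) == 0.0
    with pytest.raises(EstimationError):
        incidence_rate(1, 0.0)


def test_crude_incidence_person_time_accounting():
    hist = make_histories([
        # prediabetes at 50, diabetes at 54: 4 person-years, 1 event
        {"entry_age": 48.0, "pre_onset_age": 50.0, "dm_onset_age": 54.0,
         "censor_age": 60.0},
        # prediabetes at 60, censored at 70: 10 person-years
        {"entry_age": 60.0, "pre_onset_age": 60.0, "censor_age": 70.0},
        # prediabetes at 40, dies at 46: 6 person-years
        {"entry_age": 40.0, "pre_onset_age": 40.0, "death_age": 46.0,
         "censor_age": 46.0},
        # never prediabetic: contributes nothing from PRE
        {"entry_age": 30.0, "censor_age": 50.0},
    ])
    rate, events, py = crude_incidence(hist, State.PRE, State.DM)
    assert events == 1
    assert py == pytest.approx(4 + 10 + 6)
    assert rate == pytest.approx(1000.0 / 20.0)


def test_crude_incidence_invariant_to_contiguous_split():
    """Splitting one event-free follow-up into two contiguous persons leaves
    total person-time and the rate unchanged."""
    whole = make_histories([{"entry_age": 30.0, "censor_age": 50.0}])
    split = make_histories([
        {"entry_age": 30.0, "censor_age": 40.0},
        {"entry_age": 40.0, "censor_age": 50.0},
    ])
    _, _, py_whole = crude_incidence(whole, State.NORMO, State.DM)
    _, _, py_split = crude_incidence(split, State.NORMO, State.DM)
    assert py_whole == pytest.approx(py_split)
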