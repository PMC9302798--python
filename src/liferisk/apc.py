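"""Age-period-cohort rate models with natural cubic splines.

Diabetes incidence and mortality observed over a bounded calendar window
cover only part of each birth cohort's life course. A log-linear Poisson rate
model with natural cubic spline effects for age, period, and cohort
extrapolates the rates to unobserved ages, after which birth-cohort lifetime
risks follow from the modified Kaplan-Meier accumulation of the extrapolated
annual probabilities.

The exact collinearity cohort = period - age makes the three spline effects
unidentifiable up to a linear drift. Here the period effect is constrained to
have zero slope (its basis is residualized against an intercept and linear
trend), attributing the drift to cohort -- the natural allocation when the
target is cohort-indexed lifetime risk. Natural splines are linear beyond
their boundary knots, so extrapolation continues each dimension's trend at
the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm


def natural_spline_basis(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Natural cubic spline basis (truncated-power construction).

    Returns ``len(knots) - 1`` columns, the first being the linear term; the
    basis is linear beyond the boundary knots, so it extrapolates sensibly.
    No intercept column is included.
    """
    x = np.asarray(x, dtype=float)
    knots = np.asarray(sorted(set(np.asarray(knots, dtype=float))))
    if knots.size < 2:
        raise ValueError("need at least two distinct knots")
    k_last = knots[-1]
    k_penult = knots[-2]

    def d(k: float) -> np.ndarray:
        num = np.maximum(x - k, 0.0) ** 3 - np.maximum(x - k_last, 0.0) ** 3
        return num / (k_last - k)

    cols = [x]
    d_penult = d(k_penult)
    for k in knots[:-2]:
        cols.append(d(k) - d_penult)
    return np.column_stack(cols)


def _scale(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Affine map of a dimension onto [0, 1] over its knot span (pure
    reparametrization; keeps the cubic basis well conditioned on
    calendar-scale values)."""
    lo, hi = float(np.min(knots)), float(np.max(knots))
    if hi <= lo:
        raise ValueError("degenerate knot span: dimension has no spread")
    return (np.asarray(x, float) - lo) / (hi - lo)


def _scaled_basis(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    return natural_spline_basis(_scale(x, knots), _scale(knots, knots))


def default_knots(values: np.ndarray, n_interior: int = 3) -> np.ndarray:
    """Boundary knots at the data extremes plus evenly spaced interior knots."""
    lo, hi = float(np.min(values)), float(np.max(values))
    interior = np.linspace(lo, hi, n_interior + 2)[1:-1]
    return np.concatenate([[lo], interior, [hi]])


@dataclass
class APCRateModel:
    """A fitted age-period-cohort Poisson rate model for one outcome."""

    knots_age: np.ndarray
    knots_period: np.ndarray
    knots_cohort: np.ndarray
    period_detrend: np.ndarray  # least-squares coefficients removed from the period basis
    params: np.ndarray
    outcome: str = "rate"

    def _design(self, age: np.ndarray, period: np.ndarray,
                cohort: np.ndarray) -> np.ndarray:
        ba = _scaled_basis(age, self.knots_age)
        bp = _scaled_basis(period, self.knots_period)
        z = np.column_stack([np.ones_like(period), _scale(period, self.knots_period)])
        bp = bp - z @ self.period_detrend
        bc = _scaled_basis(cohort, self.knots_cohort)
        return np.column_stack([np.ones_like(age), ba, bp, bc])

    def predict_rate(self, age: np.ndarray, cohort: np.ndarray) -> np.ndarray:
        """Event rate per person-year on an (age, cohort) grid; the period is
        implied by period = cohort + age.

        The detrended period effect carries only within-window curvature, so
        outside the observed calendar span it is held at its boundary value
        (extrapolating it linearly over decades would reintroduce the drift
        the identifiability constraint removed); age and cohort effects
        extrapolate linearly, as natural splines do.
        """
        age = np.asarray(age, dtype=float)
        cohort = np.asarray(cohort, dtype=float)
        period = np.clip(cohort + age, self.knots_period.min(), self.knots_period.max())
        eta = self._design(age, period, cohort) @ self.params
        return np.exp(eta)

    def rate_grid(self, ages: np.ndarray, cohorts: np.ndarray) -> pd.DataFrame:
        rows = []
        for c in cohorts:
            r = self.predict_rate(np.asarray(ages, float), np.full(len(ages), c, float))
            rows.append(pd.DataFrame({"outcome": self.outcome, "cohort": c,
                                      "age": ages, "rate": r}))
        return pd.concat(rows, ignore_index=True)


def fit_apc(
    cells: pd.DataFrame,
    knots_age: np.ndarray | None = None,
    knots_period: np.ndarray | None = None,
    knots_cohort: np.ndarray | None = None,
    outcome: str = "rate",
) -> APCRateModel:
    """Fit the log-linear rate model to events/exposure cells.

    ``cells`` needs columns ``age``, ``period``, ``events``, ``person_years``;
    only cells with positive exposure are used. Knots default to the data
    extremes plus three evenly spaced interior knots per dimension (supply
    explicit knot vectors to reproduce a manually chosen placement).
    """
    use = cells[cells["person_years"] > 0]
    if len(use) == 0:
        raise ValueError("no cells with positive exposure")
    age = use["age"].to_numpy(float)
    period = use["period"].to_numpy(float)
    cohort = period - age
    events = use["events"].to_numpy(float)
    py = use["person_years"].to_numpy(float)

    ka = np.asarray(knots_age, float) if knots_age is not None else default_knots(age)
    kp = np.asarray(knots_period, float) if knots_period is not None else default_knots(period)
    kc = np.asarray(knots_cohort, float) if knots_cohort is not None else default_knots(cohort)

    bp = _scaled_basis(period, kp)
    z = np.column_stack([np.ones_like(period), _scale(period, kp)])
    detrend, *_ = np.linalg.lstsq(z, bp, rcond=None)

    model = APCRateModel(knots_age=ka, knots_period=kp, knots_cohort=kc,
                         period_detrend=detrend, params=np.zeros(0), outcome=outcome)
    X = model._design(age, period, cohort)
    rank = np.linalg.matrix_rank(X)
    # one degree of collinearity (the APC drift) is absorbed by the detrending;
    # anything further means a dimension carries no curvature information
    if rank < X.shape[1] - 1:
        raise ValueError(
            "rank-deficient design beyond the age-period-cohort drift; "
            "reduce the knots of the sparsest dimension"
        )
    glm = sm.GLM(events, X, family=sm.families.Poisson(), exposure=py)
    res = glm.fit()
    model.params = np.asarray(res.params)
    return model


def cohort_lifetime_risk(
    incidence_model: APCRateModel,
    mortality_model: APCRateModel | None,
    birth_year: float,
    index_age: int,
    max_age: int = 110,
) -> float:
    """Lifetime risk of diabetes for one birth cohort from ``index_age``.

    Extrapolated annual rates are converted to probabilities by
    ``p = 1 - exp(-rate)`` and accumulated by the modified Kaplan-Meier sum
    with death as the competing event (zero mortality when no mortality model
    is supplied).
    """
    ages = np.arange(index_age, max_age, dtype=float)
    if ages.size == 0:
        raise ValueError("index_age must be below max_age")
    cohorts = np.full(ages.size, float(birth_year))
    r_inc = incidence_model.predict_rate(ages, cohorts)
    p_dm = 1.0 - np.exp(-r_inc)
    if mortality_model is not None:
        r_mort = mortality_model.predict_rate(ages, cohorts)
        p_death = 1.0 - np.exp(-r_mort)
    else:
        p_death = np.zeros_like(p_dm)
    total = p_dm + p_death
    over = total > 1.0
    p_dm = np.where(over, p_dm / total, p_dm)
    p_death = np.where(over, p_death / total, p_death)
    surv = np.cumprod(1.0 - p_dm - p_death)
    surv_prev = np.concatenate([[1.0], surv[:-1]])
    return float(np.sum(surv_prev * p_dm))


def rate_cells_from_histories(
    histories: pd.DataFrame,
    origin_state,
    event: str = "dm",
    max_age: int = 110,
) -> pd.DataFrame:
    """Events and person-years by (age, calendar period) cells.

    Person-time at risk follows the same origin conventions as the crude
    incidence: from entry into the origin state to the event, death, or
    censoring; each whole or partial year of age is attributed to the
    calendar year ``birth_year + age``. ``event`` is ``"dm"`` (progression)
    or ``"death"``.
    """
    from .states import State

    entry = histories["entry_age"].to_numpy(float)
    censor = histories["censor_age"].to_numpy(float)
    death = (histories["death_age"].to_numpy(float)
             if "death_age" in histories else np.full(len(histories), np.nan))
    pre = histories["pre_onset_age"].to_numpy(float)
    dm = histories["dm_onset_age"].to_numpy(float)
    birth = histories["birth_year"].to_numpy(float)

    if origin_state == State.PRE:
        start = pre
        keep = np.isfinite(pre) & ~(dm <= pre)
    else:
        start = entry
        keep = ~((pre <= entry) | (dm <= entry))
    if event == "dm":
        evt = dm
        stop = np.fmin(np.fmin(dm, death), censor)
    elif event == "death":
        # vital status is known through the linkage bound regardless of
        # testing; diabetes onset censors the diabetes-free mortality clock
        evt = death
        linkage = (histories["linkage_end_age"].to_numpy(float)
                   if "linkage_end_age" in histories
                   else np.full(len(histories), np.nan))
        linkage = np.where(np.isfinite(linkage), linkage,
                           np.where(np.isfinite(death), death, censor))
        stop = np.fmin(np.fmin(dm, death), linkage)
    else:
        raise ValueError(f"unknown event: {event!r}")
    stop = np.fmax(stop, start)

    idx = np.flatnonzero(keep & np.isfinite(start) & (stop > start))
    counts = (np.floor(stop[idx]).astype(int) - np.floor(start[idx]).astype(int) + 1)
    pid = np.repeat(idx, counts)
    offs = _ragged(counts)
    a = np.floor(start)[pid].astype(int) + offs
    seg_start = np.maximum(a, start[pid])
    seg_end = np.minimum(a + 1, stop[pid])
    py = np.maximum(seg_end - seg_start, 0.0)
    year = birth[pid] + a

    cells = pd.DataFrame({"age": a, "period": year, "py": py})
    py_tab = cells.groupby(["age", "period"], as_index=False)["py"].sum()

    has_evt = keep & np.isfinite(evt) & (evt >= start) & (evt <= stop + 1e-9)
    ev_age = np.floor(evt[has_evt]).astype(int)
    ev_year = birth[has_evt] + ev_age
    ev_tab = (pd.DataFrame({"age": ev_age, "period": ev_year})
              .groupby(["age", "period"]).size().rename("events").reset_index())
    out = py_tab.merge(ev_tab, on=["age", "period"], how="left")
    out["events"] = out["events"].fillna(0).astype(int)
    out = out.rename(columns={"py": "person_years"})
    out = out[(out["age"] >= 0) & (out["age"] <= max_age)]
    return out[["age", "period", "events", "person_years"]]


def _ragged(counts: np.ndarray) -> np.ndarray:
    total = int(counts.sum())
    if total == 0:
        return np.zeros(0, dtype=int)
    ends = np.cumsum(counts)
    return np.arange(total) - np.repeat(ends - counts, counts)
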