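"""Age- and sex-indexed one-year transition probability tables.

A :class:`TransitionTable` holds, for every integer age 0..110, a 4x4
row-stochastic matrix of one-year transition probabilities between the states
normoglycemia, prediabetes, diabetes, and death, together with the transition
and at-risk counts it was estimated from (zero for analytically constructed
tables). Structurally forbidden transitions (reversion in severity, leaving
death) are exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .states import ALLOWED_TRANSITIONS, MAX_AGE, N_STATES, State

_ROW_TOL = 1e-9


@dataclass
class TransitionTable:
    """One-year transition probabilities P[age, from_state, to_state].

    Parameters
    ----------
    probs : ndarray of shape (max_age + 1, 4, 4)
        Row-stochastic matrices; ``probs[a, s, t]`` is the probability of being
        in state ``t`` at age ``a + 1`` given state ``s`` at age ``a``.
    n_transitions, n_at_risk : ndarray, optional
        Observed transition counts and at-risk counts; zero when the table is
        analytic rather than estimated.
    sex : str
        ``"M"``, ``"F"`` or ``"pooled"``.
    """

    probs: np.ndarray
    n_transitions: np.ndarray = field(default=None)  # type: ignore[assignment]
    n_at_risk: np.ndarray = field(default=None)  # type: ignore[assignment]
    n_at_risk_living: np.ndarray = field(default=None)  # type: ignore[assignment]
    sex: str = "pooled"
    max_age: int = MAX_AGE

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        expected = (self.max_age + 1, N_STATES, N_STATES)
        if self.probs.shape != expected:
            raise ValueError(f"probs must have shape {expected}, got {self.probs.shape}")
        if self.n_transitions is None:
            self.n_transitions = np.zeros_like(self.probs)
        if self.n_at_risk is None:
            self.n_at_risk = np.zeros((self.max_age + 1, N_STATES))
        self.n_transitions = np.asarray(self.n_transitions, dtype=float)
        self.n_at_risk = np.asarray(self.n_at_risk, dtype=float)
        if self.n_at_risk_living is None:
            self.n_at_risk_living = self.n_transitions[:, :, :State.DEATH].sum(axis=2)
        self.n_at_risk_living = np.asarray(self.n_at_risk_living, dtype=float)

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        """Raise ``ValueError`` if rows are not stochastic or structure is violated."""
        p = self.probs
        if np.any(p < -_ROW_TOL) or np.any(p > 1 + _ROW_TOL):
            raise ValueError("transition probabilities must lie in [0, 1]")
        rows = p.sum(axis=2)
        if not np.allclose(rows, 1.0, atol=1e-6):
            bad = np.argwhere(~np.isclose(rows, 1.0, atol=1e-6))
            raise ValueError(f"non-stochastic rows at (age, state): {bad[:5].tolist()}")
        forbidden = p[:, ~ALLOWED_TRANSITIONS]
        if np.any(forbidden != 0.0):
            raise ValueError("structurally forbidden transitions carry positive mass")

    @property
    def ages(self) -> np.ndarray:
        return np.arange(self.max_age + 1)

    # -- construction helpers ----------------------------------------------

    @classmethod
    def from_hazards(
        cls,
        normo_pre: np.ndarray,
        normo_dm: np.ndarray,
        pre_dm: np.ndarray,
        death_normo: np.ndarray,
        death_pre: np.ndarray,
        death_dm: np.ndarray,
        sex: str = "pooled",
        max_age: int = MAX_AGE,
    ) -> "TransitionTable":
        """Assemble a table from per-age annual transition probabilities.

        Each argument is an array of length ``max_age + 1`` giving the annual
        probability of the named transition; the diagonal absorbs the remainder.
        Competing probabilities out of a state are rescaled proportionally if
        they would exceed 1.
        """
        n = max_age + 1
        p = np.zeros((n, N_STATES, N_STATES))
        arrs = [np.broadcast_to(np.asarray(a, dtype=float), (n,)).copy()
                for a in (normo_pre, normo_dm, pre_dm, death_normo, death_pre, death_dm)]
        npre, ndm, pdm, qn, qp, qd = arrs
        for a in arrs:
            if np.any(a < 0) or np.any(a > 1):
                raise ValueError("annual transition probabilities must lie in [0, 1]")
        # normo row
        out = npre + ndm + qn
        scale = np.where(out > 1, 1.0 / np.maximum(out, 1e-300), 1.0)
        p[:, State.NORMO, State.PRE] = npre * scale
        p[:, State.NORMO, State.DM] = ndm * scale
        p[:, State.NORMO, State.DEATH] = qn * scale
        p[:, State.NORMO, State.NORMO] = 1.0 - p[:, State.NORMO, 1:].sum(axis=1)
        # pre row
        out = pdm + qp
        scale = np.where(out > 1, 1.0 / np.maximum(out, 1e-300), 1.0)
        p[:, State.PRE, State.DM] = pdm * scale
        p[:, State.PRE, State.DEATH] = qp * scale
        p[:, State.PRE, State.PRE] = 1.0 - p[:, State.PRE, 2:].sum(axis=1)
        # dm row
        p[:, State.DM, State.DEATH] = np.minimum(qd, 1.0)
        p[:, State.DM, State.DM] = 1.0 - p[:, State.DM, State.DEATH]
        # death absorbing
        p[:, State.DEATH, State.DEATH] = 1.0
        table = cls(probs=p, sex=sex, max_age=max_age)
        table.validate()
        return table

    @classmethod
    def identity(cls, sex: str = "pooled", max_age: int = MAX_AGE) -> "TransitionTable":
        """A table with no movement at all (everyone stays in place, forever)."""
        zeros = np.zeros(max_age + 1)
        return cls.from_hazards(zeros, zeros, zeros, zeros, zeros, zeros,
                                sex=sex, max_age=max_age)

    # -- operations ---------------------------------------------------------

    def substitute_mortality(self, death_probs: np.ndarray) -> "TransitionTable":
        """Replace the death column, rescaling surviving mass proportionally.

        ``death_probs[a, s]`` is the new annual death probability from living
        state ``s`` at age ``a`` (shape ``(max_age + 1, 3)``). The non-death
        destinations keep their original conditional shares, scaled so each row
        remains stochastic. Used to re-estimate lifetime risks of one
        population under the mortality schedule of another.
        """
        q = np.asarray(death_probs, dtype=float)
        if q.shape != (self.max_age + 1, 3):
            raise ValueError(f"death_probs must have shape {(self.max_age + 1, 3)}")
        if np.any(q < 0) or np.any(q > 1):
            raise ValueError("replacement death probabilities must lie in [0, 1]")
        p = self.probs.copy()
        for s in (State.NORMO, State.PRE, State.DM):
            old_q = p[:, s, State.DEATH]
            old_surv = 1.0 - old_q
            new_q = q[:, s]
            new_surv = 1.0 - new_q
            with np.errstate(divide="ignore", invalid="ignore"):
                scale = np.where(old_surv > 0, new_surv / old_surv, 0.0)
            nondeath = p[:, s, :State.DEATH] * scale[:, None]
            # q_old == 1 leaves no conditional shares; park surviving mass on staying
            degenerate = (old_surv <= 0) & (new_surv > 0)
            nondeath[degenerate, :] = 0.0
            nondeath[degenerate, s] = new_surv[degenerate]
            p[:, s, :State.DEATH] = nondeath
            p[:, s, State.DEATH] = new_q
        out = replace(self, probs=p)
        out.validate()
        return out

    def death_probabilities(self) -> np.ndarray:
        """Annual death probability per (age, living state), shape (max_age+1, 3)."""
        return self.probs[:, :State.DEATH, State.DEATH].copy()

    @classmethod
    def pool(cls, tables: list["TransitionTable"]) -> "TransitionTable":
        """Exposure-weighted pooling of estimated tables (exact on counts)."""
        if not tables:
            raise ValueError("nothing to pool")
        max_age = tables[0].max_age
        trans = sum(t.n_transitions for t in tables)
        risk = sum(t.n_at_risk for t in tables)
        deaths = trans[:, :, State.DEATH]
        living = trans.copy()
        living[:, :, State.DEATH] = 0.0
        probs = probs_from_two_part(deaths, risk, living, max_age)
        out = cls(probs=probs, n_transitions=trans, n_at_risk=risk,
                  sex="pooled", max_age=max_age)
        out.validate()
        return out

    # -- input/output -------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        """Long format: one row per (sex, age, from_state, to_state)."""
        ages, froms, tos = np.meshgrid(
            self.ages, np.arange(N_STATES), np.arange(N_STATES), indexing="ij"
        )
        keep = ALLOWED_TRANSITIONS[froms, tos]
        return pd.DataFrame(
            {
                "sex": self.sex,
                "age": ages[keep],
                "from_state": [State(s).name for s in froms[keep]],
                "to_state": [State(s).name for s in tos[keep]],
                "probability": self.probs[ages[keep], froms[keep], tos[keep]],
                "n_transitions": self.n_transitions[ages[keep], froms[keep], tos[keep]],
                "n_at_risk": self.n_at_risk[ages[keep], froms[keep]],
                "n_at_risk_living": self.n_at_risk_living[ages[keep], froms[keep]],
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, max_age: int = MAX_AGE) -> "TransitionTable":
        probs = np.zeros((max_age + 1, N_STATES, N_STATES))
        trans = np.zeros_like(probs)
        risk = np.zeros((max_age + 1, N_STATES))
        ages = frame["age"].to_numpy(int)
        fr = frame["from_state"].map(lambda s: int(State[s])).to_numpy()
        to = frame["to_state"].map(lambda s: int(State[s])).to_numpy()
        probs[ages, fr, to] = frame["probability"].to_numpy(float)
        trans[ages, fr, to] = frame["n_transitions"].to_numpy(float)
        risk[ages, fr] = frame["n_at_risk"].to_numpy(float)
        living = None
        if "n_at_risk_living" in frame.columns:
            living = np.zeros((max_age + 1, N_STATES))
            living[ages, fr] = frame["n_at_risk_living"].to_numpy(float)
        sexes = frame["sex"].unique()
        sex = sexes[0] if len(sexes) == 1 else "pooled"
        out = cls(probs=probs, n_transitions=trans, n_at_risk=risk,
                  n_at_risk_living=living, sex=str(sex), max_age=max_age)
        out.validate()
        return out

    @classmethod
    def read_csv(cls, path, max_age: int = MAX_AGE) -> "TransitionTable":
        return cls.from_frame(pd.read_csv(path), max_age=max_age)


def probs_from_two_part(
    deaths: np.ndarray,
    death_exposure: np.ndarray,
    living_transitions: np.ndarray,
    max_age: int = MAX_AGE,
) -> np.ndarray:
    """Combine two-part counts into row-stochastic transition matrices.

    For each age and origin state the death probability is
    ``deaths / death_exposure`` (vital-linkage exposure); the surviving mass
    ``1 - q`` is split across living destinations in proportion to the
    glycemic-known transition counts. Ages whose origin state has no
    death exposure borrow the nearest populated age's finished row; an origin
    with no living-split information keeps all surviving mass in place.
    """
    n = max_age + 1
    probs = np.zeros((n, N_STATES, N_STATES))
    probs[:, State.DEATH, State.DEATH] = 1.0
    for s in (State.NORMO, State.PRE, State.DM):
        n1 = death_exposure[:, s]
        populated = np.flatnonzero(n1 > 0)
        if populated.size == 0:
            probs[:, s, s] = 1.0
            continue
        rows = np.zeros((n, N_STATES))
        with np.errstate(divide="ignore", invalid="ignore"):
            q = np.where(n1 > 0, deaths[:, s] / np.where(n1 > 0, n1, 1.0), 0.0)
        n2 = living_transitions[:, s, :].sum(axis=1)
        split = np.zeros((n, N_STATES))
        has_split = n2 > 0
        split[has_split] = (living_transitions[has_split, s, :]
                            / n2[has_split, None])
        split[~has_split, s] = 1.0  # no information: surviving mass stays put
        rows[:, :] = (1.0 - q)[:, None] * split
        rows[:, State.DEATH] = q
        # nearest-neighbor borrow for ages without exposure
        all_ages = np.arange(n)
        idx = np.clip(np.searchsorted(populated, all_ages), 0, populated.size - 1)
        left = populated[np.maximum(idx - 1, 0)]
        right = populated[idx]
        nearest = np.where(np.abs(all_ages - left) <= np.abs(right - all_ages),
                           left, right)
        empty = n1 <= 0
        rows[empty] = rows[nearest[empty]]
        rows[:, ~ALLOWED_TRANSITIONS[s]] = 0.0
        sums = rows.sum(axis=1)
        dead_rows = sums <= 0
        rows[dead_rows, s] = 1.0
        sums[dead_rows] = 1.0
        probs[:, s, :] = rows / sums[:, None]
    return probs
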