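"""The four-state illness-death model: normoglycemia, prediabetes, diabetes, death.

States are ordered by severity; the living states can only move up the order
(no reversion), diabetes is absorbing among the living, and death is absorbing.
"""

from __future__ import annotations

from enum import IntEnum

import numpy as np


class State(IntEnum):
    """Glycemic status of a person-year, ordered by severity."""

    NORMO = 0
    PRE = 1
    DM = 2
    DEATH = 3


N_STATES = 4
LIVING_STATES = (State.NORMO, State.PRE, State.DM)
STATE_NAMES = {s: s.name for s in State}
NAME_TO_STATE = {s.name: s for s in State}

#: allowed[i, j] is True when a one-year transition i -> j is structurally possible:
#: severity never decreases, death is reachable from every living state and absorbing.
ALLOWED_TRANSITIONS = np.zeros((N_STATES, N_STATES), dtype=bool)
for _s in State:
    for _t in State:
        if _s == State.DEATH:
            ALLOWED_TRANSITIONS[_s, _t] = _t == State.DEATH
        else:
            ALLOWED_TRANSITIONS[_s, _t] = _t >= _s
del _s, _t

MAX_AGE = 110


def state_from_name(name: str) -> State:
    try:
        return NAME_TO_STATE[name.upper()]
    except KeyError:
        raise ValueError(f"unknown state name: {name!r}") from None
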