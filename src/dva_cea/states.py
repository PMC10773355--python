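"""The five health states of the DVA Markov cohort model.

The chain tracks a primary-care registered population. Abuse status is
layered with identification status: a person experiencing abuse is either
not yet identified by their practice, or identified and referred — in which
case they are either receiving advocacy support or not. Death (all-cause,
including domestic homicide for the abuse states) is absorbing.

A single fixed state ordering is used for every matrix, trace and file in
the package to rule out silent transposition bugs.
"""

from __future__ import annotations

from enum import Enum


class HealthState(str, Enum):
    """Health states, in canonical order."""

    NO_ABUSE = "no_abuse"
    ABUSE_UNIDENTIFIED = "unidentified"
    ABUSE_ID_ADVOCATE = "id_advocate"
    ABUSE_ID_NO_ADVOCATE = "id_no_advocate"
    DEAD = "dead"


#: Canonical ordering of states in matrices and traces.
STATE_ORDER: tuple[HealthState, ...] = tuple(HealthState)

#: Integer index of each state under the canonical ordering.
STATE_INDEX: dict[HealthState, int] = {s: i for i, s in enumerate(STATE_ORDER)}

N_STATES: int = len(STATE_ORDER)

#: The four transient (alive) states, canonical order preserved.
ALIVE_STATES: tuple[HealthState, ...] = STATE_ORDER[:-1]

#: The three states associated with ongoing abuse exposure.
ABUSE_STATES: tuple[HealthState, ...] = (
    HealthState.ABUSE_UNIDENTIFIED,
    HealthState.ABUSE_ID_ADVOCATE,
    HealthState.ABUSE_ID_NO_ADVOCATE,
)
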