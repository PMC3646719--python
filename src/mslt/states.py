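"""Disability-state and survey-item encodings shared across the package.

The analysis tracks four states: three living levels of functional
limitation (healthy / moderately limited / severely limited) derived from
two SF-12-style activity-limitation items, plus death as an absorbing
state.  Integer codes are fixed here and used everywhere, including CSV
output, so files round-trip without a label dictionary.
"""

from __future__ import annotations

from enum import IntEnum

__all__ = [
    "State",
    "ItemLevel",
    "PainLevel",
    "LIVING_STATES",
    "MISSING",
    "STATE_LABELS",
    "ITEM_LABELS",
    "PAIN_LABELS",
]

# Sentinel integer for a missing categorical response (distinct from every
# substantive level, which are all >= 0).
MISSING: int = -1


class State(IntEnum):
    """Four-state disability classification; DEAD is absorbing."""

    HEALTHY = 0
    MODERATE = 1
    SEVERE = 2
    DEAD = 3


class ItemLevel(IntEnum):
    """Response levels of the two activity-limitation items."""

    NOT_LIMITED = 0
    LIMITED_A_LITTLE = 1
    LIMITED_A_LOT = 2


class PainLevel(IntEnum):
    """Five ordered levels of pain interference with normal work."""

    NOT_AT_ALL = 0
    A_LITTLE_BIT = 1
    MODERATELY = 2
    QUITE_A_BIT = 3
    EXTREMELY = 4


LIVING_STATES = (State.HEALTHY, State.MODERATE, State.SEVERE)

STATE_LABELS = {
    State.HEALTHY: "healthy",
    State.MODERATE: "moderately limited",
    State.SEVERE: "severely limited",
    State.DEAD: "dead",
}

ITEM_LABELS = {
    ItemLevel.NOT_LIMITED: "not limited",
    ItemLevel.LIMITED_A_LITTLE: "limited a little",
    ItemLevel.LIMITED_A_LOT: "limited a lot",
}

PAIN_LABELS = {
    PainLevel.NOT_AT_ALL: "not at all",
    PainLevel.A_LITTLE_BIT: "a little bit",
    PainLevel.MODERATELY: "moderately",
    PainLevel.QUITE_A_BIT: "quite a bit",
    PainLevel.EXTREMELY: "extremely",
}
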