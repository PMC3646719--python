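"""Map raw limitation items to disability states.

Three coding schemes are provided:

``code_state_3level``
    The main classification.  A respondent flagged as too ill/weak to be
    interviewed is severely limited regardless of the items.  Otherwise
    "limited a lot" on either the moderate-activity or strenuous-activity
    item codes severe; "limited a little" on either codes moderate; "not
    limited" on both codes healthy.  If neither item qualifies and at
    least one is missing, the state is missing (a single "not limited"
    answer cannot rule out limitation on the other item).

``code_state_2level``
    Healthy versus limited (moderate and severe collapsed), used as a
    robustness check of the three-level classification.

``code_state_pain``
    An alternative classification from the five-level pain-interference
    item: {not at all, a little bit} -> healthy, {moderately, quite a
    bit} -> moderate, {extremely} -> severe.  This keeps the conventional
    binary "limited by pain" cut at "moderately" while still yielding
    three states, and the cut points are configurable.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .states import MISSING, ItemLevel, PainLevel, State

__all__ = [
    "code_state_3level",
    "code_state_2level",
    "code_state_pain",
    "code_records",
    "LIMITED",
]

#: Two-level scheme: the single "limited" category.
LIMITED: int = 1

# Default pain-item cut points: first level coded MODERATE, first level
# coded SEVERE (levels below the first cut are HEALTHY).
_PAIN_CUTS = (PainLevel.MODERATELY, PainLevel.EXTREMELY)


def code_state_3level(moderate_item: int, strenuous_item: int, too_ill: bool = False) -> int:
    """Return the three-level disability state, or ``MISSING``.

    Parameters are the integer-coded responses of the moderate-activity
    and strenuous-activity items (``ItemLevel`` values or ``MISSING``)
    and the interviewer's too-ill-to-respond flag.
    """
    if too_ill:
        return int(State.SEVERE)
    items = (moderate_item, strenuous_item)
    if ItemLevel.LIMITED_A_LOT in items:
        return int(State.SEVERE)
    if ItemLevel.LIMITED_A_LITTLE in items:
        return int(State.MODERATE)
    if all(it == ItemLevel.NOT_LIMITED for it in items):
        return int(State.HEALTHY)
    return MISSING


def code_state_2level(moderate_item: int, strenuous_item: int, too_ill: bool = False) -> int:
    """Collapse the three-level state to healthy (0) vs limited (1)."""
    s = code_state_3level(moderate_item, strenuous_item, too_ill)
    if s == MISSING:
        return MISSING
    return int(State.HEALTHY) if s == State.HEALTHY else LIMITED


def code_state_pain(
    pain_item: int,
    cuts: tuple[int, int] = _PAIN_CUTS,
) -> int:
    """Three-level state from the pain-interference item.

    ``cuts = (moderate_cut, severe_cut)``: levels below ``moderate_cut``
    are healthy, levels in ``[moderate_cut, severe_cut)`` moderate, and
    levels at or above ``severe_cut`` severe.  Missing propagates.
    """
    if pain_item == MISSING or pain_item is None:
        return MISSING
    moderate_cut, severe_cut = cuts
    if pain_item >= severe_cut:
        return int(State.SEVERE)
    if pain_item >= moderate_cut:
        return int(State.MODERATE)
    return int(State.HEALTHY)


def code_records(records: pd.DataFrame, scheme: str = "3level") -> pd.DataFrame:
    """Attach a coded ``state`` column to a wave-level record table.

    Death records (``vital_status == "died"``) are coded ``State.DEAD``;
    all other rows are coded from their items under the chosen scheme
    (``"3level"``, ``"2level"`` or ``"pain"``).  Under the two-level
    scheme the limited category is stored as ``State.MODERATE`` so the
    downstream four-state machinery applies unchanged (severe is then
    structurally absent).
    """
    out = records.copy()
    mod = out["moderate_item"].to_numpy()
    stren = out["strenuous_item"].to_numpy()
    too_ill = out["too_ill"].to_numpy().astype(bool)

    if scheme == "3level":
        state = np.array(
            [code_state_3level(m, s, t) for m, s, t in zip(mod, stren, too_ill)]
        )
    elif scheme == "2level":
        state = np.array(
            [code_state_2level(m, s, t) for m, s, t in zip(mod, stren, too_ill)]
        )
        state = np.where(state == LIMITED, int(State.MODERATE), state)
    elif scheme == "pain":
        state = np.array([code_state_pain(p) for p in out["pain_item"].to_numpy()])
    else:
        raise ValueError(f"unknown coding scheme: {scheme!r}")

    died = (out["vital_status"] == "died").to_numpy()
    state = np.where(died, int(State.DEAD), state)
    out["state"] = state
    return out
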