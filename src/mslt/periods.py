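"""Wave-level records -> annual person-period transition records.

Exact transition dates are interval-censored: a subject observed in
state A at one wave and state B two years later is assumed to make a
single transition at the interval midpoint.  Operationally each 2-year
interval starting at age a emits

* living end state B != A:  (a, A->B) and (a+1, B->B)
* living end state B == A:  (a, A->A) and (a+1, A->A)
* death before next wave:   (a, A->DEAD) only

For longer (skipped-wave) intervals the single transition is placed at
the integer year nearest the interval midpoint, with stayer-years before
and after; deaths are likewise assigned to the midpoint year.  The
module also applies the sample-inclusion filters: age 45+ at first
eligible wave, at least two interviews or one interview followed by
death between waves, and removal of records with missing sex, age or
coded state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .states import MISSING, State

__all__ = ["FilterCounts", "apply_sample_filters", "build_person_periods"]


@dataclass
class FilterCounts:
    """Accounting of records/subjects removed by the sample filters."""

    records_in: int
    records_missing_dropped: int
    subjects_in: int
    subjects_underage: int
    subjects_single_wave: int
    subjects_retained: int
    records_retained: int


def apply_sample_filters(
    records: pd.DataFrame, min_age: int = 45
) -> tuple[pd.DataFrame, FilterCounts]:
    """Apply the cohort-inclusion rules to coded wave-level records.

    Keeps subjects who were at least ``min_age`` at their first usable
    interview and either attended two or more waves or attended one and
    died between waves.  Interview records with missing sex, age or
    coded state are dropped first (death records carry no items and are
    exempt from the state requirement).
    """
    records_in = len(records)
    df = records.copy()

    is_death = df["vital_status"] == "died"
    usable = is_death | (
        df["state"].notna()
        & (df["state"] != MISSING)
        & df["age"].notna()
        & df["male"].notna()
    )
    dropped_missing = int((~usable).sum())
    df = df[usable]

    subjects_in = df["subject"].nunique()
    flags = pd.DataFrame(
        {
            "subject": df["subject"].to_numpy(),
            "alive": (df["vital_status"] == "alive").to_numpy(),
            "died": (df["vital_status"] == "died").to_numpy(),
            "age": df["age"].to_numpy(),
        }
    )
    grp = flags.groupby("subject")
    n_interviews = grp["alive"].sum()
    died = grp["died"].any()
    first_age = grp["age"].min()

    of_age = first_age >= min_age
    enough = (n_interviews >= 2) | ((n_interviews >= 1) & died)
    keep = of_age & enough

    counts = FilterCounts(
        records_in=records_in,
        records_missing_dropped=dropped_missing,
        subjects_in=subjects_in,
        subjects_underage=int((~of_age).sum()),
        subjects_single_wave=int((of_age & ~enough).sum()),
        subjects_retained=int(keep.sum()),
        records_retained=int(df["subject"].isin(keep[keep].index).sum()),
    )
    out = df[df["subject"].isin(keep[keep].index)].reset_index(drop=True)
    return out, counts


def build_person_periods(records: pd.DataFrame, max_gap: int | None = None) -> pd.DataFrame:
    """Expand filtered wave-level records into annual person-periods.

    ``records`` must be coded and filtered; subjects' rows are paired by
    consecutive observed waves.  Returns a table with columns subject,
    age, male, origin, dest, village, region.  Intervals longer than
    ``max_gap`` years (if given) are dropped instead of expanded.

    Raises ``ValueError`` if any interval starts in the DEAD state.
    """
    df = records.sort_values(["subject", "year"], kind="stable")
    sub = df["subject"].to_numpy()
    year = df["year"].to_numpy()
    age = df["age"].to_numpy(dtype=int)
    male = df["male"].to_numpy(dtype=int)
    state = df["state"].to_numpy(dtype=int)
    village = df["village"].to_numpy()
    region = df["region"].to_numpy()

    same = sub[1:] == sub[:-1]
    i0 = np.flatnonzero(same)          # interval start rows
    i1 = i0 + 1                        # interval end rows

    origin = state[i0]
    dest = state[i1]
    if np.any(origin == int(State.DEAD)):
        raise ValueError("interval starting in the DEAD state: corrupt record ordering")
    gap = year[i1] - year[i0]
    if max_gap is not None:
        keep = gap <= max_gap
        i0, i1, origin, dest, gap = i0[keep], i1[keep], origin[keep], dest[keep], gap[keep]

    out_sub, out_age, out_male = [], [], []
    out_orig, out_dest, out_vil, out_reg = [], [], [], []

    # transition year index within the interval: nearest the midpoint,
    # i.e. year g//2 of g (0-based index g//2 - 1 for even g)
    for g in np.unique(gap):
        m = gap == g
        t_idx = max(0, int(np.ceil(g / 2)) - 1)
        a0 = age[i0[m]]
        A, B = origin[m], dest[m]
        is_death = B == int(State.DEAD)

        for k in range(int(g)):
            if k < t_idx:
                o, d = A, A
            elif k == t_idx:
                o, d = A, B
            else:
                o, d = B, B
            if is_death.any() and k > t_idx:
                # death intervals end at the midpoint year
                live = ~is_death
                if not live.any():
                    continue
                _emit(out_sub, out_age, out_male, out_orig, out_dest, out_vil, out_reg,
                      sub[i0[m]][live], a0[live] + k, male[i0[m]][live],
                      o[live], d[live], village[i0[m]][live], region[i0[m]][live])
            else:
                _emit(out_sub, out_age, out_male, out_orig, out_dest, out_vil, out_reg,
                      sub[i0[m]], a0 + k, male[i0[m]], o, d,
                      village[i0[m]], region[i0[m]])

    periods = pd.DataFrame(
        {
            "subject": np.concatenate(out_sub) if out_sub else np.array([], dtype=int),
            "age": np.concatenate(out_age) if out_age else np.array([], dtype=int),
            "male": np.concatenate(out_male) if out_male else np.array([], dtype=int),
            "origin": np.concatenate(out_orig) if out_orig else np.array([], dtype=int),
            "dest": np.concatenate(out_dest) if out_dest else np.array([], dtype=int),
            "village": np.concatenate(out_vil) if out_vil else np.array([], dtype=int),
            "region": np.concatenate(out_reg) if out_reg else np.array([], dtype=int),
        }
    )
    return periods.sort_values(["subject", "age"], kind="stable").reset_index(drop=True)


def _emit(subs, ages, males, origs, dests, vils, regs, s, a, m, o, d, v, r):
    subs.append(np.asarray(s))
    ages.append(np.asarray(a))
    males.append(np.asarray(m))
    origs.append(np.asarray(o, dtype=int))
    dests.append(np.asarray(d, dtype=int))
    vils.append(np.asarray(v))
    regs.append(np.asarray(r))
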