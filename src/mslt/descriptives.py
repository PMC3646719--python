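"""Descriptive cross-tabulations of the panel and simulation output.

``wave_cross_tab`` reproduces the standard presentation of disability
prevalence over waves: counts and percentages by age group (45-64 and
65+) and state.  For the first wave the denominator is living
respondents; for later waves respondents who died between waves are kept
in the denominator, so the dead row is a between-wave mortality share.

``auxiliary_by_state`` tabulates the share working for income, the share
whose pain interfered with work (pain item at "moderately" or above),
and the share with low life satisfaction (the two lowest satisfaction
levels), by age group and state, excluding missing item responses from
the denominators.

``observed_vs_simulated_proportions`` compares the observed state mix by
age band with the state mix implied by a microsimulation occupancy
table, the usual internal-consistency check of a fitted multistate
model.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .lifetable import OccupancyTable
from .states import LIVING_STATES, MISSING, PainLevel, State

__all__ = [
    "wave_cross_tab",
    "auxiliary_by_state",
    "observed_vs_simulated_proportions",
]

AGE_GROUPS = ((45, 64), (65, 200))


def _age_group(age: np.ndarray) -> np.ndarray:
    return np.where(age <= 64, "45-64", "65+")


def wave_cross_tab(records: pd.DataFrame) -> pd.DataFrame:
    """Counts and percentages by (age group, wave, state incl. dead).

    Percentages are computed at full precision in ``percent`` and
    rounded to one decimal in ``percent_rounded``.
    """
    df = records[records["state"] != MISSING].copy()
    df["age_group"] = _age_group(df["age"].to_numpy())
    first_wave = df["wave"].min()

    rows = []
    for (grp_label, wave), g in df.groupby(["age_group", "wave"]):
        if wave == first_wave:
            g = g[g["vital_status"] == "alive"]
        denom = len(g)
        for st in list(map(int, State)):
            if wave == first_wave and st == int(State.DEAD):
                continue
            n = int((g["state"] == st).sum())
            pct = 100.0 * n / denom if denom else np.nan
            rows.append((grp_label, int(wave), st, n, pct, round(pct, 1)))
    return pd.DataFrame(
        rows,
        columns=["age_group", "wave", "state", "n", "percent", "percent_rounded"],
    )


def auxiliary_by_state(records: pd.DataFrame, wave: int) -> pd.DataFrame:
    """Auxiliary-item shares by age group and state at one wave.

    Returns one row per (age group, state, item) with the non-missing
    denominator and the percentage; a cell whose denominator is empty is
    reported with ``percent`` missing rather than zero.
    """
    g = records[
        (records["wave"] == wave)
        & (records["vital_status"] == "alive")
        & records["state"].isin([int(s) for s in LIVING_STATES])
    ].copy()
    g["age_group"] = _age_group(g["age"].to_numpy())

    items = {
        "worked_for_income": g["work_income"].to_numpy() == 1,
        "pain_interfered": g["pain_item"].to_numpy() >= int(PainLevel.MODERATELY),
        "low_satisfaction": g["satisfaction_item"].to_numpy() >= 3,
    }
    missing = {
        "worked_for_income": g["work_income"].to_numpy() == MISSING,
        "pain_interfered": g["pain_item"].to_numpy() == MISSING,
        "low_satisfaction": g["satisfaction_item"].to_numpy() == MISSING,
    }

    rows = []
    for (grp_label, st), sub_idx in g.groupby(["age_group", "state"]).groups.items():
        loc = g.index.get_indexer(sub_idx)
        for item, hit in items.items():
            ok = ~missing[item][loc]
            denom = int(ok.sum())
            if denom == 0:
                rows.append((grp_label, int(st), item, 0, denom, np.nan))
            else:
                n = int(hit[loc][ok].sum())
                rows.append((grp_label, int(st), item, n, denom, 100.0 * n / denom))
    return pd.DataFrame(
        rows, columns=["age_group", "state", "item", "n", "denominator", "percent"]
    )


def observed_vs_simulated_proportions(
    records: pd.DataFrame,
    occ: OccupancyTable,
    band_width: int = 5,
    n_boot: int = 0,
    seed: int = 0,
) -> pd.DataFrame:
    """Observed vs simulated living-state proportions by age band and sex.

    Observed proportions pool all waves' living coded respondents;
    simulated proportions are person-year shares from the occupancy
    table.  Bands with no observations are reported missing.  With
    ``n_boot > 0``, subject-level resampling adds central-95% percentile
    bands (``observed_lo``/``observed_hi``) around the observed
    proportions; no smoothing is applied.
    """
    living = [int(s) for s in LIVING_STATES]
    obs = records[
        (records["vital_status"] == "alive") & records["state"].isin(living)
    ].copy()
    obs["band"] = (obs["age"] // band_width) * band_width

    rng = np.random.default_rng(seed)
    subjects = obs["subject"].unique()

    def _props(frame, s, band):
        og = frame[(frame["male"] == s) & (frame["band"] == band)]
        if len(og) == 0:
            return np.full(3, np.nan), 0
        return np.array([(og["state"] == st).mean() for st in living]), len(og)

    boot_frames = []
    for _ in range(n_boot):
        draw = rng.choice(subjects, size=len(subjects), replace=True)
        picked = pd.DataFrame({"subject": draw}).merge(obs, on="subject", how="left")
        boot_frames.append(picked)

    sim_band = (occ.ages // band_width) * band_width
    rows = []
    for s, sex_label in ((0, "women"), (1, "men")):
        for band in sorted(set(sim_band)):
            m = sim_band == band
            py = occ.person_years[m, s][:, :3].sum(axis=0)
            sim_p = py / py.sum() if py.sum() > 0 else np.full(3, np.nan)
            obs_p, n_og = _props(obs, s, band)
            if n_boot:
                reps = np.stack([_props(bf, s, band)[0] for bf in boot_frames])
                lo = np.nanpercentile(reps, 2.5, axis=0) if n_og else np.full(3, np.nan)
                hi = np.nanpercentile(reps, 97.5, axis=0) if n_og else np.full(3, np.nan)
            for k, st in enumerate(living):
                row = [sex_label, int(band), st, n_og, obs_p[k], sim_p[k]]
                if n_boot:
                    row += [lo[k], hi[k]]
                rows.append(row)
    cols = ["sex", "age_band", "state", "n_observed", "observed", "simulated"]
    if n_boot:
        cols += ["observed_lo", "observed_hi"]
    return pd.DataFrame(rows, columns=cols)
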