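"""Microsimulation multistate life table and its exact analytic twin.

A synthetic cohort (default 100,000 members) starts at a given age with
a joint sex x disability-state distribution and is aged forward one year
at a time under the fitted annual transition model until death or the
age cap.  Person-years are credited with a mid-cycle convention:

* remaining in the same living state: 1.0 year in that state;
* moving between living states: 0.5 year in the origin + 0.5 in the
  destination;
* dying during the cycle: 0.5 year in the origin state;
* anyone reaching the age cap alive is terminated in that final cycle
  with a 0.5-year credit (i.e. treated as dying mid-cycle).

Health expectancies are state-specific person-years divided by the
number of cohort members (within sex strata), so active + moderate +
severe expectancy adds up exactly to total life expectancy.

``analytic_expectancies`` propagates the state-occupancy vector through
the same age-specific transition matrices and credits expected
person-years under the identical rules.  It has no Monte-Carlo error and
serves as the exact oracle for the microsimulation; the two agree to
within Monte-Carlo sampling noise by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .hazard import TransitionModelParams, transition_probs
from .states import LIVING_STATES, State

__all__ = [
    "CohortSpec",
    "OccupancyTable",
    "run_microsim",
    "health_expectancies",
    "analytic_expectancies",
    "conditional_expectancies",
    "empirical_initial_distribution",
    "microsim_mc_se",
]

_SEX_LABEL = {0: "women", 1: "men"}


def _uniform_initial_distribution() -> dict[tuple[int, int], float]:
    # equal sex split, all healthy
    return {(0, int(State.HEALTHY)): 0.5, (1, int(State.HEALTHY)): 0.5}


@dataclass
class CohortSpec:
    """Configuration of one synthetic cohort.

    ``initial_distribution`` maps (male, state) to a probability; it
    must sum to one over the six (sex, living-state) cells.
    """

    starting_age: int = 45
    size: int = 100_000
    initial_distribution: dict[tuple[int, int], float] = field(
        default_factory=_uniform_initial_distribution
    )
    age_cap: int = 110
    seed: int = 0
    credit: str = "midcycle"  # or "origin_full_year" sensitivity mode

    def validate(self) -> None:
        if self.starting_age < 45 or self.starting_age >= self.age_cap:
            raise ValueError("starting_age must lie in [45, age_cap)")
        total = sum(self.initial_distribution.values())
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"initial_distribution sums to {total}, not 1")
        for (male, st), p in self.initial_distribution.items():
            if st not in [int(s) for s in LIVING_STATES] or male not in (0, 1) or p < 0:
                raise ValueError("initial_distribution keys must be (male, living state)")


@dataclass
class OccupancyTable:
    """Person-years by (age, sex, state) from one completed simulation.

    ``person_years[a, s, k]`` is the total person-years credited to
    state k by members of sex s during the cycle starting at
    ``starting_age + a``.  ``person_totals`` holds each member's total
    years per state, kept so Monte-Carlo standard errors of the derived
    expectancies can be estimated from the same run.
    """

    starting_age: int
    ages: np.ndarray
    person_years: np.ndarray      # (n_ages, 2, 4)
    deaths_by_age: np.ndarray     # (n_ages, 2)
    n_by_sex: np.ndarray          # (2,)
    person_totals: np.ndarray | None = None  # (size, 4)
    person_sex: np.ndarray | None = None     # (size,)


def _init_arrays(spec: CohortSpec, rng: np.random.Generator):
    keys = sorted(spec.initial_distribution)
    probs = np.array([spec.initial_distribution[k] for k in keys])
    draw = rng.choice(len(keys), size=spec.size, p=probs / probs.sum())
    male = np.array([keys[i][0] for i in draw], dtype=np.int8)
    state = np.array([keys[i][1] for i in draw], dtype=np.int8)
    return male, state


def _prob_lookup(params: TransitionModelParams, ages: np.ndarray) -> np.ndarray:
    """Cumulative transition probabilities indexed [origin, sex, age, dest].

    Built once per run so the annual loop is pure array indexing.
    """
    n_ages = len(ages)
    cum = np.empty((3, 2, n_ages, 4))
    for origin in map(int, LIVING_STATES):
        for s in (0, 1):
            p = transition_probs(params, origin, ages.astype(float), s)
            cum[origin, s] = np.cumsum(p, axis=1)
    return cum


def run_microsim(params: TransitionModelParams, spec: CohortSpec) -> OccupancyTable:
    """Age a synthetic cohort forward and tally person-years by state."""
    spec.validate()
    if spec.credit not in ("midcycle", "origin_full_year"):
        raise ValueError(f"unknown credit convention: {spec.credit!r}")
    rng = np.random.default_rng(spec.seed)
    male, state = _init_arrays(spec, rng)
    male = male.astype(np.int64)
    state = state.astype(np.int64)

    n_ages = spec.age_cap - spec.starting_age
    ages = spec.starting_age + np.arange(n_ages)
    cum = _prob_lookup(params, ages)
    py = np.zeros((n_ages, 2, 4))
    deaths = np.zeros((n_ages, 2))
    totals = np.zeros((spec.size, 4))
    n_by_sex = np.array([(male == 0).sum(), (male == 1).sum()], dtype=float)

    idx_all = np.arange(spec.size)
    alive_idx = idx_all[state != int(State.DEAD)]
    for a, age in enumerate(ages):
        if alive_idx.size == 0:
            break
        st = state[alive_idx]
        sx = male[alive_idx]
        if age == spec.age_cap - 1:
            # forced terminal death: half-cycle credit in the current state
            dest = np.full(alive_idx.size, int(State.DEAD))
            cred_origin = np.full(alive_idx.size, 0.5)
        else:
            u = rng.random(alive_idx.size)
            dest = (u[:, None] > cum[st, sx, a]).sum(axis=1)
            stay = dest == st
            if spec.credit == "midcycle":
                cred_origin = np.where(stay, 1.0, 0.5)
                movers = ~stay & (dest != int(State.DEAD))
                np.add.at(totals, (alive_idx[movers], dest[movers]), 0.5)
                np.add.at(
                    py, (a, sx[movers], dest[movers]), 0.5
                )
            else:
                cred_origin = np.ones(alive_idx.size)
        np.add.at(totals, (alive_idx, st), cred_origin)
        np.add.at(py, (a, sx, st), cred_origin)
        died = dest == int(State.DEAD)
        np.add.at(deaths, (a, sx[died]), 1.0)
        state[alive_idx] = dest
        alive_idx = alive_idx[~died]

    return OccupancyTable(
        starting_age=spec.starting_age,
        ages=ages,
        person_years=py,
        deaths_by_age=deaths,
        n_by_sex=n_by_sex,
        person_totals=totals,
        person_sex=male.astype(int),
    )


def health_expectancies(occ: OccupancyTable, by_sex: bool = True) -> pd.DataFrame:
    """Health expectancies (years per cohort member) from an occupancy table.

    Returns a tidy table with columns starting_age, sex, total, active,
    moderate, severe and the state shares of total.  A sex stratum with
    no members is reported as missing.
    """
    rows = []
    strata = [(0, "women"), (1, "men")] if by_sex else [(None, "all")]
    state_py = occ.person_years.sum(axis=0)  # (2, 4)
    for s, label in strata:
        if s is None:
            n = occ.n_by_sex.sum()
            py = state_py.sum(axis=0)
        else:
            n = occ.n_by_sex[s]
            py = state_py[s]
        if n == 0:
            rows.append((occ.starting_age, label, *([np.nan] * 7)))
            continue
        e = py / n
        total = e[:3].sum()  # DEAD accrues no person-years
        shares = e[:3] / total if total > 0 else np.full(3, np.nan)
        rows.append((occ.starting_age, label, total, e[0], e[1], e[2], *shares))
    return pd.DataFrame(
        rows,
        columns=[
            "starting_age", "sex", "total", "active", "moderate", "severe",
            "share_active", "share_moderate", "share_severe",
        ],
    )


def analytic_expectancies(params: TransitionModelParams, spec: CohortSpec) -> pd.DataFrame:
    """Exact matrix-propagation equivalent of the microsimulation.

    Propagates the expected state occupancy through the age-specific
    transition matrices, crediting expected person-years with the same
    mid-cycle rules.  No Monte-Carlo error; same output shape as
    :func:`health_expectancies`.
    """
    spec.validate()
    living = [int(s) for s in LIVING_STATES]
    rows = []
    # per-sex propagation, then the combined cohort as the mixture
    per_sex = {}
    for s in (0, 1):
        mass = sum(spec.initial_distribution.get((s, st), 0.0) for st in living)
        p = np.array([spec.initial_distribution.get((s, st), 0.0) for st in living])
        ey = np.zeros(3)
        if mass > 0:
            p = p / mass
            for age in range(spec.starting_age, spec.age_cap):
                if age == spec.age_cap - 1:
                    ey += 0.5 * p
                    break
                Q = np.stack([transition_probs(params, o, float(age), s) for o in living])
                Qll = Q[:, :3]          # living -> living
                qd = Q[:, 3]            # living -> dead
                stay = np.diag(Qll)
                if spec.credit == "midcycle":
                    move_out = Qll.sum(axis=1) - stay
                    ey += p * (stay + 0.5 * move_out + 0.5 * qd)
                    ey += 0.5 * (p @ (Qll - np.diag(stay)))
                else:
                    ey += p
                p = p @ Qll
        per_sex[s] = (mass, ey)
    for s, label in ((0, "women"), (1, "men")):
        mass, ey = per_sex[s]
        if mass == 0:
            rows.append((spec.starting_age, label, *([np.nan] * 7)))
            continue
        total = ey.sum()
        shares = ey / total if total > 0 else np.full(3, np.nan)
        rows.append((spec.starting_age, label, total, ey[0], ey[1], ey[2], *shares))
    return pd.DataFrame(
        rows,
        columns=[
            "starting_age", "sex", "total", "active", "moderate", "severe",
            "share_active", "share_moderate", "share_severe",
        ],
    )


def conditional_expectancies(
    params: TransitionModelParams,
    spec: CohortSpec,
    initial_state: int,
    mode: str = "analytic",
) -> pd.DataFrame:
    """Expectancies with the whole cohort started in one disability state.

    The sex mix of ``spec.initial_distribution`` is preserved; only the
    state dimension is collapsed onto ``initial_state``.  ``mode`` is
    ``"analytic"`` or ``"microsim"``.
    """
    if initial_state not in [int(s) for s in LIVING_STATES]:
        raise ValueError("initial_state must be a living state")
    p_male = sum(p for (m, _), p in spec.initial_distribution.items() if m == 1)
    dist = {(0, int(initial_state)): 1.0 - p_male, (1, int(initial_state)): p_male}
    cond = replace(spec, initial_distribution=dist)
    if mode == "analytic":
        return analytic_expectancies(params, cond)
    occ = run_microsim(params, cond)
    return health_expectancies(occ)


def empirical_initial_distribution(
    records: pd.DataFrame, starting_age: int, band: int = 2
) -> dict[tuple[int, int], float]:
    """Joint sex x state distribution among respondents aged within
    ``starting_age +/- band`` (all waves pooled), used to seed cohorts
    the way the study population seeds them."""
    living = [int(s) for s in LIVING_STATES]
    sub = records[
        (records["vital_status"] == "alive")
        & records["state"].isin(living)
        & (records["age"] >= starting_age - band)
        & (records["age"] <= starting_age + band)
    ]
    if sub.empty:
        raise ValueError(f"no respondents near age {starting_age}")
    counts = sub.groupby(["male", "state"]).size()
    total = counts.sum()
    return {(int(m), int(s)): c / total for (m, s), c in counts.items()}


def microsim_mc_se(occ: OccupancyTable) -> pd.DataFrame:
    """Monte-Carlo standard errors of the per-sex state expectancies.

    Uses the per-person total years in each state from the same run:
    SE = sd(person totals) / sqrt(n) within the sex stratum, plus the
    total as the SE of the summed years.
    """
    if occ.person_totals is None:
        raise ValueError("occupancy table lacks per-person totals")
    rows = []
    for s, label in ((0, "women"), (1, "men")):
        sel = occ.person_sex == s
        n = int(sel.sum())
        if n == 0:
            rows.append((label, *([np.nan] * 4)))
            continue
        tot = occ.person_totals[sel][:, :3]
        se_states = tot.std(axis=0, ddof=1) / np.sqrt(n)
        se_total = tot.sum(axis=1).std(ddof=1) / np.sqrt(n)
        rows.append((label, se_total, *se_states))
    return pd.DataFrame(rows, columns=["sex", "total", "active", "moderate", "severe"])
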