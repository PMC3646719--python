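"""Synthetic three-wave panel generator.

Emulates a biennial longitudinal survey of adults aged 45+ clustered in
villages across a small number of regions: latent annual disability
histories follow a first-order Markov chain driven by the logit-linear
annual transition model (age, age squared, sex), interviews observe the
state every other year through two activity-limitation items, deaths
between waves are always ascertained, and wave non-response follows a
logit model in which attrition increases with age and with physical
limitation.  The generator is the ground-truth oracle for the estimation
pipeline: the latent annual state paths are returned alongside the
observed records so tests can compare estimates against the simulated
truth.

Default magnitudes (cohort size, village count, initial state mix by age
band, transition-model coefficients, auxiliary-item distributions) are
chosen to resemble a rural sub-Saharan ageing cohort: high prevalence of
limitation that rises steeply with age, declining recovery rates, and
strongly state-graded mortality.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .hazard import TransitionModelParams, transition_probs
from .states import LIVING_STATES, MISSING, ItemLevel, State

__all__ = [
    "TruePopulationSpec",
    "LatentHistories",
    "default_true_params",
    "generate_population",
    "observe_waves",
    "generate_panel",
]


def default_true_params() -> TransitionModelParams:
    """Ground-truth annual transition coefficients (centred age, c=65).

    Chosen so that at the youngest ages healthy individuals rarely leave
    the healthy state, recovery from limitation is common but declines
    sharply with age, severe limitation is retentive, and annual
    mortality from severe limitation is several-fold that of healthy
    individuals, with male mortality somewhat higher.
    """
    H, M, S, D = (int(s) for s in State)
    coef = {
        # origin HEALTHY                 b0      b1       b2      b3(male)
        (H, M): np.array([-2.20, 0.060, 0.00050, -0.40]),
        (H, S): np.array([-3.60, 0.060, 0.00050, -0.30]),
        (H, D): np.array([-4.60, 0.070, 0.00070, 0.30]),
        # origin MODERATE
        (M, H): np.array([-0.80, -0.070, 0.00030, 0.30]),
        (M, S): np.array([-2.00, 0.060, 0.00050, -0.20]),
        (M, D): np.array([-3.60, 0.080, 0.00080, 0.30]),
        # origin SEVERE
        (S, H): np.array([-2.20, -0.090, 0.00050, 0.20]),
        (S, M): np.array([-1.60, -0.050, 0.00040, 0.10]),
        (S, D): np.array([-2.30, 0.070, 0.00080, 0.30]),
    }
    return TransitionModelParams(coef=coef, age_center=65.0, age_eval_cap=90.0)


def _default_entry_age_probs() -> np.ndarray:
    """Entry-age distribution over 45..94: discretised exponential decay."""
    ages = np.arange(45, 95)
    w = np.exp(-(ages - 45) / 12.0)
    return w / w.sum()


@dataclass
class TruePopulationSpec:
    """Configuration of the simulated study population.

    ``initial_state_distribution`` maps age bands (lo, hi inclusive) to
    probability vectors over (healthy, moderate, severe) at first
    interview.  ``attrition_coefficients`` are the logit coefficients of
    the per-wave *response* probability: (intercept, per-year-over-45,
    moderate indicator, severe indicator); the age and limitation terms
    default to negative, i.e. attrition increases with age and
    limitation.  Death is always ascertained regardless of response.
    """

    n_subjects: int = 2500
    entry_age_probs: np.ndarray = field(default_factory=_default_entry_age_probs)
    entry_age_min: int = 45
    sex_ratio: float = 0.48  # proportion male
    n_villages: int = 121
    n_regions: int = 3
    initial_state_distribution: Mapping[tuple[int, int], Sequence[float]] = field(
        default_factory=lambda: {
            (45, 64): (0.72, 0.225, 0.055),
            (65, 200): (0.54, 0.32, 0.14),
        }
    )
    true_params: TransitionModelParams = field(default_factory=default_true_params)
    wave_years: tuple[int, ...] = (2006, 2008, 2010)
    attrition_coefficients: tuple[float, float, float, float] = (2.5, -0.02, -0.30, -0.60)
    p_too_ill_given_severe: float = 0.03
    work_prob_by_state: tuple[float, float, float] = (0.38, 0.34, 0.26)
    pain_dist_by_state: tuple[Sequence[float], ...] = (
        (0.55, 0.30, 0.10, 0.04, 0.01),
        (0.15, 0.35, 0.30, 0.15, 0.05),
        (0.05, 0.25, 0.30, 0.25, 0.15),
    )
    satisfaction_dist_by_state: tuple[Sequence[float], ...] = (
        (0.40, 0.35, 0.21, 0.03, 0.01),
        (0.30, 0.35, 0.25, 0.07, 0.03),
        (0.15, 0.28, 0.30, 0.17, 0.10),
    )
    aux_missing_prob: float = 0.01
    age_cap: int = 110
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects <= 0 or self.n_villages <= 0 or self.n_regions <= 0:
            raise ValueError("counts must be positive")
        if not 0.0 <= self.sex_ratio <= 1.0:
            raise ValueError("sex_ratio must lie in [0, 1]")
        if not np.isclose(np.sum(self.entry_age_probs), 1.0, atol=1e-12):
            raise ValueError("entry_age_probs must sum to 1")
        for band, p in self.initial_state_distribution.items():
            if abs(sum(p) - 1.0) > 1e-12:
                raise ValueError(f"initial state probabilities for band {band} must sum to 1")
        for dist in (*self.pain_dist_by_state, *self.satisfaction_dist_by_state):
            if abs(sum(dist) - 1.0) > 1e-12:
                raise ValueError("auxiliary item distributions must sum to 1")
        if any(b - a <= 0 for a, b in zip(self.wave_years, self.wave_years[1:])):
            raise ValueError("wave_years must be strictly increasing")


@dataclass
class LatentHistories:
    """Latent annual state paths for every simulated subject.

    ``states[s, t]`` is the state of subject ``s`` in calendar year
    ``years[t]``; the grid covers every year from the first to the last
    wave.  DEAD is absorbing on the grid.
    """

    subject: np.ndarray
    male: np.ndarray
    village: np.ndarray
    region: np.ndarray
    entry_age: np.ndarray
    years: np.ndarray
    states: np.ndarray

    def truth_frame(self) -> pd.DataFrame:
        """Long-format truth sidecar: one row per subject per year."""
        n, T = self.states.shape
        return pd.DataFrame(
            {
                "subject": np.repeat(self.subject, T),
                "year": np.tile(self.years, n),
                "age": (self.entry_age[:, None] + np.arange(T)[None, :]).ravel(),
                "state": self.states.ravel(),
            }
        )


def _draw_categorical(rng: np.random.Generator, probs: np.ndarray) -> np.ndarray:
    """Vectorised draw from per-row probability vectors (n, K)."""
    u = rng.random(probs.shape[0])
    cum = np.cumsum(probs, axis=1)
    return (u[:, None] > cum).sum(axis=1)


def generate_population(spec: TruePopulationSpec) -> LatentHistories:
    """Simulate latent annual disability histories for the cohort.

    Each subject enters at the first wave year with an age drawn from
    the entry-age distribution and an initial state drawn from the
    age-band-specific mixture, then evolves annually under the true
    transition model until death or the age cap (reaching the cap is
    recorded as death in that year).  Reproducible from ``spec.seed``.
    """
    spec.validate()
    ss = np.random.SeedSequence(spec.seed).spawn(4)
    rng_pop = np.random.default_rng(ss[0])
    rng_path = np.random.default_rng(ss[1])

    n = spec.n_subjects
    subject = np.arange(n)
    male = (rng_pop.random(n) < spec.sex_ratio).astype(int)
    village = rng_pop.integers(0, spec.n_villages, size=n)
    region = village * spec.n_regions // spec.n_villages
    ages = spec.entry_age_min + np.arange(len(spec.entry_age_probs))
    entry_age = rng_pop.choice(ages, size=n, p=spec.entry_age_probs)

    years = np.arange(spec.wave_years[0], spec.wave_years[-1] + 1)
    T = len(years)
    states = np.full((n, T), int(State.DEAD), dtype=np.int8)

    # initial state by age band
    init = np.empty(n, dtype=np.int8)
    assigned = np.zeros(n, dtype=bool)
    for (lo, hi), p in spec.initial_state_distribution.items():
        m = (entry_age >= lo) & (entry_age <= hi) & ~assigned
        if m.any():
            probs = np.broadcast_to(np.asarray(p, dtype=float), (int(m.sum()), 3))
            init[m] = _draw_categorical(rng_pop, probs)
            assigned[m] = True
    if not assigned.all():
        raise ValueError("initial_state_distribution bands do not cover all entry ages")
    states[:, 0] = init

    for t in range(1, T):
        prev = states[:, t - 1]
        cur = np.full(n, int(State.DEAD), dtype=np.int8)
        age_now = entry_age + t - 1  # age during the year of transition
        for origin in map(int, LIVING_STATES):
            m = prev == origin
            if not m.any():
                continue
            p = transition_probs(spec.true_params, origin, age_now[m].astype(float), male[m])
            cur[m] = _draw_categorical(rng_path, p)
        # age cap: anyone reaching the cap is dead in that year
        cur[(entry_age + t) >= spec.age_cap] = int(State.DEAD)
        states[:, t] = cur

    return LatentHistories(
        subject=subject,
        male=male,
        village=village,
        region=region,
        entry_age=entry_age,
        years=years,
        states=states,
    )


def observe_waves(hist: LatentHistories, spec: TruePopulationSpec) -> pd.DataFrame:
    """Observe the latent histories at the survey waves.

    Returns one row per subject per attended wave plus one row per
    between-wave death (``vital_status == "died"``, items missing).
    Raw items are realised so that the three-level coding rules invert
    them exactly: healthy -> both items "not limited"; moderate ->
    exactly one item "limited a little"; severe -> one item "limited a
    lot" (or the too-ill flag with missing items).  Every living subject
    responds at the first wave; later waves apply the response logit.
    """
    ss = np.random.SeedSequence(spec.seed).spawn(4)
    rng_att = np.random.default_rng(ss[2])
    rng_item = np.random.default_rng(ss[3])

    offsets = [y - spec.wave_years[0] for y in spec.wave_years]
    a0, a_age, a_mod, a_sev = spec.attrition_coefficients
    rows = []

    for w, off in enumerate(offsets):
        year = spec.wave_years[w]
        st = hist.states[:, off]
        age_w = hist.entry_age + off
        alive = st != int(State.DEAD)

        if w == 0:
            respond = alive.copy()
        else:
            eta = (
                a0
                + a_age * (age_w - 45)
                + a_mod * (st == int(State.MODERATE))
                + a_sev * (st == int(State.SEVERE))
            )
            respond = alive & (rng_att.random(len(st)) < expit(eta))
            # deaths between waves are always ascertained
            prev_off = offsets[w - 1]
            died = (hist.states[:, prev_off] != int(State.DEAD)) & ~alive
            for i in np.flatnonzero(died):
                rows.append(
                    _record(hist, i, w, year, age_w[i], "died",
                            MISSING, MISSING, False, MISSING, MISSING, MISSING)
                )

        for i in np.flatnonzero(respond):
            s = int(st[i])
            too_ill = False
            if s == State.HEALTHY:
                mod_item = stren_item = int(ItemLevel.NOT_LIMITED)
            elif s == State.MODERATE:
                which = rng_item.random() < 0.5
                mod_item = int(ItemLevel.LIMITED_A_LITTLE) if which else int(ItemLevel.NOT_LIMITED)
                stren_item = int(ItemLevel.NOT_LIMITED) if which else int(ItemLevel.LIMITED_A_LITTLE)
            else:  # SEVERE
                if rng_item.random() < spec.p_too_ill_given_severe:
                    too_ill = True
                    mod_item = stren_item = MISSING
                else:
                    which = rng_item.random() < 0.5
                    other = int(rng_item.integers(0, 2))  # not limited / a little
                    mod_item = int(ItemLevel.LIMITED_A_LOT) if which else other
                    stren_item = other if which else int(ItemLevel.LIMITED_A_LOT)

            work, pain, sat = _aux_items(rng_item, spec, s)
            rows.append(
                _record(hist, i, w, year, age_w[i], "alive",
                        mod_item, stren_item, too_ill, work, pain, sat)
            )

    df = pd.DataFrame(
        rows,
        columns=[
            "subject", "wave", "year", "age", "male", "village", "region",
            "moderate_item", "strenuous_item", "too_ill", "work_income",
            "pain_item", "satisfaction_item", "vital_status",
        ],
    )
    return df.sort_values(["subject", "wave"], kind="stable").reset_index(drop=True)


def _aux_items(rng: np.random.Generator, spec: TruePopulationSpec, state: int):
    if rng.random() < spec.aux_missing_prob:
        return MISSING, MISSING, MISSING
    work = int(rng.random() < spec.work_prob_by_state[state])
    pain = int(_draw_categorical(rng, np.asarray(spec.pain_dist_by_state[state])[None, :])[0])
    sat = int(_draw_categorical(rng, np.asarray(spec.satisfaction_dist_by_state[state])[None, :])[0])
    return work, pain, sat


def _record(hist, i, wave, year, age, vital, mod_item, stren_item, too_ill, work, pain, sat):
    return (
        int(hist.subject[i]), wave, year, int(age), int(hist.male[i]),
        int(hist.village[i]), int(hist.region[i]),
        mod_item, stren_item, bool(too_ill), work, pain, sat, vital,
    )


def generate_panel(spec: TruePopulationSpec) -> tuple[pd.DataFrame, LatentHistories]:
    """Generate latent histories and the observed wave-level records."""
    hist = generate_population(spec)
    return observe_waves(hist, spec), hist
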