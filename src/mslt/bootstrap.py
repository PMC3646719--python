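"""Village-stratified bootstrap confidence intervals.

Within each village, subjects (all their waves together) are redrawn
with replacement to the village's original subject count, preserving the
clustered sample design.  For every resample the whole analysis sequence
is repeated — sample filters, person-period expansion, hazard-model
refit, and a fresh microsimulation — so the intervals reflect both
parameter uncertainty and Monte-Carlo simulation noise.  The interval
for each cell is the central 95% (by default) of the replicate values,
with percentiles computed by linear interpolation between order
statistics.  An alternative mode resamples whole villages within regions
as primary sampling units.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .hazard import EstimationError, fit_transition_model
from .lifetable import (
    CohortSpec,
    empirical_initial_distribution,
    health_expectancies,
    run_microsim,
)
from .periods import apply_sample_filters, build_person_periods

__all__ = ["BootstrapConfig", "resample", "he_pipeline", "bootstrap_he"]


@dataclass
class BootstrapConfig:
    """Settings of the stratified bootstrap."""

    replicates: int = 499
    percentile: float = 0.95
    base_seed: int = 0
    microsim_size: int = 100_000
    unit: str = "subject"  # or "village" (PSU resampling within regions)
    max_failure_fraction: float = 0.10

    def validate(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if not 0.0 < self.percentile < 1.0:
            raise ValueError("percentile must lie in (0, 1)")


class _ResamplePlan:
    """Precomputed grouping structure for repeated stratified resampling."""

    def __init__(self, records: pd.DataFrame, unit: str):
        df = records.sort_values(["subject", "wave"], kind="stable").reset_index(drop=True)
        self.columns = {c: df[c].to_numpy() for c in df.columns}
        subj = self.columns["subject"]
        self.uniq, self.starts = np.unique(subj, return_index=True)
        self.counts = np.diff(np.append(self.starts, len(subj)))
        self.unit = unit
        vil = self.columns["village"][self.starts]
        reg = self.columns["region"][self.starts]
        order = np.argsort(vil, kind="stable")
        self.subj_pos_by_village = order
        v_sorted = vil[order]
        self.villages, self.v_starts = np.unique(v_sorted, return_index=True)
        self.v_counts = np.diff(np.append(self.v_starts, len(v_sorted)))
        self.region_of_village = np.array(
            [reg[order[s]] for s in self.v_starts]
        )

    def draw(self, rng: np.random.Generator) -> np.ndarray:
        """Positions (into the unique-subject arrays) of the drawn subjects."""
        parts = []
        if self.unit == "subject":
            for vs, vc in zip(self.v_starts, self.v_counts):
                block = self.subj_pos_by_village[vs:vs + vc]
                parts.append(block[rng.integers(0, vc, size=vc)])
        elif self.unit == "village":
            for r in np.unique(self.region_of_village):
                vidx = np.flatnonzero(self.region_of_village == r)
                for v in vidx[rng.integers(0, len(vidx), size=len(vidx))]:
                    vs, vc = self.v_starts[v], self.v_counts[v]
                    parts.append(self.subj_pos_by_village[vs:vs + vc])
        else:
            raise ValueError(f"unknown resampling unit: {self.unit!r}")
        return np.concatenate(parts) if parts else np.array([], dtype=int)

    def gather(self, sel: np.ndarray) -> pd.DataFrame:
        """Materialise the resampled records, re-keyed 0..m-1."""
        row_idx = np.concatenate(
            [np.arange(self.starts[i], self.starts[i] + self.counts[i]) for i in sel]
        ) if len(sel) else np.array([], dtype=int)
        data = {c: v[row_idx] for c, v in self.columns.items()}
        data["subject"] = np.repeat(np.arange(len(sel)), self.counts[sel])
        return pd.DataFrame(data)


def resample(
    records: pd.DataFrame, config: BootstrapConfig, replicate_index: int
) -> pd.DataFrame:
    """One stratified resample of the wave-level records.

    Subjects are drawn with replacement within villages (or villages
    within regions when ``config.unit == "village"``), keeping each
    stratum's original unit count.  Drawn subjects are re-keyed so
    repeated draws stay distinct downstream.  Deterministic given
    ``config.base_seed`` and ``replicate_index``.
    """
    plan = _ResamplePlan(records, config.unit)
    rng = np.random.default_rng(config.base_seed + replicate_index)
    return plan.gather(plan.draw(rng))


def he_pipeline(
    records: pd.DataFrame,
    starting_ages: Sequence[int] = (45, 55, 65, 75),
    microsim_size: int = 100_000,
    seed: int = 0,
    age_cap: int = 110,
    initial_distributions: dict[int, dict] | None = None,
) -> pd.DataFrame:
    """Full analysis sequence: filters -> person-periods -> hazard fit ->
    microsimulation -> health-expectancy table.

    ``records`` must already carry coded states.  Initial cohort
    distributions default to the empirical sex x state mix near each
    starting age.  Returns the stacked HE table over starting ages.
    """
    filtered, _ = apply_sample_filters(records)
    periods = build_person_periods(filtered)
    params = fit_transition_model(periods)
    tables = []
    for k, age in enumerate(starting_ages):
        dist = (
            initial_distributions[age]
            if initial_distributions is not None
            else empirical_initial_distribution(filtered, age)
        )
        spec = CohortSpec(
            starting_age=age,
            size=microsim_size,
            initial_distribution=dist,
            age_cap=age_cap,
            seed=seed + k,
        )
        tables.append(health_expectancies(run_microsim(params, spec)))
    return pd.concat(tables, ignore_index=True)


def bootstrap_he(
    records: pd.DataFrame,
    config: BootstrapConfig,
    pipeline: Callable[..., pd.DataFrame] | None = None,
    **pipeline_kwargs,
) -> pd.DataFrame:
    """Point estimates with stratified-bootstrap percentile intervals.

    ``pipeline(records, microsim_size=..., seed=...)`` must return a
    tidy HE table keyed by (starting_age, sex); :func:`he_pipeline` is
    used when none is given.  Replicates that fail to converge are
    dropped and counted; more than ``max_failure_fraction`` failures
    raises.  Returns the point-estimate table with lower/upper columns
    appended for every value column, plus replicate accounting columns.
    """
    config.validate()
    if pipeline is None:
        pipeline = he_pipeline

    point = pipeline(
        records, microsim_size=config.microsim_size, seed=config.base_seed,
        **pipeline_kwargs,
    )

    plan = _ResamplePlan(records, config.unit)
    reps = []
    failures = 0
    for r in range(config.replicates):
        try:
            rng = np.random.default_rng(config.base_seed + r)
            rec_r = plan.gather(plan.draw(rng))
            he_r = pipeline(
                rec_r,
                microsim_size=config.microsim_size,
                seed=config.base_seed + r + 1,
                **pipeline_kwargs,
            )
        except (EstimationError, ValueError):
            failures += 1
            continue
        reps.append(he_r)
    if failures > config.max_failure_fraction * config.replicates:
        raise EstimationError(
            f"{failures}/{config.replicates} bootstrap replicates failed"
        )

    alpha = (1.0 - config.percentile) / 2.0
    stacked = pd.concat(reps, ignore_index=True)
    value_cols = [c for c in point.columns if c not in ("starting_age", "sex")]
    lo = (
        stacked.groupby(["starting_age", "sex"])[value_cols]
        .quantile(alpha, interpolation="linear")
        .add_suffix("_lo")
    )
    hi = (
        stacked.groupby(["starting_age", "sex"])[value_cols]
        .quantile(1.0 - alpha, interpolation="linear")
        .add_suffix("_hi")
    )
    out = point.merge(lo, on=["starting_age", "sex"]).merge(hi, on=["starting_age", "sex"])
    out["n_replicates"] = len(reps)
    out["n_failures"] = failures
    return out
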