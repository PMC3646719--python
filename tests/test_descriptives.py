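import numpy as np
import pandas as pd
import pytest

from mslt.descriptives import (
    auxiliary_by_state,
    observed_vs_simulated_proportions,
    wave_cross_tab,
)
from mslt.coding import code_records
from mslt.lifetable import CohortSpec, run_microsim
from mslt.states import MISSING, State
from mslt.synthetic import TruePopulationSpec, default_true_params, generate_panel

H, M, S, D = (int(s) for s in State)


def _records_from_counts(counts_by_state, wave, age=50, start_subject=0):
    """Build minimal coded records with given state counts at one wave."""
    rows = []
    sid = start_subject
    for st, n in counts_by_state.items():
        for _ in range(n):
            rows.append(
                dict(subject=sid, wave=wave, year=2006 + 2 * wave, age=age,
                     male=0, village=0, region=0, state=st,
                     vital_status="died" if st == D else "alive",
                     work_income=MISSING, pain_item=MISSING,
                     satisfaction_item=MISSING)
            )
            sid += 1
    return pd.DataFrame(rows)


def test_first_wave_percentages_living_denominator():
    """427 active of 590 living respondents is 72.4%."""
    rec = _records_from_counts({H: 427, M: 132, S: 31}, wave=0)
    ct = wave_cross_tab(rec)
    active = ct[(ct.state == H) & (ct.wave == 0)]
    assert active["n"].item() == 427
    assert active["percent_rounded"].item() == 72.4


def test_later_wave_includes_deaths_in_denominator():
    """Interval deaths stay in the denominator: 64 severe of 754 is
    8.5%, and 23 dead of 754 is 3.1%."""
    rec = _records_from_counts({H: 428, M: 239, S: 64, D: 23}, wave=2)
    rec0 = _records_from_counts({H: 1}, wave=0, start_subject=10_000)
    ct = wave_cross_tab(pd.concat([rec0, rec], ignore_index=True))
    block = ct[(ct.age_group == "45-64") & (ct.wave == 2)]
    assert block[block.state == S]["percent_rounded"].item() == 8.5
    assert block[block.state == D]["percent_rounded"].item() == 3.1


def test_older_age_group_block():
    """65+ block: 93 severe of 354 (incl. 32 dead) is 26.3%."""
    rec = _records_from_counts({H: 87, M: 142, S: 93, D: 32}, wave=2, age=70)
    rec0 = _records_from_counts({H: 1}, wave=0, age=70, start_subject=10_000)
    ct = wave_cross_tab(pd.concat([rec0, rec], ignore_index=True))
    block = ct[(ct.age_group == "65+") & (ct.wave == 2)]
    assert block[block.state == S]["percent_rounded"].item() == 26.3


def test_percentages_sum_to_hundred(default_params_fit):
    coded, _, _, _ = default_params_fit
    ct = wave_cross_tab(coded)
    sums = ct.groupby(["age_group", "wave"])["percent"].sum()
    assert np.allclose(sums, 100.0, atol=1e-9)
    # counts conserved within blocks
    df = coded[coded.state != MISSING].copy()
    df["age_group"] = np.where(df.age <= 64, "45-64", "65+")
    for (grp, wave), block in ct.groupby(["age_group", "wave"]):
        sub = df[(df.age_group == grp) & (df.wave == wave)]
        if wave == 0:
            sub = sub[sub.vital_status == "alive"]
        assert block["n"].sum() == len(sub)


def test_auxiliary_share_with_missing_removed():
    """16 workers among 61 non-missing severe respondents is 26.2%."""
    rows = []
    for k in range(64):
        work = MISSING if k < 3 else (1 if k < 19 else 0)
        rows.append(
            dict(subject=k, wave=2, year=2010, age=50, male=0, village=0,
                 region=0, state=S, vital_status="alive", work_income=work,
                 pain_item=MISSING, satisfaction_item=MISSING)
        )
    aux = auxiliary_by_state(pd.DataFrame(rows), wave=2)
    cell = aux[(aux.state == S) & (aux.item == "worked_for_income")]
    assert cell["denominator"].item() == 61
    assert cell["percent"].item() == pytest.approx(100 * 16 / 61, abs=1e-9)
    assert round(cell["percent"].item(), 1) == 26.2


def test_auxiliary_empty_denominator_reported_missing():
    rows = [dict(subject=0, wave=2, year=2010, age=50, male=0, village=0,
                 region=0, state=H, vital_status="alive", work_income=MISSING,
                 pain_item=MISSING, satisfaction_item=MISSING)]
    aux = auxiliary_by_state(pd.DataFrame(rows), wave=2)
    assert aux["percent"].isna().all()
    assert (aux["denominator"] == 0).all()


def test_auxiliary_state_gradient_matches_generator(small_panel):
    """Work-for-income shares by state reflect the generating
    probabilities within binomial error."""
    spec, records, _ = small_panel
    coded = code_records(records)
    aux = auxiliary_by_state(coded, wave=2)
    work = aux[aux.item == "worked_for_income"]
    for st in (H, M, S):
        cells = work[work.state == st]
        n = cells["denominator"].sum()
        p_hat = cells["n"].sum() / n
        p_true = spec.work_prob_by_state[st]
        assert abs(p_hat - p_true) < 3 * np.sqrt(p_true * (1 - p_true) / n)


def test_observed_vs_simulated_self_consistency(default_params_fit):
    """Simulation driven by the fitted model reproduces the observed
    state mix by age band to within a loose tolerance."""
    coded, filtered, _, params = default_params_fit
    from mslt.lifetable import empirical_initial_distribution

    dist = empirical_initial_distribution(filtered, 45)
    occ = run_microsim(params, CohortSpec(starting_age=45, size=30_000,
                                          initial_distribution=dist, seed=2))
    cmp = observed_vs_simulated_proportions(filtered, occ)
    # proportions sum to one per (sex, band) on both sides
    for col in ("observed", "simulated"):
        sums = cmp.dropna(subset=[col]).groupby(["sex", "age_band"])[col].sum()
        assert np.allclose(sums, 1.0, atol=1e-9)
    # bands with no observations are missing, not zero
    empty = cmp[cmp.n_observed == 0]
    assert empty["observed"].isna().all()
    # where data are plentiful the two agree loosely
    rich = cmp[(cmp.n_observed >= 200) & (cmp.age_band <= 65)]
    assert (np.abs(rich["observed"] - rich["simulated"]) < 0.15).all()


def test_observed_vs_simulated_percentile_bands(default_params_fit):
    coded, filtered, _, params = default_params_fit
    from mslt.lifetable import empirical_initial_distribution

    dist = empirical_initial_distribution(filtered, 45)
    occ = run_microsim(params, CohortSpec(starting_age=45, size=5000,
                                          initial_distribution=dist, seed=2))
    cmp = observed_vs_simulated_proportions(filtered, occ, n_boot=40, seed=1)
    ok = cmp.dropna(subset=["observed"])
    assert (ok["observed_lo"] <= ok["observed"] + 1e-12).all()
    assert (ok["observed_hi"] >= ok["observed"] - 1e-12).all()
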