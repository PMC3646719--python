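import numpy as np
import pandas as pd
import pytest

from mslt.hazard import TransitionModelParams
from mslt.synthetic import TruePopulationSpec, generate_panel, generate_population

H, M, S, D = 0, 1, 2, 3
_ALL_PAIRS = [(i, j) for i, dests in ((H, (M, S, D)), (M, (H, S, D)), (S, (H, M, D))) for j in dests]


def constant_params(eta_by_pair=None, default=-30.0) -> TransitionModelParams:
    """Params with age- and sex-independent log-odds per transition pair.

    Pairs absent from ``eta_by_pair`` get ``default`` (-30 is an
    effectively impossible transition).
    """
    eta_by_pair = eta_by_pair or {}
    coef = {
        pair: np.array([eta_by_pair.get(pair, default), 0.0, 0.0, 0.0])
        for pair in _ALL_PAIRS
    }
    return TransitionModelParams(coef=coef)


def sidecar_person_periods(hist) -> pd.DataFrame:
    """Annual person-periods straight from the latent truth paths.

    Every latent year is observed, so these records follow the annual
    transition model exactly (no interval censoring) and serve as the
    unbiased oracle for parameter recovery.
    """
    tf = hist.truth_frame().sort_values(["subject", "year"], kind="stable")
    s = tf["subject"].to_numpy()
    st = tf["state"].to_numpy()
    age = tf["age"].to_numpy()
    same = s[1:] == s[:-1]
    i0 = np.flatnonzero(same)
    ok = st[i0] != D
    i0 = i0[ok]
    return pd.DataFrame(
        {
            "subject": s[i0],
            "age": age[i0],
            "male": hist.male[s[i0]],
            "origin": st[i0],
            "dest": st[i0 + 1],
            "village": hist.village[s[i0]],
            "region": hist.region[s[i0]],
        }
    )


@pytest.fixture(scope="session")
def small_panel():
    """A modest synthetic panel shared by read-only tests."""
    spec = TruePopulationSpec(n_subjects=1200, seed=42)
    records, hist = generate_panel(spec)
    return spec, records, hist


@pytest.fixture(scope="session")
def default_params_fit(small_panel):
    """Hazard fit on the small panel (coded, filtered, expanded)."""
    from mslt.coding import code_records
    from mslt.hazard import fit_transition_model
    from mslt.periods import apply_sample_filters, build_person_periods

    _, records, _ = small_panel
    coded = code_records(records)
    filtered, counts = apply_sample_filters(coded)
    periods = build_person_periods(filtered)
    params = fit_transition_model(periods)
    return coded, filtered, periods, params
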