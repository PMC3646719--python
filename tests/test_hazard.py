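import numpy as np
import pandas as pd
import pytest

from conftest import constant_params, sidecar_person_periods
from mslt.hazard import (
    EstimationError,
    fit_transition_model,
    predict_curves,
    transition_matrix,
    transition_probs,
)
from mslt.states import State
from mslt.synthetic import TruePopulationSpec, default_true_params, generate_population

H, M, S, D = (int(s) for s in State)


def _iid_periods(params, n, seed):
    """Person-periods drawn directly from the annual model (no interval
    censoring): the cleanest parameter-recovery oracle."""
    rng = np.random.default_rng(seed)
    age = rng.integers(45, 85, n).astype(float)
    male = rng.integers(0, 2, n)
    origin = rng.integers(0, 3, n)
    dest = np.empty(n, dtype=int)
    for o in (H, M, S):
        sel = origin == o
        p = transition_probs(params, o, age[sel], male[sel])
        u = rng.random(int(sel.sum()))
        dest[sel] = (u[:, None] > p.cumsum(axis=1)).sum(axis=1)
    return pd.DataFrame(
        dict(subject=np.arange(n), age=age, male=male, origin=origin,
             dest=dest, village=0, region=0)
    )


def test_intercept_only_fit_matches_empirical_proportions():
    rows = [(H, H)] * 70 + [(H, M)] * 20 + [(H, S)] * 5 + [(H, D)] * 5
    pp = pd.DataFrame(
        dict(subject=range(100), age=60.0, male=0,
             origin=[r[0] for r in rows], dest=[r[1] for r in rows],
             village=0, region=0)
    )
    params = fit_transition_model(pp, covariates=())
    p = transition_probs(params, H, 60.0, 0)
    assert np.allclose(p, [0.70, 0.20, 0.05, 0.05], atol=1e-6)


def test_inverse_logit_hand_computed_values():
    """eta = -2 toward each destination: stay = 1/(1+3e^-2)."""
    params = constant_params({(H, M): -2.0, (H, S): -2.0, (H, D): -2.0})
    p = transition_probs(params, H, 65.0, 0)
    stay = 1.0 / (1.0 + 3.0 * np.exp(-2.0))
    other = np.exp(-2.0) / (1.0 + 3.0 * np.exp(-2.0))
    assert np.allclose(p, [stay, other, other, other], atol=1e-12)
    assert abs(stay - 0.7112) < 5e-4 and abs(other - 0.0963) < 5e-4


def test_dead_origin_absorbing():
    params = default_true_params()
    assert np.array_equal(transition_probs(params, D, 60.0, 1), [0, 0, 0, 1])


def test_zero_coefficients_give_uniform_quarter():
    params = constant_params({(H, M): 0.0, (H, S): 0.0, (H, D): 0.0})
    assert np.allclose(transition_probs(params, H, 70.0, 1), 0.25, atol=1e-12)


def test_rows_sum_to_one_and_age_clamping():
    params = default_true_params()
    for age in (45.0, 63.0, 90.0, 100.0):
        Q = transition_matrix(params, age, 1)
        assert np.allclose(Q.sum(axis=1), 1.0, atol=1e-12)
        assert np.all((Q >= 0) & (Q <= 1))
        assert np.array_equal(Q[D], [0, 0, 0, 1])
    # above the evaluation cap the matrix is clamped, not extrapolated
    assert np.allclose(
        transition_matrix(params, 95.0, 0), transition_matrix(params, 90.0, 0)
    )


def test_structural_zero_destination():
    pp = pd.DataFrame(
        dict(subject=range(8), age=[50.0, 55, 60, 65, 70, 75, 60, 62],
             male=[0, 1] * 4, origin=S, dest=[S, S, M, M, D, D, S, M],
             village=0, region=0)
    )
    params = fit_transition_model(pp)
    assert (S, H) in params.structural_zero
    for age in (50.0, 70.0):
        assert transition_probs(params, S, age, 1)[H] == 0.0


def test_parameter_recovery_within_three_se():
    """MLE on 200,000 model-generated person-periods recovers every
    coefficient within 3 asymptotic standard errors."""
    truth = default_true_params()
    pp = _iid_periods(truth, 200_000, seed=1)
    fit = fit_transition_model(pp)
    for key, b in truth.coef.items():
        z = np.abs(fit.coef[key] - b) / fit.se[key]
        assert z.max() < 3.0, (key, z)


def test_parameter_recovery_from_latent_histories():
    """Fits on annually-observed latent paths recover the generator
    truth across several seeds (unbiased oracle: no interval censoring)."""
    for seed in (1, 4, 5):
        spec = TruePopulationSpec(n_subjects=4000, seed=seed)
        hist = generate_population(spec)
        fit = fit_transition_model(sidecar_person_periods(hist))
        worst = max(
            (np.abs(fit.coef[k] - b) / fit.se[k]).max()
            for k, b in spec.true_params.coef.items()
        )
        assert worst < 3.5, (seed, worst)


def test_score_equation_intercept_consistency(default_params_fit):
    """Mean predicted destination probabilities equal observed
    destination frequencies per origin (intercept score equation)."""
    _, _, periods, params = default_params_fit
    for origin in (H, M, S):
        sub = periods[periods["origin"] == origin]
        pred = transition_probs(
            params, origin, sub["age"].to_numpy(float), sub["male"].to_numpy()
        )
        for j in range(4):
            obs = (sub["dest"] == j).mean()
            assert abs(pred[:, j].mean() - obs) < 1e-8


def test_loglik_no_worse_than_intercept_only(default_params_fit):
    _, _, periods, params = default_params_fit
    params0 = fit_transition_model(periods, covariates=())
    for origin in (H, M, S):
        assert (
            params.diagnostics[origin].loglik
            >= params0.diagnostics[origin].loglik - 1e-9
        )


def test_matches_statsmodels_mnlogit():
    """Independent cross-check of the Newton fitter against statsmodels."""
    sm = pytest.importorskip("statsmodels.api")
    truth = default_true_params()
    pp = _iid_periods(truth, 5000, seed=2)
    sub = pp[pp["origin"] == H]
    mine = fit_transition_model(pp)
    a = sub["age"].to_numpy() - 65.0
    X = sm.add_constant(
        np.column_stack([a, a * a, sub["male"].to_numpy(float)])
    )
    ref = sm.MNLogit(sub["dest"].to_numpy(), X).fit(disp=0, method="newton")
    refb = np.asarray(ref.params)
    for k, j in enumerate((M, S, D)):
        assert np.allclose(refb[:, k], mine.coef[(H, j)], atol=1e-5)


def test_binary_link_mode_close_to_multinomial():
    truth = default_true_params()
    pp = _iid_periods(truth, 20_000, seed=3)
    pm = fit_transition_model(pp, link="multinomial")
    pb = fit_transition_model(pp, link="binary")
    for origin in (H, M, S):
        a = transition_probs(pm, origin, 60.0, 1)
        b = transition_probs(pb, origin, 60.0, 1)
        assert abs(a.sum() - 1) < 1e-12 and abs(b.sum() - 1) < 1e-12
        assert np.abs(a - b).max() < 0.05


def test_predict_curves_consistent_and_monotone():
    params = constant_params({(H, D): -3.0})
    # positive age slope on H->D only
    params.coef[(H, D)][1] = 0.1
    curves = predict_curves(params, range(45, 91), sexes=(0,))
    hd = curves[(curves.origin == H) & (curves.destination == D)]
    assert (np.diff(hd["probability"].to_numpy()) > 0).all()
    row = hd[hd.age == 60]["probability"].item()
    assert row == pytest.approx(transition_probs(params, H, 60.0, 0)[D], abs=1e-15)


def test_json_round_trip(tmp_path, default_params_fit):
    _, _, _, params = default_params_fit
    path = tmp_path / "params.json"
    params.to_json(path)
    back = type(params).from_json(path)
    for k, v in params.coef.items():
        assert np.allclose(back.coef[k], v, atol=0)
    assert back.structural_zero == params.structural_zero
    assert back.age_center == params.age_center


def test_empty_periods_raise():
    with pytest.raises(EstimationError):
        fit_transition_model(pd.DataFrame(columns=["origin", "dest", "age", "male"]))
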