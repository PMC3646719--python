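"""Discrete-time hazard model for annual disability-state transitions.

For each living origin state i, the probability of moving to destination
state j over one year is modelled with a multinomial logit whose baseline
category is remaining in i:

    eta_ij  = b0_ij + b1_ij * (age - c) + b2_ij * (age - c)^2 + b3_ij * male
    p_ij    = exp(eta_ij) / (1 + sum_k exp(eta_ik))        (j != i)
    p_ii    = 1 / (1 + sum_k exp(eta_ik))

which guarantees each row of the age- and sex-specific transition matrix
sums to one.  Death is absorbing.  Destinations never observed from an
origin are structural zeros (probability fixed at 0 at every age).

Ages are centred at ``age_center`` (default 65 y) to keep the quadratic
term well conditioned.  Predicted probabilities are never extrapolated
beyond ``age_eval_cap`` (default 90 y): older ages are clamped to the cap
because the quadratic predictor is unsupported beyond the observed range
and can turn over.

A per-pair binary-logit mode (each destination fit against all other
outcomes, stay obtained by subtraction with renormalisation if needed) is
provided for sensitivity analysis; the multinomial fit is the default.

The fitter is a damped Newton iteration on the exact multinomial
log-likelihood (analytic gradient and Hessian), with an optional small
ridge penalty that is switched on automatically when quasi-separation
inflates coefficients.  It is written in vectorised numpy so that the
bootstrap, which refits the model hundreds of times, stays cheap.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .states import LIVING_STATES, State

__all__ = [
    "TransitionModelParams",
    "FitDiagnostics",
    "EstimationError",
    "DESTINATIONS",
    "fit_transition_model",
    "transition_probs",
    "transition_matrix",
    "predict_curves",
]

#: Non-stay destinations per origin, in canonical order.
DESTINATIONS: dict[int, tuple[int, ...]] = {
    int(State.HEALTHY): (int(State.MODERATE), int(State.SEVERE), int(State.DEAD)),
    int(State.MODERATE): (int(State.HEALTHY), int(State.SEVERE), int(State.DEAD)),
    int(State.SEVERE): (int(State.HEALTHY), int(State.MODERATE), int(State.DEAD)),
}

_COEF_NAMES = ("intercept", "age", "age_sq", "male")
_ETA_CLIP = 35.0  # keeps exp() finite; |eta| beyond this is saturated anyway


class EstimationError(RuntimeError):
    """Raised when the hazard-model fit fails to converge."""


@dataclass
class FitDiagnostics:
    """Convergence information for one origin-state fit."""

    origin: int
    n_obs: int
    n_iter: int
    converged: bool
    grad_norm: float
    loglik: float
    ridge: float
    separation_flagged: bool


@dataclass
class TransitionModelParams:
    """Coefficients of the annual transition model.

    ``coef[(i, j)]`` holds ``(b0, b1, b2, b3)`` for origin i and
    destination j on the centred-age scale; ``se`` holds the matching
    asymptotic standard errors when the params come from a fit.
    ``structural_zero`` lists (i, j) pairs with probability fixed at 0.
    """

    coef: dict[tuple[int, int], np.ndarray]
    age_center: float = 65.0
    age_min: float = 45.0
    age_eval_cap: float = 90.0
    link: str = "multinomial"  # or "binary"
    structural_zero: frozenset[tuple[int, int]] = frozenset()
    se: dict[tuple[int, int], np.ndarray] = field(default_factory=dict)
    diagnostics: dict[int, FitDiagnostics] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for key, b in self.coef.items():
            b = np.asarray(b, dtype=float)
            if b.shape != (4,):
                raise ValueError(f"coef{key} must have 4 entries, got {b.shape}")
            if not np.all(np.isfinite(b)):
                raise ValueError(f"coef{key} contains non-finite values")
            self.coef[key] = b

    # -- serialisation -------------------------------------------------
    def to_json(self, path) -> None:
        payload = {
            "age_center": self.age_center,
            "age_min": self.age_min,
            "age_eval_cap": self.age_eval_cap,
            "link": self.link,
            "structural_zero": sorted(list(self.structural_zero)),
            "coef": {
                f"{i}->{j}": dict(zip(_COEF_NAMES, map(float, b)))
                for (i, j), b in sorted(self.coef.items())
            },
            "se": {
                f"{i}->{j}": dict(zip(_COEF_NAMES, map(float, s)))
                for (i, j), s in sorted(self.se.items())
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "TransitionModelParams":
        with open(path) as fh:
            payload = json.load(fh)

        def parse(d):
            out = {}
            for key, cdict in d.items():
                i, j = key.split("->")
                out[(int(i), int(j))] = np.array([cdict[n] for n in _COEF_NAMES])
            return out

        return cls(
            coef=parse(payload["coef"]),
            age_center=payload["age_center"],
            age_min=payload["age_min"],
            age_eval_cap=payload["age_eval_cap"],
            link=payload["link"],
            structural_zero=frozenset(tuple(p) for p in payload["structural_zero"]),
            se=parse(payload.get("se", {})),
        )


# ---------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------

def _eta(params: TransitionModelParams, i: int, j: int, age, male) -> np.ndarray:
    a = np.clip(np.asarray(age, dtype=float), params.age_min, params.age_eval_cap)
    a = a - params.age_center
    b = params.coef[(i, j)]
    eta = b[0] + b[1] * a + b[2] * a * a + b[3] * np.asarray(male, dtype=float)
    return np.clip(eta, -_ETA_CLIP, _ETA_CLIP)


def transition_probs(params: TransitionModelParams, origin: int, age, male) -> np.ndarray:
    """Annual transition probability vector over the four states.

    ``age`` and ``male`` may be scalars or equal-length arrays; the
    result has shape ``(4,)`` or ``(n, 4)`` accordingly.  Ages outside
    ``[age_min, age_eval_cap]`` are clamped, never extrapolated.  Origin
    DEAD returns the absorbing row.
    """
    origin = int(origin)
    age_arr = np.asarray(age, dtype=float)
    male_arr = np.broadcast_to(np.asarray(male, dtype=float), age_arr.shape)
    scalar = age_arr.ndim == 0
    n = 1 if scalar else age_arr.shape[0]

    out = np.zeros((n, 4))
    if origin == State.DEAD:
        out[:, int(State.DEAD)] = 1.0
        return out[0] if scalar else out

    dests = [j for j in DESTINATIONS[origin] if (origin, j) not in params.structural_zero]
    if params.link == "multinomial":
        if dests:
            etas = np.stack([_eta(params, origin, j, age_arr, male_arr) for j in dests], axis=-1)
            etas = etas.reshape(n, len(dests))
            ex = np.exp(etas)
            denom = 1.0 + ex.sum(axis=1)
            for k, j in enumerate(dests):
                out[:, j] = ex[:, k] / denom
            out[:, origin] = 1.0 / denom
        else:
            out[:, origin] = 1.0
    elif params.link == "binary":
        from scipy.special import expit

        p = np.zeros((n, len(dests)))
        for k, j in enumerate(dests):
            p[:, k] = expit(_eta(params, origin, j, age_arr, male_arr).reshape(n))
        total = p.sum(axis=1)
        # stay probability by subtraction; renormalise rows where the
        # separate binary fits overshoot one
        over = total > 1.0
        p[over] /= total[over, None]
        for k, j in enumerate(dests):
            out[:, j] = p[:, k]
        out[:, origin] = np.clip(1.0 - p.sum(axis=1), 0.0, 1.0)
    else:
        raise ValueError(f"unknown link: {params.link!r}")
    return out[0] if scalar else out


def transition_matrix(params: TransitionModelParams, age: float, male: int) -> np.ndarray:
    """Row-stochastic 4x4 transition matrix at a given age and sex."""
    Q = np.zeros((4, 4))
    for i in LIVING_STATES:
        Q[int(i)] = transition_probs(params, int(i), age, male)
    Q[int(State.DEAD), int(State.DEAD)] = 1.0
    return Q


def predict_curves(
    params: TransitionModelParams,
    ages: Iterable[float],
    sexes: Sequence[int] = (0, 1),
) -> pd.DataFrame:
    """Long table of transition probabilities by age for plotting.

    Columns: age, male, origin, destination, probability.
    """
    rows = []
    ages = list(ages)
    for male in sexes:
        for i in LIVING_STATES:
            p = transition_probs(params, int(i), np.asarray(ages, dtype=float), male)
            for j in range(4):
                for age, prob in zip(ages, p[:, j]):
                    rows.append((age, male, int(i), j, prob))
    return pd.DataFrame(rows, columns=["age", "male", "origin", "destination", "probability"])


# ---------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------

def _design(age: np.ndarray, male: np.ndarray, center: float, covariates,
            age_min: float = 45.0, age_cap: float = 90.0) -> np.ndarray:
    # ages are clamped exactly as at evaluation time, so the fitted and
    # predicted linear predictors agree beyond the support cap
    a = np.clip(age, age_min, age_cap) - center
    cols = [np.ones_like(a)]
    if "age" in covariates:
        cols.append(a)
    if "age_sq" in covariates:
        cols.append(a * a)
    if "male" in covariates:
        cols.append(male.astype(float))
    return np.column_stack(cols)


def _nll(B: np.ndarray, X: np.ndarray, Y: np.ndarray, ridge: float) -> float:
    eta = np.clip(X @ B.T, -_ETA_CLIP, _ETA_CLIP)
    lse = np.logaddexp(0.0, _logsumexp_rows(eta))
    ll = (Y * eta).sum() - lse.sum()
    return -ll + 0.5 * ridge * float((B * B).sum())


def _logsumexp_rows(eta: np.ndarray) -> np.ndarray:
    m = eta.max(axis=1)
    return m + np.log(np.exp(eta - m[:, None]).sum(axis=1))


def _newton_mnlogit(
    X: np.ndarray,
    Y: np.ndarray,
    ridge: float = 0.0,
    max_iter: int = 200,
    tol: float = 1e-10,
) -> tuple[np.ndarray, np.ndarray, int, bool, float]:
    """Damped Newton fit of a multinomial logit with baseline class.

    ``Y`` is the (n, K) one-hot matrix of non-baseline classes (a row of
    zeros means the baseline was observed).  Returns (B, cov, n_iter,
    converged, grad_norm) with ``B`` of shape (K, p).
    """
    n, p = X.shape
    K = Y.shape[1]
    B = np.zeros((K, p))
    obj = _nll(B, X, Y, ridge)
    grad_norm = np.inf
    converged = False
    H = np.eye(K * p)
    for it in range(1, max_iter + 1):
        eta = np.clip(X @ B.T, -_ETA_CLIP, _ETA_CLIP)
        ex = np.exp(eta)
        denom = 1.0 + ex.sum(axis=1)
        P = ex / denom[:, None]  # (n, K)

        G = (Y - P).T @ X - ridge * B  # (K, p)
        grad_norm = float(np.abs(G).max())
        if grad_norm < tol * max(1.0, n):
            converged = True
            break

        # Hessian of the NLL, (K*p, K*p) in class-major blocks
        H = np.empty((K * p, K * p))
        for k in range(K):
            for l in range(K):
                w = P[:, k] * ((1.0 if k == l else 0.0) - P[:, l])
                H[k * p:(k + 1) * p, l * p:(l + 1) * p] = (X * w[:, None]).T @ X
        H[np.diag_indices_from(H)] += ridge + 1e-12

        try:
            step = np.linalg.solve(H, G.reshape(-1)).reshape(K, p)
        except np.linalg.LinAlgError:
            step = G / max(1.0, np.abs(H).max())

        # step-halving line search on the penalised NLL
        t = 1.0
        for _ in range(30):
            cand = B + t * step
            cobj = _nll(cand, X, Y, ridge)
            if cobj <= obj + 1e-12:
                break
            t *= 0.5
        B = B + t * step
        if abs(obj - cobj) < 1e-13 * max(1.0, abs(obj)) and grad_norm < 1e-6 * max(1.0, n):
            obj = cobj
            converged = True
            break
        obj = cobj
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov = np.full((K * p, K * p), np.nan)
    return B, cov, it, converged, grad_norm


def fit_transition_model(
    periods: pd.DataFrame,
    age_center: float = 65.0,
    age_eval_cap: float = 90.0,
    covariates: Sequence[str] = ("age", "age_sq", "male"),
    link: str = "multinomial",
    ridge: float = 0.0,
    separation_bound: float = 25.0,
) -> TransitionModelParams:
    """Maximum-likelihood fit of the annual transition model.

    ``periods`` is a person-period table with columns ``origin``,
    ``dest``, ``age`` and ``male``; one multinomial logit (baseline =
    stay) is fit per living origin state.  Destinations with zero
    observed events are flagged as structural zeros.  If any fitted
    coefficient exceeds ``separation_bound`` in absolute value the origin
    is refit with a small ridge penalty (1e-6) and flagged.

    Raises :class:`EstimationError` on non-convergence.
    """
    if periods.empty:
        raise EstimationError("no person-periods supplied")
    coef: dict[tuple[int, int], np.ndarray] = {}
    se: dict[tuple[int, int], np.ndarray] = {}
    zeros: set[tuple[int, int]] = set()
    diagnostics: dict[int, FitDiagnostics] = {}

    for origin in map(int, LIVING_STATES):
        sub = periods[periods["origin"] == origin]
        if sub.empty:
            # origin never at risk: every destination is structurally zero
            zeros.update((origin, j) for j in DESTINATIONS[origin])
            continue
        age = sub["age"].to_numpy(dtype=float)
        male = sub["male"].to_numpy(dtype=float)
        dest = sub["dest"].to_numpy(dtype=int)

        observed = [j for j in DESTINATIONS[origin] if np.any(dest == j)]
        zeros.update((origin, j) for j in DESTINATIONS[origin] if j not in observed)
        if not observed:
            continue

        X = _design(age, male, age_center, covariates, age_cap=age_eval_cap)
        K = len(observed)
        Y = np.zeros((len(sub), K))
        for k, j in enumerate(observed):
            Y[dest == j, k] = 1.0

        if link == "multinomial":
            fits = [(observed, Y)]
        elif link == "binary":
            # one binary logit per destination: j versus everything else
            fits = [([j], Y[:, [k]]) for k, j in enumerate(observed)]
        else:
            raise ValueError(f"unknown link: {link!r}")

        sep_flag = False
        used_ridge = ridge
        for dest_set, Yf in fits:
            B, cov, n_iter, conv, gnorm = _newton_mnlogit(X, Yf, ridge=ridge)
            if conv and np.abs(B).max() > separation_bound and ridge == 0.0:
                sep_flag = True
                used_ridge = 1e-6
                B, cov, n_iter, conv, gnorm = _newton_mnlogit(X, Yf, ridge=used_ridge)
            if not conv:
                raise EstimationError(
                    f"origin {origin}: no convergence after {n_iter} iterations "
                    f"(|grad|={gnorm:.3g})"
                )
            p = X.shape[1]
            ses = np.sqrt(np.maximum(np.diag(cov), 0.0)).reshape(len(dest_set), p)
            for k, j in enumerate(dest_set):
                b_full = np.zeros(4)
                s_full = np.full(4, np.nan)
                idx = 0
                for ci, name in enumerate(_COEF_NAMES):
                    if name == "intercept" or name in covariates:
                        b_full[ci] = B[k, idx]
                        s_full[ci] = ses[k, idx]
                        idx += 1
                coef[(origin, j)] = b_full
                se[(origin, j)] = s_full

        # log-likelihood at the optimum for diagnostics (multinomial scale)
        Bm = np.stack([
            np.array([coef[(origin, j)][ci] for ci, name in enumerate(_COEF_NAMES)
                      if name == "intercept" or name in covariates])
            for j in observed
        ])
        ll = -_nll(Bm, X, Y, 0.0) if link == "multinomial" else np.nan
        diagnostics[origin] = FitDiagnostics(
            origin=origin,
            n_obs=len(sub),
            n_iter=n_iter,
            converged=True,
            grad_norm=gnorm,
            loglik=float(ll),
            ridge=used_ridge,
            separation_flagged=sep_flag,
        )

    return TransitionModelParams(
        coef=coef,
        age_center=age_center,
        age_eval_cap=age_eval_cap,
        link=link,
        structural_zero=frozenset(zeros),
        se=se,
        diagnostics=diagnostics,
    )
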