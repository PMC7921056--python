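"""Adjacent-category logit structural model on the latent classes.

After the number of classes is fixed by the measurement step, class
membership probabilities are parameterized by treatments and external
covariates through adjacent logits,

    log p(U = u) / p(U = u-1) = beta_0u + d' beta_1u ,   u = 2..k,

with class 1 (best outcomes) as the reference.  Under the
inverse-probability-of-treatment weighted likelihood the coefficients
beta_1u encode average causal effects on the treated (ATET) in the
distribution of the latent variable: negative values favor the lower
(better) class.

The default fitting mode re-maximizes the full weighted likelihood jointly
(measurement and structural parameters) by EM, starting from the
measurement-step estimates with class labels frozen in outcome order; a
two-step mode keeps the measurement parameters fixed and only fits the
concomitant logit on the posterior class probabilities.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize
from scipy.special import logsumexp

from .lc2pl import (
    FitResult,
    LC2PLParameters,
    _log_cond_matrix,
    _pack_free,
    _unpack_free,
)
from .study_data import PatientRecord, StudyDesign

logger = logging.getLogger("causallc")

STAR_LEGEND_TABLE = "*significant at 10%; **significant at 5%; ***significant at 1%"
STAR_LEGEND_FOOTNOTE = "*significant at 1%; **significant at 5%; ***significant at 10%"


@dataclass
class StructuralParameters:
    """Adjacent-logit coefficients with SEs, CIs and Wald tests."""

    k: int
    predictor_names: list[str]
    beta: np.ndarray           # (k-1, 1+q): column 0 = intercept beta_0u
    se: np.ndarray             # same shape, NaN when information is singular
    loglik: float
    converged: bool
    n_iter: int
    measurement: LC2PLParameters | None = None
    posterior: np.ndarray | None = None
    mode: str = "joint"

    def table(self, transition: int, star_mode: str = "table") -> pd.DataFrame:
        """Coefficient table for the u-1 -> u transition (transition = u)."""
        if not 2 <= transition <= self.k:
            raise ValueError(f"transition must be in 2..{self.k}")
        row = transition - 2
        names = ["intercept", *self.predictor_names]
        est, se = self.beta[row], self.se[row]
        z = np.where(se > 0, est / se, np.nan)
        p = 2 * stats.norm.sf(np.abs(z))
        return pd.DataFrame(
            {
                "predictor": names,
                "estimate": est,
                "se": se,
                "ci_low": est - 1.96 * se,
                "ci_high": est + 1.96 * se,
                "z": z,
                "p_value": p,
                "stars": [significance_stars(pv, star_mode) for pv in p],
            }
        )


def significance_stars(p: float, mode: str = "table") -> str:
    """Map a two-sided p-value to stars.

    ``table``: the conventional mapping (*** at 1%, ** at 5%, * at 10%).
    ``legend``: the inverted mapping (* at 1%, ** at 5%, *** at 10%).
    """
    if not np.isfinite(p):
        return ""
    levels = [(0.01, 3), (0.05, 2), (0.10, 1)]
    n = 0
    for cut, stars in levels:
        if p < cut:
            n = stars
            break
    if n == 0:
        return ""
    if mode == "legend":
        n = 4 - n
    elif mode != "table":
        raise ValueError(f"unknown star mode {mode!r}")
    return "*" * n


def wald_test(estimate: float, se: float) -> tuple[float, float]:
    """z statistic and two-sided normal p-value for H0: parameter = 0."""
    if se <= 0:
        raise ValueError("se must be positive")
    z = estimate / se
    return float(z), float(2 * stats.norm.sf(abs(z)))


# ---------------------------------------------------------------------------
# Adjacent-logit machinery
# ---------------------------------------------------------------------------

def _class_log_probs(beta: np.ndarray, Dmat: np.ndarray) -> np.ndarray:
    """(n, k) log pi_iu from adjacent-logit coefficients.

    beta is (k-1, 1+q); cumulative sums of the adjacent logits give the
    baseline-category representation with class 1 as reference."""
    lin = beta[:, 0][None, :] + Dmat @ beta[:, 1:].T     # (n, k-1)
    c = np.concatenate([np.zeros((len(Dmat), 1)), np.cumsum(lin, axis=1)], axis=1)
    return c - logsumexp(c, axis=1, keepdims=True)


def _structural_negll_grad(
    bvec: np.ndarray, Dmat: np.ndarray, tau: np.ndarray, w: np.ndarray, k: int
):
    """Weighted multinomial M-step objective for the concomitant model."""
    q = Dmat.shape[1]
    beta = bvec.reshape(k - 1, 1 + q)
    logpi = _class_log_probs(beta, Dmat)
    f = -float(np.sum(w[:, None] * tau * logpi))
    diff = tau - np.exp(logpi)                          # (n, k)
    # gradient wrt adjacent logit v: sum over classes u >= v
    A = np.cumsum(diff[:, ::-1], axis=1)[:, ::-1][:, 1:]  # (n, k-1), col v-2
    wA = w[:, None] * A
    g0 = wA.sum(axis=0)
    g1 = wA.T @ Dmat
    grad = -np.concatenate([g0[:, None], g1], axis=1).ravel()
    return f, grad


def _fit_concomitant(
    Dmat: np.ndarray, tau: np.ndarray, w: np.ndarray, k: int, beta0: np.ndarray
) -> np.ndarray:
    bvec0 = beta0.ravel()
    res = minimize(
        _structural_negll_grad, bvec0, args=(Dmat, tau, w, k), jac=True,
        method="L-BFGS-B",
        options={"maxiter": 30, "ftol": 1e-13, "gtol": 1e-10},
    )
    f0 = _structural_negll_grad(bvec0, Dmat, tau, w, k)[0]
    if res.fun <= f0:
        return res.x.reshape(beta0.shape)
    return beta0


def predictor_matrix(
    records: Sequence[PatientRecord], design: StudyDesign
) -> tuple[np.ndarray, list[str]]:
    """Structural predictors: all treatments plus external covariates."""
    names = list(design.treatment_names()) + list(design.external_covariates)
    X = np.array([[rec.value(c) for c in names] for rec in records], dtype=float)
    return X, names


# ---------------------------------------------------------------------------
# Joint weighted likelihood
# ---------------------------------------------------------------------------

def _joint_loglik(
    params: LC2PLParameters, beta: np.ndarray, Y: np.ndarray, Dmat: np.ndarray,
    w: np.ndarray,
) -> float:
    logpi = _class_log_probs(beta, Dmat)
    ll_iu = _log_cond_matrix(params, np.asarray(Y, dtype=float)) + logpi
    return float(w @ logsumexp(ll_iu, axis=1))


def fit_structural(
    Y: np.ndarray,
    weights: np.ndarray | None,
    measurement_fit: FitResult,
    Dmat: np.ndarray,
    predictor_names: Sequence[str],
    mode: Literal["joint", "twostep"] = "joint",
    tol: float = 1e-8,
    max_iter: int = 500,
    compute_se: bool = True,
    se_method: Literal["sandwich", "information"] = "sandwich",
) -> StructuralParameters:
    """Estimate the adjacent-logit structural model.

    ``joint`` (default): EM on the full weighted likelihood, re-estimating
    measurement parameters together with the concomitant coefficients.
    ``twostep``: measurement parameters frozen at the step-3 estimates;
    the concomitant logit is fitted to the posterior class probabilities.
    """
    Y = np.asarray(Y)
    n, p = Y.shape
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    Dmat = np.asarray(Dmat, dtype=float)
    if Dmat.ndim == 1:
        Dmat = Dmat[:, None]
    q = Dmat.shape[1]
    if q != len(predictor_names):
        raise ValueError("predictor_names must match Dmat columns")
    params = measurement_fit.params.copy()
    k = params.k

    # quasi-separation screen: a binary predictor observed at a single level
    # within a MAP class makes its coefficient drift
    map_cls = measurement_fit.map_classes
    for j, nm in enumerate(predictor_names):
        col = Dmat[:, j]
        if set(np.unique(col)) <= {0.0, 1.0}:
            for u in np.unique(map_cls):
                if len(np.unique(col[map_cls == u])) < 2:
                    warnings.warn(
                        f"possible quasi-separation: predictor {nm!r} is "
                        f"constant within MAP class {u}", stacklevel=2,
                    )
                    break

    # intercept start: invert the measurement-step class masses
    beta = np.zeros((k - 1, 1 + q))
    beta[:, 0] = np.log(params.pi[1:] / params.pi[:-1])

    Yf = np.asarray(Y, dtype=float)
    if mode == "twostep":
        tau = measurement_fit.posterior
        beta = _fit_concomitant(Dmat, tau, w, k, beta)
        loglik = _joint_loglik(params, beta, Y, Dmat, w)
        n_iter, converged = 1, True
        posterior = tau
    elif mode == "joint":
        # direct quasi-Newton maximization of the joint weighted
        # log-likelihood with its analytic gradient, warm-started at the
        # measurement-step estimates (intercepts inverted from the masses)
        anchors = params.anchor_mask()
        nb = beta.size
        x0 = np.concatenate([beta.ravel(), _pack_free(params, anchors)])

        def negll_grad(theta):
            b = theta[:nb].reshape(beta.shape)
            par = _unpack_free(theta[nb:], params, anchors)
            ll = float(_per_patient_loglik(par, b, Y, Dmat, w).sum())
            g = _per_patient_scores(par, b, Y, Dmat, w, True).sum(axis=0)
            return -ll, -g

        res = minimize(
            negll_grad, x0, jac=True, method="L-BFGS-B",
            bounds=[(-30.0, 30.0)] * len(x0),
            options={"maxiter": max_iter, "ftol": tol, "gtol": 1e-7},
        )
        beta = res.x[:nb].reshape(beta.shape)
        params = _unpack_free(res.x[nb:], params, anchors)
        n_iter = int(res.nit)
        converged = bool(res.success)
        logpi = _class_log_probs(beta, Dmat)
        ll_iu = _log_cond_matrix(params, Yf) + logpi
        posterior = np.exp(ll_iu - logsumexp(ll_iu, axis=1, keepdims=True))
        loglik = float(w @ logsumexp(ll_iu, axis=1))
        if not converged:
            warnings.warn(
                f"structural optimization did not converge: {res.message}",
                stacklevel=2,
            )
    else:
        raise ValueError(f"unknown mode {mode!r}")

    se = np.full_like(beta, np.nan)
    if compute_se:
        se = _structural_se(params, beta, Y, Dmat, w, mode, se_method)
    return StructuralParameters(
        k=k, predictor_names=list(predictor_names), beta=beta, se=se,
        loglik=loglik, converged=converged, n_iter=n_iter,
        measurement=params, posterior=posterior, mode=mode,
    )


def _per_patient_loglik(
    params: LC2PLParameters, beta: np.ndarray, Y: np.ndarray, Dmat: np.ndarray,
    w: np.ndarray,
) -> np.ndarray:
    logpi = _class_log_probs(beta, Dmat)
    ll_iu = _log_cond_matrix(params, np.asarray(Y, dtype=float)) + logpi
    return w * logsumexp(ll_iu, axis=1)


def _per_patient_scores(
    params: LC2PLParameters, beta: np.ndarray, Y: np.ndarray, Dmat: np.ndarray,
    w: np.ndarray, include_measurement: bool,
) -> np.ndarray:
    """(n, q) per-patient weighted scores of the joint log-likelihood.

    Mixture identity: the observed-data score equals the posterior-weighted
    complete-data score.  Parameter order matches the SE packing:
    [beta.ravel(), xi.ravel(), eta_free, delta_free]."""
    Yf = np.asarray(Y, dtype=float)
    n = len(Yf)
    k = params.k
    logpi = _class_log_probs(beta, Dmat)
    ll_iu = _log_cond_matrix(params, Yf) + logpi
    tau = np.exp(ll_iu - logsumexp(ll_iu, axis=1, keepdims=True))
    # concomitant block: d l_i / d(beta_0v, beta_1v) = w_i A_iv [1, d_i]
    diff = tau - np.exp(logpi)                          # (n, k)
    A = np.cumsum(diff[:, ::-1], axis=1)[:, ::-1][:, 1:]  # (n, k-1)
    wA = w[:, None] * A
    cols = [
        np.concatenate([wA[:, [v]], wA[:, [v]] * Dmat], axis=1)
        for v in range(k - 1)
    ]
    S = np.concatenate(cols, axis=1)
    if not include_measurement:
        return S
    anchors = params.anchor_mask()
    dimx = params.dim_index
    P = params.conditional_probs()                      # (k, p)
    G = w[:, None, None] * tau[:, :, None] * (Yf[:, None, :] - P[None, :, :])
    D = params.n_dimensions
    grad_xi = np.empty((n, k, D))
    for d in range(D):
        sel = dimx == d
        grad_xi[:, :, d] = (G[:, :, sel] * params.eta[None, None, sel]).sum(axis=2)
    grad_eta = (G * (params.xi[:, dimx] - params.delta[None, :])[None, :, :]).sum(
        axis=1
    )
    grad_delta = (-params.eta[None, :] * G.sum(axis=1))
    return np.concatenate(
        [
            S,
            grad_xi.reshape(n, k * D),
            grad_eta[:, ~anchors],
            grad_delta[:, ~anchors],
        ],
        axis=1,
    )


def _structural_se(
    params: LC2PLParameters, beta: np.ndarray, Y: np.ndarray, Dmat: np.ndarray,
    w: np.ndarray, mode: str, se_method: str = "sandwich",
) -> np.ndarray:
    """Standard errors for the concomitant coefficients.

    ``sandwich`` (default): robust variance H^{-1} B H^{-1} with H the
    observed information of the weighted log-likelihood and B the outer
    product of per-patient weighted scores — the consistent choice under
    estimated, non-unit inverse-probability weights.  ``information``:
    plain inverse observed information.  In joint mode the parameter vector
    covers concomitant plus measurement parameters; in two-step mode the
    concomitant block only (measurement treated as known)."""
    anchors = params.anchor_mask()
    nb = beta.size
    joint = mode == "joint"
    if joint:
        x0 = np.concatenate([beta.ravel(), _pack_free(params, anchors)])
    else:
        x0 = beta.ravel()

    def unpack(theta):
        b = theta[:nb].reshape(beta.shape)
        if joint:
            par = _unpack_free(theta[nb:], params, anchors)
        else:
            par = params
        return par, b

    def total_grad(theta):
        par, b = unpack(theta)
        return _per_patient_scores(par, b, Y, Dmat, w, joint).sum(axis=0)

    # observed information from central differences of the analytic gradient
    q = len(x0)
    h = 1e-5 * np.maximum(1.0, np.abs(x0))
    H = np.empty((q, q))
    for j in range(q):
        e = np.zeros(q)
        e[j] = h[j]
        H[:, j] = -(total_grad(x0 + e) - total_grad(x0 - e)) / (2 * h[j])
    H = (H + H.T) / 2.0
    try:
        Hinv = np.linalg.inv(H)
        if se_method == "sandwich":
            par0, b0 = unpack(x0)
            S = _per_patient_scores(par0, b0, Y, Dmat, w, joint)
            cov = Hinv @ (S.T @ S) @ Hinv
        elif se_method == "information":
            cov = Hinv
        else:
            raise ValueError(f"unknown se_method {se_method!r}")
        diag = np.diag(cov)[:nb]
        if np.any(diag <= 0):
            raise np.linalg.LinAlgError("non-positive diagonal")
        return np.sqrt(diag).reshape(beta.shape)
    except np.linalg.LinAlgError:
        warnings.warn(
            "observed information not positive definite; structural SEs NaN",
            stacklevel=2,
        )
        return np.full_like(beta, np.nan)


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------

def atet_table(
    params: StructuralParameters,
    pair: tuple[int, int],
    star_mode: str = "table",
) -> pd.DataFrame:
    """Comparison table for an adjacent class pair (u_low, u_high).

    Predictors are split into those favoring the lower (better) class
    (negative estimates) and those favoring the higher class (positive),
    each sorted by estimate; the intercept leads the table."""
    u_low, u_high = pair
    if u_high != u_low + 1 or not (1 <= u_low < params.k):
        raise ValueError(f"pair must be adjacent within 1..{params.k}")
    tab = params.table(u_high, star_mode=star_mode)
    intercept = tab.iloc[[0]].assign(group="intercept")
    rest = tab.iloc[1:].sort_values("estimate", kind="stable")
    rest = rest.assign(
        group=np.where(
            rest["estimate"] < 0,
            f"favor class {u_low}",
            f"favor class {u_high}",
        )
    )
    out = pd.concat([intercept, rest], ignore_index=True)
    out.attrs["legend"] = (
        STAR_LEGEND_TABLE if star_mode == "table" else STAR_LEGEND_FOOTNOTE
    )
    out.attrs["comparison"] = f"class {u_low} vs class {u_high}"
    return out
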