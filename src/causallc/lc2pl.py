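"""Weighted-EM estimation of the multidimensional latent-class 2PL model.

Patients carry a vector of p binary outcomes partitioned into D latent
dimensions.  A discrete latent variable U with k support points (classes)
drives the outcomes through a two-parameter-logistic response:

    P(Y_r = 1 | U = u) = 1 / (1 + exp[-eta_r (xi_{u,d(r)} - delta_r)]),

where eta_r is the item's discriminating power, delta_r its difficulty and
xi_{u,d(r)} the support point of class u on the item's dimension.  Outcomes
are conditionally independent given the class (local independence), so the
weighted log-likelihood is

    l(theta) = sum_i w_i log sum_u pi_u prod_r P(Y_ir = y_ir | U = u).

Identifiability: for each dimension the first item is the anchor, with
eta fixed to 1 and delta to 0; the support points xi are free.  Classes are
reported in increasing order of mean conditional outcome probability, so
class 1 always collects the patients with the best (least adverse) outcomes.

Estimation maximizes l(theta) by EM.  Internally patients are collapsed to
unique response patterns, which makes the per-iteration cost independent of
the number of patients; the M-step for the item parameters maximizes the
expected complete-data log-likelihood on the collapsed sufficient
statistics with a quasi-Newton step.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logsumexp

from .study_data import OutcomeSpec, PatientRecord, StudyDesign

logger = logging.getLogger("causallc")

PARAM_BOUND = 30.0       # box bound on xi, eta, delta during optimization
EMPTY_CLASS_TOL = 1e-4


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------

@dataclass
class LC2PLParameters:
    """Class masses, support points and item parameters."""

    pi: np.ndarray        # (k,)
    xi: np.ndarray        # (k, D)
    eta: np.ndarray       # (p,)  anchors fixed at 1
    delta: np.ndarray     # (p,)  anchors fixed at 0
    dim_index: np.ndarray  # (p,) 0-based dimension per item

    @property
    def k(self) -> int:
        return len(self.pi)

    @property
    def n_items(self) -> int:
        return len(self.eta)

    @property
    def n_dimensions(self) -> int:
        return self.xi.shape[1]

    def anchor_mask(self) -> np.ndarray:
        """True for the first item of each dimension (eta=1, delta=0 fixed)."""
        mask = np.zeros(self.n_items, dtype=bool)
        for d in range(self.n_dimensions):
            mask[np.argmax(self.dim_index == d)] = True
        return mask

    def conditional_probs(self) -> np.ndarray:
        """(k, p) matrix of P(Y_r=1 | U=u)."""
        lin = self.eta[None, :] * (self.xi[:, self.dim_index] - self.delta[None, :])
        return expit(lin)

    def copy(self) -> "LC2PLParameters":
        return LC2PLParameters(
            self.pi.copy(), self.xi.copy(), self.eta.copy(), self.delta.copy(),
            self.dim_index.copy(),
        )

    def normalize_anchors(self) -> "LC2PLParameters":
        """Map to the anchor gauge (eta=1, delta=0 for each dimension's first
        item) via the per-dimension affine rescaling the model is invariant
        under; conditional probabilities are unchanged."""
        out = self.copy()
        anchors = self.anchor_mask()
        for d in range(self.n_dimensions):
            items = np.where(self.dim_index == d)[0]
            r0 = items[anchors[items]][0]
            a, b = self.eta[r0], self.delta[r0]
            if a == 0:
                raise ValueError(f"anchor item {r0} has zero discrimination")
            out.xi[:, d] = a * (self.xi[:, d] - b)
            out.eta[items] = self.eta[items] / a
            out.delta[items] = a * (self.delta[items] - b)
        return out


@dataclass
class FitResult:
    """Converged (or flagged) weighted-EM fit."""

    params: LC2PLParameters
    loglik: float
    n_par: int
    bic: float
    posterior: np.ndarray      # (n, k)
    map_classes: np.ndarray    # (n,) 1-based
    n_iter: int
    converged: bool
    loglik_history: np.ndarray = field(default_factory=lambda: np.empty(0))
    empty_classes: tuple[int, ...] = ()
    seed: int | None = None


def item_probability(eta_r: float, delta_r: float, xi: float) -> float:
    """2PL response probability, overflow-safe."""
    lin = eta_r * (xi - delta_r)
    if lin >= 0:
        return float(1.0 / (1.0 + np.exp(-lin)))
    e = np.exp(lin)
    return float(e / (1.0 + e))


def compute_bic(loglik: float, n: int, n_par: int) -> float:
    """BIC = -2 l + log(n) * #par (natural log)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return -2.0 * loglik + np.log(n) * n_par


def count_parameters(k: int, p: int, n_dimensions: int) -> int:
    """Free parameters: (k-1) masses + k*D support points + (p-D) each of
    free discriminations and difficulties (one anchor per dimension)."""
    if not (p >= n_dimensions >= 1):
        raise ValueError("require p >= n_dimensions >= 1")
    return (k - 1) + k * n_dimensions + 2 * (p - n_dimensions)


# ---------------------------------------------------------------------------
# Data plumbing
# ---------------------------------------------------------------------------

def outcome_matrix(
    records: Sequence[PatientRecord], outcome_set: str, design: StudyDesign
) -> tuple[np.ndarray, np.ndarray]:
    """(n, p) binary outcome matrix and 0-based dimension index for one set."""
    spec: OutcomeSpec = design.outcome_sets[outcome_set]
    items = spec.items
    Y = np.array(
        [[rec.outcomes[outcome_set][o] for o in items] for rec in records],
        dtype=np.int8,
    )
    return Y, spec.dimension_index()


def _collapse(Y: np.ndarray, w: np.ndarray):
    """Collapse to unique response patterns.

    Returns (patterns, summed pattern weights W_g, inverse index mapping
    patients to patterns)."""
    patterns, inverse = np.unique(Y, axis=0, return_inverse=True)
    G = len(patterns)
    W = np.bincount(inverse, weights=w, minlength=G)
    return patterns.astype(float), W, inverse


# ---------------------------------------------------------------------------
# Likelihood
# ---------------------------------------------------------------------------

def _log_cond_matrix(params: LC2PLParameters, patterns: np.ndarray) -> np.ndarray:
    """(G, k) log P(pattern | class).

    Computed from the linear predictors with the stable log-sigmoid, so the
    same (finite) likelihood is used in the E-step, the M-step and external
    evaluations even for near-degenerate probabilities."""
    lin = params.eta[None, :] * (
        params.xi[:, params.dim_index] - params.delta[None, :]
    )
    logP = -np.logaddexp(0.0, -lin)
    log1mP = -np.logaddexp(0.0, lin)
    return patterns @ logP.T + (1.0 - patterns) @ log1mP.T


def weighted_loglik(
    params: LC2PLParameters, Y: np.ndarray, weights: np.ndarray
) -> float:
    """l(theta) = sum_i w_i log sum_u pi_u prod_r P(y_ir | u)."""
    patterns, W, _ = _collapse(np.asarray(Y), np.asarray(weights, dtype=float))
    ll_gu = _log_cond_matrix(params, patterns) + np.log(params.pi)[None, :]
    return float(W @ logsumexp(ll_gu, axis=1))


# ---------------------------------------------------------------------------
# M-step for item parameters (shared with the structural module)
# ---------------------------------------------------------------------------

def _pack_free(params: LC2PLParameters, anchors: np.ndarray) -> np.ndarray:
    return np.concatenate(
        [params.xi.ravel(), params.eta[~anchors], params.delta[~anchors]]
    )


def _unpack_free(
    theta: np.ndarray, params: LC2PLParameters, anchors: np.ndarray
) -> LC2PLParameters:
    k, D, p = params.k, params.n_dimensions, params.n_items
    out = params.copy()
    out.xi = theta[: k * D].reshape(k, D)
    nfree = p - anchors.sum()
    eta = np.ones(p)
    delta = np.zeros(p)
    eta[~anchors] = theta[k * D: k * D + nfree]
    delta[~anchors] = theta[k * D + nfree:]
    eta[anchors], delta[anchors] = 1.0, 0.0
    out.eta, out.delta = eta, delta
    return out


def _item_q_and_grad(
    theta: np.ndarray,
    template: LC2PLParameters,
    anchors: np.ndarray,
    s_ur: np.ndarray,      # (k, p) weighted posterior item successes
    wcell: np.ndarray,     # (k,) weighted posterior class totals
):
    """Negative expected complete-data log-likelihood (item part) + gradient."""
    par = _unpack_free(theta, template, anchors)
    dimx = par.dim_index
    lin = par.eta[None, :] * (par.xi[:, dimx] - par.delta[None, :])
    # stable log sigmoid / log(1 - sigmoid)
    log_p = -np.logaddexp(0.0, -lin)
    log_1mp = -np.logaddexp(0.0, lin)
    Q = np.sum(s_ur * log_p + (wcell[:, None] - s_ur) * log_1mp)
    p_ur = expit(lin)
    g = s_ur - wcell[:, None] * p_ur          # dQ/d lin
    k, D, p = par.k, par.n_dimensions, par.n_items
    grad_xi = np.zeros((k, D))
    for d in range(D):
        sel = dimx == d
        grad_xi[:, d] = (g[:, sel] * par.eta[None, sel]).sum(axis=1)
    grad_eta = (g * (par.xi[:, dimx] - par.delta[None, :])).sum(axis=0)
    grad_delta = (-par.eta[None, :] * g).sum(axis=0)
    grad = np.concatenate([grad_xi.ravel(), grad_eta[~anchors], grad_delta[~anchors]])
    return -Q, -grad


def _maximize_item_params(
    params: LC2PLParameters, s_ur: np.ndarray, wcell: np.ndarray
) -> LC2PLParameters:
    """Maximize the item part of the expected complete-data log-likelihood.

    Falls back to the incoming parameters if the optimizer fails to improve,
    preserving EM monotonicity (generalized EM)."""
    anchors = params.anchor_mask()
    theta0 = _pack_free(params, anchors)
    bounds = [(-PARAM_BOUND, PARAM_BOUND)] * len(theta0)
    # partial maximization (generalized EM): a handful of quasi-Newton steps
    # from the warm start is enough; the fallback below keeps EM monotone
    res = minimize(
        _item_q_and_grad, theta0, args=(params, anchors, s_ur, wcell),
        jac=True, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": 12, "ftol": 1e-13, "gtol": 1e-10},
    )
    q0 = _item_q_and_grad(theta0, params, anchors, s_ur, wcell)[0]
    if res.fun <= q0:
        return _unpack_free(res.x, params, anchors)
    return params


# ---------------------------------------------------------------------------
# EM
# ---------------------------------------------------------------------------

def _estep(params: LC2PLParameters, patterns: np.ndarray, W: np.ndarray):
    ll_gu = _log_cond_matrix(params, patterns) + np.log(
        np.clip(params.pi, 1e-300, None)
    )[None, :]
    norm = logsumexp(ll_gu, axis=1)
    tau = np.exp(ll_gu - norm[:, None])
    loglik = float(W @ norm)
    return tau, loglik


def _em_run(
    params: LC2PLParameters,
    patterns: np.ndarray,
    W: np.ndarray,
    tol: float,
    max_iter: int,
) -> tuple[LC2PLParameters, float, np.ndarray, int, bool]:
    """One EM run from the given start; returns (params, loglik, history,
    n_iter, converged).  Raises on a log-likelihood decrease beyond rounding."""
    params = params.normalize_anchors()
    history = []
    prev = -np.inf
    converged = False
    Wtot = W.sum()
    for it in range(1, max_iter + 1):
        tau, loglik = _estep(params, patterns, W)
        history.append(loglik)
        if loglik < prev - 1e-8 * (1.0 + abs(prev)):
            raise RuntimeError(
                f"EM log-likelihood decreased at iteration {it}: "
                f"{prev:.10g} -> {loglik:.10g}"
            )
        if it > 1 and abs(loglik - prev) <= tol * (1.0 + abs(prev)):
            converged = True
            break
        prev = loglik
        # M-step
        wtau = W[:, None] * tau
        wcell = wtau.sum(axis=0)                   # (k,)
        params.pi = wcell / Wtot
        s_ur = wtau.T @ patterns                   # (k, p)
        params = _maximize_item_params(params, s_ur, wcell)
    _, loglik = _estep(params, patterns, W)
    history.append(loglik)
    return params, loglik, np.asarray(history), len(history) - 1, converged


def _deterministic_start(
    patterns: np.ndarray, W: np.ndarray, inverse: np.ndarray, Y: np.ndarray,
    k: int, dim_index: np.ndarray,
) -> LC2PLParameters:
    """Start from a k-quantile split of patient outcome sums."""
    p = Y.shape[1]
    D = int(dim_index.max()) + 1
    scores = Y.sum(axis=1)
    edges = np.quantile(scores, np.linspace(0, 1, k + 1)[1:-1]) if k > 1 else []
    cls = np.searchsorted(np.asarray(edges), scores, side="right")
    pi = np.array([max((cls == u).mean(), 1.0 / (10 * k)) for u in range(k)])
    pi = pi / pi.sum()
    xi = np.zeros((k, D))
    for u in range(k):
        sub = Y[cls == u] if (cls == u).any() else Y
        for d in range(D):
            items = dim_index == d
            m = np.clip(sub[:, items].mean(), 0.02, 0.98)
            xi[u, d] = np.log(m / (1 - m))
    pbar = np.clip(Y.mean(axis=0), 0.02, 0.98)
    delta = -np.log(pbar / (1 - pbar))
    params = LC2PLParameters(
        pi=pi, xi=xi, eta=np.ones(p), delta=delta, dim_index=dim_index.copy()
    )
    anchors = params.anchor_mask()
    params.eta[anchors], params.delta[anchors] = 1.0, 0.0
    return params


def _random_start(
    rng: np.random.Generator, Y: np.ndarray, k: int, dim_index: np.ndarray
) -> LC2PLParameters:
    p = Y.shape[1]
    D = int(dim_index.max()) + 1
    pi = rng.dirichlet(np.full(k, 2.0))
    xi = rng.uniform(-2.5, 2.5, size=(k, D))
    pbar = np.clip(Y.mean(axis=0), 0.02, 0.98)
    delta = -np.log(pbar / (1 - pbar)) + rng.normal(0, 0.5, size=p)
    eta = np.exp(rng.normal(0, 0.3, size=p))
    params = LC2PLParameters(
        pi=pi, xi=xi, eta=eta, delta=delta, dim_index=dim_index.copy()
    )
    anchors = params.anchor_mask()
    params.eta[anchors], params.delta[anchors] = 1.0, 0.0
    return params


def _order_classes(params: LC2PLParameters, tau: np.ndarray):
    """Relabel classes by increasing mean conditional outcome probability
    (class 1 = best outcomes)."""
    order = np.argsort(params.conditional_probs().mean(axis=1), kind="stable")
    params.pi = params.pi[order]
    params.xi = params.xi[order, :]
    return params, tau[:, order]


def em_fit(
    Y: np.ndarray,
    weights: np.ndarray | None,
    k: int,
    dim_index: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 1000,
    n_starts: int = 20,
    burn_iter: int = 40,
    seed: int | None = 0,
) -> FitResult:
    """Fit the k-class weighted LC-2PL model by multi-start EM.

    One deterministic start (quantile split of outcome sums) plus
    ``n_starts`` seeded random starts each run for ``burn_iter`` iterations;
    the best is polished to convergence (relative tolerance ``tol``, cap
    ``max_iter``).
    """
    Y = np.asarray(Y)
    n, p = Y.shape
    dim_index = np.asarray(dim_index, dtype=int)
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    # run on mean-1 weights so estimates are exactly invariant to the weight
    # scale; the reported log-likelihood is rescaled to the given weights
    wscale = float(w.mean())
    w = w / wscale
    D = int(dim_index.max()) + 1
    n_par = count_parameters(k, p, D)
    if n <= n_par:
        warnings.warn(
            f"n={n} does not exceed the number of free parameters ({n_par})",
            stacklevel=2,
        )
    patterns, W, inverse = _collapse(Y, w)
    rng = np.random.default_rng(seed)

    starts = [_deterministic_start(patterns, W, inverse, Y, k, dim_index)]
    starts += [_random_start(rng, Y, k, dim_index) for _ in range(n_starts)]
    best = None
    for s, start in enumerate(starts):
        par, ll, _, _, _ = _em_run(
            start.copy(), patterns, W, tol=tol, max_iter=burn_iter
        )
        if best is None or ll > best[1]:
            best = (par, ll)
    params, loglik, history, n_iter, converged = _em_run(
        best[0], patterns, W, tol=tol, max_iter=max_iter
    )
    if not converged:
        warnings.warn("EM did not converge within max_iter", stacklevel=2)

    tau, loglik = _estep(params, patterns, W)
    params, tau = _order_classes(params, tau)
    posterior = tau[inverse, :]
    empty = tuple(int(u) + 1 for u in np.where(params.pi < EMPTY_CLASS_TOL)[0])
    if empty:
        logger.warning("classes with near-zero mass at convergence: %s", empty)
    loglik *= wscale
    return FitResult(
        params=params,
        loglik=loglik,
        n_par=n_par,
        bic=compute_bic(loglik, n, n_par),
        posterior=posterior,
        map_classes=classify_posterior(posterior),
        n_iter=n_iter,
        converged=converged,
        loglik_history=history * wscale,
        empty_classes=empty,
        seed=seed,
    )


def classify_posterior(posterior: np.ndarray) -> np.ndarray:
    """MAP class per patient (1-based); ties break toward the lower index."""
    return np.argmax(posterior, axis=1) + 1


def classify(fit: FitResult) -> np.ndarray:
    return classify_posterior(fit.posterior)


# ---------------------------------------------------------------------------
# Model selection
# ---------------------------------------------------------------------------

def select_k(
    Y: np.ndarray,
    weights: np.ndarray | None,
    k_range: Sequence[int],
    dim_index: np.ndarray,
    **em_kwargs,
) -> tuple[FitResult, pd.DataFrame]:
    """Fit each k in order and pick the k before the first BIC increase."""
    k_range = list(k_range)
    if k_range != list(range(1, len(k_range) + 1)):
        raise ValueError("k_range must be contiguous from 1")
    fits: list[FitResult] = []
    rows = []
    best_idx = None
    for k in k_range:
        fit = em_fit(Y, weights, k, dim_index, **em_kwargs)
        fits.append(fit)
        rows.append(
            {"k": k, "loglik": fit.loglik, "n_par": fit.n_par, "bic": fit.bic}
        )
        if len(fits) > 1 and fit.bic > fits[-2].bic and best_idx is None:
            best_idx = len(fits) - 2
            break
    table = pd.DataFrame(rows)
    if best_idx is None:
        best_idx = len(fits) - 1
        if len(fits) > 1:
            warnings.warn(
                "BIC decreasing over the whole k range; extend the range",
                stacklevel=2,
            )
    table["selected"] = [i == best_idx for i in range(len(fits))]
    return fits[best_idx], table


# ---------------------------------------------------------------------------
# Standard errors
# ---------------------------------------------------------------------------

def _full_free_vector(params: LC2PLParameters) -> np.ndarray:
    """Free parameters incl. class masses as log-ratios against class 1."""
    lam = np.log(params.pi[1:] / params.pi[0])
    anchors = params.anchor_mask()
    return np.concatenate([lam, _pack_free(params, anchors)])


def _params_from_full(theta: np.ndarray, template: LC2PLParameters) -> LC2PLParameters:
    k = template.k
    lam = np.concatenate([[0.0], theta[: k - 1]])
    pi = np.exp(lam - logsumexp(lam))
    par = _unpack_free(theta[k - 1:], template, template.anchor_mask())
    par.pi = pi
    return par


def free_parameter_names(params: LC2PLParameters) -> list[str]:
    anchors = params.anchor_mask()
    names = [f"log_mass_ratio_{u + 1}" for u in range(1, params.k)]
    names += [
        f"xi[{u + 1},{d + 1}]"
        for u in range(params.k)
        for d in range(params.n_dimensions)
    ]
    names += [f"eta[{r + 1}]" for r in range(params.n_items) if not anchors[r]]
    names += [f"delta[{r + 1}]" for r in range(params.n_items) if not anchors[r]]
    return names


def finite_difference_hessian(fun, x0: np.ndarray, rel_step: float = 1e-4):
    """Symmetric central-difference Hessian of a scalar function."""
    q = len(x0)
    h = rel_step * np.maximum(1.0, np.abs(x0))
    H = np.empty((q, q))
    for i in range(q):
        for j in range(i, q):
            ei = np.zeros(q); ei[i] = h[i]
            ej = np.zeros(q); ej[j] = h[j]
            fpp = fun(x0 + ei + ej)
            fpm = fun(x0 + ei - ej)
            fmp = fun(x0 - ei + ej)
            fmm = fun(x0 - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[j])
    return H


def standard_errors(
    fit: FitResult, Y: np.ndarray, weights: np.ndarray | None
) -> pd.DataFrame:
    """SEs from the numerically inverted observed information of l(theta).

    Reports the free parameters and, via the delta method, the conditional
    response probabilities per (class, item).  A non-positive-definite
    information matrix yields NaN SEs with a warning.
    """
    Y = np.asarray(Y)
    n = len(Y)
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    template = fit.params
    x0 = _full_free_vector(template)

    def negll(theta):
        return -weighted_loglik(_params_from_full(theta, template), Y, w)

    H = finite_difference_hessian(negll, x0)
    names = free_parameter_names(template)
    try:
        cov = np.linalg.inv(H)
        diag = np.diag(cov)
        if np.any(diag <= 0):
            raise np.linalg.LinAlgError("non-positive diagonal")
        se = np.sqrt(diag)
    except np.linalg.LinAlgError:
        warnings.warn(
            "observed information is not positive definite; SEs set to NaN",
            stacklevel=2,
        )
        cov = np.full((len(x0), len(x0)), np.nan)
        se = np.full(len(x0), np.nan)

    rows = [
        {"parameter": nm, "estimate": est, "se": s}
        for nm, est, s in zip(names, x0, se)
    ]
    # delta-method SEs for the conditional probabilities
    k, p = template.k, template.n_items
    for u in range(k):
        for r in range(p):
            def prob(theta, u=u, r=r):
                return _params_from_full(theta, template).conditional_probs()[u, r]
            g = _fd_gradient(prob, x0)
            var = float(g @ cov @ g) if np.all(np.isfinite(cov)) else np.nan
            rows.append(
                {
                    "parameter": f"P(Y{r + 1}=1|U={u + 1})",
                    "estimate": prob(x0),
                    "se": np.sqrt(var) if var == var and var >= 0 else np.nan,
                }
            )
    return pd.DataFrame(rows)


def _fd_gradient(fun, x0: np.ndarray, rel_step: float = 1e-6) -> np.ndarray:
    h = rel_step * np.maximum(1.0, np.abs(x0))
    g = np.empty(len(x0))
    for i in range(len(x0)):
        e = np.zeros(len(x0)); e[i] = h[i]
        g[i] = (fun(x0 + e) - fun(x0 - e)) / (2 * h[i])
    return g


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------

def measurement_table(fit: FitResult, item_names: Sequence[str]) -> pd.DataFrame:
    """Class masses plus the item-by-class conditional probability table."""
    P = fit.params.conditional_probs()
    k = fit.params.k
    cols = [f"class_{u + 1}" for u in range(k)]
    rows = [dict(zip(cols, fit.params.pi), row="class_mass")]
    for r, name in enumerate(item_names):
        rows.append(dict(zip(cols, P[:, r]), row=name))
    return pd.DataFrame(rows)[["row", *cols]]
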