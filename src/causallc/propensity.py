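"""Sequential treatment models and inverse-probability-of-treatment weights.

Treatments are modelled block by block: every treatment in block v is
regressed on the confounders available at that block plus all treatments of
earlier blocks.  Binary treatments get a maximum-likelihood logistic
regression; continuous treatments get a linear model with a residual-scale
estimate and contribute a stabilized density ratio (marginal normal density
of the observed dose over its conditional density — a generalized propensity
score).

The per-patient weight combines the per-block inverse probabilities.  The
default combination is the sum over blocks of the inverse of the within-block
product,

    w_i = sum_v 1 / prod_j p_ij ,

with the conventional product over all blocks available as an alternative
mode.  Weights are stabilized by winsorizing at empirical quantiles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import linalg, stats

from .study_data import BINARY, PatientRecord, StudyDesign, records_to_frame

logger = logging.getLogger("causallc")

DEFAULT_PROB_FLOOR = 1e-6
DEFAULT_TRIM_QUANTILES = (0.01, 0.99)


class SeparationError(RuntimeError):
    """Perfect separation in a treatment model."""


class SingularDesignError(RuntimeError):
    """Collinear predictors in a treatment model."""


@dataclass
class TreatmentModelFit:
    """Fitted assignment model for one treatment.

    For binary treatments ``scale`` additionally stores nothing; for
    continuous treatments it is the residual standard deviation and
    ``marginal`` the (mean, sd) of the marginal dose distribution used for
    stabilization.
    """

    treatment: str
    block: int
    kind: str
    predictors: list[str]
    intercept: float
    coef: np.ndarray
    scale: float | None = None
    marginal: tuple[float, float] | None = None

    def linear_predictor(self, X: np.ndarray) -> np.ndarray:
        return self.intercept + X @ self.coef


@dataclass
class WeightVector:
    """Raw and trimmed IPT weights plus the per-treatment probabilities."""

    ids: list
    prob: pd.DataFrame            # per-patient per-treatment p_ij
    block_inverse: pd.DataFrame   # per-patient 1 / prod_j p_ij per block
    raw: np.ndarray
    trimmed: np.ndarray
    trim_bounds: tuple[float, float]
    mode: str = "sum"

    @property
    def normalized(self) -> np.ndarray:
        """Trimmed weights scaled to mean 1.

        Estimates are invariant to the scale of the weights, but
        information-based standard errors and the BIC's log(n) penalty are
        only on the right scale when the weighted pseudo-sample size equals
        n; this is the weight vector the likelihood stages should use."""
        return self.trimmed / self.trimmed.mean()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"id": self.ids, "raw_weight": self.raw, "trimmed_weight": self.trimmed,
             "normalized_weight": self.normalized}
        )


# ---------------------------------------------------------------------------
# Model fitting
# ---------------------------------------------------------------------------

def _design_matrix(df: pd.DataFrame, predictors: Sequence[str]) -> np.ndarray:
    return df[list(predictors)].to_numpy(dtype=float)


def _check_rank(X: np.ndarray, predictors: Sequence[str], treatment: str) -> None:
    Xc = np.column_stack([np.ones(len(X)), X])
    if np.linalg.matrix_rank(Xc) == Xc.shape[1]:
        return
    # locate the dependent columns via pivoted QR on the centered predictors
    _, r, piv = linalg.qr(Xc, pivoting=True, mode="economic")
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(Xc.shape) * np.finfo(float).eps
    names = ["<intercept>", *predictors]
    bad = [names[piv[i]] for i in range(len(diag)) if diag[i] < tol]
    raise SingularDesignError(
        f"singular design matrix for treatment {treatment!r}; "
        f"collinear columns: {bad}"
    )


def fit_block_models(
    records: Sequence[PatientRecord], design: StudyDesign
) -> list[TreatmentModelFit]:
    """Fit one assignment model per treatment, in block order."""
    df = records_to_frame(records, design)
    fits: list[TreatmentModelFit] = []
    for block in design.blocks:
        predictors = design.predictors_for_block(block.index)
        for name, kind in block.treatments:
            y = df[name].to_numpy(dtype=float)
            if len(np.unique(y)) < 2:
                raise ValueError(
                    f"treatment {name!r} has a single observed value; cannot model"
                )
            X = _design_matrix(df, predictors)
            _check_rank(X, predictors, name)
            Xc = sm.add_constant(X, has_constant="add")
            if kind == BINARY:
                try:
                    res = sm.Logit(y, Xc).fit(disp=0, maxiter=200)
                except Exception as exc:  # statsmodels PerfectSeparationError etc.
                    raise SeparationError(
                        f"logistic fit failed for treatment {name!r} "
                        f"(possible perfect separation): {exc}; review predictors"
                    ) from exc
                p = res.predict(Xc)
                if np.any((p < 1e-10) | (p > 1 - 1e-10)) and not res.mle_retvals.get(
                    "converged", True
                ):
                    raise SeparationError(
                        f"perfect separation for treatment {name!r}; review predictors"
                    )
                fit = TreatmentModelFit(
                    treatment=name, block=block.index, kind=kind,
                    predictors=list(predictors),
                    intercept=float(res.params[0]), coef=np.asarray(res.params[1:]),
                )
            else:
                res = sm.OLS(y, Xc).fit()
                resid_sd = float(np.sqrt(res.scale))
                fit = TreatmentModelFit(
                    treatment=name, block=block.index, kind=kind,
                    predictors=list(predictors),
                    intercept=float(res.params[0]), coef=np.asarray(res.params[1:]),
                    scale=resid_sd,
                    marginal=(float(y.mean()), float(y.std(ddof=1))),
                )
            if not np.all(np.isfinite(fit.coef)) or not np.isfinite(fit.intercept):
                raise SeparationError(
                    f"non-finite coefficients for treatment {name!r}; "
                    "review predictors"
                )
            fits.append(fit)
    return fits


def assignment_probability(
    fit: TreatmentModelFit,
    record: PatientRecord,
    floor: float = DEFAULT_PROB_FLOOR,
) -> float:
    """Probability (binary) or stabilized density ratio (continuous) of the
    treatment value this patient actually received."""
    x = np.array([record.value(c) for c in fit.predictors], dtype=float)
    z = record.value(fit.treatment)
    lp = fit.intercept + float(x @ fit.coef)
    if fit.kind == BINARY:
        p1 = 1.0 / (1.0 + np.exp(-lp))
        p = p1 if z == 1 else 1.0 - p1
    else:
        mu_m, sd_m = fit.marginal  # type: ignore[misc]
        num = stats.norm.pdf(z, loc=mu_m, scale=max(sd_m, 1e-12))
        den = stats.norm.pdf(z, loc=lp, scale=max(fit.scale, 1e-12))
        p = num / max(den, 1e-300)
    if p < floor:
        logger.warning(
            "assignment probability %.3g for treatment %r floored at %g "
            "(positivity nearly violated)", p, fit.treatment, floor,
        )
        p = floor
    return float(p)


# ---------------------------------------------------------------------------
# Weights
# ---------------------------------------------------------------------------

def _probability_table(
    fits: Sequence[TreatmentModelFit],
    records: Sequence[PatientRecord],
    design: StudyDesign,
    floor: float,
) -> pd.DataFrame:
    df = records_to_frame(records, design)
    out = {}
    for fit in fits:
        X = _design_matrix(df, fit.predictors)
        z = df[fit.treatment].to_numpy(dtype=float)
        lp = fit.linear_predictor(X)
        if fit.kind == BINARY:
            p1 = 1.0 / (1.0 + np.exp(-lp))
            p = np.where(z == 1, p1, 1.0 - p1)
        else:
            mu_m, sd_m = fit.marginal  # type: ignore[misc]
            num = stats.norm.pdf(z, loc=mu_m, scale=max(sd_m, 1e-12))
            den = np.maximum(stats.norm.pdf(z, loc=lp, scale=max(fit.scale, 1e-12)),
                             1e-300)
            p = num / den
        n_floored = int((p < floor).sum())
        if n_floored:
            logger.warning(
                "%d assignment probabilities for %r floored at %g",
                n_floored, fit.treatment, floor,
            )
        out[fit.treatment] = np.maximum(p, floor)
    return pd.DataFrame(out, index=df.index)


def compute_weights(
    fits: Sequence[TreatmentModelFit],
    records: Sequence[PatientRecord],
    design: StudyDesign,
    mode: Literal["sum", "product"] = "sum",
    floor: float = DEFAULT_PROB_FLOOR,
) -> WeightVector:
    """Combine per-treatment assignment probabilities into patient weights.

    ``mode="sum"`` (default): w_i = sum over blocks of the inverse of the
    within-block product of p_ij.  ``mode="product"``: the conventional
    single inverse of the product over all blocks.
    """
    fitted = {f.treatment: f for f in fits}
    missing = [t for t in design.treatment_names() if t not in fitted]
    if missing:
        raise ValueError(f"no fitted model for treatments {missing}")
    prob = _probability_table(fits, records, design, floor)
    block_inv = {}
    for block in design.blocks:
        block_prod = prob[list(block.names)].prod(axis=1)
        block_inv[block.index] = 1.0 / block_prod
    block_inverse = pd.DataFrame(block_inv)
    if mode == "sum":
        raw = block_inverse.sum(axis=1).to_numpy()
    elif mode == "product":
        raw = block_inverse.prod(axis=1).to_numpy()
    else:
        raise ValueError(f"unknown weight mode {mode!r}")
    ids = [r.id for r in records]
    return WeightVector(
        ids=ids, prob=prob, block_inverse=block_inverse,
        raw=raw, trimmed=raw.copy(),
        trim_bounds=(float(raw.min()), float(raw.max())), mode=mode,
    )


def trim_weights(
    weights: WeightVector,
    lower_q: float = DEFAULT_TRIM_QUANTILES[0],
    upper_q: float = DEFAULT_TRIM_QUANTILES[1],
) -> WeightVector:
    """Winsorize raw weights at the given empirical quantiles (idempotent)."""
    if not (0 <= lower_q < upper_q <= 1):
        raise ValueError("require 0 <= lower_q < upper_q <= 1")
    lo = float(np.quantile(weights.raw, lower_q))
    hi = float(np.quantile(weights.raw, upper_q))
    trimmed = np.clip(weights.raw, lo, hi)
    return WeightVector(
        ids=weights.ids, prob=weights.prob, block_inverse=weights.block_inverse,
        raw=weights.raw, trimmed=trimmed, trim_bounds=(lo, hi), mode=weights.mode,
    )


# ---------------------------------------------------------------------------
# Balance diagnostics
# ---------------------------------------------------------------------------

def _weighted_mean(x: np.ndarray, w: np.ndarray) -> float:
    return float(np.sum(w * x) / np.sum(w))


def balance_diagnostics(
    records: Sequence[PatientRecord],
    weights: WeightVector | None,
    design: StudyDesign,
) -> pd.DataFrame:
    """Standardized mean differences per (binary treatment, confounder).

    For each binary treatment the comparison covers the confounders in its
    adjustment set — those available at the treatment's block; later-entering
    confounders are downstream of earlier blocks and balancing on them would
    be improper.  The weighted SMD uses that treatment's own
    inverse-assignment-probability weight 1/p_ij (Hájek-normalized), the
    weight relevant to its treated/untreated contrast.  SMD = (weighted mean
    among treated − weighted mean among untreated) / pooled unweighted SD,
    sqrt((s_t² + s_c²)/2).  Reported both unweighted and weighted.
    """
    df = records_to_frame(records, design)
    rows = []
    for block in design.blocks:
        confs = [c for c in design.confounders_all]
        confs += [c for c, entry in design.confounders_post if entry <= block.index]
        for name, kind in block.treatments:
            if kind != BINARY:
                continue
            z = df[name].to_numpy(dtype=float)
            if weights is not None:
                w = 1.0 / weights.prob[name].to_numpy()
            else:
                w = np.ones(len(df))
            t, c = z == 1, z == 0
            if t.sum() == 0 or c.sum() == 0:
                continue
            for conf in confs:
                x = df[conf].to_numpy(dtype=float)
                s_t = x[t].std(ddof=1) if t.sum() > 1 else 0.0
                s_c = x[c].std(ddof=1) if c.sum() > 1 else 0.0
                pooled = np.sqrt((s_t**2 + s_c**2) / 2.0)
                if pooled == 0:
                    logger.warning(
                        "zero pooled SD for confounder %r vs treatment %r; SMD=0",
                        conf, name,
                    )
                    smd_u = smd_w = 0.0
                else:
                    smd_u = (x[t].mean() - x[c].mean()) / pooled
                    smd_w = (
                        _weighted_mean(x[t], w[t]) - _weighted_mean(x[c], w[c])
                    ) / pooled
                rows.append(
                    {"treatment": name, "confounder": conf,
                     "smd_unweighted": smd_u, "smd_weighted": smd_w}
                )
    return pd.DataFrame(
        rows, columns=["treatment", "confounder", "smd_unweighted", "smd_weighted"]
    )
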