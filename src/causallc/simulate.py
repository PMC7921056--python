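"""Seeded synthetic cohorts with the full causal structure of the study design.

Each scenario draws, in causal order: confounders; treatments block by
block, each depending on the confounders available at its block plus all
earlier treatments; external covariates; a latent class from the
adjacent-logit structural truth given treatments and external covariates;
and binary outcomes from the class-conditional 2PL truth.  The latent truth
(classes, structural coefficients, measurement parameters) is returned
alongside the records so recovery tests never re-derive it.

The shipped scenario library emulates the published frequency structure of
a perioperative enhanced-recovery registry (marginal treatment and
confounder frequencies, class masses, class-conditional outcome profiles);
it reproduces the study *structure*, not the registry's joint distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np
import pandas as pd
import yaml
from scipy.optimize import root
from scipy.special import expit, logit

from .lc2pl import LC2PLParameters
from .structural import _class_log_probs
from .study_data import (
    BINARY,
    CONTINUOUS,
    OutcomeSpec,
    PatientRecord,
    StudyDesign,
    TreatmentBlock,
    _records_from_frame,
)

CALIBRATION_SEED = 202409   # internal; independent of user seeds
CALIBRATION_N = 20000


@dataclass
class TreatmentTruth:
    """Assignment-model truth for one treatment: linear predictor over
    standardized continuous / raw binary predictors."""

    alpha: float
    coefs: dict[str, float] = field(default_factory=dict)
    resid_sd: float | None = None   # continuous treatments only


@dataclass
class SyntheticScenario:
    """Complete generative truth for one synthetic study."""

    name: str
    design: StudyDesign
    confounder_dists: dict[str, tuple]
    external_dists: dict[str, tuple]
    treatment_models: dict[str, TreatmentTruth]
    measurement: LC2PLParameters        # truth; pi unused (set by structure)
    beta: np.ndarray                    # (k-1, 1+q) adjacent-logit truth
    outcome_set: str
    n_default: int = 2000
    target_masses: np.ndarray | None = None

    def __post_init__(self) -> None:
        for t in self.design.treatment_names():
            if t not in self.treatment_models:
                raise ValueError(f"no assignment truth for treatment {t!r}")
        for name, model in self.treatment_models.items():
            allowed = set(
                self.design.predictors_for_block(self._block_of(name))
            )
            unknown = set(model.coefs) - allowed
            if unknown:
                raise ValueError(
                    f"treatment {name!r} references unavailable predictors "
                    f"{sorted(unknown)}"
                )
        k = self.measurement.k
        q = len(self.design.treatment_names()) + len(self.design.external_covariates)
        if self.beta.shape != (k - 1, 1 + q):
            raise ValueError(
                f"beta must be (k-1, 1+q) = ({k - 1}, {1 + q}), "
                f"got {self.beta.shape}"
            )

    def _block_of(self, treatment: str) -> int:
        for b in self.design.blocks:
            if treatment in b.names:
                return b.index
        raise KeyError(treatment)

    @property
    def predictor_names(self) -> list[str]:
        return list(self.design.treatment_names()) + list(
            self.design.external_covariates
        )


# ---------------------------------------------------------------------------
# Drawing
# ---------------------------------------------------------------------------

def _draw_dist(rng: np.random.Generator, dist: tuple, n: int) -> np.ndarray:
    kind = dist[0]
    if kind == "normal":
        return rng.normal(dist[1], dist[2], size=n)
    if kind == "bernoulli":
        if not 0 < dist[1] < 1:
            raise ValueError(f"bernoulli parameter must be in (0,1): {dist}")
        return rng.binomial(1, dist[1], size=n).astype(float)
    raise ValueError(f"unknown distribution {kind!r}")


def _standardizer(scenario: SyntheticScenario) -> dict[str, tuple[float, float]]:
    """Column -> (center, scale) for continuous variables entering linear
    predictors; binary columns pass through raw."""
    out = {}
    for col, dist in {**scenario.confounder_dists, **scenario.external_dists}.items():
        if dist[0] == "normal":
            out[col] = (float(dist[1]), float(dist[2]))
    for name, model in scenario.treatment_models.items():
        if model.resid_sd is not None:
            # marginal scale of a continuous treatment: alpha +/- ~2 resid sd
            out[name] = (model.alpha, max(model.resid_sd, 1e-6))
    return out


def _draw_upstream(
    scenario: SyntheticScenario, n: int, rng: np.random.Generator
) -> pd.DataFrame:
    """Confounders, sequential treatments and external covariates."""
    cols: dict[str, np.ndarray] = {}
    for col, dist in scenario.confounder_dists.items():
        cols[col] = _draw_dist(rng, dist, n)
    scales = _standardizer(scenario)

    def std(name: str) -> np.ndarray:
        x = cols[name]
        if name in scales:
            mu, sd = scales[name]
            return (x - mu) / sd
        return x

    for block in scenario.design.blocks:
        for name, kind in block.treatments:
            model = scenario.treatment_models[name]
            lp = model.alpha + sum(
                c * std(pred) for pred, c in model.coefs.items()
            )
            lp = np.asarray(lp) if np.ndim(lp) else np.full(n, float(lp))
            if kind == BINARY:
                cols[name] = rng.binomial(1, expit(lp)).astype(float)
            else:
                cols[name] = lp + rng.normal(0, model.resid_sd, size=n)
    for col, dist in scenario.external_dists.items():
        cols[col] = _draw_dist(rng, dist, n)
    return pd.DataFrame(cols)


def generate(
    scenario: SyntheticScenario, n: int | None = None, seed: int = 0
) -> tuple[list[PatientRecord], dict]:
    """Draw a cohort and return (records, truth).

    Bit-reproducible for a given (scenario, n, seed)."""
    n = scenario.n_default if n is None else int(n)
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = np.random.default_rng(seed)
    df = _draw_upstream(scenario, n, rng)
    Dmat = df[scenario.predictor_names].to_numpy(dtype=float)
    logpi = _class_log_probs(scenario.beta, Dmat)
    pi = np.exp(logpi)
    k = scenario.measurement.k
    u = (rng.random(n)[:, None] > np.cumsum(pi, axis=1)[:, :-1]).sum(axis=1)
    u = u.astype(int)
    P = scenario.measurement.conditional_probs()      # (k, p)
    spec: OutcomeSpec = scenario.design.outcome_sets[scenario.outcome_set]
    items = spec.items
    Ymat = (rng.random((n, len(items))) < P[u, :]).astype(int) if n else np.zeros(
        (0, len(items)), dtype=int
    )
    for r, item in enumerate(items):
        df[item] = Ymat[:, r]
    df.insert(0, scenario.design.id_column, np.arange(1, n + 1))
    records = _records_from_frame(df, scenario.design)
    truth = {
        "scenario": scenario.name,
        "classes": u + 1,
        "class_probs": pi,
        "marginal_masses": pi.mean(axis=0) if n else np.full(k, np.nan),
        "beta": scenario.beta.copy(),
        "measurement": scenario.measurement.copy(),
        "conditional_probs": P,
        "predictor_names": scenario.predictor_names,
        "outcome_set": scenario.outcome_set,
        "seed": seed,
        "n": n,
    }
    return records, truth


# ---------------------------------------------------------------------------
# Measurement truth from a target conditional-probability table
# ---------------------------------------------------------------------------

def measurement_from_targets(
    target: np.ndarray, dim_index: np.ndarray, masses: np.ndarray
) -> LC2PLParameters:
    """Build 2PL truth whose conditional probabilities approximate a target
    (k, p) table.

    On the logit scale the 2PL model restricts each dimension's class-by-item
    table to rank one plus a column offset, L_ur = eta_r * (xi_u - delta_r).
    The projection is fitted on the probability scale: alternating weighted
    least squares on the logits with weights p(1-p) — a Pearson-chi-square
    metric on the probability scale, sum (p - phat)^2 / [p(1-p)] after
    linearization — so informative mid-range entries dominate while
    near-degenerate entries (printed as 0.00 or 1.00) stay near-degenerate.  Initialized from the
    leading singular vectors of the column-centered logit table; signs fixed
    so support points increase with the class index (class 1 = best
    outcomes)."""
    target = np.asarray(target, dtype=float)
    k, p = target.shape
    dim_index = np.asarray(dim_index, dtype=int)
    D = int(dim_index.max()) + 1
    Pt = np.clip(target, 1e-4, 1 - 1e-4)
    L = logit(Pt)
    Wt = Pt * (1.0 - Pt)
    xi = np.zeros((k, D))
    eta = np.ones(p)
    delta = np.zeros(p)
    for d in range(D):
        items = np.where(dim_index == d)[0]
        M = L[:, items]                       # (k, m)
        Wd = Wt[:, items]
        mu = M.mean(axis=0)
        if len(items) == 1 or k == 1:
            xi[:, d] = M[:, 0]
            eta[items], delta[items] = 1.0, 0.0
            continue
        U, s, Vt_ = np.linalg.svd(M - mu, full_matrices=False)
        x = U[:, 0] * s[0]
        v = Vt_[0].copy()
        if x[-1] < x[0]:                      # orient: worst class highest
            x, v = -x, -v
        v = np.where(np.abs(v) < 1e-3, np.sign(v + 1e-12) * 1e-3, v)
        c = mu                                # column intercepts, L ~ v*x + c
        for _ in range(200):
            # classes given item params
            num = (Wd * v[None, :] * (M - c[None, :])).sum(axis=1)
            den = np.maximum((Wd * v[None, :] ** 2).sum(axis=1), 1e-12)
            x = num / den
            # item params given classes: weighted simple regression per item
            sw = Wd.sum(axis=0)
            xm = (Wd * x[:, None]).sum(axis=0) / sw
            Lm = (Wd * M).sum(axis=0) / sw
            cov = (Wd * (x[:, None] - xm) * (M - Lm)).sum(axis=0)
            var = np.maximum((Wd * (x[:, None] - xm) ** 2).sum(axis=0), 1e-12)
            v_new = cov / var
            v_new = np.where(np.abs(v_new) < 1e-3,
                             np.sign(v_new + 1e-12) * 1e-3, v_new)
            c_new = Lm - v_new * xm
            if np.max(np.abs(v_new - v)) < 1e-10 and np.max(np.abs(c_new - c)) < 1e-10:
                v, c = v_new, c_new
                break
            v, c = v_new, c_new
        xi[:, d] = x
        eta[items] = v
        delta[items] = -c / v
    return LC2PLParameters(
        pi=np.asarray(masses, dtype=float), xi=xi, eta=eta, delta=delta,
        dim_index=dim_index,
    )


def calibrate_intercepts(
    scenario: SyntheticScenario,
    target_masses: np.ndarray,
    n_cal: int = CALIBRATION_N,
    cal_seed: int = CALIBRATION_SEED,
) -> np.ndarray:
    """Solve for adjacent-logit intercepts so the population-average class
    masses hit the target, given the scenario's treatment distribution.

    Uses a fixed internal calibration draw, so the result does not depend on
    user seeds."""
    target = np.asarray(target_masses, dtype=float)
    rng = np.random.default_rng(cal_seed)
    df = _draw_upstream(scenario, n_cal, rng)
    Dmat = df[scenario.predictor_names].to_numpy(dtype=float)
    beta = scenario.beta.copy()
    k = scenario.measurement.k

    def gap(b0):
        b = beta.copy()
        b[:, 0] = b0
        masses = np.exp(_class_log_probs(b, Dmat)).mean(axis=0)
        return masses[1:] - target[1:]

    b0_init = np.log(target[1:] / target[:-1])
    sol = root(gap, b0_init, method="hybr")
    if not sol.success:
        raise RuntimeError(f"intercept calibration failed: {sol.message}")
    out = beta.copy()
    out[:, 0] = sol.x
    return out


# ---------------------------------------------------------------------------
# Scenario library
# ---------------------------------------------------------------------------

def _perioperative_design(outcome_sets: dict[str, OutcomeSpec]) -> StudyDesign:
    return StudyDesign(
        blocks=(
            TreatmentBlock(1, (("preop_stay", CONTINUOUS), ("no_bowel_prep", BINARY))),
            TreatmentBlock(2, (("epidural", BINARY), ("no_drainage", BINARY))),
            TreatmentBlock(
                3, (("ambulation_pod1", BINARY), ("ivfluid_stop_pod2", BINARY))
            ),
        ),
        confounders_all=("age", "asa_gt2", "diabetes"),
        confounders_post=(("surgery_length", 3), ("laparotomy", 3)),
        external_covariates=("blood_transfusion",),
        outcome_sets=outcome_sets,
        continuous_columns=("age", "surgery_length"),
    )


_CONFOUNDER_DISTS = {
    "age": ("normal", 67.25, 11.78),
    "asa_gt2": ("bernoulli", 0.35),
    "diabetes": ("bernoulli", 0.129),
    "surgery_length": ("normal", 203.3, 75.6),
    "laparotomy": ("bernoulli", 0.199),
}
_EXTERNAL_DISTS = {"blood_transfusion": ("bernoulli", 0.092)}


def _assignment_models(strength: float = 1.0) -> dict[str, TreatmentTruth]:
    s = strength
    return {
        "preop_stay": TreatmentTruth(
            1.56, {"age": 0.4 * s, "asa_gt2": 0.8 * s, "diabetes": 0.4 * s},
            resid_sd=2.0,
        ),
        "no_bowel_prep": TreatmentTruth(
            1.9, {"age": -0.3 * s, "asa_gt2": -0.3 * s}
        ),
        "epidural": TreatmentTruth(
            -0.55, {"age": 0.3 * s, "asa_gt2": 0.2 * s, "no_bowel_prep": -0.2 * s}
        ),
        "no_drainage": TreatmentTruth(
            -0.75, {"asa_gt2": -0.3 * s, "diabetes": -0.2 * s}
        ),
        "ambulation_pod1": TreatmentTruth(
            1.55,
            {
                "age": -0.3 * s, "asa_gt2": -0.4 * s, "surgery_length": -0.4 * s,
                "laparotomy": -0.5 * s, "epidural": 0.2 * s,
            },
        ),
        "ivfluid_stop_pod2": TreatmentTruth(
            0.2,
            {"asa_gt2": -0.3 * s, "surgery_length": -0.3 * s, "laparotomy": -0.3 * s},
        ),
    }


_PRIMARY_ITEMS = {
    "complications": (
        "any_complication", "ssi", "medical_complication",
    ),
    "discharge": ("trd_pod5", "discharge_pod6"),
}
# class-conditional outcome probabilities emulating the published
# three-class profile (best / late-discharge / complicated patients)
_PRIMARY_TARGET = np.array(
    [
        [0.07, 0.01, 0.02, 0.005, 0.005],
        [0.08, 0.01, 0.02, 0.94, 0.65],
        [0.82, 0.35, 0.28, 0.95, 0.87],
    ]
)
_PRIMARY_MASSES = np.array([0.47, 0.35, 0.18])

_SECONDARY_ITEMS = {
    "gastrointestinal": (
        "bowel_recovery_pod1", "iv_resumption", "ngt_replacement", "ponv",
    ),
    "severe": ("reintervention", "readmission", "death_pod30"),
}
_SECONDARY_TARGET = np.array(
    [
        [0.51, 0.03, 0.004, 0.08, 0.01, 0.004, 0.004],
        [0.56, 0.57, 0.34, 0.41, 0.16, 0.07, 0.012],
    ]
)
_SECONDARY_MASSES = np.array([0.78, 0.22])

# adjacent-logit treatment/covariate effects; predictor order is
# treatments (block order) then external covariates
_PRIMARY_BETA1 = np.array(
    [
        # preop  no_bowel  epidural no_drain ambulate iv_stop  transfusion
        [0.05, -0.85, -0.39, -0.35, -0.76, -0.75, 1.16],
        [0.05, -0.48, -0.90, -0.67, -1.51, -0.81, 1.90],
    ]
)
_SECONDARY_BETA1 = np.array(
    [[0.00, -0.77, -0.47, -0.48, -1.48, -1.45, 0.87]]
)


def _build_scenario(
    name: str,
    outcome_sets: dict[str, OutcomeSpec],
    outcome_set: str,
    target: np.ndarray,
    masses: np.ndarray,
    beta1: np.ndarray,
    strength: float = 1.0,
    calibrate: bool = True,
    n_default: int = 2000,
) -> SyntheticScenario:
    design = _perioperative_design(outcome_sets)
    spec = design.outcome_sets[outcome_set]
    measurement = measurement_from_targets(target, spec.dimension_index(), masses)
    beta = np.column_stack([np.log(masses[1:] / masses[:-1]), beta1])
    scenario = SyntheticScenario(
        name=name,
        design=design,
        confounder_dists=dict(_CONFOUNDER_DISTS),
        external_dists=dict(_EXTERNAL_DISTS),
        treatment_models=_assignment_models(strength),
        measurement=measurement,
        beta=beta,
        outcome_set=outcome_set,
        n_default=n_default,
        target_masses=np.asarray(masses, dtype=float),
    )
    if calibrate and np.any(beta1):
        scenario.beta = calibrate_intercepts(scenario, masses)
    return scenario


def _atet_recovery_scenario() -> SyntheticScenario:
    outcome_sets = {
        "primary": OutcomeSpec(
            dimensions=(
                ("outcomes", ("y1", "y2", "y3", "y4", "y5")),
            )
        )
    }
    design = StudyDesign(
        blocks=(TreatmentBlock(1, (("treatment", BINARY),)),),
        confounders_all=("risk_factor",),
        confounders_post=(),
        external_covariates=(),
        outcome_sets=outcome_sets,
    )
    target = np.array(
        [
            [0.10, 0.15, 0.20, 0.10, 0.25],
            [0.70, 0.80, 0.75, 0.85, 0.60],
        ]
    )
    measurement = measurement_from_targets(
        target, np.zeros(5, dtype=int), np.array([0.6, 0.4])
    )
    beta = np.array([[0.9, -0.8]])     # effect -0.8 on the 1<->2 logit
    return SyntheticScenario(
        name="atet-recovery",
        design=design,
        confounder_dists={"risk_factor": ("bernoulli", 0.5)},
        external_dists={},
        treatment_models={
            "treatment": TreatmentTruth(0.0, {"risk_factor": 0.4})
        },
        measurement=measurement,
        beta=beta,
        outcome_set="primary",
        n_default=3000,
    )


def default_scenarios() -> dict[str, SyntheticScenario]:
    """Named scenario library.

    - ``primary-like``: 3 blocks, 5 binary + 1 continuous treatment,
      5 outcomes in 2 dimensions, k=3 with masses (0.47, 0.35, 0.18).
    - ``secondary-like``: 7 outcomes in 2 dimensions, k=2 with masses
      (0.78, 0.22), including a near-degenerate death item (~0.6%).
    - ``null``: primary-like structure with all treatment effects zero.
    - ``strong-confounding``: primary-like with doubled confounder effects
      on treatment assignment (assignment probabilities still bounded away
      from 0 and 1, respecting positivity), for balance diagnostics.
    - ``atet-recovery``: single binary treatment with adjacent-logit effect
      -0.8, for structural recovery and coverage checks.
    """
    primary_sets = {
        "primary": OutcomeSpec(
            dimensions=tuple((d, items) for d, items in _PRIMARY_ITEMS.items())
        )
    }
    secondary_sets = {
        "secondary": OutcomeSpec(
            dimensions=tuple((d, items) for d, items in _SECONDARY_ITEMS.items())
        )
    }
    scenarios = {
        "primary-like": _build_scenario(
            "primary-like", primary_sets, "primary",
            _PRIMARY_TARGET, _PRIMARY_MASSES, _PRIMARY_BETA1,
        ),
        "secondary-like": _build_scenario(
            "secondary-like", secondary_sets, "secondary",
            _SECONDARY_TARGET, _SECONDARY_MASSES, _SECONDARY_BETA1,
        ),
        "null": _build_scenario(
            "null", primary_sets, "primary",
            _PRIMARY_TARGET, _PRIMARY_MASSES, np.zeros_like(_PRIMARY_BETA1),
            calibrate=False,
        ),
        "strong-confounding": _build_scenario(
            "strong-confounding", primary_sets, "primary",
            _PRIMARY_TARGET, _PRIMARY_MASSES, _PRIMARY_BETA1, strength=2.0,
        ),
        "atet-recovery": _atet_recovery_scenario(),
    }
    return scenarios


# ---------------------------------------------------------------------------
# Scenario files
# ---------------------------------------------------------------------------

def scenario_from_yaml(path) -> SyntheticScenario:
    """Load a scenario from a YAML file.

    Expected keys: name, design (same schema as the study design config),
    confounder_dists / external_dists (col -> [kind, params...]),
    treatment_models (name -> {alpha, coefs, resid_sd}), outcome_set,
    masses, and either target_probs (k x p) or explicit xi/eta/delta."""
    from .study_data import load_design

    with open(path) as fh:
        raw = yaml.safe_load(fh)
    design = load_design(path) if "blocks" in raw else None
    if design is None:
        raise ValueError("scenario file must embed the design (blocks, ...)")
    spec = design.outcome_sets[raw["outcome_set"]]
    masses = np.asarray(raw["masses"], dtype=float)
    if "target_probs" in raw:
        measurement = measurement_from_targets(
            np.asarray(raw["target_probs"], dtype=float),
            spec.dimension_index(), masses,
        )
    else:
        measurement = LC2PLParameters(
            pi=masses,
            xi=np.asarray(raw["xi"], dtype=float),
            eta=np.asarray(raw["eta"], dtype=float),
            delta=np.asarray(raw["delta"], dtype=float),
            dim_index=spec.dimension_index(),
        )
    beta = np.asarray(raw["beta"], dtype=float)
    models = {
        name: TreatmentTruth(
            alpha=float(m["alpha"]),
            coefs={k: float(v) for k, v in m.get("coefs", {}).items()},
            resid_sd=m.get("resid_sd"),
        )
        for name, m in raw["treatment_models"].items()
    }
    return SyntheticScenario(
        name=raw.get("name", "custom"),
        design=design,
        confounder_dists={
            c: tuple(v) for c, v in raw.get("confounder_dists", {}).items()
        },
        external_dists={
            c: tuple(v) for c, v in raw.get("external_dists", {}).items()
        },
        treatment_models=models,
        measurement=measurement,
        beta=beta,
        outcome_set=raw["outcome_set"],
        n_default=int(raw.get("n_default", 2000)),
    )
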