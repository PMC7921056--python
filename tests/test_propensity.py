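import numpy as np
import pytest
from scipy.special import expit

from causallc import (
    assignment_probability,
    balance_diagnostics,
    compute_weights,
    fit_block_models,
    generate,
    trim_weights,
)
from causallc.propensity import TreatmentModelFit, WeightVector
from causallc.study_data import _records_from_frame
import pandas as pd


def _records(df, design):
    return _records_from_frame(df, design)


def test_intercept_only_logistic_is_bernoulli_mle():
    from causallc.study_data import (
        BINARY, OutcomeSpec, StudyDesign, TreatmentBlock,
    )

    design = StudyDesign(
        blocks=(TreatmentBlock(1, (("treat", BINARY),)),),
        confounders_all=(),
        confounders_post=(),
        external_covariates=(),
        outcome_sets={"primary": OutcomeSpec(dimensions=(("all", ("out1",)),))},
    )
    df = pd.DataFrame(
        {"id": range(4), "treat": [1, 1, 1, 0], "out1": [0] * 4}
    )
    recs = _records(df, design)
    fits = fit_block_models(recs, design)
    # MLE of the Bernoulli mean: P(Z=1)=0.75, so the received-arm
    # probability is 0.75 for the treated and 0.25 for the untreated
    ps = [assignment_probability(fits[0], r) for r in recs]
    assert ps[:3] == pytest.approx([0.75] * 3, abs=1e-6)
    assert ps[3] == pytest.approx(0.25, abs=1e-6)


def test_collinear_predictors_named():
    from causallc.propensity import SingularDesignError
    from causallc.study_data import (
        BINARY, OutcomeSpec, StudyDesign, TreatmentBlock,
    )

    design = StudyDesign(
        blocks=(TreatmentBlock(1, (("treat", BINARY),)),),
        confounders_all=("x1", "x2"),
        confounders_post=(),
        external_covariates=(),
        outcome_sets={"primary": OutcomeSpec(dimensions=(("all", ("out1",)),))},
        continuous_columns=("x1", "x2"),
    )
    rng = np.random.default_rng(0)
    x = rng.normal(size=30)
    df = pd.DataFrame(
        {"id": range(30), "x1": x, "x2": 2 * x,  # exactly collinear
         "treat": rng.integers(0, 2, 30), "out1": 0}
    )
    with pytest.raises(SingularDesignError, match="collinear"):
        fit_block_models(_records(df, design), design)


def test_perfect_separation_names_treatment(toy_design):
    from causallc.propensity import SeparationError

    df = pd.DataFrame(
        {"id": range(20), "risk": [0.0] * 10 + [1.0] * 10,
         "treat": [0] * 10 + [1] * 10, "out1": 0, "out2": 0}
    )
    with pytest.raises(SeparationError, match="treat"):
        fit_block_models(_records(df, toy_design), toy_design)


def test_fitted_probability_of_received_treatment():
    fit = TreatmentModelFit(
        treatment="t", block=1, kind="binary", predictors=["x"],
        intercept=0.0, coef=np.array([0.0]),
    )

    class R:
        def value(self, c):
            return {"x": 3.0, "t": self._t}[c]

    treated, untreated = R(), R()
    treated._t, untreated._t = 1.0, 0.0
    assert assignment_probability(fit, treated) == pytest.approx(0.5)
    assert assignment_probability(fit, untreated) == pytest.approx(0.5)


def test_probability_floor_applied():
    fit = TreatmentModelFit(
        treatment="t", block=1, kind="binary", predictors=["x"],
        intercept=-40.0, coef=np.array([0.0]),
    )

    class R:
        def value(self, c):
            return {"x": 0.0, "t": 1.0}[c]

    assert assignment_probability(fit, R()) == pytest.approx(1e-6)


def test_continuous_density_ratio_is_one_when_marginal_equals_conditional():
    fit = TreatmentModelFit(
        treatment="t", block=1, kind="continuous", predictors=["x"],
        intercept=2.0, coef=np.array([0.0]), scale=1.5, marginal=(2.0, 1.5),
    )

    class R:
        def value(self, c):
            return {"x": 7.0, "t": 3.3}[c]

    assert assignment_probability(fit, R()) == pytest.approx(1.0)


def test_parameter_recovery_logistic_assignment():
    """Estimates land within 2 SEs of truth in most seeded replicates."""
    rng = np.random.default_rng(42)
    alpha, gamma = -0.4, 0.8
    hits = 0
    reps = 40
    import statsmodels.api as sm

    checks = 0
    for _ in range(reps):
        x = rng.normal(size=5000)
        z = rng.binomial(1, expit(alpha + gamma * x))
        res = sm.Logit(z, sm.add_constant(x)).fit(disp=0)
        for truth_j, est, se in zip(
            (alpha, gamma), res.params, res.bse
        ):
            checks += 1
            hits += abs(est - truth_j) <= 2 * se
    assert hits / checks >= 0.90


def test_block2_predictors_include_all_block1_treatments(scenarios):
    design = scenarios["primary-like"].design
    preds = design.predictors_for_block(2)
    for t in design.blocks[0].names:
        assert t in preds
    # post confounders enter only at block 3
    assert "surgery_length" not in preds
    assert "surgery_length" in design.predictors_for_block(3)


def _weight_vector(raw):
    raw = np.asarray(raw, dtype=float)
    n = len(raw)
    return WeightVector(
        ids=list(range(n)),
        prob=pd.DataFrame({"t": np.ones(n)}),
        block_inverse=pd.DataFrame({1: raw}),
        raw=raw, trimmed=raw.copy(), trim_bounds=(raw.min(), raw.max()),
    )


def test_weight_formula_sum_of_block_inverse_products(scenarios):
    sc = scenarios["primary-like"]
    recs, _ = generate(sc, n=300, seed=3)
    fits = fit_block_models(recs, sc.design)
    w = compute_weights(fits, recs, sc.design, mode="sum")
    # the raw weight is exactly the sum of the per-block inverse products
    np.testing.assert_allclose(
        w.raw, w.block_inverse.sum(axis=1).to_numpy(), rtol=1e-12
    )
    wp = compute_weights(fits, recs, sc.design, mode="product")
    np.testing.assert_allclose(
        wp.raw, w.block_inverse.prod(axis=1).to_numpy(), rtol=1e-12
    )
    # with all p_ij <= 1 the sum-mode weight is at least the number of blocks
    assert (w.raw >= len(sc.design.blocks) - 1e-9).all()


def test_trimming_winsorizes_and_is_idempotent():
    w = _weight_vector(np.arange(1.0, 101.0))
    t = trim_weights(w, 0.0, 0.95)
    q95 = np.quantile(w.raw, 0.95)
    assert t.trimmed.max() == pytest.approx(q95)
    assert (t.trimmed[w.raw <= q95] == w.raw[w.raw <= q95]).all()
    t2 = trim_weights(t, 0.0, 0.95)
    np.testing.assert_allclose(t2.trimmed, t.trimmed)

    same = _weight_vector(np.full(50, 3.3))
    np.testing.assert_allclose(trim_weights(same).trimmed, same.raw)


def test_trimming_reduces_variance_heavy_tail():
    rng = np.random.default_rng(11)
    w = _weight_vector(np.exp(rng.normal(0, 1.5, size=1000)))
    t = trim_weights(w, 0.01, 0.99)
    assert t.trimmed.var() < w.raw.var()


def test_normalized_weights_have_mean_one():
    w = _weight_vector(np.exp(np.random.default_rng(0).normal(size=200)))
    t = trim_weights(w)
    assert t.normalized.mean() == pytest.approx(1.0)


def test_pseudo_population_size_invariant_to_patient_order(scenarios):
    sc = scenarios["primary-like"]
    recs, _ = generate(sc, n=300, seed=5)
    fits = fit_block_models(recs, sc.design)
    w1 = compute_weights(fits, recs, sc.design)
    rng = np.random.default_rng(1)
    perm = rng.permutation(len(recs))
    w2 = compute_weights(fits, [recs[i] for i in perm], sc.design)
    assert w1.raw.sum() == pytest.approx(w2.raw.sum())


def test_smd_closed_forms(toy_design):
    df = pd.DataFrame(
        {
            "id": range(8),
            "risk": [1.0, 1, 1, 1, 0, 0, 0, 0],
            "treat": [1, 1, 1, 1, 0, 0, 0, 0],
            "out1": [0] * 8,
            "out2": [0] * 8,
        }
    )
    recs = _records(df, toy_design)
    bal = balance_diagnostics(recs, None, toy_design)
    # means 1 vs 0; pooled SD 0 within arms -> warning path gives SMD 0
    assert bal.loc[0, "smd_unweighted"] == 0.0

    df["risk"] = [2.0, 1, 2, 1, 1, 0, 1, 0]  # means 1.5 vs 0.5, pooled sd ~0.577
    recs = _records(df, toy_design)
    bal = balance_diagnostics(recs, None, toy_design)
    pooled = np.sqrt((np.var([2, 1, 2, 1], ddof=1) + np.var([1, 0, 1, 0], ddof=1)) / 2)
    assert bal.loc[0, "smd_unweighted"] == pytest.approx(1.0 / pooled)

    # identical arms -> SMD 0
    df["risk"] = [0, 1, 0, 1, 0, 1, 0, 1]
    recs = _records(df, toy_design)
    bal = balance_diagnostics(recs, None, toy_design)
    assert bal.loc[0, "smd_unweighted"] == pytest.approx(0.0)
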