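import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from causallc import (
    compute_bic,
    count_parameters,
    em_fit,
    generate,
    item_probability,
    select_k,
    standard_errors,
    weighted_loglik,
)
from causallc.lc2pl import (
    LC2PLParameters,
    classify_posterior,
    measurement_table,
)
from conftest import brute_force_loglik


def _params(pi, xi, eta, delta, dim_index):
    return LC2PLParameters(
        pi=np.asarray(pi, float), xi=np.asarray(xi, float),
        eta=np.asarray(eta, float), delta=np.asarray(delta, float),
        dim_index=np.asarray(dim_index, int),
    )


# ---------------------------------------------------------------------------
# closed forms
# ---------------------------------------------------------------------------

def test_item_probability_closed_forms():
    assert item_probability(1.0, 0.3, 0.3) == pytest.approx(0.5)
    assert item_probability(0.0, 5.0, -2.0) == pytest.approx(0.5)
    assert item_probability(2.0, 0.0, 1.0) == pytest.approx(0.8807971, abs=1e-7)
    # overflow-safe at extreme linear predictors
    assert item_probability(30.0, -40.0, 40.0) == pytest.approx(1.0)
    assert item_probability(30.0, 40.0, -40.0) == pytest.approx(0.0)


def test_bic_formula():
    assert compute_bic(-500.0, 1261, 20) == pytest.approx(
        1000.0 + 20 * np.log(1261)
    )
    assert compute_bic(-500.0, 1261, 20) == pytest.approx(1142.794, abs=5e-3)
    assert compute_bic(-7.0, 100, 0) == pytest.approx(14.0)
    assert compute_bic(-7.0, 1, 12) == pytest.approx(14.0)


def test_parameter_count():
    assert count_parameters(3, 5, 2) == 14
    assert count_parameters(1, 6, 2) == 2 * 6 - 2
    assert count_parameters(2, 2, 2) == 5


def test_weighted_loglik_single_class_single_item():
    params = _params([1.0], [[0.0]], [1.0], [0.0], [0])  # p = 0.5
    Y = np.array([[0], [1], [0], [1]])
    w = np.ones(4)
    assert weighted_loglik(params, Y, w) == pytest.approx(4 * np.log(0.5))
    # linear in the weights
    assert weighted_loglik(params, Y, 2 * w) == pytest.approx(
        2 * weighted_loglik(params, Y, w)
    )


def test_weighted_loglik_matches_brute_force_random_instances():
    rng = np.random.default_rng(7)
    for _ in range(30):
        n, p, k = 6, 3, 2
        Y = rng.integers(0, 2, size=(n, p))
        w = rng.uniform(0.5, 2.0, size=n)
        dim_index = np.array([0, 0, 1])
        params = _params(
            rng.dirichlet([1.5, 1.5]),
            rng.normal(0, 2, size=(k, 2)),
            rng.uniform(0.3, 3, size=p),
            rng.normal(0, 1, size=p),
            dim_index,
        )
        expected = brute_force_loglik(
            params.pi, params.conditional_probs(), Y, w
        )
        assert weighted_loglik(params, Y, w) == pytest.approx(
            expected, abs=1e-10
        )


# ---------------------------------------------------------------------------
# EM
# ---------------------------------------------------------------------------

def test_k1_em_matches_weighted_item_means():
    rng = np.random.default_rng(3)
    Y = rng.integers(0, 2, size=(50, 4))
    w = rng.uniform(0.2, 3.0, size=50)
    fit = em_fit(Y, w, k=1, dim_index=np.array([0, 0, 1, 1]), seed=0, n_starts=3)
    pbar = (w[:, None] * Y).sum(axis=0) / w.sum()
    np.testing.assert_allclose(
        fit.params.conditional_probs()[0], pbar, atol=1e-6
    )
    # saturated-independence log-likelihood
    ll = np.sum(
        w[:, None] * (Y * np.log(pbar) + (1 - Y) * np.log(1 - pbar))
    )
    assert fit.loglik == pytest.approx(ll, abs=1e-6)


def test_em_monotone_loglik_history(scenarios):
    sc = scenarios["primary-like"]
    recs, _ = generate(sc, n=400, seed=9)
    from causallc import outcome_matrix

    Y, dim = outcome_matrix(recs, "primary", sc.design)
    fit = em_fit(Y, None, 3, dim, seed=1, n_starts=5)
    h = fit.loglik_history
    assert np.all(np.diff(h) >= -1e-8 * (1 + np.abs(h[:-1])))


def test_em_beats_grid_oracle_tiny_instance():
    """EM attains the dense-grid oracle maximum on an unconstrained tiny
    model (every item its own dimension, so conditional probabilities are
    free)."""
    rng = np.random.default_rng(21)
    Y = rng.integers(0, 2, size=(8, 3))
    w = np.ones(8)
    dim_index = np.array([0, 1, 2])
    fit = em_fit(Y, w, k=2, dim_index=dim_index, seed=4, n_starts=10)

    grid_p = np.linspace(0.05, 0.95, 7)
    grid_pi = np.linspace(0.1, 0.9, 9)
    patterns, counts = np.unique(Y, axis=0, return_counts=True)
    P1 = np.stack(np.meshgrid(grid_p, grid_p, grid_p, indexing="ij"), -1)
    P1 = P1.reshape(-1, 3)                       # all class prob triples
    # (grid, pattern) class-conditional pattern likelihoods
    lik = np.prod(
        np.where(patterns[None, :, :] == 1, P1[:, None, :], 1 - P1[:, None, :]),
        axis=2,
    )
    best = -np.inf
    for pi1 in grid_pi:
        mix = pi1 * lik[:, None, :] + (1 - pi1) * lik[None, :, :]
        ll = (counts[None, None, :] * np.log(mix)).sum(axis=2)
        best = max(best, float(ll.max()))
    assert fit.loglik >= best - 1e-4


def test_em_permutation_invariance(scenarios):
    sc = scenarios["primary-like"]
    recs, _ = generate(sc, n=300, seed=2)
    from causallc import outcome_matrix

    Y, dim = outcome_matrix(recs, "primary", sc.design)
    fit1 = em_fit(Y, None, 2, dim, seed=0, n_starts=5)
    perm = np.random.default_rng(0).permutation(len(Y))
    fit2 = em_fit(Y[perm], None, 2, dim, seed=0, n_starts=5)
    assert fit1.loglik == pytest.approx(fit2.loglik, abs=1e-6)
    np.testing.assert_allclose(fit1.params.pi, fit2.params.pi, atol=1e-6)
    np.testing.assert_allclose(fit1.posterior[perm], fit2.posterior, atol=1e-6)


def test_weight_scale_invariance(scenarios):
    sc = scenarios["primary-like"]
    recs, _ = generate(sc, n=200, seed=4)
    from causallc import outcome_matrix

    Y, dim = outcome_matrix(recs, "primary", sc.design)
    w = np.random.default_rng(1).uniform(0.5, 2, size=len(Y))
    f1 = em_fit(Y, w, 2, dim, seed=0, n_starts=5)
    f2 = em_fit(Y, 3.0 * w, 2, dim, seed=0, n_starts=5)
    # likelihood scales linearly; the maximizer is unchanged up to the
    # optimizer's floating-point path
    assert f2.loglik == pytest.approx(3 * f1.loglik, rel=1e-6)
    np.testing.assert_allclose(f1.params.pi, f2.params.pi, atol=5e-3)
    assert (f1.map_classes == f2.map_classes).mean() >= 0.99


def test_posterior_rows_and_masses_sum_to_one(scenarios):
    sc = scenarios["secondary-like"]
    recs, _ = generate(sc, n=500, seed=6)
    from causallc import outcome_matrix

    Y, dim = outcome_matrix(recs, "secondary", sc.design)
    fit = em_fit(Y, None, 2, dim, seed=0, n_starts=5)
    np.testing.assert_allclose(fit.posterior.sum(axis=1), 1.0, atol=1e-10)
    assert fit.params.pi.sum() == pytest.approx(1.0, abs=1e-10)
    assert fit.bic == pytest.approx(
        -2 * fit.loglik + np.log(len(Y)) * fit.n_par
    )


def test_classes_ordered_by_outcome_probability(scenarios):
    sc = scenarios["primary-like"]
    recs, _ = generate(sc, n=800, seed=8)
    from causallc import outcome_matrix

    Y, dim = outcome_matrix(recs, "primary", sc.design)
    fit = em_fit(Y, None, 3, dim, seed=0, n_starts=5)
    means = fit.params.conditional_probs().mean(axis=1)
    assert np.all(np.diff(means) >= 0)


def test_classify_map_and_tie_break():
    assert classify_posterior(np.array([[0.9, 0.1]]))[0] == 1
    assert classify_posterior(np.array([[0.5, 0.5]]))[0] == 1
    assert classify_posterior(np.array([[0.2, 0.3, 0.5]]))[0] == 3


def test_map_recovery_well_separated():
    """On well-separated classes MAP recovers nearly all memberships."""
    rng = np.random.default_rng(12)
    n, k = 1000, 2
    truth = rng.integers(0, 2, size=n)
    P = np.array([[0.05, 0.05, 0.05, 0.05], [0.95, 0.95, 0.95, 0.95]])
    Y = (rng.random((n, 4)) < P[truth]).astype(int)
    fit = em_fit(Y, None, 2, np.zeros(4, int), seed=0, n_starts=5)
    agree = (fit.map_classes - 1 == truth).mean()
    assert agree >= 0.98


# ---------------------------------------------------------------------------
# selection and SEs
# ---------------------------------------------------------------------------

def test_select_k_first_bic_increase_rule(monkeypatch):
    import causallc.lc2pl as mod

    bics = iter([100.0, 90.0, 95.0, 80.0])

    class Dummy:
        def __init__(self, k, bic):
            self.bic = bic
            self.loglik = -bic
            self.n_par = 0

            class P:
                pass

            self.params = P()
            self.params.k = k

    def fake_em(Y, w, k, dim_index, **kw):
        return Dummy(k, next(bics))

    monkeypatch.setattr(mod, "em_fit", fake_em)
    best, table = mod.select_k(np.zeros((4, 2)), None, [1, 2, 3, 4], np.zeros(2, int))
    assert best.params.k == 2
    assert list(table["k"]) == [1, 2, 3]
    assert table.loc[table["selected"], "k"].item() == 2


def test_select_k_single_k():
    Y = np.random.default_rng(0).integers(0, 2, size=(30, 2))
    best, table = select_k(Y, None, [1], np.array([0, 1]), seed=0, n_starts=2)
    assert best.params.k == 1
    assert len(table) == 1


def test_select_k_warns_when_bic_keeps_decreasing(monkeypatch):
    import causallc.lc2pl as mod

    bics = iter([100.0, 90.0, 80.0])

    class Dummy:
        def __init__(self, k, bic):
            self.bic = bic
            self.loglik = -bic
            self.n_par = 0

            class P:
                pass

            self.params = P()
            self.params.k = k

    monkeypatch.setattr(mod, "em_fit", lambda *a, **k: Dummy(a[2], next(bics)))
    with pytest.warns(UserWarning, match="extend"):
        best, _ = mod.select_k(np.zeros((4, 2)), None, [1, 2, 3], np.zeros(2, int))
    assert best.params.k == 3


def test_standard_errors_bernoulli_closed_form():
    """k=1, one item: delta-method SE of the mean is sqrt(p(1-p)/n)."""
    Y = np.array([[1]] * 50 + [[0]] * 50)
    fit = em_fit(Y, None, 1, np.array([0]), seed=0, n_starts=2)
    tab = standard_errors(fit, Y, None).set_index("parameter")
    assert tab.loc["P(Y1=1|U=1)", "estimate"] == pytest.approx(0.5, abs=1e-6)
    assert tab.loc["P(Y1=1|U=1)", "se"] == pytest.approx(0.05, rel=1e-3)


def test_standard_errors_shrink_with_n(scenarios):
    sc = scenarios["secondary-like"]
    ses = {}
    for n in (500, 2000):
        recs, _ = generate(sc, n=n, seed=13)
        from causallc import outcome_matrix

        Y, dim = outcome_matrix(recs, "secondary", sc.design)
        fit = em_fit(Y, None, 2, dim, seed=0, n_starts=5)
        tab = standard_errors(fit, Y, None)
        ses[n] = tab.loc[tab.parameter == "log_mass_ratio_2", "se"].item()
    ratio = ses[500] / ses[2000]
    assert 1.4 <= ratio <= 2.9  # ~sqrt(4) = 2 up to noise


def test_fd_hessian_symmetric():
    from causallc.lc2pl import finite_difference_hessian

    H = finite_difference_hessian(
        lambda x: float(x[0] ** 2 * x[1] + np.sin(x[1])), np.array([1.2, 0.7])
    )
    np.testing.assert_allclose(H, H.T)
    assert H[0, 1] == pytest.approx(2 * 1.2, rel=1e-4)


def test_measurement_table_shape(scenarios):
    sc = scenarios["secondary-like"]
    recs, _ = generate(sc, n=300, seed=1)
    from causallc import outcome_matrix

    Y, dim = outcome_matrix(recs, "secondary", sc.design)
    fit = em_fit(Y, None, 2, dim, seed=0, n_starts=3)
    items = sc.design.outcome_sets["secondary"].items
    tab = measurement_table(fit, items)
    assert list(tab["row"]) == ["class_mass", *items]
    assert tab.loc[0, ["class_1", "class_2"]].sum() == pytest.approx(1.0)


@settings(max_examples=25, deadline=None)
@given(
    eta=st.floats(-5, 5),
    delta=st.floats(-5, 5),
    xi=st.floats(-5, 5),
)
def test_item_probability_in_unit_interval(eta, delta, xi):
    p = item_probability(eta, delta, xi)
    assert 0.0 <= p <= 1.0
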