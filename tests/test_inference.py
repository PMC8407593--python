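"""Full-model behavior: standardization, activations, averaging, estimator API."""

import numpy as np
import pytest

import bann
from conftest import toy_mask
from bann.inference import (
    BANN,
    HiddenLayerPrior,
    InputLayerPrior,
    average_over_grid,
    compute_hidden_activations,
    compute_pips,
    estimate_pve,
    fit_inner,
    fit_outer,
    leaky_relu,
    log_spaced_grid,
    standardize,
)


class TestStandardize:
    def test_closed_form_zscores(self):
        Xs, _, _ = standardize(np.array([[0.0], [1.0], [2.0]]))
        np.testing.assert_allclose(Xs.ravel(), [-1.2247448, 0, 1.2247448], atol=1e-6)

    def test_idempotent(self, rng):
        X = rng.binomial(2, 0.3, (100, 5)).astype(float)
        y = rng.standard_normal(100)
        Xs, ys, _ = standardize(X, y)
        Xs2, ys2, _ = standardize(Xs, ys)
        np.testing.assert_allclose(Xs, Xs2, atol=1e-12)
        np.testing.assert_allclose(ys, ys2, atol=1e-12)

    def test_covariates_residualized_before_scaling(self, rng):
        X = rng.binomial(2, 0.4, (200, 3)).astype(float)
        q = rng.standard_normal(200)
        y = 2 * q + rng.standard_normal(200)
        _, ys, _ = standardize(X, y, covariates=q[:, None])
        assert abs(np.corrcoef(ys, q)[0, 1]) < 1e-10

    def test_phenotype_as_its_own_covariate_is_degenerate(self, rng):
        X = rng.binomial(2, 0.4, (50, 3)).astype(float)
        y = rng.standard_normal(50)
        with pytest.raises(ValueError, match="zero variance"):
            standardize(X, y, covariates=y[:, None])

    def test_monomorphic_column_listed_by_id(self):
        X = np.column_stack([np.ones(10), np.arange(10.0)])
        with pytest.raises(ValueError, match="rs0"):
            standardize(X, snp_ids=["rs0", "rs1"])


class TestLeakyRelu:
    @pytest.mark.parametrize(
        "x,expect", [(2.0, 2.0), (-1.0, -0.01), (0.0, 0.0), (1e-9, 1e-9)]
    )
    def test_branches(self, x, expect):
        assert leaky_relu(np.array([x]))[0] == pytest.approx(expect, abs=1e-18)

    def test_slope_is_one_percent_on_negative_branch(self, rng):
        x = -np.abs(rng.standard_normal(100)) - 0.1
        np.testing.assert_allclose(leaky_relu(x) / x, 0.01)


class TestHiddenActivations:
    def test_zero_weights_flag_every_column(self, rng):
        X = rng.standard_normal((50, 6))
        mask = toy_mask(6, [[0, 1, 2], [3, 4, 5]])
        H, b1, flags = compute_hidden_activations(X, mask, np.zeros(6))
        assert flags.all() and np.all(H == 0)

    def test_linear_single_set_recovers_projection(self, rng):
        X = rng.standard_normal((50, 4))
        X -= X.mean(axis=0)
        m = rng.standard_normal(4)
        mask = toy_mask(4, [[0, 1, 2, 3]])
        H, b1, flags = compute_hidden_activations(X, mask, m, linear=True)
        z = X @ m
        np.testing.assert_allclose(H.ravel(), (z - z.mean()) / z.std(), atol=1e-12)
        assert not flags.any()

    def test_negative_branch_of_preactivation(self):
        X = np.array([[1.0], [-1.0]])
        mask = toy_mask(1, [[0]])
        # bypass centering effects: pre-activation is (1, -1) once b1 = 0
        H, b1, _ = compute_hidden_activations(X, mask, np.array([1.0]))
        raw = leaky_relu(np.array([1.0, -1.0]))
        np.testing.assert_allclose(H.ravel(), (raw - raw.mean()) / raw.std(), atol=1e-12)

    def test_low_inclusion_sets_are_gated_out(self, rng):
        X = rng.standard_normal((50, 6))
        mask = toy_mask(6, [[0, 1, 2], [3, 4, 5]])
        m = rng.standard_normal(6) * 0.1
        pip = np.array([0.9, 0.2, 0.0, 1e-3, 1e-3, 1e-3])
        _, _, flags = compute_hidden_activations(X, mask, m, pip_snp=pip)
        assert not flags[0]  # P(any nonzero) = 1-(0.1*0.8) > 0.5
        assert flags[1]  # essentially no posterior mass


class TestGridAveraging:
    def test_single_point_gets_unit_weight(self, rng):
        A = rng.standard_normal((30, 3))
        y = rng.standard_normal(30)
        st = fit_inner(A, y, InputLayerPrior(), 0.1, max_sweeps=5)
        w, alpha, m = average_over_grid([st])
        assert w.tolist() == [1.0]

    def test_softmax_arithmetic(self):
        class Stub:
            def __init__(self, e):
                self.elbo_trace = [e]
                self.alpha = np.array([[1.0]])
                self.m = np.array([1.0])

        w, _, _ = average_over_grid([Stub(-5.0), Stub(-5.0)])
        np.testing.assert_allclose(w, [0.5, 0.5])
        w, _, _ = average_over_grid([Stub(-2.0), Stub(-2.0 - np.log(3))])
        np.testing.assert_allclose(w, [0.75, 0.25])

    def test_all_minus_inf_rejected(self):
        class Stub:
            elbo_trace = [-np.inf]
            alpha = np.array([[0.0]])
            m = np.array([0.0])

        with pytest.raises(ValueError):
            average_over_grid([Stub(), Stub()])

    def test_grid_is_log_spaced_within_bounds(self):
        g = log_spaced_grid(1 / 500, 20)
        assert g[0] == pytest.approx(1 / 500) and g[-1] == pytest.approx(1.0)
        np.testing.assert_allclose(np.diff(np.log(g)), np.diff(np.log(g))[0])


class TestPips:
    def test_sum_rule_and_bounds(self):
        alpha_in = np.array([[0.2, 0.15, 0.05], [0.0, 0.0, 0.0]])
        alpha_out = np.array([[0.7]])
        pip_snp, pip_set = compute_pips(alpha_in, alpha_out)
        np.testing.assert_allclose(pip_snp, [0.4, 0.0])
        np.testing.assert_allclose(pip_set, [0.7])

    def test_grid_weighted_average(self):
        p = 0.5 * np.array([[0.2]]) + 0.5 * np.array([[0.6]])
        pip_snp, _ = compute_pips(p, np.array([[0.0]]))
        assert pip_snp[0] == pytest.approx(0.4)


class TestPve:
    def test_zero_weights_give_zero_pve(self, rng):
        X = rng.standard_normal((40, 5))
        y = rng.standard_normal(40)
        H = rng.standard_normal((40, 2))
        assert estimate_pve(X, y, np.zeros(5), H, np.zeros(2)) == (0.0, 0.0)

    def test_exact_recovery_gives_pve_one(self, rng):
        X = rng.standard_normal((40, 5))
        theta = rng.standard_normal(5)
        y = X @ theta
        pve_snp, _ = estimate_pve(X, y, theta, X, theta)
        assert pve_snp == pytest.approx(1.0, abs=1e-12)


class TestFitOuter:
    def test_perfect_single_predictor(self, rng):
        y = rng.standard_normal(100)
        y = (y - y.mean()) / y.std()
        st = fit_outer(y[:, None], y, HiddenLayerPrior(), 0.5, max_sweeps=200)
        assert st.pip[0] > 0.999
        assert st.m[0] == pytest.approx(1.0, abs=0.05)

    def test_orthogonal_columns_match_exact_spike_slab(self, rng):
        """K=1 fixed point on an orthogonal design equals the closed-form
        per-column spike-and-slab posterior."""
        from bann._vem import coordinate_sweep, init_state

        N, G = 40, 5
        Q, _ = np.linalg.qr(rng.standard_normal((N, G)))
        H = np.asfortranarray(Q * 2.0)
        y = H @ np.array([1.0, 0, 0, 0.5, 0]) + 0.3 * rng.standard_normal(N)
        tau2, sigma2_w, pi = 0.09, 1.0, 0.3
        atA = np.einsum("ij,ij->j", H, H)
        st = init_state(H, y, [sigma2_w], [1.0], pi, tau2=tau2)
        coordinate_sweep(st, H, atA)
        s2 = 1.0 / (atA / tau2 + 1.0 / sigma2_w)
        mu = s2 * (H.T @ y) / tau2
        bf = np.sqrt(s2 / sigma2_w) * np.exp(mu**2 / (2 * s2))
        alpha = pi * bf / (pi * bf + 1 - pi)
        np.testing.assert_allclose(st.alpha.ravel(), alpha, atol=1e-9)
        np.testing.assert_allclose(st.mu.ravel(), mu, atol=1e-9)


class TestBANNEstimator:
    def test_sklearn_get_set_params_roundtrip(self, small_dataset):
        _, _, mask, _ = small_dataset
        model = BANN(membership=mask, grid_size=4)
        params = model.get_params()
        assert params["grid_size"] == 4
        model.set_params(tol=1e-3)
        assert model.tol == 1e-3

    def test_fit_exposes_posterior_attributes(self, small_dataset):
        X, _, mask, trait = small_dataset
        model = BANN(membership=mask, grid_size=4).fit(X, trait.y)
        assert model.pip_snp_.shape == (X.shape[1],)
        assert model.pip_set_.shape == (mask.n_sets,)
        assert 0 <= model.pve_snp_ <= 1 and 0 <= model.pve_set_ <= 1
        assert model.result_.grid_weights_inner.sum() == pytest.approx(1.0, abs=1e-12)

    def test_predict_tracks_signal(self, small_dataset):
        X, _, mask, trait = small_dataset
        model = BANN(membership=mask, grid_size=4).fit(X, trait.y)
        yhat = model.predict(X)
        assert np.corrcoef(yhat, trait.y)[0, 1] > 0.5

    def test_missing_mask_rejected(self, small_dataset):
        X, _, _, trait = small_dataset
        with pytest.raises(ValueError, match="membership"):
            BANN().fit(X, trait.y)

    def test_mask_dimension_mismatch_rejected(self, small_dataset):
        X, _, mask, trait = small_dataset
        with pytest.raises(ValueError, match="membership"):
            BANN(membership=mask).fit(X[:, :-5], trait.y)

    def test_single_sweep_when_tolerance_infinite(self, small_dataset):
        X, _, mask, trait = small_dataset
        st = fit_inner(
            bann.standardize(X)[0], (trait.y - trait.y.mean()) / trait.y.std(),
            InputLayerPrior(), 0.01, tol=np.inf, max_sweeps=100,
        )
        assert st.n_sweeps == 1
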