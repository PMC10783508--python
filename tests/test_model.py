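import numpy as np
import pytest

from decontpro import (
    DecontPro,
    SimConfig,
    contamination_summary,
    decompose_counts,
    estimate_ambient_from_cells,
    estimate_ambient_from_empties,
    expected_rate,
    expected_rates,
    simulate_cells,
)
from decontpro.model import ModelPriors
from decontpro.triage import DegenerateProfileError


class TestExpectedRate:
    def test_native_only_limit(self):
        assert expected_rate(theta=0.0, beta=0.0, eta_j=0.3, phi_kj=0.7) == 0.7

    def test_ambient_only_limit(self):
        assert expected_rate(theta=1.0, beta=0.0, eta_j=0.3, phi_kj=0.7) == 0.3

    def test_three_term_hand_value(self):
        # (1-0.2)*0.5*0.1 + (1-0.2)*0.5*0.1 + 0.2 = 0.04 + 0.04 + 0.2
        lam = expected_rate(theta=0.5, beta=0.2, eta_j=0.1, phi_kj=0.1)
        assert lam == pytest.approx(0.28)

    @pytest.mark.parametrize("theta,beta", [(-0.1, 0.1), (1.1, 0.1), (0.5, 0.6)])
    def test_out_of_bounds_rejected(self, theta, beta):
        with pytest.raises(ValueError):
            expected_rate(theta=theta, beta=beta, eta_j=0.1, phi_kj=0.1)

    def test_vectorized_matches_scalar(self):
        rng = np.random.default_rng(0)
        I, J, K = 6, 4, 2
        theta = rng.uniform(0.01, 0.2, (I, J))
        beta = rng.uniform(0.001, 0.05, (I, J))
        eta = rng.dirichlet(np.ones(J))
        phi = rng.dirichlet(np.ones(J), size=K)
        labels = rng.integers(0, K, I)
        lam = expected_rates(theta, beta, eta, phi, labels)
        i, j = 3, 2
        assert lam[i, j] == pytest.approx(
            expected_rate(theta[i, j], beta[i, j], eta[j], phi[labels[i], j])
        )


class TestDecompose:
    def _uniform_fit(self, x, theta, beta, eta_j, phi_j):
        I, J = x.shape
        return dict(
            theta=np.full((I, J), theta),
            beta=np.full((I, J), beta),
            eta=np.full(J, eta_j),
            phi=np.full((1, J), phi_j),
            labels=np.zeros(I, dtype=int),
        )

    def test_hand_worked_example(self):
        # weights 0.04 / 0.04 / 0.20 over lambda = 0.28 on x = 28
        x = np.array([[28.0]])
        d = decompose_counts(
            x, **self._uniform_fit(x, theta=0.5, beta=0.2, eta_j=0.1, phi_j=0.1)
        )
        assert d.native[0, 0] == pytest.approx(4.0)
        assert d.ambient[0, 0] == pytest.approx(4.0)
        assert d.background[0, 0] == pytest.approx(20.0)

    def test_native_only_limit(self):
        x = np.array([[10.0]])
        d = decompose_counts(
            x, **self._uniform_fit(x, theta=0.0, beta=0.0, eta_j=0.1, phi_j=0.1)
        )
        assert d.native[0, 0] == 10.0
        assert d.ambient[0, 0] == 0.0 and d.background[0, 0] == 0.0

    def test_zero_counts_give_zero_components(self):
        x = np.array([[0.0, 5.0]])
        d = decompose_counts(
            x, **self._uniform_fit(x, theta=0.3, beta=0.1, eta_j=0.5, phi_j=0.5)
        )
        assert d.native[0, 0] == d.ambient[0, 0] == d.background[0, 0] == 0.0

    def test_conservation_for_random_parameters(self):
        rng = np.random.default_rng(1)
        x = rng.poisson(20, (15, 6)).astype(float)
        theta = rng.uniform(0.01, 0.9, (15, 6))
        beta = rng.uniform(0.001, 0.49, (15, 6))
        eta = rng.dirichlet(np.ones(6))
        phi = rng.dirichlet(np.ones(6), size=3)
        labels = rng.integers(0, 3, 15)
        d = decompose_counts(x, theta, beta, eta, phi, labels)
        assert np.abs(d.total - x).max() < 1e-9
        assert (d.native >= 0).all() and (d.ambient >= 0).all()
        assert (d.native <= x + 1e-12).all()

    def test_stochastic_rounding_preserves_totals_and_is_integer(self):
        rng = np.random.default_rng(2)
        x = rng.poisson(30, (10, 4)).astype(float)
        args = self._uniform_fit(x, theta=0.3, beta=0.2, eta_j=0.25, phi_j=0.25)
        d = decompose_counts(x, **args, rounding="stochastic", seed=7)
        total = d.native + d.ambient + d.background
        assert np.array_equal(total, x)
        assert np.allclose(d.native, np.round(d.native))
        d2 = decompose_counts(x, **args, rounding="stochastic", seed=7)
        assert np.array_equal(d.native, d2.native)


class TestContaminationSummary:
    def test_hand_fractions(self):
        x = np.array([[28.0]])
        d = decompose_counts(
            x,
            theta=np.full((1, 1), 0.5),
            beta=np.full((1, 1), 0.2),
            eta=np.array([0.1]),
            phi=np.array([[0.1]]),
            labels=np.zeros(1, dtype=int),
        )
        df, summary = contamination_summary(d)
        assert df.loc[0, "native"] == pytest.approx(4 / 28)
        assert df.loc[0, "background"] == pytest.approx(20 / 28)

    def test_zero_library_droplet_excluded(self):
        from decontpro.model import Decomposition

        d = Decomposition(
            native=np.array([[5.0], [0.0]]),
            ambient=np.array([[0.0], [0.0]]),
            background=np.array([[0.0], [0.0]]),
        )
        df, summary = contamination_summary(d)
        assert summary["n_undefined"] == 1
        assert summary["native"]["median"] == 1.0


class TestAmbientEstimation:
    def test_from_empties_hand_value(self, toy_count_matrix):
        adt = toy_count_matrix.subset_features([0])  # single column
        import scipy.sparse as sp

        from decontpro.io import CountMatrix

        cm = CountMatrix(
            sp.csr_matrix(np.array([[3, 1]])),
            np.array(["B1"], dtype=object),
            np.array(["A", "B"], dtype=object),
            np.array(["Antibody Capture"] * 2, dtype=object),
        )
        eta = estimate_ambient_from_empties(cm, np.array([True]))
        assert np.allclose(eta, [0.75, 0.25])

    def test_from_cells_identical_profiles(self):
        p = np.array([0.5, 0.3, 0.2])
        X = np.outer([100, 200, 400], p)
        assert np.allclose(estimate_ambient_from_cells(X), p)

    def test_from_cells_zero_total_raises(self):
        with pytest.raises(DegenerateProfileError):
            estimate_ambient_from_cells(np.zeros((3, 2)))


@pytest.fixture(scope="module")
def small_fit():
    cfg = SimConfig(I=120, J=8, K=2, seed=21)
    cm, labels, truth = simulate_cells(cfg)
    model = DecontPro(random_state=3, max_iter=4000).fit(cm, labels)
    return cm, labels, truth, model


class TestDecontProEstimator:
    def test_fitted_attributes_and_bounds(self, small_fit):
        cm, labels, truth, m = small_fit
        I, J = cm.shape
        assert m.phi_.shape == (2, J)
        assert np.allclose(m.phi_.sum(axis=1), 1.0, atol=1e-6)
        assert ((m.theta_ > 0) & (m.theta_ < 1)).all()
        assert ((m.beta_ > 0) & (m.beta_ < 0.5)).all()
        assert ((m.delta_ > 0) & (m.delta_ < 1)).all()
        assert ((m.mu_ > 0) & (m.mu_ < 0.5)).all()
        assert len(m.elbo_trace_) == m.n_iter_

    def test_lambda_recomputable_from_parameters(self, small_fit):
        _, _, _, m = small_fit
        lam = expected_rates(m.theta_, m.beta_, m.eta_, m.phi_, m.labels_)
        assert np.allclose(lam, m.lambda_)

    def test_conservation(self, small_fit):
        cm, _, _, m = small_fit
        d = m.decompose()
        assert np.abs(d.total - cm.dense()).max() < 1e-9

    def test_transform_returns_native(self, small_fit):
        _, _, _, m = small_fit
        assert np.array_equal(m.transform(), m.decompose().native)

    def test_determinism_same_seed(self):
        cfg = SimConfig(I=60, J=5, K=2, seed=22)
        cm, labels, _ = simulate_cells(cfg)
        m1 = DecontPro(random_state=5, max_iter=1500).fit(cm, labels)
        m2 = DecontPro(random_state=5, max_iter=1500).fit(cm, labels)
        assert np.array_equal(m1.theta_, m2.theta_)
        assert np.array_equal(m1.phi_, m2.phi_)
        assert np.array_equal(m1.elbo_trace_, m2.elbo_trace_)

    def test_sklearn_get_set_params_round_trip(self):
        m = DecontPro(tau1=1e-4)
        params = m.get_params()
        assert params["tau1"] == 1e-4
        m2 = DecontPro().set_params(**params)
        assert m2.tau1 == 1e-4

    def test_label_length_mismatch_rejected(self):
        cfg = SimConfig(I=30, J=4, K=2, seed=23)
        cm, labels, _ = simulate_cells(cfg)
        with pytest.raises(ValueError):
            DecontPro(max_iter=100).fit(cm, labels[:-1])

    def test_cluster_with_zero_counts_rejected(self):
        X = np.vstack([np.zeros((3, 4)), np.ones((3, 4))]).astype(int)
        labels = np.array([0, 0, 0, 1, 1, 1])
        with pytest.raises(ValueError, match="zero total"):
            DecontPro(max_iter=100).fit(X, labels)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            DecontPro(max_iter=100).fit(np.array([[-1, 2]]), np.array([0]))

    def test_priors_wrapper(self):
        priors = ModelPriors(tau1=1e-4, tau2=1e-5, max_iter=500)
        from decontpro import fit_model

        cfg = SimConfig(I=40, J=4, K=2, seed=24)
        cm, labels, _ = simulate_cells(cfg)
        m = fit_model(cm, labels, priors=priors, seed=1)
        assert m.tau1 == 1e-4 and m.n_iter_ <= 500

    def test_invalid_priors_rejected(self):
        with pytest.raises(ValueError):
            ModelPriors(tau1=-1.0)
        with pytest.raises(ValueError):
            ModelPriors(beta_upper=0.9)


class TestBackgroundMonotonicity:
    def test_higher_true_background_not_estimated_lower(self):
        """Dataset-mean estimated background fraction does not decrease
        when the generative per-ADT background level increases."""
        fracs = []
        for mu_law in [(2.0, 798.0), (2.0, 98.0)]:  # mean 0.00125 vs 0.01
            cfg = SimConfig(I=250, J=10, K=2, seed=31, mu_law=mu_law)
            cm, labels, _ = simulate_cells(cfg)
            m = DecontPro(random_state=2, max_iter=6000).fit(cm, labels)
            fracs.append(np.nanmean(m.decompose().fractions[:, 2]))
        assert fracs[1] >= fracs[0]
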