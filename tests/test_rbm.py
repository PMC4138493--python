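"""RBM energy, conditionals, CD gradients, the enumeration oracle and
training behavior."""

import dataclasses

import numpy as np
import pytest
from scipy import stats

from neurodeep import rbm
from conftest import tiny_params


def flat(g):
    return np.concatenate([g.dW.ravel(), g.da, g.db])


def cosine(u, v):
    return float(u @ v / (np.linalg.norm(u) * np.linalg.norm(v)))


class TestEnergy:
    def test_zero_configuration_vanishes(self):
        p = rbm.RBMParams(W=np.ones((2, 3)), a=np.zeros(3), b=np.ones(2),
                          sigma=np.ones(3), hidden_type="logistic")
        assert rbm.energy(np.zeros(3), np.zeros(2), p) == 0.0

    def test_hand_evaluation(self):
        p = rbm.RBMParams(W=np.array([[2.0]]), a=np.array([0.0]),
                          b=np.array([0.5]), sigma=np.array([1.0]),
                          hidden_type="logistic")
        assert rbm.energy(np.array([1.0]), np.array([1.0]), p) == pytest.approx(-3.5)

    @pytest.mark.parametrize("form", ["legacy", "standard"])
    def test_tanh_sign_symmetry(self, form):
        """Negating a feature row and its hidden unit together leaves the
        energy unchanged (b_i = 0)."""
        p = tiny_params(seed=1)
        p = dataclasses.replace(p, b=np.zeros(3))
        v = np.array([0.5, -1.0, 2.0, 0.3])
        h = np.array([1.0, -1.0, 1.0])
        W2 = p.W.copy()
        W2[1] *= -1
        h2 = h.copy()
        h2[1] *= -1
        p2 = dataclasses.replace(p, W=W2)
        assert rbm.energy(v, h, p, form) == pytest.approx(rbm.energy(v, h2, p2, form))

    def test_dimension_mismatch(self, tiny_rbm):
        with pytest.raises(ValueError):
            rbm.energy(np.zeros(5), np.zeros(3), tiny_rbm)


class TestConditionals:
    def test_zero_preactivation_is_symmetric(self):
        p = rbm.RBMParams(W=np.zeros((2, 2)), a=np.zeros(2), b=np.zeros(2),
                          sigma=np.ones(2))
        means, _ = rbm.hidden_conditional(np.zeros(2), p)
        assert np.all(means == 0.0)
        r = np.random.default_rng(0)
        _, samples = rbm.hidden_conditional(np.zeros((4000, 2)), p, r)
        assert abs(samples.mean()) < 0.05  # P(+1) = 0.5

    def test_tanh_closed_form(self):
        p = rbm.RBMParams(W=np.array([[1.0]]), a=np.array([0.0]),
                          b=np.array([0.5]), sigma=np.array([1.0]))
        means, _ = rbm.hidden_conditional(np.array([2.0]), p)
        assert means[0] == pytest.approx(np.tanh(2.5), abs=1e-9)
        assert means[0] == pytest.approx(0.98661, abs=1e-5)

    @pytest.mark.parametrize("hidden_type", ["tanh", "logistic"])
    def test_saturation_limit(self, hidden_type):
        p = rbm.RBMParams(W=np.array([[1.0]]), a=np.array([0.0]),
                          b=np.array([0.0]), sigma=np.array([1.0]),
                          hidden_type=hidden_type)
        means, _ = rbm.hidden_conditional(np.array([50.0]), p)
        assert means[0] == pytest.approx(1.0, abs=1e-6)

    def test_visible_mean_conventions(self):
        base = dict(W=np.array([[2.0]]), a=np.array([0.5]), b=np.array([0.0]),
                    sigma=np.array([1.0]))
        std = rbm.RBMParams(**base, standard_form=True)
        leg = rbm.RBMParams(**base, standard_form=False)
        h = np.array([1.0])
        assert rbm.visible_conditional(h, std)[0][0] == pytest.approx(2.5)
        assert rbm.visible_conditional(h, leg)[0][0] == pytest.approx(1.5)
        zeros = np.array([0.0])
        for p in (std, leg):
            assert rbm.visible_conditional(zeros, p)[0][0] == pytest.approx(0.5)

    def test_visible_sampling_matches_analytic_moments(self):
        p = tiny_params(seed=2)
        h = np.array([1.0, -1.0, 1.0])
        means, _ = rbm.visible_conditional(h, p)
        r = np.random.default_rng(1)
        draws = np.array([rbm.visible_conditional(h, p, r)[1] for _ in range(10000)])
        se = p.sigma / np.sqrt(10000)
        assert np.all(np.abs(draws.mean(axis=0) - means) < 3 * se)


class TestGradients:
    def test_null_model_gradient_is_centered(self):
        p = rbm.RBMParams(W=np.zeros((3, 4)), a=np.zeros(4), b=np.zeros(3),
                          sigma=np.ones(4))
        r = np.random.default_rng(0)
        X = r.normal(0, 1, (10000, 4))
        X = (X - X.mean(0)) / X.std(0)
        g = rbm.cd_gradient(X, p, 1, np.random.default_rng(1))
        assert np.all(np.abs(flat(g)) < 4.0 / np.sqrt(10000))

    def test_gradient_invariant_to_row_order(self, tiny_rbm, rng):
        X = rng.normal(0, 1, (16, 4))
        g1 = rbm.cd_gradient(X, tiny_rbm, 1, mean_field=True)
        g2 = rbm.cd_gradient(X[::-1], tiny_rbm, 1, mean_field=True)
        assert np.allclose(flat(g1), flat(g2))

    def test_empty_batch_rejected(self, tiny_rbm):
        with pytest.raises(ValueError):
            rbm.cd_gradient(np.empty((0, 4)), tiny_rbm, 1)

    def test_cd_converges_to_exact_gradient(self):
        """Median cosine similarity with the enumeration oracle increases
        over cd_steps in {1, 10, 200} and reaches 0.95 at 200 steps.  The
        coupling scale is large enough that a short chain is visibly biased
        (at weak coupling every CD-k is already unbiased and the ordering
        drowns in Monte-Carlo noise)."""
        med = {1: [], 10: [], 200: []}
        for seed in range(10):
            p = tiny_params(seed=seed, scale=0.8)
            X = np.random.default_rng(seed).normal(0, 1, (500, 4))
            ex = flat(rbm.exact_gradient_oracle(p, X))
            for k in med:
                g = flat(rbm.cd_gradient(X, p, k, np.random.default_rng(100 + seed)))
                med[k].append(cosine(g, ex))
        m = {k: np.median(v) for k, v in med.items()}
        assert m[1] < m[10] <= m[200] + 1e-6
        assert m[200] >= 0.95


class TestUpdateStep:
    def test_pure_ascent_without_decay(self, tiny_rbm):
        cfg = rbm.TrainConfig(epsilon=0.5, lambda_l1=0.0)
        g = rbm.Gradients(dW=np.ones_like(tiny_rbm.W), da=np.ones(4), db=np.ones(3))
        p2 = rbm.update_step(tiny_rbm, g, cfg)
        assert np.allclose(p2.W, tiny_rbm.W + 0.5)
        assert np.allclose(p2.a, tiny_rbm.a + 0.5)

    def test_l1_hand_evaluation(self):
        p = rbm.RBMParams(W=np.array([[1.0, -1.0]]), a=np.zeros(2),
                          b=np.zeros(1), sigma=np.ones(2))
        cfg = rbm.TrainConfig(epsilon=0.1, lambda_l1=0.1)
        g = rbm.Gradients(dW=np.zeros((1, 2)), da=np.zeros(2), db=np.zeros(1))
        p2 = rbm.update_step(p, g, cfg)
        assert np.allclose(p2.W, [[0.99, -0.99]])

    def test_zero_weight_feels_no_decay(self):
        p = rbm.RBMParams(W=np.zeros((1, 2)), a=np.zeros(2), b=np.zeros(1),
                          sigma=np.ones(2))
        cfg = rbm.TrainConfig(epsilon=0.1, lambda_l1=10.0)
        g = rbm.Gradients(dW=np.zeros((1, 2)), da=np.zeros(2), db=np.zeros(1))
        assert np.all(rbm.update_step(p, g, cfg).W == 0.0)


class TestExactOracle:
    @pytest.mark.parametrize("hidden_type", ["tanh", "logistic"])
    def test_matches_finite_differences(self, hidden_type):
        """Enumeration gradient vs centered finite differences of the exact
        log-likelihood, to 1e-5 relative error."""
        p = tiny_params(seed=0, hidden_type=hidden_type)
        X = np.random.default_rng(1).normal(0, 1, (6, 4))
        g = rbm.exact_gradient_oracle(p, X)
        eps = 1e-6

        def num_grad(field, index):
            arr = getattr(p, field).copy()
            arr_p, arr_m = arr.copy(), arr.copy()
            arr_p[index] += eps
            arr_m[index] -= eps
            lp = rbm.exact_loglik(dataclasses.replace(p, **{field: arr_p}), X)
            lm = rbm.exact_loglik(dataclasses.replace(p, **{field: arr_m}), X)
            return (lp - lm) / (2 * eps)

        for field, gval, index in [("W", g.dW[1, 2], (1, 2)),
                                   ("W", g.dW[0, 0], (0, 0)),
                                   ("a", g.da[1], 1),
                                   ("b", g.db[2], 2)]:
            num = num_grad(field, index)
            assert gval == pytest.approx(num, rel=1e-5, abs=1e-8)

    def test_symmetric_null_has_zero_bias_gradients(self):
        p = rbm.RBMParams(W=np.zeros((3, 4)), a=np.zeros(4), b=np.zeros(3),
                          sigma=np.ones(4))
        X = np.array([[1.0, -0.5, 0.25, 0.0], [-1.0, 0.5, -0.25, 0.0]])
        g = rbm.exact_gradient_oracle(p, X)
        assert np.allclose(g.da, 0.0, atol=1e-12)
        assert np.allclose(g.db, 0.0, atol=1e-12)

    def test_enumeration_limit(self):
        p = tiny_params(seed=0, n_hidden=3)
        big = dataclasses.replace(p, W=np.zeros((13, 4)), b=np.zeros(13))
        with pytest.raises(ValueError, match="12"):
            rbm.exact_gradient_oracle(big, np.zeros((1, 4)))

    def test_gibbs_chain_matches_boltzmann_marginal(self):
        """Detailed-balance smoke test: hidden-state frequencies from a long
        Gibbs chain match the enumerated marginal (chi-squared, alpha 0.01)."""
        p = tiny_params(seed=3, n_visible=3, n_hidden=3, scale=0.4)
        S = rbm._hidden_states(p)
        _, logw = rbm._free_terms(p)
        probs = np.exp(logw - logw.max())
        probs /= probs.sum()
        r = np.random.default_rng(0)
        v = np.zeros(3)
        counts = np.zeros(len(S))
        n_keep, thin, burn = 10000, 5, 500
        kept = 0
        t = 0
        while kept < n_keep:
            _, h = rbm.hidden_conditional(v, p, r)
            _, v = rbm.visible_conditional(h, p, r)
            t += 1
            if t > burn and t % thin == 0:
                state = int(((h > 0).astype(int) * [4, 2, 1]).sum())
                counts[state] += 1
                kept += 1
        # map enumeration order to the same binary encoding
        enc = ((S > 0).astype(int) * [4, 2, 1]).sum(axis=1)
        expected = np.zeros(len(S))
        expected[enc] = probs * n_keep
        chi2 = ((counts - expected) ** 2 / expected).sum()
        assert chi2 < stats.chi2.ppf(0.99, df=len(S) - 1)


class TestTraining:
    def test_reconstruction_error_decreases(self):
        from neurodeep.simulate import generate_signed_source_data
        X, _ = generate_signed_source_data(grid_side=16, n_sources=4,
                                           n_volumes=200, seed=0)
        _, log = rbm.train_rbm(X, 8, rbm.TrainConfig(n_epochs=20, seed=0))
        assert log.recon_error[-1] < log.recon_error[0]

    def test_l1_monotone_and_sparsifying(self):
        from neurodeep.simulate import generate_signed_source_data
        X, _ = generate_signed_source_data(grid_side=16, n_sources=4,
                                           n_volumes=200, seed=1)
        mean_abs, near_zero = [], []
        for lam in (0.0, 0.01, 0.1):
            cfg = rbm.TrainConfig(n_epochs=10, lambda_l1=lam, seed=1)
            p, _ = rbm.train_rbm(X, 8, cfg)
            mean_abs.append(np.abs(p.W).mean())
            near_zero.append((np.abs(p.W) < 1e-3).mean())
        assert mean_abs[0] >= mean_abs[1] >= mean_abs[2]
        assert near_zero[2] > near_zero[0]

    def test_exact_loglik_increases_on_tiny_model(self):
        """Training data sampled from a known tiny RBM; CD-1 training raises
        the exact log-likelihood from initialization."""
        truth = tiny_params(seed=9, n_visible=6, n_hidden=3, scale=0.8)
        r = np.random.default_rng(0)
        v = np.zeros(6)
        samples = []
        for t in range(1200):
            _, h = rbm.hidden_conditional(v, truth, r)
            _, v = rbm.visible_conditional(h, truth, r)
            if t >= 200:
                samples.append(v.copy())
        X = np.array(samples)
        cfg = rbm.TrainConfig(epsilon=0.01, lambda_l1=0.0, batch_size=20,
                              n_epochs=30, seed=0)
        p0 = rbm.init_params(6, 3, seed=0)
        ll0 = rbm.exact_loglik(p0, X)
        p1, _ = rbm.train_rbm(X, 3, cfg, params=p0)
        assert rbm.exact_loglik(p1, X) > ll0

    def test_training_deterministic(self):
        X = np.random.default_rng(0).normal(0, 1, (50, 10))
        cfg = rbm.TrainConfig(n_epochs=3, seed=11)
        p1, _ = rbm.train_rbm(X, 4, cfg)
        p2, _ = rbm.train_rbm(X, 4, cfg)
        assert np.array_equal(p1.W, p2.W)

    def test_nan_rejected(self):
        X = np.full((5, 3), np.nan)
        with pytest.raises(ValueError, match="NaN"):
            rbm.train_rbm(X, 2, rbm.TrainConfig(n_epochs=1))


class TestFeaturePostprocessing:
    def test_projection_conventions(self, tiny_rbm):
        X = np.zeros((5, 4))
        z = rbm.project_timecourses(X, dataclasses.replace(tiny_rbm, b=np.zeros(3)))
        assert np.all(z == 0.0)
        zt = rbm.project_timecourses(np.random.default_rng(0).normal(0, 3, (5, 4)),
                                     tiny_rbm, apply_nonlinearity=True)
        assert np.all((zt > -1) & (zt < 1))

    def test_projection_onto_own_feature_dominates(self):
        W = np.eye(3, 6) * 2.0  # orthogonal features
        p = rbm.RBMParams(W=W, a=np.zeros(6), b=np.zeros(3), sigma=np.ones(6))
        z = rbm.project_timecourses(W[1][None, :], p)
        assert z[0, 1] == pytest.approx(np.sum(W[1] ** 2))
        assert np.argmax(z[0]) == 1

    def test_flip_negative_features(self):
        blob = np.exp(-np.linspace(-3, 3, 50) ** 2)
        W = np.vstack([-blob, blob, -np.ones(50)])
        p = rbm.RBMParams(W=W, a=np.zeros(50), b=np.zeros(3), sigma=np.ones(50))
        flipped, mask = rbm.flip_negative_features(p)
        assert mask[0] and not mask[1]
        r = np.corrcoef(flipped.W[0], blob)[0, 1]
        assert r == pytest.approx(1.0)
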