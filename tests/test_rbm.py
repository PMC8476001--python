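import numpy as np
import pytest
from scipy.integrate import quad
from scipy.special import logsumexp

from tcrmodels.rbm import (
    DReLUParams,
    RBMModel,
    dreu_moments,
    export_field_pwm,
    export_parameters,
    fit_independent_site,
    gamma_dreu,
    gradient_exact,
    hidden_input,
    import_parameters,
    log_likelihood,
    log_partition,
    log_partition_exact,
    log_score,
    objective_exact,
    project,
    sample,
    train_rbm,
)


def _quad_gamma(gp, gm, tp, tm, I):
    """Adaptive-quadrature oracle for Gamma(I), evaluated with a shift for
    numerical range."""

    def U(h):
        hp, hm = max(h, 0.0), min(h, 0.0)
        return 0.5 * gp * hp * hp + 0.5 * gm * hm * hm + tp * hp + tm * hm

    grid = np.linspace(-150, 150, 200001)
    shift = max(-U(h) + h * I for h in grid)
    val, _ = quad(lambda h: np.exp(-U(h) + h * I - shift), -150, 150, limit=500)
    return np.log(val) + shift


class TestGamma:
    def test_symmetric_quadratic_closed_form(self):
        for gamma in (0.5, 1.0, 3.0):
            p = DReLUParams(np.array([gamma]), np.array([gamma]), np.zeros(1), np.zeros(1))
            for I in (-2.0, 0.0, 1.7):
                expected = I * I / (2 * gamma) + 0.5 * np.log(2 * np.pi / gamma)
                assert gamma_dreu(p, np.array([I]))[0] == pytest.approx(expected, rel=1e-12)

    def test_gamma_zero_standard(self):
        p = DReLUParams(np.ones(1), np.ones(1), np.zeros(1), np.zeros(1))
        assert gamma_dreu(p, np.array([0.0]))[0] == pytest.approx(0.5 * np.log(2 * np.pi))

    @pytest.mark.parametrize(
        "gp,gm,tp,tm",
        [(1.0, 1.0, 0.0, 0.0), (0.7, 2.3, 0.4, -1.1), (3.0, 0.2, -2.0, 1.5)],
    )
    def test_matches_quadrature(self, gp, gm, tp, tm):
        p = DReLUParams(*(np.atleast_1d(float(x)) for x in (gp, gm, tp, tm)))
        for I in (-7.0, -1.0, 0.0, 0.5, 4.0, 9.0):
            ours = gamma_dreu(p, np.array([I]))[0]
            oracle = _quad_gamma(gp, gm, tp, tm, I)
            assert ours == pytest.approx(oracle, rel=1e-8)

    def test_stable_at_large_inputs(self):
        p = DReLUParams(np.ones(1), np.ones(1), np.zeros(1), np.zeros(1))
        for I in (-1e3, 1e3):
            val = gamma_dreu(p, np.array([I]))[0]
            assert np.isfinite(val)
            # the dominant half-line integral tends to the full Gaussian one
            assert val == pytest.approx(I * I / 2 + 0.5 * np.log(2 * np.pi), rel=1e-6)

    def test_nonpositive_curvature_rejected(self):
        with pytest.raises(ValueError):
            DReLUParams(np.array([0.0]), np.ones(1), np.zeros(1), np.zeros(1))

    def test_moment_h_is_derivative_of_gamma(self):
        p = DReLUParams(np.array([0.8]), np.array([1.3]), np.array([0.2]), np.array([-0.5]))
        for I in (-3.0, 0.0, 2.5):
            eps = 1e-6
            num = (gamma_dreu(p, np.array([I + eps])) - gamma_dreu(p, np.array([I - eps]))) / (
                2 * eps
            )
            assert dreu_moments(p, np.array([I]))["h"][0] == pytest.approx(num[0], rel=1e-5)


class TestHiddenInput:
    def test_zero_weights(self):
        m = RBMModel.zeros(5, 3)
        assert (hidden_input(m, np.zeros((2, 5), dtype=int)) == 0).all()

    def test_single_weight(self):
        m = RBMModel.zeros(5, 2)
        m.W[0, 0, 4] = 2.0  # residue index 4 at site 0
        seq = np.array([4, 0, 0, 0, 0])
        I = hidden_input(m, seq)
        assert I[0, 0] == 2.0
        assert I[0, 1] == 0.0

    def test_matches_naive_loop(self):
        rng = np.random.default_rng(0)
        m = RBMModel.zeros(7, 4, n_states=6)
        m.W = rng.normal(size=m.W.shape)
        V = rng.integers(0, 6, size=(10, 7))
        I = hidden_input(m, V)
        for b in range(10):
            for mu in range(4):
                naive = sum(m.W[i, mu, V[b, i]] for i in range(7))
                assert I[b, mu] == pytest.approx(naive)

    def test_shape_mismatch(self):
        m = RBMModel.zeros(5, 2)
        with pytest.raises(ValueError):
            hidden_input(m, np.zeros((2, 4), dtype=int))


class TestLogScore:
    def test_zero_weight_model(self, tiny_rbm):
        m = tiny_rbm.copy()
        m.W[:] = 0.0
        seq = np.array([0, 1, 0])
        expected = m.g[0, 0] + m.g[1, 1] + m.g[2, 0] + gamma_dreu(
            m.hidden, np.zeros(1)
        ).sum()
        assert log_score(m, seq)[0] == pytest.approx(expected)

    def test_one_site_difference(self, tiny_rbm):
        m = tiny_rbm.copy()
        m.W[:] = 0.0
        a = log_score(m, np.array([0, 0, 0]))[0]
        b = log_score(m, np.array([1, 0, 0]))[0]
        assert a - b == pytest.approx(m.g[0, 0] - m.g[0, 1])

    def test_normalized_likelihood_vs_enumeration(self, tiny_rbm):
        space = np.array([[i, j, k] for i in range(2) for j in range(2) for k in range(2)])
        lz = logsumexp(log_score(tiny_rbm, space))
        probs = np.exp(log_score(tiny_rbm, space) - lz)
        assert probs.sum() == pytest.approx(1.0, abs=1e-10)
        m = tiny_rbm.copy()
        log_partition(m, "exact_enum")
        np.testing.assert_allclose(
            np.exp(log_likelihood(m, space)), probs, rtol=1e-10
        )


class TestLogPartition:
    def test_factorized_closed_form(self):
        rng = np.random.default_rng(1)
        m = RBMModel.zeros(4, 2, n_states=3)
        m.g = rng.normal(size=(4, 3))
        analytic = logsumexp(m.g, axis=1).sum() + gamma_dreu(m.hidden, np.zeros(2)).sum()
        assert log_partition_exact(m) == pytest.approx(analytic, rel=1e-12)
        ais, err = log_partition(m, "ais", n_chains=10, n_betas=50, seed=0)
        assert ais == pytest.approx(analytic, abs=1e-9)  # W=0: all AIS weights equal

    def test_ais_within_three_stderr_of_exact(self, tiny_rbm):
        exact = log_partition_exact(tiny_rbm)
        est, err = log_partition(tiny_rbm.copy(), "ais", n_chains=40, n_betas=300, seed=3)
        assert abs(est - exact) <= max(3 * err, 0.05)

    def test_ais_variance_shrinks_with_more_betas(self, tiny_rbm):
        few, many = [], []
        for s in range(8):
            few.append(log_partition(tiny_rbm.copy(), "ais", n_chains=10, n_betas=20, seed=s)[0])
            many.append(log_partition(tiny_rbm.copy(), "ais", n_chains=10, n_betas=160, seed=s)[0])
        assert np.std(many) < np.std(few) + 1e-12

    def test_exact_enum_too_large(self):
        m = RBMModel.zeros(19, 1)  # 21**19 states
        with pytest.raises(ValueError):
            log_partition(m, "exact_enum")


class TestGradients:
    def test_analytic_matches_finite_difference(self):
        rng = np.random.default_rng(7)
        n_sites, n_states, n_hidden = 3, 2, 2
        model = RBMModel(
            g=0.3 * rng.normal(size=(n_sites, n_states)),
            W=0.5 * rng.normal(size=(n_sites, n_hidden, n_states)),
            hidden=DReLUParams(
                np.array([0.9, 1.2]), np.array([1.1, 0.7]),
                np.array([0.2, -0.1]), np.array([0.0, 0.4]),
            ),
            n_sites=n_sites,
            n_states=n_states,
        )
        V = rng.integers(0, n_states, size=(12, n_sites))
        w = rng.integers(1, 5, size=12).astype(float)
        l1sq = 0.1
        grad = gradient_exact(model, V, w, l1sq)
        eps = 1e-5

        def num_grad(setter, getter):
            base = getter()
            out = np.zeros_like(base)
            it = np.nditer(base, flags=["multi_index"])
            while not it.finished:
                idx = it.multi_index
                orig = base[idx]
                setter(idx, orig + eps)
                up = objective_exact(model, V, w, l1sq)
                setter(idx, orig - eps)
                down = objective_exact(model, V, w, l1sq)
                setter(idx, orig)
                out[idx] = (up - down) / (2 * eps)
                it.iternext()
            return out

        num_g = num_grad(lambda i, v: model.g.__setitem__(i, v), lambda: model.g)
        np.testing.assert_allclose(grad["g"], num_g, rtol=1e-5, atol=1e-7)
        num_W = num_grad(lambda i, v: model.W.__setitem__(i, v), lambda: model.W)
        np.testing.assert_allclose(grad["W"], num_W, rtol=1e-5, atol=1e-7)
        for name in ("theta_plus", "theta_minus", "gamma_plus", "gamma_minus"):
            arr = getattr(model.hidden, name)
            num_h = num_grad(lambda i, v: arr.__setitem__(i, v), lambda: arr)
            np.testing.assert_allclose(grad[name], num_h, rtol=1e-4, atol=1e-7)


class TestTraining:
    def test_invalid_hyperparameters(self):
        V = np.zeros((5, 3), dtype=int)
        with pytest.raises(ValueError):
            train_rbm(V, n_hidden=0)
        with pytest.raises(ValueError):
            train_rbm(V, epochs=0)
        with pytest.raises(ValueError):
            train_rbm(V, weights=np.zeros(5))

    def test_seeded_determinism(self):
        rng = np.random.default_rng(2)
        V = rng.integers(0, 4, size=(60, 5))
        m1, _ = train_rbm(V, n_hidden=2, epochs=5, n_states=4, seed=9, n_chains=20)
        m2, _ = train_rbm(V, n_hidden=2, epochs=5, n_states=4, seed=9, n_chains=20)
        np.testing.assert_array_equal(m1.W, m2.W)
        np.testing.assert_array_equal(m1.g, m2.g)

    def test_regularization_monotonicity(self):
        rng = np.random.default_rng(3)
        # correlated toy data: two site-blocks move together
        z = rng.integers(0, 2, size=200)
        V = np.stack([z, z, rng.integers(0, 2, 200), 1 - z], axis=1)
        norms = []
        for l1sq in (0.01, 0.1, 1.0):
            m, _ = train_rbm(
                V, n_hidden=2, l1sq=l1sq, epochs=40, n_states=2, seed=1,
                n_chains=50, learning_rate=0.05,
            )
            norms.append(np.abs(m.W).sum())
        assert norms[0] >= norms[1] >= norms[2]

    def test_nan_guard(self):
        rng = np.random.default_rng(0)
        V = rng.integers(0, 2, size=(40, 3))
        with pytest.raises((FloatingPointError, ValueError)):
            with np.errstate(all="ignore"):
                train_rbm(V, n_hidden=1, epochs=5, n_states=2, learning_rate=1e300)


class TestSampling:
    def test_factorized_frequencies(self):
        rng = np.random.default_rng(0)
        m = RBMModel.zeros(3, 1, n_states=4)
        m.g = rng.normal(size=(3, 4))
        S = sample(m, 4000, gibbs_steps=30, seed=5)
        target = np.exp(m.g - logsumexp(m.g, axis=1, keepdims=True))
        for i in range(3):
            emp = np.bincount(S[:, i], minlength=4) / len(S)
            np.testing.assert_allclose(emp, target[i], atol=0.03)

    def test_seeded_reproducibility(self, tiny_rbm):
        a = sample(tiny_rbm, 50, gibbs_steps=10, seed=4)
        b = sample(tiny_rbm, 50, gibbs_steps=10, seed=4)
        np.testing.assert_array_equal(a, b)

    def test_motif_enrichment_vs_background(self):
        # plant a 3-state motif at sites 1-3 in half the data
        rng = np.random.default_rng(8)
        n, n_sites, q = 500, 7, 5
        V = rng.integers(0, q, size=(n, n_sites))
        V[: n // 5, 1:5] = 3  # rare 4-site motif in 20% of the data
        model, _ = train_rbm(
            V, n_hidden=3, epochs=200, n_states=q, seed=0,
            n_chains=100, learning_rate=0.05, l1sq=0.01,
        )
        bg = fit_independent_site(V)  # same marginals, no correlations
        s_model = sample(model, 3000, gibbs_steps=50, seed=1)
        s_bg = sample(bg, 3000, gibbs_steps=50, seed=1)
        hit_m = ((s_model[:, 1:5] == 3).all(axis=1)).mean()
        hit_b = ((s_bg[:, 1:5] == 3).all(axis=1)).mean()
        assert hit_m >= 5 * max(hit_b, 1e-4)


class TestProject:
    def test_equals_stacked_hidden_input(self, tiny_rbm):
        V = np.array([[0, 1, 1], [1, 0, 1]])
        np.testing.assert_array_equal(project(tiny_rbm, V), hidden_input(tiny_rbm, V))

    def test_zero_weight_projection(self):
        m = RBMModel.zeros(4, 3)
        assert (project(m, np.zeros((5, 4), dtype=int)) == 0).all()

    def test_two_motif_groups_separate(self):
        rng = np.random.default_rng(11)
        n, n_sites, q = 300, 6, 5
        V = rng.integers(0, q, size=(n, n_sites))
        V[: n // 2, 1:3] = 0  # group A motif
        V[n // 2:, 3:5] = 2  # group B motif
        model, _ = train_rbm(
            V, n_hidden=4, epochs=80, n_states=q, seed=0,
            n_chains=100, learning_rate=0.05, l1sq=0.01,
        )
        I = project(model, V)
        labels = np.zeros(n, dtype=bool)
        labels[: n // 2] = True
        # some unit's input separates groups almost perfectly
        from tcrmodels.scoring import auroc

        seps = [max(auroc(I[:, mu], labels), 1 - auroc(I[:, mu], labels))
                for mu in range(model.n_hidden)]
        assert max(seps) >= 0.9


class TestIndependentSiteLimit:
    def test_matches_pwm_closed_form(self):
        rng = np.random.default_rng(4)
        V = rng.integers(0, 3, size=(50, 4))
        w = rng.integers(1, 4, size=50).astype(float)
        model = fit_independent_site(V, w, pseudocount=1e-12)
        # PWM probability: product of weighted site frequencies
        freqs = np.zeros((4, 3))
        for row, wi in zip(V, w):
            for i, a in enumerate(row):
                freqs[i, a] += wi
        freqs /= freqs.sum(axis=1, keepdims=True)
        ll = log_likelihood(model, V[:5])
        for b in range(5):
            expected = sum(np.log(freqs[i, V[b, i]]) for i in range(4))
            assert ll[b] == pytest.approx(expected, rel=1e-6)


class TestPersistence:
    def test_roundtrip_scores(self, tiny_rbm, tmp_path):
        rng = np.random.default_rng(6)
        V = rng.integers(0, 2, size=(100, 3))
        p = tmp_path / "model.npz"
        m = tiny_rbm.copy()
        log_partition(m, "exact_enum")
        export_parameters(m, p)
        back = import_parameters(p)
        np.testing.assert_array_equal(log_score(back, V), log_score(m, V))
        assert back.log_z == m.log_z

    def test_field_pwm_normalized(self, tiny_rbm):
        pwm = export_field_pwm(tiny_rbm)
        np.testing.assert_allclose(pwm.sum(axis=1), 1.0)

    def test_weight_export_preserves_order(self, tiny_rbm, tmp_path):
        p = tmp_path / "m.npz"
        export_parameters(tiny_rbm, p)
        back = import_parameters(p)
        np.testing.assert_array_equal(back.W, tiny_rbm.W)
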