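"""Log-cosh VAE: loss analytics, KL closed form, gradients, training."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from survfuse import (
    LatentCode,
    VAEConfig,
    ValidationError,
    default_vae_config,
    encode,
    fit_vae,
    kl_standard_normal,
    logcosh_loss,
    vae_total_loss,
)
from survfuse.vae import loss_and_grads, reconstruct

from .conftest import make_matrix


class TestLogcosh:
    def test_zero_at_equality(self, rng):
        x = rng.normal(size=(5, 4))
        assert logcosh_loss(x, x, a=2.0) == 0.0

    def test_unit_residual_closed_form(self):
        # single residual r=1, a=1: log(cosh(1)) = log((e + 1/e)/2)
        expected = float(np.log((np.e + 1 / np.e) / 2))
        assert logcosh_loss(np.array([[1.0]]), np.array([[0.0]]), a=1.0) == pytest.approx(
            expected, abs=1e-9
        )

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        r=st.floats(-50, 50, allow_nan=False),
        a=st.floats(0.01, 30, allow_nan=False),
    )
    def test_even_nonnegative_and_monotone(self, r, a):
        x = np.array([[r]])
        zero = np.array([[0.0]])
        loss = logcosh_loss(x, zero, a)
        assert loss >= 0.0
        assert loss == pytest.approx(logcosh_loss(-x, zero, a), rel=1e-12)
        if abs(r) > 1e-6:
            assert loss > logcosh_loss(0.5 * x, zero, a)

    def test_quadratic_regime(self):
        # |a r| <= 1e-3: loss ~ a r^2 / 2 within 1e-6 relative
        for a, r in [(1.0, 1e-3), (10.0, 1e-4), (0.5, 2e-3)]:
            loss = logcosh_loss(np.array([[r]]), np.array([[0.0]]), a)
            assert loss == pytest.approx(a * r * r / 2, rel=1e-6)

    def test_linear_regime(self):
        # |a r| >= 20: loss ~ |r| - log(2)/a within 1e-8
        for a, r in [(1.0, 25.0), (10.0, 3.0), (4.0, -8.0)]:
            loss = logcosh_loss(np.array([[r]]), np.array([[0.0]]), a)
            assert loss == pytest.approx(abs(r) - np.log(2) / a, abs=1e-8)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValidationError, match="shape"):
            logcosh_loss(np.zeros((2, 3)), np.zeros((2, 4)), a=1.0)


class TestKL:
    def test_zero_at_prior(self):
        code = LatentCode(np.zeros((3, 4)), np.zeros((3, 4)))
        assert kl_standard_normal(code) == 0.0

    def test_unit_mean_single_dim(self):
        code = LatentCode(np.array([[1.0]]), np.array([[0.0]]))
        assert kl_standard_normal(code) == pytest.approx(0.5)

    def test_nonnegative_random_codes(self, rng):
        for _ in range(20):
            code = LatentCode(rng.normal(size=(4, 3)), rng.normal(size=(4, 3)))
            assert kl_standard_normal(code) >= 0.0

    def test_matches_monte_carlo(self, rng):
        """Closed form vs a sampled KL estimate, 3 standard errors."""
        mu = rng.normal(size=(1, 2))
        logvar = rng.normal(scale=0.5, size=(1, 2))
        sd = np.exp(0.5 * logvar)
        z = mu + sd * rng.standard_normal((200_000, 2))
        log_q = -0.5 * (((z - mu) / sd) ** 2 + np.log(2 * np.pi) + logvar).sum(axis=1)
        log_p = -0.5 * (z**2 + np.log(2 * np.pi)).sum(axis=1)
        samples = log_q - log_p
        mc, se = samples.mean(), samples.std(ddof=1) / np.sqrt(len(samples))
        assert abs(kl_standard_normal(LatentCode(mu, logvar)) - mc) < 3 * se


class TestTotalLossAndGradients:
    def test_zero_at_perfect_fit(self):
        x = np.ones((2, 3))
        code = LatentCode(np.zeros((2, 2)), np.zeros((2, 2)))
        assert vae_total_loss(x, x, code, a=5.0) == 0.0

    def test_sum_of_components_bit_exact(self, rng):
        x, xhat = rng.normal(size=(4, 5)), rng.normal(size=(4, 5))
        code = LatentCode(rng.normal(size=(4, 2)), rng.normal(size=(4, 2)))
        assert vae_total_loss(x, xhat, code, 3.0) == logcosh_loss(x, xhat, 3.0) + kl_standard_normal(code)

    def test_gradients_match_finite_differences(self, rng):
        """Central differences on a tiny VAE (5 features, latent 2)."""
        from survfuse.vae import _init_params

        params = _init_params(5, [4], 2, rng)
        x = rng.normal(size=(6, 5))
        eps = rng.standard_normal((6, 2))
        a = 3.0
        _, grads, _ = loss_and_grads(params, x, eps, a)
        h = 1e-6
        worst = 0.0
        for key in params:
            flat = params[key].reshape(-1)
            for idx in range(flat.size):
                orig = flat[idx]
                flat[idx] = orig + h
                lp, _, _ = loss_and_grads(params, x, eps, a)
                flat[idx] = orig - h
                lm, _, _ = loss_and_grads(params, x, eps, a)
                flat[idx] = orig
                numeric = (lp - lm) / (2 * h)
                analytic = grads[key].reshape(-1)[idx]
                denom = max(abs(numeric), abs(analytic), 1e-8)
                worst = max(worst, abs(numeric - analytic) / denom)
        assert worst < 1e-4


class TestTraining:
    @pytest.fixture(scope="class")
    def planted(self):
        # an exact linear image of a 3-d source; 100 features so the summed
        # reconstruction term outweighs the KL and the latent space is used
        rng = np.random.default_rng(0)
        source = np.random.default_rng(1).normal(size=(200, 3))
        W = rng.normal(size=(3, 100))
        X = source @ W + 0.01 * rng.normal(size=(200, 100))
        return make_matrix(X)

    @pytest.fixture(scope="class")
    def model(self, planted):
        cfg = VAEConfig(latent_dim=3, hidden_widths=[32], epochs=200, batch_size=32,
                        patience=40, seed=9, learning_rate=3e-3)
        return fit_vae(planted, cfg)

    def test_smoothed_loss_decreases_to_convergence(self, model):
        total = np.array(model.history["total"])
        smooth = np.convolve(total, np.ones(5) / 5, mode="valid")
        assert smooth[-1] < smooth[0]
        # no sustained blow-up: every value within 10% of the running best
        running_best = np.minimum.accumulate(smooth)
        assert (smooth <= running_best * 1.1 + 0.05).all()

    def test_planted_structure_reconstructed(self, planted, model):
        recon = reconstruct(model, planted)
        resid = planted.values - recon
        assert resid.var() / planted.values.var() < 0.1

    def test_same_seed_identical_history(self, planted):
        cfg = VAEConfig(latent_dim=3, hidden_widths=[8], epochs=10, seed=4)
        h1 = fit_vae(planted, cfg).history["total"]
        h2 = fit_vae(planted, cfg).history["total"]
        assert h1 == h2

    def test_encode_is_deterministic_posterior_mean(self, planted, model):
        z1, z2 = encode(model, planted), encode(model, planted)
        assert np.array_equal(z1, z2)
        assert z1.shape == (200, 3)

    def test_latent_widths_per_modality(self):
        assert default_vae_config("cln").latent_dim == 4
        for tag in ("cnv", "dna", "mir", "mrna", "wsi"):
            assert default_vae_config(tag).latent_dim == 32

    def test_encoder_heads_give_mu_and_logvar(self, model):
        # encoder output parametrizes both mu and log-variance heads
        assert model.params["mu_W"].shape == model.params["lv_W"].shape

    def test_missing_values_rejected(self):
        bad = make_matrix(np.array([[1.0, np.nan], [0.0, 1.0]]))
        with pytest.raises(ValidationError, match="missing"):
            fit_vae(bad, VAEConfig(latent_dim=1, epochs=1))

    def test_latent_probe_beats_chance(self, tiny_cohort):
        """On planted-signal data the posterior means separate the classes."""
        from sklearn.linear_model import LogisticRegression

        m = tiny_cohort.modalities["mrna"]
        from survfuse import impute_weighted_knn

        m = impute_weighted_knn(m, k=5)
        cfg = VAEConfig(latent_dim=8, hidden_widths=[32], epochs=60, seed=2)
        model = fit_vae(m, cfg)
        z = encode(model, m)
        truth_ids = {p: l for p, l in zip(tiny_cohort.truth["patient_ids"], tiny_cohort.truth["labels"])}
        y = np.array([truth_ids[p] for p in m.patient_ids])
        half = len(y) // 2
        probe = LogisticRegression(max_iter=1000).fit(z[:half], y[:half])
        assert probe.score(z[half:], y[half:]) > max(y.mean(), 1 - y.mean())
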