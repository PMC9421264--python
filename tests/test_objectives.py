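"""Objectives: ELBO, IW-ELBO, importance weights, DReG gradients."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp
from scipy import integrate, stats

from mirtvae.encoder import init_encoder, reparameterize
from mirtvae.model import ItemParameters, unconstrain
from mirtvae.objectives import (
    dreg_posterior_gradients,
    elbo_step,
    iw_elbo,
    iw_elbo_step,
    log_importance_weights,
    log_mean_exp,
    naive_posterior_gradients,
    normalized_weights,
)


class TestLogMeanExp:
    def test_single_sample_is_identity(self, rng):
        v = rng.standard_normal((3, 2, 1))
        np.testing.assert_array_equal(log_mean_exp(v, axis=-1), v[..., 0])

    def test_constant_weights_return_the_constant(self):
        v = np.full((1, 1, 7), -3.25)
        assert log_mean_exp(v)[0, 0] == pytest.approx(-3.25)

    def test_two_point_hand_case(self):
        # log((1 + 3) / 2) = log 2
        v = np.array([[[0.0, np.log(3.0)]]])
        assert log_mean_exp(v)[0, 0] == pytest.approx(np.log(2.0))

    def test_matches_naive_path_in_safe_range(self, rng):
        v = rng.uniform(-29, 29, (4, 3, 8))
        naive = np.log(np.exp(v).mean(axis=-1))
        np.testing.assert_allclose(log_mean_exp(v), naive, atol=1e-12)

    def test_stable_for_huge_spreads(self):
        v = np.array([[[-1000.0, 1000.0]]])
        assert log_mean_exp(v)[0, 0] == pytest.approx(1000.0 - np.log(2.0))


class TestNormalizedWeights:
    def test_equal_logs_give_uniform(self):
        w = normalized_weights(np.zeros((2, 1, 5)))
        np.testing.assert_allclose(w, 0.2)

    def test_softmax_hand_case(self):
        w = normalized_weights(np.array([[[0.0, np.log(9.0)]]]))
        np.testing.assert_allclose(w[0, 0], [0.1, 0.9], atol=1e-12)

    def test_shift_invariant_and_simplex(self, rng):
        v = rng.standard_normal((3, 2, 6))
        w = normalized_weights(v)
        np.testing.assert_allclose(w, normalized_weights(v + 123.4), atol=1e-12)
        np.testing.assert_allclose(w.sum(axis=-1), 1.0, atol=1e-12)
        assert w.min() >= 0

    def test_stable_for_huge_spreads(self):
        w = normalized_weights(np.array([[[-1000.0, 0.0, 1000.0]]]))
        np.testing.assert_allclose(w[0, 0], [0.0, 0.0, 1.0], atol=1e-12)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(hnp.arrays(np.float64, (2, 1, 6),
                      elements=st.floats(-50, 50, allow_nan=False)))
    def test_simplex_and_bound_properties_hold_generally(self, v):
        w = normalized_weights(v)
        np.testing.assert_allclose(w.sum(axis=-1), 1.0, atol=1e-12)
        assert w.min() >= 0.0
        # log-mean-exp lies between min and max of the log weights
        lme = log_mean_exp(v)
        assert np.all(lme >= v.min(axis=-1) - 1e-12)
        assert np.all(lme <= v.max(axis=-1) + 1e-12)


class TestLogWeights:
    def test_flat_likelihood_prior_posterior_cancel(self, rng):
        # with q equal to the prior and likelihood identically 1, v = 0
        mu = np.zeros((2, 3))
        logvar = np.zeros((2, 3))
        theta, e = reparameterize(mu, logvar, 2, 4, rng)
        v = log_importance_weights(np.zeros((2, 2, 4)), theta, logvar, e)
        np.testing.assert_allclose(v, 0.0, atol=1e-12)

    def test_log_q_at_the_posterior_mean(self):
        logvar = np.array([[0.6, -0.2]])
        mu = np.array([[0.5, -1.0]])
        theta = mu[:, None, None, :]
        e = np.zeros((1, 1, 1, 2))
        v = log_importance_weights(np.zeros((1, 1, 1)), theta, logvar, e)
        log_q = -0.5 * (2 * np.log(2 * np.pi) + logvar.sum())
        log_p = stats.multivariate_normal(np.zeros(2), np.eye(2)).logpdf(mu)
        assert v[0, 0, 0] == pytest.approx(log_p - log_q)

    def test_exponentials_match_direct_ratio(self, rng):
        mu = 0.2 * rng.standard_normal((2, 2))
        logvar = 0.2 * rng.standard_normal((2, 2))
        theta, e = reparameterize(mu, logvar, 1, 3, rng)
        ll = -rng.random((2, 1, 3))
        v = log_importance_weights(ll, theta, logvar, e)
        q = np.exp(-0.5 * (2 * np.log(2 * np.pi) + logvar.sum(-1)[:, None, None]
                           + (e ** 2).sum(-1)))
        prior = np.exp(-0.5 * (2 * np.log(2 * np.pi) + (theta ** 2).sum(-1)))
        np.testing.assert_allclose(np.exp(v), np.exp(ll) * prior / q, rtol=1e-10)


def _toy_problem(rng):
    y = (rng.random((3, 4)) < 0.5).astype(float)
    mask = np.ones((3, 4))
    mask[0, 1] = 0.0
    state = init_encoder(4, 2, (5,), rng)
    state.w_logvar = 0.1 * rng.standard_normal(state.w_logvar.shape)
    params = ItemParameters(
        rng.standard_normal((4, 2)), rng.standard_normal(4),
        rng.standard_normal(4), rng.standard_normal(4), "4pl")
    return y, mask, state, params


class TestStepObjectives:
    def test_iw_elbo_with_one_importance_sample_equals_elbo_path(self, rng):
        # shared theta draws: logmeanexp over R=1 collapses to the plain
        # single-sample estimate of log p(y,theta) - log q
        y, mask, state, params = _toy_problem(rng)
        v1, _, _ = iw_elbo_step(y, mask, state, params, 3, 1, np.random.default_rng(0))
        from mirtvae.encoder import encoder_forward
        from mirtvae.model import masked_loglik
        mu, logvar, _ = encoder_forward(y * mask, state)
        theta, e = reparameterize(mu, logvar, 3, 1, np.random.default_rng(0))
        ll = masked_loglik(y, mask, theta, params)
        v = log_importance_weights(ll, theta, logvar, e)
        assert v1 == pytest.approx(float(v.mean()), abs=1e-12)

    def test_kl_weight_zero_is_pure_reconstruction(self, rng):
        y, mask, state, params = _toy_problem(rng)
        from mirtvae.encoder import encoder_forward
        from mirtvae.model import masked_loglik
        val, _, _ = elbo_step(y, mask, state, params, 2, 0.0, np.random.default_rng(1))
        mu, logvar, _ = encoder_forward(y * mask, state)
        theta, _ = reparameterize(mu, logvar, 2, 1, np.random.default_rng(1))
        ll = masked_loglik(y, mask, theta, params)
        assert val == pytest.approx(float(ll.mean()), abs=1e-12)

    def test_elbo_variance_shrinks_with_more_mc_samples(self, rng):
        y, mask, state, params = _toy_problem(rng)
        def spread(s):
            vals = [elbo_step(y, mask, state, params, s, 1.0,
                              np.random.default_rng(100 + i))[0] for i in range(40)]
            return np.var(vals)
        assert spread(16) < spread(1)

    def test_masked_cells_do_not_touch_gradients(self, rng):
        y, mask, state, params = _toy_problem(rng)
        v1, eg1, pg1 = elbo_step(y, mask, state, params, 2, 1.0, np.random.default_rng(3))
        y2 = y.copy()
        y2[mask == 0.0] = 1.0  # perturb placeholders only
        v2, eg2, pg2 = elbo_step(y2, mask, state, params, 2, 1.0, np.random.default_rng(3))
        assert v1 == v2
        assert np.array_equal(pg1["loadings"], pg2["loadings"])
        assert np.array_equal(eg1.weights[0], eg2.weights[0])

    @pytest.mark.parametrize("which", ["elbo", "iw"])
    def test_gradients_match_finite_differences(self, rng, which):
        y, mask, state, params = _toy_problem(rng)

        def value():
            r = np.random.default_rng(7)
            if which == "elbo":
                return elbo_step(y, mask, state, params, 2, 0.7, r)[0]
            return iw_elbo_step(y, mask, state, params, 2, 3, r)[0]

        _, eg, pg = (elbo_step(y, mask, state, params, 2, 0.7, np.random.default_rng(7))
                     if which == "elbo" else
                     iw_elbo_step(y, mask, state, params, 2, 3, np.random.default_rng(7)))
        targets = [
            (params.loadings, pg["loadings"], (1, 0)),
            (params.intercepts, pg["intercepts"], (2,)),
            (params.guessing_raw, pg["guessing_raw"], (0,)),
            (params.upper_raw, pg["upper_raw"], (3,)),
        ]
        if which == "elbo":
            # the analytic-KL ELBO gradient is exact per draw for the
            # encoder too; the IW encoder gradient is DReG (unbiased but
            # not the per-draw derivative), checked separately on the toy
            targets += [
                (state.weights[0], eg.weights[0], (0, 1)),
                (state.w_mu, eg.w_mu, (0, 2)),
                (state.w_logvar, eg.w_logvar, (1, 3)),
                (state.b_logvar, eg.b_logvar, (0,)),
            ]
        h = 1e-6
        for arr, g, idx in targets:
            old = arr[idx]
            arr[idx] = old + h; up = value()
            arr[idx] = old - h; dn = value()
            arr[idx] = old
            assert (up - dn) / (2 * h) == pytest.approx(g[idx], rel=1e-4, abs=1e-9)


def _conjugate_toy(m, r, seed, mu=0.4, logvar=0.3, y0=1.3):
    """1-D Gaussian likelihood + Gaussian posterior pieces on m paired draws."""
    rng = np.random.default_rng(seed)
    sigma = np.exp(0.5 * logvar)
    e = rng.standard_normal((m, 1, r))
    theta = mu + sigma * e
    ll = -0.5 * (np.log(2 * np.pi) + (y0 - theta) ** 2)
    lp = -0.5 * (np.log(2 * np.pi) + theta ** 2)
    lq = -0.5 * (np.log(2 * np.pi) + logvar + e ** 2)
    v = ll + lp - lq
    dll = y0 - theta
    dlp = -theta
    return v, dll, dlp, e, theta, sigma


class TestDReG:
    def test_r1_collapse_is_pathwise_gradient(self):
        v, dll, dlp, e, theta, sigma = _conjugate_toy(100, 1, 0)
        dv = (dll + dlp + e / sigma)[..., None]
        sig = np.full((100, 1), sigma)
        g_mu, _ = dreg_posterior_gradients(v, dv, e[..., None], sig)
        np.testing.assert_allclose(g_mu[:, 0], dv[:, 0, 0, 0], atol=1e-12)

    def test_unbiased_against_common_random_number_oracle(self):
        # gradient of the R=5 IW-ELBO in (mu, logvar) by central differences
        # on a large paired sample; DReG mean must agree within 3 SE
        m, r = 100_000, 5
        mu, logvar = 0.4, 0.3
        v, dll, dlp, e, theta, sigma = _conjugate_toy(m, r, 42)
        dv = (dll + dlp + e / sigma)[..., None]
        sig = np.full((m, 1), sigma)
        g_mu, g_lv = dreg_posterior_gradients(v, dv, e[..., None], sig)
        h = 1e-4

        def iwe(mu_, lv_):
            rng = np.random.default_rng(42)
            s = np.exp(0.5 * lv_)
            ee = rng.standard_normal((m, 1, r))
            th = mu_ + s * ee
            vv = (-0.5 * (np.log(2 * np.pi) + (1.3 - th) ** 2)
                  - 0.5 * (np.log(2 * np.pi) + th ** 2)
                  + 0.5 * (np.log(2 * np.pi) + lv_ + ee ** 2))
            return log_mean_exp(vv, axis=-1).mean()

        fd_mu = (iwe(mu + h, logvar) - iwe(mu - h, logvar)) / (2 * h)
        fd_lv = (iwe(mu, logvar + h) - iwe(mu, logvar - h)) / (2 * h)
        for g, fd in [(g_mu, fd_mu), (g_lv, fd_lv)]:
            se = g.std() / np.sqrt(m)
            assert abs(g.mean() - fd) < 3 * se

    def test_lower_variance_than_naive_weighting(self):
        m, r = 50_000, 5
        v, dll, dlp, e, theta, sigma = _conjugate_toy(m, r, 7)
        sig = np.full((m, 1), sigma)
        dv = (dll + dlp + e / sigma)[..., None]
        g_mu_d, g_lv_d = dreg_posterior_gradients(v, dv, e[..., None], sig)
        g_mu_n, g_lv_n = naive_posterior_gradients(
            v, (dll + dlp)[..., None], e[..., None], sig)
        assert g_mu_d.var() < g_mu_n.var()
        assert g_lv_d.var() < g_lv_n.var()


class TestBoundProperties:
    def test_iw_elbo_nondecreasing_in_r(self):
        # Burda property on >= 1e4 paired draws: more importance samples
        # tighten the bound
        v, *_ = _conjugate_toy(20_000, 25, 3)
        means = [log_mean_exp(v[:, :, :r], axis=-1).mean() for r in (1, 5, 25)]
        assert means[0] < means[1] < means[2]

    def test_iw_elbo_below_marginal_loglik(self, rng):
        # 1-factor 2-item model whose marginal is computable by quadrature
        params = ItemParameters(
            np.array([[1.0], [0.7]]), np.array([0.2, -0.3]),
            unconstrain(np.array([0.1, 0.2])), model="3pl")
        y = np.array([[1.0, 0.0]])
        mask = np.ones((1, 2))
        from mirtvae.model import irf, masked_loglik

        def integrand(t):
            p = irf(np.array([[t]]), params)[0]
            return p[0] * (1 - p[1]) * stats.norm.pdf(t)

        marginal = np.log(integrate.quad(integrand, -10, 10)[0])
        mu = np.array([[0.3]])
        logvar = np.array([[-0.1]])
        theta, e = reparameterize(mu, logvar, 1, 20_000, rng)
        ll = masked_loglik(y, mask, theta, params)
        v = log_importance_weights(ll, theta, logvar, e)
        assert iw_elbo(v) <= marginal + 1e-3
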