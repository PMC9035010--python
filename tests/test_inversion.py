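"""Generalized coordinates, free energy, and variational inversion."""

import numpy as np
import pytest

from anisofield.exceptions import UnidentifiableDataError
from anisofield.inversion import (
    InversionOptions,
    PosteriorReport,
    PriorSpec,
    _Q,
    _optimize_logprec,
    free_energy,
    generalized_embed,
    invert,
    predict_response,
)
from anisofield.simulator import FieldState, SimulationConfig, integrate, observe

_LOG2PI = np.log(2 * np.pi)


class TestGeneralizedEmbed:
    def test_constant_series_has_zero_derivatives(self):
        emb = generalized_embed(np.full(100, 3.0), order=4, smoothness=0.1, dt=0.01)
        assert np.allclose(emb.coeffs[:, 1:], 0.0, atol=1e-6)
        assert np.allclose(emb.coeffs[:, 0], 3.0)

    def test_linear_series_first_derivative(self):
        t = np.arange(200) * 0.01
        emb = generalized_embed(2.5 * t, order=4, smoothness=0.1, dt=0.01)
        assert np.allclose(emb.coeffs[10:-10, 1], 2.5, atol=1e-6)

    def test_sine_second_derivative(self):
        t = np.arange(0, 6, 0.01)
        emb = generalized_embed(np.sin(t), order=4, smoothness=0.02, dt=0.01)
        interior = slice(20, -20)
        assert np.max(np.abs(emb.coeffs[interior, 2] + np.sin(t)[interior])) < 1e-3

    def test_series_too_short(self):
        with pytest.raises(ValueError):
            generalized_embed([1.0, 2.0], order=4)


def _scalar_q(mean, var, prior_mean, prior_var, m_lam=0.0, v_lam=16.0):
    return _Q(
        param_mean=np.array([mean]),
        param_cov=np.array([[var]]),
        prior_mean=np.array([prior_mean]),
        prior_var=np.array([prior_var]),
        logprec_posteriors={"obs": (m_lam, v_lam), "state": (0.0, 16.0)},
    )


class TestFreeEnergy:
    def test_prior_posterior_with_zero_residuals_is_normalisation_only(self):
        priors = PriorSpec(logprec_obs_var=16.0)
        q = _scalar_q(0.0, 1.0, 0.0, 1.0, m_lam=0.0, v_lam=16.0)
        y = np.zeros((10, 1))
        F = free_energy(y, y, q, priors)
        assert F == pytest.approx(-0.5 * 10 * _LOG2PI)

    def test_widening_posterior_beyond_prior_decreases_f(self):
        priors = PriorSpec()
        y = np.zeros((5, 1))
        g = y + 0.1
        f_vals = [
            free_energy(y, g, _scalar_q(0.0, v, 0.0, 1.0), priors)
            for v in (1.0, 2.0, 4.0, 8.0)
        ]
        assert all(a > b for a, b in zip(f_vals, f_vals[1:]))

    def test_one_sample_scalar_closed_form(self):
        """Hand-computed Gaussian algebra for one observation."""
        y = np.array([[1.3]])
        g = np.array([[1.0]])
        m_lam, v_lam = 0.7, 0.2
        q = _scalar_q(0.4, 0.5, 0.0, 2.0, m_lam, v_lam)
        priors = PriorSpec(
            logprec_obs_mean=0.0, logprec_obs_var=4.0,
            logprec_state_mean=0.0, logprec_state_var=16.0,
        )
        r = 0.3
        accuracy = -0.5 * np.exp(m_lam) * r**2 + 0.5 * m_lam - 0.5 * _LOG2PI
        kl_params = 0.5 * (0.5 / 2.0 + 0.4**2 / 2.0 - 1 + np.log(2.0 / 0.5))
        kl_lam = 0.5 * (v_lam / 4.0 + m_lam**2 / 4.0 - 1 + np.log(4.0 / v_lam))
        expected = accuracy - kl_params - kl_lam
        assert free_energy(y, g, q, priors) == pytest.approx(expected, rel=1e-12)

    def test_jacobian_trace_term_lowers_f(self):
        priors = PriorSpec()
        y = np.zeros((5, 1))
        q = _scalar_q(0.0, 0.5, 0.0, 1.0)
        J = np.ones((5, 1))
        assert free_energy(y, y, q, priors, jac=J) < free_energy(y, y, q, priors)

    def test_nonfinite_inputs_rejected(self):
        priors = PriorSpec()
        q = _scalar_q(0.0, 1.0, 0.0, 1.0)
        y = np.zeros((3, 1))
        bad = y.copy()
        bad[0] = np.nan
        with pytest.raises(ValueError):
            free_energy(y, bad, q, priors)


class TestLogPrecisionStep:
    def test_newton_matches_grid_search(self):
        gauss_sq, n_obs, mu0, v0 = 3.7, 500, 0.0, 16.0
        m_opt, v_opt = _optimize_logprec(gauss_sq, n_obs, mu0, v0, 0.0)
        grid = np.linspace(m_opt - 2, m_opt + 2, 20001)
        f = 0.5 * n_obs * grid - 0.5 * np.exp(grid) * gauss_sq - (grid - mu0) ** 2 / (2 * v0)
        assert abs(grid[np.argmax(f)] - m_opt) < 1e-3
        assert v_opt > 0

    def test_precision_grows_as_residuals_shrink(self):
        ms = [
            _optimize_logprec(sq, 500, 0.0, 16.0, 0.0)[0]
            for sq in (10.0, 1.0, 0.1, 0.01)
        ]
        assert all(a < b for a, b in zip(ms, ms[1:]))


class TestPredictResponse:
    def _setup(self):
        rng = np.random.default_rng(4)
        init = FieldState(rng.uniform(1, 2, (3, 3)), rng.uniform(1, 2, (3, 3)))
        cfg = SimulationConfig(beta=-1.0, n_steps=60)
        return init, cfg

    def test_matches_noiseless_observation(self):
        init, cfg = self._setup()
        pred = predict_response(-1.0, init, cfg)
        ref = observe(integrate(init, cfg), 0.0, 0)
        assert pred.equals(ref)

    def test_smooth_in_beta(self):
        init, cfg = self._setup()
        a = predict_response(-1.0, init, cfg).iloc[:, 1:].to_numpy()
        b = predict_response(-1.0 + 1e-6, init, cfg).iloc[:, 1:].to_numpy()
        assert np.isfinite(b).all()
        assert np.max(np.abs(a - b)) < 1e-3

    def test_beta_jacobian_against_richardson_oracle(self):
        init, cfg = self._setup()

        def g(beta):
            return predict_response(beta, init, cfg).iloc[:, 1:].to_numpy()

        h = 1e-4
        central = (g(-1.0 + h) - g(-1.0 - h)) / (2 * h)
        half = (g(-1.0 + h / 2) - g(-1.0 - h / 2)) / h
        richardson = (4 * half - central) / 3.0
        scale = np.max(np.abs(richardson))
        assert np.max(np.abs(central - richardson)) / scale < 1e-4


def _make_dataset(truth, seed, n_steps=200, noise=0.05):
    rng = np.random.default_rng(seed)
    init = FieldState(rng.uniform(1, 2, (3, 3)), rng.uniform(1, 2, (3, 3)))
    cfg = SimulationConfig(beta=truth, n_steps=n_steps, obs_noise_sd=noise)
    df = observe(integrate(init, cfg), noise, 500 + seed)
    return df, cfg, init


class TestInvert:
    def test_recovers_isotropic_truth(self, replica_battery):
        rep = replica_battery[1]["isotropic"].full
        assert abs(rep.beta_mean) < 0.5
        assert abs(rep.beta_mean) <= 3 * np.sqrt(rep.beta_var)
        assert np.all(np.diff(rep.f_trace) >= -1e-6)

    def test_recovers_anisotropic_truth_within_3sd(self, replica_battery):
        rep = replica_battery[1]["anisotropic"].full
        assert rep.beta_mean < -1.5
        assert abs(rep.beta_mean - (-3.0)) <= 3 * np.sqrt(rep.beta_var)
        assert np.all(np.diff(rep.f_trace) >= -1e-6)

    def test_noisier_data_move_posterior_toward_prior(self):
        """As observation noise grows the beta posterior relaxes to its
        prior: the KL divergence to the prior decreases and the posterior
        widens. (The full asymptote is unreachable here: the latent field
        must stay positive, which bounds the admissible noise.)"""
        prior = PriorSpec()

        def kl_to_prior(noise):
            df, cfg, _ = _make_dataset(0.0, seed=2, n_steps=40, noise=noise)
            rep = invert(df, cfg)
            kl = 0.5 * (
                rep.beta_var / prior.beta_var
                + (rep.beta_mean - prior.beta_mean) ** 2 / prior.beta_var
                - 1.0
                + np.log(prior.beta_var / max(rep.beta_var, 1e-300))
            )
            return kl, rep.beta_var

        kl_low, var_low = kl_to_prior(0.1)
        kl_high, var_high = kl_to_prior(1.0)
        assert kl_high < kl_low
        assert var_high > var_low

    def test_more_data_does_not_widen_posterior(self):
        short_vars, long_vars = [], []
        for seed in (3, 4, 5):
            df_s, cfg_s, _ = _make_dataset(0.0, seed=seed, n_steps=80)
            df_l, cfg_l, _ = _make_dataset(0.0, seed=seed, n_steps=160)
            short_vars.append(invert(df_s, cfg_s).beta_var)
            long_vars.append(invert(df_l, cfg_l).beta_var)
        assert np.median(long_vars) <= np.median(short_vars)

    def test_constant_data_unidentifiable(self):
        import pandas as pd

        cols = {"time": np.arange(50) * 0.05}
        for x in range(3):
            for y in range(3):
                cols[f"node_{x}_{y}"] = np.full(50, 1.5)
        with pytest.raises(UnidentifiableDataError):
            invert(pd.DataFrame(cols), SimulationConfig(beta=None))

    def test_clamped_run_reports_fixed_beta(self):
        df, cfg, _ = _make_dataset(0.0, seed=6, n_steps=80)
        rep = invert(df, cfg, priors=PriorSpec().with_reduced_beta(0.0))
        assert rep.beta_mean == 0.0
        assert rep.beta_var == 0.0
        assert rep.beta_index is None
        assert "beta" not in rep.param_names

    def test_report_serialises_to_json(self):
        import json

        df, cfg, _ = _make_dataset(0.0, seed=7, n_steps=60)
        rep = invert(df, cfg)
        payload = json.dumps(rep.to_dict())
        assert "beta_mean" in payload
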