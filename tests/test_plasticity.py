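"""Unit and property tests for the synaptic-sampling plasticity rule."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sporesim.config import SporeConfig
from sporesim.plasticity import (
    AnnealSchedule,
    SynapseGroup,
    SynapseState,
    anneal_learning_rate,
    init_parameters,
    parameter_to_weight,
    update_eligibility,
    update_parameter,
    update_psp_trace,
    update_reward_gradient,
)


@pytest.fixture
def cfg():
    return SporeConfig()


def norm_cdf(x):
    return 0.5 * (1.0 + math.erf(x / math.sqrt(2.0)))


class TestPspTrace:
    @pytest.mark.parametrize("y, spike, expected", [
        (1.0, False, 0.95),  # Euler decay 1 - dt/tau_psp with tau_psp = 20 ms
        (0.0, False, 0.0),
        (0.0, True, 1.0),
        (0.5, True, 1.475),  # decay plus unit jump
        (0.0, 3, 3.0),  # several events in one step accumulate
    ])
    def test_single_step(self, cfg, y, spike, expected):
        assert update_psp_trace(y, spike, cfg) == pytest.approx(expected, abs=1e-12)

    def test_rejects_negative_trace(self, cfg):
        with pytest.raises(ValueError):
            update_psp_trace(-0.1, False, cfg)


class TestEligibility:
    def test_spike_coincidence_step(self, cfg):
        # decay -0.0001, then w*y*(1 - rho*dt) = 0.5*0.99
        s = SynapseState(y=0.5, e=0.2, w=1.0)
        out = update_eligibility(s, post_spike=True, rho_post=10.0, cfg=cfg)
        assert out.e == pytest.approx(0.6949, abs=1e-9)

    def test_pure_decay_step(self, cfg):
        s = SynapseState(y=0.0, e=1.0, w=1.0)
        out = update_eligibility(s, post_spike=False, rho_post=0.0, cfg=cfg)
        assert out.e == pytest.approx(0.9995, abs=1e-12)

    def test_quiescent_fixed_point(self, cfg):
        s = SynapseState()
        out = update_eligibility(s, post_spike=False, rho_post=5.0, cfg=cfg)
        assert out.e == 0.0

    def test_exponential_decay_profile(self, cfg):
        # with y = 0 the Euler trace at t = tau_e matches exp(-1) within 1e-3
        s = SynapseState(e=1.0)
        n = int(round(cfg.tau_e / cfg.dt_fast))
        for _ in range(n):
            s = update_eligibility(s, False, 0.0, cfg)
        assert s.e == pytest.approx(math.exp(-1.0), rel=1e-3)

    def test_rejects_negative_rate(self, cfg):
        with pytest.raises(ValueError):
            update_eligibility(SynapseState(), False, -1.0, cfg)


class TestRewardGradient:
    def test_single_step(self, cfg):
        s = SynapseState(e=0.2)
        out = update_reward_gradient(s, 0.5, cfg)
        assert out.g == pytest.approx(1.0e-4, rel=1e-12)

    def test_zero_fixed_point(self, cfg):
        assert update_reward_gradient(SynapseState(), 0.0, cfg).g == 0.0

    def test_fixed_point_is_tau_g_times_drive(self):
        # holding r*e constant, g converges to the fixed point tau_g * r * e
        cfg = SporeConfig(tau_g=0.5)
        s = SynapseState(e=0.2)
        for _ in range(int(10 * cfg.tau_g / cfg.dt_fast)):
            s = update_reward_gradient(s, 0.5, cfg)
        assert s.g == pytest.approx(cfg.tau_g * 0.5 * 0.2, rel=1e-3)

    def test_rejects_negative_reward(self, cfg):
        with pytest.raises(ValueError):
            update_reward_gradient(SynapseState(), -0.1, cfg)


class TestParameterUpdate:
    def test_prior_mean_is_drift_fixed_point(self):
        cfg = SporeConfig(c_p=1.0, mu=0.3, temperature=0.0)
        s = SynapseState(theta=0.3, g=0.0)
        out = update_parameter(s, beta=0.01, noise=0.0, cfg=cfg)
        assert out.theta == pytest.approx(0.3)

    def test_drift_only_step(self):
        cfg = SporeConfig(c_p=1.0, c_g=1.0, mu=0.0, temperature=0.0, dtheta_max=5.0)
        s = SynapseState(theta=1.0, g=2.0)
        out = update_parameter(s, beta=0.01, noise=0.0, cfg=cfg)
        assert out.theta == pytest.approx(1.001, abs=1e-12)

    def test_gradient_clipped_at_read_time(self):
        cfg = SporeConfig(c_p=0.0, temperature=0.0, dtheta_max=1.0)
        s = SynapseState(theta=0.0, g=100.0)
        out = update_parameter(s, beta=0.01, noise=0.0, cfg=cfg)
        # effective gradient is 1, not 100, and the stored g is untouched
        assert out.theta == pytest.approx(0.01 * 1.0 * 0.1)
        assert out.g == 100.0

    def test_clipping_at_bounds(self):
        cfg = SporeConfig(temperature=0.0, c_p=0.0, dtheta_max=100.0)
        s = SynapseState(theta=4.99, g=50.0)
        out = update_parameter(s, beta=1.0, noise=0.0, cfg=cfg)
        assert out.theta == cfg.theta_max == 5.0

    def test_weight_reprojected_after_update(self, cfg):
        s = SynapseState(theta=1.0, w=parameter_to_weight(1.0, cfg))
        out = update_parameter(s, beta=0.0, noise=0.0, cfg=cfg)
        assert out.w == parameter_to_weight(out.theta, cfg)

    def test_rejects_non_finite_noise(self, cfg):
        with pytest.raises(ValueError):
            update_parameter(SynapseState(), 0.01, float("nan"), cfg)


class TestProjection:
    @pytest.mark.parametrize("theta, expected", [
        (-0.5, 0.0),  # retracted branch
        (0.0, 0.0),  # boundary belongs to the retracted branch
        (math.log(2.0), 2.0),  # w0 * exp(theta - theta0) with defaults
    ])
    def test_values(self, cfg, theta, expected):
        assert parameter_to_weight(theta, cfg) == pytest.approx(expected)

    def test_offset_maps_to_scale(self):
        cfg = SporeConfig(w0=0.7, theta0=1.5)
        assert parameter_to_weight(1.5, cfg) == pytest.approx(0.7)

    @settings(max_examples=200, derandomize=True)
    @given(st.floats(-10, 10), st.floats(-10, 10))
    def test_monotone_and_zero_below_zero(self, t1, t2):
        cfg = SporeConfig()
        lo, hi = sorted((t1, t2))
        assert parameter_to_weight(lo, cfg) <= parameter_to_weight(hi, cfg)
        if hi <= 0:
            assert parameter_to_weight(hi, cfg) == 0.0


class TestAnnealing:
    def test_published_three_hour_ratio(self, cfg):
        # lambda = 8.5e-5 /s in 600 s steps: after 3 h beta is 40% of beta0
        sched = anneal_learning_rate(AnnealSchedule(beta=1.0), 10_800.0, cfg)
        assert round(100 * sched.beta) == 40

    def test_single_interval(self, cfg):
        sched = anneal_learning_rate(AnnealSchedule(beta=1.0), 600.0, cfg)
        assert sched.beta == pytest.approx(math.exp(-8.5e-5 * 600), abs=1e-6)
        assert sched.beta == pytest.approx(0.9503, abs=1e-4)

    def test_no_decay_when_lambda_zero(self):
        cfg = SporeConfig(lambda_decay=0.0)
        sched = anneal_learning_rate(AnnealSchedule(beta=2.5), 1e6, cfg)
        assert sched.beta == 2.5

    def test_piecewise_constant_between_boundaries(self, cfg):
        s0 = AnnealSchedule(beta=1.0)
        s1 = anneal_learning_rate(s0, 599.9, cfg)
        assert s1.beta == 1.0
        s2 = anneal_learning_rate(s1, 600.0, cfg)
        assert s2.beta < 1.0

    def test_closed_form_and_monotone_under_incremental_updates(self, cfg):
        sched = AnnealSchedule(beta=1.0)
        betas = []
        for k in range(1, 40):
            sched = anneal_learning_rate(sched, k * 100.0, cfg)
            betas.append(sched.beta)
            expected = math.exp(-cfg.lambda_decay * 600.0 * ((k * 100.0) // 600.0))
            assert sched.beta == pytest.approx(expected, rel=1e-12)
        assert all(b1 >= b2 for b1, b2 in zip(betas, betas[1:]))

    def test_time_cannot_run_backwards(self, cfg):
        with pytest.raises(ValueError):
            anneal_learning_rate(AnnealSchedule(beta=1.0, t_last_update=100.0), 50.0, cfg)


class TestInitialization:
    def test_statistics_match_clipped_gaussian(self, cfg):
        n = 100_000
        states = init_parameters(n, rng_seed=123, cfg=cfg)
        theta = np.array([s.theta for s in states])
        # oracle: E[max(X, 0)] for X ~ N(0.8, 0.6)
        z = cfg.init_mean / cfg.init_sd
        exp_mean = cfg.init_mean * norm_cdf(z) + cfg.init_sd * math.exp(-z * z / 2) / math.sqrt(2 * math.pi)
        assert theta.mean() == pytest.approx(exp_mean, abs=3 * cfg.init_sd / math.sqrt(n))
        assert theta.min() >= 0.0
        # clipped-at-zero mass matches the Gaussian left tail
        assert (theta == 0).mean() == pytest.approx(norm_cdf(-z), abs=0.005)

    def test_traces_start_quiescent_and_weights_projected(self, cfg):
        (s,) = init_parameters(1, rng_seed=7, cfg=cfg)
        assert (s.y, s.e, s.g) == (0.0, 0.0, 0.0)
        assert s.w == parameter_to_weight(s.theta, cfg)

    def test_reproducible(self, cfg):
        a = init_parameters(10, rng_seed=42, cfg=cfg)
        b = init_parameters(10, rng_seed=42, cfg=cfg)
        assert [s.theta for s in a] == [s.theta for s in b]

    def test_rejects_invalid_count(self, cfg):
        with pytest.raises(ValueError):
            init_parameters(0, rng_seed=1, cfg=cfg)


class TestSynapseGroup:
    def test_matches_scalar_ops(self, cfg):
        """The vectorized group reproduces the per-synapse reference ops."""
        rng = np.random.default_rng(5)
        group = SynapseGroup.initialized(4, rng, cfg)
        states = [SynapseState(theta=t, w=w) for t, w in zip(group.theta, group.w)]
        y = rng.random(4)
        r = 0.7
        for k in range(50):
            spike = bool(k % 7 == 0)
            rho = 20.0
            group.fast_step(y, spike, rho, r)
            for i, s in enumerate(states):
                s.y = y[i]
                states[i] = update_reward_gradient(
                    update_eligibility(s, spike, rho, cfg), r, cfg)
        np.testing.assert_allclose(group.e, [s.e for s in states], rtol=1e-12)
        np.testing.assert_allclose(group.g, [s.g for s in states], rtol=1e-12)

        noise = rng.standard_normal(4)
        group.slow_step(0.01, noise)
        for i, s in enumerate(states):
            states[i] = update_parameter(s, 0.01, noise[i], cfg)
        np.testing.assert_allclose(group.theta, [s.theta for s in states], rtol=1e-12)
        np.testing.assert_allclose(group.w, [s.w for s in states], rtol=1e-12)

    def test_flat_likelihood_is_ornstein_uhlenbeck(self):
        """Zero reward + flat drive: theta samples the prior N(mu, T/c_p)."""
        cfg = SporeConfig(c_p=1.0, temperature=0.1, mu=0.0)
        rng = np.random.default_rng(11)
        group = SynapseGroup(np.zeros(200), cfg)
        n_steps = 20_000
        keep = []
        for k in range(n_steps):
            group.slow_step(0.01, rng.standard_normal(200))
            if k > n_steps // 4 and k % 50 == 0:
                keep.append(group.theta.copy())
        theta = np.concatenate(keep)
        assert abs(theta.mean()) < 3 * math.sqrt(0.1 / len(theta) * 10)
        assert theta.var() == pytest.approx(cfg.temperature / cfg.c_p, rel=0.1)

    def test_annealing_shrinks_late_parameter_diffusion(self):
        """With reward off, an annealed learning rate freezes the sampled
        parameters late in the run, while a constant rate keeps them diffusing
        — the mechanism by which annealing retains policy improvements."""
        cfg = SporeConfig(c_p=0.0, temperature=0.1, lambda_decay=8.5e-4)
        rng = np.random.default_rng(3)
        disp = {}
        for annealed in (True, False):
            group = SynapseGroup(np.full(100, 2.0), cfg)
            sched = AnnealSchedule(beta=1e-3)
            start_late = None
            n_steps = 12_000  # 1200 s of slow updates
            for k in range(n_steps):
                group.slow_step(sched.beta, rng.standard_normal(100))
                if annealed:
                    sched = anneal_learning_rate(sched, (k + 1) * cfg.dt_slow, cfg)
                if k == 3 * n_steps // 4:
                    start_late = group.theta.copy()
            disp[annealed] = np.abs(group.theta - start_late).mean()
        assert disp[True] < disp[False]
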