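"""Bleach-chase and confocal-FRAP estimators."""

import numpy as np
import pytest

from eyedisc import (
    BleachChaseSeries,
    FrapRecoverySeries,
    bleach_chase_decay,
    decay_from_length,
    effective_radius,
    estimate_diffusion,
    gen_bleach_chase,
    gen_frap_recovery,
    half_life,
    half_recovery_time,
    kang_diffusion,
)
from eyedisc.errors import InsufficientData, InvalidArgument, NoRecovery


class TestBleachChase:
    def test_noiseless_recovery_is_exact(self):
        series = gen_bleach_chase(delta_true=1e-4, sigma=0.0)
        est = bleach_chase_decay(series)
        assert est.delta == pytest.approx(1e-4, rel=1e-8)
        assert est.r_squared == pytest.approx(1.0, abs=1e-10)

    def test_identical_series_insufficient(self):
        t = np.linspace(0, 100, 10)
        series = BleachChaseSeries(t, np.ones(10), np.ones(10))
        with pytest.raises(InsufficientData), pytest.warns(UserWarning):
            bleach_chase_decay(series)

    def test_constant_difference_flags_zero_decay(self):
        t = np.linspace(0, 1000, 10)
        series = BleachChaseSeries(t, np.ones(10), np.full(10, 0.5))
        est = bleach_chase_decay(series)
        assert est.delta == pytest.approx(0.0, abs=1e-12)
        assert est.warning is not None

    def test_noisy_coverage_of_two_sigma_interval(self):
        """With 5% multiplicative noise the truth lies within +-2 SE for at
        least 90% of seeded replicates."""
        delta0 = 1e-4
        hits = 0
        n_rep = 200
        for seed in range(n_rep):
            s = gen_bleach_chase(delta_true=delta0, sigma=0.05, seed=seed,
                                 duration=np.log(2) / delta0, n_points=25)
            est = bleach_chase_decay(s)
            if abs(est.delta - delta0) <= 2 * est.stderr:
                hits += 1
        assert hits / n_rep >= 0.90

    def test_short_movie_sampling_recovers_within_tolerance(self):
        """120-min movie sampled every 5 min (~0.4 half-lives) with 2% noise:
        recovered rate within 25% of truth for >= 80% of seeds."""
        delta0 = 6.97e-5
        ok = 0
        n_rep = 100
        for seed in range(n_rep):
            s = gen_bleach_chase(delta_true=delta0, sigma=0.02, seed=seed)
            est = bleach_chase_decay(s)
            if abs(est.delta - delta0) / delta0 <= 0.25:
                ok += 1
        assert ok / n_rep >= 0.80


class TestHalfLife:
    def test_published_value(self):
        # measured Hth degradation rate corresponds to a ~2.77 h half-life
        assert half_life(6.97e-5) == pytest.approx(2.77, abs=0.01)

    def test_one_hour(self):
        assert half_life(np.log(2) / 3600.0) == pytest.approx(1.0, rel=1e-12)

    def test_scaling_property(self):
        assert half_life(2e-4) == pytest.approx(half_life(1e-4) / 2, rel=1e-12)

    def test_invalid(self):
        with pytest.raises(InvalidArgument):
            half_life(0.0)


class TestEffectiveRadius:
    def test_self_inverse_e1(self):
        x = np.linspace(0, 30, 300)
        I = 1 - 0.8 * np.exp(-(x**2) / 36.0)
        er = effective_radius(x, I, convention="e1")
        assert er.K == pytest.approx(0.8, rel=1e-6)
        assert er.r_e == pytest.approx(6.0, rel=1e-6)

    def test_direct_route_crossing_level(self):
        """The (1 - 1/e)-depth crossing of the e1 Gaussian sits at x = r_e."""
        x = np.linspace(0, 30, 3000)
        I = 1 - 0.8 * np.exp(-(x**2) / 36.0)
        er = effective_radius(x, I, convention="e1")
        assert er.r_e_direct == pytest.approx(6.0, rel=1e-3)

    def test_kang_routes_agree(self):
        x = np.linspace(0, 40, 2000)
        I = 1 - 0.6 * np.exp(-2 * x**2 / 49.0)
        er = effective_radius(x, I, convention="kang")
        assert er.r_e == pytest.approx(7.0, rel=1e-6)
        # 0.86K half-width approximates r_e within 1%
        assert er.r_e_direct == pytest.approx(7.0, rel=0.02)

    def test_flat_profile_degenerate(self):
        x = np.linspace(0, 30, 100)
        with pytest.raises(InvalidArgument):
            effective_radius(x, np.ones(100))


class TestHalfRecovery:
    def test_linear_recovery(self):
        t = np.linspace(0, 100, 101)
        F = 0.2 + (1.0 - 0.2) * t / 100.0
        assert half_recovery_time(t, F, F0=0.2, F_inf=1.0) == pytest.approx(50.0)

    def test_exact_sample_hit(self):
        t = np.array([0.0, 10.0, 20.0, 30.0])
        F = np.array([0.0, 0.5, 0.9, 1.0])
        assert half_recovery_time(t, F, F0=0.0, F_inf=1.0) == 10.0

    def test_exponential_recovery_closed_form(self):
        tau = 30.0
        t = np.linspace(0, 300, 1201)
        F = 1.0 - 0.6 * np.exp(-t / tau)
        est = half_recovery_time(t, F, F0=0.4, F_inf=1.0)
        assert abs(est - tau * np.log(2)) < t[1] - t[0]

    def test_no_recovery(self):
        t = np.linspace(0, 100, 11)
        with pytest.raises(NoRecovery):
            half_recovery_time(t, np.full(11, 0.5), F0=0.5, F_inf=0.5)


class TestKangDiffusion:
    def test_algebra(self):
        assert kang_diffusion(2.0, 2.0, 25.0) == pytest.approx(0.04)
        r, tau = 3.0, 50.0
        assert kang_diffusion(r, r, tau) == pytest.approx(r**2 / (4 * tau))

    def test_warns_when_effective_below_nominal(self):
        with pytest.warns(UserWarning):
            kang_diffusion(5.0, 3.0, 10.0)

    def test_invalid(self):
        with pytest.raises(InvalidArgument):
            kang_diffusion(-1.0, 2.0, 10.0)


class TestDecayFromLength:
    def test_published_hh_value(self):
        # D = 0.033 um^2/s with a 7 um gradient length -> ~6.7e-4 1/s
        assert decay_from_length(0.033, 7.0) == pytest.approx(6.7e-4, rel=0.01)

    def test_roundtrip(self):
        D, lam = 0.1, 20.0
        delta = decay_from_length(D, lam)
        assert delta == pytest.approx(2.5e-4, rel=1e-12)
        assert np.sqrt(D / delta) == pytest.approx(lam, rel=1e-12)


class TestEndToEndDiffusion:
    @pytest.mark.parametrize("D_true", [0.01, 0.033, 0.1])
    def test_recovery_within_twenty_percent(self, D_true):
        duration = max(3600.0, 20 * (49.0 + 25.0) / (8 * D_true))
        s = gen_frap_recovery(D_true=D_true, r_n=5.0, K=0.6, r_e=7.0,
                              duration=duration, dt_frame=min(120.0, duration / 40))
        est = estimate_diffusion(s)
        assert abs(est.D - D_true) / D_true < 0.20

    def test_monotone_in_truth(self):
        estimates = []
        for D_true in (0.01, 0.033, 0.1):
            duration = max(3600.0, 20 * 74.0 / (8 * D_true))
            s = gen_frap_recovery(D_true=D_true, r_n=5.0, duration=duration,
                                  dt_frame=min(120.0, duration / 40))
            estimates.append(estimate_diffusion(s).D)
        assert estimates[0] < estimates[1] < estimates[2]
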