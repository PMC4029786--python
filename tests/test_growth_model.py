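import math

import numpy as np
import pytest

from phenogrow import (
    ThreePLFit,
    average_replicates,
    curve_derivatives,
    fit_3plm,
    flag_outlier_replicates,
    genotype_phase_plane,
    growth_rates,
    logistic3,
    logistic3_acceleration,
    logistic3_velocity,
    phase_plane_features,
)

# Published replicate parameters (gamma, A0, Aa) for the retained plants
WT1 = ThreePLFit(gamma=0.03823, a0=210.1, aa=53640.0)
WT3 = ThreePLFit(gamma=0.03907, a0=304.8, aa=66060.0)
CFQ2 = ThreePLFit(gamma=0.04296, a0=127.2, aa=24850.0)
CFQ3 = ThreePLFit(gamma=0.04128, a0=167.3, aa=22590.0)


class TestLogisticCurve:
    def test_initial_and_asymptotic_values(self):
        assert logistic3(0.0, 150.0, 25000.0, 0.04) == pytest.approx(150.0)
        assert logistic3(1e6, 150.0, 25000.0, 0.04) == pytest.approx(25000.0)

    def test_half_asymptote_at_inflection_time(self):
        t_star = math.log((WT1.aa - WT1.a0) / WT1.a0) / WT1.gamma
        assert WT1(t_star) == pytest.approx(WT1.aa / 2)  # 26820
        assert WT1(t_star) == pytest.approx(26820.0, rel=1e-6)

    def test_satisfies_logistic_ode(self):
        t = np.linspace(0, 300, 500)
        a = logistic3(t, WT1.a0, WT1.aa, WT1.gamma)
        lhs = logistic3_velocity(t, WT1.a0, WT1.aa, WT1.gamma)
        rhs = WT1.gamma * a * (1 - a / WT1.aa)
        assert np.allclose(lhs, rhs, rtol=1e-12)
        assert np.all(lhs >= 0)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            ThreePLFit(gamma=0.04, a0=100.0, aa=50.0)
        with pytest.raises(ValueError):
            ThreePLFit(gamma=-0.1, a0=100.0, aa=500.0)


class TestDerivatives:
    def test_velocity_max_is_quarter_gamma_aa(self):
        # maximum of dA/dt for the exact logistic is gamma*Aa/4 at A = Aa/2
        t = np.linspace(0, 400, 200001)
        v = logistic3_velocity(t, WT1.a0, WT1.aa, WT1.gamma)
        assert v.max() == pytest.approx(WT1.gamma * WT1.aa / 4, rel=1e-6)
        assert v.max() == pytest.approx(512.66, abs=0.05)

    def test_acceleration_zero_at_inflection(self):
        t_star = WT1.inflection_time
        assert logistic3_acceleration(t_star, WT1.a0, WT1.aa, WT1.gamma) == pytest.approx(
            0.0, abs=1e-9
        )

    def test_acceleration_extrema_at_analytic_areas(self):
        # d3A/dt3 = 0 where A/Aa = (3 -+ sqrt(3))/6; extreme value gamma^2*Aa/(6*sqrt(3))
        t = np.linspace(0, 400, 400001)
        a = logistic3_acceleration(t, WT1.a0, WT1.aa, WT1.gamma)
        area_at_max = logistic3(t[np.argmax(a)], WT1.a0, WT1.aa, WT1.gamma)
        assert area_at_max / WT1.aa == pytest.approx((3 - math.sqrt(3)) / 6, rel=1e-4)
        assert a.max() == pytest.approx(WT1.gamma**2 * WT1.aa / (6 * math.sqrt(3)), rel=1e-6)
        assert a.max() == pytest.approx(7.54, abs=0.02)

    def test_closed_forms_match_finite_differences(self):
        fit = WT1
        t = np.linspace(5, 350, 2000)
        v, a = curve_derivatives(fit, t)
        h = 1e-3
        v_fd = (fit(t + h) - fit(t - h)) / (2 * h)
        a_fd = (fit(t + h) - 2 * fit(t) + fit(t - h)) / h**2
        sig = np.abs(a) > 0.01 * np.abs(a).max()
        assert np.allclose(v, v_fd, rtol=1e-3)
        assert np.allclose(a[sig], a_fd[sig], rtol=1e-3)

    def test_acceleration_integrates_to_zero(self):
        t = np.linspace(-200, 500, 100001)
        a = logistic3_acceleration(t, WT1.a0, WT1.aa, WT1.gamma)
        integral = np.trapezoid(a, t)
        assert abs(integral) <= 0.001 * np.abs(a).max() * (t[-1] - t[0])


class TestFitting:
    def test_noiseless_recovery_to_six_digits(self):
        t = np.linspace(0, 250, 60)
        fit = fit_3plm(t, logistic3(t, 150.0, 25000.0, 0.04))
        assert fit.a0 == pytest.approx(150.0, rel=1e-6)
        assert fit.aa == pytest.approx(25000.0, rel=1e-6)
        assert fit.gamma == pytest.approx(0.04, rel=1e-6)
        assert fit.residual_sd == pytest.approx(0.0, abs=1e-6)
        assert fit.ci_gamma[0] <= fit.gamma <= fit.ci_gamma[1]

    def test_constant_series_rejected(self):
        with pytest.raises(RuntimeError, match="constant|unidentifiable"):
            fit_3plm(np.arange(20.0), np.full(20, 500.0))

    def test_decreasing_series_warned_and_degenerate(self):
        # a logistic cannot decrease: the series is flagged, and the
        # resulting degenerate optimum is reported rather than returned
        t = np.linspace(0, 100, 20)
        y = logistic3(t, 150.0, 25000.0, 0.05)[::-1]
        with pytest.warns(UserWarning, match="decreasing"):
            with pytest.raises(RuntimeError, match="degenerate|converge"):
                fit_3plm(t, y)

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError, match="10"):
            fit_3plm([0, 1, 2], [1.0, 2.0, 3.0])

    def test_non_finite_rejected(self):
        t = np.linspace(0, 100, 12)
        y = logistic3(t, 100.0, 5000.0, 0.05)
        y[3] = np.nan
        with pytest.raises(ValueError, match="finite"):
            fit_3plm(t, y)


class TestGrowthRates:
    def test_constant_curve_zero_rates(self):
        rates = growth_rates(lambda t: np.full_like(np.asarray(t, float), 42.0), [1, 2, 3])
        assert np.allclose(rates.agr, 0.0)
        assert np.allclose(rates.rgr, 0.0)

    def test_linear_curve_constant_agr(self):
        rates = growth_rates(lambda t: 10.0 * np.asarray(t, float), [1.0, 5.0, 20.0], dt=0.35)
        assert np.allclose(rates.agr, 10.0)

    def test_exponential_curve_constant_rgr(self):
        for dt in (0.35, 1.0, 2.5):
            rates = growth_rates(
                lambda t: np.exp(0.2 * np.asarray(t, float)), [5.0, 10.0, 30.0], dt=dt
            )
            assert np.allclose(rates.rgr, 0.2)

    def test_nonpositive_dt_rejected(self):
        with pytest.raises(ValueError):
            growth_rates(WT1, [1.0], dt=0.0)


class TestPhasePlane:
    def test_loop_area_matches_closed_form(self):
        # analytic loop integral of a dv for the exact logistic: gamma^3*Aa^2/30
        for fit in (WT1, WT3, CFQ2, CFQ3):
            feats = phase_plane_features(fit)
            assert feats.loop_area / (fit.gamma**3 * fit.aa**2) == pytest.approx(
                1 / 30, rel=0.005
            )

    def test_point_c_is_inflection(self):
        feats = phase_plane_features(WT1)
        assert feats.point_c[0] == pytest.approx(WT1.gamma * WT1.aa / 4, rel=1e-4)
        assert feats.point_c[1] == pytest.approx(0.0, abs=1e-3 * feats.point_b[1])

    def test_point_order_b_c_d(self):
        feats = phase_plane_features(WT1)
        assert feats.point_b[2] < feats.point_c[2] < feats.point_d[2]

    def test_trajectory_returns_to_origin(self):
        grid = np.linspace(-300, 600, 50001)
        v, a = curve_derivatives(WT1, grid)
        assert abs(v[0]) < 1e-3 * v.max() and abs(v[-1]) < 1e-3 * v.max()
        assert abs(a[0]) < 1e-3 * np.abs(a).max() and abs(a[-1]) < 1e-3 * np.abs(a).max()

    def test_flat_curve_degenerate(self):
        n = 2001
        feats = phase_plane_features(
            times=np.linspace(0, 10, n), velocity=np.zeros(n), acceleration=np.zeros(n)
        )
        assert feats.degenerate
        assert math.isnan(feats.loop_area)

    def test_sparse_sampling_rejected(self):
        t = np.linspace(0, 400, 20)
        v, a = curve_derivatives(WT1, t)
        with pytest.raises(ValueError, match="sparse"):
            phase_plane_features(times=t, velocity=v, acceleration=a)


class TestReplicates:
    def test_identical_series_not_flagged(self):
        s = logistic3(np.linspace(0, 100, 30), 100.0, 5000.0, 0.05)
        flags = flag_outlier_replicates([s, s, s])
        assert all(not f for f, _ in flags)
        assert all(p == pytest.approx(1.0) for _, p in flags)

    def test_shifted_series_flagged(self):
        rng = np.random.default_rng(0)
        t = np.linspace(0, 100, 40)
        base = logistic3(t, 100.0, 5000.0, 0.05)
        a = base + rng.normal(0, 20, t.size)
        b = base + rng.normal(0, 20, t.size)
        c = base + 10 * np.std(base)  # shifted far beyond the series spread
        flags = flag_outlier_replicates([a, b, c])
        # the shifted replicate is decisively flagged; with only three
        # replicates an extreme member also contaminates the leave-one-out
        # pool for the others, so only the outlier's flag is asserted
        assert flags[2][0]
        assert flags[2][1] < 1e-6
        assert flags[2][1] < flags[0][1] and flags[2][1] < flags[1][1]

    def test_alpha_zero_never_flags(self):
        rng = np.random.default_rng(1)
        series = [rng.normal(100 * (i + 1), 1, 30) for i in range(3)]
        assert all(not f for f, _ in flag_outlier_replicates(series, alpha=0.0))

    def test_fewer_than_three_replicates_rejected(self):
        with pytest.raises(ValueError, match="3"):
            flag_outlier_replicates([np.ones(5), np.ones(5)])


class TestAveraging:
    def test_identical_fits_mean_and_zero_sd(self):
        grid = np.linspace(0, 200, 100)
        mean, sd = average_replicates([WT1, WT1], grid)
        assert np.allclose(mean, WT1(grid))
        assert np.allclose(sd, 0.0)

    def test_wt_mean_max_acceleration(self):
        # per-replicate extrema averaged: (gamma^2*Aa/(6*sqrt(3))) per plant
        feats = genotype_phase_plane([WT1, WT3])
        oracle = np.mean(
            [f.gamma**2 * f.aa / (6 * math.sqrt(3)) for f in (WT1, WT3)]
        )
        assert feats.point_b[1] == pytest.approx(oracle, rel=1e-4)
        assert feats.point_b[1] == pytest.approx(8.6, rel=0.01)

    def test_cfq_mean_max_acceleration(self):
        feats = genotype_phase_plane([CFQ2, CFQ3])
        assert feats.point_b[1] == pytest.approx(4.0, rel=0.02)

    def test_curve_first_mode_runs_and_differs_little(self):
        per_rep = genotype_phase_plane([WT1, WT3], mode="per_replicate")
        curve_first = genotype_phase_plane([WT1, WT3], mode="curve_first")
        assert curve_first.point_b[1] == pytest.approx(per_rep.point_b[1], rel=0.10)

    def test_single_replicate_rejected(self):
        with pytest.raises(ValueError, match="2"):
            average_replicates([WT1], np.linspace(0, 10, 5))
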