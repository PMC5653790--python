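import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ringclock import (
    ClockParams,
    ColonyModel,
    LightSchedule,
    RadialProfile,
    calibrate,
    compute_periodogram,
    detect_rings,
    detrend_quadratic,
    estimate_period,
    render_profile,
    ring_deposition_times,
    rings_per_day,
)
from ringclock.rhythm import DEFAULT_SNR_THRESHOLD


def profile_from(values, positions=None):
    values = np.asarray(values, dtype=float)
    if positions is None:
        positions = np.arange(values.size, dtype=float)
    return RadialProfile(positions=positions, intensities=values)


class TestCalibrate:
    def test_first_last_ring_rule_arithmetic(self):
        cal = calibrate((100.0, 0.0), (820.0, 144.0))
        assert cal.px_per_h == pytest.approx(5.0)
        assert cal.position_to_time(460.0) == pytest.approx(72.0)
        assert cal.time_to_position(72.0) == pytest.approx(460.0)

    def test_swapped_anchors_same_scale(self):
        a, b = (100.0, 0.0), (820.0, 144.0)
        assert calibrate(a, b).px_per_h == calibrate(b, a).px_per_h

    def test_truth_anchors_recover_growth_rate_exactly(self, dd_schedule):
        clock = ClockParams(free_running_period=24.5)
        colony = ColonyModel(growth_rate=3.0, duration=144.0)
        truth = ring_deposition_times(dd_schedule, clock, 144.0, colony=colony)
        cal = calibrate((truth.ring_radii[0], truth.ring_times[0]),
                        (truth.ring_radii[-1], truth.ring_times[-1]))
        assert cal.px_per_h == pytest.approx(3.0, abs=1e-12)

    def test_degenerate_anchors_rejected(self):
        with pytest.raises(ValueError):
            calibrate((100.0, 0.0), (200.0, 0.0))
        with pytest.raises(ValueError):
            calibrate((100.0, 0.0), (100.0, 10.0))


class TestDetrendQuadratic:
    def test_exact_quadratic_gives_zero_residual(self):
        x = np.arange(200, dtype=float)
        y = 3e-4 * x**2 - 0.05 * x + 40.0
        resid = detrend_quadratic(profile_from(y)).intensities
        assert np.abs(resid).max() < 1e-9 * np.abs(y).max()

    def test_residual_matches_normal_equations_oracle(self, rng):
        x = np.arange(300, dtype=float)
        y = 2e-4 * x**2 + 0.1 * x + 10.0 + 5.0 * np.cos(2 * np.pi * x / 70.0)
        resid = detrend_quadratic(profile_from(y)).intensities
        # independent oracle: solve the normal equations directly
        X = np.vander(x, 3)
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        oracle = y - X @ beta
        assert np.allclose(resid, oracle, atol=1e-8)

    def test_constant_input_zeroed(self):
        resid = detrend_quadratic(profile_from(np.full(64, 7.0))).intensities
        assert np.abs(resid).max() < 1e-10

    def test_residual_orthogonal_to_quadratic_basis(self, rng):
        x = np.arange(256, dtype=float)
        y = rng.normal(size=256)
        resid = detrend_quadratic(profile_from(y)).intensities
        for basis in (np.ones_like(x), x, x**2):
            inner = abs(resid @ basis)
            assert inner < 1e-8 * np.linalg.norm(resid) * np.linalg.norm(basis)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_idempotence(self, seed):
        r = np.random.default_rng(seed)
        y = r.normal(size=128) + r.uniform(-1, 1) * np.arange(128.0) ** 2 / 1e3
        once = detrend_quadratic(profile_from(y))
        twice = detrend_quadratic(once)
        assert np.allclose(once.intensities, twice.intensities, atol=1e-10)


class TestPeriodogram:
    def test_cosine_peak_at_true_frequency(self):
        cal = calibrate((0.0, 0.0), (720.0, 144.0))  # 5 px/h
        x = np.arange(720, dtype=float)
        t = x / 5.0
        prof = profile_from(np.cos(2 * np.pi * t / 24.0))
        pg = compute_periodogram(prof, cal, pad_factor=8)
        f_peak = pg.frequencies[np.argmax(pg.power)]
        df = pg.frequencies[1] - pg.frequencies[0]
        assert abs(f_peak - 1.0 / 24.0) <= df

    def test_zero_signal_zero_power(self):
        cal = calibrate((0.0, 0.0), (720.0, 144.0))
        pg = compute_periodogram(profile_from(np.zeros(720)), cal)
        assert np.all(pg.power <= 1e-20)

    def test_parseval_identity(self, rng):
        cal = calibrate((0.0, 0.0), (300.0, 100.0))
        y = rng.normal(size=300)
        prof = profile_from(y)
        pg = compute_periodogram(prof, cal, pad_factor=8)
        n_pad = 8 * 300
        # full-spectrum sum from the one-sided grid (even n_pad: DC and
        # Nyquist once, everything else twice)
        total = pg.power[0] + pg.power[-1] + 2 * pg.power[1:-1].sum()
        x = y - y.mean()
        assert total / n_pad == pytest.approx(float(x @ x), rel=1e-6)

    def test_peak_invariant_to_quadratic_trend(self, rng):
        cal = calibrate((0.0, 0.0), (432.0, 144.0))
        x = np.arange(432, dtype=float)
        signal = np.cos(2 * np.pi * x / (24.5 * 3.0))
        trend = 1e-3 * x**2 - 0.2 * x + 50.0
        est_plain = estimate_period(
            compute_periodogram(detrend_quadratic(profile_from(signal)), cal))
        est_trend = estimate_period(
            compute_periodogram(detrend_quadratic(profile_from(signal + trend)), cal))
        assert est_trend.period == pytest.approx(est_plain.period, abs=1e-6)

    def test_bad_pad_factor_rejected(self):
        cal = calibrate((0.0, 0.0), (300.0, 100.0))
        with pytest.raises(ValueError):
            compute_periodogram(profile_from(np.zeros(300)), cal, pad_factor=0)


class TestEstimatePeriod:
    def test_on_bin_sinusoid_exact(self):
        # 144 h record, 24 h period lies exactly on a raw DFT bin (6 cycles)
        cal = calibrate((0.0, 0.0), (720.0, 144.0))
        t = np.arange(720) / 5.0
        prof = profile_from(np.cos(2 * np.pi * t / 24.0))
        est = estimate_period(compute_periodogram(prof, cal, pad_factor=1),
                              interpolate=False)
        assert est.period == pytest.approx(24.0, abs=1e-9)
        assert est.rhythmic

    def test_dd_profile_recovery_within_half_hour(self, dd_schedule):
        clock = ClockParams(free_running_period=24.5)
        colony = ColonyModel(growth_rate=3.0, duration=144.0)
        truth = ring_deposition_times(dd_schedule, clock, 144.0, colony=colony)
        cal = calibrate((colony.start_radius, 0.0), (colony.final_radius, colony.duration))
        for seed in range(12):
            prof = render_profile(truth, colony, noise_sd=0.02 * 255, seed=seed)
            est = estimate_period(compute_periodogram(detrend_quadratic(prof), cal))
            assert abs(est.period - 24.5) <= 0.5
            assert est.rhythmic

    def test_white_noise_rarely_called_rhythmic(self, dd_schedule):
        """Null specificity of the calibrated SNR threshold (>= 95%)."""
        clock = ClockParams(free_running_period=24.5)
        colony = ColonyModel(growth_rate=3.0, duration=144.0, ring_amplitude=0.0)
        truth = ring_deposition_times(dd_schedule, clock, 144.0, colony=colony)
        cal = calibrate((colony.start_radius, 0.0), (colony.final_radius, colony.duration))
        false_calls = 0
        for seed in range(200):
            prof = render_profile(truth, colony, noise_sd=0.02 * 255, seed=seed)
            est = estimate_period(compute_periodogram(detrend_quadratic(prof), cal))
            false_calls += est.rhythmic
        assert false_calls <= 10

    def test_band_outside_grid_rejected(self):
        cal = calibrate((0.0, 0.0), (64.0, 2.0))  # 32 px/h -> 2 h record
        prof = profile_from(np.random.default_rng(0).normal(size=64))
        with pytest.raises(ValueError, match="search band"):
            estimate_period(compute_periodogram(prof, cal, pad_factor=1),
                            band=(1000.0, 2000.0))

    def test_calibration_invariance_of_period_in_hours(self, dd_schedule):
        """Doubling the growth rate must not move the period estimate."""
        clock = ClockParams(free_running_period=24.5)
        estimates = []
        for v in (3.0, 6.0):
            colony = ColonyModel(growth_rate=v, duration=144.0)
            truth = ring_deposition_times(dd_schedule, clock, 144.0, colony=colony)
            cal = calibrate((colony.start_radius, 0.0), (colony.final_radius, 144.0))
            prof = render_profile(truth, colony)
            estimates.append(
                estimate_period(compute_periodogram(detrend_quadratic(prof), cal)).period)
        # one padded frequency bin maps to ~0.5 h at a 24.5 h period for
        # this record length
        assert estimates[0] == pytest.approx(estimates[1], abs=0.5)


class TestDetectRings:
    def test_noise_free_profile_yields_truth_rings(self, dd_schedule):
        clock = ClockParams(free_running_period=24.5)
        colony = ColonyModel(growth_rate=3.0, duration=144.0)
        truth = ring_deposition_times(dd_schedule, clock, 144.0, colony=colony)
        cal = calibrate((colony.start_radius, 0.0), (colony.final_radius, 144.0))
        prof = render_profile(truth, colony)
        rings = detect_rings(prof, calibration=cal)
        assert rings.count == len(truth.ring_times)
        assert np.all(np.abs(rings.positions - truth.ring_radii) <= 1.0)

    def test_constant_profile_zero_rings(self):
        rings = detect_rings(profile_from(np.full(64, 3.0)))
        assert rings.count == 0

    def test_dark_rings_found_with_polarity_flag(self, dd_schedule):
        clock = ClockParams(free_running_period=24.5)
        colony = ColonyModel(growth_rate=3.0, duration=144.0, ring_polarity="dark")
        truth = ring_deposition_times(dd_schedule, clock, 144.0, colony=colony)
        prof = render_profile(truth, colony)
        assert detect_rings(prof, polarity="dark").count == len(truth.ring_times)


class TestRingsPerDay:
    def test_six_rings_over_120h_is_one_per_day(self):
        from ringclock.rhythm import RingSet

        rings = RingSet(positions=np.arange(6) * 72.0, prominences=np.ones(6),
                        times=np.arange(6) * 24.0)
        assert rings_per_day(rings) == pytest.approx(1.0)

    def test_under_two_rings_is_undefined(self):
        from ringclock.rhythm import RingSet

        rings = RingSet(positions=np.array([10.0]), prominences=np.array([1.0]),
                        times=np.array([24.0]))
        assert rings_per_day(rings) is None

    def test_dd_268_rate_matches_arithmetic(self, dd_schedule):
        from ringclock import gaussian_blur

        clock = ClockParams(free_running_period=26.8)
        colony = ColonyModel(growth_rate=3.0, duration=144.0)
        truth = ring_deposition_times(dd_schedule, clock, 144.0, colony=colony)
        cal = calibrate((colony.start_radius, 0.0), (colony.final_radius, 144.0))
        prof = render_profile(truth, colony, noise_sd=0.02 * 255, seed=11)
        # ring calls expect the chain's smoothing to have tamed pixel noise
        smoothed = prof.with_intensities(
            gaussian_blur(prof.intensities[:, None], 3.0)[:, 0], "gaussian_blur (sigma=3)")
        rings = detect_rings(smoothed, calibration=cal, expected_period_h=26.8)
        rate = rings_per_day(rings, cal)
        assert rate == pytest.approx(24.0 / 26.8, abs=0.05)
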