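"""Time-of-flight velocimetry: cross-correlation lags and robust fitting."""
import numpy as np
import pytest

from elastowave import (
    default_pulse,
    depth_average,
    estimate_group_velocity,
    make_displacement_field,
    residual_weighted_fit,
    xcorr_arrival_times,
)
from elastowave.errors import EstimationError, ParameterError
from elastowave.types import ArrivalTimeSeries, SpatioTemporalMap


def _pulse_trace(t, t0, sigma=8.0):
    return np.exp(-0.5 * ((t - t0) / sigma) ** 2)


def _map_with_delays(delays, n_t=256, frame_rate=30e3, sigma=8.0):
    t = np.arange(n_t, dtype=float)
    v = np.stack([_pulse_trace(t, 60.0 + d, sigma) for d in delays])
    x = np.arange(len(delays), dtype=float) * 1e-4 + 1e-4
    return SpatioTemporalMap(
        values=v, lateral_positions=x, frame_rate=frame_rate,
        excitation_position=0.0, direction_tag="right",
    )


def _fine_grid_lag_oracle(trace, ref, upsample=100):
    """Brute-force sub-sample lag: maximize correlation over a dense grid of
    interpolated shifts."""
    n = trace.size
    t = np.arange(n, dtype=float)
    best, best_lag = -np.inf, 0.0
    for lag in np.arange(-20, 20, 1.0 / upsample):
        shifted = np.interp(t - lag, t, ref, left=0.0, right=0.0)
        nrm = np.linalg.norm(shifted)
        if nrm == 0.0:
            continue
        c = np.dot(trace, shifted) / nrm
        if c > best:
            best, best_lag = c, lag
    return best_lag


class TestXcorrArrivalTimes:
    def test_integer_delay_exact(self):
        m = _map_with_delays([0, 7, 14], frame_rate=30e3)
        s = xcorr_arrival_times(m)
        assert s.arrival_times[1] - s.arrival_times[0] == pytest.approx(
            7 / 30e3, abs=1e-9
        )

    def test_reference_against_itself(self):
        m = _map_with_delays([0, 5, 9])
        s = xcorr_arrival_times(m, reference_index=0)
        assert s.arrival_times[0] == 0.0
        assert s.correlation_peaks[0] == pytest.approx(1.0, abs=1e-12)

    def test_fractional_delay_matches_fine_grid_oracle(self):
        m = _map_with_delays([0.0, 2.5, 5.0])
        s = xcorr_arrival_times(m)
        lag_samples = s.arrival_times[1] * m.frame_rate
        oracle = _fine_grid_lag_oracle(m.values[1], m.values[0])
        assert lag_samples == pytest.approx(2.5, abs=0.1)
        assert lag_samples == pytest.approx(oracle, abs=0.1)

    @pytest.mark.parametrize("frac", [0.2, 0.5, 0.8])
    def test_parabolic_refinement_within_tenth_sample(self, frac):
        m = _map_with_delays([0.0, 3 + frac, 2 * (3 + frac)])
        s = xcorr_arrival_times(m)
        lags = s.arrival_times * m.frame_rate
        for i in (1, 2):
            oracle = _fine_grid_lag_oracle(m.values[i], m.values[0])
            assert lags[i] == pytest.approx(oracle, abs=0.1)

    def test_all_zero_trace_dropped(self):
        m = _map_with_delays([0, 3, 6, 9])
        m.values[2] = 0.0
        with pytest.warns(UserWarning, match="all-zero"):
            s = xcorr_arrival_times(m)
        assert len(s) == 3

    def test_needs_three_positions(self):
        m = _map_with_delays([0, 3])
        m2 = SpatioTemporalMap(
            values=m.values[:2], lateral_positions=m.lateral_positions[:2],
            frame_rate=m.frame_rate, excitation_position=0.0,
        )
        with pytest.raises(ParameterError):
            xcorr_arrival_times(m2)


class TestResidualWeightedFit:
    def test_perfect_line_exact_slope_equal_weights(self):
        x = np.linspace(1e-3, 5e-3, 20)
        s = ArrivalTimeSeries(
            distances=x, arrival_times=x / 3.0, correlation_peaks=np.ones_like(x)
        )
        slope, se, w, r2 = residual_weighted_fit(s)
        assert slope == pytest.approx(1.0 / 3.0, rel=1e-12)
        np.testing.assert_allclose(w, w[0])
        assert r2 == pytest.approx(1.0)

    def test_outlier_downweighted(self):
        rng = np.random.default_rng(0)
        x = np.linspace(1e-3, 6e-3, 30)
        noise = rng.normal(0, 2e-6, x.size)
        y = x / 2.5 + noise
        y_out = y.copy()
        y_out[12] += 10 * np.abs(noise).max()
        s = ArrivalTimeSeries(x, y_out, np.ones_like(x))
        slope, _, w, _ = residual_weighted_fit(s)
        # reference: ordinary least squares with the outlier removed
        clean = np.delete(np.arange(x.size), 12)
        slope_clean = np.polyfit(x[clean], y[clean], 1)[0]
        assert slope == pytest.approx(slope_clean, rel=0.01)
        assert w[12] < 0.1 * np.median(w)

    def test_bisquare_also_rejects_outlier(self):
        rng = np.random.default_rng(1)
        x = np.linspace(1e-3, 6e-3, 30)
        noise = rng.normal(0, 2e-6, x.size)
        y = x / 2.5 + noise
        y[20] += 10 * np.abs(noise).max()
        s = ArrivalTimeSeries(x, y, np.ones_like(x))
        slope, _, w, _ = residual_weighted_fit(s, weighting="bisquare")
        clean = np.delete(np.arange(x.size), 20)
        slope_clean = np.polyfit(x[clean], (x / 2.5 + noise)[clean], 1)[0]
        assert slope == pytest.approx(slope_clean, rel=0.01)
        assert w[20] == 0.0

    def test_two_points_rejected(self):
        s = ArrivalTimeSeries(
            np.array([1e-3, 2e-3, 3e-3]), np.zeros(3), np.ones(3)
        )
        s2 = ArrivalTimeSeries(s.distances[:2], s.arrival_times[:2], s.correlation_peaks[:2])
        with pytest.raises(ParameterError):
            residual_weighted_fit(s2)


class TestEstimateGroupVelocity:
    def test_zero_noise_recovery_within_one_percent(self, oce_field_3ms):
        m = depth_average(oce_field_3ms)
        est = estimate_group_velocity(m)
        assert est.speed == pytest.approx(3.0, rel=0.01)

    def test_asymmetric_sides_average(self):
        """Sides at 2 and 4 m/s report 3.0 with side_speeds (2, 4)."""
        n_x, n_t, fr = 81, 400, 30e3
        x = np.linspace(0, 8e-3, n_x)
        x0 = x[n_x // 2]
        t = np.arange(n_t)
        v = np.zeros((n_x, n_t))
        for i, xi in enumerate(x):
            c = 2.0 if xi < x0 else 4.0
            delay = abs(xi - x0) / c * fr
            v[i] = _pulse_trace(t.astype(float), 60.0 + delay)
        m = SpatioTemporalMap(values=v, lateral_positions=x, frame_rate=fr,
                              excitation_position=x0)
        est = estimate_group_velocity(m, exclusion=0.4e-3)
        assert est.speed == pytest.approx(3.0, rel=0.01)
        assert est.side_speeds[0] == pytest.approx(2.0, rel=0.01)
        assert est.side_speeds[1] == pytest.approx(4.0, rel=0.01)

    def test_scale_equivariance_in_time(self, oce_field_3ms):
        """Dilating the time axis by k scales the speed by 1/k."""
        m = depth_average(oce_field_3ms)
        m2 = SpatioTemporalMap(
            values=m.values, lateral_positions=m.lateral_positions,
            frame_rate=m.frame_rate / 2.0, excitation_position=m.excitation_position,
        )
        est1 = estimate_group_velocity(m)
        est2 = estimate_group_velocity(m2)
        assert est2.speed == pytest.approx(est1.speed / 2.0, rel=1e-9)

    def test_amplitude_invariance(self, oce_field_3ms):
        m = depth_average(oce_field_3ms)
        m2 = SpatioTemporalMap(
            values=273.15 * m.values, lateral_positions=m.lateral_positions,
            frame_rate=m.frame_rate, excitation_position=m.excitation_position,
        )
        assert estimate_group_velocity(m2).speed == pytest.approx(
            estimate_group_velocity(m).speed, rel=1e-12
        )

    def test_noisy_recovery_two_percent(self, small_oce_geom):
        """2 m/s with 0.1 rad phase noise: within 2% averaged over seeds."""
        from elastowave import encode_oce_frames, oce_phase_to_displacement

        speeds = []
        for seed in range(8):
            f = make_displacement_field(small_oce_geom, 2.0, default_pulse("OCE"),
                                        seed=seed)
            frames = encode_oce_frames(f, noise_sd_phase=0.1, seed=seed)
            m = depth_average(oce_phase_to_displacement(frames))
            speeds.append(estimate_group_velocity(m).speed)
        assert np.mean(speeds) == pytest.approx(2.0, rel=0.02)

    def test_failure_when_no_wave(self):
        x = np.linspace(0, 4e-3, 41)
        v = np.zeros((41, 64))
        m = SpatioTemporalMap(values=v, lateral_positions=x, frame_rate=30e3,
                              excitation_position=x[20])
        with pytest.raises(EstimationError):
            estimate_group_velocity(m)
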