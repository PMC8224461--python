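"""Synthetic wave-field generator: arrival structure, encodings, ensembles."""
import numpy as np
import pytest

from elastowave import (
    PulseSpec,
    anisotropic_speed_profile,
    default_pulse,
    encode_oce_frames,
    encode_us_iq,
    make_displacement_field,
    make_trial_ensemble,
    oce_geometry,
    use_geometry,
)
from elastowave.errors import ParameterError


def _surface_peak_times(field):
    """Independent oracle: per-position arrival by argmax of the surface trace."""
    trace = field.values[0]  # (lateral, time)
    return np.argmax(trace, axis=1) / field.geometry.frame_rate


class TestMakeDisplacementField:
    def test_arrival_delay_matches_distance_over_speed(self):
        """Two points 3 mm apart at 3 m/s peak 1.0 ms apart."""
        geom = oce_geometry(n_lateral=251)
        x = geom.lateral_positions - geom.excitation_position
        i_a = np.argmin(np.abs(x - 0.5e-3))
        i_b = np.argmin(np.abs(x - 3.5e-3))
        assert np.isclose(x[i_b] - x[i_a], 3e-3, atol=2e-5)
        field = make_displacement_field(geom, 3.0, default_pulse("OCE"), seed=0)
        t = _surface_peak_times(field)
        assert t[i_b] - t[i_a] == pytest.approx(1.0e-3, abs=2 / geom.frame_rate)

    def test_mirror_symmetry_without_attenuation(self, small_oce_geom):
        field = make_displacement_field(
            small_oce_geom, 2.0, default_pulse("OCE"), seed=0
        )
        u = field.values
        # grid is symmetric about the center excitation
        np.testing.assert_allclose(u, u[:, ::-1, :], rtol=0, atol=1e-18)

    def test_peak_tracking_recovers_ground_truth(self):
        """Brute-force peak tracking on the raw field recovers 2.5 +- 0.05 m/s."""
        geom = oce_geometry()
        field = make_displacement_field(geom, 2.5, default_pulse("OCE"), seed=0)
        t = _surface_peak_times(field)
        x = geom.lateral_positions - geom.excitation_position
        right = x > 0.5e-3
        slope = np.polyfit(x[right], t[right], 1)[0]
        assert 1.0 / slope == pytest.approx(2.5, abs=0.05)

    @pytest.mark.parametrize("speed", [1.5, 5.0])
    def test_arrival_times_affine_in_distance(self, speed):
        geom = oce_geometry()
        field = make_displacement_field(geom, speed, default_pulse("OCE"), seed=0)
        t = _surface_peak_times(field)
        d = np.abs(geom.lateral_positions - geom.excitation_position)
        keep = d > 0.5e-3
        slope, _ = np.polyfit(d[keep], t[keep], 1)
        resid = t[keep] - np.polyval(np.polyfit(d[keep], t[keep], 1), d[keep])
        assert slope == pytest.approx(1.0 / speed, rel=0.02)
        assert np.max(np.abs(resid)) < 1.5 / geom.frame_rate

    def test_rejects_nonpositive_speed(self, small_oce_geom):
        with pytest.raises(ParameterError):
            make_displacement_field(small_oce_geom, 0.0, default_pulse("OCE"))

    def test_rejects_time_axis_shorter_than_pulse(self, small_oce_geom):
        with pytest.raises(ParameterError):
            make_displacement_field(
                small_oce_geom, 3.0, default_pulse("OCE"), n_time=10
            )

    def test_bit_reproducible(self, small_use_geom):
        p = default_pulse("USE")
        a = make_displacement_field(small_use_geom, 3.0, p, seed=7)
        b = make_displacement_field(small_use_geom, 3.0, p, seed=7)
        assert np.array_equal(a.values, b.values)


class TestEncodeOCE:
    def test_zero_displacement_gives_zero_phase_differences(self, small_oce_geom):
        from elastowave.types import DisplacementField

        u = np.zeros((small_oce_geom.n_depth, small_oce_geom.n_lateral, 5))
        field = DisplacementField(values=u, geometry=small_oce_geom)
        frames = encode_oce_frames(field, noise_sd_phase=0.0)
        dphi = np.angle(np.conj(frames.values[:, :, :-1]) * frames.values[:, :, 1:])
        np.testing.assert_allclose(dphi, 0.0, atol=1e-15)

    def test_uniform_step_phase_matches_path_length_model(self, small_oce_geom):
        """A rigid 100 nm step: surface phase = 4 pi * 100 / 1310 rad at every
        depth (the refractive terms cancel for rigid motion)."""
        from elastowave.types import DisplacementField

        step = 100e-9
        u = np.zeros((small_oce_geom.n_depth, small_oce_geom.n_lateral, 2))
        u[:, :, 1] = step
        field = DisplacementField(values=u, geometry=small_oce_geom)
        frames = encode_oce_frames(field, noise_sd_phase=0.0)
        dphi = np.angle(np.conj(frames.values[:, :, 0]) * frames.values[:, :, 1])
        expected = 4.0 * np.pi * 100.0 / 1310.0
        np.testing.assert_allclose(dphi, expected, rtol=1e-12)

    def test_noise_reproducible_and_modality_checked(self, oce_field_3ms, use_field_3ms):
        from elastowave.errors import ConfigurationError

        a = encode_oce_frames(oce_field_3ms, noise_sd_phase=0.2, seed=3)
        b = encode_oce_frames(oce_field_3ms, noise_sd_phase=0.2, seed=3)
        assert np.array_equal(a.values, b.values)
        with pytest.raises(ConfigurationError):
            encode_oce_frames(use_field_3ms)


class TestEncodeUSIQ:
    def test_zero_motion_constant_slow_time_phase(self, small_use_geom):
        from elastowave.types import DisplacementField

        u = np.zeros((small_use_geom.n_depth, small_use_geom.n_lateral, 4))
        frames = encode_us_iq(DisplacementField(values=u, geometry=small_use_geom))
        phase = np.angle(frames.values)
        assert np.ptp(phase) == 0.0

    def test_quarter_pi_phase_for_known_step(self, small_use_geom):
        """dz = c/(8 f_c) = 24.68 um at 7.8 MHz / 1540 m/s -> slow-time phase
        shift of exactly pi/2."""
        from elastowave.types import DisplacementField

        dz = 1540.0 / (8.0 * 7.8e6)
        assert dz == pytest.approx(24.68e-6, abs=0.02e-6)
        u = np.zeros((small_use_geom.n_depth, small_use_geom.n_lateral, 2))
        u[:, :, 1] = dz
        frames = encode_us_iq(DisplacementField(values=u, geometry=small_use_geom))
        shift = np.angle(np.conj(frames.values[:, :, 0]) * frames.values[:, :, 1])
        np.testing.assert_allclose(shift, np.pi / 2.0, rtol=1e-12)

    def test_requires_use_metadata(self, oce_field_3ms):
        from elastowave.errors import ConfigurationError

        with pytest.raises(ConfigurationError):
            encode_us_iq(oce_field_3ms)


class TestTrialEnsemble:
    def test_zero_sd_gives_identical_trials(self):
        ens = make_trial_ensemble(3.0, n_trials=5, intertrial_sd=0.0, seed=0)
        np.testing.assert_array_equal(ens.speeds, 3.0)

    def test_monte_carlo_sd_consistent(self):
        """Pooled sample SD over many ensembles matches the requested SD."""
        draws = np.concatenate(
            [
                make_trial_ensemble(3.0, 5, 0.05, seed=s).speeds
                for s in range(2000)
            ]
        )
        assert draws.std(ddof=1) == pytest.approx(0.05, rel=0.05)
        assert draws.mean() == pytest.approx(3.0, abs=0.005)

    def test_single_trial_rejected(self):
        with pytest.raises(ParameterError):
            make_trial_ensemble(3.0, n_trials=1)

    def test_negative_draws_redrawn_with_warning(self):
        with pytest.warns(UserWarning, match="re-drawing"):
            ens = make_trial_ensemble(0.1, n_trials=50, intertrial_sd=1.0, seed=1)
        assert np.all(ens.speeds > 0)


class TestAnisotropicProfile:
    @pytest.mark.parametrize(
        "angle,expected",
        [(0.0, 4.0), (90.0, 3.0), (45.0, np.sqrt(8.0 + 4.5))],
    )
    def test_known_values(self, angle, expected):
        assert anisotropic_speed_profile(4.0, 3.0, angle) == pytest.approx(expected)

    def test_monotone_between_endpoints(self):
        angles = np.linspace(0, 90, 91)
        speeds = [anisotropic_speed_profile(4.4, 2.4, a) for a in angles]
        assert np.all(np.diff(speeds) < 0)  # c_par > c_perp: decreasing

    def test_angle_domain_enforced(self):
        with pytest.raises(ParameterError):
            anisotropic_speed_profile(4.0, 3.0, 120.0)


def test_pulse_sigma_matches_bandwidth():
    # FWHM of the Gaussian amplitude spectrum equals the requested bandwidth
    p = PulseSpec(center_frequency=573.0, bandwidth=573.0, amplitude=1e-6)
    sigma_f = 1.0 / (2.0 * np.pi * p.sigma_t)
    assert 2.0 * np.sqrt(2.0 * np.log(2.0)) * sigma_f == pytest.approx(573.0)
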