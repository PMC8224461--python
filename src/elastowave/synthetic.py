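"""Synthetic transient wave fields and modality-encoded frame data.

This module generates the inputs the analysis chain consumes: a transient
surface/shear wave launched at the excitation position and propagating
bilaterally at a known ground-truth group velocity, then encoded either as
phase-sensitive OCT M-B-mode frames (OCE) or as an ultrasound IQ ensemble
(USE).  Because the ground truth is known exactly, the full processing chain
can be validated end to end.
"""
from __future__ import annotations

import warnings
from typing import Optional

import numpy as np

from .errors import ParameterError
from .types import (
    AcquisitionGeometry,
    ComplexFrameSeries,
    DisplacementField,
    PulseSpec,
    TrialEnsemble,
)

__all__ = [
    "oce_geometry",
    "use_geometry",
    "default_pulse",
    "make_displacement_field",
    "encode_oce_frames",
    "encode_us_iq",
    "make_trial_ensemble",
    "anisotropic_speed_profile",
]

#: Default pulse center frequencies / bandwidths, Hz.  Transient air-puff
#: excitations on gelatin produce ~500-600 Hz bandwidths; acoustic radiation
#: force pushes produce ~750-1200 Hz.
OCE_PULSE_HZ = 573.0
USE_PULSE_HZ = 1073.0


def oce_geometry(
    n_lateral: int = 251,
    lateral_span: float = 7.83e-3,
    n_depth: int = 32,
    depth_span: float = 1.5e-3,
    frame_rate: float = 30e3,
    wavelength_lambda0: float = 1310e-9,
    refractive_index_n: float = 1.4,
) -> AcquisitionGeometry:
    """Phase-sensitive OCT line-scan geometry.

    Defaults: 251 lateral points over a 7.83 mm line, 30 kHz effective frame
    rate, 1310 nm central wavelength, excitation at the line center.
    """
    lat = np.linspace(0.0, lateral_span, n_lateral)
    dep = np.linspace(0.0, depth_span, n_depth)
    return AcquisitionGeometry(
        lateral_positions=lat,
        depth_positions=dep,
        frame_rate=frame_rate,
        excitation_position=lateral_span / 2.0,
        modality="OCE",
        wavelength_lambda0=wavelength_lambda0,
        refractive_index_n=refractive_index_n,
    )


def use_geometry(
    n_lateral: int = 128,
    lateral_span: float = 25.2e-3,
    n_depth: int = 160,
    depth_span: float = 6.0e-3,
    frame_rate: float = 10e3,
    us_center_frequency: float = 7.8e6,
    sound_speed: float = 1540.0,
    push_focus_depth: float = 4.0e-3,
) -> AcquisitionGeometry:
    """Linear-array ultrasound shear-wave geometry.

    Defaults: 7.8 MHz imaging/push frequency, push focus 4 mm deep under the
    array center, 10 kHz ensemble rate.  Depth sampling (~38 um) keeps the
    fast-time phase per sample well inside the unambiguous range.  The
    lateral field of view (25.2 mm, most of a 128-element linear-array
    aperture) is wide enough that the shear wave stays inside it for the
    whole acquisition; truncating a still-propagating wave at the edge
    smears its frequency-wavenumber signature across quadrants and biases
    directional filtering.
    """
    lat = np.linspace(0.0, lateral_span, n_lateral)
    dep = np.linspace(0.0, depth_span, n_depth)
    return AcquisitionGeometry(
        lateral_positions=lat,
        depth_positions=dep,
        frame_rate=frame_rate,
        excitation_position=lateral_span / 2.0,
        modality="USE",
        us_center_frequency=us_center_frequency,
        sound_speed=sound_speed,
        push_focus_depth=push_focus_depth,
    )


def default_pulse(modality: str, amplitude: Optional[float] = None) -> PulseSpec:
    """Modality-typical excitation pulse (center frequency == bandwidth).

    Default peak displacements reflect the excitation physics: a focused
    micro air pulse displaces the surface by a fraction of a micrometre,
    while an acoustic radiation force push displaces tissue by ~10 um near
    its focus.
    """
    if modality == "OCE":
        return PulseSpec(
            center_frequency=OCE_PULSE_HZ,
            bandwidth=OCE_PULSE_HZ,
            amplitude=0.5e-6 if amplitude is None else amplitude,
        )
    return PulseSpec(
        center_frequency=USE_PULSE_HZ,
        bandwidth=USE_PULSE_HZ,
        amplitude=10e-6 if amplitude is None else amplitude,
    )


def _depth_profile(geometry: AcquisitionGeometry, depth_scale: float) -> np.ndarray:
    """Smooth depth-decay profile of the wave amplitude.

    Surface-launched waves (OCE) decay exponentially from the surface; a
    radiation-force push displaces most strongly around its focal depth, so
    USE geometries with a push focus get a Gaussian bump centered there.
    """
    z = geometry.depth_positions
    if geometry.modality == "USE" and geometry.push_focus_depth is not None:
        return np.exp(-0.5 * ((z - geometry.push_focus_depth) / depth_scale) ** 2)
    return np.exp(-z / depth_scale)


def make_displacement_field(
    geometry: AcquisitionGeometry,
    speed: float,
    pulse: PulseSpec,
    seed: int = 0,
    n_time: Optional[int] = None,
    depth_scale: float = 1.0e-3,
) -> DisplacementField:
    """Simulate a transient wave propagating bilaterally from the excitation.

    The axial displacement is separable::

        u(z, x, t) = A * w(z) * exp(-alpha*|x-x0|) * g(t - t0 - |x-x0|/speed)

    with ``g`` a Gaussian-enveloped cosine at the pulse center frequency and
    ``w(z)`` a smooth depth-decay profile.  The onset delay ``t0`` places the
    pulse fully inside the time axis.  Deterministic given ``seed`` (the seed
    is recorded for provenance; the field itself is noise-free — noise enters
    at the encoding stage).

    Parameters
    ----------
    n_time:
        Number of frames.  By default the time axis is sized to contain the
        pulse tail at the farthest lateral position.
    depth_scale:
        Length scale of the depth profile ``w(z)``, m.
    """
    if not (speed > 0):
        raise ParameterError("wave speed must be positive")
    sigma_t = pulse.sigma_t
    t0 = 3.5 * sigma_t
    dist = np.abs(geometry.lateral_positions - geometry.excitation_position)
    t_needed = t0 + dist.max() / speed + 3.5 * sigma_t
    if n_time is None:
        n_time = int(np.ceil(t_needed * geometry.frame_rate)) + 1
    elif n_time / geometry.frame_rate < t_needed:
        raise ParameterError(
            f"time axis ({n_time / geometry.frame_rate * 1e3:.2f} ms) too short for "
            f"the pulse to traverse the line ({t_needed * 1e3:.2f} ms needed)"
        )
    t = np.arange(n_time) / geometry.frame_rate
    tau = t[None, :] - t0 - dist[:, None] / speed  # (lateral, time)
    g = np.exp(-0.5 * (tau / sigma_t) ** 2) * np.cos(
        2.0 * np.pi * pulse.center_frequency * tau
    )
    lateral_decay = np.exp(-pulse.attenuation_coeff * dist)
    w = _depth_profile(geometry, depth_scale)
    u = pulse.amplitude * w[:, None, None] * (lateral_decay[:, None] * g)[None, :, :]
    return DisplacementField(values=u, geometry=geometry, ground_truth_speed=speed)


def encode_oce_frames(
    field: DisplacementField,
    noise_sd_phase: float = 0.0,
    seed: int = 0,
    intensity_decay_scale: float = 1.0e-3,
) -> ComplexFrameSeries:
    """Encode a displacement field as phase-sensitive OCT M-B-mode frames.

    The optical phase at depth ``z`` follows the double-pass path-length model
    for a sample in air: light reflected from depth ``z`` accumulates
    ``phi(z) = (4 pi / lambda0) * (n u(z) - (n - 1) u_surface)`` where the
    second term is the air-gap change caused by the moving surface.  Circular
    Gaussian phase noise of SD ``noise_sd_phase`` (rad) is added per pixel and
    frame.  Backscatter intensity decays exponentially with depth so that the
    surface is the brightest return.
    """
    geom = field.geometry
    geom.require_oce()
    lam0 = geom.wavelength_lambda0
    n_idx = geom.refractive_index_n
    u = field.values
    u_surf = u[0:1, :, :]  # surface = shallowest depth bin
    phi = (4.0 * np.pi / lam0) * (n_idx * u - (n_idx - 1.0) * u_surf)
    if noise_sd_phase < 0:
        raise ParameterError("noise_sd_phase must be non-negative")
    if noise_sd_phase > 0:
        rng = np.random.default_rng(seed)
        phi = phi + rng.normal(0.0, noise_sd_phase, size=phi.shape)
    amp = np.exp(-geom.depth_positions / intensity_decay_scale)
    frames = amp[:, None, None] * np.exp(1j * phi)
    return ComplexFrameSeries(values=frames, geometry=geom)


def encode_us_iq(
    field: DisplacementField,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> ComplexFrameSeries:
    """Encode a displacement field as a baseband ultrasound IQ ensemble.

    The slow-time phase at each depth carries the acoustic round-trip shift
    ``phi = 4 pi f_c u / c_sound``.  Complex white Gaussian noise is added
    with per-quadrature SD ``noise_sd`` relative to the unit signal
    amplitude.  Speckle texture beyond this additive noise is not modeled.
    """
    geom = field.geometry
    geom.require_use()
    f_c = geom.us_center_frequency
    c = geom.sound_speed
    phi = 4.0 * np.pi * f_c * field.values / c
    frames = np.exp(1j * phi).astype(complex)
    if noise_sd < 0:
        raise ParameterError("noise_sd must be non-negative")
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        frames = frames + noise_sd * (
            rng.standard_normal(frames.shape) + 1j * rng.standard_normal(frames.shape)
        )
    return ComplexFrameSeries(values=frames, geometry=geom)


def make_trial_ensemble(
    base_speed: float,
    n_trials: int = 5,
    intertrial_sd: float = 0.0,
    seed: int = 0,
    sample_id: str = "sample",
) -> TrialEnsemble:
    """Draw repeated-trial speeds with removal/replacement jitter.

    Each trial speed is ``base_speed + Normal(0, intertrial_sd)``; a
    non-positive draw (possible only at extreme SD) is re-drawn with a
    warning.  Reproducible for a fixed ``seed``.
    """
    if n_trials < 2:
        raise ParameterError("need at least 2 trials")
    if intertrial_sd < 0:
        raise ParameterError("intertrial_sd must be non-negative")
    if not (base_speed > 0):
        raise ParameterError("base_speed must be positive")
    rng = np.random.default_rng(seed)
    speeds = base_speed + rng.normal(0.0, intertrial_sd, size=n_trials)
    bad = speeds <= 0
    while np.any(bad):
        warnings.warn(
            f"re-drawing {bad.sum()} non-positive trial speed(s)", stacklevel=2
        )
        speeds[bad] = base_speed + rng.normal(0.0, intertrial_sd, size=bad.sum())
        bad = speeds <= 0
    return TrialEnsemble(sample_id=sample_id, speeds=speeds)


def anisotropic_speed_profile(
    c_parallel: float, c_perpendicular: float, angle: float
) -> float:
    """Elliptical wave-speed interpolation versus fiber angle.

    ``c(theta) = sqrt((c_par cos theta)^2 + (c_perp sin theta)^2)`` with the
    angle in degrees relative to the fiber direction; monotone from
    ``c_parallel`` at 0 deg to ``c_perpendicular`` at 90 deg.
    """
    if not (c_parallel > 0 and c_perpendicular > 0):
        raise ParameterError("speeds must be positive")
    if not (0.0 <= angle <= 90.0):
        raise ParameterError("angle must lie in [0, 90] degrees")
    th = np.deg2rad(angle)
    return float(
        np.sqrt((c_parallel * np.cos(th)) ** 2 + (c_perpendicular * np.sin(th)) ** 2)
    )
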