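"""Displacement estimation from complex frame data.

Two estimators, one per modality:

* ``oce_phase_to_displacement`` — phase-sensitive OCT: inter-frame phase
  differences, optional temporal unwrapping, and the surface-motion /
  refractive-index-mismatch correction for a sample imaged in air.
* ``loupas_displacement`` — the 2-D autocorrelation (Loupas) estimator for
  ultrasound IQ ensembles, with local center-frequency correction; with a
  1-sample depth kernel and 2-frame ensemble kernel it reduces to the plain
  Kasai lag-one autocorrelator.
"""
from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage

from .errors import AliasingWarning, LowSNRWarning, ParameterError
from .types import ComplexFrameSeries, DisplacementField

__all__ = ["oce_phase_to_displacement", "loupas_displacement", "detect_surface"]


def detect_surface(frames: ComplexFrameSeries, threshold: float = 0.5) -> np.ndarray:
    """Per-A-scan surface index: first depth bin whose mean intensity exceeds
    ``threshold`` times that A-scan's maximum."""
    if not (0.0 < threshold <= 1.0):
        raise ParameterError("threshold must lie in (0, 1]")
    intensity = np.mean(np.abs(frames.values) ** 2, axis=2)  # (depth, lateral)
    cutoff = threshold * intensity.max(axis=0, keepdims=True)
    return np.argmax(intensity >= cutoff, axis=0)  # (lateral,)


def oce_phase_to_displacement(
    frames: ComplexFrameSeries,
    surface_threshold: float = 0.5,
    unwrap: bool = True,
) -> DisplacementField:
    """Convert OCT M-B-mode frames to corrected axial displacement.

    Inter-frame phase differences are taken from conjugate products and
    (optionally) unwrapped along time.  For a sample in air the double-pass
    optical path is ``n dz - (n - 1) ds`` where ``ds`` is the surface
    displacement, so the corrected per-frame displacement at depth ``z`` is::

        dz(z) = (lambda0 * dphi(z) / (4 pi) + (n - 1) * ds) / n,
        ds    = lambda0 * dphi_surface / (4 pi)

    Cumulative summation over time yields displacement relative to the first
    frame.  Rigid whole-sample motion (``dz == ds``) passes through exactly
    for any refractive index.

    A result whose phase differences look like pure noise (mean resultant
    length below 0.2) is flagged ``low_snr`` and a warning is issued.
    """
    geom = frames.geometry
    geom.require_oce()
    lam0 = geom.wavelength_lambda0
    n_idx = geom.refractive_index_n

    v = frames.values
    dphi = np.angle(np.conj(v[:, :, :-1]) * v[:, :, 1:])  # (depth, lateral, T-1)
    if unwrap:
        dphi = np.unwrap(dphi, axis=2)

    # circular concentration of the raw phase increments: ~0 for pure noise
    resultant = np.abs(np.mean(np.exp(1j * dphi)))
    low_snr = bool(resultant < 0.2)
    if low_snr:
        warnings.warn(
            "phase differences are consistent with pure noise (mean resultant "
            f"length {resultant:.3f}); flagging low-SNR result",
            LowSNRWarning,
            stacklevel=2,
        )

    surf = detect_surface(frames, surface_threshold)
    cols = np.arange(geom.n_lateral)
    dphi_surface = dphi[surf, cols, :]  # (lateral, T-1)
    ds = lam0 * dphi_surface / (4.0 * np.pi)
    dz = (lam0 * dphi / (4.0 * np.pi) + (n_idx - 1.0) * ds[None, :, :]) / n_idx

    disp = np.concatenate(
        [np.zeros_like(dz[:, :, :1]), np.cumsum(dz, axis=2)], axis=2
    )
    return DisplacementField(values=disp, geometry=geom, low_snr=low_snr)


def _moving_sum(a: np.ndarray, size: int, axis: int) -> np.ndarray:
    """Centered moving sum with zero padding (complex-safe)."""
    if size <= 1:
        return a
    shape = [1] * a.ndim
    shape[axis] = size
    kw = dict(size=tuple(shape), mode="constant", cval=0.0)
    return (
        ndimage.uniform_filter(a.real, **kw) + 1j * ndimage.uniform_filter(a.imag, **kw)
    ) * size


def loupas_displacement(
    frames: ComplexFrameSeries,
    depth_kernel: int = 5,
    ensemble_kernel: int = 2,
) -> DisplacementField:
    """Loupas 2-D autocorrelation displacement estimate from IQ data.

    The inter-frame displacement at each pixel is the mean Doppler phase of
    the slow-time lag-one autocorrelation summed over a ``depth_kernel`` x
    ``ensemble_kernel`` window, scaled by ``c_sound / (4 pi f_c)`` and
    corrected by the locally estimated center frequency from the fast-time
    (depth) lag-one autocorrelation.  With ``depth_kernel=1`` no local
    frequency estimate exists and the plain Kasai estimate is returned.
    Cumulative summation over slow time yields displacement relative to the
    first frame.

    A per-frame displacement beyond 90% of the lambda/4 unambiguous range
    triggers an aliasing warning.
    """
    geom = frames.geometry
    geom.require_use()
    if depth_kernel < 1 or ensemble_kernel < 2:
        raise ParameterError("depth_kernel >= 1 and ensemble_kernel >= 2 required")
    v = frames.values
    if depth_kernel > v.shape[0]:
        raise ParameterError("depth_kernel exceeds the depth axis")
    if ensemble_kernel > v.shape[2]:
        raise ParameterError("ensemble_kernel exceeds the ensemble length")
    f_c = geom.us_center_frequency
    c = geom.sound_speed

    # slow-time lag-one products, one per frame pair
    p_slow = np.conj(v[:, :, :-1]) * v[:, :, 1:]  # (depth, lateral, T-1)
    r_slow = _moving_sum(p_slow, depth_kernel, axis=0)
    r_slow = _moving_sum(r_slow, ensemble_kernel - 1, axis=2)
    phi_slow = np.angle(r_slow)

    if depth_kernel >= 2:
        # fast-time lag-one products -> residual demodulation phase per depth
        # sample, i.e. the deviation of the local echo center frequency from
        # the nominal one.  The local frequency is a property of the medium,
        # not of the motion, so it is estimated from the whole ensemble: the
        # transient strain contribution oscillates and averages out.
        p_fast = np.conj(v[:-1, :, :]) * v[1:, :, :]  # (depth-1, lateral, T)
        r_fast = _moving_sum(p_fast, depth_kernel - 1, axis=0).sum(axis=2)
        phi_fast = np.angle(r_fast)
        # pad back to full depth axis (edge replicate)
        phi_fast = np.concatenate([phi_fast, phi_fast[-1:, :]], axis=0)
        dz_sample = float(np.mean(np.diff(geom.depth_positions)))
        nominal = 4.0 * np.pi * f_c * dz_sample / c  # expected phase/sample at f_c
        freq_ratio = 1.0 + phi_fast[:, :, None] / nominal
        freq_ratio = np.clip(freq_ratio, 0.5, 2.0)  # guard against noise blowup
    else:
        freq_ratio = 1.0

    du = (c / (4.0 * np.pi * f_c)) * phi_slow / freq_ratio
    if np.max(np.abs(phi_slow)) > 0.9 * np.pi:
        warnings.warn(
            "inter-frame displacement approaches the lambda/4 unambiguous "
            "range; estimates may be aliased",
            AliasingWarning,
            stacklevel=2,
        )
    disp = np.concatenate(
        [np.zeros_like(du[:, :, :1]), np.cumsum(du, axis=2)], axis=2
    )
    return DisplacementField(values=disp, geometry=geom)
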