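"""Reduction of displacement fields to directional spatiotemporal maps.

The velocimetry stage consumes a (lateral, time) map; this module produces it
by depth averaging, optionally separates left- and right-travelling waves in
the f-k (frequency-wavenumber) domain, and re-indexes each propagation side
by distance from the excitation.
"""
from __future__ import annotations

import warnings
from typing import Optional

import numpy as np
from scipy import ndimage

from .errors import ParameterError
from .types import DisplacementField, SpatioTemporalMap

__all__ = ["depth_average", "directional_filter", "split_bilateral"]

DEFAULT_DEPTH_EXTENT = 400e-6  # m; averaging window to improve SNR


def depth_average(
    field: DisplacementField,
    z_start: Optional[float] = None,
    z_extent: float = DEFAULT_DEPTH_EXTENT,
) -> SpatioTemporalMap:
    """Unweighted mean of the displacement over a depth window.

    Defaults follow the modality: for a surface wave (OCE) the window starts
    at the sample surface; for a push-focused shear wave (USE) it is centered
    on the push focal depth.  The window is 400 um by default.
    """
    geom = field.geometry
    z = geom.depth_positions
    if z_start is None:
        if geom.modality == "USE" and geom.push_focus_depth is not None:
            z_start = geom.push_focus_depth - z_extent / 2.0
        else:
            z_start = z[0]
    mask = (z >= z_start) & (z <= z_start + z_extent)
    if not np.any(mask):
        raise ParameterError("depth window does not intersect the depth axis")
    values = field.values[mask].mean(axis=0)  # (lateral, time)
    return SpatioTemporalMap(
        values=values,
        lateral_positions=geom.lateral_positions,
        frame_rate=geom.frame_rate,
        excitation_position=geom.excitation_position,
        direction_tag="both",
    )


def _direction_mask(shape: tuple[int, int], direction: str, rolloff: int) -> np.ndarray:
    """Quadrant mask over (spatial freq, temporal freq) with raised-cosine
    roll-off.  A rightward wave exp(i 2 pi (f t - k x)), k = f/c > 0, maps to
    FFT bins with sign(xi) * sign(f) = -1; leftward to +1.  DC and the zero
    axes belong to neither direction."""
    n_x, n_t = shape
    xi = np.fft.fftfreq(n_x)[:, None]
    f = np.fft.fftfreq(n_t)[None, :]
    want = -1.0 if direction == "right" else 1.0
    hard = (np.sign(xi) * np.sign(f) == want).astype(float)
    if rolloff >= 1:
        # smooth each axis with a short raised-cosine kernel (circular, so the
        # mask stays symmetric under (xi, f) -> (-xi, -f) and output stays real)
        k = np.hanning(2 * rolloff + 3)[1:-1]
        k /= k.sum()
        for axis in (0, 1):
            hard = ndimage.convolve1d(hard, k, axis=axis, mode="wrap")
    hard[0, 0] = 0.0  # DC belongs to neither direction
    return hard


def directional_filter(
    st_map: SpatioTemporalMap, direction: str, rolloff: int = 2
) -> SpatioTemporalMap:
    """Isolate left- or right-travelling waves in the f-k domain.

    The 2-D Fourier transform over (lateral, time) is masked to the two
    quadrants whose phase velocity points in the requested direction, with a
    raised-cosine roll-off of ``rolloff`` bins to suppress ringing; DC is
    assigned to neither direction.  Returns the real part of the inverse
    transform.
    """
    if direction not in ("left", "right"):
        raise ParameterError("direction must be 'left' or 'right'")
    n_x, n_t = st_map.values.shape
    if n_x < 8 or n_t < 8:
        raise ParameterError("need at least 8 lateral and 8 time samples")
    # DC is assigned to neither direction: remove the mean up front (and do
    # not restore it).  Zero-pad both axes: the transform treats the map as
    # periodic, and a wave exiting one edge would otherwise wrap around and
    # bias the result.
    p_x, p_t = n_x // 2, n_t // 2
    padded = np.pad(st_map.values - st_map.values.mean(), ((p_x, p_x), (p_t, p_t)))
    spec = np.fft.fft2(padded)
    mask = _direction_mask(padded.shape, direction, rolloff)
    filtered = np.real(np.fft.ifft2(spec * mask))[p_x : p_x + n_x, p_t : p_t + n_t]
    return SpatioTemporalMap(
        values=filtered,
        lateral_positions=st_map.lateral_positions,
        frame_rate=st_map.frame_rate,
        excitation_position=st_map.excitation_position,
        direction_tag=direction,
    )


def split_bilateral(
    st_map: SpatioTemporalMap, exclusion: float = 0.5e-3
) -> tuple[Optional[SpatioTemporalMap], Optional[SpatioTemporalMap]]:
    """Split a map into left/right halves indexed by distance from the source.

    Positions within ``exclusion`` of the excitation are dropped (near-field
    time-of-flight bias); each returned map's lateral axis is the distance
    from the excitation, increasing away from it.  If the excitation sits at
    a lateral boundary only the populated side is returned (the other is
    ``None``) with a warning.
    """
    x = st_map.lateral_positions
    x0 = st_map.excitation_position
    if exclusion < 0:
        raise ParameterError("exclusion must be non-negative")
    half_span = max(x0 - x[0], x[-1] - x0)
    if exclusion >= half_span:
        raise ParameterError("exclusion zone covers the whole propagation span")

    def _side(mask: np.ndarray, tag: str) -> Optional[SpatioTemporalMap]:
        if mask.sum() < 2:
            return None
        d = np.abs(x[mask] - x0)
        order = np.argsort(d)
        return SpatioTemporalMap(
            values=st_map.values[mask][order],
            lateral_positions=d[order],
            frame_rate=st_map.frame_rate,
            excitation_position=0.0,
            direction_tag=tag,
        )

    left = _side(x < x0 - exclusion, "left")
    right = _side(x > x0 + exclusion, "right")
    if left is None or right is None:
        warnings.warn(
            "excitation at or near the lateral boundary: single-sided result",
            stacklevel=2,
        )
    return left, right
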