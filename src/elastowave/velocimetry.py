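"""Group-velocity estimation from spatiotemporal maps.

Time-of-flight velocimetry: each lateral position's time trace is
cross-correlated against a reference trace to obtain its arrival time; a
robust (residual-weighted, iteratively reweighted) linear fit of arrival
time versus propagation distance gives the slowness, whose inverse is the
group velocity.  The two propagation sides are fitted separately and the
side speeds averaged.
"""
from __future__ import annotations

import warnings
from typing import Optional

import numpy as np
from scipy import signal

from .errors import EstimationError, ParameterError
from .types import ArrivalTimeSeries, SideFit, SpatioTemporalMap, VelocityEstimate
from .wavefield import split_bilateral

__all__ = [
    "xcorr_arrival_times",
    "residual_weighted_fit",
    "estimate_group_velocity",
]


def _parabolic_refine(corr: np.ndarray, i: int) -> float:
    """Sub-sample peak location by three-point parabola; clamped to +-0.5."""
    if i <= 0 or i >= corr.size - 1:
        return 0.0
    y0, y1, y2 = corr[i - 1], corr[i], corr[i + 1]
    denom = y0 - 2.0 * y1 + y2
    if denom == 0.0:
        return 0.0
    delta = 0.5 * (y0 - y2) / denom
    return float(np.clip(delta, -0.5, 0.5))


def xcorr_arrival_times(
    st_map: SpatioTemporalMap, reference_index: int = 0
) -> ArrivalTimeSeries:
    """Arrival time of the wave at each lateral position by normalized
    cross-correlation against the reference trace.

    The integer lag at the correlation maximum (ties broken toward the
    smaller lag) is refined by three-point parabolic interpolation; the
    arrival time is lag / frame_rate.  All-zero traces are dropped with a
    warning.

    Traces are correlated as-is (transient displacement traces have zero
    baseline by construction; subtracting a per-trace mean would introduce a
    pedestal that biases the sub-sample refinement).
    """
    if st_map.values.shape[0] < 3:
        raise ParameterError("need at least 3 lateral positions")
    traces = st_map.values
    ref = traces[reference_index]
    ref_norm = np.linalg.norm(ref)
    if ref_norm == 0.0:
        raise EstimationError("reference trace is identically zero")
    n_t = traces.shape[1]
    dists, times, peaks = [], [], []
    for i, tr in enumerate(traces):
        nrm = np.linalg.norm(tr)
        if nrm == 0.0:
            warnings.warn(f"dropping all-zero trace at position {i}", stacklevel=2)
            continue
        corr = signal.correlate(tr, ref, mode="full") / (nrm * ref_norm)
        j = int(np.argmax(corr))  # first occurrence -> smaller lag on ties
        lag = j - (n_t - 1) + _parabolic_refine(corr, j)
        dists.append(st_map.lateral_positions[i])
        times.append(lag / st_map.frame_rate)
        peaks.append(float(np.clip(corr[j], -1.0, 1.0)))
    return ArrivalTimeSeries(
        distances=np.asarray(dists),
        arrival_times=np.asarray(times),
        correlation_peaks=np.asarray(peaks),
    )


def residual_weighted_fit(
    series: ArrivalTimeSeries,
    eps: float = 0.1,
    max_iter: int = 50,
    rtol: float = 1e-6,
    weighting: str = "inverse_residual",
) -> tuple[float, float, np.ndarray, float]:
    """Residual-weighted (IRLS) linear fit of arrival time versus distance.

    Starting from an ordinary least-squares fit, weights are updated from
    the current residuals and the weighted fit repeated until the slope
    changes by less than ``rtol`` (relative) or ``max_iter`` iterations.
    ``weighting`` selects the scheme:

    * ``inverse_residual`` (default): ``w_i = 1 / (|r_i| + eps * MAD(r))``
    * ``bisquare``: Tukey's biweight ``w_i = (1 - u_i^2)^2`` for
      ``|u_i| < 1`` (else 0), ``u_i = r_i / (4.685 * MAD(r) / 0.6745)``

    Either choice makes the slope robust to gross outliers in individual
    arrival times.

    Returns ``(slope, slope_se, weights, r_squared)`` with slope in s/m.
    ``r_squared`` is the unweighted coefficient of determination of the final
    line.
    """
    x = series.distances
    y = series.arrival_times
    if x.size < 3:
        raise ParameterError("need at least 3 points to fit")
    if weighting not in ("inverse_residual", "bisquare"):
        raise ParameterError(f"unknown weighting {weighting!r}")

    w = np.ones_like(x)
    slope, intercept = np.polyfit(x, y, 1, w=np.sqrt(w))
    for _ in range(max_iter):
        r = y - (slope * x + intercept)
        mad = np.median(np.abs(r - np.median(r)))
        if np.max(np.abs(r)) <= 1e-12 * max(np.max(np.abs(y)), 1e-30):
            w = np.ones_like(x)  # exact fit: equal weights
            break
        if weighting == "bisquare":
            u = r / (4.685 * mad / 0.6745)
            w = np.where(np.abs(u) < 1.0, (1.0 - u**2) ** 2, 0.0)
            if w.sum() < 3:  # keep the fit identifiable
                w = np.ones_like(x)
                break
        else:
            w = 1.0 / (np.abs(r) + eps * mad)
        w = w / w.mean()
        new_slope, intercept = np.polyfit(x, y, 1, w=np.sqrt(w))
        if abs(new_slope - slope) <= rtol * max(abs(slope), 1e-30):
            slope = new_slope
            break
        slope = new_slope

    # weighted-least-squares standard error of the slope at the final weights
    sw = w.sum()
    xbar = (w * x).sum() / sw
    sxx = (w * (x - xbar) ** 2).sum()
    r = y - (slope * x + intercept)
    dof = x.size - 2
    s2 = (w * r**2).sum() / dof if dof > 0 else np.nan
    slope_se = float(np.sqrt(s2 / sxx)) if sxx > 0 else np.nan

    ss_res = float(np.sum(r**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r_squared = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return float(slope), slope_se, w, float(r_squared)


def _fit_side(
    side_map: SpatioTemporalMap, tag: str, min_corr: float
) -> Optional[SideFit]:
    try:
        series = xcorr_arrival_times(side_map)
    except (ParameterError, EstimationError):
        return None
    keep = series.correlation_peaks >= min_corr
    if keep.sum() >= 3 and keep.sum() < len(series):
        series = ArrivalTimeSeries(
            distances=series.distances[keep],
            arrival_times=series.arrival_times[keep],
            correlation_peaks=series.correlation_peaks[keep],
        )
    if len(series) < 3:
        return None
    slope, slope_se, w, r2 = residual_weighted_fit(series)
    speed = 1.0 / slope if slope > 0 else None
    return SideFit(
        side=tag,
        speed=speed,
        slope=slope,
        slope_se=slope_se,
        r_squared=r2,
        weights=w,
        n_points=len(series),
    )


def estimate_group_velocity(
    st_map: SpatioTemporalMap,
    exclusion: float = 0.5e-3,
    min_corr: float = 0.3,
) -> VelocityEstimate:
    """Bilateral time-of-flight group-velocity estimate.

    The map is split about the excitation position (positions within
    ``exclusion`` of it are dropped); on each side, arrival times are
    estimated by cross-correlation against the trace nearest the source and
    fitted by the residual-weighted linear fit.  Each side's speed is the
    inverse slope; the reported speed is the mean of the valid sides.  A
    non-positive slope invalidates that side; if both sides are invalid an
    :class:`~elastowave.errors.EstimationError` is raised.

    Positions whose correlation peak falls below ``min_corr`` are excluded
    from the fit (decorrelated traces carry no arrival-time information).
    """
    if st_map.direction_tag == "both":
        left_map, right_map = split_bilateral(st_map, exclusion=exclusion)
    else:
        # already a single-sided, distance-indexed map
        left_map, right_map = (
            (st_map, None) if st_map.direction_tag == "left" else (None, st_map)
        )
    fits = []
    if left_map is not None:
        f = _fit_side(left_map, "left", min_corr)
        if f is not None:
            fits.append(f)
    if right_map is not None:
        f = _fit_side(right_map, "right", min_corr)
        if f is not None:
            fits.append(f)

    valid = [f for f in fits if f.speed is not None]
    if not valid:
        raise EstimationError(
            "no valid time-of-flight fit on either propagation side "
            f"(diagnostics: {fits!r})"
        )
    by_side = {f.side: f.speed for f in fits}
    speed = float(np.mean([f.speed for f in valid]))
    return VelocityEstimate(
        speed=speed,
        side_speeds=(by_side.get("left"), by_side.get("right")),
        slope=float(np.mean([f.slope for f in valid])),
        slope_se=float(np.mean([f.slope_se for f in valid])),
        r_squared=float(np.mean([f.r_squared for f in valid])),
        side_fits=tuple(fits),
    )
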