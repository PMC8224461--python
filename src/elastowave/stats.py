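"""Agreement and repeatability statistics for repeated-trial measurements.

Implements Bland-Altman limits of agreement (raw and normalized), the
two-way random-effects absolute-agreement single-measurement intraclass
correlation ICC(2,1), mean absolute percent error against a reference, and
the linear trend fit of Bland-Altman differences versus means.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats as sps

from .errors import ParameterError
from .types import TrialEnsemble

__all__ = [
    "BlandAltmanResult",
    "ICCResult",
    "TrendFitResult",
    "bland_altman",
    "icc",
    "mape",
    "trend_fit",
]

BiasVariant = Literal["from_sample_mean", "leave_one_out"]


@dataclass
class BlandAltmanResult:
    """Bland-Altman summary: bias, limits of agreement and per-trial points.

    ``points`` holds one ``(sample mean, difference)`` pair per trial; when
    ``normalized`` the differences are percentages of the sample mean.
    """

    bias: float
    loa_upper: float
    loa_lower: float
    sd_differences: float
    points: np.ndarray  # (n_trials_total, 2): mean, difference
    normalized: bool
    bias_variant: BiasVariant


@dataclass
class ICCResult:
    icc: float
    model_label: str
    var_between_subjects: float
    var_between_raters: float
    var_residual: float
    n_subjects: int
    n_raters: int


@dataclass
class TrendFitResult:
    slope: float
    slope_se: float
    p_value: float


def bland_altman(
    ensembles: Sequence[TrialEnsemble],
    normalized: bool = False,
    bias_variant: BiasVariant = "from_sample_mean",
) -> BlandAltmanResult:
    """Bland-Altman analysis of repeated trials against each sample's mean.

    For each sample the trial mean is the x-coordinate; each trial's
    difference from that mean (``from_sample_mean``) or from the mean of the
    remaining trials (``leave_one_out``) is the y-coordinate.  Normalization
    divides each difference by its sample mean and reports percent.  The bias
    is the grand mean of the differences and the limits of agreement are
    bias +- 1.96 sample SD (n-1 convention) of the differences.

    Under ``from_sample_mean`` the differences within each sample sum to zero
    by construction, so the bias is identically 0; ``leave_one_out`` breaks
    that degeneracy.
    """
    if not ensembles:
        raise ParameterError("need at least one trial ensemble")
    means, diffs = [], []
    for ens in ensembles:
        x = ens.speeds
        m = x.mean()
        if bias_variant == "from_sample_mean":
            d = x - m
        elif bias_variant == "leave_one_out":
            n = x.size
            d = (x - m) * n / (n - 1)  # x_i - mean(others)
        else:
            raise ParameterError(f"unknown bias_variant {bias_variant!r}")
        if normalized:
            if m <= 0:
                raise ParameterError(
                    "normalization requires positive sample means"
                )
            d = d / m * 100.0
        means.append(np.full_like(x, m))
        diffs.append(d)
    mean_arr = np.concatenate(means)
    diff_arr = np.concatenate(diffs)
    bias = float(diff_arr.mean())
    sd = float(diff_arr.std(ddof=1)) if diff_arr.size > 1 else 0.0
    return BlandAltmanResult(
        bias=bias,
        loa_upper=bias + 1.96 * sd,
        loa_lower=bias - 1.96 * sd,
        sd_differences=sd,
        points=np.column_stack([mean_arr, diff_arr]),
        normalized=normalized,
        bias_variant=bias_variant,
    )


def icc(matrix: np.ndarray) -> ICCResult:
    """ICC(2,1): two-way random effects, absolute agreement, single measure.

    ``matrix`` is subjects x repeated measurements (raters), complete.  From
    the two-way ANOVA mean squares (rows MS_R, columns MS_C, error MS_E)::

        ICC(2,1) = (MS_R - MS_E) /
                   (MS_R + (k - 1) MS_E + k (MS_C - MS_E) / n)

    Variance components are stored alongside.  A matrix with zero total
    variance is degenerate perfect agreement and returns ICC = 1 with a
    warning.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise ParameterError("need >= 2 subjects and >= 2 measurements")
    if not np.all(np.isfinite(m)):
        raise ParameterError("matrix must be complete and finite")
    n, k = m.shape
    grand = m.mean()
    if np.allclose(m, grand):
        warnings.warn("zero total variance: degenerate perfect agreement", stacklevel=2)
        return ICCResult(1.0, "ICC(2,1)", 0.0, 0.0, 0.0, n, k)
    row_means = m.mean(axis=1)
    col_means = m.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((m - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    ms_r = ss_rows / (n - 1)
    ms_c = ss_cols / (k - 1)
    ms_e = ss_err / ((n - 1) * (k - 1))
    value = (ms_r - ms_e) / (ms_r + (k - 1) * ms_e + k * (ms_c - ms_e) / n)
    return ICCResult(
        icc=float(value),
        model_label="ICC(2,1)",
        var_between_subjects=float(max(ms_r - ms_e, 0.0) / k),
        var_between_raters=float(max(ms_c - ms_e, 0.0) / n),
        var_residual=float(ms_e),
        n_subjects=n,
        n_raters=k,
    )


def mape(measured: Sequence[float], reference: Sequence[float]) -> float:
    """Mean absolute percent error of measurements against a reference."""
    x = np.asarray(measured, dtype=float)
    r = np.asarray(reference, dtype=float)
    if x.shape != r.shape or x.ndim != 1 or x.size == 0:
        raise ParameterError("measured and reference must be equal-length 1-D")
    if np.any(r <= 0):
        raise ParameterError("reference values must be positive")
    return float(np.mean(np.abs(x - r) / r) * 100.0)


def trend_fit(points: np.ndarray) -> TrendFitResult:
    """OLS fit of Bland-Altman differences on means, testing slope = 0.

    Accepts the ``points`` array of :func:`bland_altman` (columns: mean,
    difference).  Returns the slope, its standard error and the two-sided
    t-test p-value.  Zero-variance differences give slope 0 with p = 1.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ParameterError("need >= 3 (mean, difference) points")
    x, y = pts[:, 0], pts[:, 1]
    if np.ptp(x) == 0:
        raise ParameterError("degenerate x: all means equal")
    if np.ptp(y) == 0:
        return TrendFitResult(slope=0.0, slope_se=0.0, p_value=1.0)
    res = sps.linregress(x, y)
    return TrendFitResult(
        slope=float(res.slope),
        slope_se=float(res.stderr),
        p_value=float(res.pvalue),
    )
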