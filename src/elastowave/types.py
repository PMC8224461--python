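"""Core containers for elastographic acquisitions and derived quantities.

All values are strict SI internally (m, s, Pa, Hz, kg/m^3).  Conversion to
mm / kPa / percent happens only at report boundaries.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np

from .errors import ParameterError, ConfigurationError

Modality = Literal["OCE", "USE"]


@dataclass(frozen=True)
class MaterialSpec:
    """Linear-elastic material under the incompressible soft-tissue model.

    For a nearly incompressible medium (``poisson_ratio`` -> 0.5) the bulk
    shear wave speed follows from the Young's modulus as
    ``c_s = sqrt(E / (3 rho))``.
    """

    young_modulus: float  # Pa
    density: float = 1000.0  # kg/m^3
    poisson_ratio: float = 0.5
    label: str = ""

    def __post_init__(self) -> None:
        if not (self.young_modulus > 0):
            raise ParameterError("young_modulus must be positive")
        if not (self.density > 0):
            raise ParameterError("density must be positive")
        if not (0.0 <= self.poisson_ratio <= 0.5):
            raise ParameterError("poisson_ratio must lie in [0, 0.5]")

    @property
    def shear_speed(self) -> float:
        """Bulk shear wave speed ``sqrt(E/(3 rho))`` in m/s."""
        return float(np.sqrt(self.young_modulus / (3.0 * self.density)))


@dataclass(frozen=True)
class PulseSpec:
    """Transient excitation pulse: a Gaussian-enveloped cosine.

    ``bandwidth`` is the FWHM of the Gaussian amplitude spectrum; typical
    transient surface excitations in soft phantoms have center frequencies
    and bandwidths in the 500-1200 Hz range.
    """

    center_frequency: float  # Hz
    bandwidth: float  # Hz (FWHM of amplitude spectrum)
    amplitude: float = 0.5e-6  # m, peak displacement
    attenuation_coeff: float = 0.0  # 1/m, lateral amplitude decay

    def __post_init__(self) -> None:
        if not (self.center_frequency > 0):
            raise ParameterError("center_frequency must be positive")
        if not (self.bandwidth > 0):
            raise ParameterError("bandwidth must be positive")
        if not (self.amplitude > 0):
            raise ParameterError("amplitude must be positive")
        if self.attenuation_coeff < 0:
            raise ParameterError("attenuation_coeff must be non-negative")

    @property
    def sigma_t(self) -> float:
        """Temporal envelope SD implied by the spectral FWHM."""
        sigma_f = self.bandwidth / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        return 1.0 / (2.0 * np.pi * sigma_f)


@dataclass(frozen=True)
class AcquisitionGeometry:
    """Spatial/temporal sampling grid plus modality-specific optics/acoustics.

    OCE acquisitions carry the optical center wavelength ``wavelength_lambda0``
    and the sample refractive index ``refractive_index_n``; ultrasound (USE)
    acquisitions carry the transducer center frequency ``us_center_frequency``,
    the medium ``sound_speed`` and the push focal depth.
    """

    lateral_positions: np.ndarray  # m, strictly monotone increasing
    depth_positions: np.ndarray  # m, strictly monotone increasing
    frame_rate: float  # Hz (effective slow-time rate)
    excitation_position: float  # m, along the lateral axis
    modality: Modality
    wavelength_lambda0: Optional[float] = None  # m
    refractive_index_n: Optional[float] = None
    us_center_frequency: Optional[float] = None  # Hz
    sound_speed: Optional[float] = None  # m/s
    push_focus_depth: Optional[float] = None  # m

    def __post_init__(self) -> None:
        lat = np.asarray(self.lateral_positions, dtype=float)
        dep = np.asarray(self.depth_positions, dtype=float)
        object.__setattr__(self, "lateral_positions", lat)
        object.__setattr__(self, "depth_positions", dep)
        if lat.ndim != 1 or lat.size < 2 or np.any(np.diff(lat) <= 0):
            raise ParameterError("lateral_positions must be strictly increasing 1-D")
        if dep.ndim != 1 or dep.size < 1 or np.any(np.diff(dep) <= 0):
            raise ParameterError("depth_positions must be strictly increasing 1-D")
        if not (self.frame_rate > 0):
            raise ParameterError("frame_rate must be positive")
        if not (lat[0] <= self.excitation_position <= lat[-1]):
            raise ParameterError("excitation_position must lie within the lateral span")
        if self.modality not in ("OCE", "USE"):
            raise ParameterError("modality must be 'OCE' or 'USE'")
        if self.refractive_index_n is not None and self.refractive_index_n < 1:
            raise ParameterError("refractive_index_n must be >= 1")

    @property
    def n_lateral(self) -> int:
        return int(self.lateral_positions.size)

    @property
    def n_depth(self) -> int:
        return int(self.depth_positions.size)

    def require_oce(self) -> None:
        if self.modality != "OCE":
            raise ConfigurationError("operation requires an OCE geometry")
        if self.wavelength_lambda0 is None or self.refractive_index_n is None:
            raise ConfigurationError(
                "OCE geometry needs wavelength_lambda0 and refractive_index_n"
            )

    def require_use(self) -> None:
        if self.modality != "USE":
            raise ConfigurationError("operation requires a USE geometry")
        if self.us_center_frequency is None or self.sound_speed is None:
            raise ConfigurationError(
                "USE geometry needs us_center_frequency and sound_speed"
            )


@dataclass
class DisplacementField:
    """Axial displacement ``u(z, x, t)`` on the acquisition grid, in metres."""

    values: np.ndarray  # (depth, lateral, time)
    geometry: AcquisitionGeometry
    ground_truth_speed: Optional[float] = None
    low_snr: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ParameterError("values must be (depth, lateral, time)")
        if self.values.shape[0] != self.geometry.n_depth:
            raise ParameterError("depth axis inconsistent with geometry")
        if self.values.shape[1] != self.geometry.n_lateral:
            raise ParameterError("lateral axis inconsistent with geometry")
        if not np.all(np.isfinite(self.values)):
            raise ParameterError("displacement values must be finite")

    @property
    def n_time(self) -> int:
        return int(self.values.shape[2])

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_time) / self.geometry.frame_rate


@dataclass
class ComplexFrameSeries:
    """Complex acquisition data: OCE M-B-mode frames or ultrasound IQ ensemble.

    Axis order is (depth, lateral, time).  Inter-frame phase differences of
    OCE frames encode axial displacement through the optical path-length
    model; slow-time phase shifts of IQ data encode it through the acoustic
    round-trip phase ``4 pi f_c dz / c``.
    """

    values: np.ndarray  # complex, (depth, lateral, time)
    geometry: AcquisitionGeometry

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=complex)
        if self.values.ndim != 3:
            raise ParameterError("values must be (depth, lateral, time)")
        if self.values.shape[2] < 2:
            raise ParameterError("need at least 2 time samples")
        if self.values.shape[0] != self.geometry.n_depth:
            raise ParameterError("depth axis inconsistent with geometry")
        if self.values.shape[1] != self.geometry.n_lateral:
            raise ParameterError("lateral axis inconsistent with geometry")
        if not np.all(np.isfinite(self.values)):
            raise ParameterError("frame values must be finite")


@dataclass
class SpatioTemporalMap:
    """Depth-averaged displacement over (lateral, time).

    The propagating wavefront appears as a sloped ridge; the inverse slope of
    arrival time versus distance is the group velocity.  ``direction_tag``
    records provenance: ``both`` for an unfiltered map, ``left``/``right``
    after directional filtering or bilateral splitting (in which case
    ``lateral_positions`` are distances from the excitation).
    """

    values: np.ndarray  # (lateral, time)
    lateral_positions: np.ndarray  # m
    frame_rate: float  # Hz
    excitation_position: float  # m
    direction_tag: Literal["both", "left", "right"] = "both"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.lateral_positions = np.asarray(self.lateral_positions, dtype=float)
        if self.values.ndim != 2:
            raise ParameterError("values must be (lateral, time)")
        if self.lateral_positions.size != self.values.shape[0]:
            raise ParameterError("lateral axis length mismatch")
        if np.any(np.diff(self.lateral_positions) <= 0):
            raise ParameterError("lateral_positions must be strictly monotone")
        if not np.all(np.isfinite(self.values)):
            raise ParameterError("map values must be finite")

    @property
    def n_time(self) -> int:
        return int(self.values.shape[1])


@dataclass
class ArrivalTimeSeries:
    """Per-position wave arrival times from cross-correlation time-of-flight."""

    distances: np.ndarray  # m, strictly increasing
    arrival_times: np.ndarray  # s
    correlation_peaks: np.ndarray  # in [-1, 1]

    def __post_init__(self) -> None:
        self.distances = np.asarray(self.distances, dtype=float)
        self.arrival_times = np.asarray(self.arrival_times, dtype=float)
        self.correlation_peaks = np.asarray(self.correlation_peaks, dtype=float)
        if not (
            self.distances.size == self.arrival_times.size == self.correlation_peaks.size
        ):
            raise ParameterError("arrival-time series arrays must have equal length")
        if np.any(np.diff(self.distances) <= 0):
            raise ParameterError("distances must be strictly increasing")

    def __len__(self) -> int:
        return int(self.distances.size)


@dataclass
class SideFit:
    """Diagnostics of the time-of-flight fit on one propagation side."""

    side: Literal["left", "right"]
    speed: Optional[float]  # m/s, None if the fit was invalid
    slope: float  # s/m
    slope_se: float  # s/m
    r_squared: float
    weights: np.ndarray
    n_points: int


@dataclass
class VelocityEstimate:
    """Bilateral group-velocity estimate with per-side diagnostics."""

    speed: float  # m/s, mean of the valid side speeds
    side_speeds: tuple[Optional[float], Optional[float]]  # (left, right)
    slope: float  # s/m, mean inverse speed over valid sides
    slope_se: float
    r_squared: float
    side_fits: Sequence[SideFit] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not (self.speed > 0):
            raise ParameterError("estimated speed must be positive")


@dataclass
class TrialEnsemble:
    """Repeated speed measurements of one sample (removal/replacement trials)."""

    sample_id: str
    speeds: np.ndarray  # m/s

    def __post_init__(self) -> None:
        self.speeds = np.asarray(self.speeds, dtype=float)
        if self.speeds.size < 2:
            raise ParameterError("a trial ensemble needs at least 2 trials")
        if np.any(self.speeds <= 0):
            raise ParameterError("all trial speeds must be positive")

    @property
    def n_trials(self) -> int:
        return int(self.speeds.size)
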