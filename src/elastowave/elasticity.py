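"""Wave speed to Young's modulus conversion.

Two models for nearly incompressible soft media:

* surface (Rayleigh) waves, measured by surface-sensitive imaging:
  ``E = 2 rho (1 + nu)^3 / (0.87 + 1.12 nu)^2 * Cg^2``
* bulk shear waves: ``E = 3 rho c^2`` (the nu = 0.5 limit of
  ``E = 2 rho (1 + nu) c^2``)

plus the Rayleigh-to-shear speed correction.  In the incompressible limit a
Rayleigh wave travels at ~95.5% of the shear wave speed; surface-wave speeds
must be divided by that ratio before comparison with shear-wave measurements.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.optimize import brentq

from .errors import ParameterError

__all__ = [
    "ElasticityResult",
    "ym_rayleigh",
    "ym_shear",
    "rayleigh_shear_ratio",
    "rayleigh_to_shear_speed",
]

Method = Literal["exact_secular", "approximate"]


@dataclass(frozen=True)
class ElasticityResult:
    young_modulus: float  # Pa
    model: Literal["rayleigh_surface", "shear"]
    input_speed: float  # m/s
    poisson_ratio: float
    density: float  # kg/m^3

    @property
    def young_modulus_kpa(self) -> float:
        return self.young_modulus / 1e3


def _check_speed_nu_rho(speed: float, nu: float, rho: float) -> None:
    if not (speed > 0):
        raise ParameterError("wave speed must be positive")
    if not (0.0 <= nu <= 0.5):
        raise ParameterError("poisson ratio must lie in [0, 0.5]")
    if not (rho > 0):
        raise ParameterError("density must be positive")


def ym_rayleigh(cg: float, nu: float = 0.5, rho: float = 1000.0) -> ElasticityResult:
    """Young's modulus from a surface-wave group velocity.

    ``E = 2 rho (1 + nu)^3 / (0.87 + 1.12 nu)^2 * Cg^2``; the rational factor
    is the standard approximation of the Rayleigh speed as a fraction of the
    shear speed.
    """
    _check_speed_nu_rho(cg, nu, rho)
    e = 2.0 * rho * (1.0 + nu) ** 3 / (0.87 + 1.12 * nu) ** 2 * cg**2
    return ElasticityResult(e, "rayleigh_surface", cg, nu, rho)


def ym_shear(c: float, rho: float = 1000.0) -> ElasticityResult:
    """Young's modulus from a bulk shear-wave speed: ``E = 3 rho c^2``."""
    _check_speed_nu_rho(c, 0.5, rho)
    return ElasticityResult(3.0 * rho * c**2, "shear", c, 0.5, rho)


def rayleigh_shear_ratio(nu: float = 0.5, method: Method = "exact_secular") -> float:
    """Ratio of Rayleigh surface-wave speed to bulk shear-wave speed.

    ``exact_secular`` solves the Rayleigh secular cubic in the squared speed
    ratio ``eta = (c_R / c_s)^2``::

        eta^3 - 8 eta^2 + 8 (3 - 2 xi) eta - 16 (1 - xi) = 0,
        xi = (1 - 2 nu) / (2 (1 - nu))

    for the root in (0, 1) to 1e-12 and returns ``sqrt(eta)``; at nu = 0.5
    this gives 0.9553 (~95.5%).  ``approximate`` returns the familiar
    rational fit ``(0.87 + 1.12 nu) / (1 + nu)`` (0.9533 at nu = 0.5).
    """
    if not (0.0 <= nu <= 0.5):
        raise ParameterError("poisson ratio must lie in [0, 0.5]")
    if method == "approximate":
        return (0.87 + 1.12 * nu) / (1.0 + nu)
    if method != "exact_secular":
        raise ParameterError(f"unknown method {method!r}")
    xi = (1.0 - 2.0 * nu) / (2.0 * (1.0 - nu))

    def secular(eta: float) -> float:
        return eta**3 - 8.0 * eta**2 + 8.0 * (3.0 - 2.0 * xi) * eta - 16.0 * (1.0 - xi)

    eta = brentq(secular, 1e-12, 1.0 - 1e-12, xtol=1e-12, rtol=8.9e-16)
    return float(np.sqrt(eta))


def rayleigh_to_shear_speed(
    cg: float, nu: float = 0.5, method: Method = "exact_secular"
) -> float:
    """Convert a measured surface-wave speed to the equivalent shear-wave
    speed by dividing out the Rayleigh/shear ratio."""
    if not (cg > 0):
        raise ParameterError("wave speed must be positive")
    return cg / rayleigh_shear_ratio(nu, method)
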