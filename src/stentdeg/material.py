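"""Degradation-dependent constitutive parameters of the stent polymer.

Poly(lactic acid) loses both strength and stiffness as hydrolysis cuts its
chains.  Two laws are implemented:

* the yield strength decays exponentially with the accumulated degradation,
  scaled by a fatigue knock-down factor for the pulsatile blood-pressure
  loading, and
* the elastic modulus interpolates between the intact polymer modulus and
  the modulus of the fully hydrolysed material (treated as water-like,
  a small but non-zero stiffness so fully degraded regions are softened
  rather than removed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["MaterialLaw", "yield_strength", "modulus"]

_E_OVER_EM1 = math.e / (math.e - 1.0)


@dataclass(frozen=True)
class MaterialLaw:
    """Constitutive constants of the stent polymer.

    Parameters
    ----------
    E_s0:
        Young's modulus of the intact polymer, MPa.
    E_water:
        Modulus assigned to fully degraded material, MPa.  Degraded
        material points are never deleted; they keep this small modulus.
    sigma_y0:
        Initial yield strength, MPa.
    nu:
        Poisson's ratio (used for the torsional shear modulus).
    phi:
        Proportionality between the strength-decay rate and the local
        degradation rate (dimensionless).
    eta:
        Fatigue-induced strength-reduction coefficient in (0, 1]; applied
        as a constant multiplier representing the cyclic blood-pressure
        loading.
    modulus_form:
        ``"saturating"`` uses E(beta) = (E_s0-E_water)*e/(e-1)*(1-exp(-beta))
        + E_water; ``"exponential"`` uses the alternative
        (E_s0-E_water)*(exp(beta)-1)/(e-1) + E_water.  Both are exact at the
        endpoints beta = 0 and beta = 1.
    """

    E_s0: float = 3000.0
    E_water: float = 10.0
    sigma_y0: float = 50.0
    nu: float = 0.3
    phi: float = 1.225
    eta: float = 0.99
    modulus_form: str = "saturating"

    def __post_init__(self) -> None:
        if not (self.E_s0 > self.E_water > 0.0):
            raise ValueError("require E_s0 > E_water > 0")
        if not (0.0 < self.eta <= 1.0):
            raise ValueError("eta must be in (0, 1]")
        if self.sigma_y0 <= 0.0:
            raise ValueError("sigma_y0 must be positive")
        if self.modulus_form not in ("saturating", "exponential"):
            raise ValueError("modulus_form must be 'saturating' or 'exponential'")

    @property
    def shear_modulus(self) -> float:
        return self.E_s0 / (2.0 * (1.0 + self.nu))


def yield_strength(rate_integral, law: MaterialLaw):
    """Current yield strength after a given accumulated degradation exposure.

    ``rate_integral`` is the time integral of the local degradation rate,
    ``int_0^t lambda(tau) dtau`` (dimensionless).  The strength decays as

        sigma_y(t) = eta * sigma_y0 * exp(-phi * rate_integral)

    which for a constant rate reduces to eta*sigma_y0*exp(-Lambda*t) with
    Lambda = phi*lambda.  Accepts scalars or arrays.
    """
    rate_integral = np.asarray(rate_integral, dtype=float)
    if np.any(rate_integral < 0.0):
        raise ValueError("rate integral must be non-negative")
    out = law.eta * law.sigma_y0 * np.exp(-law.phi * rate_integral)
    return float(out) if out.ndim == 0 else out


def modulus(beta, law: MaterialLaw):
    """Elastic modulus at normalized molecular weight ``beta`` in [0, 1].

    The default form rises steeply from E_water at beta = 0 and saturates
    at E_s0 at beta = 1; both endpoints are exact.  Accepts scalars or
    arrays.
    """
    beta = np.asarray(beta, dtype=float)
    if np.any(beta < -1e-12) or np.any(beta > 1.0 + 1e-12):
        raise ValueError("beta must lie in [0, 1]")
    beta = np.clip(beta, 0.0, 1.0)
    dE = law.E_s0 - law.E_water
    if law.modulus_form == "saturating":
        out = dE * _E_OVER_EM1 * (1.0 - np.exp(-beta)) + law.E_water
        # enforce the exact endpoint at beta = 1 despite rounding
        out = np.where(beta == 1.0, law.E_s0, out)
    else:
        out = dE * (np.expm1(beta)) / (math.e - 1.0) + law.E_water
    return float(out) if out.ndim == 0 else out
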