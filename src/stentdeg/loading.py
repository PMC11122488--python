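"""Haemodynamic and structural loads.

Contains the fitted human blood-pressure waveform (a sum of three
Gaussians), the trapezoidal balloon inflation program, and the closed-form
response of an incompressible Mooney-Rivlin artery modelled as a
plane-strain thick-walled tube.  The tube solution replaces a full 3-D
vessel model: it supplies the inward "foundation" pressure the artery
exerts on a stent that holds it open beyond its unloaded lumen.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import integrate

__all__ = [
    "Waveform",
    "BalloonProgram",
    "VesselSpec",
    "blood_pressure",
    "mean_pressure",
    "mr_tube_pressure",
    "vessel_foundation",
]


@dataclass(frozen=True)
class Waveform:
    """Three-Gaussian fit of the human blood-pressure pulse.

    Each component is (amplitude kPa, center s, width s); the default
    coefficients are the fitted systolic spike, dicrotic bump and diastolic
    baseline.  Evaluated modulo ``period``.
    """

    components: tuple = (
        (3.5, 0.1543, 0.1373),
        (0.9784, 0.4168, 0.07873),
        (13.49, 0.4487, 1.006),
    )
    period: float = 0.8  # s

    def __post_init__(self) -> None:
        for amp, _, width in self.components:
            if amp <= 0.0 or width <= 0.0:
                raise ValueError("waveform amplitudes and widths must be positive")
        if self.period <= 0.0:
            raise ValueError("period must be positive")


@dataclass(frozen=True)
class BalloonProgram:
    """Trapezoidal balloon pressure history (ramp up, hold, ramp down)."""

    ramp_up: float = 0.1  # s
    hold: float = 0.1  # s
    ramp_down: float = 0.1  # s
    peak_pressure: float = 0.45  # MPa, calibrated so the built-in designs
    # deploy into the 3.0-3.4 mm band against the default vessel

    def __post_init__(self) -> None:
        if min(self.ramp_up, self.hold, self.ramp_down) < 0.0:
            raise ValueError("durations must be non-negative")
        if self.peak_pressure < 0.0:
            raise ValueError("peak pressure must be non-negative")

    def pressure(self, t: float) -> float:
        """Balloon pressure (MPa) at time t since inflation start."""
        t1 = self.ramp_up
        t2 = t1 + self.hold
        t3 = t2 + self.ramp_down
        if t < 0.0 or t > t3:
            return 0.0
        if t < t1:
            return self.peak_pressure * (t / t1 if t1 > 0 else 1.0)
        if t <= t2:
            return self.peak_pressure
        return self.peak_pressure * (1.0 - (t - t2) / self.ramp_down)


@dataclass(frozen=True)
class VesselSpec:
    """Idealized straight artery segment (incompressible Mooney-Rivlin)."""

    inner_diameter: float = 3.0  # mm
    thickness: float = 0.4  # mm
    length: float = 6.0  # mm
    C10: float = 1.023  # MPa
    C01: float = 0.710  # MPa

    def __post_init__(self) -> None:
        if self.C10 <= 0.0 or self.C01 <= 0.0:
            raise ValueError("Mooney-Rivlin constants must be positive")
        if min(self.inner_diameter, self.thickness, self.length) <= 0.0:
            raise ValueError("vessel dimensions must be positive")

    @property
    def inner_radius(self) -> float:
        return self.inner_diameter / 2.0

    @property
    def outer_radius(self) -> float:
        return self.inner_radius + self.thickness


def blood_pressure(t, waveform: Waveform | None = None):
    """Blood pressure in kPa at time(s) ``t`` (seconds, periodic)."""
    w = waveform or Waveform()
    t = np.asarray(t, dtype=float)
    if np.any(t < 0.0):
        raise ValueError("t must be non-negative")
    tm = np.mod(t, w.period)
    p = np.zeros_like(tm)
    for amp, center, width in w.components:
        p = p + amp * np.exp(-(((tm - center) / width) ** 2))
    return float(p) if p.ndim == 0 else p


def mean_pressure(waveform: Waveform | None = None, period: float | None = None) -> float:
    """Time-averaged blood pressure (kPa) over one cardiac cycle."""
    w = waveform or Waveform()
    T = period if period is not None else w.period
    if T <= 0.0:
        raise ValueError("period must be positive")
    val, err = integrate.quad(lambda t: blood_pressure(t, w), 0.0, T, limit=200)
    return val / T


def mr_tube_pressure(inner_stretch: float, vessel: VesselSpec) -> float:
    """Inflation pressure (MPa) of the artery tube at a given inner stretch.

    Plane-strain incompressible Mooney-Rivlin thick-walled cylinder: with
    circumferential stretch lambda(r) = r/r0 fixed by incompressibility,

        P = int_a^b (sigma_theta - sigma_r)/r dr,
        sigma_theta - sigma_r = 2 (C10 + C01) (lambda^2 - lambda^-2).
    """
    if inner_stretch < 1.0:
        raise ValueError("inner_stretch must be >= 1 (compression not modelled)")
    if inner_stretch == 1.0:
        return 0.0
    a0 = vessel.inner_radius
    b0 = vessel.outer_radius
    a = inner_stretch * a0
    c2 = 2.0 * (vessel.C10 + vessel.C01)

    def integrand(r: float) -> float:
        r0 = np.sqrt(r * r - a * a + a0 * a0)
        lam = r / r0
        return c2 * (lam * lam - 1.0 / (lam * lam)) / r

    b = np.sqrt(b0 * b0 + a * a - a0 * a0)
    val, err = integrate.quad(integrand, a, b, epsabs=1e-12, epsrel=1e-12, limit=200)
    return val


def vessel_foundation(stent_radius: float, vessel: VesselSpec) -> float:
    """Inward radial pressure (MPa) the artery exerts on the stent.

    Zero until the stent outer radius reaches the vessel's unloaded inner
    radius; beyond contact, the stent imposes the inner stretch and feels
    the tube inflation pressure back.  Continuous and non-decreasing in
    stent radius.
    """
    a0 = vessel.inner_radius
    if stent_radius <= a0:
        return 0.0
    return mr_tube_pressure(stent_radius / a0, vessel)
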