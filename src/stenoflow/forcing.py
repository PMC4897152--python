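"""Time-dependent driving terms and physical scales.

The flow is driven by a prescribed oscillatory axial pressure gradient

    -dp/dz = p0 + p1 cos(omega t),        t > 0,

(p0 the steady component, p1 the pulsatile component arising from the
heartbeat) and, when the body undergoes whole-body motion, by a periodic
axial body-acceleration force

    F_ext = a0 cos(omega t + phi),

with amplitude ``a0`` and phase lead ``phi`` relative to the pressure
pulse.  All quantities are nondimensional: velocities are scaled by the
mean blood speed ``u_inf``, lengths by the tube radius ``r0`` and time by
``r0 / u_inf``; :class:`PhysicalScales` converts to and from CGS units.

The default angular frequency follows from a 72 beats/min heart rate
(f = 1.2 Hz) expressed in these units for the base case (Re = 400,
aortic-scale radius r0 = 1.2 cm, blood viscosity 0.035 P, density
1.05 g/cm^3, hence u_inf = Re nu / r0 ~= 11 cm/s):
omega = 2 pi f r0 / u_inf ~= 0.8, which corresponds to a Womersley
number alpha = sqrt(omega Re) ~= 17.9, the upper physiological range of
the large arteries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "DEFAULT_OMEGA",
    "PressureForcing",
    "BodyAcceleration",
    "PhysicalScales",
]

#: default nondimensional angular frequency of the heart pulse
#: (2 pi * 1.2 Hz in units of u_inf / r0 for the Re = 400 base case)
DEFAULT_OMEGA = 0.8


@dataclass(frozen=True)
class PressureForcing:
    """Prescribed axial pressure gradient ``-dp/dz = p0 + p1 cos(omega t)``."""

    p0: float = 0.1
    p1: float = 0.02
    omega: float = DEFAULT_OMEGA

    def __post_init__(self) -> None:
        if self.p0 < 0 or self.p1 < 0 or self.omega < 0:
            raise ValueError("p0, p1 and omega must be non-negative")

    @property
    def period(self) -> float:
        """Forcing period 2 pi / omega (inf for steady forcing)."""
        return 2.0 * math.pi / self.omega if self.omega > 0 else math.inf

    def pressure_gradient(self, t):
        """Value of ``-dp/dz`` at time ``t`` (scalar or array)."""
        return self.p0 + self.p1 * np.cos(self.omega * np.asarray(t, dtype=float))

    __call__ = pressure_gradient


@dataclass(frozen=True)
class BodyAcceleration:
    """Periodic axial body force ``F_ext = a0 cos(omega t + phi)``.

    ``a0 = 0`` switches the body acceleration off exactly (the force is
    identically zero, not merely small).
    """

    a0: float = 0.1
    phi: float = 0.0
    omega: float = DEFAULT_OMEGA

    def __post_init__(self) -> None:
        if self.a0 < 0:
            raise ValueError("a0 must be non-negative")

    @property
    def period(self) -> float:
        return 2.0 * math.pi / self.omega if self.omega > 0 else math.inf

    def body_force(self, t):
        """Value of the body force at time ``t`` (scalar or array)."""
        # a0 * cos(...) is exactly 0.0 when a0 == 0 for any finite t
        return self.a0 * np.cos(self.omega * np.asarray(t, dtype=float) + self.phi)

    __call__ = body_force


@dataclass(frozen=True)
class PhysicalScales:
    """Dimensional scales used only for unit conversion and reporting.

    The solver itself runs nondimensionally; these defaults are the standard
    large-artery values of the haemodynamics literature (CGS units).

    Attributes
    ----------
    r0 : tube radius [cm]
    rho : blood density [g/cm^3]
    mu : dynamic viscosity [poise = g/(cm s)]
    """

    r0: float = 1.2
    rho: float = 1.05
    mu: float = 0.035

    def __post_init__(self) -> None:
        if self.r0 <= 0 or self.rho <= 0 or self.mu <= 0:
            raise ValueError("all physical scales must be strictly positive")

    @property
    def nu(self) -> float:
        """Kinematic viscosity [cm^2/s]."""
        return self.mu / self.rho

    def mean_velocity(self, re: float) -> float:
        """Mean blood speed u_inf [cm/s] implied by Re = r0 u_inf / nu."""
        if re <= 0:
            raise ValueError("Reynolds number must be positive")
        return re * self.nu / self.r0

    def reynolds(self, u_inf: float) -> float:
        """Reynolds number for a given mean velocity [cm/s]."""
        return self.r0 * u_inf / self.nu

    def angular_frequency(self, f_hz: float, re: float) -> float:
        """Nondimensional angular frequency of a pulse at ``f_hz`` Hz."""
        return 2.0 * math.pi * f_hz * self.r0 / self.mean_velocity(re)

    def womersley_number(self, f_hz: float) -> float:
        """Dimensional Womersley number r0 sqrt(2 pi f / nu)."""
        return self.r0 * math.sqrt(2.0 * math.pi * f_hz / self.nu)

    def wall_shear_to_cgs(self, tau_nd: float, re: float) -> float:
        """Convert a code-unit wall shear stress to dyn/cm^2."""
        return tau_nd * self.mu * self.mean_velocity(re) / self.r0
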