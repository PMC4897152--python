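"""Stenosed-artery wall geometry.

The arterial segment is modelled as a rigid axisymmetric tube of unit
dimensionless radius (lengths are scaled by the unconstricted radius
``r0``).  Two consecutive cosine-shaped constrictions are carved into the
wall: on the axial interval ``[d, d + 2l]`` the lumen radius is

    h(z) = 1 - lambda * cos(pi z / l)   for d      <= z < d + l,
    h(z) = 1 + lambda * cos(pi z / l)   for d + l  <= z <= d + 2l,
    h(z) = 1                            otherwise,

where ``lambda`` is the dimensionless constriction amplitude, ``2l`` is the
length of one stenosis and ``d`` the axial offset of the stenosed zone from
the inlet.  With the default parameters (lambda=0.5, l=2, d=3) the profile
is continuous, the stenosed zone spans ``[3, 7]`` and the two throats (the
stations of minimum lumen radius ``1 - lambda``) sit at z = 4 and z = 6.

The absolute-phase cosine makes the profile continuous at the three branch
junctions only when ``cos(pi d / l) = 0``, i.e. when ``d`` is an odd
multiple of ``l/2``; the constructor rejects constricted geometries that
violate this, since a jump in h(z) would feed unbounded derivatives into
the transformed momentum equations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["StenosisGeometry"]

#: junction mismatch (in units of the tube radius) above which a constricted
#: profile is considered discontinuous and rejected
_JUNCTION_TOL = 1e-9


@dataclass(frozen=True)
class StenosisGeometry:
    """Wall profile of a tube with two consecutive cosine stenoses.

    Parameters
    ----------
    lambda_:
        Constriction amplitude, ``0 <= lambda_ < 1``.  ``lambda_ = 0`` is a
        straight tube.
    l:
        Half-length of one stenosis unit (tube-radius units); each cosine
        branch spans an axial distance ``l``.
    d:
        Axial offset of the stenosed zone from the inlet.
    domain_length:
        Total axial extent L of the simulated segment.
    """

    lambda_: float = 0.5
    l: float = 2.0
    d: float = 3.0
    domain_length: float = 10.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.lambda_ < 1.0:
            raise ValueError(
                f"lambda: constriction amplitude must satisfy 0 <= lambda < 1, got {self.lambda_}"
            )
        if self.l <= 0.0:
            raise ValueError(f"l: stenosis half-unit length must be positive, got {self.l}")
        if self.d < 0.0:
            raise ValueError(f"d: stenosis offset must be non-negative, got {self.d}")
        if self.d + 2.0 * self.l > self.domain_length + 1e-12:
            raise ValueError(
                "d + 2 l exceeds domain_length: the stenosed zone "
                f"[{self.d}, {self.d + 2 * self.l}] must lie inside the tube of length "
                f"{self.domain_length}"
            )
        if self.lambda_ > 0.0 and abs(math.cos(math.pi * self.d / self.l)) > _JUNCTION_TOL:
            raise ValueError(
                "wall profile is discontinuous at the stenosis junctions: the "
                "absolute-phase cosine profile is continuous only when "
                "cos(pi d / l) = 0 (d an odd multiple of l/2); got "
                f"d={self.d}, l={self.l}"
            )

    # ------------------------------------------------------------------ #
    # branch bookkeeping
    # ------------------------------------------------------------------ #
    @property
    def zone(self) -> tuple[float, float]:
        """Axial interval ``[d, d + 2l]`` occupied by the stenoses."""
        return (self.d, self.d + 2.0 * self.l)

    def _check_domain(self, z: np.ndarray) -> None:
        if np.any(z < -1e-12) or np.any(z > self.domain_length + 1e-12):
            raise ValueError(
                f"axial coordinate outside the tube [0, {self.domain_length}]"
            )

    def _branches(self, z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        first = (z >= self.d) & (z < self.d + self.l)
        second = (z >= self.d + self.l) & (z <= self.d + 2.0 * self.l)
        return first, second

    # ------------------------------------------------------------------ #
    # profile and derivatives
    # ------------------------------------------------------------------ #
    def wall_radius(self, z):
        """Dimensionless lumen radius h(z); vectorized over ``z``."""
        z_arr = np.asarray(z, dtype=float)
        self._check_domain(z_arr)
        first, second = self._branches(z_arr)
        cosz = np.cos(np.pi * z_arr / self.l)
        h = np.ones_like(z_arr)
        h = np.where(first, 1.0 - self.lambda_ * cosz, h)
        h = np.where(second, 1.0 + self.lambda_ * cosz, h)
        return h if h.ndim else float(h)

    def wall_slope(self, z):
        """First axial derivative dh/dz of the wall profile."""
        z_arr = np.asarray(z, dtype=float)
        self._check_domain(z_arr)
        first, second = self._branches(z_arr)
        k = np.pi / self.l
        sinz = np.sin(k * z_arr)
        dh = np.zeros_like(z_arr)
        dh = np.where(first, self.lambda_ * k * sinz, dh)
        dh = np.where(second, -self.lambda_ * k * sinz, dh)
        return dh if dh.ndim else float(dh)

    def wall_curvature(self, z):
        """Second axial derivative d2h/dz2 of the wall profile."""
        z_arr = np.asarray(z, dtype=float)
        self._check_domain(z_arr)
        first, second = self._branches(z_arr)
        k = np.pi / self.l
        cosz = np.cos(k * z_arr)
        d2h = np.zeros_like(z_arr)
        d2h = np.where(first, self.lambda_ * k * k * cosz, d2h)
        d2h = np.where(second, -self.lambda_ * k * k * cosz, d2h)
        return d2h if d2h.ndim else float(d2h)

    # ------------------------------------------------------------------ #
    # throats
    # ------------------------------------------------------------------ #
    def throat_locations(self) -> list[float]:
        """Axial stations of maximal constriction, one per cosine branch.

        Each branch minimum of h(z) is found among its analytic critical
        points (integer multiples of ``l``, where sin(pi z / l) = 0) and the
        branch endpoints.  Returns an empty list for a straight tube
        (``lambda_ = 0``: no throat).
        """
        if self.lambda_ == 0.0:
            return []
        throats: list[float] = []
        intervals = [
            (self.d, self.d + self.l),
            (self.d + self.l, self.d + 2.0 * self.l),
        ]
        for a, b in intervals:
            candidates = [a, b]
            k_lo = math.ceil(a / self.l)
            k_hi = math.floor(b / self.l)
            candidates.extend(k * self.l for k in range(k_lo, k_hi + 1))
            zc = np.clip(np.unique(np.asarray(candidates, dtype=float)), a, b)
            # evaluate the branch expression directly so the half-open interval
            # convention cannot push an endpoint onto the neighbouring branch
            if a == self.d:
                hc = 1.0 - self.lambda_ * np.cos(np.pi * zc / self.l)
            else:
                hc = 1.0 + self.lambda_ * np.cos(np.pi * zc / self.l)
            throats.append(float(zc[int(np.argmin(hc))]))
        return throats
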