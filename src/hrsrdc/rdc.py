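"""Geometry of dipolar couplings: P2, instantaneous and ensemble RDCs."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .constants import CONSTANTS, PhysicalConstants, dipolar_constant

__all__ = [
    "RDCDefinition",
    "OrientationSample",
    "legendre_p2",
    "instantaneous_rdc",
    "ensemble_rdc",
]


@dataclass(frozen=True)
class RDCDefinition:
    """One residual dipolar coupling restraint.

    Parameters
    ----------
    id : str
        Free-form label (e.g. ``"HN2-N2"``).
    atoms : tuple[int, int]
        0-based indices of the two nuclei into a structure.
    isotopes : tuple[str, str]
        Isotope labels, e.g. ``("15N", "1H")``.
    r0 : float
        Reference internuclear distance in nm.
    d_const : float
        Maximal dipolar coupling D_k^c in Hz (sign = -sign(gamma1*gamma2)).
    target : float or None
        Target (measured) RDC D_k^0 in Hz, if any.
    """

    id: str
    atoms: tuple[int, int]
    isotopes: tuple[str, str]
    r0: float
    d_const: float
    target: float | None = None

    def __post_init__(self) -> None:
        if self.r0 <= 0:
            raise ValueError(f"r0 must be positive, got {self.r0}")

    @classmethod
    def from_isotopes(
        cls,
        id: str,
        atoms: tuple[int, int],
        isotopes: tuple[str, str],
        r0: float,
        target: float | None = None,
        constants: PhysicalConstants = CONSTANTS,
    ) -> "RDCDefinition":
        """Build a definition computing D_k^c from the gyromagnetic table."""
        dc = dipolar_constant(isotopes[0], isotopes[1], r0, constants)
        return cls(id=id, atoms=atoms, isotopes=isotopes, r0=r0,
                   d_const=dc, target=target)


@dataclass(frozen=True)
class OrientationSample:
    """A single (theta, r) orientation sample of an internuclear vector.

    ``theta`` is the angle in degrees between the internuclear vector and the
    magnetic-field vector; ``p2`` its second-order Legendre value; ``r`` the
    instantaneous internuclear distance in nm.
    """

    theta: float
    p2: float
    r: float

    @classmethod
    def from_theta(cls, theta: float, r: float) -> "OrientationSample":
        return cls(theta=theta, p2=legendre_p2(theta), r=r)


def legendre_p2(theta_deg):
    """Second-order Legendre function (3 cos^2(theta) - 1)/2.

    ``theta_deg`` is an angle in degrees in [0, 180].  The function has
    maxima of 1 at 0 and 180 degrees, a minimum of -1/2 at 90 degrees, and
    zeros at the magic angles (|cos theta| = 3^-1/2, about 54.74 and 125.26
    degrees).  It is symmetric about 90 degrees.
    """
    theta = np.asarray(theta_deg, dtype=float)
    if np.any(theta < 0) or np.any(theta > 180):
        raise ValueError("theta must lie in [0, 180] degrees")
    c = np.cos(np.deg2rad(theta))
    out = 0.5 * (3.0 * c * c - 1.0)
    return float(out) if np.isscalar(theta_deg) else out


def _cos_angle(u: np.ndarray, v: np.ndarray) -> float:
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ValueError("degenerate geometry: zero-length vector")
    return float(np.dot(u, v) / (nu * nv))


def instantaneous_rdc(
    rdc: RDCDefinition,
    bond_vec: np.ndarray,
    field_vec: np.ndarray,
) -> float:
    """Instantaneous coupling D_k(t) in Hz for one configuration.

    D_k = D_k^c * (r0/r)^3 * P2(cos theta) with theta the angle between the
    internuclear vector ``bond_vec`` and the magnetic-field vector
    ``field_vec``.  Invariant to independent rescaling of either vector's
    direction (only ``|bond_vec|`` enters through the distance ratio).
    """
    bond_vec = np.asarray(bond_vec, dtype=float)
    field_vec = np.asarray(field_vec, dtype=float)
    r = np.linalg.norm(bond_vec)
    c = _cos_angle(bond_vec, field_vec)
    p2 = 0.5 * (3.0 * c * c - 1.0)
    return rdc.d_const * (rdc.r0 / r) ** 3 * p2


def ensemble_rdc(
    rdc: RDCDefinition,
    samples: Sequence[OrientationSample],
    separate_averaging: bool = True,
    weights: Sequence[float] | None = None,
) -> float:
    """Ensemble-averaged coupling <D_k> in Hz over orientation samples.

    With ``separate_averaging`` the distance and angular factors are averaged
    independently, <D_k> = D_k^c * <(r0/r)^3> * <P2>; this is the separable
    approximation valid when bond-length fluctuations decouple from the
    rotational motion.  Without it the plain mean of the per-sample products
    is returned.  The two coincide exactly when all r equal r0.
    """
    if len(samples) == 0:
        raise ValueError("ensemble_rdc requires at least one sample")
    p2 = np.array([s.p2 for s in samples])
    ratio3 = np.array([(rdc.r0 / s.r) ** 3 for s in samples])
    w = None
    if weights is not None:
        w = np.asarray(weights, dtype=float)
        w = w / w.sum()
    if separate_averaging:
        return rdc.d_const * float(np.average(ratio3, weights=w)) * float(
            np.average(p2, weights=w)
        )
    return rdc.d_const * float(np.average(ratio3 * p2, weights=w))
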