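"""Physical constants and dipolar-coupling prefactors.

All molecular-scale quantities follow the GROMOS basic-unit convention:
nanometre (nm) for length, atomic mass unit (u) for mass, picosecond (ps)
for time, Kelvin (K) for temperature and electronic charge (e) for charge,
which fixes kJ/mol for energy.  Dipolar couplings are carried in Hz at every
interface; restraint force constants are therefore expressed in
kJ mol^-1 Hz^-2 (the equivalent of GROMOS' native THz convention with a
single 1e12 scale factor, see :data:`HZ_PER_THZ`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "PhysicalConstants",
    "CONSTANTS",
    "KB",
    "HZ_PER_THZ",
    "dipolar_prefactor",
    "dipolar_prefactor_si",
    "dipolar_constant",
]

#: Boltzmann constant, kJ mol^-1 K^-1 (GROMOS value).
KB = 8.31441e-3

#: Unit bridge between Hz-facing interfaces and ps^-1 internals.
HZ_PER_THZ = 1.0e12

#: CODATA/IUPAC gyromagnetic ratios, rad s^-1 T^-1.  15N is negative.
GYROMAGNETIC_RATIOS: dict[str, float] = {
    "1H": 2.6752219e8,
    "2H": 4.1066279e7,
    "13C": 6.728284e7,
    "14N": 1.9337792e7,
    "15N": -2.712618e7,
}


@dataclass(frozen=True)
class PhysicalConstants:
    """Fundamental constants in GROMOS units plus the gyromagnetic table.

    Attributes
    ----------
    mu0 : float
        Magnetic permeability of vacuum, kJ mol^-1 ps^2 e^-2 nm^-1.
    h_planck : float
        Planck constant, kJ mol^-1 ps.
    kB : float
        Boltzmann constant, kJ mol^-1 K^-1.
    gyromagnetic : dict
        Isotope label -> gyromagnetic ratio (rad s^-1 T^-1).
    """

    mu0: float = 1.9425913e-8
    h_planck: float = 0.3990313
    kB: float = KB
    mu0_si: float = 4.0e-7 * math.pi          # J s^2 C^-2 m^-1
    h_planck_si: float = 6.626176e-34         # J s
    gyromagnetic: dict[str, float] = field(
        default_factory=lambda: dict(GYROMAGNETIC_RATIOS)
    )

    def gamma(self, isotope: str) -> float:
        """Gyromagnetic ratio of ``isotope`` (rad s^-1 T^-1)."""
        try:
            return self.gyromagnetic[isotope]
        except KeyError:
            known = ", ".join(sorted(self.gyromagnetic))
            raise KeyError(
                f"unknown isotope {isotope!r}; known isotopes: {known}"
            ) from None


#: Module-level default constants table.
CONSTANTS = PhysicalConstants()


def dipolar_prefactor(r0_nm: float, constants: PhysicalConstants = CONSTANTS) -> float:
    """-mu0*h/(2*pi*r0^3) in GROMOS units, (kJ mol^-1)^2 ps^3 e^-2 nm^-4.

    For r0 = 0.1 nm this evaluates to -1.2336e-6.
    """
    if r0_nm <= 0:
        raise ValueError(f"r0 must be positive, got {r0_nm}")
    return -constants.mu0 * constants.h_planck / (2.0 * math.pi * r0_nm**3)


def dipolar_prefactor_si(r0_m: float, constants: PhysicalConstants = CONSTANTS) -> float:
    """-mu0*h/(2*pi*r0^3) in SI units, J^2 s^3 C^-2 m^-4.

    For r0 = 1e-10 m this evaluates to -1.3252e-10.
    """
    if r0_m <= 0:
        raise ValueError(f"r0 must be positive, got {r0_m}")
    return -constants.mu0_si * constants.h_planck_si / (2.0 * math.pi * r0_m**3)


def dipolar_constant(
    iso1: str,
    iso2: str,
    r0_nm: float,
    constants: PhysicalConstants = CONSTANTS,
) -> float:
    """Maximal dipolar coupling D_k^c in Hz for an isotope pair at r0.

    D_k^c = -mu0 * h * gamma1 * gamma2 / (8 * pi^3 * r0^3), evaluated in SI
    and returned in Hz.  The sign is opposite to that of gamma1*gamma2, so a
    15N-1H pair has a positive constant (+24.36 kHz at r0 = 0.1 nm) while
    13C-1H and 1H-1H pairs have negative ones.
    """
    if r0_nm <= 0:
        raise ValueError(f"r0 must be positive, got {r0_nm}")
    g1 = constants.gamma(iso1)
    g2 = constants.gamma(iso2)
    r0_m = r0_nm * 1e-9
    return -constants.mu0_si * constants.h_planck_si * g1 * g2 / (
        8.0 * math.pi**3 * r0_m**3
    )
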