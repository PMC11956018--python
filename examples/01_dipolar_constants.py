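"""Dipolar coupling constants and instantaneous couplings.

The maximal dipolar coupling D_k^c = -mu0 h gamma1 gamma2 / (8 pi^3 r0^3)
sets the kHz scale from which tumbling averages the measured residual
couplings down to Hz.  The instantaneous coupling for one geometry is
D_k^c (r0/r)^3 P2(cos theta) with theta the angle between the internuclear
vector and the magnetic field.
"""

import numpy as np

from hrsrdc import RDCDefinition, dipolar_constant, instantaneous_rdc, legendre_p2

for iso1, iso2, r0 in [("15N", "1H", 0.100), ("13C", "1H", 0.109),
                       ("1H", "1H", 0.178)]:
    print(f"D^c({iso1}-{iso2}, r0={r0} nm) = "
          f"{dipolar_constant(iso1, iso2, r0) / 1e3:+.2f} kHz")

rdc = RDCDefinition.from_isotopes("HN", (0, 1), ("15N", "1H"), r0=0.100)
field = np.array([0.0, 0.0, 1.0])
for theta in (0.0, 54.7356, 90.0):
    bond = 0.1 * np.array([np.sin(np.radians(theta)), 0.0,
                           np.cos(np.radians(theta))])
    print(f"theta = {theta:8.4f} deg: P2 = {legendre_p2(theta):+.3f}, "
          f"D = {instantaneous_rdc(rdc, bond, field) / 1e3:+.2f} kHz")

print("The coupling vanishes at the magic angle (|cos theta| = 3^-1/2) and")
print("spans [-D^c/2, +D^c] between perpendicular and parallel geometries.")
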