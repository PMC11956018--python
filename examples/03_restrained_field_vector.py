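"""Flat-bottom restrained stochastic dynamics of the magnetic-field vector.

A two-particle rigid rotor samples orientations under Langevin dynamics;
flat-bottom restraints on the exponentially time-averaged couplings drive
the rotational distribution so that the couplings of a fixed helix frame
match their targets.  Reported couplings are plain means over the
post-burn-in window.
"""

import numpy as np

from hrsrdc import AlignmentTensor, generate_rdc_targets, make_toy_helix
from hrsrdc.mfv import SDParams, simulate_mfv
from hrsrdc.restraints import RestraintParams

helix = make_toy_helix()
tensor = AlignmentTensor.from_components([4e-4, 2e-4, 1e-4, -1e-4, 5e-5])
rdcs = generate_rdc_targets(helix, tensor)
vecs = np.array([helix.bond_vector(r.atoms) for r in rdcs])

res = simulate_mfv(
    rdcs, vecs,
    RestraintParams(k_rdc=100.0, delta_fb=2.0, delta_h=1.0),
    SDParams(n_steps=10_000_000, seed=4),
    tau=2000.0, burn_in=1_000_000, damped_init="targets",
)

dev = res["deviations"]
print(f"{len(rdcs)} restrained couplings, 1e7 SD steps (20 ns)")
print(f"max |<D> - D0| = {np.abs(dev).max():.2f} Hz, "
      f"rmsd = {np.sqrt((dev ** 2).mean()):.2f} Hz")
print(f"kinetic temperature = {res['kinetic_temperature']:.1f} K, "
      f"max bond deviation = {res['max_bond_deviation']:.1e} (relative)")
print("Deviations within the 2 Hz flat bottom mean the restrained")
print("orientation distribution reproduces every target coupling.")
print("Note the elevated kinetic temperature: at this K/tau the restraint")
print("forces outrun the Langevin dissipation. The field vector is a")
print("sampling device, not a physical particle, but the heating marks the")
print("strong-restraint regime where magic-angle diagnostics must be")
print("watched (larger tau restores ~298 K at the cost of slower")
print("convergence; see docs/methods.md).")
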