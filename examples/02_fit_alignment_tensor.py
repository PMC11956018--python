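"""Five-parameter alignment-tensor fit on synthetic couplings.

Couplings back-calculated from a known symmetric traceless tensor on the
toy helix are refit by linear least squares; with no noise the tensor is
recovered to machine precision, and added noise propagates into the fit
residual as expected for a 5-parameter linear model.
"""

import numpy as np

from hrsrdc import (
    AlignmentTensor,
    fit_alignment_tensor,
    generate_rdc_targets,
    make_toy_helix,
)

helix = make_toy_helix()
truth = AlignmentTensor.from_components([2e-4, 1e-4, -5e-5, 3e-5, 8e-5])

for noise in (0.0, 1.0):
    rdcs = generate_rdc_targets(helix, truth, noise_sd=noise, seed=1)
    vecs = np.array([helix.bond_vector(r.atoms) for r in rdcs])
    units = vecs / np.linalg.norm(vecs, axis=1)[:, None]
    fit = fit_alignment_tensor(rdcs, units, [r.target for r in rdcs])
    err = np.abs(np.array(fit.tensor.a) - np.array(truth.a)).max()
    print(f"noise {noise:.1f} Hz: fit rmsd = {fit.rmsd:.3f} Hz, "
          f"max tensor-component error = {err:.2e}, "
          f"condition number = {fit.condition_number:.1f}")

print("Zero-noise targets are exactly fittable (the tensor is recovered);")
print("1 Hz noise leaves a ~0.9 Hz residual, sqrt((n-5)/n) of the noise.")
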