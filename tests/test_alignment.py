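"""Five-parameter alignment-tensor fitting and back-calculation."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from hrsrdc.alignment import (
    AlignmentTensor,
    at_rdc_predict,
    at_restrained_step_force,
    design_row,
    fit_alignment_tensor,
    rdc_rmsd,
)
from hrsrdc.rdc import RDCDefinition


def _random_rdcs(n, seed=0):
    rng = np.random.default_rng(seed)
    bonds = rng.normal(size=(n, 3))
    bonds /= np.linalg.norm(bonds, axis=1)[:, None]
    rdcs = [RDCDefinition.from_isotopes(f"r{i}", (2 * i, 2 * i + 1),
                                        ("15N", "1H"), 0.1)
            for i in range(n)]
    return rdcs, bonds


def test_tensor_matrix_symmetric_traceless():
    t = AlignmentTensor.from_components([0.3, -0.1, 0.05, 0.02, -0.04])
    m = t.matrix()
    assert np.allclose(m, m.T)
    assert abs(np.trace(m)) < 1e-12
    assert AlignmentTensor.from_matrix(m).a == pytest.approx(t.a)


def test_design_row_axis_case():
    # pure A_zz tensor predicts P2 of the angle with z
    row = design_row(np.array([0.0, 0.0, 1.0]))
    assert row @ np.array([1.0, 0, 0, 0, 0]) == pytest.approx(1.0)
    row_x = design_row(np.array([1.0, 0.0, 0.0]))
    assert row_x @ np.array([1.0, 0, 0, 0, 0]) == pytest.approx(-0.5)


def test_design_row_inversion_symmetry():
    rng = np.random.default_rng(1)
    b = rng.normal(size=3)
    b /= np.linalg.norm(b)
    assert design_row(b) == pytest.approx(design_row(-b))


def test_design_row_requires_unit_vector():
    with pytest.raises(ValueError):
        design_row(np.array([0.0, 0.0, 2.0]))


def test_fit_recovers_known_tensor_exactly():
    rdcs, bonds = _random_rdcs(10, seed=2)
    tensor = AlignmentTensor.from_components([3e-4, -1e-4, 5e-5, 2e-5, -8e-5])
    targets = at_rdc_predict(rdcs, bonds, tensor)
    fit = fit_alignment_tensor(rdcs, bonds, targets)
    assert np.abs(np.array(fit.tensor.a) - np.array(tensor.a)).max() < 1e-10
    assert fit.rmsd < 1e-9
    assert fit.condition_number > 1.0


def test_fit_zero_targets_gives_zero_tensor():
    rdcs, bonds = _random_rdcs(8, seed=3)
    fit = fit_alignment_tensor(rdcs, bonds, np.zeros(8))
    assert np.abs(np.array(fit.tensor.a)).max() < 1e-14
    assert fit.rmsd == 0.0


def test_fit_underdetermined_raises():
    rdcs, bonds = _random_rdcs(4, seed=4)
    with pytest.raises(ValueError, match="underdetermine"):
        fit_alignment_tensor(rdcs, bonds, np.zeros(4))
    fit = fit_alignment_tensor(rdcs, bonds, np.zeros(4),
                               allow_minimum_norm=True)
    assert fit.n_used == 4


def test_fit_invariant_under_global_rotation():
    rdcs, bonds = _random_rdcs(12, seed=5)
    tensor = AlignmentTensor.from_components([2e-4, 1e-4, 0.0, -3e-5, 6e-5])
    targets = at_rdc_predict(rdcs, bonds, tensor) + np.random.default_rng(
        6).normal(0, 0.5, 12)
    fit = fit_alignment_tensor(rdcs, bonds, targets)
    rot = Rotation.from_rotvec([0.3, -1.1, 0.7]).as_matrix()
    fit_rot = fit_alignment_tensor(rdcs, bonds @ rot.T, targets)
    assert fit_rot.rmsd == pytest.approx(fit.rmsd, rel=1e-9)
    # the fitted tensor co-rotates
    assert np.allclose(fit_rot.tensor.matrix(),
                       rot @ fit.tensor.matrix() @ rot.T, atol=1e-12)


def test_fit_residual_scales_with_noise():
    rdcs, bonds = _random_rdcs(39, seed=7)
    tensor = AlignmentTensor.from_components([2e-4, 1e-4, -5e-5, 3e-5, 8e-5])
    clean = at_rdc_predict(rdcs, bonds, tensor)
    rng = np.random.default_rng(8)
    rmsds = {}
    for sigma in (0.1, 1.0):
        vals = []
        for _ in range(200):
            noisy = clean + rng.normal(0, sigma, size=len(clean))
            vals.append(fit_alignment_tensor(rdcs, bonds, noisy).rmsd)
        rmsds[sigma] = np.mean(vals)
    # residual rmsd ~ sigma * sqrt((n-5)/n); ratio between noise levels ~ 10
    assert rmsds[1.0] / rmsds[0.1] == pytest.approx(10.0, rel=0.15)
    assert rmsds[1.0] == pytest.approx(np.sqrt(34 / 39), rel=0.3)


def test_rdc_rmsd_basics():
    assert rdc_rmsd([1.0, 2.0], [1.0, 2.0]) == 0.0
    assert rdc_rmsd([3.0], [0.0]) == 3.0
    with pytest.raises(ValueError):
        rdc_rmsd([1.0], [1.0, 2.0])


def test_at_force_zero_at_perfect_fit():
    rdcs, bonds = _random_rdcs(10, seed=9)
    coords = np.random.default_rng(10).normal(size=(20, 3))
    idx = np.array([r.atoms for r in rdcs])
    vecs = coords[idx[:, 0]] - coords[idx[:, 1]]
    units = vecs / np.linalg.norm(vecs, axis=1)[:, None]
    tensor = AlignmentTensor.from_components([1e-4, 0, 0, 0, 0])
    targets = at_rdc_predict(rdcs, units, tensor)
    forces, fit = at_restrained_step_force(rdcs, coords, targets, k_at=1.0)
    assert np.abs(forces).max() < 1e-8
    assert fit.rmsd < 1e-10


def test_at_force_matches_central_differences():
    # the tensor is refit at every displaced geometry; the envelope theorem
    # makes the fixed-tensor analytic gradient the exact total derivative
    rdcs, _ = _random_rdcs(10, seed=11)
    rng = np.random.default_rng(12)
    k_at = 0.3

    def energy(c):
        idx = np.array([r.atoms for r in rdcs])
        v = c[idx[:, 0]] - c[idx[:, 1]]
        u = v / np.linalg.norm(v, axis=1)[:, None]
        fit = fit_alignment_tensor(rdcs, u, targets)
        return 0.5 * k_at * np.sum((fit.predicted - targets) ** 2)

    for trial in range(3):
        coords = rng.normal(size=(20, 3))
        targets = rng.normal(0, 5, size=10)
        forces, _ = at_restrained_step_force(rdcs, coords, targets, k_at=k_at)
        eps = 1e-6
        for atom, axis in [(0, 0), (3, 2), (11, 1)]:
            cp, cm = coords.copy(), coords.copy()
            cp[atom, axis] += eps
            cm[atom, axis] -= eps
            fd = -(energy(cp) - energy(cm)) / (2 * eps)
            scale = max(np.abs(forces).max(), 1e-6)
            assert forces[atom, axis] == pytest.approx(fd, abs=1e-6 * scale)
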