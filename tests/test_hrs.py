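"""Hybrid field-vector/molecule loop, friction model and molecule sources."""

import numpy as np
import pytest

from hrsrdc.alignment import AlignmentTensor, at_rdc_predict
from hrsrdc.hrs import (
    FrictionModel,
    HRSParams,
    ReplaySource,
    ToySDSource,
    molecule_restraint_energy,
    molecule_restraint_forces,
    neighbor_friction,
    rigid_diffusion_source,
    run_hrs,
)
from hrsrdc.restraints import RestraintParams


class TestNeighborFriction:
    def test_isolated_atom_full_solvent_friction(self):
        gamma = neighbor_friction(np.zeros((1, 3)), np.array([True]))
        assert gamma[0] == pytest.approx(60.0)

    def test_buried_atom_zero_friction(self):
        # central atom surrounded by 6 heavy atoms within 0.3 nm
        shell = 0.2 * np.array([[1, 0, 0], [-1, 0, 0], [0, 1, 0],
                                [0, -1, 0], [0, 0, 1], [0, 0, -1]])
        coords = np.vstack([np.zeros(3), shell])
        gamma = neighbor_friction(coords, np.ones(7, bool))
        assert gamma[0] == 0.0

    def test_linear_interpolation_at_three_neighbors(self):
        coords = np.vstack([np.zeros(3),
                            0.2 * np.array([[1, 0, 0], [0, 1, 0],
                                            [0, 0, 1]])])
        gamma = neighbor_friction(coords, np.ones(4, bool))
        assert gamma[0] == pytest.approx(30.0)

    def test_hydrogens_not_counted(self):
        coords = np.vstack([np.zeros(3),
                            0.2 * np.array([[1, 0, 0], [0, 1, 0],
                                            [0, 0, 1]])])
        heavy = np.array([True, False, False, False])
        gamma = neighbor_friction(coords, heavy)
        assert gamma[0] == pytest.approx(60.0)

    def test_radius_and_reference_configurable(self):
        coords = np.vstack([np.zeros(3), [[0.25, 0, 0]]])
        tight = FrictionModel(neighbor_radius=0.2)
        assert neighbor_friction(coords, np.ones(2, bool), tight)[0] == 60.0


class TestRigidDiffusion:
    def test_axis_autocorrelation_decay(self, helix):
        tau = 50.0
        src = rigid_diffusion_source(helix.coords, tau, n_frames=20000,
                                     seed=3, frame_dt=1.0)
        u = np.einsum("nij,j->ni", src.matrices, [0.0, 0.0, 1.0])
        for lag in (10, 25, 50):
            ac = np.mean(np.einsum("ni,ni->n", u[:-lag], u[lag:]))
            assert ac == pytest.approx(np.exp(-lag / tau), rel=0.15)

    def test_zero_bias_identical_to_unbiased(self, helix):
        plain = rigid_diffusion_source(helix.coords, 10.0, n_frames=50,
                                       seed=4)
        zero = rigid_diffusion_source(helix.coords, 10.0,
                                      bias=AlignmentTensor.zero(),
                                      n_frames=50, seed=4)
        assert np.array_equal(plain.frame(7), zero.frame(7))
        assert np.all(zero.weights == 1.0)

    def test_weighted_orientations_reproduce_bias_tensor(self, helix,
                                                         targeted_rdcs):
        bias = AlignmentTensor.from_components([0.05, 0.02, -0.01, 0.015, 0.0])
        src = rigid_diffusion_source(helix.coords, 5.0, bias=bias,
                                     n_frames=200_000, seed=5)
        r = targeted_rdcs[3]
        b = helix.bond_vector(r.atoms)
        b = b / np.linalg.norm(b)
        v = np.einsum("nij,j->ni", src.matrices, b)
        p2 = 0.5 * (3.0 * v[:, 2] ** 2 - 1.0)
        weighted = np.average(p2, weights=src.weights)
        predicted = at_rdc_predict([r], b[None, :], bias)[0] / r.d_const
        assert weighted == pytest.approx(predicted, abs=0.005)

    def test_overly_strong_bias_rejected(self, helix):
        with pytest.raises(ValueError, match="too strong"):
            rigid_diffusion_source(
                helix.coords, 5.0,
                bias=AlignmentTensor.from_components([0.5, 0, 0, 0, 0]),
                n_frames=100, seed=6)


class TestMoleculeForces:
    def _setup(self, targeted_rdcs, helix, n_samples=40, seed=7):
        rng = np.random.default_rng(seed)
        fs = rng.normal(size=(n_samples, 3))
        fs /= np.linalg.norm(fs, axis=1)[:, None]
        targets = np.array([r.target for r in targeted_rdcs])
        return helix.coords.copy(), fs, targets

    def test_zero_force_inside_flat_bottom(self, helix, targeted_rdcs):
        coords, fs, _ = self._setup(targeted_rdcs, helix)
        # set targets to the exact frozen-sample averages: all in the bottom
        from hrsrdc.hrs import _bond_geometry

        _, units, _, _ = _bond_geometry(coords, targeted_rdcs)
        dc = np.array([r.d_const for r in targeted_rdcs])
        c = units @ fs.T
        d_avg = dc * np.mean(0.5 * (3 * c * c - 1), axis=1)
        f = molecule_restraint_forces(coords, targeted_rdcs, fs, d_avg,
                                      RestraintParams(0.05))
        assert np.abs(f).max() == 0.0

    def test_forces_are_negative_gradient(self, helix, targeted_rdcs):
        coords, fs, targets = self._setup(targeted_rdcs, helix)
        params = RestraintParams(0.05)
        forces = molecule_restraint_forces(coords, targeted_rdcs, fs,
                                           targets, params)
        eps = 1e-7
        rng = np.random.default_rng(8)
        for _ in range(6):
            atom = int(rng.integers(len(coords)))
            axis = int(rng.integers(3))
            cp, cm = coords.copy(), coords.copy()
            cp[atom, axis] += eps
            cm[atom, axis] -= eps
            fd = -(molecule_restraint_energy(cp, targeted_rdcs, fs, targets,
                                             params)
                   - molecule_restraint_energy(cm, targeted_rdcs, fs,
                                               targets, params)) / (2 * eps)
            scale = max(np.abs(forces).max(), 1e-9)
            assert forces[atom, axis] == pytest.approx(fd, abs=1e-6 * scale)


class TestRunHRS:
    def test_fully_unbiased_couplings_near_zero(self, helix, helix_rdcs):
        params = HRSParams(n_mfv=100, k_mfv=0.0, k_msy=0.0, n_msy=3000)
        res = run_hrs(ReplaySource([helix.coords]), helix_rdcs, params,
                      seed=1)
        dc = np.array([r.d_const for r in helix_rdcs])
        # 3e5 total field steps: sampling error of <P2> is well below 0.05
        assert np.abs(res.mean_d / dc).max() < 0.05
        assert res.energies == pytest.approx(np.zeros(3000))

    def test_single_step_blocks_run(self, helix, helix_rdcs):
        params = HRSParams(n_mfv=1, k_mfv=0.0, k_msy=0.0, n_msy=10)
        res = run_hrs(ReplaySource([helix.coords]), helix_rdcs, params,
                      seed=2)
        assert res.mean_d.shape == (len(helix_rdcs),)
        assert np.isfinite(res.mean_d).all()

    def test_seed_reproducibility(self, helix, targeted_rdcs):
        params = HRSParams(n_mfv=50, k_mfv=100.0, n_msy=50)
        a = run_hrs(ReplaySource([helix.coords]), targeted_rdcs, params,
                    seed=11)
        b = run_hrs(ReplaySource([helix.coords]), targeted_rdcs, params,
                    seed=11)
        assert np.array_equal(a.mean_d, b.mean_d)

    def test_molecule_forces_recorded_in_replay_mode(self, helix,
                                                     targeted_rdcs):
        # bias the damped averages away from the targets so forces act
        off_targets = [
            type(r)(id=r.id, atoms=r.atoms, isotopes=r.isotopes, r0=r.r0,
                    d_const=r.d_const, target=r.target + 500.0)
            for r in targeted_rdcs
        ]
        params = HRSParams(n_mfv=20, k_mfv=0.0, k_msy=0.05, n_msy=30,
                           tau_msy=0.1)
        res = run_hrs(ReplaySource([helix.coords]), off_targets, params,
                      seed=3, record_forces=True, damped_init=None)
        assert len(res.recorded_forces) == 30
        assert max(np.abs(f).max() for f in res.recorded_forces) > 0.0

    def test_tracked_angle_histograms_accumulate(self, helix, helix_rdcs):
        pairs = [(helix.index["CA(1)"], helix.index["CA(7)"]),
                 (helix.index["CA(4)"], helix.index["C(4)"])]
        params = HRSParams(n_mfv=10, k_mfv=0.0, n_msy=200)
        res = run_hrs(ReplaySource([helix.coords]), helix_rdcs, params,
                      seed=4, tracked_pairs=pairs)
        assert res.theta_counts.shape == (2, 36)
        assert res.theta_counts.sum() == pytest.approx(2 * 200)

    def test_rigid_source_frames_feed_the_loop(self, helix, helix_rdcs):
        src = rigid_diffusion_source(helix.coords, 20.0, n_frames=500,
                                     seed=5)
        params = HRSParams(n_mfv=20, k_mfv=0.0, n_msy=400)
        res = run_hrs(src, helix_rdcs, params, seed=6)
        assert np.isfinite(res.mean_d).all()


class TestToySD:
    def test_bonded_network_stays_near_reference(self, helix):
        heavy = np.array([not n.startswith(("H", "Me"))
                          for n in helix.atom_names])
        src = ToySDSource(helix.coords, heavy, seed=1)
        start = src.coords.copy()
        for _ in range(500):
            src.step()
        rmsd = np.sqrt(np.mean((src.coords - start) ** 2))
        assert rmsd < 0.1  # nm; elastic network holds the fold together

    def test_accepts_external_forces(self, helix):
        heavy = np.ones(len(helix.coords), bool)
        src = ToySDSource(helix.coords, heavy, seed=2)
        f = np.zeros_like(src.coords)
        f[0] = [100.0, 0.0, 0.0]
        out = src.step(f)
        assert np.isfinite(out).all()

    def test_runs_inside_hybrid_loop(self, helix, targeted_rdcs):
        heavy = np.array([not n.startswith(("H", "Me"))
                          for n in helix.atom_names])
        src = ToySDSource(helix.coords, heavy, seed=3)
        params = HRSParams(n_mfv=20, k_mfv=100.0, k_msy=0.05, n_msy=100)
        res = run_hrs(src, targeted_rdcs, params, seed=7)
        assert np.isfinite(res.mean_d).all()


def test_hrs_params_validation():
    with pytest.raises(ValueError):
        HRSParams(n_mfv=0)
    with pytest.raises(ValueError):
        HRSParams(k_mfv=-1.0)
    with pytest.raises(ValueError):
        HRSParams(tau_mfv=0.0001)
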