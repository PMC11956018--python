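"""NOE distances, Karplus couplings, hydrogen bonds and angle diagnostics."""

import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from hrsrdc.observables import (
    HBondCriterion,
    KARPLUS_HC_HC,
    KARPLUS_HN_HC,
    NOEBound,
    angle_distribution,
    detect_hbonds,
    dihedral_angle,
    j_stats,
    karplus_3j,
    magic_angle_ratio,
    noe_stats,
    r6_average,
    virtual_hydrogen,
)


class TestR6Average:
    def test_constant(self):
        assert r6_average([0.3, 0.3, 0.3]) == pytest.approx(0.3)

    def test_two_distances(self):
        assert r6_average([0.2, 0.4]) == pytest.approx(0.2239, abs=1e-4)

    def test_short_distance_dominance(self):
        # a single 1.0 nm frame barely moves the average of a short-distance
        # trajectory: its r^-6 weight is ~4 orders of magnitude smaller
        rng = np.random.default_rng(7)
        close = list(rng.uniform(0.2, 0.3, 25))
        base = r6_average(close)
        with_far = r6_average(close + [1.0])
        assert with_far > base  # diluting the mean of r^-6 lengthens it
        assert (with_far - base) / base < 0.01

    def test_bounds(self):
        rng = np.random.default_rng(0)
        d = rng.uniform(0.2, 0.6, 50)
        val = r6_average(d)
        assert d.min() <= val <= d.mean()

    def test_monotone_in_single_distance(self):
        d = [0.3, 0.4, 0.5]
        lower = r6_average([0.25, 0.4, 0.5])
        assert lower < r6_average(d)

    def test_invalid(self):
        with pytest.raises(ValueError):
            r6_average([])
        with pytest.raises(ValueError):
            r6_average([0.2, -0.1])


class TestNOEStats:
    def test_all_satisfied(self):
        bounds = [NOEBound(i, ("a", "b"), 0.3) for i in range(3)]
        stats = noe_stats(bounds, {0: 0.25, 1: 0.3, 2: 0.1})
        assert stats.n_viol == 0 and stats.n_viol_gt == 0
        assert stats.rmsd == 0.0

    def test_boundary_is_not_violation(self):
        bounds = [NOEBound(1, ("a", "b"), 0.30)]
        assert noe_stats(bounds, {1: 0.30}).n_viol == 0
        assert noe_stats(bounds, {1: 0.301}).n_viol == 1

    def test_margin_count_and_rmsd_over_full_set(self):
        bounds = [NOEBound(i, ("a", "b"), 0.3) for i in (1, 2, 3, 4)]
        stats = noe_stats(bounds, {1: 0.45, 2: 0.35, 3: 0.2, 4: 0.3})
        assert stats.n_viol == 2
        assert stats.n_viol_gt == 1
        assert stats.largest == (1, pytest.approx(0.15))
        assert stats.rmsd == pytest.approx(
            math.sqrt((0.15**2 + 0.05**2) / 4))

    def test_missing_distance_raises_with_ids(self):
        bounds = [NOEBound(7, ("a", "b"), 0.3)]
        with pytest.raises(KeyError, match="7"):
            noe_stats(bounds, {})


class TestKarplus:
    @pytest.mark.parametrize("theta, coeff, expected", [
        (90.0, KARPLUS_HN_HC, 1.9),       # cos = 0 leaves only c
        (180.0, KARPLUS_HN_HC, 9.7),      # a - b + c
        (0.0, KARPLUS_HC_HC, 9.7),        # a + b + c
    ])
    def test_reference_values(self, theta, coeff, expected):
        assert karplus_3j(theta, coeff) == pytest.approx(expected)

    def test_even_in_dihedral(self):
        thetas = np.linspace(0, 180, 37)
        assert np.allclose(karplus_3j(thetas, KARPLUS_HN_HC),
                           karplus_3j(-thetas, KARPLUS_HN_HC))

    def test_dihedral_angle_reference(self):
        # a planar cis arrangement has dihedral 0, trans has 180
        p = [np.array([1.0, 1.0, 0]), np.array([1.0, 0, 0]),
             np.array([0, 0, 0]), np.array([0, 1.0, 0])]
        assert dihedral_angle(*p) == pytest.approx(0.0, abs=1e-10)
        p[3] = np.array([0, -1.0, 0])
        assert abs(dihedral_angle(*p)) == pytest.approx(180.0)


def test_j_stats_counts_and_rmsd():
    assert j_stats([1.0, 2.0], [1.0, 2.0]) == (0, 0.0)
    n_dev, rmsd = j_stats([5.0, 1.0, 9.0], [1.0, 1.0, 7.0])
    assert n_dev == 1
    assert rmsd == pytest.approx(math.sqrt((16 + 0 + 4) / 3))
    # strict inequality at the threshold
    assert j_stats([4.0], [2.0])[0] == 0
    with pytest.raises(ValueError):
        j_stats([1.0], [1.0, 2.0])


class TestHBonds:
    coords = np.array([
        [0.0, 0.0, 0.0],    # donor N
        [0.1, 0.0, 0.0],    # H
        [0.3, 0.0, 0.0],    # acceptor O, collinear, d(H,A) = 0.2
    ])

    def test_collinear_bond_detected(self):
        assert detect_hbonds(self.coords, [(0, 1)], [2]) == [(0, 2)]

    def test_distance_gate(self):
        far = self.coords.copy()
        far[2, 0] = 0.36  # d(H,A) = 0.26
        assert detect_hbonds(far, [(0, 1)], [2]) == []

    def test_angle_gate(self):
        bent = self.coords.copy()
        # place acceptor so the D-H..A angle is 120 degrees at d = 0.2
        ang = math.radians(180 - 120)
        bent[2] = [0.1 + 0.2 * math.cos(ang), 0.2 * math.sin(ang), 0.0]
        assert detect_hbonds(bent, [(0, 1)], [2]) == []

    def test_invariant_under_rigid_motion(self):
        rot = Rotation.from_rotvec([0.4, 1.2, -0.3]).as_matrix()
        moved = self.coords @ rot.T + np.array([1.0, -2.0, 0.5])
        assert detect_hbonds(moved, [(0, 1)], [2]) == [(0, 2)]


class TestAngleDistribution:
    def test_identical_frames_single_bin(self):
        coords = np.array([[0.0, 0, 0], [0.0, 0, 0.1]])
        frames = [coords] * 10
        res = angle_distribution(frames, [(1, 0)],
                                 [np.array([0, 0, 1.0])] * 10)
        assert res["counts"][0].sum() == 10
        assert (res["counts"][0] > 0).sum() == 1

    def test_isotropic_frames_flat_density(self):
        rng = np.random.default_rng(1)
        coords = np.array([[0.0, 0, 0], [0.0, 0, 0.1]])
        fields = rng.normal(size=(40000, 3))
        res = angle_distribution([coords] * len(fields), [(1, 0)], fields,
                                 n_bins=18)
        density = res["density"][0]
        assert density.mean() == pytest.approx(1.0, abs=0.05)
        assert np.abs(density - 1.0).max() < 0.25


class TestMagicAngleRatio:
    def test_uniform_sphere_is_one(self):
        rng = np.random.default_rng(2)
        cos_t = rng.uniform(-1, 1, size=1_000_000)
        theta = np.degrees(np.arccos(cos_t))
        counts, edges = np.histogram(theta, bins=36, range=(0, 180))
        assert magic_angle_ratio(counts, edges) == pytest.approx(1.0,
                                                                 abs=0.02)

    def test_delta_at_magic_angle_capped(self):
        counts = np.zeros(36)
        counts[11] = 1e6  # 55-60 degree bin
        edges = np.linspace(0, 180, 37)
        assert magic_angle_ratio(counts, edges) == 1e6  # capped flag value

    def test_empty_window_raises(self):
        counts = np.ones(4)
        edges = np.linspace(0, 180, 5)
        with pytest.raises(ValueError):
            magic_angle_ratio(counts, edges)


class TestVirtualHydrogen:
    def _sp3_neighbors(self):
        # three tetrahedral directions around the origin
        dirs = np.array([
            [1, 1, 1], [1, -1, -1], [-1, 1, -1]]) / math.sqrt(3)
        return [0.15 * d for d in dirs]

    def test_ch_completes_tetrahedron(self):
        nb = self._sp3_neighbors()
        h = virtual_hydrogen(np.zeros(3), nb, "CH")[0]
        assert np.linalg.norm(h) == pytest.approx(0.109)
        # the H direction is the missing tetrahedral corner (-1,-1,1)/sqrt3
        expected = np.array([-1, -1, 1]) / math.sqrt(3)
        assert h / np.linalg.norm(h) == pytest.approx(expected, abs=1e-9)

    def test_ch2_mirror_pair_geometry(self):
        nb = self._sp3_neighbors()[:2]
        hh = virtual_hydrogen(np.zeros(3), nb, "CH2")
        assert hh.shape == (2, 3)
        assert np.linalg.norm(hh[0]) == pytest.approx(0.109)
        # ideal tetrahedral H-C-H separation
        assert np.linalg.norm(hh[0] - hh[1]) == pytest.approx(
            2 * 0.109 * math.sin(0.5 * math.acos(-1 / 3)), abs=1e-9)

    def test_prochiral_labels_stable_under_rotation(self):
        nb = self._sp3_neighbors()[:2]
        center = np.array([0.3, -0.2, 0.1])
        hh = virtual_hydrogen(center, [center + n for n in nb], "CH2")
        rot = Rotation.from_rotvec([1.0, 0.2, -0.7]).as_matrix()
        hh_rot = virtual_hydrogen(
            center @ rot.T, [(center + n) @ rot.T for n in nb], "CH2")
        # rotating the construction rotates the Re/Si positions coherently
        assert np.allclose(hh @ rot.T, hh_rot, atol=1e-12)

    def test_ch3_pseudoatom_at_carbon(self):
        c = np.array([0.1, 0.2, 0.3])
        assert virtual_hydrogen(c, [], "CH3") == pytest.approx(c[None, :])

    def test_missing_neighbors_raise(self):
        with pytest.raises(ValueError):
            virtual_hydrogen(np.zeros(3), self._sp3_neighbors()[:2], "CH")
        with pytest.raises(ValueError):
            virtual_hydrogen(np.zeros(3), [], "CH2")
        with pytest.raises(ValueError):
            virtual_hydrogen(np.zeros(3), [], "unknown")
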