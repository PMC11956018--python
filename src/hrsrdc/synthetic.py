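"""Synthetic inputs: toy helix, RDC target generation, packaged tables.

The toy helix is a geometrically idealised stand-in for a small helical
peptide: residues on a regular helix, each carrying the labelled bond
vectors common in RDC work (N-H at 0.100 nm, CB-HB and CA-HA at 0.109 nm,
with the two prochiral HA 0.178 nm apart), plus backbone N-H donors and
C=O acceptors arranged so that the i -> i+2 hydrogen bonds of a tight
helix satisfy the geometric criterion at construction.  It is not a real
peptide structure; it exists so the restraining and analysis machinery
can be exercised and validated at desk scale.

The packaged fixtures carry the printed reference tables (131 NOE bounds,
21 3J-couplings, 39 RDCs with experimental targets and the couplings
back-calculated for several restraining protocols); their footer
statistics are recomputable with the observables/alignment operations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .alignment import AlignmentTensor, at_rdc_predict
from .rdc import RDCDefinition

__all__ = [
    "ToyHelix",
    "make_toy_helix",
    "helix_rdc_definitions",
    "generate_rdc_targets",
    "load_fixture",
]

_FIXTURE_FILES = {
    "table1": "table1_noe.tsv",
    "table2": "table2_3j.tsv",
    "table4": "table4_rdc.tsv",
}


@dataclass
class ToyHelix:
    """Idealised helix with labelled RDC bond vectors and H-bond topology."""

    n_residues: int
    coords: np.ndarray                      # (n_atoms, 3) nm
    atom_names: list[str]                   # "N(3)", "HB(2)", ...
    index: dict[str, int]                   # name -> row in coords
    donors: list[tuple[int, int]]           # (N, H) pairs
    acceptors: list[int]                    # O atoms
    rdc_vectors: dict[str, tuple[int, int]] = field(default_factory=dict)

    def atom(self, name: str) -> np.ndarray:
        return self.coords[self.index[name]]

    def bond_vector(self, pair: tuple[int, int]) -> np.ndarray:
        return self.coords[pair[0]] - self.coords[pair[1]]


def make_toy_helix(
    n_residues: int = 7,
    rise_nm: float = 0.16,
    twist_deg: float = -120.0,
    radius_nm: float = 0.25,
    seed: int = 0,
) -> ToyHelix:
    """Deterministic idealised helix with n >= 3 residues.

    Residue i sits at helix angle i*twist and height i*rise.  Backbone N-H
    vectors all make the same angle with the helix axis (helical symmetry);
    the carbonyl O of residue i is placed on the extension of the
    N-H vector of residue i+2, 0.30 nm from that N, so every i -> i+2
    N-H...O=C pair satisfies d(H,O) = 0.20 nm with a collinear
    donor-hydrogen-acceptor geometry.  ``seed`` is accepted for interface
    uniformity; the construction is fully deterministic.
    """
    if n_residues < 3:
        raise ValueError("need at least 3 residues")
    del seed  # deterministic geometry

    names: list[str] = []
    coords: list[np.ndarray] = []

    def add(name: str, xyz: np.ndarray) -> int:
        names.append(name)
        coords.append(np.asarray(xyz, dtype=float))
        return len(coords) - 1

    twist = np.deg2rad(twist_deg)
    nh_tilt = np.deg2rad(60.0)  # angle of every N-H vector with the axis

    n_pos = {}
    nh_dir = {}
    for i in range(n_residues):
        ang = i * twist
        radial = np.array([np.cos(ang), np.sin(ang), 0.0])
        tangent = np.array([-np.sin(ang), np.cos(ang), 0.0])
        origin = radius_nm * radial + np.array([0.0, 0.0, i * rise_nm])

        n_xyz = origin
        # N-H points outward and down at a fixed angle to the axis
        d = np.sin(nh_tilt) * radial - np.cos(nh_tilt) * np.array([0, 0, 1.0])
        n_pos[i] = n_xyz
        nh_dir[i] = d
        add(f"N({i + 1})", n_xyz)
        add(f"H({i + 1})", n_xyz + 0.100 * d)

        ca = origin + 0.10 * tangent + np.array([0.0, 0.0, 0.05])
        add(f"CA({i + 1})", ca)
        cb = ca + 0.153 * _unit(radial + np.array([0.0, 0.0, 0.4]))
        add(f"CB({i + 1})", cb)
        add(f"HB({i + 1})", cb + 0.109 * _unit(tangent + 0.3 * radial))
        # prochiral HA pair: tetrahedral about CA, 0.178 nm apart
        perp = _unit(np.cross(radial, tangent) + 0.2 * radial)
        base = _unit(-radial + 0.2 * np.array([0.0, 0.0, 1.0]))
        half = 0.5 * np.arccos(-1.0 / 3.0)
        h1 = ca + 0.109 * (np.cos(half) * base + np.sin(half) * perp)
        h2 = ca + 0.109 * (np.cos(half) * base - np.sin(half) * perp)
        add(f"HARe({i + 1})", h1)
        add(f"HASi({i + 1})", h2)

    # carbonyls: O(i) on the N-H(i+2) line => ideal i -> i+2 H-bond
    for i in range(n_residues):
        j = i + 2
        if j < n_residues:
            o_xyz = n_pos[j] + 0.30 * nh_dir[j]
        else:
            ang = i * twist
            radial = np.array([np.cos(ang), np.sin(ang), 0.0])
            o_xyz = n_pos[i] + 0.35 * radial + np.array([0.0, 0.0, 0.1])
        o = add(f"O({i + 1})", o_xyz)
        add(f"C({i + 1})", o_xyz + 0.123 * _unit(n_pos[i] - o_xyz))

    coords_arr = np.vstack(coords)
    index = {n: k for k, n in enumerate(names)}
    donors = [(index[f"N({i + 1})"], index[f"H({i + 1})"])
              for i in range(n_residues)]
    acceptors = [index[f"O({i + 1})"] for i in range(n_residues)]

    rdc_vectors = {}
    for i in range(1, n_residues + 1):
        rdc_vectors[f"H-N({i})"] = (index[f"H({i})"], index[f"N({i})"])
        rdc_vectors[f"HB-CB({i})"] = (index[f"HB({i})"], index[f"CB({i})"])
        rdc_vectors[f"HARe-CA({i})"] = (index[f"HARe({i})"], index[f"CA({i})"])
        rdc_vectors[f"HASi-CA({i})"] = (index[f"HASi({i})"], index[f"CA({i})"])
        rdc_vectors[f"HARe-HASi({i})"] = (index[f"HARe({i})"],
                                          index[f"HASi({i})"])
    return ToyHelix(
        n_residues=n_residues,
        coords=coords_arr,
        atom_names=names,
        index=index,
        donors=donors,
        acceptors=acceptors,
        rdc_vectors=rdc_vectors,
    )


_RDC_KIND = {
    "H-N": (("1H", "15N"), 0.100),
    "HB-CB": (("1H", "13C"), 0.109),
    "HARe-CA": (("1H", "13C"), 0.109),
    "HASi-CA": (("1H", "13C"), 0.109),
    "HARe-HASi": (("1H", "1H"), 0.178),
}


def helix_rdc_definitions(helix: ToyHelix) -> list[RDCDefinition]:
    """One RDCDefinition per labelled bond vector of the helix (no targets)."""
    out = []
    for label, pair in helix.rdc_vectors.items():
        kind = label.rsplit("(", 1)[0]
        isotopes, r0 = _RDC_KIND[kind]
        out.append(RDCDefinition.from_isotopes(
            id=label, atoms=pair, isotopes=isotopes, r0=r0))
    return out


def generate_rdc_targets(
    helix: ToyHelix,
    tensor: AlignmentTensor,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> list[RDCDefinition]:
    """RDC definitions with targets back-calculated from an alignment tensor.

    D^0_k = D_k^c * (b_k^T A b_k) + N(0, noise_sd); with zero noise the
    targets are exactly fittable and the tensor is recovered by the
    least-squares fit.
    """
    rdcs = helix_rdc_definitions(helix)
    vecs = np.array([helix.bond_vector(r.atoms) for r in rdcs])
    units = vecs / np.linalg.norm(vecs, axis=1)[:, None]
    pred = at_rdc_predict(rdcs, units, tensor)
    rng = np.random.default_rng(seed)
    if noise_sd > 0.0:
        pred = pred + rng.normal(0.0, noise_sd, size=pred.shape)
    return [RDCDefinition(id=r.id, atoms=r.atoms, isotopes=r.isotopes,
                          r0=r.r0, d_const=r.d_const, target=float(t))
            for r, t in zip(rdcs, pred)]


def load_fixture(name: str) -> pd.DataFrame:
    """Load a packaged reference table ('table1', 'table2' or 'table4').

    Missing experimental cells (blank in the print) come back as NaN; the
    set-membership / reference-precedence assembly rules are applied by the
    downstream statistics, never in the fixture itself.
    """
    try:
        fname = _FIXTURE_FILES[name]
    except KeyError:
        raise ValueError(
            f"unknown fixture {name!r}; choose from {sorted(_FIXTURE_FILES)}"
        ) from None
    with resources.files("hrsrdc.data").joinpath(fname).open() as fh:
        return pd.read_csv(fh, sep="\t")


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)
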