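"""Readers and writers: PDB structures (nm), XYZ trajectories, RDC tables,
and the run configuration."""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
import yaml

from .rdc import RDCDefinition

__all__ = [
    "Structure",
    "read_structure",
    "write_structure",
    "read_trajectory",
    "write_trajectory",
    "read_rdc_table",
    "RunConfig",
    "load_config",
]

_NM_PER_ANGSTROM = 0.1


@dataclass
class Structure:
    """Coordinates (nm) plus the atom metadata needed to resolve specs."""

    coords: np.ndarray
    atom_names: list[str]
    res_ids: list[int]
    res_names: list[str]
    elements: list[str]

    def __len__(self) -> int:
        return len(self.coords)

    def find_atom(self, atom_name: str, res_id: int) -> int:
        """Index of the atom named ``atom_name`` in residue ``res_id``."""
        for i, (n, r) in enumerate(zip(self.atom_names, self.res_ids)):
            if n == atom_name and r == res_id:
                return i
        raise KeyError(
            f"atom {atom_name!r} in residue {res_id} not found in structure"
        )


def read_structure(path) -> Structure:
    """Read ATOM/HETATM records from a PDB file, converting A to nm."""
    import biotite.structure.io.pdb as pdb

    try:
        pdb_file = pdb.PDBFile.read(str(path))
        atoms = pdb_file.get_structure(model=1)
    except Exception as exc:  # biotite raises several parse error types
        raise ValueError(f"could not parse PDB file {path}: {exc}") from exc
    return Structure(
        coords=np.asarray(atoms.coord, dtype=float) * _NM_PER_ANGSTROM,
        atom_names=list(atoms.atom_name),
        res_ids=[int(r) for r in atoms.res_id],
        res_names=list(atoms.res_name),
        elements=list(atoms.element),
    )


def write_structure(structure: Structure, path) -> None:
    """Write the structure back out as PDB (nm -> A)."""
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdb

    n = len(structure)
    atoms = struc.AtomArray(n)
    atoms.coord = structure.coords / _NM_PER_ANGSTROM
    atoms.atom_name = np.array(structure.atom_names)
    atoms.res_id = np.array(structure.res_ids)
    atoms.res_name = np.array(structure.res_names)
    atoms.element = np.array(structure.elements)
    atoms.chain_id = np.array(["A"] * n)
    pdb_file = pdb.PDBFile()
    pdb_file.set_structure(atoms)
    pdb_file.write(str(path))


def write_trajectory(path, frames: Sequence[np.ndarray],
                     labels: Sequence[str] | None = None,
                     comment: str = "") -> None:
    """Write frames as a multi-frame XYZ file (coordinates in nm)."""
    frames = [np.asarray(f, dtype=float) for f in frames]
    with open(path, "w") as fh:
        for frame in frames:
            n = len(frame)
            names = labels if labels is not None else ["X"] * n
            fh.write(f"{n}\n{comment}\n")
            for name, (x, y, z) in zip(names, frame):
                fh.write(f"{name} {x:.9f} {y:.9f} {z:.9f}\n")


def read_trajectory(path) -> Iterator[np.ndarray]:
    """Stream frames from a multi-frame XYZ file.

    Raises on an empty file or on inconsistent atom counts between frames.
    """
    n_expected = None
    n_frames = 0
    with open(path) as fh:
        while True:
            header = fh.readline()
            if not header.strip():
                if n_frames == 0:
                    raise ValueError(f"empty trajectory file: {path}")
                return
            try:
                n = int(header)
            except ValueError:
                raise ValueError(
                    f"bad XYZ frame header {header!r} in {path}"
                ) from None
            if n_expected is None:
                n_expected = n
            elif n != n_expected:
                raise ValueError(
                    f"inconsistent atom count in {path}: {n} vs {n_expected}"
                )
            fh.readline()  # comment
            coords = np.empty((n, 3))
            for i in range(n):
                parts = fh.readline().split()
                coords[i] = [float(x) for x in parts[1:4]]
            n_frames += 1
            yield coords


def read_rdc_table(path, structure: Structure | None = None) -> list[RDCDefinition]:
    """Read an RDC target table (TSV).

    Columns: id, atom1_name, atom1_resnum, atom2_name, atom2_resnum,
    isotope1, isotope2, r0_nm, D0_Hz.  With a structure, atom specs are
    resolved to indices; otherwise indices are set to (-1, -1) and the
    definitions carry only constants and targets.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"id", "atom1_name", "atom1_resnum", "atom2_name",
                "atom2_resnum", "isotope1", "isotope2", "r0_nm", "D0_Hz"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"RDC table {path} missing columns: {sorted(missing)}")
    out = []
    for _, row in df.iterrows():
        if structure is not None:
            try:
                i1 = structure.find_atom(row.atom1_name, int(row.atom1_resnum))
                i2 = structure.find_atom(row.atom2_name, int(row.atom2_resnum))
            except KeyError as exc:
                raise KeyError(f"RDC {row.id}: {exc}") from None
        else:
            i1 = i2 = -1
        target = None if pd.isna(row.D0_Hz) else float(row.D0_Hz)
        out.append(RDCDefinition.from_isotopes(
            id=str(row.id), atoms=(i1, i2),
            isotopes=(str(row.isotope1), str(row.isotope2)),
            r0=float(row.r0_nm), target=target,
        ))
    return out


@dataclass
class RunConfig:
    """Resolved run parameters with the named default values.

    Defaults: flat bottom 2.0 Hz, harmonic range 1.0 Hz, field-vector
    friction 2.4 ps^-1, N_mfv = 100, K^mfv = 100 and K^msy = 0.05
    kJ mol^-1 Hz^-2, T = 298 K, dt = 0.002 ps, solvent friction 60 ps^-1.
    """

    k_rdc_mfv: float = 100.0
    k_rdc_msy: float = 0.05
    delta_fb_hz: float = 2.0
    delta_h_hz: float = 1.0
    tau_mfv_ps: float = 5000.0
    tau_msy_ps: float = 50.0
    n_mfv: int = 100
    gamma_mfv: float = 2.4
    gamma_solv: float = 60.0
    temperature_k: float = 298.0
    dt_ps: float = 0.002
    averaging_mode: str = "damped"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.averaging_mode not in ("damped", "plain"):
            raise ValueError("averaging_mode must be 'damped' or 'plain'")


def load_config(path_or_stream) -> RunConfig:
    """Load a YAML config, rejecting unknown keys."""
    if isinstance(path_or_stream, (str, Path)):
        with open(path_or_stream) as fh:
            data = yaml.safe_load(fh) or {}
    else:
        data = yaml.safe_load(path_or_stream) or {}
    known = {f.name for f in fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**data)
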