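"""NMR observable calculators: NOE distances, 3J-couplings, hydrogen bonds
and orientation-angle diagnostics.

NOE upper bounds are compared against r^-6 averaged interproton distances;
violations below 0.1 nm are conventionally insignificant.  Vicinal
3J-couplings follow the Karplus relation J = a cos^2(theta) + b cos(theta)
+ c; deviations below 2 Hz from experiment are insignificant given the
Karplus-relation uncertainty.  Hydrogen bonds use the geometric criterion
d(H..A) < 0.25 nm and angle(D-H..A) > 135 degrees.  The magic-angle ratio
flags oversampling of orientation angles near 55/125 degrees, the sampling
artifact of over-restrained rotational-sampling runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "NOEBound",
    "ViolationStats",
    "KarplusCoefficients",
    "KARPLUS_HN_HC",
    "KARPLUS_HC_HC",
    "HBondCriterion",
    "r6_average",
    "noe_stats",
    "karplus_3j",
    "dihedral_angle",
    "j_stats",
    "detect_hbonds",
    "angle_distribution",
    "magic_angle_ratio",
    "virtual_hydrogen",
]


@dataclass(frozen=True)
class NOEBound:
    """One NOE atom-atom distance upper bound (nm).

    ``atom_spec`` holds the two hydrogen specs as free-form strings (real H,
    virtual CH/CH2 H, or a methyl pseudoatom "Me").  Any methyl pseudoatom
    correction (0.1 nm) is assumed already folded into ``upper``.
    """

    id: int
    atom_spec: tuple[str, str]
    upper: float
    source_set: str = "set119"

    def __post_init__(self) -> None:
        if self.upper <= 0:
            raise ValueError("upper bound must be positive")


@dataclass(frozen=True)
class ViolationStats:
    """NOE bound-violation summary over a full bound set.

    ``rmsd`` is the root-mean-square of max(0, d - upper) over *all* bounds
    of the set (satisfied bounds contribute zero), matching the table-footer
    convention of dividing by the full set size.
    """

    n_viol: int
    n_viol_gt: int
    rmsd: float
    largest: tuple[int, float]
    margin: float = 0.1


def r6_average(distances: Sequence[float]) -> float:
    """<r^-6>^(-1/6) over trajectory distances (nm).

    Dominated by the shortest distances; always lies between min(d) and the
    arithmetic mean.
    """
    d = np.asarray(distances, dtype=float)
    if d.size == 0:
        raise ValueError("r6_average requires at least one distance")
    if np.any(d <= 0):
        raise ValueError("distances must be positive")
    return float(np.mean(d ** -6.0) ** (-1.0 / 6.0))


def noe_stats(
    bounds: Sequence[NOEBound],
    distances: Mapping[int, float],
    margin: float = 0.1,
) -> ViolationStats:
    """Violation statistics of r^-6 averaged distances against bounds.

    Counts use strict inequalities: a distance exactly at its bound is not a
    violation, and ``n_viol_gt`` counts violations strictly larger than
    ``margin``.
    """
    missing = [b.id for b in bounds if b.id not in distances]
    if missing:
        raise KeyError(f"no distance for NOE bounds: {missing}")
    viol = np.array([max(0.0, distances[b.id] - b.upper) for b in bounds])
    ids = np.array([b.id for b in bounds])
    n_viol = int(np.sum(viol > 0.0))
    n_gt = int(np.sum(viol > margin))
    i_max = int(np.argmax(viol))
    return ViolationStats(
        n_viol=n_viol,
        n_viol_gt=n_gt,
        rmsd=float(np.sqrt(np.mean(viol ** 2))),
        largest=(int(ids[i_max]), float(viol[i_max])),
        margin=margin,
    )


@dataclass(frozen=True)
class KarplusCoefficients:
    a: float
    b: float
    c: float


#: 3J(HN-HC): a = 6.4, b = -1.4, c = 1.9 Hz.
KARPLUS_HN_HC = KarplusCoefficients(6.4, -1.4, 1.9)
#: 3J(HC-HC): a = 9.5, b = -1.6, c = 1.8 Hz.
KARPLUS_HC_HC = KarplusCoefficients(9.5, -1.6, 1.8)

KARPLUS_SETS = {"HN_HC": KARPLUS_HN_HC, "HC_HC": KARPLUS_HC_HC}


def karplus_3j(dihedral_deg, coeff: KarplusCoefficients):
    """3J(theta) = a cos^2 + b cos + c in Hz; periodic and even in theta."""
    c = np.cos(np.deg2rad(np.asarray(dihedral_deg, dtype=float)))
    out = coeff.a * c * c + coeff.b * c + coeff.c
    return float(out) if out.ndim == 0 else out


def dihedral_angle(p0, p1, p2, p3) -> float:
    """Signed dihedral angle (degrees) of four points (IUPAC convention)."""
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b0, b1, b2 = p0 - p1, p2 - p1, p3 - p2
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    return float(np.degrees(np.arctan2(y, x)))


def j_stats(
    calc: Sequence[float],
    experimental: Sequence[float],
    threshold: float = 2.0,
) -> tuple[int, float]:
    """(count of |calc - exp| strictly > threshold, plain RMSD) in Hz."""
    calc = np.asarray(calc, dtype=float)
    exp = np.asarray(experimental, dtype=float)
    if calc.shape != exp.shape:
        raise ValueError("calc and experimental must have equal length")
    diff = calc - exp
    return int(np.sum(np.abs(diff) > threshold)), float(
        np.sqrt(np.mean(diff ** 2))
    )


@dataclass(frozen=True)
class HBondCriterion:
    """Geometric hydrogen-bond criterion (strict inequalities)."""

    d_ha_max: float = 0.25       # nm
    angle_dha_min: float = 135.0  # degrees


def detect_hbonds(
    coords: np.ndarray,
    donors: Sequence[tuple[int, int]],
    acceptors: Sequence[int],
    criterion: HBondCriterion = HBondCriterion(),
) -> list[tuple[int, int]]:
    """Hydrogen bonds among (donor D, hydrogen H) pairs and acceptor atoms.

    A bond exists iff d(H, A) < d_ha_max and the D-H..A angle exceeds
    angle_dha_min.  Returns (donor_index, acceptor_index) pairs keyed by the
    donor heavy atom.
    """
    coords = np.asarray(coords, dtype=float)
    out = []
    for d_idx, h_idx in donors:
        dh = coords[d_idx] - coords[h_idx]
        for a_idx in acceptors:
            if a_idx in (d_idx, h_idx):
                continue
            ha = coords[a_idx] - coords[h_idx]
            dist = np.linalg.norm(ha)
            if dist >= criterion.d_ha_max:
                continue
            cosang = np.dot(dh, ha) / (np.linalg.norm(dh) * dist)
            angle = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
            if angle > criterion.angle_dha_min:
                out.append((d_idx, a_idx))
    return out


def angle_distribution(
    frames: Iterable[np.ndarray],
    vector_pairs: Sequence[tuple[int, int]],
    field_vecs: Iterable[np.ndarray],
    n_bins: int = 36,
) -> dict:
    """Histograms of theta_ab,H per tracked intramolecular vector.

    For every frame, the angle between each atom-pair vector (a, b) and that
    frame's magnetic-field vector is binned over [0, 180] degrees.  Returns
    raw counts and the sin(theta)-corrected density (normalised so an
    isotropic distribution is flat at 1).
    """
    pairs = np.asarray(vector_pairs, dtype=int)
    counts = np.zeros((len(pairs), n_bins))
    edges = np.linspace(0.0, 180.0, n_bins + 1)
    n_frames = 0
    for coords, h in zip(frames, field_vecs):
        coords = np.asarray(coords, dtype=float)
        h = np.asarray(h, dtype=float)
        h = h / np.linalg.norm(h)
        v = coords[pairs[:, 0]] - coords[pairs[:, 1]]
        v = v / np.linalg.norm(v, axis=1)[:, None]
        c = np.clip(v @ h, -1.0, 1.0)
        theta = np.degrees(np.arccos(c))
        idx = np.minimum((theta / 180.0 * n_bins).astype(int), n_bins - 1)
        counts[np.arange(len(pairs)), idx] += 1.0
        n_frames += 1
    centers = 0.5 * (edges[:-1] + edges[1:])
    sin_w = np.sin(np.deg2rad(centers))
    # isotropic expectation per bin ~ sin(theta); density = counts/(N*p_iso)
    p_iso = sin_w / sin_w.sum()
    with np.errstate(invalid="ignore", divide="ignore"):
        density = counts / (max(n_frames, 1) * p_iso[None, :])
    return {
        "counts": counts,
        "edges": edges,
        "centers": centers,
        "density": density,
        "n_frames": n_frames,
    }


def magic_angle_ratio(
    counts: np.ndarray,
    edges: np.ndarray,
    magic_windows: tuple = ((50.0, 60.0), (120.0, 130.0)),
    reference_window: tuple[float, float] = (85.0, 95.0),
    cap: float = 1e6,
) -> float:
    """Sin-corrected mean density in the magic-angle windows over 90-degree
    window density.

    Uniform sampling on the sphere gives 1.0 by construction; ratios well
    above 1 indicate magic-angle oversampling (the restraining artifact).
    The ratio is capped at ``cap`` when the reference window is empty of
    counts but the magic windows are not.
    """
    counts = np.asarray(counts, dtype=float)
    edges = np.asarray(edges, dtype=float)
    centers = 0.5 * (edges[:-1] + edges[1:])
    sin_w = np.sin(np.deg2rad(centers))
    density = np.where(sin_w > 0, counts / sin_w, 0.0)

    def window_mean(lo: float, hi: float) -> float:
        mask = (centers >= lo) & (centers <= hi)
        if not np.any(mask):
            raise ValueError(f"no bins inside window [{lo}, {hi}]")
        return float(density[mask].mean())

    magic = np.mean([window_mean(lo, hi) for lo, hi in magic_windows])
    ref = window_mean(*reference_window)
    if ref <= 0.0:
        return cap if magic > 0 else 1.0
    return float(min(magic / ref, cap))


_TETRAHEDRAL_COS = -1.0 / 3.0


def virtual_hydrogen(
    center: np.ndarray,
    neighbors: Sequence[np.ndarray],
    kind: str,
    ch_length: float = 0.109,
) -> np.ndarray:
    """Construct virtual/pseudo hydrogen positions on a united carbon.

    kind "CH": three heavy neighbors given; the single H completes the
    tetrahedron opposite their directional mean.  kind "CH2": two heavy
    neighbors; the two prochiral H mirror each other across the heavy-atom
    plane, returned in (Re, Si)-like order fixed by the signed volume of
    (n1, n2, H).  kind "CH3": the pseudoatom sits on the carbon itself (the
    0.1 nm bound correction is carried by the NOE bound, not here).
    Returns an array of shape (n_H, 3) in nm.
    """
    center = np.asarray(center, dtype=float)
    neighbors = [np.asarray(n, dtype=float) for n in neighbors]
    if kind == "CH3":
        return center[None, :].copy()
    if kind == "CH":
        if len(neighbors) < 3:
            raise ValueError("CH construction needs three heavy neighbors")
        units = [(_unit(n - center)) for n in neighbors[:3]]
        direction = -np.sum(units, axis=0)
        return (center + ch_length * _unit(direction))[None, :]
    if kind == "CH2":
        if len(neighbors) < 2:
            raise ValueError("CH2 construction needs two heavy neighbors")
        u1, u2 = _unit(neighbors[0] - center), _unit(neighbors[1] - center)
        bisector = -_unit(u1 + u2)
        perp = _unit(np.cross(u1, u2))
        # ideal tetrahedral half-angle about the bisector
        half = 0.5 * np.arccos(_TETRAHEDRAL_COS)
        h1 = center + ch_length * (np.cos(half) * bisector + np.sin(half) * perp)
        h2 = center + ch_length * (np.cos(half) * bisector - np.sin(half) * perp)
        # Re/Si assignment by signed volume, stable under rigid rotation
        if np.dot(np.cross(neighbors[0] - center, neighbors[1] - center),
                  h1 - center) < 0:
            h1, h2 = h2, h1
        return np.vstack([h1, h2])
    raise ValueError(f"unknown virtual hydrogen kind {kind!r}")


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0.0:
        raise ValueError("zero-length vector in virtual hydrogen construction")
    return v / n
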