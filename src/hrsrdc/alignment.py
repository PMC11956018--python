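"""Five-parameter alignment-tensor fit and RDC back-calculation.

The orientation distribution of a rigidly tumbling molecule is summarised
by a symmetric traceless 3x3 tensor A with five independent components.
The reduced RDC predicted for a unit internuclear vector b is b^T A b, so
that a tensor with A_zz = 1 (others zero) predicts P2(theta_z); multiplying
by D_k^c gives the coupling in Hz.  The five components are carried in a
Saupe-style basis a = (A_zz, A_xx - A_yy, A_xy, A_xz, A_yz).

The fit minimises sum_k (D_k^c * row_k . a - D_k^0)^2 by singular-value
decomposition, the standard linear least-squares approach.  This module is
a faithful baseline of the common alignment-tensor method: the tensor is
refit instantaneously per structure (no time averaging).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "AlignmentTensor",
    "ATFitResult",
    "design_row",
    "fit_alignment_tensor",
    "at_rdc_predict",
    "rdc_rmsd",
    "at_restrained_step_force",
]


@dataclass(frozen=True)
class AlignmentTensor:
    """Saupe-style 5-component alignment tensor.

    ``a = (A_zz, A_xx - A_yy, A_xy, A_xz, A_yz)``.  The full 3x3 matrix is
    symmetric and traceless by construction.
    """

    a: tuple[float, float, float, float, float]

    @classmethod
    def from_components(cls, a) -> "AlignmentTensor":
        a = tuple(float(x) for x in np.asarray(a).ravel())
        if len(a) != 5:
            raise ValueError("alignment tensor needs exactly 5 components")
        return cls(a=a)

    @classmethod
    def zero(cls) -> "AlignmentTensor":
        return cls(a=(0.0, 0.0, 0.0, 0.0, 0.0))

    def matrix(self) -> np.ndarray:
        azz, axx_yy, axy, axz, ayz = self.a
        axx = 0.5 * (axx_yy - azz)
        ayy = 0.5 * (-axx_yy - azz)
        return np.array([
            [axx, axy, axz],
            [axy, ayy, ayz],
            [axz, ayz, azz],
        ])

    @classmethod
    def from_matrix(cls, m: np.ndarray) -> "AlignmentTensor":
        m = np.asarray(m, dtype=float)
        if not np.allclose(m, m.T, atol=1e-10):
            raise ValueError("alignment tensor matrix must be symmetric")
        if abs(np.trace(m)) > 1e-9:
            raise ValueError("alignment tensor matrix must be traceless")
        return cls(a=(m[2, 2], m[0, 0] - m[1, 1], m[0, 1], m[0, 2], m[1, 2]))

    def rotated(self, rot: np.ndarray) -> "AlignmentTensor":
        """Tensor expressed after rotating the frame by matrix ``rot``."""
        return AlignmentTensor.from_matrix(rot @ self.matrix() @ rot.T)


@dataclass(frozen=True)
class ATFitResult:
    tensor: AlignmentTensor
    predicted: np.ndarray        # Hz, per RDC
    rmsd: float                  # Hz
    condition_number: float
    n_used: int


def design_row(unit_bond: np.ndarray) -> np.ndarray:
    """Order-2 design row r(b) with predicted reduced RDC = r(b) . a.

    For a = (1, 0, 0, 0, 0) (pure A_zz) the prediction is P2(cos theta_z) =
    (3 b_z^2 - 1)/2.  The row is invariant under b -> -b (RDC inversion
    symmetry).
    """
    b = np.asarray(unit_bond, dtype=float)
    if abs(np.linalg.norm(b) - 1.0) > 1e-8:
        raise ValueError("design_row expects a unit vector")
    x, y, z = b
    return np.array([
        0.5 * (3.0 * z * z - 1.0),
        0.5 * (x * x - y * y),
        2.0 * x * y,
        2.0 * x * z,
        2.0 * y * z,
    ])


def _design_matrix(unit_bonds: np.ndarray) -> np.ndarray:
    b = np.asarray(unit_bonds, dtype=float)
    x, y, z = b[:, 0], b[:, 1], b[:, 2]
    return np.column_stack([
        0.5 * (3.0 * z * z - 1.0),
        0.5 * (x * x - y * y),
        2.0 * x * y,
        2.0 * x * z,
        2.0 * y * z,
    ])


def at_rdc_predict(
    rdcs: Sequence,
    unit_bonds: np.ndarray,
    tensor: AlignmentTensor,
) -> np.ndarray:
    """Back-calculated couplings D_k = D_k^c * (b_k^T A b_k) in Hz."""
    rows = _design_matrix(unit_bonds)
    dc = np.array([r.d_const for r in rdcs])
    return dc * (rows @ np.asarray(tensor.a))


def fit_alignment_tensor(
    rdcs: Sequence,
    unit_bonds: np.ndarray,
    targets: Sequence[float],
    allow_minimum_norm: bool = False,
) -> ATFitResult:
    """Least-squares alignment tensor from >= 5 couplings via SVD.

    Raises for fewer than five couplings unless ``allow_minimum_norm``;
    rank-deficient designs are solved in the minimum-norm sense with a
    warning recorded through numpy's lstsq rank output.
    """
    unit_bonds = np.asarray(unit_bonds, dtype=float)
    targets = np.asarray(targets, dtype=float)
    n = len(targets)
    if unit_bonds.shape[0] != n or len(rdcs) != n:
        raise ValueError("rdcs, unit_bonds and targets must have equal length")
    if n < 5 and not allow_minimum_norm:
        raise ValueError(
            f"{n} RDCs underdetermine the 5-parameter tensor; pass "
            "allow_minimum_norm=True for the minimum-norm solution"
        )
    dc = np.array([r.d_const for r in rdcs])
    design = dc[:, None] * _design_matrix(unit_bonds)
    a, _, rank, sv = np.linalg.lstsq(design, targets, rcond=None)
    if rank < 5 and not allow_minimum_norm:
        import warnings

        warnings.warn(
            f"rank-deficient design (rank {rank}); minimum-norm solution",
            stacklevel=2,
        )
    cond = float(sv[0] / sv[-1]) if sv[-1] > 0 else np.inf
    tensor = AlignmentTensor.from_components(a)
    predicted = design @ a
    return ATFitResult(
        tensor=tensor,
        predicted=predicted,
        rmsd=rdc_rmsd(predicted, targets),
        condition_number=cond,
        n_used=n,
    )


def rdc_rmsd(calc: Sequence[float], target: Sequence[float]) -> float:
    """Root-mean-square difference between two coupling lists (Hz)."""
    calc = np.asarray(calc, dtype=float)
    target = np.asarray(target, dtype=float)
    if calc.shape != target.shape or calc.size == 0:
        raise ValueError("calc and target must be equal-length, nonempty")
    return float(np.sqrt(np.mean((calc - target) ** 2)))


def at_restrained_step_force(
    rdcs: Sequence,
    coords: np.ndarray,
    targets: Sequence[float],
    k_at: float,
    tensor: AlignmentTensor | None = None,
) -> tuple[np.ndarray, ATFitResult]:
    """Per-atom forces of the harmonic AT restraint E = k/2 sum (pred-D0)^2.

    The tensor is refit for the given structure unless supplied.  The
    gradient is taken with the tensor held fixed; because the fitted tensor
    minimises the same quadratic, this equals the total derivative
    (envelope theorem), so central differences with per-structure refit
    reproduce these forces.  Forces act on the atoms of each coupling's
    bond; the distance factor is held at its reference (rigid bonds).
    """
    coords = np.asarray(coords, dtype=float)
    targets = np.asarray(targets, dtype=float)
    idx = np.array([r.atoms for r in rdcs])
    vecs = coords[idx[:, 0]] - coords[idx[:, 1]]
    lengths = np.linalg.norm(vecs, axis=1)
    units = vecs / lengths[:, None]
    if tensor is None:
        tensor = fit_alignment_tensor(rdcs, units, targets).tensor
    amat = tensor.matrix()
    dc = np.array([r.d_const for r in rdcs])
    ab = units @ amat
    pred = dc * np.einsum("ki,ki->k", units, ab)
    resid = pred - targets
    # dpred/d(bond vector) = dc * 2*(A b - (b^T A b) b)/|v|
    grad_b = dc[:, None] * 2.0 * (ab - (np.einsum("ki,ki->k", units, ab))[:, None] * units)
    grad_v = grad_b / lengths[:, None]
    forces = np.zeros_like(coords)
    contrib = -k_at * resid[:, None] * grad_v
    np.add.at(forces, idx[:, 0], contrib)
    np.add.at(forces, idx[:, 1], -contrib)
    fit = ATFitResult(
        tensor=tensor,
        predicted=pred,
        rmsd=rdc_rmsd(pred, targets),
        condition_number=np.nan,
        n_used=len(targets),
    )
    return forces, fit
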