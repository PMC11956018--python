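"""Hybrid field-vector / molecular-system RDC-restraining loop (HRS).

One molecule time step alternates with an ``n_mfv``-step stochastic-
dynamics block of the two-particle magnetic-field vector: the block samples
the rotational distribution of the field (restrained toward the target
couplings with force constant ``k_mfv`` and memory time ``tau_mfv``), and
its averaged couplings are folded into a second, ``tau_msy``-damped average
that can in turn restrain the molecule (``k_msy``).  With ``k_msy = 0`` the
molecule is untouched and the loop simply computes rotationally sampled
RDC values for its configurations.

Because full solvated molecular dynamics is out of scope here, three
molecule sources are provided: replaying stored frames, rigid-body
rotational diffusion of a fixed structure (optionally importance-weighted
by the order-2 distribution implied by an alignment tensor), and a toy
flexible molecule with elastic-network bonded terms and neighbor-dependent
friction.  These preserve the algorithm's structure at desk scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .alignment import AlignmentTensor, design_row
from .constants import KB
from .mfv import MFVState, SDParams, init_mfv, run_mfv_block
from .restraints import RestraintParams, flat_bottom_force_factor, restraint_set_energy

__all__ = [
    "HRSParams",
    "FrictionModel",
    "HRSResult",
    "neighbor_friction",
    "molecule_restraint_energy",
    "molecule_restraint_forces",
    "ReplaySource",
    "RigidDiffusionSource",
    "ToySDSource",
    "rigid_diffusion_source",
    "run_hrs",
]


@dataclass(frozen=True)
class HRSParams:
    """Parameters of the hybrid loop.

    ``n_mfv`` field-vector SD steps are run per molecule step; ``k_mfv`` and
    ``k_msy`` (kJ mol^-1 Hz^-2) are the restraint force constants on the
    field vector and on the molecule; ``tau_mfv``/``tau_msy`` (ps) the two
    memory relaxation times; ``n_msy`` the number of molecule steps.
    """

    n_mfv: int = 100
    k_mfv: float = 100.0
    k_msy: float = 0.0
    tau_mfv: float = 5000.0
    tau_msy: float = 50.0
    n_msy: int = 1000
    dt: float = 0.002
    delta_fb: float = 2.0
    delta_h: float = 1.0

    def __post_init__(self) -> None:
        if self.n_mfv < 1:
            raise ValueError("n_mfv must be >= 1")
        if self.k_mfv < 0 or self.k_msy < 0:
            raise ValueError("force constants must be >= 0")
        if self.tau_mfv < self.dt or self.tau_msy < self.dt:
            raise ValueError("memory times must be >= dt")

    def mfv_restraint(self) -> RestraintParams:
        return RestraintParams(self.k_mfv, self.delta_fb, self.delta_h)

    def msy_restraint(self) -> RestraintParams:
        return RestraintParams(self.k_msy, self.delta_fb, self.delta_h)


@dataclass(frozen=True)
class FrictionModel:
    """Neighbor-count-dependent atomic friction for in-vacuo SD.

    Solvent friction acts only on exposed atoms: gamma_i = gamma_solv *
    max(0, 1 - N_i/N_ref) with N_i the number of non-hydrogen neighbors
    within ``neighbor_radius`` (self excluded) and N_ref the buried limit.
    """

    gamma_solv: float = 60.0      # ps^-1 (methanol)
    n_nb_ref: int = 6
    neighbor_radius: float = 0.3  # nm
    update_interval: float = 1.0  # ps


def neighbor_friction(
    coords: np.ndarray,
    heavy_mask: np.ndarray,
    model: FrictionModel = FrictionModel(),
) -> np.ndarray:
    """Per-atom friction coefficients (ps^-1) from neighbor counts."""
    coords = np.asarray(coords, dtype=float)
    heavy_mask = np.asarray(heavy_mask, dtype=bool)
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.linalg.norm(diff, axis=-1)
    within = (dist < model.neighbor_radius) & heavy_mask[None, :]
    np.fill_diagonal(within, False)
    counts = within.sum(axis=1)
    return model.gamma_solv * np.clip(1.0 - counts / model.n_nb_ref, 0.0, None)


def _bond_geometry(coords: np.ndarray, rdcs: Sequence) -> tuple[np.ndarray, ...]:
    idx = np.array([r.atoms for r in rdcs])
    vecs = coords[idx[:, 0]] - coords[idx[:, 1]]
    lengths = np.linalg.norm(vecs, axis=1)
    units = vecs / lengths[:, None]
    dc_r3 = np.array([r.d_const * (r.r0 / l) ** 3
                      for r, l in zip(rdcs, lengths)])
    return idx, units, lengths, dc_r3


def molecule_restraint_energy(
    coords: np.ndarray,
    rdcs: Sequence,
    field_samples: np.ndarray,
    targets: Sequence[float],
    params: RestraintParams,
) -> float:
    """Restraint energy of the molecule for a frozen field-orientation set.

    The coupling averages are D_k = D_k^c <P2(b_hat_k . h_hat_m)>_m over the
    stored field unit vectors (the distance factor is held at one for the
    constrained bonds).  :func:`molecule_restraint_forces` is the exact
    negative gradient of this function.
    """
    coords = np.asarray(coords, dtype=float)
    _, units, _, _ = _bond_geometry(coords, rdcs)
    dc = np.array([r.d_const for r in rdcs])
    c = units @ np.asarray(field_samples, dtype=float).T      # (K, M)
    d_avg = dc * np.mean(0.5 * (3.0 * c * c - 1.0), axis=1)
    return restraint_set_energy(d_avg, np.asarray(targets, float), params)


def molecule_restraint_forces(
    coords: np.ndarray,
    rdcs: Sequence,
    field_samples: np.ndarray,
    targets: Sequence[float],
    params: RestraintParams,
    force_factors: np.ndarray | None = None,
) -> np.ndarray:
    """Per-atom restraint forces on the molecule (kJ mol^-1 nm^-1).

    With ``force_factors`` omitted they are computed from the same frozen
    field-sample averages as :func:`molecule_restraint_energy`, making the
    force the exact negative gradient of that energy.  During HRS runs the
    factors come from the tau_msy-damped coupling averages instead.
    """
    coords = np.asarray(coords, dtype=float)
    samples = np.asarray(field_samples, dtype=float)
    idx, units, lengths, _ = _bond_geometry(coords, rdcs)
    dc = np.array([r.d_const for r in rdcs])
    c = units @ samples.T                                     # (K, M)
    if force_factors is None:
        d_avg = dc * np.mean(0.5 * (3.0 * c * c - 1.0), axis=1)
        force_factors = flat_bottom_force_factor(
            d_avg, np.asarray(targets, float), params)
    # <3 c h_hat> and <3 c^2> over the field samples
    grad_vec = (3.0 * c) @ samples / samples.shape[0]          # (K, 3)
    grad_c2 = np.mean(3.0 * c * c, axis=1)                     # (K,)
    dd_db = dc[:, None] * (grad_vec - grad_c2[:, None] * units) / lengths[:, None]
    contrib = -np.asarray(force_factors)[:, None] * dd_db
    forces = np.zeros_like(coords)
    np.add.at(forces, idx[:, 0], contrib)
    np.add.at(forces, idx[:, 1], -contrib)
    return forces


class ReplaySource:
    """Replays a fixed list of coordinate frames (cycling)."""

    mode = "replay"

    def __init__(self, frames: Sequence[np.ndarray]):
        if len(frames) == 0:
            raise ValueError("replay source needs at least one frame")
        self.frames = [np.asarray(f, dtype=float) for f in frames]

    def frame(self, n: int) -> np.ndarray:
        return self.frames[n % len(self.frames)]


class RigidDiffusionSource:
    """Rigid-body rotational Brownian motion of a fixed structure.

    Axis autocorrelation of any body-fixed vector decays as
    exp(-t / rotational_diffusion_time).  With a bias tensor, per-frame
    importance weights w = 1 + 5 * e^T A e are attached (e the field
    direction expressed in the molecule frame); the weighted orientation
    average of P2 then reproduces the tensor's back-calculated reduced
    couplings exactly in the limit of many frames.
    """

    mode = "rigid_diffusion"

    def __init__(
        self,
        structure: np.ndarray,
        rotational_diffusion_time: float,
        n_frames: int,
        seed: int = 0,
        bias: AlignmentTensor | None = None,
        frame_dt: float = 1.0,
    ):
        from scipy.spatial.transform import Rotation

        self.structure = np.asarray(structure, dtype=float)
        self.tau_rot = rotational_diffusion_time
        self.frame_dt = frame_dt
        rng = np.random.default_rng(seed)
        # axis autocorrelation exp(-2 D_r t) = exp(-t/tau)  =>  D_r = 1/(2 tau)
        sigma = math.sqrt(2.0 * frame_dt / (2.0 * rotational_diffusion_time))
        rots = []
        current = Rotation.identity()
        for _ in range(n_frames):
            step = Rotation.from_rotvec(rng.normal(0.0, sigma, size=3))
            current = step * current
            rots.append(current)
        self.rotations = rots
        self.matrices = np.array([r.as_matrix() for r in rots])
        self.bias = bias
        if bias is not None and any(abs(x) > 1e-15 for x in bias.a):
            a = np.asarray(bias.a)
            ez = np.einsum("nji,j->ni", self.matrices, [0.0, 0.0, 1.0])
            rows = np.array([design_row(e) for e in ez])
            self.weights = 1.0 + 5.0 * rows @ a
            if np.any(self.weights < 0.0):
                raise ValueError(
                    "bias tensor too strong for linear order-2 weighting "
                    "(weights would be negative); use |eigenvalues| <= 0.2"
                )
        else:
            self.weights = np.ones(n_frames)

    def frame(self, n: int) -> np.ndarray:
        m = self.matrices[n % len(self.matrices)]
        return self.structure @ m.T

    def weight(self, n: int) -> float:
        return float(self.weights[n % len(self.weights)])


class ToySDSource:
    """Toy flexible molecule: elastic-network bonds + Langevin friction.

    Harmonic springs connect all atom pairs closer than ``cutoff`` in the
    reference structure; per-atom friction follows the neighbor-count model.
    This is a minimal stand-in for a solvated molecular simulation with
    only bonded-like terms.
    """

    mode = "toy_sd"

    def __init__(
        self,
        structure: np.ndarray,
        heavy_mask: np.ndarray,
        seed: int = 0,
        dt: float = 0.002,
        temperature: float = 298.0,
        k_bond: float = 20000.0,   # kJ mol^-1 nm^-2
        cutoff: float = 0.35,      # nm
        mass: float = 14.0,        # u, uniform
        friction: FrictionModel = FrictionModel(),
    ):
        self.coords = np.asarray(structure, dtype=float).copy()
        self.heavy_mask = np.asarray(heavy_mask, dtype=bool)
        self.dt = dt
        self.temperature = temperature
        self.mass = mass
        self.k_bond = k_bond
        self.friction_model = friction
        self.rng = np.random.default_rng(seed)
        n = len(self.coords)
        diff = self.coords[:, None] - self.coords[None, :]
        dist = np.linalg.norm(diff, axis=-1)
        iu, ju = np.triu_indices(n, k=1)
        mask = dist[iu, ju] < cutoff
        self.pairs = np.column_stack([iu[mask], ju[mask]])
        self.ref_len = dist[self.pairs[:, 0], self.pairs[:, 1]]
        self.vel = self.rng.normal(
            0.0, math.sqrt(KB * temperature / mass), size=self.coords.shape)
        self._gamma = neighbor_friction(self.coords, self.heavy_mask, friction)
        self._steps_since_update = 0

    def _bonded_forces(self) -> np.ndarray:
        v = self.coords[self.pairs[:, 0]] - self.coords[self.pairs[:, 1]]
        ln = np.linalg.norm(v, axis=1)
        f = -self.k_bond * (ln - self.ref_len)[:, None] * (v / ln[:, None])
        forces = np.zeros_like(self.coords)
        np.add.at(forces, self.pairs[:, 0], f)
        np.add.at(forces, self.pairs[:, 1], -f)
        return forces

    def step(self, external_forces: np.ndarray | None = None) -> np.ndarray:
        """One Langevin leapfrog step; returns the new coordinates."""
        interval = max(int(self.friction_model.update_interval / self.dt), 1)
        if self._steps_since_update >= interval:
            self._gamma = neighbor_friction(
                self.coords, self.heavy_mask, self.friction_model)
            self._steps_since_update = 0
        self._steps_since_update += 1
        g = self._gamma[:, None]
        f = self._bonded_forces()
        if external_forces is not None:
            f = f + external_forces
        sigma = np.sqrt(2.0 * self.mass * g * KB * self.temperature / self.dt)
        noise = self.rng.normal(size=self.coords.shape) * sigma
        self.vel = self.vel + self.dt * ((f + noise) / self.mass - g * self.vel)
        self.coords = self.coords + self.dt * self.vel
        return self.coords

    def frame(self, n: int) -> np.ndarray:
        return self.coords


def rigid_diffusion_source(
    structure: np.ndarray,
    rotational_diffusion_time: float,
    bias: AlignmentTensor | None = None,
    n_frames: int = 1000,
    seed: int = 0,
    frame_dt: float = 1.0,
) -> RigidDiffusionSource:
    """Convenience constructor mirroring :class:`RigidDiffusionSource`."""
    return RigidDiffusionSource(
        structure=structure,
        rotational_diffusion_time=rotational_diffusion_time,
        n_frames=n_frames,
        seed=seed,
        bias=bias,
        frame_dt=frame_dt,
    )


@dataclass
class HRSResult:
    """Outcome of a hybrid run.

    ``mean_d`` are the plain (analysis) coupling averages over all molecule
    steps, ``damped_d`` the tau_msy-damped averages driving the molecule
    forces; ``rmsd`` and ``max_dev`` compare ``mean_d`` with the targets.
    """

    mean_d: np.ndarray
    damped_d: np.ndarray
    targets: np.ndarray
    energies: np.ndarray
    rmsd: float
    max_dev: float
    theta_counts: np.ndarray | None = None
    theta_edges: np.ndarray | None = None
    recorded_forces: list = field(default_factory=list)
    final_mfv: MFVState | None = None


def run_hrs(
    source,
    rdcs: Sequence,
    params: HRSParams,
    seed: int = 0,
    sd: SDParams | None = None,
    tracked_pairs: Sequence[tuple[int, int]] | None = None,
    warm_start: bool = True,
    record_forces: bool = False,
    theta_bins: int = 36,
    damped_init: str | np.ndarray | None = "targets",
) -> HRSResult:
    """Run the hybrid loop for ``params.n_msy`` molecule steps.

    For each molecule step the current frame's bond vectors are extracted,
    an ``n_mfv``-step restrained field-vector block is run (state and
    damped averages persist across blocks when ``warm_start``), and the
    block coupling averages are folded into the tau_msy-damped molecule-
    side averages.  With ``k_msy > 0`` the resulting restraint forces are
    applied to a stepping source (toy_sd) or recorded otherwise.

    ``damped_init="targets"`` (default) starts the field-side damped
    coupling averages at the target values, i.e. inside the flat bottom, so
    no restraining force acts until the averages drift; ``None`` seeds them
    with the first instantaneous (kHz-scale) couplings instead, which for
    restrained runs produces a long startup transient.
    """
    if len(rdcs) == 0:
        raise ValueError("need at least one RDC")
    targets = np.array([r.target if r.target is not None else 0.0
                        for r in rdcs])
    sd = sd or SDParams(dt=params.dt, seed=seed)
    mfv_state = init_mfv(seed)
    mfv_restraint = params.mfv_restraint()
    msy_restraint = params.msy_restraint()
    decay_msy = math.exp(-params.dt / params.tau_msy)

    if isinstance(damped_init, str) and damped_init == "targets":
        damped_mfv = targets.copy()
    elif damped_init is None:
        damped_mfv = None
    else:
        damped_mfv = np.asarray(damped_init, dtype=float).copy()
    damped_msy: np.ndarray | None = None
    sum_d = np.zeros(len(rdcs))
    energies = np.empty(params.n_msy)
    recorded = []
    can_step = hasattr(source, "step")
    frame = source.frame(0)

    theta_counts = None
    theta_edges = np.linspace(0.0, 180.0, theta_bins + 1)
    if tracked_pairs is not None:
        tracked_pairs = np.asarray(tracked_pairs, dtype=int)
        theta_counts = np.zeros((len(tracked_pairs), theta_bins))

    for n in range(params.n_msy):
        coords = np.asarray(frame, dtype=float)
        _, units, _, dc_r3 = _bond_geometry(coords, rdcs)
        if not warm_start:
            mfv_state = init_mfv(seed + n + 1)
            damped_mfv = (targets.copy()
                          if isinstance(damped_init, str) else None)
        block, damped_mfv, mfv_state = run_mfv_block(
            mfv_state, units, dc_r3, targets, mfv_restraint, sd,
            params.tau_mfv, params.n_mfv, damped=damped_mfv,
            collect_field=True,
        )
        d_block = block.avg_d
        damped_msy = d_block.copy() if damped_msy is None else (
            decay_msy * damped_msy + (1.0 - decay_msy) * d_block)
        sum_d += dc_r3 * block.mean_p
        energies[n] = restraint_set_energy(damped_msy, targets, msy_restraint)

        if tracked_pairs is not None:
            h = mfv_state.bond_vector()
            h = h / np.linalg.norm(h)
            v = coords[tracked_pairs[:, 0]] - coords[tracked_pairs[:, 1]]
            v = v / np.linalg.norm(v, axis=1)[:, None]
            theta = np.degrees(np.arccos(np.clip(v @ h, -1.0, 1.0)))
            idx = np.minimum((theta / 180.0 * theta_bins).astype(int),
                             theta_bins - 1)
            theta_counts[np.arange(len(tracked_pairs)), idx] += 1.0

        forces = None
        if params.k_msy > 0.0:
            ff = flat_bottom_force_factor(damped_msy, targets, msy_restraint)
            forces = molecule_restraint_forces(
                coords, rdcs, block.field_samples, targets, msy_restraint,
                force_factors=ff,
            )
            if record_forces:
                recorded.append(forces)
        if can_step:
            frame = source.step(forces)
        else:
            frame = source.frame(n + 1)

    mean_d = sum_d / params.n_msy
    dev = mean_d - targets
    return HRSResult(
        mean_d=mean_d,
        damped_d=damped_msy,
        targets=targets,
        energies=energies,
        rmsd=float(np.sqrt(np.mean(dev ** 2))),
        max_dev=float(np.max(np.abs(dev))),
        theta_counts=theta_counts,
        theta_edges=theta_edges,
        recorded_forces=recorded,
        final_mfv=mfv_state,
    )
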