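"""Stochastic (Langevin) leapfrog dynamics of the magnetic-field vector.

The magnetic field is represented by two united-atom particles (mass
15.035 u each) joined by a rigid 0.153 nm bond.  The only potential-energy
term acting on the pair is the RDC-restraining one, so the vector's motion
is governed by the Langevin equation (friction gamma = 2.4 ps^-1, which
optimises rotational sampling) plus the restraint forces.  The bond length
is maintained by SHAKE-style iterative projection.

The integrator is an impulse-form leapfrog: a combined deterministic and
stochastic kick, a drift, a position-constraint projection, and a velocity
recomputation from the constrained positions.  The stochastic force has a
per-component variance of 2*m*gamma*kB*T/dt, which together with the
friction term satisfies the fluctuation-dissipation relation at T.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

import math

import numpy as np

from .constants import KB
from .restraints import RestraintParams

__all__ = [
    "IntegrationError",
    "MFVState",
    "SDParams",
    "MFVBlockResult",
    "init_mfv",
    "langevin_step",
    "run_mfv_block",
    "simulate_mfv",
]


class IntegrationError(RuntimeError):
    """Raised when the bond-constraint iteration fails to converge.

    A SHAKE failure signals unphysically large (restraining) forces.
    """


@dataclass
class MFVState:
    """Positions, velocities and SD parameters of the field-vector pair."""

    pos: np.ndarray            # (2, 3) nm
    vel: np.ndarray            # (2, 3) nm/ps
    mass: float = 15.035       # u, per particle
    bond_length: float = 0.153  # nm
    friction: float = 2.4      # ps^-1
    temperature: float = 298.0  # K
    rng: np.random.Generator = field(default_factory=np.random.default_rng)

    def bond_vector(self) -> np.ndarray:
        return self.pos[0] - self.pos[1]

    def copy(self) -> "MFVState":
        # The RNG object is shared: copying is for positions/velocities only.
        return replace(self, pos=self.pos.copy(), vel=self.vel.copy())


@dataclass(frozen=True)
class SDParams:
    """Integration parameters for the field-vector SD simulation."""

    dt: float = 0.002            # ps
    n_steps: int = 1000
    constraint_tol: float = 1e-4  # relative geometric precision
    seed: int = 0
    max_constraint_iter: int = 500

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.constraint_tol <= 0:
            raise ValueError("constraint_tol must be > 0")


def init_mfv(
    seed: int,
    direction: np.ndarray | None = None,
    mass: float = 15.035,
    bond_length: float = 0.153,
    friction: float = 2.4,
    temperature: float = 298.0,
) -> MFVState:
    """Initialise the field vector along ``direction`` (default +z).

    Particle 1 sits at ``bond_length * direction``, particle 2 at the
    origin, so the bond vector pos1 - pos2 points along ``direction``.
    Velocities are Maxwell-Boltzmann at ``temperature`` with the
    bond-parallel relative component projected out so the rigid-bond
    constraint also holds for the velocities.
    """
    rng = np.random.default_rng(seed)
    if direction is None:
        direction = np.array([0.0, 0.0, 1.0])
    direction = np.asarray(direction, dtype=float)
    norm = np.linalg.norm(direction)
    if norm == 0.0:
        raise ValueError("direction must be a nonzero vector")
    unit = direction / norm
    pos = np.vstack([bond_length * unit, np.zeros(3)])
    sigma = math.sqrt(KB * temperature / mass)
    vel = rng.normal(0.0, sigma, size=(2, 3))
    # remove bond-parallel relative velocity (RATTLE-style projection)
    rel = vel[0] - vel[1]
    corr = 0.5 * np.dot(rel, unit) * unit
    vel[0] -= corr
    vel[1] += corr
    return MFVState(pos=pos, vel=vel, mass=mass, bond_length=bond_length,
                    friction=friction, temperature=temperature, rng=rng)


def _shake_pair(
    pos_old: np.ndarray,
    pos_trial: np.ndarray,
    bond_length: float,
    tol: float,
    max_iter: int,
) -> np.ndarray:
    """Project the trial positions of a two-particle bond onto |r| = d.

    Equal masses; the correction acts along the pre-step bond vector, as in
    SHAKE.  Converges when the relative deviation of the bond length is
    below ``tol``.
    """
    r_old = pos_old[0] - pos_old[1]
    pos = pos_trial.copy()
    d2 = bond_length * bond_length
    for _ in range(max_iter):
        r = pos[0] - pos[1]
        diff = r @ r - d2
        if abs(math.sqrt(r @ r) - bond_length) <= tol * bond_length:
            return pos
        denom = 2.0 * (r @ r_old) * 2.0  # 2 * (1/m1 + 1/m2) * m, masses equal
        if denom == 0.0:
            raise IntegrationError("constraint projection degenerate")
        g = diff / denom
        corr = g * r_old
        pos[0] -= corr
        pos[1] += corr
    raise IntegrationError(
        "bond constraint did not converge; restraining forces may be "
        "unphysically large"
    )


def langevin_step(
    state: MFVState,
    force_fn: Callable[[np.ndarray], np.ndarray] | None,
    params: SDParams,
) -> MFVState:
    """Advance the field-vector pair by one Langevin leapfrog step.

    ``force_fn`` maps positions (2, 3) to per-particle forces in
    kJ mol^-1 nm^-1 (``None`` means no deterministic force).  The stochastic
    kick obeys fluctuation-dissipation at the state's temperature; with
    friction = 0 and T = 0 the step reduces to deterministic leapfrog drift
    with constraint projection (free rigid rotation).
    """
    new = state.copy()
    _step_inplace(new, force_fn, params)
    return new


def _step_inplace(
    state: MFVState,
    force_fn: Callable[[np.ndarray], np.ndarray] | None,
    params: SDParams,
) -> None:
    dt = params.dt
    m = state.mass
    gamma = state.friction
    f = force_fn(state.pos) if force_fn is not None else 0.0
    if gamma > 0.0 and state.temperature > 0.0:
        sigma = math.sqrt(2.0 * m * gamma * KB * state.temperature / dt)
        f = f + state.rng.normal(0.0, sigma, size=(2, 3))
    accel = f / m if force_fn is not None or gamma > 0.0 else 0.0
    vel = state.vel + dt * (accel - gamma * state.vel)
    trial = state.pos + dt * vel
    constrained = _shake_pair(state.pos, trial, state.bond_length,
                              params.constraint_tol,
                              params.max_constraint_iter)
    state.vel = (constrained - state.pos) / dt
    state.pos = constrained


@dataclass
class MFVBlockResult:
    """Per-RDC averages accumulated over one mfv block.

    ``avg_p`` is the exponentially damped P2-bar per RDC at the end of the
    block (dimensionless, distance factor excluded), ``avg_d`` the matching
    coupling average in Hz.  ``grad_vec`` and ``grad_c2`` are the block
    means of 3*cos(theta)*h_hat and 3*cos^2(theta) needed for the
    molecule-side chain-rule force, and ``field_samples`` optionally stores
    the field unit vectors visited during the block.
    """

    avg_p: np.ndarray
    avg_d: np.ndarray
    grad_vec: np.ndarray
    grad_c2: np.ndarray
    mean_p: np.ndarray
    field_samples: np.ndarray | None = None


def _restraint_kick(
    h_unit: np.ndarray,
    h_len: float,
    bond_units: np.ndarray,
    dc_r3: np.ndarray,
    force_factors: np.ndarray,
) -> np.ndarray:
    """Force on field particle 1 from all restraints (particle 2 gets -F).

    dD_k/dh = D_k^c R_k^3 * 3 cos(theta_k) * (b_hat_k - cos(theta_k) h_hat)
              / |h|.
    """
    c = bond_units @ h_unit
    coef = force_factors * dc_r3 * 3.0 * c / h_len      # (K,)
    grad = coef[:, None] * (bond_units - np.outer(c, h_unit))
    return -grad.sum(axis=0)


def run_mfv_block(
    state: MFVState,
    bond_units: np.ndarray,
    dc_r3: np.ndarray,
    targets: np.ndarray,
    restraint: RestraintParams,
    sd: SDParams,
    tau: float,
    n_mfv: int,
    damped: np.ndarray | None = None,
    collect_field: bool = False,
    fast: bool = True,
    kernel_seed: int | None = None,
) -> tuple[MFVBlockResult, np.ndarray, MFVState]:
    """Advance ``n_mfv`` restrained SD steps against one molecule frame.

    ``bond_units`` (K, 3) are the unit internuclear vectors of the K RDCs in
    the current (fixed) molecular configuration and ``dc_r3`` the product
    D_k^c * (r0/r)^3 in Hz.  The restraining force on the field particles
    uses the tau-damped coupling average ``damped`` (seeded with the first
    instantaneous values when ``None``).  Returns the block result, the
    updated damped averages and the updated state.
    """
    if n_mfv < 1:
        raise ValueError("n_mfv must be >= 1")
    bond_units = np.asarray(bond_units, dtype=float)
    dc_r3 = np.asarray(dc_r3, dtype=float)
    targets = np.asarray(targets, dtype=float)
    decay = math.exp(-sd.dt / tau)
    if fast:
        try:
            return _run_mfv_block_fast(
                state, bond_units, dc_r3, targets, restraint, sd, tau,
                n_mfv, damped, collect_field, kernel_seed)
        except ImportError:
            pass
    dt = sd.dt
    m = state.mass
    gamma = state.friction
    sigma = (
        math.sqrt(2.0 * m * gamma * KB * state.temperature / dt)
        if gamma > 0.0 and state.temperature > 0.0
        else 0.0
    )
    use_force = restraint.k_rdc > 0.0

    pos = state.pos.copy()
    vel = state.vel.copy()
    rng = state.rng
    d = damped.copy() if damped is not None else None

    k = bond_units.shape[0]
    acc_vec = np.zeros((k, 3))
    acc_c2 = np.zeros(k)
    acc_p = np.zeros(k)
    samples = np.empty((n_mfv, 3)) if collect_field else None

    for step in range(n_mfv):
        h = pos[0] - pos[1]
        h_len = math.sqrt(h @ h)
        h_unit = h / h_len
        c = bond_units @ h_unit
        p2 = 0.5 * (3.0 * c * c - 1.0)
        d_inst = dc_r3 * p2
        if d is None:
            d = d_inst.copy()
        else:
            d = decay * d + (1.0 - decay) * d_inst

        f1 = np.zeros(3)
        if use_force:
            fdev = np.clip(np.abs(d - targets) - restraint.delta_fb,
                           0.0, restraint.delta_h)
            # d(damped avg)/dx carries the (1 - exp(-dt/tau)) memory factor,
            # which makes the restraining force proportional to K/tau
            ff = (1.0 - decay) * restraint.k_rdc * fdev * np.sign(d - targets)
            f1 = _restraint_kick(h_unit, h_len, bond_units, dc_r3, ff)

        acc_vec += (3.0 * c)[:, None] * h_unit
        acc_c2 += 3.0 * c * c
        acc_p += p2
        if collect_field:
            samples[step] = h_unit

        noise = rng.normal(0.0, sigma, size=(2, 3)) if sigma > 0.0 else 0.0
        force = np.vstack([f1, -f1]) + noise if use_force else noise
        if sigma > 0.0 or use_force:
            vel = vel + dt * (force / m - gamma * vel)
        else:
            vel = vel - dt * gamma * vel
        trial = pos + dt * vel
        constrained = _shake_pair(pos, trial, state.bond_length,
                                  sd.constraint_tol, sd.max_constraint_iter)
        vel = (constrained - pos) / dt
        pos = constrained

    new_state = replace(state, pos=pos, vel=vel)
    result = MFVBlockResult(
        avg_p=d / np.where(dc_r3 != 0.0, dc_r3, 1.0),
        avg_d=d.copy(),
        grad_vec=acc_vec / n_mfv,
        grad_c2=acc_c2 / n_mfv,
        mean_p=acc_p / n_mfv,
        field_samples=samples,
    )
    return result, d, new_state


def _run_mfv_block_fast(
    state, bond_units, dc_r3, targets, restraint, sd, tau, n_mfv,
    damped, collect_field, kernel_seed,
):
    from ._kernels import mfv_block_kernel

    decay = math.exp(-sd.dt / tau)
    sigma = (
        math.sqrt(2.0 * state.mass * state.friction * KB * state.temperature
                  / sd.dt)
        if state.friction > 0.0 and state.temperature > 0.0
        else 0.0
    )
    pos = state.pos.copy()
    vel = state.vel.copy()
    k = bond_units.shape[0]
    if damped is None:
        h = pos[0] - pos[1]
        h_unit = h / np.linalg.norm(h)
        c0 = bond_units @ h_unit
        d = dc_r3 * 0.5 * (3.0 * c0 * c0 - 1.0)
    else:
        d = damped.copy()
    grad_vec = np.zeros((k, 3))
    grad_c2 = np.zeros(k)
    mean_p = np.zeros(k)
    samples = np.empty((n_mfv, 3)) if collect_field else np.empty((1, 3))
    if kernel_seed is None:
        kernel_seed = int(state.rng.integers(2**31))
    fail = mfv_block_kernel(
        pos, vel, bond_units, dc_r3, targets,
        restraint.k_rdc, restraint.delta_fb, restraint.delta_h,
        decay, sd.dt, state.mass, state.friction, sigma,
        d, n_mfv, state.bond_length, sd.constraint_tol,
        sd.max_constraint_iter, kernel_seed,
        grad_vec, grad_c2, mean_p, samples, collect_field,
    )
    if fail:
        raise IntegrationError(
            f"bond constraint failed at block step {fail - 1}; restraining "
            "forces may be unphysically large"
        )
    new_state = replace(state, pos=pos, vel=vel)
    result = MFVBlockResult(
        avg_p=d / np.where(dc_r3 != 0.0, dc_r3, 1.0),
        avg_d=d.copy(),
        grad_vec=grad_vec,
        grad_c2=grad_c2,
        mean_p=mean_p,
        field_samples=samples if collect_field else None,
    )
    return result, d, new_state


def simulate_mfv(
    rdcs,
    bond_vectors: np.ndarray,
    restraint: RestraintParams,
    sd: SDParams,
    tau: float = 5000.0,
    state: MFVState | None = None,
    report_stride: int = 1,
    burn_in: int = 0,
    theta_bins: int = 36,
    external_force=None,
    damped_init=None,
    fast: bool = True,
    maier_saupe_bias: float = 0.0,
):
    """Standalone restrained/unrestrained mfv SD run against a fixed frame.

    ``rdcs`` is a sequence of :class:`~hrsrdc.rdc.RDCDefinition`;
    ``bond_vectors`` (K, 3) their internuclear vectors (nm) in the fixed
    molecular configuration.  Couplings reported are plain means over the
    post-burn-in analysis window (the damped average drives the forces
    only).  ``external_force`` optionally maps positions to an extra
    per-particle force, used e.g. for orientation-biasing potentials.

    Returns a dict with plain-mean couplings ``mean_d`` (Hz), per-RDC
    deviations from target, a theta histogram of the field direction against
    each bond vector, and the final state.

    ``damped_init`` seeds the damped average: ``None`` uses the first
    instantaneous values; ``"targets"`` starts inside the flat bottom at the
    target couplings (recommended for restrained runs, avoiding the large
    startup transient of kHz-scale instantaneous seeds); an array is used
    as-is.  ``fast`` selects the compiled kernel when available.
    """
    bond_vectors = np.asarray(bond_vectors, dtype=float)
    lengths = np.linalg.norm(bond_vectors, axis=1)
    bond_units = bond_vectors / lengths[:, None]
    dc_r3 = np.array([r.d_const * (r.r0 / l) ** 3
                      for r, l in zip(rdcs, lengths)])
    targets = np.array([r.target if r.target is not None else 0.0
                        for r in rdcs])
    if state is None:
        state = init_mfv(sd.seed)

    if isinstance(damped_init, str) and damped_init == "targets":
        damped0 = targets.copy()
    elif damped_init is None:
        damped0 = None
    else:
        damped0 = np.asarray(damped_init, dtype=float).copy()

    if fast and external_force is None:
        try:
            return _simulate_mfv_fast(
                rdcs, bond_units, lengths, dc_r3, targets, restraint, sd,
                tau, state, report_stride, burn_in, theta_bins, damped0,
                maier_saupe_bias)
        except ImportError:
            pass

    if maier_saupe_bias != 0.0 and external_force is None:
        a = maier_saupe_bias

        def external_force(pos):  # noqa: F811 - orienting bias fallback
            h = pos[0] - pos[1]
            hl = np.linalg.norm(h)
            u = h / hl
            f1 = a * 3.0 * u[2] * (np.array([0.0, 0.0, 1.0]) - u[2] * u) / hl
            return np.vstack([f1, -f1])

    decay = math.exp(-sd.dt / tau)
    dt = sd.dt
    m, gamma = state.mass, state.friction
    sigma = (
        math.sqrt(2.0 * m * gamma * KB * state.temperature / dt)
        if gamma > 0.0 and state.temperature > 0.0
        else 0.0
    )
    use_force = restraint.k_rdc > 0.0
    pos, vel, rng = state.pos.copy(), state.vel.copy(), state.rng

    k = len(rdcs)
    damped = damped0
    sum_p = np.zeros(k)
    n_acc = 0
    hist = np.zeros((k, theta_bins))
    edges = np.linspace(0.0, 180.0, theta_bins + 1)

    for step in range(sd.n_steps):
        h = pos[0] - pos[1]
        h_len = math.sqrt(h @ h)
        h_unit = h / h_len
        c = bond_units @ h_unit
        p2 = 0.5 * (3.0 * c * c - 1.0)
        d_inst = dc_r3 * p2
        damped = d_inst.copy() if damped is None else (
            decay * damped + (1.0 - decay) * d_inst)

        f = np.zeros((2, 3))
        if use_force:
            fdev = np.clip(np.abs(damped - targets) - restraint.delta_fb,
                           0.0, restraint.delta_h)
            ff = (1.0 - decay) * restraint.k_rdc * fdev * np.sign(damped - targets)
            f1 = _restraint_kick(h_unit, h_len, bond_units, dc_r3, ff)
            f[0] += f1
            f[1] -= f1
        if external_force is not None:
            f = f + external_force(pos)

        if step >= burn_in and step % report_stride == 0:
            sum_p += p2
            n_acc += 1
            theta = np.degrees(np.arccos(np.clip(c, -1.0, 1.0)))
            idx = np.minimum((theta / 180.0 * theta_bins).astype(int),
                             theta_bins - 1)
            hist[np.arange(k), idx] += 1.0

        noise = rng.normal(0.0, sigma, size=(2, 3)) if sigma > 0.0 else 0.0
        vel = vel + dt * ((f + noise) / m - gamma * vel)
        trial = pos + dt * vel
        constrained = _shake_pair(pos, trial, state.bond_length,
                                  sd.constraint_tol, sd.max_constraint_iter)
        vel = (constrained - pos) / dt
        pos = constrained

    mean_p = sum_p / max(n_acc, 1)
    mean_d = dc_r3 * mean_p
    final = replace(state, pos=pos, vel=vel)
    return {
        "mean_p": mean_p,
        "mean_d": mean_d,
        "deviations": mean_d - targets,
        "damped_d": damped,
        "theta_hist": hist,
        "theta_edges": edges,
        "state": final,
        "n_samples": n_acc,
    }


def _simulate_mfv_fast(
    rdcs, bond_units, lengths, dc_r3, targets, restraint, sd, tau,
    state, report_stride, burn_in, theta_bins, damped0,
    maier_saupe_bias=0.0,
):
    from ._kernels import mfv_run_kernel

    decay = math.exp(-sd.dt / tau)
    sigma = (
        math.sqrt(2.0 * state.mass * state.friction * KB * state.temperature
                  / sd.dt)
        if state.friction > 0.0 and state.temperature > 0.0
        else 0.0
    )
    pos = state.pos.copy()
    vel = state.vel.copy()
    k = len(rdcs)
    if damped0 is None:
        h = pos[0] - pos[1]
        h_unit = h / np.linalg.norm(h)
        c0 = bond_units @ h_unit
        damped = dc_r3 * 0.5 * (3.0 * c0 * c0 - 1.0)
    else:
        damped = damped0
    sum_p = np.zeros(k)
    hist = np.zeros((k, theta_bins))
    out_stats = np.zeros(2)
    kernel_seed = int(state.rng.integers(2**31))
    n_acc, fail = mfv_run_kernel(
        pos, vel, bond_units, dc_r3, targets,
        restraint.k_rdc, restraint.delta_fb, restraint.delta_h,
        decay, sd.dt, state.mass, state.friction, sigma,
        damped, sd.n_steps, burn_in, report_stride,
        state.bond_length, sd.constraint_tol, sd.max_constraint_iter,
        kernel_seed, sum_p, hist, theta_bins,
        maier_saupe_bias, out_stats,
    )
    if fail:
        raise IntegrationError(
            f"bond constraint failed at step {fail - 1}; restraining forces "
            "may be unphysically large"
        )
    mean_p = sum_p / max(n_acc, 1)
    mean_d = dc_r3 * mean_p
    final = replace(state, pos=pos, vel=vel)
    return {
        "mean_p": mean_p,
        "mean_d": mean_d,
        "deviations": mean_d - targets,
        "damped_d": damped,
        "theta_hist": hist,
        "theta_edges": np.linspace(0.0, 180.0, theta_bins + 1),
        "state": final,
        "n_samples": n_acc,
        # 5 degrees of freedom: 2 particles x 3 minus one bond constraint
        "kinetic_temperature": 2.0 * out_stats[0] / sd.n_steps / (5.0 * KB),
        "max_bond_deviation": out_stats[1],
    }
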