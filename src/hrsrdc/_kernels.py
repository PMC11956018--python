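"""Numba-compiled propagation kernels for the field-vector SD loops.

These implement exactly the same impulse-leapfrog + constraint-projection
step as the pure-numpy code in :mod:`hrsrdc.mfv`; they exist because the
restraining statistics converge on the 1e7-1e8 step scale, which a Python
loop cannot reach interactively.  The kernels are deterministic given the
seed passed in.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _shake_pair_nb(pos, r_old, bond_length, tol, max_iter):
    d2 = bond_length * bond_length
    for _ in range(max_iter):
        rx = pos[0, 0] - pos[1, 0]
        ry = pos[0, 1] - pos[1, 1]
        rz = pos[0, 2] - pos[1, 2]
        rr = rx * rx + ry * ry + rz * rz
        if abs(np.sqrt(rr) - bond_length) <= tol * bond_length:
            return True
        dot = rx * r_old[0] + ry * r_old[1] + rz * r_old[2]
        denom = 4.0 * dot
        if denom == 0.0:
            return False
        g = (rr - d2) / denom
        for a in range(3):
            corr = g * r_old[a]
            pos[0, a] -= corr
            pos[1, a] += corr
    return False


@njit(cache=True)
def mfv_run_kernel(
    pos, vel,
    bond_units, dc_r3, targets,
    k_rdc, delta_fb, delta_h,
    decay, dt, mass, gamma, sigma,
    damped,
    n_steps, burn_in, stride,
    bond_length, tol, max_iter,
    seed,
    sum_p, hist, theta_bins,
    bias_a, out_stats,
):
    """Restrained SD of the field pair against one fixed frame.

    Accumulates per-RDC plain-mean P2 (``sum_p``) and a theta histogram of
    the field direction against each bond over the post-burn-in window.
    ``damped`` is updated in place.  ``bias_a`` adds an external orienting
    (Maier-Saupe) potential U = -bias_a * P2(cos theta_z) on the field
    direction; ``out_stats`` receives [sum of kinetic energies, max relative
    bond-length deviation] over all steps.  Returns (number of accumulated
    samples, 0 on success / step index of a constraint failure + 1).
    """
    np.random.seed(seed)
    k = bond_units.shape[0]
    fscale = (1.0 - decay) * k_rdc
    c = np.empty(k)
    r_old = np.empty(3)
    n_acc = 0
    for step in range(n_steps):
        hx = pos[0, 0] - pos[1, 0]
        hy = pos[0, 1] - pos[1, 1]
        hz = pos[0, 2] - pos[1, 2]
        h_len = np.sqrt(hx * hx + hy * hy + hz * hz)
        ux, uy, uz = hx / h_len, hy / h_len, hz / h_len

        f1x = 0.0
        f1y = 0.0
        f1z = 0.0
        if bias_a != 0.0:
            # F = +bias_a * dP2(u_z)/dr1 = bias_a * 3 u_z (e_z - u_z u)/|h|
            coef_b = bias_a * 3.0 * uz / h_len
            f1x -= coef_b * uz * ux
            f1y -= coef_b * uz * uy
            f1z += coef_b * (1.0 - uz * uz)
        for i in range(k):
            ci = (bond_units[i, 0] * ux + bond_units[i, 1] * uy
                  + bond_units[i, 2] * uz)
            c[i] = ci
            p2 = 0.5 * (3.0 * ci * ci - 1.0)
            d_inst = dc_r3[i] * p2
            damped[i] = decay * damped[i] + (1.0 - decay) * d_inst
            if k_rdc > 0.0:
                dev = damped[i] - targets[i]
                adev = abs(dev)
                exc = adev - delta_fb
                if exc > 0.0:
                    if exc > delta_h:
                        exc = delta_h
                    ff = fscale * exc if dev > 0.0 else -fscale * exc
                    coef = ff * dc_r3[i] * 3.0 * ci / h_len
                    f1x -= coef * (bond_units[i, 0] - ci * ux)
                    f1y -= coef * (bond_units[i, 1] - ci * uy)
                    f1z -= coef * (bond_units[i, 2] - ci * uz)
            if step >= burn_in and step % stride == 0:
                sum_p[i] += p2

        if step >= burn_in and step % stride == 0:
            n_acc += 1
            for i in range(k):
                ci = c[i]
                if ci > 1.0:
                    ci = 1.0
                elif ci < -1.0:
                    ci = -1.0
                theta = np.degrees(np.arccos(ci))
                bi = int(theta / 180.0 * theta_bins)
                if bi >= theta_bins:
                    bi = theta_bins - 1
                hist[i, bi] += 1.0

        r_old[0] = hx
        r_old[1] = hy
        r_old[2] = hz
        for p in range(2):
            s = 1.0 if p == 0 else -1.0
            for a in range(3):
                fa = s * (f1x if a == 0 else (f1y if a == 1 else f1z))
                noise = sigma * np.random.normal() if sigma > 0.0 else 0.0
                vel[p, a] = vel[p, a] + dt * ((fa + noise) / mass
                                              - gamma * vel[p, a])
        old0 = pos.copy()
        for p in range(2):
            for a in range(3):
                pos[p, a] = pos[p, a] + dt * vel[p, a]
        if not _shake_pair_nb(pos, r_old, bond_length, tol, max_iter):
            return n_acc, step + 1
        ke = 0.0
        for p in range(2):
            for a in range(3):
                vel[p, a] = (pos[p, a] - old0[p, a]) / dt
                ke += vel[p, a] * vel[p, a]
        out_stats[0] += 0.5 * mass * ke
        rx = pos[0, 0] - pos[1, 0]
        ry = pos[0, 1] - pos[1, 1]
        rz = pos[0, 2] - pos[1, 2]
        bdev = abs(np.sqrt(rx * rx + ry * ry + rz * rz) - bond_length) / bond_length
        if bdev > out_stats[1]:
            out_stats[1] = bdev
    return n_acc, 0


@njit(cache=True)
def mfv_block_kernel(
    pos, vel,
    bond_units, dc_r3, targets,
    k_rdc, delta_fb, delta_h,
    decay, dt, mass, gamma, sigma,
    damped,
    n_mfv,
    bond_length, tol, max_iter,
    seed,
    grad_vec, grad_c2, mean_p, field_samples, collect_field,
):
    """One HRS block: n_mfv restrained steps with derivative accumulators.

    grad_vec accumulates <3 c h_hat>, grad_c2 <3 c^2>, mean_p <P2> per RDC
    (block means on return).  Returns 0 on success, failing step index + 1
    otherwise.
    """
    np.random.seed(seed)
    k = bond_units.shape[0]
    fscale = (1.0 - decay) * k_rdc
    r_old = np.empty(3)
    for i in range(k):
        grad_c2[i] = 0.0
        mean_p[i] = 0.0
        for a in range(3):
            grad_vec[i, a] = 0.0
    for step in range(n_mfv):
        hx = pos[0, 0] - pos[1, 0]
        hy = pos[0, 1] - pos[1, 1]
        hz = pos[0, 2] - pos[1, 2]
        h_len = np.sqrt(hx * hx + hy * hy + hz * hz)
        ux, uy, uz = hx / h_len, hy / h_len, hz / h_len
        if collect_field:
            field_samples[step, 0] = ux
            field_samples[step, 1] = uy
            field_samples[step, 2] = uz

        f1x = 0.0
        f1y = 0.0
        f1z = 0.0
        for i in range(k):
            ci = (bond_units[i, 0] * ux + bond_units[i, 1] * uy
                  + bond_units[i, 2] * uz)
            p2 = 0.5 * (3.0 * ci * ci - 1.0)
            d_inst = dc_r3[i] * p2
            damped[i] = decay * damped[i] + (1.0 - decay) * d_inst
            grad_vec[i, 0] += 3.0 * ci * ux
            grad_vec[i, 1] += 3.0 * ci * uy
            grad_vec[i, 2] += 3.0 * ci * uz
            grad_c2[i] += 3.0 * ci * ci
            mean_p[i] += p2
            if k_rdc > 0.0:
                dev = damped[i] - targets[i]
                adev = abs(dev)
                exc = adev - delta_fb
                if exc > 0.0:
                    if exc > delta_h:
                        exc = delta_h
                    ff = fscale * exc if dev > 0.0 else -fscale * exc
                    coef = ff * dc_r3[i] * 3.0 * ci / h_len
                    f1x -= coef * (bond_units[i, 0] - ci * ux)
                    f1y -= coef * (bond_units[i, 1] - ci * uy)
                    f1z -= coef * (bond_units[i, 2] - ci * uz)

        r_old[0] = hx
        r_old[1] = hy
        r_old[2] = hz
        for p in range(2):
            s = 1.0 if p == 0 else -1.0
            for a in range(3):
                fa = s * (f1x if a == 0 else (f1y if a == 1 else f1z))
                noise = sigma * np.random.normal() if sigma > 0.0 else 0.0
                vel[p, a] = vel[p, a] + dt * ((fa + noise) / mass
                                              - gamma * vel[p, a])
        old0 = pos.copy()
        for p in range(2):
            for a in range(3):
                pos[p, a] = pos[p, a] + dt * vel[p, a]
        if not _shake_pair_nb(pos, r_old, bond_length, tol, max_iter):
            return step + 1
        for p in range(2):
            for a in range(3):
                vel[p, a] = (pos[p, a] - old0[p, a]) / dt
    for i in range(k):
        grad_c2[i] /= n_mfv
        mean_p[i] /= n_mfv
        for a in range(3):
            grad_vec[i, a] /= n_mfv
    return 0
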