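"""Flat-bottom RDC restraining energy and exponential memory averaging.

The restraining function is zero within a flat bottom of half-width
``delta_fb`` around the target, half-harmonic for the next ``delta_h`` Hz of
deviation, and linear beyond, with value and slope continuous at both
junctions (the GROMOS half-K-squared convention).  Keeping the asymptotic
branch linear bounds the restraining force at K*delta_h, avoiding the large
forces a plain harmonic term would exert on badly violated restraints.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import math

import numpy as np

__all__ = [
    "RestraintParams",
    "MemoryAverage",
    "flat_bottom_energy",
    "flat_bottom_force_factor",
    "restraint_set_energy",
    "memory_update",
]


@dataclass(frozen=True)
class RestraintParams:
    """Restraint force constant and piecewise-region widths.

    k_rdc in kJ mol^-1 Hz^-2; delta_fb (flat-bottom half-width) and delta_h
    (harmonic range) in Hz.
    """

    k_rdc: float
    delta_fb: float = 2.0
    delta_h: float = 1.0

    def __post_init__(self) -> None:
        if self.k_rdc < 0:
            raise ValueError("k_rdc must be >= 0")
        if self.delta_fb < 0:
            raise ValueError("delta_fb must be >= 0")
        if self.delta_h <= 0:
            raise ValueError("delta_h must be > 0")


def flat_bottom_energy(d_avg, d_target, params: RestraintParams):
    """Restraint energy (kJ/mol) of one coupling, piecewise in the deviation.

    Zero for |dev| <= delta_fb; 0.5*k*(|dev|-delta_fb)^2 up to
    delta_fb+delta_h; linear with matching value and slope beyond.  Both the
    energy and its first derivative are continuous everywhere (junction
    points belong to the inner regime, which leaves the value unchanged).
    """
    dev = np.abs(np.asarray(d_avg, dtype=float) - d_target)
    fb, dh, k = params.delta_fb, params.delta_h, params.k_rdc
    exc = np.clip(dev - fb, 0.0, None)
    harmonic = 0.5 * k * np.minimum(exc, dh) ** 2
    linear = k * dh * np.clip(exc - dh, 0.0, None)
    out = harmonic + linear
    return float(out) if out.ndim == 0 else out


def flat_bottom_force_factor(d_avg, d_target, params: RestraintParams):
    """dE/d(d_avg) in kJ mol^-1 Hz^-1 (signed; bounded by +-k*delta_h)."""
    diff = np.asarray(d_avg, dtype=float) - d_target
    dev = np.abs(diff)
    fb, dh, k = params.delta_fb, params.delta_h, params.k_rdc
    exc = np.clip(dev - fb, 0.0, None)
    out = k * np.minimum(exc, dh) * np.sign(diff)
    return float(out) if out.ndim == 0 else out


def restraint_set_energy(
    d_avgs: Sequence[float],
    targets: Sequence[float],
    params: RestraintParams,
) -> float:
    """Total restraint energy for a set of couplings with a common K^RDC."""
    d_avgs = np.asarray(d_avgs, dtype=float)
    targets = np.asarray(targets, dtype=float)
    if d_avgs.shape != targets.shape:
        raise ValueError(
            f"length mismatch: {d_avgs.shape} averages vs {targets.shape} targets"
        )
    return float(np.sum(flat_bottom_energy(d_avgs, targets, params)))


@dataclass(frozen=True)
class MemoryAverage:
    """Exponentially damped running average with relaxation time tau (ps).

    The recursion for step n is
        value_n = exp(-dt/tau) * value_{n-1} + (1 - exp(-dt/tau)) * x_n,
    an exponentially weighted sum over the history with memory time tau.
    ``seeded`` marks whether the first input has been folded in; by default
    the average is seeded with the first instantaneous value instead of 0,
    which avoids a spurious startup force transient.
    """

    tau: float
    dt: float
    value: float = 0.0
    n_steps: int = 0
    seeded: bool = False
    seed_with_first: bool = True

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.tau < self.dt:
            raise ValueError(
                f"memory relaxation time tau={self.tau} must be >= dt={self.dt}"
            )

    @property
    def decay(self) -> float:
        return math.exp(-self.dt / self.tau)


def memory_update(avg: MemoryAverage, x_now: float) -> MemoryAverage:
    """Fold one instantaneous value into the damped average."""
    if not avg.seeded and avg.seed_with_first:
        return replace(avg, value=float(x_now), n_steps=avg.n_steps + 1,
                       seeded=True)
    f = avg.decay
    return replace(
        avg,
        value=f * avg.value + (1.0 - f) * float(x_now),
        n_steps=avg.n_steps + 1,
        seeded=True,
    )


def damped_average_series(
    values: np.ndarray, tau: float, dt: float, initial: float | None = None
) -> np.ndarray:
    """Vectorised damped average over a series (helper for analysis).

    ``initial=None`` seeds with the first value, matching
    :func:`memory_update`'s default.
    """
    values = np.asarray(values, dtype=float)
    f = math.exp(-dt / tau)
    out = np.empty_like(values)
    acc = values[0] if initial is None else initial
    for i, x in enumerate(values):
        if i == 0 and initial is None:
            acc = x
        else:
            acc = f * acc + (1.0 - f) * x
        out[i] = acc
    return out
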