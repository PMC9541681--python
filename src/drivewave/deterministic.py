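"""Aspatial recursions and invasion wave-speed theory.

The drive allele frequency ``q`` obeys, per generation,

    W-shredder:  q' = (8q - 3cq - cq^2) / (8 - 4c)
    X-shredder:  q' = 2q / (2 - c + cq)

with ``c`` the shredding efficiency.  Both maps fix 0 and 1 and increase
``q`` monotonically for ``c > 0``.  Treating the per-generation change as a
time derivative gives a logistic form ``dq/dt = m q (1 - q)`` with intrinsic
drive fitness ``m = c/(8-4c)`` (W-shredder, frequency independent) or
``m = c/(2-c+cq)`` (X-shredder).  Coupled with Fisher's asymptotic spreading
speed ``2*sqrt(D*growth)`` for a reaction–diffusion invasion, this yields
the wild-type wave speed ``2*sqrt(D*r)`` and the drive's speed *upper bound*
``2*sqrt(D*m)`` (advection — the asymmetric gene flow caused by the density
gradient behind a suppressing wave — is ignored, so the true drive speed is
lower).  Mapping the low-density growth rate into the non-overlapping-
generations model via ``r = R_max/2 - 1`` gives critical fecundities above
which the wild-type wave outruns the drive: 2.5 for the W-shredder and 4
for the X-shredder at ``c = 1``.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from scipy.optimize import brentq

from .model_core import DriveSystem, density_response_coefficient

__all__ = [
    "TheoryParams",
    "next_drive_frequency",
    "female_fraction",
    "next_population_density",
    "intrinsic_fitness",
    "wt_wave_speed",
    "drive_wave_speed_bound",
    "rmax_to_growth_rate",
    "critical_fecundity",
    "predicted_wave_width",
    "iterate_recursion",
]


@dataclasses.dataclass(frozen=True)
class TheoryParams:
    """Parameters of the aspatial recursions and the wave-speed theory.

    ``D`` is the diffusion coefficient (spatial units^2 per generation),
    ``r`` the intrinsic low-density growth rate and ``K`` the carrying
    capacity per spatial unit.
    """

    c: float = 1.0
    R_max: float = 6.0
    K: float = 5.0
    D: float = 0.0
    system: DriveSystem = DriveSystem.X_SHREDDER

    @property
    def r(self) -> float:
        return rmax_to_growth_rate(self.R_max)

    @property
    def a(self) -> float:
        return density_response_coefficient(self.R_max, self.K)


def _check_qc(q, c) -> None:
    q = np.asarray(q, dtype=float)
    if np.any((q < 0) | (q > 1)):
        raise ValueError("drive frequency q must lie in [0, 1]")
    if not 0 <= c <= 1:
        raise ValueError("shredding efficiency c must lie in [0, 1]")


def next_drive_frequency(q, c: float, system: DriveSystem):
    """One step of the drive-frequency recursion for either shredder."""
    _check_qc(q, c)
    q = np.asarray(q, dtype=float)
    system = DriveSystem(system)
    if system is DriveSystem.W_SHREDDER:
        out = (8.0 * q - 3.0 * c * q - c * q * q) / (8.0 - 4.0 * c)
    elif system is DriveSystem.X_SHREDDER:
        out = 2.0 * q / (2.0 - c + c * q)
    else:
        out = q.copy()
    out = np.clip(out, 0.0, 1.0)  # guard rounding at the fixed points
    return float(out) if out.ndim == 0 else out


def female_fraction(q, c: float):
    """Offspring female fraction ``(2 - c - cq) / (4 - 2c)``.

    Equals 1/2 with no distortion (c=0) and ``(1-q)/2`` for the ideal
    drive (c=1); identical for the two shredder systems.
    """
    _check_qc(q, c)
    q = np.asarray(q, dtype=float)
    out = (2.0 - c - c * q) / (4.0 - 2.0 * c)
    return float(out) if out.ndim == 0 else out


def next_population_density(N, q, params: TheoryParams):
    """One step of the density recursion ``N' = N * phi(q) * R/(1 + a N)``."""
    N = np.asarray(N, dtype=float)
    if np.any(N < 0):
        raise ValueError("density must be non-negative")
    out = N * female_fraction(q, params.c) * params.R_max / (1.0 + params.a * N)
    return float(out) if out.ndim == 0 else out


def intrinsic_fitness(q, c: float, system: DriveSystem):
    """Logistic coefficient ``m`` of ``dq/dt = m q (1 - q)``.

    ``c/(8-4c)`` for the W-shredder (frequency independent because the
    drive spreads through both sexes in a ZW system) and ``c/(2-c+cq)``
    for the X-shredder (male-limited spread).
    """
    _check_qc(q, c)
    q = np.asarray(q, dtype=float)
    system = DriveSystem(system)
    if system is DriveSystem.W_SHREDDER:
        out = np.full_like(q, c / (8.0 - 4.0 * c))
    elif system is DriveSystem.X_SHREDDER:
        out = c / (2.0 - c + c * q)
    else:
        out = np.zeros_like(q)
    return float(out) if out.ndim == 0 else out


def wt_wave_speed(D: float, r: float) -> float:
    """Fisher asymptotic speed ``2*sqrt(D*r)`` of the wild-type invasion."""
    if D < 0 or r < 0:
        raise ValueError("D and r must be non-negative")
    return 2.0 * math.sqrt(D * r)


def drive_wave_speed_bound(D: float, c: float, system: DriveSystem) -> float:
    """Upper bound ``2*sqrt(D*m)`` on the drive wave speed.

    Uses the intrinsic fitness at the leading edge (q ~ 0).  An upper
    bound because advection against the drive is ignored.
    """
    if D < 0:
        raise ValueError("D must be non-negative")
    m = intrinsic_fitness(0.0, c, system)
    return 2.0 * math.sqrt(D * m)


def rmax_to_growth_rate(R_max: float) -> float:
    """Low-density growth rate ``r = R_max/2 - 1``.

    Per-capita growth at low density with an unskewed sex ratio: half the
    offspring are female and a female expects ``R_max`` offspring, so the
    population multiplies by ``R_max/2`` per generation.
    """
    if R_max < 0:
        raise ValueError("R_max must be non-negative")
    return R_max / 2.0 - 1.0


def critical_fecundity(system: DriveSystem, c: float = 1.0) -> float:
    """Fecundity above which the WT wave outruns the drive's speed bound.

    Solves ``rmax_to_growth_rate(R) == intrinsic_fitness(0, c, system)``
    for ``R`` numerically (the speeds ``2*sqrt(D r)`` and ``2*sqrt(D m)``
    share the diffusion coefficient, so the threshold is where r = m).
    """
    m = intrinsic_fitness(0.0, c, system)
    f = lambda R: rmax_to_growth_rate(R) - m
    return float(brentq(f, 2.0, 50.0, xtol=1e-12))


def predicted_wave_width(D: float, growth: float) -> float:
    """Fisher-wave width scale ``sqrt(D / growth)`` (helper for scaling)."""
    if D < 0 or growth <= 0:
        raise ValueError("need D >= 0 and a positive growth coefficient")
    return math.sqrt(D / growth)


def iterate_recursion(
    q0: float, N0: float, params: TheoryParams, generations: int
) -> np.ndarray:
    """Coupled trajectory of (q_t, N_t) under the two recursions.

    Returns an array of shape ``(generations + 1, 2)`` with columns
    ``q`` and ``N``; row 0 is the initial condition.  The density update
    uses the current generation's drive frequency in the sex-ratio term.
    """
    _check_qc(q0, params.c)
    traj = np.empty((generations + 1, 2), dtype=float)
    q, N = float(q0), float(N0)
    traj[0] = q, N
    for t in range(1, generations + 1):
        N = next_population_density(N, q, params)
        q = next_drive_frequency(q, params.c, params.system)
        traj[t] = q, N
    return traj
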