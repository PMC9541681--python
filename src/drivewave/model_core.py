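"""Shared parameters and demographic kernels.

Local crowding is measured with a unit-bandwidth Gaussian kernel: each
individual spreads one unit of "density" across continuous 1D space as a
standard normal centred on its position, and the local density experienced
at a point is the sum of those contributions over the whole population.
Reproduction is Beverton–Holt: a mated female expects ``R / (1 + a * N)``
offspring at local density ``N``, with ``a = (R - 2) / (2 * N_star)`` chosen
so that the expectation is exactly 2 (replacement, given a 1:1 sex ratio) at
the equilibrium density ``N_star``.
"""

from __future__ import annotations

import dataclasses
import enum
import json
import math
import pathlib
from typing import Iterable, Sequence

import numpy as np
import yaml

__all__ = [
    "KERNEL_NORM",
    "KERNEL_CUTOFF",
    "DriveSystem",
    "ScenarioConfig",
    "Individual",
    "local_density",
    "kernel_density",
    "density_response_coefficient",
    "expected_offspring",
    "draw_offspring_count",
    "load_scenarios",
]

#: Height of the unit Gaussian kernel at distance zero, 1/sqrt(2*pi).
KERNEL_NORM = 1.0 / math.sqrt(2.0 * math.pi)

#: Pairwise kernel terms beyond this distance (6 SD) are dropped; the
#: neglected mass per pair is below 1e-8.
KERNEL_CUTOFF = 6.0


class DriveSystem(str, enum.Enum):
    """Which sex-distorter drive (if any) a scenario simulates."""

    X_SHREDDER = "X_SHREDDER"
    W_SHREDDER = "W_SHREDDER"
    NONE = "NONE"


@dataclasses.dataclass(frozen=True)
class ScenarioConfig:
    """All parameters of one simulated scenario.

    Parameters
    ----------
    drive_system:
        ``X_SHREDDER`` (drive on the Y, XY sex determination),
        ``W_SHREDDER`` (drive on the Z, ZW sex determination) or ``NONE``
        for a wild-type control run.
    R:
        Maximum expected offspring per mated female at zero density
        (dimensionless, must be >= 2 so the density response is >= 0).
    sigma:
        Root-mean-square natal dispersal distance (spatial units).
    N_star:
        Equilibrium population density per spatial unit.
    c:
        Shredding efficiency in [0, 1]; 1 is the ideal drive.
    landscape_length:
        Extent of the bounded 1D landscape; boundaries are absorbing.
    wt_init_range:
        Interval initially occupied uniformly by the wild-type population.
    intro_fraction:
        Drive carriers introduced as this fraction of the initial WT count.
    intro_position:
        All introduced carriers are placed exactly here.
    mate_radius:
        Females only mate with males within this distance (spatial Allee
        effect); fixed at 3 in the study design regardless of sigma.
    max_generations:
        Hard stop for the generation loop.
    post_loss_generations:
        Extra generations simulated after the drive allele is lost
        (only meaningful when a drive system is configured).
    seed:
        Seed for the replicate's random generator.
    """

    drive_system: DriveSystem = DriveSystem.NONE
    R: float = 6.0
    sigma: float = 10.0
    N_star: float = 5.0
    c: float = 1.0
    landscape_length: float = 2500.0
    wt_init_range: tuple[float, float] = (250.0, 1250.0)
    intro_fraction: float = 0.01
    intro_position: float = 250.0
    mate_radius: float = 3.0
    max_generations: int = 1000
    post_loss_generations: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "drive_system", DriveSystem(self.drive_system))
        object.__setattr__(
            self, "wt_init_range", (float(self.wt_init_range[0]), float(self.wt_init_range[1]))
        )
        if self.R < 2:
            raise ValueError(f"R must be >= 2 (got {self.R})")
        if not 0 <= self.c <= 1:
            raise ValueError(f"c must lie in [0, 1] (got {self.c})")
        if self.sigma <= 0:
            raise ValueError(f"sigma must be positive (got {self.sigma})")
        if self.N_star <= 0:
            raise ValueError(f"N_star must be positive (got {self.N_star})")
        if self.landscape_length <= 0:
            raise ValueError("landscape_length must be positive")
        lo, hi = self.wt_init_range
        if not (0 <= lo < hi <= self.landscape_length):
            raise ValueError(
                f"wt_init_range {self.wt_init_range} must be a sub-interval of "
                f"[0, {self.landscape_length}]"
            )
        if not 0 <= self.intro_position <= self.landscape_length:
            raise ValueError("intro_position must lie inside the landscape")
        if self.intro_fraction < 0:
            raise ValueError("intro_fraction must be non-negative")
        if self.mate_radius <= 0:
            raise ValueError("mate_radius must be positive")
        if self.max_generations < 0 or self.post_loss_generations < 0:
            raise ValueError("generation counts must be non-negative")

    @property
    def a(self) -> float:
        """Density-response coefficient of the Beverton–Holt kernel."""
        return density_response_coefficient(self.R, self.N_star)

    def replace(self, **changes) -> "ScenarioConfig":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["drive_system"] = self.drive_system.value
        d["wt_init_range"] = list(self.wt_init_range)
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "ScenarioConfig":
        data = dict(data)
        if "wt_init_range" in data:
            data["wt_init_range"] = tuple(data["wt_init_range"])
        return cls(**data)


@dataclasses.dataclass(frozen=True)
class Individual:
    """Position and genotype of one individual (scalar convenience type)."""

    x: float
    genotype: object = None


def density_response_coefficient(R: float, N_star: float) -> float:
    """Beverton–Holt coefficient ``a = (R - 2) / (2 * N_star)``.

    This is the unique choice for which a mated female at the equilibrium
    density ``N_star`` expects exactly two offspring — replacement, given
    an expected 1:1 sex ratio.
    """
    if R < 2:
        raise ValueError(f"R must be >= 2 (got {R})")
    if N_star <= 0:
        raise ValueError(f"N_star must be positive (got {N_star})")
    return (R - 2.0) / (2.0 * N_star)


def expected_offspring(N_i: float, R: float, a: float) -> float:
    """Expected brood size ``R / (1 + a * N_i)`` of a mated female."""
    N_i = np.asarray(N_i, dtype=float)
    if np.any(N_i < 0):
        raise ValueError("local density must be non-negative")
    out = R / (1.0 + a * N_i)
    return float(out) if out.ndim == 0 else out


def draw_offspring_count(expectation, rng: np.random.Generator):
    """Realized brood size, Poisson-distributed around the expectation."""
    return rng.poisson(expectation)


def kernel_density(
    query_x: np.ndarray,
    source_x: np.ndarray,
    cutoff: float = KERNEL_CUTOFF,
    chunk_elems: int = 4_000_000,
) -> np.ndarray:
    """Local density at each query position from a set of source individuals.

    Sums the unit Gaussian kernel over all sources within ``cutoff`` of each
    query point (terms beyond 6 SD contribute < 1e-8 each and are dropped).
    If a query position coincides with a source individual, that
    individual's own kernel term is included.
    """
    query_x = np.atleast_1d(np.asarray(query_x, dtype=float))
    source_x = np.asarray(source_x, dtype=float)
    out = np.zeros(query_x.shape, dtype=float)
    if source_x.size == 0 or query_x.size == 0:
        return out
    src = np.sort(source_x)
    lo = np.searchsorted(src, query_x - cutoff, side="left")
    hi = np.searchsorted(src, query_x + cutoff, side="right")
    width = int(np.max(hi - lo)) if query_x.size else 0
    if width == 0:
        return out
    chunk = max(1, chunk_elems // width)
    for start in range(0, query_x.size, chunk):
        stop = min(start + chunk, query_x.size)
        l, h = lo[start:stop], hi[start:stop]
        idx = l[:, None] + np.arange(width)[None, :]
        valid = idx < h[:, None]
        np.clip(idx, 0, src.size - 1, out=idx)
        d = query_x[start:stop, None] - src[idx]
        k = KERNEL_NORM * np.exp(-0.5 * d * d)
        k[~valid] = 0.0
        out[start:stop] = k.sum(axis=1)
    return out


def local_density(focal_x: float, positions: Sequence[float]) -> float:
    """Local density experienced at ``focal_x`` (scalar form).

    ``sum_j (1/sqrt(2*pi)) * exp(-d_j**2 / 2)`` over every individual in
    ``positions``; an empty population gives 0.  No cutoff is applied here,
    so this is also the exact reference for the truncated fast path.
    """
    positions = np.asarray(list(positions), dtype=float)
    if positions.size == 0:
        return 0.0
    d = positions - float(focal_x)
    return float(np.sum(KERNEL_NORM * np.exp(-0.5 * d * d)))


def load_scenarios(path) -> list[ScenarioConfig]:
    """Read scenario configurations from a YAML or JSON file.

    The file may contain a single mapping or a list of mappings; each
    mapping holds ``ScenarioConfig`` fields (missing fields take the
    defaults of the study design).
    """
    path = pathlib.Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if isinstance(data, dict):
        data = [data]
    return [ScenarioConfig.from_dict(block) for block in data]
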