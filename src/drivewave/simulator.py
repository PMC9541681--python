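"""The generation loop: initialization, mating, reproduction, dispersal.

Generations are discrete and non-overlapping.  Each generation is, in
order: record statistics -> females find a mate within the mating radius
(the spatial Allee effect: an unmated female leaves no offspring) ->
mated females produce Poisson(Beverton–Holt) broods whose genotypes follow
the shredder gamete rules -> offspring are born at the mother's position
and disperse by a Normal(0, sigma^2) step, dying if they cross the
absorbing landscape boundaries -> offspring replace all adults.

Wave measurements follow the study design: leading-edge positions are
tracked every generation for velocity estimation (the usable window ends
at the first boundary contact or the first penetration of the drive wave
by wild-types), and wave heights/widths are measured once, one generation
after drive introduction.
"""

from __future__ import annotations

import dataclasses
from typing import Optional

import numpy as np
import pandas as pd

from . import genetics, wave_analysis
from .genetics import ChromosomeSystem
from .model_core import (
    DriveSystem,
    Individual,
    KERNEL_NORM,
    ScenarioConfig,
    draw_offspring_count,
    expected_offspring,
    kernel_density,
    local_density,
)

__all__ = [
    "PopulationState",
    "GenerationRecord",
    "SimulationRecord",
    "initialize_population",
    "find_mate",
    "reproduce_generation",
    "disperse",
    "run_simulation",
]


def _chromosome_system(drive_system: DriveSystem) -> ChromosomeSystem:
    return (
        ChromosomeSystem.ZW
        if drive_system is DriveSystem.W_SHREDDER
        else ChromosomeSystem.XY
    )


@dataclasses.dataclass
class PopulationState:
    """The living population at one generation (vectorized storage)."""

    generation: int
    x: np.ndarray
    geno: np.ndarray
    system: ChromosomeSystem

    @property
    def size(self) -> int:
        return self.x.size

    @property
    def is_female(self) -> np.ndarray:
        return genetics.is_female_codes(self.geno, self.system)

    @property
    def is_carrier(self) -> np.ndarray:
        return genetics.is_carrier_codes(self.geno, self.system)

    def drive_allele_frequency(self) -> Optional[float]:
        return genetics.drive_frequency_from_codes(self.geno, self.system)

    def genotype_strings(self) -> list[str]:
        return [genetics.code_to_string(g, self.system) for g in self.geno]


@dataclasses.dataclass
class GenerationRecord:
    """Per-generation recorded statistics."""

    generation: int
    population_size: int
    female_fraction: Optional[float]
    mean_local_density: Optional[float]
    sd_local_density: Optional[float]
    drive_allele_frequency: Optional[float]
    mean_offspring_total: Optional[float] = None
    mean_offspring_wt_parents: Optional[float] = None
    mean_offspring_drive_parents: Optional[float] = None


@dataclasses.dataclass
class SimulationRecord:
    """Full output of one simulated replicate."""

    config: ScenarioConfig
    per_generation: list[GenerationRecord]
    edges: pd.DataFrame
    first_penetration_generation: Optional[int]
    chasing_observed: bool
    drive_loss_generation: Optional[int]
    wt_extinction_generation: Optional[int]
    extinction_generation: Optional[int]
    wave_metrics: Optional[wave_analysis.WaveMetrics]
    outcome: Optional[wave_analysis.OutcomeLabel] = None
    final_population_size: int = 0

    @property
    def generations_elapsed(self) -> int:
        return self.per_generation[-1].generation if self.per_generation else 0

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([dataclasses.asdict(r) for r in self.per_generation])


def initialize_population(
    config: ScenarioConfig, rng: np.random.Generator
) -> PopulationState:
    """Found the population: a uniform WT block plus a point drive release.

    The wild-type count is ``round(N_star * |wt_init_range|)`` with
    positions uniform on the range and sexes drawn independently with
    probability 1/2.  Drive carriers are added on top at
    ``round(intro_fraction * WT count)`` heterozygotes, all placed exactly
    at ``intro_position``: XYd males for the X-shredder, ZdW (actively
    shredding) females for the W-shredder.
    """
    system = _chromosome_system(config.drive_system)
    lo, hi = config.wt_init_range
    n_wt = int(round(config.N_star * (hi - lo)))
    x = rng.uniform(lo, hi, size=n_wt)
    female = rng.random(n_wt) < 0.5
    geno = np.empty(n_wt, dtype=np.int8)
    if system is ChromosomeSystem.XY:
        geno[:] = np.where(female, genetics.XY_CODES["XX"], genetics.XY_CODES["XY"])
    else:
        geno[:] = np.where(female, genetics.ZW_CODES["ZW"], genetics.ZW_CODES["ZZ"])
    if config.drive_system is not DriveSystem.NONE:
        n_drive = int(round(config.intro_fraction * n_wt))
        if n_drive > 0:
            carrier_code = (
                genetics.XY_CODES["XYd"]
                if config.drive_system is DriveSystem.X_SHREDDER
                else genetics.ZW_CODES["ZdW"]
            )
            x = np.concatenate([x, np.full(n_drive, float(config.intro_position))])
            geno = np.concatenate(
                [geno, np.full(n_drive, carrier_code, dtype=np.int8)]
            )
    return PopulationState(0, x, geno, system)


def find_mate(
    female: Individual,
    males: list[Individual],
    mate_radius: float,
    rng: np.random.Generator,
) -> Optional[Individual]:
    """Choose a mate among males within the radius (scalar reference form).

    Selection probability is proportional to the density the male provides
    at the female's position, ``(1/sqrt(2*pi)) * exp(-d^2/2)``.  Returns
    ``None`` when no male is in reach — the female dies unmated.
    """
    candidates = [m for m in males if abs(m.x - female.x) <= mate_radius]
    if not candidates:
        return None
    w = np.array([KERNEL_NORM * np.exp(-0.5 * (m.x - female.x) ** 2) for m in candidates])
    return candidates[rng.choice(len(candidates), p=w / w.sum())]


def _assign_mates(
    female_x: np.ndarray,
    male_x: np.ndarray,
    mate_radius: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Vectorized mate choice; returns male index per female (-1 = unmated)."""
    nf = female_x.size
    out = np.full(nf, -1, dtype=np.int64)
    if nf == 0 or male_x.size == 0:
        return out
    order = np.argsort(male_x, kind="stable")
    mx = male_x[order]
    lo = np.searchsorted(mx, female_x - mate_radius, side="left")
    hi = np.searchsorted(mx, female_x + mate_radius, side="right")
    width = int(np.max(hi - lo))
    if width == 0:
        return out
    chunk = max(1, 4_000_000 // width)
    cols = np.arange(width)[None, :]
    for start in range(0, nf, chunk):
        stop = min(start + chunk, nf)
        l, h = lo[start:stop], hi[start:stop]
        idx = l[:, None] + cols
        valid = idx < h[:, None]
        np.clip(idx, 0, mx.size - 1, out=idx)
        d = female_x[start:stop, None] - mx[idx]
        w = np.exp(-0.5 * d * d)
        w[~valid] = 0.0
        total = w.sum(axis=1)
        mated = total > 0
        if not np.any(mated):
            continue
        cum = np.cumsum(w, axis=1)
        u = rng.random(stop - start) * total
        pick = (cum < u[:, None]).sum(axis=1)
        np.clip(pick, 0, width - 1, out=pick)
        sel = l + pick
        out[start:stop][mated] = order[sel[mated]]
    return out


def reproduce_generation(
    state: PopulationState, config: ScenarioConfig, rng: np.random.Generator
) -> tuple[PopulationState, dict]:
    """One round of mating and reproduction; all adults die afterwards.

    Returns the (pre-dispersal) offspring population, born at their
    mothers' positions, together with mean brood sizes per parent class
    (a mating counts as a drive-parent mating if either parent carries
    the drive).
    """
    female = state.is_female
    fx = state.x[female]
    male_idx = np.flatnonzero(~female)
    mate = _assign_mates(fx, state.x[male_idx], config.mate_radius, rng)
    mated = mate >= 0
    stats = {
        "mean_offspring_total": None,
        "mean_offspring_wt_parents": None,
        "mean_offspring_drive_parents": None,
    }
    if not np.any(mated):
        empty = PopulationState(
            state.generation + 1,
            np.empty(0, dtype=float),
            np.empty(0, dtype=np.int8),
            state.system,
        )
        return empty, stats

    mother_x = fx[mated]
    mother_geno = state.geno[female][mated]
    father_geno = state.geno[male_idx[mate[mated]]]

    dens = kernel_density(mother_x, state.x)
    brood = draw_offspring_count(expected_offspring(dens, config.R, config.a), rng)

    carrier_pair = genetics.is_carrier_codes(
        mother_geno, state.system
    ) | genetics.is_carrier_codes(father_geno, state.system)
    stats["mean_offspring_total"] = float(brood.mean())
    if np.any(~carrier_pair):
        stats["mean_offspring_wt_parents"] = float(brood[~carrier_pair].mean())
    if np.any(carrier_pair):
        stats["mean_offspring_drive_parents"] = float(brood[carrier_pair].mean())

    off_x = np.repeat(mother_x, brood)
    off_geno = genetics.draw_offspring_codes(
        np.repeat(mother_geno, brood),
        np.repeat(father_geno, brood),
        state.system,
        config.c,
        rng,
    )
    return PopulationState(state.generation + 1, off_x, off_geno, state.system), stats


def disperse(
    state: PopulationState,
    sigma: float,
    landscape_length: float,
    rng: np.random.Generator,
) -> PopulationState:
    """Normal(0, sigma^2) displacement; absorbing boundaries remove leavers."""
    if state.size == 0:
        return state
    x = state.x + rng.normal(0.0, sigma, size=state.size)
    keep = (x >= 0.0) & (x <= landscape_length)
    return PopulationState(state.generation, x[keep], state.geno[keep], state.system)


def _record(state: PopulationState, stats: dict) -> GenerationRecord:
    n = state.size
    if n == 0:
        return GenerationRecord(state.generation, 0, None, None, None, None, **stats)
    dens = kernel_density(state.x, state.x)
    return GenerationRecord(
        generation=state.generation,
        population_size=n,
        female_fraction=float(state.is_female.mean()),
        mean_local_density=float(dens.mean()),
        sd_local_density=float(dens.std()),
        drive_allele_frequency=state.drive_allele_frequency(),
        **stats,
    )


def run_simulation(config: ScenarioConfig) -> SimulationRecord:
    """Run one replicate to completion and measure its waves and events.

    The loop stops at the first of: ``max_generations`` reached, total
    extinction, or ``post_loss_generations`` generations elapsed since the
    drive allele was first absent (the latter only when a drive system is
    configured; wild-type control runs are exempt).
    """
    rng = np.random.default_rng(config.seed)
    state = initialize_population(config, rng)
    has_drive_system = config.drive_system is not DriveSystem.NONE

    records: list[GenerationRecord] = []
    edge_rows: list[dict] = []
    first_penetration: Optional[int] = None
    chasing = False
    drive_loss_gen: Optional[int] = None
    wt_extinct_gen: Optional[int] = None
    extinct_gen: Optional[int] = None
    metrics: Optional[wave_analysis.WaveMetrics] = None
    prev_trail = np.nan

    stats: dict = {
        "mean_offspring_total": None,
        "mean_offspring_wt_parents": None,
        "mean_offspring_drive_parents": None,
    }
    while True:
        gen = state.generation
        carrier = state.is_carrier
        wt_x = state.x[~carrier]
        dr_x = state.x[carrier]
        records.append(_record(state, stats))

        row = {
            "generation": gen,
            "wt_min": wt_x.min() if wt_x.size else np.nan,
            "wt_max": wt_x.max() if wt_x.size else np.nan,
            "dr_min": dr_x.min() if dr_x.size else np.nan,
            "dr_max": dr_x.max() if dr_x.size else np.nan,
            "wt_max_behind_prev_trail": np.nan,
        }
        if wt_x.size and np.isfinite(prev_trail):
            behind = wt_x[wt_x < prev_trail]
            if behind.size:
                row["wt_max_behind_prev_trail"] = float(behind.max())
        edge_rows.append(row)

        # Event detection (only meaningful while the drive is present).
        if dr_x.size:
            if first_penetration is None and wt_x.size and wave_analysis.detect_penetration(
                wt_x, dr_x, config.sigma
            ):
                first_penetration = gen
            if (
                first_penetration is not None
                and gen > first_penetration
                and np.isfinite(row["wt_max_behind_prev_trail"])
                and dr_x.min() <= row["wt_max_behind_prev_trail"]
            ):
                chasing = True
        prev_trail = dr_x.min() if dr_x.size else np.nan

        if has_drive_system and drive_loss_gen is None and dr_x.size == 0 and wt_x.size > 0:
            drive_loss_gen = gen
        if wt_extinct_gen is None and wt_x.size == 0:
            wt_extinct_gen = gen
        if state.size == 0 and extinct_gen is None:
            extinct_gen = gen

        if gen == 1 and wt_x.size and dr_x.size:
            metrics = wave_analysis.measure_wave_snapshot(state.x, carrier, gen)

        if state.size == 0:
            break
        if gen >= config.max_generations:
            break
        if (
            drive_loss_gen is not None
            and gen - drive_loss_gen >= config.post_loss_generations
        ):
            break

        state, stats = reproduce_generation(state, config, rng)
        state = disperse(state, config.sigma, config.landscape_length, rng)

    edges = pd.DataFrame(edge_rows)
    metrics = wave_analysis.attach_velocities(
        metrics,
        edges,
        sigma=config.sigma,
        landscape_length=config.landscape_length,
        first_penetration=first_penetration,
    )

    record = SimulationRecord(
        config=config,
        per_generation=records,
        edges=edges,
        first_penetration_generation=first_penetration,
        chasing_observed=chasing,
        drive_loss_generation=drive_loss_gen,
        wt_extinction_generation=wt_extinct_gen,
        extinction_generation=extinct_gen,
        wave_metrics=metrics,
        final_population_size=state.size,
    )
    record.outcome = wave_analysis.classify_outcome(record)
    return record
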