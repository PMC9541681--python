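# drivewave

Spatially explicit, individual-based stochastic simulation of
**sex-distorter suppression gene drives** — the X-shredder (driving-Y, XY
systems) and the W-shredder (Z-linked, ZW systems) — on a bounded 1D
landscape, together with the matching aspatial allele-frequency recursions
and Fisher wave-speed theory.

Suppression drives skew offspring sex ratios toward males until a
population collapses.  In well-mixed models an ideal shredder (efficiency
c = 1, no resistance, no fitness cost) always eradicates the target
population.  In continuous space with finite local densities, new failure
routes emerge: the drive forms a travelling wave behind the wild-type (WT)
invasion front, and stochastic founder events let WTs *penetrate* the drive
wave, recolonize cleared ground, and either escape the drive entirely (WT
escape), get *chased* indefinitely (coexistence), or watch the drive drift
out early (drift loss).  `drivewave` is a tool for simulating those
dynamics, measuring the waves (velocity, height, width), detecting the
events, and classifying outcomes — for modellers evaluating drive designs
before anyone builds one.

## The model in brief

* Discrete non-overlapping generations on a continuous interval
  (default length 2500, absorbing boundaries).
* Local density: each individual contributes a unit Gaussian kernel;
  `N_i = Σ_j φ(d_ij)` with `φ(d) = e^{−d²/2}/√(2π)`.
* Mating: a female chooses one male within 3 units, weighted by his kernel
  density at her position; no male in reach ⇒ no brood (spatial Allee
  effect).
* Reproduction: brood ~ Poisson(`R/(1 + a N_i)`), `a = (R−2)/(2N*)`, so a
  female at the equilibrium density `N*` expects exactly 2 offspring.
* Dispersal: offspring move by Normal(0, σ²); `σ` is the RMS dispersal
  distance.
* Drives: an XYd male (or ZdW female) transmits the drive chromosome with
  probability `1/(2−c)` — shredding destroys the targeted gametes and the
  survivors are renormalized, so carrier fecundity is unchanged.

Aspatial theory (module `drivewave.deterministic`): per-generation maps
`q' = (8q−3cq−cq²)/(8−4c)` (W-shredder) and `q' = 2q/(2−c+cq)`
(X-shredder); intrinsic drive fitness `m = c/(8−4c)` and `m = c/(2−c+cq)`;
Fisher speeds `v_WT = 2√(Dr)` with `r = R/2 − 1`, and the drive's upper
bound `v̂ = 2√(Dm)`.  Equating `r = m` at `c = 1` gives the critical
fecundities **2.5** (W-shredder) and **4.0** (X-shredder) above which the
WT wave outruns the drive.

## Worked example

```python
from drivewave import ScenarioConfig, DriveSystem, run_simulation

cfg = ScenarioConfig(
    drive_system=DriveSystem.X_SHREDDER,
    R=6.0, sigma=8.0,
    landscape_length=500.0, wt_init_range=(50.0, 250.0),
    intro_position=50.0, max_generations=200, seed=7,
)
rec = run_simulation(cfg)
print(rec.outcome.outcome.value, rec.outcome.failure_mode.value)
print("penetration at", rec.first_penetration_generation,
      "chasing:", rec.chasing_observed,
      "generations:", rec.generations_elapsed)
df = rec.to_dataframe()
print(df[["generation", "population_size", "female_fraction",
          "drive_allele_frequency"]].iloc[[0, 20, -1]])
```

prints

```
SUCCESS NONE
penetration at 1 chasing: True generations: 66
    generation  population_size  female_fraction  drive_allele_frequency
0            0             1010         0.505941                0.020040
20          20             1001         0.486513                0.079767
66          66                0              NaN                     NaN
```

A 1000-strong WT population is seeded with 10 XYd males (2% of the Y
chromosomes).  The drive builds slowly while it is rare (`q` reaches 0.08
by generation 20), then sweeps; WTs penetrate the young drive wave early
and are chased down, and the whole population is eradicated by generation
66 — a drive **success**.  The same object carries the wave measurements
(`rec.wave_metrics`) and the per-generation edge table used for event
re-scoring.

Scenario grids and analyses from the shell:

```bash
drivewave simulate --config scenarios.yaml --out runs/
drivewave grid --out grid_out/ --replicates 100        # the full study grid
drivewave analyze --results grid_out/outcomes.csv --out analysis/
```

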