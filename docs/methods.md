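# Methods

## The model

`drivewave` simulates the release of a sex-distorter suppression gene drive
into a wild-type (WT) population living on a bounded, continuous
one-dimensional landscape, and measures the emergent invasion waves and the
stochastic events — drift, founder events, recolonization — that decide
whether the drive eradicates the population.

**Local dynamics.** Generations are discrete and non-overlapping.  Each
individual spreads one unit of density over space as a standard normal
kernel centred on its position; the local density `N_i` experienced by
individual *i* is the sum of those kernels over the whole population
(including the focal individual's own term).  Females mate with a single
male chosen within a fixed radius of 3 spatial units, with probability
proportional to the density the male contributes at her position; a female
with no male in reach dies unmated — a spatial Allee effect.  A mated
female's brood is Poisson with Beverton–Holt mean `R / (1 + a N_i)`, where
`R ∈ [2, 10]` is the maximum fecundity and `a = (R − 2)/(2 N*)` is fixed so
that the expected brood is exactly 2 (replacement, with an expected 1:1 sex
ratio) at the equilibrium density `N*` (default 5 per unit).  Offspring are
born at the mother's position and take one Normal(0, σ²) dispersal step;
`σ ∈ [2, 20]` is the root-mean-square dispersal distance.  The landscape
(default length 2500) has absorbing boundaries: dispersers that leave it
die.

**Genetics.**  Two ideal shredder drives are modelled, with efficiency
`c ∈ [0, 1]` (default 1), no fitness costs and no resistance evolution:

* *X-shredder* (XY system): XYd males shred X-bearing gametes, so they
  transmit Yd with probability `1/(2−c)` and X with probability
  `(1−c)/(2−c)`; at `c = 1` every offspring of a carrier male is a carrier
  son.
* *W-shredder* (ZW system): ZdW females shred W-bearing gametes with the
  analogous renormalized distribution; at `c = 1` every offspring of a
  carrier female is a carrier son.

Shredding renormalizes the surviving gametes (carrier fecundity is
unchanged).  All other genotypes transmit Mendelianly; at `c = 0` both
systems are neutral.  The recorded drive allele frequency is Yd over Y-type
chromosomes (XY; equivalently, over males) and Zd over Z-type chromosomes
(ZW).

**Scenario defaults** are the study conditions: WT initialized uniformly on
[250, 1250] at `N*` per unit (5000 individuals), carriers released at 1% of
the WT count, all at x = 250 (XYd males, or ZdW females for the
W-shredder), runs capped at 1000 generations, stopping early on total
extinction or 10 generations after the drive allele is lost.  The
drive-loss stopping clock only runs when a drive system is configured;
WT-only control runs are exempt so that carrying-capacity experiments can
run to their horizon.

## Events, waves and outcomes

*Penetration* is scored when the leftmost WT sits at least σ units left of
the leftmost carrier (the drive wave's trailing edge); only the first event
is reliable once the landscape fragments.  *Chasing* is scored when, after
penetration, a carrier falls at or left of the rightmost WT that was behind
the previous generation's trailing edge — the drive re-entering recolonized
ground.  The per-generation edge table stores the ingredients so
alternative chasing definitions can be re-scored without re-simulation.
A run is a *success* if the WT population is eradicated by the horizon;
otherwise it fails by *drift loss* (drive lost, never penetrated), *WT
escape* (drive lost after penetration) or *coexistence*.

*Velocities* are the mean per-generation displacement of each wave's
leading individual, measured from introduction until the first boundary
contact (leading individual within σ of the right edge) or first
penetration.  *Heights* are the maximum class-specific local density
(carriers and non-carriers are measured against their own class only).
*Widths* are measured one generation after introduction: the drive wave's
leading/trailing half widths are the distances from its density peak to its
extreme members, and the WT width is twice the distance from the leading WT
to the WT wave's *leading-edge peak*.

**Leading-edge peak.**  At the measurement time the WT profile is a flat
plateau at carrying capacity plus an invasion front, so the global density
argmax is a noise excursion located anywhere in the plateau; a width built
on it measures the plateau, not the wave (we measured a log–log slope of
≈ 0.19 against σ under that definition, against the Fisher expectation of
≈ 1).  The front's crest is therefore operationalized, parameter-free, as
the rightmost class member whose class density reaches the class *median*
(bulk) density.  The drive wave is a single hump, so its peak stays the
plain density maximizer (ties toward the leading edge).

**Width scaling at one generation.**  One generation after a point
release, carrier positions are approximately a Gaussian(σ) sample, so
drive half-widths scale essentially linearly with σ (measured exponents
≈ 0.9–1.0).  Super-linear drive-width scaling (≈ 1.2–1.3) is a property of
*formed* waves shaped by advection over many generations; a one-generation
snapshot cannot contain it.  The snapshot time is kept because the study
design prescribes it; the reported exponents should be read accordingly.

## Aspatial theory

The deterministic module iterates the per-generation drive-frequency maps

* W-shredder: `q' = (8q − 3cq − cq²)/(8 − 4c)`
* X-shredder: `q' = 2q/(2 − c + cq)`

coupled with density `N' = N · φ(q) · R/(1 + aN)`, where
`φ(q) = (2 − c − cq)/(4 − 2c)` is the offspring female fraction.  Writing
`Δq = m q(1 − q)` gives the intrinsic drive fitness `m = c/(8 − 4c)` (W)
and `m = c/(2 − c + cq)` (X).  With diffusion `D` the WT invades empty
space at Fisher speed `2√(Dr)`, `r = R/2 − 1`, and the drive's speed is
bounded by `2√(Dm)` (advection ignored).  Equating `r` and `m` at `c = 1`
yields the critical fecundities 2.5 (W) and 4.0 (X), computed by root
solving, not hard-coded.  For theory-vs-simulation overlays the mapping
`D = σ²/2` is used (the one-generation Gaussian kernel's diffusion
equivalent).

**A verified discrepancy.**  The X-shredder map is reproduced *exactly*
(to 1e-12 on a dense (q, c) grid) by taking expectations over mating
classes built from the gamete rules, as is the female-fraction formula for
both systems.  The W-shredder map is not: exhaustive enumeration (carrier
mothers at frequency q, random-union male genotypes, renormalized
shredding) yields `q' = 2q(3 − c)/(6 − 3c + cq)`, a slightly *faster* map
with the same fixed points, monotonicity and X-over-W ordering (e.g. at
`c = 1, q = 0.5`: mechanism 0.5714 vs map 0.5625; intrinsic fitness 1/3 vs
1/4 at low q).  The deterministic module keeps the stated W-shredder map —
it underpins the published critical fecundity of 2.5 — and the genetics
module keeps the mechanistic rules; the unit tests pin the mechanism to its
own closed form and record the mismatch explicitly.

## Numerical choices

* Pairwise kernel sums are truncated at 6 SD (error < 1e-8 per pair) and
  evaluated with sorted positions and windowed gathers; the naive exact sum
  is kept as the test reference.
* One `numpy` Generator per replicate, seeded from the scenario seed; grid
  cells use `seed_base + scenario_index × replicates + replicate`, so any
  cell reproduces in isolation.
* Initialization counts round to the nearest integer (5000 WT + 50
  carriers at the defaults); WT sexes are independent fair draws.
* Event order within a generation: record → mate/reproduce → disperse →
  replace adults.
* Degenerate inputs: empty populations yield flagged (None/NaN)
  statistics, never silent zeros; undefined allele frequencies (no
  denominator chromosomes) are `None`; zero-width rows are dropped from
  log regressions with a reported count.
* The frequency recursions clip to [0, 1] to guard floating-point
  overshoot at the fixed points.

## What the synthetic scenarios do and do not show

All data are generated by the simulator itself under the study defaults;
there is no external input.  The generator emulates a single closed 1D
population with nearest-unit mating structure and Gaussian dispersal.  It
does not emulate 2D landscapes, overlapping generations, resistance
evolution, drive fitness costs, inbreeding structure, or environmental
heterogeneity — conclusions about those regimes do not follow from passing
tests here.  The WT-only equilibrium sits ~4–5% below `N* × length`
because each individual's own kernel term is included in its experienced
density (the spec-level convention), which shifts the realized equilibrium
density to about `N* − 1/√(2π)` per unit; tests and targets use sampling
tolerances that accommodate this.

## Problem sizes used in the shipped checks

Full-scale replication of the published outcome grid (20,000 runs × up to
1000 generations) is a batch job (`drivewave grid`), not a test.  The
shipped checks use: 300 one-generation runs for the width-scaling slopes,
a 120–200-generation full-landscape control run for carrying-capacity
recovery, a 96-run miniature grid (500-unit landscape) for the qualitative
outcome structure, and 5 near-panmictic replicates per system for the
deterministic comparison.  These sizes are the package's own choice of a
scale at which every mechanism is exercised while the suite stays fast.
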