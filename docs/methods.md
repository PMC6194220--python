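# Methods

## Model

The model tracks a single female's body mass through her breeding career
(ages 4–13; the terminal age 14 carries zero future value). Mass is both the
state variable and the currency: fitness is the expected weaning-mass-
weighted number of pups surviving to age one. Each model year applies, in
calendar order and each on the mass left by the previous stage:

1. **Parturition** — pup birth mass `p = b − 107·exp(−0.0055·x)` with
   intercept `b` = 47.8 kg (female pup) or 52.6 kg (male pup; mothers under
   380 kg bear females, larger mothers bear either sex with probability ½).
   Negative extrapolations at very small maternal mass are floored at zero.
2. **Lactation** — daily loss `0.013·m + 2.48` kg/day over 22.1 days, on the
   postpartum mass.
3. **Post-breeding foraging** — gain of 36.7% of the mass entering the trip
   for breeders; non-breeders feed through the breeding season instead and
   gain 50%.
4. **Molt** — `0.0396·m + 1.92` days (floored at 0) at 4.58 kg/day.
5. **Post-molt foraging** — gain of 66.6% of the mass entering the trip.

In a *bad year* (probability `a`) every foraging gain is multiplied by 0.75.
Mass is capped at x_max = 1,060 kg; any stage mass below x_crit = 140 kg is
starvation and certain death. Maternal survival is a hockey stick: 0 at or
below x_crit, rising linearly to `s_max` at `x_cutoff`, flat above
(`x_cutoff = x_crit` gives mass-independent survival). Pup first-year
survival is a step function of weaning mass `m_p = 0.171·m + 31.457`
(capped at 160 kg): 0 below 66 kg, then 0.14 / 0.50 / 0.67 / 0.93 / 1.0
at 66 / 80 / 95 / 140 / 155 kg.

The Bellman equation `F(x,y) = max{V_breed, V_skip}` is solved backward from
`F(x,14) = 0` on a 140–1,060 kg grid in 10-kg steps. Off-grid continuation
masses are handled by linear interpolation, which is exactly a stochastic
transition onto the two bracketing grid points — the grid model is therefore
a finite MDP, and the test suite exploits this by checking the solver
against exhaustive enumeration of all closed-loop policy matrices on a tiny
grid (agreement to 1e−9). The solver is deterministic: point-estimate
parameters, the sex-averaged expected pup mass, and environmental
stochasticity only through the (1−a)/a mixture. Ties between breeding and
skipping resolve to breed, so skip regions are conservative.

## Parameters and uncertainty

Every regression coefficient carries a standard error, stored alongside its
point estimate in `ModelParams` (single source of truth; YAML-configurable
with unknown keys rejected, and every run can echo its full configuration).
Scenario knobs: `x_cutoff` (default 200 kg, the default comparison
scenario), `s_max` (0.912, post-breeding survival of experienced breeders),
`a` (0), and quality classes that replace the three foraging fractions with
the upper half (good: 0.4/0.55/0.7 ± 0.015) or lower half (poor:
0.33/0.45/0.63 ± 0.015) of their plausible ranges; bad-year gains are always
0.75 × the (possibly class-overridden) good-year fraction.

Monte Carlo draws are truncated normals (rejection, not clipping, so no
probability mass piles up at bounds): probabilities to [0,1], rates,
durations and fractions to [0,∞), intercepts unbounded. The pup-survival
step values are drawn jointly and re-drawn in the rare case the step
function would lose monotonicity.

## Open choices and how they were resolved

Four implementation points are underdetermined by the source equations; each
is a config switch, with defaults chosen so the simulator reproduces the
published cohort statistics:

* **Survival evaluation mass** (`survival_eval`, default `nadir`): annual
  survival is evaluated at the female's yearly low point — post-lactation
  mass for breeders, arrival mass for non-breeders. This is what makes
  breeding survival-costly at low mass; evaluating at year-end mass
  (`end_of_year`) barely differentiates the strategies and cannot produce
  the observed collapse of annual breeders.
* **Draw placement** (`draw_mode`, default `per_year`): uncertain parameters
  are re-drawn every simulated year, as an implementation calling stochastic
  equation functions at each evaluation would do. Drawing once per lifetime
  (`per_lifetime`) creates persistent lucky individuals and inflates
  annual-cohort longevity.
* **Policy coupling** (`policy_mode`, default `per_individual`): each
  simulated female's policy is re-solved from her own parameter draw,
  mirroring a Monte Carlo that re-runs the whole model per simulation. With
  a single point-estimate policy (`mean`) no female can ever be a
  never-skipper, contrary to the reported behaviour distribution.
* **Weaning-mass reporting**: cohort weaning-mass summaries default to pups
  that survived to age one (`mean_wean_mass("surviving")`); the all-attempts
  pool is retained and one call away. Annual breeders' masses decline from
  ~427 kg, so an all-attempts mean sits near 100 kg and the reported
  ~126 kg level is only consistent with survivor-conditioning.

Further fixed conventions: a female who starves before weaning loses both
pup and future (starving at or after the molt, months past weaning, voids
only her future); attempts count every year with a breed decision, whether
or not the pup survives; the pup-survival outcome of a year stands even if
the mother dies in the subsequent survival draw; longevity is the last age
alive, so attempts + skips always equals years lived; policy lookups snap
mass to the nearest grid point with ties to the lower mass; the bad-year
sweep pairs strategies on common random numbers (same per-individual seeds)
to match its per-pair differencing, with streams keyed by (seed, a) so a
repeated probability reproduces exactly.

## What the simulations do and do not show

Cohorts are 1,000 independent lifetimes (four uniform variates per year in a
fixed order, so strategies share random numbers when seeded identically; all
experiments run in seconds at full published sizes). The simulator emulates
parameter-estimation error, demographic stochasticity (pup sex, pup and
maternal survival) and environmental bad years. It does not emulate density
dependence, senescence or other mass-independent age effects, individual
behavioural error, or spatial variation — so passing cohort checks shows the
decision model's internal logic, not field realism.

Two published patterns do not emerge from the equations as printed, and are
deliberately left as failing expectations rather than patched: (1) under
mass-independent survival our skip regions grow smoothly with s_max from the
low end (surfaces for s_max 0.45–0.85 differ in up to ~15% of cells, while
0.95 differs from 0.85 in ~1%), rather than being insensitive except above
0.90; (2) the skip-count difference between quality classes comes out
medium-sized (d ≈ 0.65) rather than small (≈ 0.1). Both trace to the same
structural feature: one skip year multiplies body mass by ≈ 1.9, which the
stage equations imply directly, making skipping economically attractive up
to ≈ 650 kg — higher than the source figures suggest. The annual-cohort
attempt count (≈ 3.8 vs 3.3 reported) and the longevity effect size
(≈ 1.0 vs 1.21) carry the same residual.

## Numerical notes

Grid: 93 masses × 10 ages; the solver precomputes the four per-mass annual
transitions (breed/skip × good/bad) once — they are age-independent — and
runs the Bellman sweep vectorized, ≈ 3 ms per solve, which is what makes
per-individual policy re-solving affordable (≈ 3 s per 1,000-female cohort).
Degenerate inputs are handled explicitly: sd = 0 draws return the mean
exactly; `s_max = 0` collapses the policy to breed-everywhere (no future);
`n = 1` cohorts report NaN standard deviations; zero pooled variance makes
Cohen's d raise rather than return ±inf.
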