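# sealskip

State-dependent optimal reproductive skipping in the southern elephant seal
(*Mirounga leonina*): a dynamic state variable model solved by stochastic
dynamic programming, plus a Monte Carlo lifetime simulator that quantifies
what intermittent breeding is worth.

## The problem

Southern elephant seals are capital breeders: a female finances a whole
lactation from stored blubber, losing on the order of 200 kg per pup, and
both her own survival and her pup's first-year survival depend on body mass.
Field studies show females sometimes skip a breeding season when condition is
low. This package reconstructs the decision problem behind that behaviour:
given body mass *x* and age *y*, is it better to breed now or to skip, feed,
and breed from a heavier state later?

## The model

The state dynamics follow the female's annual cycle — parturition, lactation,
post-breeding foraging trip, molt, post-molt foraging trip — with every loss
and gain mass-specific:

    x(y+1) = x − p − r + f_b − m_l + f_m      (breeder)
    x(y+1) = x + f_b′ − m_l + f_m             (non-breeder)

where *p* is pup birth mass, *r* lactation loss, *f* foraging gains
(multiplied by 0.75 in a "bad year", which occurs with probability *a*), and
*m_l* molt loss. A female whose mass falls below x_crit = 140 kg at any
stage starves; masses are capped at x_max = 1,060 kg. Maternal survival is a
hockey-stick in mass (0 at x_crit, linear up to x_cutoff, flat at s_max
above); pup first-year survival is a step function of weaning mass.

Fitness is the expected mass-weighted production of pups surviving to age 1
from age *y* to the terminal age 14:

    F(x, y) = max{ V_breed(x, y), V_skip(x, y) },    F(x, 14) = 0

solved by backward iteration over a 93-mass × 10-age grid with linear
interpolation of the continuation value. A forward Monte Carlo layer then
simulates individual lifetimes (ages 4–13) under either the optimal policy
or obligate annual breeding, propagating the published parameter-estimation
errors by normal draws, and compares cohorts with Cohen's *d*.

## Worked example

```python
from sealskip import ModelParams, compare_strategies

comp = compare_strategies(ModelParams(), n=1000, seed=42)
print(comp.summary_table()[["cohort", "mean_lro", "mean_attempts", "mean_wean_mass"]])
print(f"Cohen's d, LRO: {comp.d_lro:.2f}")
```

prints

```
 cohort  mean_lro  mean_attempts  mean_wean_mass
optimal     5.174          5.732      153.164303
 annual     1.978          3.831      121.580766
Cohen's d, LRO: 1.19
```

Optimal females average 5.7 breeding attempts and 5.2 pups surviving to age
one; obligate annual breeders average 3.8 attempts and 2.0 surviving pups,
because repeated breeding runs body mass down until survival collapses and
pups wean light. The standardized difference in lifetime reproductive output
is d ≈ 1.2 — a large effect. Most optimal females skip exactly once, early,
then breed annually from a rebuilt body mass.

The `examples/` directory holds one short script per capability: the policy
surface and its skip regions, the strategy comparison above, good- vs
poor-quality foraging classes, and the bad-year frequency sweep. A thin CLI
mirrors these (`sealskip solve`, `sealskip simulate`, `sealskip sweep`).

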