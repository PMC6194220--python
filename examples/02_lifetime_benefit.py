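"""Lifetime benefit of the optimal strategy over annual breeding.

Simulates 1000 female lifetimes per strategy under the default scenario
(x_cutoff = 200 kg, s_max = 0.912, no bad years) with per-year parameter
draws and per-individual policies, then compares the cohorts.
"""

from sealskip import ModelParams, compare_strategies

comp = compare_strategies(ModelParams(), n=1000, seed=42)

print(comp.summary_table().to_string(index=False))
print(f"\nCohen's d, lifetime reproductive output: {comp.d_lro:.2f}")
print(f"Cohen's d, longevity:                    {comp.d_longevity:.2f}")
print("\nSkips per female (optimal-policy cohort):")
print(comp.skip_histogram.to_string())

print(
    "\nFemales following the optimal policy typically skip one year early in\n"
    "life, rebuild body mass, and then breed annually from a higher mass —\n"
    "yielding more attempts, heavier pups and a large gain in pups surviving\n"
    "to age one relative to obligate annual breeders."
)
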