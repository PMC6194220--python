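"""Persistent individual quality and reproductive skipping.

Splits the foraging-gain distributions into a good class (fractions
0.4 / 0.55 / 0.7 of body mass) and a poor class (0.33 / 0.45 / 0.63),
solves each class's own optimal policy, simulates 1000 lifetimes per class
and compares skip counts and lifetime reproductive output.
"""

from sealskip import ModelParams, compare_heterogeneity

comp = compare_heterogeneity(ModelParams(), n=1000, seed=7)

for summary in (comp.good, comp.poor):
    print(
        f"{summary.label:>5}: mean skips {summary.skips.mean():.2f}, "
        f"mean lifetime reproductive output {summary.lro.mean():.2f}, "
        f"mean attempts {summary.attempts.mean():.2f}"
    )
print(f"\nCohen's d, skips (poor - good): {comp.d_skips_poor_minus_good:.2f}")
print(f"Cohen's d, LRO (good - poor):   {comp.d_lro_good_minus_poor:.2f}")

print(
    "\nPoor foragers rebuild mass more slowly, so their policies call for\n"
    "skipping up to higher body masses and they skip more often, ending with\n"
    "slightly fewer pups surviving to age one than good foragers."
)
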