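"""Solve the optimal breed/skip policy for the default survival scenario.

Builds the default parameter set (x_cutoff = 200 kg, maximum annual survival
0.912, no bad years), runs the backward iteration over the 93-mass x 10-age
grid, and prints the decision surface plus the skip intervals per age.
"""

from sealskip import ModelParams, skip_region_summary, solve

params = ModelParams()
solution = solve(params)

print("Decision surface (B = breed, s = skip; columns run 140 -> 1060 kg):")
print(solution.decision_map())

print("\nContiguous skip intervals (kg) per age:")
print(skip_region_summary(solution).to_string(index=False))

print(
    "\nEach 's' cell marks a (mass, age) state where forgoing this year's pup\n"
    "and refeeding yields more expected surviving pups over the remaining\n"
    "lifetime than breeding now."
)
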