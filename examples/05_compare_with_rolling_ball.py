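"""Score the snake correction against rolling-ball baselines.

Generates five notched lung phantoms and prints the mean overlap metrics of
the uncorrected input, the proposed correction, and morphological closing
with 5/10/15-px disks — the classical notch fillers.
"""

import numpy as np

from lungrepair import carve_notches, compare_methods, make_lung_truth

rng = np.random.default_rng(7)
cases = []
for _ in range(5):
    seed = int(rng.integers(2**31 - 2))
    truth = make_lung_truth(512, 512, seed=seed)
    cases.append(carve_notches(truth, int(rng.integers(1, 4)), (8.0, 15.0), seed=seed + 1))

table = compare_methods(cases, radii=(5, 10, 15))
means = table[table["case"] == "mean"]
print(means.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
# ACC: percentage of truth pixels present; R_u: missed truth; R_o: excess.
# Closing can only fill concavities narrower than its ball, so small radii
# barely help while the snake refills most of the notch area.
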