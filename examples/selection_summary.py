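"""Carrier frequencies, scaled selection coefficients, empirical nulls.

The analytic conversions for the ADSL expression-lowering haplotype:
how many people carry it, how strong the inferred selection is on the
population scale, and how a focal statistic is ranked against
frequency-matched control variants.
"""

import numpy as np

from adslkit.popgen import (
    carrier_frequency,
    empirical_null_pvalue,
    scaled_selection_coefficient,
)

print("Hardy-Weinberg carrier share (>= 1 copy) by allele frequency:")
for p in (0.82, 0.88, 0.93):
    print(f"  p = {p:.2f} -> {100 * carrier_frequency(p):.2f}%")

print("\npopulation-scaled selection coefficients (alpha = 2*Ne*s, Ne = 10,000):")
for s in (0.0018, 0.0016):
    alpha, above = scaled_selection_coefficient(s, 10_000)
    note = "above" if above else "below"
    print(f"  s = {s:.4f} -> alpha = {alpha:.0f} ({note} the nearly neutral threshold of 1)")

rng = np.random.default_rng(3)
controls = [(float(f), float(v)) for f, v in zip(rng.uniform(0.7, 0.95, 500), rng.normal(0, 1, 500))]
res = empirical_null_pvalue((0.85, 3.1), controls, delta=0.05, direction="greater")
print(
    f"\nempirical null: focal statistic 3.1 vs {res.n_matched} frequency-matched "
    f"controls -> p = {res.p_value:.4f}"
)
print(
    "\nCarrier shares near 97% mean almost everyone carries the variant; "
    "alpha >> 1 indicates selection, not drift; the empirical p ranks the "
    "focal signal against comparable neutral variants."
)
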