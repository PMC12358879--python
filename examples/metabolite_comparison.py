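"""Normalize simulated peak areas and compare genotypes per tissue.

Plants a 2-fold SAICAr increase in the liver of humanized animals,
hides it behind random per-sample scale factors, then recovers it with
upper-quartile normalization and pooled-variance t-tests. Also shows
the negative correlation between enzyme expression and the metabolic
fold change across tissues.
"""

import numpy as np

from adslkit.metabolomics import (
    expression_metabolite_correlation,
    group_compare,
    upper_quartile_normalize,
)
from adslkit.simulate import MetaboliteSimParams, simulate_metabolite_table

params = MetaboliteSimParams(
    tissues=("forebrain", "liver", "muscle"),
    fold={("SAICAr", "forebrain"): 2.0, ("SAICAr", "liver"): 2.0},
    sigma=0.15,
    seed=7,
)
table = simulate_metabolite_table(params)
norm = upper_quartile_normalize(table)
report = group_compare(norm, metabolites=["SAICAr", "S-Ado"])

cols = ["tissue", "sex", "metabolite", "fold", "t", "p"]
print("genotype comparisons (fold = hAdsl mean / WT mean):")
print(report[cols].round(4).to_string(index=False))

# tissues with low enzyme expression show the largest metabolite increase
expression = np.array([1.0, 1.5, 4.0, 5.0, 6.0])
fold_change = 3.2 - 0.45 * expression + np.random.default_rng(0).normal(0, 0.15, 5)
res = expression_metabolite_correlation(expression, fold_change)
print(f"\nexpression vs fold-change Pearson R = {res.r:.2f} (p = {res.p:.3f})")
print(
    "\nFolds near 2 with small p mark the planted tissues; folds near 1 "
    "elsewhere show normalization removed the sample-scale nuisance. The "
    "negative R says the effect is largest where expression is lowest."
)
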