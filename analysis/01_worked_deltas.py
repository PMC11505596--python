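#!/usr/bin/env python
"""Excess fractions from the published summary diversity ratios.

Two mammalian contrasts provide the inputs: the mouse pair M. m. castaneous
(large) vs M. m. musculus (small), and the chimpanzee pair P. t. troglodytes
(large) vs P. t. verus (small).  For each, the large/small ratio of intron
diversity (neutral) exceeds the ratio of nonsynonymous diversity
(constrained), and the gap is the excess fraction of deleterious variation
segregating in the small population:

    delta = 1 - R_C / R_N   (cross-population class ratios), or
    delta = 1 - omega_L / omega_S  (within-population piN/piI ratios).

Writes results/worked_deltas.tsv.
"""

import os

import pandas as pd

from hetexcess import delta, delta_from_class_ratios

rows = [
    {
        "comparison": "castaneous/musculus (mouse)",
        "inputs": "R_N=2.26 (intron), R_C=1.56 (nonsynonymous)",
        "delta_percent": 100 * delta_from_class_ratios(R_C=1.56, R_N=2.26),
    },
    {
        "comparison": "troglodytes/verus (chimpanzee)",
        "inputs": "R_N=2.1 (intron), R_C=1.62 (nonsynonymous)",
        "delta_percent": 100 * delta_from_class_ratios(R_C=1.62, R_N=2.1),
    },
    {
        "comparison": "castaneous/musculus (mouse, piN/piI form)",
        "inputs": "omega_L=0.15, omega_S=0.22",
        "delta_percent": delta(omega_L=0.15, omega_S=0.22).delta_percent,
    },
]

table = pd.DataFrame(rows)
os.makedirs("results", exist_ok=True)
table.to_csv("results/worked_deltas.tsv", sep="\t", index=False, float_format="%.1f")
print(table.to_string(index=False, float_format=lambda v: f"{v:.1f}"))
print(
    "\nThe small mouse population carries a ~31% excess in nonsynonymous "
    "heterozygosity, the small chimpanzee population ~23%."
)
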