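#!/usr/bin/env python
"""The excess fraction grows with gene-level selective constraint and expression.

Genes are simulated with log-uniform selection coefficients; per-site
conservation scores and expression levels rise with log(1+|gamma|), so
stratifying genes by the proportion of constrained sites (score > 2.0) or by
expression orders them by selection intensity.  Per-stratum delta% (each
stratum using its own intron diversity as the neutral reference) is then
tested for trend with a permutation Spearman correlation — the synthetic
counterpart of the published constraint and expression category analyses.

Writes results/strata_constraint.tsv, results/strata_expression.tsv and
results/strata_spearman.tsv.
"""

import os

import numpy as np
import pandas as pd

from hetexcess import GeneRecord, SimConfig, gene_constraint_proportion, generate_dataset
from hetexcess.gene_strata import equal_count_bins, spearman, stratified_excess
from hetexcess.pipeline import _gene_site_counts

rng = np.random.default_rng(1)
N_GENES = 300
s_per_gene = np.exp(rng.uniform(np.log(1e-6), np.log(2e-4), N_GENES))

config = SimConfig(
    ne_small=24_000,
    n_chrom=15,
    genes_per_chrom=20,
    gene_spacing=100_000,
    intergenic_length=2_000,
    intron_length=4_000,
    gene_s=s_per_gene,
    seed=1,
)
dataset = generate_dataset(config)
counts = _gene_site_counts(dataset.genes)

os.makedirs("results", exist_ok=True)
spearman_rows = []
for label, values, bin_size in (
    (
        "constraint",
        pd.Series(
            {
                row.gene_id: gene_constraint_proportion(
                    GeneRecord(row.gene_id, row.chrom, [[row.cds_start, row.cds_end]]),
                    dataset.scores,
                    threshold=2.0,
                )
                for row in dataset.genes.itertuples(index=False)
            }
        ),
        20,  # 300 genes -> 15 constraint strata
    ),
    (
        "expression",
        pd.Series(
            dataset.genes["expression"].to_numpy(), index=dataset.genes["gene_id"]
        ),
        33,  # 300 genes -> 9 expression strata
    ),
):
    strata = equal_count_bins(values, bin_size=bin_size)
    table = stratified_excess(
        strata, values, dataset.variants, counts, "large", "small"
    )
    table.to_csv(f"results/strata_{label}.tsv", sep="\t", index=False, float_format="%.4f")
    ok = table["delta_percent"].notna()
    res = spearman(
        table.loc[ok, "mean_stratifier"].to_numpy(),
        table.loc[ok, "delta_percent"].to_numpy(),
        seed=1,
    )
    spearman_rows.append(
        {"stratifier": label, "rho": res.rho, "p_perm": res.p_value, "p_t": res.p_t,
         "n_strata": res.n}
    )
    print(f"\n{label} strata:")
    print(table[["stratum", "mean_stratifier", "delta_percent"]].to_string(index=False))
    print(f"Spearman rho = {res.rho:.3f}, permutation p = {res.p_value:.2e}")

pd.DataFrame(spearman_rows).to_csv(
    "results/strata_spearman.tsv", sep="\t", index=False, float_format="%.6g"
)
print(
    "\ndelta% rises from the least to the most constrained strata and with "
    "expression, mirroring the published gene-category trends."
)
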