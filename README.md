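# hetexcess

Quantify the excess of constrained-site heterozygosity segregating in small
populations.

## The problem

Heterozygosity (nucleotide diversity, π) is the standard currency for
comparing genetic variation between populations, but the comparison is
confounded by purifying selection: in a small population drift overwhelms
selection, so mildly deleterious variants that a large population would
purge keep segregating at constrained sites.  The constrained-site diversity
of the small population is thereby inflated.  With ω = π_C/π_N the ratio of
constrained-site to neutral-site diversity within one population, the excess
fraction in the small population is

    δ = 1 − ω_L/ω_S,      δ% = 100·(ω_S − ω_L)/ω_S,

equivalently δ = 1 − R_C/R_N from the large/small cross-population ratios of
constrained (R_C) and neutral (R_N) diversity.  Unlike π_N/π_S itself, δ is
comparable across species.  This package is for population geneticists who
want that number, with honest errors, from standard files.

It provides:

- **`formats_io`** — VCF (cyvcf2), BED class maps, bedGraph-like
  conservation scores, expression TSVs; site-class assignment; Nei–Gojobori
  synonymous/nonsynonymous site counting for CDS denominators.
- **`diversity`** — Tajima's mean pairwise differences per site, per
  (population, site class), with 1-Mb block-bootstrap standard errors.
- **`excess`** — ω, δ, δ% with a joint block bootstrap that preserves the
  covariance among the four diversities entering δ.
- **`gene_strata`** — gene stratification by constraint proportion
  (conservation score > 2.0) or expression, per-stratum δ%, permutation
  Spearman trend tests.
- **`synthetic_data`** — a two-population generator on the diffusion site
  frequency spectrum with closed-form oracles r(γ) and the expected δ, so
  every stage is verifiable without downloads.
- **`pipeline` / `hetexcess` CLI** — one entry point chaining
  simulate → diversity → excess → strata with a reproducibility manifest.

## Worked example

The published mouse and chimpanzee comparisons arrive as summary diversity
ratios; δ follows directly:

```python
>>> from hetexcess import delta, delta_from_class_ratios
>>> 100 * delta_from_class_ratios(R_C=1.56, R_N=2.26)   # mouse pair
30.973451327433622
>>> 100 * delta_from_class_ratios(R_C=1.62, R_N=2.1)    # chimpanzee pair
22.857142857142854
>>> delta(omega_L=0.15, omega_S=0.22).delta_percent     # mouse, piN/piI form
31.818181818181824
```

About 31% of the nonsynonymous heterozygosity of the small mouse population
(M. m. musculus) and 23% of that of the small chimpanzee population
(P. t. verus) is excess segregating deleterious variation.

End to end on synthetic data with known truth:

```python
>>> from hetexcess import (SimConfig, generate_dataset, partition_blocks,
...                        excess_with_bootstrap)
>>> ds = generate_dataset(SimConfig(seed=3))        # Ne 60,000 vs 10,000, gamma_L=5
>>> blocks = partition_blocks(ds.variants, ds.class_map)
>>> est = excess_with_bootstrap(blocks, "large", "small", B=1000, seed=9)
>>> round(est.delta, 4), round(est.se_delta, 4)
(0.5502, 0.0196)
>>> round(ds.truth["theoretical_delta"], 4)
0.5521
```

The pipeline estimate of δ lands within one bootstrap SE of the diffusion
expectation 1 − r(−4N_e^L s)/r(−4N_e^S s).

The `analysis/` drivers run the full narrative and write tables under
`results/`: `01_worked_deltas.py` (the numbers above),
`02_simulate_dataset.py` (a dataset as standard files plus truth JSON, under
`scratch/`), `03_ne_trend.py` (δ grows with the N_e ratio: 46.1%, 50.3%,
56.7% at ratios 2.4, 3.4, 5.9 against theoretical 42.8%, 49.4%, 55.1%), and
`04_strata_trends.py` (δ% rises from ≈ 0–10% in the least constrained gene
strata to ≈ 55% in the most constrained, Spearman ρ = 0.91, permutation
p = 5×10⁻⁵; similarly for expression strata, ρ = 0.93).

A CLI mirrors the stages for file-based work:

```sh
hetexcess simulate --seed 1 --out scratch/simdata
hetexcess report --vcf scratch/simdata/variants.vcf \
    --populations 'large=L01,...;small=S01,...' \
    --bed intron scratch/simdata/intron.bed ... --out results/run1
```

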