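# Methods

## The statistic

Comparing heterozygosities between a large and a small population of the
same species is confounded by purifying selection: in the small population,
genetic drift overwhelms selection against mildly deleterious variants, so a
disproportionate number of them segregate at constrained sites.  The
constrained-site diversity of the small population is therefore inflated
relative to what its neutral diversity would predict.

Writing π_C and π_N for nucleotide diversity at constrained sites
(nonsynonymous, or the whole exome) and at putatively neutral sites (intron
by default), and ω = π_C/π_N within one population, the excess fraction of
constrained-site heterozygosity in the small population is

    δ = 1 − ω_L/ω_S,     δ% = 100 · (ω_S − ω_L)/ω_S.

Equivalently, with R_C and R_N the large/small cross-population ratios of
constrained and neutral diversity, δ = 1 − R_C/R_N (`delta_from_class_ratios`
and `delta` agree to machine precision on the same four diversities; the
test suite checks this identity, the swap identity (1−δ)(1−δ′) = 1, and
scale invariance).  δ is reported signed; ω_L > ω_S yields a negative value
carrying a `negative_delta` flag rather than being clipped, because the
inequality ω_L < ω_S is an empirical expectation, not a constraint.

## Diversity estimation

Heterozygosity is Tajima's mean pairwise difference per site.  A biallelic
site with j alternate alleles among n called chromosomes contributes
2j(n−j)/(n(n−1)) — the exact fraction of differing chromosome pairs, and an
unbiased estimator of 2q(1−q) under binomial sampling.  A class estimate
divides the summed contributions by the class's callable-site total L_c;
monomorphic callable sites enter only the denominator.  Design points:

- Missing genotypes reduce n at a site rather than dropping it; sites with
  n < 4 called chromosomes in any population are excluded because the
  per-site estimator's variance explodes at tiny n.
- Denominators are caller-supplied (`site_counts`): whether intron and
  intergenic totals are annotated lengths or coverage-filtered callable
  counts is a data-preparation decision this package does not make.
  Synonymous/nonsynonymous site totals may be fractional; Nei–Gojobori
  (1986) counting (`ng86_site_counts`) computes them from CDS sequence, with
  mutations to stop codons counted as nonsynonymous (the classical
  convention) and S + N equal to the CDS length exactly.
- The "exome" class is defined as the union of synonymous and nonsynonymous
  CDS sites (whether published exome analyses include UTRs is not derivable
  from the summary data; this package fixes the CDS definition).

Standard errors come from a block bootstrap resampling 1-Mb genomic windows
with replacement (B = 1000 by default).  Each replicate recomputes the
statistic as a ratio of pooled sums (numerators and denominators summed
before dividing), which stays stable when a resample is sparse in one
class.  For δ the four diversities share a single block resample per
replicate, preserving the covariance between classes and populations —
resampling them independently would overstate SE(δ).  Replicates on which
the statistic is undefined (zero neutral sum) are dropped from the SE with a
logged count; more than 10% undefined is an error.  The bootstrap seed is a
required, logged configuration value (default 1).

## Gene stratification

Genes are ranked by a stratifier and cut into equal-count strata.  The
stratifiers are (a) the proportion of CDS positions with a conservation
score strictly greater than 2.0 (PhyloP-style; positions lacking a score
stay in the denominator as non-constrained, with the coverage fraction
logged), computed over CDS because the diversity being compared is
nonsynonymous, and (b) log-mean expression.  The number of strata is the
gene count over the bin size rounded to the nearest integer, with genes
split as evenly as possible — so 14,870 genes at bin size 1000 give 15
strata and 9,089 give 9, which is the only reading consistent with "1000
genes per category" at both totals.  Ties are broken by gene id so the
partition is deterministic.

Each stratum's δ% pools nonsynonymous SNVs and site counts over the
stratum's CDS and intron SNVs and lengths over the stratum's genes' introns,
so every stratum carries its own neutral reference (per-stratum intron π;
a global neutral reference is available as an option).  Strata with zero
neutral diversity are reported missing, never fabricated.  The trend of δ%
against the stratifier is tested with Spearman rank correlation — Pearson
correlation of average ranks — with a two-sided permutation p-value
(99,999 permutations, add-one correction, so p ≥ 1/(n_perm+1)) and the
parametric t-approximation reported alongside.

## Synthetic data

The generator emulates the statistical structure the analysis assumes, with
every parameter an explicit study condition:

- Two populations at mutation–selection–drift equilibrium, simulated
  independently (no shared ancestry, migration or non-equilibrium
  demography — δ is defined on per-population equilibrium diversities, so
  divergence structure is irrelevant to it).  Defaults: N_e = 60,000 and
  10,000 (the largest published chimpanzee contrast), μ = 8.3×10⁻⁸ per site
  per generation so θ_L = 4N_eμ ≈ 0.02, ten diploids per population.
- Segregating sites follow the diffusion (Poisson random field) frequency
  spectrum f(q;γ) ∝ (1−e^{−γ(1−q)})/((1−e^{−γ})q(1−q)) for semidominant
  (genic) selection, γ = 4N_e·s; dominance is out of scope.  Site counts are
  Poisson(θ·L·∫f) over [1/(2N_e), 1−1/(2N_e)]; frequencies are inverse-CDF
  draws on a ~10⁴-point grid geometric towards both boundaries; sample
  genotypes are Hardy–Weinberg binomial draws.  Grid sampling was chosen
  over forward Wright–Fisher for desk-scale speed; a slow forward-WF
  cross-check at N_e = 200 lives in the test suite and agrees with the
  diffusion expectations within 10%.
- Genome layout: gene cassettes (intergenic / intron / CDS) spaced along
  5-Mb chromosomes so 1-Mb bootstrap blocks carry realistic site mixtures;
  default 80 genes giving ≈ 9×10⁴ nonsynonymous and ≈ 1.5×10⁶ neutral sites.
  Within each CDS every fourth position is synonymous (so S:N = 1:3
  exactly); neutral classes (intron, intergenic, synonymous) use γ = 0 and
  nonsynonymous sites of gene g use γ_g = −4N_e·s_g.  The default scalar
  s = 5/(4N_e^L) puts γ_L = 5; per-gene tables of s drive the stratification
  studies.
- Per-site conservation scores are a·log(1+|γ_g|) + Gaussian noise
  (a = 1, SD = 1) and gene expression is 4.0 + 1.2·log(1+|γ_g|) + noise
  (SD 0.5), encoding the observed positive association between expression
  and selective constraint, so score thresholding at 2.0 and expression
  binning are exercised against known truth.
- The infinite-sites regime is enforced (4N_eμ < 0.1) and positions are
  drawn without replacement within a class, jointly across populations, so
  sites never collide.

Closed-form oracles accompany the generator: the diversity reduction at
selected sites r(γ) = 2(γ−(1−e^{−γ}))/(γ(1−e^{−γ})) (validated against
adaptive quadrature to 1e−8 relative error in the tests; computed via expm1
with the 2/|γ| asymptote beyond |γ| = 700), and the expected excess
δ = 1 − r(−4N_e^L s)/r(−4N_e^S s), since neutral diversity 4N_eμ cancels
from each ω.  The truth JSON written with every dataset records the per-gene
γ values and this expectation.

What the generator does not emulate — hence what passing tests do not show
about real data: linkage and background selection (sites are exchangeable
within blocks; real 1-Mb blocks share genealogies), shared ancestry between
the populations, a distribution of fitness effects within a gene,
non-equilibrium demography, sequencing error and genotype-missingness
structure.  Recovery of δ on these data demonstrates the estimator and its
bootstrap are correct under the model, not that real-data δ is unbiased
under background selection (which published work addresses by the
distal-intergenic neutral reference, available here as a distance filter on
the class map).

## Problem sizes and numerical choices

Simulation checks use sizes chosen from analytic error budgets (per-site
contributions form compound-Poisson sums, so SE(Σ) ≈ √(Σx²), and δ's SE
follows by the delta method): the N_e-trend recovery runs 20 seeds × three
N_e ratios (2.4, 3.4, 5.9) at the default genome, where SE(δ̂) ≈ 0.02
against ordering gaps of ≈ 0.06; the constraint-trend check runs 20 seeds
of 300 genes in 15 strata, where per-stratum SE(δ%) ≈ 4 against a truth
range of ≈ 2–60%.  Block partitioning assigns a variant at 1-based position
p to block ⌊(p−1)/10⁶⌋ and apportions interval lengths to blocks by
intersection; fractional class totals are spread over blocks in proportion
to exome length.  Bootstrap SEs use the B−1 denominator; all randomness
flows through seeded `numpy` generators, and identical configuration plus
seed reproduces every output byte for byte.

## Known limitations

Effect annotation is consumed, not computed: synonymous/nonsynonymous labels
must arrive as VCF annotation tags (or be derivable from the class map), and
the NG86 counts stand in for codon-model site counting — adequate for
denominators, not for dN/dS inference.  The permutation Spearman test treats
strata as exchangeable units and ignores the estimation error of each
stratum's δ%.  The distal-intergenic filter needs gene spans covering all
protein-coding genes; with sparse gene annotations it under-filters.
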