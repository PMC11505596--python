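"""Two-population synthetic SNV datasets with closed-form diversity oracles.

Each population is simulated independently at mutation–selection–drift
equilibrium (no shared ancestry, migration, or non-equilibrium demography —
the delta statistic compares per-population equilibrium diversities, so
divergence structure is irrelevant to its definition).  Segregating sites are
drawn from the standard diffusion (Poisson random field) frequency spectrum
for semidominant selection,

    f(q; gamma) ∝ (1 - e^{-gamma (1-q)}) / ((1 - e^{-gamma}) q (1-q)),

with gamma = 4 N_e s the scaled selection coefficient (deleterious sites have
gamma < 0; gamma -> 0 recovers the neutral 1/q spectrum).  Site counts are
Poisson with mean theta * L * ∫ f, frequencies come from inverse-CDF sampling
on a fine grid over [1/(2N_e), 1 - 1/(2N_e)], and sample genotypes are
Hardy–Weinberg binomial draws.

Neutral classes (intron, intergenic, synonymous) are simulated with gamma = 0;
the nonsynonymous sites of gene g use gamma_g = -4 N_e s_g.  Per-site
conservation scores rise with log(1 + |gamma_g|) plus Gaussian noise, and
gene expression does the same (highly expressed genes are the most
constrained), so constraint- and expression-based stratification can be
exercised end to end against known truth.

The closed-form oracle is the expected diversity reduction at selected sites
relative to neutral ones,

    r(gamma) = ∫ 2q(1-q) f(q; gamma) dq / ∫ 2q(1-q) f(q; 0) dq
             = 2 (gamma - (1 - e^{-gamma})) / (gamma (1 - e^{-gamma})),

from which the expected excess fraction is
delta = 1 - r(-4 N_e^L s) / r(-4 N_e^S s).
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd

from .formats_io import SiteClassMap, write_vcf

GRID_POINTS = 10_001


# ---------------------------------------------------------------------------
# Frequency-spectrum oracles
# ---------------------------------------------------------------------------

def sfs_weight(q, gamma: float):
    """(1 - e^{-gamma(1-q)}) / (1 - e^{-gamma}), computed stably for any gamma.

    This is the selection factor of the diffusion SFS; the full density is
    weight / (q (1 - q)).  At gamma = 0 the limit is (1 - q).
    """
    q = np.asarray(q, dtype=float)
    if not np.isfinite(gamma):
        raise ValueError("gamma must be finite")
    if abs(gamma) < 1e-8:
        return 1.0 - q
    if gamma > 0:
        return np.expm1(-gamma * (1.0 - q)) / np.expm1(-gamma)
    # gamma < 0: factor out the growing exponential to avoid overflow
    g = -gamma
    if g > 700:
        # e^{g} dominates both numerator and denominator
        return np.exp(-g * q) * -np.expm1(-g * (1.0 - q))
    return np.exp(-g * q) * np.expm1(-g * (1.0 - q)) / np.expm1(-g)


def sfs_density(q, gamma: float):
    """Unnormalized diffusion SFS density f(q; gamma)."""
    q = np.asarray(q, dtype=float)
    return sfs_weight(q, gamma) / (q * (1.0 - q))


def expected_pi_reduction(gamma: float) -> float:
    """Expected pi at selected sites relative to neutral sites, r(gamma).

    Closed form of the ratio of heterozygosity integrals over the diffusion
    SFS (validated against adaptive numerical integration in the test suite).
    Strictly decreasing in |gamma| for gamma < 0; r(0) = 1 by the neutral
    limit; r ~ 2/|gamma| as gamma -> -inf.
    """
    if not np.isfinite(gamma):
        raise ValueError("gamma must be finite")
    if abs(gamma) < 1e-8:
        return 1.0
    if gamma < -700:
        return -2.0 / gamma
    E = -np.expm1(-gamma)  # 1 - e^{-gamma}
    return float(2.0 * (1.0 - E / gamma) / E)


def theoretical_delta(ne_large: int, ne_small: int, s: float) -> float:
    """Expected excess fraction delta for two equilibrium populations.

    The neutral diversity 4 N_e mu cancels from each omega, leaving
    delta = 1 - r(-4 Ne_L s) / r(-4 Ne_S s).
    """
    if not (ne_large > ne_small > 0):
        raise ValueError("require ne_large > ne_small > 0")
    if s < 0:
        raise ValueError("s must be >= 0")
    if s == 0:
        return 0.0
    return 1.0 - expected_pi_reduction(-4.0 * ne_large * s) / expected_pi_reduction(
        -4.0 * ne_small * s
    )


@dataclass
class SfsModel:
    """Frequency-spectrum model for one site class in one population."""

    gamma: float
    theta_site: float
    ne: int

    def __post_init__(self) -> None:
        if self.theta_site < 0 or self.ne <= 0:
            raise ValueError("theta_site >= 0 and ne > 0 required")


@lru_cache(maxsize=4096)
def _grid_cdf(gamma: float, ne: int) -> tuple[np.ndarray, np.ndarray, float]:
    """Frequency grid, cumulative density, and total mass over [1/2Ne, 1-1/2Ne].

    The grid is geometric towards both boundaries (the density has 1/q and,
    for positive gamma, 1/(1-q) mass concentrations).
    """
    lo = 1.0 / (2.0 * ne)
    half = GRID_POINTS // 2
    left = np.geomspace(lo, 0.5, half + 1)
    right = 1.0 - np.geomspace(lo, 0.5, half + 1)[::-1]
    grid = np.unique(np.concatenate([left, right]))
    dens = sfs_density(grid, gamma)
    if not np.all(np.isfinite(dens)):
        raise ValueError("SFS density non-finite; integration bounds misconfigured")
    seg = 0.5 * (dens[1:] + dens[:-1]) * np.diff(grid)
    cdf = np.concatenate([[0.0], np.cumsum(seg)])
    return grid, cdf, float(cdf[-1])


def sfs_mass(gamma: float, ne: int) -> float:
    """∫ f(q; gamma) dq over the sampling bounds (segregating-site density)."""
    return _grid_cdf(float(gamma), int(ne))[2]


def sample_population_frequencies(
    model: SfsModel, L_sites: float, rng: np.random.Generator
) -> np.ndarray:
    """Draw population frequencies of the segregating sites in L_sites bases.

    The number of segregating sites is Poisson(theta_site * L * ∫ f dq) and
    frequencies are inverse-CDF draws from the normalized density; identical
    generator state gives identical draws.
    """
    grid, cdf, mass = _grid_cdf(float(model.gamma), int(model.ne))
    lam = model.theta_site * L_sites * mass
    if not np.isfinite(lam):
        raise ValueError("Poisson mean non-finite; check theta and L")
    k = rng.poisson(lam)
    u = rng.uniform(0.0, mass, size=k)
    return np.interp(u, cdf, grid)


def pi_mc_se(site_contributions: np.ndarray, L: float) -> float:
    """Monte-Carlo SE of a per-site pi estimate from its site contributions.

    The numerator is a compound-Poisson sum of per-site heterozygosities, so
    Var(sum) is estimated by the sum of squared contributions.
    """
    x = np.asarray(site_contributions, dtype=float)
    return float(np.sqrt((x**2).sum()) / L)


# ---------------------------------------------------------------------------
# Dataset generation
# ---------------------------------------------------------------------------

@dataclass
class SimConfig:
    """Study conditions for a two-population dataset.

    Defaults mirror the largest published chimpanzee contrast (N_e 60,000 vs
    10,000) at theta_L = 4 N_e mu ≈ 0.02, gamma_L = 4 N_e^L s = 5, ten
    diploids per population, and a genome of 80 gene cassettes spread over
    8 × 5 Mb chromosomes (≈ 9×10⁴ nonsynonymous and 1.5×10⁶ neutral sites),
    so 1-Mb blocks carry realistic site mixtures.
    """

    ne_large: int = 60_000
    ne_small: int = 10_000
    mu: float = 8.3e-8
    s: float = 5.0 / (4.0 * 60_000)
    gene_s: np.ndarray | None = None  # per-gene s; overrides the scalar
    n_diploids_large: int = 10
    n_diploids_small: int = 10
    n_chrom: int = 8
    genes_per_chrom: int = 10
    gene_spacing: int = 500_000
    intergenic_length: int = 13_750
    intron_length: int = 5_000
    cds_length: int = 1_500
    score_slope: float = 1.0
    score_noise_sd: float = 1.0
    score_threshold: float = 2.0
    expr_baseline: float = 4.0
    expr_slope: float = 1.2
    expr_noise_sd: float = 0.5
    seed: int = 1

    def __post_init__(self) -> None:
        if self.ne_large <= 0 or self.ne_small <= 0:
            raise ValueError("effective sizes must be positive")
        for ne in (self.ne_large, self.ne_small):
            if 4.0 * ne * self.mu >= 0.1:
                raise ValueError(
                    "4*Ne*mu must stay < 0.1 (infinite-sites regime)"
                )
        if 2 * self.n_diploids_large > 2 * self.ne_large:
            raise ValueError("sample size exceeds 2*Ne (large)")
        if 2 * self.n_diploids_small > 2 * self.ne_small:
            raise ValueError("sample size exceeds 2*Ne (small)")
        if self.cds_length % 12 != 0:
            raise ValueError("cds_length must be divisible by 12")
        cassette = self.intergenic_length + self.intron_length + self.cds_length
        if cassette > self.gene_spacing:
            raise ValueError("gene cassette does not fit in gene_spacing")
        if self.gene_s is not None:
            self.gene_s = np.asarray(self.gene_s, dtype=float)
            if len(self.gene_s) != self.n_genes:
                raise ValueError("gene_s must have one entry per gene")
            if np.any(self.gene_s < 0):
                raise ValueError("selection coefficients must be >= 0")

    @property
    def n_genes(self) -> int:
        return self.n_chrom * self.genes_per_chrom

    @property
    def chrom_length(self) -> int:
        return self.genes_per_chrom * self.gene_spacing

    def per_gene_s(self) -> np.ndarray:
        if self.gene_s is not None:
            return self.gene_s
        return np.full(self.n_genes, self.s)

    def theta(self, population: str) -> float:
        ne = self.ne_large if population == "large" else self.ne_small
        return 4.0 * ne * self.mu


@dataclass
class SimDataset:
    """In-memory synthetic dataset plus ground truth."""

    config: SimConfig
    variants: pd.DataFrame
    genotypes: dict[str, np.ndarray]
    populations: dict[str, list[str]]
    class_map: SiteClassMap
    genes: pd.DataFrame
    scores: dict[str, dict[int, float]]
    truth: dict = field(default_factory=dict)

    def write(self, outdir: str) -> dict[str, str]:
        """Write VCF/BED/TSV/JSON files; returns the path of each artifact."""
        os.makedirs(outdir, exist_ok=True)
        paths = {}
        contigs = {
            f"chr{i + 1}": self.config.chrom_length
            for i in range(self.config.n_chrom)
        }
        paths["vcf"] = os.path.join(outdir, "variants.vcf")
        write_vcf(
            paths["vcf"], self.variants, self.populations, self.genotypes, contigs
        )
        for cls in ("intron", "intergenic", "exome"):
            p = os.path.join(outdir, f"{cls}.bed")
            with open(p, "w") as fh:
                for chrom in sorted(self.class_map.intervals.get(cls, {})):
                    for s, e in self.class_map.intervals[cls][chrom]:
                        fh.write(f"{chrom}\t{s}\t{e}\n")
            paths[f"bed_{cls}"] = p
        paths["site_counts"] = os.path.join(outdir, "site_counts.tsv")
        with open(paths["site_counts"], "w") as fh:
            fh.write("site_class\tL\n")
            for cls, L in sorted(self.class_map.totals.items()):
                fh.write(f"{cls}\t{L}\n")
        paths["genes"] = os.path.join(outdir, "genes.tsv")
        self.genes.to_csv(paths["genes"], sep="\t", index=False)
        paths["scores"] = os.path.join(outdir, "scores.bedgraph")
        with open(paths["scores"], "w") as fh:
            for chrom in sorted(self.scores):
                for pos in sorted(self.scores[chrom]):
                    fh.write(f"{chrom}\t{pos}\t{pos + 1}\t{self.scores[chrom][pos]:.4f}\n")
        paths["expression"] = os.path.join(outdir, "expression.tsv")
        with open(paths["expression"], "w") as fh:
            fh.write("gene_id\texpression\n")
            for row in self.genes.itertuples(index=False):
                fh.write(f"{row.gene_id}\t{row.expression:.4f}\n")
        paths["truth"] = os.path.join(outdir, "truth.json")
        with open(paths["truth"], "w") as fh:
            json.dump(self.truth, fh, indent=1, default=_jsonable)
        return paths


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _gene_layout(config: SimConfig) -> pd.DataFrame:
    rows = []
    s_per_gene = config.per_gene_s()
    g = 0
    for ci in range(config.n_chrom):
        chrom = f"chr{ci + 1}"
        for k in range(config.genes_per_chrom):
            start = k * config.gene_spacing
            ig_s, ig_e = start, start + config.intergenic_length
            in_s, in_e = ig_e, ig_e + config.intron_length
            cds_s, cds_e = in_e, in_e + config.cds_length
            rows.append(
                {
                    "gene_id": f"g{g:04d}",
                    "chrom": chrom,
                    "intergenic_start": ig_s,
                    "intergenic_end": ig_e,
                    "intron_start": in_s,
                    "intron_end": in_e,
                    "cds_start": cds_s,
                    "cds_end": cds_e,
                    "s": s_per_gene[g],
                    "gamma_large": -4.0 * config.ne_large * s_per_gene[g],
                    "gamma_small": -4.0 * config.ne_small * s_per_gene[g],
                }
            )
            g += 1
    return pd.DataFrame(rows)


def _class_offsets(genes: pd.DataFrame, config: SimConfig):
    """Global 0-based offsets (per class) mapping a flat index to (chrom, pos)."""
    chrom_arr: dict[str, np.ndarray] = {}
    pos_arr: dict[str, np.ndarray] = {}
    gene_arr: dict[str, np.ndarray] = {}
    for cls, (cs, ce) in {
        "intergenic": ("intergenic_start", "intergenic_end"),
        "intron": ("intron_start", "intron_end"),
    }.items():
        chroms, poss, gids = [], [], []
        for row in genes.itertuples(index=False):
            span = np.arange(getattr(row, cs), getattr(row, ce), dtype=np.int64)
            poss.append(span)
            chroms.append(np.full(len(span), row.chrom, dtype=object))
            gids.append(np.full(len(span), row.gene_id, dtype=object))
        chrom_arr[cls] = np.concatenate(chroms)
        pos_arr[cls] = np.concatenate(poss)
        gene_arr[cls] = np.concatenate(gids)
    # CDS positions split deterministically: offset % 4 == 3 -> synonymous
    syn_p, syn_c, syn_g = [], [], []
    for row in genes.itertuples(index=False):
        span = np.arange(row.cds_start, row.cds_end, dtype=np.int64)
        syn_mask = (span - row.cds_start) % 4 == 3
        syn_p.append(span[syn_mask])
        syn_c.append(np.full(syn_mask.sum(), row.chrom, dtype=object))
        syn_g.append(np.full(syn_mask.sum(), row.gene_id, dtype=object))
    chrom_arr["synonymous"] = np.concatenate(syn_c)
    pos_arr["synonymous"] = np.concatenate(syn_p)
    gene_arr["synonymous"] = np.concatenate(syn_g)
    return chrom_arr, pos_arr, gene_arr


_BASES = np.array(list("ACGT"))


def generate_dataset(config: SimConfig, rng: np.random.Generator | None = None) -> SimDataset:
    """Simulate a two-population dataset with known per-gene selection truth."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    genes = _gene_layout(config)
    chrom_off, pos_off, gene_off = _class_offsets(genes, config)

    pops = {"large": config.n_diploids_large, "small": config.n_diploids_small}
    populations = {
        "large": [f"L{i + 1:02d}" for i in range(config.n_diploids_large)],
        "small": [f"S{i + 1:02d}" for i in range(config.n_diploids_small)],
    }
    ne = {"large": config.ne_large, "small": config.ne_small}

    parts: list[pd.DataFrame] = []
    doses: dict[str, list[np.ndarray]] = {"large": [], "small": []}

    def emit(pop, chroms, positions, freqs, site_class, gene_ids, effect):
        """Draw HW genotypes for `pop`, keep sample-segregating sites."""
        n_dip = pops[pop]
        other = "small" if pop == "large" else "large"
        dose = rng.binomial(2, freqs[:, None], size=(len(freqs), n_dip)).astype(np.int8)
        j = dose.sum(axis=1)
        keep = j > 0
        if not keep.any():
            return
        dose = dose[keep]
        part = pd.DataFrame(
            {
                "chrom": chroms[keep],
                "pos": positions[keep] + 1,  # to 1-based
                "site_class": site_class,
                "gene_id": gene_ids[keep] if gene_ids is not None else None,
                "effect": effect,
                f"j_{pop}": j[keep],
                f"n_{pop}": 2 * n_dip,
                f"j_{other}": 0,
                f"n_{other}": 2 * pops[other],
            }
        )
        parts.append(part)
        doses[pop].append(dose)
        doses[other].append(np.zeros((keep.sum(), pops[other]), dtype=np.int8))

    # --- neutral classes: one draw per (class, population), positions shared
    #     without replacement so the two populations never collide
    for cls, effect in (("intergenic", ""), ("intron", ""), ("synonymous", "synonymous_variant")):
        L = len(pos_off[cls])
        counts = {}
        freqs = {}
        for pop in pops:
            model = SfsModel(gamma=0.0, theta_site=config.theta(pop), ne=ne[pop])
            freqs[pop] = sample_population_frequencies(model, L, rng)
            counts[pop] = len(freqs[pop])
        total = counts["large"] + counts["small"]
        if total > L:
            raise ValueError(f"class {cls}: more segregating sites than positions")
        picks = rng.choice(L, size=total, replace=False)
        cut = counts["large"]
        for pop, sl in (("large", picks[:cut]), ("small", picks[cut:])):
            emit(
                pop,
                chrom_off[cls][sl],
                pos_off[cls][sl],
                freqs[pop],
                cls,
                gene_off[cls][sl],
                effect,
            )

    # --- nonsynonymous sites, gene by gene with gene-specific gamma
    for row in genes.itertuples(index=False):
        span = np.arange(row.cds_start, row.cds_end, dtype=np.int64)
        nonsyn = span[(span - row.cds_start) % 4 != 3]
        L = len(nonsyn)
        counts = {}
        freqs = {}
        for pop in pops:
            gamma = row.gamma_large if pop == "large" else row.gamma_small
            model = SfsModel(gamma=gamma, theta_site=config.theta(pop), ne=ne[pop])
            freqs[pop] = sample_population_frequencies(model, L, rng)
            counts[pop] = len(freqs[pop])
        total = counts["large"] + counts["small"]
        if total > L:
            raise ValueError(
                f"gene {row.gene_id}: more segregating sites than nonsynonymous positions"
            )
        picks = rng.choice(L, size=total, replace=False)
        cut = counts["large"]
        for pop, sl in (("large", picks[:cut]), ("small", picks[cut:])):
            emit(
                pop,
                np.full(len(sl), row.chrom, dtype=object),
                nonsyn[sl],
                freqs[pop],
                "nonsynonymous",
                np.full(len(sl), row.gene_id, dtype=object),
                "missense_variant",
            )

    variants = pd.concat(parts, ignore_index=True)
    geno = {p: np.concatenate(doses[p], axis=0) for p in pops}
    order = np.lexsort((variants["pos"].to_numpy(), variants["chrom"].to_numpy()))
    variants = variants.iloc[order].reset_index(drop=True)
    geno = {p: geno[p][order] for p in pops}

    ref_i = rng.integers(0, 4, len(variants))
    alt_i = (ref_i + rng.integers(1, 4, len(variants))) % 4
    variants.insert(2, "ref", _BASES[ref_i])
    variants.insert(3, "alt", _BASES[alt_i])

    # --- class map: physical intervals plus fractional CDS site totals
    intervals: dict[str, dict[str, list]] = {"intergenic": {}, "intron": {}, "exome": {}}
    for row in genes.itertuples(index=False):
        intervals["intergenic"].setdefault(row.chrom, []).append(
            (row.intergenic_start, row.intergenic_end)
        )
        intervals["intron"].setdefault(row.chrom, []).append(
            (row.intron_start, row.intron_end)
        )
        intervals["exome"].setdefault(row.chrom, []).append((row.cds_start, row.cds_end))
    interval_arrays = {
        cls: {c: np.array(iv, dtype=np.int64) for c, iv in by.items()}
        for cls, by in intervals.items()
    }
    L_syn = len(pos_off["synonymous"])
    L_nonsyn = config.n_genes * config.cds_length - L_syn
    class_map = SiteClassMap(
        interval_arrays,
        totals={"nonsynonymous": float(L_nonsyn), "synonymous": float(L_syn)},
    )

    # --- synthetic conservation scores over CDS positions and expression
    scores: dict[str, dict[int, float]] = {}
    expr = np.empty(len(genes))
    for gi, row in enumerate(genes.itertuples(index=False)):
        strength = np.log1p(abs(row.gamma_large))
        span = np.arange(row.cds_start, row.cds_end)
        vals = config.score_slope * strength + rng.normal(
            0.0, config.score_noise_sd, len(span)
        )
        chrom_map = scores.setdefault(row.chrom, {})
        chrom_map.update(zip(span.tolist(), vals.tolist()))
        expr[gi] = (
            config.expr_baseline
            + config.expr_slope * strength
            + rng.normal(0.0, config.expr_noise_sd)
        )
    genes = genes.copy()
    genes["expression"] = expr

    # --- ground truth
    r_large = np.array([expected_pi_reduction(g) for g in genes["gamma_large"]])
    r_small = np.array([expected_pi_reduction(g) for g in genes["gamma_small"]])
    truth = {
        "config": {
            k: (v.tolist() if isinstance(v, np.ndarray) else v)
            for k, v in dataclasses.asdict(config).items()
        },
        "theta": {p: config.theta(p) for p in pops},
        "gamma_large": genes["gamma_large"].tolist(),
        "gamma_small": genes["gamma_small"].tolist(),
        "expected_pi": {
            p: {
                "neutral": config.theta(p),
                "nonsynonymous": config.theta(p)
                * float((r_large if p == "large" else r_small).mean()),
            }
            for p in pops
        },
        "theoretical_delta": 1.0 - float(r_large.mean()) / float(r_small.mean()),
    }

    return SimDataset(
        config=config,
        variants=variants,
        genotypes=geno,
        populations=populations,
        class_map=class_map,
        genes=genes,
        scores=scores,
        truth=truth,
    )
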