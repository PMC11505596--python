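"""The excess fraction of constrained-site heterozygosity in small populations.

Within each population, ω = π_C/π_N compares diversity at constrained sites
(nonsynonymous, exome) with diversity at putatively neutral sites (intron by
default; synonymous and distal-intergenic are selectable alternatives).
Under neutrality the ratio is the same in a large and a small population;
purifying selection, being less effective at small N_e, leaves an excess of
segregating deleterious variants in the small population, so empirically
ω_S > ω_L.  The excess fraction

    delta = 1 - omega_L / omega_S,        delta% = 100 * (omega_S - omega_L) / omega_S

is the proportion of the small population's constrained-site heterozygosity
attributable to that excess.  Equivalently, writing R_C and R_N for the
large/small ratios of constrained and neutral diversity, delta = 1 - R_C/R_N.

delta is reported signed: a negative value (omega_L > omega_S) is flagged,
not clipped, since the inequality is an empirical expectation rather than a
constraint.  Standard errors come from a joint block bootstrap: one block
resample per replicate is shared by all four diversities entering delta, so
the covariance between classes and populations is preserved.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .diversity import DEFAULT_B, BlockIndex, block_bootstrap
from .formats_io import SiteClassMap, merge_intervals


@dataclass
class ExcessEstimate:
    """omega_L, omega_S, delta and delta% for one large/small comparison."""

    large_pop: str
    small_pop: str
    constrained_class: str
    neutral_class: str
    omega_L: float
    omega_S: float
    delta: float
    se_delta: float | None = None
    flags: list[str] = field(default_factory=list)

    @property
    def delta_percent(self) -> float:
        return 100.0 * self.delta


def omega(pi_C: float, pi_N: float) -> float:
    """Constrained-to-neutral diversity ratio pi_C / pi_N within one population."""
    if pi_N <= 0:
        raise ValueError("neutral diversity is zero")
    if pi_C < 0:
        raise ValueError("constrained diversity must be >= 0")
    return pi_C / pi_N


def delta(
    omega_L: float,
    omega_S: float,
    large_pop: str = "large",
    small_pop: str = "small",
    constrained_class: str = "nonsynonymous",
    neutral_class: str = "intron",
) -> ExcessEstimate:
    """Excess fraction delta = 1 - omega_L/omega_S from the two within-population ratios."""
    if omega_S <= 0:
        raise ValueError("omega_S must be > 0")
    d = 1.0 - omega_L / omega_S
    flags = ["negative_delta"] if d < 0 else []
    return ExcessEstimate(
        large_pop=large_pop,
        small_pop=small_pop,
        constrained_class=constrained_class,
        neutral_class=neutral_class,
        omega_L=omega_L,
        omega_S=omega_S,
        delta=d,
        flags=flags,
    )


def delta_from_class_ratios(R_C: float, R_N: float) -> float:
    """delta from cross-population ratios instead of within-population ones.

    With R_C = pi_CL/pi_CS and R_N = pi_NL/pi_NS (large over small),
    omega_L/omega_S = R_C/R_N, so delta = 1 - R_C/R_N.  Agrees with
    :func:`delta` to machine precision when both are computable from the same
    four diversities.
    """
    if R_N <= 0:
        raise ValueError("R_N must be > 0")
    if R_C <= 0:
        raise ValueError("R_C must be > 0")
    return 1.0 - R_C / R_N


def delta_from_pi(
    pi_CL: float, pi_NL: float, pi_CS: float, pi_NS: float, **kwargs
) -> ExcessEstimate:
    """delta from the four per-(population, class) diversities."""
    return delta(omega(pi_CL, pi_NL), omega(pi_CS, pi_NS), **kwargs)


def excess_with_bootstrap(
    blocks: BlockIndex,
    large_pop: str,
    small_pop: str,
    constrained_class: str = "nonsynonymous",
    neutral_class: str = "intron",
    B: int = DEFAULT_B,
    seed: int = 1,
) -> ExcessEstimate:
    """Point estimate of delta plus a joint block-bootstrap standard error.

    Each replicate draws one multiset of blocks shared by all four
    (population, class) diversities and recomputes delta from ratio-of-sums;
    replicates with a zero neutral sum or zero omega_S are recorded missing
    per the bootstrap contract.
    """
    num_CL = blocks.numerators(large_pop, constrained_class)
    num_NL = blocks.numerators(large_pop, neutral_class)
    num_CS = blocks.numerators(small_pop, constrained_class)
    num_NS = blocks.numerators(small_pop, neutral_class)
    den_C = blocks.class_lengths(constrained_class)
    den_N = blocks.class_lengths(neutral_class)
    if den_C.sum() <= 0 or den_N.sum() <= 0:
        raise ValueError("both classes need positive callable-site totals")

    def delta_of(idx: np.ndarray) -> float:
        dC, dN = den_C[idx].sum(), den_N[idx].sum()
        if dC <= 0 or dN <= 0:
            return np.nan
        pi_CL, pi_NL = num_CL[idx].sum() / dC, num_NL[idx].sum() / dN
        pi_CS, pi_NS = num_CS[idx].sum() / dC, num_NS[idx].sum() / dN
        if pi_NL <= 0 or pi_NS <= 0 or pi_CL <= 0:
            return np.nan
        return 1.0 - (pi_CL / pi_NL) / (pi_CS / pi_NS)

    full = np.arange(blocks.n_blocks)
    pi_CL = num_CL.sum() / den_C.sum()
    pi_NL = num_NL.sum() / den_N.sum()
    pi_CS = num_CS.sum() / den_C.sum()
    pi_NS = num_NS.sum() / den_N.sum()
    est = delta_from_pi(
        pi_CL,
        pi_NL,
        pi_CS,
        pi_NS,
        large_pop=large_pop,
        small_pop=small_pop,
        constrained_class=constrained_class,
        neutral_class=neutral_class,
    )
    se, _ = block_bootstrap(blocks, delta_of, B=B, seed=seed)
    est.se_delta = se
    # sanity: point estimate equals the statistic on the identity resample
    assert np.isclose(est.delta, delta_of(full), rtol=1e-12, atol=1e-12)
    return est


def distal_intergenic_map(
    class_map: SiteClassMap,
    gene_spans: dict[str, np.ndarray],
    distance: int = 1_000_000,
) -> SiteClassMap:
    """Restrict the intergenic class to sites >= ``distance`` from any gene.

    ``gene_spans`` maps chromosome -> (k, 2) gene extents (0-based half-open).
    Returns a new map whose ``intergenic`` intervals exclude everything within
    ``distance`` of a gene span, for use as a neutral reference free of
    background selection from linked constrained sites.
    """
    new_intervals = {
        cls: {c: iv.copy() for c, iv in by_chrom.items()}
        for cls, by_chrom in class_map.intervals.items()
    }
    out: dict[str, np.ndarray] = {}
    for chrom, iv in class_map.intervals.get("intergenic", {}).items():
        spans = gene_spans.get(chrom)
        if spans is None or len(spans) == 0:
            out[chrom] = iv
            continue
        buffered = merge_intervals(
            np.column_stack(
                [np.maximum(spans[:, 0] - distance, 0), spans[:, 1] + distance]
            )
        )
        kept: list[tuple[int, int]] = []
        for s, e in iv:
            cur = s
            for bs, be in buffered:
                if be <= cur or bs >= e:
                    continue
                if bs > cur:
                    kept.append((cur, min(bs, e)))
                cur = max(cur, be)
                if cur >= e:
                    break
            if cur < e:
                kept.append((cur, e))
        if kept:
            out[chrom] = np.array(kept, dtype=np.int64)
    new_intervals["intergenic"] = out
    totals = {
        cls: L for cls, L in class_map.totals.items() if cls != "intergenic"
    }
    return SiteClassMap(new_intervals, totals)
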