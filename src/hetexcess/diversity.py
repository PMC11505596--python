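"""Nucleotide diversity per (population, site class) with block-bootstrap errors.

Heterozygosity is Tajima's mean number of pairwise differences per site: at a
biallelic site with j alternate alleles among n called chromosomes the
unbiased per-site contribution is

    h(j, n) = 2 j (n - j) / (n (n - 1)),

the fraction of chromosome pairs that differ at the site, and the class
estimate is the sum of h over the class's SNVs divided by the class's callable
site total L_c (monomorphic callable sites contribute only to the
denominator).  Standard errors come from a block bootstrap that resamples
1-Mb genomic windows with replacement, recomputing each replicate as a
ratio of pooled sums so the statistic stays stable when a resample is sparse
in one class.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .formats_io import SiteClassMap

logger = logging.getLogger(__name__)

DEFAULT_BLOCK_SIZE = 1_000_000
DEFAULT_B = 1000
#: sites with fewer called chromosomes than this in any population are
#: excluded from pi (the per-site estimator's variance explodes at tiny n)
MIN_CALLED = 4

#: querying the "exome" class pools these labels
_EXOME_UNION = ("nonsynonymous", "synonymous", "exome")


@dataclass
class DiversityEstimate:
    """pi for one (population, site class)."""

    population: str
    site_class: str
    pi: float
    n_snvs: int
    L: float
    se: float | None = None
    B: int | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.L <= 0:
            raise ValueError("L must be > 0")
        if self.pi < 0:
            raise ValueError("pi must be >= 0")


def site_pi(j, n):
    """Per-site heterozygosity 2 j (n-j) / (n (n-1)); accepts arrays."""
    j = np.asarray(j, dtype=np.float64)
    n = np.asarray(n, dtype=np.float64)
    if np.any(n < 2):
        raise ValueError("site_pi requires n >= 2 called chromosomes")
    if np.any((j < 0) | (j > n)):
        raise ValueError("require 0 <= j <= n")
    out = 2.0 * j * (n - j) / (n * (n - 1.0))
    return float(out) if out.ndim == 0 else out


def _class_mask(table: pd.DataFrame, site_class: str) -> np.ndarray:
    if site_class == "exome":
        return table["site_class"].isin(_EXOME_UNION).to_numpy()
    return (table["site_class"] == site_class).to_numpy()


def _called_ok(table: pd.DataFrame, min_called: int) -> np.ndarray:
    """Sites with n >= min_called in every population carried by the table."""
    ok = np.ones(len(table), dtype=bool)
    for col in table.columns:
        if col.startswith("n_"):
            ok &= table[col].to_numpy() >= min_called
    return ok


def class_pi(
    table: pd.DataFrame,
    site_class: str,
    L_c: float,
    population: str,
    min_called: int = MIN_CALLED,
) -> DiversityEstimate:
    """Tajima's pi for one population over one site class.

    ``table`` is a variant table (see ``formats_io.read_vcf_table``) with
    ``site_class`` already assigned; ``L_c`` is the callable-site denominator.
    """
    if L_c <= 0:
        raise ValueError("L_c must be > 0")
    jcol, ncol = f"j_{population}", f"n_{population}"
    if jcol not in table.columns:
        raise ValueError(f"population {population!r} not in variant table")
    if site_class not in set(table["site_class"]) and site_class not in (
        "exome",
        *_EXOME_UNION,
        "intron",
        "intergenic",
    ):
        raise ValueError(f"site class {site_class!r} absent from variant table")
    mask = _class_mask(table, site_class) & _called_ok(table, min_called)
    sub = table.loc[mask]
    j = sub[jcol].to_numpy()
    n = sub[ncol].to_numpy()
    total = float(site_pi(j, n).sum()) if len(sub) else 0.0
    return DiversityEstimate(
        population=population,
        site_class=site_class,
        pi=total / L_c,
        n_snvs=int((j > 0).sum() if len(sub) else 0),
        L=float(L_c),
    )


class BlockIndex:
    """Variants and per-class callable lengths partitioned into genomic blocks.

    ``block_of`` maps each variant row to its block ordinal; ``lengths`` is a
    (n_blocks, n_classes) frame of callable sites apportioned to each block by
    interval intersection.  Every variant belongs to exactly one block and the
    per-class block lengths sum to L_c.
    """

    def __init__(
        self,
        table: pd.DataFrame,
        block_of: np.ndarray,
        blocks: list[tuple[str, int]],
        lengths: pd.DataFrame,
        block_size: int,
        min_called: int = MIN_CALLED,
    ):
        self.table = table
        self.block_of = block_of
        self.blocks = blocks
        self.lengths = lengths
        self.block_size = block_size
        self.min_called = min_called

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    def populations(self) -> list[str]:
        return [c[2:] for c in self.table.columns if c.startswith("j_")]

    def numerators(self, population: str, site_class: str) -> np.ndarray:
        """Per-block sums of site heterozygosity for one (population, class)."""
        if len(self.table) == 0:
            return np.zeros(self.n_blocks)
        mask = _class_mask(self.table, site_class) & _called_ok(
            self.table, self.min_called
        )
        w = np.zeros(len(self.table))
        j = self.table[f"j_{population}"].to_numpy()[mask]
        n = self.table[f"n_{population}"].to_numpy()[mask]
        w[mask] = site_pi(j, n)
        return np.bincount(self.block_of, weights=w, minlength=self.n_blocks)

    def class_lengths(self, site_class: str) -> np.ndarray:
        # the exome column, when present, already spans the full CDS; the
        # nonsynonymous/synonymous columns are its fractional split
        if site_class == "exome" and (
            "exome" not in self.lengths.columns or self.lengths["exome"].sum() == 0
        ):
            cols = [
                c for c in ("nonsynonymous", "synonymous")
                if c in self.lengths.columns
            ]
            return self.lengths[cols].sum(axis=1).to_numpy()
        return self.lengths[site_class].to_numpy()


def partition_blocks(
    table: pd.DataFrame,
    class_map: SiteClassMap,
    block_size: int = DEFAULT_BLOCK_SIZE,
    min_called: int = MIN_CALLED,
) -> BlockIndex:
    """Partition variants and class intervals into fixed-width genomic blocks.

    A variant at 1-based position ``pos`` goes to block ``floor((pos-1) /
    block_size)`` on its chromosome; class interval lengths are apportioned to
    blocks by intersection.  Classes whose totals were overridden (fractional
    site counts) get each block's share scaled so the blocks still sum to L_c.
    """
    if block_size <= 0:
        raise ValueError("block_size must be > 0")

    # interval-derived block keys first so empty blocks with length still exist
    iv_chrom: list[str] = []
    iv_ord: list[int] = []
    iv_cls: list[str] = []
    iv_len: list[float] = []
    for cls, by_chrom in class_map.intervals.items():
        for chrom, iv in by_chrom.items():
            for s, e in iv:
                b0, b1 = int(s // block_size), int((e - 1) // block_size)
                for b in range(b0, b1 + 1):
                    lo = max(s, b * block_size)
                    hi = min(e, (b + 1) * block_size)
                    iv_chrom.append(chrom)
                    iv_ord.append(b)
                    iv_cls.append(cls)
                    iv_len.append(float(hi - lo))

    if len(table):
        pos0 = table["pos"].to_numpy(dtype=np.int64) - 1
        var_chrom = table["chrom"].to_numpy()
        var_ord = pos0 // block_size
    else:
        var_chrom = np.array([], dtype=object)
        var_ord = np.array([], dtype=np.int64)

    all_chrom = np.concatenate([np.asarray(iv_chrom, dtype=object), var_chrom])
    all_ord = np.concatenate([np.asarray(iv_ord, dtype=np.int64), var_ord])
    chrom_codes, chrom_names = pd.factorize(all_chrom)
    span = int(all_ord.max()) + 1 if len(all_ord) else 1
    composite = chrom_codes.astype(np.int64) * span + all_ord
    uniq, inverse = np.unique(composite, return_inverse=True)
    block_of = inverse[len(iv_chrom):].astype(np.intp)

    blocks = [
        (str(chrom_names[int(c // span)]), int(c % span)) for c in uniq
    ]
    lengths = pd.DataFrame(
        0.0, index=range(len(uniq)), columns=sorted(class_map.totals)
    )
    iv_block = inverse[: len(iv_chrom)]
    for cls in set(iv_cls):
        m = np.asarray(iv_cls) == cls
        lengths[cls] = np.bincount(
            iv_block[m], weights=np.asarray(iv_len)[m], minlength=len(uniq)
        )
    # rescale to externally supplied totals (e.g. fractional NG86 counts)
    for cls in class_map.totals:
        interval_sum = lengths[cls].sum() if cls in lengths.columns else 0.0
        target = class_map.totals[cls]
        if interval_sum > 0 and not np.isclose(interval_sum, target):
            lengths[cls] *= target / interval_sum
        elif interval_sum == 0 and target > 0:
            # class with totals but no intervals of its own (synonymous /
            # nonsynonymous counts living on exome intervals): spread in
            # proportion to the exome block lengths
            if "exome" in lengths.columns and lengths["exome"].sum() > 0:
                lengths[cls] = lengths["exome"] * (target / lengths["exome"].sum())
            elif len(lengths):
                lengths[cls] = target / len(lengths)

    return BlockIndex(table, block_of, blocks, lengths, block_size, min_called)


def block_bootstrap(
    blocks: BlockIndex | int,
    statistic: Callable[[np.ndarray], float],
    B: int = DEFAULT_B,
    seed: int = 1,
    max_missing: float = 0.10,
) -> tuple[float, np.ndarray]:
    """Standard error of a block statistic by resampling blocks with replacement.

    ``statistic`` receives an integer array of resampled block indices (a
    multiset of size n_blocks) and must return the statistic recomputed on the
    pooled resample — sum numerators and denominators before dividing.
    Replicates on which the statistic is undefined (raise, or return NaN) are
    recorded as missing and excluded from the SE; more than ``max_missing`` of
    them is an error.  Identical seeds give identical output.
    """
    n_blocks = blocks.n_blocks if isinstance(blocks, BlockIndex) else int(blocks)
    if n_blocks < 2:
        raise ValueError("block bootstrap requires at least 2 blocks")
    if B < 2:
        raise ValueError("B must be >= 2")
    rng = np.random.default_rng(seed)
    reps = np.empty(B)
    for b in range(B):
        idx = rng.integers(0, n_blocks, n_blocks)
        try:
            reps[b] = statistic(idx)
        except (ZeroDivisionError, FloatingPointError, ValueError):
            reps[b] = np.nan
    missing = int(np.isnan(reps).sum())
    if missing:
        logger.info("block bootstrap: %d of %d replicates undefined", missing, B)
    if missing > max_missing * B:
        raise ValueError(
            f"statistic undefined on {missing}/{B} bootstrap replicates"
        )
    valid = reps[~np.isnan(reps)]
    se = float(np.std(valid, ddof=1))
    return se, reps


def class_pi_with_bootstrap(
    blocks: BlockIndex,
    site_class: str,
    population: str,
    L_c: float | None = None,
    B: int = DEFAULT_B,
    seed: int = 1,
) -> DiversityEstimate:
    """:func:`class_pi` plus a block-bootstrap standard error."""
    num = blocks.numerators(population, site_class)
    den = blocks.class_lengths(site_class)
    total_L = float(den.sum()) if L_c is None else float(L_c)
    est = class_pi(
        blocks.table, site_class, total_L, population, blocks.min_called
    )

    scale = total_L / den.sum() if den.sum() > 0 else 1.0

    def stat(idx: np.ndarray) -> float:
        d = den[idx].sum() * scale
        if d <= 0:
            return np.nan
        return num[idx].sum() / d

    se, _ = block_bootstrap(blocks, stat, B=B, seed=seed)
    est.se, est.B, est.seed = se, B, seed
    return est


def diversity_table(
    blocks: BlockIndex,
    class_totals: dict[str, float],
    populations: Sequence[str] | None = None,
    B: int = DEFAULT_B,
    seed: int = 1,
) -> pd.DataFrame:
    """Per-(population, class) diversity table with bootstrap SEs."""
    pops = list(populations) if populations is not None else blocks.populations()
    rows = []
    for pop in pops:
        for cls, L in sorted(class_totals.items()):
            if L <= 0:
                continue
            est = class_pi_with_bootstrap(blocks, cls, pop, L_c=L, B=B, seed=seed)
            rows.append(
                {
                    "population": est.population,
                    "site_class": est.site_class,
                    "n_snvs": est.n_snvs,
                    "L": est.L,
                    "pi": est.pi,
                    "se": est.se,
                    "B": est.B,
                    "seed": est.seed,
                }
            )
    return pd.DataFrame(rows)
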