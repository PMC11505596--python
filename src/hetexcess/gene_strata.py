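"""Gene stratification by selective constraint or expression.

Genes are ranked by a stratifier — the proportion of CDS sites with a
conservation (PhyloP-style) score above a threshold (default 2.0), or the
log-mean expression level — and cut into equal-count strata (default 1000
genes per stratum, the remainder in the last).  Per stratum, nonsynonymous
and intron diversities are computed over that stratum's genes only and
combined into delta%, and the trend of delta% against the stratifier is
tested with a permutation Spearman rank correlation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .excess import delta_from_pi
from .formats_io import GeneRecord

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLD = 2.0
DEFAULT_BIN_SIZE = 1000
DEFAULT_N_PERM = 99_999


@dataclass
class StratumResult:
    ordinal: int
    n_genes: int
    mean_stratifier: float
    pi_constrained_large: float
    pi_constrained_small: float
    pi_neutral_large: float
    pi_neutral_small: float
    delta_percent: float | None
    se: float | None = None


@dataclass
class SpearmanResult:
    rho: float
    p_value: float  # permutation p, add-one corrected
    p_t: float  # t-approximation, reported alongside
    n: int
    n_perm: int


def gene_constraint_proportion(
    gene: GeneRecord,
    scores: dict[str, dict[int, float]],
    threshold: float = DEFAULT_THRESHOLD,
) -> float:
    """Fraction of a gene's CDS positions with score strictly > threshold.

    Positions lacking a score stay in the denominator and count as
    non-constrained; the score coverage fraction is logged.
    """
    if gene.cds_length <= 0:
        raise ValueError(f"gene {gene.gene_id}: zero-length CDS")
    chrom_scores = scores.get(gene.chrom, {})
    n_scored = 0
    n_constrained = 0
    total = 0
    for s, e in gene.cds:
        for p in range(int(s), int(e)):
            total += 1
            sc = chrom_scores.get(p)
            if sc is not None:
                n_scored += 1
                if sc > threshold:
                    n_constrained += 1
    if n_scored < total:
        logger.info(
            "gene %s: score coverage %.3f (%d/%d CDS positions)",
            gene.gene_id,
            n_scored / total,
            n_scored,
            total,
        )
    return n_constrained / total


def equal_count_bins(
    stratifier: pd.Series, bin_size: int = DEFAULT_BIN_SIZE
) -> pd.Series:
    """Assign genes to equal-count strata, ascending in the stratifier.

    ``stratifier`` is indexed by gene id.  Ties are broken by gene id so the
    partition is deterministic.  The number of strata is the gene count
    divided by ``bin_size``, rounded to the nearest integer, and genes are
    split as evenly as possible — so 14,870 genes at bin size 1000 give 15
    strata and 9,089 give 9, matching how "1000 genes per category" plays
    out when the total is not a multiple of the bin size.  Fewer genes than
    half a bin yields a single stratum with a warning.
    """
    if bin_size < 2:
        raise ValueError("bin_size must be >= 2")
    order = stratifier.sort_index().sort_values(kind="mergesort")
    n = len(order)
    n_strata = max(1, int(np.floor(n / bin_size + 0.5)))
    if n_strata == 1 and n < bin_size:
        logger.warning(
            "only %d genes for bin size %d: single stratum", n, bin_size
        )
    strata = np.concatenate(
        [np.full(len(chunk), i) for i, chunk in enumerate(np.array_split(np.arange(n), n_strata))]
    )
    return pd.Series(strata, index=order.index, name="stratum")


def stratum_delta(
    gene_ids: list[str],
    variants: pd.DataFrame,
    gene_site_counts: pd.DataFrame,
    large_pop: str,
    small_pop: str,
    constrained_class: str = "nonsynonymous",
    neutral_class: str = "intron",
    min_called: int = 4,
) -> tuple[float | None, dict[str, float]]:
    """delta% over one stratum of genes, with the four underlying diversities.

    Constrained SNVs and site counts are summed over the stratum's CDS, and
    neutral (intron) SNVs and lengths over the stratum's genes' introns, so
    each stratum gets its own neutral reference.  ``gene_site_counts`` is
    indexed by gene id with columns ``L_<class>``.  A stratum whose neutral
    diversity is zero in either population is reported missing (None), never
    fabricated.
    """
    ids = set(gene_ids)
    sub = variants[variants["gene_id"].isin(ids)]
    counts = gene_site_counts.loc[gene_site_counts.index.isin(ids)]
    L_C = float(counts[f"L_{constrained_class}"].sum())
    L_N = float(counts[f"L_{neutral_class}"].sum())
    if L_C <= 0 or L_N <= 0:
        return None, {}

    def pool_pi(pop: str, cls: str, L: float) -> float:
        rows = sub[sub["site_class"] == cls]
        ok = np.ones(len(rows), dtype=bool)
        for col in rows.columns:
            if col.startswith("n_"):
                ok &= rows[col].to_numpy() >= min_called
        rows = rows.loc[ok]
        j = rows[f"j_{pop}"].to_numpy(dtype=float)
        n = rows[f"n_{pop}"].to_numpy(dtype=float)
        if len(rows) == 0:
            return 0.0
        return float((2.0 * j * (n - j) / (n * (n - 1.0))).sum()) / L

    pis = {
        "pi_constrained_large": pool_pi(large_pop, constrained_class, L_C),
        "pi_constrained_small": pool_pi(small_pop, constrained_class, L_C),
        "pi_neutral_large": pool_pi(large_pop, neutral_class, L_N),
        "pi_neutral_small": pool_pi(small_pop, neutral_class, L_N),
    }
    if pis["pi_neutral_large"] <= 0 or pis["pi_neutral_small"] <= 0:
        return None, pis
    est = delta_from_pi(
        pis["pi_constrained_large"],
        pis["pi_neutral_large"],
        pis["pi_constrained_small"],
        pis["pi_neutral_small"],
        large_pop=large_pop,
        small_pop=small_pop,
        constrained_class=constrained_class,
        neutral_class=neutral_class,
    )
    return est.delta_percent, pis


def stratified_excess(
    strata: pd.Series,
    stratifier: pd.Series,
    variants: pd.DataFrame,
    gene_site_counts: pd.DataFrame,
    large_pop: str,
    small_pop: str,
    constrained_class: str = "nonsynonymous",
    neutral_class: str = "intron",
) -> pd.DataFrame:
    """Per-stratum table of diversities, delta%, and the mean stratifier value."""
    rows = []
    for ordinal in sorted(strata.unique()):
        ids = list(strata.index[strata == ordinal])
        d_pct, pis = stratum_delta(
            ids,
            variants,
            gene_site_counts,
            large_pop,
            small_pop,
            constrained_class,
            neutral_class,
        )
        rows.append(
            {
                "stratum": int(ordinal),
                "n_genes": len(ids),
                "mean_stratifier": float(stratifier.loc[ids].mean()),
                **pis,
                "delta_percent": d_pct,
            }
        )
    return pd.DataFrame(rows)


def spearman(
    x,
    y,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 1,
) -> SpearmanResult:
    """Spearman rank correlation with a two-sided permutation p-value.

    rho is the Pearson correlation of average ranks (ties averaged); the
    permutation p permutes y against x with an add-one correction, so
    p >= 1/(n_perm + 1).  The parametric t-approximation is reported
    alongside.  rho is invariant under strictly monotone transforms of
    either variable.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-d arrays")
    n = len(x)
    if n < 4:
        raise ValueError("need at least 4 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("rho undefined for constant x or y")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])

    rng = np.random.default_rng(seed)
    perm = rng.permuted(np.broadcast_to(ry, (n_perm, n)).copy(), axis=1)
    rxc = rx - rx.mean()
    pc = perm - perm.mean(axis=1, keepdims=True)
    rho_perm = (pc @ rxc) / np.sqrt((pc**2).sum(axis=1) * (rxc**2).sum())
    p_perm = (np.sum(np.abs(rho_perm) >= abs(rho) - 1e-12) + 1) / (n_perm + 1)

    if abs(rho) >= 1.0:
        p_t = 0.0
    else:
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
        p_t = float(2 * stats.t.sf(abs(t), df=n - 2))
    return SpearmanResult(rho=rho, p_value=float(p_perm), p_t=p_t, n=n, n_perm=n_perm)


def assign_gene_ids(
    variants: pd.DataFrame,
    genes: pd.DataFrame,
) -> pd.DataFrame:
    """Tag coding and intron variants with the gene whose intervals contain them.

    ``genes`` needs columns chrom, cds_start, cds_end, intron_start,
    intron_end (single-interval genes).  Variants outside every gene get
    gene_id None.
    """
    variants = variants.copy()
    gene_id = np.full(len(variants), None, dtype=object)
    pos0 = variants["pos"].to_numpy(dtype=np.int64) - 1
    for chrom, sub in genes.groupby("chrom"):
        m = (variants["chrom"] == chrom).to_numpy()
        if not m.any():
            continue
        p = pos0[m]
        assigned = np.full(p.shape, None, dtype=object)
        for col_s, col_e in (("cds_start", "cds_end"), ("intron_start", "intron_end")):
            starts = sub[col_s].to_numpy(dtype=np.int64)
            order = np.argsort(starts)
            starts = starts[order]
            ends = sub[col_e].to_numpy(dtype=np.int64)[order]
            ids = sub["gene_id"].to_numpy()[order]
            k = np.searchsorted(starts, p, side="right") - 1
            ok = (k >= 0) & (assigned == None)  # noqa: E711
            ok[ok] &= p[ok] < ends[k[ok]]
            assigned[ok] = ids[k[ok]]
        gene_id[m] = assigned
    variants["gene_id"] = gene_id
    return variants
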