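"""Readers/writers for the standard formats the pipeline touches.

VCF genotypes come in through :func:`read_vcf` (cyvcf2), interval class maps
through BED, per-base conservation scores through bedGraph-like tables, and
expression through two-column TSV.  Coordinates follow the named standards:
VCF positions are 1-based; BED intervals and all internal interval arithmetic
are 0-based half-open.

Synonymous/nonsynonymous status of a coding SNV is taken from an annotation
tag carried by the VCF (mirroring an upstream effect-annotation step such as
SnpEff); this module never re-derives codon effects from coordinates.  What it
does provide is Nei--Gojobori (1986) counting of synonymous and nonsynonymous
*sites* in a CDS, which supplies the per-class denominators for diversity.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

logger = logging.getLogger(__name__)

SITE_CLASSES = (
    "nonsynonymous",
    "synonymous",
    "intron",
    "intergenic",
    "exome",
    "unassigned",
)

#: default pattern for chromosome names that are *not* autosomes
AUTOSOME_EXCLUDE = r"^(chr)?(x|y|m|mt|w|z)$"

#: effect-annotation strings accepted for coding SNVs, mapped to site classes
CODING_EFFECTS = {
    "missense_variant": "nonsynonymous",
    "missense": "nonsynonymous",
    "nonsynonymous": "nonsynonymous",
    "stop_gained": "nonsynonymous",
    "stop_lost": "nonsynonymous",
    "start_lost": "nonsynonymous",
    "synonymous_variant": "synonymous",
    "synonymous": "synonymous",
    "stop_retained_variant": "synonymous",
}

_ACGT = frozenset("ACGT")


@dataclass
class VariantRecord:
    """One biallelic SNV with per-population allele counts.

    ``alt_count[p]`` (j) is the number of alternate alleles observed among the
    ``called[p]`` (n) called chromosomes of population ``p``; missing genotypes
    reduce n rather than dropping the site.
    """

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    alt_count: dict[str, int]
    called: dict[str, int]
    site_class: str = "unassigned"
    gene_id: str | None = None

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError(f"ref == alt at {self.chrom}:{self.pos}")
        if len(self.ref) != 1 or len(self.alt) != 1:
            raise ValueError(f"not a SNV at {self.chrom}:{self.pos}")
        for pop, j in self.alt_count.items():
            n = self.called[pop]
            if not (0 <= j <= n):
                raise ValueError(
                    f"allele count j={j} outside [0, n={n}] for population "
                    f"{pop!r} at {self.chrom}:{self.pos}"
                )
        if self.site_class not in SITE_CLASSES:
            raise ValueError(f"unknown site class {self.site_class!r}")


@dataclass
class GeneRecord:
    """A protein-coding gene: CDS intervals plus optional stratifier values."""

    gene_id: str
    chrom: str
    cds: np.ndarray  # (k, 2) 0-based half-open
    introns: np.ndarray | None = None
    constraint_prop: float | None = None
    expression: float | None = None

    def __post_init__(self) -> None:
        self.cds = np.asarray(self.cds, dtype=np.int64).reshape(-1, 2)
        if self.cds_length <= 0:
            raise ValueError(f"gene {self.gene_id}: CDS length must be > 0")
        if self.constraint_prop is not None and not 0 <= self.constraint_prop <= 1:
            raise ValueError(f"gene {self.gene_id}: constraint_prop outside [0,1]")

    @property
    def cds_length(self) -> int:
        return int((self.cds[:, 1] - self.cds[:, 0]).sum())


def merge_intervals(intervals: np.ndarray) -> np.ndarray:
    """Sort and merge overlapping/adjacent-overlapping 0-based half-open intervals."""
    iv = np.asarray(intervals, dtype=np.int64).reshape(-1, 2)
    if iv.size == 0:
        return iv
    if np.any(iv[:, 1] <= iv[:, 0]):
        bad = iv[iv[:, 1] <= iv[:, 0]][0]
        raise ValueError(f"interval with end <= start: [{bad[0]}, {bad[1]})")
    iv = iv[np.lexsort((iv[:, 1], iv[:, 0]))]
    out = [iv[0].copy()]
    for s, e in iv[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append(np.array([s, e]))
    return np.array(out, dtype=np.int64)


class SiteClassMap:
    """Genomic intervals per site class plus callable-site totals L_c.

    Intervals are stored merged and sorted per (class, chromosome).  ``totals``
    holds the per-class callable-site count used as the diversity denominator:
    the summed interval length unless an explicit override is supplied (which
    may be fractional, e.g. Nei--Gojobori synonymous/nonsynonymous site counts
    for a CDS class whose physical intervals are the exome).
    """

    def __init__(
        self,
        intervals: dict[str, dict[str, np.ndarray]],
        totals: dict[str, float] | None = None,
    ):
        self.intervals: dict[str, dict[str, np.ndarray]] = {}
        for cls, by_chrom in intervals.items():
            self.intervals[cls] = {
                chrom: merge_intervals(iv) for chrom, iv in by_chrom.items()
            }
        self.totals: dict[str, float] = {}
        for cls in self.intervals:
            self.totals[cls] = float(self.interval_length(cls))
        if totals:
            for cls, L in totals.items():
                if L < 0:
                    raise ValueError(f"negative callable-site total for {cls!r}")
                self.totals[cls] = float(L)

    def interval_length(self, site_class: str) -> int:
        by_chrom = self.intervals.get(site_class, {})
        return int(
            sum((iv[:, 1] - iv[:, 0]).sum() for iv in by_chrom.values())
        )

    def classes(self) -> list[str]:
        return sorted(set(self.intervals) | set(self.totals))

    def contains(self, site_class: str, chrom: np.ndarray, pos0: np.ndarray) -> np.ndarray:
        """Vectorized membership of 0-based positions in a class's intervals."""
        chrom = np.asarray(chrom)
        pos0 = np.asarray(pos0, dtype=np.int64)
        hit = np.zeros(pos0.shape, dtype=bool)
        by_chrom = self.intervals.get(site_class, {})
        for c, iv in by_chrom.items():
            m = chrom == c
            if not m.any() or iv.size == 0:
                continue
            p = pos0[m]
            k = np.searchsorted(iv[:, 0], p, side="right") - 1
            ok = k >= 0
            ok[ok] &= p[ok] < iv[k[ok], 1]
            hit[m] = ok
        return hit

    @classmethod
    def from_bed(
        cls,
        bed_paths: dict[str, str],
        totals: dict[str, float] | None = None,
        known_classes: tuple[str, ...] = SITE_CLASSES,
    ) -> "SiteClassMap":
        intervals: dict[str, dict[str, np.ndarray]] = {}
        for name, path in bed_paths.items():
            if name not in known_classes:
                raise ValueError(f"unknown site class {name!r} in class map")
            by_chrom: dict[str, list[tuple[int, int]]] = {}
            with open(path) as fh:
                for ln, line in enumerate(fh, 1):
                    line = line.strip()
                    if not line or line.startswith(("#", "track", "browser")):
                        continue
                    parts = line.split("\t")
                    try:
                        chrom, start, end = parts[0], int(parts[1]), int(parts[2])
                    except (IndexError, ValueError) as exc:
                        raise ValueError(f"{path}:{ln}: malformed BED line") from exc
                    if end <= start:
                        raise ValueError(
                            f"{path}:{ln}: interval with end <= start"
                        )
                    by_chrom.setdefault(chrom, []).append((start, end))
            intervals[name] = {
                chrom: np.array(iv, dtype=np.int64) for chrom, iv in by_chrom.items()
            }
        if totals:
            for name in totals:
                if name not in known_classes:
                    raise ValueError(f"unknown site class {name!r} in totals")
        return cls(intervals, totals)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf_table(
    path: str,
    populations: dict[str, list[str]],
    autosome_exclude: str = AUTOSOME_EXCLUDE,
    annotation_key: str = "ANN",
) -> pd.DataFrame:
    """Read biallelic autosomal SNVs into a variant table.

    Returns a DataFrame with columns ``chrom, pos, ref, alt, effect`` and, per
    population ``p``, ``j_<p>`` (alt-allele count) and ``n_<p>`` (called
    chromosomes), sorted by (chrom, pos).  ``effect`` carries the raw
    annotation string (empty when absent).
    """
    from cyvcf2 import VCF

    vcf = VCF(path, gts012=False)
    samples = list(vcf.samples)
    pop_idx: dict[str, np.ndarray] = {}
    for pop, ids in populations.items():
        for sid in ids:
            if sid not in samples:
                raise ValueError(f"unknown sample id {sid!r} (population {pop!r})")
        pop_idx[pop] = np.array([samples.index(s) for s in ids], dtype=np.intp)

    excl = re.compile(autosome_exclude, re.IGNORECASE)
    rows: list[tuple] = []
    for i, v in enumerate(vcf, 1):
        try:
            if excl.match(v.CHROM):
                continue
            if len(v.ALT) != 1:
                continue
            ref, alt = v.REF.upper(), v.ALT[0].upper()
            if len(ref) != 1 or len(alt) != 1 or ref not in _ACGT or alt not in _ACGT:
                continue
            # cyvcf2 gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
            gt = v.gt_types
            effect = v.INFO.get(annotation_key) or ""
            row = [v.CHROM, v.POS, ref, alt, str(effect)]
            for pop in populations:
                g = gt[pop_idx[pop]]
                called = g != 2
                j = int((g == 1).sum() + 2 * (g == 3).sum())
                row.extend([j, int(2 * called.sum())])
            rows.append(tuple(row))
        except ValueError:
            raise
        except Exception as exc:  # malformed record
            raise ValueError(f"{path}: malformed VCF record #{i}") from exc

    cols = ["chrom", "pos", "ref", "alt", "effect"]
    for pop in populations:
        cols.extend([f"j_{pop}", f"n_{pop}"])
    table = pd.DataFrame(rows, columns=cols)
    if len(table):
        table = table.sort_values(["chrom", "pos"], kind="mergesort").reset_index(
            drop=True
        )
    table["site_class"] = "unassigned"
    return table


def read_vcf(
    path: str,
    populations: dict[str, list[str]],
    autosome_exclude: str = AUTOSOME_EXCLUDE,
    annotation_key: str = "ANN",
) -> list[VariantRecord]:
    """Record-oriented counterpart of :func:`read_vcf_table`."""
    table = read_vcf_table(path, populations, autosome_exclude, annotation_key)
    return table_to_records(table, list(populations))


def table_to_records(table: pd.DataFrame, populations: list[str]) -> list[VariantRecord]:
    records = []
    for row in table.itertuples(index=False):
        records.append(
            VariantRecord(
                chrom=row.chrom,
                pos=int(row.pos),
                ref=row.ref,
                alt=row.alt,
                alt_count={p: int(getattr(row, f"j_{p}")) for p in populations},
                called={p: int(getattr(row, f"n_{p}")) for p in populations},
                site_class=getattr(row, "site_class", "unassigned"),
                gene_id=getattr(row, "gene_id", None),
            )
        )
    return records


def records_to_table(records: list[VariantRecord], populations: list[str]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {
            "chrom": r.chrom, "pos": r.pos, "ref": r.ref, "alt": r.alt,
            "effect": "", "site_class": r.site_class, "gene_id": r.gene_id,
        }
        for p in populations:
            row[f"j_{p}"] = r.alt_count[p]
            row[f"n_{p}"] = r.called[p]
        rows.append(row)
    return pd.DataFrame(rows)


def write_vcf(
    path: str,
    table: pd.DataFrame,
    populations: dict[str, list[str]],
    genotypes: dict[str, np.ndarray] | None = None,
    contigs: dict[str, int] | None = None,
    annotation_key: str = "ANN",
) -> None:
    """Write a variant table as uncompressed VCF v4.2.

    ``genotypes[pop]`` is an optional (n_sites, n_diploids) array of alt-allele
    dosages 0/1/2 (−1 = missing).  When omitted, genotypes consistent with the
    table's (j, n) counts are synthesized (hom-alt, then het, then hom-ref,
    then missing), which preserves the counts on re-reading.
    """
    pops = list(populations)
    lines = ["##fileformat=VCFv4.2"]
    if contigs:
        for c, length in contigs.items():
            lines.append(f"##contig=<ID={c},length={length}>")
    lines.append(
        f'##INFO=<ID={annotation_key},Number=1,Type=String,'
        f'Description="Coding effect annotation">'
    )
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    sample_names = [s for p in pops for s in populations[p]]
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(sample_names)
    )
    _GT = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}

    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
        for i, row in enumerate(table.itertuples(index=False)):
            gts: list[str] = []
            for p in pops:
                n_dip = len(populations[p])
                if genotypes is not None:
                    dose = genotypes[p][i]
                else:
                    j = int(getattr(row, f"j_{p}"))
                    n = int(getattr(row, f"n_{p}"))
                    n_called = n // 2
                    dose = np.full(n_dip, -1, dtype=np.int8)
                    n_hom = j // 2
                    n_het = j % 2
                    dose[:n_hom] = 2
                    dose[n_hom : n_hom + n_het] = 1
                    dose[n_hom + n_het : n_called] = 0
                gts.extend(_GT[int(d)] for d in dose)
            effect = getattr(row, "effect", "") or ""
            info = f"{annotation_key}={effect}" if effect else "."
            fh.write(
                f"{row.chrom}\t{row.pos}\t.\t{row.ref}\t{row.alt}\t.\tPASS\t"
                f"{info}\tGT\t" + "\t".join(gts) + "\n"
            )


# ---------------------------------------------------------------------------
# Site-class assignment
# ---------------------------------------------------------------------------

def read_site_classes(
    bed_paths: dict[str, str], totals: dict[str, float] | None = None
) -> SiteClassMap:
    """BED files per class -> normalized :class:`SiteClassMap` with L_c totals."""
    return SiteClassMap.from_bed(bed_paths, totals)


def assign_site_class(
    table: pd.DataFrame, class_map: SiteClassMap
) -> pd.DataFrame:
    """Set ``site_class`` for every variant in the table.

    Coding SNVs are labelled synonymous/nonsynonymous from the ``effect``
    annotation column; coding SNVs without a recognized effect fall back to
    the bare ``exome`` class.  A map that labels a variant both intron and
    intergenic is inconsistent and rejected.  Assignment is deterministic and
    independent of record order.
    """
    table = table.copy()
    pos0 = table["pos"].to_numpy(dtype=np.int64) - 1
    chrom = table["chrom"].to_numpy()

    in_exome = class_map.contains("exome", chrom, pos0)
    in_intron = class_map.contains("intron", chrom, pos0)
    in_intergenic = class_map.contains("intergenic", chrom, pos0)
    both = in_intron & in_intergenic
    if both.any():
        i = int(np.flatnonzero(both)[0])
        raise ValueError(
            "site-class map labels variant "
            f"{table['chrom'].iat[i]}:{table['pos'].iat[i]} both intron and "
            "intergenic"
        )

    effect = (
        table["effect"].fillna("").astype(str).str.lower()
        if "effect" in table
        else pd.Series("", index=table.index)
    )
    coding = effect.map(lambda e: CODING_EFFECTS.get(e, "")).to_numpy()

    cls = np.full(len(table), "unassigned", dtype=object)
    cls[in_intergenic] = "intergenic"
    cls[in_intron] = "intron"
    cls[in_exome] = "exome"
    has_effect = coding != ""
    cls[has_effect] = coding[has_effect]
    table["site_class"] = cls
    return table


# ---------------------------------------------------------------------------
# NG86 site counting
# ---------------------------------------------------------------------------

_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]


def ng86_site_counts(cds: str) -> tuple[float, float]:
    """Nei--Gojobori (1986) synonymous/nonsynonymous site counts for a CDS.

    Each codon position contributes (number of the 3 possible single-base
    changes that are synonymous)/3 synonymous sites; changes creating a stop
    codon count as nonsynonymous (the classical convention).  The sequence
    must be in-frame, ACGT-only, and free of stop codons (strip the terminal
    stop before calling).  Returns (S, N) with S + N == len(cds) exactly.
    """
    cds = cds.upper()
    if len(cds) % 3 != 0:
        raise ValueError("CDS length not divisible by 3")
    fwd = _STANDARD_TABLE.forward_table
    stops = set(_STANDARD_TABLE.stop_codons)
    syn_thirds = 0
    n_codons = len(cds) // 3
    for ci in range(n_codons):
        codon = cds[3 * ci : 3 * ci + 3]
        if not set(codon) <= _ACGT:
            raise ValueError(f"non-ACGT character in codon {ci}")
        if codon in stops:
            raise ValueError(f"stop codon at codon index {ci}")
        aa = fwd[codon]
        for p in range(3):
            for b in "ACGT":
                if b == codon[p]:
                    continue
                mutant = codon[:p] + b + codon[p + 1 :]
                if mutant not in stops and fwd[mutant] == aa:
                    syn_thirds += 1
    S = syn_thirds / 3.0
    N = 3.0 * n_codons - S
    return S, N


# ---------------------------------------------------------------------------
# Scores and expression
# ---------------------------------------------------------------------------

def read_scores(path: str) -> dict[str, dict[int, float]]:
    """Read a bedGraph-like table into a per-position score map (0-based keys).

    Columns: chrom, start, end, score (tab-separated); an interval's score is
    expanded to every position it covers.
    """
    scores: dict[str, dict[int, float]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            try:
                chrom, start, end = parts[0], int(parts[1]), int(parts[2])
                score = float(parts[3])
            except (IndexError, ValueError) as exc:
                raise ValueError(f"{path}:{ln}: non-numeric or malformed score line") from exc
            if end <= start:
                raise ValueError(f"{path}:{ln}: interval with end <= start")
            chrom_map = scores.setdefault(chrom, {})
            for p in range(start, end):
                chrom_map[p] = score
    return scores


def read_expression(path: str) -> dict[str, float]:
    """Read a gene->expression TSV (gene id, numeric value); duplicates last-win."""
    expr: dict[str, float] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            try:
                gene, value = parts[0], float(parts[1])
            except (IndexError, ValueError) as exc:
                if ln == 1:  # tolerate a header row
                    continue
                raise ValueError(f"{path}:{ln}: non-numeric expression value") from exc
            if gene in expr:
                logger.warning("duplicate gene id %r at %s:%d; last value wins", gene, path, ln)
            expr[gene] = value
    return expr
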