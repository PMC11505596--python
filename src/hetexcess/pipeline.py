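"""End-to-end run: (simulate | load) -> diversity -> excess -> strata -> report.

One entry point, :func:`run_pipeline`, chains the stages with logging at stage
granularity (variants read, filtered, per-class totals) and writes TSV tables
plus a JSON run manifest (config echo, seed, library versions, input
checksums).  Outputs are deterministic for a fixed config and seed; on a stage
failure the partially written outputs are removed and the error names the
stage.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .diversity import (
    DEFAULT_B,
    DEFAULT_BLOCK_SIZE,
    diversity_table,
    partition_blocks,
)
from .excess import excess_with_bootstrap
from .formats_io import (
    GeneRecord,
    assign_site_class,
    read_expression,
    read_scores,
    read_site_classes,
    read_vcf_table,
)
from .gene_strata import (
    DEFAULT_BIN_SIZE,
    DEFAULT_THRESHOLD,
    assign_gene_ids,
    equal_count_bins,
    gene_constraint_proportion,
    spearman,
    stratified_excess,
)
from .synthetic_data import SimConfig, SimDataset, generate_dataset

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration for one pipeline run.

    Either ``sim`` is set (synthetic mode) or ``vcf_path``/``bed_paths``/
    ``site_counts_path`` point at real inputs with ``populations`` mapping the
    large/small population ids to VCF sample ids.  Defaults follow the
    published analysis: 1-Mb blocks, 1000 bootstrap replicates, 1000-gene
    strata, constraint threshold 2.0, intron as the neutral class.
    """

    outdir: str = "results"
    seed: int = 1
    large_pop: str = "large"
    small_pop: str = "small"
    constrained_class: str = "nonsynonymous"
    neutral_class: str = "intron"
    block_size: int = DEFAULT_BLOCK_SIZE
    B: int = DEFAULT_B
    bin_size: int = DEFAULT_BIN_SIZE
    phylop_threshold: float = DEFAULT_THRESHOLD
    run_strata: bool = True
    sim: SimConfig | None = None
    vcf_path: str | None = None
    bed_paths: dict[str, str] = field(default_factory=dict)
    site_counts_path: str | None = None
    genes_path: str | None = None
    scores_path: str | None = None
    expression_path: str | None = None
    populations: dict[str, list[str]] = field(default_factory=dict)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _md5(path: str) -> str:
    h = hashlib.md5()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _load_inputs(config: RunConfig):
    """Stage 1: synthetic dataset or files -> (variants, class_map, genes, scores, expr)."""
    if config.sim is not None:
        ds: SimDataset = generate_dataset(config.sim)
        genes = ds.genes
        expr = dict(zip(genes["gene_id"], genes["expression"]))
        logger.info("simulated %d variants, %d genes", len(ds.variants), len(genes))
        return ds.variants, ds.class_map, genes, ds.scores, expr, {}

    if not config.vcf_path:
        raise ValueError("either sim or vcf_path must be configured")
    checks = {config.vcf_path: _md5(config.vcf_path)}
    totals = {}
    if config.site_counts_path:
        counts = pd.read_csv(config.site_counts_path, sep="\t")
        totals = dict(zip(counts["site_class"], counts["L"].astype(float)))
        checks[config.site_counts_path] = _md5(config.site_counts_path)
    class_map = read_site_classes(config.bed_paths, totals)
    for p in config.bed_paths.values():
        checks[p] = _md5(p)
    variants = read_vcf_table(config.vcf_path, config.populations)
    logger.info("read %d biallelic autosomal SNVs", len(variants))
    variants = assign_site_class(variants, class_map)
    per_class = variants["site_class"].value_counts().to_dict()
    logger.info("per-class SNV totals: %s", per_class)

    genes = None
    scores = None
    expr = None
    if config.genes_path:
        genes = pd.read_csv(config.genes_path, sep="\t")
        variants = assign_gene_ids(variants, genes)
        checks[config.genes_path] = _md5(config.genes_path)
    if config.scores_path:
        scores = read_scores(config.scores_path)
        checks[config.scores_path] = _md5(config.scores_path)
    if config.expression_path:
        expr = read_expression(config.expression_path)
        checks[config.expression_path] = _md5(config.expression_path)
    return variants, class_map, genes, scores, expr, checks


def _gene_site_counts(genes: pd.DataFrame) -> pd.DataFrame:
    """Per-gene denominators: nonsynonymous = 3/4 CDS, intron = intron span."""
    cds = (genes["cds_end"] - genes["cds_start"]).to_numpy(dtype=float)
    intron = (genes["intron_end"] - genes["intron_start"]).to_numpy(dtype=float)
    return pd.DataFrame(
        {
            "L_nonsynonymous": 0.75 * cds,
            "L_synonymous": 0.25 * cds,
            "L_intron": intron,
        },
        index=pd.Index(genes["gene_id"], name="gene_id"),
    )


def _strata_stage(
    variants: pd.DataFrame,
    genes: pd.DataFrame,
    stratifier: pd.Series,
    config: RunConfig,
    label: str,
):
    strata = equal_count_bins(stratifier, config.bin_size)
    table = stratified_excess(
        strata,
        stratifier,
        variants,
        _gene_site_counts(genes),
        config.large_pop,
        config.small_pop,
        config.constrained_class,
        config.neutral_class,
    )
    ok = table["delta_percent"].notna()
    corr = None
    if ok.sum() >= 4:
        corr = spearman(
            table.loc[ok, "mean_stratifier"].to_numpy(),
            table.loc[ok, "delta_percent"].to_numpy(),
            seed=config.seed,
        )
        logger.info(
            "%s strata: rho=%.3f perm p=%.2e over %d strata",
            label,
            corr.rho,
            corr.p_value,
            int(ok.sum()),
        )
    return table, corr


def run_pipeline(config: RunConfig) -> dict[str, str]:
    """Run all stages and write report files; returns artifact paths."""
    os.makedirs(config.outdir, exist_ok=True)
    written: list[str] = []

    def out(name: str) -> str:
        p = os.path.join(config.outdir, name)
        written.append(p)
        return p

    stage = "load"
    try:
        variants, class_map, genes, scores, expr, checksums = _load_inputs(config)

        stage = "diversity"
        blocks = partition_blocks(variants, class_map, config.block_size)
        div = diversity_table(
            blocks, class_map.totals, B=config.B, seed=config.seed
        )
        div.to_csv(out("diversity.tsv"), sep="\t", index=False)

        stage = "excess"
        est = excess_with_bootstrap(
            blocks,
            config.large_pop,
            config.small_pop,
            config.constrained_class,
            config.neutral_class,
            B=config.B,
            seed=config.seed,
        )
        pd.DataFrame(
            [
                {
                    "large_pop": est.large_pop,
                    "small_pop": est.small_pop,
                    "constrained_class": est.constrained_class,
                    "neutral_class": est.neutral_class,
                    "omega_L": est.omega_L,
                    "omega_S": est.omega_S,
                    "delta": est.delta,
                    "delta_percent": est.delta_percent,
                    "se_delta": est.se_delta,
                    "flags": ";".join(est.flags),
                }
            ]
        ).to_csv(out("excess.tsv"), sep="\t", index=False)

        spearman_rows = []
        if config.run_strata and genes is not None:
            stage = "strata"
            if scores is not None:
                props = pd.Series(
                    {
                        row.gene_id: gene_constraint_proportion(
                            GeneRecord(
                                gene_id=row.gene_id,
                                chrom=row.chrom,
                                cds=[[row.cds_start, row.cds_end]],
                            ),
                            scores,
                            config.phylop_threshold,
                        )
                        for row in genes.itertuples(index=False)
                    },
                    name="constraint_prop",
                )
                table, corr = _strata_stage(variants, genes, props, config, "constraint")
                table.to_csv(out("strata_constraint.tsv"), sep="\t", index=False)
                if corr:
                    spearman_rows.append(
                        {"stratifier": "constraint", "rho": corr.rho,
                         "p_perm": corr.p_value, "p_t": corr.p_t, "n": corr.n}
                    )
            if expr:
                evals = pd.Series(expr, name="expression")
                evals = evals.loc[evals.index.isin(genes["gene_id"])]
                table, corr = _strata_stage(variants, genes, evals, config, "expression")
                table.to_csv(out("strata_expression.tsv"), sep="\t", index=False)
                if corr:
                    spearman_rows.append(
                        {"stratifier": "expression", "rho": corr.rho,
                         "p_perm": corr.p_value, "p_t": corr.p_t, "n": corr.n}
                    )
        if spearman_rows:
            pd.DataFrame(spearman_rows).to_csv(out("spearman.tsv"), sep="\t", index=False)

        stage = "manifest"
        manifest = {
            "hetexcess_version": __version__,
            "versions": {
                "numpy": np.__version__,
                "pandas": pd.__version__,
            },
            "seed": config.seed,
            "config": _config_echo(config),
            "input_checksums": checksums,
            "n_variants": int(len(variants)),
            "class_totals": class_map.totals,
        }
        with open(out("manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
    except Exception as exc:
        for p in written:
            if os.path.exists(p):
                os.remove(p)
        raise PipelineError(stage, exc) from exc

    return {os.path.basename(p): p for p in written}


def _config_echo(config: RunConfig) -> dict:
    echo = dataclasses.asdict(config)
    if config.sim is not None:
        echo["sim"] = {
            k: (v.tolist() if isinstance(v, np.ndarray) else v)
            for k, v in dataclasses.asdict(config.sim).items()
        }
    return echo
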