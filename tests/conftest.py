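import numpy as np
import pandas as pd
import pytest

from hetexcess import SimConfig

TOY_VCF = """\
##fileformat=VCFv4.2
##contig=<ID=chr1,length=100000>
##contig=<ID=chrX,length=100000>
##INFO=<ID=ANN,Number=1,Type=String,Description="Coding effect annotation">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ta1\ta2\tb1\tb2
chr1\t100\t.\tA\tG\t.\tPASS\t.\tGT\t0/1\t1/1\t0/0\t0/0
chr1\t200\t.\tA\tG,T\t.\tPASS\t.\tGT\t0/1\t0/0\t0/0\t0/1
chr1\t300\t.\tA\tAT\t.\tPASS\t.\tGT\t0/1\t0/0\t0/0\t0/0
chrX\t400\t.\tC\tT\t.\tPASS\t.\tGT\t0/1\t0/1\t0/0\t0/0
chr1\t500\t.\tC\tT\t.\tPASS\tANN=missense_variant\tGT\t./.\t0/1\t0/1\t1/1
"""

POPULATIONS = {"p1": ["a1", "a2"], "p2": ["b1", "b2"]}


@pytest.fixture
def toy_vcf(tmp_path):
    path = tmp_path / "toy.vcf"
    path.write_text(TOY_VCF)
    return str(path)


@pytest.fixture
def tiny_sim_config():
    """Small but structurally complete two-population genome."""
    return SimConfig(
        n_chrom=2,
        genes_per_chrom=3,
        gene_spacing=50_000,
        intergenic_length=2_000,
        intron_length=3_000,
        cds_length=1_500,
        seed=5,
    )


def make_variant_table(rows, populations=("large", "small")):
    """rows: (chrom, pos, site_class, j_per_pop dict, n_per_pop dict)."""
    out = []
    for chrom, pos, cls, j, n in rows:
        row = {
            "chrom": chrom,
            "pos": pos,
            "ref": "A",
            "alt": "G",
            "effect": "",
            "site_class": cls,
            "gene_id": None,
        }
        for p in populations:
            row[f"j_{p}"] = j[p]
            row[f"n_{p}"] = n[p]
        out.append(row)
    return pd.DataFrame(out)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
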