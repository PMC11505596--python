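import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hetexcess import (
    SiteClassMap,
    assign_site_class,
    ng86_site_counts,
    read_expression,
    read_scores,
    read_site_classes,
    read_vcf,
    read_vcf_table,
    write_vcf,
)
from hetexcess.formats_io import VariantRecord, merge_intervals

from .conftest import POPULATIONS


class TestReadVcf:
    def test_allele_counts_from_genotypes(self, toy_vcf):
        records = read_vcf(toy_vcf, POPULATIONS)
        first = records[0]
        assert (first.chrom, first.pos) == ("chr1", 100)
        # genotypes 0/1 and 1/1 -> three alt alleles among four chromosomes
        assert first.alt_count["p1"] == 3 and first.called["p1"] == 4
        assert first.alt_count["p2"] == 0 and first.called["p2"] == 4

    def test_filters_triallelic_indel_and_sex_chromosomes(self, toy_vcf):
        records = read_vcf(toy_vcf, POPULATIONS)
        assert [(r.chrom, r.pos) for r in records] == [("chr1", 100), ("chr1", 500)]

    def test_missing_genotype_reduces_called_count(self, toy_vcf):
        table = read_vcf_table(toy_vcf, POPULATIONS)
        row = table[table["pos"] == 500].iloc[0]
        assert row["n_p1"] == 2 and row["j_p1"] == 1
        assert row["effect"] == "missense_variant"

    def test_empty_body_gives_empty_list(self, tmp_path):
        from .conftest import TOY_VCF

        path = tmp_path / "empty.vcf"
        # only the header lines of the toy VCF, no records
        path.write_text("".join(l + "\n" for l in TOY_VCF.splitlines()[:6]))
        assert read_vcf(str(path), POPULATIONS) == []

    def test_unknown_sample_is_fatal(self, toy_vcf):
        with pytest.raises(ValueError, match="nope"):
            read_vcf(toy_vcf, {"p1": ["a1", "nope"]})

    def test_round_trip_preserves_counts(self, tmp_path, rng):
        pops = {"big": [f"x{i}" for i in range(5)], "sml": [f"y{i}" for i in range(4)]}
        rows = []
        for pos in range(1, 40):
            row = {"chrom": "chr1", "pos": 10 * pos, "ref": "A", "alt": "C",
                   "effect": "", "site_class": "unassigned"}
            for p, ids in pops.items():
                n = 2 * len(ids) - 2 * rng.integers(0, 2)
                row[f"n_{p}"] = n
                row[f"j_{p}"] = int(rng.integers(0, n + 1))
            rows.append(row)
        table = pd.DataFrame(rows)
        path = str(tmp_path / "rt.vcf")
        write_vcf(path, table, pops)
        back = read_vcf_table(path, pops)
        for col in ("chrom", "pos", "ref", "alt", "j_big", "n_big", "j_sml", "n_sml"):
            assert (back[col].to_numpy() == table[col].to_numpy()).all()


class TestVariantRecord:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError, match="ref == alt"):
            VariantRecord("chr1", 1, "A", "A", {"p": 0}, {"p": 2})
        with pytest.raises(ValueError, match="outside"):
            VariantRecord("chr1", 1, "A", "G", {"p": 3}, {"p": 2})


class TestSiteClassMap:
    def test_overlapping_intervals_merge(self):
        m = SiteClassMap({"intron": {"chr1": np.array([[0, 100], [50, 150]])}})
        assert m.intervals["intron"]["chr1"].tolist() == [[0, 150]]
        assert m.totals["intron"] == 150

    def test_explicit_total_override_passthrough(self):
        m = SiteClassMap(
            {"exome": {"chr1": np.array([[0, 10]])}},
            totals={"nonsynonymous": 1000.5},
        )
        assert m.totals["nonsynonymous"] == 1000.5

    def test_disjoint_classes_sum_lengths(self, tmp_path):
        (tmp_path / "a.bed").write_text("chr1\t0\t100\nchr1\t200\t250\n")
        (tmp_path / "b.bed").write_text("chr2\t0\t40\n")
        m = read_site_classes(
            {"intron": str(tmp_path / "a.bed"), "intergenic": str(tmp_path / "b.bed")}
        )
        assert m.totals == {"intron": 150.0, "intergenic": 40.0}

    def test_bad_interval_and_unknown_class(self, tmp_path):
        (tmp_path / "bad.bed").write_text("chr1\t50\t50\n")
        with pytest.raises(ValueError, match="end <= start"):
            read_site_classes({"intron": str(tmp_path / "bad.bed")})
        (tmp_path / "ok.bed").write_text("chr1\t0\t10\n")
        with pytest.raises(ValueError, match="unknown site class"):
            read_site_classes({"promoter": str(tmp_path / "ok.bed")})

    def test_merge_rejects_empty_interval(self):
        with pytest.raises(ValueError):
            merge_intervals(np.array([[10, 10]]))


class TestAssignSiteClass:
    def _map(self):
        return SiteClassMap(
            {
                "intron": {"chr1": np.array([[100, 200]])},
                "intergenic": {"chr1": np.array([[300, 400]])},
                "exome": {"chr1": np.array([[500, 600]])},
            }
        )

    def _table(self, rows):
        return pd.DataFrame(
            [
                {"chrom": "chr1", "pos": pos, "ref": "A", "alt": "G",
                 "effect": eff, "site_class": "unassigned", "j_p": 1, "n_p": 4}
                for pos, eff in rows
            ]
        )

    def test_interval_membership_is_half_open_on_pos_minus_one(self):
        table = self._table([(150, ""), (200, ""), (201, ""), (350, ""), (999, "")])
        out = assign_site_class(table, self._map())
        # 1-based 200 is 0-based 199, still inside [100, 200); 201 is outside
        assert out["site_class"].tolist() == [
            "intron", "intron", "unassigned", "intergenic", "unassigned",
        ]

    def test_annotation_tag_labels_coding_variants(self):
        table = self._table([(550, "missense_variant"), (560, "synonymous_variant"), (570, "")])
        out = assign_site_class(table, self._map())
        assert out["site_class"].tolist() == ["nonsynonymous", "synonymous", "exome"]

    def test_order_independence(self, rng):
        table = self._table([(150, ""), (550, "missense"), (350, ""), (50, "")])
        shuffled = table.sample(frac=1, random_state=7).reset_index(drop=True)
        a = assign_site_class(table, self._map()).set_index("pos")["site_class"]
        b = assign_site_class(shuffled, self._map()).set_index("pos")["site_class"]
        assert a.sort_index().equals(b.sort_index())

    def test_intron_intergenic_conflict_is_map_error(self):
        m = SiteClassMap(
            {
                "intron": {"chr1": np.array([[100, 200]])},
                "intergenic": {"chr1": np.array([[150, 250]])},
            }
        )
        with pytest.raises(ValueError, match="both intron and intergenic"):
            assign_site_class(self._table([(160, "")]), m)


class TestNg86:
    @pytest.mark.parametrize(
        "cds, S, N",
        [
            ("ATG", 0.0, 3.0),  # every change to ATG is nonsynonymous
            ("TTT", 1 / 3, 8 / 3),  # only TTT->TTC is synonymous
            ("ATGTTT", 1 / 3, 17 / 3),
        ],
    )
    def test_known_codons(self, cds, S, N):
        s, n = ng86_site_counts(cds)
        assert s == pytest.approx(S, abs=1e-12)
        assert n == pytest.approx(N, abs=1e-12)
        assert s + n == len(cds)

    def test_errors_identify_codon(self):
        with pytest.raises(ValueError, match="codon index 1"):
            ng86_site_counts("ATGTAA")
        with pytest.raises(ValueError, match="codon 1"):
            ng86_site_counts("ATGNNN")
        with pytest.raises(ValueError, match="divisible"):
            ng86_site_counts("ATGA")

    @given(
        st.lists(
            st.sampled_from(
                [c for c in
                 [a + b + d for a in "ACGT" for b in "ACGT" for d in "ACGT"]
                 if c not in ("TAA", "TAG", "TGA")]
            ),
            min_size=1,
            max_size=20,
        )
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_sites_sum_to_length(self, codons):
        cds = "".join(codons)
        s, n = ng86_site_counts(cds)
        assert s + n == len(cds)
        assert 0 <= s <= len(cds)


class TestScoresAndExpression:
    def test_interval_scores_expand_per_position(self, tmp_path):
        p = tmp_path / "s.bedgraph"
        p.write_text("chr1\t10\t13\t2.5\n")
        scores = read_scores(str(p))
        assert scores == {"chr1": {10: 2.5, 11: 2.5, 12: 2.5}}

    def test_empty_and_malformed(self, tmp_path):
        p = tmp_path / "e.bedgraph"
        p.write_text("")
        assert read_scores(str(p)) == {}
        p.write_text("chr1\t1\t2\tNaNope\n")
        with pytest.raises(ValueError, match=":1"):
            read_scores(str(p))

    def test_expression_map_and_duplicates(self, tmp_path, caplog):
        p = tmp_path / "x.tsv"
        p.write_text("g1\t4.5\ng2\t6.0\ng3\t5.1\ng1\t9.9\n")
        expr = read_expression(str(p))
        assert len(expr) == 3
        assert expr["g1"] == 9.9  # last wins
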