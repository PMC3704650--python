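"""Association-table construction rules and binary matrix building."""

import numpy as np
import pandas as pd
import pytest

from phenologs import (
    AssociationTable,
    build_matrix,
    expand_location_stage,
    filter_evidence_codes,
    filter_min_genes,
    profile_to_phenotypes,
    read_associations,
)
from phenologs.phenotypes import ParseError


class TestReadAssociations:
    def test_deduplicates(self, tmp_path):
        p = tmp_path / "a.tsv"
        p.write_text(
            "species\tphenotype_id\tphenotype_name\tgene_id\n"
            "hs\tP1\tone\tg1\nhs\tP1\tone\tg1\nhs\tP1\tone\tg2\n"
        )
        assert len(read_associations(p)) == 2

    def test_empty_file(self, tmp_path):
        p = tmp_path / "a.tsv"
        p.write_text("")
        assert len(read_associations(p)) == 0

    def test_missing_column(self, tmp_path):
        p = tmp_path / "a.tsv"
        p.write_text("species\tphenotype_id\tgene_id\nhs\tP1\tg1\n")
        with pytest.raises(ParseError, match="missing column"):
            read_associations(p)

    def test_empty_gene_id(self, tmp_path):
        p = tmp_path / "a.tsv"
        p.write_text(
            "species\tphenotype_id\tphenotype_name\tgene_id\nhs\tP1\tone\t\n"
        )
        with pytest.raises(ParseError, match="gene_id"):
            read_associations(p)


class TestFilterMinGenes:
    @pytest.mark.parametrize("n_genes,kept", [(2, False), (3, True), (5, True)])
    def test_threshold_inclusive_at_three(self, n_genes, kept):
        t = AssociationTable.from_records(
            [("hs", "P1", "p", f"g{i}") for i in range(n_genes)]
        )
        out = filter_min_genes(t, 3)
        assert (len(out) > 0) == kept

    def test_minimum_one_is_identity(self):
        t = AssociationTable.from_records([("hs", "P1", "p", "g1")])
        assert filter_min_genes(t, 1).df.equals(t.df)

    def test_idempotent(self):
        t = AssociationTable.from_records(
            [("hs", "P1", "p", "g1"), ("hs", "P1", "p", "g2"),
             ("hs", "P2", "p", "g1"), ("hs", "P2", "p", "g2"),
             ("hs", "P2", "p", "g3")]
        )
        once = filter_min_genes(t, 3)
        twice = filter_min_genes(once, 3)
        assert once.df.equals(twice.df)


GAF = """!gaf-version: 2.1
DB\tID1\tGENE1\t\tGO:0001\tREF\tIMP\t\tP\t\t\tprotein\ttaxon:9606\t20110101\tDB\t\t
DB\tID2\tGENE2\t\tGO:0001\tREF\tIEA\t\tP\t\t\tprotein\ttaxon:9606\t20110101\tDB\t\t
DB\tID1\tGENE1\t\tGO:0001\tREF\tIDA\t\tP\t\t\tprotein\ttaxon:9606\t20110101\tDB\t\t
DB\tID3\tGENE3\tNOT\tGO:0002\tREF\tIMP\t\tP\t\t\tprotein\ttaxon:9606\t20110101\tDB\t\t
DB\tID4\tGENE4\t\tGO:0002\tREF\tXYZ\t\tP\t\t\tprotein\ttaxon:9606\t20110101\tDB\t\t
"""


class TestFilterEvidenceCodes:
    def test_gaf_rules(self, tmp_path, caplog):
        p = tmp_path / "x.gaf"
        p.write_text(GAF)
        with caplog.at_level("WARNING"):
            out = filter_evidence_codes(p, species="hs")
        # IMP kept, IEA dropped, IMP+IDA de-duplicated, NOT dropped,
        # unknown code excluded with a warning
        assert len(out) == 1
        rec = out.df.iloc[0]
        assert (rec["gene_id"], rec["phenotype_id"]) == ("GENE1", "GO:0001")
        assert "unknown evidence code" in caplog.text


class TestProfileToPhenotypes:
    def test_hundred_conditions_give_eighty(self):
        rng = np.random.default_rng(0)
        prof = pd.DataFrame(
            rng.normal(size=(3, 100)),
            index=[f"g{i}" for i in range(3)],
            columns=[f"c{i:03d}" for i in range(100)],
        )
        out = profile_to_phenotypes(prof, species="ec")
        counts = out.df.groupby("gene_id")["phenotype_id"].nunique()
        assert (counts == 80).all()

    @pytest.mark.parametrize("n_cond", [60, 10])
    def test_fewer_conditions_than_windows(self, n_cond):
        prof = pd.DataFrame(
            np.arange(n_cond, dtype=float).reshape(1, -1),
            index=["g0"],
            columns=[f"c{i:03d}" for i in range(n_cond)],
        )
        out = profile_to_phenotypes(prof, species="ec")
        assert out.df["phenotype_id"].nunique() == n_cond

    def test_tie_break_deterministic(self):
        prof = pd.DataFrame(
            np.zeros((1, 5)), index=["g0"], columns=list("edcba")
        )
        a = profile_to_phenotypes(prof, species="ec", top_k=2, bottom_k=2)
        b = profile_to_phenotypes(prof, species="ec", top_k=2, bottom_k=2)
        assert a.df.equals(b.df)
        # all scores tied: bottom-2 = {a,b}, top-2 = {d,e} lexicographically
        assert set(a.df["phenotype_id"]) == {"a", "b", "d", "e"}

    def test_association_count_bounded(self):
        rng = np.random.default_rng(3)
        prof = pd.DataFrame(
            rng.normal(size=(4, 30)),
            index=[f"g{i}" for i in range(4)],
            columns=[f"c{i:02d}" for i in range(30)],
        )
        out = profile_to_phenotypes(prof, species="ec", top_k=7, bottom_k=9)
        counts = out.df.groupby("gene_id")["phenotype_id"].nunique()
        assert (counts <= min(30, 7 + 9)).all()

    def test_non_numeric_rejected(self):
        prof = pd.DataFrame({"c1": ["x"]}, index=["g0"])
        with pytest.raises(ParseError):
            profile_to_phenotypes(prof, species="ec")


def _expr(rows):
    return pd.DataFrame(rows, columns=["gene", "location", "stage"])


class TestExpandLocationStage:
    def test_large_location_with_stage(self):
        rows = [(f"g{i}", "heart", "HH10") for i in range(5)]
        rows += [(f"h{i}", "heart", f"HH{i}") for i in range(56)]
        out = expand_location_stage(_expr(rows), species="gg")
        pids = set(out.df["phenotype_id"])
        assert "heart" in pids
        assert "heart at stage HH10" in pids

    def test_small_location_no_stage_phenotypes(self):
        rows = [(f"g{i}", "eye", "HH10") for i in range(40)]
        out = expand_location_stage(_expr(rows), species="gg")
        assert set(out.df["phenotype_id"]) == {"eye"}

    def test_stage_threshold_strict(self):
        # location passes (>50 genes) but the stage has exactly 3 genes
        rows = [(f"g{i}", "limb", "HH12") for i in range(3)]
        rows += [(f"h{i}", "limb", f"s{i}") for i in range(55)]
        out = expand_location_stage(_expr(rows), species="gg")
        assert "limb at stage HH12" not in set(out.df["phenotype_id"])

    def test_location_threshold_strict(self):
        # exactly 50 genes: no stage phenotypes even with a big stage
        rows = [(f"g{i}", "gut", "HH5") for i in range(50)]
        out = expand_location_stage(_expr(rows), species="gg")
        assert set(out.df["phenotype_id"]) == {"gut"}


class TestBuildMatrix:
    def test_cardinalities(self):
        t = AssociationTable.from_records(
            [("hs", "P1", "p", "g1"), ("hs", "P1", "p", "g2")]
        )
        mat = build_matrix(t, "genes", species="hs")
        assert mat.cardinality("P1") == 2
        assert mat.descriptor("P1").cardinality == 2

    def test_gene_based_expansion_vs_orthogroup(self, toy_orthology):
        """A mouse phenotype on an expanded family: three incidences in the
        human gene rows, one in the orthogroup rows."""
        from phenologs import project_to_orthogroups, translate_gene_based

        t = AssociationTable.from_records([("mouse", "M:P", "p", "mB")])
        gene_rows = translate_gene_based(t, "mouse", "human", toy_orthology)
        m1 = build_matrix(gene_rows, "genes", species="human")
        assert m1.cardinality("M:P") == 3
        og_rows = project_to_orthogroups(t, "human", "mouse", toy_orthology)
        m2 = build_matrix(og_rows, "orthogroups",
                          universe=["OG1", "OG2", "OG3"], pair=("human", "mouse"))
        assert m2.cardinality("M:P") == 1

    def test_universe_restriction_drops(self):
        t = AssociationTable.from_records(
            [("hs", "P1", "p", "g1"), ("hs", "P1", "p", "g9")]
        )
        mat = build_matrix(t, "genes", universe=["g1", "g2"], species="hs")
        assert mat.column("P1") == {"g1"}

    def test_incidence_count_matches_distinct_pairs(self, small_synth):
        t = small_synth.associations["human"]
        mat = build_matrix(t, "genes", species="human")
        total = sum(len(c) for c in mat.columns.values())
        assert total == len(t.df.drop_duplicates(["phenotype_id", "gene_id"]))

    def test_ordering_deterministic(self):
        t = AssociationTable.from_records(
            [("hs", "P2", "p", "b"), ("hs", "P1", "p", "a"), ("hs", "P1", "p", "c")]
        )
        mat = build_matrix(t, "genes", species="hs")
        assert list(mat.phenotype_ids) == ["P1", "P2"]
        assert list(mat.elements) == ["a", "b", "c"]
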