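"""Parsing, validation and round-trip behaviour of the flat-file readers."""

import random

import pytest

from adrnet.errors import FormatError, StructuralError
from adrnet.io import (load_cardiotoxicity_icd10, read_drug_adr_table,
                       read_drug_target_table, read_icd10_table, read_obo,
                       read_ppi_table, write_drug_adr_table,
                       write_drug_target_table, write_icd10_table,
                       write_ppi_table)

OBO_CHAIN = """format-version: 1.2

[Term]
id: GO:0000001
name: biological process
namespace: biological_process

[Term]
id: GO:0000002
name: term A
namespace: biological_process
is_a: GO:0000001 ! biological process

[Term]
id: GO:0000003
name: term B
namespace: biological_process
is_a: GO:0000002 ! term A
"""


class TestDrugTargetTable:
    def test_parses_and_dedups(self, tsv_writer):
        path = tsv_writer("dt.tsv", ["drug_id", "protein_id"],
                          [("d1", "pA"), ("d2", "pA"), ("d2", "pB"),
                           ("d1", "pA")])
        m = read_drug_target_table(path)
        assert m.pairs == {("d1", "pA"), ("d2", "pA"), ("d2", "pB")}

    def test_short_row_is_format_error_with_line(self, tsv_writer):
        path = tsv_writer("dt.tsv", ["drug_id", "protein_id"],
                          [("d1", "pA"), ("d2",)])
        with pytest.raises(FormatError, match="line 3"):
            read_drug_target_table(path)

    def test_missing_column_names_it(self, tsv_writer):
        path = tsv_writer("dt.tsv", ["drug_id", "target"], [("d1", "pA")])
        with pytest.raises(FormatError, match="protein_id"):
            read_drug_target_table(path)

    def test_empty_file_yields_empty_map(self, tmp_path):
        path = tmp_path / "dt.tsv"
        path.write_text("")
        assert read_drug_target_table(path).pairs == frozenset()


class TestDrugAdrTable:
    def test_distinct_adrs_kept(self, tsv_writer):
        path = tsv_writer("da.tsv", ["drug_id", "adr_name"],
                          [("d1", "Cardiac Arrest"), ("d1", "Nausea")])
        assert len(read_drug_adr_table(path).pairs) == 2

    def test_casefold_canonicalization_merges(self, tsv_writer):
        path = tsv_writer("da.tsv", ["drug_id", "adr_name"],
                          [("d1", "cardiac  arrest"), ("d1", "Cardiac Arrest")])
        m = read_drug_adr_table(path)
        assert m.pairs == {("d1", "cardiac arrest")}


class TestPPITable:
    def test_unordered_dedup_keeps_max_stars(self, tsv_writer):
        path = tsv_writer("ppi.tsv", ["protein_a", "protein_b", "stars"],
                          [("A", "B", 3), ("B", "A", 2)])
        net = read_ppi_table(path)
        assert net.edges() == {("A", "B", 3)}

    def test_self_edge_dropped(self, tsv_writer, caplog):
        path = tsv_writer("ppi.tsv", ["protein_a", "protein_b", "stars"],
                          [("A", "A", 5), ("A", "B", 1)])
        with caplog.at_level("INFO"):
            net = read_ppi_table(path)
        assert net.edges() == {("A", "B", 1)}
        assert "1 self interaction" in caplog.text

    @pytest.mark.parametrize("stars", [0, 7, "2.5", "x"])
    def test_invalid_stars_rejected(self, tsv_writer, stars):
        path = tsv_writer("ppi.tsv", ["protein_a", "protein_b", "stars"],
                          [("A", "B", stars)])
        with pytest.raises(FormatError):
            read_ppi_table(path)


class TestIcd10Table:
    def test_packaged_cardiotoxicity_map(self):
        m = load_cardiotoxicity_icd10()
        assert len(m.entries) == 29
        assert m.entries["cardiac arrest"] == "I46"
        assert m.entries["valvular heart disease"] == "I08.8"
        assert m.category("Valvular Heart Disease") == "I08"
        assert m.category("Heart Disease") == "I30"  # range lower bound

    def test_malformed_code_rejected(self, tsv_writer):
        path = tsv_writer("icd.tsv", ["adr_name", "icd10_code"],
                          [("Something", "X9")])
        with pytest.raises(FormatError):
            read_icd10_table(path)


class TestObo:
    def test_chain_parses_with_annotation(self, tmp_path, tsv_writer):
        obo = tmp_path / "o.obo"
        obo.write_text(OBO_CHAIN)
        annot = tsv_writer("ann.tsv", ["protein_id", "go_id"],
                           [("p1", "GO:0000003")])
        dag = read_obo(obo, annot)
        assert dag.root == "GO:0000001"
        assert dag.parents["GO:0000003"] == {"GO:0000002"}
        assert dag.annotations == {"p1": {"GO:0000003"}}

    def test_unknown_annotation_dropped(self, tmp_path, tsv_writer, caplog):
        obo = tmp_path / "o.obo"
        obo.write_text(OBO_CHAIN)
        annot = tsv_writer("ann.tsv", ["protein_id", "go_id"],
                           [("p1", "GO:9999999")])
        with caplog.at_level("INFO"):
            dag = read_obo(obo, annot)
        assert dag.annotations == {}
        assert "dropped 1" in caplog.text

    def test_two_roots_is_structural_error(self, tmp_path, tsv_writer):
        obo = tmp_path / "o.obo"
        obo.write_text(OBO_CHAIN.replace(
            "is_a: GO:0000002 ! term A\n", ""))
        annot = tsv_writer("ann.tsv", ["protein_id", "go_id"], [])
        with pytest.raises(StructuralError):
            read_obo(obo, annot)


class TestRoundTripAndOrder:
    """Write-then-read identity and row-order insensitivity."""

    def test_round_trips(self, tmp_path, tsv_writer):
        dt = read_drug_target_table(tsv_writer(
            "dt.tsv", ["drug_id", "protein_id"], [("d1", "pA"), ("d2", "pB")]))
        write_drug_target_table(dt, tmp_path / "dt2.tsv")
        assert read_drug_target_table(tmp_path / "dt2.tsv") == dt

        da = read_drug_adr_table(tsv_writer(
            "da.tsv", ["drug_id", "adr_name"], [("d1", "Cardiac Arrest")]))
        write_drug_adr_table(da, tmp_path / "da2.tsv")
        assert read_drug_adr_table(tmp_path / "da2.tsv") == da

        net = read_ppi_table(tsv_writer(
            "ppi.tsv", ["protein_a", "protein_b", "stars"],
            [("A", "B", 3), ("B", "C", 5)]))
        write_ppi_table(net, tmp_path / "ppi2.tsv")
        assert read_ppi_table(tmp_path / "ppi2.tsv") == net

        icd = load_cardiotoxicity_icd10()
        write_icd10_table(icd, tmp_path / "icd2.tsv")
        assert read_icd10_table(tmp_path / "icd2.tsv") == icd

    def test_row_shuffle_is_irrelevant(self, tsv_writer):
        rows = [("d%d" % i, "p%d" % (i % 5)) for i in range(20)]
        shuffled = rows[:]
        random.Random(0).shuffle(shuffled)
        a = read_drug_target_table(
            tsv_writer("a.tsv", ["drug_id", "protein_id"], rows))
        b = read_drug_target_table(
            tsv_writer("b.tsv", ["drug_id", "protein_id"], shuffled))
        assert a == b
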