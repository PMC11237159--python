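import json

import numpy as np
import pytest

from glueevo.formats import (
    AnalysisReport,
    CodonAlignmentSet,
    ConfigurationError,
    ExpressionTable,
    FormatError,
    ResidueTrack,
    SequenceRecord,
    read_expression_table,
    read_fasta,
    read_report,
    read_residue_track,
    read_spans_tsv,
    write_expression_table,
    write_fasta,
    write_report,
    write_residue_track,
)


class TestFasta:
    def test_single_record(self, tmp_path):
        p = tmp_path / "a.fa"
        p.write_text(">a\nACDEF\n")
        (rec,) = read_fasta(p)
        assert (rec.id, rec.residues) == ("a", "ACDEF")

    def test_line_wrapped_records_are_concatenated(self, tmp_path):
        p = tmp_path / "a.fa"
        p.write_text(">a desc one\nACDEF\n>b\nACD\nEFG\nHIK\n")
        recs = read_fasta(p)
        assert [r.id for r in recs] == ["a", "b"]
        assert recs[0].description == "desc one"
        assert recs[1].residues == "ACDEFGHIK"

    def test_duplicate_id_rejected(self, tmp_path):
        p = tmp_path / "a.fa"
        p.write_text(">a\nACD\n>a\nEFG\n")
        with pytest.raises(FormatError, match="duplicate"):
            read_fasta(p)

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "a.fa"
        p.write_text("")
        with pytest.raises(FormatError, match="no FASTA records"):
            read_fasta(p)

    def test_illegal_character_located(self, tmp_path):
        p = tmp_path / "a.fa"
        p.write_text(">a\nAC1DE\n")
        with pytest.raises(FormatError, match="position 3"):
            read_fasta(p)

    def test_round_trip_fixed_wrap(self, tmp_path):
        recs = [
            SequenceRecord(id="long", description="d", residues="ACDEFGHIKL" * 13),
            SequenceRecord(id="short", description="", residues="MKV"),
        ]
        p = tmp_path / "out.fa"
        write_fasta(recs, p)
        back = read_fasta(p)
        assert [(r.id, r.description, r.residues) for r in back] == [
            (r.id, r.description, r.residues) for r in recs
        ]
        # fixed 60-column wrap
        lines = p.read_text().splitlines()
        assert max(len(ln) for ln in lines if not ln.startswith(">")) == 60


class TestExpressionTable:
    def test_read_3x2(self, tmp_path):
        (tmp_path / "t.tsv").write_text(
            "gene\tsp1\tsp2\ng1\t1.0\t2.0\ng2\t3.0\t4.0\ng3\t5.0\t6.0\n"
        )
        (tmp_path / "r.tsv").write_text("species\tsp1\tglue\nspecies\tsp2\tnonglue\n")
        t = read_expression_table(tmp_path / "t.tsv", tmp_path / "r.tsv")
        assert t.values.shape == (3, 2)
        assert t.tpm("g2", "sp2") == 4.0
        assert t.gene_class["g1"] == "reference"  # default class

    def test_negative_cell_located(self, tmp_path):
        (tmp_path / "t.tsv").write_text("gene\tsp1\tsp2\ng1\t1.0\t-1.0\n")
        (tmp_path / "r.tsv").write_text("species\tsp1\tglue\nspecies\tsp2\tnonglue\n")
        with pytest.raises(FormatError, match="g1.*sp2"):
            read_expression_table(tmp_path / "t.tsv", tmp_path / "r.tsv")

    def test_species_missing_from_roles(self, tmp_path):
        (tmp_path / "t.tsv").write_text("gene\tsp1\tsp2\ng1\t1.0\t2.0\n")
        (tmp_path / "r.tsv").write_text("species\tsp1\tglue\n")
        with pytest.raises(ConfigurationError, match="sp2"):
            read_expression_table(tmp_path / "t.tsv", tmp_path / "r.tsv")

    def test_needs_both_roles(self):
        with pytest.raises(ConfigurationError, match="glue and one non-glue"):
            ExpressionTable(
                genes=["g"],
                species=["a", "b"],
                values=np.ones((1, 2)),
                species_role={"a": "glue", "b": "glue"},
                gene_class={"g": "reference"},
            )

    def test_write_read_round_trip(self, tmp_path, tiny_table):
        write_expression_table(tiny_table, tmp_path / "t.tsv", tmp_path / "r.tsv")
        back = read_expression_table(tmp_path / "t.tsv", tmp_path / "r.tsv")
        assert back.genes == tiny_table.genes
        assert back.gene_class == tiny_table.gene_class
        np.testing.assert_allclose(back.values, tiny_table.values)


class TestResidueTrack:
    def test_read_five_positions(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text("1\t0.1\n2\t0.2\n3\t0.3\n4\t0.4\n5\t0.5\n")
        track = read_residue_track(p, kind="disorder")
        assert len(track) == 5
        assert track.values[-1] == 0.5

    def test_gap_in_positions_rejected(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text("1\t0.1\n2\t0.2\n4\t0.4\n")
        with pytest.raises(FormatError, match="contiguity"):
            read_residue_track(p, kind="disorder")

    def test_value_outside_unit_interval_rejected(self):
        with pytest.raises(FormatError, match=r"outside \[0, 1\]"):
            ResidueTrack(sequence_id="s", kind="glyco", values=[0.5, 1.2])

    def test_secstruct_symbols_checked(self):
        with pytest.raises(FormatError, match="position 2"):
            ResidueTrack(sequence_id="s", kind="secstruct", values=list("HZC"))

    def test_round_trip(self, tmp_path):
        track = ResidueTrack(sequence_id="s", kind="disorder", values=[0.25, 0.5, 1.0])
        write_residue_track(track, tmp_path / "t.tsv")
        back = read_residue_track(tmp_path / "t.tsv", kind="disorder", sequence_id="s")
        assert back.values == track.values


class TestCodonAlignment:
    def test_partial_codon_gap_rejected(self):
        recs = [
            SequenceRecord(id="a", description="", residues="ATGAAA", alphabet="dna"),
            SequenceRecord(id="b", description="", residues="ATGA-A", alphabet="dna"),
        ]
        with pytest.raises(FormatError, match="partial-codon gap"):
            CodonAlignmentSet(records=recs)

    def test_whole_codon_gap_allowed_and_tree_leaves_checked(self):
        recs = [
            SequenceRecord(id="a", description="", residues="ATGAAA", alphabet="dna"),
            SequenceRecord(id="b", description="", residues="ATG---", alphabet="dna"),
        ]
        aln = CodonAlignmentSet(records=recs, tree="(a:1,b:1);")
        assert aln.n_codons == 2
        with pytest.raises(ConfigurationError, match="leaves"):
            CodonAlignmentSet(records=recs, tree="(a:1,c:1);")

    def test_length_must_be_codon_multiple(self):
        rec = SequenceRecord(id="a", description="", residues="ATGA", alphabet="dna")
        with pytest.raises(FormatError, match="divisible by 3"):
            CodonAlignmentSet(records=[rec])


class TestReportAndSpans:
    def test_report_round_trip_identity(self, tmp_path):
        rep = AnalysisReport(
            content={"stages": {"x": {"value": 1.5, "list": [1, 2, 3]}}, "seed": 7}
        )
        write_report(rep, tmp_path / "r.json")
        back = read_report(tmp_path / "r.json")
        assert back.content == rep.content

    def test_numpy_scalars_serialised(self, tmp_path):
        rep = AnalysisReport(content={"v": np.float64(2.5), "n": np.int64(3)})
        write_report(rep, tmp_path / "r.json")
        data = json.loads((tmp_path / "r.json").read_text())
        assert data["v"] == 2.5 and data["n"] == 3

    def test_spans_tsv(self, tmp_path):
        p = tmp_path / "s.tsv"
        p.write_text("seq_id\tstart\tend\tlabel\nprot\t1\t20\tsignal\nprot\t21\t410\tIgGFcBD\n")
        spans = read_spans_tsv(p)
        assert spans == {"prot": [(1, 20, "signal"), (21, 410, "IgGFcBD")]}
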