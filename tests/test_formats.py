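"""File-format readers and writers and their round-trip identities."""

import pytest

from popvar import formats
from popvar.detect import (
    GenotypeMatrix,
    Variant,
    detect_variants,
    genotype_matrix,
)
from popvar.fixtures import PlantedIndel, PlantedSNP, SimulationSpec, make_alignment
from popvar.network import build_mjn


class TestFastaAlignment:
    def write(self, tmp_path, records):
        p = tmp_path / "aln.fa"
        p.write_text("".join(f">{n}\n{s}\n" for n, s in records))
        return p

    def test_wellformed_input(self, tmp_path):
        p = self.write(tmp_path, [("g1_a1", "ACGTA"), ("g1_a2", "ACGTT"),
                                  ("g1_a3", "ACCTA")])
        aln = formats.read_fasta_alignment(p)
        assert aln.n_accessions == 3 and aln.length == 5
        assert aln.gene_id == "g1" and aln.accessions == ["a1", "a2", "a3"]

    def test_length_mismatch_names_offender(self, tmp_path):
        p = self.write(tmp_path, [("g_a", "ACGTA"), ("g_b", "ACGTAA")])
        with pytest.raises(ValueError, match="g_b"):
            formats.read_fasta_alignment(p)

    def test_lowercase_normalized(self, tmp_path):
        p = self.write(tmp_path, [("g_a", "acgt-"), ("g_b", "ACGTA")])
        aln = formats.read_fasta_alignment(p)
        assert aln.rows[0] == "ACGT-"

    def test_illegal_character_reports_position(self, tmp_path):
        p = self.write(tmp_path, [("g_a", "ACXTA"), ("g_b", "ACGTA")])
        with pytest.raises(ValueError, match="position 3"):
            formats.read_fasta_alignment(p)

    def test_accession_only_template_takes_gene_from_stem(self, tmp_path):
        p = self.write(tmp_path, [("s1", "AC"), ("s2", "AT")])
        aln = formats.read_fasta_alignment(p, id_template="{accession}")
        assert aln.gene_id == "aln"


class TestPed:
    def test_format_definition(self, tmp_path):
        p = tmp_path / "g.ped"
        p.write_text("F1 A1 0 0 0 0 A A G T\nF1 A2 0 0 0 0 0 0 G G\n")
        m = formats.read_ped(p)
        assert m.accessions == ["A1", "A2"]
        assert m.variants[0].calls["A1"] == ("A", "A")
        assert m.variants[1].calls["A1"] == ("G", "T")
        assert m.variants[0].calls["A2"] is None  # 0 0 -> missing

    def test_odd_allele_columns_rejected(self, tmp_path):
        p = tmp_path / "bad.ped"
        p.write_text("F1 A1 0 0 0 0 A A G\n")
        with pytest.raises(ValueError):
            formats.read_ped(p)

    def test_roundtrip_identity_on_calls(self, tmp_path):
        spec = SimulationSpec(
            n_accessions=8, length=60,
            snps=[PlantedSNP(10, ("A", "T")), PlantedSNP(25, ("C", "G"))],
            indels=[PlantedIndel(40, 2)], missing_rate=0.1, seed=7,
        )
        aln, _, _ = make_alignment(spec)
        m = genotype_matrix(aln.accessions, detect_variants(aln))
        path = tmp_path / "rt.ped"
        formats.write_ped(m, path)
        back = formats.read_ped(path)
        assert back.accessions == m.accessions
        for v_in, v_out in zip(m.variants, back.variants):
            assert v_out.calls == v_in.calls
            assert v_out.kind == v_in.kind


class TestGff3:
    GFF = """##gff-version 3
chr1\tsrc\tgene\t1\t60\t.\t+\t.\tID=g1
chr1\tsrc\tmRNA\t1\t60\t.\t+\t.\tID=m1;Parent=g1
chr1\tsrc\texon\t1\t19\t.\t+\t.\tParent=m1
chr1\tsrc\texon\t30\t60\t.\t+\t.\tParent=m1
chr1\tsrc\tCDS\t11\t19\t.\t+\t0\tParent=m1
chr1\tsrc\tCDS\t30\t35\t.\t+\t0\tParent=m1
chr2\tsrc\tgene\t5\t40\t.\t-\t.\tID=g2
chr2\tsrc\tmRNA\t5\t40\t.\t-\t.\tID=m2;Parent=g2
chr2\tsrc\texon\t5\t40\t.\t-\t.\tParent=m2
chr2\tsrc\tCDS\t10\t30\t.\t-\t0\tParent=m2
chr2\tsrc\tmRNA\t5\t40\t.\t-\t.\tID=m3;Parent=g2
chr2\tsrc\texon\t5\t40\t.\t-\t.\tParent=m3
chr2\tsrc\tCDS\t10\t21\t.\t-\t0\tParent=m3
"""

    def test_parse_segments_strand_and_multiple_mrnas(self, tmp_path):
        p = tmp_path / "ann.gff3"
        p.write_text(self.GFF)
        models = {m.gene_id: m for m in formats.read_gff3(p)}
        assert set(models) == {"m1", "m2", "m3"}
        assert models["m1"].cds_intervals == [(11, 19), (30, 35)]
        assert models["m2"].strand == "-"


class TestBlastTab:
    def line(self, q, s, ident, qs, qe, ss, se, score):
        return (f"{q}\t{s}\t{ident}\t50\t0\t0\t{qs}\t{qe}\t{ss}\t{se}"
                f"\t1e-10\t{score}")

    def test_strand_identity_and_sort(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text("\n".join([
            self.line("q1", "chr1", "98.50", 1, 50, 401, 500, 150),
            self.line("q1", "chr2", "99.00", 1, 50, 500, 401, 200),
        ]) + "\n")
        hits = formats.read_blast_tab(p)
        assert [h.bitscore for h in hits] == [200.0, 150.0]
        assert hits[0].strand == "-" and hits[1].strand == "+"
        assert hits[1].identity == pytest.approx(0.985)

    def test_short_line_reports_line_number(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("q1\tchr1\t99.0\n")
        with pytest.raises(ValueError, match=":1"):
            formats.read_blast_tab(p)


class TestMetadata:
    def test_parse_and_unassigned(self, tmp_path):
        p = tmp_path / "meta.tsv"
        p.write_text("id\tstatus\torigin\nA1\twild\tsouth\nA2\t\teast\n")
        meta = formats.read_metadata(p)
        assert meta.label_of("A1", "status") == "wild"
        assert meta.label_of("A2", "status") == "unassigned"
        assert meta.groups("origin") == {"south": ["A1"], "east": ["A2"]}

    def test_duplicate_id_rejected(self, tmp_path):
        p = tmp_path / "meta.tsv"
        p.write_text("id\tstatus\nA1\twild\nA1\tcultivated\n")
        with pytest.raises(ValueError):
            formats.read_metadata(p)


def _snp(gene, pos, alleles, calls):
    return Variant(gene, "SNP", pos, alleles, calls)


class TestIlluminaDesign:
    def test_bracket_notation_and_boundaries(self, tmp_path):
        cons = "CCCAGGG"
        calls = {"x": ("A", "A"), "y": ("T", "T")}
        variants = [
            _snp("g", 4, ("A", "T"), calls),
            _snp("g", 1, ("C", "T"), {"x": ("C", "C"), "y": ("T", "T")}),
            Variant("g", "indel", 6, ("absent", "present"),
                    {"x": ("absent", "absent"), "y": ("present", "present")},
                    indel_length=1, indel_sequence="G"),
        ]
        out = tmp_path / "design.tsv"
        n = formats.write_illumina_design(variants, cons, out, flank_len=3)
        lines = out.read_text().splitlines()[1:]
        assert n == 2 and len(lines) == 2  # indel omitted
        assert lines[0].split("\t")[1] == "CCC[A/T]GGG"
        assert lines[1].split("\t")[1] == "[C/T]CCA"  # empty left flank


class TestAllelicWriters:
    @pytest.fixture
    def matrix(self):
        return GenotypeMatrix(
            ["A1", "A2"],
            [
                _snp("g", 3, ("A", "T"), {"A1": ("A", "T"), "A2": ("A", "A")}),
                _snp("g", 9, ("C", "G"), {"A1": ("C", "C"), "A2": None}),
            ],
        )

    def test_phase_v2_layout(self, matrix, tmp_path):
        p = tmp_path / "phase.inp"
        formats.write_phase_input(matrix, p)
        lines = p.read_text().splitlines()
        assert lines[:4] == ["2", "2", "P 3 9", "SS"]
        assert lines[4] == "A1"
        assert lines[5:7] == ["A C", "T C"]
        assert lines[8:10] == ["A ?", "A ?"]

    def test_structure_two_rows_per_accession(self, matrix, tmp_path):
        p = tmp_path / "structure.tsv"
        formats.write_structure_input(matrix, p)
        lines = p.read_text().splitlines()
        assert len(lines) == 1 + 4  # header + 2 rows x 2 accessions
        assert lines[2].split("\t") == ["A1", "4", "2"]  # T=4, C=2

    def test_empty_matrix_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            formats.write_ped(GenotypeMatrix([], []), tmp_path / "x.ped")


class TestDotRoundTrip:
    def test_node_and_edge_sets_survive(self, tmp_path):
        nw = build_mjn(["AAA", "AAT", "ATT", "AAT"])
        p = tmp_path / "net.dot"
        formats.write_dot(nw, p)
        nodes, edges = formats.read_dot(p)
        assert nodes == set(nw.graph.nodes)
        assert edges == {
            (min(u, v), max(u, v), nw.graph.edges[u, v]["weight"])
            for u, v in nw.graph.edges
        }
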