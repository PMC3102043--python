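"""Variant detection, site statistics, consensus and filtering."""

import numpy as np
import pytest

from conftest import oracle_detect, random_alignment, variant_tuple
from popvar.detect import (
    Alignment,
    GenotypeMatrix,
    Variant,
    consensus,
    detect_variants,
    filter_missing_columns,
    genotype_matrix,
    project_summary,
    site_stats,
    subset_accessions,
    variant_table,
)
from popvar.fixtures import PlantedIndel, PlantedSNP, SimulationSpec, make_alignment


def make(rows, accs=None):
    accs = accs or [f"a{i + 1}" for i in range(len(rows))]
    return Alignment("g", accs, rows)


class TestDetectVariants:
    def test_snp_and_indel_in_mixed_alignment(self):
        aln = make(["ACG-T", "ACGGT", "ACRGT"], ["a1", "a2", "a3"])
        variants = detect_variants(aln)
        assert [(v.kind, v.position) for v in variants] == [
            ("SNP", 3), ("indel", 4)
        ]
        snp, indel = variants
        assert snp.alleles == ("A", "G")
        assert snp.calls == {"a1": ("G", "G"), "a2": ("G", "G"),
                             "a3": ("A", "G")}
        assert indel.indel_length == 1 and indel.indel_sequence == "G"
        assert indel.calls == {
            "a1": ("absent", "absent"),
            "a2": ("present", "present"),
            "a3": ("present", "present"),
        }

    def test_identical_rows_yield_no_variants(self):
        assert detect_variants(make(["ACGT", "ACGT", "ACGT"])) == []

    def test_iupac_expansion_makes_het_call(self):
        variants = detect_variants(make(["AAAA", "AAAA", "AWAA"]))
        (v,) = variants
        assert v.position == 2 and v.alleles == ("A", "T")
        assert v.calls["a3"] == ("A", "T")

    def test_threefold_code_is_missing(self):
        variants = detect_variants(make(["ABAA", "AGAA", "ATAA"]))
        (v,) = variants
        assert v.alleles == ("G", "T")
        assert v.calls["a1"] is None

    def test_distinct_gap_extents_are_separate_events(self):
        aln = make(["AC--GT", "AC---T", "ACGTGT"])
        indels = [v for v in detect_variants(aln) if v.kind == "indel"]
        assert [(v.position, v.indel_length) for v in indels] == [(3, 2), (3, 3)]

    def test_single_accession_rejected(self):
        with pytest.raises(ValueError):
            detect_variants(Alignment("g", ["a"], ["ACGT"]))

    def test_matches_bruteforce_oracle_on_random_alignments(self, rng):
        for _ in range(40):
            aln = random_alignment(rng, max_acc=12, max_len=60)
            got = [variant_tuple(v) for v in detect_variants(aln)]
            expected = [
                t[:4] if t[0] == "SNP" else t for t in oracle_detect(aln)
            ]
            assert got == expected


class TestSiteStats:
    def test_balanced_het_site(self):
        v = Variant("g", "SNP", 1, ("A", "T"),
                    {"x": ("T", "T"), "y": ("A", "A"), "z": ("A", "T")})
        st = site_stats(v)
        assert (st.n_readable, st.n_hom, st.n_het) == (3, 2, 1)
        assert st.freq_major == st.freq_minor == 0.5
        assert st.variation == "A/T"

    def test_missing_calls_excluded_from_copies(self):
        v = Variant("g", "SNP", 1, ("A", "T"),
                    {"x": ("A", "A"), "y": ("A", "T"), "z": None})
        st = site_stats(v)
        assert st.n_readable == 2
        assert st.freq_major == pytest.approx(0.75)

    def test_all_missing_is_error(self):
        v = Variant("g", "SNP", 1, ("A", "T"), {"x": None})
        with pytest.raises(ValueError):
            site_stats(v)

    def test_frequency_and_zygosity_invariants_on_random_sites(self, rng):
        for _ in range(50):
            aln = random_alignment(rng, max_acc=10, max_len=30)
            for v in detect_variants(aln):
                st = site_stats(v)
                assert sum(st.allele_freqs.values()) == pytest.approx(1.0)
                assert st.n_hom + st.n_het == st.n_readable
                assert st.freq_major >= st.freq_minor
                if st.n_alleles == 2:
                    assert st.freq_major + st.freq_minor == pytest.approx(1.0)


class TestConsensus:
    @pytest.mark.parametrize(
        "rows, expected",
        [
            (["A", "A", "T"], "A"),
            (["A", "T"], "A"),  # documented tie-break A<C<G<T
            (["N", "N"], "N"),
            (["R", "G", "G"], "G"),  # het codes weigh half
            (["-", "-", "A"], "-"),  # gap-majority column
            (["-", "A", "A"], "A"),
        ],
    )
    def test_column_rules(self, rows, expected):
        assert consensus(make(rows)).sequence == expected

    def test_length_preserved(self, rng):
        aln = random_alignment(rng, max_acc=8, max_len=40)
        assert len(consensus(aln).sequence) == aln.length


class TestFilterMissingColumns:
    def test_threshold_semantics(self):
        aln = make(["ANNAN", "AANNN", "AAANN", "AAAAN", "AAANN"])
        # column N fractions: 0, .2, .4, .6, 1.0
        filtered, report = filter_missing_columns(aln, 0.5)
        assert report.removed_columns == [4, 5]
        assert filtered.length == 3
        _, rep_all = filter_missing_columns(aln, 1.0)
        assert rep_all.removed_columns == []
        _, rep_none = filter_missing_columns(aln, 0.0)
        assert rep_none.removed_columns == [2, 3, 4, 5]

    def test_report_supports_backmapping(self):
        aln = make(["AN", "AN"])
        filtered, report = filter_missing_columns(aln, 0.5)
        assert report.kept_columns == [1] and filtered.length == 1


class TestSubsetAccessions:
    def test_monomorphic_sites_disappear_on_resubset(self):
        aln = make(["AAAA", "ATAA", "AAAA"])
        full = detect_variants(aln)
        assert len(full) == 1
        sub = subset_accessions(aln, ids=["a1", "a3"])
        assert detect_variants(sub) == []

    def test_full_set_is_identity(self):
        aln = make(["ACGT", "ACTT"])
        sub = subset_accessions(aln, ids=["a1", "a2"])
        assert sub.rows == aln.rows

    def test_unknown_id_rejected(self):
        aln = make(["ACGT", "ACTT"])
        with pytest.raises(KeyError):
            subset_accessions(aln, ids=["nope"])

    def test_matrix_subset_drops_monomorphic(self):
        aln = make(["AT", "AT", "TT"])
        m = genotype_matrix(aln.accessions, detect_variants(aln))
        sub = subset_accessions(m, ids=["a1", "a2"])
        assert sub.n_variants == 0

    def test_metadata_filter(self):
        spec = SimulationSpec(
            n_accessions=6, length=30,
            snps=[PlantedSNP(5, ("A", "T"))],
            groups={"wild": 0.5, "cultivated": 0.5}, seed=1,
        )
        aln, _, grouping = make_alignment(spec)

        class Meta:
            def label_of(self, acc, field):
                return grouping[acc]

        sub = subset_accessions(aln, metadata=Meta(), field_name="status",
                                value="wild")
        assert all(grouping[a] == "wild" for a in sub.accessions)


class TestProjectSummary:
    def test_heterozygosity_substitutions_and_indel_histogram(self):
        aln = make(["ARGG-TA", "AAGGCTA", "AAGSCTT"])
        m = genotype_matrix(aln.accessions, detect_variants(aln))
        summary = project_summary(m, surveyed_bp=10_000)
        assert summary.heterozygosity["a1"] == 1.0  # one het call per 10 kb
        assert summary.substitution_counts == {"A/G": 1, "C/G": 1, "A/T": 1}
        assert summary.indel_length_histogram == {1: 1}

    def test_zero_surveyed_bp_is_error(self):
        aln = make(["AT", "TT"])
        m = genotype_matrix(aln.accessions, detect_variants(aln))
        with pytest.raises(ValueError):
            project_summary(m, surveyed_bp=0)


class TestPlantedRecovery:
    def test_planted_snps_and_indels_recovered_exactly(self):
        spec = SimulationSpec(
            n_accessions=10, length=120,
            snps=[PlantedSNP(11, ("A", "G"), 0.6),
                  PlantedSNP(40, ("C", "T"), 0.3),
                  PlantedSNP(77, ("A", "C"), 0.5)],
            indels=[PlantedIndel(55, 3, absent_freq=0.3)],
            missing_rate=0.1, seed=42,
        )
        aln, truth, _ = make_alignment(spec)
        got = [variant_tuple(v) for v in detect_variants(aln)]
        assert got == [variant_tuple(v) for v in truth]

    def test_variant_table_columns(self):
        spec = SimulationSpec(
            n_accessions=6, length=50,
            snps=[PlantedSNP(10, ("A", "T"))],
            indels=[PlantedIndel(30, 2)], seed=0,
        )
        aln, truth, _ = make_alignment(spec)
        table = variant_table(
            GenotypeMatrix(aln.accessions, detect_variants(aln))
        )
        assert list(table["kind"]) == ["SNP", "indel"]
        assert table.loc[1, "indel_len"] == 2
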