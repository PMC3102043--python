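"""Group comparison, Venn sharing, experiment merging and variant queries."""

import numpy as np
import pytest

from popvar.detect import GenotypeMatrix, Variant, variant_table
from popvar.fixtures import simulate_neutral
from popvar.groups import (
    GREEN,
    WHITE,
    YELLOW,
    compare_diversity,
    group_variant_sets,
    merge_experiments,
    query_variants,
    venn,
)


def snp(pos, alleles, calls, gene="g"):
    return Variant(gene, "SNP", pos, alleles, calls)


def matrix_with_groups():
    """6 accessions, grouping g1 = a1-a3, g2 = a4-a6.

    site 1: polymorphic only in g1; site 2: polymorphic in both;
    site 3: fixed-different between groups (monomorphic within each).
    """
    accs = [f"a{i}" for i in range(1, 7)]
    v1 = snp(1, ("A", "T"), {"a1": ("A", "A"), "a2": ("A", "T"),
                             "a3": ("T", "T"), "a4": ("A", "A"),
                             "a5": ("A", "A"), "a6": ("A", "A")})
    v2 = snp(2, ("C", "G"), {"a1": ("C", "C"), "a2": ("C", "G"),
                             "a3": ("C", "C"), "a4": ("G", "G"),
                             "a5": ("C", "G"), "a6": ("C", "C")})
    v3 = snp(3, ("A", "G"), {"a1": ("A", "A"), "a2": ("A", "A"),
                             "a3": ("A", "A"), "a4": ("G", "G"),
                             "a5": ("G", "G"), "a6": ("G", "G")})
    m = GenotypeMatrix(accs, [v1, v2, v3])
    grouping = {a: ("g1" if a in {"a1", "a2", "a3"} else "g2") for a in accs}
    return m, grouping


class TestGroupVariantSets:
    def test_within_group_polymorphism_semantics(self):
        m, grouping = matrix_with_groups()
        sets = group_variant_sets(m, grouping)
        ids = {v.position: v.variant_id for v in m.variants}
        assert sets["g1"] == {ids[1], ids[2]}
        assert sets["g2"] == {ids[2]}
        # fixed-different site 3 is in neither set
        assert ids[3] not in sets["g1"] | sets["g2"]

    def test_small_group_excluded(self):
        m, grouping = matrix_with_groups()
        grouping["a6"] = "tiny"
        sets = group_variant_sets(m, grouping)
        assert "tiny" not in sets

    def test_single_group_rejected(self):
        m, _ = matrix_with_groups()
        with pytest.raises(ValueError):
            group_variant_sets(m, {a: "all" for a in m.accessions})


class TestVenn:
    def test_set_arithmetic_two_groups(self):
        report = venn({"A": {1, 2, 3}, "B": {2, 3, 4}})
        assert report.region_count("A") == 1
        assert report.region_count("A", "B") == 2
        assert report.region_count("B") == 1

    def test_disjoint_sets_share_nothing(self):
        report = venn({"A": {1}, "B": {2}})
        assert report.region_count("A", "B") == 0

    def test_inclusion_exclusion_identity_random_triples(self, rng):
        for _ in range(30):
            sets = {
                name: set(rng.integers(0, 30,
                                       size=int(rng.integers(0, 20))).tolist())
                for name in ("A", "B", "C")
            }
            report = venn(sets)
            for name in sets:
                assert report.group_total(name) == len(sets[name])
            union = set().union(*sets.values())
            total = sum(len(ids) for ids in report.regions.values())
            assert total == len(union)  # regions partition the union

    def test_pooled_cumulative_can_exceed_plain_union(self):
        m, grouping = matrix_with_groups()
        sets = group_variant_sets(m, grouping)
        report = venn(sets, m, grouping)
        key = frozenset({"g1", "g2"})
        # fixed-different site reappears when accessions are pooled
        assert report.cumulative[key] == report.union_counts[key] + 1

    def test_more_than_three_groups_fall_back_to_pairs(self):
        sets = {c: {1} for c in "ABCD"}
        reports = venn(sets)
        assert isinstance(reports, list) and len(reports) == 6


class TestCompareDiversity:
    def seqs_by_gene(self, rng, n_genes=3, n_per_group=5, L=40):
        genes = {}
        for g in range(n_genes):
            reps = simulate_neutral(2 * (2 * n_per_group), 3.0, L, 1,
                                    seed=100 + g)[0]
            per_acc = {}
            for i in range(2 * n_per_group):
                per_acc[f"a{i}"] = [reps[2 * i], reps[2 * i + 1]]
            genes[f"gene{g}"] = per_acc
        grouping = {
            f"a{i}": ("g1" if i < n_per_group else "g2")
            for i in range(2 * n_per_group)
        }
        return genes, grouping

    def test_identical_groups_give_zero_delta_and_large_p(self, rng):
        # both "groups" hold the same sequences -> dD = 0 exactly
        genes, _ = self.seqs_by_gene(rng, n_genes=1)
        per_acc = genes["gene0"]
        mirrored = {}
        grouping = {}
        for acc, seqs in per_acc.items():
            mirrored[acc + "_1"] = seqs
            mirrored[acc + "_2"] = seqs
            grouping[acc + "_1"] = "g1"
            grouping[acc + "_2"] = "g2"
        comps = compare_diversity({"gene0": mirrored}, grouping,
                                  ("g1", "g2"), n_permutations=50, seed=1)
        (c,) = comps
        assert c.delta_d == pytest.approx(0.0, abs=1e-12)
        assert c.p_value > 0.5

    def test_no_permutations_disables_flags(self, rng):
        genes, grouping = self.seqs_by_gene(rng, n_genes=1)
        (c,) = compare_diversity(genes, grouping, ("g1", "g2"),
                                 n_permutations=0)
        assert c.p_value is None and c.significant is None
        assert c.delta_d == pytest.approx(c.d_group1 - c.d_group2)

    def test_null_permutation_pvalues_center_near_half(self, rng):
        genes, grouping = self.seqs_by_gene(rng, n_genes=12)
        comps = compare_diversity(genes, grouping, ("g1", "g2"),
                                  n_permutations=60, seed=9)
        ps = [c.p_value for c in comps if c.p_value is not None]
        assert len(ps) >= 8
        assert 0.3 < float(np.mean(ps)) < 0.8


class TestMergeExperiments:
    def test_agreement_is_green(self):
        report = merge_experiments({
            (100, "A1", "exp1"): ("A", "A"),
            (100, "A1", "exp2"): ("A", "A"),
        })
        assert report.calls[(100, "A1")] == ("A", "A")
        assert report.position_status[100] == GREEN

    def test_conflict_becomes_missing_and_yellow(self):
        report = merge_experiments({
            (100, "A1", "exp1"): ("A", "A"),
            (100, "A1", "exp2"): ("A", "G"),
        })
        assert report.calls[(100, "A1")] is None
        assert report.position_status[100] == YELLOW

    def test_single_experiment_is_white(self):
        report = merge_experiments({(100, "A1", "exp1"): ("A", "G")})
        assert report.calls[(100, "A1")] == ("A", "G")
        assert report.position_status[100] == WHITE

    def test_het_comparison_is_unordered(self):
        report = merge_experiments({
            (5, "A1", "e1"): ("A", "G"),
            (5, "A1", "e2"): ("G", "A"),
        })
        assert report.calls[(5, "A1")] == ("A", "G")
        assert report.position_status[5] == GREEN

    def test_missing_does_not_conflict(self):
        report = merge_experiments({
            (5, "A1", "e1"): None,
            (5, "A1", "e2"): ("T", "T"),
        })
        assert report.calls[(5, "A1")] == ("T", "T")
        assert report.position_status[5] == GREEN

    def test_idempotent(self):
        calls = {
            (1, "A1", "e1"): ("A", "A"),
            (1, "A1", "e2"): ("A", "G"),
            (2, "A1", "e1"): ("C", "C"),
        }
        first = merge_experiments(calls)
        again = merge_experiments({
            (pos, acc, "merged"): call
            for (pos, acc), call in first.calls.items()
        })
        assert again.calls == first.calls

    def test_commutative_in_experiment_order(self):
        calls = {
            (1, "A1", "e1"): ("A", "A"),
            (1, "A1", "e2"): ("T", "T"),
            (2, "A2", "e2"): ("C", "G"),
        }
        swapped = {
            (pos, acc, {"e1": "e2", "e2": "e1"}[exp]): call
            for (pos, acc, exp), call in calls.items()
        }
        r1, r2 = merge_experiments(calls), merge_experiments(swapped)
        assert r1.calls == r2.calls
        assert r1.position_status == r2.position_status

    def test_experiment_level_bypasses_merging(self):
        calls = {
            (1, "A1", "e1"): ("A", "A"),
            (1, "A1", "e2"): ("T", "T"),
        }
        report = merge_experiments(calls, merging_level="experiment",
                                   experiment="e1")
        assert report.calls[(1, "A1")] == ("A", "A")
        assert report.position_status[1] == WHITE


class TestQueryVariants:
    @pytest.fixture
    def table(self):
        accs = ["a1", "a2", "a3", "a4", "a5"]
        variants = [
            snp(10, ("A", "T"), {a: ("A", "A") for a in accs[:-1]}
                | {"a5": ("A", "T")}),
            snp(20, ("C", "G"), {a: ("C", "G") for a in accs}),
            Variant("g", "indel", 30, ("absent", "present"),
                    {a: ("present", "present") for a in accs[:2]}
                    | {a: ("absent", "absent") for a in accs[2:]},
                    indel_length=2, indel_sequence="AT"),
            Variant("g", "indel", 40, ("absent", "present"),
                    {a: ("present", "present") for a in accs[:4]}
                    | {"a5": ("absent", "absent")},
                    indel_length=1, indel_sequence="G"),
        ]
        return variant_table(GenotypeMatrix(accs, variants))

    def test_kind_and_length_filters(self, table):
        out = query_variants(table, kind="indel", indel_length_range=(2, 99))
        assert list(out["position"]) == [30]

    def test_maf_filter_drops_singleton(self, table):
        out = query_variants(table, maf_range=(0.2, 1.0))
        assert 10 not in set(out["position"])

    def test_no_filters_returns_everything(self, table):
        assert len(query_variants(table)) == len(table)

    def test_contradictory_interval_empty_not_error(self, table):
        out = query_variants(table, interval=(1000, 500))
        assert out.empty

    def test_filter_composition(self, table):
        both = query_variants(table, kind="SNP", maf_range=(0.2, 1.0))
        f1 = query_variants(table, kind="SNP")
        f2 = query_variants(table, maf_range=(0.2, 1.0))
        merged = f1.merge(f2)
        assert sorted(both["position"]) == sorted(merged["position"])
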