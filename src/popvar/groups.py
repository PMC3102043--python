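"""Group-wise comparison and multi-experiment genotype merging.

A site belongs to a group's polymorphism set iff it is polymorphic within
that group's accessions alone, so a site fixed-different between two groups
is in neither set yet reappears when the groups' accessions are pooled --
the "newly formed when crossing groups" effect the cumulative counts
capture.  Experiment merging follows the traffic-light convention: green
when several experiments agree, yellow when they conflict (the conflicting
call is replaced by missing data), white when a single experiment covers
the position.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .detect import GenotypeMatrix, subset_accessions
from .diversity import diversity_stats

logger = logging.getLogger(__name__)

VariantId = tuple[str, int, str]  # (gene, position, kind)

GREEN = "green"
YELLOW = "yellow"
WHITE = "white"


def _polymorphic_ids(matrix: GenotypeMatrix, accessions: list[str]) -> set[VariantId]:
    out: set[VariantId] = set()
    for v in matrix.variants:
        alleles = set()
        for acc in accessions:
            call = v.calls.get(acc)
            if call is not None:
                alleles.update(call)
        if len(alleles) >= 2:
            out.add(v.variant_id)
    return out


def group_variant_sets(
    matrix: GenotypeMatrix, grouping: dict[str, str]
) -> dict[str, set[VariantId]]:
    """Per-group sets of sites polymorphic within the group alone.

    Groups with fewer than two accessions cannot segregate and are excluded
    with a warning.
    """
    members: dict[str, list[str]] = {}
    for acc in matrix.accessions:
        g = grouping.get(acc)
        if g is not None:
            members.setdefault(g, []).append(acc)
    if len(members) < 2:
        raise ValueError("grouping must cover at least 2 groups")
    sets = {}
    for g, accs in sorted(members.items()):
        if len(accs) < 2:
            logger.warning("group %r has <2 accessions; excluded", g)
            continue
        sets[g] = _polymorphic_ids(matrix, accs)
    return sets


@dataclass
class VennReport:
    """Region-by-region polymorphism sharing for 2 or 3 groups."""

    group_names: list[str]
    regions: dict[frozenset, set[VariantId]]
    cumulative: dict[frozenset, int] = field(default_factory=dict)
    union_counts: dict[frozenset, int] = field(default_factory=dict)

    def region_count(self, *names: str) -> int:
        return len(self.regions[frozenset(names)])

    def group_total(self, name: str) -> int:
        return sum(
            len(ids) for key, ids in self.regions.items() if name in key
        )


def venn(
    sets: dict[str, set[VariantId]],
    matrix: GenotypeMatrix | None = None,
    grouping: dict[str, str] | None = None,
):
    """Inclusion-exclusion regions for 2 or 3 group polymorphism sets.

    With the genotype matrix and grouping supplied, cumulative counts per
    union re-detect polymorphism on the pooled accessions (which can exceed
    the plain set union when groups are fixed for different alleles); the
    plain union counts are reported alongside.  More than 3 groups fall back
    to all pairwise reports.
    """
    names = sorted(sets)
    if len(names) < 2:
        raise ValueError("need at least 2 groups")
    if len(names) > 3:
        return [
            venn({a: sets[a], b: sets[b]}, matrix, grouping)
            for a, b in itertools.combinations(names, 2)
        ]

    regions: dict[frozenset, set[VariantId]] = {}
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(names, r):
            inside = set.intersection(*(sets[g] for g in combo))
            outside = set.union(
                *(sets[g] for g in names if g not in combo), set()
            )
            regions[frozenset(combo)] = inside - outside

    report = VennReport(group_names=names, regions=regions)
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(names, r):
            key = frozenset(combo)
            report.union_counts[key] = len(
                set.union(*(sets[g] for g in combo))
            )
            if matrix is not None and grouping is not None:
                pooled = [
                    a
                    for a in matrix.accessions
                    if grouping.get(a) in combo
                ]
                report.cumulative[key] = len(_polymorphic_ids(matrix, pooled))
    return report


@dataclass
class GeneComparison:
    gene_id: str
    d_group1: float | None
    d_group2: float | None
    delta_d: float | None
    p_value: float | None
    significant: bool | None


def compare_diversity(
    sequences_by_gene: dict[str, dict[str, list[str]]],
    grouping: dict[str, str],
    group_pair: tuple[str, str],
    n_permutations: int = 1000,
    seed: int | None = None,
    alpha: float = 0.05,
) -> list[GeneComparison]:
    """Per-gene difference in Tajima's D between two groups.

    *sequences_by_gene* maps gene -> accession -> its (two) phased
    sequences.  Significance is assessed by label permutation: accession
    group labels are shuffled *n_permutations* times and the p-value is the
    fraction of permuted |dD| at least as large as observed (with the +1
    small-sample correction).  ``n_permutations=0`` disables the test and
    only reports dD.
    """
    g1, g2 = group_pair
    rng = np.random.default_rng(seed)
    out = []
    for gene in sorted(sequences_by_gene):
        per_acc = sequences_by_gene[gene]
        accs = sorted(a for a in per_acc if grouping.get(a) in (g1, g2))
        labels = [grouping[a] for a in accs]

        def delta(lab: list[str]) -> float | None:
            s1 = [s for a, l in zip(accs, lab) if l == g1 for s in per_acc[a]]
            s2 = [s for a, l in zip(accs, lab) if l == g2 for s in per_acc[a]]
            if len(s1) < 2 or len(s2) < 2:
                return None
            d1 = diversity_stats(s1, gene).tajima_d
            d2 = diversity_stats(s2, gene).tajima_d
            if d1 is None or d2 is None:
                return None
            return d1 - d2

        obs = delta(labels)
        if obs is None:
            d1 = d2 = None
            out.append(GeneComparison(gene, None, None, None, None, None))
            continue
        d1 = diversity_stats(
            [s for a, l in zip(accs, labels) if l == g1 for s in per_acc[a]], gene
        ).tajima_d
        d2 = diversity_stats(
            [s for a, l in zip(accs, labels) if l == g2 for s in per_acc[a]], gene
        ).tajima_d
        if n_permutations <= 0:
            out.append(GeneComparison(gene, d1, d2, obs, None, None))
            continue
        hits = 0
        valid = 0
        for _ in range(n_permutations):
            perm = list(labels)
            rng.shuffle(perm)
            dd = delta(perm)
            if dd is None:
                continue
            valid += 1
            if abs(dd) >= abs(obs) - 1e-12:
                hits += 1
        p = (hits + 1) / (valid + 1) if valid else None
        out.append(
            GeneComparison(
                gene, d1, d2, obs, p, (p is not None and p < alpha)
            )
        )
    return out


Call = tuple[str, str]


@dataclass
class MergeReport:
    """Merged calls per (position, accession) with traffic-light statuses."""

    calls: dict[tuple[int, str], Call | None]
    position_status: dict[int, str]
    contributing: dict[int, list[str]]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "position": pos,
                "accession": acc,
                "call": "/".join(call) if call else "missing",
                "status": self.position_status[pos],
                "experiments": ",".join(self.contributing[pos]),
            }
            for (pos, acc), call in sorted(self.calls.items())
        ]
        return pd.DataFrame(rows)


def merge_experiments(
    calls: dict[tuple[int, str, str], Call | None],
    merging_level: str = "global",
    experiment: str | None = None,
) -> MergeReport:
    """Combine genotype calls observed in distinct experiments.

    Keys are (genomic position, accession, experiment); het calls compare
    unordered.  Per accession-position, agreeing non-missing calls merge to
    that call; any disagreement merges to missing.  Position status: white
    when a single experiment covers it, green when several experiments
    contributed without conflict, yellow when any accession conflicted.
    ``merging_level="experiment"`` restricts to one experiment and bypasses
    merging entirely.
    """
    seen: set[tuple[int, str, str]] = set()
    for key in calls:
        if key in seen:
            raise ValueError(f"duplicate call for {key}")
        seen.add(key)
    if merging_level == "experiment":
        if experiment is None:
            raise ValueError("experiment-level merging needs an experiment id")
        calls = {k: v for k, v in calls.items() if k[2] == experiment}

    by_pos_acc: dict[tuple[int, str], dict[str, Call | None]] = {}
    experiments_at: dict[int, set[str]] = {}
    for (pos, acc, exp), call in calls.items():
        by_pos_acc.setdefault((pos, acc), {})[exp] = (
            tuple(sorted(call)) if call is not None else None
        )
        experiments_at.setdefault(pos, set()).add(exp)

    merged: dict[tuple[int, str], Call | None] = {}
    conflict_at: dict[int, bool] = {}
    for (pos, acc), per_exp in by_pos_acc.items():
        non_missing = {c for c in per_exp.values() if c is not None}
        if len(non_missing) > 1:
            merged[(pos, acc)] = None  # conflict -> missing data
            conflict_at[pos] = True
        else:
            merged[(pos, acc)] = next(iter(non_missing), None)
            conflict_at.setdefault(pos, False)

    status = {}
    for pos, exps in experiments_at.items():
        if len(exps) == 1:
            status[pos] = WHITE
        elif conflict_at.get(pos):
            status[pos] = YELLOW
        else:
            status[pos] = GREEN
    return MergeReport(
        calls=merged,
        position_status=status,
        contributing={p: sorted(e) for p, e in experiments_at.items()},
    )


def query_variants(
    table: pd.DataFrame,
    chrom: str | None = None,
    interval: tuple[int, int] | None = None,
    max_missing: float | None = None,
    kind: str | None = None,
    maf_range: tuple[float, float] | None = None,
    synonymous: bool | None = None,
    indel_length_range: tuple[int, int] | None = None,
) -> pd.DataFrame:
    """Conjunctive filtering of a variant table (see ``detect.variant_table``).

    Frequencies must already have been recomputed on the accession subset of
    interest (``detect.subset_accessions``) before filtering.  A
    contradictory interval yields an empty result, not an error.
    """
    df = table
    if chrom is not None and "chrom" in df.columns:
        df = df[df["chrom"] == chrom]
    if interval is not None:
        lo, hi = interval
        col = "genomic_position" if "genomic_position" in df.columns else "position"
        df = df[(df[col] >= lo) & (df[col] <= hi)]
    if max_missing is not None:
        df = df[df["missing_frac"] <= max_missing]
    if kind is not None:
        df = df[df["kind"] == kind]
    if maf_range is not None:
        lo, hi = maf_range
        df = df[(df["maf"] >= lo) & (df["maf"] <= hi)]
    if synonymous is not None and "synonymous" in df.columns:
        df = df[df["synonymous"] == synonymous]
    if indel_length_range is not None:
        lo, hi = indel_length_range
        df = df[
            (df["kind"] == "indel")
            & (df["indel_len"] >= lo)
            & (df["indel_len"] <= hi)
        ]
    return df.reset_index(drop=True)


def recompute_on_subset(
    matrix: GenotypeMatrix, ids: list[str]
) -> GenotypeMatrix:
    """Frequencies/sites recomputed for a selected genotype subset."""
    return subset_accessions(matrix, ids=ids)
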