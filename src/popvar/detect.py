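"""SNP and indel detection from multiple sequence alignments.

The scan is a per-column parse of an equal-length alignment in which each row
is one (diploid) accession: a SNP is any column whose resolved diploid allele
multiset contains at least two distinct bases (two-fold IUPAC codes expand to
their base pair), and an indel is any maximal per-accession gap run for which
at least one other accession carries bases over the same extent.  Alleles are
then assigned back to every accession so that each variant carries a full set
of unordered diploid calls, from which per-site statistics, allelic exports
and the consensus sequence are derived.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field, replace

import pandas as pd

from ._alphabet import BASES, GAP, IUPAC_HET, MISSING, THREEFOLD, resolve

logger = logging.getLogger(__name__)

SNP = "SNP"
INDEL = "indel"

#: allele labels for binary-coded indel events
PRESENT = "present"
ABSENT = "absent"

Call = tuple[str, str]  # unordered diploid call, stored sorted


@dataclass
class Alignment:
    """Equal-length sequence matrix for one gene/amplicon, one row per accession."""

    gene_id: str
    accessions: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.accessions) != len(self.rows):
            raise ValueError("one row required per accession")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError(f"alignment rows have unequal lengths: {sorted(lengths)}")

    @property
    def n_accessions(self) -> int:
        return len(self.accessions)

    @property
    def length(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def column(self, j: int) -> str:
        """Characters of 0-based column *j*, in accession order."""
        return "".join(row[j] for row in self.rows)


@dataclass
class Variant:
    """One polymorphic event (SNP or indel) with per-accession diploid calls.

    ``position`` is the 1-based alignment column; for an indel it is the first
    column of the gap run.  Indels are binary-coded with the pseudo-alleles
    ``present``/``absent`` so that downstream phasing and LD treat them as
    biallelic sites; the deleted/inserted sequence and its length are kept.
    """

    gene_id: str
    kind: str
    position: int
    alleles: tuple[str, ...]
    calls: dict[str, Call | None]
    indel_length: int | None = None
    indel_sequence: str | None = None
    experiment: str | None = None

    @property
    def variant_id(self) -> tuple[str, int, str]:
        return (self.gene_id, self.position, self.kind)

    def observed_alleles(self) -> list[str]:
        """Distinct alleles actually observed among non-missing calls."""
        seen: set[str] = set()
        for call in self.calls.values():
            if call is not None:
                seen.update(call)
        return sorted(seen)

    @property
    def is_biallelic(self) -> bool:
        return len(self.observed_alleles()) == 2


@dataclass
class SiteStats:
    variation: str
    n_alleles: int
    freq_major: float
    freq_minor: float
    n_readable: int
    n_hom: int
    n_het: int
    allele_freqs: dict[str, float] = field(default_factory=dict)


@dataclass
class ConsensusSequence:
    gene_id: str
    sequence: str


@dataclass
class GenotypeMatrix:
    """Accessions x variants diploid call matrix with per-variant provenance."""

    accessions: list[str]
    variants: list[Variant]

    @property
    def n_accessions(self) -> int:
        return len(self.accessions)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def calls_for(self, accession: str) -> list[Call | None]:
        return [v.calls.get(accession) for v in self.variants]


@dataclass
class ColumnFilterReport:
    """1-based original column indices removed/kept by the missing-data filter."""

    removed_columns: list[int]
    kept_columns: list[int]


def filter_missing_columns(
    alignment: Alignment, threshold: float
) -> tuple[Alignment, ColumnFilterReport]:
    """Drop columns whose fraction of ``N`` exceeds *threshold*.

    This mirrors the usual cleanup of low-quality sequence ends.  The report
    retains original 1-based indices for coordinate back-mapping.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be within [0, 1]")
    n = alignment.n_accessions
    removed: list[int] = []
    kept: list[int] = []
    for j in range(alignment.length):
        n_missing = sum(1 for row in alignment.rows if row[j] == MISSING)
        if n_missing / n > threshold:
            removed.append(j + 1)
        else:
            kept.append(j + 1)
    keep0 = [k - 1 for k in kept]
    rows = ["".join(row[j] for j in keep0) for row in alignment.rows]
    filtered = Alignment(alignment.gene_id, list(alignment.accessions), rows)
    return filtered, ColumnFilterReport(removed, kept)


def _snp_at_column(alignment: Alignment, j: int) -> Variant | None:
    calls: dict[str, Call | None] = {}
    bases: Counter[str] = Counter()
    for acc, row in zip(alignment.accessions, alignment.rows):
        ch = row[j]
        if ch == GAP:
            calls[acc] = None  # structural gap: no base call at this column
            continue
        if ch in THREEFOLD:
            logger.warning(
                "three-fold ambiguity %r at %s column %d treated as missing",
                ch, alignment.gene_id, j + 1,
            )
            calls[acc] = None
            continue
        pair = resolve(ch)
        if pair is None:
            calls[acc] = None
        else:
            calls[acc] = tuple(sorted(pair))  # type: ignore[assignment]
            bases.update(pair)
    if len(bases) < 2:
        return None
    return Variant(
        gene_id=alignment.gene_id,
        kind=SNP,
        position=j + 1,
        alleles=tuple(sorted(bases)),
        calls=calls,
    )


def _gap_runs(row: str) -> list[tuple[int, int]]:
    """Maximal 0-based [start, end] runs of '-' in one row."""
    runs = []
    start = None
    for j, ch in enumerate(row):
        if ch == GAP:
            if start is None:
                start = j
        elif start is not None:
            runs.append((start, j - 1))
            start = None
    if start is not None:
        runs.append((start, len(row) - 1))
    return runs


def _indel_events(alignment: Alignment) -> list[Variant]:
    # one event per distinct gap-run extent; accessions sharing the extent
    # share the event, overlapping-but-different extents stay separate
    extents: dict[tuple[int, int], None] = {}
    for row in alignment.rows:
        for run in _gap_runs(row):
            extents[run] = None
    events = []
    for start, end in sorted(extents):
        calls: dict[str, Call | None] = {}
        present_segments: Counter[str] = Counter()
        for acc, row in zip(alignment.accessions, alignment.rows):
            seg = row[start : end + 1]
            if all(ch == GAP for ch in seg):
                calls[acc] = (ABSENT, ABSENT)
            elif all(ch in BASES or ch in IUPAC_HET for ch in seg):
                calls[acc] = (PRESENT, PRESENT)
                present_segments[seg] += 1
            else:
                calls[acc] = None  # partially gapped or missing over the extent
        if not present_segments:
            continue  # no accession carries sequence over this extent
        top = max(present_segments.values())
        seq = min(s for s, c in present_segments.items() if c == top)
        events.append(
            Variant(
                gene_id=alignment.gene_id,
                kind=INDEL,
                position=start + 1,
                alleles=(ABSENT, PRESENT),
                calls=calls,
                indel_length=end - start + 1,
                indel_sequence=seq,
            )
        )
    return events


def detect_variants(alignment: Alignment) -> list[Variant]:
    """Scan every alignment column and emit SNP and indel events.

    A heterozygous-indel state cannot be encoded in a single FASTA row, so a
    gapped row is a homozygous ``absent`` call; rows only partially gapped
    over an indel's extent are missing for that event.
    """
    if alignment.n_accessions < 2:
        raise ValueError("variant detection needs at least two accessions")
    variants: list[Variant] = []
    for j in range(alignment.length):
        snp = _snp_at_column(alignment, j)
        if snp is not None:
            variants.append(snp)
    variants.extend(_indel_events(alignment))
    variants.sort(key=lambda v: (v.position, v.kind))
    return variants


def site_stats(variant: Variant) -> SiteStats:
    """Per-site summary over allele copies (two per readable accession)."""
    copies: Counter[str] = Counter()
    n_readable = n_hom = n_het = 0
    for call in variant.calls.values():
        if call is None:
            continue
        n_readable += 1
        copies.update(call)
        if call[0] == call[1]:
            n_hom += 1
        else:
            n_het += 1
    if n_readable == 0:
        raise ValueError("site statistics undefined: all calls missing")
    total = sum(copies.values())
    freqs = {a: c / total for a, c in copies.items()}
    # alleles ordered by descending frequency, ties alphabetical
    ordered = sorted(copies, key=lambda a: (-copies[a], a))
    return SiteStats(
        variation="/".join(ordered),
        n_alleles=len(copies),
        freq_major=freqs[ordered[0]],
        freq_minor=freqs[ordered[-1]],
        n_readable=n_readable,
        n_hom=n_hom,
        n_het=n_het,
        allele_freqs=freqs,
    )


def consensus(alignment: Alignment) -> ConsensusSequence:
    """Most abundant nucleotide per column.

    Heterozygous codes contribute half a count to each of their two bases and
    ``N`` is ignored.  A column is rendered as a gap only when gaps outnumber
    all base weight combined; an all-missing column is ``N``.  Base ties break
    in the fixed order A < C < G < T.
    """
    if alignment.n_accessions == 0 or alignment.length == 0:
        raise ValueError("cannot build a consensus of an empty alignment")
    out = []
    for j in range(alignment.length):
        weight = dict.fromkeys(BASES, 0.0)
        n_gap = 0
        for row in alignment.rows:
            ch = row[j]
            if ch == GAP:
                n_gap += 1
            elif ch in IUPAC_HET:
                a, b = IUPAC_HET[ch]
                weight[a] += 0.5
                weight[b] += 0.5
            elif ch in BASES:
                weight[ch] += 1.0
        total = sum(weight.values())
        if total == 0 and n_gap == 0:
            out.append(MISSING)
        elif n_gap > total:
            out.append(GAP)
        elif total == 0:
            out.append(MISSING)
        else:
            out.append(max(BASES, key=lambda b: (weight[b], -ord(b))))
    return ConsensusSequence(alignment.gene_id, "".join(out))


def genotype_matrix(
    accessions: list[str], variants: list[Variant], experiment: str | None = None
) -> GenotypeMatrix:
    """Assemble the accessions x variants call matrix, tagging provenance."""
    if experiment is not None:
        variants = [replace(v, experiment=experiment) for v in variants]
    return GenotypeMatrix(list(accessions), list(variants))


def subset_accessions(
    obj: Alignment | GenotypeMatrix,
    ids: list[str] | None = None,
    metadata=None,
    field_name: str | None = None,
    value: str | None = None,
):
    """Restrict an alignment or genotype matrix to a subset of accessions.

    Either pass explicit *ids* or a metadata filter (``field_name == value``).
    On a genotype matrix, sites monomorphic within the subset are dropped so
    that downstream statistics see only what is polymorphic in the selection.
    """
    if ids is None:
        if metadata is None or field_name is None:
            raise ValueError("pass ids or a metadata filter")
        ids = [
            a for a in obj.accessions if metadata.label_of(a, field_name) == value
        ]
    unknown = set(ids) - set(obj.accessions)
    if unknown:
        raise KeyError(f"unknown accessions: {sorted(unknown)}")
    keep = [a for a in obj.accessions if a in set(ids)]
    if isinstance(obj, Alignment):
        idx = {a: i for i, a in enumerate(obj.accessions)}
        return Alignment(obj.gene_id, keep, [obj.rows[idx[a]] for a in keep])
    variants = []
    for v in obj.variants:
        calls = {a: v.calls.get(a) for a in keep}
        sub = replace(v, calls=calls)
        if len(sub.observed_alleles()) >= 2:
            variants.append(sub)
    return GenotypeMatrix(keep, variants)


@dataclass
class ProjectSummary:
    heterozygosity: "pd.Series"
    substitution_counts: dict[str, int]
    indel_length_histogram: dict[int, int]
    coding_counts: dict[str, int] | None = None


def project_summary(
    matrix: GenotypeMatrix,
    surveyed_bp: int | dict[str, int],
    window: int = 10_000,
    annotations=None,
) -> ProjectSummary:
    """Project-level descriptive statistics.

    Heterozygosity is the number of heterozygous calls per accession scaled to
    a fixed *window* (default 10 kb) of surveyed sequence; substitution types
    are the unordered base pairs of biallelic SNPs; indel sizes are binned at
    unit resolution.  If annotations are supplied, synonymous/non-synonymous
    and coding/non-coding counts are tabulated.
    """
    if matrix.n_variants == 0:
        raise ValueError("empty genotype matrix")

    def bp_for(acc: str) -> int:
        bp = surveyed_bp[acc] if isinstance(surveyed_bp, dict) else surveyed_bp
        if bp <= 0:
            raise ValueError(f"surveyed bp must be positive for {acc}")
        return bp

    het = {}
    for acc in matrix.accessions:
        n_het = sum(
            1
            for call in matrix.calls_for(acc)
            if call is not None and call[0] != call[1]
        )
        het[acc] = n_het * window / bp_for(acc)

    subs: Counter[str] = Counter()
    indel_hist: Counter[int] = Counter()
    for v in matrix.variants:
        if v.kind == SNP:
            obs = v.observed_alleles()
            if len(obs) == 2:
                subs["/".join(obs)] += 1
        else:
            indel_hist[v.indel_length or 0] += 1

    coding = None
    if annotations is not None:
        coding = Counter()
        for ann in annotations:
            coding["coding" if ann.region == "CDS" else "non-coding"] += 1
            if ann.synonymous is True:
                coding["synonymous"] += 1
            elif ann.synonymous is False:
                coding["non-synonymous"] += 1
        coding = dict(coding)

    return ProjectSummary(
        heterozygosity=pd.Series(het, name="het_per_window"),
        substitution_counts=dict(subs),
        indel_length_histogram=dict(sorted(indel_hist.items())),
        coding_counts=coding,
    )


def variant_table(matrix: GenotypeMatrix) -> pd.DataFrame:
    """One row per variant with its site statistics (the per-site TSV)."""
    rows = []
    for v in matrix.variants:
        st = site_stats(v)
        n_total = len(v.calls)
        rows.append(
            {
                "gene": v.gene_id,
                "position": v.position,
                "kind": v.kind,
                "variation": st.variation,
                "n_alleles": st.n_alleles,
                "freq_major": st.freq_major,
                "freq_minor": st.freq_minor,
                "maf": st.freq_minor,
                "n_readable": st.n_readable,
                "n_hom": st.n_hom,
                "n_het": st.n_het,
                "missing_frac": 1 - st.n_readable / n_total if n_total else 0.0,
                "indel_len": v.indel_length,
                "indel_seq": v.indel_sequence,
                "experiment": v.experiment,
            }
        )
    return pd.DataFrame(rows)
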