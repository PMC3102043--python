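"""Readers and writers for every external format the pipeline touches.

All public coordinates are 1-based inclusive (FASTA columns, GFF3, BLAST
tabular); any 0-based arithmetic is internal and converted at the I/O
boundary.  Writers are bit-stable given identical inputs.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import gffutils
import pandas as pd
from Bio import SeqIO

from ._alphabet import ALPHABET
from .detect import (
    ABSENT,
    INDEL,
    PRESENT,
    SNP,
    Alignment,
    GenotypeMatrix,
    Variant,
)

logger = logging.getLogger(__name__)

UNASSIGNED = "unassigned"


@dataclass
class SequenceRecord:
    identifier: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.identifier:
            raise ValueError("empty sequence identifier")
        self.sequence = self.sequence.upper()
        for i, ch in enumerate(self.sequence):
            if ch not in ALPHABET:
                raise ValueError(
                    f"illegal character {ch!r} at position {i + 1} "
                    f"in record {self.identifier!r}"
                )


@dataclass
class GeneModel:
    """Gene structure for one mRNA, 1-based inclusive genomic intervals."""

    gene_id: str
    chrom: str
    strand: str
    exon_intervals: list[tuple[int, int]]
    cds_intervals: list[tuple[int, int]]
    utr5_intervals: list[tuple[int, int]] = field(default_factory=list)
    utr3_intervals: list[tuple[int, int]] = field(default_factory=list)
    cds_phase: list[int] = field(default_factory=list)
    complete: bool = False

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        for name in ("exon_intervals", "cds_intervals", "utr5_intervals",
                     "utr3_intervals"):
            ivs = sorted(getattr(self, name))
            for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
                if s2 <= e1:
                    raise ValueError(f"overlapping {name} in {self.gene_id}")
            setattr(self, name, ivs)
        if not self.cds_phase:
            self.cds_phase = [0] * len(self.cds_intervals)
        if self.complete and self.cds_length % 3 != 0:
            raise ValueError(
                f"complete model {self.gene_id} has CDS length "
                f"{self.cds_length} not divisible by 3"
            )

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds_intervals)

    @property
    def span(self) -> tuple[int, int]:
        ivs = self.exon_intervals or self.cds_intervals
        return (min(s for s, _ in ivs), max(e for _, e in ivs))


@dataclass
class MappingHit:
    """One tabular alignment hit locating an amplicon on the genome."""

    query_id: str
    chrom: str
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    identity: float
    bitscore: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.identity <= 1.0:
            raise ValueError("identity must be a fraction in [0, 1]")

    @property
    def strand(self) -> str:
        return "-" if self.s_start > self.s_end else "+"

    @property
    def subject_interval(self) -> tuple[int, int]:
        return (min(self.s_start, self.s_end), max(self.s_start, self.s_end))


class GroupAssignment:
    """Accession metadata: per-field group labels, missing -> 'unassigned'."""

    def __init__(self, table: dict[str, dict[str, str]]):
        self._table = table
        fields: list[str] = []
        for labels in table.values():
            for f in labels:
                if f not in fields:
                    fields.append(f)
        self.fields = fields

    @property
    def accessions(self) -> list[str]:
        return list(self._table)

    def label_of(self, accession: str, field_name: str) -> str:
        return self._table.get(accession, {}).get(field_name) or UNASSIGNED

    def groups(self, field_name: str) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for acc in self._table:
            out.setdefault(self.label_of(acc, field_name), []).append(acc)
        return out

    def grouping(self, field_name: str) -> dict[str, str]:
        return {acc: self.label_of(acc, field_name) for acc in self._table}


# ---------------------------------------------------------------------------
# readers


def _template_regex(id_template: str) -> re.Pattern[str]:
    pattern = re.escape(id_template)
    pattern = pattern.replace(re.escape("{gene}"), r"(?P<gene>.+?)")
    pattern = pattern.replace(re.escape("{accession}"), r"(?P<accession>.+)")
    return re.compile(f"^{pattern}$")


def read_fasta_alignment(
    path: str | Path, id_template: str = "{gene}_{accession}"
) -> Alignment:
    """Read one equal-length FASTA alignment.

    Sequence identifiers are split into gene/amplicon and accession names with
    *id_template* (placeholders ``{gene}`` and ``{accession}``); a template
    without ``{gene}`` takes the gene name from the file stem.
    """
    path = Path(path)
    records = [SequenceRecord(r.id, str(r.seq)) for r in SeqIO.parse(path, "fasta")]
    if len(records) < 2:
        raise ValueError(f"{path}: an alignment needs at least 2 records")
    length = len(records[0].sequence)
    for rec in records:
        if len(rec.sequence) != length:
            raise ValueError(
                f"{path}: record {rec.identifier!r} has length "
                f"{len(rec.sequence)}, expected {length}"
            )
    rx = _template_regex(id_template)
    genes: set[str] = set()
    accessions: list[str] = []
    for rec in records:
        m = rx.match(rec.identifier)
        if m is None:
            raise ValueError(
                f"identifier {rec.identifier!r} does not match template "
                f"{id_template!r}"
            )
        d = m.groupdict()
        genes.add(d.get("gene") or path.stem)
        accessions.append(d["accession"])
    if len(genes) > 1:
        raise ValueError(f"{path}: mixed gene names {sorted(genes)} in one alignment")
    return Alignment(genes.pop(), accessions, [r.sequence for r in records])


_PED_MISSING = {"0", "?", "N"}
_PED_INDEL_CODE = {"I": PRESENT, "D": ABSENT}


def read_ped(path: str | Path, gene_id: str | None = None) -> GenotypeMatrix:
    """Read a linkage-pedigree genotype file (PLINK-style ``.ped`` dialect).

    Six leading pedigree columns, then one allele pair per marker; ``0`` (or
    ``?``) is missing; ``I``/``D`` code indel presence/absence.
    """
    path = Path(path)
    gene = gene_id or path.stem
    rows: list[tuple[str, list[tuple[str, str] | None]]] = []
    n_markers = None
    for lineno, line in enumerate(path.read_text().splitlines(), 1):
        if not line.strip():
            continue
        toks = line.split()
        if len(toks) < 8 or (len(toks) - 6) % 2 != 0:
            raise ValueError(
                f"{path}:{lineno}: expected 6 pedigree columns plus allele "
                f"pairs, got {len(toks)} fields"
            )
        acc = toks[1]
        alleles = toks[6:]
        if n_markers is None:
            n_markers = len(alleles) // 2
        elif len(alleles) // 2 != n_markers:
            raise ValueError(f"{path}:{lineno}: inconsistent marker count")
        calls: list[tuple[str, str] | None] = []
        for a, b in zip(alleles[::2], alleles[1::2]):
            a, b = a.upper(), b.upper()
            if a in _PED_MISSING or b in _PED_MISSING:
                calls.append(None)
            else:
                a = _PED_INDEL_CODE.get(a, a)
                b = _PED_INDEL_CODE.get(b, b)
                calls.append(tuple(sorted((a, b))))  # type: ignore[arg-type]
        rows.append((acc, calls))
    accessions = [acc for acc, _ in rows]
    variants = []
    for j in range(n_markers or 0):
        calls = {acc: row[j] for acc, row in rows}
        observed = sorted(
            {a for c in calls.values() if c is not None for a in c}
        )
        kind = INDEL if set(observed) <= {PRESENT, ABSENT} and observed else SNP
        variants.append(
            Variant(
                gene_id=gene,
                kind=kind,
                position=j + 1,
                alleles=tuple(observed) or ("?",),
                calls=calls,
                indel_length=1 if kind == INDEL else None,
            )
        )
    return GenotypeMatrix(accessions, variants)


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Parse GFF3 gene annotations into one :class:`GeneModel` per mRNA."""
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    for feat in db.features_of_type("CDS"):
        if "Parent" not in feat.attributes:
            logger.warning("CDS %s without Parent skipped", feat.id)
    models = []
    for mrna in db.features_of_type(("mRNA", "transcript")):
        exons, cds, utr5, utr3, phases = [], [], [], [], []
        for child in db.children(mrna.id, order_by="start"):
            iv = (child.start, child.end)
            if child.featuretype == "exon":
                exons.append(iv)
            elif child.featuretype == "CDS":
                cds.append(iv)
                phases.append(int(child.frame) if child.frame in "012" else 0)
            elif child.featuretype == "five_prime_UTR":
                utr5.append(iv)
            elif child.featuretype == "three_prime_UTR":
                utr3.append(iv)
        models.append(
            GeneModel(
                gene_id=mrna.id,
                chrom=mrna.seqid,
                strand=mrna.strand if mrna.strand in "+-" else "+",
                exon_intervals=exons or cds,
                cds_intervals=cds,
                utr5_intervals=utr5,
                utr3_intervals=utr3,
                cds_phase=phases,
            )
        )
    return models


def read_blast_tab(path: str | Path) -> list[MappingHit]:
    """Read 12-column tabular mapping hits, sorted per query by bitscore."""
    path = Path(path)
    hits = []
    for lineno, line in enumerate(path.read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.rstrip("\n").split("\t")
        if len(cols) < 12:
            raise ValueError(f"{path}:{lineno}: expected 12 columns, got {len(cols)}")
        hits.append(
            MappingHit(
                query_id=cols[0],
                chrom=cols[1],
                identity=float(cols[2]) / 100.0,
                q_start=int(cols[6]),
                q_end=int(cols[7]),
                s_start=int(cols[8]),
                s_end=int(cols[9]),
                bitscore=float(cols[11]),
            )
        )
    hits.sort(key=lambda h: (h.query_id, -h.bitscore))
    return hits


def read_metadata(path: str | Path) -> GroupAssignment:
    """Read the accession metadata TSV (header row, first column = id)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    id_col = df.columns[0]
    if df[id_col].duplicated().any():
        dups = sorted(df[id_col][df[id_col].duplicated()].unique())
        raise ValueError(f"duplicate accession ids in metadata: {dups}")
    table: dict[str, dict[str, str]] = {}
    for _, row in df.iterrows():
        table[row[id_col]] = {
            col: (row[col].strip() or UNASSIGNED) for col in df.columns[1:]
        }
    return GroupAssignment(table)


# ---------------------------------------------------------------------------
# writers


def write_fasta(records: list[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n{seq}\n")


def write_illumina_design(
    variants: list[Variant],
    consensus_sequence: str,
    path: str | Path,
    flank_len: int = 60,
) -> int:
    """Write the SNP-chip assay design file in bracket notation.

    One row per biallelic SNP: locus name, then ``LEFT[X/Y]RIGHT`` with up to
    *flank_len* consensus bases each side (trimmed at sequence ends).  Indels
    and multiallelic SNPs are excluded and logged.  Returns rows written.
    """
    n = 0
    with open(path, "w") as fh:
        fh.write("locus\tsequence\n")
        for v in variants:
            if v.kind != SNP:
                logger.info("indel at %s:%d excluded from chip design",
                            v.gene_id, v.position)
                continue
            obs = v.observed_alleles()
            if len(obs) != 2:
                logger.info("multiallelic SNP at %s:%d excluded from chip design",
                            v.gene_id, v.position)
                continue
            i = v.position - 1
            left = consensus_sequence[max(0, i - flank_len) : i]
            right = consensus_sequence[i + 1 : i + 1 + flank_len]
            fh.write(f"{v.gene_id}_{v.position}\t{left}[{obs[0]}/{obs[1]}]{right}\n")
            n += 1
    return n


def write_ped(matrix: GenotypeMatrix, path: str | Path, family: str = "FAM1") -> None:
    """Write the genotype matrix as a PLINK-style ``.ped`` file."""
    if matrix.n_variants == 0 or matrix.n_accessions == 0:
        raise ValueError("cannot write an empty genotype matrix")
    code = {PRESENT: "I", ABSENT: "D"}
    with open(path, "w") as fh:
        for acc in matrix.accessions:
            toks = [family, acc, "0", "0", "0", "0"]
            for call in matrix.calls_for(acc):
                if call is None:
                    toks += ["0", "0"]
                else:
                    toks += [code.get(call[0], call[0]), code.get(call[1], call[1])]
            fh.write(" ".join(toks) + "\n")


def _biallelic_codes(variant: Variant) -> dict[str, str]:
    obs = list(variant.alleles) if len(variant.alleles) == 2 \
        else variant.observed_alleles()
    if len(obs) != 2:
        raise ValueError(
            f"site {variant.gene_id}:{variant.position} is not biallelic"
        )
    if variant.kind == INDEL:
        return {PRESENT: "1", ABSENT: "0"}
    return {obs[0]: obs[0], obs[1]: obs[1]}


def write_phase_input(matrix: GenotypeMatrix, path: str | Path) -> None:
    """Write the classic PHASE v2 unphased-genotype input file.

    Header: individual count, locus count, ``P`` position line, locus-type
    line (``S`` per biallelic site, indels binary-coded); then per accession
    an id line and two allele rows (missing = ``?``).
    """
    if matrix.n_variants == 0 or matrix.n_accessions == 0:
        raise ValueError("cannot write an empty genotype matrix")
    codes = [_biallelic_codes(v) for v in matrix.variants]
    with open(path, "w") as fh:
        fh.write(f"{matrix.n_accessions}\n{matrix.n_variants}\n")
        fh.write("P " + " ".join(str(v.position) for v in matrix.variants) + "\n")
        fh.write("S" * matrix.n_variants + "\n")
        for acc in matrix.accessions:
            fh.write(f"{acc}\n")
            calls = matrix.calls_for(acc)
            for k in (0, 1):
                row = [
                    "?" if c is None else codes[j][c[k]]
                    for j, c in enumerate(calls)
                ]
                fh.write(" ".join(row) + "\n")


_STRUCTURE_CODE = {"A": "1", "C": "2", "G": "3", "T": "4",
                   PRESENT: "5", ABSENT: "6"}


def write_structure_input(matrix: GenotypeMatrix, path: str | Path) -> None:
    """Write a STRUCTURE input file, two rows (one per allele) per accession."""
    if matrix.n_variants == 0 or matrix.n_accessions == 0:
        raise ValueError("cannot write an empty genotype matrix")
    with open(path, "w") as fh:
        fh.write("\t".join(f"{v.gene_id}_{v.position}" for v in matrix.variants) + "\n")
        for acc in matrix.accessions:
            calls = matrix.calls_for(acc)
            for k in (0, 1):
                row = [
                    "-9" if c is None else _STRUCTURE_CODE.get(c[k], "-9")
                    for c in calls
                ]
                fh.write(acc + "\t" + "\t".join(row) + "\n")


def write_dot(network, path: str | Path) -> None:
    """Write a haplotype network as a Graphviz DOT graph.

    Node width is scaled so that circle *area* is proportional to haplotype
    frequency; median vectors are rendered as points; edge ``len``/``label``
    carry the number of mutational steps.
    """
    g = network.graph
    lines = ["graph haplotype_network {", "  node [shape=circle];"]
    for node in sorted(g.nodes):
        attrs = g.nodes[node]
        freq = attrs.get("frequency", 0)
        if attrs.get("is_median"):
            lines.append(f'  "{node}" [shape=point, label=""];')
        else:
            width = round((freq ** 0.5) * 0.3, 4)
            lines.append(
                f'  "{node}" [width={width}, height={width}, fixedsize=true, '
                f'label="{node} ({freq})"];'
            )
    for u, v in sorted(g.edges):
        w = g.edges[u, v].get("weight", 1)
        lines.append(f'  "{u}" -- "{v}" [label={w}, len={w}];')
    lines.append("}")
    Path(path).write_text("\n".join(lines) + "\n")


_DOT_NODE = re.compile(r'^\s*"([^"]+)"\s*\[')
_DOT_EDGE = re.compile(r'^\s*"([^"]+)"\s*--\s*"([^"]+)"\s*\[label=(\d+)')


def read_dot(path: str | Path) -> tuple[set[str], set[tuple[str, str, int]]]:
    """Node and edge sets of a DOT file written by :func:`write_dot`.

    A deliberately small parser for this package's own dialect (round-trip
    checks); it is not a general Graphviz reader.
    """
    nodes: set[str] = set()
    edges: set[tuple[str, str, int]] = set()
    for line in Path(path).read_text().splitlines():
        m = _DOT_EDGE.match(line)
        if m:
            u, v, w = m.group(1), m.group(2), int(m.group(3))
            edges.add((min(u, v), max(u, v), w))
            continue
        m = _DOT_NODE.match(line)
        if m:
            nodes.add(m.group(1))
    return nodes, edges
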