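"""Genomic placement and functional classification of variants.

An amplicon's consensus is located on the reference genome through
precomputed tabular hits (best hit by score); variant columns are projected
onto genomic coordinates by offset arithmetic, classified against gene
models (CDS > UTR > intron > intergenic), and CDS SNPs are translated with
the standard genetic code to decide synonymy.  The projection assumes the
best hit is co-linear over the variant's neighbourhood.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from Bio.Seq import Seq

from .detect import INDEL, SNP, Variant
from .formats import GeneModel, MappingHit

logger = logging.getLogger(__name__)

CDS = "CDS"
INTRON = "intron"
UTR5 = "5'UTR"
UTR3 = "3'UTR"
INTERGENIC = "intergenic"

_REGION_PRIORITY = {CDS: 0, UTR5: 1, UTR3: 1, INTRON: 2}

_COMPL = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass
class SnpAnnotation:
    variant: Variant
    chrom: str | None
    genomic_position: int | None
    region: str
    gene_id: str | None = None
    codon_ref: str | None = None
    codon_alt: str | None = None
    aa_ref: str | None = None
    aa_alt: str | None = None
    synonymous: bool | None = None
    consequence: str | None = None

    def __post_init__(self) -> None:
        if self.synonymous is not None:
            assert self.synonymous == (self.aa_ref == self.aa_alt)


def select_best_hit(hits: list[MappingHit]) -> tuple[MappingHit, int]:
    """Best hit for one query: highest score, ties by chrom then coordinate.

    The hit count is returned alongside to flag putative duplicate genes or
    pseudo-genes.
    """
    if not hits:
        raise ValueError("no hits: query is unmapped")
    queries = {h.query_id for h in hits}
    if len(queries) > 1:
        raise ValueError(f"hits for several queries passed: {sorted(queries)}")
    best = min(
        hits, key=lambda h: (-h.bitscore, h.chrom, min(h.s_start, h.s_end))
    )
    return best, len(hits)


def project_position(position: int, hit: MappingHit) -> int | None:
    """Project a 1-based query position through a hit onto the genome.

    Returns ``None`` (unplaced) when the position falls outside the aligned
    query interval.
    """
    if not hit.q_start <= position <= hit.q_end:
        return None
    offset = position - hit.q_start
    if hit.strand == "+":
        return hit.s_start + offset
    return hit.s_start - offset


def classify_region(
    chrom: str, position: int, gene_models: list[GeneModel]
) -> tuple[str, str | None]:
    """Region label for a genomic position; CDS > UTR > intron priority.

    Every position gets exactly one label; positions in no gene span are
    intergenic.
    """
    best: tuple[int, str, str] | None = None
    for model in gene_models:
        if model.chrom != chrom:
            continue
        lo, hi = model.span
        if not lo <= position <= hi:
            continue
        region = None
        if any(s <= position <= e for s, e in model.cds_intervals):
            region = CDS
        elif any(s <= position <= e for s, e in model.utr5_intervals):
            region = UTR5
        elif any(s <= position <= e for s, e in model.utr3_intervals):
            region = UTR3
        elif any(s <= position <= e for s, e in model.exon_intervals):
            # exonic but not CDS/UTR-annotated: treat as UTR-less exon -> CDS
            # only when CDS intervals are absent entirely, else intron rules
            region = CDS if not model.cds_intervals else INTRON
        else:
            region = INTRON
        cand = (_REGION_PRIORITY[region], model.gene_id, region)
        if best is None or cand[:2] < best[:2]:
            best = cand
    if best is None:
        return INTERGENIC, None
    return best[2], best[1]


def _spliced_cds_offset(model: GeneModel, position: int) -> int | None:
    """Offset of a genomic position within the spliced coding sequence."""
    segments = list(zip(model.cds_intervals, model.cds_phase))
    if model.strand == "-":
        segments = segments[::-1]
    offset = 0
    for (s, e), _phase in segments:
        if s <= position <= e:
            if model.strand == "+":
                return offset + (position - s)
            return offset + (e - position)
        offset += e - s + 1
    return None


def _spliced_cds(model: GeneModel, genome: dict[str, str]) -> str:
    chrom_seq = genome[model.chrom]
    parts = [chrom_seq[s - 1 : e] for s, e in model.cds_intervals]
    if model.strand == "-":
        parts = [str(Seq(p).reverse_complement()) for p in reversed(parts)]
    return "".join(parts).upper()


def synonymy(
    variant: Variant,
    genomic_position: int,
    model: GeneModel,
    genome: dict[str, str],
) -> SnpAnnotation:
    """Translate both alleles of a CDS SNP and decide synonymy.

    The spliced CDS is rebuilt from the genome (reverse-complemented for
    ``-`` strand genes); the first transcribed segment's phase shifts the
    reading frame; a stop-gain allele is reported as ``*`` and is
    non-synonymous.  If the reference base matches neither allele the
    mismatch is logged and the annotation still computed.
    """
    obs = variant.observed_alleles()
    if variant.kind != SNP or len(obs) != 2:
        raise ValueError("synonymy is defined for biallelic SNPs only")
    cds = _spliced_cds(model, genome)
    offset = _spliced_cds_offset(model, genomic_position)
    if offset is None:
        raise ValueError(
            f"position {genomic_position} is not inside the CDS of {model.gene_id}"
        )
    first_phase = (
        model.cds_phase[-1] if model.strand == "-" else model.cds_phase[0]
    ) if model.cds_phase else 0
    coding_offset = offset - first_phase
    if coding_offset < 0 or coding_offset >= 3 * ((len(cds) - first_phase) // 3):
        raise ValueError("position falls in an incomplete terminal codon")

    # alleles are given on the genomic (+) strand; flip for - strand genes
    if model.strand == "-":
        coding_alleles = [_COMPL[a] for a in obs]
    else:
        coding_alleles = list(obs)

    ref_base = cds[offset]
    if ref_base not in coding_alleles:
        logger.warning(
            "reference base %s at %s:%d matches neither allele %s; using "
            "alignment alleles as-is",
            ref_base, model.chrom, genomic_position, "/".join(obs),
        )
        ref_allele, alt_allele = coding_alleles
    else:
        ref_allele = ref_base
        alt_allele = next(a for a in coding_alleles if a != ref_base) \
            if coding_alleles[0] != coding_alleles[1] else coding_alleles[0]

    codon_index = coding_offset // 3
    codon_start = first_phase + 3 * codon_index
    within = offset - codon_start
    codon = cds[codon_start : codon_start + 3]
    codon_ref = codon[:within] + ref_allele + codon[within + 1 :]
    codon_alt = codon[:within] + alt_allele + codon[within + 1 :]
    aa_ref = str(Seq(codon_ref).translate())
    aa_alt = str(Seq(codon_alt).translate())
    return SnpAnnotation(
        variant=variant,
        chrom=model.chrom,
        genomic_position=genomic_position,
        region=CDS,
        gene_id=model.gene_id,
        codon_ref=codon_ref,
        codon_alt=codon_alt,
        aa_ref=aa_ref,
        aa_alt=aa_alt,
        synonymous=aa_ref == aa_alt,
    )


def coding_proportion(hit: MappingHit, gene_models: list[GeneModel]) -> float:
    """Fraction of the mapped amplicon's subject interval overlapping CDS."""
    lo, hi = hit.subject_interval
    length = hi - lo + 1
    cds = sorted(
        iv
        for m in gene_models
        if m.chrom == hit.chrom
        for iv in m.cds_intervals
    )
    covered = 0
    cursor = lo
    for s, e in cds:  # union of CDS intervals clipped to the amplicon
        s, e = max(s, cursor), min(e, hi)
        if e >= s:
            covered += e - s + 1
            cursor = e + 1
    return covered / length


def annotate_variant(
    variant: Variant,
    hits: list[MappingHit],
    gene_models: list[GeneModel],
    genome: dict[str, str] | None = None,
) -> SnpAnnotation:
    """Full annotation of one variant: projection, region, synonymy."""
    if not hits:
        return SnpAnnotation(variant, None, None, region="unmapped")
    hit, _count = select_best_hit(hits)
    pos = project_position(variant.position, hit)
    if pos is None:
        return SnpAnnotation(variant, hit.chrom, None, region="unplaced")
    region, gene_id = classify_region(hit.chrom, pos, gene_models)
    if region == CDS and variant.kind == SNP and genome is not None:
        model = next(m for m in gene_models if m.gene_id == gene_id)
        if variant.is_biallelic:
            try:
                return synonymy(variant, pos, model, genome)
            except ValueError:
                pass
    ann = SnpAnnotation(variant, hit.chrom, pos, region=region, gene_id=gene_id)
    if region == CDS and variant.kind == INDEL:
        length = variant.indel_length or 0
        ann.consequence = "in-frame" if length % 3 == 0 else "frameshift"
    return ann
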