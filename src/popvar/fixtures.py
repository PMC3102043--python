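"""Synthetic data generators.

Everything the pipeline reads can be generated here: alignments with
planted SNPs/indels/heterozygotes/missing data (plus the exact truth table
detection must recover), consistent toy genome + GFF3 pairs for annotation
tests (including a reverse-complemented mirror gene), a Hudson-style
neutral coalescent simulator for diversity and LD property tests, and a
complete multi-gene project directory for end-to-end runs.

These generators emulate Sanger-style amplicon resequencing of a diploid
panel: one IUPAC-coded row per accession, no sequencing error model, no
recombination, demography or selection.
"""

from __future__ import annotations

import logging
import zipfile
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np

from ._alphabet import IUPAC_HET, revcomp
from .detect import ABSENT, INDEL, PRESENT, SNP, Alignment, Variant
from .formats import GeneModel

logger = logging.getLogger(__name__)

_PAIR_TO_IUPAC = {pair: code for code, pair in IUPAC_HET.items()}


def _het_char(a: str, b: str) -> str:
    return _PAIR_TO_IUPAC[tuple(sorted((a, b)))]


@dataclass
class PlantedSNP:
    position: int  # 1-based alignment column
    alleles: tuple[str, str]
    allele_freq: float = 0.5  # population frequency of alleles[0]
    group_freqs: dict[str, float] | None = None  # per-group overrides


@dataclass
class PlantedIndel:
    position: int  # 1-based first column of the gap run
    length: int = 1
    absent_freq: float = 0.3  # fraction of accessions carrying the deletion


@dataclass
class SimulationSpec:
    """Study conditions for one synthetic alignment."""

    n_accessions: int = 20
    length: int = 500
    snps: list[PlantedSNP] = dc_field(default_factory=list)
    indels: list[PlantedIndel] = dc_field(default_factory=list)
    missing_rate: float = 0.0
    het_rate: float | None = None  # None -> Hardy-Weinberg proportions
    groups: dict[str, float] | None = None  # label -> fraction of accessions
    seed: int = 0
    gene_id: str = "gene1"

    def __post_init__(self) -> None:
        for rate in (self.missing_rate,):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must be within [0, 1]")
        occupied: set[int] = set()
        for s in self.snps:
            if not 1 <= s.position <= self.length:
                raise ValueError(f"SNP position {s.position} outside alignment")
            if s.position in occupied:
                raise ValueError(f"overlapping planted events at {s.position}")
            occupied.add(s.position)
        for ind in self.indels:
            cols = range(ind.position, ind.position + ind.length)
            if ind.position < 1 or ind.position + ind.length - 1 > self.length:
                raise ValueError("indel outside alignment")
            if occupied & set(cols):
                raise ValueError(f"overlapping planted events at {ind.position}")
            occupied.update(cols)


def _assign_groups(spec: SimulationSpec, accessions: list[str]) -> dict[str, str]:
    if not spec.groups:
        return {}
    labels = sorted(spec.groups)
    counts = {
        g: int(round(spec.groups[g] * len(accessions))) for g in labels
    }
    grouping = {}
    i = 0
    for g in labels:
        for _ in range(counts[g]):
            if i < len(accessions):
                grouping[accessions[i]] = g
                i += 1
    while i < len(accessions):  # remainder to the last group
        grouping[accessions[i]] = labels[-1]
        i += 1
    return grouping


def make_alignment(
    spec: SimulationSpec,
) -> tuple[Alignment, list[Variant], dict[str, str]]:
    """Generate an alignment with planted variation and its truth table.

    Returns (alignment, truth variants, accession grouping).  Running the
    detector on the alignment must recover exactly the truth table:
    positions, alleles, per-accession diploid calls.
    """
    rng = np.random.default_rng(spec.seed)
    accessions = [f"acc{i + 1:02d}" for i in range(spec.n_accessions)]
    grouping = _assign_groups(spec, accessions)

    background = rng.choice(list("ACGT"), size=spec.length)
    rows = [[str(b) for b in background] for _ in accessions]

    truth: list[Variant] = []
    for snp in sorted(spec.snps, key=lambda s: s.position):
        j = snp.position - 1
        a, b = snp.alleles
        calls: dict[str, tuple[str, str] | None] = {}
        for i, acc in enumerate(accessions):
            p = snp.allele_freq
            if snp.group_freqs and grouping.get(acc) in snp.group_freqs:
                p = snp.group_freqs[grouping[acc]]
            if spec.het_rate is not None and rng.random() < spec.het_rate:
                call = tuple(sorted((a, b)))
            elif spec.het_rate is not None:
                call = (a, a) if rng.random() < p else (b, b)
            else:  # Hardy-Weinberg: two independent allele copies
                copies = tuple(
                    a if rng.random() < p else b for _ in range(2)
                )
                call = tuple(sorted(copies))
            if rng.random() < spec.missing_rate:
                rows[i][j] = "N"
                calls[acc] = None
            else:
                rows[i][j] = call[0] if call[0] == call[1] else _het_char(*call)
                calls[acc] = call
        observed = {x for c in calls.values() if c for x in c}
        if len(observed) < 2:  # force the site polymorphic
            for k, forced in ((0, (a, a)), (1, (b, b))):
                rows[k][j] = forced[0]
                calls[accessions[k]] = forced
        bases = sorted({x for c in calls.values() if c for x in c})
        truth.append(
            Variant(spec.gene_id, SNP, snp.position, tuple(bases), calls)
        )

    for ind in sorted(spec.indels, key=lambda x: x.position):
        j0 = ind.position - 1
        calls = {}
        absent = [bool(rng.random() < ind.absent_freq) for _ in accessions]
        if not any(absent):
            absent[-1] = True
        if all(absent):
            absent[0] = False
        seg = "".join(str(background[k]) for k in range(j0, j0 + ind.length))
        for i, acc in enumerate(accessions):
            if absent[i]:
                for k in range(j0, j0 + ind.length):
                    rows[i][k] = "-"
                calls[acc] = (ABSENT, ABSENT)
            else:
                calls[acc] = (PRESENT, PRESENT)
        truth.append(
            Variant(
                spec.gene_id,
                INDEL,
                ind.position,
                (ABSENT, PRESENT),
                calls,
                indel_length=ind.length,
                indel_sequence=seg,
            )
        )

    truth.sort(key=lambda v: (v.position, v.kind))
    alignment = Alignment(
        spec.gene_id, accessions, ["".join(r) for r in rows]
    )
    return alignment, truth, grouping


@dataclass
class GeneFixture:
    """A toy genome/annotation pair with a forward gene and its mirror twin."""

    genome: dict[str, str]
    models: list[GeneModel]
    forward: GeneModel
    mirror: GeneModel

    def genomic_position(self, cds_offset: int, mirrored: bool = False) -> int:
        """Genomic 1-based position of a 0-based offset in the spliced CDS."""
        model = self.mirror if mirrored else self.forward
        segments = list(model.cds_intervals)
        if model.strand == "-":
            segments = segments[::-1]
        remaining = cds_offset
        for s, e in segments:
            seg_len = e - s + 1
            if remaining < seg_len:
                return s + remaining if model.strand == "+" else e - remaining
            remaining -= seg_len
        raise ValueError("offset beyond CDS")


def make_gene_fixture(
    cds_segments: list[str],
    intron_len: int = 20,
    utr5_len: int = 12,
    utr3_len: int = 9,
    pad: int = 30,
    chrom: str = "chrF",
    seed: int = 0,
) -> GeneFixture:
    """Build a consistent genome + gene model, plus a reverse-strand mirror.

    The mirror chromosome is the reverse complement of the forward one, with
    the gene model's intervals mirrored and its strand flipped, so synonymy
    calls on the two twins must agree site for site.
    """
    total_cds = sum(len(s) for s in cds_segments)
    if total_cds % 3 != 0:
        raise ValueError("total CDS length must be divisible by 3")
    rng = np.random.default_rng(seed)

    def rand(n: int) -> str:
        return "".join(rng.choice(list("ACGT"), size=n))

    pieces = [rand(pad), rand(utr5_len)]
    pos = pad + utr5_len
    utr5 = [(pad + 1, pad + utr5_len)] if utr5_len else []
    cds_intervals = []
    for k, seg in enumerate(cds_segments):
        if k > 0:
            pieces.append(rand(intron_len))
            pos += intron_len
        cds_intervals.append((pos + 1, pos + len(seg)))
        pieces.append(seg)
        pos += len(seg)
    utr3 = [(pos + 1, pos + utr3_len)] if utr3_len else []
    pieces.append(rand(utr3_len))
    pos += utr3_len
    pieces.append(rand(pad))
    pos += pad
    seq = "".join(pieces)
    assert len(seq) == pos

    exons = []
    if utr5:
        exons.append((utr5[0][0], cds_intervals[0][1]))
    else:
        exons.append(cds_intervals[0])
    for iv in cds_intervals[1:-1]:
        exons.append(iv)
    if len(cds_intervals) > 1:
        last = cds_intervals[-1]
        exons.append((last[0], utr3[0][1] if utr3 else last[1]))
    elif utr3:
        exons[0] = (exons[0][0], utr3[0][1])

    forward = GeneModel(
        gene_id="gene_fwd",
        chrom=chrom,
        strand="+",
        exon_intervals=exons,
        cds_intervals=cds_intervals,
        utr5_intervals=utr5,
        utr3_intervals=utr3,
        complete=True,
    )

    L = len(seq)
    mirror_chrom = chrom + "_rc"

    def flip(iv: tuple[int, int]) -> tuple[int, int]:
        s, e = iv
        return (L - e + 1, L - s + 1)

    mirror = GeneModel(
        gene_id="gene_rev",
        chrom=mirror_chrom,
        strand="-",
        exon_intervals=sorted(flip(iv) for iv in exons),
        cds_intervals=sorted(flip(iv) for iv in cds_intervals),
        utr5_intervals=sorted(flip(iv) for iv in utr5),
        utr3_intervals=sorted(flip(iv) for iv in utr3),
        complete=True,
    )
    genome = {chrom: seq, mirror_chrom: revcomp(seq)}
    return GeneFixture(genome, [forward, mirror], forward, mirror)


def simulate_neutral(
    n: int,
    theta: float,
    L: int,
    replicates: int = 1,
    seed: int | None = None,
) -> list[list[str]]:
    """Neutral-coalescent haplotype samples (Hudson-style, infinite sites).

    For each replicate a single coalescent genealogy is drawn (exponential
    coalescence times at rate k(k-1)/2), mutations fall on branches as a
    Poisson process with rate theta/2 per unit branch length, and each
    mutation is mapped to a distinct position on an L-site grid (ancestral
    ``A``, derived ``T``).  If more mutations arise than grid positions, the
    surplus is placed with replacement and a warning is logged (finite-grid
    approximation of infinite sites).
    """
    if n < 2:
        raise ValueError("need n >= 2 samples")
    if theta < 0:
        raise ValueError("theta must be non-negative")
    rng = np.random.default_rng(seed)
    reps = []
    for _ in range(replicates):
        lineages: list[frozenset[int]] = [frozenset([i]) for i in range(n)]
        pending = [0.0] * n
        branches: list[tuple[frozenset[int], float]] = []
        while len(lineages) > 1:
            k = len(lineages)
            t = rng.exponential(2.0 / (k * (k - 1)))
            pending = [x + t for x in pending]
            i, j = sorted(rng.choice(k, size=2, replace=False))
            branches.append((lineages[i], pending[i]))
            branches.append((lineages[j], pending[j]))
            merged = lineages[i] | lineages[j]
            for idx in (j, i):  # j first: higher index
                del lineages[idx]
                del pending[idx]
            lineages.append(merged)
            pending.append(0.0)
        total = sum(length for _, length in branches)
        n_mut = int(rng.poisson(theta / 2.0 * total)) if total > 0 else 0
        if n_mut > L:
            logger.warning(
                "%d mutations exceed %d sites; placing surplus with replacement",
                n_mut, L,
            )
            positions = rng.integers(0, L, size=n_mut)
        else:
            positions = rng.choice(L, size=n_mut, replace=False)
        seqs = [["A"] * L for _ in range(n)]
        if n_mut and total > 0:
            weights = np.array([length for _, length in branches])
            weights = weights / weights.sum()
            chosen = rng.choice(len(branches), size=n_mut, p=weights)
        else:
            chosen = []
        for pos, bidx in zip(positions, chosen):
            for leaf in branches[bidx][0]:
                seqs[leaf][int(pos)] = "T"
        reps.append(["".join(s) for s in seqs])
    return reps


def make_project(
    outdir: str | Path,
    n_genes: int = 10,
    n_accessions: int = 12,
    seed: int = 0,
) -> Path:
    """Write a complete synthetic multi-gene project directory.

    Contents: ``alignments.zip`` (one FASTA per gene, ids ``{gene}_{acc}``),
    ``genome.fasta`` + ``annotations.gff3`` (each amplicon embedded in a toy
    chromosome with a single-mRNA gene model), ``hits.tsv`` (12-column
    tabular hits locating each amplicon), ``metadata.tsv`` (origin/status
    groups).  Suitable as direct input to the pipeline runner.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    chrom_seqs: dict[str, list[str]] = {"chr1": [], "chr2": []}
    gff_lines = ["##gff-version 3"]
    hit_lines = []
    fasta_files: dict[str, str] = {}
    offsets = {"chr1": 0, "chr2": 0}

    for g in range(n_genes):
        gene = f"gene{g + 1:02d}"
        length = 120 + 30 * int(rng.integers(0, 3))
        n_snps = 3 + int(rng.integers(0, 3))
        positions = sorted(
            int(p) + 1
            for p in rng.choice(np.arange(10, length - 10), size=n_snps + 1,
                                replace=False)
        )
        indel_pos = positions.pop(int(rng.integers(0, len(positions))))
        snps = [
            PlantedSNP(
                position=p,
                alleles=tuple(rng.choice(list("ACGT"), size=2, replace=False)),
                allele_freq=float(rng.uniform(0.2, 0.8)),
            )
            for p in positions
        ]
        spec = SimulationSpec(
            n_accessions=n_accessions,
            length=length,
            snps=snps,
            indels=[PlantedIndel(position=indel_pos, length=1,
                                 absent_freq=0.25)],
            missing_rate=0.02,
            groups={"south": 0.34, "east": 0.33, "west": 0.33},
            seed=int(rng.integers(0, 2**31 - 1)),
            gene_id=gene,
        )
        alignment, _truth, _grouping = make_alignment(spec)
        fasta = "".join(
            f">{gene}_{acc}\n{row}\n"
            for acc, row in zip(alignment.accessions, alignment.rows)
        )
        fasta_files[f"{gene}.fa"] = fasta

        # embed the (gap-free) consensus in a toy chromosome
        from .detect import consensus as _consensus

        cons = _consensus(alignment).sequence.replace("-", "A").replace("N", "A")
        chrom = "chr1" if g % 2 == 0 else "chr2"
        pad = 40
        start = offsets[chrom] + pad + 1  # 1-based start of the amplicon
        chrom_seqs[chrom].append("A" * pad + cons + "A" * pad)
        offsets[chrom] += pad + length + pad
        # single-exon gene model over the middle of the amplicon
        cds_len = 3 * ((length - 40) // 3)
        cds_s = start + 20
        cds_e = cds_s + cds_len - 1
        mrna = f"{gene}.1"
        gff_lines += [
            f"{chrom}\tsynth\tgene\t{start}\t{start + length - 1}\t.\t+\t.\tID={gene}",
            f"{chrom}\tsynth\tmRNA\t{start}\t{start + length - 1}\t.\t+\t.\t"
            f"ID={mrna};Parent={gene}",
            f"{chrom}\tsynth\texon\t{start}\t{start + length - 1}\t.\t+\t.\t"
            f"Parent={mrna}",
            f"{chrom}\tsynth\tfive_prime_UTR\t{start}\t{cds_s - 1}\t.\t+\t.\t"
            f"Parent={mrna}",
            f"{chrom}\tsynth\tCDS\t{cds_s}\t{cds_e}\t.\t+\t0\tParent={mrna}",
            f"{chrom}\tsynth\tthree_prime_UTR\t{cds_e + 1}\t{start + length - 1}"
            f"\t.\t+\t.\tParent={mrna}",
        ]
        hit_lines.append(
            f"{gene}\t{chrom}\t100.00\t{length}\t0\t0\t1\t{length}\t{start}\t"
            f"{start + length - 1}\t1e-50\t{2 * length:.1f}"
        )

    with zipfile.ZipFile(outdir / "alignments.zip", "w") as zf:
        for name in sorted(fasta_files):
            zf.writestr(name, fasta_files[name])
    with open(outdir / "genome.fasta", "w") as fh:
        for chrom in sorted(chrom_seqs):
            fh.write(f">{chrom}\n{''.join(chrom_seqs[chrom])}\n")
    (outdir / "annotations.gff3").write_text("\n".join(gff_lines) + "\n")
    (outdir / "hits.tsv").write_text("\n".join(hit_lines) + "\n")

    origins = ["south", "east", "west"]
    lines = ["id\torigin\tstatus"]
    for i in range(n_accessions):
        lines.append(
            f"acc{i + 1:02d}\t{origins[i % 3]}\t"
            f"{'wild' if i % 2 else 'cultivated'}"
        )
    (outdir / "metadata.tsv").write_text("\n".join(lines) + "\n")
    return outdir
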