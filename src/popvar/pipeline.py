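"""Orchestration of the seven-step analysis workflow.

Steps run in dependency order: detection -> mapping -> annotation ->
phasing -> LD -> diversity -> haplotype network (plus optional group
comparison when metadata is supplied).  Genotype-only input (PED) disables
the sequence-dependent steps (mapping, annotation, diversity).  Every run
writes a JSON manifest recording parameters, seeds and per-step status so
that two runs with the same configuration and seed are byte-identical.
"""

from __future__ import annotations

import json
import logging
import zipfile
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import pandas as pd

from . import __version__
from . import annotate as ann_mod
from . import detect as det
from . import formats, groups as grp, ld as ld_mod, network as net
from .diversity import diversity_map, diversity_stats
from .phase import complete_sequences, em_phase

logger = logging.getLogger(__name__)

STEPS = ["detect", "map", "annotate", "phase", "ld", "diversity", "network"]

#: step -> steps it needs
_REQUIRES = {
    "map": ["detect"],
    "annotate": ["detect", "map"],
    "phase": ["detect"],
    "ld": ["phase"],
    "diversity": ["phase"],
    "network": ["phase"],
    "compare": ["detect", "phase"],
}


class LimitExceeded(ValueError):
    pass


@dataclass
class Limits:
    """Input caps; they were sized for a shared server and stay overridable."""

    max_alignments: int = 4000
    max_sequences_per_alignment: int = 200
    max_snps: int = 500
    max_accessions: int = 500


@dataclass
class RunConfig:
    outdir: Path
    alignments: Path | None = None  # FASTA file, directory or zip
    ped: Path | None = None
    genome: Path | None = None
    gff3: Path | None = None
    hits: Path | None = None
    metadata: Path | None = None
    id_template: str = "{gene}_{accession}"
    missing_threshold: float = 1.0
    subset: list[str] | None = None
    group_field: str | None = None
    steps: list[str] = dc_field(default_factory=lambda: list(STEPS))
    seed: int = 0
    flank_len: int = 60
    n_permutations: int = 100
    limits: Limits = dc_field(default_factory=Limits)
    override_limits: bool = False

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        if (self.alignments is None) == (self.ped is None):
            raise ValueError("exactly one of alignments/ped must be given")
        for attr in ("alignments", "ped", "genome", "gff3", "hits", "metadata"):
            val = getattr(self, attr)
            if val is not None:
                val = Path(val)
                setattr(self, attr, val)
                if not val.exists():
                    raise FileNotFoundError(f"{attr} input not found: {val}")


def enforce_limits(
    counts: dict[str, int], limits: Limits, override: bool = False
) -> None:
    checks = [
        ("n_alignments", limits.max_alignments, "alignment files"),
        ("max_sequences", limits.max_sequences_per_alignment,
         "sequences in one alignment"),
        ("n_snps", limits.max_snps, "SNPs"),
        ("n_accessions", limits.max_accessions, "accessions"),
    ]
    for key, cap, what in checks:
        if counts.get(key, 0) > cap:
            msg = f"input exceeds the configured cap: {counts[key]} {what} > {cap}"
            if override:
                logger.warning("%s (accepted: limits overridden)", msg)
            else:
                raise LimitExceeded(msg)


def _load_alignments(config: RunConfig) -> list[det.Alignment]:
    src = config.alignments
    assert src is not None
    paths: list[Path] = []
    if src.is_dir():
        paths = sorted(src.glob("*.fa")) + sorted(src.glob("*.fasta"))
    elif src.suffix == ".zip":
        tmp = config.outdir / "_alignments"
        tmp.mkdir(parents=True, exist_ok=True)
        with zipfile.ZipFile(src) as zf:
            zf.extractall(tmp)
        paths = sorted(tmp.rglob("*.fa")) + sorted(tmp.rglob("*.fasta"))
    else:
        paths = [src]
    alignments = [
        formats.read_fasta_alignment(p, config.id_template) for p in paths
    ]
    return sorted(alignments, key=lambda a: a.gene_id)


def run(config: RunConfig) -> dict:
    """Execute the configured steps and return the manifest (also written).

    A step failure marks its dependents skipped and the manifest
    ``ok=False``; the command-line wrapper turns that into a nonzero exit.
    """
    out = config.outdir
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "parameters": {
            "id_template": config.id_template,
            "missing_threshold": config.missing_threshold,
            "flank_len": config.flank_len,
            "n_permutations": config.n_permutations,
        },
        "steps": {},
        "ok": True,
    }
    status = manifest["steps"]

    genotype_only = config.ped is not None
    enabled = [s for s in STEPS if s in config.steps]
    if config.metadata is not None and "compare" not in enabled:
        enabled.append("compare")
    if genotype_only:
        for s in ("map", "annotate", "diversity"):
            if s in enabled:
                enabled.remove(s)
                status[s] = {"status": "disabled",
                             "reason": "sequence information lacking"}
    for s in STEPS + ["compare"]:
        status.setdefault(s, {"status": "skipped"})
        if s in enabled:
            status[s] = {"status": "pending"}

    done: set[str] = set()
    failed: set[str] = set()

    def ready(step: str) -> bool:
        return all(r in done for r in _REQUIRES.get(step, []))

    state: dict = {}

    for step in [s for s in STEPS + ["compare"] if s in enabled]:
        if not ready(step):
            status[step] = {"status": "skipped",
                            "reason": "upstream step failed or disabled"}
            continue
        try:
            info = _STEP_FUNCS[step](config, state)
            status[step] = {"status": "ok", **(info or {})}
            done.add(step)
        except Exception as exc:  # noqa: BLE001 - manifest records any failure
            logger.exception("step %s failed", step)
            status[step] = {"status": "failed", "error": str(exc)}
            failed.add(step)
            manifest["ok"] = False

    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return manifest


# ---------------------------------------------------------------------------
# individual steps; each receives the shared mutable state dict


def _step_detect(config: RunConfig, state: dict) -> dict:
    out = config.outdir
    metadata = (
        formats.read_metadata(config.metadata) if config.metadata else None
    )
    state["metadata"] = metadata

    if config.ped is not None:
        matrix = formats.read_ped(config.ped)
        if config.subset:
            matrix = det.subset_accessions(matrix, ids=config.subset)
        state["matrices"] = {matrix.variants[0].gene_id if matrix.variants
                             else "ped": matrix}
        state["consensus"] = {}
        enforce_limits(
            {
                "n_alignments": 1,
                "n_snps": matrix.n_variants,
                "n_accessions": matrix.n_accessions,
            },
            config.limits,
            config.override_limits,
        )
        det.variant_table(matrix).to_csv(out / "site_stats.tsv", sep="\t",
                                         index=False)
        formats.write_phase_input(matrix, out / "allelic.phase.inp")
        formats.write_structure_input(matrix, out / "allelic.structure.tsv")
        return {"genes": 1, "variants": matrix.n_variants,
                "accessions": matrix.n_accessions}

    alignments = _load_alignments(config)
    enforce_limits(
        {
            "n_alignments": len(alignments),
            "max_sequences": max(a.n_accessions for a in alignments),
        },
        config.limits,
        config.override_limits,
    )
    matrices: dict[str, det.GenotypeMatrix] = {}
    consensus: dict[str, str] = {}
    filter_reports = {}
    tables = []
    for alignment in alignments:
        if config.subset:
            alignment = det.subset_accessions(alignment, ids=config.subset)
        alignment, report = det.filter_missing_columns(
            alignment, config.missing_threshold
        )
        filter_reports[alignment.gene_id] = len(report.removed_columns)
        variants = det.detect_variants(alignment)
        matrix = det.genotype_matrix(alignment.accessions, variants)
        matrices[alignment.gene_id] = matrix
        cons = det.consensus(alignment).sequence
        consensus[alignment.gene_id] = cons
        tables.append(det.variant_table(matrix))
        formats.write_illumina_design(
            variants, cons, out / f"{alignment.gene_id}.design.tsv",
            config.flank_len,
        )
        if variants:
            formats.write_ped(matrix, out / f"{alignment.gene_id}.ped")
            formats.write_phase_input(matrix,
                                      out / f"{alignment.gene_id}.phase.inp")
            formats.write_structure_input(
                matrix, out / f"{alignment.gene_id}.structure.tsv"
            )
    n_snps = sum(
        sum(1 for v in m.variants if v.kind == det.SNP)
        for m in matrices.values()
    )
    n_acc = max(m.n_accessions for m in matrices.values())
    enforce_limits(
        {"n_snps": n_snps, "n_accessions": n_acc},
        config.limits, config.override_limits,
    )
    pd.concat(tables, ignore_index=True).to_csv(
        out / "site_stats.tsv", sep="\t", index=False
    )
    formats.write_fasta(
        sorted(consensus.items()), out / "consensus.fasta"
    )
    state["matrices"] = matrices
    state["consensus"] = consensus
    state["filter_reports"] = filter_reports
    return {
        "genes": len(matrices),
        "variants": sum(m.n_variants for m in matrices.values()),
        "snps": n_snps,
        "removed_columns": sum(filter_reports.values()),
    }


def _step_map(config: RunConfig, state: dict) -> dict:
    if config.hits is None:
        raise ValueError("mapping needs a tabular hits file")
    hits = formats.read_blast_tab(config.hits)
    by_query: dict[str, list] = {}
    for h in hits:
        by_query.setdefault(h.query_id, []).append(h)
    best = {}
    rows = []
    for gene in sorted(state["matrices"]):
        if gene in by_query:
            hit, count = ann_mod.select_best_hit(by_query[gene])
            best[gene] = hit
            lo, hi = hit.subject_interval
            rows.append({"gene": gene, "chrom": hit.chrom, "start": lo,
                         "end": hi, "strand": hit.strand, "n_hits": count})
        else:
            rows.append({"gene": gene, "chrom": None, "start": None,
                         "end": None, "strand": None, "n_hits": 0})
    pd.DataFrame(rows).to_csv(config.outdir / "mapping.tsv", sep="\t",
                              index=False)
    state["best_hits"] = best
    return {"mapped": len(best), "unmapped": len(rows) - len(best)}


def _read_genome(path: Path) -> dict[str, str]:
    from Bio import SeqIO

    return {r.id: str(r.seq).upper() for r in SeqIO.parse(path, "fasta")}


def _step_annotate(config: RunConfig, state: dict) -> dict:
    if config.gff3 is None:
        raise ValueError("annotation needs a GFF3 file")
    models = formats.read_gff3(config.gff3)
    genome = _read_genome(config.genome) if config.genome else None
    best = state.get("best_hits", {})
    rows = []
    annotations = {}
    for gene in sorted(state["matrices"]):
        hit = best.get(gene)
        hit_list = [hit] if hit else []
        for v in state["matrices"][gene].variants:
            a = ann_mod.annotate_variant(v, hit_list, models, genome)
            annotations[(gene, v.position, v.kind)] = a
            rows.append(
                {
                    "gene": gene,
                    "position": v.position,
                    "kind": v.kind,
                    "chrom": a.chrom,
                    "genomic_position": a.genomic_position,
                    "region": a.region,
                    "gene_model": a.gene_id,
                    "codon_ref": a.codon_ref,
                    "codon_alt": a.codon_alt,
                    "aa_ref": a.aa_ref,
                    "aa_alt": a.aa_alt,
                    "synonymous": a.synonymous,
                    "consequence": a.consequence,
                }
            )
        if hit is not None:
            rows[-1]["coding_proportion"] = ann_mod.coding_proportion(
                hit, models
            )
    pd.DataFrame(rows).to_csv(config.outdir / "annotations.tsv", sep="\t",
                              index=False)
    state["annotations"] = annotations
    n_syn = sum(1 for a in annotations.values() if a.synonymous is True)
    n_non = sum(1 for a in annotations.values() if a.synonymous is False)
    return {"annotated": len(annotations), "synonymous": n_syn,
            "non_synonymous": n_non}


def _biallelic(matrix: det.GenotypeMatrix) -> det.GenotypeMatrix:
    keep = [v for v in matrix.variants if v.is_biallelic]
    return det.GenotypeMatrix(matrix.accessions, keep)


def _step_phase(config: RunConfig, state: dict) -> dict:
    rows = []
    hapsets = {}
    for gene, matrix in sorted(state["matrices"].items()):
        bi = _biallelic(matrix)
        if bi.n_variants == 0:
            continue
        hapset = em_phase(bi, seed=config.seed)
        hapsets[gene] = hapset
        for acc in sorted(hapset.pairs):
            haps = hapset.haplotypes_of(acc)
            if haps is None:
                rows.append({"gene": gene, "accession": acc, "hap1": None,
                             "hap2": None, "posterior": None})
            else:
                rows.append(
                    {
                        "gene": gene,
                        "accession": acc,
                        "hap1": hapset.haplotype_string(haps[0]),
                        "hap2": hapset.haplotype_string(haps[1]),
                        "posterior": round(hapset.posteriors[acc], 6),
                    }
                )
    pd.DataFrame(rows).to_csv(config.outdir / "phased.tsv", sep="\t",
                              index=False)
    state["hapsets"] = hapsets

    completed = {}
    for gene, hapset in hapsets.items():
        cons = state["consensus"].get(gene)
        if cons:
            seqs = complete_sequences(hapset, cons)
            completed[gene] = seqs
            formats.write_fasta(seqs, config.outdir / f"{gene}.phased.fasta")
    state["completed"] = completed
    return {"phased_genes": len(hapsets)}


def _step_ld(config: RunConfig, state: dict) -> dict:
    frames = []
    for gene, hapset in sorted(state["hapsets"].items()):
        df = ld_mod.ld_matrix(hapset)
        if df.empty:
            continue
        df.insert(0, "gene", gene)
        frames.append(df)
    table = (
        pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    )
    table.to_csv(config.outdir / "ld.tsv", sep="\t", index=False)
    return {"pairs": int(len(table))}


def _step_diversity(config: RunConfig, state: dict) -> dict:
    stats = []
    rows = []
    for gene, seqs in sorted(state["completed"].items()):
        # indels shift lengths; diversity runs on the SNP-substituted common
        # length when all sequences agree, else on the truncated overlap
        L = min(len(s) for _, s in seqs)
        st = diversity_stats([s[:L] for _, s in seqs], gene)
        stats.append(st)
        rows.append(
            {
                "gene": gene,
                "n": st.n,
                "L": st.L,
                "S": st.S,
                "pi_total": st.pi_total,
                "pi_per_site": st.pi_per_site,
                "theta_w": st.theta_w,
                "H": st.H,
                "Hd": st.Hd,
                "tajima_d": st.tajima_d,
            }
        )
    pd.DataFrame(rows).to_csv(config.outdir / "diversity.tsv", sep="\t",
                              index=False)
    state["diversity"] = stats

    best = state.get("best_hits", {})
    positions = {}
    for st in stats:
        hit = best.get(st.gene_id)
        if hit is not None and st.tajima_d is not None:
            lo, hi = hit.subject_interval
            positions[st.gene_id] = (hit.chrom, (lo + hi) // 2)
    mappable = [s for s in stats
                if s.gene_id in positions and s.tajima_d is not None]
    if mappable:
        entries = diversity_map(mappable, positions)
        pd.DataFrame(
            [
                {
                    "gene": e.gene_id,
                    "chrom": e.chrom,
                    "position": e.position,
                    "tajima_d": e.tajima_d,
                    "class": e.classification,
                    "quantile": e.empirical_quantile,
                }
                for e in entries
            ]
        ).to_csv(config.outdir / "diversity_map.tsv", sep="\t", index=False)
    return {"genes": len(stats), "mapped_on_diversity_map": len(mappable)}


def _step_network(config: RunConfig, state: dict) -> dict:
    metadata = state.get("metadata")
    grouping = None
    if metadata is not None:
        field_name = config.group_field or (
            metadata.fields[0] if metadata.fields else None
        )
        if field_name:
            grouping = metadata.grouping(field_name)
    built = 0
    for gene, hapset in sorted(state["hapsets"].items()):
        haps = hapset.all_haplotype_strings()
        if not haps:
            continue
        nw = net.build_mjn(haps)
        acc_haps = {}
        for acc in hapset.pairs:
            pair = hapset.haplotypes_of(acc)
            if pair is not None:
                acc_haps[acc] = (
                    hapset.haplotype_string(pair[0]),
                    hapset.haplotype_string(pair[1]),
                )
        net.attach_groups(nw, acc_haps, grouping)
        net.network_layout_export(nw, config.outdir / f"{gene}.network.dot")
        pd.DataFrame(nw.node_table()).to_csv(
            config.outdir / f"{gene}.network_nodes.tsv", sep="\t", index=False
        )
        built += 1
    return {"networks": built}


def _step_compare(config: RunConfig, state: dict) -> dict:
    metadata = state.get("metadata")
    if metadata is None:
        raise ValueError("group comparison needs accession metadata")
    field_name = config.group_field or metadata.fields[0]
    grouping = metadata.grouping(field_name)

    variants = [v for m in state["matrices"].values() for v in m.variants]
    accessions = sorted(
        {a for m in state["matrices"].values() for a in m.accessions}
    )
    pooled = det.GenotypeMatrix(accessions, variants)
    sets = grp.group_variant_sets(pooled, grouping)
    report = grp.venn(
        dict(list(sets.items())[:3]), pooled, grouping
    )
    venn_json = {
        "groups": report.group_names,
        "regions": {
            "+".join(sorted(k)): len(v) for k, v in report.regions.items()
        },
        "cumulative": {
            "+".join(sorted(k)): v for k, v in report.cumulative.items()
        },
        "union": {
            "+".join(sorted(k)): v for k, v in report.union_counts.items()
        },
    }
    (config.outdir / "venn.json").write_text(
        json.dumps(venn_json, indent=2, sort_keys=True) + "\n"
    )

    info: dict = {"groups": report.group_names}
    labels = sorted({g for g in grouping.values()})
    if len(labels) >= 2 and state.get("completed"):
        seq_by_gene = {}
        for gene, seqs in state["completed"].items():
            per_acc: dict[str, list[str]] = {}
            L = min(len(s) for _, s in seqs)
            for name, s in seqs:
                acc = name.rsplit("_hap", 1)[0]
                per_acc.setdefault(acc, []).append(s[:L])
            seq_by_gene[gene] = per_acc
        comps = grp.compare_diversity(
            seq_by_gene,
            grouping,
            (labels[0], labels[1]),
            n_permutations=config.n_permutations,
            seed=config.seed,
        )
        pd.DataFrame(
            [
                {
                    "gene": c.gene_id,
                    "d_group1": c.d_group1,
                    "d_group2": c.d_group2,
                    "delta_d": c.delta_d,
                    "p": c.p_value,
                    "significant": c.significant,
                }
                for c in comps
            ]
        ).to_csv(config.outdir / "compare_diversity.tsv", sep="\t",
                 index=False)
        info["compared_groups"] = [labels[0], labels[1]]
    return info


_STEP_FUNCS = {
    "detect": _step_detect,
    "map": _step_map,
    "annotate": _step_annotate,
    "phase": _step_phase,
    "ld": _step_ld,
    "diversity": _step_diversity,
    "network": _step_network,
    "compare": _step_compare,
}
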