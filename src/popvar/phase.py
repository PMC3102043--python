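"""Haplotype reconstruction from unphased diploid genotypes.

Classical EM over population haplotype frequencies (the Excoffier-Slatkin
gene-counting scheme): the E-step distributes each accession's genotype mass
over all compatible ordered haplotype pairs in proportion to the product of
the current pair frequencies, the M-step re-estimates frequencies from the
expected counts.  Each accession is then assigned its maximum-posterior
compatible pair, which simultaneously imputes its missing alleles.  The
whole region is treated as a single block.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .detect import ABSENT, GenotypeMatrix, PRESENT, Variant

logger = logging.getLogger(__name__)

Haplotype = tuple[str, ...]  # one allele per site


@dataclass
class HaplotypeSet:
    """Phased haplotypes: population frequencies plus per-accession pairs."""

    sites: list[Variant]
    haplotypes: list[Haplotype]
    frequencies: np.ndarray
    pairs: dict[str, tuple[int, int] | None]
    posteriors: dict[str, float]
    log_likelihood: float
    log_likelihood_trace: list[float] = field(default_factory=list)

    def haplotypes_of(self, accession: str) -> tuple[Haplotype, Haplotype] | None:
        pair = self.pairs.get(accession)
        if pair is None:
            return None
        return self.haplotypes[pair[0]], self.haplotypes[pair[1]]

    def haplotype_string(self, hap: Haplotype) -> str:
        """Single-character-per-site rendering (indels binary recoded)."""
        out = []
        for allele, site in zip(hap, self.sites):
            if site.kind == "indel":
                out.append("1" if allele == PRESENT else "0")
            else:
                out.append(allele)
        return "".join(out)

    def all_haplotype_strings(self) -> list[str]:
        """One string per chromosome copy over all phased accessions."""
        out = []
        for acc in sorted(self.pairs):
            haps = self.haplotypes_of(acc)
            if haps is not None:
                out.extend(self.haplotype_string(h) for h in haps)
        return out


def _site_alleles(variant: Variant) -> tuple[str, str]:
    obs = list(variant.alleles) if len(variant.alleles) == 2 \
        else variant.observed_alleles()
    if len(obs) != 2:
        raise ValueError(
            f"site {variant.gene_id}:{variant.position} is not biallelic; "
            "exclude multiallelic sites before phasing"
        )
    return obs[0], obs[1]


def _compatible_pairs(
    calls: list[tuple[str, str] | None], alleles: list[tuple[str, str]]
) -> list[tuple[Haplotype, Haplotype]]:
    """All ordered haplotype pairs consistent with one accession's genotype."""
    per_site: list[list[tuple[str, str]]] = []
    for call, (a, b) in zip(calls, alleles):
        if call is None:
            per_site.append([(a, a), (a, b), (b, a), (b, b)])
        elif call[0] == call[1]:
            per_site.append([(call[0], call[0])])
        else:
            per_site.append([(call[0], call[1]), (call[1], call[0])])
    pairs = []
    for combo in itertools.product(*per_site):
        hap_a = tuple(x for x, _ in combo)
        hap_b = tuple(y for _, y in combo)
        pairs.append((hap_a, hap_b))
    return pairs


def em_phase(
    matrix: GenotypeMatrix,
    max_iter: int = 1000,
    tol: float = 1e-8,
    restarts: int = 5,
    seed: int | None = None,
    max_ambiguous: int = 25,
) -> HaplotypeSet:
    """Phase a biallelic genotype matrix by EM on haplotype frequencies.

    Accessions with more than *max_ambiguous* heterozygous-plus-missing sites
    would require enumerating over 2^k pairs and are left unphased with a
    warning.  ``restarts`` random Dirichlet(1) initialisations are run and
    the best final log-likelihood kept; the log-likelihood is asserted
    non-decreasing within every run.
    """
    if matrix.n_variants == 0 or matrix.n_accessions == 0:
        raise ValueError("cannot phase an empty genotype matrix")
    alleles = [_site_alleles(v) for v in matrix.variants]
    rng = np.random.default_rng(seed)

    acc_pairs: dict[str, list[tuple[Haplotype, Haplotype]]] = {}
    unphased: list[str] = []
    hap_index: dict[Haplotype, int] = {}
    for acc in matrix.accessions:
        calls = matrix.calls_for(acc)
        ambiguous = sum(
            1 for c in calls if c is None or c[0] != c[1]
        )
        if ambiguous > max_ambiguous:
            logger.warning(
                "accession %s has %d ambiguous sites (> %d); left unphased",
                acc, ambiguous, max_ambiguous,
            )
            unphased.append(acc)
            continue
        pairs = _compatible_pairs(calls, alleles)
        acc_pairs[acc] = pairs
        for ha, hb in pairs:
            for h in (ha, hb):
                if h not in hap_index:
                    hap_index[h] = len(hap_index)
    if not acc_pairs:
        raise ValueError("no accession could be phased")

    haplotypes = sorted(hap_index)  # deterministic order
    hap_index = {h: i for i, h in enumerate(haplotypes)}
    H = len(haplotypes)
    # index pairs once per accession
    idx_pairs = {
        acc: np.array([(hap_index[a], hap_index[b]) for a, b in pairs])
        for acc, pairs in acc_pairs.items()
    }
    n = len(idx_pairs)

    best: tuple[float, np.ndarray, list[float]] | None = None
    for _ in range(max(1, restarts)):
        p = rng.dirichlet(np.ones(H))
        trace: list[float] = []
        prev_ll = -math.inf
        for _it in range(max_iter):
            counts = np.zeros(H)
            ll = 0.0
            for acc, ij in idx_pairs.items():
                w = p[ij[:, 0]] * p[ij[:, 1]]
                total = w.sum()
                if total <= 0.0:
                    total = 1e-300
                ll += math.log(total)
                w = w / total
                np.add.at(counts, ij[:, 0], w)
                np.add.at(counts, ij[:, 1], w)
            assert ll >= prev_ll - 1e-9, "EM log-likelihood decreased"
            trace.append(ll)
            prev_ll = ll
            new_p = counts / (2 * n)
            if np.max(np.abs(new_p - p)) < tol:
                p = new_p
                break
            p = new_p
        if best is None or prev_ll > best[0]:
            best = (prev_ll, p, trace)

    assert best is not None
    ll, p, trace = best

    pairs_out: dict[str, tuple[int, int] | None] = {a: None for a in unphased}
    posteriors: dict[str, float] = {}
    for acc, ij in idx_pairs.items():
        w = p[ij[:, 0]] * p[ij[:, 1]]
        total = w.sum()
        w = w / total if total > 0 else np.full(len(w), 1 / len(w))
        # aggregate ordered pairs into unordered ones before choosing
        agg: dict[tuple[int, int], float] = {}
        for (i, j), wk in zip(map(tuple, ij), w):
            key = (i, j) if i <= j else (j, i)
            agg[key] = agg.get(key, 0.0) + float(wk)
        pick = min(agg.items(), key=lambda kv: (-kv[1], kv[0]))
        pairs_out[acc] = pick[0]
        posteriors[acc] = pick[1]
        # hard guarantee: the chosen pair is genotype-consistent
        ha, hb = haplotypes[pick[0][0]], haplotypes[pick[0][1]]
        for call, x, y in zip(matrix.calls_for(acc), ha, hb):
            if call is not None:
                assert tuple(sorted((x, y))) == call

    return HaplotypeSet(
        sites=list(matrix.variants),
        haplotypes=list(haplotypes),
        frequencies=p,
        pairs=pairs_out,
        posteriors=posteriors,
        log_likelihood=ll,
        log_likelihood_trace=trace,
    )


def complete_sequences(
    hapset: HaplotypeSet, consensus_sequence: str
) -> list[tuple[str, str]]:
    """Render two full-length phased sequences per accession.

    Non-polymorphic positions come from the consensus; variant columns are
    substituted with the accession's phased alleles.  An ``absent`` indel
    allele deletes the event's columns, so sequence lengths may differ.
    """
    L = len(consensus_sequence)
    for v in hapset.sites:
        end = v.position + (v.indel_length or 1) - 1
        if not 1 <= v.position <= L or end > L:
            raise ValueError(
                f"variant at column {v.position} outside consensus (length {L})"
            )
    out = []
    for acc in sorted(hapset.pairs):
        haps = hapset.haplotypes_of(acc)
        if haps is None:
            continue
        for k, hap in enumerate(haps, start=1):
            seq = list(consensus_sequence)
            # apply right-to-left so deletions do not shift later columns
            for v, allele in sorted(
                zip(hapset.sites, hap), key=lambda t: -t[0].position
            ):
                i = v.position - 1
                if v.kind == "indel":
                    if allele == ABSENT:
                        del seq[i : i + (v.indel_length or 1)]
                else:
                    seq[i] = allele
            out.append((f"{acc}_hap{k}", "".join(seq)))
    return out
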