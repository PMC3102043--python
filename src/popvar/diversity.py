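"""Per-gene diversity indices from completed phased sequences.

Statistics follow the classical neutral-theory toolbox: nucleotide diversity
pi (mean pairwise difference), Watterson's theta_W = S/a1, haplotype count
and diversity, and Tajima's D with the standard coefficient chain

    a1 = sum_{k<n} 1/k          a2 = sum_{k<n} 1/k^2
    b1 = (n+1)/(3(n-1))         b2 = 2(n^2+n+3)/(9n(n-1))
    c1 = b1 - 1/a1              c2 = b2 - (n+2)/(a1 n) + a2/a1^2
    e1 = c1/a1                  e2 = c2/(a1^2 + a2)
    D  = (pi - theta_W) / sqrt(e1 S + e2 S(S-1))

Sites containing any missing or indel character in any sequence are removed
before counting (complete-site deletion), and the surveyed length L is
reduced accordingly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

_VALID = frozenset("ACGT")


@dataclass
class TajimaCoefficients:
    a1: float
    a2: float
    b1: float
    b2: float
    c1: float
    c2: float
    e1: float
    e2: float


def tajima_coefficients(n: int) -> TajimaCoefficients:
    if n < 2:
        raise ValueError("coefficients need n >= 2 sequences")
    a1 = sum(1.0 / k for k in range(1, n))
    a2 = sum(1.0 / k**2 for k in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return TajimaCoefficients(a1, a2, b1, b2, c1, c2, e1, e2)


@dataclass
class DiversityStats:
    gene_id: str
    n: int
    L: int
    S: int
    pi_total: float
    pi_per_site: float
    theta_w: float
    H: int
    Hd: float
    tajima_d: float | None
    coefficients: TajimaCoefficients


def diversity_stats(
    sequences: list[str] | list[tuple[str, str]], gene_id: str = ""
) -> DiversityStats:
    """Diversity indices of a set of equal-length (phased) sequences.

    pi is computed from per-site allele counts (the number of differing
    pairs at a site with base counts c_a is (n^2 - sum c_a^2)/2), which
    equals the mean over all explicit sequence pairs.
    """
    if sequences and isinstance(sequences[0], tuple):
        seqs = [s for _, s in sequences]  # type: ignore[misc]
    else:
        seqs = [s.upper() for s in sequences]  # type: ignore[union-attr]
    n = len(seqs)
    if n < 2:
        raise ValueError("diversity needs at least 2 sequences")
    if len({len(s) for s in seqs}) > 1:
        raise ValueError("sequences must have equal length")
    coeff = tajima_coefficients(n)

    arr = np.frombuffer("".join(seqs).encode(), dtype="S1").reshape(n, -1)
    valid = np.zeros(arr.shape[1], dtype=bool)
    counts = np.stack([(arr == base.encode()).sum(axis=0) for base in "ACGT"])
    valid = counts.sum(axis=0) == n  # complete-site deletion
    counts = counts[:, valid]
    L = int(valid.sum())

    segregating = (counts > 0).sum(axis=0) > 1
    S = int(segregating.sum())
    diff_pairs = (n * n - (counts**2).sum(axis=0)) / 2.0
    n_pairs = n * (n - 1) // 2
    pi_total = float(diff_pairs.sum()) / n_pairs

    sub = arr[:, valid]
    uniq, hap_counts = np.unique(sub, axis=0, return_counts=True)
    H = len(uniq)
    Hd = n * (1.0 - float(((hap_counts / n) ** 2).sum())) / (n - 1)

    if S == 0:
        theta_w = 0.0
        tajima_d = None
    else:
        theta_w = S / coeff.a1
        var = coeff.e1 * S + coeff.e2 * S * (S - 1)
        if var <= 0:
            # at n <= 3 the variance vanishes because pi == theta_w exactly
            num = pi_total - theta_w
            tajima_d = 0.0 if abs(num) < 1e-9 else None
        else:
            tajima_d = (pi_total - theta_w) / math.sqrt(var)

    return DiversityStats(
        gene_id=gene_id,
        n=n,
        L=L,
        S=S,
        pi_total=pi_total,
        pi_per_site=pi_total / L if L else 0.0,
        theta_w=theta_w,
        H=H,
        Hd=Hd,
        tajima_d=tajima_d,
        coefficients=coeff,
    )


SIGNIFICANT_NEGATIVE = "significant_negative"
SIGNIFICANT_POSITIVE = "significant_positive"
NEUTRAL = "neutral"


@dataclass
class DiversityMapEntry:
    gene_id: str
    chrom: str
    position: int
    tajima_d: float
    classification: str
    empirical_quantile: float


def diversity_map(
    stats: list[DiversityStats],
    gene_positions: dict[str, tuple[str, int]],
    alpha: float = 0.05,
) -> list[DiversityMapEntry]:
    """Chromosome-scale classification of Tajima's D values.

    Significance assumes a standard-normal distribution of D (two-sided at
    *alpha*); the empirical quantile of each gene's D among all genes with a
    defined D supports "most extreme tail" selection scans.  Entries are
    ordered by chromosome then position; the gene position is conventionally
    the midpoint of its mapped amplicon.
    """
    defined = [s for s in stats if s.tajima_d is not None]
    if not defined:
        raise ValueError("no gene has a defined Tajima's D")
    crit = norm.ppf(1 - alpha / 2)
    values = sorted(s.tajima_d for s in defined)  # type: ignore[arg-type]
    n = len(values)
    entries = []
    for s in defined:
        d = s.tajima_d
        assert d is not None
        if d < -crit:
            cls = SIGNIFICANT_NEGATIVE
        elif d > crit:
            cls = SIGNIFICANT_POSITIVE
        else:
            cls = NEUTRAL
        rank = sum(1 for v in values if v <= d)
        chrom, pos = gene_positions[s.gene_id]
        entries.append(
            DiversityMapEntry(s.gene_id, chrom, pos, d, cls, rank / n)
        )
    entries.sort(key=lambda e: (e.chrom, e.position))
    return entries
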