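"""Pairwise linkage disequilibrium.

Two routes are provided, matching the two kinds of input the pipeline sees:

* phased haplotypes -> the classical D, D' = |D|/Dmax and
  r^2 = D^2 / (pA pa pB pb), with significance from the chi-square
  approximation chi2 = n r^2 (1 df), replaced by Fisher's exact test on the
  2x2 haplotype table whenever an expected count drops below 5;
* unphased genotypes -> the Rogers-Huff composite r^2, the squared Pearson
  correlation of per-accession allele dosages, which needs no phasing.

Raw p-values are complemented by Benjamini-Hochberg q-values across each
region's pair table.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .detect import GenotypeMatrix
from .phase import HaplotypeSet

PHASED = "phased"
COMPOSITE = "composite"


@dataclass
class LDResult:
    site_i: int
    site_j: int
    D: float | None
    d_prime: float | None
    r2: float | None
    p_value: float | None
    n: int
    method: str
    defined: bool = True


def ld_from_counts(n_ab_both: int, n_Ab: int, n_aB: int, n_ab_none: int) -> LDResult:
    """LD coefficients from the four haplotype counts (AB, Ab, aB, ab)."""
    n = n_ab_both + n_Ab + n_aB + n_ab_none
    if n == 0:
        return LDResult(0, 1, None, None, None, None, 0, PHASED, defined=False)
    p_AB = n_ab_both / n
    p_A = (n_ab_both + n_Ab) / n
    p_B = (n_ab_both + n_aB) / n
    p_a, p_b = 1 - p_A, 1 - p_B
    if min(p_A, p_a, p_B, p_b) == 0:
        return LDResult(0, 1, None, None, None, None, n, PHASED, defined=False)
    D = p_AB - p_A * p_B
    if D > 0:
        d_max = min(p_A * p_b, p_a * p_B)
    else:
        d_max = min(p_A * p_B, p_a * p_b)
    d_prime = abs(D) / d_max if d_max > 0 else 0.0
    r2 = D * D / (p_A * p_a * p_B * p_b)

    table = np.array([[n_ab_both, n_Ab], [n_aB, n_ab_none]])
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / n
    if expected.min() < 5:
        _, p_value = stats.fisher_exact(table)
    else:
        chi2 = n * r2
        p_value = float(stats.chi2.sf(chi2, df=1))
    return LDResult(0, 1, D, d_prime, r2, p_value, n, PHASED)


def _haplotype_counts(
    hapset: HaplotypeSet, site_i: int, site_j: int
) -> tuple[dict[tuple[str, str], int], tuple[str, str], tuple[str, str]]:
    from .phase import _site_alleles

    counts: dict[tuple[str, str], int] = {}
    for acc in hapset.pairs:
        haps = hapset.haplotypes_of(acc)
        if haps is None:
            continue
        for hap in haps:
            key = (hap[site_i], hap[site_j])
            counts[key] = counts.get(key, 0) + 1
    ai = _site_alleles(hapset.sites[site_i])
    aj = _site_alleles(hapset.sites[site_j])
    return counts, ai, aj


def ld_phased(hapset: HaplotypeSet, site_i: int, site_j: int) -> LDResult:
    """Classical LD between two biallelic sites of a phased haplotype set."""
    counts, (A, a), (B, b) = _haplotype_counts(hapset, site_i, site_j)
    res = ld_from_counts(
        counts.get((A, B), 0),
        counts.get((A, b), 0),
        counts.get((a, B), 0),
        counts.get((a, b), 0),
    )
    res.site_i, res.site_j = site_i, site_j
    return res


def dosages(matrix: GenotypeMatrix, site: int) -> np.ndarray:
    """Per-accession count (0/1/2, NaN missing) of the first sorted allele."""
    from .phase import _site_alleles

    ref, _ = _site_alleles(matrix.variants[site])
    out = np.full(matrix.n_accessions, np.nan)
    for k, acc in enumerate(matrix.accessions):
        call = matrix.variants[site].calls.get(acc)
        if call is not None:
            out[k] = sum(1 for x in call if x == ref)
    return out


def ld_composite(matrix: GenotypeMatrix, site_i: int, site_j: int) -> LDResult:
    """Composite (Rogers-Huff) r^2: squared dosage correlation, no phasing."""
    x = dosages(matrix, site_i)
    y = dosages(matrix, site_j)
    keep = ~np.isnan(x) & ~np.isnan(y)
    x, y = x[keep], y[keep]
    n = int(keep.sum())
    if n < 2 or x.std() == 0 or y.std() == 0:
        return LDResult(site_i, site_j, None, None, None, None, n,
                        COMPOSITE, defined=False)
    r = float(np.corrcoef(x, y)[0, 1])
    r2 = r * r
    # large-sample chi-square approximation on the dosage correlation
    p = float(stats.chi2.sf(n * r2, df=1))
    return LDResult(site_i, site_j, None, None, r2, p, n, COMPOSITE)


def ld_matrix(
    source: HaplotypeSet | GenotypeMatrix,
    positions: list[int] | None = None,
    genomic_positions: list[int | None] | None = None,
) -> pd.DataFrame:
    """All-pairs LD table (upper triangle, i < j) with inter-site distances.

    The method (phased vs composite) follows the input type.  Benjamini-
    Hochberg q-values are appended across the region.  Columns for the
    structure/kinship-corrected measures are reserved (empty) so an
    extension can slot in.
    """
    if isinstance(source, HaplotypeSet):
        n_sites = len(source.sites)
        site_positions = positions or [v.position for v in source.sites]
        compute = lambda i, j: ld_phased(source, i, j)  # noqa: E731
    else:
        n_sites = source.n_variants
        site_positions = positions or [v.position for v in source.variants]
        compute = lambda i, j: ld_composite(source, i, j)  # noqa: E731

    rows = []
    for i, j in itertools.combinations(range(n_sites), 2):
        res = compute(i, j)
        row = {
            "site_i": site_positions[i],
            "site_j": site_positions[j],
            "distance_bp": abs(site_positions[j] - site_positions[i]),
            "D": res.D,
            "d_prime": res.d_prime,
            "r2": res.r2,
            "p": res.p_value,
            "method": res.method,
            "n": res.n,
            "defined": res.defined,
            "r2S": None,
            "r2K": None,
            "r2SK": None,
        }
        if genomic_positions is not None:
            gi, gj = genomic_positions[i], genomic_positions[j]
            row["genomic_distance_bp"] = (
                abs(gj - gi) if gi is not None and gj is not None else None
            )
        rows.append(row)
    df = pd.DataFrame(rows)
    if not df.empty:
        mask = df["p"].notna()
        q = pd.Series(np.nan, index=df.index)
        if mask.any():
            q[mask] = stats.false_discovery_control(df.loc[mask, "p"], method="bh")
        df["q"] = q
    return df
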