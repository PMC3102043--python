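"""Shared test fixtures and independent oracles.

The oracles here deliberately re-derive results by the most literal route
available (explicit per-column scans, O(n^2 L) pairwise loops, textbook
formula chains, exhaustive searches) so that the package implementations
are checked against an independent computation path.
"""

from __future__ import annotations

import itertools
import math
import re

import numpy as np
import pytest

from popvar.detect import Alignment

IUPAC = {
    "R": ("A", "G"), "Y": ("C", "T"), "S": ("C", "G"),
    "W": ("A", "T"), "K": ("G", "T"), "M": ("A", "C"),
}


def oracle_detect(alignment: Alignment):
    """Literal column-by-column scan, written independently of the package.

    Returns tuples (kind, position, alleles, calls[, length, sequence]).
    """
    accs, rows = alignment.accessions, alignment.rows
    found = []
    for col in range(len(rows[0])):
        bag: list[str] = []
        calls = {}
        for acc, row in zip(accs, rows):
            ch = row[col]
            if ch in "ACGT":
                calls[acc] = (ch, ch)
                bag += [ch, ch]
            elif ch in IUPAC:
                pair = IUPAC[ch]
                calls[acc] = tuple(sorted(pair))
                bag += list(pair)
            else:  # N, three-fold codes and gaps give no base call
                calls[acc] = None
        if len(set(bag)) >= 2:
            found.append(("SNP", col + 1, tuple(sorted(set(bag))), calls))
    extents = set()
    for row in rows:
        for m in re.finditer("-+", row):
            extents.add((m.start(), m.end() - 1))
    for s, e in sorted(extents):
        calls = {}
        segments = []
        for acc, row in zip(accs, rows):
            seg = row[s : e + 1]
            if set(seg) == {"-"}:
                calls[acc] = ("absent", "absent")
            elif all(c in "ACGT" or c in IUPAC for c in seg):
                calls[acc] = ("present", "present")
                segments.append(seg)
            else:
                calls[acc] = None
        if segments:
            best = max(segments.count(x) for x in segments)
            seq = min(x for x in segments if segments.count(x) == best)
            found.append(
                ("indel", s + 1, ("absent", "present"), calls, e - s + 1, seq)
            )
    return sorted(found, key=lambda t: (t[1], t[0]))


def variant_tuple(v):
    """Canonical comparison form of a package Variant."""
    base = (v.kind, v.position, tuple(v.alleles), dict(v.calls))
    if v.kind == "indel":
        return base + (v.indel_length, v.indel_sequence)
    return base


def random_alignment(rng: np.random.Generator, max_acc=20, max_len=200):
    """Alignment fuzzer mixing bases, het codes, N and gap runs."""
    n = int(rng.integers(2, max_acc + 1))
    L = int(rng.integers(5, max_len + 1))
    rows = []
    for _ in range(n):
        chars = list(rng.choice(list("ACGT"), size=L))
        for j in range(L):
            r = rng.random()
            if r < 0.05:
                chars[j] = str(rng.choice(list(IUPAC)))
            elif r < 0.08:
                chars[j] = "N"
        # sprinkle a few gap runs
        for _ in range(int(rng.integers(0, 3))):
            start = int(rng.integers(0, L))
            length = int(rng.integers(1, 4))
            for j in range(start, min(L, start + length)):
                chars[j] = "-"
        rows.append("".join(chars))
    return Alignment("fuzz", [f"a{i}" for i in range(n)], rows)


def oracle_diversity(seqs: list[str]):
    """Explicit pairwise-difference loop + literal coefficient chain."""
    n = len(seqs)
    sites = [j for j in range(len(seqs[0]))
             if all(s[j] in "ACGT" for s in seqs)]
    S = sum(1 for j in sites if len({s[j] for s in seqs}) > 1)
    diffs = 0
    for i, j in itertools.combinations(range(n), 2):
        diffs += sum(1 for k in sites if seqs[i][k] != seqs[j][k])
    pi = diffs / (n * (n - 1) / 2)
    a1 = sum(1.0 / k for k in range(1, n))
    a2 = sum(1.0 / k**2 for k in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    theta = S / a1 if S else 0.0
    D = None
    if S:
        var = e1 * S + e2 * S * (S - 1)
        if var <= 0:
            D = 0.0 if abs(pi - theta) < 1e-9 else None
        else:
            D = (pi - theta) / math.sqrt(var)
    haps = {"".join(s[k] for k in sites) for s in seqs}
    counts = {}
    for s in seqs:
        key = "".join(s[k] for k in sites)
        counts[key] = counts.get(key, 0) + 1
    Hd = n * (1 - sum((c / n) ** 2 for c in counts.values())) / (n - 1)
    return {"S": S, "pi": pi, "theta": theta, "D": D, "H": len(haps),
            "Hd": Hd, "L": len(sites)}


def oracle_ld(n_AB, n_Ab, n_aB, n_ab):
    """2x2 contingency-table LD by the closed forms, computed literally."""
    n = n_AB + n_Ab + n_aB + n_ab
    pAB, pA, pB = n_AB / n, (n_AB + n_Ab) / n, (n_AB + n_aB) / n
    D = pAB - pA * pB
    if D >= 0:
        dmax = min(pA * (1 - pB), (1 - pA) * pB)
    else:
        dmax = min(pA * pB, (1 - pA) * (1 - pB))
    dprime = abs(D) / dmax if dmax else 0.0
    r2 = D * D / (pA * (1 - pA) * pB * (1 - pB))
    return D, dprime, r2


def hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _prim_mst_cost(nodes: list[str], dist: dict[tuple[str, str], int]) -> int:
    if len(nodes) <= 1:
        return 0
    in_tree = {nodes[0]}
    cost = 0
    best = {v: dist[(nodes[0], v)] for v in nodes[1:]}
    while best:
        v = min(best, key=lambda x: (best[x], x))
        cost += best.pop(v)
        in_tree.add(v)
        for u in list(best):
            d = dist[(v, u)]
            if d < best[u]:
                best[u] = d
    return cost


def oracle_steiner_cost(observed: list[str], max_extra: int = 3) -> int:
    """Exhaustive Steiner search over observed-allele combinations.

    Minimum spanning-tree cost over the observed haplotypes plus any subset
    (up to *max_extra*, enough for <=5 terminals) of candidate intermediate
    vectors drawn from the per-site observed alleles.
    """
    obs = sorted(set(observed))
    L = len(obs[0])
    site_alleles = [sorted({h[j] for h in obs}) for j in range(L)]
    candidates = [
        "".join(combo)
        for combo in itertools.product(*site_alleles)
        if "".join(combo) not in set(obs)
    ]
    universe = obs + candidates
    dist = {}
    for a in universe:
        for b in universe:
            dist[(a, b)] = hamming(a, b)
    best = _prim_mst_cost(obs, dist)
    for r in range(1, max_extra + 1):
        for extra in itertools.combinations(candidates, r):
            c = _prim_mst_cost(obs + list(extra), dist)
            if c < best:
                best = c
    return best


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)
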