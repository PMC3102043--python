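"""Nucleotide alphabet shared across the package.

Diploid sequences are stored one row per accession: a plain base means a
homozygous call, a two-fold IUPAC ambiguity code (R, Y, S, W, K, M) encodes a
heterozygous call, ``N`` is missing data and ``-`` is an alignment gap.
``-`` is structural (it participates in indel events), never missing.
"""

from __future__ import annotations

BASES = "ACGT"

#: two-fold IUPAC codes -> the unordered base pair they encode
IUPAC_HET: dict[str, tuple[str, str]] = {
    "R": ("A", "G"),
    "Y": ("C", "T"),
    "S": ("C", "G"),
    "W": ("A", "T"),
    "K": ("G", "T"),
    "M": ("A", "C"),
}

#: three-fold codes carry no usable diploid information; treated as missing
THREEFOLD = frozenset("BDHV")

MISSING = "N"
GAP = "-"

ALPHABET = frozenset(BASES) | frozenset(IUPAC_HET) | THREEFOLD | {MISSING, GAP}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN-", "TGCAYRSWMKVHDBN-")


def revcomp(seq: str) -> str:
    """Reverse-complement, preserving ambiguity codes and gaps."""
    return seq.translate(_COMPLEMENT)[::-1]


def resolve(char: str) -> tuple[str, str] | None:
    """Diploid base pair encoded by one alignment character.

    Returns ``None`` for missing data (``N`` and three-fold codes).
    Gaps are structural and must be handled by the caller.
    """
    if char in IUPAC_HET:
        return IUPAC_HET[char]
    if char in "ACGT":
        return (char, char)
    if char == MISSING or char in THREEFOLD:
        return None
    raise ValueError(f"cannot resolve {char!r} to a diploid call")
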