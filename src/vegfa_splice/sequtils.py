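"""Small DNA string helpers used throughout the package."""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

DNA_BASES = "ACGT"


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (A/C/G/T/N, case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


def random_dna(rng: np.random.Generator, n: int) -> str:
    """Uniform random DNA string of length ``n`` drawn from ``rng``."""
    return "".join(np.array(list(DNA_BASES))[rng.integers(0, 4, size=n)])


def is_dna(seq: str) -> bool:
    """True if ``seq`` is non-empty and contains only A, C, G, T."""
    return bool(seq) and set(seq.upper()) <= set(DNA_BASES)


def hamming_within(a: str, b: str, k: int) -> bool:
    """True if equal-length strings ``a`` and ``b`` differ at <= ``k`` positions.

    Early-exits as soon as the mismatch budget is exceeded.
    """
    budget = k
    for x, y in zip(a, b):
        if x != y:
            budget -= 1
            if budget < 0:
                return False
    return True


def longest_shared_suffix(a: str, b: str) -> int:
    """Length of the longest common suffix of two strings."""
    s = 0
    for x, y in zip(reversed(a), reversed(b)):
        if x != y:
            break
        s += 1
    return s


def longest_shared_prefix(a: str, b: str) -> int:
    """Length of the longest common prefix of two strings."""
    s = 0
    for x, y in zip(a, b):
        if x != y:
            break
        s += 1
    return s
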