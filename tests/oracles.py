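"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's optimised code paths: structure
enumeration is recursive generate-and-test, the Poisson test oracle is
exact big-rational arithmetic, and the duplex scorer is a straight
per-position loop.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb
from typing import Iterator, Tuple

from nitromir.energies import MIN_LOOP, PAIRABLE


def enumerate_structures(seq: str, min_loop: int = MIN_LOOP) -> Iterator[Tuple[Tuple[int, int], ...]]:
    """Every nested pair set of ``seq`` with the minimum loop constraint."""

    def rec(i: int, j: int):
        if j - i < min_loop + 1:
            yield ()
            return
        yield from rec(i + 1, j)
        for k in range(i + min_loop + 1, j + 1):
            if (seq[i] + seq[k]) in PAIRABLE:
                for left in rec(i + 1, k - 1):
                    for right in rec(k + 1, j):
                        yield ((i, k),) + left + right

    yield from rec(0, len(seq) - 1)


def exact_audic_claverie(x: int, y: int, n1: int, n2: int) -> Tuple[Fraction, Fraction, Fraction]:
    """(p(y|x), C, D) as exact rationals."""
    r = Fraction(n2, n1)

    def p(yy: int) -> Fraction:
        return r ** yy * comb(x + yy, x) / (1 + r) ** (x + yy + 1)

    c = sum(p(t) for t in range(y + 1))
    d = 1 - c + p(y)
    return p(y), c, d


_COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}


def naive_duplex_score(mirna: str, window: str) -> float:
    """Position-by-position mismatch score, written independently."""
    assert len(mirna) == len(window)
    L = len(mirna)
    score = 0.0
    for p in range(1, L + 1):
        m = mirna[p - 1]
        t = window[L - p]
        if t == _COMP[m]:
            continue
        if (m == "G" and t == "T") or (m == "T" and t == "G"):
            score += 0.5
        else:
            score += 1.0
    return score
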