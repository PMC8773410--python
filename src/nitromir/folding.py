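"""Deterministic RNA secondary-structure prediction by dynamic programming.

The model scores a nested (pseudoknot-free) set of base pairs as

    E = sum of stacking energies over directly stacked pairs
      + a flat initiation penalty for every hairpin-closing pair,

with the stack table and wobble rule from :mod:`nitromir.energies` and a
minimum hairpin loop of 3 unpaired bases.  The recursion is exact for this
model (verified against exhaustive enumeration in the test suite), so the
returned structure is the true minimum free energy structure under the
shipped table -- the point is determinism and testability, not kcal-level
agreement with full Turner-rule folders.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

from .energies import HAIRPIN_PENALTY, MIN_LOOP, PAIRABLE, stack_energy
from .seq_utils import validate_nucleotides

_INF = float("inf")
_EPS = 1e-9

MAX_FOLD_LEN = 400


@dataclass(frozen=True)
class HairpinStructure:
    """A folded sequence: dot-bracket string and minimum free energy."""

    sequence: str
    dotbracket: str
    mfe: float
    pairs: Tuple[Tuple[int, int], ...] = field(default=(), repr=False)

    def __post_init__(self):
        assert len(self.dotbracket) == len(self.sequence)


def structure_energy(
    seq: str,
    pairs: Sequence[Tuple[int, int]],
    hairpin_penalty: float = HAIRPIN_PENALTY,
) -> float:
    """Energy of an explicit pair set, straight from the model definition."""
    s = validate_nucleotides(seq)
    pair_set = {(min(i, j), max(i, j)) for i, j in pairs}
    e = 0.0
    starts = sorted(pair_set)
    for (i, j) in starts:
        if (i + 1, j - 1) in pair_set:
            e += stack_energy(s[i] + s[j], s[i + 1] + s[j - 1])
        if not any(i < a and b < j for (a, b) in pair_set):
            e += hairpin_penalty
    return e


def fold(
    sequence: str,
    hairpin_penalty: float = HAIRPIN_PENALTY,
    min_loop: int = MIN_LOOP,
) -> HairpinStructure:
    """Minimum-free-energy nested structure of ``sequence``.

    Accepts ACGT/U input up to 400 nt; raises ValueError otherwise.
    Ties are broken deterministically (hairpin before stack before
    bifurcation, leftmost split first), so identical inputs always give
    byte-identical dot-bracket strings.
    """
    s = validate_nucleotides(sequence)
    n = len(s)
    if n > MAX_FOLD_LEN:
        raise ValueError(f"sequence longer than {MAX_FOLD_LEN} nt")
    if n <= min_loop + 1:
        return HairpinStructure(sequence, "." * n, 0.0)

    # V[i][j]: best energy on [i..j] given (i,j) paired; Wne[i][j]: best
    # energy on [i..j] with at least one pair.
    V = [[_INF] * n for _ in range(n)]
    Wne = [[_INF] * n for _ in range(n)]
    can = [[(s[i] + s[j]) in PAIRABLE and j - i > min_loop for j in range(n)] for i in range(n)]

    def W(i: int, k: int) -> float:
        if k < i:
            return 0.0
        w = Wne[i][k]
        return w if w < 0.0 else 0.0

    for span in range(min_loop + 1, n):
        for i in range(0, n - span):
            j = i + span
            if can[i][j]:
                best = hairpin_penalty
                if span >= min_loop + 3 and can[i + 1][j - 1] and V[i + 1][j - 1] < _INF:
                    cand = stack_energy(s[i] + s[j], s[i + 1] + s[j - 1]) + V[i + 1][j - 1]
                    if cand < best:
                        best = cand
                a, b = i + 1, j - 1
                if b - 1 >= a and Wne[a][b - 1] < best:
                    best = Wne[a][b - 1]
                for k in range(a + 1, b - min_loop):
                    vkb = V[k][b]
                    if vkb < _INF:
                        cand = vkb + W(a, k - 1)
                        if cand < best:
                            best = cand
                V[i][j] = best
            best = Wne[i][j - 1] if j - 1 >= i else _INF
            for k in range(i, j - min_loop):
                vkj = V[k][j]
                if vkj < _INF:
                    cand = vkj + (0.0 if k == i else W(i, k - 1))
                    if cand < best:
                        best = cand
            Wne[i][j] = best

    mfe = W(0, n - 1)
    pairs: List[Tuple[int, int]] = []
    if mfe < 0.0:
        _traceback(s, V, Wne, W, can, pairs, hairpin_penalty, min_loop)
    db = ["."] * n
    for (i, j) in pairs:
        db[i], db[j] = "(", ")"
    return HairpinStructure(sequence, "".join(db), mfe if mfe < 0 else 0.0, tuple(sorted(pairs)))


def _traceback(s, V, Wne, W, can, pairs, hairpin_penalty, min_loop):
    tasks = [("Wne", 0, len(s) - 1)]
    while tasks:
        kind, i, j = tasks.pop()
        if kind == "Wne":
            if j < i or Wne[i][j] >= _INF:
                continue
            t = Wne[i][j]
            if j - 1 >= i and Wne[i][j - 1] <= t + _EPS:
                tasks.append(("Wne", i, j - 1))
                continue
            for k in range(i, j - min_loop):
                vkj = V[k][j]
                if vkj < _INF and vkj + (0.0 if k == i else W(i, k - 1)) <= t + _EPS:
                    tasks.append(("V", k, j))
                    if k > i and Wne[i][k - 1] < 0.0:
                        tasks.append(("Wne", i, k - 1))
                    break
        else:  # V
            pairs.append((i, j))
            t = V[i][j]
            if hairpin_penalty <= t + _EPS:
                continue
            span = j - i
            if span >= min_loop + 3 and can[i + 1][j - 1] and V[i + 1][j - 1] < _INF:
                if stack_energy(s[i] + s[j], s[i + 1] + s[j - 1]) + V[i + 1][j - 1] <= t + _EPS:
                    tasks.append(("V", i + 1, j - 1))
                    continue
            a, b = i + 1, j - 1
            if b - 1 >= a and Wne[a][b - 1] <= t + _EPS:
                tasks.append(("Wne", a, b - 1))
                continue
            for k in range(a + 1, b - min_loop):
                vkb = V[k][b]
                if vkb < _INF and vkb + W(a, k - 1) <= t + _EPS:
                    tasks.append(("V", k, b))
                    if Wne[a][k - 1] < 0.0 if k - 1 >= a else False:
                        tasks.append(("Wne", a, k - 1))
                    break
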