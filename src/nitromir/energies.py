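"""Nearest-neighbour stacking energy table shared by folding and duplexes.

The model is deliberately compact: the 16 Watson-Crick stack types carry
literature-scale free energies (kcal/mol at 37 C), a G:U wobble pair
participates in stacking through a mapping onto the geometrically closest
A:U/U:A stack plus a destabilisation offset, and every hairpin-closing pair
pays a flat loop-initiation penalty.  The table is a package constant: the
same numbers drive precursor folding, duplex energies and the MFE-ratio
target rule, which keeps all energy comparisons internally consistent and
makes exhaustive-enumeration oracles possible.
"""

from __future__ import annotations

from typing import Optional

# pairs are written (base_i, base_j) for the 5' partner first; DNA letters,
# with T standing in for U.
WATSON_CRICK = {"AT", "TA", "GC", "CG"}
WOBBLE = {"GT", "TG"}
PAIRABLE = WATSON_CRICK | WOBBLE

# hairpin-loop initiation penalty (kcal/mol), charged once per hairpin loop
HAIRPIN_PENALTY = 3.0

# minimum number of unpaired bases in a hairpin loop
MIN_LOOP = 3

# destabilisation added per wobble pair taking part in a stack
GU_OFFSET = 0.2

# canonical Watson-Crick stacks, keyed (pair(i,j), pair(i+1,j-1)).
# Ten independent values; the remaining six follow from the two-fold
# rotational symmetry E[(p, q)] = E[(rev q, rev p)].
_CANONICAL = {
    ("AT", "AT"): -0.93,
    ("AT", "TA"): -1.10,
    ("TA", "AT"): -1.33,
    ("CG", "TA"): -2.08,
    ("CG", "AT"): -2.11,
    ("GC", "TA"): -2.24,
    ("GC", "AT"): -2.35,
    ("CG", "GC"): -2.36,
    ("GC", "GC"): -3.26,
    ("GC", "CG"): -3.42,
}


def _rev(pair: str) -> str:
    return pair[::-1]


def _build_wc_table() -> dict:
    table = dict(_CANONICAL)
    for (p, q), e in list(_CANONICAL.items()):
        table.setdefault((_rev(q), _rev(p)), e)
    # sanity: all 16 WC combinations present
    assert len(table) == 16, sorted(table)
    return table


STACK16 = _build_wc_table()

# wobble pairs borrow the geometry of the weak A:U pairs (purine side kept)
_GU_MAP = {"GT": "AT", "TG": "TA"}


def pairable(a: str, b: str) -> bool:
    return (a + b) in PAIRABLE


def stack_energy(pair1: str, pair2: str) -> Optional[float]:
    """Energy of pair2 stacked on pair1 (both 5'->3' on the left strand).

    Returns None when either pair is not pairable.
    """
    if pair1 not in PAIRABLE or pair2 not in PAIRABLE:
        return None
    offset = 0.0
    if pair1 in WOBBLE:
        offset += GU_OFFSET
        pair1 = _GU_MAP[pair1]
    if pair2 in WOBBLE:
        offset += GU_OFFSET
        pair2 = _GU_MAP[pair2]
    return STACK16[(pair1, pair2)] + offset
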