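"""Rule-based miRNA target search over transcripts.

A candidate site is an ungapped antiparallel duplex between a miRNA
(positions numbered 1..L from its 5' end) and an equal-length transcript
window.  Each position is classified match / G:U wobble / mismatch, with
wobbles weighing 0.5 mismatches, and a hit must satisfy all six of the
classic plant-miRNA complementarity rules:

1. total mismatch score <= 4;
2. no run of more than two adjacent mismatches anywhere in the duplex;
3. no adjacent mismatches within miRNA positions 2-12;
4. no mismatch at positions 10-11 (the expected cleavage site);
5. mismatch score over positions 1-12 <= 2.5;
6. duplex MFE at least 75% of the MFE of the miRNA bound to its perfect
   complement (magnitudes of negative energies).

Wobbles count toward the scores of rules 1 and 5 but are not "mismatches"
for the adjacency rules 2-4.  Energies reuse the package stacking table;
mismatches interrupt stacks, wobbles do not.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .energies import stack_energy
from .seq_utils import revcomp, to_dna, validate_nucleotides

MATCH, GU, MISMATCH = 0, 1, 2
_WEIGHTS = np.array([0.0, 0.5, 1.0])
_CODE = {c: i for i, c in enumerate("ACGT")}

DEFAULT_MAX_SCORE = 4.0
DEFAULT_SEED_SCORE_MAX = 2.5
DEFAULT_MFE_RATIO = 0.75
DEFAULT_MAX_ADJACENT = 2


@dataclass(frozen=True)
class DuplexAlignment:
    """Per-position pairing states of a miRNA against a transcript window."""

    mirna_id: str
    transcript_id: str
    site_start: int
    mirna_seq: str
    window_seq: str
    states: Tuple[int, ...]  # index p-1 = miRNA position p (5'->3')
    mismatch_score: float

    def __post_init__(self):
        assert len(self.states) == len(self.mirna_seq)

    @property
    def state_string(self) -> str:
        return "".join("|oX"[s] for s in self.states)


@dataclass(frozen=True)
class TargetHit:
    alignment: DuplexAlignment
    duplex_mfe: float
    perfect_mfe: float
    mfe_ratio: float
    rule_verdicts: Tuple[bool, ...]

    @property
    def accepted(self) -> bool:
        return all(self.rule_verdicts)


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(to_dna(seq).encode(), dtype=np.uint8)


_CODE_LUT = np.full(256, 255, dtype=np.uint8)
for _c, _i in _CODE.items():
    _CODE_LUT[ord(_c)] = _i


def _codes(seq: str) -> np.ndarray:
    codes = _CODE_LUT[_encode(seq)]
    if (codes == 255).any():
        raise ValueError("sequence contains non-ACGTU characters")
    return codes


def pair_states(mirna: str, window: str) -> np.ndarray:
    """State vector over miRNA positions 1..L for an ungapped duplex.

    miRNA position p (1-based, 5'->3') faces window base L-p (0-based):
    the window is the target site read 5'->3' on the transcript, so the
    duplex is antiparallel.
    """
    m = _codes(mirna)
    w = _codes(window)
    if len(m) != len(w):
        raise ValueError("window length must equal miRNA length")
    wr = w[::-1]  # wr[p-1] is the base opposite miRNA position p
    comp = 3 - m  # A<->T, C<->G under the 0..3 encoding
    states = np.full(len(m), MISMATCH, dtype=np.int8)
    states[wr == comp] = MATCH
    states[((m == 2) & (wr == 3)) | ((m == 3) & (wr == 2))] = GU
    return states


def mismatch_score(states: np.ndarray) -> float:
    return float(_WEIGHTS[states].sum())


def score_window(
    mirna: str,
    window: str,
    mirna_id: str = "",
    transcript_id: str = "",
    site_start: int = 0,
) -> DuplexAlignment:
    states = pair_states(mirna, window)
    return DuplexAlignment(
        mirna_id=mirna_id,
        transcript_id=transcript_id,
        site_start=site_start,
        mirna_seq=to_dna(mirna),
        window_seq=to_dna(window),
        states=tuple(int(s) for s in states),
        mismatch_score=mismatch_score(states),
    )


def _longest_mismatch_run(states: Sequence[int]) -> int:
    run = best = 0
    for s in states:
        run = run + 1 if s == MISMATCH else 0
        best = max(best, run)
    return best


def apply_rules(
    alignment: DuplexAlignment,
    energies: Tuple[float, float],
    max_score: float = DEFAULT_MAX_SCORE,
    seed_score_max: float = DEFAULT_SEED_SCORE_MAX,
    mfe_ratio_min: float = DEFAULT_MFE_RATIO,
    max_adjacent: int = DEFAULT_MAX_ADJACENT,
) -> Tuple[bool, ...]:
    """Verdicts of the six rules for a scored alignment.

    ``energies`` is (duplex_mfe, perfect_mfe); rule 6 compares magnitudes
    of the (negative) energies.
    """
    states = alignment.states
    duplex_mfe, perfect_mfe = energies
    s = np.asarray(states)
    score = float(_WEIGHTS[s].sum())
    L = len(states)

    r1 = score <= max_score
    r2 = _longest_mismatch_run(states) <= max_adjacent
    # adjacent mismatches with both positions inside 2..12 (1-based)
    r3 = not any(
        states[p - 1] == MISMATCH and states[p] == MISMATCH
        for p in range(2, min(12, L))
    )
    r4 = all(states[p - 1] != MISMATCH for p in (10, 11) if p <= L)
    r5 = float(_WEIGHTS[s[: min(12, L)]].sum()) <= seed_score_max
    if perfect_mfe == 0.0:
        r6 = duplex_mfe == 0.0
    else:
        r6 = abs(duplex_mfe) >= mfe_ratio_min * abs(perfect_mfe)
    return (r1, r2, r3, r4, r5, bool(r6))


def duplex_energy(mirna: str, window: str) -> float:
    """Stack-sum energy of the ungapped duplex; mismatches break stacks."""
    m = to_dna(mirna)
    w = to_dna(window)
    states = pair_states(m, w)
    L = len(m)
    wr = w[::-1]
    e = 0.0
    for p in range(L - 1):
        if states[p] != MISMATCH and states[p + 1] != MISMATCH:
            e += stack_energy(m[p] + wr[p], m[p + 1] + wr[p + 1])
    return e


def perfect_energy(mirna: str) -> float:
    """Energy of the miRNA bound to its perfect reverse complement."""
    return duplex_energy(mirna, revcomp(mirna))


def evaluate_site(
    mirna: str,
    transcript: str,
    site_start: int,
    mirna_id: str = "",
    transcript_id: str = "",
    **rule_kwargs,
) -> TargetHit:
    """Score one window and apply the six rules (accepted or not)."""
    L = len(mirna)
    window = to_dna(transcript)[site_start : site_start + L]
    aln = score_window(mirna, window, mirna_id, transcript_id, site_start)
    dup = duplex_energy(mirna, window)
    per = perfect_energy(mirna)
    verdicts = apply_rules(aln, (dup, per), **rule_kwargs)
    ratio = dup / per if per != 0 else 0.0
    return TargetHit(aln, dup, per, ratio, verdicts)


def scan_transcript(
    mirna: str,
    transcript: str,
    mirna_id: str = "",
    transcript_id: str = "",
    max_score: float = DEFAULT_MAX_SCORE,
    **rule_kwargs,
) -> List[TargetHit]:
    """All accepted sites of one miRNA on one transcript.

    Windows are pre-screened on the rule-1 score with a vectorised pass;
    only windows at or below ``max_score`` get the full rule/energy
    treatment.
    """
    m = _codes(mirna)
    t = _codes(transcript)
    L = len(m)
    if len(t) < L:
        return []
    win = np.lib.stride_tricks.sliding_window_view(t, L)[:, ::-1]
    comp = 3 - m
    match = win == comp
    gu = ((m == 2) & (win == 3)) | ((m == 3) & (win == 2))
    scores = np.where(match, 0.0, np.where(gu, 0.5, 1.0)).sum(axis=1)
    hits = []
    for q in np.nonzero(scores <= max_score)[0]:
        hit = evaluate_site(
            mirna, transcript, int(q), mirna_id, transcript_id,
            max_score=max_score, **rule_kwargs,
        )
        if hit.accepted:
            hits.append(hit)
    return hits


def scan_transcriptome(
    mirnas: Mapping[str, str],
    transcripts: Mapping[str, str],
    max_score: float = DEFAULT_MAX_SCORE,
    **rule_kwargs,
) -> Tuple[List[TargetHit], List[str]]:
    """Accepted hits for every miRNA x transcript pair, plus the
    deduplicated target-gene list (for functional summarisation)."""
    all_hits: List[TargetHit] = []
    for mid, mseq in mirnas.items():
        for tid, tseq in transcripts.items():
            all_hits.extend(
                scan_transcript(mseq, tseq, mid, tid, max_score=max_score, **rule_kwargs)
            )
    unique_genes = sorted({h.alignment.transcript_id for h in all_hits})
    return all_hits, unique_genes
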