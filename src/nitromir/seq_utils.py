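"""Sequence alphabet helpers and light-weight file I/O.

Sequences are held internally in the DNA alphabet (A/C/G/T); the U<->T
conversion happens only at RNA-facing boundaries (user input, FASTA of
mature miRNAs, printed structures).
"""

from __future__ import annotations

from typing import Dict, Iterable, Iterator, Tuple

import numpy as np
from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator

_COMPLEMENT = str.maketrans("ACGTUacgtu", "TGCAAtgcaa")

DNA_ALPHABET = "ACGT"


def to_dna(seq: str) -> str:
    """Uppercase and convert U -> T."""
    return seq.upper().replace("U", "T")


def to_rna(seq: str) -> str:
    """Uppercase and convert T -> U."""
    return seq.upper().replace("T", "U")


def revcomp(seq: str) -> str:
    """Reverse complement (DNA or RNA input; output keeps DNA letters)."""
    return to_dna(seq).translate(_COMPLEMENT)[::-1]


def validate_nucleotides(seq: str) -> str:
    """Return the DNA-normalised sequence, raising on non-ACGTU letters."""
    s = to_dna(seq)
    if not s:
        raise ValueError("empty sequence")
    if set(s) - set(DNA_ALPHABET):
        bad = sorted(set(s) - set(DNA_ALPHABET))
        raise ValueError(f"sequence contains non-ACGTU characters: {bad}")
    return s


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance needs equal-length strings")
    return sum(x != y for x, y in zip(a, b))


# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------

def read_fasta(path) -> Dict[str, str]:
    """FASTA file -> ordered {id: DNA-normalised sequence}."""
    out: Dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        out[rec.id] = to_dna(str(rec.seq))
    return out


def write_fasta(path, records: Dict[str, str] | Iterable[Tuple[str, str]]) -> None:
    items = records.items() if isinstance(records, dict) else records
    with open(path, "w") as fh:
        for name, seq in items:
            fh.write(f">{name}\n{seq}\n")


def iter_fastq(path) -> Iterator[Tuple[str, str, str]]:
    """Yield (title, sequence, quality) from a Sanger Phred+33 FASTQ file.

    Malformed records raise ValueError carrying the index of the offending
    record.
    """
    with open(path) as fh:
        it = FastqGeneralIterator(fh)
        i = 0
        while True:
            try:
                title, seq, qual = next(it)
            except StopIteration:
                return
            except ValueError as exc:
                raise ValueError(f"malformed FASTQ record #{i} in {path}: {exc}") from exc
            yield title, seq, qual
            i += 1


def write_fastq(path, records: Iterable[Tuple[str, str, str]]) -> None:
    with open(path, "w") as fh:
        for name, seq, qual in records:
            fh.write(f"@{name}\n{seq}\n+\n{qual}\n")


def parse_collapsed_fasta(path) -> Dict[str, int]:
    """Pre-collapsed FASTA with count-encoded headers ``>tagN_xCOUNT``."""
    out: Dict[str, int] = {}
    for name, seq in read_fasta(path).items():
        try:
            count = int(name.rsplit("_x", 1)[1])
        except (IndexError, ValueError) as exc:
            raise ValueError(
                f"collapsed-FASTA header {name!r} does not end in _xCOUNT"
            ) from exc
        out[seq] = out.get(seq, 0) + count
    return out


def mean_phred(qual: str) -> float:
    if not qual:
        return 0.0
    return float(np.mean([ord(c) - 33 for c in qual]))


# ---------------------------------------------------------------------------
# shuffles and random sequences
# ---------------------------------------------------------------------------

def random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(DNA_ALPHABET), size=length))


def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Shuffle preserving dinucleotide composition (Altschul-Erickson style).

    Builds the transition multigraph of the sequence and draws a random
    Eulerian walk with the same start and end states.
    """
    s = to_dna(seq)
    if len(s) < 3:
        return s
    # adjacency lists of outgoing edges
    edges: Dict[str, list] = {}
    for a, b in zip(s, s[1:]):
        edges.setdefault(a, []).append(b)
    for a in edges:
        perm = rng.permutation(len(edges[a]))
        edges[a] = [edges[a][i] for i in perm]
    # For the walk to be Eulerian and end at the terminal letter, the last
    # edge out of each non-terminal vertex must lie on a path to the end.
    # Retry-based approach: attempt the walk; if stuck early, reshuffle.
    for _ in range(200):
        avail = {a: list(bs) for a, bs in edges.items()}
        walk = [s[0]]
        cur = s[0]
        ok = True
        for _ in range(len(s) - 1):
            if not avail.get(cur):
                ok = False
                break
            nxt = avail[cur].pop()
            walk.append(nxt)
            cur = nxt
        if ok:
            return "".join(walk)
        for a in edges:
            perm = rng.permutation(len(edges[a]))
            edges[a] = [edges[a][i] for i in perm]
    # fallback: plain shuffle (vanishingly rare for realistic sequences)
    arr = list(s)
    rng.shuffle(arr)
    return "".join(arr)
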