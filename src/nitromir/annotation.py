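"""Classify clean tags against reference noncoding-RNA / miRNA sets.

Classification is by exact, full-length, strand-as-given identity against
an ordered list of reference sets: the first set containing the tag wins,
anything else is unannotated.  The default precedence mirrors the usual
annotation cascade (structural ncRNA databases before the mature-miRNA
reference): rRNA > tRNA > snRNA > snoRNA > known_miRNA.  Only perfectly
matched tags are ever counted as known miRNAs; no isomiR aggregation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import pandas as pd

from .de import normalize_tpm
from .seq_utils import read_fasta

DEFAULT_PRECEDENCE = ("rRNA", "tRNA", "snRNA", "snoRNA", "known_miRNA")
UNANNOTATED = "unannotated"


@dataclass
class ReferenceSet:
    """A named reference sequence collection (ids unique within the set)."""

    name: str
    sequences: Dict[str, str]
    _members: Optional[frozenset] = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        if len(set(self.sequences)) != len(self.sequences):
            raise ValueError(f"duplicate ids in reference set {self.name}")

    @classmethod
    def from_fasta(cls, name: str, path) -> "ReferenceSet":
        return cls(name, read_fasta(path))

    @property
    def members(self) -> frozenset:
        if self._members is None:
            self._members = frozenset(self.sequences.values())
        return self._members

    def __contains__(self, seq: str) -> bool:
        return seq in self.members


def classify_tag(sequence: str, refsets: Sequence[ReferenceSet]) -> str:
    """First reference set containing the tag wins; else 'unannotated'."""
    for rs in refsets:
        if sequence in rs:
            return rs.name
    return UNANNOTATED


def classify_all(
    tag_counts: Mapping[str, int] | Iterable[str],
    refsets: Sequence[ReferenceSet],
) -> Tuple[Dict[str, str], pd.Series]:
    """Classify every tag; returns {seq: class} and the unique-tag class
    counts (a partition: counts sum to the number of distinct tags)."""
    seqs = tag_counts.keys() if isinstance(tag_counts, Mapping) else tag_counts
    classes = {s: classify_tag(s, refsets) for s in seqs}
    order = [rs.name for rs in refsets] + [UNANNOTATED]
    counts = pd.Series(
        {name: 0 for name in order}, dtype=int, name="unique_tags"
    )
    for c in classes.values():
        counts[c] += 1
    return classes, counts


def known_mirna_table(
    tags_a: Mapping[str, int],
    tags_b: Mapping[str, int],
    mirna_ref: ReferenceSet,
    totals: Tuple[int, int],
) -> pd.DataFrame:
    """Per-known-miRNA count/TPM profile across the two libraries.

    One row per reference mature miRNA with a nonzero count in either
    library; ``presence`` records whether it was seen in both, a_only or
    b_only.  TPM uses the clean-read totals of the respective library.
    """
    n_a, n_b = totals
    rows = []
    for mirna_id, seq in mirna_ref.sequences.items():
        ca = tags_a.get(seq, 0)
        cb = tags_b.get(seq, 0)
        if ca == 0 and cb == 0:
            continue
        presence = "both" if (ca and cb) else ("a_only" if ca else "b_only")
        rows.append(
            dict(
                mirna_id=mirna_id,
                sequence=seq,
                count_a=ca,
                count_b=cb,
                tpm_a=normalize_tpm(ca, n_a),
                tpm_b=normalize_tpm(cb, n_b),
                presence=presence,
            )
        )
    return pd.DataFrame(
        rows,
        columns=["mirna_id", "sequence", "count_a", "count_b", "tpm_a", "tpm_b", "presence"],
    )
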