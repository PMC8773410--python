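"""Raw reads -> clean unique tags with per-library counts.

A clean tag is an 18-30 nt insert whose 3' adaptor was located and removed
and which passed the ambiguity and quality filters.  Every discarded read is
tallied under exactly one discard class, so read counts are conserved at
the stage boundary (raw = clean + sum of discards), an identity asserted by
the pipeline on every run.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, asdict
from typing import Dict, Iterable, Iterator, List, Mapping, Optional, Tuple, Union

import pandas as pd

from .seq_utils import iter_fastq, mean_phred

DEFAULT_MIN_LEN = 18
DEFAULT_MAX_LEN = 30
DEFAULT_QUALITY_FLOOR = 20.0
ADAPTOR_SEED_LEN = 8
ADAPTOR_MIN_OVERLAP = 6


@dataclass(frozen=True)
class CleanTag:
    """A distinct clean sequence with its read count in each library."""

    sequence: str
    count_a: int
    count_b: int

    def __post_init__(self):
        if self.count_a < 0 or self.count_b < 0 or self.count_a + self.count_b < 1:
            raise ValueError("tag counts must be non-negative and sum to >= 1")

    @property
    def total(self) -> int:
        return self.count_a + self.count_b


@dataclass
class TrimStats:
    """Per-library accounting of the trim/filter stage."""

    raw_reads: int = 0
    clean_reads: int = 0
    no_adaptor: int = 0
    too_short: int = 0
    too_long: int = 0
    low_quality: int = 0
    ambiguous: int = 0

    def check_conservation(self) -> None:
        discarded = (
            self.no_adaptor + self.too_short + self.too_long
            + self.low_quality + self.ambiguous
        )
        if self.clean_reads + discarded != self.raw_reads:
            raise AssertionError(
                f"read accounting broken: {self.raw_reads} raw != "
                f"{self.clean_reads} clean + {discarded} discarded"
            )

    def as_dict(self) -> Dict[str, int]:
        return asdict(self)


@dataclass(frozen=True)
class LibraryAccounting:
    """Library-level tag bookkeeping (unique = common + specific)."""

    raw_reads: int
    clean_reads: int
    unique_tags: int
    common_tags: int
    specific_tags: int

    def __post_init__(self):
        if self.specific_tags != self.unique_tags - self.common_tags:
            raise ValueError("specific_tags must equal unique_tags - common_tags")
        if self.clean_reads > self.raw_reads:
            raise ValueError("clean_reads cannot exceed raw_reads")


def find_adaptor(
    read: str,
    adaptor3: str,
    seed_len: int = ADAPTOR_SEED_LEN,
    min_overlap: int = ADAPTOR_MIN_OVERLAP,
) -> int:
    """Start of the 3' adaptor in ``read``, or -1.

    Exact match of the adaptor's first ``seed_len`` bases anywhere wins;
    otherwise adaptor prefixes down to ``min_overlap`` bases are tried
    against the read's end (adaptor running off the read).
    """
    pos = read.find(adaptor3[: seed_len])
    if pos >= 0:
        return pos
    for k in range(min(seed_len - 1, len(adaptor3)), min_overlap - 1, -1):
        if read.endswith(adaptor3[:k]):
            return len(read) - k
    return -1


def trim_and_filter(
    reads: Union[str, Iterable[Tuple[str, str]]],
    adaptor3: str,
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
    quality_floor: float = DEFAULT_QUALITY_FLOOR,
) -> Tuple[List[str], TrimStats]:
    """Trim the 3' adaptor and filter reads; returns clean inserts + stats.

    ``reads`` is a FASTQ path or an iterable of (sequence, quality)
    pairs.  Discard classes, checked in order: no_adaptor, ambiguous (any
    N in the insert), low_quality (mean Phred of the insert below
    ``quality_floor``), too_short / too_long.
    """
    if len(adaptor3) < 6:
        raise ValueError("adaptor must be at least 6 nt")
    if isinstance(reads, str):
        reads = ((seq, qual) for _, seq, qual in iter_fastq(reads))
    stats = TrimStats()
    clean: List[str] = []
    for seq, qual in reads:
        stats.raw_reads += 1
        seq = seq.upper()
        pos = find_adaptor(seq, adaptor3)
        if pos < 0:
            stats.no_adaptor += 1
            continue
        insert = seq[:pos]
        if "N" in insert or not insert:
            stats.ambiguous += 1
            continue
        if qual is not None and mean_phred(qual[:pos]) < quality_floor:
            stats.low_quality += 1
            continue
        if len(insert) < min_len:
            stats.too_short += 1
            continue
        if len(insert) > max_len:
            stats.too_long += 1
            continue
        clean.append(insert.replace("U", "T"))
        stats.clean_reads += 1
    stats.check_conservation()
    return clean, stats


def collapse_tags(sequences: Iterable[str]) -> Counter:
    """Distinct sequence -> occurrence count.  Idempotent on tag keys."""
    return Counter(sequences)


def collapse_pair(
    seqs_a: Union[Iterable[str], Mapping[str, int]],
    seqs_b: Union[Iterable[str], Mapping[str, int]],
) -> List[CleanTag]:
    """Collapse two clean-sequence streams into a joint tag table.

    Accepts raw sequence iterables or pre-collapsed ``{seq: count}``
    mappings.  Output order is deterministic: by descending total count,
    then sequence.
    """
    ca = seqs_a if isinstance(seqs_a, Mapping) else collapse_tags(seqs_a)
    cb = seqs_b if isinstance(seqs_b, Mapping) else collapse_tags(seqs_b)
    seqs = set(ca) | set(cb)
    tags = [CleanTag(s, ca.get(s, 0), cb.get(s, 0)) for s in seqs]
    tags.sort(key=lambda t: (-t.total, t.sequence))
    return tags


def library_overlap(
    tags_a: Mapping[str, int],
    tags_b: Mapping[str, int],
    raw_reads: Tuple[int, int] = (0, 0),
) -> Tuple[LibraryAccounting, LibraryAccounting]:
    """Unique/common/specific accounting for two collapsed libraries."""
    set_a, set_b = set(tags_a), set(tags_b)
    common = len(set_a & set_b)
    clean_a, clean_b = sum(tags_a.values()), sum(tags_b.values())
    acc_a = LibraryAccounting(
        raw_reads=max(raw_reads[0], clean_a),
        clean_reads=clean_a,
        unique_tags=len(set_a),
        common_tags=common,
        specific_tags=len(set_a) - common,
    )
    acc_b = LibraryAccounting(
        raw_reads=max(raw_reads[1], clean_b),
        clean_reads=clean_b,
        unique_tags=len(set_b),
        common_tags=common,
        specific_tags=len(set_b) - common,
    )
    return acc_a, acc_b


def length_histogram(
    tags: Union[Mapping[str, int], Iterable[CleanTag]],
    weight: str = "unique",
    lo: int = 10,
    hi: int = 32,
) -> pd.Series:
    """Tag-length histogram over [lo, hi]; out-of-range lengths excluded.

    ``weight='unique'`` counts distinct sequences, ``'abundance'`` counts
    reads.
    """
    if weight not in ("unique", "abundance"):
        raise ValueError("weight must be 'unique' or 'abundance'")
    if isinstance(tags, Mapping):
        items = tags.items()
    else:
        items = ((t.sequence, t.total) for t in tags)
    hist = Counter()
    for seq, count in items:
        L = len(seq)
        if lo <= L <= hi:
            hist[L] += 1 if weight == "unique" else count
    return pd.Series([hist.get(L, 0) for L in range(lo, hi + 1)],
                     index=pd.RangeIndex(lo, hi + 1, name="length"),
                     name=weight)
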