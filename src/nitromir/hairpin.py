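"""Novel miRNA discovery from unannotated tags.

Pipeline per tag: map to the genome (both strands, up to one substitution),
excise candidate precursor windows around each locus, screen windows for a
plausible star arm (an approximate reverse complement of the tag elsewhere
in the window), fold the most promising windows, and accept the
best-scoring window that behaves like a plant miRNA precursor:

* precursor length within [62, 96] nt and fold MFE at or below the ceiling
  (default -18 kcal/mol);
* the mature tag lies fully on one arm of the stem (never across the
  terminal loop) and is predominantly paired;
* the mature/star duplex carries at most 4 mismatches, with G:U wobbles
  scored as half a mismatch (the same scorer as target prediction).

Multi-locus tags are reported once with their locus count; read counts are
not multiplied by locus number.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np

from .folding import HairpinStructure, fold
from .seq_utils import revcomp
from .tags import CleanTag
from .targets import score_window

DEFAULT_MFE_CEILING = -18.0
DEFAULT_MAX_DUPLEX_SCORE = 4.0
DEFAULT_MIN_PRECURSOR = 62
DEFAULT_MAX_PRECURSOR = 96
DEFAULT_MIN_MATURE = 20
DEFAULT_MAX_MATURE = 23
DEFAULT_FLANK = 150
DEFAULT_MAX_FOLDS = 16
MIN_LOOP_GAP = 3  # minimum unpaired gap between mature and star

REJECTION_REASONS = (
    "no_hairpin",
    "mature_in_loop",
    "too_many_mismatches",
    "energy_too_high",
    "length_out_of_range",
)


@dataclass(frozen=True)
class GenomicLocus:
    contig: str
    start: int  # 0-based, plus-strand coordinates
    end: int  # exclusive
    strand: str  # '+' or '-'
    n_mismatches: int = 0


@dataclass(frozen=True)
class MappedTag:
    tag: CleanTag
    loci: Tuple[GenomicLocus, ...]


@dataclass(frozen=True)
class NovelMiRNACandidate:
    id: str
    mature: str
    star: str
    precursor: HairpinStructure
    locus: GenomicLocus  # precursor locus (plus-strand coords)
    mature_offset: int  # 0-based offset of the mature within the precursor
    n_loci: int
    count_a: int
    count_b: int


@dataclass(frozen=True)
class Rejection:
    sequence: str
    reason: str

    def __post_init__(self):
        assert self.reason in REJECTION_REASONS + ("unmapped",)


# ---------------------------------------------------------------------------
# genome mapping
# ---------------------------------------------------------------------------

class GenomeIndex:
    """Exact k-mer index over both strands for seed-and-verify mapping.

    A tag aligned with <= 1 substitution must match exactly on one of its
    two halves, so looking both halves up in the index and verifying the
    full-length Hamming distance finds every locus.
    """

    def __init__(self, genome: Mapping[str, str], kmer_sizes: Iterable[int]):
        self.genome = {c: s.upper() for c, s in genome.items()}
        self.oriented = {}
        for contig, seq in self.genome.items():
            self.oriented[(contig, "+")] = seq
            self.oriented[(contig, "-")] = revcomp(seq)
        self.ks = sorted(set(kmer_sizes))
        self.index: Dict[int, Dict[str, List[Tuple[str, str, int]]]] = {}
        for k in self.ks:
            idx: Dict[str, List[Tuple[str, str, int]]] = {}
            for (contig, strand), seq in sorted(self.oriented.items()):
                for pos in range(len(seq) - k + 1):
                    idx.setdefault(seq[pos : pos + k], []).append((contig, strand, pos))
            self.index[k] = idx

    def lookup(self, kmer: str) -> List[Tuple[str, str, int]]:
        return self.index.get(len(kmer), {}).get(kmer, [])


def _hamming_leq(a: str, b: str, limit: int) -> int:
    d = 0
    for x, y in zip(a, b):
        if x != y:
            d += 1
            if d > limit:
                return d
    return d


def map_tags(
    tags: Iterable[CleanTag],
    genome: Mapping[str, str],
    max_mismatches: int = 1,
    index: Optional[GenomeIndex] = None,
) -> List[MappedTag]:
    """All genomic loci of each tag with <= ``max_mismatches``
    substitutions; tags with zero loci are dropped."""
    tags = list(tags)
    lengths = {len(t.sequence) for t in tags}
    ks = {L // 2 for L in lengths} | {L - L // 2 for L in lengths}
    if index is None:
        index = GenomeIndex(genome, ks)
    out: List[MappedTag] = []
    for tag in tags:
        seq = tag.sequence
        L = len(seq)
        k1 = L // 2
        cands = set()
        for start_shift, kmer in ((0, seq[:k1]), (k1, seq[k1:])):
            for contig, strand, pos in index.lookup(kmer):
                cands.add((contig, strand, pos - start_shift))
        loci = []
        for contig, strand, pos in sorted(cands):
            oriented = index.oriented[(contig, strand)]
            if pos < 0 or pos + L > len(oriented):
                continue
            d = _hamming_leq(seq, oriented[pos : pos + L], max_mismatches)
            if d <= max_mismatches:
                if strand == "+":
                    start = pos
                else:
                    start = len(oriented) - (pos + L)
                loci.append(GenomicLocus(contig, start, start + L, strand, d))
        if loci:
            out.append(MappedTag(tag, tuple(loci)))
    return out


# ---------------------------------------------------------------------------
# precursor excision
# ---------------------------------------------------------------------------

def oriented_tag_start(locus: GenomicLocus, contig_len: int) -> int:
    """Tag start in the transcription-orientation coordinate system."""
    if locus.strand == "+":
        return locus.start
    return contig_len - locus.end


def excise_windows(
    locus: GenomicLocus,
    genome: Mapping[str, str],
    flank: int = DEFAULT_FLANK,
    min_len: int = DEFAULT_MIN_PRECURSOR,
    max_len: int = DEFAULT_MAX_PRECURSOR,
    margin: int = 4,
    len_step: int = 2,
    offset_step: int = 2,
) -> List[Tuple[int, int]]:
    """Candidate precursor windows around a tag locus.

    Returned as half-open, 0-based intervals in the locus's transcription
    orientation (i.e. on the reverse-complemented contig for '-' loci).
    The tag is placed at varying offsets on either arm and window lengths
    sweep [min_len, max_len + margin]; windows are clipped to the contig,
    so coordinates are never negative.
    """
    contig_len = len(genome[locus.contig])
    s = oriented_tag_start(locus, contig_len)
    tag_len = locus.end - locus.start
    lo = max(0, s - flank)
    hi = min(contig_len, s + tag_len + flank)
    windows = set()
    for w in range(min_len, max_len + margin + 1, len_step):
        for off in range(0, w - tag_len + 1, offset_step):
            a = s - off
            b = a + w
            a2, b2 = max(lo, a), min(hi, b)
            if b2 - a2 >= tag_len and a2 <= s and s + tag_len <= b2:
                windows.add((a2, b2))
    return sorted(windows)


# ---------------------------------------------------------------------------
# candidate calling
# ---------------------------------------------------------------------------

def _star_scores(tag: str, region: str) -> np.ndarray:
    """Duplex mismatch score of ``tag`` against every window of ``region``
    (vectorised; the star arm is an approximate reverse complement)."""
    from .targets import _codes

    m = _codes(tag)
    t = _codes(region)
    L = len(m)
    if len(t) < L:
        return np.empty(0)
    win = np.lib.stride_tricks.sliding_window_view(t, L)[:, ::-1]
    comp = 3 - m
    match = win == comp
    gu = ((m == 2) & (win == 3)) | ((m == 3) & (win == 2))
    return np.where(match, 0.0, np.where(gu, 0.5, 1.0)).sum(axis=1)


_STAGE_RANK = {
    "unmapped": -1,
    "length_out_of_range": 0,
    "too_many_mismatches_screen": 1,
    "energy_too_high": 2,
    "no_hairpin": 3,
    "mature_in_loop": 4,
    "too_many_mismatches": 5,
}


def call_novel(
    tag: CleanTag,
    loci: Sequence[GenomicLocus],
    genome: Mapping[str, str],
    mfe_ceiling: float = DEFAULT_MFE_CEILING,
    max_duplex_score: float = DEFAULT_MAX_DUPLEX_SCORE,
    min_precursor: int = DEFAULT_MIN_PRECURSOR,
    max_precursor: int = DEFAULT_MAX_PRECURSOR,
    min_mature: int = DEFAULT_MIN_MATURE,
    max_mature: int = DEFAULT_MAX_MATURE,
    flank: int = DEFAULT_FLANK,
    max_folds: int = DEFAULT_MAX_FOLDS,
    candidate_id: str = "",
) -> Union[NovelMiRNACandidate, Rejection]:
    """Evaluate one mapped tag as a putative novel miRNA.

    Folds the most star-plausible windows at each locus and returns the
    accepted window with the lowest MFE, or a Rejection naming the most
    advanced failure stage.
    """
    seq = tag.sequence
    L = len(seq)
    if not (min_mature <= L <= max_mature):
        return Rejection(seq, "length_out_of_range")

    best: Optional[Tuple[float, NovelMiRNACandidate]] = None
    worst_stage = -1

    def note(reason: str) -> None:
        nonlocal worst_stage
        worst_stage = max(worst_stage, _STAGE_RANK[reason])

    for locus in loci:
        contig_len = len(genome[locus.contig])
        oriented = genome[locus.contig].upper() if locus.strand == "+" else revcomp(genome[locus.contig])
        s = oriented_tag_start(locus, contig_len)
        ra = max(0, s - flank - 4)
        rb = min(contig_len, s + L + flank + 4)
        region = oriented[ra:rb]
        scores = _star_scores(seq, region)

        windows = excise_windows(locus, genome, flank=flank,
                                 min_len=min_precursor, max_len=max_precursor,
                                 margin=0)
        scored_windows = []
        for (a, b) in windows:
            if not (min_precursor <= b - a <= max_precursor):
                note("length_out_of_range")
                continue
            # best candidate star offset inside the window, clear of the tag
            best_q = None
            for q0, q1 in ((a, s - L - MIN_LOOP_GAP + 1), (s + L + MIN_LOOP_GAP, b - L + 1)):
                q0i, q1i = max(q0, ra) - ra, min(q1, rb - L + 1) - ra
                if q1i > q0i and len(scores):
                    seg = scores[q0i:q1i]
                    qmin = int(np.argmin(seg))
                    val = float(seg[qmin])
                    if best_q is None or val < best_q[0]:
                        best_q = (val, q0i + qmin + ra)
            if best_q is None or best_q[0] > max_duplex_score:
                note("too_many_mismatches_screen")
                continue
            scored_windows.append((best_q[0], b - a, a, b))

        scored_windows.sort()
        for _, _, a, b in scored_windows[:max_folds]:
            window = oriented[a:b]
            st = fold(window)
            if st.mfe > mfe_ceiling:
                note("energy_too_high")
                continue
            ms = s - a  # mature offset in window
            pair_map = {}
            for (i, j) in st.pairs:
                pair_map[i] = j
                pair_map[j] = i
            partners = [pair_map[p] for p in range(ms, ms + L) if p in pair_map]
            if len(partners) < L // 2:
                note("no_hairpin")
                continue
            db = st.dotbracket[ms : ms + L]
            if "(" in db and ")" in db:
                note("mature_in_loop")
                continue
            p0 = min(partners)
            if p0 + L > len(window):
                p0 = len(window) - L
            star = window[p0 : p0 + L]
            if not (p0 + L <= ms or p0 >= ms + L):
                note("mature_in_loop")
                continue
            duplex = score_window(seq, star)
            if duplex.mismatch_score > max_duplex_score:
                note("too_many_mismatches")
                continue
            # accepted: convert window back to plus-strand coordinates
            if locus.strand == "+":
                w_start, w_end = a, b
            else:
                w_start, w_end = contig_len - b, contig_len - a
            cand = NovelMiRNACandidate(
                id=candidate_id,
                mature=seq,
                star=star,
                precursor=st,
                locus=GenomicLocus(locus.contig, w_start, w_end, locus.strand),
                mature_offset=ms,
                n_loci=len(loci),
                count_a=tag.count_a,
                count_b=tag.count_b,
            )
            if best is None or st.mfe < best[0]:
                best = (st.mfe, cand)
    if best is not None:
        return best[1]
    if worst_stage < 0:
        return Rejection(seq, "no_hairpin")
    reason = [k for k, v in _STAGE_RANK.items() if v == worst_stage][0]
    if reason == "too_many_mismatches_screen":
        reason = "too_many_mismatches"
    return Rejection(seq, reason)


def discover_novel(
    tags: Sequence[CleanTag],
    genome: Mapping[str, str],
    min_count: int = 5,
    max_mismatches: int = 1,
    id_prefix: str = "mir-novel",
    **call_kwargs,
) -> Tuple[List[NovelMiRNACandidate], List[Rejection]]:
    """Full discovery pass over unannotated tags.

    Tags below ``min_count`` total reads are ignored (singleton background
    never supports a miRNA call).  Candidates whose precursor loci overlap
    are deduplicated, keeping the most abundant mature tag.
    """
    eligible = [t for t in tags if t.total >= min_count]
    eligible.sort(key=lambda t: (-t.total, t.sequence))
    mapped = map_tags(eligible, genome, max_mismatches=max_mismatches)
    candidates: List[NovelMiRNACandidate] = []
    rejections: List[Rejection] = []
    for mt in mapped:
        res = call_novel(mt.tag, mt.loci, genome, **call_kwargs)
        if isinstance(res, Rejection):
            rejections.append(res)
        else:
            candidates.append(res)
    # deduplicate overlapping precursors (e.g. 1-substitution read variants)
    kept: List[NovelMiRNACandidate] = []
    for cand in sorted(candidates, key=lambda c: (-(c.count_a + c.count_b), c.mature)):
        loc = cand.locus
        clash = any(
            k.locus.contig == loc.contig
            and k.locus.strand == loc.strand
            and k.locus.start < loc.end
            and loc.start < k.locus.end
            for k in kept
        )
        if clash:
            continue
        kept.append(cand)
    kept.sort(key=lambda c: (c.locus.contig, c.locus.start, c.mature))
    out = []
    for i, cand in enumerate(kept, start=1):
        out.append(
            NovelMiRNACandidate(
                id=f"{id_prefix}-{i}", mature=cand.mature, star=cand.star,
                precursor=cand.precursor, locus=cand.locus,
                mature_offset=cand.mature_offset, n_loci=cand.n_loci,
                count_a=cand.count_a, count_b=cand.count_b,
            )
        )
    return out, rejections


# ---------------------------------------------------------------------------
# output
# ---------------------------------------------------------------------------

def candidates_to_gff3(candidates: Sequence[NovelMiRNACandidate]) -> str:
    """GFF3 (1-based, inclusive) of precursor loci."""
    lines = ["##gff-version 3"]
    for c in candidates:
        lines.append(
            "\t".join(
                [
                    c.locus.contig, "nitromir", "miRNA_primary_transcript",
                    str(c.locus.start + 1), str(c.locus.end), ".",
                    c.locus.strand, ".",
                    f"ID={c.id};mfe={c.precursor.mfe:.2f};n_loci={c.n_loci}",
                ]
            )
        )
    return "\n".join(lines) + "\n"


def candidates_to_table(candidates: Sequence[NovelMiRNACandidate]):
    import pandas as pd

    rows = []
    for c in candidates:
        rows.append(
            dict(
                id=c.id, mature=c.mature, star=c.star,
                precursor=c.precursor.sequence, dotbracket=c.precursor.dotbracket,
                mfe=c.precursor.mfe, contig=c.locus.contig,
                start=c.locus.start, end=c.locus.end, strand=c.locus.strand,
                n_loci=c.n_loci, count_a=c.count_a, count_b=c.count_b,
            )
        )
    return pd.DataFrame(
        rows,
        columns=["id", "mature", "star", "precursor", "dotbracket", "mfe",
                 "contig", "start", "end", "strand", "n_loci", "count_a", "count_b"],
    )
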