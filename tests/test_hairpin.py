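"""Hairpin discovery: mapping, excision, calling, shuffle rejection."""

from __future__ import annotations

import numpy as np
import pytest

from nitromir.hairpin import (
    GenomicLocus,
    NovelMiRNACandidate,
    Rejection,
    call_novel,
    discover_novel,
    excise_windows,
    map_tags,
)
from nitromir.seq_utils import dinucleotide_shuffle, random_seq, revcomp
from nitromir.synthetic import build_genome_with_hairpins
from nitromir.tags import CleanTag
from nitromir.targets import score_window


def test_map_tags_finds_planted_loci_on_both_strands():
    rng = np.random.default_rng(0)
    tag = random_seq(rng, 21)
    backbone = random_seq(rng, 3000)
    genome = {"c1": backbone[:500] + tag + backbone[500:2000] + revcomp(tag) + backbone[2000:]}
    mapped = map_tags([CleanTag(tag, 3, 2)], genome)
    assert len(mapped) == 1
    loci = mapped[0].loci
    strands = {l.strand for l in loci}
    assert strands == {"+", "-"} and len(loci) == 2
    for l in loci:
        sub = genome["c1"][l.start : l.end]
        assert (sub if l.strand == "+" else revcomp(sub)) == tag


def test_map_tags_multi_locus_count():
    rng = np.random.default_rng(1)
    tag = random_seq(rng, 21)
    spacer = lambda: random_seq(rng, 120)
    genome = {"c1": spacer() + (tag + spacer()) * 9}
    mapped = map_tags([CleanTag(tag, 5, 5)], genome)
    assert len(mapped[0].loci) == 9


def test_map_tags_mismatch_threshold():
    rng = np.random.default_rng(2)
    tag = random_seq(rng, 22)
    one_mm = "G" + tag[1:] if tag[0] != "G" else "A" + tag[1:]
    two_mm = one_mm[:-1] + ("G" if one_mm[-1] != "G" else "A")
    genome = {"c1": random_seq(rng, 400) + tag + random_seq(rng, 400)}
    assert map_tags([CleanTag(one_mm, 1, 1)], genome)[0].loci[0].n_mismatches == 1
    assert map_tags([CleanTag(two_mm, 1, 1)], genome) == []


def test_excise_windows_truncate_at_contig_edges():
    genome = {"c1": "ACGT" * 100}
    locus = GenomicLocus("c1", 2, 23, "+")
    for a, b in excise_windows(locus, genome):
        assert a >= 0 and b <= len(genome["c1"])
        assert a <= 2 and 23 <= b


def test_excise_windows_cover_planted_precursor():
    genome, truth = build_genome_with_hairpins(4, 12_000, seed=3)
    for m in truth:
        contig, start, end, strand = m.genome_locus
        L = len(genome[contig])
        if strand == "+":
            ms = start + m.mature_offset
            locus = GenomicLocus(contig, ms, ms + len(m.mature_seq), "+")
            want = (start, end)
        else:
            # mature position on the oriented (revcomp) contig
            ms_oriented = (L - end) + m.mature_offset
            locus = GenomicLocus(contig, L - (ms_oriented + len(m.mature_seq)),
                                 L - ms_oriented, "-")
            want = (L - end, L - start)
        windows = excise_windows(locus, genome, len_step=1, offset_step=1)
        assert want in windows


def test_call_novel_accepts_planted_hairpin_with_correct_mature():
    genome, truth = build_genome_with_hairpins(5, 15_000, seed=7)
    for m in truth:
        tag = CleanTag(m.mature_seq, 20, 30)
        mapped = map_tags([tag], genome)
        assert mapped, m.id
        res = call_novel(tag, mapped[0].loci, genome)
        assert isinstance(res, NovelMiRNACandidate), (m.id, res)
        assert res.mature == m.mature_seq
        assert res.precursor.mfe <= -18
        assert 62 <= len(res.precursor.sequence) <= 96
        assert score_window(res.mature, res.star).mismatch_score <= 4


def test_call_novel_rejects_mature_spanning_the_loop():
    """A tag centred on the terminal loop of a planted hairpin cannot be a
    mature miRNA."""
    genome, truth = build_genome_with_hairpins(3, 10_000, seed=9)
    m = truth[0]
    contig, start, end, strand = m.genome_locus
    prec = m.precursor_seq
    # take 21 nt centred on the middle of the precursor (the loop region)
    mid = len(prec) // 2
    loop_tag = prec[mid - 10 : mid + 11]
    if strand == "+":
        ts = start + (mid - 10)
        locus = GenomicLocus(contig, ts, ts + 21, "+")
    else:
        L = len(genome[contig])
        ms_oriented = (L - end) + (mid - 10)
        locus = GenomicLocus(contig, L - (ms_oriented + 21), L - ms_oriented, "-")
    res = call_novel(CleanTag(loop_tag, 10, 10), [locus], genome)
    assert isinstance(res, Rejection)
    assert res.reason in ("mature_in_loop", "no_hairpin", "too_many_mismatches")


def test_call_novel_rejects_length_out_of_range():
    genome = {"c1": "ACGT" * 300}
    res = call_novel(CleanTag("ACGTACGTACGTACGTAC", 9, 9), [GenomicLocus("c1", 0, 18, "+")], genome)
    assert isinstance(res, Rejection) and res.reason == "length_out_of_range"


def test_shuffled_precursors_are_rejected():
    """Dinucleotide-shuffling the precursor around a planted mature destroys
    the hairpin: >= 90% of 100 shuffles are rejected."""
    genome, truth = build_genome_with_hairpins(2, 8_000, seed=13)
    m = truth[0]
    prec, off, L = m.precursor_seq, m.mature_offset, len(m.mature_seq)
    rng = np.random.default_rng(17)
    rejected = 0
    n = 100
    for _ in range(n):
        shuffled = list(dinucleotide_shuffle(prec, rng))
        shuffled[off : off + L] = m.mature_seq  # keep the mature in place
        fake = "".join(shuffled)
        g = {"c1": random_seq(rng, 300) + fake + random_seq(rng, 300)}
        locus = GenomicLocus("c1", 300 + off, 300 + off + L, "+")
        res = call_novel(CleanTag(m.mature_seq, 10, 10), [locus], g)
        rejected += isinstance(res, Rejection)
    assert rejected >= 0.9 * n


def test_discover_deduplicates_variant_tags(small_study):
    """A 1-substitution variant of a mature tag maps to the same hairpin and
    must not create a second candidate."""
    from nitromir import tags as tags_mod

    truth = small_study["truth"]
    m = truth[0]
    variant = ("A" if m.mature_seq[5] != "A" else "C").join(
        [m.mature_seq[:5], m.mature_seq[6:]]
    )
    pair = [CleanTag(m.mature_seq, 50, 60), CleanTag(variant, 6, 7)]
    cands, _ = discover_novel(pair, small_study["genome"], min_count=5)
    assert len(cands) == 1
    assert cands[0].mature == m.mature_seq  # the abundant tag wins
    assert cands[0].n_loci == m.n_loci
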