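"""Target prediction: scoring conventions, the six rules, energies, scans."""

from __future__ import annotations

import numpy as np
import pytest

from nitromir.seq_utils import random_seq, revcomp
from nitromir.targets import (
    GU,
    MATCH,
    MISMATCH,
    apply_rules,
    duplex_energy,
    evaluate_site,
    pair_states,
    perfect_energy,
    scan_transcript,
    scan_transcriptome,
    score_window,
)

from oracles import naive_duplex_score

MIR = "TGGAGCTCCCTTCATTCCAAT"  # 21 nt


def mutate_site(mirna, changes):
    """Apply {position: target_base} edits to the perfect-complement site."""
    w = list(revcomp(mirna))
    L = len(mirna)
    for p, base in changes.items():
        w[L - p] = base
    return "".join(w)


def test_perfect_complement_scores_zero_and_passes_all_rules():
    site = revcomp(MIR)
    aln = score_window(MIR, site)
    assert aln.mismatch_score == 0.0
    assert set(aln.states) == {MATCH}
    hit = evaluate_site(MIR, site, 0)
    assert hit.accepted and hit.mfe_ratio == pytest.approx(1.0)


def test_single_wobble_scores_half():
    p = MIR.index("G") + 1
    site = mutate_site(MIR, {p: "T"})  # G:U wobble
    aln = score_window(MIR, site)
    assert aln.states[p - 1] == GU
    assert aln.mismatch_score == 0.5


def test_scores_match_independent_naive_scorer():
    rng = np.random.default_rng(4)
    for _ in range(60):
        m = random_seq(rng, 21)
        w = random_seq(rng, 21)
        assert score_window(m, w).mismatch_score == naive_duplex_score(m, w)


def test_position_convention_is_five_prime_anchored():
    """A mismatch only at miRNA position 1 leaves rules 2-4 passing."""
    m = MIR
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    bad = {"A": "C", "C": "A", "G": "G", "T": "T"}[m[0]]  # no pair, no wobble
    site = mutate_site(m, {1: bad})
    hit = evaluate_site(m, site, 0)
    assert hit.alignment.states[0] == MISMATCH
    assert hit.rule_verdicts[1] and hit.rule_verdicts[2] and hit.rule_verdicts[3]


def _mm_base(m):
    """A base that mismatches miRNA base m without forming a wobble."""
    return {"A": "C", "C": "A", "G": "G", "T": "T"}[m]


def test_rule4_cleavage_site_mismatch():
    site = mutate_site(MIR, {10: _mm_base(MIR[9])})
    hit = evaluate_site(MIR, site, 0)
    assert hit.rule_verdicts == (True, True, True, False, True, True)


def test_rule3_adjacent_seed_mismatches_also_shape_rule2():
    """Adjacent mismatches at 2-3 violate rule 3; a run of two stays within
    rule 2 ('no more than two adjacent'), a run of three breaks it."""
    changes = {p: _mm_base(MIR[p - 1]) for p in (2, 3)}
    hit = evaluate_site(MIR, mutate_site(MIR, changes), 0)
    assert hit.rule_verdicts[2] is False
    assert hit.rule_verdicts[1] is True
    changes = {p: _mm_base(MIR[p - 1]) for p in (14, 15, 16)}
    hit = evaluate_site(MIR, mutate_site(MIR, changes), 0)
    assert hit.rule_verdicts[1] is False
    assert hit.rule_verdicts[2] is True  # run outside positions 2-12


def test_rule5_seed_score_threshold():
    # 5 wobble-able or mismatch positions in 1..12 summing over 2.5
    changes = {p: _mm_base(MIR[p - 1]) for p in (2, 4, 6)}
    hit = evaluate_site(MIR, mutate_site(MIR, changes), 0)
    assert hit.rule_verdicts[4] is False
    assert hit.rule_verdicts[0] is True  # total 3 <= 4


def test_energies_perfect_identity_and_mismatch_monotonicity():
    assert perfect_energy(MIR) == pytest.approx(duplex_energy(MIR, revcomp(MIR)))
    pe = perfect_energy(MIR)
    site = revcomp(MIR)
    for pos in range(len(MIR)):
        for alt in "ACGT":
            if site[pos] == alt:
                continue
            w = site[:pos] + alt + site[pos + 1:]
            assert duplex_energy(MIR, w) >= pe - 1e-9
    assert duplex_energy(MIR, MIR[::-1].translate(str.maketrans("ACGT", "ACGT"))) <= 0


def test_all_mismatch_window_has_zero_energy():
    m = "A" * 21
    w = "C" * 21
    assert duplex_energy(m, w) == 0.0


def test_adding_a_mismatch_never_rescues_a_failing_rule():
    rng = np.random.default_rng(8)
    for _ in range(25):
        m = random_seq(rng, 21)
        site = list(revcomp(m))
        # start from a site with one random mismatch, add another
        p1 = int(rng.integers(1, 22))
        site[21 - p1] = _mm_base(m[p1 - 1])
        before = evaluate_site(m, "".join(site), 0).rule_verdicts
        p2 = int(rng.integers(1, 22))
        site2 = list(site)
        site2[21 - p2] = _mm_base(m[p2 - 1])
        after = evaluate_site(m, "".join(site2), 0).rule_verdicts
        for b, a in zip(before, after):
            if not b:
                assert not a


def test_scan_matches_brute_force_all_windows():
    rng = np.random.default_rng(5)
    m = random_seq(rng, 21)
    transcript = random_seq(rng, 120) + revcomp(m) + random_seq(rng, 60)
    hits = scan_transcript(m, transcript, "m", "t")
    brute = [
        q
        for q in range(len(transcript) - 21 + 1)
        if evaluate_site(m, transcript, q).accepted
    ]
    assert [h.alignment.site_start for h in hits] == brute
    assert 120 in brute


def test_two_sites_one_gene_deduplicates():
    rng = np.random.default_rng(6)
    m = random_seq(rng, 21)
    t = random_seq(rng, 40) + revcomp(m) + random_seq(rng, 40) + revcomp(m) + random_seq(rng, 20)
    hits, genes = scan_transcriptome({"m": m}, {"g1": t})
    assert len(hits) == 2
    assert genes == ["g1"]
    assert scan_transcriptome({"m": m}, {})[0] == []


def test_truth_set_sites_fail_exactly_their_tagged_rule(small_study):
    """Every planted violation site fails exactly its rule; every clean
    site is accepted, and scanning recovers the clean sites."""
    transcripts = small_study["transcripts"]
    sites = small_study["planted_sites"]
    matures = {m.id: m.mature_seq for m in small_study["truth"]}
    assert sites, "fixture must plant sites"
    for s in sites:
        hit = evaluate_site(matures[s.mirna_id], transcripts[s.transcript_id], s.site_start)
        if s.violation == "none":
            assert hit.accepted
        else:
            idx = int(s.violation[-1]) - 1
            expected = tuple(i != idx for i in range(6))
            assert hit.rule_verdicts == expected, (s, hit.rule_verdicts)
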