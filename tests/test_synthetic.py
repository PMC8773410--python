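"""Generator contracts: determinism, invariants, count conservation."""

from __future__ import annotations

import filecmp

import numpy as np
import pytest

from nitromir.synthetic import (
    CapacityError,
    LibrarySimSpec,
    build_genome_with_hairpins,
    build_reference_sets,
    simulate_libraries,
    write_simulation,
)
from nitromir.targets import score_window


def test_empty_case_returns_random_genome():
    genome, truth = build_genome_with_hairpins(0, 2000, seed=0)
    assert truth == [] and len(genome["chr1"]) == 2000


def test_planted_hairpin_invariants():
    genome, truth = build_genome_with_hairpins(30, 60_000, seed=2)
    assert len(truth) == 30
    for m in truth:
        assert 62 <= len(m.precursor_seq) <= 96
        assert 20 <= len(m.mature_seq) <= 23
        assert m.mature_seq in m.precursor_seq
        assert m.precursor_seq[m.mature_offset : m.mature_offset + len(m.mature_seq)] == m.mature_seq
        assert score_window(m.mature_seq, m.star_seq).mismatch_score <= 4
        assert m.n_loci == len(m.loci) >= 1
        assert m.tpm_condition_a > 0 and m.tpm_condition_b > 0
    assert any(m.n_loci > 1 for m in truth)


def test_same_seed_gives_byte_identical_output(tmp_path):
    a = tmp_path / "runA"
    b = tmp_path / "runB"
    for d in (a, b):
        write_simulation(d, n_hairpins=4, depth_a=3000, depth_b=3000,
                         error_rate=0.01, seed=21)
    for name in ("genome.fa", "reads_a.fastq", "reads_b.fastq",
                 "transcripts.fa", "kog_map.tsv", "truth_mirnas.tsv"):
        assert filecmp.cmp(a / name, b / name, shallow=False), name


def test_capacity_error_when_genome_too_small():
    with pytest.raises(CapacityError):
        build_genome_with_hairpins(30, 3000, seed=0)


def test_count_conservation_and_composition(tmp_path):
    """Emitted reads per library = expected count table + background."""
    genome, truth = build_genome_with_hairpins(5, 15_000, seed=4)
    refsets = build_reference_sets(seed=5)
    spec = LibrarySimSpec(depth=5000, error_rate=0.0, seed=6)
    sim = simulate_libraries(truth, spec, LibrarySimSpec(depth=5000, seed=7),
                            refsets, tmp_path / "a.fastq", tmp_path / "b.fastq")
    n_lines = sum(1 for _ in open(tmp_path / "a.fastq"))
    assert n_lines == 4 * spec.depth
    assert sim.library_a.n_reads == spec.depth
    assert sim.library_a.n_mirna_reads == sim.expected.count_a.sum()
    assert sim.library_a.n_reads == sim.library_a.n_mirna_reads + sim.library_a.n_background


def test_error_free_reads_are_planted_or_background(tmp_path):
    genome, truth = build_genome_with_hairpins(3, 10_000, seed=8)
    refsets = build_reference_sets(seed=9)
    spec = LibrarySimSpec(depth=2000, error_rate=0.0, seed=10)
    simulate_libraries(truth, spec, spec, refsets, tmp_path / "a.fastq", tmp_path / "b.fastq")
    matures = {m.mature_seq for m in truth}
    ref_pool = {s for n in ("rRNA", "tRNA", "snRNA", "snoRNA")
                for s in refsets[n].sequences.values()}
    adaptor = spec.adaptor3
    with open(tmp_path / "a.fastq") as fh:
        for i, line in enumerate(fh):
            if i % 4 == 1:
                read = line.strip()
                assert read.endswith(adaptor)
                insert = read[: -len(adaptor)]
                assert (insert in matures) or (insert in ref_pool) or (18 <= len(insert) <= 30)


def test_degenerate_composition_single_mirna(tmp_path):
    """One miRNA at TPM 1e6 and no background: ~every read is that miRNA."""
    genome, truth = build_genome_with_hairpins(1, 5_000, seed=12)
    m = truth[0]
    boosted = [
        type(m)(
            **{**m.__dict__, "tpm_condition_a": 1e6, "tpm_condition_b": 1e6}
        )
    ]
    spec = LibrarySimSpec(depth=1000, error_rate=0.0, seed=13)
    sim = simulate_libraries(boosted, spec, spec, build_reference_sets(0),
                             tmp_path / "a.fastq", tmp_path / "b.fastq")
    count = int(sim.expected.count_a.iloc[0])
    assert count == pytest.approx(1000, abs=120)  # Poisson(1000) spread
    assert sim.library_a.n_background == max(0, 1000 - count)
    assert sim.library_a.n_reads == count + sim.library_a.n_background


def test_planted_fold_change_recovered_within_poisson_error(tmp_path):
    """A planted TPM ratio of 4 gives an empirical log2 ratio ~ 2 within a
    binomial/Poisson confidence interval at the simulated depth."""
    genome, truth = build_genome_with_hairpins(1, 5_000, seed=14)
    m = truth[0]
    planted = [
        type(m)(**{**m.__dict__, "tpm_condition_a": 5e3, "tpm_condition_b": 2e4})
    ]
    spec_a = LibrarySimSpec(depth=100_000, error_rate=0.0, seed=15)
    spec_b = LibrarySimSpec(depth=100_000, error_rate=0.0, seed=16)
    sim = simulate_libraries(planted, spec_a, spec_b, build_reference_sets(1),
                             tmp_path / "a.fastq", tmp_path / "b.fastq")
    ca, cb = int(sim.expected.count_a.iloc[0]), int(sim.expected.count_b.iloc[0])
    # expected counts 500 and 2000; +/- 4 sigma Poisson band on the ratio
    se = np.sqrt(1 / ca + 1 / cb)
    assert np.log2(cb / ca) == pytest.approx(2.0, abs=4 * se / np.log(2))


def test_background_length_mode_is_21(small_study):
    from nitromir import tags

    clean_a, _ = tags.trim_and_filter(small_study["reads_a"], small_study["adaptor3"])
    hist = tags.length_histogram(tags.collapse_tags(clean_a), "unique")
    assert hist.idxmax() == 21
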