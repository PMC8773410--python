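"""Synthetic small-RNA study generator with planted ground truth.

Emulates the statistical shape of a two-condition (nitrogen-replete vs
nitrogen-deprived) small-RNA sequencing experiment:

* a random genome carrying planted miRNA hairpins (precursors 62-96 nt,
  matures 20-23 nt, a minority at 2-9 genomic loci);
* two read libraries at configurable depths in which each planted miRNA
  receives a Poisson count with mean ``tpm * depth / 1e6`` and the
  remainder of the library is background: degradation fragments of the
  generated structural-ncRNA references plus uniform random 18-30-mers,
  with lengths peaked at 21 nt as in real Dicer-product libraries;
* every read is the insert plus a 3' adaptor, with sequencing errors as
  independent per-base substitutions;
* a transcript set carrying planted miRNA target sites that either satisfy
  all six complementarity rules or violate exactly one of them, plus a
  gene->KOG mapping table.

Planted log2 fold changes between the conditions are drawn from
{0, +/-1, +/-2, +/-3}; the lower of the two TPMs is log-uniform in about
[80, 1600] so that planted differential miRNAs are comfortably above the
1-TPM reporting floor.  All randomness flows from explicit seeds: the same
seed gives byte-identical output files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .annotation import ReferenceSet
from .folding import fold
from .hairpin import DEFAULT_MFE_CEILING
from .kog import KOG_CATEGORIES
from .seq_utils import random_seq, revcomp, write_fasta, write_fastq
from .targets import GU, MISMATCH, evaluate_site, score_window

#: default 3' adaptor (standard small-RNA 3' adaptor prefix, 20 nt)
DEFAULT_ADAPTOR3 = "TCGTATGCCGTCTTCTGCTT"

#: background insert length distribution, peaked at 21 nt
LENGTH_WEIGHTS = {
    18: 2.0, 19: 3.0, 20: 8.0, 21: 20.0, 22: 10.0, 23: 6.0, 24: 3.0,
    25: 2.0, 26: 1.5, 27: 1.2, 28: 1.0, 29: 0.8, 30: 0.7,
}

VIOLATIONS = ("none", "rule1", "rule2", "rule3", "rule4", "rule5", "rule6")


class CapacityError(ValueError):
    """Genome too small to hold the requested hairpins without overlap."""


class TargetConstructionError(ValueError):
    """A requested rule violation cannot be built for a given miRNA."""

    def __init__(self, mirna_id: str, violation: str):
        super().__init__(
            f"could not construct a {violation} site for miRNA {mirna_id}"
        )
        self.mirna_id = mirna_id
        self.violation = violation


@dataclass(frozen=True)
class PlantedMiRNA:
    id: str
    mature_seq: str
    star_seq: str
    precursor_seq: str
    genome_locus: Tuple[str, int, int, str]  # primary locus
    loci: Tuple[Tuple[str, int, int, str], ...]
    n_loci: int
    mature_offset: int  # offset of mature within precursor
    tpm_condition_a: float
    tpm_condition_b: float

    @property
    def log2fc(self) -> float:
        return math.log2(self.tpm_condition_b / self.tpm_condition_a)


@dataclass(frozen=True)
class LibrarySimSpec:
    depth: int
    adaptor3: str = DEFAULT_ADAPTOR3
    error_rate: float = 0.0
    seed: int = 0
    background_fraction: float = 0.5  # ncRNA share of the background

    def __post_init__(self):
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if not (0.0 <= self.error_rate < 1.0):
            raise ValueError("error_rate must be in [0, 1)")
        if not (0.0 <= self.background_fraction <= 1.0):
            raise ValueError("background_fraction must be in [0, 1]")


@dataclass(frozen=True)
class PlantedTargetSite:
    transcript_id: str
    site_start: int
    mirna_id: str
    violation: str
    expected_pass: bool

    def __post_init__(self):
        assert self.violation in VIOLATIONS
        assert self.expected_pass == (self.violation == "none")


# ---------------------------------------------------------------------------
# hairpin construction
# ---------------------------------------------------------------------------

def _mutate(rng: np.random.Generator, seq: str, n: int) -> str:
    s = list(seq)
    if n <= 0:
        return seq
    pos = rng.choice(len(s), size=min(n, len(s)), replace=False)
    for p in pos:
        alts = [c for c in "ACGT" if c != s[p]]
        s[p] = alts[int(rng.integers(len(alts)))]
    return "".join(s)


def _certify_hairpin(precursor: str, mature_offset: int, mature_len: int,
                     mfe_ceiling: float = DEFAULT_MFE_CEILING) -> bool:
    """Does the precursor behave like a miRNA hairpin under the package's
    own discovery criteria?"""
    st = fold(precursor)
    if st.mfe > mfe_ceiling:
        return False
    db = st.dotbracket[mature_offset : mature_offset + mature_len]
    if "(" in db and ")" in db:
        return False
    pair_map = {}
    for i, j in st.pairs:
        pair_map[i] = j
        pair_map[j] = i
    partners = [pair_map[p] for p in range(mature_offset, mature_offset + mature_len)
                if p in pair_map]
    if len(partners) < mature_len // 2:
        return False
    p0 = min(partners)
    if p0 + mature_len > len(precursor):
        p0 = len(precursor) - mature_len
    if not (p0 + mature_len <= mature_offset or p0 >= mature_offset + mature_len):
        return False
    star = precursor[p0 : p0 + mature_len]
    mature = precursor[mature_offset : mature_offset + mature_len]
    return score_window(mature, star).mismatch_score <= 4.0


def _make_hairpin(rng: np.random.Generator) -> Tuple[str, str, str, int]:
    """Return (precursor, mature, star, mature_offset), certified."""
    for _ in range(80):
        m_len = int(rng.integers(20, 24))
        mature = random_seq(rng, m_len)
        star = _mutate(rng, revcomp(mature), int(rng.integers(0, 3)))
        ext_len = int(rng.integers(7, 13))
        loop_len = int(rng.integers(8, 16))
        ext5 = random_seq(rng, ext_len)
        ext3 = _mutate(rng, revcomp(ext5), int(rng.integers(0, 3)))
        loop = random_seq(rng, loop_len)
        if rng.random() < 0.5:  # mature on the 5' arm
            precursor = ext5 + mature + loop + star + ext3
            offset = ext_len
        else:
            precursor = ext5 + star + loop + mature + ext3
            offset = ext_len + m_len + loop_len
        if not 62 <= len(precursor) <= 96:
            continue
        if _certify_hairpin(precursor, offset, m_len):
            mature_out = precursor[offset : offset + m_len]
            assert mature_out == mature
            return precursor, mature, star, offset
    raise RuntimeError("could not construct a certified hairpin (seed pathology)")


def _draw_tpms(rng: np.random.Generator) -> Tuple[float, float]:
    base = float(10 ** rng.uniform(1.9, 3.2))
    lfc = float(rng.choice([0, 1, -1, 2, -2, 3, -3],
                           p=[0.4, 0.1, 0.1, 0.1, 0.1, 0.1, 0.1]))
    if lfc >= 0:
        return base, base * 2 ** lfc
    return base * 2 ** (-lfc), base


def _draw_n_loci(rng: np.random.Generator) -> int:
    r = rng.random()
    if r < 0.70:
        return 1
    if r < 0.85:
        return 2
    if r < 0.93:
        return 3
    if r < 0.97:
        return 4
    if r < 0.99:
        return 5
    return 9


def build_genome_with_hairpins(
    n_hairpins: int,
    genome_length: int = 50_000,
    seed: int = 0,
    contig_name: str = "chr1",
    min_gap: int = 170,
) -> Tuple[Dict[str, str], List[PlantedMiRNA]]:
    """Random genome with ``n_hairpins`` planted, certified miRNA hairpins.

    Each precursor occurs verbatim at every recorded locus (reverse
    complemented on '-' loci); a minority of miRNAs is planted at 2-9 loci.
    Raises CapacityError when the precursors cannot be placed without
    overlap.
    """
    rng = np.random.default_rng(seed)
    backbone = list(random_seq(rng, genome_length))
    truth: List[PlantedMiRNA] = []
    if n_hairpins == 0:
        return {contig_name: "".join(backbone)}, truth

    plans = []
    total_needed = 0
    for i in range(n_hairpins):
        precursor, mature, star, offset = _make_hairpin(rng)
        n_loci = _draw_n_loci(rng)
        tpm_a, tpm_b = _draw_tpms(rng)
        plans.append((precursor, mature, star, offset, n_loci, tpm_a, tpm_b))
        total_needed += n_loci * (len(precursor) + min_gap)
    if total_needed + min_gap > genome_length:
        raise CapacityError(
            f"genome of {genome_length} nt cannot hold {n_hairpins} hairpins "
            f"({total_needed + min_gap} nt needed including spacing)"
        )

    occupied: List[Tuple[int, int]] = []

    def place(length: int) -> int:
        for _ in range(2000):
            start = int(rng.integers(0, genome_length - length))
            lo, hi = start - min_gap, start + length + min_gap
            if all(e <= lo or s >= hi for s, e in occupied):
                occupied.append((start, start + length))
                return start
        raise CapacityError("could not place a precursor without overlap")

    for i, (precursor, mature, star, offset, n_loci, tpm_a, tpm_b) in enumerate(plans):
        loci = []
        for _ in range(n_loci):
            start = place(len(precursor))
            strand = "+" if rng.random() < 0.5 else "-"
            inserted = precursor if strand == "+" else revcomp(precursor)
            backbone[start : start + len(precursor)] = list(inserted)
            loci.append((contig_name, start, start + len(precursor), strand))
        truth.append(
            PlantedMiRNA(
                id=f"mir-planted-{i + 1}",
                mature_seq=mature,
                star_seq=star,
                precursor_seq=precursor,
                genome_locus=loci[0],
                loci=tuple(loci),
                n_loci=n_loci,
                mature_offset=offset,
                tpm_condition_a=tpm_a,
                tpm_condition_b=tpm_b,
            )
        )
    return {contig_name: "".join(backbone)}, truth


# ---------------------------------------------------------------------------
# reference sets
# ---------------------------------------------------------------------------

def _draw_lengths(rng: np.random.Generator, n: int) -> np.ndarray:
    lengths = np.array(sorted(LENGTH_WEIGHTS))
    w = np.array([LENGTH_WEIGHTS[L] for L in lengths], dtype=float)
    return rng.choice(lengths, size=n, p=w / w.sum())


def build_reference_sets(
    seed: int = 0,
    n_fragments: int = 40,
    n_known_decoys: int = 20,
    known_matures: Optional[Mapping[str, str]] = None,
) -> Dict[str, ReferenceSet]:
    """Structural-ncRNA fragment references plus a known-miRNA reference.

    The ncRNA sets are degradation-fragment collections (18-30 nt entries)
    that background reads are sampled from; the known-miRNA set holds
    decoy matures plus any supplied ``known_matures``.
    """
    rng = np.random.default_rng(seed)
    refsets: Dict[str, ReferenceSet] = {}
    for name in ("rRNA", "tRNA", "snRNA", "snoRNA"):
        lengths = _draw_lengths(rng, n_fragments)
        seqs = {f"{name}_frag{i + 1}": random_seq(rng, int(L))
                for i, L in enumerate(lengths)}
        refsets[name] = ReferenceSet(name, seqs)
    known = {f"known-mir-decoy-{i + 1}": random_seq(rng, int(rng.integers(20, 24)))
             for i in range(n_known_decoys)}
    if known_matures:
        known.update({k: v.upper().replace("U", "T") for k, v in known_matures.items()})
    refsets["known_miRNA"] = ReferenceSet("known_miRNA", known)
    return refsets


# ---------------------------------------------------------------------------
# library simulation
# ---------------------------------------------------------------------------

@dataclass
class SimulatedLibrary:
    path: str
    n_reads: int
    n_mirna_reads: int
    n_background: int


@dataclass
class SimResult:
    library_a: SimulatedLibrary
    library_b: SimulatedLibrary
    expected: pd.DataFrame  # mirna_id, count_a, count_b


def _simulate_one(
    truth: Sequence[PlantedMiRNA],
    spec: LibrarySimSpec,
    refsets: Mapping[str, ReferenceSet],
    path,
    which: str,
) -> Tuple[SimulatedLibrary, np.ndarray]:
    rng = np.random.default_rng(spec.seed)
    tpms = np.array(
        [m.tpm_condition_a if which == "a" else m.tpm_condition_b for m in truth]
    )
    counts = rng.poisson(tpms * spec.depth / 1e6) if len(truth) else np.array([], dtype=int)
    n_mirna = int(counts.sum())
    # background fills the library up to the nominal depth; if Poisson
    # noise oversubscribes it (only possible when planted TPMs sum to
    # ~1e6), the library is slightly deeper than nominal
    n_bg = max(0, spec.depth - n_mirna)
    n_ref = int(round(spec.background_fraction * n_bg))
    n_rand = n_bg - n_ref

    inserts: List[str] = []
    for m, c in zip(truth, counts):
        inserts.extend([m.mature_seq] * int(c))
    pool = [s for name in ("rRNA", "tRNA", "snRNA", "snoRNA")
            for s in refsets[name].sequences.values()] if refsets else []
    if n_ref and not pool:
        raise ValueError("background requested but no ncRNA reference supplied")
    if n_ref:
        idx = rng.integers(0, len(pool), size=n_ref)
        inserts.extend(pool[i] for i in idx)
    if n_rand:
        lengths = _draw_lengths(rng, n_rand)
        letters = rng.integers(0, 4, size=int(lengths.sum()))
        alph = np.frombuffer(b"ACGT", dtype=np.uint8)
        flat = alph[letters].tobytes().decode()
        offs = np.concatenate([[0], np.cumsum(lengths)])
        inserts.extend(flat[offs[i]: offs[i + 1]] for i in range(n_rand))

    reads = [ins + spec.adaptor3 for ins in inserts]
    if spec.error_rate > 0 and reads:
        lens = np.fromiter((len(r) for r in reads), dtype=np.int64)
        total = int(lens.sum())
        n_err = rng.binomial(total, spec.error_rate)
        if n_err:
            flat_pos = np.sort(rng.integers(0, total, size=n_err))
            cum = np.cumsum(lens)
            read_idx = np.searchsorted(cum, flat_pos, side="right")
            for fp, ri in zip(flat_pos, read_idx):
                off = int(fp - (cum[ri] - lens[ri]))
                r = reads[ri]
                alts = [c for c in "ACGT" if c != r[off]]
                reads[ri] = r[:off] + alts[int(rng.integers(3))] + r[off + 1:]

    order = rng.permutation(len(reads))
    records = (
        (f"lib{which}_read{i + 1}", reads[j], "I" * len(reads[j]))
        for i, j in enumerate(order)
    )
    write_fastq(path, records)
    lib = SimulatedLibrary(str(path), len(reads), n_mirna, n_bg)
    return lib, counts


def simulate_libraries(
    truth: Sequence[PlantedMiRNA],
    spec_a: LibrarySimSpec,
    spec_b: LibrarySimSpec,
    refsets: Mapping[str, ReferenceSet],
    path_a,
    path_b,
) -> SimResult:
    """Write two FASTQ libraries and return the expected count table.

    Planted counts are Poisson with mean ``tpm * depth / 1e6``; background
    (ncRNA fragments + random inserts) fills the library up to ``depth``,
    so each library emits exactly ``depth`` reads = expected counts +
    background.
    """
    if not truth and spec_a.background_fraction < 1 and spec_a.depth > 0:
        # all-background libraries are fine; planted table is empty
        pass
    lib_a, counts_a = _simulate_one(truth, spec_a, refsets, path_a, "a")
    lib_b, counts_b = _simulate_one(truth, spec_b, refsets, path_b, "b")
    expected = pd.DataFrame(
        dict(
            mirna_id=[m.id for m in truth],
            mature=[m.mature_seq for m in truth],
            count_a=counts_a.astype(int),
            count_b=counts_b.astype(int),
        )
    )
    return SimResult(lib_a, lib_b, expected)


# ---------------------------------------------------------------------------
# target truth set
# ---------------------------------------------------------------------------

_EXPECTED_VERDICTS = {
    "none": (True,) * 6,
    "rule1": (False, True, True, True, True, True),
    "rule2": (True, False, True, True, True, True),
    "rule3": (True, True, False, True, True, True),
    "rule4": (True, True, True, False, True, True),
    "rule5": (True, True, True, True, False, True),
    "rule6": (True, True, True, True, True, False),
}


def _apply_changes(mature: str, changes, rng: np.random.Generator) -> Optional[str]:
    """Build a target window from revcomp(mature) plus (position, kind)
    edits; kind 'gu' makes a wobble (only at G/U miRNA positions), 'mm' a
    true mismatch."""
    L = len(mature)
    window = list(revcomp(mature))
    for p, kind in changes:
        mb = mature[p - 1]
        idx = L - p
        if kind == "gu":
            if mb == "G":
                window[idx] = "T"
            elif mb == "T":
                window[idx] = "G"
            else:
                return None
        else:
            comp = {"A": "T", "C": "G", "G": "C", "T": "A"}[mb]
            wob = {"G": "T", "T": "G"}.get(mb)
            alts = [c for c in "ACGT" if c != comp and c != wob]
            window[idx] = alts[int(rng.integers(len(alts)))]
    return "".join(window)


def _propose_changes(mature: str, violation: str, rng: np.random.Generator):
    """One random candidate edit set aiming at the requested violation."""
    L = len(mature)
    gu_all = [p for p in range(1, L + 1) if mature[p - 1] in "GT"]
    gu12 = [p for p in gu_all if p <= 12]
    gu3p = [p for p in gu_all if p >= 13]

    def sample(pool, k):
        k = min(k, len(pool))
        return [int(x) for x in rng.choice(pool, size=k, replace=False)] if k else []

    def nonadjacent_mm(pool, k):
        """Sample up to k mutually non-adjacent mismatch positions."""
        picked: List[int] = []
        for p in [int(x) for x in rng.permutation(pool)]:
            if len(picked) >= k:
                break
            if all(abs(p - q) > 1 for q in picked):
                picked.append(p)
        return picked

    if violation == "none":
        return []
    if violation == "rule1":
        # score > 4 while positions 1-12 stay <= 2.5 and adjacency rules
        # hold.  Terminal mismatches (positions 1 and L) and wobbles at U
        # positions are preferred: they cost little duplex energy, which
        # rule 6 must survive.
        mm = []
        if rng.random() < 0.5:
            mm.append(1)
        if rng.random() < 0.7:
            mm.append(L)
        n_mm3 = int(rng.integers(0, 3)) if L >= 15 else 0
        mm += nonadjacent_mm([p for p in range(13, L - 1) if p - 1 not in mm], n_mm3)
        score = float(len(mm))
        seed_budget = 2.5 - (1.0 if 1 in mm else 0.0)
        u_first = lambda pool: sorted(pool, key=lambda p: (mature[p - 1] != "T", rng.random()))
        w12 = [p for p in u_first(gu12) if p not in mm][: int(seed_budget / 0.5)]
        w3 = [p for p in u_first(gu3p) if p not in mm]
        k12 = int(rng.integers(0, len(w12) + 1))
        changes = [(p, "mm") for p in mm] + [(p, "gu") for p in w12[:k12]]
        score += 0.5 * k12
        target = 4.5 + 0.5 * int(rng.integers(0, 2))
        for p in w3:
            if score >= target:
                break
            changes.append((p, "gu"))
            score += 0.5
        if score <= 4.0:
            return None
        return changes
    if violation == "rule2":
        if L < 16:
            return None
        p = int(rng.integers(13, L - 2))
        return [(p, "mm"), (p + 1, "mm"), (p + 2, "mm")]
    if violation == "rule3":
        p = int(rng.integers(2, 9))
        return [(p, "mm"), (p + 1, "mm")]
    if violation == "rule4":
        return [(int(rng.choice([10, 11])), "mm")]
    if violation == "rule5":
        # drive the 1-12 score above 2.5 with total <= 4: mix isolated
        # mismatches (never at 10-11) and wobbles
        n_mm = int(rng.integers(0, 4))
        mm_pool = [p for p in range(1, 13) if p not in (10, 11)]
        mm = nonadjacent_mm(mm_pool, n_mm)
        gu_pool = [p for p in gu12 if p not in mm]
        need = max(0, int(math.ceil((2.75 - len(mm)) / 0.5)))
        k_gu = need + int(rng.integers(0, 2))
        if k_gu > len(gu_pool):
            return None
        score = len(mm) + 0.5 * k_gu
        if not (2.5 < score <= 4.0):
            return None
        return [(p, "mm") for p in mm] + [(p, "gu") for p in sample(gu_pool, k_gu)]
    if violation == "rule6":
        # drain duplex stability: wobbles at G positions (strong stacks
        # lost) plus isolated 3' mismatches, staying within rules 1-5
        g12 = [p for p in gu12 if mature[p - 1] == "G" and p not in (10, 11)]
        g3p = list(gu3p)
        n_mm = int(rng.integers(0, 3))
        mm_pool = [p for p in range(13, L + 1)]
        mm = []
        for p in sample(mm_pool, n_mm):
            if all(abs(p - q) > 1 for q in mm):
                mm.append(p)
        budget = 4.0 - len(mm)
        k12 = min(len(g12), 5, int(budget / 0.5))
        k3 = min(len(g3p), int((budget - 0.5 * k12) / 0.5))
        changes = [(p, "mm") for p in mm]
        changes += [(p, "gu") for p in sample(g12, k12) + sample(g3p, k3)]
        return changes
    raise ValueError(f"unknown violation {violation!r}")


def make_site(mature: str, violation: str, rng: np.random.Generator,
              max_tries: int = 1500) -> str:
    """A target window for which exactly the tagged rule fails (or none).

    The candidate is certified with the package's own rule engine; raises
    TargetConstructionError when no proposal satisfies the pattern.
    """
    mature = mature.upper().replace("U", "T")
    expected = _EXPECTED_VERDICTS[violation]
    for _ in range(max_tries):
        changes = _propose_changes(mature, violation, rng)
        if changes is None:
            continue
        window = _apply_changes(mature, changes, rng)
        if window is None:
            continue
        hit = evaluate_site(mature, window, 0)
        if tuple(hit.rule_verdicts) == expected:
            return window
    raise TargetConstructionError(mature, violation)


_KOG_LETTER_WEIGHTS = {
    "T": 12.6, "R": 10.2, "K": 7.5, "I": 7.1, "O": 6.5, "S": 6.3, "E": 5.5,
    "G": 4.5, "C": 4.5, "J": 4.0, "U": 4.0, "P": 3.5, "A": 3.0, "L": 2.5,
    "Q": 2.5, "D": 2.3, "F": 2.0, "H": 2.0, "Z": 2.0, "M": 1.5, "B": 1.5,
    "V": 1.2, "N": 1.0, "Y": 0.8, "W": 0.5,
}


def build_target_truth_set(
    mirnas: Sequence[PlantedMiRNA],
    n_sites_per_rule: int = 1,
    seed: int = 0,
    transcript_length: Tuple[int, int] = (300, 500),
    on_unsatisfiable: str = "raise",
) -> Tuple[Dict[str, str], List[PlantedTargetSite], pd.DataFrame]:
    """Transcripts with planted target sites plus a gene->KOG table.

    For every miRNA and every rule r, emits ``n_sites_per_rule`` sites that
    violate exactly r, and as many fully clean sites.  Each transcript
    carries one site and one KOG assignment.  A handful of sequences
    cannot host certain single-rule violations (e.g. too few G/U positions
    to exceed 4 half-mismatches while keeping the duplex stable);
    ``on_unsatisfiable`` selects whether that raises
    TargetConstructionError (default) or skips the pair.
    """
    if n_sites_per_rule < 1:
        raise ValueError("n_sites_per_rule must be >= 1")
    if on_unsatisfiable not in ("raise", "skip"):
        raise ValueError("on_unsatisfiable must be 'raise' or 'skip'")
    rng = np.random.default_rng(seed)
    letters = sorted(_KOG_LETTER_WEIGHTS)
    w = np.array([_KOG_LETTER_WEIGHTS[l] for l in letters])
    w = w / w.sum()
    assert set(letters) == set(KOG_CATEGORIES)

    transcripts: Dict[str, str] = {}
    sites: List[PlantedTargetSite] = []
    kog_rows = []
    for m in mirnas:
        for violation in VIOLATIONS:
            for rep in range(n_sites_per_rule):
                try:
                    window = make_site(m.mature_seq, violation, rng)
                except TargetConstructionError:
                    if on_unsatisfiable == "skip":
                        continue
                    raise TargetConstructionError(m.id, violation) from None
                t_len = int(rng.integers(*transcript_length))
                offset = int(rng.integers(0, t_len - len(window) + 1))
                backbone = random_seq(rng, t_len)
                seq = backbone[:offset] + window + backbone[offset + len(window):]
                tid = f"gene_{m.id}_{violation}_{rep + 1}"
                transcripts[tid] = seq
                sites.append(
                    PlantedTargetSite(tid, offset, m.id, violation, violation == "none")
                )
                letter = str(rng.choice(letters, p=w))
                kog_rows.append(
                    dict(gene_id=tid, kog_id=f"KOG{int(rng.integers(1000, 9999))}",
                         category_letter=letter)
                )
    kog_map = pd.DataFrame(kog_rows)
    return transcripts, sites, kog_map


# ---------------------------------------------------------------------------
# one-call study writer
# ---------------------------------------------------------------------------

def write_simulation(
    outdir,
    n_hairpins: int = 30,
    genome_length: int = 50_000,
    depth_a: int = 200_000,
    depth_b: int = 200_000,
    error_rate: float = 0.005,
    background_fraction: float = 0.5,
    adaptor3: str = DEFAULT_ADAPTOR3,
    n_sites_per_rule: int = 1,
    seed: int = 0,
) -> Dict[str, object]:
    """Generate a complete synthetic study into ``outdir``.

    Writes genome, reference sets, two FASTQ libraries, transcripts,
    KOG map and the truth tables; returns paths plus the in-memory truth.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome, truth = build_genome_with_hairpins(n_hairpins, genome_length, seed=seed)
    refsets = build_reference_sets(seed=seed + 1)
    spec_a = LibrarySimSpec(depth_a, adaptor3, error_rate, seed + 2, background_fraction)
    spec_b = LibrarySimSpec(depth_b, adaptor3, error_rate, seed + 3, background_fraction)
    sim = simulate_libraries(truth, spec_a, spec_b, refsets,
                             outdir / "reads_a.fastq", outdir / "reads_b.fastq")
    transcripts, planted_sites, kog_map = build_target_truth_set(
        truth, n_sites_per_rule=n_sites_per_rule, seed=seed + 4,
        on_unsatisfiable="skip",
    )

    write_fasta(outdir / "genome.fa", genome)
    for name, rs in refsets.items():
        write_fasta(outdir / f"ref_{name}.fa", rs.sequences)
    write_fasta(outdir / "transcripts.fa", transcripts)
    kog_map.to_csv(outdir / "kog_map.tsv", sep="\t", index=False)
    sim.expected.to_csv(outdir / "expected_counts.tsv", sep="\t", index=False)
    pd.DataFrame(
        dict(
            mirna_id=[m.id for m in truth],
            mature=[m.mature_seq for m in truth],
            star=[m.star_seq for m in truth],
            precursor=[m.precursor_seq for m in truth],
            contig=[m.genome_locus[0] for m in truth],
            start=[m.genome_locus[1] for m in truth],
            end=[m.genome_locus[2] for m in truth],
            strand=[m.genome_locus[3] for m in truth],
            n_loci=[m.n_loci for m in truth],
            tpm_a=[m.tpm_condition_a for m in truth],
            tpm_b=[m.tpm_condition_b for m in truth],
        )
    ).to_csv(outdir / "truth_mirnas.tsv", sep="\t", index=False)
    pd.DataFrame([s.__dict__ for s in planted_sites]).to_csv(
        outdir / "truth_sites.tsv", sep="\t", index=False
    )
    return dict(
        outdir=str(outdir),
        genome=genome,
        truth=truth,
        refsets=refsets,
        sim=sim,
        transcripts=transcripts,
        planted_sites=planted_sites,
        kog_map=kog_map,
        reads_a=str(outdir / "reads_a.fastq"),
        reads_b=str(outdir / "reads_b.fastq"),
        adaptor3=adaptor3,
    )
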