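# Methods

`nitromir` re-implements, as a tested library, the computational analysis
applied to two pooled small-RNA libraries from *Chlamydomonas reinhardtii*
grown in nitrogen-replete (TAP) and nitrogen-deprived (TAP-N) medium: tag
processing, known/novel miRNA identification, exact Poisson differential
expression, rule-based target prediction, and KOG functional
summarisation. This note records the models, the defaults and why they
were chosen, and what the synthetic validation does and does not show.

## Tag processing

Reads are trimmed by locating the 3' adaptor — an exact match of its
first 8 bases anywhere in the read, falling back to adaptor prefixes of
7 down to 6 bases at the read end (the adaptor running off the read).
No mismatches are tolerated in the adaptor seed; this is a deliberate
choice favouring determinism over maximal yield, and it means a per-base
error rate e loses roughly `8e` of reads to the `no_adaptor` class.
Inserts are kept when they are 18–30 nt (the gel-isolation window of the
protocol being modelled), contain no N, and the insert's mean Phred
quality is ≥ 20. "Low quality" has no published definition in this
analysis family, so mean-Phred < 20 or any N is the documented default,
not an inference of intent. Discards are tallied under exactly one class
and `raw = clean + Σ discards` is asserted on every run.

Unique 18–30 nt sequences with per-library counts are the *clean tags*.
Library accounting (`specific = unique − common`) and length histograms
over 10–32 nt (by distinct sequence or by read abundance) follow directly.

## Annotation

Tags are classified against an ordered list of reference sets by exact,
full-length, strand-as-given identity; the first set containing the tag
wins. Default precedence is rRNA > tRNA > snRNA > snoRNA > known_miRNA,
mirroring the usual cascade of structural-ncRNA databases before the
mature-miRNA reference. Known-miRNA counting is exact-match only — no
isomiR aggregation — because only perfectly matched tags are treated as
known miRNAs in the analysis being reproduced; whether the original
summed isomiRs is unknowable from the text, so the strict reading is the
documented choice.

## Secondary-structure model

Folding uses an interval dynamic program over nested pair sets with a
compact energy model:

* the 16 Watson–Crick stack types carry literature-scale nearest-neighbour
  free energies (−0.93 to −3.42 kcal/mol at 37 °C);
* a G:U wobble participates in stacks by mapping onto the A:U/U:A stack
  with the purine on the same side, plus +0.2 kcal/mol per wobble pair in
  the stack;
* every hairpin-closing pair pays a flat +3.0 kcal/mol loop-initiation
  penalty; other loops cost only their lost stacking;
* minimum hairpin loop of 3 unpaired bases; no pseudoknots.

This is intentionally not the full Turner model: the published analysis
used external folding servers, and what matters downstream is a
deterministic, internally consistent energy scale shared by precursor
folding, duplex energies and the MFE-ratio target rule. The recursion is
exact for this model; the test suite proves it by exhaustive enumeration
of all nested structures for sequences up to 18 nt. Ties are broken
deterministically (hairpin before stack before bifurcation, leftmost
split first), so identical inputs give byte-identical dot-bracket
strings. Because the model rewards only stacking, its MFE values are
systematically shallower than Turner-rule folders for loop-rich
structures; planted 62–96 nt precursors come out around −25 to −60
kcal/mol, the right scale for plant miRNA hairpins.

## Novel miRNA discovery

Unannotated tags with at least `min_tag_count = 5` total reads (singleton
background cannot support a miRNA call) and mature-length 20–23 nt are
mapped to the genome on both strands with at most one substitution, via
an exact half-index: any ≤1-mismatch alignment matches exactly on one of
the tag's two halves. The "perfect match or one mismatch" retention rule
is applied to genome mapping (its original scope is ambiguous between
genome mapping and miRNA homology; genome mapping is the reading that
makes discovery well-defined).

Around each locus, candidate precursor windows sweep lengths 62–96 nt
with the tag at varying offsets on either arm (2-nt steps; flank 150 nt,
clipped at contig edges). Each window is pre-screened for a star arm — an
approximate reverse complement of the tag elsewhere in the window, found
with a vectorised duplex scan — and only the most star-plausible windows
(up to 16 per tag) are folded. An accepted candidate must have: fold MFE
≤ −18 kcal/mol (the ceiling leaves margin below the weakest published
precursor, ~−22 kcal/mol, and is configurable); the mature tag fully on
one arm, predominantly paired, never across the terminal loop; and a
mature/star duplex with mismatch score ≤ 4 under the same G:U = 0.5
scorer as target prediction. Rejections carry the most advanced failure
stage (`no_hairpin`, `mature_in_loop`, `too_many_mismatches`,
`energy_too_high`, `length_out_of_range`). Candidates from
1-substitution read variants of the same hairpin are deduplicated by
precursor-locus overlap, keeping the most abundant mature; multi-locus
miRNAs are reported once with their locus count, counts not multiplied.

## Differential expression

Normalised expression is TPM: `count / total_clean_reads × 1e6`. A zero
TPM is replaced by 0.01 *for the fold change only*; the test always runs
on raw integer counts (the substitution belongs to the normalisation
step, and the exact test needs integers). Features below 1 TPM in both
libraries are removed before testing. The fold change is
`log2(TPM_b / TPM_a)` (computed as a log difference, which is exactly
antisymmetric under library swap); features observed in only one library
are flagged `a_specific`/`b_specific` rather than given a star label.

Significance uses the exact Poisson two-library conditional

    p(y|x) = (N2/N1)^y (x+y)! / (x! y! (1 + N2/N1)^(x+y+1))

with lower tail C = Σ_{y'≤y} p(y'|x) and upper tail
D = 1 − C + p(y|x), all in log space via log-gamma (overflow-free by
construction). The two-sided combination is p = min(1, 2·min(C, D)),
capped at 1 and configurable to min(C, D); the doubled-tail convention
reproduces the published per-row p-values closely where they can be
checked (one small-count row falls between the two conventions, which is
recorded in the tests rather than resolved). Labels: `**` for p < 0.01
and |log2FC| > 1, `*` for 0.01 ≤ p < 0.05 and |log2FC| > 1. No multiple-
testing correction by default (raw p-values are what the analysis family
reports); Benjamini–Hochberg is available behind a flag.

One property worth stating: the C/D construction is *not* exactly
symmetric under swapping libraries together with the count roles —
p(x'|y) with ratio N1/N2 equals p(y'|x)·N1/N2 pointwise, so the swapped
tails differ by up to a factor ~2 deep in the tails and negligibly at
moderate p. This is a property of the statistic, not of the
implementation; the tests assert the achievable form (matching decisions,
close p-values).

## Target prediction

Sites are ungapped antiparallel duplexes between a miRNA (positions
1..L from the 5' end) and an equal-length transcript window. Gaps are
excluded deliberately: all six rules are positional over miRNA
coordinates, and bulges would make "positions 10–11" ill-defined; this is
a documented restriction relative to the original alignment-based
scoring. Per-position states are match, G:U wobble (0.5 mismatches), or
mismatch. The rules: (1) total score ≤ 4; (2) no run of more than two
adjacent mismatches; (3) no adjacent mismatches within positions 2–12;
(4) no mismatch at positions 10–11; (5) score over positions 1–12 ≤ 2.5;
(6) duplex MFE ≥ 75% of the MFE of the miRNA bound to its perfect
complement, compared on magnitudes of the (negative) energies — the
magnitude reading is the only one that rejects weak duplexes. Wobbles
count toward scores (rules 1, 5) but are not "mismatches" for the
adjacency rules 2–4. Energies reuse the folding stack table; mismatches
interrupt stacks. Full transcripts are scanned (whether the original
restricted to UTRs is unstated); hits are deduplicated to a unique gene
list for functional counting.

## Functional annotation

KOG assignment is table-driven — a gene → (KOG id, category letter) TSV,
such as the precomputed table distributed with the *C. reinhardtii* v4
annotation — because the underlying database search is not reproducible
offline and the analysis step itself is tabulation. The 25 standard
letters map to the four main classes; a gene with several letters counts
once per letter, so percentages are over gene–category pairs (the
published denominators are unstated; pair counting is the documented
default). Concordance of a miRNA/target pair is `opposite` when the
signed fold changes disagree (consistent with cleavage) and `positive`
when they agree (consistent with translational repression).

## Synthetic data: what it emulates, and what it does not

The generator plants full ground truth so every stage has an oracle:

* **Hairpins**: mature 20–23 nt, star = mutated reverse complement (≤ 2
  substitutions), stem extensions of 7–12 nt with ≤ 2 mutations, loops of
  8–15 nt; total 62–96 nt. Every planted precursor is *certified* against
  the discovery criteria before planting (the truth is defined as
  hairpins that satisfy the field's precursor criteria), and occurs
  verbatim at every recorded locus. ~30% of miRNAs get 2–9 loci
  (mostly 2–5, rarely 9), matching the multi-locus minority observed in
  this genome.
* **Expression**: planted log2 fold changes from {0, ±1, ±2, ±3}
  (40% null, 10% each); the lower TPM is log-uniform in ~[80, 1600] so
  planted differential miRNAs sit well above the 1-TPM floor, with total
  miRNA abundance ~2% of the library as in real profiles. Counts are
  Poisson with mean `tpm × depth / 1e6` — no overdispersion, matching the
  test's own model, because the study pools replicates into one library
  per condition.
* **Background**: the rest of each library, half degradation fragments of
  generated structural-ncRNA references, half uniform random 18–30-mers,
  lengths peaked at 21 nt like real Dicer-product libraries. Background
  fills each library to the nominal depth, so emitted reads = planted
  counts + background exactly.
* **Reads**: insert + a fixed 20-nt 3' adaptor, independent per-base
  substitution errors (default 0.005), constant high quality strings,
  deterministic order given the seed.
* **Target truth**: for each miRNA, transcripts carrying a site that
  passes all six rules or violates exactly one, constructed by seeded
  search over wobble/mismatch placements and certified with the package's
  own rule engine (the rule engine itself is tested against hand-built
  oracles, so the circularity is broken one level down). A small fraction
  of sequences cannot host particular single-rule violations (e.g. too
  few G/U positions to exceed 4 half-mismatches while keeping 75% duplex
  stability); these raise a construction error, or are skipped and
  recorded when building the bundled study.

What passing on this data does **not** show: robustness to biological
replicate variance (not modelled; the analysis pools replicates),
instrument-specific error profiles, adaptor ligation biases, isomiR
spectra, or genome-scale mapping ambiguity — the synthetic genome is 50 kb
and repeat-free, so multi-mapping behaviour is exercised only through the
deliberately planted multi-locus hairpins.

## Problem sizes and runtime

The default validation study is 30 planted hairpins in a 50-kb genome
with 200,000 reads per library — large enough for every planted
|log2FC| ≥ 2 miRNA to be unambiguous under the Poisson test (the smaller
count of a differential pair is ≥ ~16 reads), small enough that the full
pipeline runs in well under a minute on one core. The null-calibration
experiment uses 10,000 equal-TPM features; exhaustive folding oracles run
to 18 nt, where enumeration is still thousands of structures per
sequence. End-to-end recovery at these sizes is typically 100% for both
hairpin rediscovery and differential calls, comfortably above the 90%
bar the test suite enforces.

## Known limitations

* The energy model's absolute kcal/mol values are approximate; only
  comparisons within the package (MFE ceilings, the 75% duplex ratio) are
  meaningful, and both thresholds are configurable.
* Ungapped target duplexes miss bulged sites that alignment-based tools
  would report.
* Exact-match annotation undercounts miRNAs expressed mainly as isomiRs.
* The discovery star-screen folds only the most plausible windows per
  tag; pathological precursors whose star arm scores worse than 4
  mismatches against the mature are rejected by design.
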