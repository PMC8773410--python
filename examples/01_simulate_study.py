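"""Generate a small synthetic two-condition small-RNA study.

Plants miRNA hairpins in a random genome, draws Poisson read counts from
the planted TPMs, and writes FASTQ libraries plus every truth table.
"""

from nitromir.synthetic import write_simulation

study = write_simulation(
    "example_study", n_hairpins=8, depth_a=20_000, depth_b=20_000,
    error_rate=0.005, seed=3,
)

truth = study["truth"]
print(f"planted {len(truth)} miRNA hairpins; library files in {study['outdir']}")
print(f"{'miRNA':<16} {'len(pre)':>8} {'n_loci':>6} {'TPM a':>9} {'TPM b':>9} {'log2FC':>7}")
for m in truth:
    print(f"{m.id:<16} {len(m.precursor_seq):>8} {m.n_loci:>6} "
          f"{m.tpm_condition_a:>9.1f} {m.tpm_condition_b:>9.1f} {m.log2fc:>7.2f}")
# log2FC is the planted expression change between the nitrogen-replete (a)
# and nitrogen-deprived (b) conditions; the pipeline should call the
# |log2FC| >= 2 rows significant.
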