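"""The whole pipeline on a synthetic study, checked against the truth.

Simulates a study, runs every stage (tags -> annotation -> hairpin
discovery -> Poisson DE -> targets -> KOG), and compares the calls with
what was planted.
"""

from nitromir.pipeline import RunConfig, run_all
from nitromir.synthetic import write_simulation

study = write_simulation(
    "example_study_full", n_hairpins=12, depth_a=40_000, depth_b=40_000,
    error_rate=0.005, seed=9,
)
base = study["outdir"]
cfg = RunConfig(
    reads_a=study["reads_a"], reads_b=study["reads_b"],
    genome=f"{base}/genome.fa",
    ref_rrna=f"{base}/ref_rRNA.fa", ref_trna=f"{base}/ref_tRNA.fa",
    ref_snrna=f"{base}/ref_snRNA.fa", ref_snorna=f"{base}/ref_snoRNA.fa",
    ref_known_mirna=f"{base}/ref_known_miRNA.fa",
    transcripts=f"{base}/transcripts.fa", kog_map=f"{base}/kog_map.tsv",
    outdir="example_pipeline_out", adaptor3=study["adaptor3"], verbose=False,
)
report = run_all(cfg)

truth = study["truth"]
found = set(report.novel_candidates.mature)
print(f"hairpins rediscovered: {sum(m.mature_seq in found for m in truth)}/{len(truth)}")
sig = report.de_table[report.de_table.label.isin(['*', '**'])]
print(f"significant miRNAs called: {len(sig)} "
      f"(planted with |log2FC| >= 2: {sum(abs(m.log2fc) >= 2 for m in truth)})")
print(f"target sites accepted: {len(report.target_hits)}")
if report.kog_by_class is not None:
    print("KOG main-class composition of predicted targets:")
    print(report.kog_by_class.to_string(index=False))
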