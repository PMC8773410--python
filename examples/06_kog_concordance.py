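"""miRNA/target concordance and KOG category tabulation."""

from nitromir import datasets
from nitromir.kog import concordance, ratio_to_log2_sign

pairs = datasets.lipid_target_pairs()
calls = []
for r in pairs.itertuples():
    c = concordance(
        ratio_to_log2_sign(float(r.mirna_fold_change)),
        ratio_to_log2_sign(float(r.target_fold_change)),
        r.mirna_id, r.gene_product,
    )
    calls.append(c)
    print(f"{c.mirna_id:<16} {c.mirna_direction:<5} vs {c.gene_id[:40]:<42} "
          f"{c.target_direction:<5} -> {c.call}")

n_opp = sum(c.call == "opposite" for c in calls)
print(f"\n{n_opp} of {len(calls)} pairs move in opposite directions "
      "(the signature of miRNA-guided mRNA cleavage); the rest are "
      "co-expressed (translational repression).")
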