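"""The exact Poisson (Audic-Claverie) test on two-library counts.

Reproduces the worked examples of the bundled novel-miRNA table: TPM
normalisation, zero substitution, log2 fold change, and significance
labels.
"""

from nitromir import datasets
from nitromir.de import audic_claverie, classify, fold_change, reconstruct_count

table = datasets.novel_mirna_expression()
t = datasets.LIBRARY_TOTALS
n1, n2 = t["clean_a"], t["clean_b"]

print(f"{'miRNA':<16} {'TPM a':>8} {'TPM b':>8} {'log2FC':>8} {'p':>10} label")
for r in table.head(10).itertuples():
    fc = fold_change(float(r.tpm_a), float(r.tpm_b))
    x = reconstruct_count(float(r.tpm_a), n1)
    y = reconstruct_count(float(r.tpm_b), n2)
    p = audic_claverie(x, y, n1, n2).p_value
    label = classify(fc.value, p, fc.flag)
    print(f"{r.mirna_id:<16} {r.tpm_a:>8} {r.tpm_b:>8} {fc.value:>8.3f} {p:>10.3g} {label}")
# label ** means |log2FC| > 1 and p < 0.01; * means 0.01 <= p < 0.05;
# counts are reconstructed from the printed TPMs at the two library depths
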