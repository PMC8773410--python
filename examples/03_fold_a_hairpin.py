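"""Fold an RNA sequence and inspect its minimum-free-energy structure."""

from nitromir.folding import fold
from nitromir.seq_utils import revcomp

stem5 = "GCGAUGCCAUGGCAUCGCAA"
hairpin = stem5 + "GAAA" + revcomp(stem5)

st = fold(hairpin)
print(hairpin)
print(st.dotbracket)
print(f"MFE = {st.mfe:.1f} kcal/mol over {len(st.pairs)} base pairs")
# a perfect 20-bp inverted repeat folds into a fully paired stem; planted
# miRNA precursors (62-96 nt) come out between about -25 and -60 kcal/mol
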