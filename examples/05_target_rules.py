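"""Six-rule miRNA target evaluation on constructed sites."""

from nitromir.seq_utils import revcomp
from nitromir.targets import evaluate_site

mir = "TGGAGCTCCCTTCATTCCAAT"
perfect = revcomp(mir)

# a site with a single mismatch at position 10 (the cleavage site):
# miRNA position 10 is C, so anything but G (and not a wobble) mismatches
broken = list(perfect)
broken[len(mir) - 10] = "C"  # opposite miRNA position 10
broken = "".join(broken)

for name, site in [("perfect complement", perfect), ("mismatch at position 10", broken)]:
    hit = evaluate_site(mir, site, 0)
    verdicts = " ".join(f"r{i+1}={'ok' if v else 'FAIL'}" for i, v in enumerate(hit.rule_verdicts))
    print(f"{name}: score={hit.alignment.mismatch_score:.1f} "
          f"mfe_ratio={hit.mfe_ratio:.2f} accepted={hit.accepted}")
    print("  ", verdicts)
# rule 4 forbids mismatches at positions 10-11, where cleavage occurs;
# G:U wobbles count half a mismatch toward rules 1 and 5
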