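"""Bundled worked-example tables from a nitrogen-deprivation small-RNA
experiment in *Chlamydomonas reinhardtii*.

Two tiny reference tables ship with the package so that the arithmetic of
the analysis (fold changes, significance labels, concordance calls,
library accounting) can be validated without any sequencing data:

* ``novel_mirna_expression()`` -- per-novel-miRNA TPM in the
  nitrogen-replete (TAP) and nitrogen-deprived (TAP-N) libraries, with the
  published log2 fold change, p-value and significance label;
* ``lipid_target_pairs()`` -- the 13 miRNA/target pairs annotated to lipid
  transport and metabolism, with linear fold changes and directions.

``LIBRARY_TOTALS`` carries the library-level read accounting of the same
experiment (raw, clean, unique, and common tag counts).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

#: library-level accounting; libraries a/b are TAP (nitrogen-replete)
#: and TAP-N (nitrogen-deprived)
LIBRARY_TOTALS = dict(
    raw_a=15_360_483,
    raw_b=16_105_446,
    clean_a=13_790_887,
    clean_b=14_571_121,
    unique_a=891_186,
    unique_b=1_403_685,
    common=220_552,
)


def _load(name: str) -> pd.DataFrame:
    with resources.files("nitromir.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t", keep_default_na=False)


def novel_mirna_expression() -> pd.DataFrame:
    """Novel-miRNA expression table (30 rows).

    ``printed_log2fc`` holds the published log2(TAP-N/TAP) value, or the
    sentinel ``a_only`` / ``b_only`` for library-specific miRNAs.
    """
    return _load("novel_mirna_expression.tsv")


def lipid_target_pairs() -> pd.DataFrame:
    """The 13 lipid-pathway miRNA/target pairs with linear fold changes."""
    df = _load("lipid_target_pairs.tsv")
    assert len(df) == 13
    return df
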