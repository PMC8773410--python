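"""KOG (eukaryotic orthologous groups) category assignment and summaries.

The 25 single-letter KOG functional categories group into four main
classes.  Assignment here is table-driven: the caller supplies a
gene -> (kog id, category letter) mapping (for C. reinhardtii, the genome
portal's precomputed table plugs in unchanged), and the module tabulates
category composition and classifies miRNA/target expression concordance.
A gene carrying several letters counts once per letter, so percentages are
over gene-category pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import pandas as pd

CLASS_CPS = "Cellular Processes and Signaling"
CLASS_ISP = "Information Storage and Processing"
CLASS_MET = "Metabolism"
CLASS_POOR = "Poorly characterized"
MAIN_CLASSES = (CLASS_CPS, CLASS_ISP, CLASS_MET, CLASS_POOR)

# the standard 25 KOG categories
KOG_CATEGORIES: Dict[str, Tuple[str, str]] = {
    "J": ("Translation, ribosomal structure and biogenesis", CLASS_ISP),
    "A": ("RNA processing and modification", CLASS_ISP),
    "K": ("Transcription", CLASS_ISP),
    "L": ("Replication, recombination and repair", CLASS_ISP),
    "B": ("Chromatin structure and dynamics", CLASS_ISP),
    "D": ("Cell cycle control, cell division, chromosome partitioning", CLASS_CPS),
    "Y": ("Nuclear structure", CLASS_CPS),
    "V": ("Defense mechanisms", CLASS_CPS),
    "T": ("Signal transduction mechanisms", CLASS_CPS),
    "M": ("Cell wall/membrane/envelope biogenesis", CLASS_CPS),
    "N": ("Cell motility", CLASS_CPS),
    "Z": ("Cytoskeleton", CLASS_CPS),
    "W": ("Extracellular structures", CLASS_CPS),
    "U": ("Intracellular trafficking, secretion, and vesicular transport", CLASS_CPS),
    "O": ("Posttranslational modification, protein turnover, chaperones", CLASS_CPS),
    "C": ("Energy production and conversion", CLASS_MET),
    "G": ("Carbohydrate transport and metabolism", CLASS_MET),
    "E": ("Amino acid transport and metabolism", CLASS_MET),
    "F": ("Nucleotide transport and metabolism", CLASS_MET),
    "H": ("Coenzyme transport and metabolism", CLASS_MET),
    "I": ("Lipid transport and metabolism", CLASS_MET),
    "P": ("Inorganic ion transport and metabolism", CLASS_MET),
    "Q": ("Secondary metabolites biosynthesis, transport and catabolism", CLASS_MET),
    "R": ("General function prediction only", CLASS_POOR),
    "S": ("Function unknown", CLASS_POOR),
}


@dataclass(frozen=True)
class KOGAssignment:
    gene_id: str
    kog_id: str
    category_letter: str
    main_class: str

    def __post_init__(self):
        if self.category_letter not in KOG_CATEGORIES:
            raise ValueError(f"unknown KOG category letter {self.category_letter!r}")
        if KOG_CATEGORIES[self.category_letter][1] != self.main_class:
            raise ValueError("main_class inconsistent with category letter")


@dataclass(frozen=True)
class ConcordanceCall:
    """Sign relation of a miRNA and its predicted target under stress."""

    mirna_id: str
    gene_id: str
    mirna_direction: str  # 'up' | 'down'
    target_direction: str
    call: str  # 'opposite' | 'positive'
    interpretation: str


def load_kog_map(path) -> pd.DataFrame:
    """Read a gene->KOG TSV with columns (gene_id, kog_id, category_letter).

    Malformed rows raise with their 1-based line number.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if lineno == 1 and parts[:3] == ["gene_id", "kog_id", "category_letter"]:
                continue
            if len(parts) < 3 or parts[2] not in KOG_CATEGORIES:
                raise ValueError(f"{path}: malformed KOG map row at line {lineno}: {line!r}")
            rows.append(parts[:3])
    return pd.DataFrame(rows, columns=["gene_id", "kog_id", "category_letter"])


def assign_kog(
    gene_ids: Sequence[str],
    kog_map: Union[pd.DataFrame, str],
) -> Tuple[List[KOGAssignment], List[str]]:
    """Map genes to KOG assignments; genes absent from the map are
    reported in the second return value, never silently dropped."""
    if not isinstance(kog_map, pd.DataFrame):
        kog_map = load_kog_map(kog_map)
    by_gene: Dict[str, List[Tuple[str, str]]] = {}
    for r in kog_map.itertuples():
        by_gene.setdefault(str(r.gene_id), []).append((str(r.kog_id), str(r.category_letter)))
    assignments: List[KOGAssignment] = []
    unannotated: List[str] = []
    for g in gene_ids:
        if g in by_gene:
            for kog_id, letter in by_gene[g]:
                assignments.append(
                    KOGAssignment(g, kog_id, letter, KOG_CATEGORIES[letter][1])
                )
        else:
            unannotated.append(g)
    return assignments, unannotated


def summarize_categories(
    assignments: Sequence[KOGAssignment],
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Percentage composition per sub-category and per main class.

    Returns (by_category, by_class) long-format tables; percentages at each
    level sum to 100 over the assigned gene-category pairs.
    """
    if not assignments:
        raise ValueError("no KOG assignments to summarize")
    n = len(assignments)
    letters = [a.category_letter for a in assignments]
    cat_rows = []
    for letter, (name, main_class) in KOG_CATEGORIES.items():
        count = letters.count(letter)
        cat_rows.append(
            dict(
                category_letter=letter,
                category_name=name,
                main_class=main_class,
                count=count,
                percent=100.0 * count / n,
            )
        )
    by_category = pd.DataFrame(cat_rows)
    by_class = (
        by_category.groupby("main_class", sort=False)[["count", "percent"]]
        .sum()
        .reindex(list(MAIN_CLASSES))
        .reset_index()
    )
    return by_category, by_class


def _direction(value: Union[str, float, int], what: str) -> str:
    if isinstance(value, str):
        v = value.lower()
        if v not in ("up", "down"):
            raise ValueError(f"{what}: direction must be 'up' or 'down', got {value!r}")
        return v
    if value == 0:
        raise ValueError(f"{what}: zero fold change has no direction")
    return "up" if value > 0 else "down"


def concordance(
    mirna_fc: Union[str, float],
    target_fc: Union[str, float],
    mirna_id: str = "",
    gene_id: str = "",
) -> ConcordanceCall:
    """Classify a miRNA/target pair as opposite or positively correlated.

    Numeric inputs are signed log2 fold changes (sign carries the
    direction); strings 'up'/'down' are accepted directly.  Opposite
    expression is the signature expected of target-mRNA cleavage; positive
    co-expression points to translational repression instead.
    """
    md = _direction(mirna_fc, "miRNA")
    td = _direction(target_fc, "target")
    if md != td:
        call, why = "opposite", "consistent with miRNA-guided mRNA cleavage"
    else:
        call, why = "positive", "consistent with translational repression (miRNA and target co-expressed)"
    return ConcordanceCall(mirna_id, gene_id, md, td, call, why)


def ratio_to_log2_sign(ratio: float) -> float:
    """Signed log2 of a linear fold-change ratio (>1 up, <1 down)."""
    import math

    if ratio <= 0:
        raise ValueError("fold-change ratio must be positive")
    return math.log2(ratio)
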