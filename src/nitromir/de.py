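"""Two-library differential expression for count features.

Implements the normalisation and test used for pooled small-RNA libraries:

* TPM normalisation: ``count / total_clean_reads * 1e6``.
* A zero TPM is replaced by 0.01 before forming the ratio, and the log2
  fold change is ``log2(TPM_b / TPM_a)`` (condition b = treatment).
* Features below 1 TPM in both libraries are removed before testing.
* Significance comes from the exact Poisson (Audic-Claverie) conditional

      p(y | x) = (N2/N1)^y * (x+y)! / (x! y! (1 + N2/N1)^(x+y+1))

  with lower/upper tail sums C = sum_{y'<=y} p(y'|x) and
  D = sum_{y'>=y} p(y'|x); the two-sided p-value is min(1, 2*min(C, D)).
  Everything is evaluated in log space via log-gamma, so arbitrarily deep
  libraries cannot overflow.

The test always runs on raw integer counts; the 0.01 substitution only
affects the reported fold change.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

LABEL_STRONG = "**"
LABEL_WEAK = "*"
LABEL_NS = "ns"
LABEL_A_ONLY = "a_specific"
LABEL_B_ONLY = "b_specific"

ZERO_SUBSTITUTE = 0.01


@dataclass(frozen=True)
class DEInput:
    feature_id: str
    x: int  # count in library 1 (control, TAP)
    y: int  # count in library 2 (treatment, TAP-N)
    n1: int
    n2: int

    def __post_init__(self):
        if self.n1 < 1 or self.n2 < 1:
            raise ValueError("library totals must be >= 1")
        if not (0 <= self.x <= self.n1) or not (0 <= self.y <= self.n2):
            raise ValueError(f"{self.feature_id}: counts outside [0, N]")


@dataclass(frozen=True)
class ACTest:
    """Audic-Claverie conditional density at (x, y) and its tail sums."""

    p_cond: float
    c: float  # lower tail, y' = 0..y
    d: float  # upper tail, y' = y..inf
    p_value: float


@dataclass(frozen=True)
class FoldChange:
    value: float
    flag: Optional[str]  # None, 'a_only' or 'b_only'


def normalize_tpm(count: int, total: int) -> float:
    """Transcripts per million: count / total * 1e6."""
    if total <= 0:
        raise ValueError("total clean reads must be positive")
    if count < 0:
        raise ValueError("negative count")
    return count / total * 1_000_000.0


def reconstruct_count(tpm: float, total: int) -> int:
    """Nearest integer count giving the stated TPM at the stated depth."""
    return int(round(tpm * total / 1_000_000.0))


def fold_change(ne_a: float, ne_b: float, zero_sub: float = ZERO_SUBSTITUTE) -> FoldChange:
    """log2(b/a) with zero substitution; flags one-library-only features."""
    if ne_a < 0 or ne_b < 0:
        raise ValueError("normalized expression must be non-negative")
    flag = None
    if ne_a == 0.0 and ne_b > 0.0:
        flag = "b_only"
    elif ne_b == 0.0 and ne_a > 0.0:
        flag = "a_only"
    a = ne_a if ne_a > 0 else zero_sub
    b = ne_b if ne_b > 0 else zero_sub
    # log difference rather than log of the ratio: exactly antisymmetric
    # and immune to underflow for extreme TPM pairs
    return FoldChange(math.log2(b) - math.log2(a), flag)


def audic_claverie(x: int, y: int, n1: int, n2: int, method: str = "doubled") -> ACTest:
    """Exact Poisson two-library test of a feature observed (x, y) times.

    ``method`` 'doubled' gives p = min(1, 2 min(C, D)); 'min' gives
    p = min(C, D).
    """
    if n1 < 1 or n2 < 1:
        raise ValueError("library totals must be >= 1")
    if x < 0 or y < 0:
        raise ValueError("counts must be non-negative")
    log_r = math.log(n2) - math.log(n1)
    log1p_r = math.log1p(n2 / n1)
    ys = np.arange(0, y + 1)
    logp = (
        ys * log_r
        + gammaln(x + ys + 1)
        - gammaln(x + 1)
        - gammaln(ys + 1)
        - (x + ys + 1) * log1p_r
    )
    c = float(np.exp(logsumexp(logp)))
    p_cond = float(np.exp(logp[-1]))
    c = min(c, 1.0)
    d = min(max(1.0 - c + p_cond, p_cond), 1.0)
    if method == "doubled":
        p = min(1.0, 2.0 * min(c, d))
    elif method == "min":
        p = min(c, d)
    else:
        raise ValueError(f"unknown method {method!r}")
    return ACTest(p_cond=p_cond, c=c, d=d, p_value=p)


def classify(
    log2fc: float,
    p_value: float,
    flag: Optional[str] = None,
    fc_threshold: float = 1.0,
    alpha: float = 0.05,
    alpha_strong: float = 0.01,
) -> str:
    """Significance label from fold change and p-value.

    Library-specific features keep their flag rather than a star label.
    """
    if flag == "a_only":
        return LABEL_A_ONLY
    if flag == "b_only":
        return LABEL_B_ONLY
    if abs(log2fc) > fc_threshold:
        if p_value < alpha_strong:
            return LABEL_STRONG
        if p_value < alpha:
            return LABEL_WEAK
    return LABEL_NS


def run_de(
    inputs: Sequence[DEInput] | pd.DataFrame,
    n1: Optional[int] = None,
    n2: Optional[int] = None,
    fc_threshold: float = 1.0,
    alpha: float = 0.05,
    alpha_strong: float = 0.01,
    min_tpm: float = 1.0,
    method: str = "doubled",
    bh: bool = False,
) -> pd.DataFrame:
    """Full differential-expression table for a set of features.

    Features with TPM < ``min_tpm`` in both libraries are removed before
    testing.  With ``bh=True`` a Benjamini-Hochberg adjusted column
    ``p_adj`` is added (labels still use the raw p, as in the original
    analysis, unless you re-classify).
    """
    if isinstance(inputs, pd.DataFrame):
        if n1 is None or n2 is None:
            raise ValueError("n1/n2 required with a DataFrame input")
        inputs = [
            DEInput(str(r.feature_id), int(r.count_a), int(r.count_b), n1, n2)
            for r in inputs.itertuples()
        ]
    ids = [i.feature_id for i in inputs]
    if len(set(ids)) != len(ids):
        dups = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate feature ids: {dups}")
    if inputs:
        n1s = {i.n1 for i in inputs} | ({n1} if n1 else set())
        n2s = {i.n2 for i in inputs} | ({n2} if n2 else set())
        if len(n1s) != 1 or len(n2s) != 1:
            raise ValueError("all inputs must share the same library totals")

    rows = []
    for inp in inputs:
        ne_a = normalize_tpm(inp.x, inp.n1)
        ne_b = normalize_tpm(inp.y, inp.n2)
        if ne_a < min_tpm and ne_b < min_tpm:
            continue
        fc = fold_change(ne_a, ne_b)
        test = audic_claverie(inp.x, inp.y, inp.n1, inp.n2, method=method)
        label = classify(fc.value, test.p_value, fc.flag, fc_threshold, alpha, alpha_strong)
        rows.append(
            dict(
                feature_id=inp.feature_id,
                count_a=inp.x,
                count_b=inp.y,
                tpm_a=ne_a,
                tpm_b=ne_b,
                log2fc=fc.value,
                flag=fc.flag,
                p_lower=test.c,
                p_upper=test.d,
                p_value=test.p_value,
                label=label,
            )
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "feature_id", "count_a", "count_b", "tpm_a", "tpm_b",
            "log2fc", "flag", "p_lower", "p_upper", "p_value", "label",
        ],
    )
    if bh and len(df):
        from scipy.stats import false_discovery_control

        df["p_adj"] = false_discovery_control(df["p_value"].to_numpy(), method="bh")
    return df
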