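"""Cross-structure significance handling and evaluation statistics.

When k structures are scanned, per-structure p-values are compared against
the rough false-discovery-rate cutoff

    rFDR = α (k + 1) / (2k)

(a cheap approximation to the Benjamini–Hochberg procedure appropriate for
many positively correlated tests), rounded down to three decimals when
applied.  Structures are then classified into the trinary outcome
clustering / no-clustering / blank, and tertiary (per-chain) calls can be
cross-classified against the quaternary call.  Association between methods
is summarized with Cramér's V and differences in proportions with a
one-sided two-proportion test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "StructureResult",
    "RunSummary",
    "rfdr_threshold",
    "applied_cutoff",
    "classify_trinary",
    "cross_classify",
    "cramers_v",
    "compare_proportions_one_sided",
]


@dataclass
class StructureResult:
    structure_id: str
    method: str
    outcome: str          # "clustering" | "no_clustering" | "blank"
    min_p: float | None
    n_mutations: int
    clusters: list = field(default_factory=list)
    hotspots: list = field(default_factory=list)


@dataclass
class RunSummary:
    k: int
    alpha: float
    rfdr_cutoff: float
    applied_cutoff: float
    results: list[StructureResult]


def rfdr_threshold(alpha: float, k: int) -> float:
    """Rough-FDR cutoff α(k+1)/(2k) for k analyzed structures."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must be in (0, 1)")
    return alpha * (k + 1) / (2 * k)


def applied_cutoff(alpha: float, k: int) -> float:
    """The conservative cutoff actually applied: rFDR rounded DOWN to 3
    decimals."""
    return math.floor(rfdr_threshold(alpha, k) * 1000) / 1000


def classify_trinary(n_mutations: int, min_p: float | None,
                     cutoff: float) -> str:
    """blank if n < 2; clustering if min_p <= cutoff; else no_clustering."""
    if n_mutations < 2:
        return "blank"
    if min_p is not None and min_p <= cutoff:
        return "clustering"
    return "no_clustering"


def cross_classify(tertiary_outcomes: list[str], quaternary_outcome: str) -> str:
    """Four-way tertiary-vs-quaternary classification for one structure and
    method: the tertiary side counts as clustering if any chain clusters."""
    t = any(o == "clustering" for o in tertiary_outcomes)
    q = quaternary_outcome == "clustering"
    if t and q:
        return "both"
    if t:
        return "only_3d"
    if q:
        return "only_4d"
    return "neither"


def cramers_v(contingency) -> float:
    """Cramér's V = sqrt( (χ²/n) / min(r−1, c−1) ), Pearson χ² without
    continuity correction."""
    table = np.asarray(contingency, dtype=float)
    if table.ndim != 2 or (table < 0).any():
        raise ValueError("need a nonnegative 2D contingency table")
    n = table.sum()
    if n <= 0:
        raise ValueError("empty table")
    rows = (table.sum(axis=1) > 0).sum()
    cols = (table.sum(axis=0) > 0).sum()
    if rows < 2 or cols < 2:
        raise ValueError("degenerate margins: need 2+ rows and columns with mass")
    chi2 = stats.chi2_contingency(table[table.sum(axis=1) > 0][:, table.sum(axis=0) > 0],
                                  correction=False).statistic
    return float(np.sqrt((chi2 / n) / min(rows - 1, cols - 1)))


def compare_proportions_one_sided(
    a_hits: int, a_total: int, b_hits: int, b_total: int,
    method: str = "score_cc",
) -> float:
    """One-sided test of H0: p_a = p_b vs Ha: p_a > p_b.

    Default ``score_cc`` is the pooled two-proportion z-test with continuity
    correction (the one-sided Yates chi-square, as in R's ``prop.test``);
    ``fisher`` gives the exact hypergeometric tail.
    """
    if not (0 <= a_hits <= a_total and 0 <= b_hits <= b_total):
        raise ValueError("hits must be between 0 and totals")
    if a_total == 0 or b_total == 0:
        raise ValueError("totals must be positive")
    if method == "fisher":
        table = [[a_hits, a_total - a_hits], [b_hits, b_total - b_hits]]
        return float(stats.fisher_exact(table, alternative="greater")[1])
    if method == "score_cc":
        p0, p1 = a_hits / a_total, b_hits / b_total
        pooled = (a_hits + b_hits) / (a_total + b_total)
        se = math.sqrt(pooled * (1 - pooled) * (1 / a_total + 1 / b_total))
        if se == 0:
            return 1.0 if p0 <= p1 else 0.0
        cc = 0.5 * (1 / a_total + 1 / b_total)
        z = (p0 - p1 - min(cc, abs(p0 - p1))) / se
        return float(stats.norm.sf(z))
    if method == "score":
        p0, p1 = a_hits / a_total, b_hits / b_total
        pooled = (a_hits + b_hits) / (a_total + b_total)
        se = math.sqrt(pooled * (1 - pooled) * (1 / a_total + 1 / b_total))
        if se == 0:
            return 1.0 if p0 <= p1 else 0.0
        return float(stats.norm.sf((p0 - p1) / se))
    raise ValueError(f"unknown method {method!r}")
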