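"""Per-gene differential scores between two sample groups and filter rules.

Each scoring method produces one score per gene mirroring the expression
difference between group A and group B (positive = higher in A).  The
implemented core is log2 fold-change, the Welch t statistic, and a
tie-corrected rank-sum z; scores can be transformed to absolute values when
the direction of change is not of interest.  Filter procedures turn a score
list into a deregulated gene set for downstream over-representation analysis.

Tie-breaking is everywhere a stable sort with the lexicographic gene token as
the final key, so results are bit-reproducible.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .types import ComputationError, ExpressionMatrix, ScoreList, ValidationError

log = logging.getLogger(__name__)

__all__ = [
    "GroupAssignment",
    "score_log_fold_change",
    "score_t_test",
    "score_wilcoxon",
    "transform_abs",
    "select_deregulated",
]


@dataclass(frozen=True)
class GroupAssignment:
    """Maps every matrix column to group ``"A"`` or ``"B"``."""

    assignment: Mapping[str, str]

    def __post_init__(self) -> None:
        bad = {v for v in self.assignment.values() if v not in ("A", "B")}
        if bad:
            raise ValidationError(f"group labels must be 'A' or 'B', got {sorted(bad)}")
        if self.n_a < 1 or self.n_b < 1:
            raise ValidationError("both groups need at least one sample")

    @property
    def n_a(self) -> int:
        return sum(1 for v in self.assignment.values() if v == "A")

    @property
    def n_b(self) -> int:
        return sum(1 for v in self.assignment.values() if v == "B")

    def columns(self, group: str) -> list[str]:
        return [c for c, v in self.assignment.items() if v == group]

    def swapped(self) -> "GroupAssignment":
        return GroupAssignment(
            {c: ("B" if v == "A" else "A") for c, v in self.assignment.items()}
        )

    @classmethod
    def from_metadata(
        cls, meta: pd.DataFrame, key: str, group_a: str, group_b: str
    ) -> "GroupAssignment":
        if key not in meta.columns:
            raise ValidationError(f"metadata has no column {key!r}")
        mapping: dict[str, str] = {}
        for col, label in meta[key].items():
            if label == group_a:
                mapping[str(col)] = "A"
            elif label == group_b:
                mapping[str(col)] = "B"
        return cls(mapping)


def _split(m: ExpressionMatrix, g: GroupAssignment) -> tuple[np.ndarray, np.ndarray]:
    unassigned = [c for c in m.columns if c not in g.assignment]
    if unassigned:
        raise ValidationError(
            f"{len(unassigned)} matrix column(s) not assigned to a group "
            f"(first: {unassigned[0]})"
        )
    a = m.values[g.columns("A")].to_numpy(dtype=float)
    b = m.values[g.columns("B")].to_numpy(dtype=float)
    return a, b


def score_log_fold_change(
    m: ExpressionMatrix, g: GroupAssignment, pseudocount: float = 1.0
) -> ScoreList:
    """log2((meanA + c) / (meanB + c)) per gene.

    ``pseudocount`` must be positive unless both group means are nonzero for
    every gene; for counts a default of 1.0 keeps the score finite.
    """
    if pseudocount < 0:
        raise ValidationError("pseudocount must be >= 0")
    a, b = _split(m, g)
    if np.any(a < 0) or np.any(b < 0):
        raise ValidationError("fold-change scoring requires non-negative values")
    ma = a.mean(axis=1) + pseudocount
    mb = b.mean(axis=1) + pseudocount
    zero = (ma == 0) | (mb == 0)
    if np.any(zero):
        gene = m.genes[int(np.flatnonzero(zero)[0])]
        raise ComputationError(
            f"zero group mean with pseudocount 0 for gene {gene}; "
            "use a positive pseudocount"
        )
    scores = np.log2(ma) - np.log2(mb)
    return ScoreList(zip(m.genes, scores), normalize=False).sorted_descending()


def score_t_test(
    m: ExpressionMatrix, g: GroupAssignment, variant: str = "unequal_variance"
) -> ScoreList:
    """Welch (unequal-variance) t statistic per gene, A minus B.

    Genes with zero variance in both groups receive score 0; their count is
    logged as a warning.
    """
    if variant != "unequal_variance":
        raise ValidationError(f"unknown t-test variant: {variant}")
    if g.n_a < 2 or g.n_b < 2:
        raise ValidationError("t-test requires at least 2 samples per group")
    a, b = _split(m, g)
    na, nb = a.shape[1], b.shape[1]
    va = a.var(axis=1, ddof=1)
    vb = b.var(axis=1, ddof=1)
    denom = np.sqrt(va / na + vb / nb)
    diff = a.mean(axis=1) - b.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(denom > 0, diff / np.where(denom > 0, denom, 1.0), 0.0)
    n_degenerate = int((denom == 0).sum())
    if n_degenerate:
        log.warning("%d gene(s) with zero variance in both groups scored 0", n_degenerate)
    return ScoreList(zip(m.genes, t), normalize=False).sorted_descending()


def score_wilcoxon(m: ExpressionMatrix, g: GroupAssignment) -> ScoreList:
    """Normal-approximation z of the rank-sum statistic per gene.

    Tie-corrected, no continuity correction; positive when group A ranks
    higher.  Genes fully tied across both groups score 0.
    """
    a, b = _split(m, g)
    na, nb = a.shape[1], b.shape[1]
    n = na + nb
    combined = np.concatenate([a, b], axis=1)
    ranks = rankdata(combined, axis=1)  # average ranks handle ties
    w = ranks[:, :na].sum(axis=1)
    mean_w = na * (n + 1) / 2.0
    # tie correction: subtract sum(t^3 - t) over tie groups per gene
    tie_term = np.zeros(combined.shape[0])
    for i in range(combined.shape[0]):
        _, counts = np.unique(combined[i], return_counts=True)
        tie_term[i] = float(((counts**3) - counts).sum())
    var_w = na * nb / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(var_w > 0, (w - mean_w) / np.sqrt(np.where(var_w > 0, var_w, 1.0)), 0.0)
    return ScoreList(zip(m.genes, z), normalize=False).sorted_descending()


def transform_abs(s: ScoreList) -> ScoreList:
    """Replace scores by absolute values; re-sort descending (gene tie-break)."""
    return ScoreList(
        zip(s.genes, np.abs(s.scores)), normalize=False
    ).sorted_descending()


def select_deregulated(s: ScoreList, rule: str, value: float) -> set[str]:
    """Select deregulated genes from a score list.

    Rules:

    ``top_k``
        the ``k`` highest-scoring genes (ties broken by gene token);
    ``upper_lower_percent``
        the top ``q`` percent plus the bottom ``q`` percent by score, with
        rank-based cutoffs of ``ceil(q/100 * n)`` genes per tail;
    ``abs_threshold``
        all genes with ``|score| >= t``.
    """
    n = len(s)
    if n == 0:
        raise ValidationError("empty score list")
    ordered = s.sorted_descending()
    if rule == "top_k":
        k = int(value)
        if k < 1 or k > n:
            raise ValidationError(f"top_k: k={k} outside [1, {n}]")
        return set(ordered.genes[:k])
    if rule == "upper_lower_percent":
        q = float(value)
        if not (0 < q <= 50):
            raise ValidationError(f"upper_lower_percent: q={q} outside (0, 50]")
        tail = math.ceil(q / 100.0 * n)
        # bottom tail: ascending score, same lexicographic tie-break
        bottom_order = sorted(range(n), key=lambda i: (ordered.scores[i], ordered.genes[i]))
        return set(ordered.genes[:tail]) | {ordered.genes[i] for i in bottom_order[:tail]}
    if rule == "abs_threshold":
        t = float(value)
        if t < 0:
            raise ValidationError(f"abs_threshold: t={t} must be >= 0")
        return {g for g, v in s if abs(v) >= t}
    raise ValidationError(f"unknown filter rule: {rule}")
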