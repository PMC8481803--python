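"""Set-level enrichment statistics over biological categories.

Two families are provided.  Over-representation analysis (ORA) tests a
preselected gene set against a reference background with the hypergeometric
distribution.  Functional class scoring (FCS) operates on a complete ranked
score list: the running-sum enrichment score (ES) in weighted and unweighted
(Kolmogorov-Smirnov-like) form with a membership-permutation null, a
rank-sum test of member positions, a Welch t test of member scores against
the rest, and mean/median summary statistics with a permutation null.
Multiple-testing adjustment (Benjamini-Hochberg, Bonferroni,
Benjamini-Yekutieli) is applied across tested categories.

Category sizes are reported AFTER intersection with the reference or ranked
list: genes annotated to a category but absent from the data do not count.
Permutation p-values use the add-one estimator (1 + exceed) / (B + 1), so
they are never zero and never below 1/(B+1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .types import (
    ComputationError,
    EnrichmentRecord,
    GeneSet,
    GeneSetCollection,
    ScoreList,
    ValidationError,
    gene_id,
)

log = logging.getLogger(__name__)

__all__ = [
    "RankedList",
    "OraInput",
    "ora",
    "gsea_es",
    "gsea_pvalue",
    "fcs_wilcoxon",
    "fcs_ttest",
    "fcs_mean",
    "adjust_pvalues",
    "run_enrichment",
    "CategorySkipped",
]

DEFAULT_PERMUTATIONS = 1000
DEFAULT_SEED = 42


class CategorySkipped(ComputationError):
    """Raised when a category cannot be tested; run_enrichment records it."""


class RankedList:
    """A score list in strictly canonical order: descending score, gene
    token as tie-break, 1-based rank semantics downstream."""

    __slots__ = ("genes", "scores", "_index")

    def __init__(self, s: ScoreList) -> None:
        if len(s) < 2:
            raise ValidationError("ranked list needs at least 2 genes")
        ordered = s.sorted_descending()
        self.genes: list[str] = ordered.genes
        self.scores: np.ndarray = ordered.scores
        self._index: dict[str, int] = {g: i for i, g in enumerate(self.genes)}

    def __len__(self) -> int:
        return len(self.genes)

    def positions_of(self, members: Iterable[str]) -> np.ndarray:
        """Sorted 0-based positions of the members present in the list."""
        pos = sorted(self._index[g] for g in members if g in self._index)
        return np.asarray(pos, dtype=np.int64)

    def member_mask(self, members: Iterable[str]) -> np.ndarray:
        mask = np.zeros(len(self), dtype=bool)
        mask[self.positions_of(members)] = True
        return mask


@dataclass(frozen=True)
class OraInput:
    """A preselected test set inside a reference background."""

    test_set: frozenset[str]
    reference_set: frozenset[str]

    def __post_init__(self) -> None:
        if not self.test_set:
            raise ValidationError("ORA test set is empty")
        if not self.test_set <= self.reference_set:
            extra = sorted(self.test_set - self.reference_set)[0]
            raise ValidationError(
                f"test set is not a subset of the reference (e.g., {extra})"
            )

    @classmethod
    def from_sets(cls, test: Iterable[str], reference: Iterable[str]) -> "OraInput":
        return cls(
            frozenset(gene_id(g) for g in test),
            frozenset(gene_id(g) for g in reference),
        )


def ora(oin: OraInput, category: GeneSet, sided: str = "enrichment") -> EnrichmentRecord:
    """Hypergeometric over-representation test of one category.

    With N = |reference|, K = |category ∩ reference|, n = |test set| and
    k = |category ∩ test set|: enrichment p = P(X >= k), depletion
    p = P(X <= k), two_sided = 2 * min(tails) capped at 1.  Direction is the
    sign of k - n*K/N.
    """
    if sided not in ("enrichment", "depletion", "two_sided"):
        raise ValidationError(f"unknown sidedness: {sided}")
    ref = oin.reference_set
    cat_in_ref = category.members & ref
    if not cat_in_ref:
        raise CategorySkipped(
            f"category {category.name!r} has no members in the reference"
        )
    N, K, n = len(ref), len(cat_in_ref), len(oin.test_set)
    hit_genes = sorted(category.members & oin.test_set)
    k = len(hit_genes)
    hg = stats.hypergeom(N, K, n)
    p_enr = float(hg.sf(k - 1))
    p_dep = float(hg.cdf(k))
    if sided == "enrichment":
        p = p_enr
    elif sided == "depletion":
        p = p_dep
    else:
        p = min(1.0, 2.0 * min(p_enr, p_dep))
    p = min(1.0, max(0.0, p))
    expected = n * K / N
    statistic = k - expected
    if statistic > 0:
        direction = "enriched"
    elif statistic < 0:
        direction = "depleted"
    else:
        direction = "none"
    return EnrichmentRecord(
        category=category.name,
        category_size=K,
        hits=k,
        statistic=statistic,
        direction=direction,
        p_raw=p,
        p_adj=p,
        hit_genes=hit_genes,
    )


def _hit_weights(scores: np.ndarray, positions: np.ndarray, weight_p: float) -> np.ndarray:
    """Per-hit increments |score|^p normalized to sum 1 (uniform fallback
    when the weighted mass is zero)."""
    w = np.abs(scores[positions]) ** weight_p if weight_p != 0 else np.ones(len(positions))
    total = w.sum()
    if total == 0:
        w = np.ones(len(positions))
        total = float(len(positions))
    return w / total


def gsea_es(
    r: RankedList, category: GeneSet, weight_p: float = 0.0
) -> tuple[float, list[str], list[int]]:
    """Running-sum enrichment score of a category in a ranked list.

    Walking down the list, a category member ("hit") at rank i increments the
    running sum by |score_i|^p / N_R (N_R = sum of |score|^p over hits;
    uniform fallback when N_R = 0), a non-member decrements by 1/(N - N_h).
    ES is the signed maximum deviation from zero (earliest position on ties).
    ``weight_p = 0`` gives the unweighted Kolmogorov-Smirnov-like statistic.

    Returns (es, leading_edge_genes, 1-based hit positions).  For ES >= 0 the
    leading edge is the hits at or before the extremum; for ES < 0 the hits
    strictly after it.
    """
    if weight_p < 0:
        raise ValidationError("weight_p must be >= 0")
    N = len(r)
    pos = r.positions_of(category.members)
    h = len(pos)
    if h == 0:
        raise CategorySkipped(f"category {category.name!r} has no members in the list")
    if h == N:
        raise ValidationError(
            f"category {category.name!r} covers the whole ranked list; "
            "the running-sum statistic is undefined"
        )
    inc = _hit_weights(r.scores, pos, weight_p)
    steps = np.full(N, -1.0 / (N - h))
    steps[pos] = inc
    running = np.cumsum(steps)
    extremum = int(np.argmax(np.abs(running)))
    es = float(running[extremum])
    if es >= 0:
        lead = [r.genes[i] for i in pos if i <= extremum]
    else:
        lead = [r.genes[i] for i in pos if i > extremum]
    return es, lead, [int(i) + 1 for i in pos]


def _sample_positions(rng: np.random.Generator, B: int, N: int, h: int) -> np.ndarray:
    """B rows of h distinct positions in [0, N), each row sorted."""
    keys = rng.random((B, N))
    part = np.argpartition(keys, h - 1, axis=1)[:, :h]
    return np.sort(part, axis=1)


def _batch_es(pos: np.ndarray, weights: np.ndarray, N: int) -> np.ndarray:
    """Signed max-deviation ES for each row of sorted hit positions.

    ``weights`` (same shape as ``pos``) are the per-hit increments, already
    normalized to sum 1 per row.  The running sum is piecewise: it only
    attains local maxima immediately after hits and local minima immediately
    before hits, so the extremum is found from those 2h candidates.
    """
    B, h = pos.shape
    miss = 1.0 / (N - h)
    j = np.arange(1, h + 1, dtype=float)
    hit_cum = np.cumsum(weights, axis=1)
    after = hit_cum - (pos + 1 - j) * miss  # value right after each hit
    before = after - weights  # value right before each hit
    cand = np.concatenate([after, before], axis=1)
    idx = np.argmax(np.abs(cand), axis=1)
    return cand[np.arange(B), idx]


def gsea_pvalue(
    r: RankedList,
    category: GeneSet,
    weight_p: float = 0.0,
    B: int = DEFAULT_PERMUTATIONS,
    seed: int = DEFAULT_SEED,
) -> EnrichmentRecord:
    """ES with a gene-label permutation null.

    The null shuffles category membership over ranks (B random draws of the
    same number of distinct ranks; the rank-attached score weights stay in
    place).  p = (1 + #{|ES_null| >= |ES|}) / (B + 1), two-sided by |ES|;
    direction is the sign of the observed ES.
    """
    if B < 100:
        raise ValidationError("at least 100 permutations required")
    es, lead, hit_positions = gsea_es(r, category, weight_p)
    N = len(r)
    h = len(hit_positions)
    rng = np.random.default_rng(seed)
    pos_null = _sample_positions(rng, B, N, h)
    if weight_p == 0:
        w_null = np.full_like(pos_null, 1.0 / h, dtype=float)
    else:
        absw = np.abs(r.scores) ** weight_p
        w_null = absw[pos_null]
        totals = w_null.sum(axis=1, keepdims=True)
        zero = totals[:, 0] == 0
        w_null = np.where(totals > 0, w_null / np.where(totals > 0, totals, 1.0), 1.0 / h)
        if zero.any():
            w_null[zero] = 1.0 / h
    es_null = _batch_es(pos_null, w_null, N)
    p = float((1 + np.sum(np.abs(es_null) >= abs(es) - 1e-15)) / (B + 1))
    direction = "enriched" if es > 0 else ("depleted" if es < 0 else "none")
    return EnrichmentRecord(
        category=category.name,
        category_size=h,
        hits=h,
        statistic=es,
        direction=direction,
        p_raw=p,
        p_adj=p,
        hit_genes=lead,
    )


def fcs_wilcoxon(r: RankedList, category: GeneSet) -> EnrichmentRecord:
    """Rank-sum z of member positions versus non-member positions.

    Ranks in the list are distinct by construction, so no tie correction is
    needed; z > 0 means members sit nearer the top (enriched).  Two-sided
    normal p.
    """
    N = len(r)
    pos = r.positions_of(category.members)
    h = len(pos)
    if h == 0 or h == N:
        raise CategorySkipped(
            f"category {category.name!r}: needs 1 <= members < N in the list"
        )
    # rank value = N - position, so large values = top of the list
    w = float(np.sum(N - pos))
    mean_w = h * (N + 1) / 2.0
    var_w = h * (N - h) * (N + 1) / 12.0
    z = (w - mean_w) / np.sqrt(var_w)
    p = float(2.0 * stats.norm.sf(abs(z)))
    p = min(1.0, p)
    direction = "enriched" if z > 0 else ("depleted" if z < 0 else "none")
    return EnrichmentRecord(
        category=category.name,
        category_size=h,
        hits=h,
        statistic=float(z),
        direction=direction,
        p_raw=p,
        p_adj=p,
        hit_genes=[r.genes[i] for i in pos],
    )


def fcs_ttest(r: RankedList, category: GeneSet) -> EnrichmentRecord:
    """Welch two-sample t of member scores against non-member scores."""
    mask = r.member_mask(category.members)
    h = int(mask.sum())
    if h < 2 or len(r) - h < 2:
        raise CategorySkipped(
            f"category {category.name!r}: needs >= 2 members and >= 2 non-members"
        )
    a = r.scores[mask]
    b = r.scores[~mask]
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        raise CategorySkipped(f"category {category.name!r}: degenerate variances")
    res = stats.ttest_ind(a, b, equal_var=False)
    t, p = float(res.statistic), float(res.pvalue)
    direction = "enriched" if t > 0 else ("depleted" if t < 0 else "none")
    return EnrichmentRecord(
        category=category.name,
        category_size=h,
        hits=h,
        statistic=t,
        direction=direction,
        p_raw=min(1.0, p),
        p_adj=min(1.0, p),
        hit_genes=[g for g, m in zip(r.genes, mask) if m],
    )


def fcs_mean(
    r: RankedList,
    category: GeneSet,
    stat: str = "mean",
    B: int = DEFAULT_PERMUTATIONS,
    seed: int = DEFAULT_SEED,
) -> EnrichmentRecord:
    """Summary statistic (mean or median) of member scores with a
    membership-permutation null (two-sided, add-one estimator)."""
    if stat not in ("mean", "median"):
        raise ValidationError(f"unknown summary statistic: {stat}")
    mask = r.member_mask(category.members)
    h = int(mask.sum())
    if h == 0:
        raise CategorySkipped(f"category {category.name!r} has no members in the list")
    agg = np.mean if stat == "mean" else np.median
    observed = float(agg(r.scores[mask]))
    rng = np.random.default_rng(seed)
    pos_null = _sample_positions(rng, B, len(r), h)
    null_vals = agg(r.scores[pos_null], axis=1)
    p_hi = (1 + np.sum(null_vals >= observed - 1e-15)) / (B + 1)
    p_lo = (1 + np.sum(null_vals <= observed + 1e-15)) / (B + 1)
    p = float(min(1.0, 2.0 * min(p_hi, p_lo)))
    direction = "enriched" if p_hi < p_lo else ("depleted" if p_lo < p_hi else "none")
    return EnrichmentRecord(
        category=category.name,
        category_size=h,
        hits=h,
        statistic=observed,
        direction=direction,
        p_raw=p,
        p_adj=p,
        hit_genes=[g for g, m in zip(r.genes, mask) if m],
    )


_ADJUST_METHODS = {
    "benjamini_hochberg": "fdr_bh",
    "bonferroni": "bonferroni",
    "benjamini_yekutieli": "fdr_by",
}


def adjust_pvalues(p: Sequence[float], method: str = "benjamini_hochberg") -> list[float]:
    """Adjust raw p-values for multiple testing; input order preserved.

    Benjamini-Hochberg is the step-up procedure with cumulative minimum from
    the largest rank, capped at 1.
    """
    if method not in _ADJUST_METHODS:
        raise ValidationError(f"unknown adjustment method: {method}")
    arr = np.asarray(list(p), dtype=float)
    if arr.size == 0:
        return []
    if np.any((arr < 0) | (arr > 1) | ~np.isfinite(arr)):
        raise ValidationError("p-values must lie in [0, 1]")
    _, adj, _, _ = multipletests(arr, alpha=0.05, method=_ADJUST_METHODS[method])
    return [float(v) for v in np.minimum(adj, 1.0)]


_FCS_METHODS = ("gsea", "wilcoxon", "ttest", "mean", "median")


def run_enrichment(
    data: OraInput | RankedList,
    coll: GeneSetCollection,
    method: str,
    min_size: int = 3,
    max_size: int = 700,
    adjust: str = "benjamini_hochberg",
    *,
    sided: str = "enrichment",
    weight_p: float = 0.0,
    B: int = DEFAULT_PERMUTATIONS,
    seed: int = DEFAULT_SEED,
) -> tuple[list[EnrichmentRecord], list[tuple[str, str]]]:
    """Test every category of a collection; returns (records, skipped).

    Categories are filtered to [min_size, max_size] by members-in-reference
    (ORA) or members-in-list (FCS).  Adjusted p-values are computed over the
    tested categories only; records are sorted by raw p, then category name.
    Skipped categories are reported as (name, reason) pairs.
    """
    if min_size < 1 or max_size < min_size:
        raise ValidationError("need 1 <= min_size <= max_size")
    records: list[EnrichmentRecord] = []
    skipped: list[tuple[str, str]] = []
    if method == "ora":
        if not isinstance(data, OraInput):
            raise ValidationError("ORA requires an OraInput (test set + reference)")
        size_of = lambda gs: len(gs.members & data.reference_set)  # noqa: E731
    elif method in _FCS_METHODS:
        if not isinstance(data, RankedList):
            raise ValidationError(f"{method} requires a RankedList of scores")
        size_of = lambda gs: int(data.member_mask(gs.members).sum())  # noqa: E731
    else:
        raise ValidationError(f"unknown enrichment method: {method}")

    for i, gs in enumerate(coll):
        size = size_of(gs)
        if size < min_size or size > max_size:
            skipped.append((gs.name, f"size {size} outside [{min_size}, {max_size}]"))
            continue
        try:
            if method == "ora":
                rec = ora(data, gs, sided=sided)
            elif method == "gsea":
                rec = gsea_pvalue(data, gs, weight_p=weight_p, B=B, seed=seed + i)
            elif method == "wilcoxon":
                rec = fcs_wilcoxon(data, gs)
            elif method == "ttest":
                rec = fcs_ttest(data, gs)
            else:
                rec = fcs_mean(data, gs, stat=method, B=B, seed=seed + i)
        except CategorySkipped as exc:
            skipped.append((gs.name, str(exc)))
            continue
        records.append(rec)
    if not records:
        raise ComputationError(
            f"no category survived filtering ({len(skipped)} skipped)"
        )
    adj = adjust_pvalues([rec.p_raw for rec in records], method=adjust)
    for rec, a in zip(records, adj):
        rec.p_adj = max(a, rec.p_raw)
    records.sort(key=lambda rec: (rec.p_raw, rec.category))
    return records, skipped
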