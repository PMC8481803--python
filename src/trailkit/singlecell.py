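"""Single-cell enrichment workflow.

The pipeline mirrors a per-cell functional profiling strategy: quality
filtering of cells, depth normalization, selection of each cell's most
highly expressed genes, a per-cell over-representation test of those genes
against a category collection ("activity" = -log10 of the raw per-cell p),
a rank-based one-vs-rest test of category activity between cell groups, and
pseudo-bulk aggregation of counts per sample for downstream bulk methods.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .enrichment import adjust_pvalues
from .types import (
    ComputationError,
    ExpressionMatrix,
    GeneSetCollection,
    ValidationError,
)

log = logging.getLogger(__name__)

__all__ = [
    "CellActivityMatrix",
    "GroupActivityRecord",
    "qc_filter",
    "normalize_cells",
    "top_n_genes",
    "per_cell_ora",
    "build_activity_matrix",
    "group_activity_test",
    "pseudo_bulk",
]

DEFAULT_MIN_GENES = 200
DEFAULT_MAX_GENES = 6000
DEFAULT_TOP_N = 500
NORMALIZE_SCALE = 10_000.0


@dataclass
class CellActivityMatrix:
    """Cells x categories activity scores (-log10 raw per-cell ORA p)."""

    activity: pd.DataFrame  # cells x categories, >= 0
    p_raw: pd.DataFrame  # same shape, raw per-cell p-values
    cell_meta: pd.DataFrame  # indexed by cell id
    tested_categories: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if (self.activity.to_numpy() < 0).any():
            raise ValidationError("activity scores must be >= 0")
        if self.activity.shape != self.p_raw.shape:
            raise ValidationError("activity and p_raw shapes differ")
        if not self.activity.index.equals(self.p_raw.index):
            raise ValidationError("activity and p_raw cell indices differ")
        missing = [c for c in self.activity.index if c not in self.cell_meta.index]
        if missing:
            raise ValidationError(f"cell metadata missing for {missing[0]!r}")


@dataclass(frozen=True)
class GroupActivityRecord:
    """One (category, group) one-vs-rest activity comparison."""

    category: str
    group: str
    direction: str  # more_active | less_active
    p_raw: float
    p_adj: float


def qc_filter(
    m: ExpressionMatrix,
    min_genes: int = DEFAULT_MIN_GENES,
    max_genes: int = DEFAULT_MAX_GENES,
    max_total: float = float("inf"),
) -> ExpressionMatrix:
    """Remove cells failing quality controls (damaged cells, doublets).

    Keeps cells whose detected-gene count lies in [min_genes, max_genes] and
    whose total counts are <= max_total; genes detected in no remaining cell
    are dropped.  Removal counts are logged per criterion.
    """
    if m.mode != "counts":
        raise ValidationError("qc_filter requires a counts matrix")
    arr = m.values.to_numpy()
    detected = (arr > 0).sum(axis=0)
    totals = arr.sum(axis=0)
    too_few = detected < min_genes
    too_many = detected > max_genes
    too_big = totals > max_total
    keep = ~(too_few | too_many | too_big)
    log.info(
        "qc_filter: removed %d cell(s) with < %d genes, %d with > %d genes, "
        "%d with total > %g",
        int(too_few.sum()), min_genes, int(too_many.sum()), max_genes,
        int(too_big.sum()), max_total,
    )
    if not keep.any():
        raise ComputationError("no cell survives quality filtering")
    cols = [c for c, k in zip(m.columns, keep) if k]
    sub = m.values[cols]
    gene_keep = (sub.to_numpy() > 0).any(axis=1)
    dropped_genes = int((~gene_keep).sum())
    if dropped_genes:
        log.info("qc_filter: dropped %d gene(s) detected in no remaining cell", dropped_genes)
    return ExpressionMatrix(
        sub.loc[gene_keep], m.column_meta.loc[cols], mode="counts"
    )


def normalize_cells(m: ExpressionMatrix, scale: float = NORMALIZE_SCALE) -> ExpressionMatrix:
    """Depth-normalize each cell to ``scale`` total counts, then log(1 + x).

    Counts-per-10k by default (``scale=1e6`` gives CPM).  A zero-total cell
    is an error — it should have been removed by QC.
    """
    if m.mode != "counts":
        raise ValidationError("normalize_cells requires a counts matrix")
    arr = m.values.to_numpy(dtype=float)
    totals = arr.sum(axis=0)
    if (totals == 0).any():
        bad = m.columns[int(np.flatnonzero(totals == 0)[0])]
        raise ValidationError(f"cell {bad!r} has zero total counts; run qc_filter first")
    normed = np.log1p(arr / totals * scale)
    return ExpressionMatrix(
        pd.DataFrame(normed, index=m.genes, columns=m.columns),
        m.column_meta,
        mode="normalized",
    )


def top_n_genes(m_norm: ExpressionMatrix, n: int = DEFAULT_TOP_N) -> dict[str, frozenset[str]]:
    """Per cell, the n most highly expressed (detected) genes.

    Ties at the boundary break lexicographically by gene token.  Cells with
    fewer than n detected genes contribute all their detected genes (the
    shortfall is logged).
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    genes = np.asarray(m_norm.genes)
    arr = m_norm.values.to_numpy(dtype=float)
    gene_order = np.argsort(genes, kind="stable")
    out: dict[str, frozenset[str]] = {}
    short = 0
    for ci, cell in enumerate(m_norm.columns):
        vals = arr[:, ci]
        # sort by descending value, then gene token ascending
        order = gene_order[np.argsort(-vals[gene_order], kind="stable")]
        detected = vals[order] > 0
        chosen = order[detected][:n]
        if len(chosen) < n:
            short += 1
        out[cell] = frozenset(genes[chosen])
    if short:
        log.info("top_n_genes: %d cell(s) with fewer than %d detected genes", short, n)
    return out


def per_cell_ora(
    top: dict[str, frozenset[str]],
    coll: GeneSetCollection,
    reference: set[str],
    min_size: int = 3,
    max_size: int = 700,
) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Enrichment-sided hypergeometric test of every cell's top-gene set.

    The reference must be the gene universe of the filtered matrix; the
    category filter (members-in-reference within [min_size, max_size]) is
    identical across cells.  Returns (activity, p_raw, tested category
    names); activity = -log10 p_raw.
    """
    ref = sorted(reference)
    ref_index = {g: i for i, g in enumerate(ref)}
    N = len(ref)
    cells = list(top)
    for cell in cells:
        extra = top[cell] - reference
        if extra:
            raise ValidationError(
                f"cell {cell!r}: top gene {sorted(extra)[0]} not in the reference"
            )
    tested: list[str] = []
    cat_cols: list[np.ndarray] = []
    Ks: list[int] = []
    for gs in coll:
        members = gs.members & reference
        if not (min_size <= len(members) <= max_size):
            continue
        col = np.zeros(N, dtype=np.int8)
        col[[ref_index[g] for g in members]] = 1
        tested.append(gs.name)
        cat_cols.append(col)
        Ks.append(len(members))
    if not tested:
        raise ComputationError("no category survives the size filter")
    C = np.column_stack(cat_cols)  # genes x categories
    T = np.zeros((len(cells), N), dtype=np.int8)
    for i, cell in enumerate(cells):
        T[i, [ref_index[g] for g in top[cell]]] = 1
    hits = T.astype(np.int32) @ C.astype(np.int32)  # cells x categories
    n_per_cell = T.sum(axis=1).astype(np.int64)
    K = np.asarray(Ks, dtype=np.int64)
    p = stats.hypergeom.sf(hits - 1, N, K[None, :], n_per_cell[:, None])
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    p_df = pd.DataFrame(p, index=cells, columns=tested)
    activity = pd.DataFrame(-np.log10(p), index=cells, columns=tested)
    return activity, p_df, tested


def build_activity_matrix(
    m_norm: ExpressionMatrix,
    coll: GeneSetCollection,
    n: int = DEFAULT_TOP_N,
    min_size: int = 3,
    max_size: int = 700,
) -> CellActivityMatrix:
    """Convenience wrapper: top-N selection + per-cell ORA on one matrix."""
    top = top_n_genes(m_norm, n)
    activity, p_raw, tested = per_cell_ora(
        top, coll, set(m_norm.genes), min_size=min_size, max_size=max_size
    )
    return CellActivityMatrix(
        activity=activity, p_raw=p_raw, cell_meta=m_norm.column_meta,
        tested_categories=tested,
    )


def group_activity_test(
    a: CellActivityMatrix,
    grouping: str = "group",
    adjust: str = "benjamini_hochberg",
    min_cells: int = 3,
) -> list[GroupActivityRecord]:
    """One-vs-rest rank-sum test of category activity per group.

    For each tested category and each group with >= min_cells cells, the
    group's activity scores are compared against all other cells (two-sided
    rank-sum); direction follows the sign of the rank statistic.  BH across
    all (category, group) pairs.
    """
    if grouping not in a.cell_meta.columns:
        raise ValidationError(f"cell metadata has no column {grouping!r}")
    labels = a.cell_meta.loc[a.activity.index, grouping]
    if labels.isna().any():
        bad = a.activity.index[labels.isna()][0]
        raise ValidationError(f"cell {bad!r} has no {grouping!r} label")
    groups = sorted(labels.unique())
    usable = [g for g in groups if (labels == g).sum() >= min_cells]
    for g in set(groups) - set(usable):
        log.warning("group %r excluded: fewer than %d cells", g, min_cells)
    if len(usable) < 2:
        raise ValidationError("need at least 2 groups with enough cells")
    rows: list[tuple[str, str, str, float]] = []
    act = a.activity
    for cat in act.columns:
        col = act[cat].to_numpy()
        for g in usable:
            mask = (labels == g).to_numpy()
            res = stats.ranksums(col[mask], col[~mask])
            direction = "more_active" if res.statistic >= 0 else "less_active"
            rows.append((cat, g, direction, float(res.pvalue)))
    p_adj = adjust_pvalues([r[3] for r in rows], method=adjust)
    return [
        GroupActivityRecord(category=c, group=g, direction=d, p_raw=p, p_adj=max(ap, p))
        for (c, g, d, p), ap in zip(rows, p_adj)
    ]


def pseudo_bulk(m: ExpressionMatrix, sample_key: str = "sample") -> ExpressionMatrix:
    """Sum counts over the cells of each sample into bulk-like columns.

    Total counts are conserved exactly; every cell must carry a sample label.
    """
    if m.mode != "counts":
        raise ValidationError("pseudo_bulk requires a counts matrix")
    if sample_key not in m.column_meta.columns:
        raise ValidationError(f"cell metadata has no column {sample_key!r}")
    labels = m.column_meta[sample_key]
    if labels.isna().any():
        bad = labels.index[labels.isna()][0]
        raise ValidationError(f"cell {bad!r} has no {sample_key!r} label")
    summed = m.values.T.groupby(labels, sort=True).sum().T
    meta = pd.DataFrame(index=summed.columns)
    meta[sample_key] = summed.columns
    return ExpressionMatrix(summed, meta, mode="counts")
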