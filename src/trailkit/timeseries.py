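"""Time-resolved expression analysis.

Genes are scored by their aggregated expression change over consecutive
time-points, filtered to the strongest changers, clustered into groups with
similar time courses (seeded k-medoids under a z-normalized Euclidean or
1 - Pearson distance), and each cluster is tested by ORA for the molecular
functions it controls.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .enrichment import OraInput, run_enrichment
from .types import (
    ComputationError,
    EnrichmentRecord,
    GeneSetCollection,
    ScoreList,
    ValidationError,
    gene_id,
)

log = logging.getLogger(__name__)

__all__ = [
    "TimeCourseSet",
    "GeneCluster",
    "change_score",
    "filter_changing",
    "cluster_timecourses",
    "cluster_ora",
]


class TimeCourseSet:
    """Genes x time-points matrix with strictly increasing time-points."""

    def __init__(self, values: pd.DataFrame, timepoints: np.ndarray | list[float]) -> None:
        tp = np.asarray(timepoints, dtype=float)
        if tp.ndim != 1 or len(tp) < 3:
            raise ValidationError("need at least 3 time-points")
        if not np.all(np.diff(tp) > 0):
            raise ValidationError("time-points must be strictly increasing")
        if values.shape[1] != len(tp):
            raise ValidationError(
                f"matrix has {values.shape[1]} columns but {len(tp)} time-points"
            )
        values = values.copy()
        values.index = [gene_id(g) for g in values.index]
        if values.index.has_duplicates:
            dup = values.index[values.index.duplicated()][0]
            raise ValidationError(f"duplicate gene: {dup}")
        arr = values.to_numpy(dtype=float)
        if arr.size and not np.all(np.isfinite(arr)):
            raise ValidationError("time-course values must be finite")
        self.values = values
        self.timepoints = tp

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    def __len__(self) -> int:
        return len(self.values)

    def subset(self, genes: list[str]) -> "TimeCourseSet":
        return TimeCourseSet(self.values.loc[genes], self.timepoints)


@dataclass(frozen=True)
class GeneCluster:
    """One cluster of genes with similar time courses."""

    label: int
    members: frozenset[str]
    centroid: np.ndarray  # mean course over members
    medoid: str

    def __post_init__(self) -> None:
        if not self.members:
            raise ValidationError("empty cluster")


def change_score(t: TimeCourseSet) -> ScoreList:
    """Aggregated expression change: sum of |x_{t+1} - x_t| per gene."""
    arr = t.values.to_numpy(dtype=float)
    scores = np.abs(np.diff(arr, axis=1)).sum(axis=1)
    return ScoreList(zip(t.genes, scores), normalize=False).sorted_descending()


def filter_changing(t: TimeCourseSet, s: ScoreList, rule: str, value: float) -> TimeCourseSet:
    """Restrict to genes with the strongest changes.

    ``threshold``: keep genes with change score >= v.  ``top_fraction``:
    keep the ceil(f * n) genes with the highest change scores (descending
    order, gene tie-break).
    """
    ordered = s.sorted_descending()
    if rule == "threshold":
        if value < 0:
            raise ValidationError("threshold must be >= 0")
        keep = [g for g, v in ordered if v >= value]
    elif rule == "top_fraction":
        f = float(value)
        if not (0 < f <= 1):
            raise ValidationError("top_fraction must lie in (0, 1]")
        n_keep = int(np.ceil(f * len(ordered)))
        keep = ordered.genes[:n_keep]
    else:
        raise ValidationError(f"unknown filter rule: {rule}")
    keep = [g for g in t.genes if g in set(keep)]  # preserve matrix order
    if not keep:
        raise ComputationError("no gene passes the change filter")
    return t.subset(keep)


def _distance_matrix(arr: np.ndarray, distance: str) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise distances and a flag vector of constant (degenerate) rows."""
    constant = arr.std(axis=1) == 0
    if distance == "euclidean_z":
        sd = arr.std(axis=1, keepdims=True)
        z = (arr - arr.mean(axis=1, keepdims=True)) / np.where(sd > 0, sd, 1.0)
        z[constant] = 0.0  # constant course -> flat zero profile
        diff = z[:, None, :] - z[None, :, :]
        d = np.sqrt((diff**2).sum(axis=2))
    elif distance == "one_minus_pearson":
        sd = arr.std(axis=1, keepdims=True)
        c = (arr - arr.mean(axis=1, keepdims=True)) / np.where(sd > 0, sd, 1.0)
        corr = c @ c.T / arr.shape[1]
        # convention: a constant course has zero correlation with everything
        corr[constant, :] = 0.0
        corr[:, constant] = 0.0
        np.fill_diagonal(corr, 1.0)
        d = 1.0 - corr
    else:
        raise ValidationError(f"unknown distance: {distance}")
    np.fill_diagonal(d, 0.0)
    return d, constant


def cluster_timecourses(
    t: TimeCourseSet,
    k: int,
    distance: str = "euclidean_z",
    seed: int = 42,
    max_iter: int = 100,
) -> list[GeneCluster]:
    """Seeded k-medoids partition of the time courses.

    Initial medoids are k distinct random genes; assignment goes to the
    nearest medoid (lowest index on ties), each medoid is then replaced by
    the member minimizing the within-cluster distance sum (gene token
    tie-break).  The objective (sum of distances to medoids) is
    non-increasing across iterations; convergence when the medoid set is
    fixed.  Constant courses under 1 - Pearson are flagged in the log.
    """
    n = len(t)
    if k < 2:
        raise ValidationError("k must be >= 2")
    if k > n:
        raise ValidationError(f"k={k} exceeds the number of genes ({n})")
    arr = t.values.to_numpy(dtype=float)
    genes = t.genes
    d, constant = _distance_matrix(arr, distance)
    if distance == "one_minus_pearson" and constant.any():
        log.warning(
            "%d constant course(s) under one_minus_pearson assigned by the "
            "zero-correlation convention", int(constant.sum()),
        )
    rng = np.random.default_rng(seed)
    medoids = np.sort(rng.choice(n, size=k, replace=False))
    prev_objective = np.inf
    for _ in range(max_iter):
        assign = np.argmin(d[:, medoids], axis=1)  # lowest medoid index on ties
        objective = float(d[np.arange(n), medoids[assign]].sum())
        if objective > prev_objective + 1e-9:
            raise ComputationError("k-medoids objective increased")  # pragma: no cover
        prev_objective = objective
        new_medoids = medoids.copy()
        for ci in range(k):
            members = np.flatnonzero(assign == ci)
            if len(members) == 0:
                continue  # keep old medoid; its point re-joins next assignment
            sums = d[np.ix_(members, members)].sum(axis=0)
            best = min(range(len(members)), key=lambda i: (sums[i], genes[members[i]]))
            new_medoids[ci] = members[best]
        if np.array_equal(np.sort(new_medoids), np.sort(medoids)):
            break
        medoids = new_medoids
    assign = np.argmin(d[:, medoids], axis=1)
    clusters: list[GeneCluster] = []
    for ci in range(k):
        members = np.flatnonzero(assign == ci)
        if len(members) == 0:
            continue
        member_genes = frozenset(genes[i] for i in members)
        clusters.append(
            GeneCluster(
                label=ci,
                members=member_genes,
                centroid=arr[members].mean(axis=0),
                medoid=genes[medoids[ci]],
            )
        )
    total = sum(len(c.members) for c in clusters)
    if total != n:
        raise ComputationError("clusters do not partition the gene set")  # pragma: no cover
    return clusters


def cluster_ora(
    clusters: list[GeneCluster],
    coll: GeneSetCollection,
    reference: set[str],
    adjust: str = "benjamini_hochberg",
    min_size: int = 3,
    max_size: int = 700,
) -> dict[int, list[EnrichmentRecord]]:
    """Per-cluster ORA of cluster members against the reference universe."""
    clustered = set().union(*(c.members for c in clusters))
    if not clustered <= reference:
        missing = sorted(clustered - reference)[0]
        raise ValidationError(f"clustered gene {missing} not in the reference")
    out: dict[int, list[EnrichmentRecord]] = {}
    for c in clusters:
        oin = OraInput.from_sets(c.members, reference)
        records, _ = run_enrichment(
            oin, coll, "ora", min_size=min_size, max_size=max_size, adjust=adjust
        )
        out[c.label] = records
    return out
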