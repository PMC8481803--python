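"""Seeded synthetic-data generators with known ground truth.

Every pipeline in the toolkit is testable without external downloads: these
generators produce bulk two-group matrices with planted differentially
expressed genes, gene-set collections with one planted category among
decoys, directed networks with an injected deregulated path, a three-group
single-cell counts fixture shaped like a COVID-19 monocyte study (ARDS /
NonVent / Healthy cell groups, a group-specific gene program, deliberately
failing-QC cells), regulator-target tables with one causal regulator, and
time-course sets with planted shape families.

All generators are driven by a dataclass spec whose ``seed`` fully
determines the output (identical spec -> byte-identical data); the returned
``truth`` dictionary names the planted structure so recovery tests can
check it.  Defaults encode the study conditions the methods are meant for:
10 + 10 bulk samples with an effect size of two standard deviations, 50
decoy gene sets, three cell groups of 100 cells, a causal regulator with
generating correlation 0.8.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .scoring import GroupAssignment
from .timeseries import TimeCourseSet
from .types import (
    DirectedGeneNetwork,
    ExpressionMatrix,
    GeneSet,
    GeneSetCollection,
    RtiTable,
    ValidationError,
)

__all__ = [
    "BulkSpec",
    "GenesetSpec",
    "NetworkSpec",
    "SingleCellSpec",
    "RtiSpec",
    "TimeCourseSpec",
    "make_bulk",
    "make_genesets",
    "make_network",
    "make_single_cell",
    "make_rti",
    "make_timecourses",
]


def _gene_names(n: int, prefix: str = "G") -> list[str]:
    width = max(4, len(str(n)))
    return [f"{prefix}{i:0{width}d}" for i in range(1, n + 1)]


@dataclass(frozen=True)
class BulkSpec:
    """Two-group bulk expression fixture with planted DE genes."""

    seed: int = 0
    n_genes: int = 1000
    n_per_group: tuple[int, int] = (10, 10)
    n_de: int = 25
    effect: float = 2.0  # shift in log2 units applied to group A
    sigma: float = 1.0  # log2-scale biological noise
    baseline_mean: float = 6.0
    baseline_sd: float = 1.5

    def __post_init__(self) -> None:
        if min(self.n_per_group) < 3:
            raise ValidationError("need at least 3 samples per group")
        if self.n_de > self.n_genes:
            raise ValidationError("more planted DE genes than genes")


def make_bulk(spec: BulkSpec) -> tuple[ExpressionMatrix, GroupAssignment, dict]:
    """Log-normal baseline intensities; planted genes shifted up in group A."""
    rng = np.random.default_rng(spec.seed)
    genes = _gene_names(spec.n_genes)
    na, nb = spec.n_per_group
    samples = [f"A{i:02d}" for i in range(1, na + 1)] + [
        f"B{i:02d}" for i in range(1, nb + 1)
    ]
    base = rng.normal(spec.baseline_mean, spec.baseline_sd, size=spec.n_genes)
    log2x = base[:, None] + rng.normal(0.0, spec.sigma, size=(spec.n_genes, na + nb))
    de_idx = rng.choice(spec.n_genes, size=spec.n_de, replace=False)
    log2x[de_idx, :na] += spec.effect
    values = pd.DataFrame(np.exp2(log2x), index=genes, columns=samples)
    meta = pd.DataFrame(
        {"group": ["A"] * na + ["B"] * nb}, index=samples
    )
    m = ExpressionMatrix(values, meta, mode="normalized")
    g = GroupAssignment({s: ("A" if s.startswith("A") else "B") for s in samples})
    truth = {"de_genes": sorted(genes[i] for i in de_idx), "effect": spec.effect}
    return m, g, truth


@dataclass(frozen=True)
class GenesetSpec:
    """Decoy gene sets plus one planted category around the true DE genes."""

    seed: int = 0
    n_decoys: int = 50
    size_range: tuple[int, int] = (10, 50)
    padding: int = 5  # random genes added to the planted set
    planted_name: str = "planted_program"


def make_genesets(
    spec: GenesetSpec, universe: list[str], truth: dict
) -> GeneSetCollection:
    """Uniform decoy sets over the universe; the planted set is the planted
    DE (or program) genes plus a little random padding."""
    rng = np.random.default_rng(spec.seed)
    planted_genes = truth.get("de_genes") or truth.get("program_genes")
    if not planted_genes:
        raise ValidationError("truth carries no planted gene list")
    uni = np.asarray(universe)
    pool = np.asarray(sorted(set(universe) - set(planted_genes)))
    pad = rng.choice(pool, size=min(spec.padding, len(pool)), replace=False)
    coll = GeneSetCollection()
    coll.add(
        GeneSet(
            name=spec.planted_name,
            description="planted category",
            members=frozenset(planted_genes) | frozenset(pad.tolist()),
        )
    )
    lo, hi = spec.size_range
    sizes = rng.integers(lo, hi + 1, size=spec.n_decoys)
    for i, size in enumerate(sizes, start=1):
        members = rng.choice(uni, size=int(size), replace=False)
        coll.add(
            GeneSet(
                name=f"decoy_{i:03d}",
                description="random decoy category",
                members=frozenset(members.tolist()),
            )
        )
    return coll


@dataclass(frozen=True)
class NetworkSpec:
    """Random DAG plus an injected causal path through top planted genes."""

    seed: int = 0
    n_nodes: int = 30
    edge_prob: float = 0.12
    path_len: int = 5


def make_network(
    spec: NetworkSpec, universe: list[str], truth: dict
) -> tuple[DirectedGeneNetwork, dict]:
    """Erdos-Renyi DAG on a topological order over a node sample from the
    universe, with a simple path injected through planted genes."""
    rng = np.random.default_rng(spec.seed)
    planted = list(truth.get("de_genes") or truth.get("program_genes") or [])
    if len(planted) < spec.path_len:
        raise ValidationError("not enough planted genes for the injected path")
    path_nodes = planted[: spec.path_len]
    others_pool = sorted(set(universe) - set(path_nodes))
    n_other = max(0, spec.n_nodes - spec.path_len)
    others = rng.choice(np.asarray(others_pool), size=n_other, replace=False).tolist()
    nodes = path_nodes + others
    order = rng.permutation(len(nodes))  # topological order -> acyclic
    # the injected path must respect the topological order: give the path
    # nodes their own ranks sorted in path order
    path_ranks = np.sort(order[: len(path_nodes)])
    order[: len(path_nodes)] = path_ranks
    rank = {nodes[i]: order[i] for i in range(len(nodes))}
    edges: list[tuple[str, str]] = []
    for i, u in enumerate(nodes):
        for v in nodes[i + 1:]:
            if rng.random() < spec.edge_prob:
                edges.append((u, v) if rank[u] < rank[v] else (v, u))
    edges.extend(zip(path_nodes[:-1], path_nodes[1:]))
    # drop any edge that would run against the injected path direction
    path_pairs = set(zip(path_nodes[:-1], path_nodes[1:]))
    edges = [e for e in edges if (e[1], e[0]) not in path_pairs]
    net = DirectedGeneNetwork.from_edges(edges)
    return net, {**truth, "path": path_nodes}


@dataclass(frozen=True)
class SingleCellSpec:
    """Three-group single-cell counts fixture with a planted gene program.

    Groups emulate a severity contrast (ARDS / NonVent / Healthy); the
    program genes are up-shifted in one group's cells.  ``n_fail_low`` cells
    are near-empty (fail the min-genes QC rule) and ``n_fail_high`` carry
    doublet-like total counts (fail the max-total rule).
    """

    seed: int = 0
    n_genes: int = 800
    cells_per_group: tuple[int, int, int] = (100, 100, 100)
    group_names: tuple[str, str, str] = ("ARDS", "NonVent", "Healthy")
    samples_per_group: int = 2
    program_size: int = 50
    program_group: str = "ARDS"
    program_log2fc: float = 2.0
    mean_depth: float = 2000.0
    dispersion: float = 0.5  # NB: var = mu + dispersion * mu^2
    n_fail_low: int = 3
    n_fail_high: int = 3
    qc_min_genes: int = 50
    qc_max_total: float = 40_000.0


def make_single_cell(
    spec: SingleCellSpec,
) -> tuple[ExpressionMatrix, pd.DataFrame, dict]:
    """Negative-binomial counts with a group-specific planted program."""
    rng = np.random.default_rng(spec.seed)
    genes = _gene_names(spec.n_genes)
    program_idx = rng.choice(spec.n_genes, size=spec.program_size, replace=False)
    base_log = rng.normal(0.0, 1.0, size=spec.n_genes)
    rel = np.exp(base_log)

    cells: list[str] = []
    groups: list[str] = []
    samples: list[str] = []
    cols: list[np.ndarray] = []
    r = 1.0 / spec.dispersion  # NB shape parameter
    for gname, n_cells in zip(spec.group_names, spec.cells_per_group):
        for ci in range(n_cells):
            rel_c = rel.copy()
            if gname == spec.program_group:
                rel_c[program_idx] *= 2.0**spec.program_log2fc
            frac = rel_c / rel_c.sum()
            depth = rng.lognormal(np.log(spec.mean_depth), 0.25)
            mu = frac * depth
            p = r / (r + mu)
            counts = rng.negative_binomial(r, p)
            cells.append(f"{gname}_c{ci + 1:04d}")
            groups.append(gname)
            samples.append(f"{gname}_s{(ci % spec.samples_per_group) + 1}")
            cols.append(counts)
    mat = np.column_stack(cols).astype(float)

    # planted QC failures: near-empty cells and doublet-like cells
    fail_low = [f"faillow_c{i + 1:02d}" for i in range(spec.n_fail_low)]
    for name in fail_low:
        col = np.zeros(spec.n_genes)
        on = rng.choice(spec.n_genes, size=max(1, spec.qc_min_genes // 5), replace=False)
        col[on] = 1.0
        mat = np.column_stack([mat, col])
        cells.append(name)
        groups.append(spec.group_names[0])
        samples.append(f"{spec.group_names[0]}_s1")
    fail_high = [f"failhigh_c{i + 1:02d}" for i in range(spec.n_fail_high)]
    for name in fail_high:
        frac = rel / rel.sum()
        mu = frac * (spec.qc_max_total * 3.0)
        p = r / (r + mu)
        col = rng.negative_binomial(r, p).astype(float)
        if col.sum() <= spec.qc_max_total:  # force past the threshold
            col = col * np.ceil((spec.qc_max_total + 1) / max(col.sum(), 1.0))
        mat = np.column_stack([mat, col])
        cells.append(name)
        groups.append(spec.group_names[0])
        samples.append(f"{spec.group_names[0]}_s1")

    meta = pd.DataFrame({"group": groups, "sample": samples}, index=cells)
    m = ExpressionMatrix(
        pd.DataFrame(mat, index=genes, columns=cells), meta, mode="counts"
    )
    truth = {
        "program_genes": sorted(genes[i] for i in program_idx),
        "program_group": spec.program_group,
        "failing_cells": sorted(fail_low + fail_high),
        "qc_min_genes": spec.qc_min_genes,
        "qc_max_total": spec.qc_max_total,
    }
    return m, meta, truth


@dataclass(frozen=True)
class RtiSpec:
    """Regulator-target table with one causal activator among decoys."""

    seed: int = 0
    n_regulators: int = 20
    targets_per_regulator: int = 80
    causal_corr: float = 0.8  # generating correlation with the target mean profile
    causal_name: str = "REGCAUSAL"


def make_rti(
    spec: RtiSpec, m: ExpressionMatrix, truth: dict
) -> tuple[RtiTable, ExpressionMatrix, dict]:
    """Build an RTI table and append regulator expression rows to the matrix.

    The causal regulator targets the planted DE genes and its expression row
    is generated to correlate positively (generating correlation
    ``causal_corr``) with the standardized mean profile of those targets;
    decoy regulators draw targets uniformly and express independent noise.
    """
    rng = np.random.default_rng(spec.seed)
    planted = list(truth.get("de_genes") or truth.get("program_genes") or [])
    if len(planted) < 2:
        raise ValidationError("truth carries no planted gene list")
    universe = np.asarray(m.genes)
    pairs: list[tuple[str, str]] = []
    causal = spec.causal_name
    for t in planted:
        pairs.append((causal, t))
    decoys = [f"REGDECOY{i:02d}" for i in range(1, spec.n_regulators)]
    for d in decoys:
        targets = rng.choice(universe, size=spec.targets_per_regulator, replace=False)
        pairs.extend((d, t) for t in targets.tolist())
    rti = RtiTable.from_pairs(pairs)

    n_samples = m.shape[1]
    target_profile = m.values.loc[planted].to_numpy(dtype=float).mean(axis=0)
    z = (target_profile - target_profile.mean()) / max(target_profile.std(), 1e-12)
    c = spec.causal_corr
    causal_row = c * z + np.sqrt(1 - c**2) * rng.normal(size=n_samples)
    rows = {causal: causal_row - causal_row.min() + 1.0}
    for d in decoys:
        noise = rng.normal(size=n_samples)
        rows[d] = noise - noise.min() + 1.0
    reg_df = pd.DataFrame(rows, index=m.columns).T
    values = pd.concat([m.values, reg_df])
    m_aug = ExpressionMatrix(values, m.column_meta, mode=m.mode)
    return rti, m_aug, {**truth, "causal_regulator": causal}


@dataclass(frozen=True)
class TimeCourseSpec:
    """Planted shape families (up, down, transient peak) plus flat noise."""

    seed: int = 0
    n_per_shape: int = 20
    n_flat: int = 40
    timepoints: tuple[float, ...] = (0.0, 2.0, 4.0, 8.0, 12.0, 24.0)
    amplitude: float = 2.0
    noise_sd: float = 0.3


def make_timecourses(spec: TimeCourseSpec) -> tuple[TimeCourseSet, dict]:
    rng = np.random.default_rng(spec.seed)
    tp = np.asarray(spec.timepoints, dtype=float)
    frac = (tp - tp[0]) / (tp[-1] - tp[0])
    shapes = {
        "up": spec.amplitude * frac,
        "down": -spec.amplitude * frac,
        "peak": spec.amplitude * np.sin(np.pi * frac),
    }
    rows: list[np.ndarray] = []
    labels: dict[str, str] = {}
    names: list[str] = []
    i = 0
    for shape, template in shapes.items():
        for _ in range(spec.n_per_shape):
            i += 1
            name = f"G{i:04d}"
            rows.append(template + rng.normal(0.0, spec.noise_sd, size=len(tp)))
            names.append(name)
            labels[name] = shape
    for _ in range(spec.n_flat):
        i += 1
        name = f"G{i:04d}"
        rows.append(rng.normal(0.0, spec.noise_sd, size=len(tp)))
        names.append(name)
        labels[name] = "flat"
    ts = TimeCourseSet(pd.DataFrame(np.vstack(rows), index=names, columns=tp), tp)
    return ts, {"shape_labels": labels, "noise_sd": spec.noise_sd}
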