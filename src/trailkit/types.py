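"""Core domain types shared across the toolkit.

The central currencies are :class:`ScoreList` (an ordered list of per-gene
deregulation scores), :class:`GeneSetCollection` (named biological
categories), :class:`ExpressionMatrix` (genes x samples/cells), and
:class:`DirectedGeneNetwork` (substrate for path search).  Gene identifiers
are opaque, case-insensitive tokens stored upper-cased; no organism-specific
identifier mapping is performed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "TrailkitError",
    "InputError",
    "ValidationError",
    "ComputationError",
    "gene_id",
    "ScoreList",
    "GeneSet",
    "GeneSetCollection",
    "ExpressionMatrix",
    "DirectedGeneNetwork",
    "RtiTable",
    "EnrichmentRecord",
]


class TrailkitError(Exception):
    """Base class for all toolkit errors."""


class InputError(TrailkitError):
    """An input file is missing, unreadable, or malformed."""


class ValidationError(TrailkitError):
    """Inputs are readable but violate a documented contract."""


class ComputationError(TrailkitError):
    """A computation cannot be carried out on otherwise valid inputs."""


def gene_id(token: str) -> str:
    """Normalize a gene token: strip whitespace, upper-case, validate.

    Raises :class:`ValidationError` for empty tokens or tokens containing
    tab/newline characters (which would corrupt the tab-separated formats).
    """
    if not isinstance(token, str):
        token = str(token)
    stripped = token.strip()
    if not stripped:
        raise ValidationError("empty gene identifier")
    if "\t" in stripped or "\n" in stripped or "\r" in stripped:
        raise ValidationError(f"gene identifier contains tab/newline: {token!r}")
    return stripped.upper()


class ScoreList:
    """Ordered (gene, score) pairs: the universal currency between modules.

    Genes are unique and scores finite.  Order is meaningful; use
    :meth:`sorted_descending` to obtain the canonical descending order with
    lexicographic gene tie-break (bit-reproducible).
    """

    __slots__ = ("genes", "scores")

    def __init__(
        self,
        entries: Iterable[tuple[str, float]],
        *,
        normalize: bool = True,
    ) -> None:
        genes: list[str] = []
        scores: list[float] = []
        for g, s in entries:
            genes.append(gene_id(g) if normalize else g)
            scores.append(float(s))
        arr = np.asarray(scores, dtype=float)
        if len(set(genes)) != len(genes):
            seen: set[str] = set()
            dup = next(g for g in genes if g in seen or seen.add(g))  # type: ignore[func-returns-value]
            raise ValidationError(f"duplicate gene in score list: {dup}")
        if arr.size and not np.all(np.isfinite(arr)):
            bad = genes[int(np.flatnonzero(~np.isfinite(arr))[0])]
            raise ValidationError(f"non-finite score for gene {bad}")
        self.genes: list[str] = genes
        self.scores: np.ndarray = arr

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self) -> Iterator[tuple[str, float]]:
        return zip(self.genes, self.scores.tolist())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ScoreList):
            return NotImplemented
        return self.genes == other.genes and np.array_equal(self.scores, other.scores)

    def __repr__(self) -> str:
        return f"ScoreList(n={len(self)})"

    def score_of(self, gene: str) -> float:
        try:
            return float(self.scores[self.genes.index(gene_id(gene))])
        except ValueError:
            raise KeyError(gene) from None

    def as_series(self) -> pd.Series:
        return pd.Series(self.scores, index=self.genes, name="score")

    def sorted_descending(self) -> "ScoreList":
        """Stable sort: descending score, ties broken by gene token."""
        order = sorted(range(len(self)), key=lambda i: (-self.scores[i], self.genes[i]))
        return ScoreList(
            [(self.genes[i], self.scores[i]) for i in order], normalize=False
        )

    def head(self, n: int) -> "ScoreList":
        return ScoreList(list(self)[:n], normalize=False)

    @classmethod
    def from_series(cls, s: pd.Series) -> "ScoreList":
        return cls(zip(s.index.astype(str), s.to_numpy(dtype=float)))


@dataclass(frozen=True)
class GeneSet:
    """A named biological category (e.g., a GO term or KEGG pathway)."""

    name: str
    description: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.name:
            raise ValidationError("gene set name must be non-empty")
        if not self.members:
            raise ValidationError(f"gene set {self.name!r} has no members")
        object.__setattr__(
            self, "members", frozenset(gene_id(m) for m in self.members)
        )

    def __len__(self) -> int:
        return len(self.members)


class GeneSetCollection:
    """An ordered, name-keyed collection of :class:`GeneSet` objects."""

    def __init__(self, sets: Iterable[GeneSet] = ()) -> None:
        self._sets: dict[str, GeneSet] = {}
        for gs in sets:
            self.add(gs)

    def add(self, gs: GeneSet) -> None:
        if gs.name in self._sets:
            raise ValidationError(f"duplicate gene set name: {gs.name}")
        self._sets[gs.name] = gs

    def __len__(self) -> int:
        return len(self._sets)

    def __iter__(self) -> Iterator[GeneSet]:
        return iter(self._sets.values())

    def __contains__(self, name: str) -> bool:
        return name in self._sets

    def __getitem__(self, name: str) -> GeneSet:
        return self._sets[name]

    @property
    def names(self) -> list[str]:
        return list(self._sets)


class ExpressionMatrix:
    """A genes x columns expression matrix with per-column metadata.

    ``values`` is a dense :class:`pandas.DataFrame` (rows = genes, columns =
    sample/cell identifiers).  ``column_meta`` is indexed by column id and may
    carry group labels, time-points, sample ids, cluster labels, or embedding
    coordinates.  ``mode`` is ``"counts"`` (non-negative) or ``"normalized"``.
    """

    def __init__(
        self,
        values: pd.DataFrame,
        column_meta: pd.DataFrame | None = None,
        mode: str = "normalized",
    ) -> None:
        if mode not in ("counts", "normalized"):
            raise ValidationError(f"unknown matrix mode: {mode}")
        values = values.copy()
        values.index = [gene_id(g) for g in values.index]
        values.columns = [str(c) for c in values.columns]
        if values.index.has_duplicates:
            dup = values.index[values.index.duplicated()][0]
            raise ValidationError(f"duplicate gene row: {dup}")
        if len(set(values.columns)) != len(values.columns):
            raise ValidationError("duplicate column identifiers")
        arr = values.to_numpy(dtype=float)
        if arr.size and not np.all(np.isfinite(arr)):
            raise ValidationError("expression values must be finite")
        if mode == "counts" and arr.size and arr.min() < 0:
            r, c = np.unravel_index(int(np.argmin(arr)), arr.shape)
            raise ValidationError(
                f"negative count at gene {values.index[r]}, column {values.columns[c]}"
            )
        if column_meta is None:
            column_meta = pd.DataFrame(index=values.columns)
        else:
            column_meta = column_meta.copy()
            column_meta.index = column_meta.index.astype(str)
            missing = [c for c in values.columns if c not in column_meta.index]
            if missing:
                raise ValidationError(
                    f"column metadata missing for {len(missing)} columns "
                    f"(first: {missing[0]})"
                )
            column_meta = column_meta.loc[list(values.columns)]
        self.values = values
        self.column_meta = column_meta
        self.mode = mode

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def columns(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_columns(self, columns: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values[list(columns)], self.column_meta.loc[list(columns)], self.mode
        )

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values.loc[list(genes)], self.column_meta, self.mode
        )


class DirectedGeneNetwork:
    """A directed gene-gene network (no self-loops, deduplicated edges)."""

    def __init__(self, graph: nx.DiGraph, dropped_self_loops: int = 0) -> None:
        loops = list(nx.selfloop_edges(graph))
        if loops:
            raise ValidationError(f"network contains self-loop: {loops[0]}")
        self.graph = graph
        self.dropped_self_loops = dropped_self_loops

    @classmethod
    def from_edges(cls, edges: Iterable[tuple[str, str]]) -> "DirectedGeneNetwork":
        """Build from (source, target) pairs; duplicates collapsed, self-loops
        dropped (count recorded on ``dropped_self_loops``)."""
        g = nx.DiGraph()
        dropped = 0
        for s, t in edges:
            s, t = gene_id(s), gene_id(t)
            if s == t:
                dropped += 1
                continue
            g.add_edge(s, t)
        return cls(g, dropped_self_loops=dropped)

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[tuple[str, str]]:
        return set(self.graph.edges)

    def __len__(self) -> int:
        return self.graph.number_of_nodes()


@dataclass(frozen=True)
class RtiTable:
    """Experimentally validated regulator-target interactions (RTIs)."""

    interactions: frozenset[tuple[str, str]]
    self_regulations: frozenset[tuple[str, str]] = field(default_factory=frozenset)

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "RtiTable":
        inter: set[tuple[str, str]] = set()
        selfs: set[tuple[str, str]] = set()
        for r, t in pairs:
            r, t = gene_id(r), gene_id(t)
            inter.add((r, t))
            if r == t:
                selfs.add((r, t))
        return cls(frozenset(inter), frozenset(selfs))

    @property
    def regulators(self) -> set[str]:
        return {r for r, _ in self.interactions}

    def targets_of(self, regulator: str) -> set[str]:
        reg = gene_id(regulator)
        return {t for r, t in self.interactions if r == reg}

    def __len__(self) -> int:
        return len(self.interactions)


@dataclass
class EnrichmentRecord:
    """One category's enrichment test result."""

    category: str
    category_size: int
    hits: int
    statistic: float
    direction: str  # enriched | depleted | none
    p_raw: float
    p_adj: float
    hit_genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (0 <= self.hits <= self.category_size):
            raise ValidationError(
                f"{self.category}: hits {self.hits} outside [0, {self.category_size}]"
            )
        if not (0.0 <= self.p_raw <= 1.0):
            raise ValidationError(f"{self.category}: p_raw {self.p_raw} outside [0,1]")
        if not (self.p_raw <= self.p_adj + 1e-15 and self.p_adj <= 1.0):
            raise ValidationError(
                f"{self.category}: p_adj {self.p_adj} violates p_raw <= p_adj <= 1"
            )
        if self.direction not in ("enriched", "depleted", "none"):
            raise ValidationError(f"bad direction: {self.direction}")
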