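"""Readers and writers for the standard text formats the toolkit touches.

Formats: GMT gene-set collections (Broad 3+ column), dense expression TSV,
two-column score TSV, SIF / two-column edge lists, regulator-target tables,
Matrix Market sparse counts with gene/barcode index files, and the fixed
eight-column enrichment result table.  All text I/O is UTF-8 with a decimal
point (no locale handling).  Readers reject invariant violations with a
located error; the only silent repairs are the documented deduplication and
self-loop rules.
"""

from __future__ import annotations

import logging
import os
from typing import Iterable

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .types import (
    DirectedGeneNetwork,
    EnrichmentRecord,
    ExpressionMatrix,
    GeneSet,
    GeneSetCollection,
    InputError,
    RtiTable,
    ScoreList,
    ValidationError,
    gene_id,
)

log = logging.getLogger(__name__)

ENRICHMENT_COLUMNS = [
    "category",
    "category_size",
    "hits",
    "statistic",
    "direction",
    "p_raw",
    "p_adj",
    "hit_genes",
]


def _open_text(path: str):
    if not os.path.exists(path):
        raise InputError(f"input file not found: {path}")
    return open(path, encoding="utf-8")


def read_gmt(path: str) -> GeneSetCollection:
    """Read a Broad-style GMT file: name, description, members... per line.

    Duplicate member tokens within a line are collapsed after case
    normalization; a line with fewer than three fields is a parse error.
    """
    coll = GeneSetCollection()
    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise InputError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields, expected >= 3"
                )
            name, description = fields[0], fields[1]
            members = frozenset(gene_id(tok) for tok in fields[2:] if tok.strip())
            if not members:
                raise InputError(f"{path}:{lineno}: gene set {name!r} has no members")
            try:
                coll.add(GeneSet(name=name, description=description, members=members))
            except ValidationError as exc:
                raise InputError(f"{path}:{lineno}: {exc}") from exc
    return coll


def write_gmt(coll: GeneSetCollection, path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for gs in coll:
            members = "\t".join(sorted(gs.members))
            fh.write(f"{gs.name}\t{gs.description}\t{members}\n")


def read_expression_tsv(path: str, mode: str = "normalized") -> ExpressionMatrix:
    """Read a dense expression table (first row column ids, first column genes)."""
    with _open_text(path) as fh:
        try:
            df = pd.read_csv(fh, sep="\t", index_col=0, comment=None)
        except Exception as exc:  # noqa: BLE001 - surface as located input error
            raise InputError(f"{path}: cannot parse expression table: {exc}") from exc
    if df.shape[1] == 0:
        raise InputError(f"{path}: expression table has no sample columns")
    for col in df.columns:
        bad = df[col].map(lambda v: not isinstance(v, (int, float, np.number)))
        if bad.any():
            row = df.index[bad.to_numpy().nonzero()[0][0]]
            raise InputError(f"{path}: non-numeric value at gene {row}, column {col}")
    try:
        return ExpressionMatrix(df, mode=mode)
    except ValidationError as exc:
        raise InputError(f"{path}: {exc}") from exc


def write_expression_tsv(m: ExpressionMatrix, path: str) -> None:
    df = m.values.copy()
    df.index.name = "gene"
    df.to_csv(path, sep="\t", float_format="%.17g")


def read_metadata_tsv(path: str) -> pd.DataFrame:
    """Read a column-metadata table keyed by its first column (sample/cell id)."""
    with _open_text(path) as fh:
        df = pd.read_csv(fh, sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise InputError(f"{path}: duplicate metadata row for {dup!r}")
    return df


def read_scores_tsv(path: str) -> ScoreList:
    """Read a two-column gene/score table (header optional)."""
    entries: list[tuple[str, float]] = []
    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise InputError(
                    f"{path}:{lineno}: expected 2 tab-separated fields, got {len(fields)}"
                )
            if lineno == 1:
                try:
                    float(fields[1])
                except ValueError:
                    continue  # header row
            try:
                entries.append((fields[0], float(fields[1])))
            except ValueError as exc:
                raise InputError(f"{path}:{lineno}: non-numeric score {fields[1]!r}") from exc
    try:
        return ScoreList(entries)
    except ValidationError as exc:
        raise InputError(f"{path}: {exc}") from exc


def write_scores_tsv(s: ScoreList, path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene\tscore\n")
        for g, v in s:
            fh.write(f"{g}\t{v:.17g}\n")


def read_gene_list(path: str) -> set[str]:
    """Read a one-token-per-line gene list."""
    genes: set[str] = set()
    with _open_text(path) as fh:
        for raw in fh:
            tok = raw.strip()
            if tok:
                genes.add(gene_id(tok))
    return genes


def read_edge_list(path: str, dialect: str = "tsv2col") -> DirectedGeneNetwork:
    """Read a directed edge list.

    ``tsv2col``: "source<TAB>target" per line.  ``sif``: "source<TAB>relation
    <TAB>target".  Duplicate edges collapse; self-loops are dropped with a
    logged count (available as ``dropped_self_loops`` on the result).
    """
    if dialect not in ("tsv2col", "sif"):
        raise ValidationError(f"unknown edge-list dialect: {dialect}")
    arity = 2 if dialect == "tsv2col" else 3
    edges: list[tuple[str, str]] = []
    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != arity:
                raise InputError(
                    f"{path}:{lineno}: expected {arity} fields for {dialect}, "
                    f"got {len(fields)}"
                )
            if dialect == "tsv2col":
                edges.append((fields[0], fields[1]))
            else:
                edges.append((fields[0], fields[2]))
    net = DirectedGeneNetwork.from_edges(edges)
    if net.dropped_self_loops:
        log.info("%s: dropped %d self-loop edge(s)", path, net.dropped_self_loops)
    return net


def write_edge_list(net: DirectedGeneNetwork, path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for s, t in sorted(net.edges):
            fh.write(f"{s}\t{t}\n")


def read_rti_tsv(path: str) -> RtiTable:
    """Read a two-column regulator/target interaction table (header optional)."""
    pairs: list[tuple[str, str]] = []
    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise InputError(
                    f"{path}:{lineno}: expected 2 fields (regulator, target), "
                    f"got {len(fields)}"
                )
            if lineno == 1 and fields[0].lower() in ("regulator", "source"):
                continue
            pairs.append((fields[0], fields[1]))
    table = RtiTable.from_pairs(pairs)
    if table.self_regulations:
        log.info("%s: %d self-regulation pair(s) kept", path, len(table.self_regulations))
    return table


def write_rti_tsv(rti: RtiTable, path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("regulator\ttarget\n")
        for r, t in sorted(rti.interactions):
            fh.write(f"{r}\t{t}\n")


def write_enrichment_tsv(
    records: Iterable[EnrichmentRecord], path: str, adjust_method: str = "benjamini_hochberg"
) -> None:
    """Write the fixed eight-column enrichment table.

    The shared adjustment method is recorded in a header comment; hit genes
    are comma-joined.  Numeric fields round-trip through :func:`read_enrichment_tsv`
    to within 1e-12 (written with 17 significant digits).
    """
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# adjustment={adjust_method}\n")
        fh.write("\t".join(ENRICHMENT_COLUMNS) + "\n")
        for r in records:
            fh.write(
                f"{r.category}\t{r.category_size}\t{r.hits}\t{r.statistic:.17g}\t"
                f"{r.direction}\t{r.p_raw:.17g}\t{r.p_adj:.17g}\t"
                f"{','.join(r.hit_genes)}\n"
            )


def read_enrichment_tsv(path: str) -> list[EnrichmentRecord]:
    records: list[EnrichmentRecord] = []
    with _open_text(path) as fh:
        header_seen = False
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if not header_seen:
                if fields != ENRICHMENT_COLUMNS:
                    raise InputError(f"{path}:{lineno}: unexpected header {fields!r}")
                header_seen = True
                continue
            if len(fields) != len(ENRICHMENT_COLUMNS):
                raise InputError(
                    f"{path}:{lineno}: expected {len(ENRICHMENT_COLUMNS)} fields, "
                    f"got {len(fields)}"
                )
            records.append(
                EnrichmentRecord(
                    category=fields[0],
                    category_size=int(fields[1]),
                    hits=int(fields[2]),
                    statistic=float(fields[3]),
                    direction=fields[4],
                    p_raw=float(fields[5]),
                    p_adj=float(fields[6]),
                    hit_genes=[g for g in fields[7].split(",") if g],
                )
            )
    return records


def read_mtx_counts(mtx_path: str, genes_path: str, cells_path: str) -> ExpressionMatrix:
    """Read sparse single-cell counts: Matrix Market file + gene and barcode
    index files (one token per line, genes = rows, cells = columns).

    The matrix is densified (desk-scale data); counts mode enforced.
    """
    if not os.path.exists(mtx_path):
        raise InputError(f"input file not found: {mtx_path}")
    genes = _read_index_file(genes_path)
    cells = _read_index_file(cells_path)
    try:
        mat = scipy.io.mmread(mtx_path)
    except Exception as exc:  # noqa: BLE001
        raise InputError(f"{mtx_path}: cannot parse Matrix Market file: {exc}") from exc
    if scipy.sparse.issparse(mat):
        mat = mat.toarray()
    mat = np.asarray(mat, dtype=float)
    if mat.shape != (len(genes), len(cells)):
        raise InputError(
            f"{mtx_path}: matrix shape {mat.shape} does not match "
            f"{len(genes)} genes x {len(cells)} cells"
        )
    df = pd.DataFrame(mat, index=genes, columns=cells)
    try:
        return ExpressionMatrix(df, mode="counts")
    except ValidationError as exc:
        raise InputError(f"{mtx_path}: {exc}") from exc


def write_mtx_counts(m: ExpressionMatrix, mtx_path: str, genes_path: str, cells_path: str) -> None:
    sp = scipy.sparse.coo_matrix(m.values.to_numpy())
    scipy.io.mmwrite(mtx_path, sp)
    with open(genes_path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(m.genes) + "\n")
    with open(cells_path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(m.columns) + "\n")


def _read_index_file(path: str) -> list[str]:
    with _open_text(path) as fh:
        # first tab-separated token per line (10x-style files carry extras)
        toks = [line.split("\t")[0].strip() for line in fh if line.strip()]
    if not toks:
        raise InputError(f"{path}: empty index file")
    return toks
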