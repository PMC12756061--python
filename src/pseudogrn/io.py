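"""Readers and writers for expression matrices, edge lists and networks.

Dense expression is accepted as delimited text (genes-by-cells or
cells-by-genes, header row/column of identifiers); sparse expression as
a MatrixMarket triple with gene and cell name sidecar files. Networks
travel as plain TSV.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

logger = logging.getLogger("pseudogrn")

LAYOUTS = ("genes_by_cells", "cells_by_genes")


@dataclass
class ExpressionMatrix:
    """Genes × cells matrix of non-negative expression values.

    ``values[i, j]`` is the expression of gene ``gene_ids[i]`` in cell
    ``cell_ids[j]``; units are arbitrary (raw counts or normalized).
    """

    values: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        m, n = self.values.shape
        if m != len(self.gene_ids) or n != len(self.cell_ids):
            raise ValueError("shape does not match identifier lists")
        if m < 2 or n < 2:
            raise ValueError("need at least 2 genes and 2 cells")
        for kind, ids in (("gene", self.gene_ids), ("cell", self.cell_ids)):
            dup = _first_duplicate(ids)
            if dup is not None:
                raise ValueError(f"duplicate {kind} identifier: {dup!r}")
        if not np.all(np.isfinite(self.values)):
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"non-finite value at gene {self.gene_ids[i]!r}, "
                f"cell {self.cell_ids[j]!r}"
            )
        if np.any(self.values < 0):
            i, j = np.argwhere(self.values < 0)[0]
            raise ValueError(
                f"negative value at gene {self.gene_ids[i]!r}, "
                f"cell {self.cell_ids[j]!r}"
            )

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def gene_index(self, gene: str) -> int:
        try:
            return self.gene_ids.index(gene)
        except ValueError:
            raise KeyError(f"gene {gene!r} not in matrix") from None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.cell_ids)


def _first_duplicate(items) -> str | None:
    seen: set = set()
    for x in items:
        if x in seen:
            return x
        seen.add(x)
    return None


def read_expression(
    path: str | Path,
    layout: str = "genes_by_cells",
    format: str | None = None,
    genes_path: str | Path | None = None,
    cells_path: str | Path | None = None,
) -> ExpressionMatrix:
    """Read an expression matrix from CSV/TSV/MTX into genes × cells form.

    For ``mtx``, row/column names come from sidecar text files (one id
    per line): ``genes_path``/``cells_path``, defaulting to
    ``<stem>_genes.txt`` and ``<stem>_cells.txt`` next to the matrix.
    ``layout`` states the on-disk orientation; the returned matrix is
    always genes × cells.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if layout not in LAYOUTS:
        raise ValueError(f"layout must be one of {LAYOUTS}, got {layout!r}")
    if format is None:
        format = {".csv": "csv", ".tsv": "tsv", ".mtx": "mtx"}.get(
            path.suffix.lower(), "csv"
        )

    if format == "mtx":
        mat = scipy.io.mmread(path)
        if scipy.sparse.issparse(mat):
            mat = mat.toarray()
        mat = np.asarray(mat, dtype=float)
        genes_path = Path(genes_path) if genes_path else path.with_name(path.stem + "_genes.txt")
        cells_path = Path(cells_path) if cells_path else path.with_name(path.stem + "_cells.txt")
        row_ids = [l.strip() for l in Path(genes_path if layout == "genes_by_cells" else cells_path).read_text().splitlines() if l.strip()]
        col_ids = [l.strip() for l in Path(cells_path if layout == "genes_by_cells" else genes_path).read_text().splitlines() if l.strip()]
        df = pd.DataFrame(mat, index=row_ids, columns=col_ids)
    else:
        sep = "\t" if format == "tsv" else ","
        df = pd.read_csv(path, sep=sep, index_col=0)
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        bad = df.select_dtypes(exclude=[np.number])
        if bad.shape[1]:
            col = bad.columns[0]
            row = bad[col].index[pd.to_numeric(bad[col], errors="coerce").isna()]
            where = row[0] if len(row) else "?"
            raise ValueError(
                f"non-numeric value in column {col!r}, row {where!r} of {path}"
            )

    if layout == "cells_by_genes":
        df = df.T
    expr = ExpressionMatrix(df.to_numpy(dtype=float), list(df.index), list(df.columns))
    logger.info("read expression: %d genes x %d cells from %s",
                expr.n_genes, expr.n_cells, path)
    return expr


def read_tf_list(path: str | Path) -> list[str]:
    """Read one gene symbol per line; order preserved, duplicates dropped."""
    tfs: list[str] = []
    seen: set = set()
    for line in Path(path).read_text().splitlines():
        sym = line.strip()
        if sym and sym not in seen:
            tfs.append(sym)
            seen.add(sym)
    if not tfs:
        raise ValueError(f"TF list {path} is empty")
    return tfs


def read_edge_list(path: str | Path) -> set[tuple[str, str]]:
    """Read directed (regulator, target) pairs from a ≥2-column TSV.

    Self-loops are dropped with a warning; duplicate pairs collapse. A
    leading header line whose first two fields are ``regulator`` and
    ``target`` is skipped so files written by :func:`write_network`
    round-trip.
    """
    lines = [l for l in Path(path).read_text().splitlines() if l.strip()]
    if lines:
        first = [f.strip().lower() for f in lines[0].split("\t")[:2]]
        if first == ["regulator", "target"]:
            lines = lines[1:]
    if not lines:
        raise ValueError(f"edge list {path} is empty")
    edges: set[tuple[str, str]] = set()
    for lineno, line in enumerate(lines, 1):
        fields = line.split("\t")
        if len(fields) < 2:
            raise ValueError(f"{path}:{lineno}: expected at least two columns")
        reg, tgt = fields[0].strip(), fields[1].strip()
        if reg == tgt:
            logger.warning("dropping self-loop %s -> %s in %s", reg, tgt, path)
            continue
        edges.add((reg, tgt))
    if not edges:
        raise ValueError(f"edge list {path} contains no usable edges")
    return edges


def write_network(net, path: str | Path) -> None:
    """Write a signed network as TSV ``regulator target score sign``.

    Rows are ordered by target ascending, then selection rank ascending,
    so repeated runs produce byte-identical files. Scores are printed
    with 6 significant digits.
    """
    rows = sorted(net.edges, key=lambda e: (e.target, e.rank))
    with open(path, "w") as fh:
        fh.write("regulator\ttarget\tscore\tsign\n")
        for e in rows:
            fh.write(f"{e.regulator}\t{e.target}\t{e.score:.6g}\t{e.sign}\n")
    logger.info("wrote %d edges to %s", len(rows), path)


def write_scores_long(frame: pd.DataFrame, path: str | Path) -> None:
    """Write a long-format score table ``regulator target score``."""
    frame.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_scores_long(path: str | Path) -> pd.DataFrame:
    """Read a long-format score table with columns regulator/target/score."""
    df = pd.read_csv(path, sep="\t")
    needed = {"regulator", "target", "score"}
    if not needed.issubset(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(needed)}")
    return df[["regulator", "target", "score"]]
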