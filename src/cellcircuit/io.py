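"""Core data model and TSV/MatrixMarket readers and writers.

Every external format the pipeline touches goes through this module: per-cell
spatial tables, sparse gene-by-cell count matrices, ligand-receptor pair
databases, differential-expression tables and interaction-network edge lists.

TSV dialect: tab-separated, UTF-8, ``#`` comment lines ignored, no quoting.
Gene symbols are case-preserved and matched exactly.
"""

from __future__ import annotations

import io as _io
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .errors import IntegrityError, ParseError, SchemaError

logger = logging.getLogger(__name__)

CELL_TABLE_COLUMNS = ("cell_id", "x_um", "y_um", "cell_type", "sample_id", "condition")

DE_TABLE_COLUMNS = (
    "gene",
    "group",
    "log_fold_change",
    "p_value",
    "adjusted_p",
    "frac_fg",
    "frac_bg",
)


def _read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype=str, **kwargs)


@dataclass
class CellTable:
    """Per-cell spatial records: position (µm), type, sample and condition.

    Coordinates are physical micrometres with an arbitrary per-sample origin;
    all distance logic downstream is strictly within-sample.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in CELL_TABLE_COLUMNS if c not in self.df.columns]
        if missing:
            raise SchemaError(f"cell table missing column(s): {', '.join(missing)}")
        for col in ("x_um", "y_um"):
            vals = pd.to_numeric(self.df[col], errors="coerce")
            bad = vals.index[vals.isna() | ~np.isfinite(vals)]
            if len(bad):
                raise ParseError(
                    f"non-numeric or non-finite {col} at row index {bad[0]}"
                )
            self.df[col] = vals.astype(float)
        dup = self.df.duplicated(subset=["sample_id", "cell_id"])
        if dup.any():
            row = self.df.loc[dup].iloc[0]
            raise IntegrityError(
                f"duplicate cell_id {row['cell_id']!r} within sample {row['sample_id']!r}"
            )
        if len(self.df) == 0:
            raise IntegrityError("cell table is empty")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def samples(self) -> list[str]:
        return list(pd.unique(self.df["sample_id"]))

    @property
    def cell_types(self) -> list[str]:
        return sorted(pd.unique(self.df["cell_type"]))

    def coords(self) -> np.ndarray:
        return self.df[["x_um", "y_um"]].to_numpy(float)


def read_cell_table(path: str | Path) -> CellTable:
    """Read a validated :class:`CellTable` from TSV; row order is preserved."""
    df = _read_tsv(path)
    return CellTable(df.reset_index(drop=True))


def write_cell_table(cells: CellTable, path: str | Path) -> None:
    cells.df.to_csv(path, sep="\t", index=False)


@dataclass
class ExpressionMatrix:
    """Sparse genes x cells count (or normalized) matrix with aligned labels."""

    genes: list[str]
    cells: list[str]
    counts: sp.csr_matrix
    normalized: bool = False

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        if self.counts.shape != (len(self.genes), len(self.cells)):
            raise IntegrityError(
                f"matrix shape {self.counts.shape} inconsistent with "
                f"{len(self.genes)} genes x {len(self.cells)} cells"
            )
        if self.counts.nnz and self.counts.data.min() < 0:
            raise IntegrityError("expression matrix has negative entries")

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def gene_index(self, gene: str) -> int:
        try:
            return self.genes.index(gene)
        except ValueError:
            raise KeyError(f"gene {gene!r} not in expression matrix") from None

    def row(self, gene: str) -> np.ndarray:
        """Dense 1-D expression vector of one gene across cells."""
        return np.asarray(self.counts[self.gene_index(gene)].todense()).ravel()

    def lognorm(self, scale: float = 1e4) -> "ExpressionMatrix":
        """Library-size normalize to ``scale`` counts per cell, then log1p.

        Standard logTP10K at the default scale. Already-normalized matrices
        are returned unchanged.
        """
        if self.normalized:
            return self
        m = self.counts.tocsc().astype(float)
        libsize = np.asarray(m.sum(axis=0)).ravel()
        libsize[libsize == 0] = 1.0
        m = m.multiply(scale / libsize).tocsr()
        m.data = np.log1p(m.data)
        return ExpressionMatrix(self.genes, self.cells, m, normalized=True)


def _read_label_file(path: str | Path) -> list[str]:
    labels = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            labels.append(line.split("\t")[0])
    return labels


def read_expression(
    mtx_path: str | Path, genes_path: str | Path, cells_path: str | Path
) -> ExpressionMatrix:
    """Read MatrixMarket counts with one-column gene/cell label TSVs.

    Orientation is normalized internally to genes x cells; duplicate
    coordinate entries in the MTX file are summed.
    """
    mat = scipy.io.mmread(str(mtx_path))
    genes = _read_label_file(genes_path)
    cells = _read_label_file(cells_path)
    if mat.shape == (len(genes), len(cells)):
        pass
    elif mat.shape == (len(cells), len(genes)):
        mat = mat.T
    else:
        raise IntegrityError(
            f"MTX dimensions {mat.shape} match neither {len(genes)} genes x "
            f"{len(cells)} cells nor its transpose"
        )
    return ExpressionMatrix(genes, cells, sp.csr_matrix(mat))


def write_expression(
    expr: ExpressionMatrix,
    mtx_path: str | Path,
    genes_path: str | Path,
    cells_path: str | Path,
) -> None:
    scipy.io.mmwrite(str(mtx_path), expr.counts.tocoo())
    Path(genes_path).write_text("\n".join(expr.genes) + "\n", encoding="utf-8")
    Path(cells_path).write_text("\n".join(expr.cells) + "\n", encoding="utf-8")


@dataclass
class LRDatabase:
    """Ligand-receptor pair list; single-subunit pairs only."""

    pairs: pd.DataFrame  # columns ligand, receptor[, pathway]

    def __post_init__(self) -> None:
        for col in ("ligand", "receptor"):
            if col not in self.pairs.columns:
                raise SchemaError(f"LR database missing column {col!r}")
        if self.pairs.duplicated(subset=["ligand", "receptor"]).any():
            raise IntegrityError("duplicate (ligand, receptor) pair in LR database")

    def __len__(self) -> int:
        return len(self.pairs)

    def receptors_for(self, ligand: str) -> list[str]:
        return self.pairs.loc[self.pairs["ligand"] == ligand, "receptor"].tolist()

    def warn_missing_genes(self, genes: Iterable[str]) -> list[str]:
        """Warn (not error) about DB genes absent from an expression matrix."""
        known = set(genes)
        used = set(self.pairs["ligand"]) | set(self.pairs["receptor"])
        missing = sorted(used - known)
        if missing:
            warnings.warn(
                f"{len(missing)} LR database gene(s) absent from expression "
                f"matrix: {', '.join(missing[:10])}",
                stacklevel=2,
            )
        return missing


def read_lr_database(path: str | Path) -> LRDatabase:
    return LRDatabase(_read_tsv(path))


def write_lr_database(db: LRDatabase, path: str | Path) -> None:
    db.pairs.to_csv(path, sep="\t", index=False)


@dataclass
class DETable:
    """Differential-expression results, one row per (gene, group) contrast."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in DE_TABLE_COLUMNS if c not in self.df.columns]
        if missing:
            raise SchemaError(f"DE table missing column(s): {', '.join(missing)}")
        for col in DE_TABLE_COLUMNS[2:]:
            self.df[col] = pd.to_numeric(self.df[col])
        p = self.df["p_value"].to_numpy(float)
        if ((p < 0) | (p > 1)).any():
            raise IntegrityError("p_value outside [0, 1]")
        for col in ("frac_fg", "frac_bg"):
            f = self.df[col].to_numpy(float)
            if ((f < 0) | (f > 1)).any():
                raise IntegrityError(f"{col} outside [0, 1]")

    def upregulated(self, group: str, alpha: float = 0.05) -> set[str]:
        """Genes significantly up (adjusted p < alpha, positive lfc) in group."""
        sub = self.df[
            (self.df["group"] == group)
            & (self.df["adjusted_p"] < alpha)
            & (self.df["log_fold_change"] > 0)
        ]
        return set(sub["gene"])


def read_de_table(path: str | Path) -> DETable:
    return DETable(_read_tsv(path))


def write_de_table(de: DETable, path: str | Path) -> None:
    de.df.to_csv(path, sep="\t", index=False)


def write_network(net, path: str | Path, graphml_path: str | Path | None = None) -> None:
    """Write an interaction network as a deterministic TSV edge list.

    Rows are sorted lexicographically by (sender, receiver). An optional
    GraphML copy is written when ``graphml_path`` is given.
    """
    import networkx as nx

    rows = [
        (u, v, d["weight"], d["n_interactions"])
        for u, v, d in net.graph.edges(data=True)
    ]
    rows.sort(key=lambda r: (r[0], r[1]))
    df = pd.DataFrame(
        rows, columns=["sender", "receiver", "weight", "n_significant_interactions"]
    )
    df.to_csv(path, sep="\t", index=False)
    if graphml_path is not None:
        nx.write_graphml(net.graph, graphml_path)


def read_network(path: str | Path):
    """Read back an edge-list TSV written by :func:`write_network`."""
    from .communication import InteractionNetwork
    import networkx as nx

    df = _read_tsv(path)
    g = nx.DiGraph()
    for _, r in df.iterrows():
        g.add_edge(
            r["sender"],
            r["receiver"],
            weight=float(r["weight"]),
            n_interactions=int(r["n_significant_interactions"]),
        )
    return InteractionNetwork(graph=g)
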