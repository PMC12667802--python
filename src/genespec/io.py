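"""Reading and writing the on-disk formats the tool touches.

The in-memory container is an :class:`anndata.AnnData` with cells as rows
(``obs``) and genes as columns (``var``), values stored column-accessible
sparse (CSC) since per-gene slicing is the hot path. On disk: Matrix Market
coordinate format plus one-identifier-per-line TSVs for genes and cells and
a header-bearing metadata TSV keyed by cell id. An ``.h5ad`` reader is
provided as a convenience. Values are accepted as any nonnegative reals —
raw counts or library-normalized values — and treated as weights by the
entropy machinery.
"""

from __future__ import annotations

import logging
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .errors import DegenerateDataError, FormatError, ValidationError

__all__ = ["read_matrix", "read_h5ad", "filter_genes", "write_scores", "write_matrix"]

log = logging.getLogger(__name__)


def _read_ids(path) -> list[str]:
    ids = pd.read_csv(path, sep="\t", header=None, dtype=str)[0].tolist()
    if len(set(ids)) != len(ids):
        raise ValidationError(f"duplicate identifiers in {path}")
    return ids


def read_matrix(matrix_path, genes_path, cells_path, metadata_path) -> ad.AnnData:
    """Assemble an annotated matrix from MTX + TSV sidecars.

    Orientation is auto-resolved so rows are cells: if the MTX dimensions
    match genes x cells, the matrix is transposed. The metadata TSV must
    carry a header and key every cell id in its first column.
    """
    M = sparse.csc_matrix(spio.mmread(matrix_path))
    genes = _read_ids(genes_path)
    cells = _read_ids(cells_path)
    if M.shape == (len(cells), len(genes)):
        pass
    elif M.shape == (len(genes), len(cells)):
        M = M.T.tocsc()
    else:
        raise FormatError(
            f"matrix is {M.shape[0]}x{M.shape[1]} but annotation files "
            f"declare {len(cells)} cells and {len(genes)} genes"
        )
    if M.nnz and M.data.min() < 0:
        raise ValidationError("matrix contains negative values")

    meta = pd.read_csv(metadata_path, sep="\t", dtype=str)
    meta = meta.set_index(meta.columns[0])
    if meta.index.duplicated().any():
        dup = sorted(meta.index[meta.index.duplicated()].unique())
        raise ValidationError(f"duplicate metadata rows for cells {dup}")
    missing = [c for c in cells if c not in meta.index]
    if missing:
        raise ValidationError(f"metadata missing cell ids: {missing}")
    obs = meta.loc[cells]
    return ad.AnnData(
        X=M.astype(np.float64),
        obs=obs,
        var=pd.DataFrame(index=pd.Index(genes, name="gene")),
    )


def read_h5ad(path) -> ad.AnnData:
    """Convenience reader for a single annotated-matrix HDF5 container."""
    adata = ad.read_h5ad(path)
    X = adata.X
    if sparse.issparse(X):
        if X.data.size and X.data.min() < 0:
            raise ValidationError("matrix contains negative values")
        adata.X = X.tocsc()
    elif np.asarray(X).min() < 0:
        raise ValidationError("matrix contains negative values")
    return adata


def write_matrix(adata: ad.AnnData, out_dir) -> None:
    """Write an annotated matrix as MTX + TSV sidecars (read_matrix layout)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(str(out / "matrix.mtx"), sparse.coo_matrix(adata.X))
    pd.Series(list(adata.var_names)).to_csv(
        out / "genes.tsv", sep="\t", header=False, index=False
    )
    pd.Series(list(adata.obs_names)).to_csv(
        out / "cells.tsv", sep="\t", header=False, index=False
    )
    meta = adata.obs.copy()
    meta.insert(0, "cell_id", list(adata.obs_names))
    meta.to_csv(out / "metadata.tsv", sep="\t", index=False)


def filter_genes(adata: ad.AnnData, min_cells: int = 100) -> ad.AnnData:
    """Drop genes expressed (value > 0) in fewer than ``min_cells`` cells.

    Strict "fewer than": a gene nonzero in exactly ``min_cells`` cells is
    retained. The cell set is unchanged. Idempotent for a fixed threshold.
    """
    if min_cells < 1:
        raise ValidationError("min_cells must be >= 1")
    X = adata.X
    if sparse.issparse(X):
        n_expr = np.asarray((X > 0).sum(axis=0)).ravel()
    else:
        n_expr = (np.asarray(X) > 0).sum(axis=0)
    keep = n_expr >= min_cells
    n_removed = int((~keep).sum())
    if not keep.any():
        raise DegenerateDataError(
            f"all {adata.shape[1]} genes are expressed in fewer than "
            f"{min_cells} cells; lower the threshold"
        )
    log.info("filter_genes removed %d of %d genes", n_removed, adata.shape[1])
    out = adata[:, keep].copy()
    out.uns["n_genes_removed"] = n_removed
    if sparse.issparse(out.X):
        out.X = out.X.tocsc()
    return out


def _score_columns(df: pd.DataFrame) -> list[str]:
    """Deterministic output column order for a score table."""
    blocks = [
        c[len("psi_") :]
        for c in df.columns
        if c.startswith("psi_") and not c.endswith("_gsd")
    ]
    order = ["partition", "Psi_mean", "Psi_sd", "zeta_mean", "zeta_sd"]
    order += [f"psi_{b}" for b in blocks]
    order += [f"psi_{b}_gsd" for b in blocks]
    order += ["p_Psi", "p_zeta"] + [f"p_psi_{b}" for b in blocks]
    order += ["q_Psi", "q_zeta"] + [f"q_psi_{b}" for b in blocks]
    order += ["n_draws_used"]
    return [c for c in order if c in df.columns] + [
        c for c in df.columns if c not in order and not c.startswith("psi_")
        and not c.startswith("p_") and not c.startswith("q_")
    ]


def write_scores(scores: pd.DataFrame, out_path) -> None:
    """Write an aggregated score table as TSV.

    One row per gene (per partition); columns in a deterministic order with
    psi columns following partition block order; floats at 12 significant
    digits so a round-trip read reproduces values.
    """
    df = scores.copy()
    if df.index.name is None:
        df.index.name = "gene"
    cols = _score_columns(df)
    df[cols].to_csv(out_path, sep="\t", float_format="%.12g")
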