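"""Per-gene entropy decomposition and specificity scores.

For a gene with nonnegative per-cell weights ``x`` and a partition of the
``n`` cells into ``r`` blocks:

* ``p_i = x_i / sum(x)`` and the total entropy ``E_T = -sum p_i log p_i``;
* within block ``C``, ``q_j = x_j / sum_{k in C} x_k`` and
  ``E_C = -sum q_j log q_j``;
* the block mass is ``p_C = sum_{j in C} p_j``, the within entropy
  ``E_W = sum_C p_C E_C``, and the between entropy ``E_B = E_T - E_W``
  (Shannon's grouping identity).

The three specificity scores are

* ``Psi = E_W / E_T`` — fraction of the gene's information explained by the
  partition;
* ``psi_block(C) = p_C E_C / E_W`` — the compositional share of within
  information carried by block ``C`` (sums to one over blocks);
* ``zeta = 1 - H(psi_blocks) / log r`` — normalized KL divergence of the
  psi-block composition from uniform; 1 means fully partition-specific,
  0 means evenly spread (housekeeping-like).

Natural logarithms are used internally; all three scores are ratios and
therefore base-invariant. Block-wise reductions are summed in sorted order so
that ``Psi`` and ``zeta`` are bit-identical under any permutation of the
block labels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse

from .errors import ValidationError
from .partition import Partition

__all__ = [
    "EntropyDecomposition",
    "SpecificityScores",
    "decompose_entropy",
    "specificity_scores",
    "score_matrix",
]

# degenerate_flag values
FLAG_NONE = "none"
FLAG_ZERO_TOTAL = "zero_total"  # E_T = 0 (at most one expressing cell)
FLAG_ZERO_WITHIN = "zero_within"  # E_T > 0 but E_W = 0 (<=1 expressing cell/block)


def _sorted_sum(a: np.ndarray) -> np.ndarray:
    """Sum over axis 0 in ascending value order.

    Makes block-wise reductions independent of block label order down to the
    bit, so permuting labels cannot perturb Psi or zeta.
    """
    return np.sort(a, axis=0).sum(axis=0)


def _as_csc(X) -> sparse.csc_matrix:
    if sparse.issparse(X):
        X = X.tocsc().astype(np.float64)
    else:
        X = sparse.csc_matrix(np.asarray(X, dtype=np.float64))
    X.eliminate_zeros()
    if X.nnz and X.data.min() < 0:
        raise ValidationError("expression values must be nonnegative")
    return X


def _entropy_terms(X, partition: Partition):
    """Vectorized entropy decomposition for all genes (columns) of ``X``.

    Returns a dict of arrays: ``total`` (gene sums), ``e_t``, ``e_w``,
    ``e_b`` (length n_genes, NaN where total is 0) and ``p_block``,
    ``e_block`` of shape (r, n_genes).
    """
    X = _as_csc(X)
    if X.shape[0] != partition.n_cells:
        raise ValidationError(
            f"matrix has {X.shape[0]} cells but partition covers "
            f"{partition.n_cells}"
        )
    if partition.r < 2:
        raise ValidationError("r >= 2 blocks required")

    xlogx = X.copy()
    if xlogx.nnz:
        xlogx.data = xlogx.data * np.log(xlogx.data)

    B = partition.indicator()
    S = np.asarray((B @ X).todense())  # (r, G) block sums
    T = np.asarray((B @ xlogx).todense())  # (r, G) block sum of x log x
    total = np.asarray(X.sum(axis=0)).ravel()
    sum_xlogx = np.asarray(xlogx.sum(axis=0)).ravel()

    with np.errstate(divide="ignore", invalid="ignore"):
        e_t = np.where(total > 0, np.log(total) - sum_xlogx / total, np.nan)
        e_block = np.where(S > 0, np.log(S) - T / S, 0.0)
        p_block = np.where(total > 0, S / total, np.nan)
    # Jensen guarantees E_C >= 0; clamp float dust.
    e_block = np.maximum(e_block, 0.0)
    e_w = _sorted_sum(p_block * e_block)
    e_b = e_t - e_w
    return {
        "total": total,
        "e_t": e_t,
        "e_w": e_w,
        "e_b": e_b,
        "p_block": p_block,
        "e_block": e_block,
    }


def _scores_from_terms(terms: dict, r: int):
    """Psi / psi_blocks / zeta (+ flags) from decomposition terms.

    Degenerate genes: ``E_T = 0`` (including zero total) gets flag
    ``zero_total`` and missing scores; ``E_T > 0, E_W = 0`` gets flag
    ``zero_within`` with ``Psi = 0`` and ``psi_blocks := (p_C)`` so zeta
    stays defined.
    """
    e_t, e_w = terms["e_t"], terms["e_w"]
    p_block = terms["p_block"]
    G = e_t.size

    zero_total = ~(e_t > 0)  # covers total == 0 (NaN e_t) and e_t == 0
    zero_within = (~zero_total) & (e_w == 0)
    ok = (~zero_total) & (~zero_within)

    psi = np.full(G, np.nan)
    psi[ok] = e_w[ok] / e_t[ok]
    psi[zero_within] = 0.0
    np.clip(psi, 0.0, 1.0, out=psi)

    comp = np.full((r, G), np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        w = terms["p_block"] * terms["e_block"]
        comp[:, ok] = w[:, ok] / e_w[ok]
    comp[:, zero_within] = p_block[:, zero_within]
    np.clip(comp, 0.0, 1.0, out=comp)

    with np.errstate(divide="ignore", invalid="ignore"):
        h_terms = np.where(comp > 0, -comp * np.log(comp), 0.0)
    zeta = 1.0 - _sorted_sum(h_terms) / np.log(r)
    zeta[zero_total] = np.nan
    np.clip(zeta, 0.0, 1.0, out=zeta)

    flags = np.full(G, FLAG_NONE, dtype=object)
    flags[zero_total] = FLAG_ZERO_TOTAL
    flags[zero_within] = FLAG_ZERO_WITHIN
    return psi, zeta, comp, flags


@dataclass(frozen=True)
class EntropyDecomposition:
    """Entropy terms for one gene under one partition (natural log, nats)."""

    e_t: float
    e_b: float
    e_w: float
    p_block: np.ndarray  # (r,) block mass fractions, sums to 1
    e_block: np.ndarray  # (r,) within-block entropies
    block_labels: tuple[str, ...]


@dataclass(frozen=True)
class SpecificityScores:
    """Psi, zeta and the psi-block composition for one gene."""

    psi: float
    zeta: float
    psi_blocks: np.ndarray  # (r,) sums to 1 unless degenerate
    block_labels: tuple[str, ...]
    degenerate_flag: str = FLAG_NONE


def decompose_entropy(x, partition: Partition) -> EntropyDecomposition:
    """Entropy decomposition ``E_T = E_B + E_W`` for a single gene vector."""
    x = np.asarray(x, dtype=np.float64).ravel()
    if x.min() < 0:
        raise ValidationError("expression values must be nonnegative")
    if x.sum() == 0:
        raise ValidationError("gene has zero total expression")
    terms = _entropy_terms(x[:, None], partition)
    return EntropyDecomposition(
        e_t=float(terms["e_t"][0]),
        e_b=float(terms["e_b"][0]),
        e_w=float(terms["e_w"][0]),
        p_block=terms["p_block"][:, 0].copy(),
        e_block=terms["e_block"][:, 0].copy(),
        block_labels=partition.block_labels,
    )


def specificity_scores(d: EntropyDecomposition) -> SpecificityScores:
    """Psi, psi_blocks and zeta from a decomposition."""
    r = len(d.block_labels)
    terms = {
        "e_t": np.array([d.e_t]),
        "e_w": np.array([d.e_w]),
        "p_block": d.p_block[:, None],
        "e_block": d.e_block[:, None],
    }
    psi, zeta, comp, flags = _scores_from_terms(terms, r)
    return SpecificityScores(
        psi=float(psi[0]),
        zeta=float(zeta[0]),
        psi_blocks=comp[:, 0].copy(),
        block_labels=d.block_labels,
        degenerate_flag=str(flags[0]),
    )


def score_matrix(
    m, partition: Partition, *, gene_ids=None, chunk_size: int | None = None
) -> pd.DataFrame:
    """Score every gene of an expression matrix under a partition.

    ``m`` may be an AnnData (cells x genes) or any array/sparse matrix.
    Returns one row per gene with columns ``Psi``, ``zeta``,
    ``psi_<block>`` per block, ``E_T``, ``E_B``, ``E_W`` and
    ``degenerate_flag``. Thin wrapper over
    :class:`genespec.estimators.EntropySpecificity`.
    """
    from .estimators import EntropySpecificity

    X = getattr(m, "X", m)
    if gene_ids is None:
        var_names = getattr(m, "var_names", None)
        gene_ids = list(var_names) if var_names is not None else None
    est = EntropySpecificity(chunk_size=chunk_size).fit(X, partition)
    return est.score_table(gene_ids=gene_ids)
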