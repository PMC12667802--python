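"""Gene-selection workflows over aggregated scores.

Three standard reads of the score table:

* marker genes — high ``psi_block`` for a chosen block and high ``Psi``;
* partition-specific genes — high ``zeta`` and high ``Psi``;
* housekeeping genes — low ``zeta`` with high ``Psi`` (informative
  expression spread evenly over blocks).

All selections gate on global BH q-values first, then apply strict
threshold inequalities (a gene at exactly the threshold is excluded),
mirroring the ``>0.5``-style cutoffs used in practice. Ties in ranking
break lexicographically by gene id for determinism.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = [
    "SelectionRule",
    "select_markers",
    "select_partition_specific",
    "select_housekeeping",
    "upset_membership",
    "psi_feature_matrix",
]


@dataclass(frozen=True)
class SelectionRule:
    """Thresholds for gene selection; 0.5 is the no-prior-knowledge default."""

    psi_block_min: float = 0.5
    Psi_min: float = 0.5
    zeta_min: float = 0.5
    zeta_max: float | None = None
    q_max: float = 0.05

    def __post_init__(self):
        for v in (self.psi_block_min, self.Psi_min, self.zeta_min, self.q_max):
            if not 0 <= v <= 1:
                raise ValidationError("thresholds must lie in [0, 1]")
        if self.zeta_max is not None and not 0 <= self.zeta_max <= 1:
            raise ValidationError("zeta_max must lie in [0, 1]")


def _cols(scores: pd.DataFrame):
    psi_col = "Psi_mean" if "Psi_mean" in scores.columns else "Psi"
    zeta_col = "zeta_mean" if "zeta_mean" in scores.columns else "zeta"
    return psi_col, zeta_col


def _blocks(scores: pd.DataFrame) -> list[str]:
    return [
        c[len("psi_") :]
        for c in scores.columns
        if c.startswith("psi_") and not c.endswith("_gsd")
    ]


def _rank(df: pd.DataFrame, by: list[str], ascending: list[bool]) -> pd.DataFrame:
    tmp = df.reset_index()
    gene_col = tmp.columns[0]
    tmp = tmp.sort_values(by + [gene_col], ascending=ascending + [True])
    return tmp.set_index(gene_col)


def select_markers(scores: pd.DataFrame, block: str, rule: SelectionRule) -> pd.DataFrame:
    """Genes specific to one block: significant, high psi_block and Psi.

    Requires q < q_max for both the block's psi and Psi, then
    ``psi_block > psi_block_min`` and ``Psi > Psi_min``; ranked by
    descending psi_block then Psi.
    """
    blocks = _blocks(scores)
    if block not in blocks:
        raise ValidationError(
            f"unknown block {block!r}; valid blocks: {blocks}"
        )
    psi_col, _ = _cols(scores)
    pcol = f"psi_{block}"
    keep = (
        (scores[f"q_psi_{block}"] < rule.q_max)
        & (scores["q_Psi"] < rule.q_max)
        & (scores[pcol] > rule.psi_block_min)
        & (scores[psi_col] > rule.Psi_min)
    )
    return _rank(scores[keep.fillna(False)], [pcol, psi_col], [False, False])


def select_partition_specific(scores: pd.DataFrame, rule: SelectionRule) -> pd.DataFrame:
    """Genes specific to the partition: significant, high zeta and Psi."""
    psi_col, zeta_col = _cols(scores)
    keep = (
        (scores["q_Psi"] < rule.q_max)
        & (scores["q_zeta"] < rule.q_max)
        & (scores[psi_col] > rule.Psi_min)
        & (scores[zeta_col] > rule.zeta_min)
    )
    return _rank(scores[keep.fillna(False)], [zeta_col, psi_col], [False, False])


def select_housekeeping(scores: pd.DataFrame, rule: SelectionRule) -> pd.DataFrame:
    """Least-specific genes: significant high Psi with low zeta.

    ``zeta_max`` must be set; ranked by ascending zeta then descending Psi.
    """
    if rule.zeta_max is None:
        raise ValidationError("housekeeping selection requires zeta_max")
    psi_col, zeta_col = _cols(scores)
    keep = (
        (scores["q_Psi"] < rule.q_max)
        & (scores[psi_col] > rule.Psi_min)
        & (scores[zeta_col] < rule.zeta_max)
    )
    return _rank(scores[keep.fillna(False)], [zeta_col, psi_col], [True, False])


def upset_membership(selections: dict[str, set]) -> tuple[pd.DataFrame, pd.Series]:
    """Boolean gene x partition membership plus exclusive-intersection counts.

    Returns the indicator table (the standard input of upset-plot tools)
    and a Series of exclusive region sizes keyed by membership tuples;
    every gene counts in exactly one region, so region sizes sum to the
    size of the union.
    """
    if len(selections) < 2:
        raise ValidationError("upset membership needs at least 2 partitions")
    names = list(selections)
    genes = sorted(set().union(*selections.values()))
    table = pd.DataFrame(
        {name: [g in selections[name] for g in genes] for name in names},
        index=pd.Index(genes, name="gene"),
    )
    if genes:
        counts = table.groupby(names, sort=True).size()
    else:
        counts = pd.Series(dtype=int)
    return table, counts


def psi_feature_matrix(
    scores: pd.DataFrame, block_labels: list[str] | None = None
) -> tuple[pd.DataFrame, list[str]]:
    """Gene x block matrix of Aitchison-mean psi values for external clustering.

    Degenerate genes (missing compositions) are excluded; their ids are
    returned as a sidecar list. Column order follows partition block order.
    """
    blocks = block_labels if block_labels is not None else _blocks(scores)
    mat = scores[[f"psi_{b}" for b in blocks]]
    bad = mat.isna().any(axis=1)
    dropped = list(scores.index[bad])
    out = mat[~bad].copy()
    out.columns = blocks
    return out, dropped
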