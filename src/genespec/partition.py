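"""Partitions of cells into labeled blocks.

A partition assigns every cell to exactly one of ``r`` labeled blocks
(e.g. by tissue, by strain, or by an interaction such as ``sex:strain:tissue``).
Block label order is explicit and stable: it fixes output column order and
polygon vertex order downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DegenerateDataError, ValidationError

__all__ = ["Partition", "partition_from_metadata", "is_refinement", "restrict"]


@dataclass(frozen=True)
class Partition:
    """Assignment of ``n`` cells to ``r`` labeled, nonempty blocks.

    Parameters
    ----------
    name
        Human-readable name, e.g. ``"tissue"`` or ``"sex:strain:tissue"``.
    block_labels
        Ordered, unique block labels. The order is meaningful.
    codes
        Integer array of length ``n_cells``; ``codes[i]`` indexes
        ``block_labels``.
    """

    name: str
    block_labels: tuple[str, ...]
    codes: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        codes = np.asarray(self.codes, dtype=np.intp)
        object.__setattr__(self, "codes", codes)
        labels = tuple(str(b) for b in self.block_labels)
        object.__setattr__(self, "block_labels", labels)
        if len(set(labels)) != len(labels):
            raise ValidationError(f"duplicate block labels in partition {self.name!r}")
        if codes.size == 0:
            raise ValidationError("partition over zero cells")
        if codes.min() < 0 or codes.max() >= len(labels):
            raise ValidationError("partition codes out of range of block_labels")
        counts = np.bincount(codes, minlength=len(labels))
        if (counts == 0).any():
            empty = [labels[i] for i in np.flatnonzero(counts == 0)]
            raise ValidationError(f"empty blocks in partition {self.name!r}: {empty}")

    @property
    def r(self) -> int:
        """Number of blocks."""
        return len(self.block_labels)

    @property
    def n_cells(self) -> int:
        return self.codes.size

    def block_sizes(self) -> np.ndarray:
        return np.bincount(self.codes, minlength=self.r)

    def indicator(self):
        """Sparse (r, n_cells) block-indicator matrix for entropy sums."""
        from scipy import sparse

        n = self.n_cells
        return sparse.csr_matrix(
            (np.ones(n), (self.codes, np.arange(n))), shape=(self.r, n)
        )

    def reorder(self, new_order: list[str]) -> "Partition":
        """Return the same partition with blocks listed in ``new_order``."""
        if sorted(new_order) != sorted(self.block_labels):
            raise ValidationError(
                "new_order must be a permutation of block_labels; "
                f"got {new_order!r} vs {list(self.block_labels)!r}"
            )
        old_index = {b: i for i, b in enumerate(self.block_labels)}
        perm = np.empty(self.r, dtype=np.intp)  # perm[old] -> new
        for new_i, lab in enumerate(new_order):
            perm[old_index[lab]] = new_i
        return Partition(self.name, tuple(new_order), perm[self.codes])


def _metadata_frame(data) -> pd.DataFrame:
    """Accept an AnnData or a DataFrame of per-cell metadata."""
    if isinstance(data, pd.DataFrame):
        return data
    obs = getattr(data, "obs", None)
    if obs is None:
        raise ValidationError(
            "expected an AnnData or a per-cell metadata DataFrame, "
            f"got {type(data).__name__}"
        )
    return obs


def partition_from_metadata(data, columns, name: str | None = None) -> Partition:
    """Build a partition from one or more categorical metadata columns.

    Each block is one observed combination of column values, labeled by
    joining the values with ``":"`` in column order; unobserved combinations
    are omitted. Labels are sorted lexicographically.
    """
    obs = _metadata_frame(data)
    columns = list(columns)
    if not columns:
        raise ValidationError("at least one metadata column is required")
    for col in columns:
        if col not in obs.columns:
            raise ValidationError(f"metadata column {col!r} not found")
    sub = obs[columns]
    na_mask = sub.isna().any(axis=1)
    if na_mask.any():
        bad = list(obs.index[na_mask][:20])
        raise ValidationError(
            f"missing values in columns {columns} for cells {bad}"
            + (" ..." if na_mask.sum() > 20 else "")
        )
    joined = sub.astype(str).agg(":".join, axis=1)
    labels = sorted(joined.unique())
    if len(labels) < 2:
        raise ValidationError(
            f"partition over {columns} has a single block ({labels[0]!r}); "
            "at least 2 blocks are required"
        )
    index = {b: i for i, b in enumerate(labels)}
    codes = joined.map(index).to_numpy(dtype=np.intp)
    return Partition(name or ":".join(columns), tuple(labels), codes)


def is_refinement(fine: Partition, coarse: Partition) -> bool:
    """True iff every block of ``fine`` lies wholly inside one ``coarse`` block."""
    if fine.n_cells != coarse.n_cells:
        raise ValidationError(
            f"partitions cover different cell sets "
            f"({fine.n_cells} vs {coarse.n_cells} cells)"
        )
    # For each fine block, the set of coarse codes it meets must be a singleton.
    df = pd.DataFrame({"fine": fine.codes, "coarse": coarse.codes})
    return bool((df.groupby("fine")["coarse"].nunique() == 1).all())


def restrict(p: Partition, cells: np.ndarray) -> Partition:
    """Restrict a partition to a subset of cell indices (or a boolean mask).

    Blocks emptied by the restriction are dropped from ``block_labels`` with
    a warning; fewer than two surviving blocks is an error.
    """
    cells = np.asarray(cells)
    if cells.dtype == bool:
        cells = np.flatnonzero(cells)
    if cells.size == 0:
        raise ValidationError("cannot restrict a partition to an empty cell set")
    sub = p.codes[cells]
    counts = np.bincount(sub, minlength=p.r)
    keep = np.flatnonzero(counts > 0)
    if keep.size < 2:
        raise DegenerateDataError(
            f"restriction of partition {p.name!r} collapses to "
            f"{keep.size} block(s)"
        )
    if keep.size < p.r:
        dropped = [p.block_labels[i] for i in np.flatnonzero(counts == 0)]
        warnings.warn(
            f"restriction of partition {p.name!r} drops empty blocks {dropped}",
            stacklevel=2,
        )
    remap = np.full(p.r, -1, dtype=np.intp)
    remap[keep] = np.arange(keep.size)
    return Partition(p.name, tuple(p.block_labels[i] for i in keep), remap[sub])
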