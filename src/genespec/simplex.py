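"""Projection of psi-block compositions onto a regular polygon.

A psi-block vector for a partition with ``r`` blocks lives on the
``(r-1)``-simplex; it projects onto a regular ``r``-gon by placing each
block at a vertex and taking the barycentric combination of vertex
coordinates. Proximity to a vertex means specificity to that block; the
centroid is the uniform (housekeeping-like) composition. Up to rotation
and reflection of the polygon there are ``(r-1)!/2`` distinct vertex
orderings, i.e. distinct 2D projections of the same simplex.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import factorial

import numpy as np

from .errors import ValidationError

__all__ = [
    "PolygonLayout",
    "project_composition",
    "project_points",
    "count_unique_layouts",
    "draw_cloud",
]


@dataclass(frozen=True)
class PolygonLayout:
    """Regular r-gon with one block label per vertex.

    Vertices sit on the unit circle, the first at angle pi/2 (top),
    proceeding counter-clockwise, in ``vertex_order``. The ordering is
    user-supplied domain knowledge (e.g. strains ordered by genetic
    distance); the default is partition block order.
    """

    vertex_order: tuple[str, ...]

    def __post_init__(self):
        order = tuple(str(b) for b in self.vertex_order)
        object.__setattr__(self, "vertex_order", order)
        if len(order) < 3:
            raise ValidationError("a polygon layout needs r >= 3 blocks")
        if len(set(order)) != len(order):
            raise ValidationError("vertex_order must be unique labels")

    @property
    def r(self) -> int:
        return len(self.vertex_order)

    @property
    def vertex_coords(self) -> np.ndarray:
        ang = np.pi / 2 + 2 * np.pi * np.arange(self.r) / self.r
        return np.column_stack([np.cos(ang), np.sin(ang)])


def _check_composition(psi: np.ndarray, r: int) -> np.ndarray:
    psi = np.asarray(psi, dtype=float)
    if psi.shape[-1] != r:
        raise ValidationError(f"composition has {psi.shape[-1]} parts, expected {r}")
    if (psi < 0).any():
        raise ValidationError("composition parts must be nonnegative")
    if not np.allclose(psi.sum(axis=-1), 1.0, atol=1e-8):
        raise ValidationError("composition must sum to 1 (±1e-8)")
    return psi


def project_composition(psi, layout: PolygonLayout, block_labels=None) -> np.ndarray:
    """Barycentric projection of one composition to a 2D point.

    ``block_labels`` gives the order of ``psi``'s parts if it differs from
    ``layout.vertex_order``. The point lies in the polygon's convex hull;
    a one-hot composition maps exactly to its vertex and the uniform
    composition to the centroid (0, 0).
    """
    psi = _check_composition(psi, layout.r)
    if block_labels is not None:
        labels = [str(b) for b in block_labels]
        if sorted(labels) != sorted(layout.vertex_order):
            raise ValidationError("block_labels do not match layout vertices")
        idx = [labels.index(v) for v in layout.vertex_order]
        psi = psi[..., idx]
    return psi @ layout.vertex_coords


def project_points(compositions, layout: PolygonLayout, block_labels=None) -> np.ndarray:
    """Project an (n, r) array of compositions; returns (n, 2) coordinates."""
    return project_composition(np.atleast_2d(compositions), layout, block_labels)


def count_unique_layouts(r: int) -> int:
    """Distinct vertex orderings of the r-gon up to rotation and reflection.

    ``r!`` orderings divided by the dihedral symmetry group of order
    ``2r`` gives ``(r-1)!/2``.
    """
    if r < 3:
        raise ValidationError("count_unique_layouts requires r >= 3")
    return factorial(r - 1) // 2


def draw_cloud(
    points: np.ndarray,
    center: np.ndarray,
    layout: PolygonLayout,
    out_path=None,
    ax=None,
    title: str | None = None,
):
    """Scatter per-draw projections with an emphasized mean marker.

    Draw points appear as grey circles, the Aitchison-mean projection as a
    star; the polygon outline and vertex labels frame the plot. Saves
    vector graphics when ``out_path`` ends in .svg/.pdf.
    """
    import matplotlib

    if ax is None:
        matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    points = np.atleast_2d(np.asarray(points, dtype=float))
    if points.size == 0:
        raise ValidationError("draw_cloud needs at least one point")
    if ax is None:
        fig, ax = plt.subplots(figsize=(5, 5))
    else:
        fig = ax.figure
    verts = layout.vertex_coords
    ring = np.vstack([verts, verts[:1]])
    ax.plot(ring[:, 0], ring[:, 1], color="black", lw=1)
    for (x, y), lab in zip(verts, layout.vertex_order):
        ax.annotate(
            lab, (1.08 * x, 1.08 * y), ha="center", va="center", fontsize=9
        )
    ax.scatter(points[:, 0], points[:, 1], s=18, color="grey", alpha=0.7, zorder=2)
    c = np.asarray(center, dtype=float).ravel()
    ax.scatter([c[0]], [c[1]], marker="*", s=220, color="crimson", zorder=3)
    ax.set_aspect("equal")
    ax.set_axis_off()
    if title:
        ax.set_title(title)
    if out_path is not None:
        fig.savefig(out_path, bbox_inches="tight")
        plt.close(fig)
    return ax
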