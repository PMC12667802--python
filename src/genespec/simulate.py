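"""Synthetic expression data with known ground truth.

Emulates the structure of factorial single-cell designs (e.g. strains x
sexes x tissues with several replicate animals per combination): sample
level factors define replicates, within-sample factors (e.g. cell type)
define blocks, and genes come in three planted classes:

* **marker** genes — negative-binomial mean ``baseline_mean x
  fold_enrichment`` inside their target block and a small ambient-level
  leak mean elsewhere (``marker_leak_mean``; set it to 0 for strictly
  block-exclusive expression);
* **housekeeping** genes — one shared mean everywhere;
* **noise** genes — a per-gene random mean (lognormal across genes),
  constant across cells, hence independent of any block structure.

Counts are negative binomial with dispersion ``theta`` (variance
``mu + mu^2/theta``); each sample carries a lognormal random effect so
balanced sampling has real replicate variance to average over. Everything
is seeded and reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse

from .errors import ValidationError
from .partition import Partition

__all__ = ["SimulationDesign", "simulate", "simulate_null"]

_DEFAULT_FACTORS = {
    "strain": ("B6J", "CASTJ", "NZOJ", "PWKJ"),
    "sex": ("F", "M"),
    "celltype": ("Tcell", "Bcell", "NK", "Mono"),
}


@dataclass(frozen=True)
class SimulationDesign:
    """Factorial design plus expression-model parameters.

    ``marker_factor`` names the column whose levels receive planted marker
    genes and which varies *within* samples; all other factors are
    sample-level. Defaults give a 4-strain x 2-sex design with 3 replicate
    samples per combination, 4 cell types and 25 cells per (sample, cell
    type) — 2400 cells.
    """

    factors: dict = field(default_factory=lambda: dict(_DEFAULT_FACTORS))
    marker_factor: str = "celltype"
    samples_per_combo: int = 3
    cells_per_group: int = 25
    n_marker_genes_per_block: int = 5
    n_housekeeping_genes: int = 10
    n_noise_genes: int = 30
    baseline_mean: float = 1.0
    fold_enrichment: float = 8.0
    marker_leak_mean: float = 0.02
    noise_mean: float = 0.3
    noise_sigma: float = 0.7
    theta: float = 10.0
    sample_effect_sd: float = 0.2
    seed: int | None = None

    def __post_init__(self):
        if self.marker_factor not in self.factors:
            raise ValidationError(
                f"marker_factor {self.marker_factor!r} is not a design factor"
            )
        if len(self.factors[self.marker_factor]) < 2:
            raise ValidationError(
                "degenerate design: the marker factor needs >= 2 levels"
            )
        if self.fold_enrichment <= 1:
            raise ValidationError("fold_enrichment must be > 1")
        for name, levels in self.factors.items():
            if len(levels) < 1:
                raise ValidationError(f"factor {name!r} has no levels")
        if min(self.samples_per_combo, self.cells_per_group) < 1:
            raise ValidationError("counts must be >= 1")


def _nb(rng: np.random.Generator, mu: np.ndarray, theta: float) -> np.ndarray:
    out = np.zeros(mu.shape, dtype=np.int64)
    pos = mu > 0
    p = theta / (theta + mu[pos])
    out[pos] = rng.negative_binomial(theta, p)
    return out


def simulate(design: SimulationDesign) -> tuple[ad.AnnData, pd.DataFrame]:
    """Draw a matrix + metadata + truth manifest from a design.

    Returns ``(adata, manifest)`` where the manifest has one row per gene
    with columns ``gene_class`` (marker/housekeeping/noise) and
    ``target_block`` (the marker's block level, else missing).
    """
    rng = np.random.default_rng(design.seed)
    sample_factors = [f for f in design.factors if f != design.marker_factor]
    marker_levels = [str(v) for v in design.factors[design.marker_factor]]

    rows = []
    sample_combos = list(
        product(*[design.factors[f] for f in sample_factors])
    ) or [()]
    for combo in sample_combos:
        for rep in range(design.samples_per_combo):
            sid = "_".join([*map(str, combo), f"r{rep}"]) or f"r{rep}"
            for level in marker_levels:
                for _ in range(design.cells_per_group):
                    rows.append((*combo, level, sid))
    obs = pd.DataFrame(
        rows, columns=[*sample_factors, design.marker_factor, "sample_id"]
    )
    obs.index = pd.Index([f"cell{i}" for i in range(len(obs))], name="cell_id")
    n_cells = len(obs)

    gene_ids, gene_class, target = [], [], []
    for level in marker_levels:
        for i in range(design.n_marker_genes_per_block):
            gene_ids.append(f"marker_{level}_{i}")
            gene_class.append("marker")
            target.append(level)
    for i in range(design.n_housekeeping_genes):
        gene_ids.append(f"hk_{i}")
        gene_class.append("housekeeping")
        target.append(None)
    noise_means = np.exp(
        rng.normal(np.log(design.noise_mean), design.noise_sigma, design.n_noise_genes)
    )
    for i in range(design.n_noise_genes):
        gene_ids.append(f"noise_{i}")
        gene_class.append("noise")
        target.append(None)
    n_genes = len(gene_ids)

    mu = np.empty((n_cells, n_genes))
    cell_level = obs[design.marker_factor].to_numpy(str)
    col = 0
    for level in marker_levels:
        in_block = cell_level == level
        for _ in range(design.n_marker_genes_per_block):
            mu[:, col] = np.where(
                in_block,
                design.baseline_mean * design.fold_enrichment,
                design.marker_leak_mean,
            )
            col += 1
    for _ in range(design.n_housekeeping_genes):
        mu[:, col] = design.baseline_mean
        col += 1
    for m in noise_means:
        mu[:, col] = m
        col += 1

    # lognormal per-sample replicate effect, shared across genes
    samples = obs["sample_id"].to_numpy(str)
    uniq = sorted(set(samples))
    eff = {
        s: float(np.exp(rng.normal(0.0, design.sample_effect_sd))) for s in uniq
    }
    mu *= np.array([eff[s] for s in samples])[:, None]

    counts = _nb(rng, mu, design.theta)
    adata = ad.AnnData(
        X=sparse.csc_matrix(counts.astype(np.float64)),
        obs=obs,
        var=pd.DataFrame(index=pd.Index(gene_ids, name="gene")),
    )
    manifest = pd.DataFrame(
        {"gene_class": gene_class, "target_block": target},
        index=pd.Index(gene_ids, name="gene"),
    )
    return adata, manifest


def simulate_null(
    n_cells: int,
    n_genes: int,
    r: int,
    seed: int | None = None,
    mean: float = 1.0,
    theta: float = 10.0,
) -> tuple[ad.AnnData, Partition]:
    """Expression independent of block labels, for permutation calibration.

    Counts are iid negative binomial; blocks are assigned round-robin so
    sizes are as equal as possible. By construction the labels are
    exchangeable, so any valid permutation test must be uniform on it.
    """
    if r < 2:
        raise ValidationError("r >= 2 blocks required")
    rng = np.random.default_rng(seed)
    mu = np.full((n_cells, n_genes), float(mean))
    counts = _nb(rng, mu, theta)
    labels = tuple(f"b{i}" for i in range(r))
    codes = (np.arange(n_cells) % r).astype(np.intp)
    obs = pd.DataFrame(
        {"block": [labels[c] for c in codes]},
        index=pd.Index([f"cell{i}" for i in range(n_cells)], name="cell_id"),
    )
    adata = ad.AnnData(
        X=sparse.csc_matrix(counts.astype(np.float64)),
        obs=obs,
        var=pd.DataFrame(
            index=pd.Index([f"g{i}" for i in range(n_genes)], name="gene")
        ),
    )
    return adata, Partition("block", labels, codes)
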