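"""Permutation significance for Psi, zeta and psi-block, with global BH FDR.

The null is generated by scrambling block labels: the cell-to-block
assignment is permuted uniformly at random (block sizes preserved) and the
whole statistic pipeline — including the mean over balanced draws when
sampling is in use — is recomputed. Empirical p-values use the add-one
estimator ``p = (1 + #{perm >= obs}) / (1 + n_perm)`` (one-sided, high is
significant); the raw proportion is available via ``raw=True``. All
p-values are then pooled across metrics (and, in the CLI, across
partitions) for a single global Benjamini-Hochberg correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .entropy import _entropy_terms, _scores_from_terms
from .errors import ValidationError
from .partition import Partition, restrict
from .sampling import _aggregate_compositions

__all__ = ["PermutationConfig", "permutation_pvalues", "bh_qvalues"]


@dataclass(frozen=True)
class PermutationConfig:
    """Number of label scrambles, RNG seed, and null-pipeline mode.

    ``use_sampling=True`` recomputes the null statistic as the mean over the
    same balanced draws used for the observed statistic, mirroring its
    definition; ``False`` scores the full matrix once per permutation.
    """

    n_permutations: int = 100
    seed: int | None = None
    use_sampling: bool = True
    raw: bool = False

    def __post_init__(self):
        if self.n_permutations < 20:
            raise ValidationError(
                "n_permutations < 20 gives useless empirical p-value resolution"
            )


def _pipeline_stats(X, partition: Partition, draw_cells, block_labels):
    """(psi, zeta, comp) arrays for one assignment, optionally over draws.

    ``draw_cells`` is None (full-matrix mode) or a list of
    (row-subset matrix, cell index array) pairs, one per draw.
    """
    r = len(block_labels)
    if draw_cells is None:
        terms = _entropy_terms(X, partition)
        psi, zeta, comp, _ = _scores_from_terms(terms, r)
        return psi, zeta, comp.T  # comp -> (G, r)
    psis, zetas, comps = [], [], []
    for X_sub, cells in draw_cells:
        sub_codes = partition.codes[cells]
        if np.bincount(sub_codes, minlength=r).min() == 0:
            continue
        sub_p = Partition(partition.name, block_labels, sub_codes)
        terms = _entropy_terms(X_sub, sub_p)
        psi, zeta, comp, _ = _scores_from_terms(terms, r)
        psis.append(psi)
        zetas.append(zeta)
        comps.append(comp.T)
    if not psis:
        G = X.shape[1]
        return np.full(G, np.nan), np.full(G, np.nan), np.full((G, r), np.nan)
    psi = np.stack(psis)
    zeta = np.stack(zetas)
    comp = np.stack(comps)  # (D, G, r)
    usable = ~np.isnan(psi)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        psi_mean = np.nanmean(np.where(usable, psi, np.nan), axis=0)
        zeta_mean = np.nanmean(np.where(usable, zeta, np.nan), axis=0)
    amean, _ = _aggregate_compositions(comp, usable)
    return psi_mean, zeta_mean, amean


def _observed_arrays(observed: pd.DataFrame, block_labels):
    psi_col = "Psi_mean" if "Psi_mean" in observed.columns else "Psi"
    zeta_col = "zeta_mean" if "zeta_mean" in observed.columns else "zeta"
    psi = observed[psi_col].to_numpy(float)
    zeta = observed[zeta_col].to_numpy(float)
    comp = observed[[f"psi_{b}" for b in block_labels]].to_numpy(float)
    return psi, zeta, comp


def permutation_pvalues(
    adata,
    partition: Partition,
    observed: pd.DataFrame,
    cfg: PermutationConfig,
    draws: list[list] | None = None,
    design=None,
) -> pd.DataFrame:
    """Empirical p-values for Psi, zeta and every psi-block of every gene.

    ``observed`` must be the score table computed on the same matrix,
    partition and draws. A permutation that degenerates a gene contributes a
    null value of 0 (counted as a tie only when the observed value is also
    0); genes whose observed scores are missing get missing p-values.
    """
    X = getattr(adata, "X", adata)
    labels = partition.block_labels
    r = len(labels)
    obs_psi, obs_zeta, obs_comp = _observed_arrays(observed, labels)
    G = obs_psi.size

    draw_cells = None
    if cfg.use_sampling and draws:
        if design is None:
            raise ValidationError("draws were given but design is None")
        sample_ids = adata.obs[design.sample_id_column].astype(str).to_numpy()
        from scipy import sparse

        Xr = X.tocsr() if sparse.issparse(X) else np.asarray(X)
        draw_cells = []
        for draw in draws:
            cells = np.flatnonzero(np.isin(sample_ids, np.asarray(draw, dtype=str)))
            if cells.size:
                draw_cells.append((Xr[cells], cells))

    rng = np.random.default_rng(cfg.seed)
    ge_psi = np.zeros(G)
    ge_zeta = np.zeros(G)
    ge_comp = np.zeros((G, r))
    for _ in range(cfg.n_permutations):
        perm = Partition(partition.name, labels, rng.permutation(partition.codes))
        n_psi, n_zeta, n_comp = _pipeline_stats(X, perm, draw_cells, labels)
        n_psi = np.nan_to_num(n_psi, nan=0.0)
        n_zeta = np.nan_to_num(n_zeta, nan=0.0)
        n_comp = np.nan_to_num(n_comp, nan=0.0)
        # tie comparison with float-dust tolerance so mathematically equal
        # statistics (e.g. after rescaling a gene) compare as ties
        ge_psi += n_psi >= obs_psi - 1e-12
        ge_zeta += n_zeta >= obs_zeta - 1e-12
        ge_comp += n_comp >= obs_comp - 1e-12

    P = cfg.n_permutations
    if cfg.raw:
        p_psi, p_zeta, p_comp = ge_psi / P, ge_zeta / P, ge_comp / P
    else:
        p_psi = (1.0 + ge_psi) / (1.0 + P)
        p_zeta = (1.0 + ge_zeta) / (1.0 + P)
        p_comp = (1.0 + ge_comp) / (1.0 + P)
    p_psi[np.isnan(obs_psi)] = np.nan
    p_zeta[np.isnan(obs_zeta)] = np.nan
    p_comp[np.isnan(obs_comp)] = np.nan

    out = {"p_Psi": p_psi, "p_zeta": p_zeta}
    for i, b in enumerate(labels):
        out[f"p_psi_{b}"] = p_comp[:, i]
    return pd.DataFrame(out, index=observed.index)


def bh_qvalues(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted q-values for a pooled p-value vector.

    Missing p-values propagate as missing q-values and do not count toward
    the number of tests. Input p must lie in (0, 1].
    """
    p = np.asarray(pvalues, dtype=float).ravel()
    q = np.full(p.shape, np.nan)
    mask = np.isfinite(p)
    if mask.any():
        pm = p[mask]
        if (pm <= 0).any() or (pm > 1).any():
            raise ValidationError("p-values must lie in (0, 1]")
        q[mask] = multipletests(pm, method="fdr_bh")[1]
    return q


def attach_qvalues(tables: dict[str, pd.DataFrame]) -> dict[str, pd.DataFrame]:
    """Globally pool every p_* column across tables and attach q_* columns.

    ``tables`` maps partition name -> score table bearing ``p_*`` columns.
    One BH correction runs over the concatenation of all p-values from all
    metrics and all partitions, as required for a global FDR statement.
    """
    pooled, slots = [], []
    for name, tab in tables.items():
        for col in tab.columns:
            if col.startswith("p_"):
                vals = tab[col].to_numpy(float)
                slots.append((name, col, len(pooled), len(pooled) + len(vals)))
                pooled.append(vals)
    if not pooled:
        return tables
    flat = np.concatenate(pooled)
    qflat = bh_qvalues(flat)
    out = {name: tab.copy() for name, tab in tables.items()}
    offsets = np.cumsum([0] + [len(v) for v in pooled])
    for (name, col, _, _), start, stop in zip(
        slots, offsets[:-1], offsets[1:]
    ):
        out[name]["q" + col[1:]] = qflat[start:stop]
    return out
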