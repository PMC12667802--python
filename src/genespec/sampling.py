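"""Balanced sampling over biological replicates and score aggregation.

Specificity scores computed on all cells at once are hostage to replicate
imbalance (one over-sequenced mouse can dominate a block). The remedy used
here: draw balanced subsets of *samples* — exactly one sample id per
(category, condition) pair — score each draw, and aggregate across draws.
Psi and zeta aggregate arithmetically; psi-block vectors are compositions
and aggregate in Aitchison geometry (component-wise geometric mean,
renormalized), with the geometric SD as the spread measure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .entropy import _entropy_terms, _scores_from_terms
from .errors import BalanceError, DegenerateDataError, ValidationError
from .partition import Partition, restrict

__all__ = [
    "SamplingDesign",
    "balanced_draws",
    "scores_over_draws",
    "aggregate",
    "aitchison_mean",
]


@dataclass(frozen=True)
class SamplingDesign:
    """Which metadata columns define balance, and how many draws to take.

    ``category_column`` and ``condition_column`` are interchangeable roles
    over metadata columns (e.g. strain and sex); ``sample_id_column`` names
    the replicate identifier (e.g. mouse id). Every observed category x
    condition pair must have at least one sample.
    """

    category_column: str
    condition_column: str
    sample_id_column: str
    n_draws: int = 100
    seed: int | None = None

    def __post_init__(self):
        if self.n_draws < 1:
            raise ValidationError("n_draws must be >= 1")


def _sample_table(metadata: pd.DataFrame, design: SamplingDesign) -> pd.DataFrame:
    for col in (
        design.category_column,
        design.condition_column,
        design.sample_id_column,
    ):
        if col not in metadata.columns:
            raise ValidationError(f"metadata column {col!r} not found")
    tab = metadata[
        [design.sample_id_column, design.category_column, design.condition_column]
    ].drop_duplicates()
    dup = tab[design.sample_id_column].duplicated()
    if dup.any():
        bad = sorted(tab.loc[dup, design.sample_id_column].unique())
        raise ValidationError(
            f"sample ids spanning multiple category/condition pairs: {bad}"
        )
    return tab


def balanced_draws(metadata: pd.DataFrame, design: SamplingDesign) -> list[list]:
    """Generate balanced draws of sample ids.

    Each draw holds exactly one sample per (category, condition) pair.
    Selection prefers the least-used eligible sample across draws (usage
    counter), with ties broken by a seeded RNG, which minimizes repeated
    selection of the same replicates. Deterministic for a fixed seed.
    """
    tab = _sample_table(metadata, design)
    cats = sorted(tab[design.category_column].astype(str).unique())
    conds = sorted(tab[design.condition_column].astype(str).unique())
    pools: dict[tuple[str, str], list] = {}
    for (c, d), grp in tab.groupby(
        [design.category_column, design.condition_column], sort=True, observed=True
    ):
        pools[(str(c), str(d))] = sorted(grp[design.sample_id_column])
    missing = [(c, d) for c in cats for d in conds if (c, d) not in pools]
    if missing:
        raise BalanceError(
            "balanced sampling requires at least one sample for every "
            f"category-condition pair; empty pairs: {missing}"
        )
    rng = np.random.default_rng(design.seed)
    usage: dict = {s: 0 for pool in pools.values() for s in pool}
    draws: list[list] = []
    pairs = sorted(pools)
    for _ in range(design.n_draws):
        chosen = []
        for pair in pairs:
            pool = pools[pair]
            m = min(usage[s] for s in pool)
            cands = [s for s in pool if usage[s] == m]
            pick = cands[rng.integers(len(cands))]
            usage[pick] += 1
            chosen.append(pick)
        draws.append(chosen)
    return draws


def _score_frame(terms, r, block_labels, gene_ids) -> pd.DataFrame:
    psi, zeta, comp, flags = _scores_from_terms(terms, r)
    out = {"Psi": psi, "zeta": zeta}
    for i, b in enumerate(block_labels):
        out[f"psi_{b}"] = comp[i]
    out["degenerate_flag"] = flags
    return pd.DataFrame(out, index=pd.Index(gene_ids, name="gene"))


def scores_over_draws(
    adata,
    partition: Partition,
    draws: list[list],
    design: SamplingDesign,
) -> list[pd.DataFrame]:
    """Score every gene once per balanced draw.

    Each draw restricts the matrix to cells whose sample id is in the draw
    and rescores under the restricted partition. A draw whose restriction
    fails to retain every block of the partition is skipped with a warning
    (psi-block compositions from different block sets are not comparable);
    more than 50% skipped draws is a hard error. Genes degenerate within a
    draw carry NaN scores for that draw only.
    """
    sample_ids = adata.obs[design.sample_id_column].astype(str).to_numpy()
    X = adata.X
    gene_ids = list(adata.var_names)
    tables, skipped = [], []
    for k, draw in enumerate(draws):
        mask = np.isin(sample_ids, np.asarray(draw, dtype=str))
        if not mask.any():
            skipped.append(k)
            continue
        try:
            sub_p = restrict(partition, mask)
        except DegenerateDataError:
            skipped.append(k)
            continue
        if sub_p.r < partition.r:
            skipped.append(k)
            continue
        # restrict() preserves surviving-label order, so block columns align
        terms = _entropy_terms(X[mask], sub_p)
        tables.append(
            _score_frame(terms, sub_p.r, partition.block_labels, gene_ids)
        )
    if skipped:
        warnings.warn(
            f"skipped {len(skipped)} of {len(draws)} draws with incomplete "
            f"partitions: draws {skipped}",
            stacklevel=2,
        )
    if len(skipped) > len(draws) / 2:
        raise DegenerateDataError(
            f"{len(skipped)}/{len(draws)} draws lost partition blocks; "
            "the design cannot support this partition"
        )
    return tables


def _stack(per_draw: list[pd.DataFrame], block_labels):
    psi = np.stack([t["Psi"].to_numpy(float) for t in per_draw])
    zeta = np.stack([t["zeta"].to_numpy(float) for t in per_draw])
    comp = np.stack(
        [t[[f"psi_{b}" for b in block_labels]].to_numpy(float) for t in per_draw]
    )  # (D, G, r)
    return psi, zeta, comp


def aitchison_mean(comp: np.ndarray, return_gsd: bool = False):
    """Aitchison mean (and optional geometric SD) of compositions.

    ``comp`` is (n_draws, r), strictly positive rows summing to one.
    The mean is the closed component-wise geometric mean; the geometric SD
    is ``exp(sd(log component))`` per component (1.0 for a single draw).
    """
    comp = np.asarray(comp, dtype=float)
    if (comp <= 0).any():
        raise ValidationError("Aitchison mean requires strictly positive parts")
    logc = np.log(comp)
    g = np.exp(logc.mean(axis=0))
    mean = g / g.sum()
    if not return_gsd:
        return mean
    if comp.shape[0] > 1:
        gsd = np.exp(logc.std(axis=0, ddof=1))
    else:
        gsd = np.ones(comp.shape[1])
    return mean, gsd


def _replace_zeros(comp: np.ndarray) -> np.ndarray:
    """Multiplicative zero replacement for one gene's (D, r) compositions.

    delta = half the smallest nonzero part observed for the gene across
    draws; zeros become delta and rows are re-closed to sum one.
    """
    pos = comp[comp > 0]
    if pos.size == 0:
        return comp
    delta = 0.5 * pos.min()
    out = np.where(comp > 0, comp, delta)
    return out / out.sum(axis=1, keepdims=True)


def _aggregate_compositions(comp: np.ndarray, usable: np.ndarray):
    """Per-gene Aitchison mean + gsd over usable draws; comp is (D, G, r)."""
    D, G, r = comp.shape
    amean = np.full((G, r), np.nan)
    gsd = np.full((G, r), np.nan)
    for g in range(G):
        rows = comp[usable[:, g], g, :]
        if rows.shape[0] == 0:
            continue
        rows = _replace_zeros(rows)
        amean[g], gsd[g] = aitchison_mean(rows, return_gsd=True)
    return amean, gsd


def aggregate(
    per_draw: list[pd.DataFrame], block_labels=None, name: str | None = None
) -> pd.DataFrame:
    """Aggregate per-draw score tables into replicate-robust summaries.

    Psi and zeta get the arithmetic mean and (n-1)-denominator SD over the
    draws in which the gene was scoreable; psi-block compositions get the
    Aitchison mean after multiplicative zero replacement, plus per-block
    geometric SDs. Genes with zero usable draws keep their row with NaN
    scores and ``n_draws_used = 0``.
    """
    if not per_draw:
        raise ValidationError("aggregate requires at least one draw table")
    if block_labels is None:
        block_labels = [
            c[len("psi_") :] for c in per_draw[0].columns if c.startswith("psi_")
        ]
    genes = per_draw[0].index
    psi, zeta, comp = _stack(per_draw, block_labels)
    usable = ~np.isnan(psi)  # (D, G); zero_total draws are NaN
    n_used = usable.sum(axis=0)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices
        psi_mean = np.nanmean(np.where(usable, psi, np.nan), axis=0)
        zeta_mean = np.nanmean(np.where(usable, zeta, np.nan), axis=0)
        psi_sd = np.nanstd(np.where(usable, psi, np.nan), axis=0, ddof=1)
        zeta_sd = np.nanstd(np.where(usable, zeta, np.nan), axis=0, ddof=1)
    psi_sd[n_used == 1] = 0.0
    zeta_sd[n_used == 1] = 0.0
    psi_sd[n_used == 0] = np.nan
    zeta_sd[n_used == 0] = np.nan

    amean, gsd = _aggregate_compositions(comp, usable)

    out = {"Psi_mean": psi_mean, "Psi_sd": psi_sd}
    out["zeta_mean"] = zeta_mean
    out["zeta_sd"] = zeta_sd
    for i, b in enumerate(block_labels):
        out[f"psi_{b}"] = amean[:, i]
    for i, b in enumerate(block_labels):
        out[f"psi_{b}_gsd"] = gsd[:, i]
    out["n_draws_used"] = n_used
    result = pd.DataFrame(out, index=genes)
    if name is not None:
        result.insert(0, "partition", name)
    return result
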