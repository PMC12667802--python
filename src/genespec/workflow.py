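"""End-to-end scoring pipeline: filter -> partitions -> draws -> scores ->
permutation p-values -> one global BH correction across all partitions and
metrics."""

from __future__ import annotations

import numpy as np

from .estimators import BalancedEntropySpecificity
from .inference import attach_qvalues
from .io import filter_genes

__all__ = ["score_workflow"]


def score_workflow(
    adata,
    partitions: list,
    *,
    category_col: str | None = None,
    condition_col: str | None = None,
    sample_col: str | None = None,
    n_draws: int = 100,
    n_permutations: int = 100,
    use_sampling: bool = True,
    raw_pvalues: bool = False,
    seed: int | None = None,
    min_cells: int = 100,
):
    """Score every requested partition and pool q-values globally.

    ``partitions`` is a list of column specs; each spec is a metadata column
    name, a ``"col1:col2"`` interaction string, or a list of columns.
    Returns ``{partition_name: score table}`` with ``q_*`` columns from one
    BH correction over all p-values of all partitions and metrics.
    """
    adata = filter_genes(adata, min_cells=min_cells)
    tables = {}
    for i, spec in enumerate(partitions):
        est = BalancedEntropySpecificity(
            partition_by=spec,
            category_col=category_col,
            condition_col=condition_col,
            sample_col=sample_col,
            n_draws=n_draws,
            n_permutations=n_permutations,
            use_sampling=use_sampling,
            raw_pvalues=raw_pvalues,
            random_state=None if seed is None else int(seed) + 97 * i,
        )
        est.fit(adata)
        name = est.partition_.name
        tab = est.results_.drop(
            columns=[c for c in est.results_.columns if c.startswith("q_")]
        )
        tab.insert(0, "partition", name)
        tables[name] = tab
    if n_permutations:
        tables = attach_qvalues(tables)
    # Normalize single-shot tables to the aggregated schema (one "draw").
    for name, tab in tables.items():
        if "Psi" in tab.columns:
            tab = tab.rename(columns={"Psi": "Psi_mean", "zeta": "zeta_mean"})
            tab.insert(tab.columns.get_loc("Psi_mean") + 1, "Psi_sd", 0.0)
            tab.insert(tab.columns.get_loc("zeta_mean") + 1, "zeta_sd", 0.0)
            for b in [
                c[len("psi_") :]
                for c in tab.columns
                if c.startswith("psi_") and not c.endswith("_gsd")
            ]:
                tab[f"psi_{b}_gsd"] = 1.0
            tab["n_draws_used"] = np.where(tab["Psi_mean"].notna(), 1, 0)
            tables[name] = tab
    return tables
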