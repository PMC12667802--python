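"""Scikit-learn style estimators wrapping the entropy-specificity pipeline.

:class:`EntropySpecificity` is the core per-gene scorer: ``fit(X, y)`` with
``X`` a cells x genes matrix and ``y`` a block label per cell (or a
:class:`~genespec.partition.Partition`). :class:`BalancedEntropySpecificity`
runs the full replicate-robust pipeline on an annotated matrix: balanced
draws, per-draw scoring, Aitchison aggregation and permutation inference.
Both follow sklearn conventions (``get_params``/``set_params``, fitted
attributes with trailing underscores) and compose with sklearn tooling.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .entropy import _entropy_terms, _scores_from_terms
from .errors import ValidationError
from .partition import Partition, partition_from_metadata

__all__ = ["EntropySpecificity", "BalancedEntropySpecificity"]


def _as_partition(y, n_cells: int) -> Partition:
    if isinstance(y, Partition):
        if y.n_cells != n_cells:
            raise ValidationError(
                f"partition covers {y.n_cells} cells but X has {n_cells} rows"
            )
        return y
    y = np.asarray(y)
    if y.ndim != 1 or y.size != n_cells:
        raise ValidationError("y must be one block label per cell")
    labels, codes = np.unique(y.astype(str), return_inverse=True)
    if labels.size < 2:
        raise ValidationError("y must contain at least 2 distinct blocks")
    return Partition("y", tuple(labels), codes.astype(np.intp))


class EntropySpecificity(BaseEstimator):
    """Per-gene entropy decomposition and specificity scores.

    Parameters
    ----------
    chunk_size
        Process genes in column chunks of this size (memory control on wide
        matrices); results are independent of chunking. ``None`` scores all
        genes at once.

    Attributes (after ``fit``)
    --------------------------
    block_labels_ : tuple of str
    e_t_, e_b_, e_w_ : (n_genes,) entropy terms in nats (NaN for all-zero genes)
    p_block_, e_block_ : (n_genes, r) block masses and within-block entropies
    psi_, zeta_ : (n_genes,) scores in [0, 1]
    psi_blocks_ : (n_genes, r) compositions summing to 1
    degenerate_ : (n_genes,) object array of flags
    """

    def __init__(self, *, chunk_size: int | None = None):
        self.chunk_size = chunk_size

    def fit(self, X, y):
        """Compute scores for every gene (column) of ``X``.

        ``y`` is a length-``n_cells`` vector of block labels or a Partition.
        """
        X = getattr(X, "X", X)  # accept AnnData
        partition = _as_partition(y, X.shape[0])
        r = partition.r
        G = X.shape[1]
        step = self.chunk_size or G or 1
        parts = []
        for lo in range(0, G, step):
            parts.append(_entropy_terms(X[:, lo : lo + step], partition))
        if not parts:
            parts = [_entropy_terms(np.empty((X.shape[0], 0)), partition)]
        terms = {
            k: np.concatenate([p[k] for p in parts], axis=-1) for k in parts[0]
        }
        psi, zeta, comp, flags = _scores_from_terms(terms, r)

        self.partition_ = partition
        self.block_labels_ = partition.block_labels
        self.n_features_in_ = G
        self.e_t_ = terms["e_t"]
        self.e_b_ = terms["e_b"]
        self.e_w_ = terms["e_w"]
        self.p_block_ = terms["p_block"].T
        self.e_block_ = terms["e_block"].T
        self.psi_ = psi
        self.zeta_ = zeta
        self.psi_blocks_ = comp.T
        self.degenerate_ = flags
        return self

    def score_table(self, gene_ids=None) -> pd.DataFrame:
        """Fitted scores as one DataFrame row per gene."""
        if not hasattr(self, "psi_"):
            raise ValidationError("estimator is not fitted")
        if gene_ids is None:
            gene_ids = [f"g{i}" for i in range(self.n_features_in_)]
        out = {"Psi": self.psi_, "zeta": self.zeta_}
        for i, b in enumerate(self.block_labels_):
            out[f"psi_{b}"] = self.psi_blocks_[:, i]
        out["E_T"] = self.e_t_
        out["E_B"] = self.e_b_
        out["E_W"] = self.e_w_
        out["degenerate_flag"] = self.degenerate_
        return pd.DataFrame(out, index=pd.Index(gene_ids, name="gene"))


class BalancedEntropySpecificity(BaseEstimator):
    """Replicate-robust specificity scoring with permutation inference.

    ``fit`` takes an AnnData (cells x genes with per-cell ``.obs`` metadata).
    When ``category_col``/``condition_col``/``sample_col`` are set, scores
    are means over ``n_draws`` balanced sample draws; otherwise the full
    matrix is scored once. With ``n_permutations > 0``, block labels are
    scrambled to produce empirical p-values, pooled across metrics for a
    global BH correction.

    Attributes (after ``fit``)
    --------------------------
    partition_ : the Partition used
    draws_ : list of balanced draws (sample id lists), or None
    results_ : DataFrame with Psi/zeta means and SDs, psi-block Aitchison
        means and geometric SDs, p-values and q-values per gene.
    """

    def __init__(
        self,
        *,
        partition_by=None,
        category_col: str | None = None,
        condition_col: str | None = None,
        sample_col: str | None = None,
        n_draws: int = 100,
        n_permutations: int = 100,
        use_sampling: bool = True,
        raw_pvalues: bool = False,
        random_state: int | None = None,
    ):
        self.partition_by = partition_by
        self.category_col = category_col
        self.condition_col = condition_col
        self.sample_col = sample_col
        self.n_draws = n_draws
        self.n_permutations = n_permutations
        self.use_sampling = use_sampling
        self.raw_pvalues = raw_pvalues
        self.random_state = random_state

    def _partition(self, adata, y) -> Partition:
        if y is not None:
            return _as_partition(y, adata.shape[0])
        if self.partition_by is None:
            raise ValidationError("either y or partition_by must be given")
        cols = (
            self.partition_by.split(":")
            if isinstance(self.partition_by, str)
            else list(self.partition_by)
        )
        return partition_from_metadata(adata.obs, cols)

    def fit(self, X, y=None):
        from . import inference, sampling

        adata = X
        if not hasattr(adata, "obs"):
            raise ValidationError(
                "BalancedEntropySpecificity.fit expects an AnnData"
            )
        partition = self._partition(adata, y)
        gene_ids = list(adata.var_names)

        sampled = all(
            c is not None
            for c in (self.category_col, self.condition_col, self.sample_col)
        )
        draws = None
        design = None
        if sampled:
            design = sampling.SamplingDesign(
                category_column=self.category_col,
                condition_column=self.condition_col,
                sample_id_column=self.sample_col,
                n_draws=self.n_draws,
                seed=self.random_state,
            )
            draws = sampling.balanced_draws(adata.obs, design)
            per_draw = sampling.scores_over_draws(adata, partition, draws, design)
            observed = sampling.aggregate(
                per_draw, block_labels=partition.block_labels
            )
        else:
            est = EntropySpecificity().fit(adata.X, partition)
            observed = est.score_table(gene_ids=gene_ids)

        if self.n_permutations:
            cfg = inference.PermutationConfig(
                n_permutations=self.n_permutations,
                seed=None
                if self.random_state is None
                else self.random_state + 1,
                use_sampling=self.use_sampling and sampled,
                raw=self.raw_pvalues,
            )
            pvals = inference.permutation_pvalues(
                adata, partition, observed, cfg, draws=draws, design=design
            )
            observed = pd.concat([observed, pvals], axis=1)
            qtab = inference.attach_qvalues({partition.name: observed})
            observed = qtab[partition.name]

        observed.index = pd.Index(gene_ids, name="gene")
        self.partition_ = partition
        self.block_labels_ = partition.block_labels
        self.draws_ = draws
        self.results_ = observed
        self.n_features_in_ = adata.shape[1]
        return self
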