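# genespec

Entropy-based gene specificity scores for multivariate single-cell (and
bulk) expression data.

Modern single-cell experiments span many categorical variables at once —
strain, sex, tissue, age, cell type — and a recurring question is *which
genes are specific to which variable*. Classical indices (τ/TSI, PEM, Gini)
give a single number per gene but do not decompose coherently when the data
are partitioned along several variables or refined hierarchically.
`genespec` scores specificity with Shannon entropy, which does.

## The scores

Let `x_i ≥ 0` be a gene's weight (count or normalized value) in cell `i`,
`p_i = x_i / Σx`, and partition the `n` cells into `r` blocks. With
`E_T = −Σ p_i log p_i` the total entropy, `q_j = x_j / Σ_{k∈C} x_k` within
block `C`, `E_C = −Σ q_j log q_j`, block mass `p_C = Σ_{j∈C} p_j`, and
`E_W = Σ_C p_C E_C`, Shannon's grouping identity gives `E_T = E_B + E_W`.
Three scores follow, all in `[0, 1]`:

| score | definition | reads as |
|---|---|---|
| `Ψ` | `E_W / E_T` | fraction of the gene's information explained by the partition |
| `ψ_block(C)` | `p_C E_C / E_W` | compositional share of within-block information in block `C` (sums to 1) |
| `ζ` | `1 − H(ψ_blocks)/log r` | normalized KL divergence of the ψ composition from uniform |

A marker gene has high `ψ_block` for its block and high `Ψ`; a
partition-specific gene has high `ζ` and `Ψ`; a housekeeping-like gene has
high `Ψ` with `ζ` near 0. `E_B` is additive under hierarchical refinement
(`E_B(fine) = E_B(coarse) + Σ_C p_C E_B(fine|C)`), which is what makes the
scores comparable across nested partitions.

Around the core scores the package provides:

* **balanced replicate sampling** — draws containing exactly one sample
  (e.g. mouse) per category×condition pair, scored per draw; `Ψ`/`ζ`
  aggregate arithmetically, `ψ_block` compositions by Aitchison mean with
  geometric SDs;
* **permutation inference** — block labels scrambled, one-sided empirical
  p-values per metric, pooled across all metrics and partitions for one
  global Benjamini–Hochberg correction;
* **selection workflows** — marker / partition-specific / housekeeping gene
  lists, upset-plot membership export, and a gene×block `ψ` feature matrix
  for external clustering;
* **simplex visualization** — `ψ_block` compositions projected
  barycentrically onto a regular `r`-gon (vertex = fully block-specific,
  centroid = uniform);
* **a seeded synthetic-data generator** with planted marker, housekeeping
  and noise genes for validation.

The library core is a pair of scikit-learn-style estimators:
`EntropySpecificity` (`fit(X, y)` with cells×genes `X` and per-cell block
labels `y`) and `BalancedEntropySpecificity` (the full pipeline on an
AnnData). A `genespec` CLI wraps them.

## Worked example

The library on a four-cell gene with counts `[8, 2, 1, 1]` split into
blocks `{c1,c2}` and `{c3,c4}`:

```python
>>> import numpy as np
>>> from genespec import Partition, decompose_entropy, specificity_scores
>>> p = Partition("group", ("A", "B"), np.array([0, 0, 1, 1]))
>>> d = decompose_entropy([8, 2, 1, 1], p)
>>> print(f"E_T = {d.e_t:.5f}  E_B = {d.e_b:.5f}  E_W = {d.e_w:.5f}")
E_T = 0.98309  E_B = 0.45056  E_W = 0.53253
>>> s = specificity_scores(d)
>>> print(f"Psi = {s.psi:.4f}  zeta = {s.zeta:.4f}  psi_blocks = {np.round(s.psi_blocks, 4)}")
Psi = 0.5417  zeta = 0.2455  psi_blocks = [0.7831 0.2169]
```

54% of this gene's expression information lies within the blocks, and 78%
of that within-block information sits in block A — the gene leans toward A
but is far from exclusive (`ζ = 0.25`).

End to end from a shell, on a simulated 2400-cell factorial design
(4 strains × 2 sexes × 3 replicate samples, 4 cell types, 60 genes):

```sh
$ genespec simulate --seed 7 --out-dir sim
simulated 2400 cells x 60 genes
$ genespec score --matrix sim/matrix.mtx --genes sim/genes.tsv \
    --cells sim/cells.tsv --metadata sim/metadata.tsv \
    --partition celltype --category strain --condition sex \
    --sample-col sample_id --n-draws 20 --n-perms 200 --min-cells 50 \
    --seed 1 --out-dir run
celltype: 60 genes scored
$ genespec select --scores run/scores_celltype.tsv --mode marker \
    --block Tcell --out markers.tsv
5 genes selected
```

The five selected genes are exactly the five planted T-cell markers:

```
gene            psi_Tcell  Psi_mean  zeta_mean  q_psi_Tcell  q_Psi
marker_Tcell_2     0.9989    0.9919     0.9909       0.0289  0.0289
marker_Tcell_1     0.9983    0.9906     0.9887       0.0289  0.0289
marker_Tcell_3     0.9982    0.9898     0.9870       0.0289  0.0289
...
```

`psi_Tcell ≈ 1` says essentially all of each gene's informative expression
sits in the T-cell block; `q` values are globally BH-corrected permutation
p-values. Planted housekeeping genes score `Ψ ≈ 0.77, ζ ≈ 0.002` —
informative but spread evenly — and `genespec select --mode housekeeping
--zeta-max 0.1` ranks them by uniformity.

`genespec upset` exports cross-partition membership tables, and
`genespec project` writes polygon coordinates plus an SVG of the
composition cloud.

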