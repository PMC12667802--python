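# Methods

## Model

For one gene, expression across `n` cells is treated as a discrete
probability distribution `p_i = x_i / Σ x` over cells; `x` can be raw
counts or library-normalized values, since every downstream quantity is
invariant to rescaling `x` by a positive constant. A *partition* assigns
every cell to exactly one of `r ≥ 2` labeled blocks. Shannon's grouping
identity splits the total entropy `E_T = −Σ p_i log p_i` into a
between-block part `E_B = −Σ_C p_C log p_C` and a within-block part
`E_W = Σ_C p_C E_C`, where `p_C` is the block's share of the gene's mass
and `E_C` the entropy of the gene's distribution inside block `C`.

Three ratios summarize specificity:

* `Ψ = E_W / E_T ∈ [0, 1]` — how much of the gene's information the
  partition *fails* to separate between blocks, i.e. the fraction explained
  within blocks. `Ψ = 1` iff all mass sits in one block.
* `ψ_block(C) = p_C E_C / E_W` — the compositional share of within
  information contributed by block `C`. We use the mass-weighted form: it is
  the unique decomposition consistent with `E_W = Σ_C p_C E_C` and it makes
  the ψ vector a probability distribution (sums to one), which the
  definition of ζ requires. The unweighted ratio `E_C / E_W` does not sum
  to one and is not used.
* `ζ = 1 − H(ψ_blocks)/log r` — the normalized KL divergence of the ψ
  composition from the uniform composition. `ζ = 1` means one block carries
  all within information (fully partition-specific); `ζ = 0` means the
  information is spread evenly (housekeeping-like).

All entropies use the natural logarithm with the convention
`0 · log 0 = 0`; the three reported scores are ratios and therefore
independent of the base.

Key properties, each enforced by tests: conservation
(`E_T = E_B + E_W`), bounds (`E_B ≤ log r`, `E_C ≤ log |C|`, scores in
`[0, 1]`), invariance to block label order and to gene scaling, and
hierarchical additivity — for a refinement `fine ⊑ coarse`,
`E_B(fine) = E_B(coarse) + Σ_C p_C E_B(fine restricted to C)` — which makes
scores commensurable across nested partitions (e.g. `tissue` vs
`sex:strain:tissue`).

### Degenerate genes

* `E_T = 0` (at most one expressing cell, or zero total): scores are
  undefined and reported missing with flag `zero_total`.
* `E_T > 0` but `E_W = 0` (at most one expressing cell per block): `Ψ = 0`
  and the ψ composition is taken as the block mass vector `(p_C)` so that ζ
  remains defined; flag `zero_within`. This is the limit of the regular
  formulas as within-block entropies vanish. The default min-cells filter
  makes both cases rare.

## Numerical choices

Per-gene computation is vectorized over a CSC matrix; entropies accumulate
in double precision over nonzero entries only, with `E_C` computed as
`log S − (Σ x log x)/S` per block and clamped at 0 against float dust.
Block-wise reductions (`E_W`, `H(ψ)`) sum terms in ascending value order,
which makes `Ψ` and `ζ` bit-identical under any permutation of block
labels. `E_B` is reported as `E_T − E_W` for exact conservation; agreement
with the direct form `−Σ p_C log p_C` is asserted in tests at 1e-10.
Gene columns can be processed in chunks (`chunk_size`); results are
independent of chunking because no cross-gene reduction exists.

## Balanced sampling over replicates

Scores on the full matrix are dominated by whichever replicate contributed
the most cells. The sampler draws subsets of *sample ids* containing
exactly one sample per (category, condition) pair — both roles are
user-chosen metadata columns, e.g. strain × sex with mouse ids as samples —
and rescores each draw. Selection prefers the least-used eligible sample
(a usage counter across draws), with ties broken by a seeded RNG, so
replicates rotate through draws as evenly as possible; a pair with no
sample is an error, a pair with one sample is simply used every time.
Default 100 draws.

Aggregation over draws: `Ψ` and `ζ` get the arithmetic mean and
(n−1)-denominator SD. ψ compositions live on a simplex, so their central
tendency is the Aitchison mean (component-wise geometric mean, re-closed)
and their spread the per-component geometric SD. Because Aitchison geometry
is undefined at zero, zeros are first replaced multiplicatively with
`δ = ½ × (smallest nonzero ψ observed for that gene across draws)` and each
draw re-closed. A draw whose cell subset loses *any* block of the partition
is skipped with a warning — compositions over different block sets are not
comparable — and more than 50% skipped draws aborts with an error. A gene
unscoreable in every draw keeps its output row with missing scores and
`n_draws_used = 0`.

## Permutation inference

The null scrambles block labels: the cell→block assignment vector is
permuted uniformly at random, preserving block sizes, and the full observed
pipeline (including the mean over the same balanced draws, when sampling is
on) is recomputed. Empirical p-values are one-sided (high is significant)
with the add-one estimator `p = (1 + #{perm ≥ obs})/(1 + n_perm)`, which
avoids `p = 0`; the raw proportion is available behind a flag. The `≥`
comparison carries an absolute tolerance of 1e-12 so that mathematically
tied statistics (e.g. the same gene after rescaling) count as ties
regardless of last-ulp rounding. A permutation that degenerates a gene
contributes a null value of 0. P-values for `Ψ`, `ζ` and every `ψ_block`
are pooled — across partitions too, when several are scored in one run —
into a single Benjamini–Hochberg correction (via
`statsmodels.stats.multitest`), giving a global FDR statement.

Note an intrinsic property of the one-sided high test: a gene whose
expression is genuinely exchangeable with respect to the blocks has an
observed `Ψ` that is a typical draw from its own null, so truly uniform
(housekeeping-like) genes are *not* expected to reach significance on
exchangeable data; on real data, housekeeping genes are block-structured
enough in `Ψ` for the published workflow's q-gate to be meaningful.
Permutation counts: default 100. The empirical p floor is
`1/(n_perm + 1)`; when many p-values are pooled for BH, `n_perm` must be
large enough that the floor clears the BH cut or no discovery is possible —
the acceptance FDR run uses 500 for this reason.

## Selection workflows

All selections gate on global q-values (`q < q_max`, default 0.05) first,
then apply strict thresholds (default 0.5): markers require high
`ψ_block(target)` and `Ψ` (ranked by ψ then Ψ); partition-specific genes
high `ζ` and `Ψ` (ranked by ζ then Ψ); housekeeping genes high `Ψ` with
`ζ < ζ_max` (ranked by ascending ζ). Ties break lexicographically by gene
id. Cross-partition memberships are exported as a boolean gene×partition
indicator table plus exclusive intersection-region counts — the input
format of standard upset-plot tools — and the gene×block Aitchison-mean ψ
matrix is exported for external clustering (e.g. Leiden on a kNN graph);
clustering itself is out of scope.

## Simplex projection

A ψ composition over `r` blocks is a point of the `(r−1)`-simplex and maps
to a regular `r`-gon by barycentric combination of vertex coordinates
(first vertex at the top, counter-clockwise). One-hot compositions land on
vertices, uniform at the centroid, and the map is affine. Vertex ordering
matters: up to the dihedral symmetries of the polygon there are `(r−1)!/2`
distinct projections (2520 for an octagon), and the choice among them is
domain knowledge (e.g. ordering strains by genetic distance), so the
ordering is user-supplied with partition order as the default.

## Synthetic data

The generator emulates factorial designs with replicates: sample-level
factors (e.g. strain × sex) times replicate samples, each containing cells
of every level of a within-sample factor (e.g. cell type) that carries the
planted structure. Counts are negative binomial with dispersion `θ`
(variance `μ + μ²/θ`, default `θ = 10`), and each sample gets a lognormal
random effect (σ = 0.2) shared across genes, so balanced sampling has real
replicate variance to average over. Defaults: 4 strains × 2 sexes ×
3 samples, 4 cell types × 25 cells — 2400 cells.

Gene classes: **markers** have mean `baseline × fold_enrichment` (defaults
1.0 × 8) inside their target block and a small ambient-level leak mean
elsewhere (default 0.02 counts/cell, the scale of ambient-RNA
contamination; set to 0 for strictly block-exclusive expression, which
yields `Ψ = ζ = 1` exactly); **housekeeping** genes share one mean
everywhere; **noise** genes get a per-gene lognormal mean constant across
cells, hence exchangeable with respect to any block structure. A separate
`simulate_null` produces fully exchangeable matrices with equal blocks for
calibration tests.

What the generator does *not* emulate: gene–gene correlation, cell-level
library-size variation, batch effects, zero inflation beyond NB, or
realistic mean–variance spectra. Passing tests on it demonstrates
correctness of the scoring, aggregation and inference machinery under known
ground truth — not performance on any particular real dataset.

## Problem sizes used in validation

The acceptance checks run at desk scale, chosen to keep the whole
validation under a minute while leaving no property under-sampled: ~1000
random genes across partitions with `r ∈ {2,…,10}` for conservation; 100
random nested-partition genes for hierarchical additivity; 200 null genes ×
400 cells × 100 permutations for calibration; 20 seeds × 200 genes × 500
permutations for the realized-FDP check; and an 8-block, 200-cells-per-block
design at fold-enrichment 8 for planted-structure recovery.

## Known limitations

* Continuous covariates must be binned by the user before partitioning.
* The permutation null treats cells as exchangeable units; correlation
  between cells of the same sample is addressed by balanced draws, not by
  a sample-level permutation scheme.
* The Aitchison zero-replacement δ is conventional; compositions dominated
  by structural zeros (blocks where a gene is never informative) are pulled
  slightly toward the interior.
* With few permutations the p floor `1/(n_perm+1)` limits attainable
  q-values under global pooling; raise `--n-perms` when scoring many genes
  or partitions.
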