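# Methods

## Mixing model and residual profiles

Bulk whole-blood expression is modelled on the linear (un-logged) scale
as `X = B·F + R`: `B` (genes × cell types) is the cell-type expression
under healthy conditions, `F` (cell types × samples) the per-sample
frequencies, `R` the residual.  Deconvolution and residualization
operate on the linear scale because the mixture is linear there; log
transforms break additivity.  Residuals are left on the linear scale
(the downstream Z-transform removes per-gene scale anyway); the
raw-expression classifier branch uses `log2(x+1)` features, the field's
standard representation for expression magnitudes.

For a control sample `R` is measurement noise; for a disease sample it
adds the difference between diseased and healthy cell-type expression
weighted by the cell's frequency.  Deviations caused purely by
composition change cancel, which is the entire point: `R` carries cell
*state* change per sample, not cell *abundance* change.  `R` cannot
attribute a change to a specific cell type.

## Frequency estimation

**Marker-based (digital sorting).**  With cell-type-exclusive markers,
the mean marker expression obeys `m_kj = c_k · f_kj`.  Summing over cell
types and imposing `Σ_k f_kj = 1` gives the linear system
`Σ_k m_kj · g_k = 1` over samples, solved for `g = 1/c` by NNLS
(`scipy.optimize.nnls`); then `f_kj = m_kj · g_k`, rescaled to the
simplex by default.  The stage-2 reformulation on `g` rather than a
constrained program on `c` is exactly solvable on toy systems, which the
tests exploit.  Samples whose marker means are all zero cannot be scaled
and come back as missing columns.

**Signature-based.**  Per-sample non-negative regression of the bulk
profile onto a genes × cell-types signature matrix.  The gene overlap
between matrix and signature must exceed the number of cell types.

**Basis estimation.**  `B` is fitted one gene at a time by NNLS with the
control-sample frequency columns as design.  NNLS equals OLS whenever
the OLS solution is non-negative; a warning is emitted for
near-rank-deficient designs (condition number above 1e8) or fewer
controls than cell types.

## Preprocessing

Quantile normalization maps every sample column onto the across-sample
mean of sorted columns; ties take the mean of the reference values over
the tied ranks.  Gene filtering drops genes at or below the 25th
percentile of per-gene means *within each dataset* (a gene low in any
dataset is dropped from the combined matrix) and genes missing in more
than 20% of all samples; remaining gaps are imputed from the `k = 10`
nearest genes by Euclidean distance over shared observed samples,
averaging neighbors observed at the target sample.  Setting the
percentile to 0 disables the low-expression filter.

The control-anchored Z-transform standardizes each feature by the mean
and n−1 SD of its dataset's **control samples only**, so controls are
approximately N(0,1) everywhere while case deviations survive.
Features with control SD ≤ 1e−8 are excluded and reported rather than
producing infinities.  Fitting (`fit_z_params`) and application
(`apply_z`) are separate so parameters can come exclusively from
training-partition controls.  A gene-wise multiplicative batch factor —
the nuisance the simulator injects per dataset — is an additive gene
offset after log, and is removed exactly by this transform in the
noiseless limit.

## Classification and evaluation schema

A disease-specific classifier takes one disease's cases as positives
and everything else (controls and other diseases' cases) as negatives.
Branches are elastic-net logistic regressions
(`sklearn.LogisticRegression`, saga solver, inverse-prevalence class
weights); features are pre-selected by |Welch t| on training labels
(ties broken by feature id), and the penalty mix / strength are chosen
by seeded stratified inner cross-validation maximizing mean AUC, with
ties resolved toward stronger regularization.  `train_branch` defaults
to the full grid (l1_ratio ∈ {0, .25, .5, .75, 1} × five log-spaced C
values, 10 inner folds).  Model selection runs at a loose optimizer
tolerance; the winning pair is refit tightly.  The combined score is the
element-wise product of the residual-branch and cell-component-branch
posteriors; combination is restricted to two branches.

Evaluation is leakage-controlled: for each dataset D of the target
disease, D's samples rotate through ten sub-folds — nine tenths are used
*only* to fit D's Z-params and basis, the remaining tenth is scored.
Other datasets of the same disease contribute all their samples to
training; datasets of other diseases rotate through a stratified
10-fold train/test-negative split, with their parameters fitted on their
training-portion controls.  Every round asserts (a) no sample is both
parameter-fitting and scored and (b) no test positive shares a
dataset id with a training positive; `audit_leakage` re-checks the
recorded role assignments.  AUC uses the Mann–Whitney formulation with
half-credit for ties.  The whole schema repeats `outer_repeats` times
under distinct derived seeds.

`evaluate_disease_specific` defaults to a compact hyperparameter grid
(l1_ratio {0, .5, 1} × C {0.1, 1, 10}, 3 inner folds) so a full
3-disease × 10-repeat benchmark (600 rounds, ~1800 branch fits with
model selection) completes in a few minutes on one CPU; this is the
package's benchmark-scale choice, and the full grid remains available
through the function's arguments.

## Meta-analysis

Per-dataset differential statistics use Welch's t with
Benjamini–Hochberg FDR (a deliberate substitution for moderated-t
empirical-Bayes approaches, which shrink variances but change little at
these group sizes; swap in a moderated backend by providing your own
stats frames).  Disease-informative genes are the union over datasets of
the top-m genes by p-value (ties by |log2FC| then gene id), restricted
to genes measured in more than half the datasets.  Dataset similarity is
the pairwise-complete Spearman correlation of log2 fold-change profiles
over those genes; clustering is complete linkage on 1 − correlation.
Commonly regulated genes: per dataset the up/down sets at BH-FDR < 0.1
are fixed; the observed count of genes moving in the same direction in
≥ n datasets is compared with the mean count over permutations that
reassign each dataset's labels uniformly among its measured genes at
fixed set sizes; FDR = expected/observed, undefined when nothing is
observed.

## Synthetic cohorts

The generator runs the mixing model forward: a log-normal basis
(meanlog 3, sdlog 0.5 by default), Dirichlet frequency columns,
disease-condition basis obtained by multiplying selected entries by a
fold in case samples only, unit-mean multiplicative log-normal noise
with a chosen coefficient of variation, and one gene-wise batch factor
`exp(N(0, sd²))` per dataset.  Frequency shifts act on Dirichlet
concentrations (`α_k ← α_k(1+shift)`, floored at 0.01), so columns stay
on the simplex without clipping; note that shifts are therefore
*relative* re-weightings.  Marker genes are drawn disjointly and made
the row maximum of their own cell type; by default marker rows are
zeroed outside their own type (strictly cell-type-exclusive markers,
the regime marker-based deconvolution assumes).

### Default benchmark conditions

The standard study conditions (`default_benchmark`) encode the
mechanisms the method is built around, chosen once and used by tests
and the acceptance script alike:

- **Composition variance dominates measurement noise.**  Dirichlet
  concentrations (3.84, 1.28, 1.92, 0.96) — granulocyte ~48%,
  monocyte ~16%, CD4 T ~24%, B ~12% on average with realistic
  between-individual spread — and multiplicative noise cv 0.1.  Whole
  blood's defining nuisance is composition variability; if technical
  noise dominated, removing the composition component would buy nothing.
- **Strongly lineage-restricted basis** (sdlog 1.2).  Real blood genes
  concentrate in lineages; this is what makes the fluctuation of a
  cell type's frequency mask that cell's restricted expression changes
  in bulk, the effect residualization reverses.
- **Shared composition shift** (granulocyte/monocyte +0.5, CD4/B −0.35)
  across all three diseases — the common myeloid-up/lymphoid-down
  pattern that confounds raw-expression classifiers — plus distinct
  per-disease composition signatures that give the cell-component
  branch its signal.
- **Disease-specific cell-state change**: 25 disjoint genes per disease
  perturbed at a modest fold 1.7 (half up, half at 0.59) in one cell
  type — many moderately changed genes rather than a few strong ones,
  so benchmark outcomes do not hinge on which individual genes receive
  the effect.
- Two datasets per disease, 20 cases / 30 controls each, gene-wise
  batch sd 0.3, 10 markers per cell type, 400 genes.

What the generator does *not* emulate: probe-level artifacts, platform
nonlinearity, correlated gene modules beyond the cell-type structure,
within-cell-type expression gradients, or demographic confounding.
Passing benchmarks therefore demonstrate the mechanisms — composition
masking, residual unmasking, Z-removable batch structure, leakage-free
evaluation — not performance on any real cohort.

## Benchmark problem sizes and numerical choices

Deconvolution recovery runs at 500 genes / 40 samples / 4 cell types
(noise cv 0.2 and 0); residual nullification at 1000 genes with 40
cases and an ample 100-control arm (with few controls, basis-estimation
error itself induces a small systematic case/control residual
difference — a real property of the method worth knowing about);
the classification benchmark at 10 repeats × 3 diseases × 20 rounds;
cluster dissolution on a 10-dataset collection (three shared-shift
diseases, two without) with control-population-level composition
variance, since extreme composition dispersion lets chance
case/control imbalance in unshifted datasets mimic the shared axis.
Grid-search oracles for the NNLS estimators use a 1e-3-resolution
two-dimensional grid evaluated in closed quadratic form.

Degenerate inputs: duplicate gene rows collapse by the mean over
non-missing values (order-independent); all-zero marker-mean samples
become missing frequency columns; zero-variance features are excluded
from Z-params; single-class labels are errors everywhere they would
make a statistic undefined.

## Known limitations

- Residuals cannot attribute a state change to a cell type.
- The marker-based estimator assumes marker exclusivity; bleed-through
  expression biases frequencies (the `pure_markers=False` generator
  mode produces such data for sensitivity studies).
- The permutation null for common-gene detection ignores expression-
  level stratification and inter-gene correlation, making the FDR
  conservative in the correlated-genes regime tested.
- With product combination, a branch whose signal does not transfer
  across datasets can cost a little accuracy relative to the stronger
  branch; the evaluation reports all configurations so this is visible.
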