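# Methods

## Model

`ifcseq` treats cross-modal expression prediction as regression in shared
surface-marker space. The working assumption is that an IFC cell close in
marker coordinates to SCT cells has similar expression, so a map learned on
SCT (markers → log expression) transfers to IFC. The assumption holds only
to the extent that the chosen markers resolve the populations of interest;
populations that occupy a narrow marker range (the intermediate population
in the synthetic layout) are intrinsically harder to predict, which the
pipeline reproduces.

### Preprocessing (SCT)

Fixed order, asserted by `sct_preprocess.preprocess`:

1. *Species selection* (mixed-species data only): a cell is kept when it
   expresses strictly more first-species than second-species genes;
   "expressed" means a non-zero count. Ties are dropped — a cell with as
   many genes of each species is an ambiguous doublet candidate and
   keeping it would contaminate downstream filters.
2. *Minimum genes per cell* (default 200, mixed-species data only).
3. *Highly variable genes* (default on for the CITE-seq-style human case,
   off for the mouse-geometry synthetic runs): the 20-bin dispersion
   recipe with thresholds min_mean 0.0125, max_mean 3, min_disp −0.15,
   delegated to scanpy's seurat-flavor implementation. Counts are scaled
   per cell to the median library size before the dispersion statistics
   (toggleable via `hvg_library_normalize`; this scaling affects only HVG
   selection, never the final expression matrix). Genes with zero
   variance are never selected, even though the recipe's NaN→0 handling
   would otherwise pass them at negative dispersion thresholds.
4. *Minimum cells per gene* (default 20, boundary inclusive: a gene
   expressed in exactly 20 cells is kept).
5. *Log transform* x → ln(1 + x). The natural logarithm is the stated
   convention; the +1 offset is required because zero counts dominate UMI
   data and ln(0) is undefined.

Marker-gene ranking is one-vs-rest per population on log expression. The
default statistic is the Welch t-test (the historical default of the
ranking function used in this field's toolchain); a rank-sum alternative
is available via `de_method="wilcoxon"`. Equal statistics break ties by
gene id so rankings are deterministic. The union of per-population top
lists (default top 100) forms the evaluation gene subset.

### Co-registration and gating

Each marker column is min-max normalized to [0,1] independently per
modality; the original (min, max) are retained for inversion and recorded
in the run manifest. Normalization bounds are never shared across
modalities. Gates are axis-aligned rectangles supplied as configuration
data (the real datasets' gate coordinates are expert-drawn and not part of
the package); intervals are half-open [lo, hi) with the top edge hi = 1
closed, so a shared boundary never double-assigns a cell, and assignment
conflicts between overlapping gates resolve by explicit precedence order.
Ungated cells receive the reserved label "other".

### Expression model

One multi-output `RandomForestRegressor` predicts all targets jointly:
50 trees, `criterion="absolute_error"`, `max_features="sqrt"`, no
hyperparameter tuning and therefore no validation split. The SCT cells are
split 70/30 (train size = round(0.7·n), unstratified by default, seeded).
Surface channels can be appended to the target matrix (e.g. CD4 for the
human case) and are given the same ln(1+x) treatment as genes by default
(`log_extra_targets`); both choices are toggleable since the appropriate
scale for antibody counts is dataset-dependent. The linear baseline is
ordinary least squares on the same split. Forest predictions average
training leaves, so they are bounded by the per-target training range;
IFC marker values slightly outside [0,1] (possible because each modality
normalizes independently) produce a warning but are passed through
unmodified — silently clipping inputs would bias the prediction.

### Label-free CNN

A residual convolutional network maps a 32×32 single-channel brightfield
image (pixels divided by 65535) to the marker vector in [0,1]:

- input stem: 3×3 convolution (16 channels) + batch norm + ReLU;
- four stages of two residual blocks each, widths (16, 32, 64, 128);
  every block is conv–BN–ReLU–conv–BN plus an identity shortcut, with
  channel widening handled by zero-padding the shortcut (parameter-free),
  followed by ReLU;
- 2×2 max pooling between stages — every convolution uses zero padding,
  so pooling is the only source of spatial reduction;
- global average pooling, a dense layer, and a sigmoid so outputs are
  bounded in [0,1].

This gives exactly 17 convolutional layers and 688 946 parameters. The
widths were chosen to respect the block structure while keeping the
parameter count near 0.7 million. Batch normalization precedes every
activation except the final sigmoid. The network, including backward
passes and the Adam optimizer (lr 1e-3, β₁ 0.9, β₂ 0.999), is implemented
in NumPy with convolutions evaluated as batched GEMMs over a 9-offset
im2col expansion; all math is float32 and fully seeded, so training is
reproducible in a single-threaded run. Backpropagation is verified against
finite differences in the test suite.

Training: MSE loss, batch size 64 (auto-reduced with a warning when the
training set is smaller), a 10 % validation split, best-validation-loss
weights retained, early stopping after 5 epochs without strict
improvement, and on-the-fly augmentation flipping each image along the
vertical, horizontal, or both axes (on-the-fly sampling is equivalent in
expectation to a static 4× expansion and cheaper). The loss choice (MSE)
and learning rate are conventional regression defaults, exposed in
`CNNConfig`.

### Evaluation statistics

- Per-cell Pearson/Spearman/RMSE across the marker-gene subset; medians
  over cells are the headline numbers. Spearman uses average ranks for
  ties.
- Per-gene Pearson/Spearman across cells.
- Per-tree uncertainty: for each gene, the Pearson correlation of each
  tree's prediction with truth, then the population standard deviation
  (ddof = 0, n = number of trees).
- Undefined correlations (zero-variance vectors) are excluded from
  medians, never coerced to 0; exclusion counts are surfaced in the
  report.
- Population profiles: arithmetic mean expression per (population, gene);
  profile similarity: pairwise Pearson between profile rows.
- Fisher confidence intervals: tanh(atanh r ∓ z·(n−3)^(−1/2)). For a
  profile correlation, n is the number of genes in the profile vectors —
  a documented choice (`population_similarity` exposes the confidence
  level) since the effective sample size of a profile correlation is
  ambiguous. "A is significantly more similar to B than to C" means the
  lower bound of r(A,B) exceeds the upper bound of r(A,C).
- Bootstrap: correlation std over resamples of cell indices with
  replacement (default 10 000 iterations, seeded); constant resamples are
  skipped and counted.

## Synthetic study conditions

The generator fixes one set of conditions, used by tests and the
acceptance script alike:

- *Marker space*: three populations in the mouse-like geometry — extremes
  at (0.2, 0.2) and (0.8, 0.8) with spread 0.08, an intermediate at
  (0.5, 0.5) with spread 0.05 (deliberately narrow, reproducing the
  reduced predictability of an intermediate progenitor), and a diffuse
  "other" background (spread 0.28, weight 0.15). Marker coordinates are
  clipped to the unit square.
- *Counts*: negative binomial with θ = 2 (clearly overdispersed relative
  to Poisson, giving ~60 % zeros at these means so the min-cells and
  dispersion filters have realistic sparsity to act on). Gene log-means
  are base ~ N(−1, 0.5²) plus a +2.5 population effect for each of 10
  planted marker genes per population, plus marker slopes: 2.0 for 5
  dedicated marker-coding genes per marker, N(0, 0.25²) for the rest.
  120 genes by default. The gene plan is fixed by its own seed so both
  modalities and repeated calls share identical genes.
- *Noiseless targets* (`expected_log_expression`): ln(1 + exp(log-mean))
  with the population term resolved by gating the marker point — a
  deterministic monotone function of the markers, which is the quantity a
  perfect regressor could learn; used for the parameter-recovery check.
- *Images*: 32×32, 16-bit; background level 20 000 with Gaussian noise
  sd 300, a centered disk of radius 5 + 6·marker₁ at level 35 000, and
  interior speckle at level 55 000 with density 0.5·marker₂. Both markers
  are therefore recoverable from morphology alone, by construction.

What the generator does **not** emulate: batch effects within or across
modalities, ambient RNA, doublets, cell-cycle structure, realistic cell
morphology or fluorescence channels, and marker measurement noise that is
correlated with expression noise. Passing tests on this data demonstrate
that the implementation is correct and that the method recovers planted
structure under its own assumptions — not that those assumptions hold in
any particular real experiment.

## Problem sizes

Tests and the acceptance script run at desk scale, chosen once: 2 000 SCT
cells × 120 genes for parameter recovery, 2 000 training + 500 held-out
images with 8 training epochs for the label-free check, 1 000 IFC cells
for the standard-mode run. The real datasets the method was designed for
are one to two orders of magnitude larger; nothing in the implementation
is specific to the small sizes.

## Numerical choices and edge cases

- Split criterion `absolute_error` is markedly slower in scikit-learn
  than `squared_error`; it is the configured default because it is the
  published setting, and `ModelConfig.split_criterion` exposes it.
- Constant marker columns fail fast (cannot be min-max normalized;
  carry no information for regression).
- Constant targets are allowed (the forest predicts the constant).
- `fisher_ci` requires n ≥ 4 and |r| < 1; |r| = 1 returns the degenerate
  interval with a warning.
- Prediction CSVs carry a `.npy` sidecar so round trips are lossless; the
  CSV alone is accurate to 17 significant digits.
- All stage seeds derive from the single run seed via a CRC32 hash of the
  stage name, so any stage can be reproduced in isolation.

## Known limitations

- No batch-effect correction, doublet removal, or ambient-RNA cleanup;
  inputs are assumed preprocessed to that extent.
- Gates are rectangles only; polygonal or data-driven gating is out of
  scope.
- The forest is one joint multi-output model; per-gene models are not
  supported.
- The CNN trains on CPU; at the published dataset scale (65 008 images,
  50 epochs) training is feasible but slow — the architecture is small by
  design, and the implementation favors portability over speed.
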