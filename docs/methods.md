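# Methods

## Mixture model and scales

All methods assume the linear mixture model
`X[j,i] = Σ_k W[i,k]·H[j,k] + e[j,i]`: transcript counts add across cells,
so mixing is linear on the linear expression scale, while measurement and
modelling happen on log2. The simulator therefore mixes signatures
linearly and returns `log2` values; deconvolution un-logs (`2^x`)
log2-tagged input before solving; the supervised predictor works directly
on log2 expression, treating the relationship between log2 expression and
proportions as locally linear (an approximation that the held-out
evaluation, not an assumption, has to justify).

A floor of `2^-20` guards the logarithm against an exactly zero mixture.
We use a floor rather than a pseudo-count so that exact algebraic
identities (a pure sample's mixture equals its signature; a 50/50 mixture
equals the arithmetic mean of two signatures) hold to machine precision;
with realistic signature levels (tens to thousands of linear units) the
floor is never active.

## Supervised predictor

The multi-response Gaussian elastic net minimizes, over intercepts β₀ and
the genes × cell-types coefficient matrix B on centered (and by default
unit-variance standardized) data,

    (1/2N)·Σ_i ‖y_i − β₀ − Bᵀx_i‖² + λ·Σ_j [(1−α)/2·‖B_j‖₂² + α·‖B_j‖₂].

The l2 (not squared) row penalty couples the responses: row `B_j` is
soft-thresholded as a block, so a gene is selected jointly for all cell
types. Intercepts are never penalized. Responses are not standardized
(proportions already share a scale); feature standardization is internal
and coefficients are always reported on the original log2 scale.

Solver: block coordinate descent with the exact row update
`B_j ← z_j·max(0, 1 − λα/‖z_j‖)/(G_jj + λ(1−α))` on the Gram/cross-product
form (`G = XᵀX/N`, `C = XᵀY/N`), cycling full sweeps with active-set
iterations in between; the inner kernel is numba-compiled, with an
equivalent pure-numpy fallback. Two regimes have exact closed forms and
are solved directly: λ = 0 (least squares via `lstsq`, min-norm when
rank-deficient) and α = 0 (ridge, `(G + λI)⁻¹C`; the ridge λ path reuses
one eigendecomposition of `G`). Convergence: maximum absolute coefficient
change per sweep < 1e-7 (standardized scale) for final fits; fold fits
inside cross-validation use 2e-6, which resolves CV mean squared errors
far below their Monte-Carlo noise at a several-fold speedup.

λ path: `λ_max = max_j ‖x_jᵀY_c‖₂ / (N·max(α, 0.001))` — the smallest
penalty at which every row is zero (the 0.001 floor stands in for α on
the pure-ridge path, which has no finite λ_max) — descending
log-uniformly over 100 values to `λ_max·min_ratio`, with `min_ratio`
1e-4 when n > p and 1e-2 otherwise.

Tuning: k-fold cross-validation (default k = 10) over
α ∈ {1, 0.9, 0.5, 0.1, 0}, one seeded unstratified fold assignment shared
across the α grid so the comparison is paired; criterion is mean squared
prediction error pooled over all cell types; exact ties break toward the
smallest λ, then the largest α. The winning pair is refit on all samples.

Predictions are raw affine scores by default — they may leave [0, 1],
and the calibration of raw scores is part of what evaluation measures —
with `clip` and `clip_renorm` (clip to [0, 1], renormalize rows to 1)
available for downstream consumers that need closed compositions.

## Synthetic study design

The generator emulates a composition-training study on whole blood with
six leukocyte types (Gran, Mono, Bcell, CD4T, CD8T, NK). Defaults, with
units and rationale:

- `n_features = 500`, `n_samples = 150`: desk-scale stand-ins for a
  genome-wide array and a modest training cohort; every stage is O(p²)
  or better, so these sizes exercise the same code paths as real data.
- `dirichlet_mean = (0.60, 0.073, 0.05, 0.15, 0.08, 0.047)`: the
  monocyte mean matches a typical training cohort's 0.073; the others
  are standard adult whole-blood proportions chosen to close the vector.
- `dirichlet_concentration = 30` (unitless): gives a granulocyte sd of
  about 0.09 across samples, a realistic inter-individual spread.
- `markers_per_type = 5`, `marker_log2_fold = 4` (log2 units): 30
  planted marker genes, each 16-fold elevated in its own cell type —
  the strength of a good lineage marker.
- `baseline_log2_mean = 6`, `baseline_log2_sd = 1.5` (log2 units):
  moderate expression with realistic dynamic range. Each gene draws one
  baseline shared across cell types, so non-marker genes contribute
  equally under any composition and carry no composition signal: the
  planted markers are exactly the group-sparse set of informative
  features, which is what makes feature-recovery measurable.
- `noise_sd = 0.2` (log2 units): additive Gaussian noise on the log2
  mixture, equivalently multiplicative linear noise — the simplest model
  consistent with microarray error structure.
- `label_noise_sd = 0.03` (proportion units): truncated-Gaussian noise,
  clipped to [0, 1] and renormalized, standing in for proxy ("silver
  standard") training labels; at this setting the per-cell-type RMSE
  against truth lands near 0.03, inside the 0.01–0.08 range typical of
  methylation-derived composition estimates.

Randomness: `numpy.random.default_rng` (PCG64) throughout, with a fixed
stream layout — stage s of a run seeded with `seed` draws from
`default_rng([seed, s])` (0 basis, 1 compositions, 2 mixture noise,
3 label noise) — so outputs are bit-reproducible across platforms and
each stage is independently re-runnable. The CLI expands its single
`--seed` into per-stage seeds through `SeedSequence([seed, stage])`.

What the generator does **not** emulate: probe-level microarray physics,
batch effects, cross-platform identifier mapping, correlated biological
programs independent of composition (e.g. activation states), and cell
types absent from the panel. Passing tests therefore demonstrate
correctness of the algorithms under the stated generative model, not
field performance on any particular cohort.

## Low-expression filter

Features whose aggregated log2 expression falls below 5.5 are excluded
before training (`min` over samples by default, i.e. a gene is kept only
when expressed in every sample; `max` and `mean` are selectable since the
natural-language reading of "minimum expression below threshold across
samples" is ambiguous). The filter is idempotent and reports the excluded
identifiers.

## Reference-based deconvolution

Per sample, on the linear scale, aligned to the basis by exact identifier
intersection (at least K shared features required): `nnls` (default;
Lawson–Hanson via scipy) solves `min ‖x − Hw‖₂, w ≥ 0`; `iterative_prune`
re-implements the classical signature-regression procedure —
unconstrained least squares, repeatedly dropping the most negative
coefficient until all remaining are non-negative; `ols` is diagnostic.
With `normalize`, solutions are rescaled to sum to one; an identically
zero solution is returned as zeros with a degeneracy flag instead.

## Markers and surrogate proportion variables

Marker extraction assigns each retained gene to the cell type with the
largest absolute coefficient in its row, comparing on the standardized
scale (coefficient × feature sd) when the model was fit standardized so
genes of different dynamic range rank comparably. Exact ties go to the
earlier cell type in the model's canonical order and are logged. Within a
type, genes order by (|coefficient| desc, id asc); `top_k` truncates.

An SPV summarizes one cell type's markers in a target dataset: z-score
each marker across samples, take the first left singular vector of the
samples × markers submatrix (unit l2 norm), and fix the sign so the score
correlates non-negatively with mean standardized marker expression (SPVs
must track, not anti-track, abundance). Constant or absent markers are
dropped with a warning; at least two usable markers and three samples are
required. The full CellCODE procedure additionally residualizes markers
against global expression structure before the SVD; this implementation
keeps the plain eigengene summarization, which is the portable core of
the approach, and leaves residualization as an extension point.

## Evaluation conventions

Repeated k-fold cross-validation (default 20 × 10) draws a fresh seeded
partition per repeat; per left-out fold and cell type it records RMSE and
Pearson r, and summaries are mean ± sd over the repeats × k fold-level
values (fold-level, not pooled, aggregation — pooled-prediction metrics
are also emitted for transparency). Correlations undefined on a fold
(constant vector, or fewer than three test samples) are flagged and
excluded from the r summary with an exclusion count, never silently
dropped as NaN.

Marker validation on replicate isolated-cell profiles uses one-way ANOVA
per gene across cell-type groups with Benjamini–Hochberg adjustment
across the tested markers (the adjustment method is configurable; BH is
the conventional default for "adjusted p-value"). Groups with a single
replicate are excluded with a warning; genes constant across all samples
have an undefined F statistic and are reported non-significant with a
degenerate flag.

## Verification problem sizes

The test suite and `scripts/acceptance.py` run the study at 500 genes ×
150 training + 50 held-out samples (30 planted markers), 2,000 genes ×
50 samples for the noiseless deconvolution identity, 100 random
three-type instances against an exhaustive 0.001-resolution simplex grid,
and 1,000 null genes for the ANOVA type-I check — sizes chosen so the
full verification completes in a few minutes on one CPU while still
putting every algorithm in its intended n/p regime.

## Known limitations

- The predictor is linear in log2 expression while true mixtures are
  log-of-linear; accuracy at composition extremes (near-pure samples)
  degrades accordingly.
- Raw predictions are uncalibrated; penalization shrinks them toward the
  training mean (predicted-on-true slope ≤ 1 on noisy data).
- Marker assignment is winner-take-all; genes genuinely shared between
  lineages are attributed to a single type.
- The ridge (α = 0) CV path solves a p × p system per λ and is intended
  for desk-scale p, not genome-wide feature counts without prefiltering.
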