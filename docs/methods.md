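# Methods

`sparsemt` quantifies how much missing training data multitask activity
prediction can absorb. A complete compound × assay response matrix is split
3:1 into train and test compounds, the training half is progressively thinned
under one of three removal models, each model in the method suite is refit at
every sparsity level, and per-assay performance on the untouched test
compounds is tracked relative to the complete-data fit. This note records the
models, the synthetic data they are exercised on, and the numerical choices
that were genuinely open.

## Data model

An activity matrix is a dense value grid plus an explicit boolean
observed-mask; "sparse" always means mask entries cleared, never sentinel
values. Regression matrices hold percent-inhibition-like real values;
classification matrices hold {0, 1} with inactive = 0 and active = 1
everywhere (one convention feeds both the rounding rule of the factorization
classifier and the confusion counts of MCC). Missing cells in CSV are the
empty string only; "NA"-style tokens are rejected so a spreadsheet export
cannot silently alter the mask. All count arithmetic (split sizes, removal
counts) uses round-half-away-from-zero, a fixed testable convention.

Compound side information is a 1024-bit hashed circular fingerprint
(Morgan radius 2 / ECFP4-style). An optional adapter computes fingerprints
from SMILES via RDKit; molecule standardization is out of scope.

## Removal models

* **label** — round(f·L) observed cells blanked uniformly without
  replacement; the matrix keeps its size but becomes sparse;
* **compound** — round(f·n) whole rows dropped; smaller but still complete;
* **assay** — round(f·m) whole columns dropped; evaluation restricts to the
  surviving assays. Only sensible for wide panels.

Each grid fraction is sampled independently (grids are *not* nested removals;
successive fractions do not reuse one permutation). Removal never alters a
retained value. The default grids are 101 levels (0–1, step 0.01) for the
wide regression preset and 40 levels (0–0.975, step 0.025) for the
few-assay classification presets; the seed-control preset crosses 4 split
seeds with 4 removal seeds (16 runs).

At high label-removal fractions whole assays lose every label, at which point
per-assay models cannot be fit. `audit_empty` reports such assays and
compounds; the orchestrator records a status row instead of crashing, and
estimators error by default (`on_empty_assay="prune"` drops the assay and
predicts NaN for it instead). For a complete n × m grid the expected number
of emptied assays is m·C(nm−n, r−n)/C(nm, r) with r cells removed — e.g. for
367 × 454 it is ~3·10⁻⁶ at 95% removal, ~0.3 at 98% and ~11 at 99%, which is
why failures appear only beyond ~98% removal.

## Bayesian matrix factorization with side information

The core model is X ≈ UVᵀ with Gaussian noise of fixed precision α on
observed (centered, optionally standardized) cells, Gaussian priors on the
latent rows, Normal–Wishart hyperpriors on both sides' (μ, Λ), and compound
fingerprints entering through the prior mean u_i ~ N(μ_u + βᵀx_i, Λ_u⁻¹).
Assays receive no side information. Inference is blocked Gibbs sampling;
predictions average reconstructions over post-burn-in samples. For compounds
never seen in training the per-sample contribution is the prior mean
(μ_u + βᵀx)Vᵀ — the cold-start path that makes held-out compounds
predictable at all. Classification reuses the regression sampler on {0, 1}
labels; predicted values are rounded to the nearest label and clamped, with
exactly 0.5 mapping to active.

Numerical choices (all open in the model description, fixed here):

* α fixed at 5.0 on standardized values, not sampled.
* Observed values are mean-centered (and scaled by their standard deviation)
  before factorization; the transform is undone at prediction.
* Normal–Wishart constants ν₀ = k, W₀ = I, μ₀ = 0, κ₀ = 1 (weakly
  informative defaults).
* U, V, β initialized at 0; burn-in handles mixing.
* The link matrix β is resampled each sweep from the Gaussian conditional of
  a *unit-noise* ridge regression of U − μ_u on the bits with prior
  precision λ_β. The exact conditional couples latent dimensions through
  Λ_u and would need k Cholesky factorizations of a bits × bits system per
  sweep; the unit-noise form factorizes the bits Gram matrix once at fit
  time and costs O(bits²·k) per sweep. The resulting chain is an
  approximation of the full posterior; the predictive checks in the test
  suite (held-out RMSD ≈ σ, cold-start gains from real fingerprints) are
  what validate it.
* Λ must stay positive definite at every sweep; a numerical failure raises
  with the sweep index.

Per-sweep cost is O(L·k²) for the latent updates (vectorized over rows with
batched Cholesky solves), so a 367 × 454 panel at k = 8 runs at roughly
20 ms/sweep on one CPU core.

## Masked-loss network

A fully connected NumPy network: 1024 bits in, one output per assay (linear
for regression, sigmoid for classification), ReLU hidden layers, inverted
dropout, Adagrad at learning rate 0.05. The cost averages squared error
(regression) or cross-entropy (classification) over *observed* cells only;
an all-unobserved minibatch contributes exactly zero loss and zero gradient.
Minibatches are drawn over compounds, each carrying all of that compound's
observed labels, which matches the fingerprint-in/profile-out architecture.
Averaging over observed cells (rather than n·m) keeps the loss scale
comparable across removal fractions. Weights use fan-in-scaled uniform
initialization; everything is seeded, so training is bit-reproducible.
Classification is native (sigmoid + cross-entropy); the rounding rule is
specific to the factorization classifier.

## Forest baseline

scikit-learn multi-output random forests behind a strict contract: fitting
any matrix with missing cells raises and points at the compound removal
model, the only sparsification that keeps training matrices complete.
Pre-existing gaps in an otherwise complete panel are imputed with the assay's
observed mean first (`impute_assay_mean`, idempotent). Regression combines
trees by mean; classification by majority vote with ties resolved to active.

## Metrics and curves

Per assay, on held-out compounds: RMSD, MAE, R², and squared Pearson
correlation ρ² for regression; precision, recall, F1 and MCC for
classification. Conventions for degenerate slices are decisions: bounded
classification scores with a zero denominator are 0; ρ²/R² with a
zero-variance truth (or, for ρ², a constant prediction) are undefined and
excluded from medians. Aggregation is the median across assays (matching how
such benchmarks are usually reported), relative curves divide by the
fraction-0 median (exactly 1 at 0 by construction), and the knee is the
first *grid* fraction whose relative value is worse than 1 ± the chosen
relative change — no interpolation. "Worse" is metric metadata: up for
RMSD/MAE, down for everything else.

## Synthetic data

The generator reproduces the two structural causes of multitask
predictability — inter-assay correlation and fingerprint-linked compound
signal — together with the printed descriptors of the benchmark panels, so
the whole pipeline is testable without downloads.

* **Fingerprints.** Per-compound bit counts are drawn uniformly from
  [min, median] or [median, max] with equal probability, pinning the three
  order statistics. A configurable fraction of each compound's bits comes
  from a small pool of globally popular bits, which sets the mean pairwise
  Tanimoto level (~0.14 for the default presets); compounds in the same
  cluster share a fixed block of scaffold bits (chemical-series structure).
* **Latents.** Compound latents mix a standardized linear function of the
  bits (weight `signal_from_fingerprint`) with an independent component.
  The link is supported on the common-pool + scaffold bits (~100 positions):
  the informative substructure keys. A dense random link over all 1024 bits
  would be unlearnable from a few hundred compounds, drowning every effect
  the benchmark measures under an irreducible cold-start floor. Assay
  latents are drawn around shared cluster means (`cluster_scale` times a
  unit Gaussian, within-cluster spread `cluster_spread`), giving
  within-cluster correlations far above between-cluster ones.
* **Regression values.** Scores U·Vᵀ + noise are affinely mapped so that the
  quantiles enclosing `central_band_mass` (default 80%) of the values land
  exactly on the central band [0, 100], with the remaining tail mass split
  in proportion to how far the nominal value range (−77, 130) extends beyond
  the band. Anchoring interior quantiles instead of the min/max cells makes
  the in-band fraction exact and seed-stable; the realized extremes land
  beyond the nominal range (the latent-product distribution is heavier-
  tailed than the real panel's). The affine map preserves the low-rank
  structure exactly, so with zero noise and full fingerprint signal the
  values are an exact linear function of the bits. A small missing fraction
  (default 87 cells at the 367 × 454 size) emulates pre-existing gaps.
* **Classification labels.** Per-assay thresholds are empirical quantiles of
  the latent scores; compounds active nowhere are dropped, mirroring panel
  assembly. Because that drop removes only inactives, thresholds target an
  adjusted active fraction p·kept/n solved by fixed-point iteration so the
  *post-drop* ratios match their targets. Feasibility requires the active
  fractions to sum above 1 (each kept compound must be active somewhere);
  infeasible targets, or panels whose assays are too correlated to reach the
  requested balance, raise.

Preset defaults (`pkis_like`: 367 × 454, rank 3, 3 assay clusters,
`cluster_scale` 2.5, `cluster_spread` 0.3, noise 1.0 in latent units,
`signal_from_fingerprint` 0.9; `htsfp5_like`/`htsfp10_like`: 5/10 assays
with active:inactive ratios geometrically spanning 2.9–0.25 / 1.9–0.14,
bits-set 12/43/102) encode the printed descriptors; cluster counts,
correlation strength, noise level and fingerprint-signal fraction are not
printed anywhere and are this package's choices. The bits-set triple
12/43/102 is published as "minimum, maximum, median", which is internally
inconsistent (the median cannot exceed the maximum); it is treated as
min 12, median 43, max 102.

**What passing tests do and do not show.** The generator's matrices are
low-rank plus homoscedastic Gaussian noise with uniformly random missingness
— far cleaner than kinase panels or HTS data, whose missingness is
activity-biased, whose noise is assay-dependent, and whose effective rank is
higher. Results here demonstrate that the pipeline measures what it claims
under known structure (and reproduce the qualitative slow-then-steep
degradation shape); they do not calibrate how much data a particular real
panel needs.

## Problem sizes used in the shipped checks

The test suite and the acceptance script run the full 367 × 454 regression
preset for recovery, side-information and degradation checks (Gibbs chains of
140–200 sweeps, k = 8, single-seed-pair grids over ~10 fractions), a
4000-compound slice of the 5-assay classification preset, and Monte-Carlo
empty-assay simulations at 1000 repetitions — sizes at which every check
completes in minutes on one CPU core while the quantities of interest
(held-out RMSD within 1.5 σ, real-vs-shuffled fingerprint gaps, curve
ordering between 50% and 90% removal) are comfortably outside their noise.

## Known limitations

* Uniform-random removal only; real missingness is biased (e.g. follow-up
  testing of actives). The removal models here match the benchmark design,
  not real-world censoring.
* The β conditional is an approximation (above); posterior uncertainty on
  cold-start predictions is therefore mildly miscalibrated, though point
  predictions are validated.
* The degradation curves at desk scale are flatter than on real panels: a
  rank-3 truth is highly redundant, so the steep regime begins only beyond
  ~90% removal.
* The classification adaptation of the factorization model (round the
  regression output) is known to be weaker than native classification; it
  is kept because comparing the two styles is part of the benchmark's point.
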