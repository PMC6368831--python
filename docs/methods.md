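# Methods

This note documents the statistical machinery behind nichekit: the model,
its estimation, the candidate-selection statistics, the extrapolation and
risk metrics, the virtual-species simulator used for validation, and the
numerical and design choices made where the field leaves them open.

## The Gibbs model and its estimation

A fitted model is a Gibbs (maximum-entropy) probability density over the
unmasked cells of the calibration region M:

    P(c) = exp(λ · f(c)) / Z,   Z = Σ_c exp(λ · f(c)).

Environmental variables are rescaled to [0, 1] by their calibration (min,
max) before feature expansion. Feature families follow Maxent: linear `x`,
quadratic `x²`, pairwise products `x_i x_j`, step thresholds 1(x > k), and
forward/reverse hinges max(0, (x−k)/(1−k)) and max(0, (k−x)/k). Threshold
and hinge knots sit on an even grid in (0, 1) of the *rescaled* range
(default 25 per variable, hinges per direction) rather than on data
quantiles: the design matrix is then fully determined by the calibration
ranges, independent of the presence sample, which keeps bootstrap
replicates comparable and runs reproducible.

Coefficients minimize the penalized mean negative log-likelihood of the
(per-cell deduplicated) presences,

    log Z − mean_i λ·f(x_i) + Σ_j β_j |λ_j|,
    β_j = RM · base(class_j, n_presences) · s_j,

where `base` is Maxent's published class- and sample-size-dependent default
table (linearly interpolated on n, constant outside the tabulated range:
linear/quadratic {10: 1.0, 30: 0.2, 100: 0.05}; product {0: 2.6, 10: 1.6,
17: 1.4}; threshold {0: 2.0, 100: 1.0}; hinge 0.5) and `s_j` is the
feature's standard deviation over the presences (falling back to the
background when the presence spread is degenerate, floored at 1e-3 so no
feature is ever unpenalized). The regularization multiplier RM scales every
β_j; it is the knob the calibration grid sweeps.

The convex problem is solved by FISTA (accelerated proximal gradient) with
backtracking line search, adaptive momentum restart, and soft-thresholding.
Soft-thresholding produces exact zeros, so the "number of parameters" used
by AICc is the literal count of nonzero coefficients, not a thresholded
approximation. Convergence: maximum coefficient change below 1e-7 or a
stationary objective, within 10,000 iterations; non-convergence raises an
error carrying diagnostics (per-candidate failures are logged, not fatal,
during batch calibration). An earlier design routed the fit through a
weighted L1 logistic regression (the infinitely-weighted-points trick);
optimizing the Gibbs likelihood directly was preferred because the penalty
weights are per-feature and the target objective is available in closed
form — no approximation layer, no extreme case weights.

Background: all unmasked calibration cells when there are at most 10,000,
otherwise a seeded uniform sample of 10,000 (Maxent's convention). After
fitting, Z and the entropy H of the raw distribution are recomputed over
*all* calibration cells, so the raw output sums to exactly 1 over the
calibration area regardless of background subsampling.

Outputs: raw = P(c); logistic = e^H·raw / (1 + e^H·raw); cloglog =
1 − exp(−e^H·raw). All three are strictly increasing transforms of one
another, so rank-based statistics (partial ROC, omission) are identical
across outputs; AICc always uses raw.

### Extrapolation regimes

Projection onto a transfer stack G supports three regimes. *Free*: rescaled
values may leave [0, 1] and features follow their analytic trends. *Clamp*:
each variable is clipped to its calibration range before expansion, so
out-of-range cells take the boundary response. *None*: as clamp, but any
cell with at least one variable outside its calibration range is set to
exactly 0. The cells where clamp and none differ are exactly the
strict-extrapolation cells of the per-variable range rule — the same rule
MOP and MESS use, so risk maps and the "none" regime agree by construction.

## Candidate grid and selection statistics

The default calibration grid is 17 RM values (0.1–1.0 by 0.1, 2–6 by 1, 8,
10) × 29 feature-class combinations × the project's predictor sets. The
29-member catalog is all nonempty subsets of {l, q, p, t, h} minus the two
single-class sets {p} and {t}: a product-only or threshold-only model has
no usable univariate response shape. Which two subsets the conventional
"29" excludes is not documented anywhere authoritative; the choice is
isolated in one constant (`calibration.DEFAULT29`) and the full 31-subset
catalog ships alongside (`all31`). For every candidate two models are
fitted: one on all occurrences (for AICc) and one on the training subset
(for significance and omission against the held-out test records).

**Partial ROC.** Thresholds are up to 1,000 evenly spaced quantiles of the
prediction's unmasked values. The threshold region is fixed once as the
thresholds where the full test set's sensitivity is ≥ 1 − E/100; each of
the (default 500) bootstrap iterations then resamples the test values with
replacement at 50% of n and computes the AUC ratio — trapezoidal area of
bootstrap-sensitivity vs. cell-area fraction, divided by the null-line area
over the same area range — on that fixed region. The p-value is the direct
count of iterations with ratio ≤ 1 (iterations with an undefined ratio
count against significance). Restricting the region by each replicate's own
resampled sensitivity, a literal reading of the procedure, conditions on
upward noise: in null experiments it inflated the mean ratio to ~1.03 and
the false-positive rate to 30–50%. With the fixed restriction the null mean
ratio is ~1.00 and the false-positive rate ~5–8% (uniform prediction,
n_test = 50). The direct-count p remains a bootstrap approximation, not an
exact test; treat borderline p-values near α with caution.

**Omission rate.** The threshold is the nearest-rank E-th percentile of the
training-occurrence suitabilities (rank = ceil(E/100 · n), rank 0 mapped to
the minimum); the rate is the fraction of test values strictly below it, so
ties at the threshold count as predicted. Nearest-rank rather than
interpolated percentiles keeps the threshold an actually attained
suitability value.

**AICc.** For a candidate with raw prediction renormalized over unmasked
cells and n deduplicated occurrence cells, logL = Σ ln(raw_i) and AICc =
2k − 2 logL + 2k(k+1)/(n−k−1), undefined when n − k − 1 ≤ 0 (recorded,
excluded from Δ/weights). Δ_i = AICc_i − min AICc and Akaike weights
w_i ∝ exp(−Δ_i/2).

**Selection** applies the three criteria strictly in order: (1) keep
candidates with p < α (default 0.05 — the conventional level; sources
describing this workflow say only "statistically significant"); (2) among
those, keep omission ≤ E/100, falling back to the minimum-omission
significant models (flagged) when none qualifies; (3) recompute Δ within
the survivors — the reference is the minimum AICc *among significant,
low-omission candidates*, never the global minimum, which may belong to a
non-significant model — and keep Δ ≤ 2. A table can legitimately select
nothing; that is a status, not an error.

## Final models, transfers, independent evaluation

Each selected parameterization is refit on the complete occurrence set with
bootstrap replicates (default 10): each replicate resamples the occurrence
records with replacement (size n) and refits. Replicates are consolidated
by the cell-wise median (even counts: mean of the two middle values; a cell
masked in any replicate is masked in the median). When several
parameterizations are selected, a cross-model "consensus" median grid is
additionally produced. Final models are evaluated with the independent
occurrence set — partial ROC and omission on the consolidated
calibration-area prediction, the omission threshold deriving from the
complete occurrence set — for each model *and* for the consensus, all
labeled; with no independent data the step reports "skipped" rather than
failing.

## Extrapolation risk: MOP and MESS

MOP assigns each transfer cell g the mean Euclidean distance (raw variable
units by default; an option z-scores by M statistics) to its ⌈p/100·|M|⌉
nearest calibration-condition rows (default p = 5%; M subsampled to 10,000
rows, seeded, when larger). Distances are normalized to similarity
1 − d/max(d over non-strict cells), clipped to [0, 1]; cells with any
variable outside the *full* M set's range are strict extrapolation and
fixed at 0. If every cell is strict the surface is all-zero with a warning.
MESS is the classic percentile-based score: per variable, 100·(g−min)/range
below the range, 2f for percentile f ≤ 50, 2(100−f) for f < 100,
100·(max−g)/range above; the surface is the minimum over variables, with
the argmin reported as the most dissimilar variable (lowest index on ties).
MESS < 0 if and only if MOP flags the cell strict — both use the same range
rule — which the tests assert cell-wise.

## The virtual-species simulator

Validation needs a species whose truth is known. Layers are seeded Gaussian
white noise smoothed with a configurable radius (default 5 cells on a
64×64 grid) and rescaled to [0, 1]; smoothness 0 gives white noise (lag-1
autocorrelation ≈ 0), the default gives strongly autocorrelated fields like
interpolated climate surfaces. True suitability is logistic(intercept +
β_l·x + β_q·x²) per cell. The default species has a sharp unimodal niche on
the first two layers (β_l = (50, 16, 0), β_q = (−40, −20, 0), intercept
−18: optima at 0.625 and 0.4 of the layer ranges, peak suitability ≈ 0.7,
landscape prevalence ≈ 0.24) and ignores the third layer. The effect sizes
were chosen so the niche contrast clearly exceeds the engine's default
penalty at n = 200 presences — a species whose presence/background feature
contrast is smaller than the regularization is statistically unrecoverable
by design, and makes a useless fixture. Presences are 200 cells drawn
without replacement with probability proportional to suitability
(coordinates at cell centers; optional detection noise relocates a stated
fraction to random cells), split 75/25 into training/testing, with 30
independent records drawn separately. Transfer scenarios are additive
shifts of the M layers (default: "current" = +0, "future" = +0.25), so the
expected strict-extrapolation fraction is controlled directly.

What the simulator does *not* emulate: sampling bias, spatial
autocorrelation between the splits, detection error (unless enabled),
correlated predictor structure, or realistic climate gradients. Passing
recovery tests therefore demonstrate correctness of the machinery, not
field performance on real occurrence data.

Default problem sizes throughout the test-suite and acceptance runs (64×64
cells, 3 layers, 200 presences, ≤ 2,000-cell backgrounds in tests, small
candidate grids) are chosen as the smallest configurations at which every
statistic is well-resolved; all grids, knot counts, background sizes, and
iteration counts scale up through configuration.

## Determinism

Every random procedure takes a seed. The run configuration derives
per-stage seeds from the single run seed by fixed offsets
(`config.STAGE_OFFSETS`); batch calibration derives per-candidate seeds
from the stage seed by candidate index, so results do not depend on batch
order or partial completion. Two runs with equal configuration are
byte-identical in all CSV outputs; the report regenerates byte-identically
from the same inputs.

## Known limitations

- No numeric equivalence with Maxent.jar is claimed; feature knots, solver
  path, and the penalty's sample-size scaling differ in detail.
- Categorical predictors and Maxent's fade-by-clamping display are not
  implemented; there is no reprojection between coordinate systems — all
  rasters must already align.
- AICc on Gibbs densities (the Warren–Seifert convention) is a ranking
  heuristic, not a likelihood-theoretic ideal; it is used here, as in
  practice, only to rank already-significant, low-omission candidates.
- The partial-ROC p-value is a bootstrap direct count and mildly
  anti-conservative even after fixing the threshold region; its null
  false-positive rate is characterized by the test suite rather than
  guaranteed analytically.
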