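# nichekit

Detailed calibration, selection, transfer, and extrapolation-risk analysis
for Maxent-style ecological niche models (ENMs), with a built-in model
engine — no Java, no external Maxent installation.

Ecological niche modeling estimates environmental suitability for a species
from presence records and environmental raster layers. Doing this rigorously
means treating the model settings themselves as hypotheses: nichekit fits an
exhaustive grid of candidate models over regularization multipliers (RM) ×
feature-class combinations (subsets of linear `l`, quadratic `q`, product
`p`, threshold `t`, hinge `h`) × alternative predictor sets, then selects
the best candidates hierarchically by

1. **statistical significance** — partial ROC: the ROC curve restricted to
   sensitivity ≥ 1 − *E*/100, summarized as the AUC ratio
   (model partial area / null-line partial area), with a bootstrap of the
   test occurrences (default 500 iterations at 50%) and a direct-count
   p-value P(ratio ≤ 1);
2. **predictive performance** — omission rate: the fraction of test
   occurrences below the *E*-th percentile (default *E* = 5%) of the
   training-occurrence suitabilities;
3. **complexity** — AICc computed from the normalized raw output at the
   occurrence cells with *k* = number of nonzero coefficients; candidates
   with ΔAICc ≤ 2 are kept, with the Δ reference taken **within** the
   significant, low-omission set (never the global minimum).

Selected parameterizations become final models (bootstrap replicates,
median-consolidated), transferred to any number of scenarios under three
extrapolation regimes (free / clamping / none), evaluated against fully
independent occurrences, and screened for extrapolation risk with
mobility-oriented parity (MOP) and MESS surfaces.

## The model engine

The engine is a Gibbs density over the calibration-region cells,
P(cell) = exp(λ·f(cell))/Z, with Maxent's feature families expanded from
range-rescaled variables and coefficients minimizing the L1-penalized mean
negative log-likelihood of the presence cells,

    log Z − mean_i λ·f(x_i) + Σ_j β_j |λ_j|,
    β_j = RM × base(class_j, n_presences) × sd_j,

solved by proximal-gradient descent (FISTA) with soft thresholding, so
zero coefficients are exact and the parameter count is well defined. Raw,
logistic, and cloglog outputs share the cell ranking. This is a
re-derivation in the spirit of maxnet — structurally equivalent to Maxent
(same features, penalty structure, output transforms, clamping), not
numerically identical to Maxent.jar.

## Worked example

A complete run on a simulated virtual species (a known truth the pipeline
must recover):

```sh
nichekit simulate  --root demo --seed 42          # 64x64 landscape, 200 presences
nichekit calibrate --root demo --seed 42 \
    --rm 0.5 --rm 1.0 --fc lq --fc lqp --fc lqh   # 6 candidate models
nichekit evaluate  --root demo --seed 42
nichekit final     --root demo --seed 42 --n-reps 10
nichekit feval     --root demo --seed 42
nichekit mop       --root demo --seed 42
nichekit report    --root demo
```

`evaluate` prints the selection summary and writes
`calibration_results.csv`; on this fixture it reports

```
selection: ok | tallies: {'candidates': 6, 'significant': 6, 'low_omission': 6, 'selected': 2}
```

meaning all 6 candidates beat the null partial-ROC expectation (p < 0.05),
all 6 met omission ≤ 5%, and 2 fell within ΔAICc ≤ 2 of the best
significant, low-omission model. `final_evaluation.csv` then holds the
independent-data check of the final models (here p = 0.0, omission 0.067),
and `MOP_results/` maps where each transfer scenario leaves the calibrated
environmental space (the shifted "future" scenario shows ~24% strict
extrapolation, the identity scenario 0%).

The equivalent library calls are `simulate_project`, `run_calibration`,
`evaluate_candidates`, `build_final_models`, `evaluate_final`, and
`mop_batch` in `nichekit`.

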