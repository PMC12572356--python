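# Methods

This note documents the models, the numerical choices, and what the
synthetic benchmark does and does not establish.

## Circular quantities

All phases live on the 24-hour circle (24 h = 360° = 2π rad), referenced
to DLMO (phase 0). Internally everything is radians in [0, 2π); hours and
degrees are reporting conversions only. The wrapped difference
`signed_diff(a, b)` lies in (−π, π]; an exactly antipodal pair returns +π
(deterministic tie-break), so a 12-hour error is always reported as
+12 h, never −12 h.

* MAE = mean |signed_diff(θ̂ᵢ, θᵢ)| in hours, bounded by [0, 12].
* Bias = circular mean of the signed errors, mapped to (−12, 12] h; the
  accompanying spread is the circular SD √(−2 ln R̄), R̄ the mean
  resultant length. Both are undefined (raised as errors, recorded as NaN
  in metric tables) when the error resultant vanishes.
* Circular R² = 1 − Σ d(θ̂ᵢ, θᵢ)² / Σ d(θᵢ, θ̄)², with d the wrapped
  difference in radians and θ̄ the circular mean of the observations.
  It is ≤ 1, equals 0 for the constant predictor at θ̄, and is negative
  when the model is worse than that horizontal-line fit. This squared-
  circular-distance form is the package's fixed definition.
* Phase bins are half-open [k·w, (k+1)·w) starting at 0, with w a divisor
  of 360°, so they partition the samples; the n-weighted mean of per-bin
  MAEs reproduces the global MAE exactly.

Degenerate directions (vector norm, resultant length) are rejected below
ε = 1e-9 — far under the scale of any data this package handles.

## Training-locked preprocessing

Order is fixed: quantile normalization → technical-replicate collapsing →
per-feature z-scoring. The quantile reference is the mean of the
per-sample order statistics of the *training* matrix; validation samples
are mapped onto that same reference at their within-sample ranks, tied
values receiving the mean of the reference quantiles at the tied rank
positions. Control probes are removed before replicate groups are
averaged (output is invariant to that ordering). Z-scores use the
training mean and sample SD (n−1 denominator); zero-SD features are set
to 0 and flagged `uninformative` rather than dropped, keeping feature
indices aligned across sets. Missing values are a hard error — no
imputation rule is defined. Because all references are recorded at fit
time, transforming a validation sample never depends on which other
validation samples are present; this no-leakage property is tested.

## Cartesian regressors

**SIMPLS.** Implemented directly (centered predictors and responses;
successive loadings deflated through an orthonormal basis so scores stay
orthogonal). With as many components as the design rank it reproduces
ordinary least squares, and the first weight vector is the leading left
singular vector of X₀ᵀY₀ — both serve as independent oracles in the
tests. Requested components exceeding the achievable rank are capped with
a warning rather than failing, so small designs remain usable.

**Two-stage selection.** Features are ranked by the sum of absolute
SIMPLS projection weights across the latent factors; ties break by
lexicographically smaller feature id (determinism). The canonical model
*refits* SIMPLS on the selected submatrix; slicing the full-fit
coefficients instead is available behind `refit=False` for sensitivity
analysis — the two differ on collinear designs, which a regression test
pins down.

**Elastic net.** Each component is fitted by scikit-learn's coordinate
descent. The parameterization matches glmnet exactly (penalty strength λ
is glmnet's lambda; mixing α is glmnet's alpha), so published lambdas
transfer; the default λ = 0.03280596 is the reference value used with
α = 0.5 in the study design this package rebuilds. Intercepts are never
penalized. Predictors are *not* re-standardized inside the fit: inputs
are already z-scored by the preprocessing stage, and double-scaling would
silently change the penalty geometry. The CV path uses 100 log-spaced
lambdas spanning 4 decades down from the smallest all-zero-slope lambda,
10 seeded folds, squared error summed over both components, and resolves
ties toward the stronger penalty.

## ZeitZeiger

Per-feature time courses are periodic cubic B-splines on a uniform
cyclic knot grid with a circular second-difference roughness penalty;
the penalty weight is chosen per feature by generalized cross-validation
over a shared log grid, which is cheap because the effective degrees of
freedom depend only on the shared design. The basis has **n_knots = 10**
basis functions: a deliberate choice — a cyclic cubic space much smaller
than this cannot track a plain cosine to the ~1e-3 accuracy the recovery
tests demand (cubic approximation error scales as h⁴), while 10 keeps
the per-feature problem tiny.

The fitted means are evaluated at n_time = 10 equispaced phases, each
feature's column divided by its residual scale √(mean squared spline
residual), floored at 1e-6 so noiseless fixtures cannot blow up, then
centered. Penalized matrix decomposition extracts rank-one factors
maximizing uᵀMv under ‖u‖₂ ≤ 1, ‖v‖₂ ≤ 1, ‖v‖₁ ≤ sumabsv by alternating
updates (v soft-thresholded with the threshold found by bisection, 80
steps; rounding-level residue entries snapped to exact zero), initialized
from the leading right singular vector and deflated between factors.
Convergence accepts either stabilized loadings (max-abs change < 1e-8) or
a stationary objective (relative change ≤ 1e-11): near-degenerate
supports can make v drift geometrically long after the maximized value
has converged, and failing such fits would be spurious. Signs are fixed
by making each factor's largest-magnitude loading positive. With the l1
budget ≥ √p the decomposition reduces to the SVD, which the tests verify
against a dense SVD oracle.

Prediction projects a sample onto the loadings (after the same
scale/center transform) and maximizes a homoscedastic Gaussian
log-likelihood of the SPC scores — per-SPC mean curves are periodic
splines of the training projections, per-SPC SDs are their residual RMS
(floored) — over a uniform grid of 360 candidate phases. Ties and flat
likelihoods resolve to the smallest phase, with a warning for the flat
case. The grid bounds the quantization error at one grid step (1°);
there is no continuous refinement, by design, to keep predictions
deterministic. A phase-dependent variance model was considered and
rejected as out of scope.

## Experiment design

For each training condition (IP, OP, SS, IS, or "all" — an equal number
of samples from each base condition, requiring n_s divisible by their
count) and each of n_repeats = 20 replicates, n_s samples are drawn
without replacement; validation is the remaining samples of that
condition plus all samples of every other condition, scored per
condition, plus the model's own training samples as a separate row.
Strategy A allows participants to appear on both sides; strategy B first
shuffles participants into a training pool (accumulated until the draw is
feasible) and excludes those participants from every validation group.
Replicate randomness derives from a counter-based seed
(seed, replicate, condition, n_s, strategy), so any single replicate is
reproducible in isolation and replicates are mutually independent. A
failing replicate is recorded and skipped; one degenerate fit must not
abort a factorial. Hyperparameters are searched by leave-one-participant-
out CV: folds are the sorted distinct participants, the score pools all
held-out absolute errors, ties go to the first grid entry.

Statistical inference on the resulting metric tables (ANOVA, Tukey,
compact letter displays) is deliberately out of scope; tables are
exported as TSV for external tools.

## Predictor overlap

A feature "appears" in a model when its weight is positive: membership in
the selected top-n_t for PLSR, a nonzero coefficient in either component
for the elastic net, a nonzero loading in any SPC for ZeitZeiger. The
weight is √(c_cos² + c_sin²) for Cartesian models and the loading-vector
norm for ZeitZeiger. Overlapping predictors across n replicate models are
those present in at least ⌈min_fraction · n⌉ models (10 of 20 at the 50%
default — the ceiling reproduces the "at least 10 out of 20" rule), with
weights averaged over the models containing them; gene-level weights then
average a gene's probes (runs first, probes second — the two orders
differ and this one is fixed). Consistency is the coefficient of
variation (sample SD / mean) of overlap counts across conditions and
sizes. Intersection tables use exclusive (upset-style) regions, so region
counts sum to the union size.

## Synthetic generator

Each participant contributes evenly spaced sample phases with uniform
jitter of ± half the spacing (echoing around-the-clock time series; a
flag reproduces consecutive-day duplication, where half the samples
repeat the first half's clock times). Feature values on a z-score-like
scale:

* circadian: b_p + κ·A·cos(θ − ψ) + ε
* behavioral: b_p + κ·A·cos(θ + δ − ψ) + ε (δ the condition's behavioral
  offset; 12 h for OP)
* null: b_p + ε

with A log-normal (median 0.5, σ_log 0.5), ψ uniform, ε ~ N(0, σ_e = 0.5),
and participant-feature baselines b_p ~ N(0, σ_p = 0.3). IS is modeled as
amplitude damping (κ = 0.6) of both rhythmic classes — an approximation
of reduced rhythmicity after sleep restriction, not a claim of
biological fidelity. The default cohort (`paper_default`) is 30
participants × 4 conditions × 10 samples = 1,200 samples with
100 circadian + 100 behavioral + 1,800 null features; the 100/100 split
is a test-harness choice, not an estimate of the true ratio of
circadian- to behavior-driven transcripts. The `overfit_regime` preset
(one condition, 200 samples, 20 weak circadian features among 5,000
nulls, σ_e = 1.0) is sized so that n_s = 140 training draws remain
feasible while feature selection still latches onto noise at n_s = 60.

What passing tests on this generator show: the pipeline's contracts hold
(no leakage, determinism, conservation identities), the estimators
recover phase exactly when the generative assumptions hold, and the
qualitative phenomena — overfitting at small n_s, transfer failure under
mistimed sleep, strategy A/B concordance — emerge for the stated reasons.
What they do not show: performance on real microarray data, where
rhythms are non-sinusoidal, noise is non-Gaussian and correlated across
genes, and technical artifacts (dye bias, batch) exist; the generator
deliberately omits all of these.

## Known limitations

* ZeitZeiger's spline internals (knot count, discretization grid,
  likelihood variance model) are package choices where the original
  method's defaults are not fully specified; numerical output will differ
  from other implementations even on identical data.
* The elastic net fits the two components independently; a grouped
  multi-response penalty (selecting features jointly for both
  components) is a non-goal.
* Metric tables report NaN for undefined bias/R² cells rather than
  failing a whole run.
* Problem sizes in the test suite and acceptance script (replicate
  counts, cohort sizes) are the package's chosen benchmark scale: large
  enough for every phenomenon to be unambiguous, small enough to run
  routinely on a laptop.
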