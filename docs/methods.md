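# Methods

This note documents the model, the estimation pipeline, the numerical
choices, and what the synthetic-data experiments do and do not
demonstrate.

## Model and assumptions

The response of experimental unit *i* (one cell line treated with one
drug) at dose fraction *d_ij* is

    y_ij = Σ_k z_ik β_k(d_ij) + Σ_g x_ig γ_g(d_ij) + ε_ij

with smooth coefficient curves over the dose domain D = [smallest
tested fraction, 1].  Assumptions:

* **Normalization.** Raw fluorescence is mapped affinely through
  per-unit blank (BR) and zero-dose control (CR): y = (R−BR)/(CR−BR).
  Values are not clamped to [0, 1]; assay noise legitimately produces
  mild excursions.  Units with CR ≤ BR are rejected; zero-dose rows are
  consumed as controls only, never as regression rows.
* **Comparable dose scale.** Doses are fractions of each drug's maximum
  screening concentration, so different drugs share one domain.
* **Sparsity.** Only a small set of genes has a nonzero effect curve,
  and the aggregate gene contribution perturbs rather than dominates
  the response.  The preliminary variance estimate (below) leans on
  this: it is upward-biased by whatever signal the covariates-only
  model cannot explain.
* **Within-unit error structure.** Errors are independent across units,
  mean zero, with dose-dependent variance V(d) and (optionally)
  rational-quadratic correlation in the dose lag within a unit.

## Basis

All coefficient curves share a clamped B-spline basis: degree q = 3,
one interior knot at the median of the pooled observed dose fractions,
boundary knots at the observed min/max, L = K + q + 1 = 5 basis
functions.  We use the standard clamped counting convention L = K+q+1
(verified by the partition-of-unity property); all downstream formulas
are written in terms of L, so a different convention would only
relabel dimensions.  A rule-of-thumb knot count ⌊n^{1/(2q+3)}⌋ is
provided (`interior_knot_count`); because its intended sample size
(units vs pooled observations) is ambiguous for repeated-measures
designs, the knot count is an explicit configuration with default 1
rather than a silently applied formula.  No extrapolation outside the
observed dose range is supported.

## Weights

A one-time preliminary step fits the covariates-only model by OLS.
From its residuals:

* **V(d)** — squared residuals are averaged within each distinct dose
  fraction (screens use a small discrete set of fractions), smoothed by
  unpenalized projection onto the spline basis, floored at 1e-8.
  The binned means are projected unweighted; with the 2:1 mix of 9- and
  5-point series every distinct dose is supported by hundreds of
  observations, so count-weighting changes little.
* **R(φ)** — standardized residuals e = r/√V̂ are multiplied pairwise
  within units and pooled by dose lag; (a, ℓ) of
  R(h) = (1 + h²/(2aℓ²))^{−a} are fit to the pooled lag correlations by
  bounded least squares (a, ℓ ∈ [1e-3, 50] × [1e-3, 10], start (1, 0.5)).
* **Nugget.** The working matrix actually inverted is
  R_work = 0.95·R + 0.05·I.  On a 2-fold dilution series the two
  smallest doses are 1/256 and 1/128 apart by h ≈ 0.004, where any
  fitted rational-quadratic correlation is ≈ 0.9999; R⁻¹ then amplifies
  *relative* errors between the estimated variances at adjacent doses
  by 1/(1−ρ) ~ 10³–10⁴.  Because V̂ is inevitably biased by the
  omitted gene signal, that amplification systematically corrupts the
  screening utilities (in development we observed active genes pushed
  to the bottom decile of the ranking under otherwise favorable
  conditions, while oracle V and R ranked them perfectly).  A 5%
  nugget — the standard technical-noise component of assay error
  models — caps the amplification at 20× and costs almost no efficiency
  when the correlation model is correct.  Setting `nugget=0` restores
  the raw working family.

Both stages use the whitened objective: with S_i the symmetric square
root of W_i = V̂_i^{−1/2} R_work,i^{−1} V̂_i^{−1/2} / n_i, every weighted
sum of squares is ‖stacked S_i r_i‖².  Under independence and V̂ ≡ 1
this reduces to per-unit-normalized scalar weights.

## Screening

Gene g's marginal model contains all covariate curves plus x_g γ_g(d).
Its utility is the weighted mean squared error of that fit; genes are
ranked by ascending utility (ties broken by gene index) and the first
τ_n = ⌊ν·n/ln n⌋ survive (natural log; ν counts units, not
observations — at the full screen scale of n = 3805 units, ν = 2 gives
a screened set of 923 genes).  The weight model is estimated once, not
per gene.

## Group-SCAD selection

Over the screened genes, minimize

    ½ Σ_i ‖S_i(y_i − ŷ_i)‖² + Σ_g p_{λ,α}(‖η_g‖₂)

with the covariate blocks unpenalized and one group per gene (its L
spline coefficients, plain Euclidean norm — no basis-Gram
reweighting).  SCAD: λu on [0, λ]; −(u² − 2αλu + λ²)/(2(α−1)) on
[λ, αλ]; (α+1)λ²/2 beyond.  α defaults to the conventional 3.7.

**Optimizer.** Local linear approximation: each outer step majorizes
SCAD at the current group norms by a weighted group lasso with weights
ω_g = p′_{λ,α}(‖η_g‖), solved by block coordinate descent with *exact*
group updates (per group, an eigendecomposition of the block Gram
reduces the update to a scalar secular equation solved by monotone
Newton).  Numerical choices:

* The unpenalized covariate block is profiled out exactly (QR
  projection), so the descent cycles over gene groups only.
* The first majorization is taken at the origin (ω_g = λ, which
  globally majorizes SCAD).  This makes λ_max — the smallest λ that
  zeroes every group on the first step — well defined, and guarantees
  λ ≥ λ_max ⇒ all groups exactly zero.
* Single fits at λ < λ_max are reached by warm-started continuation
  (8 geometric steps from λ_max); path and CV fits warm-start from the
  previous λ.  A dense (e.g. ridge) initialization is deliberately
  avoided: from a dense start the per-sweep movement of coordinate
  descent can fall below any reasonable tolerance while the iterate is
  still far from the optimum.
* Active-set sweeps with a full Karush–Kuhn–Tucker scan on inner
  convergence; inner tolerance 1e-6 on the maximum coefficient change
  (1e-4 inside cross-validation folds), capped at 500 sweeps per
  majorization and 25 outer steps.  Non-convergence returns the best
  iterate flagged `converged=False`.
* The recorded objective trace is non-increasing across outer steps
  (majorize–minimize guarantee); λ = 0 bypasses the solver and returns
  the closed-form weighted least-squares solution.

**λ selection.** 5-fold cross-validation at the unit level (all doses
of a unit stay together), folds stratified by drug so each fold sees
every drug, seeded.  CV error is the whitened mean squared prediction
error on held-out units under the shared weight model; the grid is 50
log-spaced values from λ_max down to 10⁻³·λ_max by default, and the
minimizing λ is returned (ties to the larger λ).  Whether the weights
in the selection criterion should include the correlation structure or
only the variances is not settled; we use the same whitened objective
as the screening stage for consistency, and the independence structure
reproduces the variance-only alternative.

## Post-processing

* **AUC** — trapezoidal integral of |γ̂_g| on a 101-point equispaced
  grid over the observed dose domain.  The absolute value keeps the
  area positive for mixed-sign curves, matching how mixed-effect genes
  are ranked in practice.
* **Sign** — "+" if the grid minimum is positive, "−" if the maximum is
  negative, "0" otherwise.
* **Spearman ρ** — rank correlation of the grid-evaluated curve with
  dose (grid evaluation, not observed doses only); constant curves
  return 0 with a `defined=False` flag.  Sign and ρ are stable under
  grid refinement for monotone curves; for non-monotone curves ρ
  converges at the O(1/grid) rate as the grid refines.
* **Bootstrap** — units resampled with replacement; each replicate
  refits the *unpenalized* weighted model on the fixed selected gene
  set (no re-screening/re-selection per replicate, which would conflate
  selection variability with estimation error and is computationally
  prohibitive).  Default B = 200.  Reported: SD of each gene's AUC and
  pointwise 2.5/97.5 percentile bands.
* **Prediction metrics** — MAE over held-out observations plus four
  argmin-matching accuracies ("most effective" = lowest normalized
  viability; ties resolve to the first row identically for observed and
  predicted): best drug–dose pair per cell line, best drug per cell
  line (cell lines with one drug are skipped), best dose per unit, best
  dose range per unit with the split at 31.25% of the maximum dose.
* **IC50** — least-squares fit of y = lo + (hi−lo)/(1 + (d/m)^h); m is
  clipped to the dose domain and flagged `extrapolated` when the fitted
  curve never crosses its half level in-domain (flat curves included).

## Synthetic data generator

The generator emulates the structure of a large screen: n units, a 2:1
mix of 9-point 2-fold and 5-point 4-fold series, 5 drugs × 3 tissues ×
a mutation flag (dummy-coded against a fixed baseline), expression
multivariate normal with exchangeable correlation ρ_x = 0.2 across
genes on a microarray-like raw scale, and errors with
V(d) = σ²(1+d)² (σ = 0.1) and rational-quadratic correlation
(a, ℓ) = (2, 0.3).  Covariate curves are a declining viability baseline
1 − 0.8d plus small drug/tissue contrasts.

Active gene curves cycle through {constant, linear, sin(πd), Gaussian
bump at d = 0.5} with alternating signs, each rescaled so its root mean
square over the realized dose design equals the `amplitude` parameter
(default 0.5, ≈ 4× the RMS noise SD — a strong-signal regime).  Without
RMS normalization, shapes with mass at high doses would be far weaker
than flat shapes under log-spaced dilution designs.  By default each
unit gets its own cell line (`units_per_cell_line=1`), emulating a
subsample of a large screen; raising it toward 5 emulates the full
crossed screen and sharply reduces the number of distinct expression
profiles, making marginal screening genuinely harder.

Per-replicate seeds derive from a master seed by the counter scheme
`SeedSequence([seed, 1, rep])`, so study scenarios share data across
replicate indices and parallelize safely.

**What the generator does not emulate:** real microarray covariance
structure (block/pathway correlation rather than exchangeable),
batch effects, plate artifacts, missing doses, replicate assays of the
same pair, or model misspecification of the mean (true curves outside
any smooth family).  Passing the Monte Carlo suite therefore shows the
pipeline behaves as designed under its own assumptions, not that it
retrieves biology from a real screen.

## Study conditions used by the test suite

Problem sizes were chosen so the whole suite runs comfortably on one
CPU:

* Selection recovery: n = 190 units, G = 886 genes, 6 active genes,
  ν = 2 (τ = 72), rational-quadratic weights, 25 replicates; CV grid of
  30 λ down to 10⁻²·λ_max.  Bars: screening retains all active genes in
  ≥ 90% of replicates; mean TPR ≥ 0.8 and mean FPR ≤ 0.05 after
  selection.
* Estimator consistency: ISE of active-gene curves at n = 400 vs
  n = 100, 20 replicates, constant+linear truth (inside the spline
  space, so the measured error is estimation variance rather than a
  fixed approximation bias).
* Correlation recovery: ℓ̂ within ±0.1 of 0.3 at 1000 units, 20
  replicates, no active genes (clean residuals isolate the moment
  estimator).
* Evaluation harness: perfect-prediction fixture (exact 100% / zero
  MAE) and a 2000-cell-line binomial baseline for the best-drug
  scenario.
* Determinism: two pipeline runs with identical config and seed produce
  byte-identical ranking/fit/summary artifacts (floats serialized at 17
  significant digits; the config hash excludes the output directory).

## Known limitations

* The preliminary variance estimate absorbs omitted gene signal; under
  very dense or very strong aggregate signals the weights degrade (the
  nugget bounds, but does not remove, the effect).
* (a, ℓ) of the rational-quadratic family are only weakly jointly
  identified from short dilution series; ℓ is recovered well, a less
  so.  The weights depend on the fitted curve, not the individual
  parameters, so this barely affects downstream estimates.
* Cross-validated λ tends to over-select; spurious selections carry
  near-zero AUC and are easily recognized against their bootstrap SD,
  but the selected-set cardinality should not be over-interpreted.
* Group SCAD is non-convex: the solver guarantees a monotone descent to
  a stationary point, not a global optimum.  Continuation from λ_max
  makes the attained point reproducible.
* The bootstrap conditions on the selected set; its bands understate
  full-pipeline (selection-inclusive) uncertainty.
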