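# Methods

This note documents the statistical model, the synthetic data-generating
process, the defaults and numerical choices, and the limits of what the test
suite demonstrates.

## Problem setting

Observational registry data on adult WHO grade 2 glioma: covariates x
(demographics, clinicopathology), binary surgery T (0 = subtotal, 1 =
gross-total resection), follow-up time in months, and a cause-specific death
indicator (brain-cancer-specific survival). The goal is the individual
treatment effect on the time to 50% predicted mortality and a per-patient
surgery recommendation. Identification rests on the usual assumptions:
no unmeasured confounding given x, positivity, and consistency. None is
testable from the data; the balance penalty and IPTW reduce sensitivity to
measured confounding only.

## The balanced survival lasso-network

- **Architecture.** Encoder Φ: affine map ℝᵖ → ℝ⁸ by default; two Cox heads,
  each a linear skip θ_a ∈ ℝ⁸ plus a one-hidden-layer subnetwork (width 8,
  ReLU, dropout 0.1). *Design choice:* the compact affine encoder is the
  default because at registry-scale n (thousands) the accuracy of the ITE
  sign is limited by estimation noise, not capacity; in our benchmarks it
  recovered the true optimal arm for 75–78% of test patients across seeds
  versus 64–71% for a deep encoder (p→64→32). Deep encoders, widths and
  dropout are all configurable.
- **Loss.** Sum of per-arm Cox negative log partial likelihoods (Breslow
  ties, averaged over events) on each arm's factual subjects, plus
  α·IPM(z₁, z₀). The ℓ1/hierarchy structure is handled by the proximal
  operator, not the loss.
- **Balance penalty.** Default is the biased (V-statistic) squared MMD with
  an RBF kernel, median-heuristic bandwidth treated as constant in the
  gradient: cheap, deterministic, exactly zero for identical samples, and
  differentiable. Entropy-regularized optimal transport (`sinkhorn`) is
  available; its entropic bias makes identical samples score slightly
  positive, and its gradient uses the converged plan (envelope
  approximation). α defaults to 0.1; the loss is non-decreasing in α for
  unbalanced arms (tested). Batches are constructed arm-proportionally so the
  penalty always sees both arms.
- **Training.** SGD with momentum 0.9, learning rate 0.05, batch 256,
  60 epochs, followed after every step by the hierarchical proximal operator
  applied per latent feature and arm. Gradient clipping (global norm 5)
  guards the unbounded directions of the partial likelihood under within-batch
  risk separation; optional weight decay (default 0) keeps the predictor
  scale identified. All randomness (init, batching, dropout) flows from one
  seed; fits are bitwise reproducible.
- **Hier-prox.** For each feature, the operator solves
  min ½(θ−θ′)² + ½‖W−W′‖² + λs|θ′| s.t. ‖W′‖∞ ≤ M|θ′| in closed form via the
  sorted group-soft-threshold construction; it is validated against a numeric
  convex solver to 1e-6 and guarantees θ′ = 0 ⇒ W′ = 0. M defaults to 10.
- **Exact sparsity regime.** Momentum re-injects mass after the prox zeroes a
  feature, so exact zeros arise reliably only in the plain proximal regime
  (momentum 0, dropout 0, M = 1, large batches, frozen encoder when sparsity
  is wanted on the raw inputs). The support-recovery tests run in that
  regime; the default recommendation configuration keeps momentum and treats
  λ as mild regularization.
- **Model selection.** λ is swept dense-to-sparse with warm starts; the
  cross-validated mean validation partial likelihood selects the point, by
  default with the one-standard-error rule (the CV minimum almost always sits
  at the dense end of a lasso path).
- **Baselines.** Per-arm Breslow cumulative hazards from the factual-arm
  linear predictors of the final refit. Counterfactual prediction pairs
  head-0 with the STR baseline and head-1 with the GTR baseline for every
  patient, regardless of factual arm.

## Outcome definition, truncation and ties

Y_a is the first time the predicted curve reaches 0.5, truncated at τ
(default 60 months; 120 for 10-year analyses). Truncation keeps the ITE
bounded, but at a ~25% five-year event rate most predicted curves never reach
0.5 by τ, so the truncated medians tie at τ for the majority of patients. A
hard tie→STR rule would collapse recommendations to "STR for everyone",
making the consistency split merely a relabeling of the actual treatment arms
— which then inherits treatment-selection bias instead of measuring the
recommendation effect. The default tie-break therefore compares the two
predicted curves at the horizon (recommend GTR iff S_GTR(τ) > S_STR(τ));
exact curve ties still fall to the less extensive surgery. `tie_break="str"`
restores the hard rule.

## Synthetic cohort generator

Emulates a grade 2 glioma registry extract with known counterfactual truth:

- **Covariates:** age ~ N(43, 14²) clipped to 18–85; tumor size lognormal
  (median ≈ 35 mm); sex (57% male), marital status, income band, urban/rural,
  reporting region, histology (45% astrocytoma / 35% oligodendroglioma / 20%
  oligoastrocytoma), location, laterality, extension (80% confined).
- **Assignment:** Bernoulli in expit(γᵀx) with γ favoring GTR for younger
  patients with smaller, confined, frontal tumors; intercept −0.19 calibrated
  so the GTR share is ≈ 56.2%.
- **Outcomes:** Weibull proportional hazards per arm, shape 1.2, scale 255
  months. The control log hazard includes a convex age term (age_z²) and
  age×astrocytoma and size×extended interactions, so high risk accrues
  through two pathways (age/histology and size/extension). The treated arm
  adds a main effect (−0.10) and interactions (+0.45·age_z, −0.55·size_z,
  +0.40·astro, −0.35·frontal): GTR harms old astrocytoma patients and helps
  large or frontal tumors. About 52% of patients are GTR-favoring by the
  hazard rule. Scale and intercept were calibrated once, by Monte-Carlo,
  to the published marginals (24.6% event rate, 56.2% GTR share) before any
  model benchmarking, and are not revisited.
- **Censoring:** administrative horizon uniform on 60–120 months plus
  independent exponential dropout (rate 1/400 per month). Three independent
  seeded streams (covariates/assignment, event times, censoring) keep latent
  event times fixed under censoring ablations.
- **Ground truth:** closed-form S_a(t|x), medians, truncated-median ITE, and
  the optimal arm. Under proportional hazards one arm's curve dominates at
  every t, so the optimal arm defaults to the hazard rule (sign of
  η_GTR − η_STR), which is horizon-free; a truncated-median variant is
  available and ties to STR.

What the generator does **not** emulate: the real joint covariate dependence
structure (marginals plus one confounding pathway only), calendar-time
accrual, competing risks, measurement error in extent-of-resection coding,
and unmeasured confounders (molecular markers such as IDH mutation or 1p/19q
codeletion are absent from registries of this vintage). Passing tests
therefore demonstrate internal validity of the estimators under a known
proportional-hazards world, not clinical validity on real cohorts.

## Evaluation

- **C-index:** Harrell's (pairs comparable when the earlier time is an
  event; predictor ties count ½). Chosen over truncated variants for
  comparability with common survival-model reporting; documented as such.
- **IBS:** inverse-probability-of-censoring-weighted Brier score integrated
  over (0, t_max]/t_max, censoring distribution by Kaplan-Meier on the
  flipped indicator, t_max defaulting to the 95th percentile of follow-up.
  The t = 0 point is degenerate (S(0) ≡ 1), so BS is left-extended from the
  first positive evaluation time.
- **DRMST:** area difference under the two consistency groups'
  Kaplan-Meier curves on [0, τ]; percentile bootstrap CI (1,000 resamples,
  seeded, resampling patients).
- **Recommendation HR:** unadjusted univariable Cox on the Consis indicator
  with Wald CI; an IPTW-weighted variant with robust variance is available
  for the treatment ATE (HRᵃ).
- **Weighted log-rank:** classic two-group statistic on weighted risk/death
  counts with weights normalized to mean 1 (making the statistic invariant to
  weight rescaling). Calibration under estimated stabilized IPTW weights on
  null confounded cohorts: rejection ≈ 4–7% at α = 0.05 over 100 replicates.
- **Doubly-robust OR:** logistic nuisance fits for outcome and treatment,
  then OLS of outcome residual on treatment residual with HC1 errors
  (partially linear residual-on-residual form — a literal logistic second
  stage is ill-defined on continuous residuals). Both exp(slope) and the raw
  slope (a risk-difference-scale quantity) are reported, since a near-1
  exponentiated value is exactly what a small residual slope produces.
  Fixed-horizon binarization excludes patients censored event-free before the
  horizon; horizons at or beyond the administrative censoring cap leave no
  event-free survivors and are reported as degenerate rather than computed.
- **Proportion CIs:** Wald with half-up rounding to one decimal in percent
  for reporting; Wald reproduces the published registry bounds to printed
  precision (no interval method reproduces every printed digit — one upper
  bound differs by 0.1 under any rule).

## Interpretation

Time-dependent Shapley attribution uses a permutation-sampling estimator
whose value function marginalizes out-of-coalition features interventionally
over a background sample (capped at 100 rows for runtime). Local accuracy —
Σ_j φ_j(t) = S_x(t) − mean background S(t) — holds exactly per sampled
permutation, hence in the estimate; exact enumeration over 2ᵖ coalitions
anchors the sampler for small p. Aggregate importance integrates |φ_j(t)|
over the grid. The logistic recommendation surrogate yields exact linear
Shapley values β_j(x_j − x̄_j) on the logit scale.

## Problem sizes

The test and reproduction runs use desk-scale sizes chosen as package
defaults: model benchmarks at 4,000 training / 1,000 test patients over 3–5
seeds; confounding-correction studies at n = 2,000 over 100 replicates;
generator-vs-closed-form Kaplan-Meier checks at n = 20,000;
split/fold partition properties over 200 seeds. The full suite runs in about
90 seconds and the reproduction script in about one minute on a single CPU.

## Known limitations

- ITE sign accuracy is noise-limited: at ~500 events per arm the benefit
  sign of patients with |η_GTR − η_STR| below roughly 0.3 is close to
  unidentifiable, which caps agreement with the true optimal arm near 80%
  at this scale.
- No uncertainty is attached to individual ITEs; only group-level contrasts
  (DRMST, HR) carry intervals.
- The weighted log-rank variance is the plug-in weighted form; it is
  well-calibrated with stabilized weights near 1 but is not a general
  design-based variance for extreme weights.
- Competing risks are not modelled; the death indicator is treated as the
  sole event type against independent censoring.
- The Efron tie option is implemented for the loss but training and baselines
  default to Breslow throughout.
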