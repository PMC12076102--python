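# Methods

## Study design

`hdpsim` implements a plasmode simulation study of confounding-adjustment
methods that use high-dimensional binary proxies. Plasmode simulation keeps
covariate and exposure rows exactly as observed in a base population and
generates only the outcome from a known, investigator-controlled model, so
the causal truth is known while the covariate structure stays realistic.
Because no external data are required, the base population itself is
synthetic, built to emulate the analytic structure of a survey-style
(NHANES-like) epidemiological file.

## The synthetic base cohort

Generation is a single-pass latent-variable scheme (`cohort.py`):

* **Categorical investigator covariates** (default 14): independent
  multinomials with 2–4 levels, level probabilities proportional to
  (k, k−1, …, 1). These stand for demographic/behavioral/history variables
  that are always retained a priori and never subjected to selection.
* **Laboratory covariates** (default 11): lognormal, `L_j = exp(0.4 Z_j)`
  with Z multivariate normal under an AR(1) correlation of 0.3. Positivity
  by construction keeps the log/sqrt transformations of the outcome model
  well defined without clipping.
* **Latent comorbidity** U ~ N(0,1): the unmeasured confounder.
* **Proxies** (default 142): 94 signal proxies, Bernoulli with
  logit P = a_j + λU (loading λ default 1.0, baseline prevalences spread
  over 0.08–0.35), and 48 independent noise proxies (prevalences 0.05–0.35).
* **Exposure**: logit-linear in category indicators (coefficients ±0.25),
  standardized log-labs (±0.15) and U (coefficient default 1.0); the
  intercept is solved by bisection so the *expected* prevalence over the
  cohort equals the target to 1e-4.

The latent path U → {signal proxies, exposure} is what makes the proxies
proxies of an unmeasured confounder: conditioning on them (or on their sum)
blocks confounding that the investigator covariates alone cannot. The
association strengths (λ, the U→exposure coefficient, and a global scale on
the covariate→exposure block) are configuration parameters, not constants,
because the strength of the proxy–exposure association is a design choice
of the study, not a structural fact.

**Base size.** The default base population is 25 000 rows. Exposure is a
single Bernoulli realization that every plasmode iteration inherits, so the
base size bounds how precisely the simulated exposure prevalence can track
its calibrated target: at 25 000 rows the realization noise is ≈0.14
percentage points under 5% prevalence, comfortably inside the 0.5-point
calibration tolerance the rare-prevalence scenarios are held to. A
7 500-row base (the scale of the survey file this design emulates) is one
`CohortConfig` field away.

## The outcome model

`DgmSpec` records the complete outcome mechanism so the "oracle" adjusted
design is reconstructible in closed form:

logit P(Y=1) = β₀ + β_A A + β_X'D(X) + β_T'T(L) + β_s·score(C)

* β_A = log(true OR); the scenario presets use OR = 1, hence a true
  marginal risk difference of exactly 0.
* D(X): non-reference category indicators, coefficients ±0.15 alternating.
* T(L): nine transformed lab terms — log, sqrt, exp(−x), x², pairwise
  interaction, log, x³, sqrt, interaction — each standardized by
  base-cohort moments stored in the spec; coefficients alternate in sign
  with magnitudes 0.2–0.4 on the standardized log-odds scale ("moderate"
  nonlinear confounding). Analysts see only the raw labs; the mismatch
  between the analyst's design and the generating design is deliberate.
* score(C): the comorbidity burden, the row sum of the 94 signal proxies.
  β_s is set at spec construction so the score term contributes 0.8
  log-odds standard deviations over the base cohort — comparable to the
  whole lab block, which is what makes the latent comorbidity a material
  confounder (the unadjusted risk-difference bias in the base scenario is
  ≈ +0.13).
* β₀ is bisected so the expected outcome prevalence over the base cohort
  (exposure at observed values) equals the scenario target.

Scenario presets follow the three-prevalence design: base (30%/30%),
rare exposure (5%/30%), rare outcome (30%/5%), all OR = 1, n = 3000, 500
iterations. Rare exposure is produced by re-bisecting the exposure-model
intercept and redrawing exposure — never by rejection sampling — so every
covariate–exposure association is preserved.

## Proxy selection

* **hdPS**: each proxy's Bross bias multiplier
  |log[(p_c1(RR−1)+1)/(p_c0(RR−1)+1)]| from its exposure-stratified
  prevalences and its marginal outcome risk ratio; top 100 kept (ties to
  the lower column index). If any cell of the relevant 2×2 table is zero,
  0.1 is added to every cell of that table (the usual hdPS continuity
  correction).
* **LASSO**: L1-penalized logistic *outcome* regression offered the
  proxies, the exposure, and the investigator covariates; proxies with
  nonzero coefficients at the 10-fold minimum-CV-deviance penalty are
  selected (minimum rather than 1-SE to maximize proxy recall; the grid is
  configurable).
* **Hybrid**: sequential — Bross ranking restricts to the top k, then the
  penalized fit shrinks within the subset. The sequential (rather than
  intersection) composition follows the hdPS-refinement literature; the
  ordering is a documented design choice.

Investigator covariates are always retained downstream regardless of their
penalized coefficients.

## Learners and stacking

`cv_stack` fits each library member per training fold, collects out-of-fold
probability predictions, and chooses simplex weights minimizing the
cross-validated negative Bernoulli log-likelihood (SLSQP; the discrete-best
member is always a feasible candidate, so the ensemble CV risk never
exceeds the best member's). Members refit on the full data for prediction.
Defaults: 10 folds, automatically dropped to 5 when the minority class
supplies fewer than 30 events per fold (rare-outcome scenarios). A failing
member receives weight 0 with a warning; only all-members-failing is an
error.

Presets: `lib1` = logistic; `lib3` adds L1-logistic and the adaptive-spline
learner; `lib4` adds gradient-boosted trees (XGBoost, depth 3, 200 rounds,
learning rate 0.1, subsample 0.75, single thread — a conventional,
reproducible non-Donsker configuration; no hyperparameter search).

**Adaptive-spline member.** No MARS implementation is available as an
installed dependency, so the `adaptive_splines` tag is a piecewise-linear
hinge-basis expansion (knots at the 25/50/75% quantiles of each continuous
column) followed by a ridge-penalized logistic fit. The substitution is
recorded in `StackFit.metadata` so downstream outputs are auditable. It
captures smooth nonlinearity but, unlike MARS, performs no adaptive knot
search or term pruning.

## Estimators

All estimators target the marginal risk difference E[Y¹]−E[Y⁰] and report
Wald 95% intervals (z = 1.96), which is what makes coverage well defined.

* **IPW**: weights A/g + (1−A)/(1−g) after truncating g to
  (0.025, 0.975) (configurable; essential under 5% exposure), optionally
  stabilized by the marginal exposure probabilities. The weighted logistic
  outcome regression of Y on A plus the adjustment set is standardized by
  g-computation (predict under A=1 and A=0, average, difference). SE: a
  robust sandwich for the weighted estimating equations, treating weights
  as fixed, propagated through standardization by the delta method —
  conservative, matching common hdPS practice; a bootstrap is a config
  option, not the default, on runtime grounds.
* **Adjustment strategies** for the weighted outcome model: none,
  imbalanced measured (|SMD| > 0.1 on the unweighted sample, categorical
  covariates assessed per level), all measured, and both with the selected
  proxies appended.
* **TMLE**: initial Q from a stack on (A, covariates), g from a stack on
  covariates (either may be supplied directly, e.g., by oracle analyses);
  single-ε logistic fluctuation with offset logit(Q) and the combined
  clever covariate (a two-ε variant is behind a flag); SE = sd(EIF)/√n.
  Outcome probabilities are bounded at 1e-6 before logits.
* **DC-TMLE**: folds rotated so g, Q, and targeting/estimation always use
  disjoint data; rotation estimates averaged per partition; partitions
  repeated (default 3 splits × 20 repeats) and median-aggregated, with
  se² = median(partition variances) + median squared deviation of partition
  estimates. `n_splits=1` is a degenerate test mode that must equal plain
  TMLE bit for bit. A partition whose folds lack an exposure level is
  redrawn up to 10 times.

## Performance metrics

For K finite estimates against truth θ: bias = mean(θ̂)−θ; empirical SE
(K−1 denominator); average model SE as the arithmetic mean of reported SEs
(the literal definition; the root-mean-variance variant is reported
alongside as `rmv_model_se`); relative SE error 100(avgSE/empSE − 1); MSE
with 1/K denominator (so MSE = bias² + empSE²(K−1)/K exactly); coverage and
bias-corrected coverage; each with its standard simulation-study
Monte-Carlo SE (the exact formulas are in `evaluate.py`). Non-finite
iterations are excluded, never imputed; a method failing >5% of iterations
is flagged unstable. `zip_plot_data` exports intervals ranked by the
centile of |z| (zero-SE rows flagged, last).

## Seeds and determinism

All randomness descends from one master seed through counter-based
`SeedSequence` spawn keys: the dataset of iteration i depends only on
(master, i); method m's analysis of iteration i only on (master, i, m's
fixed grid index). Hence any iteration can be re-run in isolation and
adding a method to the grid never changes another method's estimates. The
XGBoost member runs single-threaded with a fixed seed, so full runs are
bit-reproducible.

## Problem sizes used in the shipped checks

The study-level test suite runs at sizes chosen to keep a full check useful
as a routine run: calibration targets use 100 iterations at n = 3000;
oracle-adjusted parameter recovery uses 500 iterations (IPW with the true
propensity and the reconstructed true outcome design; TMLE with the same
oracle information, 5-fold stacks); the qualitative proxy-versus-no-proxy
ordering uses 200 iterations with `lib1` and the PS.u/PS.ks pair; nominal
coverage of a correctly specified estimator uses 500 iterations of the
difference-in-means on randomized-exposure data. The full 16-method ×
3-library × 500-iteration grid is run through `hdpsim run` at the user's
discretion.

## What passing tests do and do not show

The generator reproduces the *structure* the methods are sensitive to —
many correlated binary proxies of one latent confounder, nonlinear lab
effects, controlled prevalences — not any real cohort's joint distribution,
survey weights, or variable dictionaries. One latent factor drives all
signal proxies, so the proxy panel is more exchangeable than real
prescription data with multiple comorbidity axes; selection rules may look
better here than in data where proxies divide their loyalty among several
confounders. Conclusions about method *ordering* transfer in kind, not in
magnitude.

Two estimator-level caveats worth knowing. First, when the outcome model is
correctly specified and parametric, the efficient-influence-function SE of
TMLE estimates the *nonparametric* efficiency bound and is therefore
conservative — oracle-TMLE intervals over-cover by design (≈98–99%
empirically); nominal 95% behavior is exhibited by the correctly specified
difference-in-means under randomized exposure, whose sandwich SE is exact.
Second, the plasmode base cohort fixes one exposure realization, so even a
"no-confounding" configuration carries a small fixed chance association
between exposure and covariates (≈0.006 RD at 25 000 rows); adjusted
estimators remove it, unadjusted ones inherit it.

## Known limitations

Binary point-treatment and binary outcome only; no survival or time-varying
structure; no survey weighting; no C-TMLE/CVTMLE variants; the adaptive-
spline member is a fixed-knot basis expansion, not true MARS; the IPW
sandwich ignores weight estimation (conservative); DC-TMLE's repeat count
is the main runtime knob and its aggregation rule follows the cross-fitting
literature rather than a unique standard.
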