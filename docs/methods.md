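# Methods

## The estimand

Consider a longitudinal study over intervals `j = 0..J-1` with the ordering
`O = (L_j, A_j, C_{j+1}, Y_{j+1})`: time-varying covariates `L_j` (including a
designated indication indicator `L*_j`), a binary treatment `A_j`, a censoring
indicator `C_{j+1}`, and a survival indicator `Y_{j+1}` that is monotone
(`Y_{j+1} = Y_{j+1} Y_j`).  A stochastic treatment rule g draws `A_j` from an
*intervention treatment distribution* `q^g(a | Y_j=1, l̄_j, ā_{j-1})` that may
depend on the *observed treatment process*
`f(a | Y_j=1, l̄_j, ā_{j-1})` — at a binary treatment, `f(1|·)` is the
propensity score.  The target parameter is the cumulative survival
probability `ψ^g = Pr(Y_J^g = 1)` had treatment been drawn from `q^g` at every
interval and censoring been eliminated.  Under sequential exchangeability,
consistency and a generalized positivity condition, `ψ^g` is identified by
the generalized g-formula: the sum over all covariate/treatment histories of
the product of the observed covariate and survival laws with `q^g` in place
of the treatment law.

Two incremental propensity score families are built in:

* **multiplicative shift**, `δ ∈ [0, 1]`: for subjects with `L*_j = 1` the
  probability of *not* initiating treatment is multiplied by δ,

      q^g(a|·) = (1-δ) l* a + (l* δ + 1 - l*) f(a|·).

  δ = 1 is the observed world; δ = 0 always treats the indicated.
* **odds shift**, `δ ∈ (0, ∞)`: the propensity odds are multiplied by δ,
  `q^g(1|·) = δf1 / (δf1 + 1 - f1)`.

The multiplicative shift (with static and dynamic deterministic rules) admits
the canonical linear representation

    q^g(a|·) = c1 h1 I(a=a*) + c2 h2 f(a|·) + c3 h3 p*(a|·),

with known history functions `h1..h3` and a known distribution `p*`.  For
this class the efficient influence function is the backward recursion

    U = Σ_{j=1}^{J} (T_j - Q_{j-1}) Π_{k<j} q^g_k/f_k + T_0 - ψ,
    T_J = Y_J,   Q_j = E(T_{j+1} | history, alive),
    T_j = c1 Q_j^{a*} h1 + c2 Q_j h2 + c3 {Σ_a p*(a) Q_j^a} h3,

and estimators solving it are J+1 model multiply robust: consistent whenever
the outcome regressions are correct from some interval k on and the treatment
models are correct before k.  The odds shift has no such representation and
its EIF is not doubly robust; the package therefore exposes it evaluate-only
(IPW/ICE) and the recursion-based estimators raise
`NonCanonicalInterventionError` rather than silently losing robustness.

## Estimators

* **ICE** — sequential outcome regressions with the canonical T-update and
  unit weights.  Singly robust in the outcome regressions.  Because the
  T-update consumes only outcome regressions, no treatment fit is needed.
* **IPW** — the product over intervals of weighted discrete-hazard
  complements, each the cumulative-weighted mean of `Y_{j+1}` among at-risk
  subjects with weights `Π_{k≤j} q̂_k/π̂_k`.  Identical (exactly, and verified
  to 1e-10 in the tests) to the weighted ICE algorithm with intercept-only
  outcome models.  Singly robust in the treatment (and censoring) models.
* **weighted ICE** — sequential *weighted* fractional-logistic regressions of
  `T̂_{j+1}` on interval-j history features, score-weighted by the cumulative
  `q̂/π̂` products; J+1 multiply robust with parametric working models.
* **cross-fit TMLE** — the sample is split into M near-equal seeded splits;
  on each complement S₋ₘ the treatment/censoring models and the sequential
  outcome regressions are fit by cross-validated stacked learners; on Sₘ an
  intercept-only logit fluctuation γ_j per interval solves the weighted EIF
  estimating equation backward, and T̂_j is rebuilt from the fluctuated
  regressions.  ψ̂ averages the split means of T̂_0.

Censoring is treated as a further intervention that eliminates it: fitted
per-interval censoring hazards enter the cumulative weights as
`Π 1/(1 - λ̂^c)` over uncensored at-risk rows, and all regressions condition
on remaining uncensored.  This standard inverse-probability-of-censoring
construction is the package's adopted form.

### Numerical choices

* Fractional logistic fits (responses in [0, 1], optional weights and
  offsets) are solved by Newton/IRLS with step-halving on the quasi-binomial
  log-likelihood, convergence at max-abs score < 1e-8, at most 100
  iterations.  A 1e-10-scaled ridge on the Hessian keeps the step an ascent
  direction for rank-deficient designs (empty cells of saturated models);
  a genuinely singular system falls back to a pseudoinverse step with a
  warning.  IRLS can be warm-started from a previous fit's coefficients —
  used to speed bootstrap replicates; results are unchanged because the
  score equation is solved to the same tolerance either way.
* All fitted probabilities entering ratios are clipped to [1e-6, 1 - 1e-6]
  with a logged count, so near-positivity behaviour stays visible.  No
  weight truncation by default; an optional `max_weight` cap logs how many
  products it touched.
* The TMLE fluctuation is solved by Brent's method on γ ∈ [-10, 10] (the
  weighted score is strictly decreasing) followed by Newton polish; an
  unbracketed root raises a targeting error with diagnostics.
* TMLE variance: the cross-fitted empirical variance of the EIF (evaluated
  at the fluctuated regressions, per split) averaged over splits and divided
  by n.  The subject-resampling percentile bootstrap is the alternative, and
  is what the bootstrap interval contract tests exercise.
* Degenerate inputs: constant fractional responses converge immediately to
  the clipped logit of the response mean; empty risk sets skip the interval
  model and contribute exactly zero downstream; `T̂_j` is forced to 0
  whenever `Y_j = 0`.

### Working-model scenarios

For the binary-confounder study the package ships the three scenario
formula sets: all correct (treatment `lstar + L1 + L2 + Alag`, censoring
`L1 + L2`, outcome saturated in `(A, L*, L1, L2)` before the last interval
and the true main-terms form at it); only-outcome-correct (treatment drops
the lag; the censoring working model is reduced to an intercept — the true
censoring hazard has no treatment-lag term, so something must actually
be wrong for the scenario to mean what it says); only-treatment-correct
(outcome regressions keep covariate-covariate interactions and the
treatment main effect but drop every treatment-covariate interaction).

## The built-in data-generating processes

`simulate_study1` (binary confounders, J=5): baseline
`L*_0, L1_0 ~ Ber(expit(-1))`, `L2_0 ~ Ber(expit(1 + L*_0))`; transitions
`L*_j ~ expit(-1 - A_{j-1} + L*_{j-1} - L1_{j-1} + L2_{j-1})`,
`L1_j ~ expit(-1 + A_{j-1} + L1_{j-1} - L2_{j-1})`,
`L2_j ~ expit(1 + A_{j-1} + L*_j + L2_{j-1})`; treatment
`A_j ~ expit(-1 - 2L*_j - L1_j + L2_j + 2A_{j-1})`; censoring hazard
`expit(-2 + L1_j - L2_j)`; survival
`expit(1 + 3A_j - 2L*_j + L1_j - L2_j)`.  Smaller δ (more initiation among
the indicated) improves survival.

`simulate_study2` (continuous covariates, J=5): baseline `L01 ~ Ber(0.5)`,
`L02 ~ N(0,1)`, `L1_0 ~ N(2 + L01, 1)`,
`L*_0 ~ expit(1.5 - 0.5 L1_0 + L01 + 0.25 L02)`; transitions
`L1_j ~ N(2 + A_{j-1} - L*_{j-1} + 0.5 L1_{j-1} + L01, 1)`,
`L*_j ~ expit(1.5 - A_{j-1} - 0.5 L1_j + L*_{j-1} + L01 + 0.25 L02)`;
treatment initiation
`expit(-3 + L*_j - 0.5 L1_j + 0.25 L*_j L1_j + 0.5 L01 + 0.25 L02 +
0.5|L02|)` with treatment *absorbing* (on once initiated); censoring
`expit(-4 - A_j - L*_j - 0.5|L1_j L02| + 1.5|L1_j|/(1 + e^{L02}))`; survival
`expit(-1 + 2A_j - 2L*_j + 0.25 L*_j L1_j + 0.5 L01 + 0.75|L1_j +
L02|^{1.5})`.  Each conditional law lives in its own small function so an
alternate reading of any term is a one-line change.  Under these laws the
δ=0.5 intervention-world survival at J=5 is ≈ 0.668 (the quantity
`monte_carlo_truth("study2", 0.5, ...)` computes; the package reports
whatever the implemented laws produce together with its Monte-Carlo
standard error).

Intervention-world truths always simulate with censoring disabled and
treatment drawn from q^g built from the true treatment probabilities; with
δ=1 and the same seed this reproduces the observational no-censoring
survival bit for bit, since both paths share one simulation engine.

What the generators emulate — and don't: confounding by measured
time-varying covariates, informative covariate-driven censoring, absorbing
treatment, monotone survival.  They do not produce unmeasured confounding,
measurement error, interval-censored event times, competing risks, or
non-monotone missingness, so passing tests say nothing about robustness to
those features of real data.

## CV stacking

The Super-Learner-style ensemble minimizes probability-scale squared error:
out-of-fold predictions from each candidate (5 folds by default, seeded
permutation) are combined by nonnegative least squares and the weights
renormalised to the simplex; `discrete=True` instead picks the single best
candidate.  The default library is deliberately small and cheap — a
main-terms fractional-logistic GLM, the same with all pairwise interactions,
and gradient-boosted regression trees — standing in for the larger R wrapper
libraries the field uses; candidates that fail to fit are dropped with their
weight reassigned.  Fractional responses are handled natively by the GLM
candidates and by regression trees with clipping to [0, 1].

## Replication grids and problem sizes

`ScenarioConfig`/`run_replications` drive Monte-Carlo grids with per-
replication seeds derived from the base seed by a fixed affine counter (all
below 2^31).  The shipped test suite runs the misspecification grid at
n=2500 with 200 replications (plus 1000 cheap IPW-only replications to
resolve that estimator's small bias — see the bias discussion below), the
machine-learning bias cells at n=250 with 200 replications, bootstrap
coverage at n=500 with 200 replications of B=200, and Monte-Carlo truths at
10^6 draws; these sizes are the package's chosen defaults for a
single-workstation run and can be scaled up freely through the config.

Under the multiplicative shift the weight ratio `q̂/π̂` equals δ exactly on
untreated indicated rows and 1 on unindicated rows, whatever the fitted
treatment model — only treated-with-indication rows are model-sensitive.
Misspecifying the treatment process therefore biases IPW far less here than
under deterministic interventions (measured: ≈ -0.5 survival points at
n=2500), which is also why the weighted estimators tolerate near-positivity
violations gracefully at moderate δ.

## Known limitations

* Continuous or multi-valued treatments, modified treatment policies that
  depend on the natural value of treatment, competing risks and
  representative/grace-period interventions are out of scope (the canonical
  form is the extension point for the latter).
* The odds-shift family is evaluate-only by design.
* History access in working models reaches one interval back
  (`<name>_lag`, `Alag`); deeper lags would need explicit columns.
* The TMLE assumes at least `min_split_size` subjects per split (default
  50) and M ≥ 2 for honest cross-fitting (M = 1 warns).
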