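# Methods

This note documents the statistical model behind each component of
`rwediag`, the defaults and why they were chosen, the numerical choices that
affect reproducibility, and the limits of what the synthetic evaluation can
show.

## Diagnostics

### Minimum detectable relative risk

The MDRR treats the log rate ratio as approximately normal with expected
standard error `1/sqrt(E·p_A·p_B)`, where `E` is the observed total event
count and `p_A`, `p_B` the arm shares of events (or person-time). With
`z_β = Φ⁻¹(power)` and `z_{1−α/2}`,

    log MDRR = (z_β + z_{1−α/2}) / sqrt(E · p_A · p_B).

Defaults α = 0.05, power = 0.80. This reading is validated by simulation:
two-arm Poisson studies generated at RR = MDRR, with person-time allocated so
expected events split evenly between arms (the formula conditions on the
*observed* split), reject the null in 78–81% of replicates for E between 200
and 1000. An alternative convention inflates the expected SE by √2 (treating
the two arm rates as separately estimated); it is available as
`compute_mdrr(..., conservative=True)` but is not the default because it
yields materially more than 80% power at its own MDRR.

### Preference score and empirical equipoise

`F = expit(logit S − logit P)` exactly. Equipoise is the fraction of the
*pooled* study population (each patient once) with F in [0.3, 0.7], bounds
inclusive. A per-arm fraction can be obtained by subsetting before the call,
but the pooled form is the default because the diagnostic asks whether a
sizeable group of similar patients exists in the study as a whole. The
statistic is invariant to swapping the target/comparator labels since F maps
to 1−F.

### Standardized differences

Balance and generalizability use the same SDM kernel. Weighted means and SDs
use frequency weights normalised by the *sum of weights* (not `Σw − 1`), so
a 0/1 covariate gives `sd² = p(1−p)` and the continuous formula reduces
exactly to the dichotomous one; balance numbers are therefore bit-for-bit
reproducible from the weights alone. Signs are preserved per covariate;
summaries take the maximum of absolute values over **all** observed
covariates, not only those in the propensity model. Degenerate covariates
(zero pooled SD, unequal means) yield ±inf, which the gate treats as failing.
Generalizability compares the weighted analytic cohort against the pooled
(both arms, unweighted) pre-adjustment population; comparing against the
target arm alone is possible by passing that arm as `pre_population`.

### Empirical null and EASE

Negative-control estimates are modelled as `θ_i ~ N(μ, τ² + s_i²)`. The MLE
runs on `(μ, log τ)` with L-BFGS-B (`ftol` 1e−14) from three starts — the
DerSimonian–Laird moment estimate, a small fixed τ, and a neutral point —
and always evaluates the τ = 0 boundary, where the profile MLE of μ is the
precision-weighted mean; the best log-likelihood wins and τ below 1e−8 snaps
to exactly 0. The fit is deterministic and order-invariant; non-finite
inputs are dropped with a logged count.

EASE is the folded-normal mean

    EASE(μ, τ) = τ·sqrt(2/π)·exp(−μ²/(2τ²)) + μ·(1 − 2Φ(−μ/τ)),

with EASE(μ, 0) = |μ|. Its inverse in τ (`scale_for_ease`) is closed-form
at μ = 0 (`τ = EASE·sqrt(π/2)`) and a bracketed Brent solve otherwise;
targets below |μ| are infeasible and rejected. At the conventional gate
EASE = 0.25 with μ = 0, τ = 0.3133 and a truly null RR appears in
(exp(−1.96τ), exp(+1.96τ)) = (0.54, 1.85) with 95% probability.

Calibration is the null-only variant: systematic error is assumed constant
across true effect sizes, so the calibrated interval is
`θ − μ ± z·sqrt(τ² + s²)` and the calibrated p-value its Wald analogue.
Models that let error scale with the true effect (fit from positive
controls) are out of scope.

## Threshold gating

Defaults: MDRR ≤ 10, equipoise ≥ 0.50, balance SDM < 0.10 (strict, following
the usual statement of the imbalance heuristic), generalizability SDM ≤ 0.25,
EASE ≤ 0.25. Boundary orientation is documented per diagnostic and applied
exactly as stated. Non-computable diagnostics (NaN/±inf) **fail closed**:
the analysis is blinded, never dropped from denominators. `unblind` marks
failing analyses `inestimable` and withholds the estimate and CI columns;
simulation ground-truth columns are withheld unless explicitly requested.

In evaluation mode, EASE appears twice with different roles: the `ease`
*column* of the diagnostics table is the design-time value the gate consults
(in a real evidence system, each target–comparator pair's EASE from its own
control set), while `gate_summary` re-estimates EASE from the estimates that
survive each rule. Both inputs are explicit, so the design-time set and the
evaluation set can differ.

## Synthetic generators

### Patient level

Binary covariates with prevalences U(0.01, 0.3); treatment by a logistic
model whose coefficients are `confounding_strength · U(0.5, 1.0)` with an
intercept centring the target share near ½; outcome hazards log-linear in
the same covariates with positive coefficients (U(0.5, 1.0)), so treatment
and outcome effects are aligned and positive confounding strength biases
crude estimates upward by an amount computable by exhaustive expectation
over covariate values. Event times are exponential with administrative
censoring at a 1-year horizon; every patient contributes the full horizon of
person-time and the true treatment effect is exactly null for all outcomes.
This is deliberately estimator-agnostic: no on-treatment censoring, no
competing risks, no time-varying hazards, and rate ratios rather than hazard
ratios — the diagnostics consume only a log estimate and its SE, so nothing
downstream depends on the survival machinery being realistic.

### Evidence system

Each analysis i draws a systematic error `bias_i`, realised arm event counts
`e_T, e_C` (Poisson around a log-normal expected total, truncated to ≥ 1),
sampling SE `s_i = sqrt(1/e_T + 1/e_C)`, and an observed estimate
`θ_i = bias_i + N(0, s_i²)`.

The bias distribution is a two-component mixture: with probability
`clean_fraction` the analysis is an essentially unconfounded comparison
(`N(0, clean_scale²)`, default scale 0.01), otherwise it is confounded
(`N(bias_location, bias_scale²)`). Setting `clean_fraction = 0` recovers the
single-normal bias model used for parameter-recovery checks. The mixture is
the structural point, not a nicety: if bias were a single zero-mean normal,
even a *perfect* gate that keeps the least-biased quarter of analyses would
leave E|bias| around 0.07 when the pre-gate EASE is ~0.4 — selection from a
normal cannot produce the near-zero post-gate EASE that well-behaved subsets
of real evidence systems exhibit. Observed gating behaviour therefore
implies a population in which some comparisons are intrinsically clean, and
the generator models exactly that.

Diagnostics are linked to bias through a Gaussian copula: `w_i` is the
normal score of `|bias_i|` under its own mixture distribution, each
diagnostic's latent is `ρ·w + sqrt(1−ρ²)·ε`, and marginals are chosen so a
stated fraction of analyses passes the conventional threshold. Defaults in
`legend_like_scenario`: link strengths 0.97 (equipoise), 0.90 (balance),
0.30 (generalizability), 0.60 (design-time EASE); pass fractions 23.8%,
42.0%, 42.2% and 82.9%; `clean_fraction` 0.25 with `bias_scale` solved so the
marginal E|bias| equals 0.38. The strong equipoise and balance links and the
weak generalizability link encode the qualitative pattern that equipoise is
the most bias-informative diagnostic and generalizability the least (for
null effects there is no effect modification for selection to distort).
MDRR is not simulated through the copula — it is computed from the realised
event counts. Event counts default to a median of 1000 (log-scale SD 0.6),
large enough that the post-gate EASE estimate is limited by systematic
rather than sampling error; one visible consequence is that the *ungated*
fraction of CIs excluding the null is higher than in sparser real systems,
where large per-analysis SEs mask much of the bias.

Randomness: a single integer seed feeds a `SeedSequence`, and each analysis
gets its own spawned child stream, so analysis i's draw is independent of
how many analyses are requested. Identical scenarios produce byte-identical
CSV output.

### What passing tests do and do not show

The generators reproduce the statistical *structure* of an evidence-system
evaluation — known-null controls, heteroscedastic sampling error,
bias-informative diagnostics — not real data. Covariates are independent
binaries; diagnostics are drawn, not computed from patient data, in the
aggregate generator; the strength of the diagnostic–bias association in real
systems is unknown and is a free scenario parameter here. A passing gate
evaluation therefore demonstrates that the machinery removes bias *when
diagnostics carry the configured information about bias*, and says nothing
about how informative those diagnostics are in any particular database.

## Default problem sizes

Tests and examples run at sizes where Monte-Carlo error is several times
smaller than the margins asserted: 2000-analysis evidence systems (post-gate
EASE and CI-coverage checks), 20 replicates of 1000 controls for null
recovery, 2000 replicates per event count for the MDRR power check, and
patient cohorts of 10–50k for the confounding oracles. These sizes were
chosen once, from the standard-error arithmetic, to make the checks stable
across seeds.

## Known limitations

- The effect estimator is a stratified Mantel–Haenszel rate ratio, not a Cox
  model; calendar-time and duration-of-exposure structure are absent.
- Propensity fitting targets moderate covariate counts with a fixed ridge
  penalty; large-scale regularised propensity modelling with cross-validated
  penalties is out of scope.
- Calibration propagates no uncertainty in (μ, τ) into the calibrated
  intervals; with hundreds of controls that uncertainty is small, with few
  controls it is not.
- Matching is greedy without replacement; for discrete score distributions
  whose gaps are inside the caliper it balances the score but not
  necessarily each covariate (a real property of propensity matching with
  few covariates, visible in `examples/03`).
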