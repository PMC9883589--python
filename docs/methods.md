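# Methods

## The generative task model

Each Go/No-go session presents 225 letter stimuli in fixed composition —
144 targets (X, upper half of the screen), 36 identity foils (Y, upper),
45 location foils (X or Y, lower; 36 X and 9 Y) — in a uniformly random
order, each for 300 ms followed by a 1200 ms blank (1.5 s trials). The
simulated participant is a two-accumulator linear ballistic accumulator
(LBA): on every trial each accumulator draws a start point uniformly from
`[0, A]` and a slope from `Normal(v, s)`, and rises linearly toward its
threshold `b = A + B`. The first accumulator to cross triggers its
response; a Go win within the 1.5 s trial produces a key press at
`RT = t0 + (b − start)/slope`, anything else produces no response. Drift
means depend on the stimulus class × accumulator pair (four drifts);
identity and location foils share the foil drifts, which is what caps the
free parameters at eight (`t0`, `A`, `B_Go`, `B_Nogo`, four `v`; `s` fixed
at 1 as the standard scale constraint).

Trial order carries no constraints (no run-length caps) and no
learning/fatigue drift across the 225 trials is modeled.

## Closed-form race quantities

The single-accumulator crossing CDF/PDF are the standard LBA expressions
built from `Φ` and `φ`; the `A → 0` degenerate limit is evaluated
analytically (`F(t) = Φ((tv − b)/(ts))`) instead of dividing by `A`.
Negative slopes never cross, so densities are *defective*: total crossing
mass can be below 1. The density of an observable Go response at time `t`
is `f_Go(t − t0) · (1 − F_Nogo(t − t0))`. Win probabilities integrate this
with adaptive quadrature (`scipy.integrate.quad`, absolute tolerance
1e-8). Both CDF and win probabilities are verified in the tests against
brute-force accumulator simulation (10^5–10^6 draws, 3-binomial-SE
agreement).

## Censored likelihood

Responses are cleaned before modeling: RT < 200 ms is discarded as
anticipatory, RT > 1 s as inattentive (strict inequalities; the boundary
values are retained). For the *behavioral percentages*, a trial whose only
response was discarded is excluded from numerator and denominator — the
cleaning drops responses, not trials, and an anticipatory press is not a
miss. A switch (`drop_filtered_trials=False`) scores them as non-responses
instead.

For the *likelihood*, a cleaned-away response becomes a non-response, and
the censoring deadline equals the filter's upper cut (1.0 s): the censored
mass `1 − P(Go by 1.0 s)` then absorbs exactly the slow responses the
filter removed, together with No-go wins and races where nothing finished.
This choice is load-bearing. Excluding filter-dropped trials from the
likelihood instead (while the agent can respond until 1.5 s) selectively
deletes slow Go responses, and in parameter-recovery experiments that
selection biased the posterior hard toward "No-go always wins late"
regimes (No-go drifts inflated by ~1 drift unit). With the
censor-at-the-filter-bound convention the likelihood is correctly
specified under the generative process and recovery is unbiased.

Responded trials contribute the log defective Go density at their RT; an
RT outside `(t0, deadline]` is impossible under the model and yields
`−inf`. Non-responded trials contribute `log(1 − P(Go by deadline))`,
computed as the sum of its two components — `P(No-go wins by T)`
(quadrature) plus `P(neither crossed by T)` (closed form) — because
summing the small pieces keeps the logarithm accurate when the censored
mass is tiny. Inside the MCMC the win integral uses a fixed 64-node
Gauss–Legendre rule *in log decision time*: crossing densities spike just
above zero when drifts are large, and log-spaced nodes resolve the spike
(plain linear-spaced quadrature leaves holes that the sampler will
happily exploit as spurious likelihood maxima; agreement with adaptive
quadrature is ~1e-4 across a broad random parameter sweep, tested).
Densities are floored at 1e-300 before the log. The per-session RT arrays
are sorted, so the fit is exactly invariant to trial order.

## Priors, sampler, and what is identifiable

Priors are independent truncated normals: `t0 ~ N(0.3, 0.1)` on
(0.05, 0.6) s; `A ~ N(0.5, 0.5)` on (0, 2); `B ~ N(0.5, 0.35)` on
(0.01, 2.5); drifts on (−4, 7) with class-informed centers — accumulators
matching the correct response at `N(2, 1.5)`, mismatching ones at
`N(0.5, 1)`. The class-informed drift centers matter: only Go wins are
ever observed, so the posterior has a soft ridge trading the No-go
boundary offset against the No-go drifts (raise `B_Nogo` and `v_Nogo`
together and the fit barely changes). With fully exchangeable diffuse
drift priors (provided as `diffuse_priors()` for sensitivity analysis)
session point estimates wander along that ridge; the informed centers
suppress it the same way standard practice in race-model fitting does.
Even so, regimes with almost no misses, or with `b_Nogo` far above the
range the data constrain (response bias beyond roughly ±50), remain
weakly identified at single-session sizes — point estimates of
`response_bias_go` carry a noise SD of roughly 10–15 points at 2 250
trials, and more at 225.

Sampling uses an affine-invariant ensemble (emcee) with
differential-evolution moves (80% `DEMove`, 20% `DESnookerMove`), which
handle the correlated posterior far better than the default stretch move.
Walkers initialize in a tight ball around a mode located by a cheap
multi-start Nelder–Mead search (with `t0` started below the fastest
retained RT). Defaults: 32 walkers × 3000 steps, 1500 burn-in, fixed seed
→ bit-reproducible fits. Convergence is summarized by split-R̂ and bulk
ESS across walkers (arviz); point estimates (componentwise posterior
medians) are withheld when any R̂ exceeds 1.1, and the `converged` flag
additionally requires ESS > 400 per parameter. Sessions with fewer than
two retained false alarms are refused (error RT variance undefined; the
model is not identified).

## Synthetic cohort

`CohortConfig` defaults define the study conditions: three latent groups —
noSE-like (75%), OtherSE-like (15%), ASA-like (10%) — with group-mean LBA
parameters chosen by forward simulation to land in the observed behavioral
regime: baseline ~4% misses and ~8% false alarms, the ASA-like group
+13 points of misses (via lower target-Go drift, i.e. reduced decisional
efficiency for targets), the OtherSE-like group +6 points of false alarms
(via a larger `B_Nogo − B_Go` Go bias). Session-level parameters jitter
around the group means (SD 0.15 on drifts, 0.05 on A/B, 0.02 s on t0).
Participants contribute up to three sessions (T1/T2/T3, 90 days apart);
event histories place an attempt in a session's follow-up window with the
group's rate (defaults 0.50 / 0.02 / 0.01 per window) and an other
suicide-related event likewise (0.10 / 0.50 / 0.03), at most one attempt
per window unless `allow_multiple_attempts` is set; 5% of participants
withdraw at a random day (censoring). Covariates are drawn independently
of group except an explicit +3-point SSI shift in the ASA-like group.
Days are integer offsets from a common origin. The sessions table carries
the latent group as ground truth for validation; it is never a model
input. Generation is fully vectorized and bit-reproducible from the seed.

What the generator does **not** emulate: real RT sequential dependencies,
learning or fatigue, missing data beyond censoring records, demographic
margins of any particular sample, or covariate–outcome confounding beyond
the configured SSI shift. Passing tests therefore demonstrate that the
pipeline recovers what it plants under its own assumptions — correctness
of the machinery, not clinical validity of the effect sizes.

## Outcome labeling

The follow-up window is half-open, `(test_day, test_day + 90]`: same-day
events are not "subsequent" to testing, day-90 events count. ASA takes
precedence over OtherSE; any qualifying event observed before a censoring
record still labels the window; a window is censored only when it is
truncated (study end, withdrawal, death) before day 90 *and* contains no
qualifying event. Participants without a terminal record are assumed
observed through the study length (default 365 days). One event may label
two sessions whose windows both contain it. The implementation is checked
exactly against an independent exhaustive day-by-day scan on 1 000 random
event logs.

## Risk model

"Multinomial GEE with independence working correlation" coincides with
maximum-likelihood baseline-category logit in its estimating equations, so
the model is fit by ML (statsmodels `MNLogit`) and inference uses the
cluster-robust sandwich over participants (statsmodels
`cov_type="cluster"`, with its standard finite-sample correction). noSE is
the fixed reference; testing session enters as a categorical factor (T1
reference); censored sessions are dropped before fitting; Wald tests and
symmetric log-scale 95% CIs; no multiple-testing correction (single 0.05
threshold); the two behavioral predictors enter jointly by default, and
separate models are a one-line `ModelSpec` change. Non-convergence, NaN
covariances and quasi-separation (any |β| > 15) set a flag rather than
silently reporting; `model_table` refuses to render a non-converged fit.
In the degenerate saturated single-session-per-cluster case the sandwich
equals the inverse Fisher information up to the known finite-sample
factor (tested to 1e-6). `or_for_delta(beta, delta) = exp(beta·delta)`
translates per-unit coefficients onto observed group mean differences.

## Validation experiment sizes and numerical outcomes

The validation suite (`gonogo.validation`) fixes these problem sizes:

* oracle grid: 20 random parameter points × 10^5 draws, 3-binomial-SE
  criterion;
* recovery study: 20 sessions of 2 250 trials (ten concatenated
  schedules), two planted groups separated by 1.2 drift units of
  decisional efficiency for targets and 40 points of response bias — both
  groups inside the identifiable regime (the low group misses ~35% of
  targets; the high group has moderate bias with `b_Nogo ≈ 1.05`).
  Separations sit ~2 SD of the point-estimate noise from the midpoint, so
  per-session sign classification is a meaningful check. Measured at the
  default seed: median absolute error of de_targets 0.12, sign correct
  20/20 (de) and 18/20 (bias), mean |relative error| of `v_target,Go` 8%;
* planted cohort: 500 participants × 2 sessions, joint behavioral model;
* null calibration: 200 replicates × 500 clusters with a single latent
  group (no planted effects), counting Wald rejections of the two
  predictor coefficients on both logits; non-converged replicate fits
  (~1/200, flagged) are excluded;
* label oracle: 1 000 random toy logs, exact agreement required.

## Known limitations

* Single-session (non-hierarchical) fitting only; a hierarchical LBA
  would pool the weakly identified No-go-side parameters across sessions.
* The No-go side is intrinsically weakly identified under censoring;
  response-bias point estimates are noisy and regimes with very high bias
  or almost no misses drift along the `B_Nogo`–`v_Nogo` ridge.
* The RT filter's lower cut is treated as data cleaning, not modeled
  truncation (its likelihood mass is negligible for plausible `t0`).
* No drift-diffusion comparison, no model-selection machinery beyond
  convergence checks, no ROC/discrimination analysis of the risk models.
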