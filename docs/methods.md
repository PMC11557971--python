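# Methods

## The modelling problem

Cost-benefit choices — a smaller-sooner versus a larger-later monetary
reward, or a selfish reward versus sharing with a socially distant person —
can be produced by at least two different value-comparison strategies:

* **attribute-wise**: the decision maker weighs the *differences* between
  the options' attributes (how much more money? how much more delay or
  social distance?), or
* **option-wise**: each option is first collapsed into a discounted
  subjective value, and the values are compared.

Both strategies are embedded as drift-rate models in a two-boundary
drift-diffusion model (DDM), so that each makes a joint prediction for
choices *and* response times, and they can be compared per participant by
out-of-sample fit. The package implements this pipeline end to end on
synthetic cohorts with known ground truth.

## Models

All diffusion variants share the 4-parameter Wiener first-passage setup:
drift `nu`, boundary separation `alpha > 0`, *relative* starting point
`zeta ∈ (0,1)` (fraction of `alpha`; 0.5 = unbiased), non-decision time
`tau ≥ 0`, diffusion coefficient fixed at 1. The upper boundary always codes
choosing the more distant option (larger-later or shared), the lower
boundary the closer option.

**Attribute-wise drift** for a trial with reward difference `R` and
distance difference `D` (distant minus closer):

    nu = b_intercept + b_reward * R + b_distance * D

The intercept captures a general speed bias toward one boundary; a variant
without it is available (`include_intercept=False`).

**Option-wise drift** via hyperbolic discounting with rate `k = exp(log_k)`:

    SV(m, d)  = m / (1 + k * d)
    nu'       = b_temperature * (SV_distant - SV_close)
    nu        = 2 * v_lim / (1 + exp(-nu')) - v_lim        (optional sigmoid)

The sigmoid bounds the drift strictly inside `(-v_lim, v_lim)` and gives
both families the same number of free parameters; a no-sigmoid variant
(`include_sigmoid=False`) uses `nu = nu'` directly. `log_k` is sampled on
the log scale and exponentiated inside the value function.

**Choice-only controls** replace the Wiener likelihood by a Bernoulli on
`P(distant) = logistic(predictor)`, with the predictor being the attribute
linear combination or `b_temperature * ΔSV`; RTs are ignored and the
diffusion parameters drop out.

## Likelihood and sampling

The Wiener first-passage density is evaluated with the standard small-time /
large-time series expansions; the number of terms is chosen adaptively so
the truncation error of the scaled density is below 1e-8 (far below any
fitting tolerance), and the cheaper expansion is used at each time point.
The upper-boundary density is obtained from the lower-boundary form by the
reflection `nu → -nu`, `zeta → 1 - zeta`. The density is exactly zero for
`rt ≤ tau`.

Fits are per participant × task × model (no hierarchy). Priors are flat
uniform boxes: drift-related weights on [-10, 10]; `b_temperature` on
[0, 10]; `log_k` on [-10, 3]; `v_lim` on [0.01, 10]; `alpha` on [0.05, 5];
`zeta` on [0.05, 0.95]; `tau` on [0.01, min(rt) - 0.01] — the upper bound on
`tau` reflects that the likelihood vanishes beyond the fastest retained
trial. All bounds are configurable through `PriorSpec`.

The sampler is adaptive Metropolis-within-Gibbs: per-parameter Gaussian
random-walk proposals, with log step sizes tuned by Robbins–Monro toward
0.44 acceptance during burn-in and frozen afterwards; out-of-box proposals
are rejected (zero prior density). Because the drift weights are posterior-
correlated (the intercept trades off against the reward weight), each sweep
additionally makes one joint blocked proposal whose covariance is estimated
over the second half of burn-in (scaled by 2.38²/d) and frozen afterwards;
this substantially shortens autocorrelation times along the correlated
directions. Default chain settings are 2 chains ×
10,000 iterations with the first 5,000 discarded; most tests use shorter,
documented chains. Convergence is monitored with the split Gelman–Rubin
statistic per parameter; a fit whose worst R-hat exceeds 1.05 is retried
with a fresh seed (twice by default) and otherwise flagged
(`converged=False`, `NonConvergenceWarning`) rather than silently accepted
or discarded. Everything is deterministic given the seed.

**WAIC.** From the pointwise log-likelihood matrix (trials × retained
draws): `lppd = Σ_i log mean_s exp(ll_is)` (log-sum-exp stabilized), the
variance-form penalty `p_waic = Σ_i var_s(ll_is)` with the *n−1* sample
variance, and `waic = -2 (lppd - p_waic)` (deviance scale, lower = better).
Per-participant WAICs are the unit of analysis everywhere; group sums are
reported descriptively only, since aggregation conventions vary.

## Synthetic cohorts

The generator stands in for behavioral data and defines the study
conditions:

* **Task designs.** Scanner battery (euro): 90-trial intertemporal design
  (closer option 0.5–5.0 euro in 0.5 steps at 0–90 days; distant fixed 5
  euro at 10–360 days, strictly later) and 90-trial interpersonal design
  (closer 5.5–10 euro in 0.5 steps at social distance 0/10/20; shared option
  10 euro at distance 1/10/20/50/100, strictly farther). Drug battery
  (Swiss francs): 20-trial intertemporal (5–250 CHF at 0–30 d vs 15–300 CHF
  at 3–90 d, strictly larger and later) and 54-trial interpersonal (7.5–15.5
  CHF selfish vs sharing 15 CHF at distance 1/5/10/20/50/100). Attributes
  are sampled independently and uniformly over their printed grids/ranges
  with rejection of invalid combinations; delays are whole days. The shared
  option is encoded as the *total* split amount at the farther recipient's
  distance (a per-recipient encoding is available as a config alternative);
  this is one defensible reading of how a two-recipient option maps onto a
  single (magnitude, distance) pair.
* **Populations.** Each participant carries parameters for *both* model
  families per task, drawn from truncated normals (`DEFAULT_PARAM_CONFIG`),
  plus a dominant (`true_model`) label. The spreads are calibrated to two
  joint requirements: simulated behavior must be plausible — mean RT in
  0.5–3 s and distant-choice rates in 20–80% for ≥90% of participant × task
  cells — and the generating structure must be recoverable at the design's
  90 trials (true-vs-estimated parameter correlations ≥ 0.8, WAIC picking
  the generator for ≥ 80% of participants). The second requirement sets a
  floor on the population spreads: the posterior sd of `b_reward` at 90
  trials is ≈ 0.14, so a population sd of 0.25 keeps the attenuation-limited
  recovery correlation near 0.87 (a spread of 0.15 would cap it near 0.7
  regardless of sampler quality). Spreads scale with the attribute ranges of
  each battery (reward weights of ~0.4 per euro but ~0.02 per franc in the
  5–250 CHF task). Diffusion parameters: `alpha ~ N(1.5, 0.3)` truncated
  > 0.5, `zeta ~ N(0.5, 0.05)`, `tau ~ N(0.35, 0.08)` truncated > 0.1.
* **Observation model.** Choices/RTs come from the Euler–Maruyama simulator
  (dt = 1 ms) with a Brownian-bridge crossing correction between steps,
  which removes most of the O(√dt) boundary bias (hit probabilities agree
  with the closed form to ~1e-3). Responses slower than the 5 s window are
  omissions (no boundary, no RT, excluded from likelihoods). A configurable
  fraction (default 6%) of trials is replaced by fast guesses — uniform
  0.05–0.25 s RT, random boundary — emulating anticipatory responses; the
  analysis-side filter removes trials with rt < 250 ms (strict).
* **Drug study.** Two sessions two weeks of fiction apart, counterbalanced
  order, fresh trial sets per session. Placebo sessions are generated wholly
  from the dominant model; under the antagonist each trial switches to the
  *non-dominant* family with probability `drug_effect × effect_size`
  (`drug_effect ~ U(0.5, 1)` per participant). The trial-level mixture
  realizes "attenuating the dominant strategy" without asserting a
  parameter-level mechanism.

What the generator does *not* emulate: scanner timing (jitter, miniblocks),
sequential/adaptive choice-set optimization (the drug intertemporal design
uses uniform sampling instead), within-session learning or fatigue, and any
intra-individual strategy switching beyond the drug mixture. Passing tests
therefore show that the *pipeline* is correct and well-powered under these
idealized conditions, not that real data satisfy them.

## Group analyses

* **Wilcoxon signed-rank** on per-participant WAIC differences: W = sum of
  positive-difference ranks after dropping zeros, average ranks for ties;
  exact sign-flip p (dynamic programming) for n ≤ 25 without ties, otherwise
  normal approximation with continuity and tie corrections.
* **Prediction accuracy**: `P(distant)` from the closed-form absorption
  probability at posterior-mean parameters (posterior-averaged predictive
  available behind a flag); predicted choice = P > 0.5, ties scored half.
  Cross-validation refits on random 90% subsets and scores the held-out 10%,
  averaged over repeats; accuracies are compared across participants by
  paired t-test.
* **Model recovery**: data simulated per participant from known parameters
  of each family, both candidates refitted, generator identified by the
  lower WAIC (exact ties count as errors).
* **Posterior predictive checks**: signed RTs (negative = closer choice)
  simulated with one posterior draw per trial; overlap =
  `1 − ½ Σ |p_sim − p_obs|` over fixed 0.5 s bins on ±5.5 s. The bin width
  is chosen so the overlap estimator is not badly downward-biased at ~90
  observations; the self-consistency test regenerates a 900-trial dataset
  from the fitted point parameters so the statistic measures distributional
  match rather than small-sample noise.
* **Sanity correlations**: Kendall tau-b between the summed attribute drift
  weights and each participant's distant-choice proportion (expected
  positive), and between `log_k` and the same proportion (expected
  negative).

## Drug regression

Outcome per participant × task:
`(WAIC_attr − WAIC_opt)_amisulpride − (WAIC_attr − WAIC_opt)_placebo`.
Predictors: Task (0 = interpersonal, 1 = intertemporal), Session (which
session carried the drug), the placebo-condition difference
`waic_diff_placebo`, and all interactions — all z-scored before entry
(binary ones included) so main effects need no reference category. The
model is a linear mixed model with a participant random intercept, fitted
by REML with closed-form block inverses; t-tests use Satterthwaite degrees
of freedom computed from the REML information of the two variance
components (numerical gradient/Hessian). When the random-intercept variance
estimate collapses to ~0 the model reduces exactly to OLS and residual df
are reported and labeled as such. Per-task post-hocs are OLS on z-scored
Session and `waic_diff_placebo`; the inverse-temperature control is a
paired t-test on posterior-mean `b_temperature` (drug vs placebo) per task.
The paper-reported heterogeneous denominator dfs imply some random-effects
structure that is not printed; the participant random intercept used here
is a documented choice, not a reconstruction.

## Numerical choices and edge cases

* Series truncation 1e-8; density floored at 1e-300 before the log.
* `upper_choice_probability` uses `expm1` for small `|nu·alpha|` and returns
  `zeta` in the `nu → 0` limit.
* Simulator `t_max` 8 s for behavior (beyond the 5 s window everything is an
  omission anyway), 20–30 s for density-validation runs where tail mass
  matters.
* Exact WAIC ties in recovery counted against the generating model.
* Out-of-bounds proposals rejected rather than reflected (valid under the
  uniform prior); initial states drawn from the central half of the prior
  box, re-drawn until the likelihood is finite.
* Exclusion threshold strict (`rt < 0.250` removed, `rt = 0.250` kept); RTs
  stored to 3 decimals in seconds.

## Problem sizes used by the test and acceptance runs

Chosen to keep the full suite within desk-scale runtimes while leaving the
substantive thresholds untouched: recovery and comparison cohorts of 35
participants × 90 trials at 2 × 2000 MCMC samples; model-selection cells of
16 simulated participants; CV with 3 repeats; density-vs-simulation checks
at 4 × 10^5 walks per setting; drug-pipeline power at 4 replicates of
n = 56 and a null-calibration run at 6 replicates with a Clopper–Pearson
coverage check. Discount-rate recovery is assessed on the interpersonal
design, where `k` is well identified (see limitations).
`scripts/acceptance.py` re-runs the whole pipeline at n = 20 (drug: n = 56,
one replicate) from a single seed.

## Known limitations

* **Regression to the mean in the drug outcome.** The outcome and the
  `waic_diff_placebo` predictor share the placebo-session measurement noise
  with opposite signs, so under a strict null (no drug effect at all) the
  dominant-strategy coefficient is biased negative and rejects far above the
  nominal rate — a property of the difference-of-differences design itself,
  reproducible with pure Gaussian noise and no diffusion models at all
  (signal sd 8, session-noise sd 5, n = 56 gives ~97% rejection). With only
  20/54 trials per condition cell the session noise in WAIC differences is
  necessarily large. A negative coefficient therefore combines any true
  attenuation effect with this artifact; disentangling them would require a
  design with a repeated baseline (e.g. two placebo sessions). The Session
  main effect and Session × `waic_diff_placebo` interaction do not absorb
  it, because the artifact is symmetric across sessions. The null-
  calibration test in the acceptance suite documents this inflation rather
  than hiding it.
* The intertemporal discount rate is weakly identified at 90 trials: once
  `b_temperature × ΔSV` saturates the sigmoid, the likelihood is nearly
  flat in `k`, and the posterior sd (≈ 0.8 on the log scale) rivals the
  population spread, capping recovery correlation near 0.78. The
  interpersonal design (distances 1–100) identifies `k` much better (≈ 0.9).
* Occasional fits remain flagged at R-hat ≥ 1.05 after restarts (rare with
  the blocked proposal; they stay usable and flagged).
* Inter-trial variability parameters of the full Ratcliff model (sv, szr,
  st0) are deliberately out of scope; only the 4-parameter Wiener model is
  fitted.
* Hierarchical (group-level) estimation is deliberately not implemented;
  fits are individual by design.
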