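# Methods

## The model

All analyses rest on the simple diffusion decision model (DDM) of two-choice
response times without inter-trial variability. On each trial, evidence
X(t) starts at `z·a` (z is the *relative* starting point, a fraction of the
boundary separation `a` measured from the lower boundary), accumulates with
drift `v` and diffusion coefficient `s`, and a response fires when X(t) first
reaches `a` or 0. Observed RT is the first-passage time plus the non-decision
time `t0` (encoding, motor preparation, and — centrally here — attentional
orienting latency). The upper boundary codes the *correct* response, so the
likelihood of a trial is the defective first-passage density of the boundary
matching its correctness, under the parameters of its cue-validity condition.

Densities are evaluated by the standard adaptive switch between the
small-time and large-time series expansions of the standardised density,
truncating each series so its error is below 1e-9; the two branches agree to
better than 1e-8 at the switch point (tested). Absorption probabilities use
the closed form `P(upper) = (1 − e^{−2vaz/s²}) / (1 − e^{−2va/s²})` with the
drift-free limit `z`, evaluated through `expm1` for stability.

**Scale convention.** RTs enter the likelihood in seconds with `s = 1`. The
legacy `s = 0.1` convention is available by passing `s` explicitly; passage
times are invariant under `(v, a) → (v/s, a/s)`, which is tested directly.
With hundreds of trials per participant, per-trial log-densities of order 1
(1/seconds) give raw log-likelihoods of order +10² and hence negative raw
BIC/AIC scores of order −10² to −10³, the order of magnitude typical of this
kind of analysis.

**Numerical guards.** Trial log-densities are clamped below at −700 so RTs
outside a candidate parameter set's support (rt ≤ t0) cannot inject −∞ into
likelihood sums; the clamp leaves model ranking intact because any parameter
set invoking it is already catastrophically bad.

## The eight variants

Each variant states which of `t0`, `z`, `v` may differ between cued and
miscued trials; boundary separation `a` is always shared, and `z = 0.5`
whenever it is not free. Differences are constrained to the direction implied
by a positive cueing effect: `t0c ≤ t0m`, `zc ≥ 0.5` with `zm = 1 − zc`, and
`vc ≥ vm`. The free vector carries the cued value plus a nonnegative gap
(`dt0`, `dv`), so every admissible vector satisfies the constraints by
construction. The inequalities are implemented as closed (≥ 0) rather than
strict gaps: the boundary `gap = 0` has zero prior mass in practice and a
closed set avoids a measure-zero support issue.

Starting-point coding: because the upper boundary codes correctness, a cued
trial starts at `z_c` (biased toward correct) and a miscued trial at
`1 − z_c` (biased away). This makes the `zm = 1 − zc` constraint a single
free parameter and renders the likelihood a function of correctness and
condition only.

## Stage 1 — descriptives

Trials with RT strictly below 100 ms or strictly above 5,000 ms are removed
first; participants whose accuracy over their remaining trials falls below
80% are then removed entirely. Exactly 100 ms and 5,000 ms survive the
filter (the rule is stated as strictly less / strictly greater). Accuracy is
assessed on RT-filtered trials of the analysed conditions.

The cueing magnitude is mean(miscued RT) − mean(cued RT) per participant, by
default over correct trials only (configurable; at 94–99% accuracy the choice
moves cohort means by well under a millisecond). The standardised mean
change is the change-score-standardised variant — mean change divided by the
SD of the change scores — with Hedges' small-sample correction
`J(m) = 1 − 3/(4m − 1)`, `m = n − 1`; a raw-score-standardised variant is
available, and the variant used is recorded in the result object.

## Stage 2 — individual-level fitting and comparison

Each variant is fitted per participant by differential-evolution MCMC:
chain i proposes `x_i + γ (x_m − x_n) + U(−ε, ε)` with distinct random
partners m, n, `γ = 2.38/√(2k)` and jitter half-width ε = 1e-4, accepted by a
Metropolis step on the log-posterior. Defaults are 3 chains per free
parameter, 4,000 iterations, 2,000 burn-in; the `reduced` preset (chains
capped at 12, 1,000 iterations, 500 burn-in) is used throughout the test
suite and acceptance runs, with the problem sizes given below.

Priors are wide truncated normals: `v ~ TN(2, 3)` on [0, 10], `a ~ TN(1.5,
1.5)` on [0.1, 5], `t0 ~ TN(0.3, 0.3)` on [0.03, 1] s, `dt0 ~ TN(0, 0.2)` on
[0, 1] s, `z_c ~ TN(0.5, 0.2)` on [0.5, 0.99], `dv ~ TN(0, 2)` on [0, 10];
all overridable. They are deliberately uninformative relative to typical
estimates so the likelihood maximum sits well inside the posterior.

**Initialisation.** Chains start at independent prior draws, re-drawn until
the start has data support. When the whole catalogue is fitted
(`fit_cohort`), up to half of each variant's chains are instead warm-started
at the maximum-likelihood points of already-fitted nested sub-models,
embedded with gap parameters just inside their support. Warm starts do not
change the stationary distribution; they ensure the flexible variants'
samplers actually visit the high-likelihood region that nesting guarantees
exists, at CI-scale iteration counts.

**Maximum likelihood.** `extract_max_likelihood` returns the retained sample
with the highest *data* log-likelihood (not log-posterior), ties broken in
(chain, iteration) order. Because the maximum over posterior samples falls
short of the true maximum by an amount that grows with dimension — which
would penalise flexible variants beyond the intended BIC/AIC complexity
terms — `fit_participant` refines that point with a bounded Nelder–Mead
polish by default and records the gain in the diagnostics. With the polish,
the nested-dominance invariant (complex ≥ every other variant's maximum, up
to MCMC tolerance) holds to ~1e-6 on synthetic cohorts.

Criteria: `BIC = k ln(n) − 2 maxLL`, `AIC = 2k − 2 maxLL`, with `n` the
participant's post-exclusion trial count (the only coherent choice for
per-participant scores). Weights are `exp(−Δ/2)` normalised after shifting by
the minimum score. Inclusion probability of a parameter is the summed weight
of the four variants that let it vary (for drift: the v, t0-v, z-v, and
complex variants); inclusion and exclusion masses sum to one by construction.
Best-model ties break toward fewer free parameters, then lexicographically.
The Pearson correlation between simple-model probability and cueing magnitude
is reported with a default-prior (JZS, stretched-beta) Bayes factor computed
by pingouin.

Convergence is monitored with split-R̂ (arviz) per parameter; fits with
R̂ > 1.1 are flagged in the pipeline logs rather than silently pooled.

## Stage 3 — hierarchical estimation

For each target parameter θ ∈ {t0, z, v} one hierarchical model is fitted in
which θ is estimated per condition with *unconstrained* group-level means,
while every other parameter keeps its directional individual-level constraint
through a nonnegative gap whose population distribution is truncated at zero;
`a` is shared with a single group distribution. Every individual parameter
follows a truncated-normal population distribution whose truncation equals
the parameter's domain. Group means take wide truncated-normal hyperpriors
over the domain; group SDs take half-normal priors (scales 0.1–2 depending on
the parameter's natural range).

Sampling is blocked DE-MCMC: a DE proposal on each participant's block
conditional on the group level, then on each `(μ_j, σ_j)` pair conditional on
the individuals (the population terms factorise over parameters, so the pairs
are conditionally independent blocks). One proposal in ten uses γ = 1 to
allow mode-to-mode jumps. Chains are initialised at jittered moment-based
(EZ-style) per-participant estimates — accuracy and RT moments give starting
values for `v`, `a`, and per-condition `t0` — with the group level at the
cohort mean/SD of those starts; diffuse hyperprior starts with a joint
group block needed several times more iterations to reach R̂ ≈ 1.

The quantity of interest is Δ = μ_θ(cued) − μ_θ(miscued) per retained draw,
summarised by its mean, the equal-tailed 95% credible interval (HDI available
behind a flag), and the fraction of mass in the theoretically plausible
direction (negative for t0, positive for z and v).

## Synthetic cohorts

The generator emulates two-choice localisation cueing data: per participant,
a mechanism (t0, z, v, a combination, or none) and base parameters are drawn,
trials are simulated per condition from the expanded parameter pair, and the
upper/lower absorption maps to correct/error with a balanced random target
side. Defaults — base `v = 3`, `a = 1.2`, `t0 = 0.30 s`, `s = 1`; gaps
`dt0 ≈ 50 ms`, `z_c ≈ 0.60`, `dv ≈ 0.4`; mixture 0.55 t0 / 0.25 z / 0.05 v /
0.10 none / 0.05 t0-z — put accuracy in the mid-90s%, mean RTs at a few
hundred ms, and cueing magnitudes of tens of ms, the ranges typical of this
paradigm, with the orienting mechanism most prevalent. Presets mirror three
realistic study shapes (41×240, 50×256, 71×1,500 trials). Contaminants
replace a stated fraction of RTs with values outside [100, 5000] ms and are
flagged in a truth column so the exclusion filters can be scored exactly.

What the generator does *not* emulate: stimulus-onset-asynchrony or emotion
moderators, sequential effects, fatigue or practice drifts, non-stationary
parameters, and contaminants *inside* the plausible RT window. Passing
recovery tests therefore shows the pipeline identifies mechanisms when the
generating model family is correct; it does not certify robustness to
misspecification on real data.

**Simulation accuracy.** Trials are simulated by Euler–Maruyama with default
step 1e-4 s, with the exact Brownian-bridge probability of an unobserved
within-step boundary crossing applied at every step. Plain Euler–Maruyama
biases absorption probabilities and passage times at order √dt (~2e-3 at the
default step, enough to fail distribution checks at the 0.01 KS level); the
bridge correction cancels that leading term, leaving only the dt-order timing
granularity. At the default step, 10⁵-trial samples sit within KS ≈ 0.003–
0.008 of the analytic defective CDFs on both boundaries.

## Problem sizes used in tests and acceptance runs

Stage-2 recovery cohorts: 20 participants × 250 trials/condition, gaps
`dt0 = 60 ms` or `z_c = 0.65`, fitted with the reduced preset. Hierarchical
recovery: 20 × 600/condition with `dt0 = 40 ms` at 16 chains, 600 iterations;
null calibration: cohorts of 12 × 300/condition. Density checks integrate 12
parameter sets spanning `v ∈ [−4, 4]`, `a ∈ [0.5, 3]`, `z ∈ [0.2, 0.8]` and
compare one 10⁵-trial simulation against the analytic defective CDF. These
sizes are the package's own choices for routine verification; the full
"full" preset (3k chains, 4,000 iterations) is the default configuration for
real analyses.

## Known limitations

- No inter-trial variability parameters (sv, sz, st0) and no collapsing
  bounds: deliberate scope, matching the simple DDM.
- BIC/AIC weights are approximations to model probabilities; no
  marginal-likelihood comparison is attempted.
- The hierarchical sampler is a blocked DE-MCMC, adequate for the model
  sizes here; very large cohorts would warrant gradient-based samplers.
- Moment-based initialisation assumes accuracy above ~55%; data near chance
  fall back to slower diffuse starts.
- The Bayes factor for the magnitude–weight correlation uses pingouin's
  default-prior estimator; other priors will give different numbers.
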