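# gazeddm

Cognitive-mechanism decomposition of the **gaze cueing effect** with the
diffusion decision model (DDM).

People respond faster to targets appearing where someone else's eyes point
(cued trials) than where they point away from (miscued trials). A mean RT
difference alone cannot say *why*: the speed-up could come from attentional
orienting (target processing starts earlier at the gazed-at location), a
transient head start in evidence (a starting-point bias), or a sustained gain
in processing efficiency (a drift-rate advantage). `gazeddm` separates these
accounts by fitting constrained DDM variants to two-choice localisation data,
for researchers analysing spatial-cueing experiments at the level of
individual participants as well as the group.

## The model

Evidence X(t) accumulates from a starting point `z·a` at drift `v` with
diffusion coefficient `s` between boundaries 0 and `a`; the boundary reached
first determines the response, and observed RT adds a non-decision time `t0`.
The upper boundary codes the correct response. Trial likelihoods are the
defective first-passage densities (standard small-time/large-time series
evaluation); absorption probabilities use the closed form
`P(upper) = (1 − e^{−2vaz/s²})/(1 − e^{−2va/s²})`.

The analysis runs in three stages:

1. **Descriptives** — exclusion rules (RT outside [100, 5000] ms, accuracy
   below 80%), per-participant cueing magnitudes (mean miscued − mean cued
   RT), and a bias-corrected standardised mean change.
2. **Individual-level model comparison** — eight DDM variants that let
   subsets of {t0, z, v} differ between conditions under directional
   constraints (`t0c ≤ t0m`, `zc ≥ 0.5` with `zm = 1 − zc`, `vc ≥ vm`;
   threshold `a` always shared), each fitted per participant by
   differential-evolution MCMC; BIC/AIC weights
   `w_i ∝ exp(−Δ_i/2)` and per-parameter inclusion probabilities (summed
   weight of the four variants letting that parameter vary).
3. **Hierarchical estimation** — per target parameter, a hierarchical model
   with truncated-normal group distributions in which the target is
   unconstrained per condition at the group level; reported as the posterior
   of Δ = μ_cued − μ_miscued with an equal-tailed 95% credible interval.

A seeded synthetic-cohort generator with known mechanisms (and a truth
sidecar) makes every stage testable end to end.

## Worked example

Simulate a participant whose cueing effect is a pure 60 ms orienting gap and
fit all eight variants (`examples/03_individual_model_comparison.py`):

```
true mechanism: t0, t0 cued 300 ms vs miscued 360 ms

model comparison (lower raw scores are better):
  model  k  max_log_lik         bic        w_bic        w_aic
 simple  3   324.654959 -630.666093 3.013100e-22 2.107310e-23
     t0  4   377.226028 -729.593624 9.138058e-01 5.257260e-01
      z  4   353.561322 -682.264212 4.823950e-11 2.775290e-11
      v  4   330.226222 -635.594011 3.540768e-21 2.037056e-21
    z-v  5   353.561322 -676.049604 2.157336e-12 1.020972e-11
   t0-v  5   377.226028 -723.379016 4.086664e-02 1.934038e-01
   t0-z  5   377.285879 -723.498718 4.338723e-02 2.053326e-01
complex  6   377.285879 -717.284110 1.940336e-03 7.553765e-02

BIC inclusion probabilities:
participant  inclusion_t0  inclusion_z  inclusion_v
         p1           1.0     0.045328     0.042807
```

The t0 variant carries 91% of the BIC weight and the t0 *inclusion*
probability (t0 + t0-v + t0-z + complex weights) is ~1.0, while z and v sit
near zero: the planted orienting mechanism is recovered. The hierarchical
stage on a small cohort with a −50 ms gap
(`examples/04_hierarchical_differences.py`) prints

```
group-level difference in t0 (cued - miscued): -46.6 ms
95% credible interval: [-71.0, -21.5] ms
posterior mass in the plausible (negative) direction: 1.000
```

an interval excluding zero on the negative side, i.e. a credible orienting
benefit. The other examples cover density/simulation checks and Stage 1
descriptives.

A thin CLI wraps the pipeline for file-based runs:

```bash
gazeddm simulate --preset ds1-like --out cohort.csv --seed 1
gazeddm describe --input-path cohort.csv --out-dir results/
gazeddm fit --input-path cohort.csv --out-dir results/ --mcmc-preset reduced
gazeddm hierarchical --input-path cohort.csv --out-dir results/ --target t0
```

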