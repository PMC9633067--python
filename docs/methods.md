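# Methods

This note documents the generative models, estimators and numerical
choices behind `prismadapt`, what the synthetic cohorts do and do not
emulate, and the known limitations.

## Trial-level generative model

Each simulated participant is a single-state linear error-correction
learner.  The internal compensation state `x` (degrees, rightward
positive) starts at 0 and evolves per trial:

```
error  e = shift·[prism on] + bias − x + ε,      ε ~ N(0, σ²)
with terminal feedback:   x ← ρ·x  + η·e
without feedback:         x ← ρ₀·x
```

* `η` (learning rate, 0–1) — fraction of the experienced terminal error
  absorbed into the state.
* `ρ` (retention) — per-trial persistence of the state while feedback is
  available.  With `ρ < 1` the state equilibrates at
  `x* = η·shift / (1 − ρ + η)` below the full shift, which is what lets
  the model show both a small residual prism-phase error and an
  aftereffect smaller than the shift, as real observers do.
* `ρ₀` (no-feedback retention) — persistence once feedback is gone;
  `ρ₀ < 1` produces the trial-by-trial aftereffect decay of sighted
  observers, `ρ₀ ≈ 1` its absence.
* `σ = motor_noise_sd + coupling·max(0, log₂(10.75 / acuity))` —
  pointing noise grows linearly with the observer's log-acuity deficit
  relative to the 10.75 cpd reference (the top of the CSF ladder).
  This is a phenomenological coupling, not a psychophysical law.

The canonical design is 12 pre-prism, 48 prism (terminal feedback), 48
post-prism trials, balanced over targets at −25/0/+25°, with a +11.31°
(= atan(20/100), 20 prism diopters) shift during the prism phase only.
Target eccentricity does not enter the error model (analyses collapse
over targets); a balanced seeded shuffle implements the pseudorandom
order.  No generative model is prescribed by the behavioral findings
themselves — individual learning curves are roughly exponential, which
any single-state learner produces — so the model above is the minimal
admissible choice.

### Group presets

| preset        | η    | ρ     | ρ₀    | motor SD | acuity | coupling |
|---------------|------|-------|-------|----------|--------|----------|
| control       | 0.30 | 0.878 | 0.95  | 1.0°     | 10.75  | 0        |
| control_blur  | 0.18 | 0.874 | 0.95  | 1.2°     | 5.0    | 0.4      |
| cataract      | 0.05 | 0.883 | 0.995 | 2.6°     | 5.0    | 0.8      |

The values were placed using the steady-state algebra above so that the
preset means land near the observed group behavior: recalibration
indices ordered ≈ 0.3 / 0.55 / 0.67, residual prism error ordered
cataract > blur > control, aftereffect decay only in the sighted
presets, and baseline variance an order of magnitude larger after
cataract surgery.  Between-participant dispersion is log-normal on the
learning rate, motor noise and acuity, truncated to valid ranges.
Acuity is drawn first and the learning rate scales with
`(acuity/preset acuity)^0.5` before its own jitter: observers with
poorer vision both point more noisily and learn more slowly, which is
what produces the negative variance–index and positive acuity–index
correlations at the individual level.  Without that coupling the two
jitters would be independent and no correlation could arise.

### Longitudinal cohorts

Cataract observers tested at time `t` years after surgery get
`η(t) = L_max·(1 − e^(−r·t))` with `L_max = 0.16` (asymptotic index near
the blur-control level) and default `r = 1.5`/year.  Note that the
*index* saturates faster than the learning rate does, because `i_recal`
is a concave function of `η` (via `x*`): the exponential rate fitted to
the index of a synthetic cohort therefore comes out larger (≈ 3/year)
than the generative learning-rate constant.  The two rates describe
different curves; the package reports the fitted index-level rate.

## Recalibration metrics

With `PD` the prism distortion (11.31° by default), per participant:

```
End Prism            mean of the last 3 prism-phase errors
Adaptation           PD − End Prism
Initial Aftereffect  mean of the first 3 post-phase errors
i_recal              (Adaptation − Initial Aftereffect) / (2·PD)
```

Baseline variance is the unbiased (n−1) sample variance of all
pre-phase errors (it feeds two-sample F-tests); the whole-phase
aftereffect averages all 48 post trials, and its decay is summarized by
an OLS line through the per-trial group means (a deliberately generic
reading of "trial-by-trial unfolding").

The group learning curve is fitted as `error = a·x^b` by nonlinear
least squares on the raw per-trial means (log–log regression is ruled
out because post-adaptation errors cross zero), with `x = 1` at the
first prism trial so `a` is commensurate with the induced shift, and
initialization `(first-trial mean, −0.3)`.  The 95% CI on `b` is a
seeded percentile bootstrap over participants (resample, re-average,
refit); the curvature (asymptotic) CI is reported alongside.  Group
means over learners with heterogeneous exponential rates are better
described by a power law than by any single exponential once the rates
spread over about two decades; with narrowly dispersed rates a single
exponential can still win, which is expected and not treated as an
error.

Binned summaries use consecutive non-overlapping bins (default 3
trials); a trailing partial bin is dropped with a warning (the canonical
counts divide evenly).

## CSF staircases and fit

Ladders: 9 spatial frequencies doubling from 0.042 to 10.75 cpd and 8
contrasts halving from 100% to 0.78%.  Block 1 ascends the frequency
ladder at 100% contrast until the first error, then applies the
3-up-1-down rule, stopping after 6 reversals; the threshold frequency
is the geometric mean of the reversal frequencies (log-scale mean,
matching the ladder's geometry and the contrast block's averaging
rule).  Block 2 runs a descending 3-correct-down/1-wrong-up contrast
staircase at each tested frequency; the threshold is the geometric mean
of the last six reversal contrasts.  A 3-up-1-down rule converges where
p(correct) = 0.5^(1/3) ≈ 0.794; the simulated-observer tests verify the
empirical convergence level against this value.

Ladder ends are absorbing; reversals are counted as changes of the
intended step direction, and a run pinned against a ladder end with no
reversals possible (e.g. an observer who is always correct) terminates
via a documented boundary rule at that end's value.

Block-2 coverage: frequencies from the lowest rung up to one step above
the block-1 threshold are tested (minimum three rungs); an `"all"`
switch tests every rung.  The log-parabola
`log₁₀S = peak − k·(log₁₀f − log₁₀f_peak)²` (S = 100/threshold%) is
fitted by least squares, and the cutoff is the upper root of
`log₁₀S = 0`.  Two censoring rules protect the fit:

* thresholds at/above 100% contrast are censored everywhere (the
  grating was invisible at full contrast — such points carry only an
  inequality);
* `measure_csf` fits only rungs strictly below the block-1 threshold
  frequency, and censors fitted thresholds within one rung of the
  ceiling (≥ 50%).  Contrast staircases at rungs where p(correct) never
  reaches the convergence level sit against the 100% ceiling and their
  apparent thresholds are selection-biased upward; simulation shows
  that including them inflates the median recovered cutoff by ~50% at a
  true cutoff of 5 cpd, while the restricted fit recovers it to within
  a few percent.

Degenerate fits (collinear, upward-curving, or entirely below
sensitivity 1) are flagged and return the highest tested frequency as a
conservative cutoff.  CSF matching requires the cutoff ratio within 0.5
octave and the maximum log-sensitivity difference over the shared
passband within 0.2 log₁₀ units (defaults; both configurable).

The simulated 2AFC observer uses a cumulative-Gaussian psychometric
function in log₁₀ contrast with default slope 3 and lapse 0.02 — any
monotone sigmoid is admissible; the Gaussian gives closed-form checks
(p = 0.75 exactly at threshold with zero lapse).

## Developmental fit

`i_recal(x) = (a − c)·e^(−b·x) + c` with `a = 0` fixed (no visual
experience → no recalibration) and `c` fixed externally to the mean
index of the CSF-matched blur controls — `c` is an input, never
estimated.  `b` (1/years; the rate in the exponent) is found by bounded
scalar least squares on [1e-6, 50]/year (one free parameter, so the
global search is trivial; tolerance 1e-12).  Estimates pinned at a
bound are flagged rather than silently returned.  The 95% CI is a
percentile cluster bootstrap over participants, so both measurements of
a re-tested participant move together; 1000+ resamples are recommended
(coverage simulations at 200 cohorts × 1000 resamples, 25 points each,
noise SD 0.12, give ≈ 93% empirical coverage).  The time to a fraction
`q` of the asymptote is `−ln(1 − q)/b` (≈ 2 years for q = 0.95 at
b = 1.5/year).

## Statistical battery

* Kruskal–Wallis H with tie correction; effect size defaults to
  `η²_H = (H − k + 1)/(n − k)` with `ε² = H/(n − 1)` as an alternative —
  published η² values for this design cannot be reproduced unambiguously
  from a single formula, so the formula used is always reported and
  configurable, and no attempt is made to force agreement.
* Pairwise Wilcoxon rank-sum tests with Bonferroni correction
  (`p_adj = min(1, m·p)`); the statistic is the tie-corrected normal z,
  the p-value exact (Mann–Whitney) for ≤ 25 per group without ties.
* Signed-rank: reports W⁺ with the tie-corrected z alongside (a
  published "z = 20" at n = 13 is more plausibly the W statistic; both
  readings are available).  The null is enumerated exactly over all 2ⁿ
  sign patterns for n ≤ 12 — full enumeration handles tied |d| via
  midranks, which off-the-shelf exact routines refuse — and the normal
  approximation with continuity correction is used above that.
* Variance F-tests on unbiased variances with one- and two-sided p.
* Outlier screening for correlations: pairs beyond 3 SD (computed once,
  pre-exclusion) on either variable are dropped; screened and
  unscreened r are both reported, and screening is applied per analysis,
  never globally.
* The Multisensory Influence join is an inner merge on participant id;
  unmatched ids on both sides are listed.

## Pipeline and reproducibility

`run_full_pipeline` simulates the three groups (n = 20 each by
default), computes metrics, power fits, aftereffect trends, a
longitudinal cohort (20 first tests with log-normal times clipped to
[1 day, 10 years], 13 retested 4–16 months later), the development fit
with `c` taken from the blur-control mean, and the test battery.  All
streams derive from one master seed via `numpy.random.SeedSequence`;
identical configs give bit-identical outputs.  Degenerate cohorts (one
participant per group) skip infeasible tests with a note instead of
failing.  `scripts/acceptance.py --seed S --out f.json` re-runs
everything from scratch and writes each quantity with the problem size
used; the CSF recovery there uses 100 simulated observers and the
cohort stages the default n = 20 per group, sizes chosen to keep a full
run in a few seconds while leaving Monte-Carlo error well below the
effects of interest.

## What the synthetic data do and do not emulate

Emulated: the three-phase design and trial counts, feedback gating,
group differences in learning rate / aftereffect decay / noise, the
acuity–noise–learning coupling behind the individual-difference
correlations, longitudinal growth of the index with time since surgery,
and the 2AFC staircase responses.

Not emulated: movement kinematics, reaction times, 2-D endpoint
scatter, target-eccentricity effects, age effects within groups,
session-order or fatigue effects, and any dependence of the aftereffect
on proprioceptive recalibration mechanisms beyond the single decay
constant.  Passing tests therefore validate the estimators and the
pipeline plumbing on a faithful-but-minimal generative model; they do
not certify the model as a mechanistic account of real observers.

## Limitations

* The single-state learner cannot simultaneously produce a near-zero
  residual prism error and an aftereffect much smaller than the shift;
  preset retentions < 1 trade a few degrees of residual error for
  realistic aftereffect magnitudes.
* The staircase ladders quantize thresholds in factor-2 steps; single
  CSF runs scatter accordingly and only medians over runs are tightly
  constrained.
* The development fit pools all post-surgery measurements; no
  mixed-effects structure is modelled beyond the cluster bootstrap.
* The deposited-data adapter requires a user-supplied column mapping;
  no layout is assumed.
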