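# Methods

## The study being simulated

One synthetic participant passes through four phases: (1) an 8-trial
incentive-rating phase whose mean pre-trial excitement rating
operationalises reward anticipation; (2) a 10-trial change-detection
practice block (set sizes 2/4/6 in counts 4/4/2, never used for capacity
estimation); (3) a 120-trial calibration phase, 30 trials per set size in
{2, 4, 6, 8} with half change / half no-change per size in random order;
and (4) a 30-trial effort-choice phase in which the participant repeatedly
chooses between a low-effort/low-reward trial (1 point) and a
high-effort/high-reward trial (10 points), then performs a
change-detection trial at the chosen set size (0 points when incorrect).
The offered set sizes are calibrated per participant: capacity estimate at
set size 4 of at most 3 items yields the (2, 6) pair, above 3 the (4, 8)
pair.

## Capacity estimation

Whole-display K at set size `N` is `k = N (h - f) / (1 - f)` from the hit
rate `h` and false-alarm rate `f` of calibration trials only.  Raw
proportions are used (no smoothing); negative values are preserved (the
formula's raw output is the analysis quantity; clamping is presentation);
`f = 1` produces a flagged undefined estimate so the downstream set-size
criterion fails loudly rather than propagating an infinity.

Two estimate flavours exist because the task and the analysis differ: the
*running* estimate recomputes `h`, `f` cumulatively after every trial and
uses the value after the final trial (the task's criterion input; with the
optional 2-decimal rate rounding emulating a fixed-precision task
implementation), while the *batch* estimate uses the full final tallies
(the analysis predictor).  Without rounding the two coincide exactly; with
rounding they differ by a small zero-mean amount, mirroring the small
running-versus-batch discrepancy such tasks exhibit in practice.

### Generative model of change detection, and a known estimator bias

Responses are generated from a single-parameter capacity mixture: with
probability `m = min(k_true, N) / N` the probed item is in memory and the
response is correct; otherwise the response is a guess of "change" with
probability `g` (default 0.5).  Under this model `h = m + (1-m) g` and
`f = (1-m) g`, so accuracy is `m + (1-m)/2` at `g = 0.5` — and the K
estimator converges to `N m / (1 - (1-m) g)`, which *exceeds* `k_true`
whenever `0 < m < 1` (e.g. 3.43 rather than 3.0 at `N = 4`).  This
inflation is a property of pairing the whole-display formula with
uninformed guessing; it is monotone in `k_true`, so every downstream
analysis that uses K as a predictor is unaffected in sign.  Tests assert
convergence to the model-implied asymptote, not to `k_true`.

## The diffusion model of effort choice

A Wiener accumulator with drift `v` starts at fraction `w` of the distance
between an absorbing lower boundary (low-effort choice) and an upper
boundary at separation `a` (high-effort choice); response latency is the
first-passage time plus non-decision time `t0`.  The diffusion coefficient
is fixed at 1 (scaling convention); there are no inter-trial variability
parameters — the model is deliberately the basic four-parameter form.

* **Choice probability.**  `P(HR) = (1 - e^{-2vaw}) / (1 - e^{-2va})`,
  with a series switch below `|2va| = 1e-6` for stability.
* **First-passage density.**  Classical small-time / large-time series
  expansions with per-point selection of whichever expansion needs fewer
  terms at truncation tolerance `1e-10`.  Latencies at or below `t0`
  contribute a log-likelihood floor of `-1e10` instead of `-inf` to keep
  optimisers stable.
* **Simulation.**  Default Euler–Maruyama at `dt = 1e-4` s with a
  Brownian-bridge within-step crossing correction (the crossing
  probability `exp(-2(b-x_0)(b-x_1)/dt)` is drift-free conditionally on
  the endpoints), which removes the `O(sqrt(dt))` first-passage bias of
  the naive scheme; paths are advanced in vectorised blocks.  A second,
  exact method samples the boundary from the closed-form probability and
  the conditional latency by inverting the numerically integrated series
  density on a 4096-point quadratically spaced grid; the cohort generator
  and recovery harness use it for speed, and tests verify both methods
  against the density and each other.
* **Maximum likelihood.**  Multi-start (default 5) L-BFGS-B within
  `v ∈ [-5, 5]`, `a ∈ (0.1, 5]`, `w ∈ [0.05, 0.95]`,
  `t0 ∈ [0.01, 0.99 · min latency]`; requires at least 8 trials and
  choices at both boundaries (otherwise `w` and `a` are unidentifiable).
* **Hierarchical Bayes.**  Partial pooling on unconstrained scales
  (`v`, `log a`, `logit w`, `log t0`) with normal group locations
  (weakly-informative normal priors) and half-normal(1) group scales.
  The sampler is adaptive Metropolis-within-Gibbs: a joint random-walk
  update per participant, conjugate Gibbs for locations, random-walk on
  log scales, with proposal adaptation during warmup only.  Defaults are
  4 chains × 2000 iterations with 1000 warmup; split R-hat (threshold
  1.05) and effective sample size are reported for every sampled
  parameter and the fit is flagged — never silently passed — when
  diagnostics fail.  Model comparison is exposed as held-out
  log-likelihood rather than LOOIC.

Upper boundary = high-effort choice throughout, so `w > 0.5` means a
pre-trial bias toward deploying effort.

## The synthetic cohort

Defaults encode the study conditions: n = 429 participants with sex mix
332 female / 92 male / 5 other; traits drawn from a truncated multivariate
normal with female baselines BDI proportion 0.27 (SD 0.17), PSS 20.8
(6.1), DARS 36 (11), anticipation 3.95 (1.8) on a 1–7 rating scale, male
mean shifts (−0.08, −3.1, +2.0, +0.35), and correlations
r(BDI, PSS) = 0.6, r(BDI, DARS) = r(PSS, DARS) = 0.3,
r(BDI, ant) = r(PSS, ant) = −0.2, r(DARS, ant) = −0.1.  Reported group
means constrain the marginals; the correlation magnitudes are design
defaults (only their significance is known), not claims.  The rating
scale is taken as 1–7, consistent with observed anticipation means near 4.

Latent capacity `k_true ~ N(3.0, 1.0)` truncated at 0 is independent of
all traits.  Diffusion parameters are drawn per participant from group
distributions (v: N(0.60, 0.45); a: N(1.60, 0.35) truncated > 0.15;
logit w: N(logit 0.58, 0.50); t0: N(0.35, 0.08) truncated > 0.05), and
capacity enters choice **only** through the starting point:
`logit w += 0.35 · (k_true − 3)`.  The coupling strength was fixed by a
design power analysis so that the capacity → effort-preference effect is
detectable in well over 90% of n = 429 cohorts while traits, being
causally inert, reject at the nominal rate — the pipeline-level recovery
the whole artifact is built to demonstrate.  A capacity → drift coupling
exists as a config option and is off by default.  Completion flags
(incomplete survey 7.4%, incomplete rating task 1.2%, repeated task 1.9%)
emulate the recruitment funnel.

Under these defaults low-effort trials sit near ceiling accuracy (~0.91)
and high-effort trials near 0.70, and roughly 60–65% of kept participants
fall in the high-effort group.

What the generator does *not* emulate: item-level stimulus properties,
attention lapses, learning/fatigue across trials, informed guessing, any
trait → choice causal path, and latency components beyond `t0` (whether
real choice latency includes prompt-reading time is unknowable from
summary statistics; the generator treats it as part of `t0`).  Passing
tests therefore demonstrate the *pipeline's* correctness and power under
its assumed data-generating process, not claims about real participants.

## Statistical battery

Exclusions (in order, first failure recorded): incomplete survey,
incomplete rating task, repeated task, any single choice latency strictly
over 30 s, choice-phase accuracy at or below 0.50.  Effort phenotype:
strictly more than 70% high-effort choices.  Conventions: Welch t-tests
with Welch–Satterthwaite df and pooled-SD Cohen's d; Bonferroni families
of 4 (trait measures; diffusion parameters); Pearson correlations with
t-transform p-values; logistic and linear effort-preference regressions on
K, BDI proportion, PSS and anticipation (sex optional, off by default, to
mirror the published table structure); 2×2 within-between ANOVA with
Type III sums of squares under sum-to-zero contrasts (an assumption — the
source names its wrapper, not the SS type), generalized eta squared, and a
Greenhouse–Geisser correction that is the identity for a two-level within
factor; linear mixed models with a participant random intercept and
marginal/conditional R² from the variance decomposition (singular fits
fall back to pooled OLS and are flagged); a lagged-performance OLS whose
first trial per participant is dropped.  Accuracy is aggregated to
participant × trial-type cell means for the ANOVA but kept at trial level
for the mixed models.

## Problem sizes and numerical tolerances

Density calibration checks integrate to `1e-4` tolerances by adaptive
quadrature over 50 random parameter draws; simulator validation uses 20
random parameter sets at 50 000 trials each against a KS tolerance of 0.01
(the larger sample keeps the fixed threshold meaningfully above the KS
noise floor, E[D] ≈ 0.004 at that n); recovery curves use 30 simulated
participants at 2000/500/100/30 trials, flagging budgets under 100 trials
as low-information; pipeline-level effect recovery uses 100 cohorts of
n = 429; ANOVA null calibration uses 2000 vectorised replicates.
Hierarchical-fit validation runs 12 participants × 80 trials with 2 × 700
iteration chains — enough to check group-location recovery and honest
convergence flagging, while the production defaults remain 4 × 2000.

## Known limitations

The K estimator's inflation under uninformed guessing (above) means
simulated K values are not calibrated in items.  The Metropolis-within-Gibbs
sampler mixes more slowly than gradient-based samplers; short chains can
legitimately flag non-convergence, which callers must heed.  The Euler
simulator records crossings at step resolution (`dt`), a bias far below
the validation tolerances but nonzero.  The recovery harness refits by
maximum likelihood; hierarchical refitting would show less shrinkage-induced
degradation at small trial counts but is considerably slower.
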