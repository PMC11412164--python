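# Methods

This note documents the models implemented in `tremortime`, the numerical
choices behind them, what the synthetic-data generator does and does not
emulate, and the design decisions taken where the design was genuinely
open.

## Cue combination

Duration estimates are modelled as Gaussians on a common duration scale.
Two estimates (sensory S, motor M) fuse by inverse-variance weighting:

    w_M      = sigma_S^2 / (sigma_S^2 + sigma_M^2)
    mu_SM    = w_S mu_S + w_M mu_M
    sigma_SM = sqrt(sigma_S^2 sigma_M^2 / (sigma_S^2 + sigma_M^2))

equivalently 1/sigma_SM^2 = 1/sigma_S^2 + 1/sigma_M^2. Types store
standard deviations and square internally; the module is scale-agnostic
(seconds or log-seconds) and never converts, because the internal scale of
subjective duration is not identified by this design. The operative
prediction is the *noise-response curve*: holding one channel's width
fixed and inflating the other's, the rise of the combined width over a
fixed noise grid grows with the base width — a less precise base modality
is hurt more by partner noise. An `optimality_ratio` helper (observed /
predicted combined width) is provided as a plain ratio; no suboptimality
model is fitted because the design contains no per-subject unisensory
conditions.

## Lévy-flight drift-diffusion model

Choices and response times come from a two-boundary accumulator:
evidence starts at `z*a`, evolves by the Euler scheme
`x <- x + v dt + dt^(1/alpha) xi`, and absorbs at 0 ("short") or `a`
("long"); `rt = t0 + decision time`. The momentary noise `xi` is standard
symmetric alpha-stable, sampled by the Chambers–Mallows–Stuck
construction and scaled by `2^(-1/alpha)` so the characteristic function
is `exp(-|t|^alpha / 2)` — exactly a unit-variance Gaussian at
`alpha = 2`. This standardisation is a package choice (the convention
used by hierarchical-Bayesian DDM toolboxes is not printed anywhere we
could check); its virtue is that at `alpha = 2` the process is a
unit-diffusion Wiener process with closed-form absorption probability

    P(upper) = (1 - exp(-2 v z a)) / (1 - exp(-2 v a)),

which serves as the quantitative oracle for the whole simulator.

Numerical choices:

* `dt = 1 ms` by default; decision times are capped at 10 s and capped
  trials are flagged censored, counted, and excluded from quantile
  summaries — never silently dropped.
* At `alpha = 2` a Brownian-bridge correction tests for boundary
  crossings *between* grid points (crossing probability
  `exp(-2 (a-x_k)(a-x_{k+1}) / dt)` per step and boundary, implemented as
  one Exp(1) variate per near-boundary step). This removes the
  `O(sqrt(dt))` absorption bias of discrete monitoring, so the Wiener
  oracle holds at any step size. For `alpha < 2` no closed-form bridge
  exists and crossings are detected at grid points only; the heavy-tailed
  jumps dominate boundary approach there, making the discretisation far
  less consequential.
* A numba kernel does the per-trial loop when numba is importable; a
  vectorised numpy path implements the identical scheme otherwise. Both
  are deterministic given the caller's `numpy.random.Generator`.

Stimulus coding: each of the 7 durations gets its own signed drift,
negative toward "short" below the geometric-mean duration (2,000 ms) and
positive above. The default per-duration table is antisymmetric in log
duration, `v(d) = v_max log2(d / 2000)` with `v_max = 3`, shared
`a = 1.6`, `z = 0.5`, `t0 = 0.3 s`. These base values are package
defaults chosen to produce a psychometric CV near 0.16 and mean RTs under
a second; the original fitted per-duration values were never published.

The scaling study multiplies one target parameter (`v`, `a` or `alpha`)
by 0.75 per level (three levels), holding everything else. `z` is stored
as a fraction of `a` so scaling `a` preserves relative bias. An alpha
cascade that would leave (1, 2] is clipped to 1.01 with a warning. The
three qualitative signatures checked downstream: lower drift flattens the
psychometric curve (higher CV); lower threshold also flattens it while
speeding RTs uniformly across durations; lower alpha flattens it with
slower mid-duration RTs.

## Psychometrics

RT preprocessing applies the absolute 200–2,000 ms window first and the
per-subject 3-SD rule on log RT second, computed from the windowed data.
The order is a package decision (both rules are standard but their order
is ambiguous): windowing first prevents gross outliers from inflating the
SD that defines the 3-SD cut. The pipeline is idempotent at the window
stage.

The psychometric function is a cumulative Gumbel on log10 duration,

    F(x) = 1 - exp(-exp((log10 x - m) / s)),

chosen for the log-spaced stimuli; the parameterisation is stated
explicitly because "cumulative Gumbel" admits mirrored variants. Closed
forms: `F^-1(p) = 10^(m + s ln(-ln(1-p)))`, `BP = F^-1(0.5)`,
`CV = (F^-1(0.75) - F^-1(0.25)) / (2 BP)`. CV is invariant to uniform
rescaling of all durations.

Estimation is binomial maximum a posteriori with guess and lapse rates
fixed at 0 (configurable): direct Nelder–Mead on the negative log
likelihood from three scale starts, plus a weakly-informative lognormal
prior on `s` (location 0.12 log10-units, log-SD 0.8, weight
configurable; `prior_weight=0` recovers pure ML). The prior mirrors the
practice of psychometric toolboxes that regularise with priors: on
42-trial curves, pure ML occasionally produces runaway scale estimates
that inflate the variance of derived CVs well above the information
bound, while the broad prior leaves large-sample fits essentially
untouched. Perfect separation is detected from the data (every duration
unanimous) and flagged; fitted scales below 1e-3 are floored and flagged.
Curves with fewer than 30 trials are fitted but flagged.

Expected estimation error at this design's cell sizes (7 durations × 6
trials): the Cramér–Rao bound for an observer with `s = 0.1` gives median
absolute errors near 5% for BP and near 20% for CV at 42 trials/curve,
scaling as `1/sqrt(n)` — about 3% and 11% at the 126-trial
collapsed-over-amplitude fits. Tests of BP/CV recovery should be read
against these floors.

## DDM estimation

With no closed-form Lévy likelihood, parameters are estimated by the
quantile-probability method: the data reduce to response proportions and
RT quantiles at {.1, .3, .5, .7, .9} per duration × choice; a chi-square
discrepancy compares them with the same statistics of model-simulated
trials (choices with fewer than 5 observed trials contribute a
proportion-only term). Model statistics are recomputed at every proposal
by replaying a *fixed noise bank* — the CMS base draws and
bridge-correction exponentials are generated once per fit from the seed —
so the objective is a deterministic, relatively smooth function of the
parameters (textbook common random numbers), and the bank transforms
continuously in alpha. Defaults: 3,000 bank trials, `dt = 4 ms` (the
bridge correction keeps the Gaussian case unbiased at this coarser step;
fitting sims cap decisions at 6 s), 8 Nelder–Mead starts from a
logistic-inversion heuristic plus seeded jitter, box constraints by
quadratic penalty. Drift is free per duration; `a`, `z`, `t0`, `alpha`
are shared per condition. Alpha is either fixed (the usual case), or
selected on the grid {1.2, 1.4, 1.6, 1.8, 2.0} with 2 starts each
followed by a continuous refinement with alpha free from the best grid
solution — the objective is noisy in alpha, so the grid-then-refine
scheme avoids chasing that noise. Non-convergence flags the estimate
rather than raising. Recovery at `n = 5,000` trials (v = 1.5, a = 1.6,
z = 0.5, t0 = 0.3, alpha = 2) returns drift and threshold within a few
percent (median over seeds).

Parameter-slope analysis: per subject, an OLS slope of each fitted
parameter across frequency levels coded 1, 2, 3 (level index; whether Hz
values or indices were used originally is unstated, and the choice only
rescales slopes). Drift enters as the mean absolute drift across
durations (unsigned accumulation rate). Slopes correlate with behavioural
CV/RT slopes by both Pearson and Spearman, reported together. Fits
"collapsed across amplitude" pool the trials rather than averaging fits.

## Statistics

Repeated-measures ANOVA uses the classical balanced within-subject
decomposition; each effect is tested against its own subject-by-effect
interaction error term and reported with uncorrected degrees of freedom
(partial eta squared = SS_effect / (SS_effect + SS_error)).
Greenhouse–Geisser correction is available behind a flag but off by
default, matching the uncorrected-df reporting style the analysis
follows. Balanced complete data are required; missing cells raise rather
than impute (with balanced data, sum-of-squares "types" coincide).
Linear contrasts use centred equally spaced weights (−1, 0, 1 for three
levels), a one-sample t on the per-subject scores, and
Cohen's d = mean/SD of scores. Simple main effects run the one-way
rm-ANOVA within each moderator level. Tremor-direction bins are
[0, 60], (60, 120], (120, 180) degrees — the printed integer bins
extended to continuous directions with half-open upper edges. The
Mann–Whitney comparison uses the exact null distribution up to n = 20 per
group without ties and the tie-corrected normal approximation otherwise;
rank-biserial correlation is 1 − 2U/(n1 n2). The cross-modal precision
question (visual CV > auditory CV) is answered by a between-group test on
subject-level mean CV rather than a full mixed-model ANOVA — a documented
simplification that preserves the main-effect question.

## Synthetic-data generator

The generator is the package's study-conditions definition, not a test
dial. A session is the fully crossed design — 7 log-spaced durations
(1,000…4,000 ms) × amplitudes {1, 2, 3} N × frequencies {4, 8, 12} Hz × 6
repetitions = 378 trials — shuffled per subject, with tremor direction
uniform on [0, 180); 24 subjects per modality by default.

The observer maps each condition to a combined width via cue combination:

    sigma_M(A, f) = sigma_motor_base * (1 + (freq_gain(f) - 1) * amp_gate(modality, A))
    sigma_c       = combine(sigma_sensory(modality), sigma_M)

and the combined width to a per-trial drift

    v(d) = drift_gain * ln(d / 2000 ms) / sigma_c,

with choices/RTs from the Lévy DDM (`a = 1.5`, `z = 0.5`, `t0 = 0.3 s`,
`alpha = 2`). Because the drift crosses zero at 2,000 ms for every
condition, the generator plants *no* BP shifts by construction — noise
degrades precision only — and the psychometric slope tracks `sigma_c`.

Defaults (frozen after a one-off calibration, reported in the decisions
record of the development notes; the calibration targeted the study's
qualitative effect pattern at n = 24, not any published value):

* `drift_gain = 0.52`, setting baseline auditory CV ≈ 0.17;
* `sigma_sensory`: auditory 0.17, visual 0.32. The visual width exceeds a
  naive ~1.4× auditory because the combined width saturates at the
  sensory width: with a narrower visual base the attainable visual
  CV-slope could not separate from 42-trial estimation noise at n = 24.
  The ~1.9× ratio keeps visual CVs in the 0.2–0.4 range, consistent with
  the documented auditory-over-visual advantage in interval timing;
* `freq_gain = {4 Hz: 1.0, 8 Hz: 2.1, 12 Hz: 3.6}` (non-decreasing);
* `amp_gate`: auditory 1 at every amplitude (frequency effect at all
  amplitudes); visual {1 N: 0, 2 N: 0.2, 3 N: 1} (frequency effect fully
  expressed only at the highest amplitude — the planted interaction);
* subject heterogeneity: log-normal multipliers with 0.12 log-SD on the
  sensory and motor widths and 0.10 on `t0`;
* `null_observer()` sets `freq_gain ≡ 1` for type-I-error checks.

What the generator does *not* emulate: real movement kinematics (the
optional length/force columns are structureless placeholders), lapses and
attention drifts, sequential effects and learning, any BP biases, or
heavy-tailed accumulation in behaving subjects (the generating alpha is
2). Passing pipeline tests on these data therefore demonstrates that the
analysis machinery recovers effects of the assumed generative form at
realistic sizes — not that real data satisfy those assumptions.

## Problem sizes

Default analysis scales are desk scale, chosen as package settings: the
scaling study runs 50,000 trials per level (a `--full` CLI flag restores
the original 1,400,000), DDM recovery checks use 5,000-trial conditions
over 20 seeds, psychometric recovery 500 replicates of 42-trial curves,
and the end-to-end planted-effect study 100 replicates of paired
24-subject experiments.

## Known limitations

* The QP estimator is desk-scale: standard errors are not produced, and
  hierarchical pooling across subjects (the original estimation strategy)
  is out of scope.
* For `alpha < 2` the Euler scheme's absorption is step-size dependent;
  comparisons across alpha at fixed `dt` are internally consistent but
  not a statement about the continuous-time limit.
* The mapping from combined width to CV is monotone but mildly nonlinear
  (`CV ≈ sinh(ln 3 · sigma_c / (a · drift_gain))`), so planted "slopes"
  in sigma translate to slightly convex CV trends.
* BP estimates carry a small constant model-mismatch offset (~5%) because
  the generating choice rule is logistic in log duration while the fitted
  curve is Gumbel; it cancels in all within-design comparisons.
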