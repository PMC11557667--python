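# Methods

`gazecone` measures the *gaze cone* — the wedge of gaze directions an
observer judges as directed at themself — three different ways, and asks
whether the ways agree. Because no trial-level human data are available for
this paradigm, the package pairs every analysis with a generative observer
model, and its validity claims rest on parameter recovery: data simulated
from known observers must yield the known parameters back.

## Viewing geometry

A looker at distance *D* (cm) fixates points offset *x* cm from the
observer's face; the induced gaze rotation is `arctan(x / D)`, computed
exactly (no small-angle approximation; at 165 cm the error of the linear
approximation would reach 0.6° at the widest direction). Angles are in
degrees throughout; the observer's left is negative. One-sided designs store
non-negative magnitudes plus a `sides` flag. The per-eye vergence needed to
fixate the observer is `arctan((IPD/2) / D)` — 1.13° (printed: 1.1°) for a
6.5 cm IPD at 165 cm.

The one-sided stimulus set is built from successive powers of a 2.5 cm base:
offsets {0, 2.5, 6.25, 15.625, 39.0625} cm, i.e. {0, 0.87, 2.17, 5.41,
13.31}°, matching the published direction set {0, 0.9, 2.2, 5.4}° at one
decimal. The widest published direction, 13.9°, is *not* reproduced by this
rule (`arctan(39.0625/165) = 13.3°`; 13.9° corresponds to a 40.8 cm offset);
the generator emits 13.3° and the discrepancy is documented here rather than
patched. The regression breakpoints keep the published value 13.9° because
they define analysis intervals, not stimuli.

## Generative observer model

One parameter per phenomenon, all per-observer (`ObserverParams`):

| parameter | unit | default | role |
|---|---|---|---|
| `criterion` (T) | deg | 3.3 | dyadic threshold of direct gaze |
| `psycho_width` (σ) | deg | 1.5 | SD of the judgment noise |
| `lapse` (λ) | prob | 0.02 | stimulus-independent errors, ∈ [0, 0.1] |
| `center_shift` (c) | deg | 0 | cone center (two-sided designs) |
| `adjust_criterion` | deg | = T | criterion applied in the adjustment task |
| `hysteresis` (h) | deg | −0.37 | descending-minus-ascending stop difference |
| `adjust_noise_sd` | deg | 1.03 | trial scatter of stop-points |
| `triadic_near_gain` | – | 0.18 | perceived-direction slope below the knot |
| `triadic_far_gain` | – | 1.8 | slope above the knot |
| `triadic_knot` | deg | 0.9 | where the gain changes |
| `triadic_noise_sd` | cm | 1.5 | read-off scatter on the scale |

**Dyadic yes/no.** `P(direct | θ) = (1 − λ)·Φ((T − |θ − c|)/σ) + λ/2`
(one-sided designs use |θ|). Responses are Bernoulli, presentation order is
shuffled per seed.

**Adjustment.** Ascending series stop at `T − h/2 + ε`, descending at
`T + h/2 + ε`, `ε ~ N(0, adjust_noise_sd)`; stops are quantized to the
device step (0.05° live-looker, 1° avatar), clipped to the adjustable range
[0, range_max], and sign-flipped on the left side. The symmetric ±h/2 split
makes the two-series average unbiased for T whatever h is — the reason the
analysis averages the series.

**Triadic.** Perceived direction is a continuous two-slope fold,
`g(θ) = sign(θ)·[near·min(|θ|, knot) + far·max(0, |θ| − knot)]`, mapped to
centimetres at the scale plane (`D·tan g`), perturbed with Gaussian read-off
noise, and rounded to the whole centimetre (the scale's granularity). The
rounding is a design property (`TriadicDesign.round_to_cm`) and is switched
off in noiseless-closure analyses: with it on, every perceived offset in the
first section (≤ 0.47 cm) rounds to zero and the section's slope is not
recoverable in principle.

**Cohorts.** Per-observer parameters are drawn from per-field normal
distributions (SD 0 = fixed), truncated where the model requires (criteria
≥ 0.2°, SDs ≥ 0, λ ∈ [0, 0.1]), and persisted in `truth.csv`. Random
streams are split counter-style: observer *i*'s stream for task *t* is
seeded with the triple `(master_seed, i, task_code)` via NumPy's
`SeedSequence`, so streams are independent, reproducible and insertion-order
free; identical configs give byte-identical CSVs.

### Calibration of the default cohorts

The two bundled cohort configurations mirror the two study designs this
package models. Live-looker cohort: 18 observers, dyadic criteria
N(3.3, 1.0)°, adjustment criteria N(5.2, 1.28)°, h = −0.37° (the two tasks
disagree on purpose: the methods empirically measure different thresholds).
Avatar cohort: 20 observers, criteria N(3.51, 1.44)°, center shift 0.69°
right, adjustment criteria around 4.73°, h = +4.4°.

The adjustment scatter is *deconvolved* from the reported within-observer SD
of stop magnitudes: that SD is taken over all stops of an observer and
therefore already contains the ±h/2 series split, so the generative scatter
is `σ = sqrt(SD² − (h/2)²)` — 2.39° for the avatar cohort (SD 3.25°,
h 4.4°) and 1.03° for the live-looker cohort (SD 1.05°, h 0.37°). Simulation
confirms the deconvolved value reproduces the observed SD; using the raw SD
as scatter overshoots it and, through range clipping, shrinks the
recoverable hysteresis.

The lapse default (0.02) is a small realistic rate; the original analyses do
not state one. The triadic read-off noise (1.5 cm) is of the order of the
1 cm scale granularity.

## Analysis pipeline

**Cumulative-Gaussian fit** (one-sided designs). Direct judgments are
inverted and `P(averted | θ) = (1 − λ)·Φ((θ − T)/σ) + λ/2` is fitted by
maximizing the exact binomial log-likelihood; the 50% point T is the
threshold of direct gaze, and the full cone width is 2T. The lapse is fixed
at 0 by default, with an optional free lapse bounded to [0, 0.05] — which
mode the original analyses used is not stated, so both are provided and the
default is documented, not asserted. 0% and 100% cells are handled by the
likelihood itself (probabilities clipped at 1e−12); no empirical-logit
transform is used.

**Gaussian-bell fit** (two-sided designs). `P(direct | θ) =
a·exp(−(θ − c)²/(2w²))` with amplitude a free in (0, 1] (fixable); the
bell's SD w is the threshold, c the cone center. Note w is a different
threshold *definition*, not an estimate of the fold criterion T; the package
makes no numerical equivalence claim between the two.

**Optimization.** Bounded L-BFGS-B from deterministic quantile-based starts
(five threshold starts; for the bell, four centers × two widths), `ftol`
1e−8, T bounded to the angular hull ± one span, σ ∈ [0.01, 5·span]. The
`converged` flag is honest: if no restart converges the best point is still
returned with a warning. A brute-force grid search over (T, σ) — or (c, w) —
is the independent verification route; on simulated study-sized datasets the
optimizer's threshold lands within one grid step (0.05°) of the exhaustive
argmax and its log-likelihood is never below the grid's best. When the
likelihood ridge is nearly flat (σ against its lower bound, near-separated
data), the argmax location is ill-conditioned and only the likelihood-margin
comparison is meaningful.

**Adjustment summary.** Per observer, the threshold is the *unweighted* mean
of the (series × side) cell means — "four means per observer" in the
two-sided design — not the pooled trial mean; the two differ when cells are
unbalanced. Left-side cell means are folded by sign (configurable) before
entering the overall threshold; cell means are reported signed. The
within-observer SD is taken over all stop magnitudes (ddof 1). The cohort
hysteresis contrast is a paired t on per-observer descending-minus-ascending
folded means, with Cohen's d and the between-series Pearson r (r is omitted,
not an error, when undefined — two observers or a flat series).

**Triadic regression.** Reports in cm are converted back to degrees at the
scale plane before fitting, so both axes are in degrees and the correction
composes with degree-valued thresholds. The global OLS line's slope is the
classical overestimation factor. The four-piece regression fixes breakpoints
at {0, 0.9, 2.2, 5.4, 13.9}° and fits each closed interval *independently*
(discontinuities permitted — matching the section-by-section description of
the procedure, not a continuous segmented model); boundary points enter both
adjacent segments.

**Threshold correction.** A threshold T selects the section whose closed
interval contains it (interior ties to the higher section; T beyond the last
breakpoint extrapolates with section 4 — these rules matter for thresholds
near 5.4° and are therefore explicit), and `T* = slope_k·T + intercept_k`
using both the section's slope *and* intercept; the estimation bias is
T*/T, undefined (NaN) at T = 0.

**Cohort statistics.** Paired t (`t = mean(d)·√n / sd(d)`, df n−1, Cohen's
d = mean(d)/sd(d)), Pearson r with `t = r√(n−2)/√(1−r²)` (df n−2), and a
one-way repeated-measures ANOVA by sums-of-squares decomposition (df
(k−1, (k−1)(n−1)), partial η² = SS_cond/(SS_cond+SS_err)) are implemented
from their defining sums so each can be verified against independent
brute-force oracles; SciPy supplies only the distribution tails. All
p-values are two-sided and unadjusted (the original post-hoc tests apply no
correction either). Degrees of freedom always follow the standard formulas;
published df that deviate from them (e.g. an F numerator df of 4 for four
conditions, or a correlation df equal to n−1) are not chased. Edge cases:
zero-variance zero-mean differences give t = 0, p = 1; |r| = 1 gives p = 0;
zero variance in a correlation input is an error, not a silent NaN.

**Comparison report.** The between-method ratio is
mean(adjustment)/mean(constant stimuli), computed before any rounding.
The corrected block applies each observer's own piece-wise regression to
both of that observer's thresholds and repeats the statistics. CSVs round
for presentation (2 decimals for degrees and statistics, 3 for p); the JSON
report keeps raw precision.

## What the simulator does and does not emulate

It reproduces, by construction: binomial yes/no psychometrics with lapses, a
between-task criterion difference, series hysteresis with symmetric
cancellation, device quantization and range clipping, a compressive-then-
expansive perceived-direction mapping with whole-cm report rounding, and
between-observer parameter spread.

It does not emulate: fixation error of a live looker (no quantitative model
exists to calibrate against), asymmetric series biases (only the symmetric
±h/2 split), task-order or learning effects, correlations between an
observer's parameters beyond what the field distributions induce, or
non-Gaussian psychometric shapes. Passing recovery tests therefore shows the
*pipeline* is consistent and unbiased under this model at the study's sample
sizes — not that the model is a complete account of human gaze perception.

## Problem sizes

The test suite and the acceptance script run study-sized problems: cohorts
of 18 (live-looker design: 125 yes/no, 12 adjustment, 125 triadic trials per
observer) and 20 (avatar design: 385/60 trials); recovery statistics average
6–8 such cohorts, the end-to-end pattern 20 of them, and optimizer–oracle
agreement uses 20 datasets against a 150 × 116 grid. These sizes give
standard errors comfortably below the tolerances being checked while the
whole suite runs in well under a minute.

## Known limitations

- The bell width w and the fold criterion T are related but not equal;
  recovery for the two-sided design is checked against the grid oracle, not
  against T.
- Range clipping biases the recoverable hysteresis slightly toward zero when
  the ascending mean sits within ~2 SD of the range floor (≈ −0.2° under the
  avatar calibration); this is a property of the paradigm, not of the
  estimator.
- With report rounding on, the first triadic section is unidentifiable (all
  its perceived offsets round to 0 cm at 165 cm); section-1 claims are
  meaningful only for unquantized analyses.
- The piece-wise fit assigns boundary points to both neighbouring segments;
  alternative conventions shift corrected thresholds for observers whose
  threshold sits exactly on a breakpoint.
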