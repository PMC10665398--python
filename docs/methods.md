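# Methods

## The impedance model and its estimation

The package treats the arterial wall within a single heartbeat as a
linear spring–damper: arterial pressure Pb(t) is the driving force and
the PPG amplitude Pl(t), in percent of full scale, the wall
displacement, so that dPb(t) = K·dPl(t) + B·dṖl(t) with all differences
taken against the beat-onset sample t0. The model's assumptions are
that (i) the PPG amplitude is proportional to vessel-wall displacement
over the beat, (ii) K and B are constant within a beat, and (iii)
pressure noise is additive and white.

Estimation choices, where the underlying description is open:

* **No intercept.** dPb, dPl and dṖl are all exactly zero at t0 by
  construction, so the regression passes through the origin. R² is
  nevertheless computed about the mean of dPb (1 − SSR/SST), the
  stricter convention: a constant-only fit does not get credit.
* **Derivative scheme.** Ṗl is a central finite difference at interior
  samples and one-sided at the edges (`numpy.gradient`), second-order
  accurate with no phase shift. Ṗl(t0) is the derivative evaluated at
  the onset sample, so dṖl(t0) = 0.
* **Beat boundaries.** Half-open [onset, next onset); the final onset
  only closes the previous beat. Segments with fewer than 3 samples are
  skipped with a logged warning (the 2-parameter fit needs ≥3 points).
* **Exclusion filters.** Beats are excluded when R² < 0.95 or when K or
  B is negative. The negative-coefficient rule is read as
  exclude-if-either-is-negative, since both are physical non-negative
  coefficients; an exclude-only-if-both reading is available via
  `filter_estimates(..., exclude_rule="both")`. Rank-deficient designs
  (flat PPG, collinear regressors) and zero-variance pressure beats are
  flagged invalid with a reason rather than fitted.

## MEC_K detection

Per stimulus, pre-K is the median K over [onset − 10 s, onset) and
post-K the maximum over (offset, offset + 20 s], where offset is the end
of the 5-s train; windows are closed on the side away from the stimulus
and open at the stimulus boundary, and the median of an even beat count
is the mean of the two middle values. The 20-s window is anchored at
stimulus *offset* because the response is defined "after" a stimulus
that itself lasts 5 s; `anchor="onset"` is available.

The detection rule unifies two requirements — an isolated supra-5% rise
followed by a sub-5% change is noise, and a session with no 5% rise at
80 mA is out of range — as the **suffix rule**: MEC_K is the smallest
intensity from which *every* subsequent stimulus responds, out-of-range
being exactly the empty-suffix case. This rests on the physiological
premise that a genuine evoked response is monotone in intensity. The
literal pairwise reading (reject a responded intensity whose immediate
successor failed) is implemented as `rule="pairwise"`; the two rules
differ only on interrupted runs such as Y,Y,N,Y,…, which the suffix rule
resolves conservatively (higher MEC_K). Under both rules a
non-responding top intensity forces out-of-range.

## ROC_BP

Percent change from the median sBP of the last 10 pre-incision beats to
the maximum beat sBP in (incision, incision + 120 s]. ROC_BP is a
*percent change*, (post/pre − 1)·100, not a raw ratio — the cohort-level
regression intercept (~29%) and typical values (~18%) are on that
scale; the raw ratio is kept as a derived field. The 120-s window
length is a package default (the response must be captured before any
analgesic intervention); it is configurable, and no windowing choice
affects the pre-incision median.

## Cohort statistics

* **Correlation and regression** go through `scipy.stats` (pearsonr,
  linregress); residual SD uses n − 2 degrees of freedom.
* **Smirnov–Grubbs** is two-sided and iterative: G = max|dᵢ − d̄|/s is
  compared with G_crit(n, α) = ((n−1)/√n)·√(t²/(n−2+t²)), t the upper
  α/(2n) Student-t quantile on n − 2 df; the flagged point is removed
  and the test repeated. Residuals are predicted − measured. A
  zero-SD sample flags nothing, with a warning.
* **Parallel lines** is textbook ANCOVA via closed-form normal
  equations: the two-sided t-test of the interaction term in
  y = b0 + b1·x + b2·g + b3·x·g (slope equality; with one interaction
  term the t and F tests coincide), then, refitting without the
  interaction, the t-test of the group term (intercept equality under a
  common slope — meaningful when slope equality was not rejected, which
  is the reporting order). The implementation is cross-checked against
  statsmodels OLS in the test suite.
* **Bland–Altman** of externally predicted vs measured ROC_BP: bias is
  the mean difference, the limits of agreement bias ± 1.96·SD, and
  "precision" is defined here as 1.96·SD, the half-width of the limits
  of agreement.
* **Sample size.** The default power model is the fixed-design
  regression F test (G*Power's linear-regression mode): numerator df 1,
  denominator df n − 2, noncentrality n·f² with f² = R²/(1 − R²); the
  returned n is the smallest (≥ the floor, default 4) whose power meets
  the target. At R² = 0.25, α = 0.05, power 0.8 this gives n = 26. The
  exact-correlation alternative (`method="correlation"`, a noncentral-t
  approximation with δ = r√n/√(1−r²)) is deliberately not the default:
  it models a random regressor and systematically requires more cases
  for the same assumed R². Monte-Carlo verification in the tests
  simulates the same fixed-design model, so measured power brackets the
  target at n and n − 1.
* p-values are two-sided throughout.

## What the synthetic data emulate — and what they do not

* **Waveforms.** The PPG pulse is a raised-cosine single hump per beat
  (smooth, analytically differentiable, zero amplitude and slope at
  onsets); pressure is built from the *discrete* model — the same
  central-difference derivative the estimator uses — plus i.i.d.
  Gaussian noise. With zero noise the fit therefore recovers (K, B) to
  machine precision; this is the package's definition of the forward
  model, chosen so the generator and estimator agree about what a
  derivative is at a finite sampling rate. Defaults: 100 Hz, 60 bpm,
  pulse amplitude 10%, baseline 80 mmHg.
* **Sessions.** Per-beat K at 1 Hz: baseline_k (10 mmHg/%) with 1%
  multiplicative CV, and for each stimulus at/above the subject
  threshold a multiplicative transient — linear rise over 8 s to a peak
  gain of 0.10, then exponential decay (τ = 2.5 s) — entirely inside the
  20-s post window. The 0.10 gain is twice the 5% criterion so baseline
  noise cannot mask a response; the 1% CV keeps the probability of a
  spurious ≥5% windowed rise negligible (the ~2–3% rises visible below
  threshold come from taking a max over ~20 beats). The default
  inter-stimulus gap (45 s) guarantees return to baseline before the
  next pre-window; shorter gaps are a configuration error. Optional
  single-beat artifact spikes exercise the noise-rejection rule.
* **Cohorts.** ROC_BP = slope·MEC_K + intercept + N(0, σ²) with defaults
  slope −0.27 %/mA, intercept 28.81%, σ = 5%; MEC_K is drawn from a
  histogram with mode 30 mA, more than half the mass in 20–40 mA, and a
  3% out-of-range tail (≈1 subject in 30). Out-of-range subjects carry
  no ROC_BP and are excluded from all paired analyses. Two-group
  cohorts take per-group slope/intercept overrides.
* **Not emulated:** real PPG morphology (dicrotic notch, respiratory
  modulation), motion artifacts, beat-detection errors, non-Gaussian or
  autocorrelated noise, drift in anesthetic depth, and any
  pharmacokinetics. Passing tests therefore demonstrate correctness of
  the *computation* under the stated model, and calibration of the
  statistics under Gaussian assumptions — not robustness to clinical
  artifact, which would need real recordings.

## Problem sizes used in the tests

Monte-Carlo checks run at: 1,000 beats for fit unbiasedness; 500
sessions for end-to-end threshold recovery (≥99% required); 1,000
cohorts (n = 30) for slope CI coverage (95% ± 2%); 10,000 replicates for
the Grubbs type-I rate at n = 29; 5,000 replicates for the
parallel-lines null-uniformity KS check; 50,000 replicates for power
verification; and 100 seeded cohorts for the end-to-end slope-recovery
rate (≥90%). These sizes make the binomial/KS tolerances used in the
assertions (3 SE, 1% KS level) meaningful while keeping the full suite
in the tens of seconds.

## Known limitations

* Beat onsets are inputs; there is no beat detector for raw signals.
* The stimulation ladder must be complete (10 mA steps from 10 mA);
  adaptive/staircase protocols are out of scope.
* The pairwise/suffix ambiguity on interrupted response runs cannot be
  resolved from the rule statements alone; both are implemented and the
  suffix rule is the default.
* The Grubbs critical value is the standard Bonferroni-style bound,
  marginally conservative at small n (the measured type-I rate sits just
  below α).
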