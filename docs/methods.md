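# Methods

This note documents the models and procedures implemented in `ansrisk`,
the numerical choices behind them, what the synthetic cohort does and does
not emulate, and the known limitations.

## HRV features (`ansrisk.hrv`)

**Windowing.** Mid-shift tachograms are cut into tumbling half-open 120-s
windows anchored at the recording origin (the start of the first
interval); a beat falling exactly on a boundary opens the next window.
Pre/post resting recordings use a single leading 90-s span.

**Quality gate.** A window fails when flagged-or-abnormal beats exceed 10%
of all beats (a window at exactly 10% passes — the rule is "exceeds"), or
its average heart rate leaves [30, 150] bpm. A beat is abnormal when its
RRI leaves [300, 2000] ms or jumps more than 20% relative to its
predecessor. Bad windows are excluded, never repaired: no ectopic
interpolation is attempted.

**Spectrum.** The unevenly sampled tachogram is cubic-spline interpolated
to an even 4 Hz grid and linearly detrended, then fitted with a Burg
(maximum-entropy) autoregressive model. The default order is 16 — standard
practice for ~480-sample short records — with an AIC-selected option
capped at order 30. The one-sided AR spectrum integrates over [0, 2] Hz to
the detrended series variance (checked to 5% in tests). Band powers are
trapezoidal integrals over LF = [0.04, 0.15) Hz and HF = [0.15, 0.40) Hz.
Whether the original instrumentation resamples the tachogram or models
uneven samples directly is not public; the interpolation route is this
package's documented choice. Degenerate inputs: a constant window yields a
(numerically) zero spectrum; noise-free tones produce near-unit-circle
poles, so the spectral denominator is floored at 1e-30 to keep band
integrals finite.

**Deviation scores.** `LF_score = 10 (log(LF/RRI_avg) - mu_LF(age)) /
sigma_LF(age) + 50`, and `HF_score = 10 (HF/RRI_avg - mu_HF(age)) /
sigma_HF(age) + 50`. Note the asymmetry: the HF score standardizes the
*unlogged* normalized power. That asymmetry is implemented as printed in
the source methodology; a `log_hf=True` switch provides the logged variant
if a log-scale normative table is supplied. Natural logarithms throughout.
The shipped normative table is **synthetic** — generated once from a
simulated reference population (400 subjects per age year, band powers
declining ~1.5%/yr, fixed internal seed) — because the true normative
moments come from unpublished proprietary data. All scores are therefore
relative to the supplied table; users with real normative data should load
it via `NormativeTable.from_csv`.

**Time domain.** Computed on unflagged beats only: AVGHR = 60000/mean(RRI);
SDNN with the n-1 denominator; NN50 = count of successive absolute
differences > 50 ms (the standard definition); RMSSD = RMS of successive
differences.

## Driving scenes (`ansrisk.scenes`)

Speed range proxies road type. Rules, per second, with precedence
STOPPED > XLOW > LOW > HIGH > MEDIUM:

* HIGH: a 1-min block with strictly more than 30 s above 70 km/h; a block
  also inherits HIGH from its predecessor (hysteresis). The inherited rule
  as stated never terminates, so this implementation stops carry-over at
  the first minute that independently qualifies LOW, has a majority of
  stopped/creeping seconds, or never reaches 20 km/h — bounded hysteresis
  consistent with the rule's evident intent.
* LOW: blocks with strictly more than 45 s below 20 km/h, in runs of at
  least five consecutive qualifying minutes ("over 4 min" read as >= 5).
* XLOW (creeping): speed in (0, 3) km/h while the centered 5-s moving
  average stays below 8 km/h at every second of [t-10, t+10]; never at
  speed 0.
* STOPPED: speed exactly 0. MEDIUM: everything else moving.

A 20-s feature window's scene is the majority label of its seconds, ties
resolved toward the faster scene.

## Near-miss risk model (`ansrisk.risk`)

Fifteen features per tumbling 20-s window: extrema/mean/SD of speed and of
longitudinal and lateral acceleration, the SD of speed around its centered
10-s moving average (fine speed variation), and mean-speed differences
with the previous and following windows (edge windows get 0 plus an
incompleteness flag and are excluded from training by default). A window
is labeled positive when a validated warning timestamp falls inside its
half-open span.

One `GradientBoostingClassifier` per scene in {HIGH, MEDIUM} — low-speed
scenes have no rear-end near-misses and report a missing risk.
Hyperparameters are grid-searched (default trees {100, 300} x depth
{3, 5} x learning rate {0.05, 0.1}) by mean stratified shuffled 5-fold CV
AUC with a fixed seed; the report carries pooled out-of-fold ROC/AUC and
gain-based importances normalized to sum to 1. No class re-weighting is
applied to the ~1:9 imbalance. Folds are not grouped by driver; grouped
CV would be the stricter design and is a documented extension point.

## Analysis dataset (`ansrisk.dataset`)

The 20-s risk index is averaged into 2-min blocks (all six sub-windows
required — a conservative completeness policy), sharing the shift-anchored
grid with the 120-s ANF windows so the join is exact. A record survives
when the driver drove continuously (speed > 0 each second — a work-log
flag is not available, so continuous motion defines "driving"), the block
mean speed is >= 20 km/h (an all-seconds variant is available by flag; the
mean-speed reading matches the risk index's validity domain), the ANF
window passed quality, and the risk block exists. Risk is expressed in
percent, bounding the response in [0, 100].

## Logistic quantile regression (`ansrisk.lqr`)

The bounded response is mapped to the real line by
`z = log((y - y_min)/(y_max - y))` with y clamped into
[y_min + eps, y_max - eps], eps = 0.1 by default (bounds 0/100; the
original boundary handling is unpublished, so eps is configurable).
Quantile equivariance under monotone maps gives fitted conditional
quantiles that always respect the bounds. The check-loss minimization on
the z scale is delegated to statsmodels' `QuantReg` (IRLS); an independent
brute-force lattice oracle bounds the solver's loss in the tests.

**AIC.** Quantile fits have no likelihood, so model comparison uses the
asymmetric-Laplace working likelihood with its scale at the MLE
sigma = (check loss)/n:

    loglik = n log(tau(1-tau)) - n log(sigma) - n,    AIC = 2k - 2 loglik.

Only differences at a fixed tau are meaningful; the constant terms cancel.

**Selection.** Step 1 fits the control-only baseline (AVGHR, age, mean
speed; sex is dropped automatically when invariant, as in an all-male
cohort). Step 2 fits all nine SNS x PNS two-variable additions (no
interactions) at tau in {0.25, 0.5, 0.75, 0.9, 0.95}, ranks models by AIC
within each quantile (average ranks on ties), and among models whose two
added coefficients are significant (two-sided normal test, alpha = 0.05)
at *every* quantile selects the lowest average rank. A VIF < 10 screen
over the full candidate set guards against multicollinearity. The
selection-stage significance screen uses the solver's asymptotic
(kernel-bandwidth) SEs by default: running 2000-resample bootstraps for
9 models x 5 quantiles inside selection is prohibitive, and the screen
only needs a significance *direction*. Final coefficient tables use
bootstrap SEs (records resampled i.i.d.; B = 2000 default, seeded). A
driver-clustered bootstrap would respect within-driver correlation and is
a known extension.

**Mean effects.** The "mean" column analog is OLS of z on X. The source
methodology calls this step "logistic regression" for a continuous bounded
outcome, which is ambiguous; OLS-on-logit is the reading implemented (a
fractional-regression variant would be the alternative).

**Boundary censoring caveat.** With a heavily right-tailed response a
non-trivial share of records sits below eps and is clamped, creating a
point mass on the z scale. Quantile coverage is exact on this working
response (the tests verify tau +/- 0.02 at n = 20000) but on the raw scale
low-quantile coverage is distorted by the point mass; coefficients at low
quantiles are correspondingly attenuated toward the clamp. This mirrors
any real analysis with eps-clamping and is inherent to the transform, not
a solver defect.

## Shift-phase comparison (`ansrisk.shift`)

The mid-shift representative value per index is the mean over
quality-passing 2-min windows in the 30 min after driving starts; pre and
post use the single resting 90-s window per shift. For each index all
three phases are Shapiro-Wilk tested (per group, alpha = 0.05 — the
stricter per-group reading of an ambiguous gate); if all pass,
Tukey-Kramer (scipy's studentized-range implementation, unequal n);
otherwise Steel-Dwass. Steel-Dwass jointly mid-ranks each pair, uses the
tie-corrected rank-sum variance, and refers sqrt(2)|t| to the studentized
range with infinite df; when the smaller group has <= 6 observations (and
enumeration is affordable) the pairwise p-value is computed exactly over
all assignments, then mapped through the same studentized-range
adjustment (an identity at k = 2). Time-domain indices are not compared
across phases because the pre/post instrumentation does not produce them.

## Synthetic cohort (`ansrisk.synthetic`)

The generator states a world and keeps it fixed:

* **Drivers**: age uniform on 35-63 y (matching the studied cohort's
  range), baseline HR ~ N(68, 7) clipped to [50, 90] bpm, lognormal
  stress reactivity.
* **Shift**: 30 min pre rest + 6 h driving/loading + 30 min post rest by
  default (no shift schema is published; this is a typical haul).
* **Stress** s(t) in [0, 1]: mean-reverting smooth drift (OU-like,
  stationary SD 0.08, 2-min time constant, per-second step capped at
  0.05) plus exponential event bumps (~6/h, height 0.3, 60-s decay);
  baseline 0.12 at rest, 0.35 x reactivity while driving.
* **Telemetry**: AR(1) speed around regime means (high 85, medium 45,
  low 12, stopped 0 km/h), innovation SD 2 km/h scaled by
  (1 + 1.5 s(t)) — the stress -> jerky-driving coupling is the observable
  pathway that makes a telemetry-only risk model sensitive to stress;
  without it the latent stress would be invisible to the classifier by
  construction. acc_x is the speed difference in m/s^2 plus noise, acc_y
  pure noise.
* **Warnings**: per 20-s window with mean speed >= 20 km/h,
  P(warning) = logistic(-11 + 1.2 std_speed + 2.0 mean_speed/100 +
  2.5 stress). The intercept and slopes were calibrated once against the
  generator's own telemetry distribution to give a ~10% positive-window
  rate (inside the 1-20% band implied by the published class ratios, which
  never state a per-hour base rate) while keeping the hazard strongly
  feature-dependent; warnings are timestamped uniformly among the
  window's moving seconds, so none occur at speed 0.
* **RRI**: amplitude-modulated sinusoids at 0.10 and 0.25 Hz on a
  60000/baseline_hr ms carrier — enough to place power exactly in the LF
  and HF integration bands with a closed-form oracle, deliberately *not*
  a full IPFM or point-process heart model. LF amplitude rises
  (0.030 x (1 + 1.5 s)) and HF amplitude falls (0.055 x (1 - 0.8 s)) with
  stress, so stress raises LF/HF and lowers NN50/RMSSD. White beat noise
  8 ms.
* **Artifacts**: missed beats merge adjacent interval pairs, ectopics
  split one interval 40/60; both flagged, elapsed time conserved; default
  rates 2% and 1%.

What a green test does **not** establish: the generator has no road
geometry, traffic interaction, circadian drift, respiration coupling or
realistic 1/f HRV background, and its stress variable is a scalar stand-in
for an unoperationalized construct. Tests against it validate the
*machinery* (windowing, spectra, rules, fits, selection arithmetic) and
the *recoverability of planted directions*, not any physiological claim.

`simulate_analysis_records` generates regression-ready 2-min records
directly from the logistic-quantile model (correlated sympathetic and
parasympathetic blocks, planted coefficients stored in `attrs`), which is
the right granularity for estimator-level properties (coverage, CI
calibration, selection consistency) where the full pipeline would only
add unrelated noise.

## Known limitations

* The normative score table is synthetic; absolute LF_score/HF_score
  levels carry no population meaning.
* No driver-level random effects anywhere; records are treated i.i.d. in
  fitting and bootstrapping.
* The HIGH-scene carry-over termination and the XLOW moving-average
  windowing are documented interpretations of ambiguous rules; both are
  isolated behind `ansrisk.scenes` constants for sensitivity analysis.
* AIC for quantile fits is internally consistent but its absolute values
  are tied to the asymmetric-Laplace convention; only within-quantile
  comparisons are meaningful.
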