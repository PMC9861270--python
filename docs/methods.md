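# Methods

This note documents the models, formulas, numerical choices and
limitations behind `hrvguide`, in the order data flows through the
package.

## RR-interval files and units

RR intervals are stored and processed in milliseconds throughout. The
native file dialect is one interval per line with optional `# key=value`
header lines (subject, device, position, trial, free-text origin); a CSV
dialect (sniffed by a comma on the first line) must carry an `rr_ms`
column. No device export standard is assumed — the dialect is a
repository convention. A file whose values are all below 10 almost
certainly holds seconds; it is loaded verbatim with a `UnitWarning` and
an `unit_suspect` flag on the series. There is deliberately no silent
unit conversion: a wrong guess here would silently scale every
downstream statistic by a factor of 1000.

## Stabilization trimming

Resting protocols record ~6 minutes per position and discard the first
minute while the signal stabilizes. A beat is retained iff its start
time (the cumulative sum of the preceding intervals) is at or beyond the
trim boundary, so a beat straddling the boundary is excluded — the
conservative choice, keeping only beats fully inside the analysis
segment.

## Artifact detection and correction

Detection implements the threshold rule used by standard automatic beat
correction at its "mean" level: a beat whose interval deviates more than
0.25 s from the reference mean is abnormal. The default reference is the
global recording mean, applied one-shot (no recomputation of the mean
after each exclusion). Because the exact proprietary rule in commercial
software is not public, a moving local mean (centred window, default 11
beats, not-yet-flagged neighbours only, single left-to-right pass) is
available behind the `reference="local_mean"` flag; it behaves better
under slow drifts, at the cost of a less predictable reference.

Correction fits a cubic spline to (cumulative time, RR) over the clean
beats and evaluates it at each flagged beat's original cumulative time.
Using cumulative time rather than beat index respects unequal beat
spacing. The default scipy `CubicSpline` (not-a-knot) reproduces any
polynomial of degree ≤ 3 exactly, which the tests verify to < 1e-6
relative error. At least 4 clean beats are required; a flagged beat
outside the span of the clean beats has no bracketing support and falls
back to the nearest clean value with a recorded warning rather than
trusting cubic extrapolation.

A recording is accepted only when the corrected fraction is strictly
below 20% ("less than 20%" is read as a strict inequality, so exactly
20% is rejected).

## Time-domain HRV

rMSSD = sqrt(mean((RR_{i+1} − RR_i)^2)) in milliseconds; LnrMSSD is the
natural log of the millisecond value (group means near 3.9–4.0 then
correspond to a physiological 50–55 ms). A constant window has rMSSD 0
and no Ln value; `HRVResult.ln_rmssd` is `None` there and the scalar
`ln_rmssd()` raises, so callers choose their own handling. Analysis
windows are half-open `[start, start+duration)` on beat start times, so
a boundary beat is never counted twice. The ultra-short window is the
first minute of the 5-minute analysis segment.

## Agreement and reliability statistics

* **Normality gate**: Shapiro–Wilk, defined here for 3 ≤ n < 50 (the
  small-sample regime it is intended for).
* **Paired comparison**: paired t contrast; the p value is multiplied by
  the comparison-family size (Bonferroni) and capped at 1.0. In the
  bundled validation study the families are the 2 device comparisons and
  the 4 duration comparisons.
* **Cohen's d** is computed on the paired differences
  (d = mean(x−y) / SD(x−y), often written d_z) — the natural effect size
  for within-subject designs. The 95% CI of the mean difference is
  reported as `effect_ci`, and an approximate normal-theory CI of d
  itself as `cohens_d_ci`, labelled separately, because published tables
  are often ambiguous about which of the two their CI column holds. With
  zero difference variance and a nonzero mean difference, d is reported
  as a signed infinity with a warning.
* **Interpretation bands** for d (trivial/small/moderate/large at 0.20,
  0.50, 0.80), r (trivial…almost_perfect at 0.10, 0.30, 0.50, 0.70,
  0.90) and ICC (poor_to_moderate/good/excellent at 0.75, 0.90) follow
  the conventional printed cut-offs. Printed band tables typically leave
  gaps (e.g. "small" ending at 0.49 and "moderate" starting at 0.50 with
  0.495 unassigned); each band here is the half-open interval anchored
  at its printed lower edge, applied to the magnitude, which makes the
  banding total and deterministic. Boundary behaviour is tested at every
  cut-off.
* **ICC** is ICC(2,1) — two-way random effects, absolute agreement,
  single measurement — the standard form for device-reliability designs
  where both devices/trials are interchangeable samples. The confidence
  interval uses the McGraw–Wong F-quantile construction at a
  configurable level (reliability tables conventionally print 90%). The
  implementation is checked in the tests against pingouin's ICC(A,1) at
  95%, which is the independent route; pingouin itself cannot serve as
  the implementation because its CI level is fixed. Estimates and CI
  bounds are clipped into [0, 1]. Zero between-subject variance leaves
  the ICC undefined and raises.
* **SEM and MDC**: SEM_abs = pooled two-trial SD × sqrt(1 − ICC) — the
  standard reliability formula; SEM% anchors it to the condition's own
  group mean, and MDC = 1.96 × SEM_abs × √2. Anchoring SEM% to the
  condition-specific mean (not a shared grand mean) is what makes the
  published SEM%/MDC pairs mutually consistent, and the package's
  arithmetic check reproduces all six published MDC values to two
  decimals from the printed SEM percentages and means.
* **Bland–Altman**: bias = mean(x−y), limits of agreement
  bias ± 1.96 × SD(x−y), returned with the per-subject (mean,
  difference) pairs for plotting.

## Training engine

The control month of daily LnrMSSD defines the profile:
SWC = mean ± 0.5 × SD (sample SD, rejected records excluded). At least
21 usable days of the ~30-day control period are required by default —
enough to tolerate missed measurements without voiding the profile. A
zero SD collapses the zone to a point (warned; every later day is then
"outside").

Decisions are computed on scheduled training days (default Mon/Wed/Fri
for 12 weeks → 36 decisions) from the trailing 7-day rolling mean of the
available daily records (missing days are simply absent; no
imputation). The rule set:

1. the first training day is always low intensity and does not count
   toward escalation;
2. rolling average inside the SWC → high intensity, escalation reset;
3. outside the SWC → low intensity on the first such day, rest while the
   deviation persists ("low or rest" is under-specified in the published
   description; escalating recovery mirrors the day-to-day decision
   literature this logic derives from, and the policy is a config switch
   so `always_low` can be swapped in);
4. a missing rolling value defers the decision to rest with a warning.

Above- and below-SWC deviations are treated identically, as the
published wording ("falls outside") does not distinguish them.

Progression: a completed session (high or low) earns a star; at the star
threshold the level increments and stars reset. Four levels of four
sessions are fixed by the app design; the star threshold is not
published and defaults to 9 (about three weeks of sessions per level,
filling the 3-month programme across four levels); sessions within a
level are chosen round-robin, another unpublished detail kept
configurable. At level 4 progression saturates.

## Synthetic data

The generator emulates the paced-breathing resting protocol: RR_i =
mean_rr + A·sin(ω t_i) + ε_i, with the respiratory sinus arrhythmia
(RSA) collapsed to a single sinusoid at the metronome frequency —
justified precisely because the protocol paces breathing at a constant
rate, and giving a closed-form successive-difference contribution
2A²sin²(ωτ/2). The Gaussian noise SD is solved from
target_rmssd² = 2A²sin²(ωτ/2) + 2σ², and a target below the RSA term
alone raises a configuration error. Defaults portray a healthy sedentary
adult at rest: mean RR 900 ms (~67 bpm), target rMSSD 54 ms
(LnrMSSD ≈ 3.99), breathing 9.5 breaths/min (within the 7–11 paced
range), RSA amplitude 25 ms, 6-minute recordings. The calibration
assumes beats sampled roughly τ apart; beat-spacing jitter makes the
RSA-on calibration accurate to a few percent rather than exact, which
the tolerance tests reflect.

Planted artifacts alternate sign (±magnitude) so both high and low
outliers are exercised, and return their ground-truth indices for
recall/false-positive scoring. The paired device adds a per-beat
Gaussian jitter (default 2 ms) plus optional fixed offset — the simplest
model producing the near-perfect agreement regime (LnrMSSD r > 0.99,
excellent ICC, SEM% < 5) that motivates chest-strap apps. The
study-scale dataset draws between-subject LnrMSSD per position (supine
mean 3.995 SD 0.64; seated 3.947 SD 0.66, clipped to a physiological
2.5–5.0 Ln range) with trial-to-trial Ln variation 0.18 supine / 0.085
seated, and records run ~10 s past the nominal 6 minutes so the trimmed
segment always covers the full 5-minute window.

What the generator does **not** model: real RSA harmonics and
non-stationarity, baroreflex dynamics, true ectopic-beat morphology
(compensatory pauses), device-specific filtering, or correlated daily
HRV (day-to-day values are i.i.d.). Passing tests therefore demonstrate
correctness of the algorithms under controlled statistical structure,
not performance on messy field recordings.

## Problem sizes and tolerances

Stochastic tests use seeded generators at the scale the workflows target:
20-subject studies, 100-seed Monte-Carlo loops for calibration and
artifact recovery, 2000-pair samples for limits-of-agreement recovery
(10% tolerance on the LoA halfwidth, 2 SE on recovered bias, mean
calibration within 2%). The rMSSD implementation is compared with an
explicit brute-force loop on 1000 random series (tolerance 1e-9 ms).
The acceptance script (`scripts/acceptance.py`) re-runs all of these
from a single seed and completes in a few seconds.

## Known limitations

* Only the file-ingestion path is modelled; live sensor acquisition
  (Bluetooth/SDK) and photoplethysmography imports are out of scope.
* rMSSD is the only HRV index; SDNN, pNN50, frequency-domain and
  nonlinear indices are deliberately absent.
* The detection rule is a reconstruction of the published threshold
  description, not a bit-compatible clone of any commercial correction
  algorithm.
* Published Cohen's d values in this study design could not be
  reconciled with any standard formula given their printed means and
  CIs; d here is validated only against the package's own
  paired-difference definition.
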