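# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `physioarousal`. It is written for a reader who wants to
know exactly what the package computes and what its synthetic-data tests do
and do not demonstrate.

## Protocol model

The analysis unit is a participants × segments × parameters table. The
protocol timeline is fixed in structure: four 1-min baseline recordings
(pooled to a single BL value as the mean of the usable minutes, requiring at
least two), a first question period Q1 of variable duration, a 1-min rest
R1, a second question period Q2, and a 6-min rest subdivided into R2a–R2f.
Question periods are the participant's actual typing span; spans shorter
than 30 s are treated as missing. Segment windows are half-open
`[start, end)`.

Spot blood pressure is taken three times (mid-baseline, after R1, after
R2f), so MAP is constant within each BP slot. Each distinct post-baseline
MAP value is analyzed once — at R1 (second reading) and R2f (third) —
while TPR is analyzed at all nine post-baseline segments because it varies
through CO. This yields 8×9 + 2 = 74 analysis cells and 148 tests (74
within-subject baseline contrasts + 74 between-group contrasts).

## Signal derivations

**ECG → HR.** Conditioning: 0.5 Hz high-pass, 50 Hz notch (Q = 30), 40 Hz
low-pass, resampled to 400 Hz. R waves are found Pan–Tompkins-style
(5–15 Hz band-pass, derivative, squaring, 150 ms integration, adaptive
threshold at 25% of the 99th percentile, 250 ms refractory period), refined
to the local ECG maximum, with an add/delete edit hook standing in for
manual correction. Heart period is the mean of inter-beat intervals whose
midpoints fall in the window; HR = 60000/HP. Intervals outside 300–2000 ms
are artifact-flagged.

**HRV.** The IBI series (artifact runs of ≤ 2 intervals linearly
interpolated, longer runs → window missing) is resampled at 4 Hz by cubic
interpolation and Welch-transformed (60 s segments, 50% overlap, linear
detrend). Band powers integrate the PSD over 0.14–0.4 Hz (HF) and
0.07–0.14 Hz (LF) and are floored at 1e−6 ms² before the natural log so
degenerate constant series return a finite, flagged value. Windows shorter
than 60 s are not analyzed (one Welch segment is the minimum meaningful
estimate), which makes HRV missing for sub-minute question periods.

**Impedance cardiography.** dZ/dt is 50 Hz band-stop filtered and resampled
to 1000 Hz; beats within a window are ensemble averaged by pointwise median
(≥ 10 beats, sweeps spanning −100 to +550 ms around R). Landmarks: Z is the
global maximum in a 30–300 ms systolic search window; B is the maximum of
the Savitzky–Golay-smoothed (11 ms window, cubic) second derivative within
the sub-40%-of-Z-amplitude region up to 160 ms before Z; X is the minimum
within 450 ms after Z. Boundary solutions and non-physiological orderings
return a flagged missing value. PEP = (B − R) + 20 ms (Q fixed at
R − 20 ms); LVET = X − B; SV by Kubicek with ρ = 135 Ω·cm and the
participant's measured electrode distance; CO = SV·HR/1000 using the same
segment's HP-derived HR (segment coherence); TPR = MAP/CO, exact wherever
both are defined.

**Respiration.** 0.033 Hz high-pass, 1 Hz low-pass, resampled to 25 Hz.
Breaths are zero crossings of the detrended belt signal with a 1 s minimum
cycle (consistent with the 1 Hz low-pass). The rate is derived from the
mean cycle length among inspiration onsets inside the window — exact on
constant-rate signals, unlike a raw count, which carries ±1-cycle
discretization — and averaged with equal weights across the usable belts.

**Electrodermal activity.** At 25 Hz, qualifying onsets are 3-sample local
minima at least 1 s apart (earliest kept). Local maxima are then counted as
nonspecific fluctuations: a maximum qualifies if it lies in the closed
window 3.5–12 s after its nearest preceding qualifying onset and rises
strictly more than 0.02 µS above that onset's value. Counting maxima (each
at most once) rather than onsets prevents one physical fluctuation being
credited to several nearby candidate onsets. Events belong to the segment
containing their onset. NSFR is events per minute; windows under 10 s are
missing. The count is invariant to constant offsets and to tonic drift up
to roughly the smallest event amplitude divided by the onset-to-peak time
(beyond that, drift eats into the measured rise).

## Synthetic ground truth

Two generator levels share one population model.

**Raw recordings.** Beat trains integrate IBI(t) = HP + LF·sin(2πf_lf·t) +
HF·sin(2πf_hf·t) + white noise. The ECG is a Gaussian R wave (σ = 8 ms)
with small Q/S/T deflections; the dZ/dt beat is a half-sine ejection wave
from B = R + (PEP − 20 ms) peaking at B + 60 ms, with a raised-cosine X
notch at B + LVET. The half-sine's abrupt upstroke matches the sharp
B-point inflection of real dZ/dt and makes the curvature-based B detector
exact on clean signals, which a smooth (e.g. squared-sine) onset does not.
Respiration is a quasi-sinusoid with per-segment rate; Z0 is the basal
impedance with mild respiratory coupling. EDA is a slowly declining tonic
level (−0.001 µS/s) plus skin conductance responses with a linear 5 s rise
and a compactly supported quadratic 7 s recovery. The kinked shape is a
deliberate choice: any smooth-peaked kernel whose maximum must fall in the
3.5–12 s counting window gets its peak displaced below the 3.5 s bound when
riding on a neighbor's decay, so exact count round trips would be
impossible; the kinks pin onset and peak under superposition. Events keep a
minimum onset separation of one kernel footprint (13 s), which caps the
realizable fluctuation rate near 4.6/min — requesting higher rates
saturates rather than errors.

**Population model.** Per-participant levels are normal draws: HR 75 ± 8
bpm, MAP 93 ± 8 mmHg, lnHF 6.0 ± 1.0 and lnLF 6.5 ± 1.0 ln(ms²), RR 15 ±
2.5 cpm, NSFR 6 ± 2 /min, PEP 100 ± 10 ms, CO 5.5 ± 1.0 l/min, TPR 17 ±
3.5 mmHg·min/l, electrode distance 48.28 ± 5.80 cm. Segment-to-segment
noise SDs are calibrated so that baseline-change dispersion at n = 108
matches the standard errors reported for this study design (σ_segment ≈
SE·√108/√2). Default within-subject question reactivity (both conditions)
raises HR, RR and NSFR and lowers lnHF and PEP during question periods,
with a small HR dip in the first post-question minute. Between-group
condition effects default to zero and are injected additively per
(parameter, segment) into the MS group only.

**Fast path.** `synth_segment_study` draws the analysis table directly from
the population model. It is the vehicle for statistical simulations
(imputation calibration, null replication at 200 repetitions) where raw
signal synthesis would only add runtime. On this path each parameter is
generated on its own scale; cross-parameter identities (TPR = MAP/CO) hold
only on the raw-recording path. Missingness is completely at random over
the 74 change-score cells at 13.92% by default, the level at which
imputation operates.

**What the synthetic data does not emulate:** arrhythmia and ectopy,
movement artifacts, electrode drift/detachment, respiratory sinus
arrhythmia coupling between channels, non-stationary tonic EDA, and
informative (non-MCAR) missingness. Passing round-trip tests therefore
demonstrates the correctness of the derivation algorithms on well-behaved
signals, not robustness to pathological recordings.

## Imputation

Chained predictive mean matching: for each incomplete column, a Bayesian
linear regression of the column on all other analysis cells plus a centered
condition indicator (ridge-stabilized, λ = 1e−5·tr(XᵀX)/p, since p ≈ n)
yields predicted means under a parameter draw; each missing cell receives
the observed value of one of the 5 nearest donors by predicted mean
(type-1 matching). Five sweeps over the columns, repeated m = 5 times with
independent substreams. Imputed values therefore always lie in the observed
support, and observed cells are identical across copies. Pooling follows
Rubin's rules with the Barnard–Rubin small-sample df when the complete-data
df is known; with a single imputation or zero between-imputation variance
the rules reduce to the identity.

## Inference

Within-subject: one-sample t on change scores pooled over both conditions
(n = 108, df = 107). Between: pooled-variance two-sample t (MS − DPS,
df = 106). With an imputed stack, tests run per imputation and are
Rubin-pooled; t = pooled estimate / pooled SE, p from the pooled df.

Bayes factors use the JZS (Cauchy-on-effect-size) prior with scale r = 1,
two-sided, computed from the pooled t by adaptive quadrature over the
normal-prior variance hyperparameter g mapped to a finite interval
(g = u/(1−u)), integrand in log space, relative tolerance 1e−10;
non-convergence raises rather than falling back. The two-sided form is used
throughout: the recurring ≈ 0.15 floors in the between-group family emerge
from n = 53/55 and r = 1 alone under the two-sided model, which a
directional variant would not reproduce. B is computed from the pooled t
(per-imputation B values are available by running `analyze_study` on single
datasets); how to combine Bayes factors across imputations has no canonical
answer, and the pooled-t route keeps the Bayesian and frequentist columns
on the same estimate.

FDR correction is Benjamini–Hochberg step-up over the joint 148-test family
(default); a Storey-type variant that scales q by an estimated null
proportion π₀ = min(1, 2·mean(p > 0.5)) is available as `method="storey"`
for users who prefer an empirical-null flavor. No conclusion in the package
depends on the variant.

The sensitivity analysis root-finds (Brent, tolerance 1e−4) the effect size
at which two-tailed noncentral-t power reaches the target (default 0.80 at
α = 0.05); a normal approximation replaces scipy's noncentral t only where
extreme noncentrality overflows it.

## Numerical and degenerate-input conventions

Flat ECG → empty, flagged beat series (never silent zeros). Constant IBI
series → power floor + flag. Monotone dZ/dt ramps (no systolic peak or no X
notch) → flagged missing. Fewer than 2 beats, 10 ensemble beats, 2 usable
baseline minutes, or any missing BP reading → missing values that flow into
imputation. Word-frequency ties break lexicographically. All stochastic
components accept a single integer seed; studies spawn per-participant
substreams so any participant can be regenerated in isolation.

## Problem sizes used by the test suite

Deterministic checks are instantaneous. The stochastic acceptance checks
use: a 20-participant noise-free cohort for signal round trips (HR ±0.5
bpm, PEP ±2 ms, RR ±0.5 cpm, NSF exact, ≥90% HRV band attribution); one
imputed null study at n = 53/55 with 13.92% missingness for the
evidence-pattern check; 200 complete-data replicate studies for the
false-positive rate; and 100 MCAR replicates (n = 108, 9 columns) for
imputation calibration. These sizes give stable verdicts for the assertions
made while keeping the full suite under a minute on one CPU.

## Known limitations

* B-point detection on real dZ/dt is notoriously morphology-dependent; the
  curvature criterion is standard but would need per-lab validation.
* Single-shot BP readings propagate measurement error into MAP and TPR for
  entire slots; the package accepts them as-is.
* The NSFR generator saturates above ~4.6 events/min by construction.
* PMM with 74 predictors and ~93 observed rows leans on ridge
  stabilization; with much higher missingness the chained model would need
  a reduced predictor set (the `pmm_impute` API accepts any column subset).
* Evidence percentages treat the 148 tests as exchangeable; no hierarchy
  over parameters or segments is modeled.
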