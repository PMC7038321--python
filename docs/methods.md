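# Methods

## Signal model

A protocol measurement is modelled as

    F(t) = T·g(t) + g(t)·A(t)·sin(2πf t + φ) + ε(t) + d·t

where `T` is the 300 gf force target, `g(t)` a logistic ramp envelope that
rises from exactly 0 at t = 0 to exactly 1 at the end of the ramp
(default 1 s) and stays there, `A(t) = A·(1 + m·sin(2πf_m t + φ_m))` the
slowly modulated tremor amplitude, `ε` Gaussian sensor noise, and `d` a
linear baseline drift. The tremor is scaled by the same envelope because
action tremor rides on the voluntary contraction. Optional contact-loss
dropouts (per-second probability, 0.1–0.3 s long) clamp the gauge to 0 gf,
emulating a subject tapping rather than pressing the sensor. The phases
φ, φ_m are drawn from the measurement's seed, so every trace is bit-wise
reproducible.

Parameter defaults (units gram-force, Hz, seconds): Parkinsonian tremor
frequency 6.0 with a per-subject ±0.4 jitter; amplitude mapped from the
clinical severity rating 0–4 as {0, 5, 10, 20, 40} gf — the rating scale
is ordinal, so any monotone mapping is admissible and this one is
configurable; modulation depth 0.2 at 0.3 Hz; noise SD 2 gf; drift 0;
dropouts off. Healthy subjects carry a small (1.5 gf) physiological tremor
at 10 ± 0.4 Hz — above the 3.5–7.5 Hz analysis band, so the band-pass
removes it and only broadband noise survives in-band. The shipped study
design is 36 healthy subjects × 1 session plus seven Parkinsonian
subjects contributing 13 sessions: 49 sessions × 10 fingers = 490
measurements, of which the 98 thumb measurements (2 per session) are
excluded before analysis.

The validation rig is a motor-driven eccentric pulley stretching an
elastic band against a gauge. Rotation follows
`dθ/dt = 2πr·(1 + β·sinθ)`: with β = 0 the phase is linear (closed form);
with β > 0 — the elastic band slowing the stretch and whipping the
contraction — the ODE is integrated with RK4 on a 4 kHz grid, which
distorts the gauge sinusoid and introduces harmonics. Encoder pulses fall
at equal phase increments; pulse times are interpolated on the fine grid.

## Conditioning chain

1. **Outlier repair** — samples strictly below the 1.25th percentile of
   the measurement's own sample distribution (linear-interpolated
   empirical quantile) are treated as contact-loss dips and replaced by
   linear interpolation between the nearest non-outlier neighbours;
   leading/trailing runs take the nearest non-outlier value. At most
   ⌈0.0125·N⌉ samples can be altered. The pass is not idempotent on
   continuous data (the percentile moves after repair); it is idempotent
   on plateau-plus-dropout signals, which is the regime it targets.
2. **Hold-window location** — the first contiguous run of at least
   `hold_s` seconds (default 3; 5 for the repeatability protocol) with
   |F − 300| ≤ 20% × 300, found on the *repaired raw* trace and truncated
   to exactly `round(hold_s × 40)` samples. The ±20% band width is a
   design choice (the protocol displays a target region but no numeric
   width); it is configurable. If no run qualifies the measurement is
   invalid and the protocol repeats the finger.
3. **Band-pass** — forward–backward 4th-order Butterworth, 3.5–7.5 Hz.
   The zero-phase (filtfilt) realisation keeps the window indices found
   on the raw trace aligned with the filtered signal. Measured response:
   gain 0.996 at 5.5 Hz, 0.005 at 1.5 Hz, 0.082 at 10 Hz (12 s
   sinusoids). Windowing before vs. after filtering is not dictated by
   the method; this package locates the window on the raw trace and cuts
   the same span from the filtered one, so both views refer to identical
   sample indices.

## Spectra and the validity statistic

Spectra are single-segment, mean-subtracted, rectangular-window DFTs of
the hold window — no Welch averaging, because the method analyses one
short (3–5 s) segment. The amplitude spectrum is `2|X_k|/N` (DC/Nyquist
unscaled); the PSD is the periodogram `|X_k|^2/N^2`, one-sided with
interior bins doubled, so the bin sum equals the mean square of the
mean-subtracted signal (Parseval, asserted to 1e−9 relative).

`P_peak` integrates the PSD over f_d ± 0.3 Hz by trapezoidal quadrature
of the piecewise-linear PSD curve, with linear interpolation where the
interval edges fall between bins — the definition is a continuous
integral, and this is its natural discretisation. The denominator of
`V_f` integrates the full one-sided spectrum with the *same* quadrature,
so `V_f ≤ 1` holds by construction and `V_f` is exactly invariant to
amplitude scaling. Ties in the in-band argmax break toward the lower
frequency.

**Leakage.** A 3 s rectangular window resolves 1/3 Hz bins. A tremor
frequency that is an integer number of cycles in the window (4.0, 6.0,
7.0 Hz…) concentrates ≥ 99.8% of band-passed power within ±0.35 Hz; a
half-bin-offset frequency such as 5.5 Hz spreads ~18% into sidelobes.
This bounds what concentration-based validity can promise: dominant
frequencies are quantised to the bin grid (error ≤ 1/6 Hz for 3 s
windows, ≤ 0.1 Hz for 5 s windows), which is well inside the ±0.35 Hz
recovery tolerance but visible in `V_f` for off-bin tremor.

## Features and classifiers

The amplitude spectrum is resampled by linear interpolation onto the
fixed 41-point grid 3.5, 3.6, …, 7.5 Hz. (The 0.1 Hz spacing follows
from 41 values over a 4 Hz band; the feature count is the stated
invariant.) Standardisation is column-wise z-scoring with a guard mapping
constant columns to zeros.

Benchmark classifiers, hyperparameters fixed at their reference values:
RBF-SVM with kernel coefficient γ = 6.4 (as `K = exp(−γ‖x−y‖²)`; other
toolboxes parameterise the Gaussian kernel by a scale σ with γ = 1/σ²,
so the same printed number can mean a much flatter kernel — the
coefficient reading is used here and is overridable); kernel-density
naive Bayes — per-feature Gaussian KDE with Silverman bandwidth
`0.9·min(sd, IQR/1.34)·m^(−1/5)`, the standard reading of a
"nonparametric Gaussian" naive Bayes — implemented as a
scikit-learn-compatible estimator; a Gini decision tree capped at 100
leaf nodes (scikit-learn has no total-node cap; 100 leaves ≈ 199 nodes
is the closest faithful constraint); and KNN with k = 13 and cosine
distance (k is capped at the training-fold size for tiny datasets). SVM
and KNN inputs are standardised.

Cross-validation is stratified 5-fold with a fixed seed; `val_accuracy`
is the mean per-fold accuracy, while sensitivity/specificity/precision/F1
come from confusion counts pooled over validation folds with the disease
class as target. Measurement-level splitting is the default framing; it
leaks subject identity across folds, so a grouped-by-subject mode
(`groups=` / `--group-by-subject`) is provided for honest
subject-level generalisation estimates. When stratification is impossible
(k exceeds the minority class count, e.g. leave-one-out) plain shuffled
folds are used.

## Study harnesses

**Rig validation.** Each trial draws the motor's true speed from
N(nominal, 0.05 rev/s) — real motors have trial-to-trial speed
variability, and without it both estimator arms would be degenerate
constants — simulates the rig for 3 s (the trial length is configurable;
the validation protocol is also run with 10 s records), and estimates
frequency from the encoder (`(n_pulses − 1)/(counts_per_rev × elapsed)`)
and from the gauge PSD argmax over the full band up to Nyquist. The test
statistic is the conventional unpooled two-sample z,
`z = (μ_r − μ_oe)/√(s_oe²/n + s_r²/n)` with sample (n−1) standard
deviations, two-sided at α = 0.05. Both arms identical ⇒ z = 0, no
rejection; a deterministic 1 Hz offset ⇒ certain rejection.

**Repeatability.** For each hand and each threshold in
{0.5, 0.6, 0.7, 0.8, 0.9}: the count and fraction of measurements with
`V_f` above the threshold, and the mean and sample standard deviation of
f_d over the valid set. Frequency statistics are withheld when fewer than
two measurements are valid — a two-measurement cell is too small a
sample to summarise.

## What the simulations do and do not show

The generator reproduces the protocol's structure (target, hold, finger
sweep, cohort counts), tremor phenomenology (near-sinusoidal oscillation,
amplitude modulation, severity-scaled amplitude, out-of-band physiological
tremor) and the rig's kinematics. It does not model biomechanics, sensor
nonlinearity, inter-finger coupling, medication state, fatigue, or the
multi-peaked spectra seen when contact is intermittent. Passing tests
therefore demonstrate the *pipeline's* correctness and internal
consistency on signals matching the stated model — not clinical
performance on human data; the classifier benchmark in particular
separates a synthetic cohort whose groups differ by construction.

## Problem sizes and numerical choices

Property suites use 100-seed Monte-Carlo batches (validity of white
noise, frequency recovery, rig non-rejection) and 28-window
repeatability sets, matching the study-scale framing while keeping the
full suite and the acceptance script in the seconds-to-minutes range.
Quadrature tolerance assertions are 1e−9 relative; V_f scale invariance
is asserted to 1e−12 relative. Degenerate inputs raise typed errors:
traces shorter than 3 samples (outlier filter), windows shorter than 8
samples (spectra), zero total power (V_f), bands outside Nyquist,
missing severity-rating parameter entries, fewer than 2 encoder pulses,
single-class datasets.
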