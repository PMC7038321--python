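# tremorforce

Quantifying **action tremor** from finger-force time series. A
strain-gauge keyboard-style device measures the force each finger applies
while a subject presses toward a 300 gram-force target and holds it for a
few seconds; Parkinsonian tremor rides on that voluntary contraction as an
approximately sinusoidal oscillation in the 3.5–7.5 Hz band. This package
is the hardware-free analytic stack for such measurements: it simulates
the protocol (and the motor/encoder rig used to validate the hardware),
conditions the raw 40 Hz traces, detects and quantifies tremor, classifies
healthy vs. Parkinsonian measurements, and analyses measurement
repeatability. It is aimed at researchers developing or evaluating
force-based tremor instrumentation who need a tested, reproducible
reference pipeline.

## The statistics at the core

For a hold window of N samples with discrete Fourier transform X_k, the
single-segment power spectral density is the periodogram
`P_k = |X_k|^2 / N^2` (one-sided, interior bins doubled; mean removed).
The **dominant frequency** f_d is the PSD argmax in the 3.5–7.5 Hz band.
The **peak power** integrates the PSD around it,

    P_peak = ∫_{f_d−0.3}^{f_d+0.3} P(f) df,

and the **peak power proportion**

    V_f = P_peak / Σ_i P_i

is the fraction of total spectral power concentrated at the tremor peak —
a scale-free statistic in [0, 1]. A measurement is *valid* when V_f
exceeds a threshold (0.5–0.9): genuine tremor concentrates power; noise
spreads it. Classification uses the one-sided amplitude spectrum resampled
to 41 values on the 3.5–7.5 Hz grid, benchmarked with four classifiers
(RBF-SVM, kernel-density naive Bayes, decision tree, cosine-KNN) under
stratified fivefold cross-validation.

## Worked example

```python
import tremorforce as tf
from tremorforce.preprocess import preprocess_trace

proto = tf.ProtocolConfig()                      # 300 gf target, 3 s hold, 40 Hz
params = tf.SimuParams(tremor_freq_hz=5.8, tremor_amp_gf=25,
                       noise_sd_gf=2.0, seed=42)
trace = tf.simulate_trace(params, proto, subject_id="P05",
                          hand="left", finger="index")
window = preprocess_trace(trace, proto)          # outlier repair, band-pass, cut
a = tf.assess(window, threshold=0.5)
print(f"f_d = {a.f_d:.4f} Hz   P_peak = {a.p_peak:.3f} gf^2   "
      f"V_f = {a.v_f:.3f}   valid = {a.valid}")

rig = tf.RigParams(rev_per_s=7.0, velocity_fluct_beta=0.0)
r = tf.rig_validation(rig, n_trials=40, seed=1)
print(f"mu_oe = {r.mu_oe:.3f} Hz (s = {r.s_oe:.3f})   "
      f"mu_r = {r.mu_r:.3f} Hz (s = {r.s_r:.3f})   "
      f"z = {r.z:.2f}   reject H0: {r.reject}")
```

prints

```
f_d = 5.6667 Hz   P_peak = 75.122 gf^2   V_f = 0.716   valid = True
mu_oe = 7.001 Hz (s = 0.041)   mu_r = 7.000 Hz (s = 0.000)   z = -0.08   reject H0: False
```

The simulated 5.8 Hz tremor lands on the nearest resolvable bin of the 3 s
window (5.667 Hz, bins are 1/3 Hz apart), 72% of spectral power sits
within ±0.3 Hz of the peak, and the measurement passes the 0.5 validity
threshold. On the rig, the optical-encoder and gauge-spectrum frequency
estimates agree (7.00 Hz both ways) and the two-sample z-test finds no
difference in means.

A command-line surface wraps the same operations:

```sh
tremorforce simulate --seed 1 --out data/          # shipped 490-measurement cohort
tremorforce run --in data/raw.jsonl --out results/ # full pipeline + benchmark
tremorforce rig-validate --rev-per-s 7 --trials 40 --seed 1
```

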