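"""Seeded generators for strain-gauge tremor measurements.

Three simulators live here:

* :func:`simulate_trace` — one protocol-driven finger measurement: a smooth
  force ramp to the 300 gf target, a hold plateau, an amplitude-modulated
  tremor sinusoid, broadband sensor noise, slow baseline drift, and optional
  contact-loss ("tapping") dropouts.
* :func:`simulate_cohort` — a whole labelled study: healthy subjects carry a
  small physiological tremor above the analysis band (8–12 Hz), Parkinsonian
  subjects carry a 3.5–7.5 Hz tremor whose amplitude grows with their
  clinical severity rating (Fahn–Tolosa–Marin scale, 0–4).
* :func:`simulate_rig` — the validation rig: a DC motor spins a pulley with
  an eccentrically mounted elastic band that stretches against a gauge,
  while an optical encoder logs pulses at fixed angle increments.  The
  elastic load can modulate the angular velocity within a revolution
  (``velocity_fluct_beta``), which distorts the gauge signal away from a
  pure sinusoid.

All generators are fully determined by their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import expit

from .trace import FINGERS, ForceTrace, ProtocolConfig

__all__ = [
    "SimuParams",
    "CohortDesign",
    "RigParams",
    "EncoderLog",
    "simulate_trace",
    "simulate_cohort",
    "exclude_thumbs",
    "simulate_rig",
    "encoder_frequency",
    "default_cohort_design",
    "default_healthy_params",
    "default_pd_params_by_ftmtrs",
    "DEFAULT_AMP_BY_FTMTRS",
]

# Tremor amplitude (gf) assigned to each severity rating 0-4.  Clinically the
# scale is ordinal, not metric; this mapping is monotone and configurable.
DEFAULT_AMP_BY_FTMTRS = {0: 0.0, 1: 5.0, 2: 10.0, 3: 20.0, 4: 40.0}


@dataclass
class SimuParams:
    """Signal-generation parameters for one simulated measurement.

    ``tremor_freq_hz`` should sit in 3.5–7.5 Hz for Parkinson-like signals
    and above 8 Hz for physiological tremor.  ``amp_mod_depth`` applies a
    slow sinusoidal modulation to the tremor amplitude (tremor amplitude
    varies over seconds even when frequency is stable);
    ``tap_dropout_prob`` is the per-second probability of a brief
    contact-loss interval during which the gauge reads zero.
    """

    tremor_freq_hz: float = 6.0
    tremor_amp_gf: float = 0.0
    amp_mod_depth: float = 0.2
    amp_mod_freq_hz: float = 0.3
    noise_sd_gf: float = 2.0
    drift_gf_per_s: float = 0.0
    tap_dropout_prob: float = 0.0
    ramp_s: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tremor_freq_hz <= 0:
            raise ValueError("tremor_freq_hz must be positive")
        if self.tremor_amp_gf < 0 or self.noise_sd_gf < 0:
            raise ValueError("amplitudes and noise must be non-negative")
        if not 0 <= self.amp_mod_depth <= 1:
            raise ValueError("amp_mod_depth must be in [0, 1]")
        if not 0 <= self.tap_dropout_prob <= 1:
            raise ValueError("tap_dropout_prob must be in [0, 1]")
        if self.ramp_s <= 0:
            raise ValueError("ramp_s must be positive")


@dataclass
class CohortDesign:
    """Study structure: one row per subject.

    ``subjects`` holds ``(subject_id, group, ftmtrs_tremor, n_sessions)``
    tuples with ``group`` in {"healthy", "pd"}.  Each session measures
    ``fingers_per_session`` fingers (default 10: five per hand).
    """

    subjects: list = field(default_factory=list)
    fingers_per_session: int = 10

    def __post_init__(self) -> None:
        for sid, group, rating, n_sessions in self.subjects:
            if group not in ("healthy", "pd"):
                raise ValueError(f"unknown group {group!r} for {sid}")
            if not 0 <= int(rating) <= 4:
                raise ValueError(f"ftmtrs rating must be 0-4, got {rating}")
            if int(n_sessions) < 1:
                raise ValueError("n_sessions must be >= 1")
        if self.fingers_per_session < 1:
            raise ValueError("fingers_per_session must be >= 1")

    @property
    def n_sessions(self) -> int:
        return sum(int(n) for _, _, _, n in self.subjects)

    @property
    def n_measurements(self) -> int:
        return self.n_sessions * self.fingers_per_session


def default_cohort_design() -> CohortDesign:
    """The shipped study design: 36 healthy subjects with one session each
    plus seven Parkinsonian subjects contributing 13 sessions, for 49
    sessions and 490 finger measurements in total."""
    subjects = [(f"H{i:02d}", "healthy", 0, 1) for i in range(1, 37)]
    pd_ratings = [1, 2, 3, 3, 3, 3, 4]
    pd_sessions = [2, 1, 1, 1, 6, 1, 1]  # 13 sessions
    subjects += [
        (f"P{i + 1:02d}", "pd", r, s)
        for i, (r, s) in enumerate(zip(pd_ratings, pd_sessions))
    ]
    return CohortDesign(subjects=subjects)


def default_healthy_params(seed: int = 0) -> SimuParams:
    """Small physiological tremor above the analysis band, so the 3.5-7.5 Hz
    band-pass removes it and only broadband noise survives in-band."""
    return SimuParams(
        tremor_freq_hz=10.0,
        tremor_amp_gf=1.5,
        amp_mod_depth=0.2,
        amp_mod_freq_hz=0.3,
        noise_sd_gf=2.0,
        seed=seed,
    )


def default_pd_params_by_ftmtrs(
    amp_by_rating: dict | None = None, tremor_freq_hz: float = 6.0
) -> dict:
    """Per-rating parameter table: amplitude grows with severity."""
    amps = dict(DEFAULT_AMP_BY_FTMTRS if amp_by_rating is None else amp_by_rating)
    return {
        rating: SimuParams(
            tremor_freq_hz=tremor_freq_hz,
            tremor_amp_gf=amp,
            amp_mod_depth=0.2,
            amp_mod_freq_hz=0.3,
            noise_sd_gf=2.0,
        )
        for rating, amp in amps.items()
    }


def _ramp_profile(t: np.ndarray, ramp_s: float, steepness: float = 10.0) -> np.ndarray:
    """Smooth logistic rise from exactly 0 at t=0 to exactly 1 at t>=ramp_s."""
    lo = expit(-steepness / 2)
    hi = expit(steepness / 2)
    g = (expit(steepness * (t / ramp_s - 0.5)) - lo) / (hi - lo)
    return np.where(t >= ramp_s, 1.0, g)


def simulate_trace(
    params: SimuParams,
    protocol: ProtocolConfig | None = None,
    *,
    subject_id: str = "S00",
    session_id: str = "s0",
    hand: str = "left",
    finger: str = "index",
    label: int | None = None,
    extra_s: float = 1.0,
) -> ForceTrace:
    """Simulate one protocol measurement.

    The force is a logistic ramp to the protocol target followed by an exact
    plateau, plus a tremor sinusoid with slowly modulated amplitude (scaled
    by the same ramp envelope, since the tremor rides on the voluntary
    contraction), Gaussian sensor noise and a linear baseline drift.  During
    contact-loss dropouts the gauge reads exactly 0 gf.  The trace covers
    ramp + hold + ``extra_s`` margin.
    """
    protocol = protocol or ProtocolConfig()
    rate = protocol.rate_hz
    duration = params.ramp_s + protocol.hold_s + extra_s
    n = int(round(duration * rate))
    if n < 2:
        raise ValueError("duration too short for the sampling rate")
    rng = np.random.default_rng(params.seed)
    t = np.arange(n) / rate

    envelope = _ramp_profile(t, params.ramp_s)
    force = protocol.target_gf * envelope

    phase = rng.uniform(0, 2 * np.pi)
    mod_phase = rng.uniform(0, 2 * np.pi)
    amp_t = params.tremor_amp_gf * (
        1.0 + params.amp_mod_depth * np.sin(2 * np.pi * params.amp_mod_freq_hz * t + mod_phase)
    )
    force = force + envelope * amp_t * np.sin(2 * np.pi * params.tremor_freq_hz * t + phase)

    if params.noise_sd_gf > 0:
        force = force + rng.normal(0.0, params.noise_sd_gf, size=n)
    force = force + params.drift_gf_per_s * t

    if params.tap_dropout_prob > 0:
        for sec_start in np.arange(0.0, duration, 1.0):
            if rng.random() < params.tap_dropout_prob:
                start = sec_start + rng.uniform(0.0, 1.0)
                length = rng.uniform(0.1, 0.3)
                mask = (t >= start) & (t < start + length)
                force[mask] = 0.0

    return ForceTrace(
        subject_id=subject_id,
        session_id=session_id,
        hand=hand,
        finger=finger,
        samples=force,
        rate_hz=rate,
        label=label,
    )


def simulate_cohort(
    design: CohortDesign,
    healthy_params: SimuParams | None = None,
    pd_params_by_ftmtrs: dict | None = None,
    seed: int = 0,
    protocol: ProtocolConfig | None = None,
) -> list[ForceTrace]:
    """Simulate every (session, finger) measurement of a study design.

    Each subject receives an individual tremor frequency (a seeded jitter of
    +/-0.4 Hz around the group base frequency); each measurement receives an
    independent child seed, so noise and phases differ between fingers while
    the whole cohort is reproducible from ``seed``.  Traces are labelled
    1 for Parkinsonian subjects and 0 for healthy ones.
    """
    protocol = protocol or ProtocolConfig(hold_s=3.0)
    healthy_params = healthy_params or default_healthy_params()
    pd_params_by_ftmtrs = (
        default_pd_params_by_ftmtrs() if pd_params_by_ftmtrs is None else pd_params_by_ftmtrs
    )
    for sid, group, rating, _ in design.subjects:
        if group == "pd" and int(rating) not in pd_params_by_ftmtrs:
            raise KeyError(
                f"no SimuParams entry for FTMTRS rating {rating} (subject {sid})"
            )

    root = np.random.SeedSequence(seed)
    subject_seqs = root.spawn(len(design.subjects))
    # 10 fingers per session: both hands, little-to-little sweep.
    hand_fingers = [("left", f) for f in reversed(FINGERS)] + [
        ("right", f) for f in FINGERS
    ]
    per_session = design.fingers_per_session
    traces: list[ForceTrace] = []
    for (sid, group, rating, n_sessions), sseq in zip(design.subjects, subject_seqs):
        subj_rng = np.random.default_rng(sseq.generate_state(1)[0])
        base = healthy_params if group == "healthy" else pd_params_by_ftmtrs[int(rating)]
        subj_freq = base.tremor_freq_hz + subj_rng.uniform(-0.4, 0.4)
        label = 1 if group == "pd" else 0
        meas_seqs = sseq.spawn(int(n_sessions) * per_session)
        k = 0
        for sess in range(int(n_sessions)):
            for slot in range(per_session):
                hand, finger = hand_fingers[slot % len(hand_fingers)]
                child_seed = int(meas_seqs[k].generate_state(1)[0] % (2**31))
                k += 1
                params = replace(base, tremor_freq_hz=subj_freq, seed=child_seed)
                traces.append(
                    simulate_trace(
                        params,
                        protocol,
                        subject_id=sid,
                        session_id=f"{sid}-s{sess + 1}",
                        hand=hand,
                        finger=finger,
                        label=label,
                    )
                )
    return traces


def exclude_thumbs(dataset: list[ForceTrace]) -> list[ForceTrace]:
    """Drop every thumb measurement (two per session, one per hand).

    Thumb gauges sit on a vertical surface and Parkinsonian subjects cannot
    maintain pressure on them, so thumbs are excluded uniformly.
    """
    return [tr for tr in dataset if tr.finger != "thumb"]


# ---------------------------------------------------------------------------
# Validation rig: motor + eccentric pulley + elastic band + optical encoder
# ---------------------------------------------------------------------------


@dataclass
class RigParams:
    """Parameters of the simulated validation rig.

    ``velocity_fluct_beta`` models the elastic band loading the motor: the
    angular velocity is modulated within each revolution,
    ``dtheta/dt = 2*pi*rev_per_s*(1 + beta*sin(theta))``, which is what a
    band that slows the motor while stretching and whips it forward while
    contracting does to the rotation.  ``beta = 0`` is uniform rotation.
    """

    rev_per_s: float = 7.0
    force_mean_gf: float = 300.0
    force_amp_gf: float = 50.0
    velocity_fluct_beta: float = 0.0
    encoder_counts_per_rev: int = 20
    duration_s: float = 3.0
    noise_sd_gf: float = 1.0
    seed: int = 0
    rate_hz: float = 40.0

    def __post_init__(self) -> None:
        if self.rev_per_s <= 0:
            raise ValueError("rev_per_s must be positive")
        if self.rev_per_s >= self.rate_hz / 2:
            raise ValueError(
                f"rev_per_s={self.rev_per_s} violates Nyquist at {self.rate_hz} Hz sampling"
            )
        if not 0 <= self.velocity_fluct_beta < 1:
            raise ValueError("velocity_fluct_beta must be in [0, 1)")
        if self.encoder_counts_per_rev < 1:
            raise ValueError("encoder_counts_per_rev must be >= 1")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.noise_sd_gf < 0:
            raise ValueError("noise_sd_gf must be non-negative")
        n = self.duration_s * self.rate_hz
        if abs(n - round(n)) > 1e-9:
            raise ValueError("duration_s x rate_hz must be an integer sample count")


@dataclass
class EncoderLog:
    """Optical-encoder pulse record: one pulse per fixed angle increment."""

    pulse_times_s: np.ndarray
    counts_per_rev: int

    def __post_init__(self) -> None:
        self.pulse_times_s = np.asarray(self.pulse_times_s, dtype=float)
        if self.pulse_times_s.size and np.any(np.diff(self.pulse_times_s) <= 0):
            raise ValueError("pulse times must be strictly increasing")
        if self.counts_per_rev < 1:
            raise ValueError("counts_per_rev must be >= 1")


def _rig_phase(params: RigParams, t_fine: np.ndarray) -> np.ndarray:
    """Rotation angle theta(t) on a fine grid (RK4; closed form for beta=0)."""
    omega0 = 2 * np.pi * params.rev_per_s
    beta = params.velocity_fluct_beta
    if beta == 0:
        return omega0 * t_fine
    theta = np.empty_like(t_fine)
    theta[0] = 0.0
    dt = t_fine[1] - t_fine[0]

    def f(th: float) -> float:
        return omega0 * (1.0 + beta * np.sin(th))

    th = 0.0
    for i in range(1, t_fine.size):
        k1 = f(th)
        k2 = f(th + 0.5 * dt * k1)
        k3 = f(th + 0.5 * dt * k2)
        k4 = f(th + dt * k3)
        th += dt * (k1 + 2 * k2 + 2 * k3 + k4) / 6.0
        theta[i] = th
    return theta


def simulate_rig(params: RigParams) -> tuple[ForceTrace, EncoderLog]:
    """Simulate one rig run: the gauge force trace and the encoder log.

    The gauge reads ``force_mean + force_amp*sin(theta(t)) + noise`` at the
    sampling rate; encoder pulses are emitted whenever the rotation angle
    crosses a multiple of ``2*pi/counts_per_rev`` (crossing times are found
    by linear interpolation on a fine phase grid).
    """
    rng = np.random.default_rng(params.seed)
    n = int(round(params.duration_s * params.rate_hz))
    fine_rate = 4000.0
    t_fine = np.arange(int(round(params.duration_s * fine_rate)) + 1) / fine_rate
    theta_fine = _rig_phase(params, t_fine)

    t = np.arange(n) / params.rate_hz
    theta = np.interp(t, t_fine, theta_fine)
    force = params.force_mean_gf + params.force_amp_gf * np.sin(theta)
    if params.noise_sd_gf > 0:
        force = force + rng.normal(0.0, params.noise_sd_gf, size=n)

    dtheta = 2 * np.pi / params.encoder_counts_per_rev
    n_pulses = int(np.floor(theta_fine[-1] / dtheta)) + 1
    pulse_angles = np.arange(n_pulses) * dtheta
    pulse_times = np.interp(pulse_angles, theta_fine, t_fine)

    trace = ForceTrace(
        subject_id="rig",
        session_id="rig",
        hand="left",
        finger="index",
        samples=force,
        rate_hz=params.rate_hz,
    )
    return trace, EncoderLog(pulse_times_s=pulse_times, counts_per_rev=params.encoder_counts_per_rev)


def encoder_frequency(log: EncoderLog) -> float:
    """Rotation rate (rev/s) from the encoder pulse log.

    Uses the elapsed time between the first and last pulse:
    ``(n_pulses - 1) / (counts_per_rev * (t_last - t_first))``.
    """
    if log.pulse_times_s.size < 2:
        raise ValueError("need at least 2 encoder pulses to estimate a frequency")
    elapsed = log.pulse_times_s[-1] - log.pulse_times_s[0]
    return (log.pulse_times_s.size - 1) / (log.counts_per_rev * elapsed)
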