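"""Core record types for finger-force measurements.

A measurement is one finger pressing a strain gauge toward a force target
while the applied force is sampled at 40 Hz in gram-force (gf).  The types
here carry the raw record (:class:`ForceTrace`), the measurement protocol
(:class:`ProtocolConfig`) and the analysis window cut from the steady hold
phase (:class:`HoldWindow`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

HANDS = ("left", "right")
FINGERS = ("thumb", "index", "middle", "ring", "little")

__all__ = [
    "HANDS",
    "FINGERS",
    "ForceTrace",
    "ProtocolConfig",
    "HoldWindow",
    "MeasurementInvalidError",
]


class MeasurementInvalidError(ValueError):
    """Raised when a trace does not satisfy the measurement protocol

    (e.g. the subject never held the target force for the required time;
    the protocol's response is to repeat the finger).
    """


@dataclass
class ForceTrace:
    """One finger's force-versus-time record.

    Parameters
    ----------
    subject_id, session_id : str
        Identifiers; free-form but stable within a dataset.
    hand : {"left", "right"}
    finger : {"thumb", "index", "middle", "ring", "little"}
    rate_hz : float
        Sampling rate; the reference device samples at 40 Hz.
    samples : ndarray of float
        Force in gram-force, ordered in time.
    label : int or None
        Optional class label (1 = Parkinson's disease, 0 = healthy).
    """

    subject_id: str
    session_id: str
    hand: str
    finger: str
    samples: np.ndarray
    rate_hz: float = 40.0
    label: int | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.rate_hz <= 0:
            raise ValueError(f"rate_hz must be positive, got {self.rate_hz}")
        if self.samples.ndim != 1 or self.samples.size < 2:
            raise ValueError("samples must be a 1-D array of length >= 2")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")
        if self.hand not in HANDS:
            raise ValueError(f"hand must be one of {HANDS}, got {self.hand!r}")
        if self.finger not in FINGERS:
            raise ValueError(f"finger must be one of {FINGERS}, got {self.finger!r}")

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.rate_hz

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.rate_hz

    def with_samples(self, samples: np.ndarray) -> "ForceTrace":
        """Copy of this trace with ``samples`` replaced (metadata kept)."""
        return replace(self, samples=np.asarray(samples, dtype=float))


# Default finger order: left little finger across to right little finger,
# no repetitions -- the simplest sweep a subject can follow.
_DEFAULT_SEQUENCE = tuple(
    ("left", f) for f in reversed(FINGERS)
) + tuple(("right", f) for f in FINGERS)


@dataclass
class ProtocolConfig:
    """Measurement protocol: force target, hold time and finger order.

    ``target_gf`` defaults to 300 gf (two thirds of the 450 gf the weakest
    patient cohort could exert); ``hold_s`` defaults to 3 s, a balance
    between spectral resolution and finger fatigue.  ``tolerance_frac``
    is the half-width of the acceptance band around the target, as a
    fraction of the target.
    """

    target_gf: float = 300.0
    hold_s: float = 3.0
    tolerance_frac: float = 0.2
    rate_hz: float = 40.0
    finger_sequence: tuple = field(default_factory=lambda: _DEFAULT_SEQUENCE)

    def __post_init__(self) -> None:
        if self.target_gf <= 0:
            raise ValueError("target_gf must be positive")
        if self.hold_s <= 0:
            raise ValueError("hold_s must be positive")
        if not 0 < self.tolerance_frac < 1:
            raise ValueError("tolerance_frac must be in (0, 1)")
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be positive")

    @property
    def n_hold_samples(self) -> int:
        return int(round(self.hold_s * self.rate_hz))


@dataclass
class HoldWindow:
    """The steady-hold segment cut from a trace for spectral analysis."""

    start_index: int
    samples: np.ndarray
    rate_hz: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.start_index < 0:
            raise ValueError("start_index must be non-negative")
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be positive")

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)
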