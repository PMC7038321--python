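"""Spectrum estimation and the tremor validity statistic.

A hold window is analysed with a single-segment, mean-subtracted,
rectangular-window discrete Fourier transform.  Two one-sided spectra are
derived: the amplitude spectrum (2|X_k|/N, used for classification
features) and the periodogram power spectral density (|X_k|^2/N^2, doubled
for interior bins, used for the validity statistic).

The validity statistic is the *peak power proportion*

    V_f = P_peak / sum of all power,

where ``P_peak`` is the integral of the PSD over the +/-0.3 Hz interval
around the dominant frequency f_d (the in-band PSD argmax).  A measurement
whose power concentrates around a single tremor peak has V_f near 1; a
noise-dominated one spreads power across the band and falls below the
validity threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .trace import HoldWindow

__all__ = [
    "Spectrum",
    "TremorAssessment",
    "amplitude_spectrum",
    "power_spectral_density",
    "dominant_frequency",
    "peak_power",
    "peak_power_proportion",
    "assess",
    "PEAK_HALF_WIDTH_HZ",
    "ANALYSIS_BAND_HZ",
]

PEAK_HALF_WIDTH_HZ = 0.3
ANALYSIS_BAND_HZ = (3.5, 7.5)
MIN_WINDOW_SAMPLES = 8


@dataclass
class Spectrum:
    """One-sided spectrum of a hold window.

    ``freqs_hz`` runs from 0 to the Nyquist frequency with spacing
    ``rate_hz / n_samples``; ``kind`` is "amplitude" or "psd".
    """

    freqs_hz: np.ndarray
    values: np.ndarray
    kind: str
    n_samples: int

    def __post_init__(self) -> None:
        self.freqs_hz = np.asarray(self.freqs_hz, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.freqs_hz.shape != self.values.shape:
            raise ValueError("freqs and values must have the same shape")
        if self.kind not in ("amplitude", "psd"):
            raise ValueError("kind must be 'amplitude' or 'psd'")

    @property
    def bin_hz(self) -> float:
        return float(self.freqs_hz[1] - self.freqs_hz[0])


@dataclass
class TremorAssessment:
    """Tremor statistics and validity decision for one measurement window."""

    f_d: float
    p_peak: float
    v_f: float
    threshold: float
    valid: bool
    subject_id: str = ""
    session_id: str = ""
    hand: str = ""
    finger: str = ""

    @property
    def f1(self) -> float:
        return self.f_d - PEAK_HALF_WIDTH_HZ

    @property
    def f2(self) -> float:
        return self.f_d + PEAK_HALF_WIDTH_HZ


def _dft(window: HoldWindow) -> tuple[np.ndarray, np.ndarray, int]:
    x = np.asarray(window.samples, dtype=float)
    n = x.size
    if n < MIN_WINDOW_SAMPLES:
        raise ValueError(f"window too short for spectral analysis ({n} < {MIN_WINDOW_SAMPLES})")
    X = np.fft.rfft(x - x.mean())
    freqs = np.fft.rfftfreq(n, d=1.0 / window.rate_hz)
    return freqs, X, n


def amplitude_spectrum(window: HoldWindow) -> Spectrum:
    """One-sided amplitude spectrum: 2|X_k|/N for interior bins.

    The DC bin (and the Nyquist bin when N is even) has no mirrored
    counterpart and is scaled |X_k|/N.  A pure sinusoid of amplitude A at an
    exact bin frequency yields exactly A in that bin.
    """
    freqs, X, n = _dft(window)
    amp = np.abs(X) / n
    scale = np.full(freqs.size, 2.0)
    scale[0] = 1.0
    if n % 2 == 0:
        scale[-1] = 1.0
    return Spectrum(freqs_hz=freqs, values=amp * scale, kind="amplitude", n_samples=n)


def power_spectral_density(window: HoldWindow) -> Spectrum:
    """One-sided periodogram with N^2 normalisation.

    Per-bin power |X_k|^2/N^2, doubled for interior bins, so the sum over
    bins equals the mean square of the (mean-subtracted) signal (Parseval).
    """
    freqs, X, n = _dft(window)
    p = (np.abs(X) ** 2) / n**2
    scale = np.full(freqs.size, 2.0)
    scale[0] = 1.0
    if n % 2 == 0:
        scale[-1] = 1.0
    return Spectrum(freqs_hz=freqs, values=p * scale, kind="psd", n_samples=n)


def dominant_frequency(
    psd: Spectrum, band: tuple[float, float] = ANALYSIS_BAND_HZ
) -> float:
    """Frequency of the maximal PSD bin within ``band`` (ties go low).

    ``band`` is inclusive on both edges.  np.argmax returns the first
    maximum, which is the lower-frequency bin on exact ties.
    """
    lo, hi = band
    mask = (psd.freqs_hz >= lo) & (psd.freqs_hz <= hi)
    if not mask.any():
        raise ValueError(f"band [{lo}, {hi}] Hz contains no spectrum bins")
    in_band = psd.values[mask]
    return float(psd.freqs_hz[mask][np.argmax(in_band)])


def _trapz_interval(spec: Spectrum, lo: float, hi: float) -> float:
    """Trapezoidal integral of the piecewise-linear spectrum curve over
    [lo, hi], with linear interpolation at the interval edges."""
    lo = max(lo, float(spec.freqs_hz[0]))
    hi = min(hi, float(spec.freqs_hz[-1]))
    if hi <= lo:
        return 0.0
    interior = spec.freqs_hz[(spec.freqs_hz > lo) & (spec.freqs_hz < hi)]
    grid = np.concatenate(([lo], interior, [hi]))
    vals = np.interp(grid, spec.freqs_hz, spec.values)
    return float(np.trapezoid(vals, grid))


def peak_power(psd: Spectrum, f_d: float, half_width_hz: float = PEAK_HALF_WIDTH_HZ) -> float:
    """Integral of the PSD over [f_d - 0.3, f_d + 0.3] Hz.

    Trapezoidal quadrature of the PSD curve, with linear interpolation where
    the interval edges fall between bins.
    """
    lo, hi = f_d - half_width_hz, f_d + half_width_hz
    if hi < psd.freqs_hz[0] or lo > psd.freqs_hz[-1]:
        raise ValueError("peak interval does not intersect the spectrum support")
    return _trapz_interval(psd, lo, hi)


def peak_power_proportion(psd: Spectrum, p_peak: float) -> float:
    """V_f = P_peak / (integral of the full one-sided PSD).

    Both numerator and denominator use the same trapezoidal quadrature, so
    V_f is in [0, 1] by construction and invariant to amplitude scaling.
    """
    total = _trapz_interval(psd, float(psd.freqs_hz[0]), float(psd.freqs_hz[-1]))
    if total <= 0:
        raise ValueError("zero total power: assessment undefined")
    return min(p_peak / total, 1.0)


def assess(
    window: HoldWindow,
    threshold: float = 0.5,
    band: tuple[float, float] = ANALYSIS_BAND_HZ,
    *,
    subject_id: str = "",
    session_id: str = "",
    hand: str = "",
    finger: str = "",
) -> TremorAssessment:
    """Full tremor assessment of a preprocessed hold window.

    Computes the PSD, the in-band dominant frequency, the peak power around
    it and the peak power proportion; the measurement is valid when
    ``V_f > threshold``.
    """
    psd = power_spectral_density(window)
    f_d = dominant_frequency(psd, band=band)
    p_peak = peak_power(psd, f_d)
    v_f = peak_power_proportion(psd, p_peak)
    return TremorAssessment(
        f_d=f_d,
        p_peak=p_peak,
        v_f=v_f,
        threshold=threshold,
        valid=bool(v_f > threshold),
        subject_id=subject_id,
        session_id=session_id,
        hand=hand,
        finger=finger,
    )
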