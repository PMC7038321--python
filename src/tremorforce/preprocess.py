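"""Raw-trace conditioning: outlier repair, band-pass, hold-window cut.

The analysis chain is: repair contact-loss dips (values below the 1.25th
percentile of the measurement's own sample distribution), zero-phase
band-pass to the 3.5–7.5 Hz tremor band, and cut the steady hold window
located on the *raw* trace so the same span can be taken from the filtered
one.
"""

from __future__ import annotations

import numpy as np
from scipy import signal

from .trace import ForceTrace, HoldWindow, MeasurementInvalidError, ProtocolConfig

__all__ = [
    "outlier_filter",
    "bandpass",
    "find_hold_window",
    "cut_window",
    "preprocess_trace",
]

OUTLIER_PERCENTILE = 1.25
BAND_LO_HZ = 3.5
BAND_HI_HZ = 7.5


def outlier_filter(trace: ForceTrace, percentile: float = OUTLIER_PERCENTILE) -> ForceTrace:
    """Replace sub-percentile dips by linear interpolation.

    Samples strictly below the given percentile of the trace's own sample
    distribution (linear-interpolated empirical quantile) are treated as
    sensor dropouts and replaced by interpolating between the nearest
    non-outlier neighbours; a leading or trailing run of outliers takes the
    nearest non-outlier value.
    """
    x = trace.samples
    if x.size < 3:
        raise ValueError("outlier filter needs at least 3 samples")
    cutoff = np.percentile(x, percentile)
    bad = x < cutoff
    if not bad.any():
        return trace
    good_idx = np.flatnonzero(~bad)
    if good_idx.size < 2:
        raise ValueError("fewer than 2 non-outlier samples; trace is degenerate")
    repaired = x.copy()
    repaired[bad] = np.interp(np.flatnonzero(bad), good_idx, x[good_idx])
    return trace.with_samples(repaired)


def bandpass(
    trace: ForceTrace, lo_hz: float = BAND_LO_HZ, hi_hz: float = BAND_HI_HZ
) -> ForceTrace:
    """Zero-phase band-pass keeping the tremor band.

    Forward–backward 4th-order Butterworth band-pass; zero phase so the hold
    window cut on the raw trace lines up with the filtered one.  Amplitude
    response: >= 0.9 at band centre, <= 0.1 at 1.5 Hz and below and at 10 Hz
    and above (for the default 3.5–7.5 Hz band at 40 Hz sampling).
    """
    nyq = trace.rate_hz / 2
    if not 0 < lo_hz < hi_hz < nyq:
        raise ValueError(
            f"band [{lo_hz}, {hi_hz}] Hz must satisfy 0 < lo < hi < Nyquist ({nyq} Hz)"
        )
    sos = signal.butter(2, [lo_hz, hi_hz], btype="band", fs=trace.rate_hz, output="sos")
    return trace.with_samples(signal.sosfiltfilt(sos, trace.samples))


def find_hold_window(trace: ForceTrace, protocol: ProtocolConfig) -> HoldWindow:
    """Locate the first steady hold of the target force on the raw trace.

    Returns the first contiguous run of at least ``hold_s`` seconds during
    which ``|force - target| <= tolerance_frac * target``, truncated to
    exactly ``round(hold_s * rate_hz)`` samples.  The start index refers to
    the raw trace, so the same span can be cut from the band-passed signal.

    Raises
    ------
    MeasurementInvalidError
        If no qualifying run exists (the protocol would repeat the finger).
    """
    x = trace.samples
    n_need = protocol.n_hold_samples
    tol = protocol.tolerance_frac * protocol.target_gf
    inside = np.abs(x - protocol.target_gf) <= tol
    # run-length scan over the boolean mask
    idx = 0
    n = x.size
    while idx < n:
        if inside[idx]:
            run_end = idx
            while run_end < n and inside[run_end]:
                run_end += 1
            if run_end - idx >= n_need:
                return HoldWindow(
                    start_index=idx,
                    samples=x[idx : idx + n_need],
                    rate_hz=trace.rate_hz,
                )
            idx = run_end
        else:
            idx += 1
    raise MeasurementInvalidError(
        f"no {protocol.hold_s:g} s hold within +/-{tol:g} gf of "
        f"{protocol.target_gf:g} gf target ({trace.subject_id}/{trace.session_id}"
        f"/{trace.hand}/{trace.finger})"
    )


def cut_window(trace: ForceTrace, window: HoldWindow) -> HoldWindow:
    """Cut the span of ``window`` from (a filtered version of) its trace."""
    stop = window.start_index + window.n_samples
    if stop > trace.samples.size:
        raise ValueError("window does not lie inside the trace")
    return HoldWindow(
        start_index=window.start_index,
        samples=trace.samples[window.start_index : stop],
        rate_hz=trace.rate_hz,
    )


def preprocess_trace(
    trace: ForceTrace,
    protocol: ProtocolConfig,
    lo_hz: float = BAND_LO_HZ,
    hi_hz: float = BAND_HI_HZ,
    percentile: float = OUTLIER_PERCENTILE,
) -> HoldWindow:
    """Full conditioning chain for one measurement.

    Outlier repair, hold-window location on the repaired raw trace,
    band-pass filtering, and the cut of the located span from the filtered
    signal.
    """
    repaired = outlier_filter(trace, percentile=percentile)
    window = find_hold_window(repaired, protocol)
    filtered = bandpass(repaired, lo_hz=lo_hz, hi_hz=hi_hz)
    return cut_window(filtered, window)
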