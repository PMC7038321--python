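import numpy as np
import pytest

from tremorforce import ProtocolConfig, SimuParams, simulate_trace
from tremorforce.preprocess import preprocess_trace
from tremorforce.trace import HoldWindow


@pytest.fixture
def protocol():
    return ProtocolConfig()


@pytest.fixture
def protocol_5s():
    return ProtocolConfig(hold_s=5.0)


def make_sin_window(freq_hz: float, amp: float = 1.0, n: int = 120, rate_hz: float = 40.0,
                    phase: float = 0.0) -> HoldWindow:
    """Pure sinusoid hold window (no ramp, no noise)."""
    t = np.arange(n) / rate_hz
    return HoldWindow(start_index=0, samples=amp * np.sin(2 * np.pi * freq_hz * t + phase),
                      rate_hz=rate_hz)


def simulate_tremor_window(freq_hz: float, amp: float, noise_sd: float, seed: int,
                           protocol: ProtocolConfig | None = None,
                           amp_mod_depth: float = 0.2) -> HoldWindow:
    """End-to-end: simulated protocol measurement -> preprocessed hold window."""
    protocol = protocol or ProtocolConfig()
    params = SimuParams(tremor_freq_hz=freq_hz, tremor_amp_gf=amp, noise_sd_gf=noise_sd,
                        amp_mod_depth=amp_mod_depth, seed=seed)
    trace = simulate_trace(params, protocol)
    return preprocess_trace(trace, protocol)
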