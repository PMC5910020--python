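import numpy as np
import pytest

from synaptofilter import AnalysisConfig, ReleaseModelParams, StimProtocol, TestPulse

TestPulse.__test__ = False  # a domain dataclass, not a test case


@pytest.fixture
def config():
    return AnalysisConfig()


@pytest.fixture
def quiet_params():
    """Noise-free release model for oracle-exactness tests."""
    return ReleaseModelParams(noise_sd=0.0, seed=1)


@pytest.fixture
def paired_protocol():
    return StimProtocol(kind="paired", isi_s=0.05)


def make_kernel_trace(
    amp_pa: float,
    onset_s: float,
    duration_s: float = 3.0,
    fs: float = 10_000.0,
    baseline_pa: float = 0.0,
    tau_rise_ms: float = 1.0,
    tau_decay_ms: float = 8.0,
):
    """A bare trace with one inward double-exponential kernel (no noise)."""
    from synaptofilter.synth_ephys import epsc_kernel

    n = int(round(duration_s * fs))
    trace = np.full(n, baseline_pa)
    k = epsc_kernel(tau_rise_ms, tau_decay_ms, fs)
    i = int(round(onset_s * fs))
    trace[i : i + k.size] -= amp_pa * k[: max(n - i, 0)]
    return trace
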