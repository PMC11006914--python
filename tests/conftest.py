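import numpy as np
import pytest

from axospindle import synth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_recording():
    """One-tunnel 120 s synthetic recording with ground truth, shared by
    the detection tests."""
    cfg = synth.SynthConfig(
        duration_s=120.0, seed=3,
        tunnels=[synth.TunnelConfig("t0", "CA3", "CA1")])
    return synth.generate_recording(cfg)
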