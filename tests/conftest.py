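import numpy as np
import pytest

from hrvsync import preprocess, synthetic


@pytest.fixture
def constant_series() -> preprocess.RRSeries:
    """5 minutes of perfectly regular 800 ms beats."""
    n = 375
    t = 0.8 * np.arange(1, n + 1)
    return preprocess.RRSeries(beat_time=t, rr=np.full(n, 800.0))


@pytest.fixture
def human_series() -> preprocess.RRSeries:
    """A clean synthetic human series (IPFM, 300 s, modulated)."""
    cfg = synthetic.CouplingConfig(duration_s=300.0, kappa=0.0, seed=11)
    t, m1, _, _ = synthetic.generate_modulators(cfg)
    return synthetic.ipfm_beats(t, m1, 70.0, role="participant")


@pytest.fixture
def horse_series() -> preprocess.RRSeries:
    """A clean synthetic horse series (38 bpm resting rate)."""
    cfg = synthetic.CouplingConfig(
        duration_s=300.0, mean_hr=38.0, hf_freq=0.10, lf_freq=0.05, kappa=0.0, seed=12
    )
    t, m1, _, _ = synthetic.generate_modulators(cfg)
    return synthetic.ipfm_beats(t, m1, 38.0, role="horse")


@pytest.fixture
def compact_timeline() -> synthetic.SegmentTimeline:
    return synthetic.SegmentTimeline.compact()
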