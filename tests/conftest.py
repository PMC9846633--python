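import numpy as np
import pytest

from ipsckit import synthio


@pytest.fixture(scope="session")
def small_pair():
    """A small connected synthetic pair with ground truth (session-cached)."""
    cfg = synthio.SynthPairConfig(n_trials=48, sweep_ms=600.0, seed=12345)
    pair, truth = synthio.simulate_pair(cfg, pair_id="fix_conn",
                                        phenotype="GlyT2_pos")
    return pair, truth, cfg


@pytest.fixture(scope="session")
def noiseless_pair():
    """Deterministic noiseless pair: every trial is the pure waveform."""
    cfg = synthio.SynthPairConfig(n_trials=12, sweep_ms=600.0, seed=7,
                                  noise_sd=0.0, amplitude_cv=0.0,
                                  p_ap=1.0, p_fail=0.0, p_delayed=0.0,
                                  delay_sd=0.0)
    pair, truth = synthio.simulate_pair(cfg, pair_id="fix_clean")
    return pair, truth, cfg


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
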