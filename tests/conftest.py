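import numpy as np
import pytest

from pico_coord import (
    AnalysisParams,
    GeneratorConfig,
    analyze_recording,
    generate_recording,
)


@pytest.fixture(scope="session")
def default_sessions():
    """Three full default sessions (125 pulses each) with analysis results."""
    out = []
    for seed in (1, 2, 3):
        cfg = GeneratorConfig(seed=seed)
        rec, gt = generate_recording(cfg)
        res = analyze_recording(rec)
        out.append((cfg, rec, gt, res))
    return out


@pytest.fixture(scope="session")
def session1(default_sessions):
    return default_sessions[0]


@pytest.fixture()
def quick_config():
    """A short session for tests that regenerate data."""
    return GeneratorConfig(seed=7, session_duration=70.0,
                           pulses_per_duration=3, n_water_boluses=2)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20230605)
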