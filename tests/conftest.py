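import numpy as np
import pytest

from gateqa.respiratory_signal import (
    extract_component,
    minmax_normalize,
    moving_mean_smooth,
    segment_cycles,
)
from gateqa.sync_metrics import build_session_result, pair_cycles_intervals
from gateqa.synthetic_phantom import (
    SimulationConfig,
    make_fixture_set,
    simulate_gated_beam,
    simulate_motion,
)
from gateqa.trigger_analysis import detect_beam_intervals


def analyze_simulated_session(cfg: SimulationConfig, session_id: str = "sim"):
    """Run the full timing pipeline on one simulated session in memory."""
    motion = simulate_motion(cfg)
    beam, truth = simulate_gated_beam(motion, cfg)
    smooth = moving_mean_smooth(minmax_normalize(extract_component(motion, "z")), 5)
    cycles = segment_cycles(smooth)
    intervals = detect_beam_intervals(beam)
    pairing = pair_cycles_intervals(cycles, intervals, cfg.gating_window)
    return build_session_result(session_id, pairing), truth


@pytest.fixture
def rng():
    return np.random.default_rng(20250920)


@pytest.fixture
def default_cfg():
    return SimulationConfig(seed=0)


@pytest.fixture(scope="session")
def fixture_set(tmp_path_factory):
    """A complete simulated session on disk (log + EPID stack + truth)."""
    out = tmp_path_factory.mktemp("phantom_session")
    cfg = SimulationConfig(seed=7)
    manifest = make_fixture_set(cfg, out)
    return cfg, manifest
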