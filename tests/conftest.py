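"""Shared fixtures: synthetic datasets generated once per session."""

import numpy as np
import pytest

from chronotrace.simulate import SimulationConfig, simulate_timeseries


@pytest.fixture(scope="session")
def default_fixture():
    """Default-noise barcoded time series (10 x 100 cells, 300 genes)."""
    cfg = SimulationConfig(seed=7)
    expr, bcs, truth = simulate_timeseries(cfg)
    return cfg, expr, bcs, truth


@pytest.fixture(scope="session")
def lownoise_fixture():
    """Low-noise series for probing the transfer/clustering machinery."""
    cfg = SimulationConfig.low_noise(seed=11)
    expr, bcs, truth = simulate_timeseries(cfg)
    return cfg, expr, bcs, truth


@pytest.fixture(scope="session")
def clean_barcode_fixture():
    """Zero background, no mosaicism, full capture: demux must be perfect."""
    cfg = SimulationConfig(seed=2, barcode_lambda_bg=0.0, mosaic_fraction=0.0,
                           barcode_capture_rate=1.0)
    expr, bcs, truth = simulate_timeseries(cfg)
    return cfg, expr, bcs, truth


@pytest.fixture(scope="session")
def default_norm(default_fixture):
    from chronotrace.trajectory import normalize_log1p_cp10k

    _, expr, _, _ = default_fixture
    return normalize_log1p_cp10k(np.asarray(expr.X))
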