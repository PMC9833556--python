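import numpy as np
import pytest

import stockshift as ss
from stockshift import pipeline


@pytest.fixture(scope="session")
def geo2():
    """Two equal states stacked latitudinally, symmetric rectangular EEZ."""
    return ss.make_geography(2, (35.0, 45.0), eez_width=3.0, state_waters_width=0.05)


@pytest.fixture(scope="session")
def geo11():
    return ss.default_geography()


@pytest.fixture(scope="session")
def grid11(geo11):
    return ss.build_grid(geo11.eez, 0.3)


@pytest.fixture(scope="session")
def demo_run(tmp_path_factory):
    """One full run of the 2-state / 2-stock / 20-year smoke configuration."""
    cfg = pipeline.demo_config(tmp_path_factory.mktemp("demo") / "run", seed=3)
    outputs = ss.run_pipeline(cfg)
    return cfg, outputs


@pytest.fixture(scope="session")
def study_run(tmp_path_factory):
    """One full run of the 11-state, 40-year poleward-drift study."""
    cfg = pipeline.study_config(tmp_path_factory.mktemp("study") / "run", seed=11)
    outputs = ss.run_pipeline(cfg)
    return cfg, outputs


def rect_distance(cx, cy, bounds):
    """Exact point-to-axis-aligned-rectangle distance (numpy only)."""
    minx, miny, maxx, maxy = bounds
    dx = np.maximum(np.maximum(minx - cx, cx - maxx), 0.0)
    dy = np.maximum(np.maximum(miny - cy, cy - maxy), 0.0)
    return np.hypot(dx, dy)
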