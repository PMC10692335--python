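import numpy as np
import pytest

import censpa as cs
from censpa.io import RunConfig
from censpa.pipeline import run_pipeline


@pytest.fixture(scope="session")
def small_spread():
    """A 20-particle default-geometry spread with default noise + its truth."""
    cfg = cs.paper_default()
    noise = cs.NoiseConfig(seed=11)
    stack, truth = cs.render_spread(20, cfg, noise, seed=11)
    return cfg, stack, truth


@pytest.fixture(scope="session")
def small_run():
    """Full pipeline result on a 30-particle default-geometry spread."""
    cfg = RunConfig(n_particles=30, seed=17)
    return run_pipeline(cfg)


def truth_cluster_positions(truth_row):
    """Ground-truth cluster centers (2, 3) in nm from a truth-table row."""
    th = np.radians(truth_row["angle_deg"])
    d = truth_row["separation_nm"] / 2.0 * np.array([np.cos(th), np.sin(th), 0.0])
    mid = np.array([truth_row["x_nm"], truth_row["y_nm"], truth_row["z_nm"]])
    return np.stack([mid - d, mid + d])
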