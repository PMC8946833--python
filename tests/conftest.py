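import dataclasses

import numpy as np
import pytest

from gammahq import SimFieldParams, generate_field


@pytest.fixture
def field_params():
    """Small quick field; noise and gradient on (the realistic default regime)."""

    def make(**overrides):
        base = dict(
            image_height=256,
            image_width=256,
            n_cells=25,
            rng_seed=0,
        )
        base.update(overrides)
        return SimFieldParams(**base)

    return make


@pytest.fixture
def quiet_field(field_params):
    """A noise-free, gradient-free field plus its ground truth."""
    params = field_params(noise_sd=0.0, background_gradient_amplitude=0.0, rng_seed=7)
    pair, truth = generate_field(params)
    return params, pair, truth


def match_cells_to_truth(cell_df, truth, max_dist=6.0):
    """Greedy nearest-centroid matching of detected cells to ground truth.

    Returns list of (cell_row_index, truth_cell_index) pairs within max_dist.
    """
    centers = np.array([c.center for c in truth.cells])
    pairs = []
    used = set()
    for idx, row in cell_df.iterrows():
        if len(centers) == 0:
            break
        d = np.hypot(
            centers[:, 0] - row["centroid_row"], centers[:, 1] - row["centroid_col"]
        )
        order = np.argsort(d)
        for j in order:
            if d[j] > max_dist:
                break
            if j not in used:
                used.add(int(j))
                pairs.append((idx, int(j)))
                break
    return pairs
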