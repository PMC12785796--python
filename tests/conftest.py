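"""Shared fixtures: small synthetic geometries and one session-scoped
end-to-end field that several suites reuse."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from virotrace3d.pipeline import PipelineConfig, run_pipeline
from virotrace3d.synthgen import (
    SimulationConfig,
    _make_cell,
    _rasterize_cell,
    generate_timelapse,
)


def make_cell_pair(
    shape: tuple[int, int, int], rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """One random columnar cell with its nucleus on the given grid."""
    zeros = np.zeros(3, dtype=int)
    geom = _make_cell(rng, shape, zeros, zeros, existing=[])
    return _rasterize_cell(geom, shape)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture()
def cell_pair(rng):
    return make_cell_pair((40, 96, 96), rng)


@pytest.fixture(scope="session")
def e2e_field():
    """High-SNR 3-cell field plus full pipeline output (shared: ~10 s)."""
    config = SimulationConfig(
        grid_shape=(40, 128, 128), n_cells=3, n_timepoints=3, seed=7
    ).high_snr()
    stack, truth = generate_timelapse(config)
    result = run_pipeline(stack, PipelineConfig.desk_scale())
    return config, stack, truth, result


def detection_f1(
    detected: pd.DataFrame,
    truth: pd.DataFrame,
    spacing,
    tolerance_um: float = 0.3,
) -> float:
    """Match detected to true centroids within a radius; symmetric F1."""
    from scipy.spatial import cKDTree

    sp = np.asarray(spacing)
    det = detected[["z", "y", "x"]].to_numpy() * sp
    tru = truth[["z", "y", "x"]].to_numpy() * sp
    if len(det) == 0 or len(tru) == 0:
        return 0.0
    dist, idx = cKDTree(tru).query(det)
    taken: set[int] = set()
    tp = 0
    for d, i in sorted(zip(dist, idx)):
        if d <= tolerance_um and i not in taken:
            taken.add(int(i))
            tp += 1
    precision = tp / len(det)
    recall = tp / len(tru)
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)
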