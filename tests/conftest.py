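"""Shared fixtures: tiny density grids and the planted-pose benchmark run.

The full 3-subunit planted-recovery pipeline is expensive (a few minutes),
so it runs once per session and its result is shared by every test that
inspects the end-to-end behavior.
"""

from __future__ import annotations

import numpy as np
import pytest

import mrffit as mf

PLANTED_SEED = 0


@pytest.fixture(scope="session")
def toy_complex():
    return mf.make_toy_complex(3, 40, seed=PLANTED_SEED)


@pytest.fixture(scope="session")
def benchmark(toy_complex):
    return mf.make_benchmark(toy_complex, resolution=10.0, voxel_size=1.0,
                             seed=PLANTED_SEED)


@pytest.fixture(scope="session")
def planted_pipeline(toy_complex, benchmark):
    """Full pipeline on the scrambled toy complex: 576 near-uniform rotations
    plus the three planted orientations, default weights, K = 10."""
    rotations = mf.rotation_set(576).with_extra([t.q for t in benchmark.planted])
    cfg = mf.PipelineConfig(map_kind="simulated", rotations=rotations,
                            resolution=10.0)
    return mf.run_pipeline(benchmark.map, benchmark.scrambled, cfg,
                           reference=toy_complex)


def line_map(values, origin=(0, 0, 0)):
    """A 1D stick of voxels as a DensityMap, for scalar score checks."""
    v = np.asarray(values, dtype=float).reshape(-1, 1, 1)
    return mf.DensityMap(np.asarray(origin, float), np.ones(3), v)
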