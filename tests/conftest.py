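"""Shared fixtures.

The simulation ensembles are session-scoped: the fold-outcome statistics
are expensive (tens of explicit-dynamics runs), and several tests inspect
different aspects of the same batches.
"""

from __future__ import annotations

import numpy as np
import pytest

from gyrogen.batch import BatchSpec, run_batch
from gyrogen.mechanics import SimConfig, run_simulation
from gyrogen.metrics import analyze_series
from gyrogen.synthetic import SynthGrowthParams, make_surface_series

BASE_SEED = 0


@pytest.fixture(scope="session")
def default_run():
    """One homogeneous-growth run at default desk-scale settings."""
    return run_simulation(SimConfig(seed=1))


@pytest.fixture(scope="session")
def fast_patch_report():
    """20-seed ensemble with the 1.2x fast-growing special area."""
    return run_batch(BatchSpec(modes=["fast_patch"], n_runs=20,
                               base_seed=BASE_SEED))


@pytest.fixture(scope="session")
def homogeneous_report():
    """20-seed ensemble with homogeneous cortical growth."""
    return run_batch(BatchSpec(modes=["homogeneous"], n_runs=20,
                               base_seed=BASE_SEED))


@pytest.fixture(scope="session")
def stiff_report():
    """10-seed ensembles with the stiffening special area (x2, x4, x8)."""
    return run_batch(BatchSpec(modes=["stiff_patch:2", "stiff_patch:4",
                                      "stiff_patch:8"], n_runs=10,
                               base_seed=BASE_SEED))


@pytest.fixture(scope="session")
def synthetic_series():
    """Default synthetic longitudinal surface series (~3.6k vertices)."""
    return make_surface_series(SynthGrowthParams(seed=BASE_SEED))


@pytest.fixture(scope="session")
def pipeline_result(synthetic_series):
    return analyze_series(synthetic_series)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
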