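import numpy as np
import pandas as pd
import pytest

import oralftir as of
from oralftir.dataset import SpectrumSet, WavenumberGrid, make_grid, make_meta


@pytest.fixture(scope="session")
def default_run():
    """One full pipeline run under the default study design (seed 42)."""
    return of.run_pipeline(of.RunConfig(seed=42))


@pytest.fixture(scope="session")
def zero_distortion_run():
    """Full pipeline run on an artifact-free cohort."""
    return of.run_pipeline(of.RunConfig(seed=7, distortion=of.zero_distortion()))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def grid():
    return make_grid(1800.0, 950.0, 2.0)


def spectrum_set(matrix, grid=None, mode="absorbance", sample_ids=None, area_ids=None, classes=None):
    """Build a SpectrumSet around a plain matrix with minimal provenance."""
    matrix = np.atleast_2d(np.asarray(matrix, dtype=float))
    n = matrix.shape[0]
    if grid is None:
        grid = WavenumberGrid(np.linspace(1800.0, 950.0, matrix.shape[1]))
    meta = make_meta(
        sample_ids if sample_ids is not None else [f"S-{i:02d}" for i in range(n)],
        area_ids if area_ids is not None else [f"A-{i:02d}" for i in range(n)],
        classes if classes is not None else ["H"] * n,
        n=n,
    )
    return SpectrumSet(grid=grid, intensities=matrix, meta=meta, mode=mode)


@pytest.fixture
def make_set():
    return spectrum_set


@pytest.fixture
def tiny_config():
    """A small but complete run configuration for fast end-to-end tests."""
    scenario = of.CohortScenario(
        n_hk_samples=3,
        n_oscc_samples=3,
        oed_ground_truth=("HKlike", "OSCClike", "borderline"),
        areas_per_sample=2,
        stroma_fraction=0.15,
    )
    return of.RunConfig(scenario=scenario, cv_k=3, max_lv=3, seed=99)
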