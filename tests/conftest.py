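"""Shared fixtures: default phantom, atlas population, and the stock cohort.

The expensive objects (atlas from 30 subjects, the 10-phantom stock
experiment with all reconstructions) are session-scoped and computed once;
most integration tests read from them instead of re-simulating.
"""

from __future__ import annotations

import numpy as np
import pytest

from muinpaint.atlas import build_atlas
from muinpaint.petsim import ProjectionGeometry, ReconParams, forward_project, reconstruct_osem, sample_counts, scale_to_counts
from muinpaint.phantom import PhantomSpec, make_phantom, make_population
from muinpaint.pipeline import ExperimentConfig, run_experiment, stock_artifact_suite


@pytest.fixture(scope="session")
def default_spec() -> PhantomSpec:
    return PhantomSpec()


@pytest.fixture(scope="session")
def phantom0(default_spec):
    """Artifact-free phantom at the default spec."""
    return make_phantom(default_spec)


@pytest.fixture(scope="session")
def population30(default_spec):
    """30 artifact-free subjects with independent anatomical jitter."""
    return make_population(default_spec, 30, seed=100)


@pytest.fixture(scope="session")
def atlas30(population30):
    return build_atlas([p.water_image for p in population30])


@pytest.fixture(scope="session")
def geometry() -> ProjectionGeometry:
    return ProjectionGeometry()


@pytest.fixture(scope="session")
def nac_recon0(phantom0, geometry):
    """NAC PET of the artifact-free phantom (2 OSEM iterations)."""
    sino = scale_to_counts(
        forward_project(phantom0.activity_truth, phantom0.mu_truth, geometry), 2e6
    )
    sino = sample_counts(sino, 7)
    return reconstruct_osem(sino, None, ReconParams(n_iterations=2))


@pytest.fixture(scope="session")
def stock_result():
    """The stock 10-phantom cohort (5 inner, 5 outer), fully reconstructed."""
    cfg = ExperimentConfig(artifacts=stock_artifact_suite(), seed=1)
    return run_experiment(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
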