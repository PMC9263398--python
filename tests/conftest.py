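"""Shared fixtures: small synthetic atlases and cohorts built at test time."""

import numpy as np
import pandas as pd
import pytest

from dynconn.atlas import ParcellationAtlas
from dynconn.simulate import SimulationSpec, simulate_cohort, simulate_phenotypes


@pytest.fixture(scope="session")
def atlas300():
    from dynconn.simulate import make_synthetic_atlas
    return make_synthetic_atlas()


@pytest.fixture(scope="session")
def atlas_small():
    """Tiny hand-built atlas: 6 defined ROIs in 3 networks + 2 undefined."""
    return ParcellationAtlas(pd.DataFrame({
        "roi_id": [1, 2, 3, 4, 5, 6, 7, 8],
        "network": ["DMN", "DMN", "FPN", "FPN", "VIS", "VIS",
                    "undefined", "undefined"],
        "anatomy": [f"region {i}" for i in range(1, 9)],
        "hemisphere": ["left", "right"] * 4,
        "x": np.linspace(-60, 60, 8), "y": np.zeros(8), "z": np.zeros(8),
    }))


@pytest.fixture(scope="session")
def small_spec():
    """Fast cohort: 10+10 subjects, 13 defined + 2 undefined ROIs."""
    return SimulationSpec(n_scd=10, n_nc=10, n_roi_defined=13, n_roi_undefined=2,
                          amplitude_effects=(), dfc_effects=(),
                          correlation_targets=(), seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    return simulate_cohort(small_spec, rng=11, update_scores=False)


@pytest.fixture(scope="session")
def phenotypes85():
    return simulate_phenotypes(SimulationSpec(seed=5), rng=5)
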