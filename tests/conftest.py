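from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import demicdiff as dd

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def reference():
    """The standard corridor fixture: CA run under forest-only rules."""
    return dd.reference_experiment(seed=1)


@pytest.fixture()
def homogeneous_series():
    """All-forest landscape on a 21x21 grid, single time slice."""

    def build(n: int = 21, code: int = 1):
        geom = dd.GridGeometry(n_rows=n, n_cols=n)
        raster = dd.BiomeRaster(
            geometry=geom, codes=np.full((n, n), code, dtype=int)
        )
        return dd.LandscapeSeries({5000.0: raster})

    return build
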