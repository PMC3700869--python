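"""Shared fixtures: small synthetic landscapes and GPS track sets.

Everything is generated at test time with fixed seeds; no data files ship
with the package.
"""

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from arcrange import geo_io, synthetic_data as sd

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def landscape() -> geo_io.CoverRaster:
    """Default 11-class landscape (10 covers + ~35% water), 128x128."""
    spec = sd.LandscapeSpec(n_rows=128, n_cols=128, aggregation=2.0, seed=7)
    return sd.generate_landscape(spec)


@pytest.fixture(scope="session")
def tiny_raster() -> geo_io.CoverRaster:
    """2x3 hand-built raster for exact indexing arithmetic."""
    return geo_io.CoverRaster(
        values=np.array([[0, 1, 0], [1, 0, 1]]),
        cell_size=10.0,
        origin=(100.0, 200.0),
        legend={0: "land", 1: "water"},
        water_code=1,
    )


@pytest.fixture(scope="session")
def tracks(landscape):
    """Default-preference tracks: 10 animals, annotated fixes + truth."""
    spec = sd.MovementSpec(
        n_animals=10, fixes_per_animal=(300, 500), step_scale=250.0, seed=21
    )
    fixes, truth = sd.simulate_tracks(landscape, spec)
    return geo_io.annotate_fixes(fixes, landscape), truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
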