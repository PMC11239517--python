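import numpy as np
import pandas as pd
import pytest

from paleocomm.io import derive_geometry, surface_from_frame
from paleocomm.simulate import generate_study_fixture


def make_surface(df: pd.DataFrame, surface_id="test",
                 extent=(0.0, 0.0, 10.0, 10.0), derive=True):
    s = surface_from_frame(df, surface_id, extent)
    return derive_geometry(s) if derive else s


@pytest.fixture
def simple_frame():
    """Three well-formed specimens covering the main morphologies."""
    return pd.DataFrame({
        "specimen_id": ["s1", "s2", "s3"],
        "x": [1.0, 2.0, 3.0],
        "y": [1.0, 2.0, 3.0],
        "taxon": ["Fractofusus misrai", "Charnia masoni", "Charnia masoni"],
        "morphogroup": ["reclining", "upright_frond", "upright_frond"],
        "frond_length": [80.0, 100.0, 60.0],
        "frond_width": [30.0, 40.0, 25.0],
        "stem_length": [np.nan, 20.0, 10.0],
        "stem_width": [np.nan, 4.0, 2.0],
    })


@pytest.fixture(scope="session")
def study_fixture():
    """Twelve synthetic surfaces: four community types x three stages."""
    return generate_study_fixture(seed=7, sizes=(600, 400, 250))


@pytest.fixture(scope="session")
def uniform_point_surface():
    """10,000 uniformly placed specimens of one taxon on a 10 x 8 m map."""
    rng = np.random.default_rng(42)
    n = 10_000
    df = pd.DataFrame({
        "specimen_id": [f"u{i}" for i in range(n)],
        "x": rng.uniform(0, 10, n),
        "y": rng.uniform(0, 8, n),
        "taxon": "Uniformis punctata",
    })
    return make_surface(df, "uniform", extent=(0.0, 0.0, 10.0, 8.0),
                        derive=False)
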