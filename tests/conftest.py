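import numpy as np
import pandas as pd
import pytest

from hsretina import (CohortManifest, CubeMeta, HyperCube, WavelengthGrid,
                      SpectrumMatrix)


@pytest.fixture
def grid3():
    return WavelengthGrid([500.0, 600.0, 700.0])


@pytest.fixture
def grid70():
    return WavelengthGrid.default_visible()


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


@pytest.fixture
def small_cube(grid70, rng):
    """A 6x5x70 cube of positive intensities with full provenance."""
    data = 0.5 + rng.random((6, 5, 70))
    meta = CubeMeta("AD01", "AD", 18.0, 2)
    return HyperCube(data, grid70, meta)


@pytest.fixture
def two_mouse_manifest():
    rows = []
    for mouse, cls in (("AD01", "AD"), ("CO01", "CO")):
        for f in range(1, 9):
            rows.append({"cube_path": f"{mouse}_f{f}.img", "mouse_id": mouse,
                         "class_label": cls, "age_months": 18.0,
                         "field_id": f})
    return CohortManifest(pd.DataFrame(rows))


def random_matrix(rng, n_ad, n_co, bands=5, n_mice=2):
    """Random labelled spectrum matrix spread over a few mice and fields."""
    n = n_ad + n_co
    grid = WavelengthGrid(np.linspace(400.0, 400.0 + 10 * bands, bands))
    labels = np.array(["AD"] * n_ad + ["CO"] * n_co, dtype=object)
    mice = np.array([f"{labels[i]}{i % n_mice:02d}" for i in range(n)],
                    dtype=object)
    fields = rng.integers(1, 9, size=n)
    return SpectrumMatrix(rng.normal(size=(n, bands)), labels, mice, fields,
                          grid)
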