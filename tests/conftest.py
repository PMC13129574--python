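import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from leafspec.containers import WavelengthGrid
from leafspec.synth import LeafDesign, leaf_spectroscopy_design

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def coarse_grid():
    """Reduced 400–2497.5 nm axis (840 bands) covering all planted windows."""
    return WavelengthGrid.spanning(400.0, 2499.5, 2.5)


@pytest.fixture
def tiny_design():
    return LeafDesign(
        cultivars=(("Nipponbare", "japonica"), ("IR64", "indica")),
        fields=("alluvial", "andosol"),
        dats=(21, 49, 77),
    )


@pytest.fixture
def full_design():
    return leaf_spectroscopy_design()


@pytest.fixture
def spectrum_set(coarse_grid, tiny_design):
    from leafspec.synth import gen_leaf_spectra

    s, _ = gen_leaf_spectra(tiny_design, coarse_grid, seed=101)
    return s


def make_spectrum_set(values, start=500.0, step=10.0, stage=("reflectance",)):
    """Wrap a bare matrix in a SpectrumSet with a matching uniform grid."""
    from leafspec.containers import SpectrumSet

    values = np.atleast_2d(np.asarray(values, dtype=float))
    n, p = values.shape
    grid = WavelengthGrid(start, start + step * (p - 1), step)
    meta = pd.DataFrame(
        dict(
            sample_id=[f"X{i}" for i in range(n)],
            cultivar="c",
            subspecies="japonica",
            field="alluvial",
            dat=1,
            replicate=1,
            tissue="leaf",
            form="powder",
        )
    )
    return SpectrumSet(grid, values, meta, stage)
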