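import numpy as np
import pytest

from cemsim import enhancement as enh
from cemsim import fixtures as fx
from cemsim import raster_io as rio


@pytest.fixture(scope="session")
def fixture_pair():
    """One default synthetic CEM pair (seed 1), shared across tests."""
    return fx.generate_background_pair(fx.FixtureSpec(seed=1))


@pytest.fixture(scope="session")
def fixture_cell(fixture_pair):
    """The selected 200x200 insertion cell of the seed-1 fixture."""
    from cemsim import site_selection as ss
    breast = rio.segment_breast(fixture_pair.low_energy)
    cells = ss.compute_grid_features(fixture_pair.low_energy, breast)
    site = ss.select_insertion_site(cells)
    return site, site.extract(fixture_pair.low_energy.pixels)


@pytest.fixture(scope="session")
def fitted_distribution():
    """Enhancement distribution fitted to planted measurement values."""
    values = fx.planted_enhancement_values(80, seed=11)
    return enh.fit_enhancement_distribution(values, "benign", "CC")


def make_image(pixels, spacing_mm=0.1, view="CC", kind="recombined"):
    return rio.GrayImage(pixels=np.asarray(pixels, dtype=float),
                         spacing_mm=spacing_mm, view=view, kind=kind)
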