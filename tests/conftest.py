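import numpy as np
import pandas as pd
import pytest
import shapely

from sdmfuse import (
    OccurrenceDataset,
    SpatialDomain,
    build_integration_scheme,
    make_grid,
    make_scenario,
)


@pytest.fixture(scope="session")
def unit_square():
    return SpatialDomain(shapely.box(0.0, 0.0, 1.0, 1.0))


@pytest.fixture(scope="session")
def l_shape():
    # L-shaped polygon: unit square minus its upper-right quadrant
    return SpatialDomain(
        shapely.Polygon(
            [(0, 0), (1, 0), (1, 0.5), (0.5, 0.5), (0.5, 1), (0, 1)]
        )
    )


@pytest.fixture(scope="session")
def unit_scheme(unit_square):
    return build_integration_scheme(make_grid(unit_square, 10, 10))


@pytest.fixture(scope="session")
def standard_scenario():
    """One seeded draw of the standard synthetic study (shared: read-only)."""
    return make_scenario("standard", seed=1)


def make_po(points, name="po"):
    points = np.atleast_2d(points)
    return OccurrenceDataset(
        name=name,
        process="presence_only",
        records=pd.DataFrame(
            {
                "species": "sp",
                "x": points[:, 0],
                "y": points[:, 1],
                "uncertainty_m": np.nan,
                "status": "present",
                "count": np.nan,
            }
        ),
    )


def make_pa(sites, y, name="pa", exposure=1.0):
    sites = np.atleast_2d(sites)
    y = np.asarray(y)
    return OccurrenceDataset(
        name=name,
        process="presence_absence",
        records=pd.DataFrame(
            {
                "species": "sp",
                "x": sites[:, 0],
                "y": sites[:, 1],
                "uncertainty_m": np.nan,
                "status": np.where(y > 0, "present", "absent"),
                "count": np.nan,
            }
        ),
        exposure=np.full(len(sites), exposure),
    )


def make_counts(sites, y, name="counts", exposure=1.0):
    sites = np.atleast_2d(sites)
    return OccurrenceDataset(
        name=name,
        process="count",
        records=pd.DataFrame(
            {
                "species": "sp",
                "x": sites[:, 0],
                "y": sites[:, 1],
                "uncertainty_m": np.nan,
                "status": "present",
                "count": np.asarray(y, dtype=float),
            }
        ),
        exposure=np.full(len(sites), exposure),
    )
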