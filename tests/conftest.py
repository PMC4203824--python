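import numpy as np
import pandas as pd
import pytest

from traitshift import (
    CoverMatrix,
    DistanceMatrix,
    EnvironmentTable,
    SiteCoordinates,
    TraitRecordTable,
)


@pytest.fixture
def small_cover() -> CoverMatrix:
    """3 sites x 4 species, unnormalized raw covers."""
    df = pd.DataFrame(
        [[30.0, 50.0, 20.0, 0.0], [10.0, 0.0, 60.0, 30.0], [0.0, 25.0, 25.0, 50.0]],
        index=["s1", "s2", "s3"],
        columns=["spA", "spB", "spC", "spD"],
    )
    return CoverMatrix(df)


@pytest.fixture
def small_traits() -> TraitRecordTable:
    """Five individuals of two species in two sites, one trait."""
    rows = []
    values = {
        ("s1", "spA"): [10.0, 12.0, 11.0, 9.0, 13.0],
        ("s1", "spB"): [20.0, 22.0, 18.0, 21.0, 19.0],
        ("s2", "spA"): [14.0, 15.0, 16.0, 13.0, 17.0],
        ("s2", "spB"): [24.0, 26.0, 25.0, 23.0, 27.0],
    }
    for (site, sp), vals in values.items():
        for i, v in enumerate(vals, start=1):
            rows.append({"site": site, "species": sp, "individual": i, "trait": "height", "value": v})
    return TraitRecordTable(pd.DataFrame(rows))


@pytest.fixture
def env8() -> EnvironmentTable:
    """8 environmental variables over 6 sites (fixed arbitrary values)."""
    rng = np.random.default_rng(99)
    sites = [f"s{i}" for i in range(1, 7)]
    cols = ["MAT", "MAP", "CEC", "pH", "P", "N", "OM", "sand"]
    df = pd.DataFrame(rng.uniform(1.0, 10.0, size=(6, 8)), index=sites, columns=cols)
    return EnvironmentTable(df)


@pytest.fixture
def coords5() -> SiteCoordinates:
    df = pd.DataFrame(
        {
            "lat": [43.17, 33.67, 40.0, 36.5, 44.9],
            "lon": [-76.0, -81.0, -78.3, -79.9, -74.2],
        },
        index=[f"s{i}" for i in range(1, 6)],
    )
    return SiteCoordinates(df)


def random_distance_matrix(rng: np.random.Generator, n: int = 22) -> DistanceMatrix:
    m = rng.random((n, n))
    m = (m + m.T) / 2.0
    np.fill_diagonal(m, 0.0)
    return DistanceMatrix([f"s{i}" for i in range(n)], m)
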