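import numpy as np
import pytest

import towershed as ts


@pytest.fixture
def flat_dem():
    return ts.make_dem(ts.FixtureSpec(kind="flat", nrows=41, ncols=41, resolution_m=30.0))


@pytest.fixture
def hill_dem():
    return ts.make_dem(ts.FixtureSpec(kind="gaussian_hill", nrows=41, ncols=41, resolution_m=30.0))


@pytest.fixture
def ridge_dem():
    return ts.make_dem(ts.FixtureSpec(kind="ridge", nrows=41, ncols=81, resolution_m=30.0))


@pytest.fixture
def basin_dem():
    return ts.make_dem(
        ts.FixtureSpec(
            kind="basin_with_islets",
            nrows=41,
            ncols=41,
            resolution_m=30.0,
            islet_centers=((0.3, 0.5), (0.7, 0.3), (0.6, 0.75)),
        )
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20230628)
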