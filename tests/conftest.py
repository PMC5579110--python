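import pytest

import surfchc as sc


@pytest.fixture(scope="session")
def sphere_band_21():
    grid = sc.GridSpec(n=21)
    return sc.build_band(sc.sphere_geometry(), grid, 4 * grid.h)


@pytest.fixture(scope="session")
def sphere_ops_21(sphere_band_21):
    return sc.BandOperators.build(sphere_band_21)


@pytest.fixture(scope="session")
def sphere_band_33():
    grid = sc.GridSpec(n=33)
    return sc.build_band(sc.sphere_geometry(), grid, 4 * grid.h)


@pytest.fixture(scope="session")
def sphere_ops_33(sphere_band_33):
    return sc.BandOperators.build(sphere_band_33)


@pytest.fixture(scope="session")
def dumbbell_band_33():
    grid = sc.GridSpec(n=33, lower=(-2.0, -2.0, -2.0), upper=(2.0, 2.0, 2.0))
    return sc.build_band(sc.dumbbell_geometry(), grid, 4 * grid.h)

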