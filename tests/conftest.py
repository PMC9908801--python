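"""Shared fixtures: small geometries and phantoms sized for fast unit tests."""

from __future__ import annotations

import numpy as np
import pytest

from spect_bench.geometry import SystemGeometry
from spect_bench.phantom import PhantomSpec, make_phantom
from spect_bench.volume import AttenuationMap, Volume


@pytest.fixture(scope="session")
def small_geom() -> SystemGeometry:
    """16 views / 24^3 grid, PSF on — cheap but exercises every model term."""
    return SystemGeometry(n_views=16, det_rows=24, det_cols=24,
                          psf_sigma0_mm=1.0, psf_slope=0.01)


@pytest.fixture(scope="session")
def small_phantom():
    """A tiny LV phantom matched to ``small_geom``."""
    spec = PhantomSpec(
        grid_shape=(24, 24, 24), voxel_mm=4.8,
        endo_mm=(18.0, 18.0, 26.0), epi_mm=(28.0, 28.0, 36.0),
        body_mm=(50.0, 42.0), seed=7,
    )
    return make_phantom(spec)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture()
def random_volume(rng) -> Volume:
    return Volume(rng.uniform(0.0, 2.0, (16, 16, 16)), 4.8)


@pytest.fixture()
def uniform_mu() -> AttenuationMap:
    mu = np.zeros((16, 16, 16))
    mu[4:12, 4:12, :] = 0.15
    return AttenuationMap(Volume(mu, 4.8))
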