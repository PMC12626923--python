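import numpy as np
import pytest

from alffpipe.core import BoldSeries, SpectrumBand, VoxelMap


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def band():
    return SpectrumBand(0.01, 0.08)


def make_series(values, tr_s=2.17, mask=None, voxel_size_mm=3.0, **kw):
    values = np.asarray(values, dtype=np.float64)
    if mask is None:
        mask = np.ones(values.shape[:3], dtype=bool)
    return BoldSeries(values=values, voxel_size_mm=voxel_size_mm, tr_s=tr_s, mask=mask, **kw)


def make_map(values, mask=None, kind="other", **kw):
    values = np.asarray(values, dtype=np.float64)
    if mask is None:
        mask = np.ones(values.shape, dtype=bool)
    return VoxelMap(values=values, mask=mask, kind=kind, **kw)


@pytest.fixture
def series_factory():
    return make_series


@pytest.fixture
def map_factory():
    return make_map


@pytest.fixture
def noise_series(rng):
    """Small white-noise series: 6x6x4 grid, 64 timepoints, TR 2.17 s."""
    vals = rng.standard_normal((6, 6, 4, 64))
    return make_series(vals)
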