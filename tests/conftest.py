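import numpy as np
import pytest

from ldscreen.segment import SegmentationParams
from ldscreen.synth import SceneParams, render_scene


@pytest.fixture(scope="session")
def default_seg_params():
    return SegmentationParams()


@pytest.fixture(scope="session")
def dense_scene():
    """One spec-default field (30 cells, rate 20) shared across read-only tests."""
    params = SceneParams(n_cells=30, ld_rate=20.0, seed=42)
    nuclei, droplets, truth = render_scene(params)
    return params, nuclei, droplets, truth


@pytest.fixture(scope="session")
def sparse_noiseless_scene():
    """Well-separated cells, no blur/noise: exact-recovery regime."""
    params = SceneParams(
        field_shape=(512, 512),
        n_cells=6,
        ld_rate=12.0,
        cell_min_distance_px=150.0,
        noise_sd=0.0,
        psf_sigma_px=0.0,
        seed=7,
    )
    nuclei, droplets, truth = render_scene(params)
    return params, nuclei, droplets, truth


def disk_image(shape, centers, radius, peak, background=0.0):
    """Binary-ish disk raster used as a simple nuclei-image stand-in."""
    img = np.full(shape, float(background))
    rr, cc = np.indices(shape)
    for r, c in centers:
        img[(rr - r) ** 2 + (cc - c) ** 2 <= radius**2] = peak
    return img
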