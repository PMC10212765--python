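"""Shared fixtures: small synthetic fields, generated at test time."""

import numpy as np
import pytest

from imcspatial import synth


@pytest.fixture(scope="session")
def noiseless_config():
    """Noiseless, unblurred field in the well-separated regime."""
    return synth.SimulationConfig(
        field_size_px=(512, 512),
        n_cells=200,
        seed=3,
        noise_model="none",
        psf_sigma_px=0.0,
    )


@pytest.fixture(scope="session")
def noiseless_field(noiseless_config):
    """(image, truth) pair reused by segmentation/quantification tests."""
    return synth.simulate_image(noiseless_config)


@pytest.fixture(scope="session")
def segmented_field(noiseless_field):
    """(image, truth, nuclei, cells) after the full segmentation chain."""
    from imcspatial.segment import segment_image

    image, truth = noiseless_field
    nuclei, cells = segment_image(image.channel(synth.NUCLEAR_MARKER))
    return image, truth, nuclei, cells


def disk_image(shape, centers_radii, value=1.0, background=0.0):
    """Binary-ish raster with disks at given (x, y, r)."""
    img = np.full(shape, background, dtype=float)
    h, w = shape
    for x, y, r in centers_radii:
        yy, xx = np.mgrid[0:h, 0:w]
        img[(yy - y) ** 2 + (xx - x) ** 2 <= r * r] = value
    return img
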