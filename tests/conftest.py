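import numpy as np
import pytest

from bednettrack.scene import (
    ContrastTable,
    FlightModel,
    IlluminationField,
    NoiseModel,
    SceneConfig,
    SceneGeometry,
)

FULL_COVER = [[0, 0], [128, 0], [128, 128], [0, 128]]


@pytest.fixture
def flat_rrs_field():
    """Perfectly uniform RRS-style illumination (no banding, no falloff)."""
    return IlluminationField(
        mode="rrs", base_level=200.0, corner_falloff_fraction=1.0, band_amplitude=0.0
    )


@pytest.fixture
def open_geometry():
    """128×128 scene with no bednet and no occluders."""
    return SceneGeometry(image_size=(128, 128), bednet_polygon=[])


@pytest.fixture
def single_mosquito_scene(flat_rrs_field, open_geometry):
    """Noise-free scene with one mosquito at fixed contrast 4 — every frame
    should yield exactly one cleanly detectable image."""
    return SceneConfig(
        n_frames=120,
        illumination=flat_rrs_field,
        geometry=open_geometry,
        flight=FlightModel(n_mosquitoes=1, speed_mean_mm_s=200.0, seed=5),
        contrast=ContrastTable(
            background=(4.0, 4.0), front_of_net=(4.0, 4.0), behind_net=(4.0, 4.0)
        ),
        noise=NoiseModel(relative_sd=0.0, seed=5),
    )


def blob_image(shape, x, y, depth, length=20.0, width=14.0, heading=0.0):
    """A soft-edged elliptical difference blob for segmentation tests."""
    from bednettrack.scene import _blob_profile

    img = np.zeros(shape, dtype=np.float32)
    sy, sx, prof = _blob_profile(shape, x, y, heading, length, width)
    img[sy, sx] = depth * prof
    return img
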