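"""Shared fixtures: a scaled-down synthetic well that keeps unit tests fast.

The small frame (360 x 440, 150 px growth radius) preserves every artifact
of the full-size mosaic — halo, per-tile vignette, debris, noise — at about
a tenth of the pixel count; the matching config scales the two smoothing
sigmas with the geometry and leaves everything else at its default.
"""

import warnings

import pytest

from tilecount.config import PipelineConfig
from tilecount.synth import SyntheticPlateSpec

warnings.filterwarnings("ignore", category=FutureWarning)

SMALL_GEOMETRY = dict(
    image_height=360,
    image_width=440,
    well_center=(180.0, 220.0),
    well_radius=150.0,
    halo_width=20.0,
    n_nuclei=30,
    nucleus_edge_margin_px=16.0,
)


@pytest.fixture
def small_spec() -> SyntheticPlateSpec:
    return SyntheticPlateSpec(rng_seed=0, **SMALL_GEOMETRY)


@pytest.fixture
def small_cfg() -> PipelineConfig:
    return PipelineConfig(well_smooth_sigma=12.0, illum_smooth_sigma=8.0)


@pytest.fixture
def default_cfg() -> PipelineConfig:
    return PipelineConfig()
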