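"""Shared fixtures: image builders and a session-wide synthetic study."""

from __future__ import annotations

import numpy as np
import pytest

from lumiwound import AcquisitionMeta, LumImage, WoundSimConfig, simulate_study
from lumiwound.imaging_core import LUMINESCENCE, WHITELIGHT


def make_image(
    pixels: np.ndarray,
    pixel_size_mm: float = 1.0,
    modality: str = LUMINESCENCE,
    exposure_s: float = 1200.0,
    **labels,
) -> LumImage:
    """Build a LumImage with a consistent field of view for arbitrary pixels."""
    pixels = np.asarray(pixels, dtype=float)
    nrows, ncols = pixels.shape
    meta = AcquisitionMeta(
        exposure_s=exposure_s,
        field_of_view_mm=(ncols * pixel_size_mm, nrows * pixel_size_mm),
        modality=modality,
        **labels,
    )
    return LumImage(pixels=pixels, pixel_size_mm=pixel_size_mm, meta=meta)


@pytest.fixture
def image_factory():
    return make_image


@pytest.fixture(scope="session")
def study_20_20():
    """The 20 infected + 20 control synthetic study at the pinned seed."""
    wounds, manifest = simulate_study(20, WoundSimConfig(), seed=42)
    return wounds, manifest


@pytest.fixture(scope="session")
def one_wound():
    """A single simulated control wound for geometry-level tests."""
    from lumiwound import simulate_wound

    cfg = WoundSimConfig()
    return simulate_wound(cfg, np.random.default_rng(7), wound_id="wtest")
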