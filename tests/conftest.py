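from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from specfaf import (
    SpectralFAFImage,
    SyntheticCohortConfig,
    build_sector_grid,
    compute_sector_metrics,
    select_gefc_pixels,
    synthesize_eye,
)
from specfaf.synthetic import SessionNoise


def make_image(green, red, pitch=15.0, center=None, **kw) -> SpectralFAFImage:
    green = np.asarray(green, dtype=np.uint8)
    if center is None:
        center = ((green.shape[0] - 1) / 2.0, (green.shape[1] - 1) / 2.0)
    return SpectralFAFImage(
        green_plane=green,
        red_plane=np.asarray(red, dtype=np.uint8),
        pixel_pitch_um=pitch,
        fovea_center_px=center,
        **kw,
    )


@pytest.fixture(scope="session")
def small_cfg() -> SyntheticCohortConfig:
    """Reduced-scale study conditions for fast tests: 12 eyes, 220x300 px
    at 30 um/px (the 6 mm macular circle still fits)."""
    return SyntheticCohortConfig(
        n_eyes=12, image_shape_px=(220, 300), pixel_pitch_um=30.0, seed=7
    )


@pytest.fixture(scope="session")
def small_cohort(small_cfg):
    """In-memory cohort: list of (session1, session2, truth) per eye."""
    return [synthesize_eye(small_cfg, i) for i in range(small_cfg.n_eyes)]


@pytest.fixture(scope="session")
def small_metrics(small_cfg, small_cohort) -> pd.DataFrame:
    """Tidy sector-metrics table for the small cohort (both sessions)."""
    rows = []
    for img1, img2, _truth in small_cohort:
        grid = build_sector_grid(
            img1.shape, img1.fovea_center_px, img1.pixel_pitch_um
        )
        for img in (img1, img2):
            m = compute_sector_metrics(select_gefc_pixels(img), img, grid)
            rows.extend(m.to_rows())
    return pd.DataFrame(rows)


@pytest.fixture()
def zero_noise(small_cfg) -> SyntheticCohortConfig:
    from dataclasses import replace

    return replace(
        small_cfg,
        session_noise=SessionNoise(
            registration_jitter_px=0.0,
            intensity_noise_sd=0.0,
            fraction_jitter_pct=0.0,
        ),
    )
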