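"""Sector geometry and per-sector quantification."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from conftest import make_image
from oracles import naive_sector_label

from specfaf import (
    build_sector_grid,
    compute_sector_metrics,
    quantify_cohort,
    select_gefc_pixels,
    synthesize_cohort,
)
from specfaf.segmentation import BinaryMask


def random_geometry(rng):
    rows = int(rng.integers(60, 120))
    cols = int(rng.integers(60, 120))
    r0 = rows / 2 + rng.uniform(-3, 3)
    c0 = cols / 2 + rng.uniform(-3, 3)
    margin = min(r0, rows - 1 - r0, c0, cols - 1 - c0)
    pitch = 3000.0 / ((margin - 1) * rng.uniform(0.55, 0.98))
    return (rows, cols), (r0, c0), pitch


class TestSectorGeometry:
    def test_matches_exhaustive_classification(self):
        """Masks agree with per-pixel distance classification for random
        shapes, centers and pitches; the partition invariants hold."""
        rng = np.random.default_rng(17)
        for _ in range(8):
            shape, center, pitch = random_geometry(rng)
            grid = build_sector_grid(shape, center, pitch)
            label = naive_sector_label(shape, center, pitch)
            np.testing.assert_array_equal(grid.fovea_mask.values, label == 1)
            np.testing.assert_array_equal(grid.parafovea_mask.values, label == 2)
            np.testing.assert_array_equal(grid.perifovea_mask.values, label == 3)
            np.testing.assert_array_equal(grid.macula_mask.values, label > 0)
            # disjoint rings, union = macula
            total = (
                grid.fovea_mask.values.astype(int)
                + grid.parafovea_mask.values.astype(int)
                + grid.perifovea_mask.values.astype(int)
            )
            assert total.max() <= 1
            np.testing.assert_array_equal(total == 1, grid.macula_mask.values)

    def test_fovea_radius_in_pixels_at_device_pitch(self):
        """At 15 um/px the foveal disk has radius 50 px; count matches a
        brute-force enumeration."""
        shape, center = (420, 420), (209.5, 209.5)
        grid = build_sector_grid(shape, center, 15.0)
        count = 0
        for i in range(420):
            for j in range(420):
                if (i - 209.5) ** 2 + (j - 209.5) ** 2 < 50.0**2:
                    count += 1
        assert grid.fovea_mask.count() == count

    def test_doubling_pitch_shrinks_counts_fourfold(self):
        g1 = build_sector_grid((400, 400), (199.5, 199.5), 20.0)
        g2 = build_sector_grid((400, 400), (199.5, 199.5), 40.0)
        for name in ("fovea", "parafovea", "perifovea", "macula"):
            n1 = g1.sector_masks()[name].count()
            n2 = g2.sector_masks()[name].count()
            assert n1 / n2 == pytest.approx(4.0, rel=0.05)

    def test_grid_exceeding_bounds_reports_margin(self):
        with pytest.raises(ValueError, match="need .* have"):
            build_sector_grid((100, 400), (49.5, 199.5), 15.0)

    def test_nested_disk_mode_is_nested(self):
        grid = build_sector_grid((200, 200), (99.5, 99.5), 40.0, nested_disks=True)
        f, p, peri = (
            grid.fovea_mask.values,
            grid.parafovea_mask.values,
            grid.perifovea_mask.values,
        )
        assert np.all(p[f]) and np.all(peri[p])
        np.testing.assert_array_equal(peri, grid.macula_mask.values)


class TestSectorMetrics:
    @pytest.fixture()
    def toy(self):
        rng = np.random.default_rng(23)
        shape = (160, 160)
        img = make_image(
            rng.integers(0, 256, shape), rng.integers(0, 256, shape),
            pitch=40.0, center=(79.5, 79.5),
        )
        grid = build_sector_grid(shape, img.fovea_center_px, img.pixel_pitch_um)
        return img, grid

    def test_mask_equal_to_fovea_gives_100_0_0(self, toy):
        img, grid = toy
        m = compute_sector_metrics(
            BinaryMask(grid.fovea_mask.values.copy()), img, grid
        )
        assert m.area_fraction_pct["fovea"] == 100.0
        assert m.area_fraction_pct["parafovea"] == 0.0
        assert m.area_fraction_pct["perifovea"] == 0.0

    def test_empty_mask_gives_zero_fractions_and_sector_means(self, toy):
        img, grid = toy
        m = compute_sector_metrics(
            BinaryMask(np.zeros(img.shape, dtype=bool)), img, grid
        )
        for s in ("macula", "fovea", "parafovea", "perifovea"):
            assert m.area_fraction_pct[s] == 0.0
            sector = grid.sector_masks()[s].values
            assert m.mean_green_intensity[s] == pytest.approx(
                float(img.green_plane[sector].mean())
            )

    def test_random_mask_matches_exhaustive_counting(self, toy):
        img, grid = toy
        rng = np.random.default_rng(2)
        mask = rng.uniform(size=img.shape) < 0.3
        m = compute_sector_metrics(BinaryMask(mask), img, grid)
        label = naive_sector_label(img.shape, img.fovea_center_px, 40.0)
        for code, s in [(1, "fovea"), (2, "parafovea"), (3, "perifovea")]:
            want = 100.0 * (mask & (label == code)).sum() / (label == code).sum()
            assert m.area_fraction_pct[s] == want
        assert m.gefc_pixel_count["macula"] == sum(
            m.gefc_pixel_count[s] for s in ("fovea", "parafovea", "perifovea")
        )

    def test_macular_fraction_is_count_weighted_mean_of_rings(self, toy):
        img, grid = toy
        rng = np.random.default_rng(6)
        m = compute_sector_metrics(
            BinaryMask(rng.uniform(size=img.shape) < 0.1), img, grid
        )
        weighted = sum(
            m.area_fraction_pct[s] * m.sector_pixel_count[s]
            for s in ("fovea", "parafovea", "perifovea")
        ) / m.sector_pixel_count["macula"]
        assert m.area_fraction_pct["macula"] == pytest.approx(weighted, abs=1e-12)

    def test_translation_equivariance(self):
        """Shifting image and fovea centre by the same integer offset
        leaves every metric unchanged."""
        rng = np.random.default_rng(31)
        g = rng.integers(0, 256, (180, 180))
        r = rng.integers(0, 256, (180, 180))
        img = make_image(g, r, pitch=40.0, center=(89.5, 89.5))
        shifted = make_image(
            np.roll(g, (3, -5), axis=(0, 1)),
            np.roll(r, (3, -5), axis=(0, 1)),
            pitch=40.0,
            center=(92.5, 84.5),
        )
        for a, b in [(img, shifted)]:
            grid_a = build_sector_grid(a.shape, a.fovea_center_px, 40.0)
            grid_b = build_sector_grid(b.shape, b.fovea_center_px, 40.0)
            ma = compute_sector_metrics(select_gefc_pixels(a), a, grid_a)
            mb = compute_sector_metrics(select_gefc_pixels(b), b, grid_b)
            assert ma.area_fraction_pct == mb.area_fraction_pct
            assert ma.mean_green_intensity == mb.mean_green_intensity

    def test_shape_mismatch_rejected(self, toy):
        img, grid = toy
        with pytest.raises(ValueError, match="shape mismatch"):
            compute_sector_metrics(
                BinaryMask(np.zeros((10, 10), dtype=bool)), img, grid
            )


class TestQuantifyCohort:
    def test_row_counts_and_determinism(self, tmp_path, zero_noise):
        from dataclasses import replace

        cfg = replace(zero_noise, n_eyes=2)
        manifest = synthesize_cohort(cfg, tmp_path / "cohort")
        assert len(manifest) == 4  # 2 eyes x 2 sessions
        df1 = quantify_cohort(tmp_path / "cohort" / "manifest.csv")
        df2 = quantify_cohort(tmp_path / "cohort" / "manifest.csv")
        assert len(df1) == 2 * 2 * 4  # eyes x sessions x sectors
        pd.testing.assert_frame_equal(df1, df2)

    def test_zero_noise_sessions_identical(self, tmp_path, zero_noise):
        from dataclasses import replace

        cfg = replace(zero_noise, n_eyes=2)
        synthesize_cohort(cfg, tmp_path / "c")
        df = quantify_cohort(tmp_path / "c" / "manifest.csv")
        s1 = df[df.session_id == "1"].drop(columns="session_id").reset_index(drop=True)
        s2 = df[df.session_id == "2"].drop(columns="session_id").reset_index(drop=True)
        pd.testing.assert_frame_equal(s1, s2)
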