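"""Synthetic spectrally resolved FAF cohort generator with a truth channel.

The generator emulates the statistical and topographic structure the
analysis assumes — it is a phantom, not an optical simulation (no vessels,
optic disc or point-spread function):

* per-eye sector GEFC area fractions are log-normal around the configured
  medians with dispersion matched to the configured interquartile ranges;
  a single latent "GEFC load" factor per eye drives all three sectors, so
  the fovea > parafovea > perifovea ordering holds for every eye;
* GEFC pixels are planted as spatially clustered speckle: the top-k pixels
  of a Gaussian-smoothed random score field within each sector, which hits
  the target pixel count exactly (the truth channel is exact by
  construction);
* the green plane combines a diffuse sector-level signal, brighter GEFC
  foci, a central macular-pigment attenuation profile and a per-eye global
  brightness factor; the red plane carries the lipofuscin-dominated
  background. Channel values are constrained so that the default centroid
  classifier reproduces the planted mask bit-exactly;
* session 2 repeats session 1 with configurable test-retest noise:
  integer-pixel registration jitter of the retinal pattern relative to the
  sector grid, a relative jitter of the planted fractions, and fresh
  intensity noise (a global brightness offset plus per-pixel noise).

With the seed fixed, generation is bit-reproducible; all noise terms are
(config SD) x (standard draws from a fixed-order stream), so cohorts
generated at different noise levels from the same seed are coupled
realizations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from specfaf.image_model import SpectralFAFImage, write_faf_image
from specfaf.sectors import SECTOR_NAMES, SectorGrid, build_sector_grid

_RING_SECTORS = ("fovea", "parafovea", "perifovea")
_Z75 = 0.6744897501960817  # standard normal 75th percentile


@dataclass(frozen=True)
class SessionNoise:
    """Between-session (test-retest) noise of the generator.

    registration_jitter_px
        Maximum integer translation of the retinal pattern relative to the
        sector grid between sessions (the offset is drawn uniformly).
    intensity_noise_sd
        SD, in 8-bit counts, of the session-2 intensity perturbation:
        applied once as a global brightness offset per plane and again as
        independent per-pixel noise.
    fraction_jitter_pct
        Relative (percent-of-value) log-scale jitter of the per-eye sector
        area fractions between sessions. Relative rather than absolute,
        because sector fractions span nearly two orders of magnitude.
    """

    registration_jitter_px: float = 1.0
    intensity_noise_sd: float = 3.0
    fraction_jitter_pct: float = 3.0

    def __post_init__(self) -> None:
        for name in (
            "registration_jitter_px",
            "intensity_noise_sd",
            "fraction_jitter_pct",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class SyntheticCohortConfig:
    """Study conditions of the synthetic cohort.

    Defaults reproduce the healthy-cohort conditions the analysis targets:
    30 eyes imaged twice, sector area-fraction medians/IQRs of
    33.3 (21.9-41.2) % fovea, 5.3 (2.4-8.1) % parafovea and
    0.5 (0.2-0.8) % perifovea, and green-channel sector levels of
    39.4 / 60.3 / 81.7 counts. The default frame is a reduced-scale
    822 x 1152 px at 60 um/px so the full pipeline runs in seconds; the
    device-native 3288 x 4608 px at 15 um/px is available via config.
    """

    n_eyes: int = 30
    image_shape_px: tuple[int, int] = (822, 1152)
    pixel_pitch_um: float = 60.0
    sector_fraction_median_pct: dict[str, float] = field(
        default_factory=lambda: {"fovea": 33.3, "parafovea": 5.3, "perifovea": 0.5}
    )
    sector_fraction_iqr_pct: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "fovea": (21.9, 41.2),
            "parafovea": (2.4, 8.1),
            "perifovea": (0.2, 0.8),
        }
    )
    green_intensity_levels: dict[str, float] = field(
        default_factory=lambda: {"fovea": 39.4, "parafovea": 60.3, "perifovea": 81.7}
    )
    gefc_contrast: float = 25.0
    red_background_level: float = 120.0
    red_gefc_ratio: float = 0.3
    texture_sd: float = 6.0
    eye_brightness_sigma: float = 0.25
    macular_pigment_attenuation: float = 0.15
    attenuation_scale_mm: float = 0.75
    blob_smoothing_px: float = 2.0
    session_noise: SessionNoise = field(default_factory=SessionNoise)
    age_mean: float = 26.2
    age_sd: float = 2.8
    age_range: tuple[int, int] = (23, 32)
    male_fraction: float = 22 / 30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_eyes < 1:
            raise ValueError("n_eyes must be >= 1")
        for s in _RING_SECTORS:
            f = self.sector_fraction_median_pct[s]
            if not 0 <= f <= 100:
                raise ValueError(f"fraction median for {s} outside [0, 100]: {f}")
            q1, q3 = self.sector_fraction_iqr_pct[s]
            if not (0 <= q1 <= q3 <= 100):
                raise ValueError(f"invalid IQR for {s}: ({q1}, {q3})")
            lev = self.green_intensity_levels[s]
            if not 0 <= lev <= 255:
                raise ValueError(f"intensity level for {s} outside [0, 255]: {lev}")
        if not 0 <= self.macular_pigment_attenuation <= 1:
            raise ValueError("macular_pigment_attenuation must lie in [0, 1]")
        if not 0 <= self.red_background_level <= 255:
            raise ValueError("red_background_level outside [0, 255]")

    @property
    def fovea_center_px(self) -> tuple[float, float]:
        rows, cols = self.image_shape_px
        return ((rows - 1) / 2.0, (cols - 1) / 2.0)


@dataclass
class GroundTruthRecord:
    """Exact planted values for one eye (session 1).

    ``true_fraction_pct`` is 100 x (planted GEFC pixels in sector) /
    (sector pixel count), exactly, for the macula and the three rings;
    ``true_mean_green_intensity`` is the realized session-1 green-plane
    mean over each whole sector; ``gefc_pixel_mask`` is the planted mask.
    """

    eye_id: str
    true_fraction_pct: dict[str, float]
    true_mean_green_intensity: dict[str, float]
    gefc_pixel_mask: np.ndarray


def _lognormal_sigma(q1: float, q3: float) -> float:
    """Log-scale SD whose quartile ratio matches the configured IQR."""
    if q1 <= 0 or q3 <= 0 or q3 <= q1:
        return 0.0
    return float(np.log(q3 / q1) / (2 * _Z75))


def _topk_mask(score: np.ndarray, sector: np.ndarray, k: int) -> np.ndarray:
    """Boolean mask of the k highest-scoring pixels within a sector."""
    out = np.zeros(score.shape, dtype=bool)
    idx = np.flatnonzero(sector)
    n = idx.size
    if k <= 0:
        return out
    if k >= n:
        out.flat[idx] = True
        return out
    vals = score.flat[idx]
    top = np.argpartition(vals, n - k)[n - k:]
    out.flat[idx[top]] = True
    return out


def _plant_mask(
    score: np.ndarray, grid: SectorGrid, fractions_pct: dict[str, float]
) -> np.ndarray:
    mask = np.zeros(score.shape, dtype=bool)
    for s in _RING_SECTORS:
        sector = grid.sector_masks()[s].values
        k = int(round(fractions_pct[s] / 100.0 * sector.sum()))
        mask |= _topk_mask(score, sector, k)
    return mask


def _compose_planes(
    cfg: SyntheticCohortConfig,
    mask: np.ndarray,
    level_map: np.ndarray,
    atten: np.ndarray,
    scale: float,
    tex_g: np.ndarray,
    tex_r: np.ndarray,
    extra_g: np.ndarray | float = 0.0,
    extra_r: np.ndarray | float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Render (green, red) uint8 planes from a planted mask.

    Values are constrained so the centroid classifier (GEFC iff G > 0 and
    centroid wavelength <= 560 nm, i.e. 7R <= 3G) recovers ``mask``
    bit-exactly: planted pixels keep G >= 4 and R <= floor(3G/7);
    background pixels keep 7R > 3G.
    """
    green_mu = atten * scale * (level_map + cfg.gefc_contrast * mask)
    g_float = green_mu + cfg.texture_sd * tex_g + extra_g
    g = np.rint(np.clip(g_float, 0, 255)).astype(np.int64)
    g[mask] = np.clip(g[mask], 4, 255)

    r_float = (
        scale * cfg.red_background_level + cfg.texture_sd * tex_r + extra_r
    )
    r = np.rint(np.clip(r_float, 30, 255)).astype(np.int64)
    # planted pixels: red tied to green, capped to stay inside the green band
    r_gefc = np.rint(cfg.red_gefc_ratio * g[mask]).astype(np.int64)
    r[mask] = np.minimum(r_gefc, (3 * g[mask]) // 7)
    # background pixels: green capped so the centroid stays in the red band
    bg = ~mask
    g[bg] = np.minimum(g[bg], (7 * r[bg] - 1) // 3)
    return g.astype(np.uint8), r.astype(np.uint8)


def synthesize_eye(
    cfg: SyntheticCohortConfig, eye_index: int
) -> tuple[SpectralFAFImage, SpectralFAFImage, GroundTruthRecord]:
    """Generate the two sessions of one eye plus its ground truth.

    Deterministic given (cfg.seed, eye_index); the draw order is fixed so
    that configs differing only in noise SDs consume identical random
    streams (coupled realizations).
    """
    rng = np.random.default_rng([cfg.seed, eye_index])
    noise = cfg.session_noise
    shape = cfg.image_shape_px
    center = cfg.fovea_center_px
    grid = build_sector_grid(shape, center, cfg.pixel_pitch_um)

    # -- fixed-order draws ------------------------------------------------
    rng.standard_normal()  # age latent, consumed by the cohort wrapper
    rng.uniform()  # sex latent, consumed by the cohort wrapper
    z_load = rng.standard_normal()
    z_scale = rng.standard_normal()
    z_frac2 = rng.standard_normal(len(_RING_SECTORS))
    score_raw = rng.standard_normal(shape)
    tex_g = rng.standard_normal(shape)
    tex_r = rng.standard_normal(shape)
    jitter_u = rng.uniform(-1.0, 1.0, 2)
    z_offsets = rng.standard_normal(2)
    z_pix_g = rng.standard_normal(shape)
    z_pix_r = rng.standard_normal(shape)

    # -- per-eye latent structure ----------------------------------------
    frac1: dict[str, float] = {}
    frac2: dict[str, float] = {}
    for i, s in enumerate(_RING_SECTORS):
        med = cfg.sector_fraction_median_pct[s]
        sigma = _lognormal_sigma(*cfg.sector_fraction_iqr_pct[s])
        f1 = float(np.clip(med * np.exp(sigma * z_load), 0.0, 100.0))
        jit = noise.fraction_jitter_pct / 100.0
        f2 = float(np.clip(f1 * np.exp(jit * z_frac2[i]), 0.0, 100.0))
        frac1[s], frac2[s] = f1, f2
    scale = float(np.exp(cfg.eye_brightness_sigma * z_scale))

    score = gaussian_filter(score_raw, cfg.blob_smoothing_px, mode="wrap")
    rr, cc = np.meshgrid(
        np.arange(shape[0]), np.arange(shape[1]), indexing="ij"
    )
    dist_mm = np.hypot(rr - center[0], cc - center[1]) * cfg.pixel_pitch_um / 1000.0
    atten = 1.0 - cfg.macular_pigment_attenuation * np.exp(
        -0.5 * (dist_mm / cfg.attenuation_scale_mm) ** 2
    )
    level_map = np.full(shape, cfg.green_intensity_levels["perifovea"])
    level_map[grid.parafovea_mask.values] = cfg.green_intensity_levels["parafovea"]
    level_map[grid.fovea_mask.values] = cfg.green_intensity_levels["fovea"]

    # -- session 1 ---------------------------------------------------------
    mask1 = _plant_mask(score, grid, frac1)
    g1, r1 = _compose_planes(cfg, mask1, level_map, atten, scale, tex_g, tex_r)

    # -- session 2: registration jitter, fraction jitter, fresh noise ------
    j = noise.registration_jitter_px
    dr, dc = (int(np.rint(u * j)) for u in jitter_u)
    score2 = np.roll(score, (dr, dc), axis=(0, 1))
    tex_g2 = np.roll(tex_g, (dr, dc), axis=(0, 1))
    tex_r2 = np.roll(tex_r, (dr, dc), axis=(0, 1))
    mask2 = _plant_mask(score2, grid, frac2)
    sd = noise.intensity_noise_sd
    g2, r2 = _compose_planes(
        cfg,
        mask2,
        level_map,
        atten,
        scale,
        tex_g2,
        tex_r2,
        extra_g=sd * z_offsets[0] + sd * z_pix_g,
        extra_r=sd * z_offsets[1] + sd * z_pix_r,
    )

    eye_id = f"eye{eye_index + 1:02d}"
    meta = {"excitation_peak_nm": 450, "field_of_view_deg": [60, 55]}
    img1 = SpectralFAFImage(
        green_plane=g1, red_plane=r1, pixel_pitch_um=cfg.pixel_pitch_um,
        fovea_center_px=center, eye_id=eye_id, session_id="1",
        acquisition_meta=dict(meta),
    )
    img2 = SpectralFAFImage(
        green_plane=g2, red_plane=r2, pixel_pitch_um=cfg.pixel_pitch_um,
        fovea_center_px=center, eye_id=eye_id, session_id="2",
        acquisition_meta=dict(meta),
    )

    true_frac: dict[str, float] = {}
    true_int: dict[str, float] = {}
    for s in SECTOR_NAMES:
        sector = grid.sector_masks()[s].values
        true_frac[s] = 100.0 * float((mask1 & sector).sum()) / float(sector.sum())
        true_int[s] = float(g1[sector].mean())
    truth = GroundTruthRecord(
        eye_id=eye_id,
        true_fraction_pct=true_frac,
        true_mean_green_intensity=true_int,
        gefc_pixel_mask=mask1,
    )
    return img1, img2, truth


def _draw_demographics(cfg: SyntheticCohortConfig, eye_index: int) -> tuple[int, str]:
    """Age and sex for one eye, from the same substream as the images."""
    rng = np.random.default_rng([cfg.seed, eye_index])
    age_z = rng.standard_normal()
    sex_u = rng.uniform()
    lo, hi = cfg.age_range
    age = int(np.clip(np.rint(cfg.age_mean + cfg.age_sd * age_z), lo, hi))
    sex = "M" if sex_u < cfg.male_fraction else "F"
    return age, sex


def synthesize_cohort(
    cfg: SyntheticCohortConfig, out_dir: str | Path
) -> pd.DataFrame:
    """Write a full synthetic cohort to disk and return its manifest.

    Produces n_eyes x 2 PNG images with JSON sidecars, a truth CSV
    (eye_id, sector, true_fraction_pct, true_mean_intensity) and a manifest
    CSV (eye_id, session_id, image_path, metadata_path, age, sex).
    Byte-identical across runs under a fixed config.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest_rows: list[dict] = []
    truth_rows: list[dict] = []
    for i in range(cfg.n_eyes):
        img1, img2, truth = synthesize_eye(cfg, i)
        age, sex = _draw_demographics(cfg, i)
        for img in (img1, img2):
            stem = f"{img.eye_id}_s{img.session_id}"
            image_path = out_dir / f"{stem}.png"
            meta_path = out_dir / f"{stem}.json"
            write_faf_image(img, image_path, meta_path)
            manifest_rows.append(
                {
                    "eye_id": img.eye_id,
                    "session_id": img.session_id,
                    "image_path": image_path.name,
                    "metadata_path": meta_path.name,
                    "age": age,
                    "sex": sex,
                }
            )
        for s in SECTOR_NAMES:
            truth_rows.append(
                {
                    "eye_id": truth.eye_id,
                    "sector": s,
                    "true_fraction_pct": truth.true_fraction_pct[s],
                    "true_mean_intensity": truth.true_mean_green_intensity[s],
                }
            )
    manifest = pd.DataFrame(manifest_rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    pd.DataFrame(truth_rows).to_csv(out_dir / "truth.csv", index=False)
    return manifest


def with_noise(
    cfg: SyntheticCohortConfig, **noise_overrides: float
) -> SyntheticCohortConfig:
    """Copy of ``cfg`` with selected session-noise fields replaced."""
    return replace(cfg, session_noise=replace(cfg.session_noise, **noise_overrides))
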