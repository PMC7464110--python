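"""Two-channel spectrally resolved FAF image model and I/O.

The imaging device records the autofluorescence emission simultaneously in a
short-wavelength band (500-560 nm, the green-emitting fluorophore component,
GEFC) and a long-wavelength band (560-700 nm, the red component, REFC), and
exports a color-coded raster whose green and red planes are 8-bit intensity
maps of the two bands (no blue plane). Physical calibration (pixel pitch in
micrometres) and the fovea anchor travel in a JSON sidecar because standard
raster formats carry neither.

Per-pixel spectral features follow a centroid convention: total intensity is
the channel sum G + R, and the emission-wavelength estimate is the
band-centroid weighted mean (lambda_G * G + lambda_R * R) / (G + R) with the
band centroids at the midpoints of the two detection bands (530 and 630 nm
by default). The manufacturer's exact pixel -> (intensity, wavelength)
mapping is proprietary; the centroid convention is the simplest one
consistent with a two-band measurement and is configurable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import imageio.v3 as iio
import numpy as np
import pandas as pd

#: Detection bands of the device, nm.
GREEN_BAND_NM = (500.0, 560.0)
RED_BAND_NM = (560.0, 700.0)

#: Default band centroids used for the wavelength estimate, nm.
GREEN_CENTROID_NM = 530.0
RED_CENTROID_NM = 630.0

#: Native frame geometry of the device (rows, cols) and lateral resolution.
FULL_FRAME_SHAPE = (3288, 4608)
FULL_FRAME_PITCH_UM = 15.0

_METADATA_KEYS = ("pixel_pitch_um", "fovea_center_px", "eye_id", "session_id")


class MetadataError(ValueError):
    """Sidecar metadata is missing a key or holds an invalid value."""


@dataclass
class SpectralFAFImage:
    """A two-channel 8-bit spectrally resolved FAF image.

    Parameters
    ----------
    green_plane, red_plane
        2-D ``uint8`` arrays of identical shape holding the 500-560 nm and
        560-700 nm emission-band intensities (0-255).
    pixel_pitch_um
        Lateral retinal sampling in micrometres per pixel (device native:
        15 um/px).
    fovea_center_px
        Fovea anchor as (row, col); may be fractional (pixel centres sit at
        integer coordinates, row-major, 0-based).
    eye_id, session_id
        Cohort bookkeeping; sessions are "1" and "2" in a test-retest design.
    acquisition_meta
        Free-form descriptive metadata (e.g. excitation peak 450 nm, field of
        view 60 x 55 degrees); never interpreted.
    """

    green_plane: np.ndarray
    red_plane: np.ndarray
    pixel_pitch_um: float
    fovea_center_px: tuple[float, float]
    eye_id: str = ""
    session_id: str = "1"
    acquisition_meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.green_plane = _as_uint8_plane(self.green_plane, "green_plane")
        self.red_plane = _as_uint8_plane(self.red_plane, "red_plane")
        if self.green_plane.shape != self.red_plane.shape:
            raise ValueError(
                f"channel shape mismatch: green {self.green_plane.shape} "
                f"vs red {self.red_plane.shape}"
            )
        if not np.isfinite(self.pixel_pitch_um) or self.pixel_pitch_um <= 0:
            raise MetadataError(
                f"pixel_pitch_um must be positive, got {self.pixel_pitch_um}"
            )
        r, c = self.fovea_center_px
        nr, nc = self.shape
        if not (0 <= r <= nr - 1 and 0 <= c <= nc - 1):
            raise MetadataError(
                f"fovea_center_px {self.fovea_center_px} outside image "
                f"bounds {self.shape}"
            )
        self.fovea_center_px = (float(r), float(c))

    @property
    def shape(self) -> tuple[int, int]:
        return self.green_plane.shape


def _as_uint8_plane(arr: np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(arr)
    if arr.ndim != 2:
        raise ValueError(f"{name} must be 2-D, got shape {arr.shape}")
    if arr.dtype != np.uint8:
        if not np.issubdtype(arr.dtype, np.integer):
            raise ValueError(f"{name} must be an integer array (8-bit)")
        if arr.min(initial=0) < 0 or arr.max(initial=0) > 255:
            raise ValueError(f"{name} values outside [0, 255]")
        arr = arr.astype(np.uint8)
    return arr


@dataclass(frozen=True)
class PixelSpectralFeatures:
    """Per-pixel spectral features of an image.

    ``intensity`` is G + R on a 0-510 scale; ``wavelength_nm`` is the
    centroid estimate, NaN where the total intensity is zero (the emission
    wavelength of a dark pixel is undefined).
    """

    intensity: np.ndarray
    wavelength_nm: np.ndarray


def pixel_spectral_features(
    img: SpectralFAFImage,
    green_centroid_nm: float = GREEN_CENTROID_NM,
    red_centroid_nm: float = RED_CENTROID_NM,
) -> PixelSpectralFeatures:
    """Map each pixel to (total intensity, emission-wavelength centroid).

    intensity = G + R; wavelength = (lambda_G*G + lambda_R*R) / (G + R),
    undefined (NaN) where G + R = 0. With both channels nonnegative the
    wavelength always lies between the two band centroids.
    """
    g = img.green_plane.astype(np.float64)
    r = img.red_plane.astype(np.float64)
    total = g + r
    with np.errstate(invalid="ignore", divide="ignore"):
        wl = (green_centroid_nm * g + red_centroid_nm * r) / total
    wl[total == 0] = np.nan
    return PixelSpectralFeatures(intensity=total, wavelength_nm=wl)


def write_faf_image(
    img: SpectralFAFImage, image_path: str | Path, metadata_path: str | Path
) -> None:
    """Write the image as an 8-bit RGB PNG/TIFF plus a JSON sidecar.

    The raster stores (R, G, 0) per pixel — the color-coded export has no
    blue information. The round-trip through :func:`read_faf_image` is
    bit-exact on both planes and full-precision on the metadata.
    """
    rgb = np.zeros(img.shape + (3,), dtype=np.uint8)
    rgb[..., 0] = img.red_plane
    rgb[..., 1] = img.green_plane
    iio.imwrite(Path(image_path), rgb)
    meta = {
        "pixel_pitch_um": img.pixel_pitch_um,
        "fovea_center_px": list(img.fovea_center_px),
        "eye_id": img.eye_id,
        "session_id": img.session_id,
        "acquisition_meta": img.acquisition_meta,
    }
    Path(metadata_path).write_text(json.dumps(meta, indent=1, sort_keys=True))


def read_faf_image(
    image_path: str | Path, metadata_path: str | Path
) -> SpectralFAFImage:
    """Load a raster + JSON sidecar into a validated :class:`SpectralFAFImage`.

    The raster must carry at least red and green channels; any blue channel
    is ignored. Grayscale rasters are rejected (a single plane cannot encode
    two emission bands).
    """
    image_path = Path(image_path)
    metadata_path = Path(metadata_path)
    if not image_path.exists():
        raise FileNotFoundError(image_path)
    if not metadata_path.exists():
        raise FileNotFoundError(metadata_path)
    raw = iio.imread(image_path)
    if raw.ndim != 3 or raw.shape[2] < 2:
        raise ValueError(
            f"{image_path} has no separate red/green channels (shape {raw.shape})"
        )
    if raw.dtype != np.uint8:
        raise ValueError(f"{image_path} is not 8-bit ({raw.dtype})")
    meta = json.loads(metadata_path.read_text())
    for key in ("pixel_pitch_um", "fovea_center_px"):
        if key not in meta:
            raise MetadataError(f"metadata {metadata_path} missing key '{key}'")
    return SpectralFAFImage(
        green_plane=raw[..., 1],
        red_plane=raw[..., 0],
        pixel_pitch_um=float(meta["pixel_pitch_um"]),
        fovea_center_px=tuple(meta["fovea_center_px"]),
        eye_id=str(meta.get("eye_id", "")),
        session_id=str(meta.get("session_id", "1")),
        acquisition_meta=meta.get("acquisition_meta", {}) or {},
    )


def read_manifest(manifest_path: str | Path) -> pd.DataFrame:
    """Read a cohort manifest CSV.

    Required columns: eye_id, session_id, image_path, metadata_path;
    age and sex are optional. Relative paths are resolved against the
    manifest's own directory.
    """
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path, dtype={"eye_id": str, "session_id": str})
    required = {"eye_id", "session_id", "image_path", "metadata_path"}
    missing = required - set(df.columns)
    if missing:
        raise MetadataError(f"manifest missing columns: {sorted(missing)}")
    base = manifest_path.parent
    for col in ("image_path", "metadata_path"):
        df[col] = [
            str(p if Path(p).is_absolute() else base / p) for p in df[col]
        ]
    return df
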