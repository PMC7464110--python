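"""GEFC pixel selection and binarization.

Mirrors the two processing routes applied to the color-coded FAF export:
splitting the image into its red and green channels, and selecting the
pixels whose autofluorescence falls within a chosen intensity and/or
wavelength window, rendered as a binary (white-on-black) mask.

The selection semantics of the manufacturer's segmentation tool are
unpublished; two defensible readings of "a GEFC signal at any intensity"
are provided:

``centroid`` (default)
    a pixel is GEFC when its total intensity is positive and its spectral
    centroid falls inside the green detection band — this respects the
    wavelength axis of the tool's intensity/wavelength graph;
``green-positive``
    a pixel is GEFC whenever its green channel is strictly positive,
    regardless of the red channel.

Interval endpoints are inclusive on both ends, and no smoothing, morphology
or minimum-blob filtering is applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from specfaf.image_model import (
    GREEN_BAND_NM,
    SpectralFAFImage,
    pixel_spectral_features,
)


@dataclass(frozen=True)
class SelectionRange:
    """Closed intensity x wavelength window defining GEFC membership.

    Defaults select the full green detection band (500-560 nm) at any
    positive intensity.
    """

    wavelength_min_nm: float = GREEN_BAND_NM[0]
    wavelength_max_nm: float = GREEN_BAND_NM[1]
    intensity_min: float = 0.0
    intensity_max: float = float(2 * 255)

    def __post_init__(self) -> None:
        if not (500.0 <= self.wavelength_min_nm <= self.wavelength_max_nm <= 700.0):
            raise ValueError(
                "wavelength window must satisfy "
                f"500 <= min <= max <= 700, got "
                f"[{self.wavelength_min_nm}, {self.wavelength_max_nm}]"
            )
        if not (0 <= self.intensity_min <= self.intensity_max):
            raise ValueError(
                "intensity window must satisfy 0 <= min <= max, got "
                f"[{self.intensity_min}, {self.intensity_max}]"
            )


@dataclass
class BinaryMask:
    """Boolean pixel mask aligned to a source image, with provenance."""

    values: np.ndarray
    eye_id: str = ""
    session_id: str = ""
    selection: SelectionRange | None = None
    mode: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=bool)
        if self.values.ndim != 2:
            raise ValueError("mask must be 2-D")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def count(self) -> int:
        return int(self.values.sum())

    def to_png(self, path: str | Path) -> None:
        """Export as the tool's binarized presentation: white = selected."""
        iio.imwrite(Path(path), np.where(self.values, 255, 0).astype(np.uint8))


def split_channels(img: SpectralFAFImage) -> tuple[np.ndarray, np.ndarray]:
    """Return the (green, red) planes.

    An identity accessor kept as an explicit pipeline stage: the reference
    workflow runs the export through a split-channels step before measuring
    the green-channel brightness.
    """
    return img.green_plane, img.red_plane


def select_gefc_pixels(
    img: SpectralFAFImage,
    selection: SelectionRange | None = None,
    mode: str = "centroid",
) -> BinaryMask:
    """Binarize the image into GEFC / non-GEFC pixels.

    A pixel is selected when its total intensity lies in
    [intensity_min, intensity_max] and, in ``centroid`` mode, its spectral
    centroid lies in [wavelength_min_nm, wavelength_max_nm]; in
    ``green-positive`` mode the wavelength window is replaced by G > 0.
    Zero-intensity pixels are never selected (their wavelength is undefined).
    """
    if selection is None:
        selection = SelectionRange()
    if mode not in ("centroid", "green-positive"):
        raise ValueError(f"unknown mode {mode!r}")
    feats = pixel_spectral_features(img)
    in_intensity = (feats.intensity >= selection.intensity_min) & (
        feats.intensity <= selection.intensity_max
    )
    positive = feats.intensity > 0
    if mode == "centroid":
        with np.errstate(invalid="ignore"):
            in_band = (feats.wavelength_nm >= selection.wavelength_min_nm) & (
                feats.wavelength_nm <= selection.wavelength_max_nm
            )
        selected = positive & in_intensity & in_band
    else:
        selected = positive & in_intensity & (img.green_plane > 0)
    return BinaryMask(
        values=selected,
        eye_id=img.eye_id,
        session_id=img.session_id,
        selection=selection,
        mode=mode,
    )


def mean_green_intensity(img: SpectralFAFImage, region_mask: BinaryMask) -> float:
    """Mean brightness of the green channel over a pixel region.

    All pixels of the region contribute, not only the GEFC-selected ones:
    the GEFC intensity endpoint is the mean of every green-channel pixel
    value (0-255 gray scale) in the region of interest.
    """
    if region_mask.shape != img.shape:
        raise ValueError(
            f"region shape {region_mask.shape} != image shape {img.shape}"
        )
    n = region_mask.count()
    if n == 0:
        raise ValueError("mean green intensity undefined on an empty region")
    return float(img.green_plane[region_mask.values].mean())
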