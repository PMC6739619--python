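"""Core domain types and image I/O for luminescence wound imaging.

A wound imaging session produces pairs of images of the same field of view:
a white-light (reflectance) image showing the wound bed and its vasculature,
and a long-exposure luminescence image in which pixel intensity reports local
reactive-oxygen-species (ROS) activity via a chemiluminescent probe.

Intensities are kept in arbitrary camera units (a.u.) as floating point; no
absolute radiometric (photon-flux) calibration is attempted.  The pixel grid
is row-major with the origin at the top-left pixel center, and pixels are
assumed isotropic: physical position in mm = index * ``pixel_size_mm``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import tifffile

LUMINESCENCE = "luminescence"
WHITELIGHT = "whitelight"
_MODALITIES = (LUMINESCENCE, WHITELIGHT)

#: Default tolerance for cross-axis field-of-view consistency.  Printed view
#: areas are typically rounded to three significant figures, so a few percent
#: of apparent anisotropy is metadata rounding, not a real optics problem.
DEFAULT_FOV_TOL = 0.03

#: Acceptable mean background for a dark/ambient-light QC frame, in a.u.
DEFAULT_QC_LIMIT_AU = 10.0


class ImagingError(ValueError):
    """Raised for invalid images, metadata, or geometry."""


@dataclass(frozen=True)
class AcquisitionMeta:
    """Acquisition settings attached to every image.

    Parameters
    ----------
    exposure_s:
        Exposure time in seconds (luminescence frames are long exposures,
        e.g. 20 min = 1200 s).
    field_of_view_mm:
        Physical (width, height) of the imaged field in mm.
    binning:
        On-sensor n x n pixel binning factor (>= 1).
    modality:
        ``"luminescence"`` or ``"whitelight"``.
    day:
        Study day the frame belongs to, if any.
    subject_id, wound_id:
        Opaque labels tying the frame to an animal and wound.
    """

    exposure_s: float
    field_of_view_mm: tuple[float, float]
    binning: int = 1
    modality: str = LUMINESCENCE
    day: int | None = None
    subject_id: str | None = None
    wound_id: str | None = None

    def __post_init__(self) -> None:
        if self.exposure_s <= 0:
            raise ImagingError(f"exposure_s must be > 0, got {self.exposure_s}")
        if int(self.binning) != self.binning or self.binning < 1:
            raise ImagingError(f"binning must be an integer >= 1, got {self.binning}")
        w, h = self.field_of_view_mm
        if w <= 0 or h <= 0:
            raise ImagingError(f"field_of_view_mm must be positive, got {self.field_of_view_mm}")
        if self.modality not in _MODALITIES:
            raise ImagingError(f"modality must be one of {_MODALITIES}, got {self.modality!r}")


@dataclass
class LumImage:
    """A calibrated 2-D intensity field.

    ``pixels`` holds non-negative intensities in a.u. (float64); the physical
    scale is ``pixel_size_mm`` per pixel edge, identical for both axes.
    """

    pixels: np.ndarray
    pixel_size_mm: float
    meta: AcquisitionMeta

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ImagingError("pixels must be a non-empty 2-D array")
        if np.any(self.pixels < 0):
            raise ImagingError("pixel intensities must be >= 0")
        if self.pixel_size_mm <= 0:
            raise ImagingError("pixel_size_mm must be > 0")
        _check_fov_consistency(self.pixels.shape, self.pixel_size_mm, self.meta.field_of_view_mm)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def with_pixels(self, pixels: np.ndarray) -> "LumImage":
        """A copy of this image with the same geometry/metadata, new pixels."""
        return LumImage(pixels=pixels, pixel_size_mm=self.pixel_size_mm, meta=self.meta)


@dataclass(frozen=True)
class BackgroundReport:
    """Background QC summary of a frame taken with no luminescent source."""

    mean_background_au: float
    max_background_au: float
    passes_qc: bool
    qc_limit_au: float = DEFAULT_QC_LIMIT_AU


def _check_fov_consistency(
    shape: tuple[int, int],
    pixel_size_mm: float,
    fov_mm: tuple[float, float],
    tol: float = DEFAULT_FOV_TOL,
) -> None:
    nrows, ncols = shape
    width_mm, height_mm = fov_mm
    for n, extent, axis in ((ncols, width_mm, "width"), (nrows, height_mm, "height")):
        if abs(n * pixel_size_mm - extent) / extent > tol:
            raise ImagingError(
                f"grid {axis} {n} px x {pixel_size_mm} mm = {n * pixel_size_mm:.3f} mm "
                f"disagrees with field_of_view {axis} {extent} mm by more than {tol:.0%}"
            )


def read_image(path: str | Path, meta: AcquisitionMeta, fov_tol: float = DEFAULT_FOV_TOL) -> LumImage:
    """Read a single-channel 8- or 16-bit TIFF into a :class:`LumImage`.

    The pixel size is derived from the declared field-of-view width and the
    grid width (``width_mm / ncols``); the height axis is then checked for
    consistency within ``fov_tol``.  Multi-channel or multi-page TIFFs are
    rejected — stacks must be split upstream.
    """
    try:
        arr = tifffile.imread(str(path))
    except (OSError, ValueError) as exc:
        raise ImagingError(f"cannot read TIFF {path}: {exc}") from exc
    if arr.ndim != 2:
        raise ImagingError(
            f"{path}: expected a single-channel single-page image, got shape {arr.shape}"
        )
    pixel_size_mm = meta.field_of_view_mm[0] / arr.shape[1]
    _check_fov_consistency(arr.shape, pixel_size_mm, meta.field_of_view_mm, tol=fov_tol)
    return LumImage(pixels=arr.astype(np.float64), pixel_size_mm=pixel_size_mm, meta=meta)


def write_image(img: LumImage, path: str | Path) -> None:
    """Write an image as 16-bit TIFF (values rounded and clipped to uint16)."""
    arr = np.clip(np.round(img.pixels), 0, np.iinfo(np.uint16).max).astype(np.uint16)
    tifffile.imwrite(str(path), arr)


def subtract_dark(img: LumImage, dark: "LumImage | float") -> LumImage:
    """Subtract a dark frame (or scalar dark level) pixelwise, clipping at 0.

    Acquisition metadata is preserved.  A full dark frame must share the
    image grid exactly.
    """
    if isinstance(dark, LumImage):
        if dark.shape != img.shape:
            raise ImagingError(f"dark frame shape {dark.shape} != image shape {img.shape}")
        dark_arr: np.ndarray | float = dark.pixels
    else:
        dark_arr = float(dark)
    return img.with_pixels(np.clip(img.pixels - dark_arr, 0.0, None))


def background_report(img: LumImage, qc_limit: float = DEFAULT_QC_LIMIT_AU) -> BackgroundReport:
    """Summarize a background frame: mean, max, and pass/fail at ``qc_limit``.

    QC passes only for mean background strictly below the limit.
    """
    mean = float(img.pixels.mean())
    return BackgroundReport(
        mean_background_au=mean,
        max_background_au=float(img.pixels.max()),
        passes_qc=mean < qc_limit,
        qc_limit_au=qc_limit,
    )
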