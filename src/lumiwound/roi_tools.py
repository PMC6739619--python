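"""Region-of-interest creation, statistics, overlays and cross-time transfer.

ROIs come in three flavours mirroring interactive wound-analysis practice:
manual geometry (ellipse / polygon), semiautomatic (an intensity threshold
applied inside a manual region), and fully automatic (the contiguous
iso-intensity component grown from a seed pixel).  For longitudinal studies
an ROI drawn on one day's image can be extrapolated to another day by rigid
translation estimated from the white-light pair.

Pixel membership for geometric ROIs is by pixel-center inclusion (centers on
the boundary count as inside), which makes masks unambiguous and testable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import matplotlib

matplotlib.use("Agg")
from matplotlib import colormaps
import numpy as np
import shapely
from scipy import ndimage
from shapely.geometry import Polygon

from .imaging_core import LumImage

PROVENANCES = ("manual_ellipse", "manual_polygon", "semiauto", "auto_iso", "extrapolated")

#: 8-connectivity structuring element used for "contiguous area" semantics.
STRUCTURE_8 = np.ones((3, 3), dtype=bool)


class RoiError(ValueError):
    """Raised for empty, off-grid, or otherwise invalid regions."""


class RegistrationError(RuntimeError):
    """Raised when cross-timepoint image registration is untrustworthy."""


@dataclass
class ROI:
    """A labeled binary pixel region on a stated image grid."""

    mask: np.ndarray
    label: str = ""
    provenance: str = "manual_polygon"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise RoiError("ROI mask must be 2-D")
        if not self.mask.any():
            raise RoiError("ROI mask is empty")
        if self.provenance not in PROVENANCES:
            raise RoiError(f"unknown provenance {self.provenance!r}")

    @property
    def pixel_count(self) -> int:
        return int(self.mask.sum())


@dataclass(frozen=True)
class RoiStats:
    """Absolute and statistical summary of an ROI on an intensity image."""

    mean_au: float
    total_au: float
    max_au: float
    std_au: float
    area_mm2: float
    pixel_count: int


def _pixel_centers(grid_shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    rr, cc = np.indices(grid_shape)
    return rr, cc


def roi_ellipse(
    center: tuple[float, float],
    semi_axes: tuple[float, float],
    angle_deg: float,
    grid_shape: tuple[int, int],
    label: str = "",
) -> ROI:
    """Rotated-ellipse ROI: pixels whose centers fall inside the ellipse.

    ``center`` is (row, col) in px; ``semi_axes`` (a, b) in px with ``a``
    along the row axis at angle 0; ``angle_deg`` rotates counterclockwise in
    the (row, col) plane.
    """
    a, b = semi_axes
    if a <= 0 or b <= 0:
        raise RoiError("semi-axes must be > 0")
    rr, cc = _pixel_centers(grid_shape)
    dr = rr - center[0]
    dc = cc - center[1]
    theta = np.deg2rad(angle_deg)
    u = dr * np.cos(theta) + dc * np.sin(theta)
    v = -dr * np.sin(theta) + dc * np.cos(theta)
    # small tolerance keeps boundary pixels stable under exact 90-degree
    # rotations, where cos/sin carry ~1e-16 floating-point residue
    mask = (u / a) ** 2 + (v / b) ** 2 <= 1.0 + 1e-9
    if not mask.any():
        raise RoiError("ellipse contains no pixel centers on this grid")
    return ROI(mask=mask, label=label, provenance="manual_ellipse")


def roi_polygon(
    vertices: list[tuple[float, float]],
    grid_shape: tuple[int, int],
    label: str = "",
) -> ROI:
    """Simple-polygon ROI: pixels whose centers are inside or on the polygon.

    Vertices are (row, col) in px.  Self-intersecting polygons are rejected.
    """
    if len(vertices) < 3:
        raise RoiError("a polygon needs at least 3 vertices")
    poly = Polygon(vertices)
    if not poly.is_valid or poly.area == 0:
        raise RoiError("polygon must be simple (non-self-intersecting) with nonzero area")
    rr, cc = _pixel_centers(grid_shape)
    inside = shapely.intersects_xy(poly, rr.ravel(), cc.ravel()).reshape(grid_shape)
    if not inside.any():
        raise RoiError("polygon contains no pixel centers on this grid")
    return ROI(mask=inside, label=label, provenance="manual_polygon")


def roi_semiauto(img: LumImage, base: ROI, threshold_au: float, label: str = "") -> ROI:
    """Restrict ``base`` to its pixels with intensity >= ``threshold_au``."""
    if base.mask.shape != img.shape:
        raise RoiError("base ROI is on a different grid than the image")
    mask = base.mask & (img.pixels >= threshold_au)
    if not mask.any():
        raise RoiError(f"no pixels in the base ROI reach threshold {threshold_au} a.u.")
    return ROI(mask=mask, label=label or base.label, provenance="semiauto")


def roi_auto_iso(
    img: LumImage, seed: tuple[int, int], iso_level: float, label: str = ""
) -> ROI:
    """Contiguous (8-connected) iso-intensity region containing ``seed``.

    The mask is the connected component of ``pixels >= iso_level`` that
    contains the seed pixel; the seed itself must reach the iso level.
    """
    if img.pixels[seed] < iso_level:
        raise RoiError(f"seed pixel {seed} is below the iso level {iso_level}")
    supra = img.pixels >= iso_level
    labels, _ = ndimage.label(supra, structure=STRUCTURE_8)
    mask = labels == labels[seed]
    return ROI(mask=mask, label=label, provenance="auto_iso")


def roi_stats(img: LumImage, roi: ROI) -> RoiStats:
    """Mean/total/max/std intensity and physical area over the ROI pixels."""
    if roi.mask.shape != img.shape:
        raise RoiError("ROI is on a different grid than the image")
    vals = img.pixels[roi.mask]
    n = vals.size
    mean = float(vals.mean())
    return RoiStats(
        mean_au=mean,
        total_au=mean * n,
        max_au=float(vals.max()),
        std_au=float(vals.std(ddof=0)),
        area_mm2=n * img.pixel_size_mm**2,
        pixel_count=n,
    )


def overlay(
    base: LumImage,
    layers: list[LumImage],
    colormap_names: tuple[str, ...] = ("hot", "cool"),
    opacities: tuple[float, ...] | None = None,
    display_ranges: list[tuple[float, float] | None] | None = None,
) -> np.ndarray:
    """Compose up to two pseudocolored layers over a grayscale base image.

    Returns an RGB float array in [0, 1] for visualization only; composites
    are never used for quantification.  Each layer pixel is alpha-blended
    over the running composite with alpha = layer opacity x normalized layer
    intensity, so zero-intensity layer pixels leave the base untouched and
    layer order matters deterministically.
    """
    if len(layers) > 2:
        raise RoiError("at most three images (one base + two layers) can be overlaid")
    for layer in layers:
        if layer.shape != base.shape:
            raise RoiError("all overlay images must share the base grid")
    opacities = opacities if opacities is not None else (1.0,) * len(layers)
    base_max = base.pixels.max()
    gray = base.pixels / base_max if base_max > 0 else np.zeros_like(base.pixels)
    composite = np.stack([gray] * 3, axis=-1)
    for i, layer in enumerate(layers):
        if display_ranges is not None and display_ranges[i] is not None:
            lo, hi = display_ranges[i]
        else:
            lo, hi = 0.0, float(layer.pixels.max())
        span = hi - lo
        norm = np.clip((layer.pixels - lo) / span, 0, 1) if span > 0 else np.zeros_like(layer.pixels)
        color = colormaps[colormap_names[i]](norm)[..., :3]
        alpha = (opacities[i] * norm)[..., None]
        composite = (1 - alpha) * composite + alpha * color
    return composite


def _shift_mask(mask: np.ndarray, dr: int, dc: int) -> np.ndarray:
    """Translate a boolean mask by integer (dr, dc), clipping at the grid edge."""
    out = np.zeros_like(mask)
    h, w = mask.shape
    rs_src = slice(max(0, -dr), min(h, h - dr))
    cs_src = slice(max(0, -dc), min(w, w - dc))
    rs_dst = slice(max(0, dr), min(h, h + dr))
    cs_dst = slice(max(0, dc), min(w, w + dc))
    out[rs_dst, cs_dst] = mask[rs_src, cs_src]
    return out


def _overlap_correlation(ref: np.ndarray, tgt: np.ndarray, dr: int, dc: int) -> float:
    """Pearson r between ref and tgt restricted to their overlap under shift (dr, dc)."""
    h, w = ref.shape
    ref_vals = ref[max(0, -dr) : min(h, h - dr), max(0, -dc) : min(w, w - dc)]
    tgt_vals = tgt[max(0, dr) : min(h, h + dr), max(0, dc) : min(w, w + dc)]
    if ref_vals.size < 16 or ref_vals.std() == 0 or tgt_vals.std() == 0:
        return -1.0
    return float(np.corrcoef(ref_vals.ravel(), tgt_vals.ravel())[0, 1])


def register_translation(
    reference: LumImage,
    target: LumImage,
    min_confidence: float = 0.5,
    max_shift_px: int | None = None,
) -> tuple[int, int]:
    """Estimate the integer (row, col) translation carrying ``reference`` onto ``target``.

    The normalized cross-correlation (Pearson r over the overlapping region)
    is evaluated for every candidate shift within ``max_shift_px`` (default:
    a quarter of the smaller image dimension) and the peak is taken; the
    registration is accepted only if the peak correlation reaches
    ``min_confidence``.  Restricting the score to the overlap keeps the
    estimate exact for rigidly shifted frames whose borders carry no data.
    """
    if reference.shape != target.shape:
        raise RoiError("reference and target must share a grid")
    h, w = reference.shape
    if max_shift_px is None:
        max_shift_px = max(1, min(h, w) // 4)
    ref, tgt = reference.pixels, target.pixels
    best = (-2.0, 0, 0)
    for dr in range(-max_shift_px, max_shift_px + 1):
        for dc in range(-max_shift_px, max_shift_px + 1):
            r = _overlap_correlation(ref, tgt, dr, dc)
            if r > best[0]:
                best = (r, dr, dc)
    confidence, dr, dc = best
    if confidence < min_confidence:
        raise RegistrationError(
            f"registration confidence {confidence:.3f} below floor {min_confidence}"
        )
    return dr, dc


def extrapolate_roi(
    roi: ROI, reference: LumImage, target: LumImage, min_confidence: float = 0.5
) -> ROI:
    """Transfer an ROI across timepoints by rigid translation.

    The translation is estimated between the two (same-modality, typically
    white-light) images; the mask is shifted by that integer pixel offset and
    clipped to the grid.  Rotation/scale are not modeled: the imager re-seats
    over the same wound between dressing changes.
    """
    if roi.mask.shape != reference.shape:
        raise RoiError("ROI is on a different grid than the reference image")
    dr, dc = register_translation(reference, target, min_confidence=min_confidence)
    shifted = _shift_mask(roi.mask, dr, dc)
    if not shifted.any():
        raise RoiError("extrapolated ROI falls entirely off the target grid")
    return ROI(mask=shifted, label=roi.label, provenance="extrapolated")


# --- serialization -----------------------------------------------------------

def roi_to_json(roi: ROI) -> str:
    """Serialize an ROI as run-length-encoded JSON (row-major runs)."""
    flat = roi.mask.ravel()
    boundaries = np.flatnonzero(np.diff(flat.astype(np.int8)))
    starts = np.concatenate(([0], boundaries + 1))
    lengths = np.diff(np.concatenate((starts, [flat.size])))
    runs = [
        [int(s), int(l)] for s, l, v in zip(starts, lengths, flat[starts]) if v
    ]
    return json.dumps(
        {
            "shape": list(roi.mask.shape),
            "runs": runs,
            "label": roi.label,
            "provenance": roi.provenance,
        }
    )


def roi_from_json(text: str) -> ROI:
    obj = json.loads(text)
    mask = np.zeros(int(np.prod(obj["shape"])), dtype=bool)
    for start, length in obj["runs"]:
        mask[start : start + length] = True
    return ROI(
        mask=mask.reshape(obj["shape"]), label=obj["label"], provenance=obj["provenance"]
    )


def save_mask_png(mask: np.ndarray, path: str | Path) -> None:
    """Write a binary mask as an 8-bit PNG (255 inside, 0 outside)."""
    iio.imwrite(str(path), (np.asarray(mask, bool) * 255).astype(np.uint8))
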