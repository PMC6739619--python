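"""Synthetic wound-imaging study generator.

No real wound images ship with this package, so every analysis stage is
exercised on synthetic data that reproduces the statistical structure the
pipeline assumes:

* a circular 3-cm full-thickness wound imaged as white-light / luminescence
  pairs over a 21-day course with dressing changes at days 1, 3, 7, 10, 14,
  17, 21;
* a random branching tree of large (~0.5 mm diameter) vessels, rendered
  dark on the granulation background in the white-light channel;
* a diffuse ROS field that is brighter (default 2x) in the capillary zone
  >= 2.5 mm away from large vessels, plus Gaussian ROS peaks placed by a
  Poisson process that preferentially avoids the vessel-proximal zone;
* infection status: infected wounds carry 3x the peak rate with higher,
  sharper peaks, and their temporal profile plateaus over days 3-10 while
  control wounds peak at day 3 and decay;
* calibration series and droplet-matrix images for the bench-top stages.

Everything is deterministic given (config, seed), and every generated image
comes with ground truth (vessel mask, peak records) sufficient to predict
each pipeline metric.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage

from .calibration import CalibrationSeries
from .imaging_core import (
    LUMINESCENCE,
    WHITELIGHT,
    AcquisitionMeta,
    LumImage,
    write_image,
)
from .roi_tools import ROI, save_mask_png

DEFAULT_DAYS = (1, 3, 7, 10, 14, 17, 21)


class SimulationError(ValueError):
    """Raised for invalid simulation configurations."""


@dataclass(frozen=True)
class WoundSimConfig:
    """Generative parameters for one simulated wound.

    Geometry defaults mirror an 8x8-binned 1344x1024 CCD imaging a
    5.14 x 3.92 cm field: a 168x128 px grid at 0.306 mm/px, holding a 3-cm
    diameter wound.  Rates and factors default to the study conditions the
    analyses are designed to recover: a control cluster rate of ~2 peaks per
    wound (0.283 /cm² over 7.07 cm²), an infected multiplier of 3, capillary
    zone enhancement 2.0, vessels ~0.5 mm wide.
    """

    wound_diameter_mm: float = 30.0
    grid_shape: tuple[int, int] = (128, 168)
    pixel_size_mm: float = 0.306
    infected: bool = False
    days: tuple[int, ...] = DEFAULT_DAYS

    # ROS peak statistics
    cluster_rate_per_cm2: float = 0.283
    infected_rate_multiplier: float = 3.0
    peak_amplitude_au: float = 80.0
    peak_amplitude_infected_au: float = 130.0
    peak_amplitude_cv: float = 0.10
    peak_width_mm: float = 1.2
    peak_width_infected_mm: float = 0.7
    peak_width_cv: float = 0.10
    peak_min_separation_mm: float = 4.0
    near_zone_acceptance: float = 0.25

    # diffuse field and vessels
    base_intensity_au: float = 30.0
    capillary_enhancement: float = 2.0
    capillary_cutoff_mm: float = 2.5
    radial_falloff: float = 0.0
    vessel_branches: int = 4
    vessel_width_mm: float = 0.5
    noise_sd_au: float = 2.0

    # white-light rendering
    whitelight_background_au: float = 150.0
    whitelight_vessel_au: float = 80.0
    whitelight_noise_sd_au: float = 4.0

    exposure_s: float = 1200.0
    binning: int = 8

    def __post_init__(self) -> None:
        positive = {
            "wound_diameter_mm": self.wound_diameter_mm,
            "pixel_size_mm": self.pixel_size_mm,
            "cluster_rate_per_cm2": self.cluster_rate_per_cm2,
            "infected_rate_multiplier": self.infected_rate_multiplier,
            "peak_amplitude_au": self.peak_amplitude_au,
            "peak_width_mm": self.peak_width_mm,
            "capillary_enhancement": self.capillary_enhancement,
            "vessel_width_mm": self.vessel_width_mm,
            "base_intensity_au": self.base_intensity_au,
        }
        for name, value in positive.items():
            if value <= 0:
                raise SimulationError(f"{name} must be > 0, got {value}")
        if self.noise_sd_au < 0 or self.whitelight_noise_sd_au < 0:
            raise SimulationError("noise standard deviations must be >= 0")
        if not 0 <= self.near_zone_acceptance <= 1:
            raise SimulationError("near_zone_acceptance must be in [0, 1]")
        if not 0 <= self.radial_falloff < 1:
            raise SimulationError("radial_falloff must be in [0, 1)")

    @property
    def field_of_view_mm(self) -> tuple[float, float]:
        nrows, ncols = self.grid_shape
        return (ncols * self.pixel_size_mm, nrows * self.pixel_size_mm)

    @property
    def wound_center_px(self) -> tuple[float, float]:
        return ((self.grid_shape[0] - 1) / 2.0, (self.grid_shape[1] - 1) / 2.0)

    @property
    def wound_radius_px(self) -> float:
        return self.wound_diameter_mm / 2.0 / self.pixel_size_mm

    def wound_mask(self) -> np.ndarray:
        rr, cc = np.indices(self.grid_shape)
        cr, cp = self.wound_center_px
        return (rr - cr) ** 2 + (cc - cp) ** 2 <= self.wound_radius_px**2

    def meta(self, modality: str, day: int | None = None, **labels) -> AcquisitionMeta:
        return AcquisitionMeta(
            exposure_s=self.exposure_s if modality == LUMINESCENCE else 0.1,
            field_of_view_mm=self.field_of_view_mm,
            binning=self.binning,
            modality=modality,
            day=day,
            **labels,
        )


@dataclass(frozen=True)
class PeakRecord:
    """Ground truth for one generated ROS peak."""

    row: float
    col: float
    amplitude_au: float
    sigma_mm: float


@dataclass
class SimulatedWound:
    """One wound's full ground-truthed image series."""

    wound_id: str
    subject_id: str
    group: str  # "infected" or "control"
    config: WoundSimConfig
    vessel_mask: np.ndarray
    wound_roi: ROI
    images: dict[int, tuple[LumImage, LumImage]]  # day -> (whitelight, luminescence)
    peaks: tuple[PeakRecord, ...]

    @property
    def days(self) -> tuple[int, ...]:
        return tuple(sorted(self.images))


def temporal_profile(day: float, infected: bool) -> float:
    """Relative intensity multiplier over the wound time course.

    Piecewise-linear in log intensity with knots at days 1, 3, 10 and 21:
    control wounds peak at day 3 then decline quickly; infected wounds
    plateau at peak level over days 3-10 before declining more slowly.
    """
    knots = np.array([1.0, 3.0, 10.0, 21.0])
    if infected:
        levels = np.array([0.5, 1.0, 1.0, 0.3])
    else:
        levels = np.array([0.5, 1.0, 0.25, 0.05])
    day = float(np.clip(day, knots[0], knots[-1]))
    return float(np.exp(np.interp(day, knots, np.log(levels))))


def _polyline_mask(
    points: np.ndarray, grid_shape: tuple[int, int], half_width_px: float
) -> np.ndarray:
    """Pixels within ``half_width_px`` of the polyline through ``points``."""
    rr, cc = np.indices(grid_shape)
    px = np.stack([rr.ravel(), cc.ravel()], axis=1).astype(float)
    dmin = np.full(px.shape[0], np.inf)
    for p0, p1 in zip(points[:-1], points[1:]):
        seg = p1 - p0
        seg_len2 = float(seg @ seg)
        if seg_len2 == 0:
            d = np.linalg.norm(px - p0, axis=1)
        else:
            t = np.clip(((px - p0) @ seg) / seg_len2, 0.0, 1.0)
            proj = p0 + t[:, None] * seg
            d = np.linalg.norm(px - proj, axis=1)
        np.minimum(dmin, d, out=dmin)
    return (dmin <= half_width_px).reshape(grid_shape)


def _random_branch(
    start: np.ndarray,
    direction: float,
    length_px: float,
    rng: np.random.Generator,
    step_px: float = 3.0,
    wobble_rad: float = 0.25,
) -> np.ndarray:
    """A meandering polyline: fixed-length steps with random heading drift."""
    pts = [start.copy()]
    heading = direction
    for _ in range(int(max(1, length_px / step_px))):
        heading += rng.normal(0.0, wobble_rad)
        pts.append(pts[-1] + step_px * np.array([np.sin(heading), np.cos(heading)]))
    return np.array(pts)


def simulate_vessel_tree(
    cfg: WoundSimConfig, rng: np.random.Generator
) -> tuple[np.ndarray, LumImage]:
    """Generate a branching large-vessel tree and its white-light rendering.

    Main branches start on the wound boundary heading inward and meander
    across the wound; each may spawn a shorter side branch.  Vessels are
    rendered at ``vessel_width_mm`` and appear darker than the granulation
    background in the white-light image.
    """
    mask = np.zeros(cfg.grid_shape, dtype=bool)
    cr, cp = cfg.wound_center_px
    radius = cfg.wound_radius_px
    half_width = cfg.vessel_width_mm / 2.0 / cfg.pixel_size_mm
    for _ in range(cfg.vessel_branches):
        theta = rng.uniform(0, 2 * np.pi)
        start = np.array([cr + radius * np.sin(theta), cp + radius * np.cos(theta)])
        inward = theta + np.pi + rng.uniform(-0.4, 0.4)
        trunk = _random_branch(start, inward, length_px=1.6 * radius, rng=rng)
        mask |= _polyline_mask(trunk, cfg.grid_shape, half_width)
        if rng.random() < 0.7 and len(trunk) > 4:
            origin = trunk[rng.integers(2, len(trunk) - 2)]
            side_dir = inward + rng.choice([-1, 1]) * rng.uniform(0.5, 1.2)
            side = _random_branch(origin, side_dir, length_px=0.6 * radius, rng=rng)
            mask |= _polyline_mask(side, cfg.grid_shape, half_width)
    mask &= cfg.wound_mask()

    wl = np.full(cfg.grid_shape, cfg.whitelight_background_au)
    wl[mask] = cfg.whitelight_vessel_au
    wl = ndimage.gaussian_filter(wl, 1.0)
    wl = wl + rng.normal(0.0, cfg.whitelight_noise_sd_au, cfg.grid_shape)
    wl_img = LumImage(
        pixels=np.clip(wl, 0, None),
        pixel_size_mm=cfg.pixel_size_mm,
        meta=cfg.meta(WHITELIGHT),
    )
    return mask, wl_img


def _draw_peaks(
    cfg: WoundSimConfig, vessel_mask: np.ndarray, rng: np.random.Generator
) -> tuple[PeakRecord, ...]:
    """Poisson peak placement with rejection near large vessels."""
    wound = cfg.wound_mask()
    area_cm2 = wound.sum() * cfg.pixel_size_mm**2 / 100.0
    rate = cfg.cluster_rate_per_cm2 * (
        cfg.infected_rate_multiplier if cfg.infected else 1.0
    )
    # every wound bed carries at least one inflammatory focus; the count is
    # 1 + Poisson(mean - 1), which preserves the configured mean count
    mean_count = rate * area_cm2
    n_peaks = 1 + rng.poisson(max(0.0, mean_count - 1.0)) if mean_count >= 1 else rng.poisson(mean_count)
    if vessel_mask.any():
        dist_mm = ndimage.distance_transform_edt(~vessel_mask) * cfg.pixel_size_mm
    else:
        dist_mm = np.full(cfg.grid_shape, np.inf)
    amp0 = cfg.peak_amplitude_infected_au if cfg.infected else cfg.peak_amplitude_au
    width0 = cfg.peak_width_infected_mm if cfg.infected else cfg.peak_width_mm
    cr, cp = cfg.wound_center_px
    min_sep_px = cfg.peak_min_separation_mm / cfg.pixel_size_mm
    peaks: list[PeakRecord] = []
    for _ in range(n_peaks):
        for _attempt in range(1000):
            r = cr + rng.uniform(-1, 1) * cfg.wound_radius_px
            c = cp + rng.uniform(-1, 1) * cfg.wound_radius_px
            ri, ci = int(round(r)), int(round(c))
            if not (0 <= ri < cfg.grid_shape[0] and 0 <= ci < cfg.grid_shape[1]):
                continue
            if not wound[ri, ci]:
                continue
            # distinct foci: hard-core thinning keeps peaks separated
            if any(np.hypot(r - pk.row, c - pk.col) < min_sep_px for pk in peaks):
                continue
            near = dist_mm[ri, ci] < cfg.capillary_cutoff_mm
            if near and rng.random() > cfg.near_zone_acceptance:
                continue
            break
        amp = max(1e-6, rng.normal(amp0, cfg.peak_amplitude_cv * amp0))
        sigma = max(0.1, rng.normal(width0, cfg.peak_width_cv * width0))
        peaks.append(PeakRecord(row=r, col=c, amplitude_au=amp, sigma_mm=sigma))
    return tuple(peaks)


def _render_static_field(
    cfg: WoundSimConfig, vessel_mask: np.ndarray, peaks: tuple[PeakRecord, ...]
) -> np.ndarray:
    """Noise-free day-peak ROS field: zoned diffuse base plus Gaussian peaks."""
    wound = cfg.wound_mask()
    if vessel_mask.any():
        dist_mm = ndimage.distance_transform_edt(~vessel_mask) * cfg.pixel_size_mm
    else:
        dist_mm = np.full(cfg.grid_shape, np.inf)
    far = dist_mm >= cfg.capillary_cutoff_mm
    base = cfg.base_intensity_au * np.where(far, cfg.capillary_enhancement, 1.0)
    if cfg.radial_falloff > 0:
        # inflammation concentrates centrally: quadratic falloff toward the rim
        rr0, cc0 = np.indices(cfg.grid_shape)
        cr, cp = cfg.wound_center_px
        rel_r2 = ((rr0 - cr) ** 2 + (cc0 - cp) ** 2) / cfg.wound_radius_px**2
        base = base * (1.0 - cfg.radial_falloff * np.clip(rel_r2, 0.0, 1.0))
    field = np.where(wound, base, 0.0)
    rr, cc = np.indices(cfg.grid_shape)
    for pk in peaks:
        sigma_px = pk.sigma_mm / cfg.pixel_size_mm
        bump = pk.amplitude_au * np.exp(
            -((rr - pk.row) ** 2 + (cc - pk.col) ** 2) / (2 * sigma_px**2)
        )
        field += np.where(wound, bump, 0.0)
    return field


def simulate_ros_field(
    cfg: WoundSimConfig,
    vessel_mask: np.ndarray,
    day: int,
    rng: np.random.Generator,
    peaks: tuple[PeakRecord, ...] | None = None,
) -> tuple[LumImage, tuple[PeakRecord, ...]]:
    """Render the luminescence (ROS) image of one wound on one study day.

    The diffuse base field is ``base_intensity_au`` in the vessel-proximal
    zone and ``capillary_enhancement`` x that in the capillary zone
    (>= ``capillary_cutoff_mm`` from a vessel); Gaussian peaks are drawn
    once per wound (pass ``peaks`` to reuse across days) and the whole field
    is scaled by the group's temporal profile at ``day`` before additive
    Gaussian noise, clipped at zero.
    """
    if day not in cfg.days:
        raise SimulationError(f"day {day} not in configured study days {cfg.days}")
    if vessel_mask.shape != cfg.grid_shape:
        raise SimulationError("vessel mask does not match the configured grid")
    if peaks is None:
        peaks = _draw_peaks(cfg, vessel_mask, rng)
    field = _render_static_field(cfg, vessel_mask, peaks)
    field = field * temporal_profile(day, cfg.infected)
    if cfg.noise_sd_au > 0:
        field = field + rng.normal(0.0, cfg.noise_sd_au, cfg.grid_shape)
    img = LumImage(
        pixels=np.clip(field, 0.0, None),
        pixel_size_mm=cfg.pixel_size_mm,
        meta=cfg.meta(LUMINESCENCE, day=day),
    )
    return img, peaks


def simulate_wound(
    cfg: WoundSimConfig,
    rng: np.random.Generator,
    wound_id: str = "w0",
    subject_id: str = "pig0",
) -> SimulatedWound:
    """Generate one wound's complete ground-truthed image series."""
    vessel_mask, wl_img = simulate_vessel_tree(cfg, rng)
    peaks = _draw_peaks(cfg, vessel_mask, rng)
    wound_roi = ROI(mask=cfg.wound_mask(), label=wound_id, provenance="manual_ellipse")
    images = {}
    for day in cfg.days:
        lum, _ = simulate_ros_field(cfg, vessel_mask, day, rng, peaks=peaks)
        wl_day = LumImage(
            pixels=wl_img.pixels,
            pixel_size_mm=cfg.pixel_size_mm,
            meta=cfg.meta(WHITELIGHT, day=day, subject_id=subject_id, wound_id=wound_id),
        )
        lum_meta = cfg.meta(
            LUMINESCENCE, day=day, subject_id=subject_id, wound_id=wound_id
        )
        lum = LumImage(pixels=lum.pixels, pixel_size_mm=cfg.pixel_size_mm, meta=lum_meta)
        images[day] = (wl_day, lum)
    return SimulatedWound(
        wound_id=wound_id,
        subject_id=subject_id,
        group="infected" if cfg.infected else "control",
        config=cfg,
        vessel_mask=vessel_mask,
        wound_roi=wound_roi,
        images=images,
        peaks=peaks,
    )


def simulate_study(
    n_per_group: int,
    cfg: WoundSimConfig | None = None,
    seed: int = 0,
) -> tuple[list[SimulatedWound], pd.DataFrame]:
    """Generate a two-group study: ``n_per_group`` infected and control wounds.

    Wounds are assigned to subjects two per group per animal, mirroring the
    study design.  Returns the wounds plus a tidy manifest (one row per
    wound-day).  Deterministic given (cfg, seed).
    """
    if n_per_group < 1:
        raise SimulationError("n_per_group must be >= 1")
    base_cfg = cfg if cfg is not None else WoundSimConfig()
    rng = np.random.default_rng(seed)
    wounds = []
    rows = []
    for group, infected in (("control", False), ("infected", True)):
        group_cfg = replace(base_cfg, infected=infected)
        for i in range(n_per_group):
            wound_id = f"{group[:3]}{i:02d}"
            subject_id = f"pig{i // 2:02d}"
            wound = simulate_wound(group_cfg, rng, wound_id=wound_id, subject_id=subject_id)
            wounds.append(wound)
            for day in wound.days:
                rows.append(
                    {
                        "wound_id": wound_id,
                        "subject_id": subject_id,
                        "group": group,
                        "day": day,
                        "n_true_peaks": len(wound.peaks),
                    }
                )
    return wounds, pd.DataFrame(rows)


def write_study(
    wounds: list[SimulatedWound], outdir: str | Path, seed: int | None = None
) -> Path:
    """Write a simulated study to disk: TIFF pairs, masks, manifest, truth tables.

    Returns the manifest path.  Layout: ``<outdir>/<wound_id>/d<day>_{wl,lum}.tif``
    plus per-wound vessel/wound-ROI PNG masks, a ``manifest.yaml`` with
    per-record paths and acquisition settings, and ``ground_truth.csv``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records = []
    truth_rows = []
    for wound in wounds:
        wdir = outdir / wound.wound_id
        wdir.mkdir(exist_ok=True)
        save_mask_png(wound.vessel_mask, wdir / "vessel_mask.png")
        save_mask_png(wound.wound_roi.mask, wdir / "wound_roi.png")
        for day, (wl, lum) in sorted(wound.images.items()):
            wl_path = wdir / f"d{day:02d}_wl.tif"
            lum_path = wdir / f"d{day:02d}_lum.tif"
            write_image(wl, wl_path)
            write_image(lum, lum_path)
            records.append(
                {
                    "wound_id": wound.wound_id,
                    "subject_id": wound.subject_id,
                    "group": wound.group,
                    "day": day,
                    "whitelight": str(wl_path.relative_to(outdir)),
                    "luminescence": str(lum_path.relative_to(outdir)),
                    "vessel_mask": str((wdir / "vessel_mask.png").relative_to(outdir)),
                    "wound_roi": str((wdir / "wound_roi.png").relative_to(outdir)),
                }
            )
        for pk in wound.peaks:
            truth_rows.append(
                {
                    "wound_id": wound.wound_id,
                    "row_px": pk.row,
                    "col_px": pk.col,
                    "amplitude_au": pk.amplitude_au,
                    "sigma_mm": pk.sigma_mm,
                }
            )
    cfg = wounds[0].config
    manifest = {
        "seed": seed,
        "pixel_size_mm": cfg.pixel_size_mm,
        "field_of_view_mm": list(cfg.field_of_view_mm),
        "exposure_s": cfg.exposure_s,
        "binning": cfg.binning,
        "records": records,
    }
    manifest_path = outdir / "manifest.yaml"
    manifest_path.write_text(yaml.safe_dump(manifest, sort_keys=False))
    pd.DataFrame(truth_rows).to_csv(outdir / "ground_truth.csv", index=False)
    return manifest_path


def simulate_calibration(
    slope_k: float,
    sigma_control: float,
    concentrations: tuple[float, ...] = (2500.0, 625.0, 156.25, 39.1, 0.0),
    replicates: int = 3,
    seed: int | np.random.Generator = 0,
    intercept: float = 0.0,
) -> CalibrationSeries:
    """Simulate a standard-curve series: I = slope*c + intercept + N(0, sigma²).

    Defaults mirror a fourfold H2O2 dilution series with a blank, read in
    triplicate.  Noise sd is ``sigma_control`` at every level.
    """
    if slope_k <= 0:
        raise SimulationError("slope_k must be > 0")
    if sigma_control < 0:
        raise SimulationError("sigma_control must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    # readings are left unclipped: blank replicates scatter symmetrically
    # around the intercept, which is what the sigma_control estimate assumes
    intensities = tuple(
        tuple(
            float(slope_k * c + intercept + rng.normal(0.0, sigma_control))
            for _ in range(replicates)
        )
        for c in concentrations
    )
    return CalibrationSeries(tuple(concentrations), intensities)


def simulate_droplet_matrix(
    rows: int,
    cols: int,
    spot_intensity: float = 100.0,
    edge_factor: float = 1.0,
    curvature_label: str = "flat",
    seed: int | np.random.Generator = 0,
    grid_shape: tuple[int, int] = (128, 168),
    pixel_size_mm: float = 0.306,
    spot_sigma_px: float = 3.0,
    noise_sd_au: float = 1.0,
    spot_intensity_cv: float = 0.03,
) -> LumImage:
    """Render a rows x cols matrix of probe droplets on an imaging stage.

    Spots sit on a regular grid with one spacing of margin; those on the
    outermost ring are scaled by ``edge_factor`` (1.0 by default: stage
    curvature has no measurable effect on intensity, so a flat and a curved
    stage render identically up to noise).
    """
    if rows < 2 or cols < 2:
        raise SimulationError("need rows, cols >= 2")
    h, w = grid_shape
    r_pos = np.linspace(h / (rows + 1), h * rows / (rows + 1), rows)
    c_pos = np.linspace(w / (cols + 1), w * cols / (cols + 1), cols)
    if min(r_pos[0], c_pos[0]) < 3 * spot_sigma_px:
        raise SimulationError("droplet grid does not fit in the frame")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rr, cc = np.indices(grid_shape)
    field = np.zeros(grid_shape)
    for i, r in enumerate(r_pos):
        for j, c in enumerate(c_pos):
            amp = spot_intensity * max(0.0, rng.normal(1.0, spot_intensity_cv))
            if i in (0, rows - 1) or j in (0, cols - 1):
                amp *= edge_factor
            field += amp * np.exp(
                -((rr - r) ** 2 + (cc - c) ** 2) / (2 * spot_sigma_px**2)
            )
    if noise_sd_au > 0:
        field = field + rng.normal(0.0, noise_sd_au, grid_shape)
    ncols = grid_shape[1]
    return LumImage(
        pixels=np.clip(field, 0.0, None),
        pixel_size_mm=pixel_size_mm,
        meta=AcquisitionMeta(
            exposure_s=720.0,
            field_of_view_mm=(ncols * pixel_size_mm, grid_shape[0] * pixel_size_mm),
            binning=8,
            modality=LUMINESCENCE,
            subject_id=curvature_label,
        ),
    )
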