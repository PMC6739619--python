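"""End-to-end study orchestration.

``run_study`` reproduces the full analysis flow on a collection of wounds
(in-memory simulated wounds or a manifest directory of image pairs):

1. per-day records — background QC, wound-ROI statistics, cluster metrics
   and vessel metrics for every image pair;
2. longitudinal comparison — per-wound time series, group mean curves, and
   a paired t-test on per-day group means over shared study days;
3. cluster signature — each wound reduced to its maximum-signal day, then
   cluster density and average integrated density compared between groups
   with unpaired t-tests;
4. vessel association — per-wound one-tailed paired t-tests (far > near,
   paired by day) combined into the z statistic; the directional decision
   flag uses the conventional Stouffer combination (see stats_tests).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from . import wound_metrics as wm
from .imaging_core import (
    LUMINESCENCE,
    WHITELIGHT,
    AcquisitionMeta,
    LumImage,
    background_report,
)
from .roi_tools import ROI, roi_stats
from .stats_tests import (
    CombinedZResult,
    StatsError,
    combined_z_test,
    paired_t,
    paired_t_one_tailed,
    unpaired_t,
)
from .synthetic_wound import SimulatedWound


class PipelineError(ValueError):
    """Raised for invalid manifests or insufficient study structure."""


@dataclass(frozen=True)
class AnalysisConfig:
    """Knobs of the per-wound analyses, with study defaults."""

    threshold_fraction: float = wm.DEFAULT_THRESHOLD_FRACTION
    min_area_px: int = wm.DEFAULT_MIN_AREA_PX
    vessel_cutoff_mm: float = wm.DEFAULT_VESSEL_CUTOFF_MM
    qc_limit_au: float = 10.0
    alpha: float = 0.05
    #: wound-level statistic used to pick each wound's maximum-signal day
    max_day_statistic: str = "mean"  # or "peak"


@dataclass
class StudyReport:
    """All tables and test results produced by :func:`run_study`."""

    per_day: pd.DataFrame
    group_curves: pd.DataFrame
    time_course_test: tuple[float, float] | None
    cluster_summary: pd.DataFrame
    density_test: tuple[float, float] | None
    integrated_density_test: tuple[float, float] | None
    vessel_combined: CombinedZResult | None
    vessel_combined_printed: CombinedZResult | None
    far_gt_near_flag: bool | None
    mean_far_near_ratio: float | None
    warnings: list[str] = field(default_factory=list)

    def summary(self) -> dict:
        """JSON-serializable headline numbers."""
        out = {
            "n_wounds": int(self.cluster_summary.shape[0]),
            "mean_far_near_ratio": self.mean_far_near_ratio,
            "far_gt_near_flag": self.far_gt_near_flag,
            "warnings": self.warnings,
        }
        if self.time_course_test:
            out["time_course_paired_t"] = dict(
                zip(("t", "p"), self.time_course_test)
            )
        if self.density_test:
            out["cluster_density_unpaired_t"] = dict(zip(("t", "p"), self.density_test))
        if self.integrated_density_test:
            out["integrated_density_unpaired_t"] = dict(
                zip(("t", "p"), self.integrated_density_test)
            )
        if self.vessel_combined:
            out["vessel_combined_z_stouffer"] = self.vessel_combined.z_s
        if self.vessel_combined_printed:
            out["vessel_combined_z_atanh"] = self.vessel_combined_printed.z_s
        if not self.cluster_summary.empty:
            means = self.cluster_summary.groupby("group")[
                ["clusters_per_cm2", "avg_integrated_density"]
            ].mean()
            out["group_means"] = means.to_dict()
            if {"infected", "control"} <= set(means.index):
                ctrl = means.loc["control", "clusters_per_cm2"]
                if ctrl > 0:
                    out["cluster_density_ratio"] = float(
                        means.loc["infected", "clusters_per_cm2"] / ctrl
                    )
        return out


def analyze_wound_day(
    pair: tuple[LumImage, LumImage],
    wound: ROI,
    config: AnalysisConfig = AnalysisConfig(),
    vessel_mask: np.ndarray | None = None,
) -> dict:
    """Analyze one (white-light, luminescence) pair: QC, ROI stats, clusters, vessels.

    Vessel fields are None when no vessel mask is available.  A luminescence
    frame with no signal is flagged rather than erroring.
    """
    wl, lum = pair
    outside = ~wound.mask
    row: dict = {
        "wound_id": lum.meta.wound_id,
        "subject_id": lum.meta.subject_id,
        "day": lum.meta.day,
    }
    if outside.any():
        bg = background_report(lum.with_pixels(np.where(outside, lum.pixels, 0.0)), config.qc_limit_au)
        row["background_mean_au"] = bg.mean_background_au
        row["background_qc_pass"] = bg.passes_qc
        if not bg.passes_qc:
            row["qc_warning"] = "background above QC limit"
    stats = roi_stats(lum, wound)
    row.update(mean_au=stats.mean_au, total_au=stats.total_au, max_au=stats.max_au)
    cs = wm.detect_clusters(
        lum, wound, threshold_fraction=config.threshold_fraction, min_area_px=config.min_area_px
    )
    row["cluster_count"] = len(cs)
    row["clusters_per_cm2"] = wm.cluster_density(cs)
    row["avg_integrated_density"] = (
        wm.avg_integrated_density(cs) if len(cs) else None
    )
    row["no_signal"] = cs.no_signal
    if vessel_mask is not None and vessel_mask.any():
        part = wm.vessel_partition(
            vessel_mask, wound, lum.pixel_size_mm, cutoff_mm=config.vessel_cutoff_mm
        )
        try:
            near, far, ratio = wm.vessel_association(lum, part)
            row.update(mean_near_au=near, mean_far_au=far, far_near_ratio=ratio)
        except wm.MetricsError:
            row.update(mean_near_au=None, mean_far_au=None, far_near_ratio=None)
    else:
        row.update(mean_near_au=None, mean_far_au=None, far_near_ratio=None)
    return row


def load_study(manifest_path: str | Path) -> list[SimulatedWound]:
    """Load a written study directory back into wound objects.

    Reads the YAML manifest produced by ``synthetic_wound.write_study`` (or
    a hand-written one in the same schema) and reconstructs per-wound image
    series, vessel masks and wound ROIs.  Ground-truth peak records are not
    reloaded (empty tuple).
    """
    import tifffile

    manifest_path = Path(manifest_path)
    root = manifest_path.parent
    manifest = yaml.safe_load(manifest_path.read_text())
    ps = float(manifest["pixel_size_mm"])
    fov = tuple(manifest["field_of_view_mm"])
    wounds: dict[str, dict] = {}
    for rec in manifest["records"]:
        wid = rec["wound_id"]
        entry = wounds.setdefault(
            wid,
            {
                "subject_id": rec["subject_id"],
                "group": rec["group"],
                "images": {},
                "vessel_mask": None,
                "wound_roi": None,
            },
        )
        day = int(rec["day"])
        if day in entry["images"]:
            raise PipelineError(f"duplicate (wound_id, day) = ({wid}, {day})")
        if rec["group"] not in ("infected", "control"):
            raise PipelineError(f"unknown group {rec['group']!r}")
        pairs = {}
        for key, modality, exposure in (
            ("whitelight", WHITELIGHT, 0.1),
            ("luminescence", LUMINESCENCE, float(manifest.get("exposure_s", 1200.0))),
        ):
            meta = AcquisitionMeta(
                exposure_s=exposure,
                field_of_view_mm=fov,
                binning=int(manifest.get("binning", 1)),
                modality=modality,
                day=day,
                subject_id=rec["subject_id"],
                wound_id=wid,
            )
            arr = tifffile.imread(str(root / rec[key])).astype(float)
            pairs[key] = LumImage(pixels=arr, pixel_size_mm=ps, meta=meta)
        entry["images"][day] = (pairs["whitelight"], pairs["luminescence"])
        if entry["vessel_mask"] is None and rec.get("vessel_mask"):
            entry["vessel_mask"] = iio.imread(str(root / rec["vessel_mask"])) > 0
        if entry["wound_roi"] is None and rec.get("wound_roi"):
            entry["wound_roi"] = ROI(
                mask=iio.imread(str(root / rec["wound_roi"])) > 0,
                label=wid,
                provenance="manual_ellipse",
            )
    out = []
    for wid, entry in wounds.items():
        if entry["wound_roi"] is None:
            raise PipelineError(f"wound {wid} has no wound-ROI mask in the manifest")
        from .synthetic_wound import WoundSimConfig

        out.append(
            SimulatedWound(
                wound_id=wid,
                subject_id=entry["subject_id"],
                group=entry["group"],
                config=WoundSimConfig(infected=entry["group"] == "infected"),
                vessel_mask=(
                    entry["vessel_mask"]
                    if entry["vessel_mask"] is not None
                    else np.zeros(entry["wound_roi"].mask.shape, bool)
                ),
                wound_roi=entry["wound_roi"],
                images=entry["images"],
                peaks=(),
            )
        )
    return out


def _max_signal_day(series: pd.DataFrame, statistic: str) -> int:
    col = "mean_au" if statistic == "mean" else "max_au"
    return int(series.loc[series[col].idxmax(), "day"])


def run_study(
    wounds: list[SimulatedWound],
    config: AnalysisConfig = AnalysisConfig(),
) -> StudyReport:
    """Run the full analysis flow over a study and assemble the report.

    Group-level tests need >= 2 wounds per group; when a group is too small
    the corresponding test result is None and a warning is recorded, while
    per-wound tables are still produced.
    """
    if not wounds:
        raise PipelineError("no wounds to analyze")
    warnings: list[str] = []
    rows = []
    for wound in wounds:
        for day in wound.days:
            row = analyze_wound_day(
                wound.images[day], wound.wound_roi, config, vessel_mask=wound.vessel_mask
            )
            row["group"] = wound.group
            row["wound_id"] = wound.wound_id
            rows.append(row)
    per_day = pd.DataFrame(rows).sort_values(["group", "wound_id", "day"]).reset_index(drop=True)

    # (1) longitudinal group curves + paired t over shared days
    group_curves = (
        per_day.groupby(["group", "day"])["mean_au"].mean().rename("group_mean_au").reset_index()
    )
    time_test = None
    pivot = group_curves.pivot(index="day", columns="group", values="group_mean_au")
    n_per_group = per_day.groupby("group")["wound_id"].nunique()
    enough = all(n_per_group.get(g, 0) >= 2 for g in ("infected", "control"))
    if {"infected", "control"} <= set(pivot.columns):
        shared = pivot.dropna()
        if enough and len(shared) >= 2:
            try:
                time_test = paired_t(shared["infected"], shared["control"])
            except StatsError as exc:
                warnings.append(f"time-course paired t failed: {exc}")
        elif not enough:
            warnings.append("need >= 2 wounds per group for the time-course comparison")
    else:
        warnings.append("both groups required for the time-course comparison")

    # (2) cluster signature at each wound's maximum-signal day
    summary_rows = []
    for wound in wounds:
        series = per_day[per_day.wound_id == wound.wound_id]
        day = _max_signal_day(series, config.max_day_statistic)
        rec = series[series.day == day].iloc[0]
        summary_rows.append(
            {
                "wound_id": wound.wound_id,
                "group": wound.group,
                "max_signal_day": day,
                "clusters_per_cm2": rec["clusters_per_cm2"],
                "avg_integrated_density": rec["avg_integrated_density"],
                "far_near_ratio": rec["far_near_ratio"],
            }
        )
    cluster_summary = pd.DataFrame(summary_rows)
    density_test = aid_test = None
    if enough:
        inf = cluster_summary[cluster_summary.group == "infected"]
        ctl = cluster_summary[cluster_summary.group == "control"]
        try:
            density_test = unpaired_t(inf["clusters_per_cm2"], ctl["clusters_per_cm2"])
        except StatsError as exc:
            warnings.append(f"cluster-density t-test failed: {exc}")
        aid_inf = inf["avg_integrated_density"].dropna()
        aid_ctl = ctl["avg_integrated_density"].dropna()
        if len(aid_inf) >= 2 and len(aid_ctl) >= 2:
            try:
                aid_test = unpaired_t(aid_inf, aid_ctl)
            except StatsError as exc:
                warnings.append(f"integrated-density t-test failed: {exc}")
    else:
        warnings.append("need >= 2 wounds per group for cluster-signature tests")

    # (3) vessel association: per-wound far>near paired-by-day tests, combined z
    p_values = []
    for wound in wounds:
        series = per_day[per_day.wound_id == wound.wound_id].dropna(
            subset=["mean_near_au", "mean_far_au"]
        )
        if len(series) < 2:
            continue
        try:
            _, p = paired_t_one_tailed(series["mean_far_au"], series["mean_near_au"])
            p_values.append(p)
        except StatsError as exc:
            warnings.append(f"far/near test failed for {wound.wound_id}: {exc}")
    vessel_combined = vessel_printed = None
    far_flag = None
    # headline ratio: each wound at its maximum-signal day (the same selection
    # rule as the cluster comparisons), averaged over wounds
    maxday_ratios = cluster_summary["far_near_ratio"].dropna()
    mean_ratio = float(maxday_ratios.mean()) if len(maxday_ratios) else None
    if p_values:
        vessel_combined = combined_z_test(p_values, method="stouffer")
        vessel_printed = combined_z_test(
            [min(p, 1 - 1e-12) for p in p_values], method="atanh"
        )
        far_flag = vessel_combined.significant and vessel_combined.z_s > 0
    else:
        warnings.append("no wounds with usable vessel partitions; vessel tests skipped")

    return StudyReport(
        per_day=per_day,
        group_curves=group_curves,
        time_course_test=time_test,
        cluster_summary=cluster_summary,
        density_test=density_test,
        integrated_density_test=aid_test,
        vessel_combined=vessel_combined,
        vessel_combined_printed=vessel_printed,
        far_gt_near_flag=far_flag,
        mean_far_near_ratio=mean_ratio,
        warnings=warnings,
    )
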