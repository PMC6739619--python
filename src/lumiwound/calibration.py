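"""Standard-curve calibration: sensitivity and limit of detection.

A calibration series exposes the imager to known H2O2 concentrations (uM)
with a chemiluminescent ROS probe and records intensity (a.u.) in replicate.
Sensitivity is the slope of the ordinary least-squares line through all
replicate points; the limit of detection follows the 3-sigma rule

    LOD = 3 * sigma_control / slope

where sigma_control is the sample standard deviation (n-1 denominator) of the
blank (0 uM) replicates and slope the fitted sensitivity.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats


class CalibrationError(ValueError):
    """Raised for degenerate calibration input (no spread, non-positive slope...)."""


@dataclass(frozen=True)
class CalibrationSeries:
    """Concentration levels (uM) with >= 1 replicate intensity readings each."""

    concentrations_uM: tuple[float, ...]
    intensities_au: tuple[tuple[float, ...], ...]

    def __post_init__(self) -> None:
        if len(self.concentrations_uM) != len(self.intensities_au):
            raise CalibrationError("one replicate tuple required per concentration")
        if any(c < 0 for c in self.concentrations_uM):
            raise CalibrationError("concentrations must be >= 0")
        if len(set(self.concentrations_uM)) < 2:
            raise CalibrationError("at least 2 distinct concentrations required")
        if any(len(reps) < 1 for reps in self.intensities_au):
            raise CalibrationError("every level needs at least one replicate")

    @property
    def control_replicates(self) -> tuple[float, ...] | None:
        """Replicates of the 0 uM (blank) level, or None if absent."""
        for c, reps in zip(self.concentrations_uM, self.intensities_au):
            if c == 0:
                return reps
        return None

    def points(self) -> tuple[np.ndarray, np.ndarray]:
        """All (concentration, intensity) replicate points, flattened."""
        x = np.concatenate(
            [np.full(len(reps), c) for c, reps in zip(self.concentrations_uM, self.intensities_au)]
        )
        y = np.concatenate([np.asarray(reps, dtype=float) for reps in self.intensities_au])
        return x, y

    @classmethod
    def from_csv(cls, path: str | Path) -> "CalibrationSeries":
        """Load from a CSV with columns concentration_uM, intensity_au[, replicate]."""
        df = pd.read_csv(path)
        groups = df.groupby("concentration_uM")["intensity_au"].apply(tuple)
        return cls(tuple(groups.index), tuple(groups.values))


@dataclass(frozen=True)
class CalibrationResult:
    """OLS fit of the standard curve plus blank statistics.

    slope_k is the sensitivity (a.u./uM); lod_uM = 3*sigma_control/slope_k.
    sigma_control / lod_uM are None when the series has no 0 uM level.
    """

    slope_k: float
    intercept: float
    r_squared: float
    slope_stderr: float
    sigma_control: float | None
    lod_uM: float | None

    def to_dict(self) -> dict:
        return {
            "slope_k_au_per_uM": self.slope_k,
            "intercept_au": self.intercept,
            "r_squared": self.r_squared,
            "slope_stderr": self.slope_stderr,
            "sigma_control_au": self.sigma_control,
            "lod_uM": self.lod_uM,
        }


def lod(sigma: float, slope_k: float) -> float:
    """Limit of detection in uM: ``3 * sigma / slope_k``.

    ``sigma`` is the standard deviation of the blank readings (a.u.) and
    ``slope_k`` the calibration sensitivity (a.u./uM, must be > 0).
    """
    if sigma < 0:
        raise CalibrationError(f"sigma must be >= 0, got {sigma}")
    if slope_k <= 0:
        raise CalibrationError(f"slope must be > 0 to define an LOD, got {slope_k}")
    return 3.0 * sigma / slope_k


def fit_calibration(series: CalibrationSeries) -> CalibrationResult:
    """Fit the standard curve and derive sensitivity, R², sigma_control and LOD.

    Replicates enter the ordinary least-squares fit as individual points.
    When a 0 uM level with >= 2 replicates is present, sigma_control is its
    sample standard deviation and the LOD is computed; a non-positive fitted
    slope then signals a non-responsive probe and is an error.
    """
    x, y = series.points()
    fit = stats.linregress(x, y)
    r_squared = float(fit.rvalue**2)

    control = series.control_replicates
    sigma_control = None
    lod_uM = None
    if control is not None and len(control) >= 2:
        sigma_control = float(np.std(control, ddof=1))
        lod_uM = lod(sigma_control, float(fit.slope))
    return CalibrationResult(
        slope_k=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=r_squared,
        slope_stderr=float(fit.stderr),
        sigma_control=sigma_control,
        lod_uM=lod_uM,
    )
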