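# Methods

## Intensity model and geometry

All intensities are arbitrary camera units (a.u.) held as float64; no
photon-flux calibration is attempted because every downstream statistic is
a ratio, a threshold relative to an in-image maximum, or a regression on a
calibration series in the same units. The pixel grid is row-major, origin
at the top-left pixel center; physical coordinates are `index ×
pixel_size_mm`. Pixels are assumed isotropic, with the pixel size derived
from the declared field-of-view *width* divided by the column count. The
cross-axis (height) consistency check tolerates 3% by default: printed view
areas are typically rounded to three significant figures, and a few percent
of apparent anisotropy is metadata rounding rather than optics. The
tolerance is a parameter (`fov_tol`) for stricter workflows. Background QC
passes when the mean of a no-source frame is strictly below 10 a.u.

## Calibration

Sensitivity is the OLS slope over all replicate points (replicates are not
averaged per level first; with a balanced design the slope is identical,
but the residual degrees of freedom and the slope standard error are
honest). σ of the control is the sample standard deviation (n−1) of the
0 μM replicates, and `LOD = 3σ/κ`. A non-positive fitted slope with a blank
present signals a non-responsive probe and is an error. The slope's
standard error is reported but no claim is made about which uncertainty
estimator produced the published ± values.

## ROIs

Geometric ROIs use pixel-center membership, with centers on a polygon
boundary counting as inside (so a rectangle through a k×k block of centers
contains exactly k² pixels), and a 1e-9 tolerance on the ellipse quadratic
form so that exact 90° rotations reproduce the axis-swapped mask despite
floating-point trig residue. Contiguity is 8-connectivity throughout
(semiauto/auto ROIs and cluster detection). Cross-day ROI extrapolation is
translation-only — the imager re-seats over the same wound between dressing
changes, and no warping is modeled. The translation is found by exhaustive
search of the Pearson correlation over the overlap region for every
candidate integer shift within a quarter of the frame; restricting the
score to the overlap makes recovery exact for rigidly shifted frames, and
the peak correlation doubles as the registration confidence (floor 0.5,
below which extrapolation refuses rather than guessing). Overlay composites
are for visualization only; alpha at each pixel is layer opacity ×
normalized layer intensity, so dark layer pixels leave the base visible.

## Cluster signature

Within the wound ROI, the detection threshold is 70% of the maximum
intensity *inside the wound* (not the whole frame), making the detector
invariant to positive rescaling; clusters are 8-connected supra-threshold
components of at least `min_area_px = 4` pixels (a guard against
single-pixel noise; the choice is configurable and not derived from any
published rule). No smoothing is applied before taking the maximum.
Average integrated density is the unweighted mean over clusters of
(intensity sum / area); an area-weighted pooled variant is available. For
cross-wound comparisons each wound contributes its maximum-signal day,
selected by wound-ROI mean intensity (peak intensity selectable), and
group differences are tested with unpaired Student's t-tests.

## Vessel association

The vessel mask (hand-drawn or Frangi-segmented from white light; scales
floored at 1 px since sub-pixel Gaussians only amplify noise) feeds a
Euclidean distance transform; wound pixels at ≥ 2.5 mm are the capillary
("far") zone and the rest the vessel-proximal ("near") zone — the two tile
the wound exactly. Per wound, far vs near mean intensity is compared by a
one-tailed paired t-test across study days (orientation: far > near,
stated explicitly since the source method leaves it implicit), and the
per-wound p-values are combined. The headline far/near ratio is taken at
each wound's maximum-signal day: at late days the signal decays to the
noise floor, where zero-clipping drags the ratio toward 1 — a detector
floor artifact, not a vascular effect.

## Combined z statistic

The transform is implemented exactly as described at the source:
`Z_i = tanh⁻¹(P_i)`, `Z_s = Σ Z_i/√k`, significant when |Z_s| exceeds the
95% standard-normal bound 1.96. Note the fidelity cost: tanh⁻¹ maps small
(significant) one-tailed p-values toward 0, so this statistic cannot exceed
the bound when the individual tests agree strongly — the conventional
Stouffer combination `Z_i = Φ⁻¹(1−P_i)` behaves as intended and is provided
behind `method="stouffer"`. The pipeline reports both and bases its
directional far > near decision flag on the Stouffer variant, which is the
only one able to flag the effect. The divisor √k follows the textual
description and the comparison to a standard-normal bound.

## Synthetic study generator

The generator emulates the data structure of a porcine full-thickness
excisional wound study: 3-cm circular wounds on a 168×128 px grid at
0.306 mm/px (an 8×8-binned 1344×1024 CCD viewing ≈5.14×3.92 cm), imaged as
white-light/luminescence pairs at days 1, 3, 7, 10, 14, 17, 21, two wounds
per group per animal.

**Vessels.** A random tree of meandering 0.5-mm-wide branches (4 by
default, each possibly spawning a side branch) entering from the wound
boundary, rendered dark on the granulation background with additive noise.
Across seeds the vessel fraction of the wound stays within 1–25%.

**ROS field.** A diffuse base of 30 a.u. in the vessel-proximal zone,
multiplied by the capillary enhancement factor 2.0 in the far zone — so
with no noise and no foci the far/near ratio is exactly 2 by construction.
Discrete ROS foci are isotropic Gaussians placed by a Poisson-rate process
with three structural choices: (1) every wound carries at least one focus
(count = 1 + Poisson(mean−1)), reflecting that an excisional wound is
inflamed by construction and keeping the configured group means — and hence
the infected/control mean ratio of exactly 3 — intact; (2) a 4-mm hard-core
minimum separation keeps foci distinct, since stacked foci raise the
in-wound maximum and mask one another under a relative threshold; (3)
foci avoid the vessel-proximal zone (near-zone placements accepted with
probability 0.25), mirroring ROS delivery through postcapillary venules.
Control foci default to 80 a.u. amplitude and 1.2 mm width; infected foci
are higher and sharper (130 a.u., 0.7 mm) and three times as frequent
(rate multiplier 3 over a control rate of 0.283/cm² ≈ 2 foci per 3-cm
wound; absolute rates are package choices — only the ratio is anchored).
A `radial_falloff` knob can concentrate the bed centrally but defaults to
0: combined with centrally-converging vessel trees it pushes the far zone
toward the dim rim and distorts the far/near recovery.

**Time course.** One static field per wound is scaled by a group profile,
piecewise-linear in log intensity with knots at days 1, 3, 10, 21: controls
peak at day 3 (relative levels 0.5, 1.0, 0.25, 0.05) and decline strictly
thereafter; infected wounds plateau at peak level over days 3–10 (0.5, 1.0,
1.0, 0.3). Additive Gaussian noise (σ = 2 a.u.) is drawn per day and the
field clipped at zero.

**What the generator does not model** — and what passing tests therefore do
not show about real data: optical blur/vignetting, probe kinetics and film
application variability, wound contraction and re-epithelialization,
anisotropic or curved wound surfaces, bacterial growth dynamics, and any
coupling between vessel remodeling and the ROS field over time. Recovery
results on this generator validate the analysis chain, not the biology.

## Problem sizes and numerical choices

The standard synthetic study is 20 infected + 20 control wounds × 7 days
(seed 42), chosen as a comfortably powered scale for the recovery checks;
calibration recovery uses 1000 replicates per level. At this scale the
detected cluster-density ratio lands within ±25% of 3 and the far/near
ratio within ±10% of 2 across the seeds tried during design. Ties in the
max-signal-day selection resolve to the earliest day via argmax; flat
(all-zero) luminescence frames yield an empty cluster set flagged
`no_signal` rather than an error; degenerate vessel geometry (empty near or
far zone, or zero near-zone signal) is signaled explicitly.

## Known limitations

The atanh combined statistic is reported for fidelity but is not a usable
significance decision for concordant small p-values (see above). Vessel
segmentation thresholds (50% of maximum Frangi response) were set against
the generator's rendering style and will need re-tuning for real white-light
photographs. Registration is integer-pixel and translation-only. The
droplet-grid homogeneity test requires the configured spot count to be
found exactly and, for grids with a single interior spot (3×3), reports
only the descriptive edge/center percentage with p = 1 when the groups
agree within 1%.
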