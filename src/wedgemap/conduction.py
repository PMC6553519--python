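"""Conduction velocity and isochrone analysis of activation maps.

The canonical estimator anchors rays at the stimulus site: activation
is sampled along rays at every angle, distance (cm) is regressed on
time (s), and the slope of each passing fit is the apparent speed in
that direction.  The longitudinal CV is the maximum over passing
angles (the fast, fiber-aligned direction) and the transverse CV the
minimum.  Rays are restricted to a 3-15 mm annulus to avoid near-field
wavefront curvature and far-field boundary effects, and are truncated
at the first invalid pixel.

A local gradient-tensor estimator (speed = 1/|grad t| at the extremes
of the slowness distribution) is provided as an independent
cross-check.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.ndimage import map_coordinates
from scipy.stats import linregress
from skimage import measure

from .apd import ScalarMap

__all__ = [
    "CVEstimate",
    "isochrone_map",
    "estimate_cv",
    "estimate_cv_gradient",
    "cv_restitution",
]


@dataclass
class CVEstimate:
    """Longitudinal/transverse conduction velocities with diagnostics."""

    cv_long_cm_s: float
    cv_trans_cm_s: float
    angle_long_deg: float
    angle_trans_deg: float
    r2_long: float
    r2_trans: float
    n_angles_passed: int = 0
    per_angle: Optional[pd.DataFrame] = field(default=None, repr=False)

    @property
    def ratio(self) -> float:
        return self.cv_long_cm_s / self.cv_trans_cm_s

    @property
    def axes_orthogonal(self) -> bool:
        """Soft diagnostic: fast and slow axes within 90 +/- 15 degrees."""
        d = abs(self.angle_long_deg - self.angle_trans_deg) % 180.0
        return abs(d - 90.0) <= 15.0

    def to_dict(self) -> dict:
        return {
            "cv_long_cm_s": self.cv_long_cm_s,
            "cv_trans_cm_s": self.cv_trans_cm_s,
            "angle_long_deg": self.angle_long_deg,
            "angle_trans_deg": self.angle_trans_deg,
            "r2_long": self.r2_long,
            "r2_trans": self.r2_trans,
            "ratio": self.ratio,
            "n_angles_passed": self.n_angles_passed,
        }


def isochrone_map(
    activation: ScalarMap, spacing_ms: float = 5.0
) -> dict[float, list[np.ndarray]]:
    """Activation contours at multiples of ``spacing_ms``.

    Returns {level_ms: [contour arrays of (row, col) points]}, ordered
    early to late.  Empty input gives an empty set.
    """
    if spacing_ms <= 0:
        raise ValueError("isochrone spacing must be positive")
    values = activation.values
    finite = np.isfinite(values)
    if not finite.any():
        return {}
    lo, hi = np.nanmin(values), np.nanmax(values)
    levels = np.arange(np.ceil(lo / spacing_ms), np.floor(hi / spacing_ms) + 1)
    out: dict[float, list[np.ndarray]] = {}
    work = np.where(finite, values, np.nan)
    for lev in levels * spacing_ms:
        contours = measure.find_contours(work, lev)
        if contours:
            out[float(lev)] = contours
    return out


def _sample_ray(
    values: np.ndarray,
    site: tuple[int, int],
    angle_deg: float,
    radii_px: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Bilinear samples of the map along one ray; truncated at first gap."""
    th = math.radians(angle_deg)
    rows = site[0] + radii_px * math.sin(th)
    cols = site[1] + radii_px * math.cos(th)
    t = map_coordinates(values, [rows, cols], order=1, cval=np.nan)
    bad = ~np.isfinite(t)
    if bad.any():
        first = int(np.argmax(bad))
        t, radii_px = t[:first], radii_px[:first]
    return radii_px, t


def estimate_cv(
    activation: ScalarMap,
    stimulus_site: tuple[int, int],
    angle_step_deg: float = 5.0,
    r_min_mm: float = 3.0,
    r_max_mm: float = 15.0,
    min_points: int = 8,
    min_r2: float = 0.9,
    angle_smooth: int = 3,
) -> CVEstimate:
    """Ray-regression CV estimate anchored at the stimulus site.

    For each angle, activation times are sampled along the ray at pixel
    steps within [r_min, r_max] mm, and distance (cm) is regressed on
    time (s); the slope is the apparent conduction speed in that
    direction.  Angles failing the R^2 or point-count gates are
    discarded.  The fastest/slowest directions are selected on a
    circularly smoothed per-angle speed profile (``angle_smooth``
    neighbouring rays; 1 disables), which suppresses the upward bias of
    extreme-value selection on noisy maps, but the reported speed is
    the unsmoothed ray fit at the selected angle.  Raises if no angle
    passes.
    """
    values = activation.values
    spacing = activation.pixel_spacing_mm
    if not np.isfinite(values[stimulus_site]):
        raise ValueError("stimulus site must lie in the valid region")
    radii_px = np.arange(r_min_mm / spacing, r_max_mm / spacing + 1e-9, 1.0)
    rows = []
    for ang in np.arange(0.0, 360.0, angle_step_deg):
        r_px, t_ms = _sample_ray(values, stimulus_site, ang, radii_px)
        if len(r_px) < min_points:
            continue
        if np.ptp(t_ms) <= 0:
            continue
        dist_cm = r_px * spacing / 10.0
        fit = linregress(t_ms / 1000.0, dist_cm)
        r2 = fit.rvalue**2
        if r2 < min_r2 or fit.slope <= 0:
            continue
        rows.append((ang, fit.slope, r2, len(r_px)))
    if not rows:
        raise ValueError(
            "no ray passed the quality gates "
            f"(min_points={min_points}, min_r2={min_r2})"
        )
    per_angle = pd.DataFrame(rows, columns=["angle_deg", "cv_cm_s", "r2", "n_points"])
    speeds = per_angle["cv_cm_s"].to_numpy()
    if angle_smooth > 1 and len(speeds) >= angle_smooth:
        kernel = np.ones(angle_smooth) / angle_smooth
        pad = angle_smooth // 2
        wrapped = np.r_[speeds[-pad:], speeds, speeds[:pad]]
        speeds = np.convolve(wrapped, kernel, mode="valid")
    per_angle["cv_smooth_cm_s"] = speeds
    i_max = int(per_angle["cv_smooth_cm_s"].idxmax())
    i_min = int(per_angle["cv_smooth_cm_s"].idxmin())
    est = CVEstimate(
        cv_long_cm_s=float(per_angle.loc[i_max, "cv_cm_s"]),
        cv_trans_cm_s=float(per_angle.loc[i_min, "cv_cm_s"]),
        angle_long_deg=float(per_angle.loc[i_max, "angle_deg"]),
        angle_trans_deg=float(per_angle.loc[i_min, "angle_deg"]),
        r2_long=float(per_angle.loc[i_max, "r2"]),
        r2_trans=float(per_angle.loc[i_min, "r2"]),
        n_angles_passed=len(per_angle),
        per_angle=per_angle,
    )
    if not est.axes_orthogonal:
        warnings.warn(
            "fast and slow directions are not near-orthogonal "
            f"({est.angle_long_deg:.0f} vs {est.angle_trans_deg:.0f} deg)"
        )
    return est


def estimate_cv_gradient(
    activation: ScalarMap,
    stimulus_site: tuple[int, int],
    r_min_mm: float = 3.0,
    r_max_mm: float = 15.0,
    percentile: float = 0.5,
) -> tuple[float, float]:
    """Gradient-based (cv_long, cv_trans) in cm/s — independent cross-check.

    Local speed is the inverse gradient magnitude of the activation map
    (ms/mm -> mm/ms); within the analysis annulus the fastest and
    slowest robust extremes (percentiles) of the speed distribution
    approximate CV along the principal axes of the wavefront.
    """
    values = activation.values
    spacing = activation.pixel_spacing_mm
    gy, gx = np.gradient(values, spacing)
    slowness = np.hypot(gy, gx)  # ms/mm
    h, w = values.shape
    rows, cols = np.mgrid[0:h, 0:w]
    r_mm = np.hypot(rows - stimulus_site[0], cols - stimulus_site[1]) * spacing
    sel = (r_mm >= r_min_mm) & (r_mm <= r_max_mm) & np.isfinite(slowness) & (slowness > 0)
    if not sel.any():
        raise ValueError("no valid pixels in the analysis annulus")
    speed = 100.0 / slowness[sel]  # mm/ms -> cm/s
    return (
        float(np.percentile(speed, 100.0 - percentile)),
        float(np.percentile(speed, percentile)),
    )


def cv_restitution(estimates: dict[float, CVEstimate]) -> pd.DataFrame:
    """CV-vs-BCL table from per-frequency estimates.

    ``estimates`` maps pacing frequency (Hz) to a CVEstimate; at least 3
    frequencies are required.  BCL = 1000/frequency ms.  Missing
    frequencies are simply absent rows.
    """
    valid = {f: e for f, e in estimates.items() if e is not None}
    if len(valid) < 3:
        raise ValueError("cv_restitution requires estimates at >= 3 frequencies")
    rows = [
        {
            "frequency_hz": f,
            "bcl_ms": 1000.0 / f,
            "cv_long_cm_s": e.cv_long_cm_s,
            "cv_trans_cm_s": e.cv_trans_cm_s,
            "ratio": e.ratio,
        }
        for f, e in sorted(valid.items())
    ]
    return pd.DataFrame(rows).sort_values("bcl_ms", ascending=False).reset_index(drop=True)
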