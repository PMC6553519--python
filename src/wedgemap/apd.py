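"""Activation-time, repolarization-time and APD80 mapping.

Per-pixel measurements on normalized, upstroke-positive optical traces:

* activation time (AT) — the time of maximal upstroke dF/dt, refined by
  parabolic interpolation around the discrete derivative maximum and
  reported relative to the stimulus of the analyzed beat;
* repolarization time (RT) — the first downward crossing, after the
  peak, of baseline + (1 - level) * amplitude, located by linear
  interpolation between samples (level = 0.80 for APD80); amplitude is
  referenced to the pre-upstroke baseline, not the plateau;
* APD = RT - AT wherever both are defined.

The scalar operators and the vectorized whole-map path share a single
kernel, so a per-pixel loop reproduces the map bit for bit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .preprocessing import BeatWindows, MovieStack, QualityMask

__all__ = [
    "ScalarMap",
    "ROISpec",
    "DispersionResult",
    "activation_time",
    "repolarization_time",
    "apd_map",
    "roi_mean",
    "dispersion",
    "default_rois",
]


@dataclass
class ScalarMap:
    """A per-pixel map (ms) with NaN marking missing/invalid pixels."""

    values: np.ndarray  # H x W float64
    kind: str  # activation | repolarization | apd80
    pixel_spacing_mm: float = 1.0
    reference_time_ms: float = 0.0  # stimulus time the map is relative to
    beat_index: Optional[int] = None
    frequency_hz: Optional[float] = None
    meta: dict = field(default_factory=dict)

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.values)

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())

    def nanmean(self) -> float:
        return float(np.nanmean(self.values))


@dataclass
class ROISpec:
    """A square region of interest, 5 x 5 mm by convention.

    ``center_mm`` is (y, x) in mm from the top-left pixel center, with
    the wedge long axis (base -> apex) along y/rows.
    """

    label: str  # base | mid | apex | custom
    center_mm: tuple[float, float]
    side_mm: float = 5.0

    def __post_init__(self) -> None:
        if self.side_mm <= 0:
            raise ValueError("ROI side must be positive")

    def pixel_slices(self, spacing_mm: float, shape: tuple[int, int]):
        # pixels whose centers fall inside the square
        half = self.side_mm / 2.0
        r0 = int(np.ceil((self.center_mm[0] - half) / spacing_mm - 1e-9))
        c0 = int(np.ceil((self.center_mm[1] - half) / spacing_mm - 1e-9))
        n = max(int(round(self.side_mm / spacing_mm)), 1)
        r1, c1 = r0 + n, c0 + n
        if r0 < 0 or c0 < 0 or r1 > shape[0] or c1 > shape[1]:
            raise ValueError(f"ROI {self.label} extends outside the grid")
        return slice(r0, r1), slice(c0, c1)


@dataclass
class DispersionResult:
    """Spatial dispersion of a map over valid pixels."""

    sd: float  # ms, primary metric
    p5_95_range: float  # ms, robust secondary metric
    n_pixels: int
    kind: str = "apd80"
    surface: str = ""


def default_rois(
    grid_shape: tuple[int, int], pixel_spacing_mm: float, side_mm: float = 5.0
) -> dict[str, ROISpec]:
    """Base / mid free wall / apex ROIs at 20/50/80% of the long axis."""
    h, w = grid_shape
    long_mm = h * pixel_spacing_mm
    x_mid = (w - 1) * pixel_spacing_mm / 2.0
    return {
        label: ROISpec(label, (frac * long_mm, x_mid), side_mm)
        for label, frac in (("base", 0.2), ("mid", 0.5), ("apex", 0.8))
    }


# ----------------------------------------------------------------------
# Shared kernel
# ----------------------------------------------------------------------

def _at_rt_kernel(
    seg: np.ndarray,
    dt_ms: float,
    t0_ms: float,
    level: float = 0.80,
    min_amplitude: float = 0.5,
):
    """Measure AT and RT on a (T, N) block of traces.

    Returns absolute times in ms (NaN where undefined).  Baseline is the
    mean of samples more than 3 frames before the discrete upstroke;
    traces whose peak-to-baseline amplitude is below ``min_amplitude``
    (no upstroke) are missing.
    """
    seg = np.asarray(seg, dtype=np.float64)
    nt, n = seg.shape
    if nt < 4:
        nan = np.full(n, np.nan)
        return nan, nan.copy()

    d = seg[1:] - seg[:-1]
    k = np.argmax(d, axis=0)
    cols = np.arange(n)

    # parabolic refinement of the derivative maximum (half-sample grid)
    ki = np.clip(k, 1, nt - 3)
    dm, d0, dp = d[ki - 1, cols], d[ki, cols], d[ki + 1, cols]
    denom = dm - 2.0 * d0 + dp
    with np.errstate(divide="ignore", invalid="ignore"):
        delta = np.where(np.abs(denom) > 1e-12, 0.5 * (dm - dp) / denom, 0.0)
    delta = np.clip(delta, -0.5, 0.5)
    at_idx = ki + 0.5 + delta
    at = t0_ms + at_idx * dt_ms

    # baseline from the pre-upstroke segment
    csum = np.cumsum(seg, axis=0)
    m = np.clip(k - 3, 1, nt)
    baseline = csum[m - 1, cols] / m

    p_idx = np.argmax(seg, axis=0)
    peak = seg[p_idx, cols]
    amp = peak - baseline
    ok = amp >= min_amplitude
    at = np.where(ok, at, np.nan)

    # first downward crossing of baseline + (1 - level) * amplitude
    thr = baseline + (1.0 - level) * amp
    idx = np.arange(nt)[:, None]
    below = (seg < thr[None, :]) & (idx > p_idx[None, :])
    has = below.any(axis=0)
    j = np.argmax(below, axis=0)
    jm = np.clip(j - 1, 0, nt - 1)
    prev, cur = seg[jm, cols], seg[j, cols]
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(prev != cur, (prev - thr) / (prev - cur), 0.0)
    rt = t0_ms + (jm + np.clip(frac, 0.0, 1.0)) * dt_ms
    rt = np.where(ok & has, rt, np.nan)
    return at, rt


def activation_time(
    trace: np.ndarray,
    dt_ms: float,
    t0_ms: float = 0.0,
    stimulus_ms: float = 0.0,
    min_amplitude: float = 0.5,
) -> float:
    """Activation time of a single-beat trace, relative to its stimulus."""
    at, _ = _at_rt_kernel(
        np.asarray(trace, dtype=np.float64)[:, None], dt_ms, t0_ms,
        min_amplitude=min_amplitude,
    )
    return float(at[0] - stimulus_ms)


def repolarization_time(
    trace: np.ndarray,
    dt_ms: float,
    t0_ms: float = 0.0,
    stimulus_ms: float = 0.0,
    level: float = 0.80,
    min_amplitude: float = 0.5,
) -> float:
    """Time of the ``level``-repolarization crossing, relative to the stimulus."""
    _, rt = _at_rt_kernel(
        np.asarray(trace, dtype=np.float64)[:, None], dt_ms, t0_ms,
        level=level, min_amplitude=min_amplitude,
    )
    return float(rt[0] - stimulus_ms)


# ----------------------------------------------------------------------
# Whole-map measurement
# ----------------------------------------------------------------------

def apd_map(
    movie: MovieStack,
    mask: Optional[QualityMask],
    windows: BeatWindows,
    beat: int,
    level: float = 0.80,
    region: Optional[tuple[slice, slice]] = None,
    low_quality_fraction: float = 0.5,
    lead_ms: float = 5.0,
) -> tuple[ScalarMap, ScalarMap, ScalarMap]:
    """APD80, activation and repolarization maps for one beat.

    ``beat`` indexes ``windows``.  Masked-out pixels are NaN everywhere.
    ``region`` restricts computation to a (row-slice, col-slice) crop
    (full-size maps are still returned, NaN outside the crop).  The
    analysis segment opens ``lead_ms`` before the stimulus so pixels
    that activate immediately (at the pacing site) keep a pre-upstroke
    baseline.  If more than ``low_quality_fraction`` of in-mask pixels
    are missing the maps are flagged ``low_quality`` in their metadata.
    """
    h, w = movie.grid_shape
    dt = movie.frame_interval_ms
    i0 = max(int((windows.start_ms[beat] - lead_ms) / dt), 0)
    # extend past non-capturing stimuli (2:1 block): the AP of this beat
    # ends only before the next *captured* beat
    nxt = beat + 1
    while nxt < len(windows) and not windows.captured[nxt]:
        nxt += 1
    end_ms = windows.start_ms[nxt] if nxt < len(windows) else movie.duration_ms
    i1 = min(int(np.ceil(end_ms / dt)), movie.n_frames)
    stim = float(windows.stimulus_time_ms[beat])
    rs, cs = region if region is not None else (slice(0, h), slice(0, w))

    seg = movie.frames[i0:i1, rs, cs].astype(np.float64)
    nt = seg.shape[0]
    block = seg.reshape(nt, -1)
    at, rt = _at_rt_kernel(block, dt, i0 * dt, level=level)

    def _full(vec: np.ndarray) -> np.ndarray:
        out = np.full((h, w), np.nan)
        out[rs, cs] = vec.reshape(seg.shape[1], seg.shape[2])
        return out

    at_map = _full(at) - stim
    rt_map = _full(rt) - stim
    if mask is not None:
        at_map[~mask.valid] = np.nan
        rt_map[~mask.valid] = np.nan
    apd = rt_map - at_map

    meta: dict = {}
    if mask is not None:
        inside = mask.valid[rs, cs]
        n_inside = int(inside.sum())
        n_missing = int(np.isnan(apd[rs, cs][inside]).sum()) if n_inside else 0
        if n_inside and n_missing / n_inside > low_quality_fraction:
            meta["low_quality"] = True
            warnings.warn("more than half of in-mask pixels are missing; map flagged")

    freq = windows.frequency_hz[beat]
    common = dict(
        pixel_spacing_mm=movie.pixel_spacing_mm,
        reference_time_ms=stim,
        beat_index=int(beat),
        frequency_hz=None if np.isnan(freq) else float(freq),
    )
    return (
        ScalarMap(apd, "apd80", meta=dict(meta), **common),
        ScalarMap(at_map, "activation", meta=dict(meta), **common),
        ScalarMap(rt_map, "repolarization", meta=dict(meta), **common),
    )


def roi_mean(smap: ScalarMap, roi: ROISpec, min_coverage: float = 0.5) -> float:
    """Mean of valid pixels in a square ROI; NaN below 50% coverage."""
    rs, cs = roi.pixel_slices(smap.pixel_spacing_mm, smap.values.shape)
    patch = smap.values[rs, cs]
    n_total = patch.size
    n_valid = int(np.isfinite(patch).sum())
    if n_total == 0 or n_valid / n_total < min_coverage:
        warnings.warn(
            f"ROI {roi.label}: only {n_valid}/{n_total} valid pixels; mean is missing"
        )
        return float("nan")
    return float(np.nanmean(patch))


def dispersion(
    smap: ScalarMap,
    mask: Optional[QualityMask] = None,
    min_pixels: int = 100,
    surface: str = "",
) -> DispersionResult:
    """Spatial SD (primary) and 5th-95th percentile range over valid pixels."""
    values = smap.values.copy()
    if mask is not None:
        values[~mask.valid] = np.nan
    v = values[np.isfinite(values)]
    if v.size < min_pixels:
        warnings.warn(f"only {v.size} valid pixels (<{min_pixels}); dispersion missing")
        return DispersionResult(float("nan"), float("nan"), int(v.size), smap.kind, surface)
    p5, p95 = np.percentile(v, [5.0, 95.0])
    return DispersionResult(
        sd=float(v.std(ddof=1)),
        p5_95_range=float(p95 - p5),
        n_pixels=int(v.size),
        kind=smap.kind,
        surface=surface,
    )
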