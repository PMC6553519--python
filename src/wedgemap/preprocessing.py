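"""Movie loading, calibration, denoising, normalization and beat segmentation.

The raw input is a T x H x W fluorescence stack (multi-page TIFF of
uint16 counts) with a JSON metadata sidecar carrying the physical
calibration (frame interval in ms, pixel spacing in mm), the imaged
surface, the dye polarity, and the pacing schedule.  Voltage-sensitive
dyes such as di-4-ANEPPS *decrease* fluorescence on depolarization, so
the default polarity is ``inverted``; normalization re-inverts the
signal to an upstroke-positive convention with per-beat resting level
~0 and peak ~1.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import tifffile
from scipy.ndimage import gaussian_filter
from scipy.signal import savgol_filter
from skimage.draw import polygon2mask

from .pacing import PacingProtocol

__all__ = [
    "MovieStack",
    "QualityMask",
    "BeatWindows",
    "MovieFormatError",
    "load_movie",
    "write_movie",
    "write_results",
    "normalize",
    "filter_movie",
    "build_quality_mask",
    "segment_beats",
]


class MovieFormatError(RuntimeError):
    """Raised when a movie on disk is inconsistent with its sidecar."""


@dataclass
class MovieStack:
    """A calibrated fluorescence recording of one wedge surface."""

    frames: np.ndarray  # T x H x W
    frame_interval_ms: float
    pixel_spacing_mm: float
    pacing: PacingProtocol
    surface: str = "epicardium"  # epicardium | endocardium
    polarity: str = "inverted"  # normal | inverted
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.frames.ndim != 3:
            raise ValueError("frames must be a T x H x W array")
        if self.frame_interval_ms <= 0 or self.pixel_spacing_mm <= 0:
            raise ValueError("frame interval and pixel spacing must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    @property
    def times_ms(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval_ms

    @property
    def duration_ms(self) -> float:
        return self.n_frames * self.frame_interval_ms

    def copy_with(self, frames: np.ndarray, **updates) -> "MovieStack":
        kw = dict(
            frames=frames,
            frame_interval_ms=self.frame_interval_ms,
            pixel_spacing_mm=self.pixel_spacing_mm,
            pacing=self.pacing,
            surface=self.surface,
            polarity=self.polarity,
            meta=dict(self.meta),
        )
        kw.update(updates)
        return MovieStack(**kw)


@dataclass
class QualityMask:
    """Per-pixel validity derived from SNR plus an optional manual contour.

    Pixels outside the contour are invalid; invalid pixels propagate as
    missing values through every downstream map and statistic.
    """

    valid: np.ndarray  # H x W bool
    snr: np.ndarray  # H x W float
    manual_contour: Optional[list[tuple[float, float]]] = None  # (x_mm, y_mm)

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())


@dataclass
class BeatWindows:
    """Per-stimulus analysis windows aligned to the pacing schedule."""

    start_ms: np.ndarray
    end_ms: np.ndarray
    stimulus_time_ms: np.ndarray
    stimulus_index: np.ndarray
    frequency_hz: np.ndarray  # NaN for S1-S2 protocols
    label: np.ndarray  # 's1' | 's2'
    coupling_ms: np.ndarray  # NaN except on S2 beats
    captured: np.ndarray  # bool, from the optical signal

    def __len__(self) -> int:
        return len(self.start_ms)

    def steady_state(self, last_n: int = 5) -> np.ndarray:
        """Indices of the last ``last_n`` captured beats of each frequency."""
        keep: list[int] = []
        for f in np.unique(self.frequency_hz[~np.isnan(self.frequency_hz)]):
            idx = np.where((self.frequency_hz == f) & self.captured)[0]
            keep.extend(idx[-last_n:])
        return np.array(sorted(keep), dtype=int)


# ----------------------------------------------------------------------
# I/O
# ----------------------------------------------------------------------

def write_movie(movie: MovieStack, out_dir, stem: str = "movie") -> Path:
    """Write a movie as multi-page uint16 TIFF plus JSON sidecar.

    Returns the directory written to.  Frames are stored as uint16
    counts; writing a float movie quantizes it.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    frames = movie.frames
    if frames.dtype != np.uint16:
        frames = np.clip(np.round(frames), 0, 65535).astype(np.uint16)
    tifffile.imwrite(out_dir / f"{stem}.tif", frames)
    sidecar = {
        "n_frames": int(movie.n_frames),
        "frame_interval_ms": float(movie.frame_interval_ms),
        "pixel_spacing_mm": float(movie.pixel_spacing_mm),
        "surface": movie.surface,
        "polarity": movie.polarity,
        "pacing": movie.pacing.model_dump(),
    }
    (out_dir / f"{stem}.json").write_text(json.dumps(sidecar, indent=1))
    return out_dir


def load_movie(path, stem: str = "movie") -> MovieStack:
    """Load a movie written by :func:`write_movie`.

    ``path`` may be the directory or the TIFF file itself.  A missing
    sidecar or a TIFF page count disagreeing with the sidecar raises
    :class:`MovieFormatError` rather than silently defaulting.
    """
    path = Path(path)
    if path.is_dir():
        tif_path = path / f"{stem}.tif"
    else:
        tif_path = path
    sidecar_path = tif_path.with_suffix(".json")
    if not tif_path.exists():
        raise MovieFormatError(f"movie TIFF not found: {tif_path}")
    if not sidecar_path.exists():
        raise MovieFormatError(f"metadata sidecar not found: {sidecar_path}")
    meta = json.loads(sidecar_path.read_text())
    frames = tifffile.imread(tif_path)
    if frames.ndim == 2:
        frames = frames[None]
    if frames.shape[0] != meta["n_frames"]:
        raise MovieFormatError(
            f"TIFF has {frames.shape[0]} pages but sidecar declares {meta['n_frames']}"
        )
    return MovieStack(
        frames=frames,
        frame_interval_ms=meta["frame_interval_ms"],
        pixel_spacing_mm=meta["pixel_spacing_mm"],
        pacing=PacingProtocol(**meta["pacing"]),
        surface=meta["surface"],
        polarity=meta["polarity"],
    )


def write_results(out_dir, artifacts: dict) -> Path:
    """Write a dict of analysis artifacts to ``out_dir``.

    Dispatch is by type: 2-D float arrays go to float32 TIFF + CSV,
    DataFrames to CSV, everything JSON-serializable to a single
    ``summary.json``.
    """
    import pandas as pd

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    summary: dict = {}
    for name, obj in artifacts.items():
        if isinstance(obj, np.ndarray) and obj.ndim == 2:
            tifffile.imwrite(out_dir / f"{name}.tif", obj.astype(np.float32))
            rows, cols = np.nonzero(np.isfinite(obj))
            pd.DataFrame(
                {"row": rows, "col": cols, "value": obj[rows, cols]}
            ).to_csv(out_dir / f"{name}.csv", index=False)
        elif isinstance(obj, pd.DataFrame):
            obj.to_csv(out_dir / f"{name}.csv", index=False)
        else:
            summary[name] = obj
    if summary:
        (out_dir / "summary.json").write_text(json.dumps(summary, indent=1, default=float))
    return out_dir


# ----------------------------------------------------------------------
# Signal conditioning
# ----------------------------------------------------------------------

def _window_bounds(
    movie: MovieStack, captured: Optional[np.ndarray] = None
) -> tuple[np.ndarray, np.ndarray]:
    """Frame-index boundaries of per-stimulus windows covering the movie.

    Window i runs from stimulus i to stimulus i+1 (the last one to the
    end of the recording); the first window is extended back to frame 0
    so every frame belongs to exactly one window.  When per-stimulus
    ``captured`` flags are given, windows of non-capturing stimuli are
    merged into the preceding window: on a 2:1 blocked rhythm the action
    potential outlasts the blocked stimulus, and the enclosing window
    must still contain a full AP plus diastole.
    """
    stim = movie.pacing.stimulus_times()
    keep = stim < movie.duration_ms
    stim = stim[keep]
    if captured is not None:
        cap = np.asarray(captured, dtype=bool)[: len(stim)].copy()
        cap[0] = True
        stim = stim[cap]
    starts = np.floor(stim / movie.frame_interval_ms).astype(int)
    starts[0] = 0
    ends = np.append(starts[1:], movie.n_frames)
    return starts, ends


def normalize(
    movie: MovieStack,
    captured: Optional[np.ndarray] = None,
    flat_tol: float = 1e-9,
) -> MovieStack:
    """Polarity-correct and rescale each pixel to [0, 1] per beat.

    The per-beat baseline is the 5th percentile of the window and the
    amplitude the window maximum minus baseline, which tolerates slow
    photobleaching-like drift.  ``captured`` (per-stimulus flags, e.g.
    from :func:`segment_beats`) merges the windows of non-capturing
    stimuli into the preceding beat so blocked rhythms normalize on
    whole action potentials.  Pixels whose amplitude is ~0 on every
    beat are left at zero and recorded in ``meta['flat_pixels']``; they
    are flagged invalid downstream rather than raising.
    """
    x = movie.frames.astype(np.float64)
    if movie.polarity == "inverted":
        x = -x
    starts, ends = _window_bounds(movie, captured)
    out = np.empty_like(x, dtype=np.float32)
    global_scale = float(np.ptp(x)) or 1.0
    flat = np.ones(movie.grid_shape, dtype=bool)
    for i0, i1 in zip(starts, ends):
        seg = x[i0:i1]
        base = np.percentile(seg, 5.0, axis=0)
        amp = seg.max(axis=0) - base
        ok = amp > flat_tol * global_scale
        flat &= ~ok
        amp_safe = np.where(ok, amp, 1.0)
        out[i0:i1] = np.where(ok, (seg - base) / amp_safe, 0.0).astype(np.float32)
    meta = dict(movie.meta)
    meta["flat_pixels"] = flat
    return movie.copy_with(out, polarity="normal", meta=meta)


def filter_movie(
    movie: MovieStack,
    spatial_sigma_mm: float = 1.0,
    temporal_window_ms: float = 5.0,
    polyorder: int = 2,
) -> MovieStack:
    """Gaussian spatial smoothing plus Savitzky-Golay temporal smoothing.

    ``spatial_sigma_mm=0`` and ``temporal_window_ms=0`` are each exact
    identities.  A temporal window shorter than 3 samples (but nonzero)
    is a parameter error.
    """
    if spatial_sigma_mm < 0 or temporal_window_ms < 0:
        raise ValueError("smoothing parameters must be non-negative")
    frames = movie.frames.astype(np.float32)
    if spatial_sigma_mm > 0:
        sigma_px = spatial_sigma_mm / movie.pixel_spacing_mm
        frames = gaussian_filter(frames, sigma=(0.0, sigma_px, sigma_px), mode="nearest")
    if temporal_window_ms > 0:
        win = int(round(temporal_window_ms / movie.frame_interval_ms))
        if win < 3:
            raise ValueError(
                f"temporal window {temporal_window_ms} ms is shorter than 3 samples"
            )
        if win % 2 == 0:
            win += 1
        frames = savgol_filter(frames, win, min(polyorder, win - 1), axis=0).astype(
            np.float32
        )
    return movie.copy_with(frames)


def _baseline_noise_sd(x: np.ndarray, movie: MovieStack) -> np.ndarray:
    """Per-pixel noise SD from the quiescent pre-stimulus segment.

    Uses first differences (divided by sqrt(2)) so a residual slow trend
    does not inflate the estimate.  Falls back to the first 10 frames if
    the recording starts at the first stimulus.
    """
    first_stim = movie.pacing.stimulus_times()[0]
    n0 = int(first_stim / movie.frame_interval_ms)
    n0 = max(min(n0, x.shape[0]), 10)
    seg = x[:n0]
    return np.diff(seg, axis=0).std(axis=0) / np.sqrt(2.0)


def build_quality_mask(
    movie: MovieStack,
    snr_threshold: float = 3.0,
    manual_contour: Optional[list[tuple[float, float]]] = None,
) -> QualityMask:
    """Automatic SNR gate plus optional manual exclusion contour.

    SNR is the beat-averaged action-potential amplitude over the
    baseline noise SD; the amplitude is read off a lightly smoothed
    trace so window maxima are not inflated by the very noise being
    gated on (the ratio is invariant to per-pixel scaling, so raw and
    normalized movies give the same mask).  ``manual_contour`` is a
    polygon in mm coordinates (x, y); pixels outside it are invalid
    regardless of SNR, mirroring the manual contouring used to reject
    low-quality optical signals.
    """
    if snr_threshold <= 0:
        raise ValueError("snr_threshold must be positive")
    x = movie.frames.astype(np.float32)
    if movie.polarity == "inverted":
        x = -x
    noise = _baseline_noise_sd(x, movie)
    smooth = savgol_filter(x, 11, 2, axis=0) if movie.n_frames >= 11 else x
    starts, ends = _window_bounds(movie)
    # robust amplitude: the 5th-95th percentile span of the smoothed
    # window tracks the AP excursion without the noise-inflated maximum
    amps = [
        np.percentile(smooth[i0:i1], 95.0, axis=0)
        - np.percentile(smooth[i0:i1], 5.0, axis=0)
        for i0, i1 in zip(starts, ends)
    ]
    amp = np.mean(amps, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        snr = np.where(noise > 0, amp / np.where(noise > 0, noise, 1.0), np.inf)
    snr = np.where(amp > 0, snr, 0.0)
    valid = snr >= snr_threshold
    if manual_contour is not None:
        poly_px = [
            (y / movie.pixel_spacing_mm, xx / movie.pixel_spacing_mm)
            for xx, y in manual_contour
        ]
        inside = polygon2mask(movie.grid_shape, poly_px)
        valid &= inside
    flat = movie.meta.get("flat_pixels")
    if flat is not None:
        valid &= ~flat
    if not valid.any():
        warnings.warn("quality mask is empty; downstream statistics will be missing")
    return QualityMask(valid=valid, snr=snr, manual_contour=manual_contour)


def segment_beats(
    movie: MovieStack,
    mask: Optional[QualityMask] = None,
    capture_window_ms: float = 100.0,
    capture_rise: float = 0.4,
) -> BeatWindows:
    """One analysis window per stimulus, with optical capture flags.

    Expects a normalized movie.  A beat is flagged captured when the
    masked global-mean trace rises by at least ``capture_rise`` above
    its value at the stimulus within ``capture_window_ms``.  Stimuli
    beyond the end of the recording are dropped with a warning.
    """
    table = movie.pacing.stimulus_table()
    in_range = table["time_ms"] < movie.duration_ms
    if not in_range.all():
        warnings.warn(
            f"{(~in_range).sum()} stimuli fall beyond the recording end; dropped"
        )
        table = table[in_range].reset_index(drop=True)
    stim = table["time_ms"].to_numpy()
    starts = stim.copy()
    ends = np.append(stim[1:], movie.duration_ms)
    if mask is not None and mask.valid.any():
        trace = movie.frames[:, mask.valid].mean(axis=1)
    else:
        trace = movie.frames.reshape(movie.n_frames, -1).mean(axis=1)
    dt = movie.frame_interval_ms
    captured = np.zeros(len(stim), dtype=bool)
    for i, t in enumerate(stim):
        i0 = int(t / dt)
        i1 = min(int((t + capture_window_ms) / dt) + 1, movie.n_frames)
        if i1 - i0 < 2:
            continue
        captured[i] = trace[i0:i1].max() - trace[i0] >= capture_rise
    return BeatWindows(
        start_ms=starts,
        end_ms=ends,
        stimulus_time_ms=stim,
        stimulus_index=np.arange(len(stim)),
        frequency_hz=table["frequency_hz"].to_numpy(),
        label=table["label"].to_numpy(),
        coupling_ms=table["coupling_ms"].to_numpy(),
        captured=captured,
    )
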