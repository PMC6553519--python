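"""Restitution, refractoriness, alternans and arrhythmia-event analysis.

Dynamic restitution: steady-state ROI APD80 per basic cycle length
(BCL), with the diastolic interval (DI) of each beat measured from the
same optical data (DI = activation of beat n minus repolarization of
the previous captured beat).  The curve APD(DI) is fitted with the
standard mono-exponential form and the maximal slope is evaluated over
the measured DI range; slope > 1 predisposes to alternans.

ERP: S1-S2 protocol; capture of the extrastimulus is judged from a
response region >= 5 mm from the pacing site within a 60 ms window, and
ERP is the longest non-capturing coupling interval plus half the
coupling-step resolution.

Arrhythmia events are epochs of activations in the global signal that
are not time-locked to stimuli; VT and VF are discriminated by
cycle-length regularity and ``sustained`` means lasting >= 30 s.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .apd import ROISpec, apd_map
from .preprocessing import BeatWindows, MovieStack, QualityMask, segment_beats
from .synthetic import RestitutionParams

__all__ = [
    "RestitutionCurve",
    "ERPResult",
    "AlternansResult",
    "ArrhythmiaEvent",
    "apd_restitution",
    "measure_erp",
    "detect_alternans",
    "detect_and_classify_events",
    "detect_activations",
    "events_to_frame",
]


@dataclass
class RestitutionCurve:
    """Measured (BCL, DI, APD80) points with a mono-exponential fit."""

    points: pd.DataFrame  # beat, frequency_hz, bcl_ms, di_ms, apd_ms
    fit: Optional[RestitutionParams]
    max_slope: float  # max of the fitted slope over measured DIs; NaN if no fit
    slope_at_di_ms: float
    surface: str = ""
    roi_label: str = ""


@dataclass
class ERPResult:
    """Effective refractory period from an S1-S2 protocol."""

    erp_ms: float
    s2_tested: list[tuple[float, bool]]  # (coupling ms, captured)
    resolution_ms: float
    censored: Optional[str] = None  # None | 'below' | 'above'
    monotone: bool = True


@dataclass
class AlternansResult:
    """Beat-to-beat APD alternation summary across pacing frequencies."""

    magnitude_ms: float
    phase_consistency: float
    onset_frequency_hz: Optional[float]
    significant: bool
    per_frequency: pd.DataFrame = field(default=None, repr=False)


@dataclass
class ArrhythmiaEvent:
    """A classified arrhythmic episode in the global optical signal."""

    onset_s: float
    offset_s: float
    kind: str  # VT | VF
    sustained: bool
    induction_frequency_hz: Optional[float]
    mean_cycle_length_ms: float
    cl_cv: float
    n_activations: int

    @property
    def duration_s(self) -> float:
        return self.offset_s - self.onset_s


# ----------------------------------------------------------------------
# Dynamic restitution
# ----------------------------------------------------------------------

def _beat_roi_measurements(
    movie: MovieStack,
    mask: Optional[QualityMask],
    windows: BeatWindows,
    roi: ROISpec,
) -> pd.DataFrame:
    """Per captured beat: ROI-mean absolute activation and APD80."""
    region = roi.pixel_slices(movie.pixel_spacing_mm, movie.grid_shape)
    rows = []
    for b in range(len(windows)):
        if not windows.captured[b]:
            continue
        apd, at, _ = apd_map(movie, mask, windows, b, region=region)
        rs, cs = region
        apd_roi = np.nanmean(apd.values[rs, cs])
        at_roi = np.nanmean(at.values[rs, cs])
        if not (np.isfinite(apd_roi) and np.isfinite(at_roi)):
            continue
        rows.append(
            {
                "beat": b,
                "frequency_hz": windows.frequency_hz[b],
                "stimulus_ms": windows.stimulus_time_ms[b],
                "act_abs_ms": at_roi + windows.stimulus_time_ms[b],
                "apd_ms": apd_roi,
            }
        )
    return pd.DataFrame(rows)


def apd_restitution(
    movie: MovieStack,
    mask: Optional[QualityMask],
    roi: ROISpec,
    windows: Optional[BeatWindows] = None,
    fit: bool = True,
    surface: str = "",
) -> RestitutionCurve:
    """Dynamic APD restitution curve for one ROI.

    Requires a dynamic protocol with >= 3 frequencies.  Every captured
    beat after the first contributes a (BCL, DI, APD80) point, with DI
    measured optically from the preceding captured beat; on an
    alternating rhythm the long- and short-beat branches both lie on the
    underlying restitution relation, so beat-wise points are what the
    fit uses.  Fit failure returns the points with a missing slope.
    """
    if windows is None:
        windows = segment_beats(movie, mask)
    freqs = np.unique(windows.frequency_hz[~np.isnan(windows.frequency_hz)])
    if len(freqs) < 3:
        raise ValueError("dynamic restitution requires >= 3 pacing frequencies")
    meas = _beat_roi_measurements(movie, mask, windows, roi)
    pts = []
    for i in range(1, len(meas)):
        cur, prev = meas.iloc[i], meas.iloc[i - 1]
        di = cur["act_abs_ms"] - (prev["act_abs_ms"] + prev["apd_ms"])
        if di <= 0:
            continue
        pts.append(
            {
                "beat": int(cur["beat"]),
                "frequency_hz": cur["frequency_hz"],
                "bcl_ms": 1000.0 / cur["frequency_hz"],
                "di_ms": di,
                "apd_ms": cur["apd_ms"],
            }
        )
    points = pd.DataFrame(pts)
    params, max_slope, slope_at = None, float("nan"), float("nan")
    if fit and len(points) >= 4:
        di = points["di_ms"].to_numpy()
        apd = points["apd_ms"].to_numpy()

        def model(d, apd_max, a, tau):
            return apd_max - a * np.exp(-d / tau)

        p0 = (float(apd.max()) + 10.0, float(np.ptp(apd)) + 10.0, 100.0)
        try:
            popt, _ = curve_fit(
                model, di, apd, p0=p0,
                bounds=([0.0, 0.0, 1.0], [2000.0, 5000.0, 2000.0]),
                maxfev=20000,
            )
            params = RestitutionParams(apd_max_ms=popt[0], a_ms=popt[1], tau_ms=popt[2])
            slope_at = float(di.min())
            max_slope = float(params.slope(slope_at))
        except RuntimeError:
            warnings.warn("restitution fit failed; returning points only")
    return RestitutionCurve(
        points=points, fit=params, max_slope=max_slope,
        slope_at_di_ms=slope_at, surface=surface, roi_label=roi.label,
    )


# ----------------------------------------------------------------------
# Effective refractory period
# ----------------------------------------------------------------------

def measure_erp(
    movie: MovieStack,
    mask: Optional[QualityMask] = None,
    capture_window_ms: float = 60.0,
    min_distance_mm: float = 5.0,
    rise_threshold: float = 0.5,
) -> ERPResult:
    """ERP from an S1-S2 movie.

    Capture of each S2 is a rise of the response-region trace (an
    annulus ``min_distance_mm`` to ``min_distance_mm + 3`` mm from the
    pacing site, which separates propagated activation from local
    electrotonic artifact) by >= ``rise_threshold`` within
    ``capture_window_ms`` of the extrastimulus.  ERP is the longest
    non-capturing coupling plus half the coupling step.  If every (no)
    coupling captures, the result is censored below (above) the tested
    range.
    """
    if movie.pacing.kind != "extrastimulus":
        raise ValueError("measure_erp requires an extrastimulus protocol")
    table = movie.pacing.stimulus_table()
    site = movie.pacing.stimulus_site
    h, w = movie.grid_shape
    rows, cols = np.mgrid[0:h, 0:w]
    r_mm = np.hypot(rows - site[0], cols - site[1]) * movie.pixel_spacing_mm
    sel = (r_mm >= min_distance_mm) & (r_mm <= min_distance_mm + 3.0)
    if mask is not None:
        sel &= mask.valid
    if not sel.any():
        raise ValueError("no valid response pixels beyond the minimum distance")
    trace = movie.frames[:, sel].mean(axis=1)
    dt = movie.frame_interval_ms

    tested: list[tuple[float, bool]] = []
    for _, row in table[table["label"] == "s2"].iterrows():
        t = row["time_ms"]
        i0 = int(t / dt)
        i1 = min(int((t + capture_window_ms) / dt) + 1, movie.n_frames)
        if i1 - i0 < 2:
            continue
        captured = bool(trace[i0:i1].max() - trace[i0] >= rise_threshold)
        tested.append((float(row["coupling_ms"]), captured))

    couplings = np.array([c for c, _ in tested])
    captured = np.array([ok for _, ok in tested])
    order = np.argsort(couplings)
    couplings, captured = couplings[order], captured[order]
    resolution = float(np.median(np.diff(couplings))) if len(couplings) > 1 else float("nan")

    monotone = bool(np.all(np.diff(captured.astype(int)) >= 0))
    if not monotone:
        warnings.warn("non-monotone S2 capture pattern; ERP may be unreliable")
    if captured.all():
        return ERPResult(float(couplings[0]), list(zip(couplings, captured)),
                         resolution, censored="below", monotone=monotone)
    if not captured.any():
        return ERPResult(float(couplings[-1]), list(zip(couplings, captured)),
                         resolution, censored="above", monotone=monotone)
    erp = float(couplings[~captured].max() + (resolution / 2.0 if np.isfinite(resolution) else 0.0))
    return ERPResult(erp, list(zip(couplings, captured)), resolution, monotone=monotone)


# ----------------------------------------------------------------------
# Alternans
# ----------------------------------------------------------------------

def detect_alternans(
    apd_sequences: dict[float, Sequence[float]],
    min_beats: int = 8,
    magnitude_threshold_ms: float = 5.0,
    phase_threshold: float = 0.8,
) -> AlternansResult:
    """APD alternans across pacing frequencies.

    For each frequency the last ``min_beats`` consecutive captured beats
    are analyzed: magnitude = mean |APD_n - APD_n+1| / 2 and phase
    consistency = fraction of successive differences with alternating
    sign.  A frequency is significant when magnitude >=
    ``magnitude_threshold_ms`` and phase consistency >=
    ``phase_threshold``; the onset frequency is the lowest significant
    one.  Frequencies with fewer beats are skipped.
    """
    rows = []
    for f in sorted(apd_sequences):
        seq = np.asarray(list(apd_sequences[f]), dtype=np.float64)
        # longest trailing run of captured (finite) beats
        finite = np.isfinite(seq)
        if not finite.all():
            last_bad = np.where(~finite)[0][-1]
            seq = seq[last_bad + 1:]
        if len(seq) < min_beats:
            continue
        seq = seq[-min_beats:]
        d = np.diff(seq)
        magnitude = float(np.abs(d).mean() / 2.0)
        if len(d) > 1:
            phase = float(np.mean(d[:-1] * d[1:] < 0))
        else:
            phase = 0.0
        significant = magnitude >= magnitude_threshold_ms and phase >= phase_threshold
        rows.append(
            {
                "frequency_hz": f,
                "magnitude_ms": magnitude,
                "phase_consistency": phase,
                "significant": significant,
                "n_beats": len(seq),
            }
        )
    per_freq = pd.DataFrame(rows)
    if per_freq.empty:
        return AlternansResult(float("nan"), float("nan"), None, False, per_freq)
    sig = per_freq[per_freq["significant"]]
    if len(sig):
        head = sig.iloc[0]
        onset = float(head["frequency_hz"])
    else:
        head = per_freq.iloc[int(per_freq["magnitude_ms"].idxmax())]
        onset = None
    return AlternansResult(
        magnitude_ms=float(head["magnitude_ms"]),
        phase_consistency=float(head["phase_consistency"]),
        onset_frequency_hz=onset,
        significant=bool(len(sig)),
        per_frequency=per_freq,
    )


# ----------------------------------------------------------------------
# Arrhythmia events
# ----------------------------------------------------------------------

def detect_activations(
    signal: np.ndarray,
    frame_interval_ms: float,
    threshold: float = 0.5,
    refractory_ms: float = 60.0,
) -> np.ndarray:
    """Upstroke times (ms) of a global trace: rising threshold crossings.

    The trace is rescaled to its 5th-98th percentile range first, so raw
    or normalized input both work; crossings within the refractory
    window of the previous one are ignored.
    """
    x = np.asarray(signal, dtype=np.float64)
    lo, hi = np.percentile(x, [5.0, 98.0])
    if hi <= lo:
        return np.empty(0)
    x = (x - lo) / (hi - lo)
    above = x >= threshold
    crossings = np.where(~above[:-1] & above[1:])[0] + 1
    times = crossings * frame_interval_ms
    kept: list[float] = []
    for t in times:
        if not kept or t - kept[-1] >= refractory_ms:
            kept.append(float(t))
    return np.asarray(kept)


def detect_and_classify_events(
    signal: np.ndarray,
    frame_interval_ms: float,
    pacing,
    paced_window_ms: float = 100.0,
    max_gap_ms: float = 1000.0,
    min_activations: int = 5,
    vt_cl_cv: float = 0.15,
    sustained_s: float = 30.0,
) -> list[ArrhythmiaEvent]:
    """Detect and classify arrhythmic episodes in the global signal.

    Activations not time-locked to any stimulus (within
    ``paced_window_ms`` after it) are grouped into episodes separated by
    gaps > ``max_gap_ms``.  Episodes of >= ``min_activations``
    activations are events; cycle-length coefficient of variation <=
    ``vt_cl_cv`` classifies VT, larger VF; sustained means duration >=
    ``sustained_s``.  The induction frequency is the pacing frequency
    active at the last stimulus before onset.  A fully paced recording
    yields an empty list.
    """
    acts = detect_activations(signal, frame_interval_ms)
    if acts.size == 0:
        return []
    table = pacing.stimulus_table()
    stim = table["time_ms"].to_numpy()
    paced = np.zeros(acts.shape, dtype=bool)
    for i, t in enumerate(acts):
        d = t - stim
        paced[i] = bool(np.any((d >= 0) & (d <= paced_window_ms)))
    free = acts[~paced]
    if free.size == 0:
        return []

    episodes: list[list[float]] = [[free[0]]]
    for t in free[1:]:
        if t - episodes[-1][-1] <= max_gap_ms:
            episodes[-1].append(t)
        else:
            episodes.append([t])

    events: list[ArrhythmiaEvent] = []
    for ep in episodes:
        if len(ep) < min_activations:
            continue
        ep = np.asarray(ep)
        cls = np.diff(ep)
        mean_cl = float(cls.mean())
        cv = float(cls.std() / mean_cl) if mean_cl > 0 else float("inf")
        before = stim[stim < ep[0]]
        if before.size:
            freq = table["frequency_hz"].to_numpy()[np.searchsorted(stim, before[-1])]
            induction = None if np.isnan(freq) else float(freq)
        else:
            induction = None
        duration_s = float((ep[-1] - ep[0]) / 1000.0)
        events.append(
            ArrhythmiaEvent(
                onset_s=float(ep[0] / 1000.0),
                offset_s=float(ep[-1] / 1000.0),
                kind="VT" if cv <= vt_cl_cv else "VF",
                sustained=duration_s >= sustained_s,
                induction_frequency_hz=induction,
                mean_cycle_length_ms=mean_cl,
                cl_cv=cv,
                n_activations=len(ep),
            )
        )
    return events


def events_to_frame(events: list[ArrhythmiaEvent]) -> pd.DataFrame:
    """Event log as a table (CSV-ready)."""
    return pd.DataFrame(
        [
            {
                "onset_s": e.onset_s,
                "offset_s": e.offset_s,
                "type": e.kind,
                "sustained": e.sustained,
                "induction_frequency_hz": e.induction_frequency_hz,
                "mean_cycle_length_ms": e.mean_cycle_length_ms,
                "cl_cv": e.cl_cv,
                "n_activations": e.n_activations,
            }
            for e in events
        ]
    )
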