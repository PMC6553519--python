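"""Synthetic voltage-dye movies with exact, machine-readable ground truth.

The generator emulates optical recordings of perfused LV wedge surfaces
(di-4-ANEPPS-like, 1 mm spatial resolution, 1 kHz sampling): an
anisotropic eikonal wavefront from a point stimulus, a smooth
heterogeneous APD80 field, beat-to-beat APD dynamics from a
mono-exponential restitution map (which produces alternans when the
map's slope exceeds one), loss of capture at short diastolic intervals,
additive Gaussian noise, and dye-polarity inversion.  Every quantity the
downstream pipeline measures (activation field, APD field, CV pair,
per-beat APDs) is available in closed form as ground truth, so the
whole analysis chain is testable without animal data.

Group presets parameterize the generator at the printed Sham / rTOF
cohort means (midwall APD80, longitudinal and transverse CV).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
from pydantic import BaseModel
from scipy.ndimage import gaussian_filter
from scipy.special import expit

from .apd import ScalarMap
from .pacing import PacingProtocol, dynamic_protocol
from .preprocessing import MovieStack

__all__ = [
    "RestitutionParams",
    "CVRestitutionParams",
    "GroundTruth",
    "GroundTruthSidecar",
    "GROUP_STATS",
    "RESTITUTION_PRESETS",
    "ap_template",
    "make_activation_field",
    "make_apd_field",
    "synthesize_movie",
    "synthesize_arrhythmia_segment",
    "iterate_restitution",
    "calibrate_apd_max",
    "preset_movie",
    "write_ground_truth",
]

LN4 = math.log(4.0)
TAU_UP_MS = 0.25  # logistic upstroke time constant (10-90% rise ~1.1 ms)
TAU_REP_MS = 12.0  # logistic repolarization time constant

# Printed cohort statistics (midwall APD80 at 1 Hz; CV at 1 Hz), mean/SD.
GROUP_STATS: dict[str, dict[str, float]] = {
    "sham": {
        "apd_endo_ms": 301.0, "apd_endo_sd_ms": 20.0,
        "apd_epi_ms": 280.0, "apd_epi_sd_ms": 50.0,
        "cv_long_cm_s": 65.37, "cv_long_sd_cm_s": 6.76,
        "cv_trans_cm_s": 27.34, "cv_trans_sd_cm_s": 3.08,
        "heterogeneity_epi_ms": 10.0, "heterogeneity_endo_ms": 12.0,
    },
    "rtof": {
        "apd_endo_ms": 403.0, "apd_endo_sd_ms": 34.0,
        "apd_epi_ms": 390.0, "apd_epi_sd_ms": 76.0,
        "cv_long_cm_s": 51.27, "cv_long_sd_cm_s": 0.57,
        "cv_trans_cm_s": 30.19, "cv_trans_sd_cm_s": 1.97,
        "heterogeneity_epi_ms": 25.0, "heterogeneity_endo_ms": 12.0,
    },
}


class RestitutionParams(BaseModel):
    """Mono-exponential restitution map APD(DI) = apd_max - a * exp(-DI/tau).

    The map's slope, (a/tau) * exp(-DI/tau), exceeds one at short DI for
    sufficiently large a/tau, at which point the iterated beat-to-beat
    dynamics develop APD alternans.
    """

    apd_max_ms: float
    a_ms: float
    tau_ms: float

    def apd(self, di_ms):
        return self.apd_max_ms - self.a_ms * np.exp(
            -np.maximum(np.asarray(di_ms, dtype=np.float64), 0.0) / self.tau_ms
        )

    def slope(self, di_ms):
        return (self.a_ms / self.tau_ms) * np.exp(
            -np.asarray(di_ms, dtype=np.float64) / self.tau_ms
        )


class CVRestitutionParams(BaseModel):
    """Rate dependence of conduction: CV scale = 1 - b * exp(-DI/tau_cv)."""

    b: float = 0.0
    tau_cv_ms: float = 60.0

    def scale(self, di_ms: float) -> float:
        return 1.0 - self.b * math.exp(-max(di_ms, 0.0) / self.tau_cv_ms)


# Restitution constants per group.  The rTOF map crosses slope 1 between
# BCL 666 and 500 ms, so iterated dynamics first alternate at 2-2.5 Hz;
# the Sham map stays below slope 1 until >3 Hz.  apd_max is calibrated
# per movie so the 1 Hz steady state equals the prescribed APD mean.
RESTITUTION_PRESETS: dict[str, dict[str, float]] = {
    "sham": {"a_ms": 240.0, "tau_ms": 50.0},
    "rtof": {"a_ms": 1300.0, "tau_ms": 80.0},
}


class GroundTruthSidecar(BaseModel):
    """Machine-readable ground truth written alongside a synthetic movie."""

    cv_long_cm_s: float
    cv_trans_cm_s: float
    fiber_angle_deg: float
    apd_mean_ms: float  # spatial mean of the baseline APD field
    apd_base_ms: float
    heterogeneity_sd_ms: float
    correlation_length_mm: float
    restitution: Optional[RestitutionParams] = None
    cv_restitution: Optional[CVRestitutionParams] = None
    noise_sd: float = 0.0
    seed: int = 0
    stimulus_site: tuple[int, int] = (50, 50)
    pacing: PacingProtocol
    dropped_stimulus_indices: list[int] = []
    beat_mean_apd_ms: list[float] = []  # spatial-mean APD of each captured beat
    beat_frequency_hz: list[Optional[float]] = []
    alternans_magnitude_ms: float = 0.0  # realized, at the fastest captured rate


@dataclass
class GroundTruth:
    """Arrays + sidecar for one synthetic movie."""

    activation_ms: np.ndarray  # base eikonal field (one beat, 1x CV scale)
    apd_ms: np.ndarray  # baseline APD80 field
    sidecar: GroundTruthSidecar


# ----------------------------------------------------------------------
# Building blocks
# ----------------------------------------------------------------------

def ap_template(
    s_ms, apd_ms, tau_up_ms: float = TAU_UP_MS, tau_rep_ms: float = TAU_REP_MS
):
    """Action-potential waveform with analytically known APD80.

    A product of a fast logistic upstroke (centred at s=0, where the
    temporal derivative is maximal) and a slow logistic repolarization
    centred at ``apd - tau_rep*ln 4``, so the downward crossing of 20%
    of the (unit) amplitude falls at s = apd exactly.  Requires
    ``apd > tau_rep * ln 4``.
    """
    s = np.asarray(s_ms, dtype=np.float64)
    apd = np.asarray(apd_ms, dtype=np.float64)
    c = apd - tau_rep_ms * LN4
    return expit(s / tau_up_ms) * expit((c - s) / tau_rep_ms)


def make_activation_field(
    grid_shape: tuple[int, int],
    pixel_spacing_mm: float,
    stimulus_site: tuple[int, int],
    cv_long_cm_s: float,
    cv_trans_cm_s: float,
    fiber_angle_deg: float = 0.0,
) -> ScalarMap:
    """Closed-form anisotropic eikonal activation map from a point stimulus.

    t(x) = sqrt((u/cv_long)^2 + (v/cv_trans)^2) where (u, v) are the mm
    offsets from the stimulus rotated into the fiber frame: u along the
    fast (longitudinal) axis at ``fiber_angle_deg`` from the +x (column)
    axis, v along the slow (transverse) axis.  Speeds in cm/s.
    """
    if cv_long_cm_s <= 0 or cv_trans_cm_s <= 0:
        raise ValueError("conduction velocities must be positive")
    h, w = grid_shape
    r0, c0 = stimulus_site
    if not (0 <= r0 < h and 0 <= c0 < w):
        raise ValueError("stimulus site must lie inside the grid")
    rows, cols = np.mgrid[0:h, 0:w]
    dx = (cols - c0) * pixel_spacing_mm
    dy = (rows - r0) * pixel_spacing_mm
    th = math.radians(fiber_angle_deg)
    u = math.cos(th) * dx + math.sin(th) * dy
    v = -math.sin(th) * dx + math.cos(th) * dy
    vl = cv_long_cm_s / 100.0  # cm/s -> mm/ms
    vt = cv_trans_cm_s / 100.0
    t = np.sqrt((u / vl) ** 2 + (v / vt) ** 2)
    return ScalarMap(
        t, "activation", pixel_spacing_mm=pixel_spacing_mm,
        meta={
            "cv_long_cm_s": cv_long_cm_s, "cv_trans_cm_s": cv_trans_cm_s,
            "fiber_angle_deg": fiber_angle_deg, "stimulus_site": tuple(stimulus_site),
        },
    )


def make_apd_field(
    grid_shape: tuple[int, int],
    apd_base_ms: float,
    heterogeneity_sd_ms: float = 0.0,
    correlation_length_mm: float = 10.0,
    pixel_spacing_mm: float = 1.0,
    regional_offsets_ms: Optional[dict[str, float]] = None,
    seed: int = 0,
) -> ScalarMap:
    """Smooth heterogeneous APD80 field (ms).

    A Gaussian random field (smoothed, mean-removed, variance-rescaled
    white noise with the stated correlation length) is added to
    ``apd_base_ms``, plus optional offsets applied to the base / mid /
    apex thirds of the long (row) axis.  With zero offsets the field
    mean equals ``apd_base_ms`` exactly.  Non-positive values are
    clipped with a warning.
    """
    if heterogeneity_sd_ms < 0:
        raise ValueError("heterogeneity_sd_ms must be non-negative")
    h, w = grid_shape
    field = np.full((h, w), float(apd_base_ms))
    if heterogeneity_sd_ms > 0:
        rng = np.random.default_rng(seed)
        white = rng.standard_normal((h, w))
        sigma_px = correlation_length_mm / pixel_spacing_mm / 2.0
        smooth = gaussian_filter(white, sigma_px, mode="wrap")
        smooth -= smooth.mean()
        sd = smooth.std()
        if sd > 0:
            field = field + smooth * (heterogeneity_sd_ms / sd)
    if regional_offsets_ms:
        thirds = {"base": slice(0, h // 3), "mid": slice(h // 3, 2 * h // 3),
                  "apex": slice(2 * h // 3, h)}
        for label, off in regional_offsets_ms.items():
            field[thirds[label]] += off
    min_apd = TAU_REP_MS * LN4 + 5.0
    if (field < min_apd).any():
        warnings.warn("APD field clipped at its physiological floor")
        field = np.maximum(field, min_apd)
    return ScalarMap(field, "apd80", pixel_spacing_mm=pixel_spacing_mm,
                     meta={"apd_base_ms": apd_base_ms, "seed": seed})


def calibrate_apd_max(
    target_apd_ms: float, a_ms: float, tau_ms: float, bcl_ms: float = 1000.0
) -> float:
    """apd_max such that the restitution steady state at ``bcl_ms`` is the target."""
    di = bcl_ms - target_apd_ms
    if di <= 0:
        raise ValueError("target APD must be shorter than the reference BCL")
    return target_apd_ms + a_ms * math.exp(-di / tau_ms)


def iterate_restitution(
    params: RestitutionParams,
    bcl_ms: float,
    n_beats: int,
    apd0_ms: Optional[float] = None,
    di_min_ms: float = 4.0,
    apd_floor_ms: float = 40.0,
) -> np.ndarray:
    """Iterate the restitution map at fixed BCL.

    Returns the APD sequence; NaN marks beats lost to capture failure
    (DI <= di_min).  Alternans emerges when the map slope at the
    operating point exceeds one.
    """
    apds = np.empty(n_beats)
    prev_apd = params.apd_max_ms if apd0_ms is None else apd0_ms
    debt = 0.0  # accumulated BCLs since last captured beat
    apds[0] = prev_apd
    for i in range(1, n_beats):
        di = bcl_ms * (1.0 + debt) - prev_apd
        if di <= di_min_ms:
            apds[i] = np.nan
            debt += 1.0
            continue
        prev_apd = max(float(params.apd(di)), apd_floor_ms)
        apds[i] = prev_apd
        debt = 0.0
    return apds


# ----------------------------------------------------------------------
# Movie synthesis
# ----------------------------------------------------------------------

def synthesize_movie(
    activation_field: ScalarMap,
    apd_field: ScalarMap,
    pacing: PacingProtocol,
    restitution: Optional[RestitutionParams] = None,
    cv_restitution: Optional[CVRestitutionParams] = None,
    noise_sd: float = 0.0,
    polarity: str = "inverted",
    frame_interval_ms: float = 1.0,
    pixel_spacing_mm: float = 1.0,
    surface: str = "epicardium",
    seed: int = 0,
    di_min_ms: float = 4.0,
    apd_floor_ms: float = 40.0,
    tau_up_ms: float = TAU_UP_MS,
    tau_rep_ms: float = TAU_REP_MS,
    counts_offset: float = 20000.0,
    counts_gain: float = 10000.0,
) -> tuple[MovieStack, GroundTruth]:
    """Render a movie from ground-truth fields and a pacing protocol.

    Each captured beat places the AP template at the (possibly
    CV-restitution-rescaled) eikonal arrival time after its stimulus;
    the beat's per-pixel APD comes from iterating the restitution map on
    that pixel's diastolic interval, offset by the heterogeneity of the
    prescribed APD field.  A stimulus whose diastolic interval at the
    pacing site is <= ``di_min_ms`` fails to capture: no wavefront is
    produced and the index is recorded in the sidecar.  Gaussian noise
    of SD ``noise_sd`` (fraction of AP amplitude) is added before uint16
    digitization; ``polarity='inverted'`` makes fluorescence fall on
    depolarization, as for di-4-ANEPPS.  Output is byte-reproducible
    under fixed seed and parameters.
    """
    if frame_interval_ms > 2.0:
        raise ValueError("frame interval must be <= 2 ms to resolve the upstroke")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if polarity not in ("normal", "inverted"):
        raise ValueError("polarity must be 'normal' or 'inverted'")

    T_base = activation_field.values
    apd0 = apd_field.values
    h, w = T_base.shape
    if apd0.shape != (h, w):
        raise ValueError("activation and APD fields must share a grid")
    site = tuple(activation_field.meta.get("stimulus_site", pacing.stimulus_site))

    table = pacing.stimulus_table()
    stim_times = table["time_ms"].to_numpy()
    duration_ms = float(stim_times[-1] + 1.5 * float(np.max(apd0)) + 100.0)
    nt = int(math.ceil(duration_ms / frame_interval_ms))
    t_axis = np.arange(nt) * frame_interval_ms
    signal = np.zeros((nt, h, w), dtype=np.float64)

    apd_mean = float(apd0.mean())
    apd_offset = apd0 - apd_mean  # heterogeneity enters additively

    last_act = np.full((h, w), -1e12)
    last_apd = np.zeros((h, w))
    dropped: list[int] = []
    beat_apds: list[float] = []
    beat_freqs: list[Optional[float]] = []
    fastest: dict[float, list[float]] = {}

    for i, t_stim in enumerate(stim_times):
        di_site = t_stim - (last_act[site] + last_apd[site])
        if di_site <= di_min_ms:
            dropped.append(i)
            continue
        scale = cv_restitution.scale(di_site) if cv_restitution is not None else 1.0
        act = t_stim + T_base / max(scale, 1e-6)
        di = np.maximum(act - (last_act + last_apd), di_min_ms)
        if restitution is not None:
            apd = np.maximum(restitution.apd(di) + apd_offset, apd_floor_ms)
        else:
            apd = apd0
        i0 = max(int((act.min() - 10.0 * tau_up_ms) / frame_interval_ms), 0)
        i1 = min(int(((act + apd).max() + 8.0 * tau_rep_ms) / frame_interval_ms) + 1, nt)
        if i1 > i0:
            s = t_axis[i0:i1, None, None] - act[None]
            signal[i0:i1] += ap_template(s, apd[None], tau_up_ms, tau_rep_ms)
        last_act, last_apd = act, apd
        beat_apds.append(float(apd.mean()))
        f = table["frequency_hz"].iloc[i]
        beat_freqs.append(None if np.isnan(f) else float(f))
        if not np.isnan(f):
            fastest.setdefault(float(f), []).append(float(apd.mean()))

    rng = np.random.default_rng(seed)
    counts = counts_gain * signal
    if noise_sd > 0:
        counts = counts + rng.normal(0.0, noise_sd * counts_gain, size=counts.shape)
    if polarity == "inverted":
        counts = counts_offset - counts
    else:
        counts = counts_offset + counts
    frames = np.clip(np.round(counts), 0, 65535).astype(np.uint16)

    alt = 0.0
    if fastest:
        seq = np.asarray(fastest[max(fastest)])
        if seq.size >= 3:
            alt = float(np.abs(np.diff(seq)).mean() / 2.0)

    sidecar = GroundTruthSidecar(
        cv_long_cm_s=float(activation_field.meta.get("cv_long_cm_s", np.nan)),
        cv_trans_cm_s=float(activation_field.meta.get("cv_trans_cm_s", np.nan)),
        fiber_angle_deg=float(activation_field.meta.get("fiber_angle_deg", 0.0)),
        apd_mean_ms=apd_mean,
        apd_base_ms=float(apd_field.meta.get("apd_base_ms", apd_mean)),
        heterogeneity_sd_ms=float(apd_offset.std()),
        correlation_length_mm=float(apd_field.meta.get("correlation_length_mm", 10.0)),
        restitution=restitution,
        cv_restitution=cv_restitution,
        noise_sd=noise_sd,
        seed=seed,
        stimulus_site=site,
        pacing=pacing,
        dropped_stimulus_indices=dropped,
        beat_mean_apd_ms=beat_apds,
        beat_frequency_hz=beat_freqs,
        alternans_magnitude_ms=alt,
    )
    movie = MovieStack(
        frames=frames,
        frame_interval_ms=frame_interval_ms,
        pixel_spacing_mm=pixel_spacing_mm,
        pacing=pacing,
        surface=surface,
        polarity=polarity,
    )
    truth = GroundTruth(activation_ms=T_base, apd_ms=apd0, sidecar=sidecar)
    return movie, truth


def synthesize_arrhythmia_segment(
    kind: str,
    cycle_length_ms: float = 150.0,
    cl_variability: float = 0.02,
    duration_s: float = 10.0,
    seed: int = 0,
    frame_interval_ms: float = 1.0,
) -> tuple[np.ndarray, dict]:
    """Global-signal segment of a ventricular arrhythmia, with labels.

    VT is quasi-periodic (cycle-length coefficient of variation =
    ``cl_variability``); VF draws cycle lengths from a gamma
    distribution with CV ~0.45, giving broadband irregular activation.
    Returns (trace, labels); labels carry the kind, activation times,
    and the ground-truth sustained flag (duration >= 30 s).
    """
    if kind not in ("VT", "VF"):
        raise ValueError("kind must be 'VT' or 'VF'")
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(seed)
    dur_ms = duration_s * 1000.0
    times = []
    t = 50.0
    while t < dur_ms:
        times.append(t)
        if kind == "VT":
            cl = rng.normal(cycle_length_ms, cl_variability * cycle_length_ms)
        else:
            cv = 0.45
            shape = 1.0 / cv**2
            cl = rng.gamma(shape, cycle_length_ms / shape)
        t += max(cl, 40.0)
    times = np.asarray(times)
    nt = int(dur_ms / frame_interval_ms)
    t_axis = np.arange(nt) * frame_interval_ms
    trace = np.zeros(nt)
    cls = np.append(np.diff(times), cycle_length_ms)
    for t_act, cl in zip(times, cls):
        apd = max(0.55 * cl, 30.0)
        tau_rep = min(TAU_REP_MS, apd / 4.0)
        trace += ap_template(t_axis - t_act, apd, tau_rep_ms=tau_rep)
    labels = {
        "kind": kind,
        "activation_times_ms": times.tolist(),
        "mean_cycle_length_ms": float(np.diff(times).mean()),
        "cl_cv": float(np.diff(times).std() / np.diff(times).mean()),
        "sustained": duration_s >= 30.0,
        "duration_s": duration_s,
        "seed": seed,
    }
    return trace, labels


# ----------------------------------------------------------------------
# Presets and serialization
# ----------------------------------------------------------------------

def preset_movie(
    group: str,
    surface: str = "epicardium",
    protocol: Optional[PacingProtocol] = None,
    grid_shape: tuple[int, int] = (100, 100),
    pixel_spacing_mm: float = 1.0,
    frame_interval_ms: float = 1.0,
    noise_sd: float = 0.02,
    heterogeneity_sd_ms: Optional[float] = None,
    correlation_length_mm: float = 10.0,
    fiber_angle_deg: float = 30.0,
    stimulus_site: Optional[tuple[int, int]] = None,
    apd_mean_ms: Optional[float] = None,
    cv_long_cm_s: Optional[float] = None,
    cv_trans_cm_s: Optional[float] = None,
    with_restitution: bool = True,
    seed: int = 0,
) -> tuple[MovieStack, GroundTruth]:
    """Synthesize a movie from a Sham-like or rTOF-like preset.

    Defaults come from the printed group means (midwall APD80 and CV at
    1 Hz); any of them can be overridden, e.g. to draw animal-level
    values in a cohort simulation.  Restitution constants are the group
    presets with apd_max calibrated so the 1 Hz steady state matches the
    prescribed APD mean.
    """
    if group not in GROUP_STATS:
        raise ValueError(f"unknown group preset: {group!r}")
    stats = GROUP_STATS[group]
    surf_key = "endo" if surface.startswith("endo") else "epi"
    apd_mean = apd_mean_ms if apd_mean_ms is not None else stats[f"apd_{surf_key}_ms"]
    cvl = cv_long_cm_s if cv_long_cm_s is not None else stats["cv_long_cm_s"]
    cvt = cv_trans_cm_s if cv_trans_cm_s is not None else stats["cv_trans_cm_s"]
    het = (
        heterogeneity_sd_ms
        if heterogeneity_sd_ms is not None
        else stats[f"heterogeneity_{surf_key}_ms"]
    )
    if stimulus_site is None:
        stimulus_site = (grid_shape[0] // 2, grid_shape[1] // 2)
    if protocol is None:
        protocol = dynamic_protocol([1.0], beats_per_frequency=3,
                                    stimulus_site=stimulus_site)

    act = make_activation_field(
        grid_shape, pixel_spacing_mm, stimulus_site, cvl, cvt, fiber_angle_deg
    )
    apd_field = make_apd_field(
        grid_shape, apd_mean, het, correlation_length_mm, pixel_spacing_mm,
        seed=seed + 1,
    )
    apd_field.meta["correlation_length_mm"] = correlation_length_mm
    restitution = None
    if with_restitution:
        consts = RESTITUTION_PRESETS[group]
        restitution = RestitutionParams(
            apd_max_ms=calibrate_apd_max(apd_mean, consts["a_ms"], consts["tau_ms"]),
            a_ms=consts["a_ms"],
            tau_ms=consts["tau_ms"],
        )
    return synthesize_movie(
        act, apd_field, protocol,
        restitution=restitution,
        noise_sd=noise_sd,
        frame_interval_ms=frame_interval_ms,
        pixel_spacing_mm=pixel_spacing_mm,
        surface=surface,
        seed=seed,
    )


def write_ground_truth(truth: GroundTruth, out_dir, stem: str = "truth") -> Path:
    """Write the ground-truth sidecar (JSON) and fields (float32 TIFF)."""
    import tifffile

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / f"{stem}.json").write_text(truth.sidecar.model_dump_json(indent=1))
    tifffile.imwrite(out_dir / f"{stem}_activation.tif",
                     truth.activation_ms.astype(np.float32))
    tifffile.imwrite(out_dir / f"{stem}_apd.tif", truth.apd_ms.astype(np.float32))
    return out_dir
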