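# Methods

This note documents the models and procedures behind `wedgemap`: what
the synthetic generator emulates, how each measurement is defined, the
numerical choices, and what the test suite does and does not establish
about real recordings.

## The synthetic movie model

The generator produces a T×H×W uint16 fluorescence stack plus two JSON
sidecars (acquisition metadata; ground truth). Defaults are a 100×100
grid at 1 mm/pixel and 1 kHz sampling — the spatial resolution of the
CMOS optical-mapping rigs the package targets, at a temporal resolution
that leaves the sub-millisecond upstroke resolvable — with desk-scale
runtimes (a one-second movie synthesizes in well under a second).

**Activation.** A point stimulus in an axially anisotropic, homogeneous
medium has the closed-form eikonal arrival time

    t(x) = sqrt((u / v_L)² + (v / v_T)²),

where (u, v) is the mm offset from the stimulus rotated into the fiber
frame and v_L ≥ v_T are the longitudinal and transverse conduction
velocities (defaults from the group presets; fiber angle default 30°).
This is the exact ground truth against which CV estimators are judged.
No reaction–diffusion PDE is solved: wavefront curvature, source-sink
mismatch and bath-loading effects are deliberately out of scope.

**Action potential template.** Each beat contributes
`expit(s/τ_up) · expit((c − s)/τ_rep)` with τ_up = 0.25 ms (10–90% rise
≈ 1.1 ms), τ_rep = 12 ms and `c = APD − τ_rep·ln 4`, so the downward
crossing of 20% of unit amplitude falls at `s = APD` exactly; the
template's APD80 is analytic by construction. The only deviation is the
peak deficit `≈ exp(−(APD − τ_rep·ln4)/τ_rep)`, which shifts the
crossing by ~0.1 ms at APD ≈ 80 ms and is negligible above 150 ms.
Activation (max dV/dt) is the upstroke midpoint s = 0.

**APD heterogeneity.** The baseline APD80 field is
`apd_base + GRF + regional offsets`, where the Gaussian random field is
smoothed white noise with a stated correlation length (default 10 mm),
mean-removed and rescaled to the prescribed SD, so the realized field
mean equals `apd_base` exactly. The source experiments show
heterogeneous APD maps but publish no spatial statistics; the
correlation length is therefore an explicit parameter, not an asserted
value. Preset heterogeneity SDs (Sham epi 10 ms, rTOF epi 25 ms, endo
12 ms) reproduce the qualitative ordering of epicardial dispersion
between groups.

**Restitution and alternans.** Beat-to-beat dynamics iterate the
standard mono-exponential restitution map

    APD_n = APD_max − a · exp(−DI_{n−1} / τ),

per pixel, with the heterogeneity field entering as an additive offset
to APD_max. A stimulus whose diastolic interval at the pacing site is
≤ 4 ms fails to capture (recorded in the sidecar); per-pixel APD is
floored at 40 ms. `APD_max` is calibrated per movie so the 1 Hz steady
state equals the prescribed APD mean. The functional form is a design
choice — the experiments fit restitution slopes without stating a
model — and the group constants are chosen so the map's slope crosses
1 where the biology says it should: the rTOF preset (a = 1300 ms,
τ = 80 ms) is stable at 1.5 Hz pacing and alternates from 2 Hz,
matching the reported 2–2.5 Hz alternans band that preceded
arrhythmias, while the Sham preset (a = 240 ms, τ = 50 ms) stays
stable beyond 3 Hz. Because every realized (DI, APD) pair lies on the
generating map — including both branches of an alternating rhythm —
restitution-fit recovery is an exact closed-loop test.

An optional conduction-velocity restitution scale,
`CV·(1 − b·exp(−DI/τ_cv))`, models rate-dependent slowing.

**Noise and polarity.** Gaussian noise (SD as a fraction of AP
amplitude, default 2%) is added before uint16 digitization at
10 000 counts per unit amplitude around a 20 000-count offset. The
default polarity is inverted — fluorescence falls on depolarization, as
for di-4-ANEPPS — and normalization re-inverts it. Output is
byte-reproducible for a fixed seed.

**Arrhythmia segments.** Global-signal fixtures: VT is a quasi-periodic
train (cycle-length CV = 2% by default), VF draws cycle lengths from a
gamma distribution with CV ≈ 0.45. Labels (type, activation times,
sustained flag) ride along for classifier round-trip tests. Rotor/phase
dynamics are not modelled.

## Measurement pipeline

**Filtering.** Gaussian spatial smoothing plus Savitzky–Golay temporal
smoothing (defaults 1 mm / 5 ms, order 2); zero settings are exact
identities. For conduction-velocity estimation the pipeline re-derives
the activation map with *temporal-only* smoothing: spatially smoothing
the signal mixes neighbouring upstrokes across the curved wavefront and
was measured to bias ray speeds upward by 2–3% — enough to matter at
the 2% recovery tolerance.

**Normalization.** Per pixel and per beat window: baseline is the 5th
percentile of the window, amplitude the window maximum minus baseline
(tolerant of slow photobleaching-like drift; per-beat residual drift is
the per-beat drift, ~1% at realistic rates). Windows of non-capturing
stimuli are merged into the preceding beat (two-pass: segment, then
renormalize), because on a 2:1 blocked rhythm the action potential
outlasts the blocked stimulus and the window would otherwise contain no
diastole. Flat traces are flagged, never raised on.

**Quality mask.** Valid = (SNR ≥ 3) ∧ inside the optional manual
contour (a polygon in mm, mirroring manual exclusion of low-quality
optical signals). SNR is a robust amplitude (5–95 percentile span of a
lightly smoothed trace — a raw window maximum would be inflated by the
very noise being gated on) over the baseline noise SD estimated from
first differences of the pre-stimulus segment. Invalid pixels propagate
as NaN through every map, mean, dispersion and fit.

**AT / RT / APD80.** AT is the argmax of the discrete derivative with
parabolic sub-sample refinement; baseline is the pre-upstroke mean;
traces with amplitude < 0.5 are missing. RT is the linear-interpolated
downward crossing of baseline + (1 − level)·amplitude after the peak
(level = 0.80), measured from baseline-referenced amplitude rather than
the plateau — "80% of repolarization" is ambiguous about the reference,
and this choice is stated explicitly. Analysis segments open 5 ms
before the stimulus (so the pacing-site pixel keeps a baseline) and
extend past blocked stimuli to the next captured beat. The scalar
operators and the vectorized map path share one kernel, so a per-pixel
loop reproduces maps bit for bit.

**Regional means and dispersion.** 5×5 mm square ROIs at 20/50/80% of
the long axis (base / mid free wall / apex; the experiments state the
ROI size but not coordinates — centers are overridable); an ROI mean
requires ≥ 50% valid coverage. Dispersion is the spatial SD over valid
pixels, with the 5–95 percentile range reported alongside, since the
experimental "dispersion" metric is not defined precisely; group
*orderings* are the meaningful output.

**Conduction velocity.** The canonical estimator anchors rays at the
stimulus site (the published definition refers to fastest/slowest
propagation *from the stimulus point*): activation is bilinearly
sampled along each 5°-spaced ray within a 3–15 mm annulus (inside the
near-field curvature and outside boundary effects), truncated at the
first invalid pixel, and distance (cm) is regressed on time (s). Rays
need ≥ 8 points and R² ≥ 0.9. The fastest/slowest directions are
selected on a circularly 3-ray-smoothed speed profile — raw extreme
selection is upward-biased under noise — but the reported speed is the
unsmoothed fit at the selected angle, which avoids the smoothing bias
at high anisotropy. Near-orthogonality of the two axes (90° ± 15°) is a
soft diagnostic, not a constraint. The gradient-tensor estimator
(speed = 1/|∇t|, robust 0.5/99.5 percentiles over the annulus) is kept
as an independent oracle, not the production path.

**Restitution analysis.** Every captured beat after the first yields a
(BCL, DI, APD80) point with DI measured optically from the preceding
captured beat; alternating rhythms contribute both branches, which is
exactly what identifies the map at short DI. The mono-exponential fit
uses `scipy.optimize.curve_fit`; the maximal slope is evaluated at the
shortest measured DI (slopes are a property of the fitted APD-vs-DI
curve, not of raw APD-vs-BCL secants). Fit failure returns points with
a missing slope.

**ERP.** Capture of each S2 is a ≥ 0.5-amplitude rise, within 60 ms of
the extrastimulus, of the mean trace in an annulus 5–8 mm from the
pacing site — far enough to separate propagated activation from local
electrotonic artifact (the capture rule is a design choice; none is
published). ERP = longest non-capturing coupling + step/2; all-capture
and no-capture outcomes are censored, non-monotone patterns warn.

**Alternans.** Per frequency, the last 8 consecutive captured beats
give magnitude = mean |ΔAPD|/2 and phase consistency = fraction of
sign-alternating successive differences; significance requires
magnitude ≥ 5 ms and consistency ≥ 0.8 (thresholds sit well above the
~0.5 ms APD measurement noise at default settings and are
configurable). Onset frequency = lowest significant frequency.

**Event classification.** Activations are 0.5-level rising crossings of
the percentile-rescaled global trace with a 60 ms refractory; an
activation is paced if it falls within 100 ms after a stimulus.
Non-paced activations separated by ≤ 1 s group into episodes; episodes
of ≥ 5 activations are events. VT ⇔ cycle-length CV ≤ 0.15 (the
dichotomy is published without a criterion; 0.15 cleanly separates the
generator's VT at CV 0.02 from VF at CV 0.45), sustained ⇔ ≥ 30 s, and
the induction frequency is the pacing rate of the last stimulus before
onset.

**Statistics.** The Mann-Whitney U test is exact whenever both groups
have ≤ 8 members (the 5-vs-6 regime of the motivating study): the U
statistic is computed from mid-ranks for all C(n_a+n_b, n_a) labelings
and the two-sided p is the tail fraction around n_a·n_b/2. This is a
genuine permutation test under ties, which is why it is implemented
here rather than delegated (scipy's exact method does not permute
mid-ranks); scipy is the cross-check oracle on tie-free data. Larger
groups fall back to the tie-corrected normal approximation. Spearman's
ρ comes from scipy with a seeded 10⁴-permutation p-value for n ≤ 10.
All tests are two-sided at α = 0.05. For more than two groups only
Holm-adjusted pairwise contrasts are provided — every contrast in the
motivating design is two-group.

## Cohort simulation

`simulate_cohort_comparison` draws each animal's true midwall APD80
(both surfaces) and CV pair from the published group mean ± SD, then
*measures* each value by synthesizing and analyzing a movie (40×40 px,
1 mm, 1 kHz, 2% noise, one beat at 1 Hz), so the comparison table
reflects pipeline error as well as biological spread. A caveat worth
stating: at the published SDs and n = 5 vs 6, the exact test's power is
~92% for CV_L and ~99% for endocardial midwall APD, while the CV_T
difference (27.34 ± 3.08 vs 30.19 ± 1.97 cm/s) is detected in roughly a
quarter of cohorts — "CV_T unchanged" is a statement about one
experiment, not a property guaranteed at this sample size, and the test
suite documents this rather than hiding it.

## What passing tests do and do not show

The generator shares its waveform family and restitution model with
nothing in the measurement path, but it remains an idealization: no
motion artifact, no ratiometric drift beyond linear trends, no fiber
curvature or scar anisotropy, no transmural (depth-averaged) signal
formation, and arrhythmia fixtures are global-signal surrogates rather
than spatially resolved reentry. Parameter recovery on these movies
validates the estimators' correctness and calibration; it does not
certify performance on recordings whose artifacts violate those
assumptions. Problem sizes in the test suite (30–100 px grids, 1–10
beats per frequency, 50 cohort replicates) were chosen as the smallest
at which the measured quantities are statistically stable.

## Known limitations

- The eikonal ground truth has no wavefront curvature effects; CV
  estimators are validated in their regime of validity (3–15 mm from a
  point source in homogeneous anisotropic tissue).
- Per-beat normalization removes drift between beats but not within a
  beat; within-beat drift larger than ~1% of amplitude will bias RT.
- The ERP generator implements refractoriness as capture failure at the
  pacing site only; spatially heterogeneous refractoriness is not
  modelled.
- `estimate_cv` assumes the stimulus site is known; it is not inferred
  from the activation map.
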