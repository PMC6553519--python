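"""I/O round trips, normalization, filtering, masking, segmentation."""

import json

import numpy as np
import pytest

from wedgemap.apd import apd_map, default_rois, roi_mean
from wedgemap.pacing import dynamic_protocol
from wedgemap.preprocessing import (
    MovieFormatError,
    MovieStack,
    build_quality_mask,
    filter_movie,
    load_movie,
    normalize,
    segment_beats,
    write_movie,
)
from wedgemap.synthetic import make_activation_field, make_apd_field, synthesize_movie

from conftest import prepare


class TestIO:
    def test_round_trip_is_lossless(self, tmp_path):
        rng = np.random.default_rng(0)
        frames = rng.integers(0, 5000, (10, 8, 8), dtype=np.uint16)
        movie = MovieStack(frames, 1.0, 1.0, dynamic_protocol([1.0]), "endocardium")
        write_movie(movie, tmp_path)
        back = load_movie(tmp_path)
        np.testing.assert_array_equal(back.frames, frames)
        assert back.pixel_spacing_mm == 1.0  # calibration survives exactly
        assert back.surface == "endocardium"
        assert back.pacing.frequencies_hz == [1.0]

    def test_missing_sidecar_is_explicit_error(self, tmp_path):
        frames = np.zeros((5, 4, 4), dtype=np.uint16)
        movie = MovieStack(frames, 1.0, 1.0, dynamic_protocol([1.0]))
        write_movie(movie, tmp_path)
        (tmp_path / "movie.json").unlink()
        with pytest.raises(MovieFormatError):
            load_movie(tmp_path)

    def test_page_count_mismatch_is_format_error(self, tmp_path):
        frames = np.zeros((5, 4, 4), dtype=np.uint16)
        movie = MovieStack(frames, 1.0, 1.0, dynamic_protocol([1.0]))
        write_movie(movie, tmp_path)
        sidecar = json.loads((tmp_path / "movie.json").read_text())
        sidecar["n_frames"] = 7
        (tmp_path / "movie.json").write_text(json.dumps(sidecar))
        with pytest.raises(MovieFormatError):
            load_movie(tmp_path)


def _square_pulse_movie(amplitude=-500.0, drift_per_frame=0.0, n_beats=1):
    """Inverted square pulses: counts drop by |amplitude| during each AP.

    Optional slow linear drift emulates photobleaching; pixel (0, 0)
    carries no AP at all (flat trace).
    """
    nt = 400 + 1000 * (n_beats - 1)
    frames = np.full((nt, 4, 4), 2000.0)
    for b in range(n_beats):
        i0 = 120 + 1000 * b
        frames[i0:i0 + 100] += amplitude
    frames += drift_per_frame * np.arange(nt)[:, None, None]
    frames[:, 0, 0] = 2000.0 + drift_per_frame * np.arange(nt)  # flat pixel
    return MovieStack(
        frames, 1.0, 1.0,
        dynamic_protocol([1.0], beats_per_frequency=n_beats, stimulus_site=(2, 2)),
        polarity="inverted",
    )


class TestNormalize:
    def test_inverted_pulse_becomes_upstroke_positive_unit(self):
        norm = normalize(_square_pulse_movie())
        tr = norm.frames[:, 2, 2]
        assert tr[:100].max() == pytest.approx(0.0, abs=0.02)
        assert tr[150] == pytest.approx(1.0, abs=0.02)
        assert norm.polarity == "normal"

    def test_photobleaching_drift_removed_per_beat(self):
        # drift accumulates to 3.4% of AP amplitude over the recording but
        # per-beat normalization keeps the trace within ~1% of the
        # drift-free twin
        clean = normalize(_square_pulse_movie(n_beats=4)).frames[:, 2, 2]
        drifty = normalize(
            _square_pulse_movie(n_beats=4, drift_per_frame=0.005)
        ).frames[:, 2, 2]
        assert np.abs(drifty - clean).max() < 0.015

    def test_flat_pixel_flagged_not_raised(self):
        norm = normalize(_square_pulse_movie())
        assert norm.meta["flat_pixels"][0, 0]
        assert not norm.meta["flat_pixels"][2, 2]
        mask = build_quality_mask(norm)
        assert not mask.valid[0, 0]


class TestFilter:
    def test_zero_settings_are_identity(self, homog_movie):
        movie, _ = homog_movie
        out = filter_movie(movie, 0.0, 0.0)
        np.testing.assert_array_equal(out.frames, movie.frames)

    def test_short_window_is_parameter_error(self, homog_movie):
        movie, _ = homog_movie
        with pytest.raises(ValueError):
            filter_movie(movie, 0.0, 2.0)  # 2 samples at 1 kHz

    def test_noise_reduction_matches_closed_form(self):
        # Savitzky-Golay (win 5, order 2) variance gain is sum(c^2) =
        # 595/1225; spatial Gaussian sigma=1 px gives ~1/(4 pi sigma^2).
        rng = np.random.default_rng(1)
        frames = rng.normal(1000.0, 100.0, (300, 40, 40))
        movie = MovieStack(frames, 1.0, 1.0, dynamic_protocol([1.0]))
        sd0 = 100.0
        temporal = filter_movie(movie, 0.0, 5.0).frames[50:-50].std()
        assert temporal / sd0 == pytest.approx(np.sqrt(595.0 / 1225.0), rel=0.05)
        spatial = filter_movie(movie, 1.0, 0.0).frames[:, 5:-5, 5:-5].std()
        assert spatial / sd0 == pytest.approx(np.sqrt(1.0 / (4.0 * np.pi)), rel=0.10)

    def test_filtering_improves_apd_recovery_on_noisy_movie(self):
        site = (12, 12)
        act = make_activation_field((24, 24), 1.0, site, 50.0, 30.0, 0.0)
        apd = make_apd_field((24, 24), 300.0, 0.0)
        proto = dynamic_protocol([1.0], beats_per_frequency=1, stimulus_site=site)
        movie, _ = synthesize_movie(act, apd, proto, noise_sd=0.05, seed=3)

        def error(m):
            norm, mask, win = prepare(m, filter_first=False)
            amap, _, _ = apd_map(norm, mask, win, 0)
            return float(np.nanmean(np.abs(amap.values - 300.0)))

        assert error(filter_movie(movie)) < error(movie)


class TestQualityMask:
    def test_noise_free_movie_fully_valid(self, homog_movie):
        movie, _ = homog_movie
        mask = build_quality_mask(normalize(movie))
        assert mask.valid.all()

    def test_low_snr_pixels_rejected(self):
        # amplitude 0.05 vs noise SD 0.05 -> SNR ~1, below threshold 3
        site = (10, 10)
        act = make_activation_field((20, 20), 1.0, site, 50.0, 50.0)
        apd = make_apd_field((20, 20), 250.0, 0.0)
        proto = dynamic_protocol([1.0], beats_per_frequency=2, stimulus_site=site)
        movie, _ = synthesize_movie(act, apd, proto, noise_sd=0.0, seed=4)
        frames = movie.frames.astype(np.float64)
        # shrink one pixel's AP excursion to 5% of full amplitude, then add
        # noise of SD 5% of amplitude everywhere: that pixel has SNR ~1
        frames[:, 3, 3] = 20000.0 - 0.05 * (20000.0 - frames[:, 3, 3])
        frames += np.random.default_rng(4).normal(0.0, 500.0, frames.shape)
        movie = movie.copy_with(np.clip(np.round(frames), 0, 65535).astype(np.uint16))
        mask = build_quality_mask(normalize(movie), snr_threshold=3.0)
        assert not mask.valid[3, 3]
        assert mask.valid[site]

    def test_contour_excludes_outside_pixels(self, homog_movie):
        movie, _ = homog_movie
        # polygon covering only the right half of the 30 mm field of view
        contour = [(15.0, -1.0), (30.5, -1.0), (30.5, 30.5), (15.0, 30.5)]
        mask = build_quality_mask(normalize(movie), manual_contour=contour)
        assert not mask.valid[:, :14].any()
        assert mask.valid[:, 16:].all()

    def test_empty_mask_warns(self, homog_movie):
        movie, _ = homog_movie
        tiny = [(-5.0, -5.0), (-4.0, -5.0), (-4.0, -4.0)]  # excludes every pixel
        with pytest.warns(UserWarning):
            build_quality_mask(normalize(movie), manual_contour=tiny)


class TestSegmentBeats:
    def test_window_lengths_follow_frequency(self):
        site = (6, 6)
        act = make_activation_field((12, 12), 1.0, site, 50.0, 50.0)
        apd = make_apd_field((12, 12), 150.0, 0.0)
        proto = dynamic_protocol([2.5], beats_per_frequency=4, stimulus_site=site)
        movie, _ = synthesize_movie(act, apd, proto, seed=0)
        win = segment_beats(normalize(movie))
        assert len(win) == 4
        np.testing.assert_allclose(np.diff(win.start_ms), 400.0)
        assert win.captured.all()

    def test_ten_windows_at_1hz(self, sham_restitution_movie):
        movie, _ = sham_restitution_movie
        win = segment_beats(normalize(movie))
        at_1hz = win.frequency_hz == 1.0
        assert at_1hz.sum() == 8
        np.testing.assert_allclose(np.diff(win.start_ms[at_1hz]), 1000.0)

    def test_dropped_capture_matches_sidecar(self):
        site = (6, 6)
        act = make_activation_field((12, 12), 1.0, site, 50.0, 50.0)
        apd = make_apd_field((12, 12), 499.0, 0.0)
        proto = dynamic_protocol([2.0], beats_per_frequency=6, stimulus_site=site)
        movie, truth = synthesize_movie(act, apd, proto, seed=0)
        win = segment_beats(normalize(movie))
        flagged = sorted(np.where(~win.captured)[0].tolist())
        assert flagged == truth.sidecar.dropped_stimulus_indices

    def test_stimuli_beyond_recording_are_dropped(self, homog_movie):
        movie, _ = homog_movie
        short = movie.copy_with(movie.frames[:900])
        with pytest.warns(UserWarning):
            win = segment_beats(normalize(short))
        assert len(win) == 1
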