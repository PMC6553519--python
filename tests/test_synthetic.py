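"""Generator ground truth: eikonal fields, APD fields, templates, dynamics."""

import math

import numpy as np
import pytest

from wedgemap.pacing import dynamic_protocol
from wedgemap.synthetic import (
    RESTITUTION_PRESETS,
    RestitutionParams,
    ap_template,
    calibrate_apd_max,
    iterate_restitution,
    make_activation_field,
    make_apd_field,
    preset_movie,
    synthesize_arrhythmia_segment,
    synthesize_movie,
)


class TestActivationField:
    def test_isotropic_distance_over_speed(self):
        # 50 cm/s = 0.5 mm/ms; a point 10 mm away activates at 20 ms
        f = make_activation_field((30, 30), 1.0, (15, 15), 50.0, 50.0, 0.0)
        assert f.values[15, 25] == pytest.approx(20.0)
        assert f.values[15, 15] == 0.0

    def test_anisotropic_formula_against_scalar_oracle(self):
        # independent evaluation: rotate the offset into the fiber frame
        # and apply t = sqrt((u/vL)^2 + (v/vT)^2) with speeds in mm/ms
        cvl, cvt, ang = 65.37, 27.34, 30.0
        f = make_activation_field((40, 40), 1.0, (10, 10), cvl, cvt, ang)
        dy, dx = 20.0, 5.0  # mm offset: pixel (30, 15) from stimulus (10, 10)
        th = math.radians(ang)
        u = math.cos(th) * dx + math.sin(th) * dy
        v = -math.sin(th) * dx + math.cos(th) * dy
        expected = math.hypot(u / (cvl / 100.0), v / (cvt / 100.0))
        assert f.values[30, 15] == pytest.approx(expected, rel=1e-12)

    def test_parameter_errors(self):
        with pytest.raises(ValueError):
            make_activation_field((10, 10), 1.0, (5, 5), -1.0, 30.0)
        with pytest.raises(ValueError):
            make_activation_field((10, 10), 1.0, (5, 5), 50.0, 0.0)
        with pytest.raises(ValueError):
            make_activation_field((10, 10), 1.0, (20, 5), 50.0, 30.0)


class TestApdField:
    def test_zero_heterogeneity_is_constant(self):
        f = make_apd_field((20, 20), 280.0, 0.0)
        assert np.all(f.values == 280.0)

    def test_sample_sd_near_prescribed(self):
        f = make_apd_field((100, 100), 403.0, 25.0, correlation_length_mm=10.0, seed=3)
        assert abs(f.values.std() / 25.0 - 1.0) < 0.20
        assert f.values.mean() == pytest.approx(403.0, abs=1.0)

    def test_rtof_endocardial_mean(self):
        # rTOF endocardial preset value: field mean sits at 403 ms
        f = make_apd_field((50, 50), 403.0, 12.0, seed=1)
        assert f.values.mean() == pytest.approx(403.0, abs=1.0)

    def test_regional_offsets(self):
        f = make_apd_field((30, 30), 300.0, 0.0,
                           regional_offsets_ms={"base": -20.0, "apex": 20.0})
        assert np.all(f.values[:10] == 280.0)
        assert np.all(f.values[10:20] == 300.0)
        assert np.all(f.values[20:] == 320.0)

    def test_negative_values_clipped_with_warning(self):
        with pytest.warns(UserWarning):
            f = make_apd_field((20, 20), 5.0, 0.0)
        assert np.all(f.values > 0)


class TestTemplate:
    @pytest.mark.parametrize("apd", [80.0, 300.0, 403.0])
    def test_apd80_is_closed_form(self, apd):
        # brute-force: dense sampling, peak, then first 20%-of-peak crossing
        t = np.arange(-20.0, apd + 150.0, 0.01)
        v = ap_template(t, apd)
        peak_i = int(np.argmax(v))
        thr = 0.2 * v[peak_i]
        below = np.where((v < thr) & (np.arange(len(v)) > peak_i))[0]
        crossing = t[below[0]]
        # exact up to the peak deficit 1 - exp(-(apd - tau*ln4)/tau_rep),
        # which shifts the crossing by ~0.1 ms at the shortest APDs
        assert crossing == pytest.approx(apd, abs=0.2)

    def test_upstroke_is_submillisecond(self):
        t = np.arange(-5.0, 5.0, 0.001)
        v = ap_template(t, 300.0)
        t10 = t[np.searchsorted(v, 0.1)]
        t90 = t[np.searchsorted(v, 0.9)]
        assert t90 - t10 < 2.0


class TestMovieSynthesis:
    def test_byte_identical_under_fixed_seed(self):
        site = (8, 8)
        act = make_activation_field((16, 16), 1.0, site, 50.0, 30.0, 20.0)
        apd = make_apd_field((16, 16), 250.0, 10.0, seed=2)
        proto = dynamic_protocol([2.0], beats_per_frequency=2, stimulus_site=site)
        m1, _ = synthesize_movie(act, apd, proto, noise_sd=0.02, seed=5)
        m2, _ = synthesize_movie(act, apd, proto, noise_sd=0.02, seed=5)
        m3, _ = synthesize_movie(act, apd, proto, noise_sd=0.02, seed=6)
        assert m1.frames.tobytes() == m2.frames.tobytes()
        assert m1.frames.tobytes() != m3.frames.tobytes()

    def test_polarity_inversion_flips_signal(self):
        site = (8, 8)
        act = make_activation_field((16, 16), 1.0, site, 50.0, 50.0)
        apd = make_apd_field((16, 16), 200.0, 0.0)
        proto = dynamic_protocol([1.0], beats_per_frequency=1, stimulus_site=site)
        inv, _ = synthesize_movie(act, apd, proto, polarity="inverted", seed=0)
        pos, _ = synthesize_movie(act, apd, proto, polarity="normal", seed=0)
        # depolarization lowers counts under the dye convention
        assert inv.frames[:, 8, 8].min() < inv.frames[0, 8, 8]
        assert pos.frames[:, 8, 8].max() > pos.frames[0, 8, 8]
        np.testing.assert_array_equal(
            inv.frames.astype(np.int32) + pos.frames.astype(np.int32),
            np.full(inv.frames.shape, 40000, np.int32),
        )

    def test_loss_of_capture_recorded_in_sidecar(self):
        # uniform 499 ms APD at 2 Hz: every other stimulus lands in the
        # refractory period and must be dropped
        site = (6, 6)
        act = make_activation_field((12, 12), 1.0, site, 50.0, 50.0)
        apd = make_apd_field((12, 12), 499.0, 0.0)
        proto = dynamic_protocol([2.0], beats_per_frequency=6, stimulus_site=site)
        _, truth = synthesize_movie(act, apd, proto, seed=0)
        assert truth.sidecar.dropped_stimulus_indices == [1, 3, 5]

    def test_frame_interval_guard(self):
        site = (6, 6)
        act = make_activation_field((12, 12), 1.0, site, 50.0, 50.0)
        apd = make_apd_field((12, 12), 200.0, 0.0)
        proto = dynamic_protocol([1.0], beats_per_frequency=1, stimulus_site=site)
        with pytest.raises(ValueError):
            synthesize_movie(act, apd, proto, frame_interval_ms=5.0)


class TestRestitutionDynamics:
    def test_steady_state_matches_calibration(self):
        c = RESTITUTION_PRESETS["sham"]
        p = RestitutionParams(
            apd_max_ms=calibrate_apd_max(280.0, c["a_ms"], c["tau_ms"]),
            a_ms=c["a_ms"], tau_ms=c["tau_ms"],
        )
        seq = iterate_restitution(p, 1000.0, 10)
        assert seq[-1] == pytest.approx(280.0, abs=0.5)
        assert np.abs(np.diff(seq[-5:])).max() < 0.5

    def test_alternans_when_slope_exceeds_one(self):
        c = RESTITUTION_PRESETS["rtof"]
        p = RestitutionParams(
            apd_max_ms=calibrate_apd_max(390.0, c["a_ms"], c["tau_ms"]),
            a_ms=c["a_ms"], tau_ms=c["tau_ms"],
        )
        seq = iterate_restitution(p, 500.0, 20)  # 2 Hz
        tail = seq[-6:]
        d = np.diff(tail)
        assert np.all(d[:-1] * d[1:] < 0)  # alternating
        assert np.abs(d).mean() / 2.0 > 5.0
        # the 1:1 fixed point x* = f(bcl - x*) must be unstable (slope > 1)
        from scipy.optimize import brentq

        x_star = brentq(lambda x: float(p.apd(500.0 - x)) - x, 50.0, 450.0)
        assert p.slope(500.0 - x_star) > 1.0


class TestArrhythmiaSegments:
    def test_vt_is_regular_and_vf_irregular(self):
        _, vt = synthesize_arrhythmia_segment("VT", 150.0, 0.02, 5.0, seed=1)
        _, vf = synthesize_arrhythmia_segment("VF", 120.0, 0.45, 5.0, seed=1)
        assert vt["cl_cv"] < 0.05
        assert vf["cl_cv"] > 0.25
        assert vt["mean_cycle_length_ms"] == pytest.approx(150.0, rel=0.05)

    def test_sustained_label_at_30_seconds(self):
        _, short = synthesize_arrhythmia_segment("VT", 150.0, 0.02, 10.0, seed=0)
        _, long = synthesize_arrhythmia_segment("VT", 150.0, 0.02, 35.0, seed=0)
        assert not short["sustained"]
        assert long["sustained"]

    def test_invalid_kind_rejected(self):
        with pytest.raises(ValueError):
            synthesize_arrhythmia_segment("AF", 150.0, 0.02, 5.0)
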