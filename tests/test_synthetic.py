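"""Synthetic-data generator: determinism, noise calibration, image rendering."""

import numpy as np
import pytest
from dataclasses import replace

from epperm.schedule import make_schedule
from epperm.synthetic import VesselLayout, default_truth, render_image_stack, simulate_trace
from epperm.trace import normalize_trace, subtract_background


class TestTraceGeneration:
    def test_same_seed_bitwise_identical(self, schedule):
        truth = default_truth(schedule, seed=11)
        a = simulate_trace(schedule, truth)
        b = simulate_trace(schedule, truth)
        np.testing.assert_array_equal(a.trace.values, b.trace.values)

    def test_different_seeds_differ(self, schedule):
        a = simulate_trace(schedule, default_truth(schedule, seed=1))
        b = simulate_trace(schedule, default_truth(schedule, seed=2))
        assert not np.array_equal(a.trace.values, b.trace.values)

    def test_phase_one_zero_without_background_or_noise(self, schedule):
        truth = default_truth(schedule, noise_cv=0.0, background=0.0)
        ds = simulate_trace(schedule, truth)
        _, ph1 = ds.trace.phase("I")
        assert np.all(ph1 == 0.0)

    def test_sample_times_match_schedule(self, noiseless_ds, schedule):
        np.testing.assert_array_equal(noiseless_ds.trace.times, schedule.frame_times())

    def test_control_trace_decays_after_peak(self, schedule):
        truth = default_truth(schedule, d_sat=0.0, noise_cv=0.0)
        ds = simulate_trace(schedule, truth)
        t, y = ds.trace.phase("II")
        t3, y3 = ds.trace.phase("III")
        post = np.concatenate([y[np.argmax(y):], y3])
        assert np.all(np.diff(post) <= 1e-12)

    def test_control_equals_ep_before_delay(self, schedule, noiseless_ds):
        control = simulate_trace(schedule, replace(noiseless_ds.truth, wall=replace(noiseless_ds.truth.wall, d_sat=0.0)))
        pre = noiseless_ds.trace.times < noiseless_ds.truth.wall.t_del
        np.testing.assert_allclose(
            noiseless_ds.clean_values[pre], control.clean_values[pre], rtol=0, atol=1e-12
        )

    def test_normalized_trace_independent_of_gain(self, schedule):
        ref = None
        for gain in (0.1, 1.0, 10.0):
            truth = replace(default_truth(schedule, d_sat=0.0, noise_cv=0.0), gain=gain)
            ds = simulate_trace(schedule, truth)
            norm = normalize_trace(subtract_background(ds.trace))
            if ref is None:
                ref = norm.values
            else:
                np.testing.assert_allclose(norm.values, ref, rtol=1e-12)

    def test_noise_cv_calibration(self):
        # 10,000 pre-injection frames: empirical CV converges to noise_cv
        sched = make_schedule([("A", 10000.0, 1.0)], b_gap=0.0, control=True)
        truth = default_truth(sched, d_sat=0.0, noise_cv=0.04, seed=5)
        ds = simulate_trace(sched, truth)
        _, ph1 = ds.trace.phase("I")
        assert ph1.size == 10000
        cv = ph1.std() / ph1.mean()
        assert cv == pytest.approx(0.04, rel=0.05)


class TestImageRendering:
    def test_empty_layout_gives_empty_mask(self, schedule):
        layout = VesselLayout(stripes=())
        ds = render_image_stack(schedule, default_truth(schedule, noise_cv=0.0), layout)
        assert not ds.true_mask.any()

    def test_stripe_mask_pixel_count(self, schedule):
        layout = VesselLayout(shape=(96, 128), stripes=((10, 12), (60, 12)))
        ds = render_image_stack(schedule, default_truth(schedule, noise_cv=0.0), layout)
        assert int(ds.true_mask.sum()) == 2 * 12 * 96

    def test_layout_exceeding_frame_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            VesselLayout(shape=(96, 128), stripes=((120, 12),))

    def test_noiseless_pre_injection_frames_flat(self, schedule):
        truth = default_truth(schedule, noise_cv=0.0, background=100.0)
        ds = render_image_stack(schedule, truth)
        pre = ds.trace.times < schedule.t_fd
        assert np.all(ds.images[pre] == 100.0)

    def test_seeded_determinism(self, schedule):
        truth = default_truth(schedule, noise_cv=0.05, seed=9)
        a = render_image_stack(schedule, truth)
        b = render_image_stack(schedule, truth)
        np.testing.assert_array_equal(a.images, b.images)
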