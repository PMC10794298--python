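"""Trajectory generator: waveform, sampling, resampling, sessions."""

import numpy as np
import pytest

import pursuittrack as pt
from pursuittrack.trajectory import FIXED_MIDDLE


class TestWaveform:
    def test_zero_coefficients_give_zero(self):
        zero = pt.SegmentCoefficients(a=(0, 0, 0), b=(0, 0, 0))
        assert np.all(pt.eval_trig_segment(zero, np.linspace(0, 7, 50)) == 0)

    def test_pure_fundamental_sine(self):
        c = pt.SegmentCoefficients(a=(1, 0, 0), b=(0, 0, 0))
        assert pt.eval_trig_segment(c, [np.pi / 2])[0] == pytest.approx(1.0)

    def test_fixed_middle_at_phase_zero(self):
        # hand evaluation: sin terms vanish, cos terms sum to 23 - 15 - 9
        assert pt.eval_trig_segment(FIXED_MIDDLE, [0.0])[0] == pytest.approx(-1.0)

    def test_amplitude_bound(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            c = pt.sample_segment_coefficients(rng, 40.0)
            y = pt.eval_trig_segment(c, np.linspace(0, 2 * np.pi, 500))
            assert np.max(np.abs(y)) <= c.amplitude_bound() <= 240.0

    def test_rejects_non_finite_phase(self):
        with pytest.raises(ValueError):
            pt.eval_trig_segment(FIXED_MIDDLE, [0.0, np.nan])


class TestCoefficientSampling:
    def test_bounds_and_determinism(self):
        rng = np.random.default_rng(9)
        draws = [pt.sample_segment_coefficients(rng, 40.0) for _ in range(10_000)]
        vals = np.array([c.a + c.b for c in draws])
        assert vals.min() >= -40.0 and vals.max() <= 40.0
        a = pt.sample_segment_coefficients(np.random.default_rng(3), 40.0)
        b = pt.sample_segment_coefficients(np.random.default_rng(3), 40.0)
        assert a == b

    def test_uniformity(self):
        # a uniform sample on [-40, 40] should fill the range and match the
        # uniform CDF; chi-squared over 16 equal bins at 1e5 draws
        rng = np.random.default_rng(11)
        vals = np.concatenate([pt.sample_segment_coefficients(rng, 40.0).a
                               + pt.sample_segment_coefficients(rng, 40.0).b
                               for _ in range(9_000)])
        assert vals.min() < -39.5 and vals.max() > 39.5
        counts, _ = np.histogram(vals, bins=16, range=(-40, 40))
        expected = len(vals) / 16
        chi2 = np.sum((counts - expected) ** 2 / expected)
        assert chi2 < 50  # df=15, p~1e-5 cutoff

    def test_rejects_nonpositive_range(self):
        with pytest.raises(ValueError):
            pt.sample_segment_coefficients(np.random.default_rng(0), 0.0)


class TestBuildTrial:
    def test_gapless_concatenation_length(self):
        cfg = pt.GeneratorConfig(gap_length=0, samples_per_segment=50)
        dense = pt.build_trial_trajectory(cfg, pt.Condition("low", "right"),
                                          np.random.default_rng(1))
        assert dense.n_samples == 150
        assert set(dense.segment) == {"random1", "constant", "random2"}

    def test_spline_bridge_continuity(self):
        # first differences across a gap bridge should not exceed the largest
        # within-segment first difference (no jumps introduced)
        cfg = pt.GeneratorConfig()
        for seed in range(100):
            dense = pt.build_trial_trajectory(cfg, pt.Condition("medium", "right"),
                                              np.random.default_rng(seed))
            dy = np.abs(np.diff(dense.y))
            in_seg = dense.segment[:-1] != "gap"
            assert dy[~in_seg].max() <= dy[in_seg].max() * 1.5 + 1e-9

    def test_constant_segment_shared_random_segments_differ(self):
        cfg = pt.GeneratorConfig()
        cond = pt.Condition("medium", "right")
        t1 = pt.generate_trial(cfg, cond, np.random.default_rng(1))
        t2 = pt.generate_trial(cfg, cond, np.random.default_rng(2))
        c1 = t1.y[t1.segment == "constant"]
        c2 = t2.y[t2.segment == "constant"]
        assert np.array_equal(c1, c2)
        r1 = t1.y[t1.segment == "random1"]
        r2 = t2.y[t2.segment == "random1"]
        assert len(c1) > 0 and not np.array_equal(r1[:min(len(r1), len(r2))],
                                                  r2[:min(len(r1), len(r2))])

    def test_degenerate_phase_domain_rejected(self):
        with pytest.raises(ValueError, match="phase"):
            pt.GeneratorConfig(phase_start=1.0, phase_stop=1.0)

    def test_trial_starts_at_screen_centre(self, small_session):
        for t in small_session:
            assert t.x[0] == 0.0
            assert t.y[0] == pytest.approx(0.0, abs=1e-9)


class TestResampling:
    def test_straight_line_closed_form(self):
        line = np.column_stack([np.linspace(0, 100, 41), np.zeros(41)])
        out = pt.resample_constant_speed(line, 10.0)
        assert out.shape == (11, 2)
        np.testing.assert_allclose(np.diff(out[:, 0]), 10.0, rtol=1e-12)

    def test_doubling_speed_halves_count(self):
        rng = np.random.default_rng(4)
        pts = np.column_stack([np.cumsum(rng.uniform(0.5, 1.5, 300)),
                               np.cumsum(rng.normal(0, 2, 300))])
        n1 = len(pt.resample_constant_speed(pts, 3.0))
        n2 = len(pt.resample_constant_speed(pts, 6.0))
        assert abs((n1 - 1) - 2 * (n2 - 1)) <= 2

    def test_spacing_uniform_within_half_percent(self):
        cfg = pt.GeneratorConfig(n_repeats_per_condition=1)
        for seed in range(17):
            cfg2 = pt.GeneratorConfig(seed=seed, n_repeats_per_condition=1)
            for t in pt.generate_session(cfg2):
                sp = np.hypot(np.diff(t.x), np.diff(t.y))
                assert sp.std() / sp.mean() < 0.005

    def test_degenerate_speed_gives_two_points(self, caplog):
        line = np.column_stack([[0.0, 1.0], [0.0, 0.0]])
        out = pt.resample_constant_speed(line, 50.0)
        assert out.shape == (2, 2)

    def test_points_lie_on_polyline(self):
        rng = np.random.default_rng(8)
        pts = np.column_stack([np.cumsum(rng.uniform(0.5, 1.5, 200)),
                               np.cumsum(rng.normal(0, 3, 200))])
        out = pt.resample_constant_speed(pts, 4.0)
        # each output point within numerical tolerance of some input segment
        for q in out[:-1:7]:
            d = []
            for i in range(len(pts) - 1):
                a, b = pts[i], pts[i + 1]
                ab = b - a
                t = np.clip(np.dot(q - a, ab) / np.dot(ab, ab), 0, 1)
                d.append(np.hypot(*(a + t * ab - q)))
            assert min(d) < 1e-8


class TestDirectionAndSession:
    def test_mirror_is_involution(self, small_session):
        t = small_session[0]
        twice = pt.apply_direction(pt.apply_direction(t, "left"), "right")
        back = pt.apply_direction(twice, t.condition.side)
        np.testing.assert_array_equal(back.x, t.x)

    def test_left_trials_strictly_decreasing(self, small_session):
        for t in small_session:
            dx = np.diff(t.x)
            if t.condition.side == "left":
                assert np.all(dx < 0)
            else:
                assert np.all(dx > 0)

    def test_default_session_size_and_counterbalance(self, default_session):
        assert len(default_session) == 72
        from collections import Counter
        counts = Counter((t.condition.velocity_level, t.condition.side)
                         for t in default_session)
        assert len(counts) == 6 and set(counts.values()) == {12}

    def test_minimal_grid(self):
        trials = pt.generate_session(pt.GeneratorConfig(n_repeats_per_condition=1))
        assert len(trials) == 6
        assert len({(t.condition.velocity_level, t.condition.side) for t in trials}) == 6

    def test_session_determinism(self):
        cfg = pt.GeneratorConfig(seed=33, n_repeats_per_condition=1)
        s1 = pt.generate_session(cfg)
        s2 = pt.generate_session(cfg)
        for a, b in zip(s1, s2):
            assert a.condition == b.condition
            np.testing.assert_array_equal(a.y, b.y)

    def test_y_within_screen_bounds(self, default_session):
        for t in default_session:
            assert np.max(np.abs(t.y)) < t.screen_size[1] / 2

    def test_constant_segment_identical_across_session_trials(self, default_session):
        for level in ("low", "medium", "high"):
            group = [t for t in default_session if t.condition.velocity_level == level]
            ref = group[0]
            ref_y = ref.y[ref.segment == "constant"]
            ref_x = np.abs(ref.x)[ref.segment == "constant"]
            for t in group[1:]:
                np.testing.assert_array_equal(t.y[t.segment == "constant"], ref_y)
                np.testing.assert_array_equal(np.abs(t.x)[t.segment == "constant"], ref_x)
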