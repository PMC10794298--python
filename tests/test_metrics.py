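"""Error metrics, segment/block summaries and QC rules."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import pursuittrack as pt


class TestReducers:
    def test_constant_series(self):
        assert pt.trial_error_reduce(np.full(10, 4.0), "mean") == 4.0
        assert pt.trial_error_reduce(np.full(10, 4.0), "rmse") == pytest.approx(4.0)

    def test_two_point_closed_form(self):
        assert pt.trial_error_reduce([0.0, 2.0], "mean") == 1.0
        assert pt.trial_error_reduce([0.0, 2.0], "rmse") == pytest.approx(np.sqrt(2.0))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            pt.trial_error_reduce([], "mean")

    @given(st.lists(st.floats(min_value=0, max_value=1e4), min_size=1, max_size=50))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_rmse_at_least_mean(self, errors):
        assert pt.trial_error_reduce(errors, "rmse") >= \
            pt.trial_error_reduce(errors, "mean") - 1e-9


class TestErrorSeries:
    def test_temporal_is_elementwise_absolute_difference(self, small_session):
        ts = pt.simulate_pursuit(small_session[0], pt.PursuitModel(lag=5, noise_sd=4, seed=1))
        np.testing.assert_array_equal(pt.temporal_error_series(ts),
                                      np.abs(ts.cursor_y - ts.target_y))

    def test_spatial_recomputes_from_assignment_table(self, small_session):
        ts = pt.simulate_pursuit(small_session[1], pt.PursuitModel(lag=6, noise_sd=3, seed=4))
        a = pt.analyze_trial(ts)
        s = a.series
        recomputed = np.hypot(s.cursor_x - a.assignments.intended_x,
                              s.cursor_y - a.assignments.intended_y)
        np.testing.assert_allclose(pt.spatial_error_series(a.assignments),
                                   recomputed, rtol=1e-12)

    def test_anticipation_rate_bounds(self):
        assert pt.anticipation_rate([False] * 5) == 0.0
        assert pt.anticipation_rate([True] * 5) == 1.0
        assert pt.anticipation_rate([True, False], mask=[True, False]) == 1.0


class TestSegmentSummary:
    def test_constant_error_everywhere(self, small_session):
        ts = pt.simulate_pursuit(small_session[0], pt.PursuitModel(lag=0, noise_sd=0, offset=7))
        a = pt.analyze_trial(ts)
        table = pt.segment_summary(a.series, a.temporal_error, a.spatial_error, a.anticipated)
        np.testing.assert_allclose(table["temporal_mean"], 7.0, atol=1e-9)

    def test_random_avg_is_mean_of_random_segments(self, small_session):
        ts = pt.simulate_pursuit(small_session[2], pt.PursuitModel(lag=6, noise_sd=3, seed=8))
        a = pt.analyze_trial(ts)
        t = pt.segment_summary(a.series, a.temporal_error, a.spatial_error, a.anticipated)
        t = t.set_index("scope")
        for col in ("temporal_mean", "spatial_mean", "anticipation_rate"):
            assert t.loc["random_avg", col] == pytest.approx(
                (t.loc["random1", col] + t.loc["random2", col]) / 2.0)

    def test_gap_samples_fold_into_adjacent_random(self):
        labels = ["random1"] * 3 + ["gap"] * 2 + ["constant"] * 3 + ["gap"] * 2 + ["random2"] * 3
        out = pt.effective_segments(labels)
        assert list(out) == ["random1"] * 5 + ["constant"] * 3 + ["random2"] * 5

    def test_whole_trial_mean_is_weighted_segment_mean(self, small_session):
        ts = pt.simulate_pursuit(small_session[3], pt.PursuitModel(lag=6, noise_sd=3, seed=2))
        a = pt.analyze_trial(ts)
        t = pt.segment_summary(a.series, a.temporal_error, a.spatial_error, a.anticipated)
        t = t.set_index("scope")
        segs = t.loc[["random1", "constant", "random2"]]
        weighted = np.average(segs["temporal_mean"], weights=segs["n_samples"])
        assert t.loc["trial", "temporal_mean"] == pytest.approx(weighted)

    def test_doubled_noise_on_random_segments_detected(self, small_session):
        # construct asymmetry: extra noise outside the constant segment
        traj = small_session[4]
        ts = pt.simulate_pursuit(traj, pt.PursuitModel(lag=0, noise_sd=0))
        rng = np.random.default_rng(12)
        extra = rng.normal(0, 25, ts.n_samples)
        extra[pt.effective_segments(ts.segment) == "constant"] = 0.0
        ts.cursor_y = ts.cursor_y + extra
        a = pt.analyze_trial(ts)
        t = pt.segment_summary(a.series, a.temporal_error, a.spatial_error,
                               a.anticipated).set_index("scope")
        assert t.loc["constant", "temporal_mean"] < t.loc["random_avg", "temporal_mean"]

    def test_missing_labels_rejected(self, small_session):
        ts = pt.simulate_pursuit(small_session[0], pt.PursuitModel(lag=0, noise_sd=0))
        ts.segment = np.array(["mystery"] * ts.n_samples, dtype=object)
        a_err = np.zeros(ts.n_samples)
        with pytest.raises(ValueError, match="segment"):
            pt.segment_summary(ts, a_err, a_err, a_err.astype(bool))


class TestBlocks:
    def test_exact_division(self):
        np.testing.assert_array_equal(np.bincount(pt.assign_blocks(72, 3))[1:], [24, 24, 24])

    def test_remainder_to_earlier_blocks(self):
        np.testing.assert_array_equal(np.bincount(pt.assign_blocks(7, 3))[1:], [3, 2, 2])

    def test_contiguous_and_nondecreasing(self):
        ids = pt.assign_blocks(29, 4)
        assert np.all(np.diff(ids) >= 0)

    def test_more_blocks_than_trials_rejected(self):
        with pytest.raises(ValueError):
            pt.assign_blocks(2, 3)


class TestQC:
    def test_start_offset_boundary_is_strict(self, small_session):
        ts = pt.simulate_pursuit(small_session[0], pt.PursuitModel(lag=0, noise_sd=0))
        exactly = pt.inject_start_offset(ts, 100.0)
        assert not pt.qc_flag_start_offset(exactly, threshold=100.0)
        above = pt.inject_start_offset(ts, 100.5)
        assert pt.qc_flag_start_offset(above, threshold=100.0)

    def test_identical_trials_never_flagged(self):
        assert not pt.qc_flag_outliers([5.0] * 10).any()

    def test_flags_invariant_under_reordering(self):
        rng = np.random.default_rng(3)
        vals = rng.uniform(10, 30, 40)
        vals[7] = 500.0
        perm = rng.permutation(40)
        flags = pt.qc_flag_outliers(vals)
        assert pt.qc_flag_outliers(vals[perm])[np.argsort(perm)].tolist() == flags.tolist()

    def test_too_few_trials_rejected(self):
        with pytest.raises(ValueError):
            pt.qc_flag_outliers([1.0, 2.0])


@pytest.fixture(scope="module")
def summary(small_session):
    analyses = []
    for i, traj in enumerate(small_session):
        ts = pt.simulate_pursuit(traj, pt.PursuitModel(lag=6, noise_sd=3),
                                 rng=np.random.default_rng([9, i]))
        analyses.append(pt.analyze_trial(ts))
    return pt.summarize_session(analyses, n_blocks=3)


class TestSessionSummary:
    def test_row_count_trials_times_scopes(self, summary, small_session):
        assert len(summary) == len(small_session) * 5

    def test_blocks_cover_session_in_thirds(self, summary):
        per_trial = summary[summary.scope == "trial"]
        np.testing.assert_array_equal(np.bincount(per_trial.block)[1:], [4, 4, 4])

    def test_anticipation_rate_within_unit_interval(self, summary):
        assert summary.anticipation_rate.between(0, 1).all()

    def test_reducer_column_selection(self, small_session):
        ts = pt.simulate_pursuit(small_session[0], pt.PursuitModel(lag=6, noise_sd=3, seed=1))
        analyses = [pt.analyze_trial(ts)] * 3
        rmse = pt.summarize_session(analyses, reducer="rmse")
        assert (rmse["temporal_error"] == rmse["temporal_rmse"]).all()
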