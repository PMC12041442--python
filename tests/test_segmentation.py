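import numpy as np
import pandas as pd
import pytest

from flushcurve.gompertz import gompertz
from flushcurve.segmentation import (FlushBoundaries, SegmentationConfig,
                                     boundary_rmse, build_weights,
                                     daily_change, find_boundaries,
                                     first_harvest_day, pool_series,
                                     rolling_mean, segment,
                                     sensitivity_analysis, smooth_cumulative,
                                     split_flushes)
from flushcurve.simulate import (ExperimentDesign, PauseSpec,
                                 evenly_spaced_flush_truths,
                                 simulate_experiment)


def one_bed_table(stems, bed="b1", block="B1", trt="R"):
    return pd.DataFrame({"bed_id": bed, "block_id": block, "treatment": trt,
                         "day": np.arange(len(stems)), "stems": stems})


class TestPooling:
    def test_sum_over_beds(self):
        frames = [one_bed_table([0, 1, 0], bed=f"b{i}", block="B1")
                  for i in range(15)]
        pooled = pool_series(pd.concat(frames, ignore_index=True))
        assert pooled.loc[1] == 15
        assert pooled.loc[2] == 15  # cumulative

    def test_single_bed_identity(self):
        t = one_bed_table([1, 2, 0, 3])
        pooled = pool_series(t)
        np.testing.assert_array_equal(pooled.to_numpy(), [1, 3, 3, 6])

    def test_monotone(self, default_dataset):
        pooled = pool_series(default_dataset.yield_table)
        assert (np.diff(pooled.to_numpy()) >= 0).all()


class TestSmoothing:
    @pytest.mark.parametrize("method", ["gam", "loess"])
    def test_linear_series_reproduced(self, method):
        days = np.arange(100)
        pooled = pd.Series(5.0 * days + 40.0, index=days)
        cfg = SegmentationConfig(method=method)
        fitted = smooth_cumulative(pooled, cfg)
        np.testing.assert_allclose(fitted.to_numpy(), pooled.to_numpy(),
                                   rtol=1e-6)

    def test_gompertz_curve_residual_bound(self):
        """A basis dimension of 18 tracks one smooth sigmoid to <1% of A."""
        days = np.arange(150)
        pooled = pd.Series(gompertz(days, 5000.0, 2.0, 0.08), index=days)
        fitted = smooth_cumulative(pooled, SegmentationConfig(gam_basis_dim=18))
        assert np.max(np.abs(fitted - pooled)) < 0.01 * 5000.0

    @pytest.mark.parametrize("method", ["gam", "loess"])
    def test_constant_series(self, method):
        pooled = pd.Series(7.0, index=np.arange(80))
        fitted = smooth_cumulative(pooled, SegmentationConfig(method=method))
        np.testing.assert_allclose(fitted.to_numpy(), 7.0, atol=1e-6)

    def test_too_short_series_reports_minimum(self):
        pooled = pd.Series(np.arange(10.0), index=np.arange(10))
        with pytest.raises(ValueError, match="need >"):
            smooth_cumulative(pooled, SegmentationConfig(gam_basis_dim=18))


class TestRateSeries:
    def test_constant_diffs(self):
        s = pd.Series(np.full(20, 3.0), index=np.arange(20))
        rm = rolling_mean(s, 7)
        np.testing.assert_allclose(rm.to_numpy(), 3.0)

    def test_single_spike_window_mean(self):
        s = pd.Series([0, 0, 0, 7, 0, 0, 0], index=np.arange(7), dtype=float)
        rm = rolling_mean(s, 7)
        assert rm.iloc[3] == pytest.approx(1.0)

    def test_centered_window_preserves_linear_trend(self):
        s = pd.Series(2.0 * np.arange(30) + 1, index=np.arange(30))
        rm = rolling_mean(s, 7)
        np.testing.assert_allclose(rm.iloc[3:-3], s.iloc[3:-3])

    def test_daily_change_is_diff(self):
        s = pd.Series([1.0, 4.0, 9.0], index=[5, 6, 7])
        d = daily_change(s)
        np.testing.assert_allclose(d.to_numpy(), [3.0, 5.0])
        assert list(d.index) == [6, 7]


class TestFindBoundaries:
    def test_concave_rate_has_no_boundaries(self):
        days = np.arange(100)
        rate = pd.Series(-((days - 50.0) ** 2), index=days)
        with pytest.warns(UserWarning, match="no interior local minima"):
            b = find_boundaries(rate, SegmentationConfig())
        assert b.boundary_days == []

    def test_close_minima_merge_to_deeper(self):
        days = np.arange(200)
        rate = np.full(200, 10.0)
        rate[60], rate[100] = 2.0, 1.0  # 40 days apart < 2*30
        b = find_boundaries(pd.Series(rate, index=days),
                            SegmentationConfig(candidate_window_halfwidth=30))
        assert b.boundary_days == [100]

    def test_argmin_tie_prefers_earlier_day(self):
        days = np.arange(120)
        rate = np.full(120, 5.0)
        rate[58:62] = 1.0  # flat plateau minimum
        b = find_boundaries(pd.Series(rate, index=days),
                            SegmentationConfig(candidate_window_halfwidth=15))
        assert b.boundary_days == [58]

    def test_two_sigmoid_boundary_recovered(self):
        """Generator truth comparison: boundary at day 136 found within 3 days."""
        design = ExperimentDesign(horizon=91 + 2 * 45)
        fl = evenly_spaced_flush_truths(design, n_flushes=2)
        ds = simulate_experiment(design, fl, seed=0)
        cfg = SegmentationConfig(method="loess", loess_span=0.2,
                                 candidate_window_halfwidth=15)
        b = segment(ds.yield_table, cfg)
        assert len(b.boundary_days) == 1
        assert abs(b.boundary_days[0] - fl[1].start_day) <= 3


class TestSensitivity:
    def test_rmse_identities(self):
        assert boundary_rmse([129, 186, 240], [129, 186, 240]) == 0.0
        assert boundary_rmse([131, 188, 242], [129, 186, 240]) == pytest.approx(2.0)

    def test_mismatched_counts_not_comparable(self):
        with pytest.raises(ValueError, match="not comparable"):
            boundary_rmse([1, 2], [1, 2, 3])

    def test_report_on_synthetic_experiment(self):
        design = ExperimentDesign(horizon=91 + 8 * 45)
        fl = evenly_spaced_flush_truths(design, sigma_bed_A=80, sigma_block=50)
        ds = simulate_experiment(design, fl, seed=1)
        ref = SegmentationConfig(method="loess", loess_span=0.06,
                                 candidate_window_halfwidth=15)
        rep = sensitivity_analysis(ds.yield_table, gam_dims=[40],
                                   spans=[0.05, 0.06, 0.08], reference=ref)
        ref_row = rep.grid[(rep.grid.method == "loess") & (rep.grid.value == 0.06)]
        assert ref_row["rmse"].iloc[0] == 0.0
        assert rep.grid["comparable"].any()
        assert rep.recommended is not None


class TestSplitFlushes:
    def test_offset_removal_and_partition(self, default_dataset, true_boundaries):
        table = default_dataset.yield_table
        fl = split_flushes(table, true_boundaries)
        # y' starts at zero for every flush after the first
        firsts = fl[fl.flush > 1].groupby(["flush", "bed_id"]).first()
        assert (firsts["y_prime"] == 0).all()
        # reconstruction: y' + y_k reproduces the original cumulative exactly
        offs = true_boundaries.per_bed_offsets.set_index(["flush", "bed_id"])["y_k"]
        merged = fl.join(offs, on=["flush", "bed_id"])
        rebuilt = merged["y_prime"] + merged["y_k"]
        orig = table.set_index(["bed_id", "day"])["cumulative"]
        np.testing.assert_array_equal(
            rebuilt.to_numpy(),
            orig.loc[list(zip(merged["bed_id"], merged["day"]))].to_numpy())

    def test_partition_covers_every_day_once(self, default_dataset, true_boundaries):
        fl = split_flushes(default_dataset.yield_table, true_boundaries)
        first = first_harvest_day(default_dataset.yield_table)
        for bed, grp in fl.groupby("bed_id"):
            days = np.sort(grp["day"].to_numpy())
            assert days[0] == first
            assert (np.diff(days) == 1).all()

    def test_boundary_outside_range_rejected(self, default_dataset):
        bad = FlushBoundaries(boundary_days=[9999], config=SegmentationConfig())
        with pytest.raises(ValueError, match="outside data range"):
            split_flushes(default_dataset.yield_table, bad)


class TestWeights:
    def test_pause_window_downweighted(self, flush_table):
        sub = flush_table[flush_table.flush == 3]
        w = build_weights(sub, PauseSpec(201, 213, 220))
        days = sub["day"].to_numpy()
        assert (w[(days >= 201) & (days <= 220)] == 0.01).all()
        assert (w[(days < 201) | (days > 220)] == 1.0).all()

    def test_no_pause_all_ones(self, flush_table):
        sub = flush_table[flush_table.flush == 3]
        w = build_weights(sub, None)
        assert w.shape == (len(sub),)
        assert (w == 1.0).all()
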