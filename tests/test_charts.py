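"""Multivariate control charts: deviations, bootstrap limits, flagging."""

import numpy as np
import pandas as pd
import pytest

import ecomcc as ec
from ecomcc.charts import _cell_block_sums, _deviations_from_blocks, plot_time_points

from conftest import design_metadata, euclidean_dm


def series_dm(positions_by_plot):
    """Euclidean 1-D fixture: {plot: [[reps at t1], [reps at t2], ...]}.

    Returns (D, metadata) with sample ids encoding plot/time/replicate.
    """
    coords, rows, ids = [], [], []
    for plot, series in positions_by_plot.items():
        for t, reps in enumerate(series):
            for r, x in enumerate(reps):
                ids.append(f"{plot}_t{t + 1}_r{r + 1}")
                coords.append([float(x)])
                rows.append(dict(site="siteA", plot=plot, time=str(2000 + t),
                                 replicate=f"r{r + 1}"))
    md = pd.DataFrame(rows, index=ids)
    return euclidean_dm(coords, ids=ids), md


class TestPlotTimePoints:
    def test_single_replicate_is_the_sample(self):
        D, md = series_dm({"p1": [[0.0], [2.0]]})
        layout = plot_time_points(md, D.sample_ids)
        assert len(layout) == 1
        assert [c.size for c in layout[0].cells] == [1, 1]

    def test_identical_replicates_zero_dispersion(self):
        D, md = series_dm({"p1": [[3.0, 3.0, 3.0, 3.0], [5.0]]})
        layout = plot_time_points(md, D.sample_ids)
        cell = layout[0].cells[0]
        assert ec.centroid_sq_distance(D, cell, cell) == pytest.approx(0.0, abs=1e-12)

    def test_replicate_centroid_behaves_as_midpoint(self):
        D, md = series_dm({"p1": [[0.0, 2.0], [5.0]]})
        layout = plot_time_points(md, D.sample_ids)
        d = np.sqrt(ec.centroid_sq_distance(D, layout[0].cells[0], layout[0].cells[1]))
        assert d == pytest.approx(4.0, abs=1e-10)

    def test_missing_cell_warns(self):
        D, md = series_dm({"p1": [[0.0], [1.0], [2.0]], "p2": [[0.0], [1.0]]})
        with pytest.warns(RuntimeWarning, match="missing time"):
            plot_time_points(md, D.sample_ids)


class TestChartBaseline:
    def test_constant_community_all_zero(self):
        D, md = series_dm({"p1": [[1.0], [1.0], [1.0]]})
        chart = ec.chart_baseline(D, md, ec.ChartSpec(n_boot=1))
        np.testing.assert_allclose(chart.deviations[("siteA", "p1")][1], 0.0, atol=1e-12)

    def test_euclidean_series_oracle(self):
        # series 0, 2, 5 with m=2: baseline centroid at 1 -> d = (1, 1, 4)
        D, md = series_dm({"p1": [[0.0], [2.0], [5.0]]})
        chart = ec.chart_baseline(D, md, ec.ChartSpec(baseline_size=2, n_boot=1))
        np.testing.assert_allclose(chart.deviations[("siteA", "p1")][1], [1, 1, 4], atol=1e-10)

    def test_m1_baseline_time_zero(self):
        D, md = series_dm({"p1": [[0.0], [3.0]]})
        chart = ec.chart_baseline(D, md, ec.ChartSpec(baseline_size=1, n_boot=1))
        d = chart.deviations[("siteA", "p1")][1]
        assert d[0] == pytest.approx(0.0, abs=1e-12)
        assert d[1] == pytest.approx(3.0, abs=1e-10)

    def test_too_few_times_names_plot(self):
        D, md = series_dm({"p9": [[0.0]]})
        with pytest.raises(ValueError, match="p9"):
            ec.chart_baseline(D, md, ec.ChartSpec(baseline_size=2, n_boot=1))


class TestChartSequential:
    def test_constant_community_all_zero(self):
        D, md = series_dm({"p1": [[2.0], [2.0], [2.0]]})
        chart = ec.chart_sequential(D, md, ec.ChartSpec(chart_type="sequential", n_boot=1))
        np.testing.assert_allclose(chart.deviations[("siteA", "p1")][1], 0.0, atol=1e-12)

    def test_euclidean_series_oracle(self):
        # d_2 = |2-0| = 2; d_3 = |5 - mean(0,2)| = 4
        D, md = series_dm({"p1": [[0.0], [2.0], [5.0]]})
        chart = ec.chart_sequential(D, md, ec.ChartSpec(chart_type="sequential", n_boot=1))
        times, d = chart.deviations[("siteA", "p1")]
        assert times == ["2001", "2002"]
        np.testing.assert_allclose(d, [2.0, 4.0], atol=1e-10)

    def test_pulse_at_final_time_is_maximum(self):
        D, md = series_dm({"p1": [[1.0], [1.2], [0.9], [1.1], [9.0]]})
        chart = ec.chart_sequential(D, md, ec.ChartSpec(chart_type="sequential", n_boot=1))
        _, d = chart.deviations[("siteA", "p1")]
        assert d.argmax() == len(d) - 1


class TestEuclideanChartOracle:
    def test_both_charts_match_coordinate_centroids(self, rng):
        # replicated multivariate Euclidean data vs explicit centroid arithmetic
        n_plots, n_times, n_reps, p = 3, 5, 4, 2
        coords = rng.normal(size=(n_plots * n_times * n_reps, p))
        md = design_metadata(n_plots, n_times, n_reps)
        D = euclidean_dm(coords, ids=list(md.index))
        m = 2
        base_chart = ec.chart_baseline(D, md, ec.ChartSpec(baseline_size=m, n_boot=1))
        seq_chart = ec.chart_sequential(
            D, md, ec.ChartSpec(chart_type="sequential", n_boot=1))
        pos = {s: i for i, s in enumerate(md.index)}
        for pi in range(n_plots):
            plot = f"p{pi + 1}"
            cells = [
                np.array([pos[s] for s in md.index
                          if md.loc[s, "plot"] == plot and md.loc[s, "time"] == str(2000 + t)])
                for t in range(n_times)
            ]
            cell_centroids = [coords[c].mean(axis=0) for c in cells]
            base_centroid = coords[np.concatenate(cells[:m])].mean(axis=0)
            expected_base = [np.linalg.norm(c - base_centroid) for c in cell_centroids]
            np.testing.assert_allclose(
                base_chart.deviations[("siteA", plot)][1], expected_base, atol=1e-10)
            expected_seq = [
                np.linalg.norm(
                    cell_centroids[t] - coords[np.concatenate(cells[:t])].mean(axis=0))
                for t in range(1, n_times)
            ]
            np.testing.assert_allclose(
                seq_chart.deviations[("siteA", plot)][1], expected_seq, atol=1e-10)


class TestReplicateLevelCharts:
    def test_each_replicate_charted_against_observation_reference(self):
        D, md = series_dm({"p1": [[0.0, 2.0], [4.0, 6.0], [10.0]]})
        spec = ec.ChartSpec(chart_type="sequential", n_boot=5, replicate_level=True)
        chart = ec.chart_sequential(D, md, spec)
        times, d = chart.deviations[("siteA", "p1")]
        # t2: replicates at 4 and 6 vs centroid(0,2)=1; t3: 10 vs centroid(0,2,4,6)=3
        assert times == ["2001", "2001", "2002"]
        np.testing.assert_allclose(d, [3.0, 5.0, 7.0], atol=1e-10)
        assert chart.time_indices[("siteA", "p1")] == [2, 2, 3]

    def test_singleton_replicates_match_observation_level(self):
        D, md = series_dm({"p1": [[0.0], [2.0], [5.0]]})
        for builder, ctype in ((ec.chart_baseline, "baseline"),
                               (ec.chart_sequential, "sequential")):
            plain = builder(D, md, ec.ChartSpec(chart_type=ctype, n_boot=5))
            rep = builder(D, md, ec.ChartSpec(chart_type=ctype, n_boot=5,
                                              replicate_level=True))
            np.testing.assert_allclose(rep.deviations[("siteA", "p1")][1],
                                       plain.deviations[("siteA", "p1")][1], atol=1e-12)

    def test_flag_table_has_one_row_per_replicate(self):
        D, md = series_dm({"p1": [[0.0, 1.0], [2.0, 3.0], [4.0, 5.0]],
                           "p2": [[0.0, 1.0], [2.0, 3.0], [4.0, 5.0]]})
        spec = ec.ChartSpec(baseline_size=2, n_boot=20, replicate_level=True, seed=2)
        chart = ec.chart_baseline(D, md, spec)
        limits = ec.bootstrap_limits(D, md, spec)
        table = ec.flag_out_of_control(chart, limits)
        assert len(table) == 2 * 3 * 2  # plots x times x replicates


class TestBlockSums:
    def test_identity_order_reproduces_chart(self, rng):
        coords = rng.normal(size=(3 * 4 * 2, 3))
        md = design_metadata(3, 4, 2)
        D = euclidean_dm(coords, ids=list(md.index))
        layout = plot_time_points(md, D.sample_ids)
        spec = ec.ChartSpec(baseline_size=2, n_boot=1)
        chart = ec.chart_baseline(D, md, spec)
        for ps in layout:
            S, sizes = _cell_block_sums(D, ps)
            d = _deviations_from_blocks(S, sizes, np.arange(len(ps.cells)), "baseline", 2)
            np.testing.assert_allclose(d, chart.deviations[ps.plot][1], atol=1e-10)


class TestBootstrapLimits:
    def test_constant_communities_zero_limits(self):
        D, md = series_dm({"p1": [[1.0], [1.0], [1.0]], "p2": [[4.0], [4.0], [4.0]]})
        spec = ec.ChartSpec(n_boot=50, seed=1)
        lim = ec.bootstrap_limits(D, md, spec)
        assert lim.global_limits[50.0] == pytest.approx(0.0, abs=1e-12)
        assert lim.global_limits[95.0] == pytest.approx(0.0, abs=1e-12)

    def test_single_plot_sequential_percentiles_coincide(self):
        D, md = series_dm({"p1": [[0.0], [2.0], [5.0], [1.0]]})
        spec = ec.ChartSpec(chart_type="sequential", n_boot=30, seed=2)
        lim = ec.bootstrap_limits(D, md, spec)
        for t in lim.per_time_limits[50.0]:
            assert lim.per_time_limits[50.0][t] == pytest.approx(
                lim.per_time_limits[95.0][t], abs=1e-12)

    def test_95th_at_least_50th(self, rng):
        coords = rng.normal(size=(3 * 5 * 2, 2))
        md = design_metadata(3, 5, 2)
        D = euclidean_dm(coords, ids=list(md.index))
        for ctype in ("baseline", "sequential"):
            spec = ec.ChartSpec(chart_type=ctype, n_boot=50, seed=3)
            lim = ec.bootstrap_limits(D, md, spec)
            if ctype == "baseline":
                assert lim.global_limits[95.0] >= lim.global_limits[50.0]
            else:
                for t in lim.per_time_limits[50.0]:
                    assert lim.per_time_limits[95.0][t] >= lim.per_time_limits[50.0][t]

    def test_seed_reproducibility(self, rng):
        coords = rng.normal(size=(2 * 4 * 2, 2))
        md = design_metadata(2, 4, 2)
        D = euclidean_dm(coords, ids=list(md.index))
        spec = ec.ChartSpec(n_boot=100, seed=11)
        l1 = ec.bootstrap_limits(D, md, spec)
        l2 = ec.bootstrap_limits(D, md, spec)
        assert l1.global_limits == l2.global_limits

    def test_monotonicity_under_distance_scaling(self, rng):
        coords = rng.normal(size=(2 * 4 * 3, 2))
        md = design_metadata(2, 4, 3)
        D = euclidean_dm(coords, ids=list(md.index))
        c = 2.5
        D2 = ec.DissimilarityMatrix(D.sample_ids, D.values * c, kind="general")
        spec = ec.ChartSpec(n_boot=60, seed=5)
        chart1, chart2 = ec.chart_baseline(D, md, spec), ec.chart_baseline(D2, md, spec)
        lim1, lim2 = ec.bootstrap_limits(D, md, spec), ec.bootstrap_limits(D2, md, spec)
        for key in chart1.deviations:
            np.testing.assert_allclose(
                chart2.deviations[key][1], c * chart1.deviations[key][1], atol=1e-10)
        assert lim2.global_limits[95.0] == pytest.approx(c * lim1.global_limits[95.0], rel=1e-10)
        f1 = ec.flag_out_of_control(chart1, lim1)["flag"]
        f2 = ec.flag_out_of_control(chart2, lim2)["flag"]
        assert (f1 == f2).all()


class TestSelfExceedanceCalibration:
    def test_baseline_limit_near_nominal_on_long_stationary_series(self):
        # 3 plots x 20 times: the fraction of observed pooled deviations above
        # the 95th limit should sit near 5% (mean-of-bootstrap-percentiles
        # limits and sampling noise prevent exactness)
        cfg = ec.SimulationConfig(seed=17, n_plots=3, n_times=20, n_replicates=2)
        M, _ = ec.simulate_community(cfg)
        D = ec.bray_curtis(ec.fourth_root_transform(M))
        spec = ec.ChartSpec(chart_type="baseline", n_boot=1000, seed=3)
        chart = ec.chart_baseline(D, M.metadata, spec)
        limits = ec.bootstrap_limits(D, M.metadata, spec)
        pooled = chart.pooled()
        frac = (pooled > limits.global_limits[95.0]).mean()
        assert abs(frac - 0.05) <= 0.03


class TestFlagging:
    def test_mismatched_types_rejected(self):
        D, md = series_dm({"p1": [[0.0], [2.0], [5.0]]})
        chart = ec.chart_baseline(D, md, ec.ChartSpec(n_boot=5))
        lim = ec.bootstrap_limits(D, md, ec.ChartSpec(chart_type="sequential", n_boot=5))
        with pytest.raises(ValueError, match="does not match"):
            ec.flag_out_of_control(chart, lim)

    def test_deviations_at_50th_not_flagged(self):
        D, md = series_dm({"p1": [[1.0], [1.0], [1.0]], "p2": [[2.0], [2.0], [2.0]]})
        chart = ec.chart_baseline(D, md, ec.ChartSpec(n_boot=20))
        lim = ec.bootstrap_limits(D, md, ec.ChartSpec(n_boot=20))
        assert not ec.flag_out_of_control(chart, lim)["flag"].any()

    def test_constructed_pulse_flags_exactly_final_time(self):
        # stable series in two plots; one aberrant final value in p1
        D, md = series_dm({
            "p1": [[1.0], [1.1], [0.9], [1.0], [9.0]],
            "p2": [[2.0], [2.1], [1.9], [2.0], [2.05]],
        })
        spec = ec.ChartSpec(chart_type="sequential", n_boot=200, seed=7)
        chart = ec.chart_sequential(D, md, spec)
        lim = ec.bootstrap_limits(D, md, spec)
        table = ec.flag_out_of_control(chart, lim)
        flagged = table[table["flag"]]
        assert len(flagged) == 1
        assert flagged.iloc[0]["plot"] == "p1"
        assert flagged.iloc[0]["time"] == "2004"

    def test_sequential_first_point_unstable(self):
        D, md = series_dm({"p1": [[0.0], [1.0], [2.0]]})
        spec = ec.ChartSpec(chart_type="sequential", n_boot=10)
        table = ec.flag_out_of_control(
            ec.chart_sequential(D, md, spec), ec.bootstrap_limits(D, md, spec))
        assert table.iloc[0]["unstable"] and not table.iloc[1:]["unstable"].any()

    def test_baseline_times_not_flagged_by_default(self):
        D, md = series_dm({"p1": [[0.0], [50.0], [0.0], [0.4]]})
        spec = ec.ChartSpec(baseline_size=2, n_boot=100, seed=3)
        chart = ec.chart_baseline(D, md, spec)
        lim = ec.bootstrap_limits(D, md, spec)
        table = ec.flag_out_of_control(chart, lim)
        assert not table.iloc[:2]["flag"].any()


class TestPseudoPlots:
    def test_twelve_replicates_three_plots_of_four(self):
        md = pd.DataFrame(
            {"site": ["s"] * 12, "plot": ["na"] * 12, "time": ["2006"] * 12,
             "replicate": [f"r{i}" for i in range(12)]},
            index=[f"x{i}" for i in range(12)])
        labels = ec.assign_pseudo_plots(md, k=3, seed=1)
        counts = labels.value_counts()
        assert sorted(counts) == [4, 4, 4]

    def test_ten_replicates_sizes_differ_by_at_most_one(self):
        md = pd.DataFrame(
            {"site": ["s"] * 10, "plot": ["na"] * 10, "time": ["2006"] * 10,
             "replicate": [f"r{i}" for i in range(10)]},
            index=[f"x{i}" for i in range(10)])
        counts = ec.assign_pseudo_plots(md, k=3, seed=2).value_counts()
        assert sorted(counts) == [3, 3, 4]

    def test_same_seed_identical(self):
        md = pd.DataFrame(
            {"site": ["s"] * 8, "plot": ["na"] * 8,
             "time": ["2006"] * 4 + ["2007"] * 4,
             "replicate": [f"r{i}" for i in range(4)] * 2},
            index=[f"x{i}" for i in range(8)])
        a = ec.assign_pseudo_plots(md, k=2, seed=9)
        b = ec.assign_pseudo_plots(md, k=2, seed=9)
        assert (a == b).all()

    def test_too_few_samples_names_time(self):
        md = pd.DataFrame(
            {"site": ["s"] * 2, "plot": ["na"] * 2, "time": ["2007"] * 2,
             "replicate": ["r1", "r2"]}, index=["x1", "x2"])
        with pytest.raises(ValueError, match="2007"):
            ec.assign_pseudo_plots(md, k=3, seed=0)
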