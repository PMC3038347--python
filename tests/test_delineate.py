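import shutil
import subprocess

import numpy as np
import pytest

from occurange.delineate import (apply_threshold, error_rates,
                                 inclusion_level, kde2d, partition_range,
                                 select_threshold, ste_bandwidth)
from occurange.grids import PresenceRecords, RasterStack


def small_grid(n=40, cell=1.0):
    return RasterStack({"d": np.zeros((n, n))}, cell_size_km=cell,
                       origin=(cell / 2, cell / 2))


class TestErrorRates:
    def test_extreme_thresholds(self):
        pred = np.array([0.1, 0.9])
        truth = np.array([False, True])
        a = error_rates(pred, truth, n_thresholds=101)
        assert a.fnr[0] == 0.0 and a.fpr[0] == 1.0
        assert a.fnr[-1] == 1.0 and a.fpr[-1] == 0.0

    def test_hand_counted_rates(self):
        pred = np.array([0.9, 0.3, 0.2, 0.8])
        truth = np.array([True, True, False, False])
        a = error_rates(pred, truth, n_thresholds=1001)
        i = np.searchsorted(a.thresholds, 0.5)
        assert a.fnr[i] == 0.5
        assert a.fpr[i] == 0.5

    def test_monotone_step_functions(self):
        rng = np.random.default_rng(0)
        pred = rng.random(500)
        truth = rng.random(500) < 0.3
        a = error_rates(pred, truth)
        assert np.all(np.diff(a.fnr) >= 0)
        assert np.all(np.diff(a.fpr) <= 0)

    def test_requires_both_classes(self):
        with pytest.raises(ValueError):
            error_rates(np.array([0.5, 0.6]), np.array([True, True]))


class TestSelectThreshold:
    def test_separable_case_returns_largest_admissible(self):
        pred = np.array([0.7, 0.8, 0.9, 0.1, 0.2])
        truth = np.array([True, True, True, False, False])
        a = error_rates(pred, truth)
        t = select_threshold(a, target_fnr=0.05)
        # largest grid threshold not exceeding the minimum presence score
        # (up to the threshold-grid resolution of 0.001)
        assert 0.7 - 1.5e-3 <= t <= 0.7
        i = np.searchsorted(a.thresholds, t)
        assert a.fnr[i] == 0.0

    def test_target_one_returns_top_of_grid(self):
        pred = np.array([0.2, 0.8])
        truth = np.array([True, False])
        a = error_rates(pred, truth)
        assert select_threshold(a, target_fnr=1.0) == 1.0

    def test_monotone_in_target(self):
        rng = np.random.default_rng(1)
        pred = rng.random(300)
        truth = pred + rng.normal(0, 0.3, 300) > 0.5
        truth[0] = True
        truth[1] = False
        a = error_rates(pred, truth)
        ts = [select_threshold(a, f) for f in (0.01, 0.05, 0.2, 0.5)]
        assert ts == sorted(ts)

    def test_selected_fnr_below_target(self):
        rng = np.random.default_rng(2)
        pred = rng.random(400)
        truth = rng.random(400) < pred
        a = error_rates(pred, truth)
        t = select_threshold(a, 0.05)
        i = np.searchsorted(a.thresholds, t)
        assert a.fnr[i] <= 0.05


class TestSteBandwidth:
    def test_near_gaussian_reference_at_large_n(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(10000)
        h = ste_bandwidth(x)
        h_ref = (4 / (3 * 10000)) ** 0.2 * x.std(ddof=1)
        assert abs(h - h_ref) / h_ref < 0.15

    def test_scale_equivariance(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal(500)
        assert ste_bandwidth(10 * x) == pytest.approx(10 * ste_bandwidth(x),
                                                      rel=1e-6)

    def test_shrinks_at_fifth_root_rate(self):
        rng = np.random.default_rng(5)
        ratios = []
        for _ in range(10):
            x1 = rng.standard_normal(1000)
            x2 = rng.standard_normal(2000)
            ratios.append(ste_bandwidth(x2) / ste_bandwidth(x1))
        assert np.mean(ratios) == pytest.approx(2 ** (-0.2), abs=0.05)

    @pytest.mark.skipif(shutil.which("Rscript") is None,
                        reason="Rscript not available")
    def test_matches_reference_implementation(self, tmp_path):
        # independent oracle: the classic statistical computing
        # implementation of the same solve-the-equation selector
        rng = np.random.default_rng(6)
        x = np.concatenate([rng.standard_normal(400),
                            rng.normal(4, 0.5, 200)])
        f = tmp_path / "x.txt"
        np.savetxt(f, x)
        out = subprocess.run(
            ["Rscript", "-e",
             f'x <- scan("{f}"); cat(bw.SJ(x, method="ste"))'],
            capture_output=True, text=True, timeout=120)
        ref = float(out.stdout.strip())
        assert abs(ste_bandwidth(x) - ref) / ref < 0.03

    def test_degenerate_sample_rejected(self):
        with pytest.raises(ValueError):
            ste_bandwidth(np.ones(50))


class TestKde2d:
    def test_density_peaks_at_cluster(self):
        grid = small_grid(30)
        rng = np.random.default_rng(7)
        pts = PresenceRecords(rng.normal(20, 0.5, 200),
                              rng.normal(10, 0.5, 200))
        s = kde2d(pts, grid, bandwidth=(1.0, 1.0))
        r, c = np.unravel_index(np.argmax(s.density), s.density.shape)
        xs, ys = grid.cell_centres()
        assert abs(xs[c] - 20) <= 1.5 and abs(ys[r] - 10) <= 1.5

    def test_integrates_to_one_when_grid_covers_points(self):
        grid = small_grid(60)
        rng = np.random.default_rng(8)
        pts = PresenceRecords(rng.normal(30, 3, 300), rng.normal(30, 3, 300))
        s = kde2d(pts, grid, bandwidth=(1.5, 1.5))
        assert s.density.sum() * grid.cell_size_km**2 == pytest.approx(
            1.0, abs=0.01)

    def test_linear_in_point_measure(self):
        grid = small_grid(20)
        rng = np.random.default_rng(9)
        a = PresenceRecords(rng.uniform(2, 18, 40), rng.uniform(2, 18, 40))
        b = PresenceRecords(rng.uniform(2, 18, 60), rng.uniform(2, 18, 60))
        pooled = PresenceRecords.concat([a, b])
        da = kde2d(a, grid, (1.0, 1.0)).density
        db = kde2d(b, grid, (1.0, 1.0)).density
        dp = kde2d(pooled, grid, (1.0, 1.0)).density
        np.testing.assert_allclose(dp, (40 * da + 60 * db) / 100,
                                   atol=1e-12)

    def test_zero_bandwidth_rejected(self):
        grid = small_grid(10)
        pts = PresenceRecords([2.0, 3.0], [2.0, 3.0])
        with pytest.raises(ValueError):
            kde2d(pts, grid, bandwidth=(0.0, 1.0))


class TestInclusionLevel:
    def test_fraction_one_includes_all(self):
        grid = small_grid(20)
        rng = np.random.default_rng(10)
        pts = PresenceRecords(rng.uniform(2, 18, 50), rng.uniform(2, 18, 50))
        s = kde2d(pts, grid, (1.0, 1.0))
        level = inclusion_level(s, pts, grid, fraction=1.0)
        assert s.included_fraction == 1.0
        r, c = grid.point_to_cell(pts.x, pts.y)
        assert level == pytest.approx(s.density[r, c].min())

    def test_target_count_ceiling(self):
        grid = small_grid(40)
        rng = np.random.default_rng(11)
        pts = PresenceRecords(rng.uniform(2, 38, 200),
                              rng.uniform(2, 38, 200))
        s = kde2d(pts, grid, (2.0, 2.0))
        inclusion_level(s, pts, grid, fraction=0.995)
        # ceil(0.995 * 200) = 199 of 200 points must fall inside
        r, c = grid.point_to_cell(pts.x, pts.y)
        assert (s.density[r, c] >= s.level).sum() >= 199

    def test_median_level_at_half(self):
        grid = small_grid(30)
        rng = np.random.default_rng(12)
        pts = PresenceRecords(rng.uniform(2, 28, 101),
                              rng.uniform(2, 28, 101))
        s = kde2d(pts, grid, (1.5, 1.5))
        level = inclusion_level(s, pts, grid, fraction=0.5)
        r, c = grid.point_to_cell(pts.x, pts.y)
        frac = (s.density[r, c] >= level).mean()
        assert 0.5 <= frac <= 0.52


class TestPartition:
    def test_level_zero_everything_current(self):
        grid = small_grid(10)
        pts = PresenceRecords([3.0, 6.0], [3.0, 6.0])
        s = kde2d(pts, grid, (1.0, 1.0))
        suitable = np.random.default_rng(13).random((10, 10)) > 0.4
        part = partition_range(suitable, s, 0.0, grid.cell_size_km)
        assert part.area_potential_km2 == 0.0
        assert part.area_current_km2 == part.area_suitable_km2

    def test_level_above_max_nothing_current(self):
        grid = small_grid(10)
        pts = PresenceRecords([3.0, 6.0], [3.0, 6.0])
        s = kde2d(pts, grid, (1.0, 1.0))
        suitable = np.ones((10, 10), dtype=bool)
        part = partition_range(suitable, s, s.density.max() * 2,
                               grid.cell_size_km)
        assert part.area_current_km2 == 0.0

    def test_areas_additive_and_integer_multiples(self):
        grid = small_grid(20, cell=2.0)
        rng = np.random.default_rng(14)
        pts = PresenceRecords(rng.uniform(4, 36, 80), rng.uniform(4, 36, 80))
        s = kde2d(pts, grid, (2.0, 2.0))
        suitable = rng.random((20, 20)) > 0.5
        level = inclusion_level(s, pts, grid, 0.995)
        part = partition_range(suitable, s, level, 2.0)
        assert (part.area_current_km2 + part.area_potential_km2
                == part.area_suitable_km2)
        for a in (part.area_current_km2, part.area_potential_km2):
            assert a % 4.0 == 0.0

    def test_recovers_compact_occupied_core(self):
        # suitable everywhere in a band; occupied core is a tight cluster
        # of sightings: the partition should label >=90% of core cells
        # current
        grid = small_grid(50)
        rng = np.random.default_rng(15)
        pts = PresenceRecords(
            np.clip(rng.normal(15, 3, 1000), 0.6, 49.4),
            np.clip(rng.normal(15, 3, 1000), 0.6, 49.4),
        )
        suitable = np.ones((50, 50), dtype=bool)
        s = kde2d(pts, grid, None)  # solve-the-equation bandwidths
        level = inclusion_level(s, pts, grid, 0.995)
        part = partition_range(suitable, s, level, 1.0)
        xs, ys = grid.cell_centres()
        XX, YY = np.meshgrid(xs, ys)
        core = (np.hypot(XX - 15, YY - 15) < 6)
        labelled_current = part.labels == part.CURRENT
        assert labelled_current[core].mean() >= 0.9


def test_apply_threshold_area_accounting():
    pred = np.array([[0.2, 0.6], [0.8, np.nan]])
    mask, area = apply_threshold(pred, 0.5, cell_size_km=2.0)
    assert mask.sum() == 2
    assert area == 8.0
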