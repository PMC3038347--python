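import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from occurange.grids import RasterStack
from occurange.maxent import (compute_auc, compute_fpa, fit_maxent,
                              jackknife_gain, predict_hsi, roc_summary,
                              training_gain, variable_contributions)


def toy_grid(values, name="v"):
    vals = np.asarray(values, dtype=float).reshape(1, -1)
    return RasterStack({name: vals}, cell_size_km=1.0, origin=(0.5, 0.5))


def brute_force_lambda(x, presence_idx, reg, grid_pts):
    """Maximize the identical regularized objective over a 1D lambda grid."""
    best_lam, best_obj = None, -np.inf
    for lam in grid_pts:
        scores = lam * x
        lse = np.log(np.exp(scores - scores.max()).sum()) + scores.max()
        obj = np.mean(lam * x[presence_idx]) - lse - reg * abs(lam)
        if obj > best_obj:
            best_obj, best_lam = obj, lam
    return best_lam, best_obj


class TestFit:
    def test_uniform_presences_give_zero_weights_and_gain(self):
        rng = np.random.default_rng(0)
        grid = toy_grid(rng.normal(size=400))
        # presences drawn uniformly: max-entropy solution is uniform
        pres = rng.choice(400, 80, replace=False)
        m = fit_maxent(pres, grid, n_background=400, seed=1)
        assert np.abs(m.lambda_).max() < 0.15
        assert abs(training_gain(m, grid=grid)) < 0.05

    def test_matches_brute_force_on_1d_toy(self):
        # 20 cells, presences concentrated at high covariate values
        x = np.linspace(-2, 2, 20)
        grid = toy_grid(x)
        pres = np.array([15, 16, 17, 18, 19])
        m = fit_maxent(pres, grid, n_background=20, features=("linear",),
                       seed=2)
        reg = m.reg_beta[0]
        lam_grid = np.arange(-5, 5, 1e-4)
        lam_bf, _ = brute_force_lambda(x, pres, reg, lam_grid)
        assert abs(m.lambda_[0] - lam_bf) < 1e-3

    def test_deterministic_given_seed(self, landscape, sightings):
        from occurange import bin_to_cells

        mask, _ = bin_to_cells(sightings, landscape)
        cells = np.flatnonzero(mask.ravel())
        a = fit_maxent(cells, landscape, n_background=500, seed=3)
        b = fit_maxent(cells, landscape, n_background=500, seed=3)
        np.testing.assert_array_equal(a.lambda_, b.lambda_)

    def test_objective_monotone_over_iterations(self, landscape, sightings):
        from occurange import bin_to_cells

        mask, _ = bin_to_cells(sightings, landscape)
        cells = np.flatnonzero(mask.ravel())
        m = fit_maxent(cells, landscape, n_background=1000, seed=4)
        assert np.all(np.diff(m.objective_path) >= -1e-8)

    def test_gain_invariant_to_background_order(self):
        # the Gibbs normalization is a sum: permuting cells cannot matter
        rng = np.random.default_rng(5)
        x = rng.normal(size=100)
        perm = rng.permutation(100)
        pres_a = np.array([10, 20, 30])
        m_a = fit_maxent(pres_a, toy_grid(x), n_background=100, seed=6)
        pres_b = np.array([np.flatnonzero(perm == i)[0] for i in pres_a])
        m_b = fit_maxent(pres_b, toy_grid(x[perm]), n_background=100, seed=6)
        ga = training_gain(m_a, grid=toy_grid(x))
        gb = training_gain(m_b, grid=toy_grid(x[perm]))
        assert abs(ga - gb) < 1e-6


class TestPredict:
    def test_uniform_model_predicts_half(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=200)
        grid = toy_grid(x)
        m = fit_maxent(rng.choice(200, 40, replace=False), grid,
                       n_background=200, seed=8)
        m.lambda_[:] = 0.0
        # recompute normalization for the zeroed model
        m.log_partition = np.log(m.n_eval)
        m.entropy_H = np.log(m.n_eval)
        hsi = predict_hsi(m, grid)
        np.testing.assert_allclose(hsi, 0.5)

    def test_monotone_in_covariate_when_linear_only(self):
        x = np.linspace(-2, 2, 30)
        grid = toy_grid(x)
        m = fit_maxent(np.array([26, 27, 28, 29]), grid, n_background=30,
                       features=("linear",), seed=9)
        h = predict_hsi(m, grid).ravel()
        assert np.all(np.diff(h) * np.sign(m.lambda_[0]) >= 0)

    def test_outputs_strictly_inside_unit_interval(self, landscape,
                                                   sightings):
        from occurange import bin_to_cells

        mask, _ = bin_to_cells(sightings, landscape)
        cells = np.flatnonzero(mask.ravel())
        m = fit_maxent(cells, landscape, n_background=1000, seed=10)
        h = predict_hsi(m, landscape)
        assert np.all((h > 0) & (h < 1))


class TestGain:
    def test_exp_gain_is_likelihood_ratio_to_random_cell(self):
        x = np.linspace(-2, 2, 20)
        grid = toy_grid(x)
        pres = np.array([15, 16, 17, 18, 19])
        m = fit_maxent(pres, grid, n_background=20, seed=11)
        g = training_gain(m, grid=grid)
        # direct evaluation: geometric-mean presence probability over the
        # uniform probability, penalized
        scores = m.lambda_ @ np.vstack([x[pres], x[pres] ** 2])
        logq = scores - m.log_partition
        direct = (logq.mean() + np.log(m.n_eval)
                  - m.reg_beta @ np.abs(m.lambda_))
        assert abs(g - direct) < 1e-10
        assert np.exp(g) > 1  # concentrated presences fit better than uniform


class TestAuc:
    def test_perfect_separation_is_exactly_one(self):
        assert compute_auc([0.7, 0.8, 0.9], [0.1, 0.2, 0.3]) == 1.0

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(12)
        auc = compute_auc(rng.random(10000), rng.random(10000))
        se = np.sqrt(1 / 12 / 10000 * 2)  # rough rank-stat SE bound
        assert abs(auc - 0.5) < 5 * se

    def test_tie_counts_half(self):
        # 4 pairs: win, win, tie (1/2), win -> 3.5/4
        assert compute_auc([0.9, 0.8], [0.8, 0.1]) == pytest.approx(0.875)

    # scores on a coarse grid so the transform is exactly injective in
    # floating point (ties are preserved, non-ties stay distinct)
    _scores = st.lists(
        st.integers(0, 1000).map(lambda k: k / 1000.0),
        min_size=2, max_size=30)

    @given(_scores, _scores)
    @settings(max_examples=50, deadline=None)
    def test_invariant_under_monotone_transform(self, pres, bg):
        a = compute_auc(pres, bg)
        # affine map: strictly increasing and preserves ties exactly
        f = lambda v: 3.0 * np.asarray(v) + 1.0
        b = compute_auc(f(pres), f(bg))
        assert a == pytest.approx(b)


class TestFpa:
    def test_threshold_zero_is_one(self):
        assert compute_fpa(np.array([0.2, 0.6, 0.8]), 0.0) == 1.0

    def test_threshold_above_max_is_zero(self):
        assert compute_fpa(np.array([0.2, 0.6, 0.8]), 0.9) == 0.0

    def test_half_of_four_cells(self):
        assert compute_fpa(np.array([0.2, 0.6, 0.8, 0.9]), 0.7) == 0.5

    def test_fpa_non_increasing_in_threshold(self, landscape, sightings):
        from occurange import bin_to_cells

        mask, _ = bin_to_cells(sightings, landscape)
        cells = np.flatnonzero(mask.ravel())
        m = fit_maxent(cells, landscape, n_background=800, seed=13)
        roc = roc_summary(predict_hsi(m, landscape), cells,
                          landscape.nodata_mask)
        assert np.all(np.diff(roc.fpa) <= 1e-12)
        np.testing.assert_allclose(roc.fnr, 1 - roc.sensitivity)


class TestContributions:
    def test_single_covariate_gets_everything(self):
        x = np.linspace(-2, 2, 30)
        grid = toy_grid(x)
        m = fit_maxent(np.array([26, 27, 28, 29]), grid, n_background=30,
                       seed=14)
        c = variable_contributions(m, grid, seed=15)
        assert c.sum() == pytest.approx(100.0)
        assert c["v"] == pytest.approx(100.0)

    def test_zero_weight_covariate_contributes_nothing(self, landscape,
                                                       sightings):
        from occurange import bin_to_cells

        mask, _ = bin_to_cells(sightings, landscape)
        pres = np.flatnonzero(mask.ravel())
        m = fit_maxent(pres, landscape, n_background=1000, seed=17)
        # force one covariate's features to zero weight
        for i, n in enumerate(m.feature_names):
            if n.startswith("cov3"):
                m.lambda_[i] = 0.0
        c = variable_contributions(m, landscape, seed=18)
        assert c.sum() == pytest.approx(100.0)
        assert c["cov3"] == pytest.approx(0.0, abs=1e-9)


class TestJackknife:
    def test_fit_accounting_and_redundancy(self, landscape, sightings):
        from occurange import bin_to_cells

        mask, _ = bin_to_cells(sightings, landscape)
        cells = np.flatnonzero(mask.ravel())
        dup = landscape.copy()
        dup.layers["cov1b"] = dup.layers["cov1"].copy()
        names = ["cov1", "cov1b", "cov2"]
        jk = jackknife_gain(cells, dup, names, n_background=500, seed=19)
        assert jk.attrs["n_fits"] == 2 * len(names) + 1
        # dropping a duplicated covariate loses (almost) no gain
        assert abs(jk.loc["cov1", "gain_without"]
                   - jk.attrs["gain_full"]) < 0.05

    def test_noise_covariate_gains_little_alone(self, landscape, sightings):
        from occurange import bin_to_cells

        mask, _ = bin_to_cells(sightings, landscape)
        cells = np.flatnonzero(mask.ravel())
        jk = jackknife_gain(cells, landscape, ["cov1", "cov3"],
                            n_background=500, seed=20)
        # cov3 has a zero coefficient in the occupancy truth
        assert jk.loc["cov3", "gain_alone"] < jk.loc["cov1", "gain_alone"]
        assert jk.loc["cov3", "gain_alone"] < 0.05
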