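"""Feature construction and the penalized maximum-entropy fitter."""

import numpy as np
import pytest

import avistack as av
from avistack.maxent import MaxentFit, penalized_objective, training_gain


@pytest.fixture()
def five_var_background():
    rng = np.random.default_rng(0)
    return {f"v{i}": rng.normal(size=300) for i in range(5)}


class TestBuildFeatures:
    def test_product_feature_count(self, five_var_background):
        fs = av.build_features(five_var_background, classes="P")
        products = [f for f in fs.features if f.kind == "product"]
        assert len(products) == 10  # 5*4/2 unordered pairs

    def test_product_with_single_variable_contributes_nothing(self):
        fs = av.build_features({"x": np.arange(5.0)}, classes="LP")
        assert all(f.kind != "product" for f in fs.features)

    def test_hinge_ramp_endpoints(self):
        x = np.linspace(0.0, 10.0, 101)
        fs = av.build_features({"x": x}, classes="H", n_knots=3)
        design, _ = fs.design_matrix({"x": x})
        for j, f in enumerate(fs.features):
            if f.kind == "hinge_fwd":
                at_knot = np.interp(f.param, (x - x.min()) / np.ptp(x), design[:, j])
                assert at_knot == pytest.approx(0.0, abs=1e-8)
                assert design[-1, j] == pytest.approx(1.0)  # at the maximum
            if f.kind == "hinge_rev":
                assert design[0, j] == pytest.approx(1.0)  # at the minimum

    def test_threshold_step(self):
        x = np.linspace(0.0, 1.0, 11)
        fs = av.build_features({"x": x}, classes="T", n_knots=1)
        (f,) = [f for f in fs.features if f.kind == "threshold"]
        design, _ = fs.design_matrix({"x": x})
        scaled = (x - x.min()) / np.ptp(x)
        np.testing.assert_array_equal(design[:, 0], (scaled >= f.param).astype(float))

    def test_all_features_map_into_unit_interval(self, five_var_background):
        fs = av.build_features(five_var_background, classes="LQPHT", n_knots=5)
        design, n_clamped = fs.design_matrix(five_var_background)
        assert n_clamped == 0
        assert design.min() >= 0.0 and design.max() <= 1.0

    def test_out_of_range_values_are_clamped_and_counted(self):
        fs = av.build_features({"x": np.linspace(0, 1, 50)}, classes="L")
        design, n_clamped = fs.design_matrix({"x": np.array([-5.0, 0.5, 9.0])})
        assert n_clamped == 2
        assert design[0, 0] == 0.0 and design[2, 0] == 1.0

    def test_categorical_indicators(self):
        fs = av.build_features(
            {"lc": np.array([0.0, 1, 2, 1])}, classes="L", categorical_legend={"lc": [0, 1, 2]}
        )
        cats = [f for f in fs.features if f.kind == "categorical"]
        assert len(cats) == 3
        design, _ = fs.design_matrix({"lc": np.array([1.0])})
        np.testing.assert_array_equal(design[0, -3:], [0.0, 1.0, 0.0])


class TestFitMaxent:
    def test_no_features_gives_uniform(self):
        pres = np.zeros((3, 0))
        bg = np.zeros((7, 0))
        fit = av.fit_maxent(pres, bg, beta=np.zeros(0))
        assert fit.raw(bg) == pytest.approx(np.full(7, 1 / 7))
        assert fit.entropy == pytest.approx(np.log(7))

    def test_huge_penalty_forces_uniform(self):
        rng = np.random.default_rng(1)
        bg = rng.uniform(0, 1, (50, 3))
        pres = bg[:10]
        fit = av.fit_maxent(pres, bg, rm=1.0, beta=np.full(3, 10.0))
        np.testing.assert_array_equal(fit.lam, 0.0)

    def test_single_feature_matches_1d_grid_search(self):
        # 4 background cells, 2 presences, one linear feature, no penalty
        bg = np.array([[0.0], [0.3], [0.7], [1.0]])
        pres = np.array([[0.7], [1.0]])
        fit = av.fit_maxent(pres, bg, beta=np.zeros(1), tol=1e-12)
        grid = np.arange(-20.0, 20.0, 1e-3)
        objs = [penalized_objective(np.array([l]), pres, bg, np.zeros(1)) for l in grid]
        best = grid[int(np.argmax(objs))]
        assert abs(fit.lam[0] - best) < 1e-3

    def test_objective_at_least_dense_grid_optimum_2d(self):
        rng = np.random.default_rng(7)
        bg = rng.uniform(0, 1, (6, 2))
        pres = bg[:2]
        fit = av.fit_maxent(pres, bg, rm=1.0, tol=1e-10)
        obj = penalized_objective(fit.lam, pres, bg, fit.beta)
        axis = np.arange(-3.0, 3.0, 0.05)
        g1, g2 = np.meshgrid(axis, axis)
        best = max(
            penalized_objective(np.array([a, b]), pres, bg, fit.beta)
            for a, b in zip(g1.ravel(), g2.ravel())
        )
        assert obj >= best - 1e-6

    def test_l1_stationarity_zeroes_all_features_at_large_penalty(self):
        # beta_j above |empirical mean - background mean| makes lambda = 0
        # stationary for every feature
        rng = np.random.default_rng(3)
        bg = rng.uniform(0, 1, (200, 3))
        pres = bg[:40]
        gap = np.abs(pres.mean(axis=0) - bg.mean(axis=0))
        fit = av.fit_maxent(pres, bg, beta=gap * 1.05 + 1e-6)
        np.testing.assert_array_equal(fit.lam, 0.0)

    def test_training_gain_nonnegative_when_unpenalized(self):
        rng = np.random.default_rng(4)
        bg = rng.uniform(0, 1, (80, 2))
        pres = bg[bg[:, 0] > 0.5][:20]
        fit = av.fit_maxent(pres, bg, beta=np.zeros(2))
        assert training_gain(fit, pres) >= -1e-9

    def test_raw_sums_to_one_over_background(self):
        rng = np.random.default_rng(5)
        bg = rng.uniform(0, 1, (60, 2))
        fit = av.fit_maxent(bg[:12], bg, rm=1.0)
        assert fit.raw(bg).sum() == pytest.approx(1.0, abs=1e-9)

    def test_empty_background_rejected(self):
        with pytest.raises(ValueError, match="background"):
            av.fit_maxent(np.ones((1, 1)), np.ones((0, 1)))

    def test_nonfinite_design_rejected(self):
        bg = np.ones((4, 1))
        bg[2] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            av.fit_maxent(np.ones((1, 1)), bg)


class TestPredictSuitability:
    @pytest.fixture()
    def fitted(self, small_env, linear_species):
        occ = av.sample_occurrences(linear_species, 150, seed=21)
        rows, cols = small_env.grid.point_to_cell(
            occ["longitude"].to_numpy(), occ["latitude"].to_numpy()
        )
        bg_vals = {"bio1": small_env.layers["bio1"][small_env.valid_mask()]}
        pres_vals = {"bio1": small_env.layers["bio1"][rows, cols]}
        fs = av.build_features(bg_vals, classes="LQ")
        P, _ = fs.design_matrix(pres_vals)
        B, _ = fs.design_matrix(bg_vals)
        return av.fit_maxent(P, B, fs, rm=1.0)

    def test_raw_normalized_over_background(self, fitted, small_env):
        suit = av.predict_suitability(fitted, small_env, scale="raw")
        assert np.nansum(suit.values) == pytest.approx(1.0, abs=1e-9)

    def test_logistic_half_at_entropy_point(self, fitted):
        # a cell with raw probability e^-H maps to logistic 0.5 exactly
        r = np.exp(-fitted.entropy)
        eh_r = np.exp(fitted.entropy) * r
        assert eh_r / (1 + eh_r) == pytest.approx(0.5)

    def test_scales_are_rank_equivalent(self, fitted, small_env):
        raw = av.predict_suitability(fitted, small_env, scale="raw")
        logi = av.predict_suitability(fitted, small_env, scale="logistic")
        clog = av.predict_suitability(fitted, small_env, scale="cloglog")
        ok = small_env.valid_mask()
        order = np.argsort(raw.values[ok])
        for other in (logi, clog):
            assert (np.diff(other.values[ok][order]) >= -1e-15).all()

    def test_serialization_round_trip(self, fitted, small_env):
        restored = MaxentFit.from_text(fitted.to_text())
        a = av.predict_suitability(fitted, small_env, scale="logistic")
        b = av.predict_suitability(restored, small_env, scale="logistic")
        np.testing.assert_allclose(a.values, b.values, rtol=0, atol=1e-12)


class TestVariableContribution:
    def test_single_active_variable_gets_everything(self):
        rng = np.random.default_rng(8)
        bg_vals = {"x": rng.normal(size=200), "y": rng.normal(size=200)}
        fs = av.build_features(bg_vals, classes="L")
        B, _ = fs.design_matrix(bg_vals)
        pres_idx = np.argsort(bg_vals["x"])[-30:]
        pres_vals = {k: v[pres_idx] for k, v in bg_vals.items()}
        P, _ = fs.design_matrix(pres_vals)
        fit = av.fit_maxent(P, B, fs, rm=1.0)
        fit.lam[[j for j, f in enumerate(fs.features) if f.variables[0] == "y"]] = 0.0
        contrib = av.variable_contribution(fit, pres_vals, bg_vals, n_permutations=5, seed=0)
        assert contrib["x"] == pytest.approx(100.0)
        assert contrib["y"] == pytest.approx(0.0)

    def test_duplicated_variables_share_contribution(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=400)
        bg_vals = {"a": x, "b": x.copy()}
        fs = av.build_features(bg_vals, classes="L")
        B, _ = fs.design_matrix(bg_vals)
        pres_idx = np.argsort(x)[-60:]
        pres_vals = {k: v[pres_idx] for k, v in bg_vals.items()}
        P, _ = fs.design_matrix(pres_vals)
        fit = av.fit_maxent(P, B, fs, rm=1.0)
        # symmetrize the coefficients across the twin features
        mean_lam = fit.lam.mean()
        fit.lam[:] = mean_lam
        contrib = av.variable_contribution(fit, pres_vals, bg_vals, n_permutations=100, seed=1)
        assert contrib["a"] == pytest.approx(contrib["b"], abs=8.0)
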