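"""Two-step estimation: discretized linear system, constrained least squares,
weighted nonlinear refinement, and the shared-parameter variant."""

import warnings

import numpy as np
import pytest

import sphingokin as sk
from sphingokin.estimation import FitConfig, identifiability_report, interval_weights
from sphingokin.network import RateParams
from sphingokin.timecourse import DEFAULT_GRID, ConditionDataset, TimeCourse


class TestFiniteDifferences:
    def test_two_point_slope(self):
        tc = TimeCourse("x", "control", [0.0, 1.0], [1.0, 2.0])
        t, d = sk.finite_difference_derivatives(tc)
        assert t.tolist() == [1.0] and d.tolist() == [1.0]

    def test_constant_series_zero(self):
        tc = TimeCourse("x", "control", DEFAULT_GRID, np.full(8, 3.3))
        _, d = sk.finite_difference_derivatives(tc)
        np.testing.assert_array_equal(d, np.zeros(7))

    def test_first_order_error_bound_on_exponential(self):
        """Backward differences of e^(-t) on the sampling grid obey the
        |x''| dt / 2 truncation bound."""
        tc = TimeCourse("x", "control", DEFAULT_GRID, np.exp(-DEFAULT_GRID))
        t, d = sk.finite_difference_derivatives(tc)
        true = -np.exp(-t)
        dt = np.diff(DEFAULT_GRID)
        bound = np.exp(-DEFAULT_GRID[:-1]) * dt / 2  # max |x''| on each interval
        assert np.all(np.abs(d - true) <= bound + 1e-12)

    def test_duplicate_times_rejected(self):
        tc = TimeCourse("x", "control", [0.0, 1.0, 2.0], [1.0, 2.0, 3.0])
        tc.times = np.array([0.0, 1.0, 1.0])  # bypass constructor check
        with pytest.raises(ValueError, match="duplicate|increasing"):
            sk.finite_difference_derivatives(tc)


class TestRegressionSystem:
    def test_dimensions(self, network, clean_dataset):
        system = sk.build_regression_system(network, clean_dataset)
        assert system.Y.shape == (9 * 7 * 2,)
        assert system.X.shape == (126, 29)
        assert set(system.meta["condition"]) == {"control", "treatment"}

    def test_control_rows_use_unit_gene_folds(self, network, clean_dataset):
        """In control rows, enzyme-carrying regressors collapse to fold 1:
        the kf1 (with CerS6) and kf2 (enzyme-free) columns coincide there."""
        system = sk.build_regression_system(network, clean_dataset)
        names = list(system.param_names)
        ctrl = (system.meta["condition"] == "control").to_numpy()
        col1, col2 = system.X[ctrl, names.index("kf1")], system.X[ctrl, names.index("kf2")]
        np.testing.assert_allclose(col1, col2, rtol=1e-12)
        trt = ~ctrl
        assert not np.allclose(system.X[trt, names.index("kf1")],
                               system.X[trt, names.index("kf2")])

    def _dataset_on_grid(self, network, ref_params, grid):
        truth = sk.SyntheticTruth.default(network, noise_frac_sem=0.0, n_bio=1, n_tech=1)
        x0 = sk.control_steady_state(network, ref_params, truth)
        scaffold = sk.generate_dataset(network, truth)  # for input courses
        courses = {}
        for cond in ("control", "treatment"):
            for name in network.catalog.input_lipids + network.catalog.gene_inputs:
                src = scaffold.course(name, cond)
                courses[(name, cond)] = TimeCourse(name, cond, grid, src.interpolate(grid))
            traj = sk.simulate(network, ref_params, x0, scaffold, cond, t_grid=grid,
                               method="LSODA", rtol=1e-10, atol=1e-12)
            for j, s in enumerate(network.catalog.dynamic_species):
                courses[(s, cond)] = TimeCourse(s, cond, grid, traj.states[:, j])
        return ConditionDataset(network.catalog, courses)

    def test_discretization_residual_shrinks_with_grid(self, network, ref_params):
        """||Y - X b_true|| / ||Y|| is pure discretization error and drops as
        the sampling grid refines."""
        rels = []
        for npts in (8, 33):
            grid = DEFAULT_GRID if npts == 8 else np.linspace(0, 24, npts)
            ds = self._dataset_on_grid(network, ref_params, grid)
            system = sk.build_regression_system(network, ds)
            r = np.linalg.norm(system.Y - system.X @ ref_params.values)
            rels.append(r / np.linalg.norm(system.Y))
        assert rels[1] < 0.5 * rels[0]


class TestLinearEstimate:
    def _system(self, X, y):
        import pandas as pd

        from sphingokin.estimation import RegressionSystem

        names = tuple(f"b{i}" for i in range(X.shape[1]))
        meta = pd.DataFrame({"species": ["s"] * len(y), "time_hr": 0.0, "condition": "c"})
        return RegressionSystem(np.asarray(y, float), np.asarray(X, float), meta, names)

    def test_exact_recovery(self, rng):
        X = rng.random((60, 5)) + 0.1
        b_true = np.array([0.5, 2.0, 0.0, 1.2, 0.01])
        est = sk.linear_estimate(self._system(X, X @ b_true))
        np.testing.assert_allclose(est.values, b_true, rtol=1e-6, atol=1e-9)

    def test_zero_response_gives_zero(self, rng):
        X = rng.random((30, 4)) + 0.1
        est = sk.linear_estimate(self._system(X, np.zeros(30)))
        np.testing.assert_allclose(est.values, np.zeros(4), atol=1e-10)

    def test_active_constraint_matches_grid_search_oracle(self):
        """Toy problem whose unconstrained optimum has b2 < 0: the constrained
        solution must match an exhaustive quadratic-program grid search."""
        X = np.array([[1.0, 0.9], [0.9, 1.0], [1.0, 1.0], [0.8, 1.1]])
        y = X @ np.array([1.0, -0.5])
        est = sk.linear_estimate(self._system(X, y)).values
        # brute-force refinement of the (b1, b2) >= 0 grid
        lo, hi = np.zeros(2), np.full(2, 2.0)
        for _ in range(6):
            g1 = np.linspace(lo[0], hi[0], 201)
            g2 = np.linspace(lo[1], hi[1], 201)
            B1, B2 = np.meshgrid(g1, g2, indexing="ij")
            cost = ((y[:, None, None] - X[:, 0, None, None] * B1 - X[:, 1, None, None] * B2) ** 2).sum(axis=0)
            i, j = np.unravel_index(np.argmin(cost), cost.shape)
            best = np.array([g1[i], g2[j]])
            width = np.array([g1[1] - g1[0], g2[1] - g2[0]])
            lo, hi = np.maximum(best - 2 * width, 0.0), best + 2 * width
        assert best[1] == pytest.approx(0.0, abs=1e-6)
        np.testing.assert_allclose(est, best, atol=1e-6)

    def test_scale_equivariance(self, rng):
        X = rng.random((40, 3)) + 0.1
        y = X @ np.array([1.0, 0.5, 2.0])
        e1 = sk.linear_estimate(self._system(X, y)).values
        X2 = X.copy()
        X2[:, 1] *= 10.0
        e2 = sk.linear_estimate(self._system(X2, y)).values
        np.testing.assert_allclose(e2, e1 / np.array([1.0, 10.0, 1.0]), rtol=1e-6)

    def test_confounded_kinase_pair_flagged(self, network):
        """Identical Sphk1/Sphk2 treatment profiles make kf4 and kf5 collinear."""
        truth = sk.SyntheticTruth.default(network, noise_frac_sem=0.0, n_bio=1, n_tech=1)
        profiles = dict(truth.profiles)
        sphk1 = profiles[("Sphk1", "treatment")]
        profiles[("Sphk2", "treatment")] = sk.ProfileSpec(
            "Sphk2", "treatment", sphk1.shape, sphk1.values)
        truth.profiles = profiles
        ds = sk.generate_dataset(network, truth)
        system = sk.build_regression_system(network, ds)
        groups = identifiability_report(system, rank_tol=1e-7)
        assert any({"kf4", "kf5"} <= set(g) for g in groups)
        with pytest.warns(RuntimeWarning, match="kf4.*kf5|kf5.*kf4"):
            sk.linear_estimate(system)


class TestRefinement:
    def test_interval_weights_quarter_power(self):
        w = interval_weights([0.0, 1.0, 17.0], exponent=0.25)
        assert w[2] / w[1] == pytest.approx(16 ** 0.25)  # = 2
        assert w[0] == w[1]

    def test_objective_zero_when_start_reproduces_data(self, network, ref_params, clean_dataset):
        cfg = FitConfig(max_nfev=5)
        fit = sk.refine_nonlinear(network, clean_dataset, ref_params, cfg)
        assert fit.objective < 1e-10
        # the optimizer may take a vanishing exploratory step; stays at the start
        np.testing.assert_allclose(fit.params.values, ref_params.values, rtol=1e-3, atol=1e-9)

    def test_never_increases_objective(self, network, noisy_dataset):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            system = sk.build_regression_system(network, noisy_dataset)
            start = sk.linear_estimate(system)
        cfg = FitConfig(max_nfev=8, ftol=1e-8, xtol=1e-8, gtol=1e-8)
        start = RateParams(start.names, np.minimum(start.values, cfg.upper_bound))
        o0 = sk.objective_value(network, noisy_dataset, start, cfg)
        fit = sk.refine_nonlinear(network, noisy_dataset, start, cfg)
        assert fit.objective <= o0 * (1 + 1e-12)

    def test_initial_conditions_stay_in_window(self, network, recovery_fit, clean_dataset):
        for cond in ("control", "treatment"):
            c0 = clean_dataset.state_matrix(cond)[0]
            assert np.all(recovery_fit.x0[cond] >= 0.8 * c0 - 1e-9)
            assert np.all(recovery_fit.x0[cond] <= 1.2 * c0 + 1e-9)

    def test_noise_free_recovery_within_5_percent(self, network, ref_params, recovery_fit):
        """Headline property: the two-step pipeline run on noise-free synthetic
        data returns every (identifiable) generating constant within 5%."""
        for name in network.param_names:
            true = ref_params[name]
            est = recovery_fit.params[name]
            if true == 0:
                assert est == pytest.approx(0.0, abs=5e-3)
            else:
                assert est == pytest.approx(true, rel=0.05), name

    def test_out_of_bounds_start_rejected(self, network, clean_dataset, ref_params):
        bad = ref_params.replace(kf1=1e6)
        with pytest.raises(ValueError, match="bounds"):
            sk.refine_nonlinear(network, clean_dataset, bad, FitConfig())


class TestSharedParameters:
    CFG = FitConfig(ftol=1e-10, xtol=1e-10, gtol=1e-10, max_nfev=80)

    def test_unknown_pair_rejected(self, network, clean_dataset, ref_params):
        with pytest.raises(ValueError, match="kf1"):
            sk.shared_parameter_fit(network, clean_dataset, [("kf1", "kf2")],
                                    start=ref_params)

    def test_well_specified_tie_recovers_common_value(self, network, ref_params):
        """Data generated with kf7 = kf24: the tied fit finds the shared value
        and matches the generating objective (~0)."""
        common = 0.02
        params = ref_params.replace(kf7=common, kf24=common)
        truth = sk.SyntheticTruth.default(network, params=params, noise_frac_sem=0.0,
                                          n_bio=1, n_tech=1)
        ds = sk.generate_dataset(network, truth)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            fit = sk.shared_parameter_fit(network, ds, [("kf7", "kf24")], self.CFG)
        assert fit.params["kf7"] == fit.params["kf24"]
        assert fit.params["kf7"] == pytest.approx(common, rel=0.05)
        assert fit.objective < 1e-8

    def test_tie_is_nested_and_lands_between_untied_values(
            self, network, ref_params, clean_dataset, recovery_fit):
        """On data generated with unequal kf7/kf24, the tied fit cannot beat
        the untied one, and the common value falls between the untied pair."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            tied = sk.shared_parameter_fit(network, clean_dataset, [("kf7", "kf24")],
                                           self.CFG, start=recovery_fit.params)
        assert tied.objective >= recovery_fit.objective - 1e-15
        lo, hi = sorted((recovery_fit.params["kf7"], recovery_fit.params["kf24"]))
        assert lo <= tied.params["kf7"] <= hi
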