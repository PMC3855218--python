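"""Likelihood evaluation, the ML curve fits and their grid-search oracles,
the density regression and the global density fit."""

import numpy as np
import pytest

import gpacc as gp
from gpacc.eqns import AccuracyModelSpec, accuracy, w_of_density
from gpacc.fit import DegenerateScenarioError
from gpacc.relmat import InputError
from conftest import make_table

# training sizes induced by k = 2..10, 15, 20 on the 5,698-bull population
HOLSTEIN_NP = [gp.training_size(5698, k) for k in (2, 3, 4, 5, 6, 7, 8, 9, 10, 15, 20)]


def d2_mean(me=1045.6, w=0.875, h2=0.945):
    s = AccuracyModelSpec(family="D2", me=me, h2=h2, w=w)
    return lambda n: accuracy(s, float(n))


class TestLogLikelihood:
    def test_hand_computed_two_replicates(self):
        table = gp.CVScenarioTable(
            [gp.CVScenario(k=2, n_train=1000, accuracies=np.array([0.5, 0.6]))]
        )
        # force sigma2 = 0.005 by construction: var([.5,.6], ddof=1) = 0.005
        assert table.scenarios[0].empirical_variance == pytest.approx(0.005)
        spec = AccuracyModelSpec(family="D2", me=1000.0, h2=1.0, w=1.0)
        # choose me so the model mean is exactly 0.55: solve w*sqrt(N/(N+me))
        me = 1000 * (1 - 0.55 ** 2) / 0.55 ** 2
        spec = AccuracyModelSpec(family="D2", me=me, h2=1.0, w=1.0)
        assert accuracy(spec, 1000) == pytest.approx(0.55, abs=1e-12)
        # two normal log-densities at +-0.05 from the mean with var 0.005:
        # -ln(2*pi*0.005) - 0.5 = 2.96044
        assert gp.log_likelihood(table, spec) == pytest.approx(2.960440, abs=1e-5)

    def test_exact_value_when_model_interpolates(self):
        table = make_table([500, 1000, 2000], d2_mean(), noise=0.0, n_reps=5)
        # zero spread is degenerate; rebuild with equal accuracies but a
        # stated variance via manual scenarios
        scen = [
            gp.CVScenario(k=s.k, n_train=s.n_train,
                          accuracies=np.full(4, d2_mean()(s.n_train)))
            for s in table
        ]
        for s in scen:
            s.accuracies = s.accuracies + np.array([-0.01, 0.01, -0.01, 0.01])
        table = gp.CVScenarioTable(scen)
        spec = AccuracyModelSpec(family="D2", me=1045.6, h2=0.945, w=0.875)
        expected = sum(
            -0.5 * 4 * np.log(2 * np.pi * s.empirical_variance)
            - np.sum((s.accuracies - d2_mean()(s.n_train)) ** 2)
            / (2 * s.empirical_variance)
            for s in table
        )
        assert gp.log_likelihood(table, spec) == pytest.approx(expected, rel=1e-12)

    def test_maximised_at_scenario_means(self):
        rng = np.random.default_rng(3)
        table = gp.CVScenarioTable(
            [gp.CVScenario(k=2, n_train=800, accuracies=0.7 + 0.02 * rng.standard_normal(20))]
        )
        mean = table.scenarios[0].accuracies.mean()

        def ll_at(mu):
            me = 800 * (1 - mu ** 2) / mu ** 2
            return gp.log_likelihood(
                table, AccuracyModelSpec(family="D1", me=me, h2=1.0)
            )

        assert ll_at(mean) >= ll_at(mean + 0.1)

    def test_zero_variance_scenario_rejected(self):
        table = gp.CVScenarioTable(
            [gp.CVScenario(k=2, n_train=100, accuracies=np.full(5, 0.5))]
        )
        with pytest.raises(DegenerateScenarioError):
            gp.log_likelihood(
                table, AccuracyModelSpec(family="D1", me=100.0, h2=0.9)
            )


class TestFitMe:
    def test_noiseless_d1_recovery(self):
        s = AccuracyModelSpec(family="D1", me=1000.0, h2=0.9)
        table = make_table(
            range(500, 5001, 500), lambda n: accuracy(s, float(n)), noise=1e-4
        )
        res = gp.fit_me(table, "D1", 0.9)
        assert res.me_hat == pytest.approx(1000.0, abs=1.0)
        assert res.converged

    def test_agrees_with_grid_search_oracle(self):
        s = AccuracyModelSpec(family="D1", me=777.0, h2=0.9)
        table = make_table(
            range(400, 4001, 400), lambda n: accuracy(s, float(n)), noise=5e-3, seed=2
        )
        res = gp.fit_me(table, "D1", 0.9)
        grid = np.arange(100.0, 5000.0, 1.0)
        lls = [
            gp.log_likelihood(table, AccuracyModelSpec(family="D1", me=m, h2=0.9))
            for m in grid
        ]
        assert res.me_hat == pytest.approx(grid[int(np.argmax(lls))], abs=1.0)

    def test_d1_misfit_on_d2_data_has_biased_residual_pattern(self):
        """Fitting a no-ceiling model to ceiling-limited accuracies leaves
        predictions too low at small training sets and too high at large."""
        table = make_table(HOLSTEIN_NP, d2_mean(), noise=1e-3, n_reps=6)
        res = gp.fit_me(table, "D1", 0.945)
        resid = [s.mean_accuracy - res.predict(s.n_train) for s in table]
        assert resid[0] > 0 and resid[1] > 0
        assert resid[-1] < 0 and resid[-2] < 0


class TestFitMeW:
    def test_noiseless_d2_recovery_at_reference_parameterisation(self):
        table = make_table(HOLSTEIN_NP, d2_mean(), noise=1e-4, n_reps=6)
        res = gp.fit_me_w(table, "D2", 0.945)
        assert res.me_hat == pytest.approx(1045.6, rel=0.01)
        assert res.w_hat == pytest.approx(0.875, rel=0.01)

    def test_agrees_with_fine_grid_oracle(self):
        table = make_table(HOLSTEIN_NP, d2_mean(), noise=2e-3, n_reps=6, seed=5)
        res = gp.fit_me_w(table, "D2", 0.945)
        me_grid = np.arange(max(1.0, res.me_hat - 25), res.me_hat + 25, 1.0)
        w_grid = np.arange(max(0.01, res.w_hat - 0.02), min(1.0, res.w_hat + 0.02), 0.001)
        best = -np.inf
        for m in me_grid:
            for w in w_grid:
                ll = gp.log_likelihood(
                    table, AccuracyModelSpec(family="D2", me=m, h2=0.945, w=w)
                )
                best = max(best, ll)
        assert res.log_likelihood >= best - 1e-6

    def test_w_at_boundary_for_d1_generated_data(self):
        s = AccuracyModelSpec(family="D1", me=1500.0, h2=0.9)
        table = make_table(
            range(500, 5001, 500), lambda n: accuracy(s, float(n)), noise=1e-4, seed=6
        )
        res = gp.fit_me_w(table, "D2", 0.9)
        assert res.w_hat >= 0.99

    def test_nested_model_likelihood_ordering(self):
        table = make_table(HOLSTEIN_NP, d2_mean(), noise=2e-3, n_reps=6, seed=7)
        ll_d2 = gp.fit_me_w(table, "D2", 0.945).log_likelihood
        ll_d1 = gp.fit_me(table, "D1", 0.945).log_likelihood
        assert ll_d2 >= ll_d1

    def test_g3_self_recovery(self):
        s = AccuracyModelSpec(family="G3", me=904.9, h2=0.945, w=0.869)
        table = make_table(HOLSTEIN_NP, lambda n: accuracy(s, float(n)),
                           noise=1e-4, n_reps=6, seed=8)
        res = gp.fit_me_w(table, "G3", 0.945)
        assert res.me_hat == pytest.approx(904.9, rel=0.01)
        assert res.w_hat == pytest.approx(0.869, rel=0.01)


class TestGlobalDensityFit:
    def test_parameter_recovery_across_densities(self):
        me_true, z_true, L = 1000.0, 0.9, 29.0
        tables = []
        for m in (5000, 10000, 20000, 40000):
            spec = AccuracyModelSpec(
                family="D2-density", me=me_true, h2=0.9, z=z_true,
                n_markers=m, genome_length=L,
            )
            tables.append(
                (m, make_table(range(1000, 5001, 1000),
                               lambda n, s=spec: accuracy(s, float(n)),
                               noise=1e-3, seed=m))
            )
        res = gp.fit_global_density(tables, 0.9, L)
        assert res.me_hat == pytest.approx(me_true, rel=0.05)
        assert res.z_hat == pytest.approx(z_true, rel=0.05)
        # optimum dominates the same likelihood evaluated off-optimum
        model = res.model
        assert res.log_likelihood >= model.loglike([me_true * 1.2, z_true * 0.8])

    def test_single_density_unidentifiable(self):
        table = make_table([500, 1000], d2_mean(), noise=1e-3)
        with pytest.raises(InputError):
            gp.fit_global_density([(10000, table)], 0.9)


class TestRegressWDensity:
    # fitted (panel size, w) pairs of the milk-yield D2 fits across densities
    MILK_POINTS = [(10000, 0.844), (20000, 0.863), (30000, 0.868), (42551, 0.875)]

    def test_reference_points_regression(self):
        res = gp.regress_w_density(self.MILK_POINTS, 29.0)
        assert 0.989 <= round(res.r_squared, 3) <= 0.990
        assert res.intercept == pytest.approx(1.00, abs=0.01)
        assert res.slope < 0

    def test_exact_fit_on_collinear_points(self):
        pts = [(m, 1 - 0.9 / np.log(m / 29.0)) for m in (5000, 20000, 80000, 320000)]
        res = gp.regress_w_density(pts, 29.0)
        assert res.r_squared == pytest.approx(1.0, abs=1e-10)
        assert res.slope == pytest.approx(-0.9, abs=1e-10)
        assert res.intercept == pytest.approx(1.0, abs=1e-10)

    def test_matches_closed_form_ols_oracle(self):
        pts = self.MILK_POINTS
        res = gp.regress_w_density(pts, 29.0)
        x = np.array([1 / np.log(m / 29.0) for m, _ in pts])
        y = np.array([w for _, w in pts])
        slope = np.sum((x - x.mean()) * (y - y.mean())) / np.sum((x - x.mean()) ** 2)
        intercept = y.mean() - slope * x.mean()
        assert res.slope == pytest.approx(slope, abs=1e-12)
        assert res.intercept == pytest.approx(intercept, abs=1e-12)

    def test_high_density_plateau_detected(self):
        # dense-panel fits: w stops increasing beyond ~20k SNPs
        pts = [
            (2451, 0.791), (4901, 0.821), (9802, 0.849), (19604, 0.868),
            (39207, 0.868), (78414, 0.868), (156827, 0.868),
            (313653, 0.867), (627306, 0.866),
        ]
        res = gp.regress_w_density(pts, 29.0, plateau_detection=True)
        assert res.plateau_w == pytest.approx(0.868, abs=0.002)
        assert len(res.plateau_points) == 6
        assert len(res.points_used) == 3

    def test_duplicate_densities_rejected(self):
        with pytest.raises(InputError):
            gp.regress_w_density([(1000, 0.8), (1000, 0.81), (2000, 0.85)], 29.0)


class TestExtrapolate:
    def test_in_sample_target_equals_model_value(self):
        table = make_table(HOLSTEIN_NP, d2_mean(), noise=1e-4, n_reps=6, seed=9)
        res = gp.fit_me_w(table, "D2", 0.945)
        pred = gp.extrapolate(table, "D2", 0.945, HOLSTEIN_NP[3])
        assert pred == pytest.approx(float(res.predict(HOLSTEIN_NP[3])), abs=1e-6)


class TestMultiSeedStability:
    def test_w_recovery_and_me_stability_across_worlds(self):
        """Across independently seeded synthetic worlds (tagged variance
        0.75, quasi-phenotype reliability 0.9), the fitted maximum accuracy
        w tracks sqrt(0.75) and the fitted segment number is stable."""
        w_true = np.sqrt(0.75)
        w_hats, me_hats = [], []
        for seed in range(10):
            cfg = gp.PopulationConfig(
                n_individuals=2000, n_markers=5000, n_qtl=300,
                tagged_variance_fraction=0.75,
                ebv_accuracy=float(np.sqrt(0.9)), seed=100 + seed,
            )
            geno, _truth, pheno = gp.simulate_population(cfg)
            grm = gp.vanraden_grm(geno)
            vc = gp.reml_estimate(pheno.ebv, grm)
            scheme = gp.CVScheme(k_values=(2, 3, 5, 10, 20), n_replicates=3,
                                 seed=seed)
            table = gp.run_cv(None, pheno, scheme, vc, grm=grm)
            res = gp.fit_me_w(table, "D2", 0.9)
            w_hats.append(res.w_hat)
            me_hats.append(res.me_hat)
        assert np.median(np.abs(np.array(w_hats) - w_true)) <= 0.05
        me = np.array(me_hats)
        assert me.std(ddof=1) / me.mean() <= 0.2
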