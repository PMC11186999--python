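"""OLS, GLS, profile-lambda PGLS, and the regression battery."""

import math

import numpy as np
import pandas as pd
import pytest

from karyomorph import inference, phylo, synthetic, traits
from karyomorph.errors import (CollinearityError, DegenerateCovarianceError,
                               InsufficientDataError, InsufficientVariationError)
from karyomorph.inference import ModelSpec

from .conftest import make_record


def _trait_table(df: pd.DataFrame) -> pd.DataFrame:
    return df.rename(columns={"log10_x": "log10_area", "log10_y": "log10_n"})


class TestOls:
    def test_exact_line(self):
        x = np.arange(10.0)
        y = 2.0 + 0.5 * x
        fit = inference.ols_fit(y, np.column_stack([np.ones(10), x]))
        assert fit.coefficients["intercept"] == pytest.approx(2.0, abs=1e-10)
        assert fit.coefficients["x1"] == pytest.approx(0.5, abs=1e-10)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(3)
        X = np.column_stack([np.ones(10), rng.normal(size=(10, 3))])
        y = rng.normal(size=10)
        beta_oracle = np.linalg.inv(X.T @ X) @ X.T @ y  # brute-force solver
        fit = inference.ols_fit(y, X)
        np.testing.assert_allclose(list(fit.coefficients.values()), beta_oracle,
                                   rtol=1e-10)
        resid = y - X @ beta_oracle
        s2 = resid @ resid / (10 - 4)
        se_oracle = np.sqrt(np.diag(s2 * np.linalg.inv(X.T @ X)))
        np.testing.assert_allclose(list(fit.standard_errors.values()), se_oracle,
                                   rtol=1e-10)

    def test_duplicated_column_rejected(self):
        x = np.arange(6.0)
        X = np.column_stack([np.ones(6), x, x])
        with pytest.raises(CollinearityError):
            inference.ols_fit(np.ones(6), X)


class TestGls:
    def test_identity_covariance_reproduces_ols(self):
        rng = np.random.default_rng(0)
        X = np.column_stack([np.ones(25), rng.normal(size=(25, 2))])
        y = rng.normal(size=25)
        o = inference.ols_fit(y, X)
        g = inference.gls_fit(y, X, np.eye(25))
        np.testing.assert_allclose(list(g.coefficients.values()),
                                   list(o.coefficients.values()), rtol=1e-10)
        np.testing.assert_allclose(list(g.standard_errors.values()),
                                   list(o.standard_errors.values()), rtol=1e-10)
        assert g.r_squared == pytest.approx(o.r_squared, rel=1e-10)

    def test_three_tip_weighted_mean_oracle(self):
        # explicit-inverse algebra on the 3-tip tree ((A:1,B:1):1,C:2)
        V = np.array([[2.0, 1.0, 0.0], [1.0, 2.0, 0.0], [0.0, 0.0, 2.0]])
        y = np.array([1.0, 2.0, 4.0])
        ones = np.ones((3, 1))
        Vinv = np.linalg.inv(V)
        expected = float((ones.T @ Vinv @ y).item() / (ones.T @ Vinv @ ones).item())
        fit = inference.gls_fit(y, ones, V)
        assert fit.coefficients["intercept"] == pytest.approx(expected, rel=1e-12)

    def test_matches_statsmodels_gls(self):
        sm = pytest.importorskip("statsmodels.api")
        tree = synthetic.simulate_yule_tree(30, 1.0, seed=4)
        V = phylo.lambda_transform(phylo.vcv(tree), 0.6).matrix
        rng = np.random.default_rng(4)
        X = np.column_stack([np.ones(30), rng.normal(size=30)])
        y = rng.normal(size=30)
        ours = inference.gls_fit(y, X, V)
        ref = sm.GLS(y, X, sigma=V).fit()
        np.testing.assert_allclose(list(ours.coefficients.values()), ref.params,
                                   rtol=1e-8)
        np.testing.assert_allclose(list(ours.standard_errors.values()), ref.bse,
                                   rtol=1e-8)

    def test_singular_covariance_rejected(self):
        V = np.ones((4, 4))  # duplicated tips: rank 1
        with pytest.raises(DegenerateCovarianceError):
            inference.gls_fit(np.arange(4.0), np.ones((4, 1)), V)


class TestProfileLambda:
    def test_optimum_beats_grid(self):
        tree = synthetic.simulate_yule_tree(60, 1.0, seed=5)
        cov = phylo.vcv(tree)
        cfg = synthetic.SyntheticConfig(n_tips=60, true_intercept=0.5,
                                        true_slopes={"x": 0.3}, sigma2=0.02,
                                        lambda_true=0.5, seed=5)
        df = synthetic.simulate_traits(tree, cfg)
        y = df["log10_y"].to_numpy()
        X = np.column_stack([np.ones(60), df["log10_x"]])
        for mode in ("profile_REML", "profile_ML"):
            lam_hat, fit = inference.profile_lambda(y, X, cov, mode=mode)

            def ll(lam):
                core = inference._gls_core(y, X, phylo.lambda_transform(cov, lam).matrix)
                return core[4] if mode == "profile_REML" else core[3]

            grid_best = max(ll(l) for l in np.linspace(0, 1, 101))
            assert ll(lam_hat) >= grid_best - 1e-6
            # optimality at the endpoints in particular
            assert ll(lam_hat) >= ll(0.0) - 1e-9 and ll(lam_hat) >= ll(1.0) - 1e-9

    def test_brownian_signal_detected(self):
        # lambda_true = 1 on a 200-tip tree: median estimate near the top
        tree = synthetic.simulate_yule_tree(200, 1.0, seed=6)
        cov = phylo.vcv(tree)
        lams = []
        for rep in range(40):
            cfg = synthetic.SyntheticConfig(n_tips=200, true_intercept=0.0,
                                            true_slopes={"x": 0.0}, sigma2=0.05,
                                            lambda_true=1.0, seed=100 + rep)
            df = synthetic.simulate_traits(tree, cfg)
            lam_hat, _ = inference.profile_lambda(
                df["log10_y"].to_numpy(), np.ones((200, 1)), cov)
            lams.append(lam_hat)
        assert np.median(lams) >= 0.9

    def test_iid_noise_gives_no_signal(self):
        tree = synthetic.simulate_yule_tree(200, 1.0, seed=7)
        cov = phylo.vcv(tree)
        lams = []
        for rep in range(40):
            cfg = synthetic.SyntheticConfig(n_tips=200, true_intercept=0.0,
                                            true_slopes={"x": 0.0}, sigma2=0.05,
                                            lambda_true=0.0, seed=200 + rep)
            df = synthetic.simulate_traits(tree, cfg)
            lam_hat, _ = inference.profile_lambda(
                df["log10_y"].to_numpy(), np.ones((200, 1)), cov)
            lams.append(lam_hat)
        assert np.median(lams) <= 0.1

    def test_matches_independent_reml_oracle(self):
        """Frozen REML fit from an independent comparative-methods stack
        (R: nlme::gls with ape::corPagel) on a fixed 40-tip dataset."""
        tree = synthetic.simulate_yule_tree(40, 1.0, seed=9)
        cfg = synthetic.SyntheticConfig(n_tips=40, true_intercept=0.8,
                                        true_slopes={"x": 0.4}, sigma2=0.04,
                                        lambda_true=0.5, seed=9)
        tab = _trait_table(synthetic.simulate_traits(tree, cfg))
        fit = inference.pgls_fit(ModelSpec("log10_n", ["log10_area"]), tab, tree)
        assert fit.lambda_hat == pytest.approx(0.07312276, abs=2e-5)
        assert fit.coefficients["intercept"] == pytest.approx(0.6730084, abs=1e-5)
        assert fit.coefficients["log10_area"] == pytest.approx(0.4348095, abs=1e-5)
        assert fit.standard_errors["log10_area"] == pytest.approx(0.1024377, abs=1e-5)
        assert fit.standard_errors["intercept"] == pytest.approx(0.1352299, abs=1e-5)


class TestPgls:
    def test_fixed_lambda_zero_on_ultrametric_equals_ols(self):
        tree = synthetic.simulate_yule_tree(50, 1.0, seed=10)
        cfg = synthetic.SyntheticConfig(n_tips=50, true_intercept=1.0,
                                        true_slopes={"x": 0.3}, sigma2=0.03,
                                        lambda_true=0.4, seed=10)
        tab = _trait_table(synthetic.simulate_traits(tree, cfg))
        p = inference.pgls_fit(ModelSpec("log10_n", ["log10_area"],
                                         lambda_mode="fixed", lambda_fixed=0.0),
                               tab, tree)
        o = inference.pgls_fit(ModelSpec("log10_n", ["log10_area"],
                                         estimator="OLS"), tab, tree)
        for key in ("intercept", "log10_area"):
            assert p.coefficients[key] == pytest.approx(o.coefficients[key],
                                                        rel=1e-10)
            assert p.standard_errors[key] == pytest.approx(o.standard_errors[key],
                                                           rel=1e-10)

    def test_star_phylogeny_equals_ols_at_any_lambda(self):
        n = 24
        star = phylo.parse_newick(
            "(" + ",".join(f"sp{i:03d}:1" for i in range(n)) + ");")
        rng = np.random.default_rng(11)
        tab = pd.DataFrame({"species": sorted(star.tip_labels),
                            "log10_area": rng.normal(size=n),
                            "log10_n": rng.normal(size=n)})
        o = inference.pgls_fit(ModelSpec("log10_n", ["log10_area"],
                                         estimator="OLS"), tab, star)
        for lam in (0.0, 0.5, 1.0):
            p = inference.pgls_fit(ModelSpec("log10_n", ["log10_area"],
                                             lambda_mode="fixed",
                                             lambda_fixed=lam), tab, star)
            assert p.coefficients["log10_area"] == pytest.approx(
                o.coefficients["log10_area"], rel=1e-10)

    def test_indicator_on_star_tree_is_difference_of_means(self):
        n = 20
        star = phylo.parse_newick(
            "(" + ",".join(f"sp{i:03d}:1" for i in range(n)) + ");")
        species = sorted(star.tip_labels)
        rng = np.random.default_rng(12)
        s = np.array([0.0] * 10 + [1.0] * 10)
        y = rng.normal(size=n) + 0.7 * s
        tab = pd.DataFrame({"species": species, "s": s, "log10_n": y})
        fit = inference.pgls_fit(ModelSpec("log10_n", ["s"], lambda_mode="fixed",
                                           lambda_fixed=0.0), tab, star)
        assert fit.coefficients["s"] == pytest.approx(
            y[s == 1].mean() - y[s == 0].mean(), rel=1e-10)

    def test_power_law_prediction_matches_log_space(self):
        tree = synthetic.simulate_yule_tree(30, 1.0, seed=13)
        cfg = synthetic.SyntheticConfig(n_tips=30, true_intercept=0.9,
                                        true_slopes={"x": 0.5}, sigma2=0.02,
                                        lambda_true=0.3, seed=13)
        tab = _trait_table(synthetic.simulate_traits(tree, cfg))
        fit = inference.pgls_fit(ModelSpec("log10_n", ["log10_area"]), tab, tree)
        x = 17.3
        log_pred = fit.coefficients["intercept"] + \
            fit.coefficients["log10_area"] * math.log10(x)
        assert fit.predict_power_law(log10_area=x) == pytest.approx(
            10 ** log_pred, rel=1e-12)
        assert fit.power_law_constant == pytest.approx(
            10 ** fit.coefficients["intercept"], rel=1e-12)

    def test_constant_predictor_rejected(self):
        tree = synthetic.simulate_yule_tree(10, 1.0, seed=14)
        tab = pd.DataFrame({"species": sorted(tree.tip_labels),
                            "log10_area": np.ones(10),
                            "log10_n": np.arange(10.0)})
        with pytest.raises(InsufficientVariationError):
            inference.pgls_fit(ModelSpec("log10_n", ["log10_area"]), tab, tree)


class TestFitEq1:
    def _records(self, delta, alpha, beta, gamma, noise_sd, n, seed):
        tab = synthetic.simulate_lmin_table(n, seed=seed, delta=delta, alpha=alpha,
                                           beta=beta, gamma=gamma,
                                           resid_sd=noise_sd)
        return traits.records_from_frame(tab), tab

    def test_noiseless_recovery_is_exact(self):
        recs, _ = self._records(0.5, 0.2, -0.6, -0.5, 0.0, 40, seed=1)
        fit = inference.fit_lmin_model(recs)
        for name, truth in (("intercept", 0.5), ("log10_C", 0.2),
                            ("log10_K", -0.6), ("log10_n", -0.5)):
            assert fit.coefficients[name] == pytest.approx(truth, abs=1e-8)
        assert fit.power_law_constant == pytest.approx(10 ** 0.5, rel=1e-8)

    def test_bias_within_monte_carlo_error(self):
        betas, gammas = [], []
        for rep in range(200):
            recs, _ = self._records(0.5, 0.2, -0.6, -0.5, 0.1, 65, seed=300 + rep)
            fit = inference.fit_lmin_model(recs)
            betas.append(fit.coefficients["log10_K"])
            gammas.append(fit.coefficients["log10_n"])
        for est, truth in ((np.array(betas), -0.6), (np.array(gammas), -0.5)):
            mcse = est.std(ddof=1) / math.sqrt(len(est))
            assert abs(est.mean() - truth) <= 2 * mcse + 0.01

    def test_shuffled_length_columns_change_beta(self):
        recs, tab = self._records(0.5, 0.2, -0.6, -0.5, 0.05, 50, seed=15)
        fit = inference.fit_lmin_model(recs)
        shuffled = tab.copy()
        rng = np.random.default_rng(15)
        perm = rng.permutation(len(shuffled))
        shuffled[["L_max_um", "L_min_um"]] = \
            shuffled[["L_max_um", "L_min_um"]].to_numpy()[perm]
        fit2 = inference.fit_lmin_model(traits.records_from_frame(shuffled))
        assert fit2.coefficients["log10_K"] != pytest.approx(
            fit.coefficients["log10_K"], abs=1e-3)

    def test_insufficient_data(self):
        recs, _ = self._records(0.5, 0.2, -0.6, -0.5, 0.0, 65, seed=1)
        with pytest.raises(InsufficientDataError):
            inference.fit_lmin_model(recs[:4])


class TestBattery:
    def test_single_cohort_marks_missing_cells(self):
        table, tree = synthetic.simulate_database(
            n_mammals=30, n_sauropsids=2, n_genome_mammals=25,
            n_genome_sauropsids=0, seed=16)
        table = table[table["clade"] == "mammal"]
        records = traits.records_from_frame(table)
        pruned, _ = phylo.prune_to(tree, list(table["species"]))
        bat = inference.run_battery(records, pruned)
        assert len(bat) == 16
        sau = bat[bat["cohort"] == "vermiform_sauropsid"]
        assert (sau["N"] == 0).all() and (sau["significant"] == "NA").all()
        mam = bat[bat["cohort"] == "spatulate_mammal"]
        assert (mam["N"] > 0).all()

    def test_deterministic_given_inputs(self):
        table, tree = synthetic.simulate_database(
            n_mammals=25, n_sauropsids=20, n_genome_mammals=20,
            n_genome_sauropsids=15, seed=17)
        records = traits.records_from_frame(table)
        b1 = inference.run_battery(records, tree)
        b2 = inference.run_battery(records, tree)
        pd.testing.assert_frame_equal(b1, b2)
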