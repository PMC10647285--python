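import numpy as np
import pandas as pd
import pytest

from metstab.ammi import AmmiFit, joint_anova
from metstab.blup_waasb import (
    VarianceComponents,
    classify_quadrants,
    cluster_rank_profiles,
    fit_blup,
    heritability,
    variance_components,
    waas,
    waasb,
    waasby,
    weight_scenarios,
)
from metstab.data_model import cell_means
from metstab.synthetic_data import SimConfig, simulate_met

from conftest import trial_from_cells


@pytest.fixture(scope="module")
def sim_trial():
    cfg = SimConfig(g=12, e=6, r=3, mu=600, gei_rank=3, seed=21)
    trial, truth = simulate_met(cfg)
    return trial, truth


class TestVarianceComponents:
    def test_ems_matches_mean_square_algebra(self, sim_trial):
        trial, _ = sim_trial
        an = joint_anova(trial).table["MS"]
        vc = variance_components(trial, "ems")
        g, e, r = 12, 6, 3
        assert vc.sigma2_err == pytest.approx(an["Residuals"])
        assert vc.sigma2_gei == pytest.approx((an["GEN:ENV"] - an["Residuals"]) / r)
        assert vc.sigma2_gen == pytest.approx((an["GEN"] - an["GEN:ENV"]) / (r * e))
        assert vc.sigma2_rep == pytest.approx((an["REP(ENV)"] - an["Residuals"]) / g)

    def test_reml_agrees_with_ems_when_interior(self, sim_trial):
        trial, _ = sim_trial
        ems = variance_components(trial, "ems")
        reml = variance_components(trial, "reml")
        assert ems.truncated == ()
        for name in ("sigma2_gen", "sigma2_gei", "sigma2_err"):
            assert getattr(reml, name) == pytest.approx(getattr(ems, name), rel=1e-6)

    def test_reml_agrees_with_external_mixed_model(self):
        """Independent oracle: statsmodels MixedLM with crossed variance components."""
        smf = pytest.importorskip("statsmodels.formula.api")
        trial, _ = simulate_met(SimConfig(g=6, e=4, r=3, mu=600, seed=5, sigma2_env=400,
                                          sigma2_rep=100, sigma2_gen=900, sigma2_gei=400,
                                          sigma2_err=250, gei_rank=2))
        vc = variance_components(trial, "reml")
        df = trial.data.copy()
        df["envrep"] = df["env"] + ":" + df["rep"]
        md = smf.mixedlm("Q('yield') ~ C(envrep)", df, groups=np.ones(len(df)),
                         vc_formula={"gen": "0 + C(gen)", "gei": "0 + C(gen):C(env)"})
        fit = md.fit(reml=True, method="powell", maxiter=2000)
        assert fit.vcomp[1] == pytest.approx(vc.sigma2_gen, rel=0.02)
        assert fit.vcomp[0] == pytest.approx(vc.sigma2_gei, rel=0.02)
        assert fit.scale == pytest.approx(vc.sigma2_err, rel=0.02)

    def test_negative_estimates_truncated_and_flagged(self):
        # no genotype variance, strong interaction: MS_G < MS_GE in expectation
        cfg = SimConfig(g=8, e=6, r=3, mu=600, sigma2_gen=0.0, sigma2_gei=3000.0,
                        sigma2_err=100.0, gei_rank=3, seed=2)
        trial, _ = simulate_met(cfg)
        vc = variance_components(trial, "ems")
        assert vc.sigma2_gen == 0.0
        assert "sigma2_gen" in vc.truncated
        reml = variance_components(trial, "reml")
        assert reml.sigma2_gen == pytest.approx(0.0, abs=1e-6)

    def test_zero_signal_simulation(self):
        cfg = SimConfig(g=8, e=5, r=3, mu=600, sigma2_gen=0.0, sigma2_gei=0.0,
                        sigma2_err=50.0, gei_rank=0, seed=7)
        trial, _ = simulate_met(cfg)
        vc = variance_components(trial, "ems")
        assert vc.sigma2_gen < 5.0
        assert vc.sigma2_gei < 5.0

    def test_single_replicate_rejected(self):
        trial = trial_from_cells(np.arange(12.0).reshape(4, 3) + 1, r=1)
        with pytest.raises(Exception, match="r >= 2"):
            variance_components(trial, "ems")


class TestHeritability:
    def test_pure_genetic_variance(self):
        vc = VarianceComponents(1.0, 0.0, 0.0, 0.0, "ems")
        assert heritability(vc, e=12, r=3, basis="plot") == pytest.approx(1.0)
        assert heritability(vc, e=12, r=3, basis="entry_mean") == pytest.approx(1.0)

    def test_entry_mean_arithmetic(self):
        vc = VarianceComponents(1.0, 1.0, 1.0, 0.0, "ems")
        expected = 1.0 / (1.0 + 1.0 / 12 + 1.0 / 36)
        assert heritability(vc, e=12, r=3, basis="entry_mean") == pytest.approx(expected)
        assert expected == pytest.approx(0.9, abs=0.001)
        assert heritability(vc, e=12, r=3, basis="plot") == pytest.approx(1.0 / 3)

    def test_all_zero_is_nan(self):
        vc = VarianceComponents(0.0, 0.0, 0.0, 0.0, "ems")
        assert np.isnan(heritability(vc, e=4, r=2))

    def test_recovers_configured_heritability(self):
        # entry-mean H2 = VG / (VG + Vge/e + Verr/(r e)) = 600/(600+100+50) = 0.8
        cfg = SimConfig(g=40, e=6, r=2, mu=600, sigma2_gen=600.0, sigma2_gei=600.0,
                        sigma2_err=600.0, gei_rank=4, seed=3)
        h2 = []
        for seed in range(30):
            trial, _ = simulate_met(SimConfig(**{**cfg.__dict__, "seed": seed}))
            vc = variance_components(trial, "ems")
            h2.append(heritability(vc, e=6, r=2))
        # the generator's centered interaction shifts recoverable VG by -Vge/e
        vg_eff = 600.0 - 600.0 / 6
        expected = vg_eff / (vg_eff + 600.0 / 6 + 600.0 / 12)
        assert np.mean(h2) == pytest.approx(expected, abs=0.05)


class TestFitBlup:
    def test_no_noise_means_no_shrinkage(self, rng):
        # additive truth without interaction or error: both shrinkage factors are 1
        y = 100 + np.add.outer(10 * rng.standard_normal(5), 5 * rng.standard_normal(4))
        trial = trial_from_cells(y, r=2)
        blup = fit_blup(trial)
        cm = cell_means(trial)
        assert blup.shrinkage_g == pytest.approx(1.0)
        np.testing.assert_allclose(blup.blup_g, cm.genotype_means - cm.grand_mean, atol=1e-9)
        np.testing.assert_allclose(blup.predict().to_numpy(), cm.matrix, atol=1e-8)

    def test_gei_shrinkage_vanishes_without_error_variance(self, rng):
        # interaction present, zero within-cell error: the GEI BLUP is the raw Z
        y = 100 + 10 * rng.standard_normal((5, 4))
        trial = trial_from_cells(y, r=2)
        blup = fit_blup(trial)
        cm = cell_means(trial)
        z = (cm.matrix - cm.matrix.mean(axis=1, keepdims=True)
             - cm.matrix.mean(axis=0, keepdims=True) + cm.grand_mean)
        assert blup.shrinkage_ge == pytest.approx(1.0)
        np.testing.assert_allclose(blup.blup_ge.to_numpy(), z, atol=1e-9)

    def test_zero_genetic_variance_gives_zero_blups(self, sim_trial):
        trial, _ = sim_trial
        vc = VarianceComponents(0.0, 50.0, 100.0, 0.0, "ems")
        blup = fit_blup(trial, vc=vc)
        np.testing.assert_allclose(blup.blup_g, 0.0, atol=1e-12)

    def test_blups_centered(self, sim_trial):
        trial, _ = sim_trial
        blup = fit_blup(trial)
        assert blup.blup_g.sum() == pytest.approx(0, abs=1e-8)
        ge = blup.blup_ge.to_numpy()
        np.testing.assert_allclose(ge.sum(axis=0), 0, atol=1e-8)
        np.testing.assert_allclose(ge.sum(axis=1), 0, atol=1e-8)
        assert 0 <= blup.shrinkage_g <= 1
        assert 0 <= blup.shrinkage_ge <= 1

    def test_shrinkage_beats_raw_means(self):
        """BLUP genotype means have lower MSE vs truth than raw means under noise."""
        wins = 0
        for seed in range(30):
            cfg = SimConfig(g=15, e=4, r=2, mu=600, sigma2_gen=200.0, sigma2_gei=1500.0,
                            sigma2_err=3000.0, gei_rank=3, seed=seed)
            trial, truth = simulate_met(cfg)
            cm = cell_means(trial)
            blup = fit_blup(trial)
            target = truth.mu + truth.gen_effects
            mse_raw = ((cm.genotype_means - target) ** 2).mean()
            mse_blup = ((blup.predicted_genotype_means - target) ** 2).mean()
            wins += mse_blup < mse_raw
        assert wins >= 24


class TestWaasb:
    def test_single_axis_is_absolute_score(self, sim_trial):
        trial, _ = sim_trial
        res = waasb(fit_blup(trial), n_axes=1)
        z = fit_blup(trial).blup_ge.to_numpy()
        u, s, _ = np.linalg.svd(z, full_matrices=False)
        np.testing.assert_allclose(res.values.to_numpy(),
                                   np.abs(np.sqrt(s[0]) * u[:, 0]), rtol=1e-9)

    def test_weighted_average_formula(self):
        # two axes, equal variance shares, |scores| = (3, 1) -> value 2
        gamma = np.array([[3 / np.sqrt(2), 1 / np.sqrt(2)], [0.1, 0.1]])
        fit = AmmiFit(
            mu=0.0,
            alpha=pd.Series([0.0, 0.0], index=["G01", "G02"]),
            beta=pd.Series(np.zeros(3), index=["E01", "E02", "E03"]),
            lambda_=np.array([2.0, 2.0]),
            gamma=gamma,
            delta=np.zeros((3, 2)),
            genotypes=["G01", "G02"],
            environments=["E01", "E02", "E03"],
            rep_count=1,
        )
        res = waas(fit, n_axes=2)
        assert res.values["G01"] == pytest.approx(2.0)

    def test_zero_gei_genotype_ranks_first(self, rng):
        u = rng.standard_normal((6, 2))
        u[0, :] = 0.0
        u[1:, :] -= u[1:, :].mean(axis=0, keepdims=True)
        v = rng.standard_normal((4, 2))
        v -= v.mean(axis=0, keepdims=True)
        y = 100 + np.add.outer(rng.standard_normal(6), rng.standard_normal(4)) + 5 * (u @ v.T)
        trial = trial_from_cells(y, r=2)
        res = waasb(fit_blup(trial))
        assert res.values["G01"] == pytest.approx(0.0, abs=1e-8)
        assert res.ranks["G01"] == 1

    def test_all_zero_interaction_is_valid(self):
        add = np.add.outer(np.array([1.0, 2, 3, 4]), np.array([10.0, 20, 30]))
        res = waasb(fit_blup(trial_from_cells(add, r=2)))
        np.testing.assert_allclose(res.values, 0.0, atol=1e-10)

    def test_waas_matches_waasb_without_shrinkage(self, rng):
        from metstab.ammi import fit_ammi

        y = 100 + 10 * rng.standard_normal((6, 5))
        trial = trial_from_cells(y, r=2)  # sigma2_err = 0 -> no shrinkage
        rb = waasb(fit_blup(trial))
        ra = waas(fit_ammi(trial))
        pd.testing.assert_series_equal(rb.ranks, ra.ranks)

    def test_ranking_by_axes_table_shape(self, sim_trial):
        trial, _ = sim_trial
        res = waasb(fit_blup(trial))
        assert res.by_axes.shape == (12, 5)  # p = 1..min(g-1, e-1)
        for p in res.ranks_by_axes.columns:
            assert sorted(res.ranks_by_axes[p]) == list(range(1, 13))


class TestWaasby:
    def test_best_on_both_axes_scores_100(self):
        means = pd.Series([10.0, 8.0, 5.0], index=["G1", "G2", "G3"])
        w = pd.Series([1.0, 2.0, 4.0], index=["G1", "G2", "G3"])
        tab = waasby(w, means, 65, 35)
        assert tab.loc["G1", "WAASBY"] == pytest.approx(100.0)
        assert tab.loc["G1", "rank"] == 1

    def test_worked_weighting(self):
        # genotype with rY = 100 and rW = 0 at weights 65/35 scores 65
        means = pd.Series([10.0, 5.0, 0.0], index=["G1", "G2", "G3"])
        w = pd.Series([4.0, 1.0, 0.0], index=["G1", "G2", "G3"])
        tab = waasby(w, means, 65, 35)
        assert tab.loc["G1", "rY"] == pytest.approx(100.0)
        assert tab.loc["G1", "rW"] == pytest.approx(0.0)
        assert tab.loc["G1", "WAASBY"] == pytest.approx(65.0)

    def test_yield_only_weights_reproduce_yield_ranking(self, sim_trial):
        trial, _ = sim_trial
        cm = cell_means(trial)
        res = waasb(fit_blup(trial))
        tab = waasby(res.values, cm.genotype_means, 100, 0)
        by_yield = cm.genotype_means.rank(ascending=False, method="first")
        pd.testing.assert_series_equal(tab["rank"].astype(float), by_yield,
                                       check_names=False)

    def test_weights_must_sum_to_100(self):
        means = pd.Series([1.0, 2.0], index=["G1", "G2"])
        with pytest.raises(ValueError, match="100"):
            waasby(means, means, 60, 30)

    def test_constant_input_rejected(self):
        means = pd.Series([5.0, 5.0], index=["G1", "G2"])
        w = pd.Series([1.0, 2.0], index=["G1", "G2"])
        with pytest.raises(ValueError, match="rescal"):
            waasby(w, means)

    def test_monotone_in_yield(self, sim_trial):
        """Raising one genotype's mean never lowers its WAASBY at theta_y > 0."""
        trial, _ = sim_trial
        cm = cell_means(trial)
        res = waasb(fit_blup(trial))
        base = waasby(res.values, cm.genotype_means, 65, 35)
        bumped = cm.genotype_means.copy()
        target = bumped.index[3]
        bumped[target] += 5.0
        after = waasby(res.values, bumped, 65, 35)
        assert after.loc[target, "WAASBY"] >= base.loc[target, "WAASBY"] - 1e-9


class TestWeightScenarios:
    def test_endpoint_columns(self, sim_trial):
        trial, _ = sim_trial
        cm = cell_means(trial)
        res = waasb(fit_blup(trial))
        scen = weight_scenarios(res.values, cm.genotype_means, step=5)
        assert scen.shape[1] == 21
        stability_only = waasby(res.values, cm.genotype_means, 0, 100)["rank"]
        yield_only = waasby(res.values, cm.genotype_means, 100, 0)["rank"]
        pd.testing.assert_series_equal(scen[0], stability_only, check_names=False)
        pd.testing.assert_series_equal(scen[100], yield_only, check_names=False)

    def test_double_winner_holds_rank_one_everywhere(self):
        means = pd.Series([10.0, 6.0, 2.0, 1.0], index=list("ABCD"))
        w = pd.Series([0.5, 2.0, 3.0, 4.0], index=list("ABCD"))
        scen = weight_scenarios(w, means, step=5)
        assert (scen.loc["A"] == 1).all()

    def test_invalid_step(self):
        means = pd.Series([1.0, 2.0], index=["G1", "G2"])
        with pytest.raises(ValueError, match="step"):
            weight_scenarios(means, means, step=7)


class TestQuadrants:
    def test_four_corner_fixture(self):
        means = pd.Series({"A": 10.0, "B": 10.0, "C": 0.0, "D": 0.0})
        w = pd.Series({"A": 0.0, "B": 4.0, "C": 0.0, "D": 4.0})
        quad = classify_quadrants(w, means)
        assert quad.to_dict() == {"A": "IV", "B": "II", "C": "III", "D": "I"}

    def test_boundary_convention(self):
        # a genotype exactly at both means counts as high-yield, high-WAASB
        means = pd.Series({"A": 0.0, "B": 10.0, "C": 5.0})
        w = pd.Series({"A": 0.0, "B": 4.0, "C": 2.0})
        assert classify_quadrants(w, means)["C"] == "II"

    def test_extreme_genotype_in_quadrant_iv(self, sim_trial):
        trial, _ = sim_trial
        cm = cell_means(trial)
        res = waasb(fit_blup(trial))
        means = cm.genotype_means.copy()
        w = res.values.copy()
        means[means.idxmax()] += 1.0
        quad = classify_quadrants(w, means)
        best = means.idxmax()
        if w[best] < w.mean():
            assert quad[best] == "IV"


class TestClusters:
    def test_identical_profiles_share_cluster(self):
        ranks = pd.DataFrame([[1, 2, 3], [1, 2, 3], [7, 8, 9], [9, 8, 7]],
                             index=list("ABCD"))
        cl = cluster_rank_profiles(ranks, k=2)
        assert cl["A"] == cl["B"]
        assert cl["A"] != cl["C"]

    def test_separated_groups_recovered(self, rng):
        lo = rng.integers(1, 4, size=(5, 6)).astype(float)
        hi = rng.integers(20, 24, size=(5, 6)).astype(float)
        ranks = pd.DataFrame(np.vstack([lo, hi]), index=[f"G{i}" for i in range(10)])
        cl = cluster_rank_profiles(ranks, k=2)
        assert cl.iloc[:5].nunique() == 1
        assert cl.iloc[5:].nunique() == 1
        assert cl.iloc[0] != cl.iloc[5]

    def test_permutation_invariant_up_to_relabel(self, rng, sim_trial):
        trial, _ = sim_trial
        cm = cell_means(trial)
        res = waasb(fit_blup(trial))
        scen = weight_scenarios(res.values, cm.genotype_means)
        cl = cluster_rank_profiles(scen, k=4)
        perm = rng.permutation(len(scen))
        cl_p = cluster_rank_profiles(scen.iloc[perm], k=4).reindex(cl.index)
        # same partition: co-membership matrices agree
        a = cl.to_numpy()[:, None] == cl.to_numpy()[None, :]
        b = cl_p.to_numpy()[:, None] == cl_p.to_numpy()[None, :]
        np.testing.assert_array_equal(a, b)

    def test_invalid_k(self):
        ranks = pd.DataFrame([[1, 2], [2, 1]], index=["A", "B"])
        with pytest.raises(ValueError):
            cluster_rank_profiles(ranks, k=0)
        with pytest.raises(ValueError):
            cluster_rank_profiles(ranks, k=5)
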