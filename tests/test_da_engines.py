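"""Differential-abundance engines against closed forms, enumeration
oracles, statsmodels, and simulation checks."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from consenda import da_engines as eng
from consenda import synthetic_data as sd
from consenda.io_profiles import prevalence_filter, to_proportions
from conftest import make_table, make_meta


def two_group_meta(n_per, lib=None):
    ids = [f"S{i+1}" for i in range(2 * n_per)]
    return ids, make_meta(ids, ["case"] * n_per + ["control"] * n_per,
                          library_sizes=lib)


class TestAstLm:
    def test_constant_feature_gets_p_one(self):
        ids, meta = two_group_meta(3)
        table = make_table(np.full((6, 2), 0.5), sample_ids=ids, unit="proportion")
        res = eng.engine_ast_lm(table, meta, eng.Design())
        assert (res["p"] == 1.0).all()
        assert np.abs(res["effect"]).max() < 1e-12

    def test_matches_two_sample_regression_oracle(self):
        # engine's t on AST values equals the textbook two-sample t
        ids, meta = two_group_meta(3)
        prop = np.array([[0.1], [0.2], [0.3], [0.4], [0.5], [0.6]])
        table = make_table(prop, sample_ids=ids, unit="proportion")
        res = eng.engine_ast_lm(table, meta, eng.Design())
        y = np.arcsin(np.sqrt(prop[:, 0]))
        t_ref, p_ref = stats.ttest_ind(y[:3], y[3:])
        assert res["p"][0] == pytest.approx(p_ref)
        assert res["effect"][0] == pytest.approx(y[:3].mean() - y[3:].mean())

    def test_count_mode_uses_clr(self, two_group_cohort):
        table, meta, _ = two_group_cohort
        res = eng.engine_ast_lm(prevalence_filter(table), meta, eng.Design())
        assert res["engine"].iloc[0] == "ast_lm"
        assert res["q"].between(0, 1).all()


class TestClrLmBias:
    def test_shared_effect_cancels(self):
        # every feature shifted by the same delta in cases: corrected ~ 0
        rng = np.random.default_rng(0)
        n_per, m = 10, 21
        ids, meta = two_group_meta(n_per)
        base = rng.uniform(0.5, 2.0, size=(2 * n_per, m))
        base[:n_per] *= 3.0            # common multiplicative shift, all features
        table = make_table(base / base.sum(1, keepdims=True),
                           sample_ids=ids, unit="proportion")
        res = eng.engine_clr_lm_bias(table, meta, eng.Design())
        # raw shift is log 3 ~ 1.1; corrected effects collapse to noise level
        assert np.abs(res["effect"]).max() < 0.5
        assert np.abs(np.median(res["effect"])) < 0.05
        assert not res["significant"].any()

    def test_feature_permutation_equivariance(self, two_group_cohort):
        table, meta, _ = two_group_cohort
        ft = prevalence_filter(table)
        res1 = eng.engine_clr_lm_bias(ft, meta, eng.Design())
        perm = np.random.default_rng(1).permutation(ft.n_features)
        ft2 = ft.select_features([ft.feature_ids[i] for i in perm])
        res2 = eng.engine_clr_lm_bias(ft2, meta, eng.Design())
        merged = res1.merge(res2, on="feature_id", suffixes=("_a", "_b"))
        np.testing.assert_allclose(merged["p_a"], merged["p_b"], atol=1e-12)

    def test_spiked_feature_keeps_raw_effect(self):
        # one spiked feature among many nulls: median-of-effects ~ 0
        rng = np.random.default_rng(3)
        n_per, m = 15, 40
        ids, meta = two_group_meta(n_per)
        vals = rng.lognormal(0, 0.3, size=(2 * n_per, m))
        vals[:n_per, 0] *= 8.0
        table = make_table(vals / vals.sum(1, keepdims=True),
                           sample_ids=ids, unit="proportion")
        res = eng.engine_clr_lm_bias(table, meta, eng.Design())
        assert res.loc[0, "significant"]
        assert res.loc[0, "effect"] == pytest.approx(np.log(8), rel=0.25)


class TestLoglinearBias:
    def test_recovers_sample_offsets(self):
        rng = np.random.default_rng(5)
        n, m = 30, 150
        d_true = rng.normal(0, 1, n)
        y = d_true[:, None] + rng.normal(0, 0.5, (n, m))
        counts = np.rint(np.exp(y + 6))   # large counts: log1p distortion negligible
        ids = [f"S{i}" for i in range(n)]
        meta = make_meta(ids, ["case"] * 15 + ["control"] * 15,
                         library_sizes=list(counts.sum(1)))
        table = make_table(counts, sample_ids=ids)
        res = eng.engine_loglinear_bias(table, meta, eng.Design())
        offsets = res.attrs["sample_offsets"].to_numpy()
        assert np.corrcoef(offsets, d_true)[0, 1] > 0.99

    def test_offset_gauge_freedom(self):
        # multiplying every count by e adds 1 to every true offset; with
        # counts large enough that log1p ~ log, effects are unchanged
        rng = np.random.default_rng(12)
        n, m = 20, 60
        counts = np.rint(np.exp(rng.normal(0, 0.7, (n, m)) + 6))
        ids = [f"S{i}" for i in range(n)]
        meta = make_meta(ids, ["case"] * 10 + ["control"] * 10,
                         library_sizes=list(counts.sum(1)))
        res1 = eng.engine_loglinear_bias(make_table(counts, sample_ids=ids),
                                         meta, eng.Design())
        res2 = eng.engine_loglinear_bias(
            make_table(np.rint(counts * np.e), sample_ids=ids), meta, eng.Design())
        np.testing.assert_allclose(res1["effect"], res2["effect"], atol=0.01)

    def test_single_feature_refused(self):
        ids, meta = two_group_meta(3)
        table = make_table(np.ones((6, 1)), sample_ids=ids)
        with pytest.raises(ValueError, match="single feature"):
            eng.engine_loglinear_bias(table, meta, eng.Design())

    def test_requires_counts(self):
        ids, meta = two_group_meta(3)
        table = make_table(np.full((6, 3), 1 / 3), sample_ids=ids, unit="proportion")
        with pytest.raises(ValueError, match="count"):
            eng.engine_loglinear_bias(table, meta, eng.Design())


class TestDirichletMc:
    def test_separated_groups_hit_exact_wilcoxon_floor(self):
        # 4 vs 4, gamma=0, one feature completely separated: per-instance
        # exact Wilcoxon p = 2/70, so the instance-averaged p sits there too
        ids, meta = two_group_meta(4)
        counts = np.column_stack([
            [900, 910, 920, 930, 100, 110, 120, 130],
            [100, 90, 80, 70, 900, 890, 880, 870]]).astype(float) * 100
        table = make_table(counts, sample_ids=ids)
        cfg = eng.EngineConfig(mc_samples=64, scale_noise_gamma=0.0, seed=0)
        res = eng.engine_dirichlet_mc(table, meta, eng.Design(), cfg)
        np.testing.assert_allclose(res["p"], 2 / 70, atol=1e-9)

    def test_duplicated_groups_not_significant(self):
        ids, meta = two_group_meta(5)
        rng = np.random.default_rng(2)
        half = rng.integers(50, 500, size=(5, 12))
        counts = np.vstack([half, half]).astype(float)
        table = make_table(counts, sample_ids=ids)
        cfg = eng.EngineConfig(mc_samples=32, seed=1)
        res = eng.engine_dirichlet_mc(table, meta, eng.Design(), cfg)
        assert not res["significant"].any()
        assert res["q"].min() > 0.5

    def test_gamma_monotone_in_call_count(self):
        # more scale noise never finds more signal (<=1 violation in 10 seeds)
        violations = 0
        for seed in range(10):
            cfg = sd.SimConfig(n_features=50, n_subjects_per_group=12,
                               paired_fraction=0, n_diff=2, seed=seed)
            table, meta, _ = sd.simulate_cohort(cfg)
            ft = prevalence_filter(table)
            counts = []
            for gamma in (0.0, 1.0):
                c = eng.EngineConfig(mc_samples=48, scale_noise_gamma=gamma, seed=7)
                res = eng.engine_dirichlet_mc(ft, meta, eng.Design(), c)
                counts.append(int(res["significant"].sum()))
            if counts[1] > counts[0]:
                violations += 1
        assert violations <= 1

    def test_mc_samples_floor(self):
        with pytest.raises(ValueError):
            eng.EngineConfig(mc_samples=1)


class TestNegbinWald:
    def test_equal_depth_size_factors_are_one(self):
        rng = np.random.default_rng(0)
        counts = rng.multinomial(10_000, np.full(20, 0.05), size=8).astype(float)
        np.testing.assert_allclose(eng.poscounts_size_factors(counts), 1.0, atol=0.05)

    def test_doubling_one_sample_only_rescales_its_factor(self, null_cohort):
        table, meta, _ = null_cohort
        ft = prevalence_filter(table)
        res1 = eng.engine_negbin_wald(ft, meta, eng.Design())
        vals = ft.values().copy()
        vals[0] *= 2
        ft2 = make_table(vals, sample_ids=ft.sample_ids, feature_ids=ft.feature_ids)
        res2 = eng.engine_negbin_wald(ft2, meta, eng.Design())
        sf1 = res1.attrs["size_factors"].to_numpy()
        sf2 = res2.attrs["size_factors"].to_numpy()
        ratio = sf2 / sf1
        # relative size factor of the doubled sample doubles exactly
        np.testing.assert_allclose(ratio[0] / ratio[1:], 2.0, rtol=1e-9)
        # effects move only through the dispersion trend's scale dependence
        np.testing.assert_allclose(res1["effect"], res2["effect"], atol=2e-3)

    def test_poisson_data_dispersions_near_floor(self):
        rng = np.random.default_rng(1)
        mu = rng.uniform(50, 500, 80)
        counts = rng.poisson(mu, size=(30, 80)).astype(float)
        ids = [f"S{i}" for i in range(30)]
        meta = make_meta(ids, ["case"] * 15 + ["control"] * 15,
                         library_sizes=list(counts.sum(1)))
        res = eng.engine_negbin_wald(make_table(counts, sample_ids=ids),
                                     meta, eng.Design())
        assert res.attrs["dispersions"].median() < 0.05

    def test_all_zero_sample_rejected(self):
        ids, meta = two_group_meta(2)
        counts = np.array([[0, 0], [5, 5], [5, 5], [5, 5]], dtype=float)
        with pytest.raises(ValueError, match="all-zero"):
            eng.engine_negbin_wald(make_table(counts, sample_ids=ids),
                                   meta, eng.Design())

    def test_coefficient_matches_statsmodels_glm(self):
        import statsmodels.api as sm
        rng = np.random.default_rng(4)
        n = 24
        counts = rng.negative_binomial(5, 0.1, size=(n, 30)).astype(float) + 1
        ids = [f"S{i}" for i in range(n)]
        meta = make_meta(ids, ["case"] * 12 + ["control"] * 12,
                         library_sizes=list(counts.sum(1)))
        table = make_table(counts, sample_ids=ids)
        res = eng.engine_negbin_wald(table, meta, eng.Design())
        sf = res.attrs["size_factors"].to_numpy()
        disp = res.attrs["dispersions"].to_numpy()
        X = np.column_stack([np.ones(n), [1] * 12 + [0] * 12])
        j = 3
        glm = sm.GLM(counts[:, j], X, family=sm.families.NegativeBinomial(alpha=disp[j]),
                     offset=np.log(sf)).fit()
        assert res["effect"][j] == pytest.approx(glm.params[1], rel=1e-4)


class TestReferencePerm:
    def test_implanted_feature_attains_min_q(self):
        cfg = sd.SimConfig(n_features=60, n_subjects_per_group=20,
                           paired_fraction=0, n_diff=1, seed=3)
        table, meta, truth = sd.simulate_cohort(cfg)
        ft = to_proportions(prevalence_filter(table))
        res = eng.engine_reference_perm(ft, meta, eng.Design(),
                                        eng.EngineConfig(n_perm=199, seed=0))
        feat = next(iter(truth.diff_features))
        assert res.set_index("feature_id").loc[feat, "q"] == res["q"].min()

    def test_exhaustive_enumeration_small_n(self):
        # n=6: permutation p from sampling matches full enumeration
        rng = np.random.default_rng(6)
        ids, meta = two_group_meta(3)
        vals = rng.dirichlet(np.ones(8) * 2, size=6)
        table = make_table(vals, sample_ids=ids, unit="proportion")
        exact = eng.engine_reference_perm(table, meta, eng.Design(),
                                          eng.EngineConfig(seed=0), exhaustive=True)
        sampled = eng.engine_reference_perm(table, meta, eng.Design(),
                                            eng.EngineConfig(n_perm=20000, seed=1))
        np.testing.assert_allclose(sampled["p"], exact["p"], atol=0.02)

    def test_null_f_distribution_matches_permutation(self):
        # pooled over seeds so within-cohort dependence between features
        # does not dominate the comparison
        obs, null = [], []
        for seed in range(5):
            cfg = sd.SimConfig(n_features=60, n_subjects_per_group=15,
                               paired_fraction=0, n_diff=0, seed=8 + seed)
            table, meta, _ = sd.simulate_cohort(cfg)
            ft = to_proportions(prevalence_filter(table))
            res = eng.engine_reference_perm(ft, meta, eng.Design(),
                                            eng.EngineConfig(n_perm=299, seed=2))
            obs.append(res.attrs["f_observed"])
            null.append(res.attrs["f_null"].ravel())
        assert stats.ks_2samp(np.concatenate(obs),
                              np.concatenate(null)).pvalue > 0.01


class TestRunAllEngines:
    def test_bookkeeping_three_levels(self, null_cohort):
        table, meta, _ = null_cohort
        tables = {lv: table for lv in ("phylum", "genus", "sgb")}
        cfg = eng.EngineConfig(mc_samples=8, n_perm=49, seed=0)
        run = eng.run_all_engines(tables, meta, eng.Design(), cfg=cfg)
        assert len(run["results"]) == 18
        assert len(run["audit"]) == 18

    def test_method_switch_changes_only_switchable_inputs(self, null_cohort):
        table, meta, _ = null_cohort
        cfg = eng.EngineConfig(mc_samples=8, n_perm=49, seed=0)
        units = {}
        for mode in ("proportions", "counts"):
            run = eng.run_all_engines({"sgb": table}, meta, eng.Design(),
                                      input_mode=mode, cfg=cfg)
            units[mode] = {a["engine"]: a["unit"] for a in run["audit"]}
        for e in eng.ENGINE_IDS:
            if e in eng.SWITCHABLE_ENGINES:
                assert units["proportions"][e] == "proportion"
                assert units["counts"][e] == "count"
            else:
                assert units["proportions"][e] == units["counts"][e] == "count"

    def test_engine_failure_is_isolated(self, null_cohort, monkeypatch):
        table, meta, _ = null_cohort
        def boom(*a, **k):
            raise RuntimeError("engine exploded")
        monkeypatch.setitem(eng._ENGINE_FUNCS, "negbin_wald", boom)
        cfg = eng.EngineConfig(mc_samples=8, n_perm=49, seed=0)
        run = eng.run_all_engines({"sgb": table}, meta, eng.Design(), cfg=cfg)
        statuses = {a["engine"]: a["status"] for a in run["audit"]}
        assert "engine exploded" in statuses["negbin_wald"]
        assert len(run["results"]) == 5

    def test_sample_reorder_equivariance(self, two_group_cohort):
        table, meta, _ = two_group_cohort
        ft = prevalence_filter(table)
        res1 = eng.engine_ast_lm(ft, meta, eng.Design())
        perm = np.random.default_rng(0).permutation(ft.n_samples)
        ft2 = ft.select_samples([ft.sample_ids[i] for i in perm])
        res2 = eng.engine_ast_lm(ft2, meta, eng.Design())
        np.testing.assert_allclose(res1["p"], res2["p"], atol=1e-10)


class TestEngineFdrBehaviour:
    def test_no_engine_inflates_null_call_rate(self):
        """Raw p < 0.05 fraction stays near or below nominal for every
        engine on null cohorts (engines may be conservative, never badly
        anticonservative)."""
        pools = {e: [] for e in eng.ENGINE_IDS}
        for seed in range(6):
            cfg = sd.SimConfig(n_features=100, n_subjects_per_group=15,
                               paired_fraction=0, n_diff=0, seed=100 + seed)
            table, meta, _ = sd.simulate_cohort(cfg)
            c = eng.EngineConfig(mc_samples=32, n_perm=99, seed=seed)
            run = eng.run_all_engines({"sgb": table}, meta, eng.Design(),
                                      cfg=c)
            for (_, e), df in run["results"].items():
                pools[e].append(df["p"].to_numpy())
        for e, ps in pools.items():
            frac = (np.concatenate(ps) < 0.05).mean()
            assert frac < 0.09, f"{e} null p<0.05 fraction {frac:.3f}"

    def test_implanted_direction_agreement(self, two_group_cohort):
        table, meta, truth = two_group_cohort
        cfg = eng.EngineConfig(mc_samples=64, n_perm=199, seed=0)
        run = eng.run_all_engines({"sgb": table}, meta, eng.Design(), cfg=cfg)
        feat = max(truth.diff_features, key=truth.diff_features.get)
        for (_, e), df in run["results"].items():
            row = df.set_index("feature_id").loc[feat]
            if row["significant"]:
                assert row["direction"] == np.sign(truth.diff_features[feat])
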