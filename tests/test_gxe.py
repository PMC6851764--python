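import numpy as np
import pandas as pd
import pytest

from megxe.gxe import (
    ammi,
    ammi_reconstruct,
    category_variance_explained,
    cell_mean_matrix,
    compare_groups_tukey,
    finlay_wilkinson,
    fit_two_way_vc,
    gge,
    stage1_adjusted_means,
)
from megxe.simulate import SimConfig, simulate_genotype_panel, simulate_trial_phenotypes


def make_plots(rng, n_geno=40, envs=("E1", "E2", "E3"), reps=2,
               sg=0.0, sge=0.0, se=0.0, env_eff=None, geno_eff=None):
    env_eff = env_eff if env_eff is not None else np.zeros(len(envs))
    g = geno_eff if geno_eff is not None else rng.normal(0, np.sqrt(sg), n_geno)
    rows = []
    for j, env in enumerate(envs):
        ge = rng.normal(0, np.sqrt(sge), n_geno)
        for i in range(n_geno):
            for r in range(reps):
                rows.append({
                    "genotype": f"G{i:03d}", "env": env,
                    "block": f"{env}_b{r}", "rep": r + 1, "is_check": False,
                    "trait": "t",
                    "value": 50 + env_eff[j] + g[i] + ge[i]
                    + rng.normal(0, np.sqrt(se)),
                })
    return pd.DataFrame(rows)


class TestStage1:
    def test_balanced_no_noise_means_equal_raw(self, rng):
        g = rng.normal(0, 2, 30)
        plots = make_plots(rng, n_geno=30, envs=("E1",), reps=2, geno_eff=g)
        res = stage1_adjusted_means(plots, "E1")
        raw = plots.groupby("genotype")["value"].mean()
        got = res.adjusted_means.set_index("genotype")["mean"]
        np.testing.assert_allclose(got[raw.index], raw, atol=1e-6)
        assert res.h2 > 0.99

    def test_null_heritability(self):
        low = 0
        for s in range(5):
            rng = np.random.default_rng(s)
            plots = make_plots(rng, n_geno=40, envs=("E1",), reps=2,
                               sg=0.0, se=1.0)
            res = stage1_adjusted_means(plots, "E1")
            if res.h2 < 0.1:
                low += 1
        assert low >= 4

    def test_heritability_recovery(self):
        h2s, sgs = [], []
        for s in range(3):
            rng = np.random.default_rng(100 + s)
            plots = make_plots(rng, n_geno=150, envs=("E1",), reps=2,
                               sg=4.0, se=1.0)
            res = stage1_adjusted_means(plots, "E1")
            h2s.append(res.h2)
            sgs.append(res.sigma2_g)
        # expected line-mean heritability 2*4/(2*4+1)
        assert np.mean(h2s) == pytest.approx(8 / 9, abs=0.08)
        assert np.mean(sgs) == pytest.approx(4.0, rel=0.25)

    def test_no_replication_warns(self, rng):
        plots = make_plots(rng, n_geno=10, envs=("E1",), reps=1)
        plots["block"] = [f"b{i % 2}" for i in range(len(plots))]
        with pytest.warns(UserWarning, match="replication"):
            res = stage1_adjusted_means(plots, "E1")
        assert np.isnan(res.h2)


class TestTwoWayVc:
    def test_translation_invariance(self, rng):
        plots = make_plots(rng, sg=2.0, sge=1.0, se=1.0)
        v1 = fit_two_way_vc(plots)
        plots2 = plots.copy()
        plots2["value"] += 1000.0
        v2 = fit_two_way_vc(plots2)
        for k in v1:
            assert v1[k] == pytest.approx(v2[k], rel=1e-3, abs=1e-5)

    def test_zero_ge_boundary(self):
        at_zero = 0
        for s in range(5):
            rng = np.random.default_rng(s)
            plots = make_plots(rng, n_geno=60, sg=3.0, sge=0.0, se=1.0)
            v = fit_two_way_vc(plots)
            if v["sigma2_GE"] < 0.1:
                at_zero += 1
        assert at_zero >= 3

    def test_single_environment_error(self, rng):
        plots = make_plots(rng, envs=("E1",))
        with pytest.raises(ValueError):
            fit_two_way_vc(plots)

    def test_recovery(self, rng):
        cfg = SimConfig(n_lines=200, n_subpops=2, n_chrom=2,
                        snps_per_chrom=200, polygenic_var=4.0, gxe_var=2.0,
                        residual_var=1.0, prep_fraction=1.0, seed=9)
        panel, truth = simulate_genotype_panel(cfg)
        plots = simulate_trial_phenotypes(panel, truth, cfg)
        v = fit_two_way_vc(plots[~plots["is_check"]])
        assert v["sigma2_G"] == pytest.approx(4.0, rel=0.25)
        assert v["sigma2_GE"] == pytest.approx(2.0, rel=0.25)
        assert v["sigma2_e"] == pytest.approx(1.0, rel=0.25)


class TestCategoryVariance:
    def test_saturating_categories(self, rng):
        # genotype main effects generated entirely by 4 category levels
        cats = {f"G{i:03d}": f"c{i % 4}" for i in range(40)}
        cat_eff = {f"c{k}": v for k, v in zip(range(4), (-3.0, -1.0, 1.0, 3.0))}
        g = np.array([cat_eff[cats[f"G{i:03d}"]] for i in range(40)])
        plots = make_plots(rng, n_geno=40, geno_eff=g, se=0.5)
        out = category_variance_explained(plots, cats)
        assert out["pct_delta_G"] > 85.0

    def test_permuted_labels_near_zero(self, rng):
        g = rng.normal(0, 2, 40)
        plots = make_plots(rng, n_geno=40, geno_eff=g, sge=1.0, se=0.5)
        perm = rng.permutation([f"c{i % 4}" for i in range(40)])
        cats = {f"G{i:03d}": perm[i] for i in range(40)}
        out = category_variance_explained(plots, cats)
        assert out["pct_delta_G"] < 30.0

    def test_constructed_ge_signal(self, rng):
        # category drives a G-by-E contrast
        cats = {f"G{i:03d}": "a" if i < 20 else "b" for i in range(40)}
        rows = make_plots(rng, n_geno=40, sge=0.2, se=0.3)
        flip = rows["genotype"].map(cats).map({"a": 1.0, "b": -1.0})
        envsign = rows["env"].map({"E1": 1.0, "E2": -1.0, "E3": 1.0})
        rows["value"] += 2.0 * flip * envsign
        out = category_variance_explained(rows, cats)
        assert out["pct_delta_GE"] > 50.0

    def test_missing_category_error(self, rng):
        plots = make_plots(rng, n_geno=10)
        with pytest.raises(ValueError, match="without category"):
            category_variance_explained(plots, {"G000": "x"})


class TestFinlayWilkinson:
    def additive(self, rng, ng=20, envs=5):
        g = rng.normal(0, 2, ng)
        e = rng.normal(0, 3, envs)
        M = 50 + g[:, None] + e[None, :]
        return pd.DataFrame(M, index=[f"G{i}" for i in range(ng)],
                            columns=[f"E{j}" for j in range(envs)])

    def test_additive_slopes_one(self, rng):
        M = self.additive(rng)
        fw = finlay_wilkinson(M)
        np.testing.assert_allclose(fw["slope"], 1.0, atol=1e-10)

    def test_sensitive_genotype(self, rng):
        M = self.additive(rng)
        e = M.mean(axis=0) - M.to_numpy().mean()
        M.iloc[0] = 55 + 2.0 * e
        fw = finlay_wilkinson(M)
        # slopes computed against the recomputed environment means
        assert fw["slope"].iloc[0] > 1.5

    def test_mean_slope_identity(self, rng):
        M = pd.DataFrame(rng.normal(0, 1, (15, 4)))
        fw = finlay_wilkinson(M)
        assert fw["slope"].mean() == pytest.approx(1.0, abs=1e-10)

    def test_too_few_envs(self, rng):
        with pytest.raises(ValueError):
            finlay_wilkinson(pd.DataFrame(rng.normal(size=(5, 2))))

    def test_sparse_genotype_flagged(self, rng):
        M = self.additive(rng)
        M.iloc[0, :3] = np.nan
        fw = finlay_wilkinson(M)
        assert np.isnan(fw["slope"].iloc[0])
        assert fw["n_env"].iloc[0] == 2


class TestAmmiGge:
    def test_rank_one_interaction(self, rng):
        s = rng.normal(0, 1, 25)
        t = rng.normal(0, 1, 5)
        s -= s.mean()
        t -= t.mean()
        M = pd.DataFrame(50 + np.outer(s, t))
        fit = ammi(M, n_axes=4)
        total = fit.axis_ss.sum()
        assert fit.axis_ss[0] / total == pytest.approx(1.0, abs=1e-10)
        r = np.corrcoef(fit.geno_scores.iloc[:, 0], s)[0, 1]
        assert abs(r) == pytest.approx(1.0, abs=1e-8)

    def test_full_rank_reconstruction(self, rng):
        M = pd.DataFrame(rng.normal(60, 4, (12, 5)))
        fit = ammi(M, n_axes=4)
        np.testing.assert_allclose(ammi_reconstruct(fit), M.to_numpy(),
                                   atol=1e-10)

    def test_double_centering(self, rng):
        M = pd.DataFrame(rng.normal(60, 4, (10, 4)))
        fit = ammi(M, n_axes=3)
        R = (M.to_numpy() - fit.grand_mean
             - fit.genotype_main.to_numpy()[:, None]
             - fit.env_main.to_numpy()[None, :])
        np.testing.assert_allclose(R.sum(axis=0), 0, atol=1e-10)
        np.testing.assert_allclose(R.sum(axis=1), 0, atol=1e-10)

    def test_gge_additive_data(self, rng):
        g = np.sort(rng.normal(0, 3, 15))
        M = pd.DataFrame(50 + g[:, None] + np.zeros((15, 4)))
        M += rng.normal(0, 1e-9, M.shape)  # break exact rank deficiency
        fit = gge(M, n_axes=2)
        env1 = fit.env_scores.iloc[:, 0]
        assert (env1 > 0).all() or (env1 < 0).all()
        r = np.corrcoef(fit.geno_scores.iloc[:, 0], g)[0, 1]
        assert abs(r) > 0.999

    def test_gge_parseval(self, rng):
        M = pd.DataFrame(rng.normal(60, 4, (10, 4)))
        fit = gge(M, n_axes=4)
        centered = M.to_numpy() - M.to_numpy().mean(axis=0)
        assert fit.axis_ss.sum() == pytest.approx((centered ** 2).sum(),
                                                  abs=1e-8)

    def test_ammi_equals_gge_without_main_effects(self, rng):
        # pure interaction: no genotype main effects
        R = rng.normal(0, 1, (10, 4))
        R -= R.mean(axis=1, keepdims=True)
        R -= R.mean(axis=0, keepdims=True)
        M = pd.DataFrame(R)
        fa = ammi(M, n_axes=2)
        fg = gge(M, n_axes=2)
        np.testing.assert_allclose(np.abs(fa.geno_scores), np.abs(fg.geno_scores),
                                   atol=1e-8)

    def test_missing_cells_require_flag(self, rng):
        M = pd.DataFrame(rng.normal(size=(8, 4)))
        M.iloc[0, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            ammi(M, n_axes=2)
        fit = ammi(M, n_axes=2, impute_missing=True)
        assert np.isfinite(fit.axis_ss).all()


class TestTukey:
    def test_null_shares_letter(self):
        shared = 0
        for s in range(10):
            rng = np.random.default_rng(s)
            vals = rng.normal(0, 1, 45)
            grp = np.repeat(["a", "b", "c"], 15)
            out = compare_groups_tukey(vals, grp)
            letters = out["letters"].tolist()
            if len(set.intersection(*[set(l) for l in letters])) >= 1:
                shared += 1
        assert shared >= 9

    def test_separated_groups_distinct(self, rng):
        vals = np.concatenate([rng.normal(0, 1, 12), rng.normal(10, 1, 12)])
        grp = ["lo"] * 12 + ["hi"] * 12
        out = compare_groups_tukey(vals, grp)
        lets = dict(zip(out["group"], out["letters"]))
        assert set(lets["lo"]) & set(lets["hi"]) == set()

    def test_group_order_invariance(self, rng):
        vals = np.concatenate([rng.normal(0, 1, 10), rng.normal(5, 1, 10),
                               rng.normal(10, 1, 10)])
        grp = np.repeat(["x", "y", "z"], 10)
        out1 = compare_groups_tukey(vals, grp)
        perm = rng.permutation(len(vals))
        out2 = compare_groups_tukey(vals[perm], grp[perm])
        m1 = dict(zip(out1["group"], out1["mean"]))
        m2 = dict(zip(out2["group"], out2["mean"]))
        for k in m1:
            assert m1[k] == pytest.approx(m2[k])

    def test_singleton_group_excluded(self, rng):
        vals = np.concatenate([rng.normal(0, 1, 10), rng.normal(5, 1, 10),
                               [99.0]])
        grp = ["a"] * 10 + ["b"] * 10 + ["c"]
        with pytest.warns(UserWarning, match="1 observation"):
            out = compare_groups_tukey(vals, grp)
        assert "c" not in set(out["group"])


class TestCellMeans:
    def test_pivot_and_checks_excluded(self, rng):
        plots = make_plots(rng, n_geno=5)
        plots.loc[0, "is_check"] = True
        cm = cell_mean_matrix(plots)
        assert cm.shape == (5, 3)
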