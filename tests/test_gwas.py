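import numpy as np
import pandas as pd
import pytest
from scipy import stats

from megxe.genodata import filter_variants, impute_modal
from megxe.gwas import (
    genomic_control,
    li_ji_meff,
    loco_structure,
    meff_panel,
    scan_haplotypes,
    scan_snps,
    significance_threshold,
    structure_by_chromosome,
)
from megxe.gxe import cell_mean_matrix
from megxe.hapblocks import GeneRegion, build_blockset
from megxe.ldkin import local_ld_decay
from megxe.simulate import SimConfig, simulate_genotype_panel, simulate_trial_phenotypes

from conftest import make_panel


class TestLiJiMeff:
    def test_independent_markers(self):
        assert li_ji_meff(np.ones(37)) == pytest.approx(37.0)

    def test_perfectly_correlated(self):
        m = 12
        lam = np.array([float(m)] + [0.0] * (m - 1))
        assert li_ji_meff(lam) == pytest.approx(1.0)

    def test_mixed_spectrum(self):
        assert li_ji_meff([1.5, 0.5]) == pytest.approx(2.0)

    def test_meff_panel_duplicated_orthogonal_columns(self):
        # two exactly orthogonal markers, each duplicated: spectrum {2,2,0,0}
        c1 = np.array([0, 0, 2, 2], dtype=np.int8)
        c2 = np.array([0, 2, 0, 2], dtype=np.int8)
        panel = make_panel(np.column_stack([c1, c1, c2, c2]))
        assert meff_panel(panel) == pytest.approx(2.0, abs=1e-8)


class TestGenomicControl:
    def test_null_lambda_near_one(self, rng):
        W = rng.chisquare(5, size=10_000)
        lam, adj = genomic_control(W, 5)
        assert 0.95 < lam < 1.05

    def test_inflated_stats_rescaled(self, rng):
        W = 2.0 * rng.chisquare(5, size=10_000)
        lam, adj = genomic_control(W, 5)
        assert lam == pytest.approx(2.0, rel=0.05)
        assert np.median(adj) == pytest.approx(stats.chi2.median(5), rel=0.05)

    def test_no_deflation_policy(self, rng):
        W = 0.5 * rng.chisquare(5, size=1000)
        lam, adj = genomic_control(W, 5)
        assert lam < 1.0
        np.testing.assert_array_equal(adj, W)

    def test_bad_df(self):
        with pytest.raises(ValueError):
            genomic_control(np.ones(100), 0)


class TestThreshold:
    def test_examples(self):
        assert significance_threshold(100, 0.05) == pytest.approx(5e-4)
        assert significance_threshold(1, 0.05) == pytest.approx(0.05)

    def test_monotone_in_alpha(self):
        assert significance_threshold(50, 0.01) < significance_threshold(50, 0.05)

    def test_meff_below_one(self):
        with pytest.raises(ValueError):
            significance_threshold(0.5, 0.05)


@pytest.fixture(scope="module")
def scan_setup():
    """Structured panel + phenotypes with one planted sign-flip QTL."""
    qtl = 150
    cfg = SimConfig(n_lines=200, n_subpops=2, fst_target=0.15, n_chrom=3,
                    snps_per_chrom=300, copy_switch_rate=1e-2,
                    qtl_spec=((qtl, (-3.0, -3.0, 3.0, 3.0, 3.0)),),
                    polygenic_var=1.0, gxe_var=0.5, residual_var=1.0,
                    n_gene_regions=0, seed=61)
    panel, truth = simulate_genotype_panel(cfg)
    plots = simulate_trial_phenotypes(panel, truth, cfg)
    plots = plots[~plots["is_check"]]
    fpanel, _ = filter_variants(panel)
    fpanel = impute_modal(fpanel)
    with pytest.warns(UserWarning):
        prof = local_ld_decay(fpanel, thin_step=5)
    sbc = structure_by_chromosome(fpanel, prof, seed=2)
    cm = cell_mean_matrix(plots)
    return panel, truth, fpanel, prof, sbc, cm, qtl


class TestLocoStructure:
    def test_excludes_target_chromosome(self, scan_setup):
        panel, truth, fpanel, prof, sbc, cm, qtl = scan_setup
        res = loco_structure(fpanel, prof, "1S", seed=2)
        # rebuild the sampled index set and verify no chromosome-1S SNPs
        from megxe.ldkin import kinship_astle_balding, ld_aware_sample
        idx = ld_aware_sample(fpanel.snp_map, prof, seed=2,
                              exclude_chroms=("1S",))
        assert not (fpanel.snp_map["chrom"].iloc[idx] == "1S").any()

    def test_full_kinship_flag(self, scan_setup):
        panel, truth, fpanel, prof, sbc, cm, qtl = scan_setup
        full = loco_structure(fpanel, prof, "1S", seed=2, full_kinship=True)
        again = loco_structure(fpanel, prof, "2S", seed=2, full_kinship=True)
        np.testing.assert_allclose(full.scores[:, 0], again.scores[:, 0])

    def test_single_chromosome_error(self, rng):
        d = rng.choice([0, 2], size=(30, 20)).astype(np.int8)
        panel = make_panel(d)
        with pytest.raises(ValueError, match="full_kinship"):
            loco_structure(panel, None, "1S")

    def test_loco_pc_tracks_full_pc(self, scan_setup):
        panel, truth, fpanel, prof, sbc, cm, qtl = scan_setup
        full = loco_structure(fpanel, prof, "1S", seed=2, full_kinship=True)
        loco = loco_structure(fpanel, prof, "1S", seed=2)
        r = np.corrcoef(full.scores[:, 0], loco.scores[:, 0])[0, 1]
        assert abs(r) >= 0.95


class TestScanSnps:
    def test_planted_qtl_recovered(self, scan_setup):
        panel, truth, fpanel, prof, sbc, cm, qtl = scan_setup
        qtl_id = panel.snp_map["id"].iloc[qtl]
        sub = fpanel.take_snps(fpanel.snp_indices_of("1S"))
        res = scan_snps(cm, sub, {"1S": sbc["1S"]})
        row = res.table[res.table["marker_id"] == qtl_id].iloc[0]
        # orientation: the filtered panel may have recoded the minor allele
        j = int(np.flatnonzero(sub.snp_map["id"] == qtl_id)[0])
        orig = panel.dosages[:, qtl].astype(float)
        cur = sub.dosages[:, j].astype(float)
        flip = -1.0 if np.corrcoef(orig, cur)[0, 1] < 0 else 1.0
        betas = flip * np.array([row[f"beta_{e}"] for e in cm.columns])
        np.testing.assert_allclose(betas, truth.qtl_effects[0], atol=0.5)
        assert row["p_raw"] < 1e-10

    def test_monomorphic_marker_skipped(self, scan_setup):
        panel, truth, fpanel, prof, sbc, cm, qtl = scan_setup
        d = fpanel.dosages.copy()
        d[:, 0] = 0
        mono = make_panel(d[:, :5],
                          positions=fpanel.snp_map["pos"].iloc[:5].to_numpy(),
                          line_ids=list(fpanel.line_ids))
        res = scan_snps(cm, mono, {"1S": sbc["1S"]})
        assert any("monomorphic" in reason for _, reason in res.skipped)
        assert len(res.table) == 4

    def test_brute_force_equivalence(self, scan_setup):
        """GLS marker fit matches an independent per-marker WLS refit."""
        panel, truth, fpanel, prof, sbc, cm, qtl = scan_setup
        small = fpanel.take_lines(np.arange(50))
        keep = [j for j in small.snp_indices_of("1S")[:20]
                if np.ptp(small.dosages[:, j]) > 0]
        small = small.take_snps(np.array(keep))
        cms = cm.iloc[:50]
        res = scan_snps(cms, small, {"1S": sbc["1S"]})

        # oracle: explicit weighted normal equations per marker
        struct = sbc["1S"]
        pcs = struct.significant_scores[:50]
        envs = list(cms.columns)
        y = cms.to_numpy().ravel()
        gi = np.repeat(np.arange(50), len(envs))
        ei = np.tile(np.arange(len(envs)), 50)
        Xe = np.zeros((len(y), len(envs)))
        Xe[np.arange(len(y)), ei] = 1.0
        X0 = [Xe, pcs[gi]]
        for j in range(1, len(envs)):
            X0.append(pcs[gi] * Xe[:, [j]])
        X0 = np.concatenate(X0, axis=1)
        from megxe.mixed import fit_heteroscedastic_gls
        null = fit_heteroscedastic_gls(y, X0, np.array(envs)[ei])
        w = 1.0 / null.sigma2_by_group[np.searchsorted(null.group_levels,
                                                       np.array(envs)[ei])]
        for _, row in res.table.iterrows():
            j = int(np.flatnonzero(small.snp_map["id"] == row["marker_id"])[0])
            x = small.dosages[:, j].astype(float)[gi]
            X = np.concatenate([X0, Xe * x[:, None]], axis=1)
            Xw = X * w[:, None]
            A = Xw.T @ X
            beta = np.linalg.solve(A, Xw.T @ y)
            cov = np.linalg.inv(A)
            k = len(envs)
            bm, cmm = beta[-k:], cov[-k:, -k:]
            wald = bm @ np.linalg.solve(cmm, bm)
            assert row["wald"] == pytest.approx(wald, abs=1e-6)
            got = np.array([row[f"beta_{e}"] for e in envs])
            np.testing.assert_allclose(got, bm, atol=1e-6)


class TestScanHaplotypes:
    def test_two_state_block_equals_snp_scan(self, scan_setup):
        panel, truth, fpanel, prof, sbc, cm, qtl = scan_setup
        # tag SNP as a one-SNP "block" with two states
        from megxe.hapblocks import HaplotypeBlock, HaplotypeBlockSet, assign_states
        j = 10
        while np.ptp(fpanel.dosages[:, j]) == 0:
            j += 1
        blk = assign_states(
            fpanel, HaplotypeBlock("g0", "1S", np.array([j])))
        bs = HaplotypeBlockSet(blocks=[blk])
        hres = scan_haplotypes(cm, bs, sbc, min_carriers=1, panel=fpanel)
        sub = fpanel.take_snps(np.array([j]))
        sres = scan_snps(cm, sub, sbc)
        assert hres.table["wald"].iloc[0] == pytest.approx(
            sres.table["wald"].iloc[0], abs=1e-8)

    def test_rare_state_dropped(self, scan_setup):
        panel, truth, fpanel, prof, sbc, cm, qtl = scan_setup
        from megxe.hapblocks import HaplotypeBlock, HaplotypeBlockSet, assign_states
        d = fpanel.dosages.copy()
        d[:, 0] = 0
        d[:2, 0] = 2  # 2 carriers only
        rare = make_panel(d, positions=fpanel.snp_map["pos"].to_numpy(),
                          chrom=fpanel.snp_map["chrom"].tolist(),
                          line_ids=list(fpanel.line_ids))
        blk = assign_states(rare, HaplotypeBlock("g0", "1S", np.array([0])))
        bs = HaplotypeBlockSet(blocks=[blk])
        res = scan_haplotypes(cm, bs, sbc, min_carriers=5, panel=rare)
        assert len(res.table) == 0
        assert len(res.skipped) == 1

    def test_state_effect_recovery(self):
        cfg = SimConfig(n_lines=250, n_subpops=2, fst_target=0.1, n_chrom=2,
                        snps_per_chrom=100, copy_switch_rate=1e-2,
                        polygenic_var=0.5, gxe_var=0.2, residual_var=0.5,
                        n_gene_regions=0, seed=71)
        panel, truth = simulate_genotype_panel(cfg)
        plots = simulate_trial_phenotypes(panel, truth, cfg)
        plots = plots[~plots["is_check"]].copy()
        # plant a +4-day winter-only effect for carriers of dosage 2 at SNP 5
        carriers = dict(zip(panel.line_ids, panel.dosages[:, 5] == 2))
        winter = plots["env"].str.startswith("WI")
        plots.loc[winter & plots["genotype"].map(carriers), "value"] += 4.0
        fpanel, _ = filter_variants(panel)
        fpanel = impute_modal(fpanel)
        with pytest.warns(UserWarning):
            prof = local_ld_decay(fpanel, thin_step=5)
        sbc = structure_by_chromosome(fpanel, prof, seed=3)
        from megxe.hapblocks import HaplotypeBlock, HaplotypeBlockSet, assign_states
        j = int(np.flatnonzero(fpanel.snp_map["id"] == panel.snp_map["id"][5])[0])
        blk = assign_states(fpanel, HaplotypeBlock("g0", "1S", np.array([j])))
        bs = HaplotypeBlockSet(blocks=[blk])
        cm = cell_mean_matrix(plots)
        res = scan_haplotypes(cm, bs, sbc, panel=fpanel,
                              m_eff=meff_panel(fpanel))
        row = res.table.iloc[0]
        # the non-baseline state is the carrier state or its complement
        b_cols = [c for c in res.table.columns if c.startswith("beta_b_")]
        betas = np.array([row[c] for c in b_cols])
        winter_idx = [i for i, e in enumerate(cm.columns)
                      if e.startswith("WI")]
        spring_idx = [i for i, e in enumerate(cm.columns)
                      if e.startswith("SP")]
        sign = np.sign(betas[winter_idx].mean())
        assert np.abs(betas[winter_idx] * sign - 4.0).max() < 1.0
        assert np.abs(betas[spring_idx]).max() < 1.0
        assert row["p_gc"] < res.thresholds[0.05]


class TestWaldDf:
    def test_df_is_environments_times_columns(self, scan_setup):
        panel, truth, fpanel, prof, sbc, cm, qtl = scan_setup
        sub = fpanel.take_snps(fpanel.snp_indices_of("2S")[:10])
        res = scan_snps(cm, sub, {"2S": sbc["2S"]})
        assert (res.table["df"] == len(cm.columns)).all()
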