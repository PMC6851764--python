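"""Multi-environment GWAS with environment-specific marker effects.

The scan works on one adjusted mean per genotype × environment. A null
model with fixed environment effects, PC main effects and PC × environment
effects is fitted once per chromosome with heterogeneous per-environment
residual variances (REML); each marker then enters by generalized least
squares with environment-specific effect columns, and all of its
coefficients are tested jointly with a Wald statistic (χ², df =
environments × effect columns). Structure correction is
leave-one-chromosome-out. Multiple testing uses the effective number of
independent tests (eigenvalue-based) with genomic control on the joint
statistic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .genodata import GenotypePanel, MISSING
from .ldkin import KinshipMatrix, LDProfile, kinship_astle_balding, ld_aware_sample
from .mixed import fit_heteroscedastic_gls, indicator
from .structure import StructureResult, significant_pcs

logger = logging.getLogger(__name__)


@dataclass
class GwasResult:
    table: pd.DataFrame            # per-marker rows
    lambda_gc: float
    m_eff: float
    thresholds: dict               # alpha -> p-value threshold
    df: int | None = None
    skipped: list = field(default_factory=list)

    def significant(self, alpha: float = 0.05) -> pd.DataFrame:
        thr = self.thresholds[alpha]
        return self.table[self.table["p_gc"] <= thr]


# ---- structure per chromosome ---------------------------------------------


def loco_structure(
    panel: GenotypePanel,
    ld_profile: LDProfile,
    chromosome,
    alpha: float = 0.05,
    base: int = 5,
    bin_mbp: float = 2_000_000,
    seed: int = 0,
    full_kinship: bool = False,
) -> StructureResult:
    """Significant PCs from an LD-aware kinship excluding one chromosome."""
    chroms = panel.chromosomes()
    if len(chroms) < 2 and not full_kinship:
        raise ValueError(
            "single-chromosome panel: pass full_kinship=True to fall back "
            "to whole-genome kinship"
        )
    exclude = () if full_kinship else (chromosome,)
    idx = ld_aware_sample(
        panel.snp_map, ld_profile, bin_mbp=bin_mbp, base=base, seed=seed,
        exclude_chroms=exclude,
    )
    K = kinship_astle_balding(panel, idx)
    return significant_pcs(K, alpha=alpha)


def structure_by_chromosome(
    panel: GenotypePanel, ld_profile: LDProfile, alpha: float = 0.05,
    seed: int = 0, full_kinship: bool = False,
) -> dict:
    return {
        c: loco_structure(panel, ld_profile, c, alpha=alpha, seed=seed,
                          full_kinship=full_kinship)
        for c in panel.chromosomes()
    }


# ---- null model ------------------------------------------------------------


def _stack_cell_means(cell_means: pd.DataFrame):
    """Long-format y with genotype/environment index arrays."""
    M = cell_means
    envs = list(M.columns)
    genos = list(M.index)
    y = M.to_numpy(dtype=float).ravel(order="C")
    gi = np.repeat(np.arange(len(genos)), len(envs))
    ei = np.tile(np.arange(len(envs)), len(genos))
    ok = np.isfinite(y)
    return y[ok], gi[ok], ei[ok], genos, envs


def _null_design(gi, ei, n_env, pcs: np.ndarray):
    """Env dummies + PC main effects + PC×env interactions."""
    n = len(gi)
    Xe = np.zeros((n, n_env))
    Xe[np.arange(n), ei] = 1.0
    parts = [Xe]
    if pcs is not None and pcs.shape[1] > 0:
        P = pcs[gi]
        parts.append(P)
        inter = np.einsum("ij,ik->ijk", Xe[:, 1:], P).reshape(n, -1)
        parts.append(inter)
    return np.concatenate(parts, axis=1)


# ---- marker scans ----------------------------------------------------------


def _gls_wald(y, X0, marker_cols, weights):
    """Augment the null design with marker columns; return betas, cov, Wald."""
    X = np.concatenate([X0, marker_cols], axis=1)
    Xw = X * weights[:, None]
    XtWX = X.T @ Xw
    try:
        c = linalg.cho_factor(XtWX, check_finite=False)
    except linalg.LinAlgError:
        return None
    beta = linalg.cho_solve(c, Xw.T @ y, check_finite=False)
    cov = linalg.cho_solve(c, np.eye(X.shape[1]), check_finite=False)
    k = marker_cols.shape[1]
    bm = beta[-k:]
    cm = cov[-k:, -k:]
    try:
        wald = float(bm @ np.linalg.solve(cm, bm))
    except linalg.LinAlgError:
        return None
    return bm, cm, wald


def scan_snps(
    cell_means: pd.DataFrame,
    panel: GenotypePanel,
    structure_by_chrom: dict,
    alpha: tuple = (0.05, 0.01),
    m_eff: float | None = None,
    min_maf: float = 0.0,
) -> GwasResult:
    """Environment-specific SNP-effect scan over all chromosomes."""
    y, gi, ei, genos, envs = _stack_cell_means(cell_means)
    n_env = len(envs)
    order = [list(panel.line_ids).index(g) for g in genos]
    dos = panel.dosages[np.array(order), :].astype(float)
    dos[dos == MISSING] = np.nan

    rows, skipped = [], []
    for chrom in panel.chromosomes():
        struct = structure_by_chrom[chrom]
        pcs = struct.significant_scores if struct.n_significant > 0 else None
        X0 = _null_design(gi, ei, n_env, pcs)
        null = fit_heteroscedastic_gls(y, X0, np.array(envs)[ei])
        w = 1.0 / null.sigma2_by_group[
            np.searchsorted(null.group_levels, np.array(envs)[ei])
        ]
        for j in panel.snp_indices_of(chrom):
            x = dos[gi, j]
            obs = np.isfinite(x)
            if not obs.all():
                x = np.where(obs, x, np.nanmean(x))
            p_allele = np.nanmean(dos[:, j]) / 2.0
            if np.ptp(x) == 0 or min(p_allele, 1 - p_allele) < min_maf:
                skipped.append((panel.snp_map["id"].iloc[j], "monomorphic/low MAF"))
                continue
            Xe = np.zeros((len(y), n_env))
            Xe[np.arange(len(y)), ei] = 1.0
            mcols = Xe * x[:, None]
            res = _gls_wald(y, X0, mcols, w)
            if res is None:
                skipped.append((panel.snp_map["id"].iloc[j], "collinear"))
                continue
            bm, cm, wald = res
            row = {
                "marker_id": panel.snp_map["id"].iloc[j],
                "chrom": chrom,
                "pos": int(panel.snp_map["pos"].iloc[j]),
                "wald": wald,
                "df": n_env,
            }
            for jj, ename in enumerate(envs):
                row[f"beta_{ename}"] = bm[jj]
                row[f"se_{ename}"] = np.sqrt(cm[jj, jj])
            rows.append(row)
    return _finalize(rows, skipped, n_env, alpha, m_eff, panel)


def scan_haplotypes(
    cell_means: pd.DataFrame,
    blockset,
    structure_by_chrom: dict,
    min_carriers: int = 5,
    alpha: tuple = (0.05, 0.01),
    m_eff: float | None = None,
    panel: GenotypePanel | None = None,
) -> GwasResult:
    """Haplotype-state substitution-effect scan.

    Design columns are indicators of each non-baseline state (baseline =
    most frequent state ``a``); states with fewer than ``min_carriers``
    carriers are dropped and their carrier lines excluded for that
    block. Lines unassigned to any state are dropped per block.
    """
    y, gi, ei, genos, envs = _stack_cell_means(cell_means)
    n_env = len(envs)
    geno_pos = {g: i for i, g in enumerate(genos)}
    rows, skipped = [], []
    dfs = set()
    null_cache = {}
    for b in blockset.blocks:
        struct = structure_by_chrom[b.chrom]
        pcs = struct.significant_scores if struct.n_significant > 0 else None
        if panel is None:
            raise ValueError("panel required to map line assignments")
        line_state = {panel.lines["id"].iloc[i]: b.assignments[i]
                      for i in range(panel.n_lines)}
        counts = b.state_table.set_index("state")["count"]
        valid_states = [s for s in counts.index if counts[s] >= min_carriers]
        if len(valid_states) < 2:
            skipped.append((f"{b.region_id}:{b.snp_indices[0]}",
                            "fewer than 2 states after carrier filter"))
            continue
        states_nonbase = valid_states[1:]
        state_of = np.array([line_state.get(g) for g in genos], dtype=object)
        row_ok = np.array([line_state.get(genos[g]) in valid_states
                           for g in gi])
        if not row_ok.any():
            skipped.append((b.region_id, "no assigned lines"))
            continue
        ys, gis, eis = y[row_ok], gi[row_ok], ei[row_ok]
        X0 = _null_design(gis, eis, n_env, pcs)
        key = (b.chrom, row_ok.tobytes())
        if key not in null_cache:
            null = fit_heteroscedastic_gls(ys, X0, np.array(envs)[eis])
            null_cache[key] = null
        null = null_cache[key]
        w = 1.0 / null.sigma2_by_group[
            np.searchsorted(null.group_levels, np.array(envs)[eis])
        ]
        Xe = np.zeros((len(ys), n_env))
        Xe[np.arange(len(ys)), eis] = 1.0
        mcols = []
        for s in states_nonbase:
            ind = np.array([1.0 if state_of[g] == s else 0.0 for g in gis])
            mcols.append(Xe * ind[:, None])
        mcols = np.concatenate(mcols, axis=1)
        res = _gls_wald(ys, X0, mcols, w)
        if res is None:
            skipped.append((b.region_id, "collinear"))
            continue
        bm, cm, wald = res
        mid = f"{b.region_id}_blk{b.snp_indices[0]}"
        pos0 = int(panel.snp_map["pos"].iloc[b.snp_indices[0]])
        row = {"marker_id": mid, "chrom": b.chrom, "pos": pos0,
               "wald": wald, "df": n_env * len(states_nonbase)}
        for si, s in enumerate(states_nonbase):
            for jj, ename in enumerate(envs):
                row[f"beta_{s}_{ename}"] = bm[si * n_env + jj]
        rows.append(row)
        dfs.add(n_env * len(states_nonbase))
    return _finalize(rows, skipped, None, alpha, m_eff, panel)


def _finalize(rows, skipped, df_common, alpha, m_eff, panel):
    table = pd.DataFrame(rows)
    if len(table) == 0:
        return GwasResult(table=table, lambda_gc=np.nan, m_eff=np.nan,
                          thresholds={a: np.nan for a in alpha},
                          df=df_common, skipped=skipped)
    table["p_raw"] = stats.chi2.sf(table["wald"], table["df"])
    if len(table) >= 100 and table["df"].nunique() == 1:
        lam, adj = genomic_control(table["wald"].to_numpy(),
                                   int(table["df"].iloc[0]))
        table["wald_gc"] = adj
        table["p_gc"] = stats.chi2.sf(adj, table["df"])
    else:
        lam = np.nan
        table["wald_gc"] = table["wald"]
        table["p_gc"] = table["p_raw"]
    if m_eff is None and panel is not None:
        m_eff = meff_panel(panel)
    thresholds = {a: significance_threshold(m_eff, a) for a in alpha} \
        if m_eff else {a: np.nan for a in alpha}
    return GwasResult(table=table, lambda_gc=lam, m_eff=m_eff,
                      thresholds=thresholds, df=df_common, skipped=skipped)


# ---- multiple testing ------------------------------------------------------


def li_ji_meff(eigenvalues) -> float:
    """Effective number of tests: Σ [1(λ ≥ 1) + (λ − ⌊λ⌋)]."""
    lam = np.abs(np.asarray(eigenvalues, dtype=float))
    return float(np.sum((lam >= 1).astype(float) + (lam - np.floor(lam))))


def meff_panel(panel: GenotypePanel, block_size: int = 1000) -> float:
    """Li–Ji M_eff summed over chromosomes (blockwise for memory)."""
    total = 0.0
    for chrom in panel.chromosomes():
        idx = panel.snp_indices_of(chrom)
        for s in range(0, len(idx), block_size):
            blk = idx[s:s + block_size]
            G = panel.dosages[:, blk].astype(float)
            G[G == MISSING] = np.nan
            mu = np.nanmean(G, axis=0)
            G = np.where(np.isnan(G), mu[None, :], G)
            sd = G.std(axis=0)
            keep = sd > 0
            if keep.sum() == 0:
                continue
            Gz = (G[:, keep] - G[:, keep].mean(0)) / sd[keep]
            C = (Gz.T @ Gz) / Gz.shape[0]
            lam = np.linalg.eigvalsh(C)
            total += li_ji_meff(lam)
    return total


def genomic_control(wald_stats, df: int) -> tuple[float, np.ndarray]:
    """λ_GC = median(W)/median(χ²_df); deflation only (λ < 1 leaves W)."""
    if df <= 0:
        raise ValueError("df must be positive")
    W = np.asarray(wald_stats, dtype=float)
    lam = float(np.median(W) / stats.chi2.median(df))
    adjusted = W / lam if lam > 1.0 else W.copy()
    return lam, adjusted


def significance_threshold(m_eff: float, alpha: float) -> float:
    """Bonferroni on the effective number of tests."""
    if m_eff < 1:
        raise ValueError("m_eff must be >= 1")
    return alpha / m_eff
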