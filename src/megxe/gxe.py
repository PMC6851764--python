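"""Stage-1 adjusted means and genotype-by-environment models.

Covers the two-way variance partition (genotype, G×E, residual), the
contribution of genotype categorizations to those components, the
Finlay–Wilkinson regression, AMMI and GGE bilinear decompositions and
Tukey group comparisons with a compact letter display.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .mixed import cullis_h2, indicator, reml_crossed


@dataclass
class Stage1Result:
    adjusted_means: pd.DataFrame   # genotype, mean, weight
    h2: float
    sigma2_g: float
    sigma2_block: float
    sigma2_e: float


def stage1_adjusted_means(plots: pd.DataFrame, trial: str | None = None
                          ) -> Stage1Result:
    """Per-trial adjusted genotype means and generalized heritability.

    Fits value = mean + genotype (random) + block (random) + residual by
    REML for H² (Cullis, from the full BLUP prediction-error-variance
    matrix), then refits genotype as fixed (block random) for BLUE-style
    adjusted means with weights 1/SE².
    """
    df = plots if trial is None else plots[plots["env"] == trial]
    df = df.dropna(subset=["value"]).reset_index(drop=True)
    if df.empty:
        raise ValueError("no plot records for trial")
    if df["block"].nunique() < 2:
        raise ValueError("need >= 2 blocks for stage-1 adjustment")
    y = df["value"].to_numpy(dtype=float)
    X = np.ones((len(df), 1))
    replicated = df["genotype"].duplicated().any()
    if not replicated:
        warnings.warn("no replication: returning raw values, H2 undefined",
                      stacklevel=2)
        means = df.groupby("genotype")["value"].mean().reset_index()
        means.columns = ["genotype", "mean"]
        means["weight"] = 1.0
        return Stage1Result(means, np.nan, np.nan, np.nan, np.nan)

    fit = reml_crossed(
        y, X,
        {"genotype": df["genotype"].to_numpy(),
         "block": df["block"].to_numpy()},
        compute_pev=True,
    )
    h2 = cullis_h2(fit.pev["genotype"], fit.sigma2["genotype"]) \
        if fit.sigma2["genotype"] > 0 else 0.0

    # fixed-genotype refit for adjusted means, V = sigma2_b ZZ' + sigma2_e I
    Zg, geno_levels = indicator(df["genotype"].to_numpy())
    Zb, _ = indicator(df["block"].to_numpy())
    V = fit.sigma2_e * np.eye(len(df)) + fit.sigma2["block"] * (Zb @ Zb.T)
    Vi = np.linalg.inv(V)
    XtVX = Zg.T @ Vi @ Zg
    XtVy = Zg.T @ Vi @ y
    cov = np.linalg.inv(XtVX)
    blue = cov @ XtVy
    se2 = np.diag(cov)
    means = pd.DataFrame(
        {"genotype": geno_levels, "mean": blue, "weight": 1.0 / se2}
    )
    return Stage1Result(
        adjusted_means=means, h2=h2,
        sigma2_g=fit.sigma2["genotype"],
        sigma2_block=fit.sigma2["block"],
        sigma2_e=fit.sigma2_e,
    )


def cell_mean_matrix(plots: pd.DataFrame, use_checks: bool = False
                     ) -> pd.DataFrame:
    """Genotype × environment matrix of raw cell means."""
    df = plots
    if not use_checks and "is_check" in df.columns:
        df = df[~df["is_check"]]
    return df.pivot_table(index="genotype", columns="env", values="value",
                          aggfunc="mean")


# ---- variance partitioning -------------------------------------------------


def _plot_frame(plots: pd.DataFrame, use_checks: bool = False) -> pd.DataFrame:
    df = plots.dropna(subset=["value"])
    if not use_checks and "is_check" in df.columns:
        df = df[~df["is_check"]]
    return df.reset_index(drop=True)


def fit_two_way_vc(plots: pd.DataFrame) -> dict:
    """REML variance components for value = μ + env + G + G×E + ε."""
    df = _plot_frame(plots)
    if df["env"].nunique() < 2:
        raise ValueError("need >= 2 environments")
    y = df["value"].to_numpy(dtype=float)
    Xe, _ = indicator(df["env"].to_numpy())
    ge_labels = df["genotype"].astype(str) + ":" + df["env"].astype(str)
    fit = reml_crossed(
        y, Xe,
        {"G": df["genotype"].to_numpy(), "GE": ge_labels.to_numpy()},
    )
    return {
        "sigma2_G": fit.sigma2["G"],
        "sigma2_GE": fit.sigma2["GE"],
        "sigma2_e": fit.sigma2_e,
    }


def category_variance_explained(plots: pd.DataFrame, categories: dict | pd.Series
                                ) -> dict:
    """Percent reduction in σ²_G and σ²_GE when fixed category and
    category × environment terms are added.

    ``categories`` maps genotype id → category label. Values are clipped
    to [0, 100]; the raw (unclipped) values are also returned.
    """
    df = _plot_frame(plots)
    cat = df["genotype"].map(dict(categories))
    if cat.isna().any():
        missing = df["genotype"][cat.isna()].unique()[:5]
        raise ValueError(f"genotypes without category, e.g. {list(missing)}")
    if cat.nunique() < 2:
        raise ValueError("need >= 2 category levels")
    # a category level observed in only one environment is confounded
    env_per_cat = df.groupby(cat.to_numpy())["env"].nunique()
    if (env_per_cat < df["env"].nunique()).any():
        raise ValueError("category confounded with environment")

    base = fit_two_way_vc(df)
    y = df["value"].to_numpy(dtype=float)
    Xe, _ = indicator(df["env"].to_numpy())
    Xc, _ = indicator(cat.to_numpy())
    # category × environment interaction columns
    Xce = np.einsum("ij,ik->ijk", Xe, Xc).reshape(len(df), -1)
    X4 = np.concatenate([Xe, Xc, Xce], axis=1)
    ge_labels = df["genotype"].astype(str) + ":" + df["env"].astype(str)
    fit4 = reml_crossed(
        y, X4,
        {"G": df["genotype"].to_numpy(), "GE": ge_labels.to_numpy()},
    )
    out = {}
    for comp, k4 in (("G", "G"), ("GE", "GE")):
        s3 = base[f"sigma2_{comp}"]
        s4 = fit4.sigma2[k4]
        raw = 100.0 * (s3 - s4) / s3 if s3 > 0 else np.nan
        out[f"pct_delta_{comp}_raw"] = raw
        out[f"pct_delta_{comp}"] = float(np.clip(raw, 0.0, 100.0)) \
            if np.isfinite(raw) else np.nan
    return out


# ---- Finlay–Wilkinson ------------------------------------------------------


def finlay_wilkinson(cell_means: pd.DataFrame,
                     weights: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-genotype regression on the centered environment means.

    Returns intercept (general adaptation, on the grand-mean scale) and
    slope (adaptability); genotypes observed in fewer than 3
    environments are flagged NaN.
    """
    M = cell_means
    if M.shape[1] < 3:
        raise ValueError("need >= 3 environments")
    env_mean = M.mean(axis=0, skipna=True)
    e = env_mean - env_mean.mean()
    rows = []
    for g, row in M.iterrows():
        obs = row.notna()
        if obs.sum() < 3:
            rows.append({"genotype": g, "intercept": np.nan, "slope": np.nan,
                         "n_env": int(obs.sum())})
            continue
        x = e[obs].to_numpy(dtype=float)
        yv = row[obs].to_numpy(dtype=float)
        w = None
        if weights is not None:
            w = weights.loc[g, obs.index[obs]].to_numpy(dtype=float)
        X = np.column_stack([np.ones_like(x), x])
        if w is None:
            coef, *_ = np.linalg.lstsq(X, yv, rcond=None)
        else:
            Xw = X * w[:, None]
            coef = np.linalg.solve(X.T @ Xw, Xw.T @ yv)
        rows.append({"genotype": g, "intercept": coef[0], "slope": coef[1],
                     "n_env": int(obs.sum())})
    return pd.DataFrame(rows).set_index("genotype")


# ---- AMMI / GGE ------------------------------------------------------------


@dataclass
class BilinearFit:
    grand_mean: float
    genotype_main: pd.Series | None
    env_main: pd.Series
    geno_scores: pd.DataFrame      # genotypes × axes
    env_scores: pd.DataFrame       # environments × axes
    axis_ss: np.ndarray
    model: str


def _impute_additive(M: pd.DataFrame) -> pd.DataFrame:
    """Fill missing cells with the additive-model expectation."""
    mu = np.nanmean(M.to_numpy())
    g = M.mean(axis=1, skipna=True) - mu
    e = M.mean(axis=0, skipna=True) - mu
    fill = mu + np.add.outer(g.to_numpy(), e.to_numpy())
    out = M.copy()
    mask = out.isna()
    out = out.where(~mask, pd.DataFrame(fill, index=M.index, columns=M.columns))
    return out


def ammi(cell_means: pd.DataFrame, n_axes: int = 2,
         impute_missing: bool = False) -> BilinearFit:
    """SVD of the double-centered cell-mean matrix (symmetric scaling)."""
    M = cell_means
    if M.isna().to_numpy().any():
        if not impute_missing:
            raise ValueError("missing cells; impute upstream or pass "
                             "impute_missing=True")
        M = _impute_additive(M)
    nG, nE = M.shape
    if n_axes > min(nG, nE) - 1:
        raise ValueError("n_axes too large for matrix shape")
    A = M.to_numpy(dtype=float)
    mu = A.mean()
    g = A.mean(axis=1) - mu
    e = A.mean(axis=0) - mu
    R = A - mu - g[:, None] - e[None, :]
    U, s, Vt = np.linalg.svd(R, full_matrices=False)
    lam = s[:n_axes]
    geno = U[:, :n_axes] * np.sqrt(lam)[None, :]
    env = Vt[:n_axes].T * np.sqrt(lam)[None, :]
    axis_ss = s[:n_axes] ** 2
    cols = [f"axis{a + 1}" for a in range(n_axes)]
    return BilinearFit(
        grand_mean=float(mu),
        genotype_main=pd.Series(g, index=M.index),
        env_main=pd.Series(e, index=M.columns),
        geno_scores=pd.DataFrame(geno, index=M.index, columns=cols),
        env_scores=pd.DataFrame(env, index=M.columns, columns=cols),
        axis_ss=axis_ss,
        model="ammi",
    )


def gge(cell_means: pd.DataFrame, n_axes: int = 2,
        impute_missing: bool = False) -> BilinearFit:
    """SVD of the environment-centered matrix (genotype + G×E jointly)."""
    M = cell_means
    if M.isna().to_numpy().any():
        if not impute_missing:
            raise ValueError("missing cells; impute upstream or pass "
                             "impute_missing=True")
        M = _impute_additive(M)
    nG, nE = M.shape
    if n_axes > min(nG, nE):
        raise ValueError("n_axes too large for matrix shape")
    A = M.to_numpy(dtype=float)
    e = A.mean(axis=0)
    R = A - e[None, :]
    U, s, Vt = np.linalg.svd(R, full_matrices=False)
    lam = s[:n_axes]
    geno = U[:, :n_axes] * np.sqrt(lam)[None, :]
    env = Vt[:n_axes].T * np.sqrt(lam)[None, :]
    cols = [f"axis{a + 1}" for a in range(n_axes)]
    return BilinearFit(
        grand_mean=float(A.mean()),
        genotype_main=None,
        env_main=pd.Series(e, index=M.columns),
        geno_scores=pd.DataFrame(geno, index=M.index, columns=cols),
        env_scores=pd.DataFrame(env, index=M.columns, columns=cols),
        axis_ss=s[:n_axes] ** 2,
        model="gge",
    )


def ammi_reconstruct(fit: BilinearFit) -> np.ndarray:
    """Cell means implied by grand mean + main effects + bilinear terms."""
    base = (fit.grand_mean
            + fit.genotype_main.to_numpy()[:, None]
            + fit.env_main.to_numpy()[None, :])
    return base + fit.geno_scores.to_numpy() @ fit.env_scores.to_numpy().T


# ---- group comparison ------------------------------------------------------


def compare_groups_tukey(values, groups, alpha: float = 0.05) -> pd.DataFrame:
    """One-way ANOVA + Tukey HSD with a compact letter display.

    Groups with a single observation are excluded with a warning.
    Groups that share a letter are not significantly different.
    """
    df = pd.DataFrame({"value": np.asarray(values, dtype=float),
                       "group": np.asarray(groups)}).dropna()
    sizes = df.groupby("group").size()
    small = sizes[sizes < 2].index.tolist()
    if small:
        warnings.warn(f"excluding groups with 1 observation: {small}",
                      stacklevel=2)
        df = df[~df["group"].isin(small)]
    levels = sorted(df["group"].unique())
    if len(levels) < 2:
        raise ValueError("need >= 2 groups with >= 2 observations")
    samples = [df.loc[df["group"] == g, "value"].to_numpy() for g in levels]
    f_stat, anova_p = stats.f_oneway(*samples)
    tuk = stats.tukey_hsd(*samples)
    k = len(levels)
    nonsig = np.ones((k, k), dtype=bool)
    for i in range(k):
        for j in range(k):
            if i != j:
                nonsig[i, j] = tuk.pvalue[i, j] >= alpha
    letters = _compact_letter_display(levels, nonsig,
                                      order=np.argsort([-s.mean() for s in samples]))
    out = pd.DataFrame({
        "group": levels,
        "n": [len(s) for s in samples],
        "mean": [s.mean() for s in samples],
        "letters": [letters[g] for g in levels],
    })
    out.attrs["anova_F"] = float(f_stat)
    out.attrs["anova_p"] = float(anova_p)
    return out


def _compact_letter_display(levels, nonsig, order) -> dict:
    """Insert-and-absorb algorithm (Piepho 2004 style)."""
    k = len(levels)
    cols = [set(range(k))] if nonsig.all() else []
    if not cols:
        # one column per greedy non-significant clique
        for i in order:
            placed = False
            for col in cols:
                if all(nonsig[i, j] for j in col):
                    col.add(i)
                    placed = True
            if not placed:
                cols.append({int(i)})
        # absorb columns that are subsets of others
        cols = [c for c in cols
                if not any(c < other for other in cols if other is not c)]
        # ensure every significant pair is separated (greedy repair)
        for i in range(k):
            for j in range(i + 1, k):
                if not nonsig[i, j]:
                    for col in cols:
                        if i in col and j in col:
                            col.discard(j)
        cols = [c for c in cols if c]
        for i in range(k):
            if not any(i in c for c in cols):
                cols.append({i})
    letters = {lv: "" for lv in levels}
    for idx, col in enumerate(cols):
        ch = chr(ord("a") + idx)
        for i in col:
            letters[levels[i]] += ch
    return {lv: "".join(sorted(s)) for lv, s in letters.items()}
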