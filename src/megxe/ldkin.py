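"""Local LD characterization, LD-aware SNP sampling and kinship.

LD decay is profiled per chromosome with a sliding window over thinned
markers: all pairwise r² within the window are binned by physical
distance, a high quantile is taken per bin, a monotone non-increasing
curve is fitted, and the crossing distances at r² = 0.1 and 0.3 are
recorded. The structure-corrected variant replaces plain r² with the
kinship-whitened correlation (Mangin-style r²_V).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg
from scipy.interpolate import PchipInterpolator
from sklearn.isotonic import IsotonicRegression

from .genodata import GenotypePanel, MISSING

logger = logging.getLogger(__name__)


@dataclass
class KinshipMatrix:
    values: np.ndarray
    line_ids: np.ndarray
    snp_indices: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if not np.allclose(v, v.T, atol=1e-8):
            raise ValueError("kinship matrix must be symmetric")
        self.values = (v + v.T) / 2.0

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class LDWindow:
    chrom: object
    center_bp: float
    decay_bp: dict                # threshold -> distance
    capped: bool
    bin_mid: np.ndarray = field(repr=False, default=None)
    bin_q: np.ndarray = field(repr=False, default=None)


@dataclass
class LDProfile:
    windows: list
    corrected: bool
    quantile: float
    thresholds: tuple

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for w in self.windows:
            row = {"chrom": w.chrom, "window_center_bp": w.center_bp,
                   "corrected": self.corrected, "capped": w.capped}
            for t in sorted(self.thresholds):
                row[f"d{str(t).replace('0.', '0')}_bp"] = w.decay_bp[t]
            rows.append(row)
        return pd.DataFrame(rows)

    def chrom_decay(self, chrom, threshold: float) -> float:
        vals = [w.decay_bp[threshold] for w in self.windows if w.chrom == chrom]
        return float(np.median(vals)) if vals else np.nan


# ---- marker thinning -------------------------------------------------------


def thin_markers(snp_map: pd.DataFrame, step: int = 25) -> np.ndarray:
    """Every ``step``-th SNP, restarting at each chromosome."""
    if step < 1:
        raise ValueError("step must be >= 1")
    if len(snp_map) == 0:
        raise ValueError("empty map")
    idx = []
    for _, grp in snp_map.groupby("chrom", sort=False):
        gi = grp.index.to_numpy()
        idx.append(gi[::step])
    return np.concatenate(idx)


# ---- pairwise LD -----------------------------------------------------------


def _whitener(K: KinshipMatrix, ridge: float = 1e-6):
    V = K.values + ridge * np.eye(K.n)
    L = linalg.cholesky(V, lower=True)
    W = linalg.solve_triangular(L, np.eye(K.n), lower=True)
    return W


def _transform_columns(G: np.ndarray, K: KinshipMatrix | None) -> np.ndarray:
    """Center columns (GLS-center under K) and whiten; after this, r² is
    the squared cosine between columns."""
    G = np.asarray(G, dtype=float)
    if K is None:
        return G - G.mean(axis=0, keepdims=True)
    W = _whitener(K)
    A = W @ G
    w1 = W @ np.ones(K.n)
    coef = (w1 @ A) / (w1 @ w1)
    return A - np.outer(w1, coef)


def pairwise_r2(g1, g2, K: KinshipMatrix | None = None) -> float:
    """Squared correlation of two dosage vectors.

    Without ``K`` this is the plain squared Pearson correlation; with
    ``K`` it is the structure-corrected r²_V (covariance ∝ K), which
    reduces to plain r² when K is the identity.
    """
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    if g1.shape != g2.shape:
        raise ValueError("vectors must have equal length")
    if np.ptp(g1) == 0 or np.ptp(g2) == 0:
        warnings.warn("constant dosage vector: r2 undefined", stacklevel=2)
        return np.nan
    A = _transform_columns(np.column_stack([g1, g2]), K)
    a, b = A[:, 0], A[:, 1]
    denom = (a @ a) * (b @ b)
    if denom <= 0:
        return np.nan
    return float((a @ b) ** 2 / denom)


def _window_r2(A: np.ndarray) -> np.ndarray:
    """Squared cosine matrix between pre-transformed columns."""
    norms = np.sqrt((A * A).sum(axis=0))
    norms[norms == 0] = np.nan
    C = (A.T @ A) / np.outer(norms, norms)
    return C ** 2


# ---- monotone decay fit ----------------------------------------------------


def monotone_decay_fit(x: np.ndarray, y: np.ndarray):
    """Non-increasing fit through binned quantiles.

    Isotonic regression (non-increasing) followed by monotone PCHIP
    interpolation; returns a callable defined on [x.min(), x.max()],
    clamped at the ends.
    """
    order = np.argsort(x)
    x, y = np.asarray(x, float)[order], np.asarray(y, float)[order]
    iso = IsotonicRegression(increasing=False, out_of_bounds="clip")
    yhat = iso.fit_transform(x, y)
    ux, inv = np.unique(x, return_inverse=True)
    uy = np.array([yhat[inv == i].mean() for i in range(len(ux))])
    if len(ux) == 1:
        return lambda d: np.full_like(np.asarray(d, float), uy[0])
    interp = PchipInterpolator(ux, uy, extrapolate=False)

    def f(d):
        d = np.asarray(d, dtype=float)
        out = interp(np.clip(d, ux[0], ux[-1]))
        return out

    return f


def _crossing(f, lo: float, hi: float, threshold: float) -> tuple[float, bool]:
    """Smallest distance where f ≤ threshold, bisection to 1 bp."""
    if f(lo) <= threshold:
        return 0.0, False
    if f(hi) > threshold:
        return float(hi), True
    a, b = float(lo), float(hi)
    while b - a > 1.0:
        mid = 0.5 * (a + b)
        if f(mid) <= threshold:
            b = mid
        else:
            a = mid
    return b, False


# ---- local LD decay --------------------------------------------------------


def local_ld_decay(
    panel: GenotypePanel,
    window_snps: int = 500,
    overlap: int = 475,
    bin_bp: float = 20_000,
    quantile: float = 0.95,
    thresholds: tuple = (0.1, 0.3),
    K: KinshipMatrix | None = None,
    thin_step: int = 25,
) -> LDProfile:
    """Sliding-window LD decay profile over thinned markers.

    Per window, all pairwise r² among the thinned SNPs are computed,
    binned by pair distance, the given quantile taken per bin, and a
    monotone non-increasing curve fitted; the decay distance is the
    crossing point at each threshold (0 if the curve starts below it;
    the window span, flagged ``capped``, if it never crosses).
    """
    if window_snps <= overlap:
        raise ValueError("window_snps must exceed overlap")
    step = window_snps - overlap
    thin_idx = thin_markers(panel.snp_map, thin_step)
    thresholds = tuple(sorted(thresholds))
    windows = []
    for chrom in panel.chromosomes():
        cidx = thin_idx[panel.snp_map["chrom"].to_numpy()[thin_idx] == chrom]
        if len(cidx) < 2:
            continue
        if len(cidx) < window_snps:
            warnings.warn(
                f"chromosome {chrom}: {len(cidx)} thinned SNPs < window "
                f"{window_snps}; using one window", stacklevel=2,
            )
            starts = [0]
            wsize = len(cidx)
        else:
            starts = list(range(0, len(cidx) - window_snps + 1, step))
            wsize = window_snps
        pos_all = panel.snp_map["pos"].to_numpy()
        for s0 in starts:
            widx = cidx[s0:s0 + wsize]
            w = _one_window(panel, widx, pos_all, bin_bp, quantile,
                            thresholds, K, chrom)
            if w is not None:
                windows.append(w)
    return LDProfile(windows=windows, corrected=K is not None,
                     quantile=quantile, thresholds=thresholds)


def _one_window(panel, widx, pos_all, bin_bp, quantile, thresholds, K, chrom):
    G = panel.dosages[:, widx].astype(float)
    G[G == MISSING] = np.nan
    col_mean = np.nanmean(G, axis=0)
    G = np.where(np.isnan(G), col_mean[None, :], G)
    keep = np.ptp(G, axis=0) > 0
    widx, G = widx[keep], G[:, keep]
    if G.shape[1] < 2:
        return None
    A = _transform_columns(G, K)
    R2 = _window_r2(A)
    pos = pos_all[widx].astype(float)
    iu, ju = np.triu_indices(len(widx), k=1)
    dist = np.abs(pos[ju] - pos[iu])
    r2 = R2[iu, ju]
    ok = np.isfinite(r2)
    dist, r2 = dist[ok], r2[ok]
    if len(dist) == 0:
        return None
    bins = np.floor(dist / bin_bp).astype(int)
    ub = np.unique(bins)
    if len(ub) < 3:
        warnings.warn(f"chromosome {chrom}: window skipped, "
                      f"only {len(ub)} non-empty distance bins", stacklevel=2)
        return None
    mids = (ub + 0.5) * bin_bp
    qvals = np.array([np.quantile(r2[bins == b], quantile) for b in ub])
    f = monotone_decay_fit(mids, qvals)
    decay, capped = {}, False
    span = float(mids[-1])
    for t in thresholds:
        d, flag = _crossing(f, mids[0], span, t)
        decay[t] = d
        capped |= flag
    return LDWindow(chrom=chrom, center_bp=float(np.median(pos)),
                    decay_bp=decay, capped=capped, bin_mid=mids, bin_q=qvals)


# ---- LD-aware sampling -----------------------------------------------------


def ld_aware_sample(
    snp_map: pd.DataFrame,
    profile: LDProfile,
    bin_mbp: float = 2_000_000,
    base: int = 5,
    seed: int = 0,
    threshold: float = 0.3,
    exclude_chroms: tuple = (),
) -> np.ndarray:
    """Sample SNPs per 2-Mbp bin, more densely where LD decays faster.

    Target per bin: ``max(base, round(base · d_max / d_b))`` where d_b is
    the bin's decay distance at ``threshold`` and d_max the largest over
    bins, capped at the bin's SNP count. Deterministic given seed.
    """
    rng = np.random.default_rng(seed)
    centers = pd.DataFrame(
        [(w.chrom, w.center_bp, w.decay_bp[threshold]) for w in profile.windows],
        columns=["chrom", "center", "d"],
    )
    bin_d, bin_snps = {}, {}
    for chrom, grp in snp_map.groupby("chrom", sort=False):
        if chrom in exclude_chroms:
            continue
        pos = grp["pos"].to_numpy()
        gbin = np.floor(pos / bin_mbp).astype(int)
        wc = centers[centers["chrom"] == chrom]
        chrom_med = wc["d"].median() if len(wc) else np.nan
        for b in np.unique(gbin):
            key = (chrom, b)
            bin_snps[key] = grp.index.to_numpy()[gbin == b]
            if len(wc):
                inb = wc[(wc["center"] >= b * bin_mbp)
                         & (wc["center"] < (b + 1) * bin_mbp)]
                bin_d[key] = float(inb["d"].median()) if len(inb) else chrom_med
            else:
                bin_d[key] = np.nan
    if not bin_snps:
        raise ValueError("no SNPs to sample from")
    ds = np.array([v for v in bin_d.values() if np.isfinite(v)])
    d_max = ds.max() if len(ds) else np.nan
    global_med = np.median(ds) if len(ds) else 1.0
    out = []
    for key, snps in bin_snps.items():
        if len(snps) == 0:
            continue
        d_b = bin_d[key]
        if not np.isfinite(d_b):
            d_b = global_med
        if not np.isfinite(d_max) or d_max <= 0:
            target = base
        elif d_b <= 0:
            target = len(snps)
        else:
            target = int(round(base * d_max / d_b))
        target = max(base, target)
        target = min(target, len(snps))
        out.append(rng.choice(snps, size=target, replace=False))
    return np.sort(np.concatenate(out))


# ---- kinship ---------------------------------------------------------------


def kinship_astle_balding(
    panel: GenotypePanel, snp_indices=None
) -> KinshipMatrix:
    """K = (1/m) Σ_l (g_l − 2p̂_l)(g_l − 2p̂_l)' / (2 p̂_l (1 − p̂_l)).

    Monomorphic SNPs are excluded with a warning; invariant to which
    allele is counted.
    """
    if snp_indices is None:
        snp_indices = np.arange(panel.n_snps)
    snp_indices = np.asarray(snp_indices)
    G = panel.dosages[:, snp_indices].astype(float)
    G[G == MISSING] = np.nan
    p = np.nanmean(G, axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    if poly.sum() < 2:
        raise ValueError("fewer than 2 polymorphic SNPs for kinship")
    if (~poly).any():
        warnings.warn(
            f"excluded {(~poly).sum()} monomorphic SNPs from kinship",
            stacklevel=2,
        )
    G, p = G[:, poly], p[poly]
    G = np.where(np.isnan(G), 2 * p[None, :], G)
    Gc = (G - 2 * p[None, :]) / np.sqrt(2 * p * (1 - p))[None, :]
    K = (Gc @ Gc.T) / Gc.shape[1]
    return KinshipMatrix(
        values=K, line_ids=panel.line_ids, snp_indices=snp_indices[poly]
    )
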