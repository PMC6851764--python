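"""Population structure, per-SNP differentiation and spatial PCA.

Significant axes of the kinship matrix are selected with sequential
Tracy–Widom tests (Patterson-style normalization); sub-populations are
assigned by Ward hierarchical clustering on the significant PC scores.
Differentiation scans use the Weir & Cockerham (1984) two-population
estimator per SNP with a moving-median smoother. The spatial PCA
diagonalizes the spatially lagged covariance of the allele matrix built
from an inverse great-circle-distance weight matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from .genodata import GenotypePanel, MISSING
from .ldkin import KinshipMatrix

# Tracy–Widom (GOE, beta=1) upper-tail critical values, by alpha.
_TW1_CRIT = [
    (0.10, 0.4501),
    (0.05, 0.9793),
    (0.025, 1.4538),
    (0.01, 2.0234),
    (0.005, 2.4222),
    (0.001, 3.2724),
]


def tw_critical(alpha: float) -> float:
    """Interpolate the TW1 critical value in log(alpha)."""
    alphas = np.array([a for a, _ in _TW1_CRIT])
    crits = np.array([c for _, c in _TW1_CRIT])
    if alpha >= alphas[0]:
        return float(crits[0])
    if alpha <= alphas[-1]:
        return float(crits[-1])
    return float(np.interp(np.log(alpha), np.log(alphas[::-1]), crits[::-1]))


@dataclass
class StructureResult:
    eigenvalues: np.ndarray
    scores: np.ndarray          # lines × components (all retained axes)
    n_significant: int
    tw_stats: np.ndarray
    cluster_labels: np.ndarray | None = None
    linkage: np.ndarray | None = None

    @property
    def significant_scores(self) -> np.ndarray:
        k = max(self.n_significant, 1)
        return self.scores[:, :k]


def significant_pcs(
    K: KinshipMatrix, alpha: float = 0.05, max_components: int = 20
) -> StructureResult:
    """Spectral decomposition of kinship with sequential TW tests.

    Stops at the first non-significant eigenvalue; the count is capped
    at ``max_components``.
    """
    V = np.asarray(K.values, dtype=float)
    if not np.allclose(V, V.T, atol=1e-8):
        raise ValueError("kinship must be symmetric")
    lam, U = np.linalg.eigh(V)
    lam, U = lam[::-1], U[:, ::-1]
    pos = lam > max(1e-10, 1e-12 * abs(lam[0]))
    lam_pos = lam[pos]
    scores = U[:, pos] * np.sqrt(lam_pos)[None, :]

    crit = tw_critical(alpha)
    tw_stats = []
    n_sig = 0
    for i in range(min(len(lam_pos) - 1, max_components)):
        rem = lam_pos[i:]
        stat = _tw_statistic(rem)
        tw_stats.append(stat)
        if stat > crit:
            n_sig += 1
        else:
            break
    return StructureResult(
        eigenvalues=lam,
        scores=scores,
        n_significant=n_sig,
        tw_stats=np.array(tw_stats),
    )


def _tw_statistic(lam: np.ndarray) -> float:
    """Patterson normalization of the leading eigenvalue of a spectrum."""
    m = len(lam)
    if m < 3:
        return -np.inf
    s1 = lam.sum()
    s2 = (lam ** 2).sum()
    denom = (m + 1) * s2 - s1 ** 2
    if denom <= 0:
        return np.inf
    n_hat = (m + 1) * s1 ** 2 / denom
    if n_hat <= 1:
        return -np.inf
    l1 = m * lam[0] / s1
    sq_n = np.sqrt(n_hat - 1)
    sq_m = np.sqrt(m)
    mu = (sq_n + sq_m) ** 2 / n_hat
    sigma = (sq_n + sq_m) / n_hat * (1.0 / sq_n + 1.0 / sq_m) ** (1.0 / 3.0)
    return float((l1 - mu) / sigma)


def ward_cluster(scores: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Ward-linkage clustering on PC scores, cut at k clusters."""
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    if scores.ndim == 2 and scores.shape[1] == 0:
        raise ValueError("no PC scores provided")
    n = scores.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds {n} lines")
    if k < 1:
        raise ValueError("k must be >= 1")
    Z = linkage(scores, method="ward")
    labels = fcluster(Z, t=k, criterion="maxclust")
    return labels, Z


# ---- differentiation -------------------------------------------------------


def _wc_components(panel: GenotypePanel, labels) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP Weir–Cockerham variance components (a, a+b+c)."""
    labels = np.asarray(labels)
    lv = pd.unique(labels[pd.notna(labels)])
    if len(lv) != 2:
        raise ValueError(f"need a 2-level factor, got levels {list(lv)}")
    masks = [labels == l for l in lv]
    if any(m.sum() < 2 for m in masks):
        raise ValueError("both groups need >= 2 lines")
    D = panel.dosages.astype(float)
    D[D == MISSING] = np.nan
    ns, ps, het = [], [], []
    for m in masks:
        sub = D[m]
        cnt = np.sum(~np.isnan(sub), axis=0).astype(float)
        with np.errstate(invalid="ignore"):
            p = np.nansum(sub, axis=0) / (2.0 * np.maximum(cnt, 1))
            h = np.nansum(sub == 1, axis=0) / np.maximum(cnt, 1)
        p[cnt == 0] = np.nan
        ns.append(cnt)
        ps.append(p)
        het.append(h)
    n1, n2 = ns
    p1, p2 = ps
    h1, h2 = het
    r = 2.0
    nbar = (n1 + n2) / r
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (r * nbar - (n1 ** 2 + n2 ** 2) / (r * nbar)) / (r - 1)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = nbar / nc * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
        )
        b = nbar / (nbar - 1) * (
            pbar * (1 - pbar) - (r - 1) / r * s2
            - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
        denom = a + b + c
    bad = ((pbar <= 0) | (pbar >= 1) | np.isnan(p1) | np.isnan(p2)
           | (n1 < 2) | (n2 < 2))
    a[bad] = np.nan
    denom[bad] = np.nan
    return a, denom


def fst_per_snp(panel: GenotypePanel, labels) -> np.ndarray:
    """Weir–Cockerham (1984) two-population Fst per SNP.

    Each inbred line contributes two identical alleles (observed
    heterozygosity 0 in the estimator). Estimates may be slightly
    negative; SNPs monomorphic over both groups (or unobserved in a
    group) are NaN.
    """
    a, denom = _wc_components(panel, labels)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(np.abs(denom) > 0, a / denom, np.nan)


def fst_overall(panel: GenotypePanel, labels) -> float:
    """Multi-locus Weir–Cockerham Fst: ratio of summed variance components.

    This is the combination Weir & Cockerham recommend across loci; the
    plain mean of per-SNP ratio estimates is downward-biased (Jensen)
    with few populations.
    """
    a, denom = _wc_components(panel, labels)
    return float(np.nansum(a) / np.nansum(denom))


def moving_median(values, window: int = 100) -> np.ndarray:
    """Centered moving median; truncated windows at the edges, NaN ignored."""
    if window < 1:
        raise ValueError("window must be >= 1")
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty input")
    s = pd.Series(values)
    return s.rolling(window, center=True, min_periods=1).median().to_numpy()


# ---- spatial PCA -----------------------------------------------------------


@dataclass
class SPCAResult:
    L: np.ndarray
    eigenvalues: np.ndarray
    loadings: np.ndarray        # SNPs × axes
    scores: np.ndarray          # lines × axes
    moran_i: np.ndarray
    classification: np.ndarray  # "global" / "local" per axis


def great_circle_km(lat, lon) -> np.ndarray:
    """Pairwise haversine distances in km."""
    lat = np.radians(np.asarray(lat, dtype=float))
    lon = np.radians(np.asarray(lon, dtype=float))
    dlat = lat[:, None] - lat[None, :]
    dlon = lon[:, None] - lon[None, :]
    h = (np.sin(dlat / 2) ** 2
         + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlon / 2) ** 2)
    return 2 * 6371.0 * np.arcsin(np.sqrt(np.clip(h, 0, 1)))


def spatial_weights(lat, lon) -> np.ndarray:
    """Inverse-distance weights, zero diagonal, row-standardized."""
    d = great_circle_km(lat, lon)
    n = d.shape[0]
    off = d[~np.eye(n, dtype=bool)]
    pos = off[off > 0]
    if len(pos) == 0:
        raise ValueError("all coordinates coincide; spatial weights degenerate")
    d = np.where(d <= 0, pos.min(), d)
    W = 1.0 / d
    np.fill_diagonal(W, 0.0)
    rs = W.sum(axis=1, keepdims=True)
    if (rs == 0).any():
        raise ValueError("isolated line with zero total spatial weight")
    return W / rs


def morans_i(x: np.ndarray, L: np.ndarray) -> float:
    """Moran's I of a vector under a row-standardized weight matrix."""
    x = np.asarray(x, dtype=float)
    xc = x - x.mean()
    denom = xc @ xc
    if denom <= 0:
        return np.nan
    return float(xc @ (L @ xc) / denom)


def spca(X: np.ndarray, lat, lon, n_axes: int | None = None) -> SPCAResult:
    """Spatial PCA of a lines × SNPs allele matrix.

    Diagonalizes (1/n) X'c H Xc with H the symmetrized row-standardized
    inverse-distance weights; positive extreme eigenvalues indicate
    global (regional) spatial structure, negative ones local structure.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    coords = np.column_stack([lat, lon])
    if len(np.unique(coords, axis=0)) < 3:
        raise ValueError("need at least 3 distinct coordinates")
    L = spatial_weights(lat, lon)
    H = (L + L.T) / 2.0
    Xc = X - X.mean(axis=0, keepdims=True)

    # (1/n) Xc' H Xc has rank <= n: reduce via eigenbasis of H
    lamH, Q = np.linalg.eigh(H)
    B = Xc.T @ Q                      # p × n
    Qb, Rb = np.linalg.qr(B)
    M = (Rb * lamH[None, :]) @ Rb.T / n
    M = (M + M.T) / 2.0
    ev, W = np.linalg.eigh(M)
    order = np.argsort(ev)[::-1]
    ev, W = ev[order], W[:, order]
    loadings = Qb @ W                  # p × r, orthonormal
    scores = Xc @ loadings
    if n_axes is not None:
        half = max(1, n_axes // 2)
        keep = list(range(half)) + list(range(len(ev) - half, len(ev)))
        keep = sorted(set(k for k in keep if 0 <= k < len(ev)))
        ev, loadings, scores = ev[keep], loadings[:, keep], scores[:, keep]
    mi = np.array([morans_i(scores[:, a], L) for a in range(scores.shape[1])])
    cls = np.where(ev > 0, "global", "local")
    return SPCAResult(
        L=L, eigenvalues=ev, loadings=loadings, scores=scores,
        moran_i=mi, classification=cls,
    )
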