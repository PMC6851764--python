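"""Synthetic structured inbred panels with multi-environment phenotypes.

Genotypes follow a Balding–Nichols divergence model: each sub-population
gets allele frequencies drawn around a shared ancestral frequency at a
target Fst, a small set of founder haplotypes is sampled per
sub-population, and every line is a fully homozygous mosaic of its
sub-population's founders with exponential segment lengths — which
produces block-wise LD decaying with physical distance.

Phenotypes are plot-level records from an augmented partially
replicated (p-rep) design: every entry once, a fraction twice, and
check entries repeated across most incomplete blocks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genodata import GenotypePanel


@dataclass
class EnvSpec:
    name: str
    season: str  # "spring" or "winter"

    def __post_init__(self):
        if self.season not in ("spring", "winter"):
            raise ValueError(f"season must be spring/winter, got {self.season!r}")


@dataclass
class QtlSpec:
    """A planted QTL: global SNP index and per-environment additive effect
    (per minor-allele copy)."""

    snp_index: int
    effects: tuple


@dataclass
class SimConfig:
    n_lines: int = 360
    n_subpops: int = 6
    fst_target: float = 0.15
    n_chrom: int = 7
    snps_per_chrom: int = 2000
    chrom_length_bp: int = 50_000_000
    founder_haplotypes_per_subpop: int = 16
    copy_switch_rate: float = 2e-7
    n_gene_regions: int = 20
    environments: tuple = (
        EnvSpec("SP1", "spring"),
        EnvSpec("SP2", "spring"),
        EnvSpec("WI1", "winter"),
        EnvSpec("WI2", "winter"),
        EnvSpec("WI3", "winter"),
    )
    env_means: tuple | None = None      # default: spring 60, winter 139
    qtl_spec: tuple = ()                # QtlSpec items
    polygenic_var: float = 4.0
    gxe_var: float = 2.0
    residual_var: float = 1.0
    block_var: float = 0.0
    prep_fraction: float = 0.20
    n_blocks: int = 10
    n_checks: int = 2
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        envs = []
        for e in self.environments:
            if isinstance(e, EnvSpec):
                envs.append(e)
            else:
                envs.append(EnvSpec(*e))
        self.environments = tuple(envs)
        qtls = []
        for q in self.qtl_spec:
            if isinstance(q, QtlSpec):
                qtls.append(q)
            else:
                qtls.append(QtlSpec(int(q[0]), tuple(q[1])))
        self.qtl_spec = tuple(qtls)
        self.validate()

    def validate(self) -> None:
        if not (0.0 <= self.fst_target < 1.0):
            raise ValueError("fst_target must be in [0, 1)")
        if self.n_subpops > self.n_lines:
            raise ValueError("n_subpops exceeds n_lines")
        if self.snps_per_chrom < 1 or self.n_chrom < 1:
            raise ValueError("need at least one SNP and one chromosome")
        for v in (self.polygenic_var, self.gxe_var, self.residual_var,
                  self.block_var):
            if v < 0:
                raise ValueError("variances must be >= 0")
        if not (0.0 <= self.prep_fraction <= 1.0):
            raise ValueError("prep_fraction must be in [0, 1]")
        if len(self.environments) < 2:
            raise ValueError("need at least 2 environments")
        seasons = {e.season for e in self.environments}
        if seasons != {"spring", "winter"}:
            raise ValueError("both spring and winter seasons must be present")
        n_env = len(self.environments)
        for q in self.qtl_spec:
            if len(q.effects) != n_env:
                raise ValueError(
                    f"QTL effect vector length {len(q.effects)} != {n_env} environments"
                )

    @property
    def n_env(self) -> int:
        return len(self.environments)

    def default_env_means(self) -> np.ndarray:
        if self.env_means is not None:
            return np.asarray(self.env_means, dtype=float)
        return np.array(
            [60.0 if e.season == "spring" else 139.0 for e in self.environments]
        )


@dataclass
class TruthSet:
    subpop_of_line: np.ndarray
    qtl_positions: np.ndarray
    qtl_effects: np.ndarray          # QTL × environment
    variance_components: dict
    env_means: np.ndarray
    env_names: list
    gene_regions: pd.DataFrame = field(default=None)

    def to_json(self, path) -> None:
        obj = {
            "subpop_of_line": self.subpop_of_line.tolist(),
            "qtl_positions": self.qtl_positions.tolist(),
            "qtl_effects": self.qtl_effects.tolist(),
            "variance_components": self.variance_components,
            "env_means": self.env_means.tolist(),
            "env_names": list(self.env_names),
        }
        if self.gene_regions is not None:
            obj["gene_regions"] = self.gene_regions.to_dict(orient="list")
        Path(path).write_text(json.dumps(obj, indent=1))


def simulate_genotype_panel(cfg: SimConfig) -> tuple[GenotypePanel, TruthSet]:
    """Draw a structured, fully inbred panel with block-wise LD.

    Deterministic given ``cfg.seed``. Dosages are in {0, 2} (plus missing
    if ``missing_rate > 0``); monomorphic SNPs are possible and left for
    the variant filters to remove.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n_snp_total = cfg.n_chrom * cfg.snps_per_chrom
    if n_snp_total == 0:
        raise ValueError("zero SNPs requested")

    # physical map: sorted uniform positions per chromosome
    chroms, positions = [], []
    for c in range(cfg.n_chrom):
        pos = np.array([], dtype=np.int64)
        while len(pos) < cfg.snps_per_chrom:
            extra = rng.integers(1, cfg.chrom_length_bp + 1,
                                 size=2 * cfg.snps_per_chrom)
            pos = np.unique(np.concatenate([pos, extra]))
        pos = np.sort(rng.choice(pos, size=cfg.snps_per_chrom, replace=False))
        positions.append(pos)
        chroms.append(np.full(cfg.snps_per_chrom, f"{c + 1}S"))
    snp_map = pd.DataFrame(
        {
            "chrom": np.concatenate(chroms),
            "pos": np.concatenate(positions),
            "id": [f"snp{c + 1}_{i}" for c in range(cfg.n_chrom)
                   for i in range(cfg.snps_per_chrom)],
        }
    )

    # Balding–Nichols: ancestral freq, then per-subpop freq at target Fst
    p_anc = rng.uniform(0.05, 0.95, size=n_snp_total)
    F = cfg.fst_target
    if F > 0:
        a = p_anc * (1 - F) / F
        b = (1 - p_anc) * (1 - F) / F
        p_sub = rng.beta(a[None, :].repeat(cfg.n_subpops, 0),
                         b[None, :].repeat(cfg.n_subpops, 0))
    else:
        p_sub = np.repeat(p_anc[None, :], cfg.n_subpops, axis=0)

    subpop_of_line = np.sort(
        np.arange(cfg.n_lines) % cfg.n_subpops
    )
    chrom_slices = []
    off = 0
    for c in range(cfg.n_chrom):
        chrom_slices.append((slice(off, off + cfg.snps_per_chrom), positions[c]))
        off += cfg.snps_per_chrom
    haplo = np.empty((cfg.n_lines, n_snp_total), dtype=np.int8)
    for s in range(cfg.n_subpops):
        founders = _founder_pool(
            p_sub[s], cfg.founder_haplotypes_per_subpop, chrom_slices,
            0.2 * cfg.copy_switch_rate, rng,
        )
        members = np.flatnonzero(subpop_of_line == s)
        for li in members:
            haplo[li] = _mosaic_haplotype(
                founders, chrom_slices, cfg.copy_switch_rate, rng
            )
    dosages = (2 * haplo).astype(np.int8)

    if cfg.missing_rate > 0:
        mask = rng.random(dosages.shape) < cfg.missing_rate
        dosages[mask] = -1

    # geography: Gaussian scatter around distinct per-subpop centroids
    centroid_lat = 35.0 + 4.0 * np.arange(cfg.n_subpops)
    centroid_lon = -10.0 + 9.0 * np.arange(cfg.n_subpops)
    lat = centroid_lat[subpop_of_line] + rng.normal(0, 1.0, cfg.n_lines)
    lon = centroid_lon[subpop_of_line] + rng.normal(0, 1.0, cfg.n_lines)

    lines = pd.DataFrame(
        {
            "id": [f"L{i:04d}" for i in range(cfg.n_lines)],
            "subpop": [chr(ord("A") + s) for s in subpop_of_line],
            "latitude": lat,
            "longitude": lon,
        }
    )
    panel = GenotypePanel(dosages, snp_map, lines)

    gene_regions = _draw_gene_regions(cfg, snp_map, rng)

    qtl_pos = np.array([q.snp_index for q in cfg.qtl_spec], dtype=int)
    if (qtl_pos >= n_snp_total).any() or (qtl_pos < 0).any():
        raise ValueError("QTL snp_index out of range")
    qtl_eff = (
        np.array([q.effects for q in cfg.qtl_spec], dtype=float)
        if cfg.qtl_spec else np.zeros((0, cfg.n_env))
    )
    truth = TruthSet(
        subpop_of_line=subpop_of_line,
        qtl_positions=qtl_pos,
        qtl_effects=qtl_eff,
        variance_components={
            "sigma2_G": cfg.polygenic_var,
            "sigma2_GE": cfg.gxe_var,
            "sigma2_e": cfg.residual_var,
        },
        env_means=cfg.default_env_means(),
        env_names=[e.name for e in cfg.environments],
        gene_regions=gene_regions,
    )
    return panel, truth


def _founder_pool(p, nf, chrom_slices, corr_rate, rng) -> np.ndarray:
    """Founder haplotypes whose pool frequency tracks ``p`` per SNP and
    whose alleles are spatially coherent along the chromosome.

    Per SNP, the carrier count is stratified (floor + random dither), so
    the founder pool adds only quantization noise and the realized
    divergence stays at the Balding–Nichols target. Carriers are the
    top-k founders of a latent Gaussian ranking that evolves as an AR(1)
    process in physical distance (correlation exp(−corr_rate·d)); nearby
    SNPs therefore share carrier sets, giving local LD that decays with
    distance on the same length scale as the mosaic switching.
    """
    m = len(p)
    k = np.floor(p * nf).astype(int)
    k += (rng.random(m) < (p * nf - k)).astype(int)
    latent = np.empty((nf, m))
    for sl, pos in chrom_slices:
        j0 = sl.start
        latent[:, j0] = rng.normal(size=nf)
        rho = np.exp(-corr_rate * np.diff(pos))
        noise = rng.normal(size=(nf, len(pos) - 1))
        for t in range(1, len(pos)):
            latent[:, j0 + t] = (
                rho[t - 1] * latent[:, j0 + t - 1]
                + np.sqrt(1.0 - rho[t - 1] ** 2) * noise[:, t - 1]
            )
    ranks = np.argsort(np.argsort(latent, axis=0), axis=0)
    return (ranks < k[None, :]).astype(np.int8)


def _mosaic_haplotype(founders, chrom_slices, switch_rate, rng) -> np.ndarray:
    """Copy one haplotype as a founder mosaic, switching at rate/bp."""
    nf, m = founders.shape
    out = np.empty(m, dtype=np.int8)
    for sl, pos in chrom_slices:
        k = len(pos)
        gaps = np.diff(pos)
        p_switch = 1.0 - np.exp(-switch_rate * gaps)
        switches = rng.random(k - 1) < p_switch
        seg = np.concatenate([[0], np.cumsum(switches)])
        n_seg = seg[-1] + 1
        choice = rng.integers(0, nf, size=n_seg)
        out[sl] = founders[choice[seg], np.arange(sl.start, sl.stop)]
    return out


def _draw_gene_regions(cfg, snp_map, rng) -> pd.DataFrame:
    """Windows around random focal SNPs, used by the haplotype-block stage."""
    regions = []
    for g in range(cfg.n_gene_regions):
        c = int(rng.integers(0, cfg.n_chrom))
        chrom = f"{c + 1}S"
        sub = snp_map[snp_map["chrom"] == chrom]
        focal = sub["pos"].iloc[int(rng.integers(0, len(sub)))]
        half = 250_000
        regions.append(
            {
                "id": f"gene{g:03d}",
                "chrom": chrom,
                "start": max(1, int(focal) - half),
                "end": min(cfg.chrom_length_bp, int(focal) + half),
            }
        )
    return pd.DataFrame(regions)


# ---- field design ----------------------------------------------------------


def make_design(
    n_entries: int,
    prep_fraction: float,
    n_blocks: int,
    n_checks: int,
    seed: int,
) -> pd.DataFrame:
    """Augmented p-rep layout: every entry once, a fraction twice, checks
    replicated across the incomplete (main) blocks.

    Main entries fill the first ``n_blocks − 2`` blocks; the duplicated
    entries occupy the last two blocks; every check is added to each of
    the ``n_blocks − 2`` main blocks.
    """
    if n_blocks < 2:
        raise ValueError("need n_blocks >= 2")
    n_dup = int(np.ceil(prep_fraction * n_entries))
    if n_dup > n_entries:
        raise ValueError(
            f"{n_dup} duplicates exceed capacity for {n_entries} entries"
        )
    rng = np.random.default_rng(seed)
    entries = rng.permutation(n_entries)
    n_main_blocks = n_blocks - 2
    main_block = np.sort(np.arange(n_entries) % n_main_blocks)

    rows = [
        {"entry": f"E{entries[i]:04d}", "block": int(main_block[i]),
         "rep": 1, "is_check": False}
        for i in range(n_entries)
    ]
    dup_entries = rng.choice(entries, size=n_dup, replace=False)
    dup_block = n_main_blocks + (np.arange(n_dup) % 2)
    for i, e in enumerate(dup_entries):
        rows.append(
            {"entry": f"E{e:04d}", "block": int(dup_block[i]),
             "rep": 2, "is_check": False}
        )
    for c in range(n_checks):
        for b in range(n_main_blocks):
            rows.append(
                {"entry": f"CHK{c}", "block": b, "rep": b + 1, "is_check": True}
            )
    df = pd.DataFrame(rows)
    df.insert(0, "plot", np.arange(len(df)))
    return df


# ---- phenotypes ------------------------------------------------------------


def simulate_trial_phenotypes(
    panel: GenotypePanel, truth: TruthSet, cfg: SimConfig
) -> pd.DataFrame:
    """Plot-level trait values over all environments.

    value = env mean + polygenic g_i + Σ dosage × env effect + GE_ij
            + block effect + residual.

    Polygenic effects are kinship-correlated (sum of many small SNP
    effects) and standardized to sample variance σ²_G exactly; GE
    deviations are iid per line × environment, standardized to σ²_GE.
    """
    cfg.validate()
    if cfg.n_env == 0:
        raise ValueError("environment list is empty")
    rng = np.random.default_rng(cfg.seed + 1)
    n = panel.n_lines
    env_means = truth.env_means
    env_names = truth.env_names

    g = _polygenic(panel, cfg.polygenic_var, rng)
    if cfg.gxe_var > 0:
        ge = rng.normal(0.0, 1.0, size=(n, cfg.n_env))
        ge = ge - ge.mean()
        ge = ge * np.sqrt(cfg.gxe_var) / max(ge.std(), 1e-12)
    else:
        ge = np.zeros((n, cfg.n_env))

    qtl_contrib = np.zeros((n, cfg.n_env))
    if len(truth.qtl_positions):
        dos = panel.dosages[:, truth.qtl_positions].astype(float)
        dos[dos < 0] = 0.0
        qtl_contrib = dos @ truth.qtl_effects

    records = []
    for j, ename in enumerate(env_names):
        design = make_design(
            n, cfg.prep_fraction, cfg.n_blocks, cfg.n_checks,
            seed=cfg.seed + 100 + j,
        )
        blocks = design["block"].to_numpy()
        n_blocks = blocks.max() + 1
        b_eff = (
            rng.normal(0.0, np.sqrt(cfg.block_var), size=n_blocks)
            if cfg.block_var > 0 else np.zeros(n_blocks)
        )
        check_eff = {f"CHK{c}": 5.0 * (c - (cfg.n_checks - 1) / 2)
                     for c in range(cfg.n_checks)}
        for row in design.itertuples(index=False):
            if row.is_check:
                base = env_means[j] + check_eff[row.entry]
                gid = row.entry
            else:
                li = int(row.entry[1:])
                base = (
                    env_means[j] + g[li] + qtl_contrib[li, j] + ge[li, j]
                )
                gid = panel.lines["id"].iloc[li]
            eps = rng.normal(0.0, np.sqrt(cfg.residual_var)) \
                if cfg.residual_var > 0 else 0.0
            records.append(
                {
                    "genotype": gid,
                    "env": ename,
                    "block": f"{ename}_b{row.block}",
                    "rep": row.rep,
                    "is_check": row.is_check,
                    "trait": "dth",
                    "value": base + b_eff[row.block] + eps,
                }
            )
    return pd.DataFrame(records)


def _polygenic(panel: GenotypePanel, var: float, rng) -> np.ndarray:
    if var <= 0:
        return np.zeros(panel.n_lines)
    d = panel.dosages.astype(float)
    d[d < 0] = np.nan
    col_means = np.nanmean(d, axis=0)
    d = np.where(np.isnan(d), col_means[None, :], d) - col_means[None, :]
    a = rng.normal(0.0, 1.0, size=panel.n_snps)
    u = d @ a
    u = u - u.mean()
    sd = u.std()
    if sd < 1e-12:
        return np.zeros(panel.n_lines)
    return u * np.sqrt(var) / sd
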