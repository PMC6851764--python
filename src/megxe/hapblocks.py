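"""Gabriel-style haplotype blocks within gene regions.

Haplotypes are read directly off homozygous inbred genotypes
(heterozygous or missing lines excluded pairwise). Pairwise |D′| and its
90% confidence interval come from a likelihood profile over D′ on the
2×2 haplotype counts; block construction follows the Gabriel rules with
Haploview default thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import string

import numpy as np
import pandas as pd

from .genodata import GenotypePanel, MISSING

# Gabriel / Haploview defaults
CI_LOW_STRONG = 0.70
CI_HIGH_STRONG = 0.98
CI_HIGH_RECOMB = 0.90
STRONG_FRACTION = 0.95
MIN_INFORMATIVE_LINES = 10


@dataclass
class GeneRegion:
    id: str
    chrom: object
    start: int
    end: int

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"region {self.id}: start must be < end")


@dataclass
class HaplotypeBlock:
    region_id: str
    chrom: object
    snp_indices: np.ndarray
    state_table: pd.DataFrame = None     # state, allele_string, count
    assignments: np.ndarray = None       # per-line state label or None

    @property
    def n_snps(self) -> int:
        return len(self.snp_indices)


@dataclass
class HaplotypeBlockSet:
    blocks: list = field(default_factory=list)

    def to_frame(self, panel: GenotypePanel) -> pd.DataFrame:
        rows = []
        for b in self.blocks:
            ids = panel.snp_map["id"].iloc[b.snp_indices].tolist()
            for st in b.state_table.itertuples(index=False):
                rows.append({
                    "gene": b.region_id, "chrom": b.chrom,
                    "snp_ids": ",".join(ids), "state": st.state,
                    "allele_string": st.allele_string, "count": st.count,
                })
        return pd.DataFrame(rows)


def read_bed_regions(path) -> list[GeneRegion]:
    """BED (0-based half-open) → 1-based inclusive gene regions."""
    regions = []
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    for i, row in df.iterrows():
        name = str(row[3]) if df.shape[1] > 3 else f"region{i}"
        regions.append(GeneRegion(id=name, chrom=row[0],
                                  start=int(row[1]) + 1, end=int(row[2])))
    return regions


# ---- D' with confidence interval -------------------------------------------


def _haplotype_counts(g1, g2) -> np.ndarray | None:
    """2×2 haplotype counts from homozygous inbred dosage vectors."""
    g1 = np.asarray(g1)
    g2 = np.asarray(g2)
    ok = np.isin(g1, (0, 2)) & np.isin(g2, (0, 2))
    if ok.sum() < MIN_INFORMATIVE_LINES:
        return None
    a = (g1[ok] == 2).astype(int)
    b = (g2[ok] == 2).astype(int)
    counts = np.zeros((2, 2))
    for i in (0, 1):
        for j in (0, 1):
            counts[i, j] = np.sum((a == i) & (b == j))
    return counts


def dprime_with_ci(
    g1, g2, grid: int = 1001, ci: float = 0.90
) -> tuple[float, float, float]:
    """|D′| point estimate with a likelihood-profile confidence interval.

    The likelihood of the observed 2×2 haplotype table is evaluated on a
    grid over |D′| ∈ [0, 1] (allele frequencies fixed at their MLEs);
    the normalized likelihood is integrated to the (1−ci)/2 and
    1−(1−ci)/2 quantiles.
    """
    counts = _haplotype_counts(g1, g2)
    if counts is None:
        raise ValueError("fewer than 10 informative homozygous lines")
    return _dprime_ci_from_counts(counts, grid=grid, ci=ci)


def _dprime_ci_from_counts(counts, grid=1001, ci=0.90):
    n = counts.sum()
    pA = counts[1, :].sum() / n
    pB = counts[:, 1].sum() / n
    if pA in (0.0, 1.0) or pB in (0.0, 1.0):
        raise ValueError("monomorphic SNP after exclusions")
    p11 = counts[1, 1] / n
    D = p11 - pA * pB
    if D >= 0:
        dmax = min(pA * (1 - pB), (1 - pA) * pB)
    else:
        dmax = min(pA * pB, (1 - pA) * (1 - pB))
    dprime_hat = abs(D) / dmax if dmax > 0 else 0.0
    sign = 1.0 if D >= 0 else -1.0

    dgrid = np.linspace(0.0, 1.0, grid)
    logl = np.full(grid, -np.inf)
    for k, dp in enumerate(dgrid):
        Dk = sign * dp * dmax
        f = np.array([
            [(1 - pA) * (1 - pB) + Dk, (1 - pA) * pB - Dk],
            [pA * (1 - pB) - Dk, pA * pB + Dk],
        ])
        if (f < -1e-12).any():
            continue
        f = np.clip(f, 1e-12, 1.0)
        logl[k] = float((counts * np.log(f)).sum())
    lik = np.exp(logl - logl.max())
    lik /= lik.sum()
    cum = np.cumsum(lik)
    tail = (1.0 - ci) / 2.0
    lo = float(dgrid[np.searchsorted(cum, tail)])
    hi = float(dgrid[min(np.searchsorted(cum, 1.0 - tail), grid - 1)])
    return float(np.clip(dprime_hat, 0, 1)), lo, hi


# ---- Gabriel blocks --------------------------------------------------------


def gabriel_blocks(
    panel: GenotypePanel, region: GeneRegion, maf_min: float = 0.05
) -> list[HaplotypeBlock]:
    """Maximal non-overlapping strong-LD spans within a gene region.

    A pair is "strong LD" if CI_low ≥ 0.70 and CI_high ≥ 0.98, "strong
    recombination" if CI_high < 0.90; a span is a block candidate when
    ≥95% of its informative pairs are strong LD. Candidates are accepted
    largest-first (by SNP count, then bp span).
    """
    in_region = (
        (panel.snp_map["chrom"] == region.chrom)
        & (panel.snp_map["pos"] >= region.start)
        & (panel.snp_map["pos"] <= region.end)
    ).to_numpy()
    cand = np.flatnonzero(in_region)
    maf = panel.maf()
    cand = cand[np.nan_to_num(maf[cand]) >= maf_min]
    m = len(cand)
    if m < 2:
        return []

    strong = np.zeros((m, m), dtype=bool)
    recomb = np.zeros((m, m), dtype=bool)
    informative = np.zeros((m, m), dtype=bool)
    for i in range(m):
        for j in range(i + 1, m):
            counts = _haplotype_counts(
                panel.dosages[:, cand[i]], panel.dosages[:, cand[j]]
            )
            if counts is None:
                continue
            try:
                _, lo, hi = _dprime_ci_from_counts(counts, grid=201)
            except ValueError:
                continue
            is_strong = lo >= CI_LOW_STRONG and hi >= CI_HIGH_STRONG
            is_recomb = hi < CI_HIGH_RECOMB
            strong[i, j] = strong[j, i] = is_strong
            recomb[i, j] = recomb[j, i] = is_recomb
            informative[i, j] = informative[j, i] = is_strong or is_recomb

    pos = panel.snp_map["pos"].to_numpy()[cand]
    candidates = []
    for i in range(m):
        for j in range(i + 1, m):
            iu, ju = np.triu_indices(j - i + 1, k=1)
            info = informative[i:j + 1, i:j + 1][iu, ju]
            stg = strong[i:j + 1, i:j + 1][iu, ju]
            n_info = info.sum()
            if n_info == 0:
                continue
            if stg.sum() / n_info >= STRONG_FRACTION and strong[i, j]:
                candidates.append((j - i + 1, pos[j] - pos[i], i, j))
    candidates.sort(key=lambda t: (-t[0], -t[1], t[2]))
    used = np.zeros(m, dtype=bool)
    blocks = []
    for _, _, i, j in candidates:
        if used[i:j + 1].any():
            continue
        used[i:j + 1] = True
        blocks.append(HaplotypeBlock(
            region_id=region.id, chrom=region.chrom,
            snp_indices=cand[i:j + 1],
        ))
    blocks.sort(key=lambda b: b.snp_indices[0])
    for b in blocks:
        assign_states(panel, b)
    return blocks


# ---- state assignment ------------------------------------------------------


def _state_labels(n: int) -> list:
    letters = string.ascii_lowercase
    out = []
    for i in range(n):
        label = ""
        k = i
        while True:
            label = letters[k % 26] + label
            k = k // 26 - 1
            if k < 0:
                break
        out.append(label)
    return out


def assign_states(panel: GenotypePanel, block: HaplotypeBlock) -> HaplotypeBlock:
    """Enumerate allele strings over the block SNPs and label states
    a, b, c, … by descending carrier count (lexicographic tie-break).

    Lines with any missing or heterozygous call in the block are left
    unassigned.
    """
    G = panel.dosages[:, block.snp_indices]
    ok = np.all((G == 0) | (G == 2), axis=1)
    strings = np.array(["".join(str(v) for v in row) for row in G])
    strings_ok = strings[ok]
    uniq, counts = np.unique(strings_ok, return_counts=True)
    order = np.lexsort((uniq, -counts))  # by count desc, then string asc
    uniq, counts = uniq[order], counts[order]
    labels = _state_labels(len(uniq))
    table = pd.DataFrame(
        {"state": labels, "allele_string": uniq, "count": counts.astype(int)}
    )
    lookup = dict(zip(uniq, labels))
    assignments = np.array(
        [lookup.get(s) if o else None for s, o in zip(strings, ok)],
        dtype=object,
    )
    block.state_table = table
    block.assignments = assignments
    return block


def build_blockset(
    panel: GenotypePanel, regions, maf_min: float = 0.05
) -> HaplotypeBlockSet:
    blocks = []
    for r in regions:
        if isinstance(r, dict):
            r = GeneRegion(**r)
        blocks.extend(gabriel_blocks(panel, r, maf_min=maf_min))
    return HaplotypeBlockSet(blocks=blocks)
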