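"""Genotype panel data model: reading, writing, filtering and imputation.

The panel holds a lines × SNPs dosage matrix of minor-allele counts
(0/1/2, ``-1`` for missing), a physical map sorted by (chromosome,
position), and per-line metadata (id, optional categories, optional
collection coordinates).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = -1

MAP_COLUMNS = ["chrom", "pos", "id"]


class GenotypeDataError(ValueError):
    """Raised for malformed or inconsistent genotype inputs."""


@dataclass
class FilterReport:
    """Counts of SNPs removed by each criterion, in application order."""

    n_input: int
    removed_presence: int
    removed_homozygosity: int
    removed_maf: int
    n_kept: int

    def as_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "removed_presence": self.removed_presence,
            "removed_homozygosity": self.removed_homozygosity,
            "removed_maf": self.removed_maf,
            "n_kept": self.n_kept,
        }


@dataclass
class GenotypePanel:
    """Dosage matrix with physical map and line metadata.

    Attributes
    ----------
    dosages
        ``(n_lines, n_snps)`` int8 array of minor-allele counts, ``-1``
        marking missing calls.
    snp_map
        DataFrame with columns ``chrom``, ``pos`` (1-based bp), ``id``,
        sorted by (chrom, pos).
    lines
        DataFrame with at least an ``id`` column; optional columns such
        as ``latitude``, ``longitude``, ``subpop``, ``row_type``,
        ``breeding_history``, ``growth_habit``.
    """

    dosages: np.ndarray
    snp_map: pd.DataFrame
    lines: pd.DataFrame
    log: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.ndim != 2:
            raise GenotypeDataError("dosages must be a 2-D matrix")
        n_lines, n_snps = self.dosages.shape
        if len(self.snp_map) != n_snps:
            raise GenotypeDataError(
                f"map has {len(self.snp_map)} SNPs, dosages have {n_snps}"
            )
        if len(self.lines) != n_lines:
            raise GenotypeDataError(
                f"metadata has {len(self.lines)} lines, dosages have {n_lines}"
            )
        if self.lines["id"].duplicated().any():
            dups = self.lines["id"][self.lines["id"].duplicated()].tolist()
            raise GenotypeDataError(f"duplicated sample ids: {dups}")
        bad = ~np.isin(self.dosages, [0, 1, 2, MISSING])
        if bad.any():
            raise GenotypeDataError(
                f"{bad.sum()} dosage values outside {{0,1,2,{MISSING}}}"
            )
        self._sort_map()

    def _sort_map(self) -> None:
        order = self.snp_map.sort_values(
            ["chrom", "pos"], kind="stable"
        ).index.to_numpy()
        if not np.array_equal(order, np.arange(len(order))):
            self.snp_map = self.snp_map.iloc[order].reset_index(drop=True)
            self.dosages = self.dosages[:, order]
        else:
            self.snp_map = self.snp_map.reset_index(drop=True)

    # ---- basic properties -------------------------------------------------

    @property
    def n_lines(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    @property
    def line_ids(self) -> np.ndarray:
        return self.lines["id"].to_numpy()

    def present_fraction(self) -> np.ndarray:
        """Per-SNP fraction of non-missing calls."""
        return (self.dosages != MISSING).mean(axis=0)

    def allele_freq(self) -> np.ndarray:
        """Per-SNP frequency of the counted (minor) allele on non-missing calls."""
        d = self.dosages.astype(float)
        d[self.dosages == MISSING] = np.nan
        with np.errstate(invalid="ignore"):
            return np.nanmean(d, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        p = self.allele_freq()
        return np.minimum(p, 1.0 - p)

    def homozygous_fraction(self) -> np.ndarray:
        """Per-SNP fraction of non-missing calls that are homozygous."""
        obs = self.dosages != MISSING
        hom = (self.dosages == 0) | (self.dosages == 2)
        with np.errstate(invalid="ignore"):
            return np.where(obs.sum(0) > 0, hom.sum(0) / np.maximum(obs.sum(0), 1), np.nan)

    def recode_minor(self) -> "GenotypePanel":
        """Flip columns so the counted allele is the minor one (in place)."""
        p = self.allele_freq()
        flip = p > 0.5
        if flip.any():
            cols = self.dosages[:, flip]
            miss = cols == MISSING
            cols = 2 - cols
            cols[miss] = MISSING
            self.dosages[:, flip] = cols
        return self

    def take_snps(self, idx: np.ndarray) -> "GenotypePanel":
        idx = np.asarray(idx)
        return GenotypePanel(
            dosages=self.dosages[:, idx].copy(),
            snp_map=self.snp_map.iloc[idx].reset_index(drop=True),
            lines=self.lines.copy(),
            log=list(self.log),
        )

    def take_lines(self, idx: np.ndarray) -> "GenotypePanel":
        idx = np.asarray(idx)
        return GenotypePanel(
            dosages=self.dosages[idx, :].copy(),
            snp_map=self.snp_map.copy(),
            lines=self.lines.iloc[idx].reset_index(drop=True),
            log=list(self.log),
        )

    def chromosomes(self) -> list:
        return list(pd.unique(self.snp_map["chrom"]))

    def snp_indices_of(self, chrom) -> np.ndarray:
        return np.flatnonzero((self.snp_map["chrom"] == chrom).to_numpy())


# ---- input / output -------------------------------------------------------


def read_genotypes(source, format: str = "vcf") -> GenotypePanel:
    """Read a genotype panel from VCF or TSV dosage matrix.

    Dosages are recoded so that 2 counts two minor alleles; multi-allelic
    VCF records are dropped with a logged count.
    """
    source = Path(source)
    if not source.exists():
        raise FileNotFoundError(source)
    if format == "vcf":
        panel = _read_vcf(source)
    elif format == "matrix":
        panel = _read_matrix(source)
    else:
        raise ValueError(f"unknown format {format!r}")
    return panel.recode_minor()


def _read_vcf(path: Path) -> GenotypePanel:
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    if len(set(samples)) != len(samples):
        raise GenotypeDataError("duplicated sample ids in VCF header")
    chroms, poss, ids, cols = [], [], [], []
    n_multi = 0
    for i, rec in enumerate(vcf):
        if len(rec.ALT) != 1:
            n_multi += 1
            continue
        gt = np.asarray(rec.gt_types)  # 0=hom ref, 1=het, 2=hom alt, 3=missing
        col = gt.astype(np.int8)
        col[gt == 3] = MISSING
        cols.append(col)
        chroms.append(rec.CHROM)
        poss.append(rec.POS)
        ids.append(rec.ID if rec.ID else f"{rec.CHROM}_{rec.POS}")
    vcf.close()
    if n_multi:
        logger.info("dropped %d multi-allelic records", n_multi)
    if not cols:
        raise GenotypeDataError(f"no usable biallelic records in {path}")
    dosages = np.stack(cols, axis=1)
    snp_map = pd.DataFrame({"chrom": chroms, "pos": poss, "id": ids})
    lines = pd.DataFrame({"id": samples})
    panel = GenotypePanel(dosages, snp_map, lines)
    if n_multi:
        panel.log.append(f"dropped {n_multi} multi-allelic records")
    return panel


def _read_matrix(path: Path) -> GenotypePanel:
    """TSV dosage matrix: first column line id, header = SNP ids.

    A companion ``<stem>.map.tsv`` (chrom, pos, id) is required next to
    the matrix; without it all SNPs go on one pseudo-chromosome.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    bad = ~df.isin([0, 1, 2, MISSING]) & df.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise GenotypeDataError(
            f"malformed dosage at data line {r + 2} (sample {df.index[r]!r}, "
            f"column {df.columns[c]!r}): {df.iloc[r, c]!r}"
        )
    dosages = df.fillna(MISSING).to_numpy(dtype=np.int8)
    map_path = path.with_suffix("").with_suffix(".map.tsv") \
        if path.suffix == ".tsv" else Path(str(path) + ".map.tsv")
    map_path = Path(str(path)[: -len(path.suffix)] + ".map.tsv")
    if map_path.exists():
        snp_map = pd.read_csv(map_path, sep="\t")
        snp_map = snp_map[MAP_COLUMNS]
    else:
        snp_map = pd.DataFrame(
            {"chrom": "1", "pos": np.arange(1, df.shape[1] + 1), "id": df.columns}
        )
    lines = pd.DataFrame({"id": df.index.to_numpy()})
    return GenotypePanel(dosages, snp_map, lines)


def write_matrix(panel: GenotypePanel, path) -> None:
    path = Path(path)
    df = pd.DataFrame(
        panel.dosages, index=panel.line_ids, columns=panel.snp_map["id"]
    )
    df.index.name = "line"
    df.replace(MISSING, pd.NA).to_csv(path, sep="\t")
    map_path = Path(str(path)[: -len(path.suffix)] + ".map.tsv")
    panel.snp_map.to_csv(map_path, sep="\t", index=False)


def write_vcf(panel: GenotypePanel, path) -> None:
    """Write a minimal VCF 4.2 with GT only (ALT = counted/minor allele)."""
    path = Path(path)
    gt_code = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in panel.chromosomes():
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(str(s) for s in panel.line_ids)
            + "\n"
        )
        for j in range(panel.n_snps):
            row = panel.snp_map.iloc[j]
            gts = "\t".join(gt_code[int(v)] for v in panel.dosages[:, j])
            fh.write(
                f"{row['chrom']}\t{row['pos']}\t{row['id']}\tA\tT\t.\t.\t.\tGT\t{gts}\n"
            )


def attach_metadata(panel: GenotypePanel, meta: pd.DataFrame) -> GenotypePanel:
    """Merge a metadata table (must contain ``id``) onto panel lines."""
    if "id" not in meta.columns:
        raise GenotypeDataError("metadata requires an 'id' column")
    merged = panel.lines[["id"]].merge(meta, on="id", how="left")
    panel.lines = merged
    return panel


# ---- filtering and imputation ---------------------------------------------


def filter_variants(
    panel: GenotypePanel,
    min_present: float = 0.80,
    maf_min: float = 0.05,
    min_homozygous: float = 0.98,
) -> tuple[GenotypePanel, FilterReport]:
    """Drop SNPs failing presence, homozygosity or MAF criteria.

    Criteria are applied in order presence → homozygosity → MAF, each on
    non-missing calls; the report counts removals per criterion.
    """
    if panel.n_snps == 0:
        raise GenotypeDataError("empty panel")
    keep = np.ones(panel.n_snps, dtype=bool)

    present = panel.present_fraction()
    fail_presence = present < min_present
    keep &= ~fail_presence

    hom = panel.homozygous_fraction()
    fail_hom = keep & (np.nan_to_num(hom, nan=0.0) < min_homozygous)
    keep &= ~fail_hom

    maf = panel.maf()
    fail_maf = keep & (np.nan_to_num(maf, nan=0.0) < maf_min)
    keep &= ~fail_maf

    report = FilterReport(
        n_input=panel.n_snps,
        removed_presence=int(fail_presence.sum()),
        removed_homozygosity=int(fail_hom.sum()),
        removed_maf=int(fail_maf.sum()),
        n_kept=int(keep.sum()),
    )
    if report.n_kept == 0:
        raise GenotypeDataError(f"all SNPs removed by filters: {report.as_dict()}")
    out = panel.take_snps(np.flatnonzero(keep))
    out.log.append(f"filter_variants: {report.as_dict()}")
    return out.recode_minor(), report


def impute_modal(panel: GenotypePanel) -> GenotypePanel:
    """Fill missing calls with the per-SNP modal dosage.

    Ties are broken toward the smaller dosage, i.e. the major-allele
    homozygote under minor-allele coding.
    """
    d = panel.dosages.copy()
    fully_missing = (d == MISSING).all(axis=0)
    if fully_missing.any():
        raise GenotypeDataError(
            f"{fully_missing.sum()} SNPs are fully missing; filter first"
        )
    counts = np.stack([(d == v).sum(axis=0) for v in (0, 1, 2)])  # 3 × n_snps
    modal = np.argmax(counts, axis=0).astype(np.int8)  # argmax picks smallest on tie
    miss_r, miss_c = np.nonzero(d == MISSING)
    d[miss_r, miss_c] = modal[miss_c]
    out = GenotypePanel(d, panel.snp_map.copy(), panel.lines.copy(), list(panel.log))
    out.log.append(f"impute_modal: filled {len(miss_r)} cells")
    return out
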