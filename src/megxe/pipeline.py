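"""Configuration-driven orchestration of the full analysis.

A single YAML file describes either a simulation block or input paths,
per-stage parameters and stage toggles. Stages run in dependency order
(simulate/ingest → filter/impute → LD → kinship/structure → Fst/sPCA →
blocks → stage-1 means → G×E → GWAS); each writes its tables plus a
manifest recording parameters, input hashes and the seed, so a rerun
with the same config is bit-identical.
"""

from __future__ import annotations

import difflib
import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, field_validator

from . import genodata, gwas, gxe, hapblocks, ldkin, simulate, structure

logger = logging.getLogger(__name__)

ALL_STAGES = [
    "simulate", "filter", "ld", "kinship", "structure", "fst", "spca",
    "blocks", "adjust", "gxe", "gwas",
]


class SimBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_lines: int = 360
    n_subpops: int = 6
    fst_target: float = 0.15
    n_chrom: int = 7
    snps_per_chrom: int = 2000
    chrom_length_bp: int = 50_000_000
    founder_haplotypes_per_subpop: int = 16
    copy_switch_rate: float = 2e-7
    n_gene_regions: int = 20
    polygenic_var: float = 4.0
    gxe_var: float = 2.0
    residual_var: float = 1.0
    block_var: float = 0.0
    prep_fraction: float = Field(0.20, ge=0.0, le=1.0)
    n_blocks: int = 10
    n_checks: int = 2
    qtl: list = Field(default_factory=list)  # [[snp_index, [effects...]], ...]


class InputBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    genotypes: str
    format: Literal["vcf", "matrix"] = "vcf"
    metadata: Optional[str] = None
    phenotypes: Optional[str] = None
    gene_regions_bed: Optional[str] = None


class FilterParams(BaseModel):
    model_config = ConfigDict(extra="forbid")
    min_present: float = Field(0.80, ge=0.0, le=1.0)
    maf_min: float = Field(0.05, ge=0.0, le=0.5)
    min_homozygous: float = Field(0.98, ge=0.0, le=1.0)


class LDParams(BaseModel):
    model_config = ConfigDict(extra="forbid")
    thin_step: int = 25
    window_snps: int = 500
    overlap: int = 475
    bin_bp: float = 20_000
    quantile: float = 0.95
    corrected_pass: bool = False


class StructureParams(BaseModel):
    model_config = ConfigDict(extra="forbid")
    alpha: float = 0.05
    n_clusters: int = 6
    sample_base: int = 5
    sample_bin_mbp: float = 2_000_000


class GwasParams(BaseModel):
    model_config = ConfigDict(extra="forbid")
    alpha: float = 0.05
    min_carriers: int = 5
    full_kinship: bool = False
    haplotype_scan: bool = True


class PipelineConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    seed: int = 0
    out_dir: str = "megxe_out"
    log_level: str = "INFO"
    stages: list[str] = Field(default_factory=lambda: list(ALL_STAGES))
    simulation: Optional[SimBlock] = None
    inputs: Optional[InputBlock] = None
    filter: FilterParams = Field(default_factory=FilterParams)
    ld: LDParams = Field(default_factory=LDParams)
    structure: StructureParams = Field(default_factory=StructureParams)
    gwas: GwasParams = Field(default_factory=GwasParams)
    fst_groupings: list[str] = Field(default_factory=lambda: ["subpop2"])

    @field_validator("stages")
    @classmethod
    def _known_stages(cls, v):
        for s in v:
            if s not in ALL_STAGES:
                raise ValueError(f"unknown stage {s!r}; choose from {ALL_STAGES}")
        return v


def validate_config(path_or_dict) -> PipelineConfig:
    """Parse and schema-check a config; unknown keys are rejected with a
    closest-match suggestion."""
    if isinstance(path_or_dict, (str, Path)):
        raw = yaml.safe_load(Path(path_or_dict).read_text()) or {}
    else:
        raw = dict(path_or_dict)
    try:
        cfg = PipelineConfig(**raw)
    except ValidationError as err:
        msgs = []
        for e in err.errors():
            loc = ".".join(str(x) for x in e["loc"])
            msg = f"{loc}: {e['msg']}"
            if e["type"] == "extra_forbidden":
                field_name = str(e["loc"][-1])
                model = PipelineConfig
                guess = difflib.get_close_matches(
                    field_name, list(model.model_fields), n=1
                )
                if guess:
                    msg += f" (did you mean {guess[0]!r}?)"
            msgs.append(msg)
        raise ValueError("invalid config:\n  " + "\n  ".join(msgs)) from err
    if cfg.simulation is None and cfg.inputs is None:
        raise ValueError("config needs either a 'simulation' or an 'inputs' block")
    if cfg.inputs is not None:
        for key in ("genotypes", "metadata", "phenotypes", "gene_regions_bed"):
            p = getattr(cfg.inputs, key)
            if p is not None and not Path(p).exists():
                raise ValueError(f"inputs.{key}: file not found: {p}")
    logger.info("effective config: %s", cfg.model_dump())
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class PipelineRunner:
    """Executes stages, passing artifacts in memory and writing tables +
    manifests under the output directory."""

    def __init__(self, cfg: PipelineConfig):
        self.cfg = cfg
        self.out = Path(cfg.out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.state: dict = {}

    def _manifest(self, stage: str, params: dict, outputs: list[Path]):
        man = {
            "stage": stage,
            "seed": self.cfg.seed,
            "parameters": params,
            "outputs": {str(p.name): _sha256(p) for p in outputs},
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        }
        (self.out / f"manifest_{stage}.json").write_text(json.dumps(man, indent=1))

    def run(self) -> Path:
        order = [s for s in ALL_STAGES if s in self.cfg.stages]
        for stage in order:
            logger.info("stage: %s", stage)
            try:
                getattr(self, f"stage_{stage}")()
            except Exception as err:
                raise RuntimeError(
                    f"stage {stage!r} failed: {err} "
                    f"(see logs and {self.out})"
                ) from err
        return self.out

    # -- stages -------------------------------------------------------------

    def stage_simulate(self):
        if self.cfg.simulation is None:
            self._ingest()
            return
        sb = self.cfg.simulation
        sim_cfg = simulate.SimConfig(
            n_lines=sb.n_lines, n_subpops=sb.n_subpops,
            fst_target=sb.fst_target, n_chrom=sb.n_chrom,
            snps_per_chrom=sb.snps_per_chrom,
            chrom_length_bp=sb.chrom_length_bp,
            founder_haplotypes_per_subpop=sb.founder_haplotypes_per_subpop,
            copy_switch_rate=sb.copy_switch_rate,
            n_gene_regions=sb.n_gene_regions,
            qtl_spec=tuple((q[0], tuple(q[1])) for q in sb.qtl),
            polygenic_var=sb.polygenic_var, gxe_var=sb.gxe_var,
            residual_var=sb.residual_var, block_var=sb.block_var,
            prep_fraction=sb.prep_fraction, n_blocks=sb.n_blocks,
            n_checks=sb.n_checks, seed=self.cfg.seed,
        )
        panel, truth = simulate.simulate_genotype_panel(sim_cfg)
        plots = simulate.simulate_trial_phenotypes(panel, truth, sim_cfg)
        self.state.update(panel=panel, truth=truth, plots=plots,
                          regions=truth.gene_regions)
        geno_path = self.out / "genotypes.tsv"
        genodata.write_matrix(panel, geno_path)
        pheno_path = self.out / "phenotypes.csv"
        plots.to_csv(pheno_path, index=False)
        truth_path = self.out / "truth.json"
        truth.to_json(truth_path)
        self._manifest("simulate", {"sim": sb.model_dump()},
                       [geno_path, pheno_path, truth_path])

    def _ingest(self):
        ib = self.cfg.inputs
        panel = genodata.read_genotypes(ib.genotypes, format=ib.format)
        if ib.metadata:
            meta = pd.read_csv(ib.metadata)
            genodata.attach_metadata(panel, meta)
        plots = pd.read_csv(ib.phenotypes) if ib.phenotypes else None
        regions = None
        if ib.gene_regions_bed:
            regions = pd.DataFrame(
                [vars(r) for r in hapblocks.read_bed_regions(ib.gene_regions_bed)]
            )
        self.state.update(panel=panel, truth=None, plots=plots, regions=regions)
        self._manifest("simulate", {"inputs": ib.model_dump()}, [])

    def stage_filter(self):
        fp = self.cfg.filter
        panel, report = genodata.filter_variants(
            self.state["panel"], min_present=fp.min_present,
            maf_min=fp.maf_min, min_homozygous=fp.min_homozygous,
        )
        panel = genodata.impute_modal(panel)
        self.state["panel"] = panel
        path = self.out / "filter_report.json"
        path.write_text(json.dumps(report.as_dict(), indent=1))
        self._manifest("filter", fp.model_dump(), [path])

    def stage_ld(self):
        lp = self.cfg.ld
        profile = ldkin.local_ld_decay(
            self.state["panel"], window_snps=lp.window_snps,
            overlap=lp.overlap, bin_bp=lp.bin_bp, quantile=lp.quantile,
            thin_step=lp.thin_step,
        )
        self.state["ld_profile"] = profile
        path = self.out / "ld_profile.tsv"
        profile.to_frame().to_csv(path, sep="\t", index=False)
        outputs = [path]
        if lp.corrected_pass and "kinship" in self.state:
            prof_c = ldkin.local_ld_decay(
                self.state["panel"], window_snps=lp.window_snps,
                overlap=lp.overlap, bin_bp=lp.bin_bp, quantile=lp.quantile,
                thin_step=lp.thin_step, K=self.state["kinship"],
            )
            path_c = self.out / "ld_profile_corrected.tsv"
            prof_c.to_frame().to_csv(path_c, sep="\t", index=False)
            self.state["ld_profile_corrected"] = prof_c
            outputs.append(path_c)
        self._manifest("ld", lp.model_dump(), outputs)

    def stage_kinship(self):
        sp = self.cfg.structure
        idx = ldkin.ld_aware_sample(
            self.state["panel"].snp_map, self.state["ld_profile"],
            bin_mbp=sp.sample_bin_mbp, base=sp.sample_base,
            seed=self.cfg.seed,
        )
        K = ldkin.kinship_astle_balding(self.state["panel"], idx)
        self.state["kinship"] = K
        path = self.out / "kinship.csv"
        pd.DataFrame(K.values, index=K.line_ids, columns=K.line_ids).to_csv(path)
        self._manifest("kinship", {"n_snps_sampled": int(len(idx))}, [path])
        if self.cfg.ld.corrected_pass:
            self.stage_ld()  # second pass now that kinship exists

    def stage_structure(self):
        sp = self.cfg.structure
        res = structure.significant_pcs(self.state["kinship"], alpha=sp.alpha)
        labels, Z = structure.ward_cluster(res.significant_scores, sp.n_clusters)
        res.cluster_labels, res.linkage = labels, Z
        self.state["structure"] = res
        panel = self.state["panel"]
        panel.lines["cluster"] = labels
        path = self.out / "structure.csv"
        df = pd.DataFrame(
            res.scores[:, : max(res.n_significant, 1)],
            columns=[f"PC{i + 1}" for i in range(max(res.n_significant, 1))],
        )
        df.insert(0, "id", panel.line_ids)
        df["cluster"] = labels
        df.to_csv(path, index=False)
        self._manifest("structure",
                       {"n_significant": int(res.n_significant),
                        "k": sp.n_clusters}, [path])

    def stage_fst(self):
        panel = self.state["panel"]
        outputs = []
        for grouping in self.cfg.fst_groupings:
            if grouping == "subpop2":
                if "cluster" in panel.lines:
                    lab = panel.lines["cluster"].to_numpy()
                    top2 = pd.Series(lab).value_counts().index[:2]
                    labels = np.where(np.isin(lab, top2), lab.astype(str), None)
                else:
                    continue
            elif grouping in panel.lines.columns:
                labels = panel.lines[grouping].to_numpy()
                lv = pd.Series(labels).dropna().unique()
                if len(lv) != 2:
                    labels = np.where(np.isin(labels, lv[:2]),
                                      labels.astype(str), None)
            else:
                logger.warning("fst grouping %r not in metadata", grouping)
                continue
            fst = structure.fst_per_snp(panel, labels)
            mm = structure.moving_median(fst, window=100)
            out = panel.snp_map.copy()
            out["fst"] = fst
            out["moving_median_fst"] = mm
            path = self.out / f"fst_{grouping}.tsv"
            out.to_csv(path, sep="\t", index=False)
            outputs.append(path)
        self._manifest("fst", {"groupings": self.cfg.fst_groupings}, outputs)

    def stage_spca(self):
        panel = self.state["panel"]
        if not {"latitude", "longitude"}.issubset(panel.lines.columns):
            logger.warning("no coordinates; skipping sPCA")
            return
        X = panel.dosages.astype(float)
        X[X == genodata.MISSING] = np.nan
        mu = np.nanmean(X, axis=0)
        X = np.where(np.isnan(X), mu[None, :], X)
        res = structure.spca(
            X, panel.lines["latitude"].to_numpy(),
            panel.lines["longitude"].to_numpy(), n_axes=6,
        )
        self.state["spca"] = res
        path = self.out / "spca_scores.csv"
        df = pd.DataFrame(res.scores,
                          columns=[f"axis{i + 1}" for i in range(res.scores.shape[1])])
        df.insert(0, "id", panel.line_ids)
        df.to_csv(path, index=False)
        epath = self.out / "spca_eigen.csv"
        pd.DataFrame({"eigenvalue": res.eigenvalues, "moran_i": res.moran_i,
                      "class": res.classification}).to_csv(epath, index=False)
        self._manifest("spca", {}, [path, epath])

    def stage_blocks(self):
        regions_df = self.state.get("regions")
        if regions_df is None or len(regions_df) == 0:
            logger.warning("no gene regions; skipping blocks")
            return
        regions = [hapblocks.GeneRegion(r["id"], r["chrom"],
                                        int(r["start"]), int(r["end"]))
                   for r in regions_df.to_dict(orient="records")]
        bs = hapblocks.build_blockset(self.state["panel"], regions,
                                      maf_min=self.cfg.filter.maf_min)
        self.state["blockset"] = bs
        path = self.out / "haplotype_blocks.tsv"
        bs.to_frame(self.state["panel"]).to_csv(path, sep="\t", index=False)
        self._manifest("blocks", {"n_blocks": len(bs.blocks)}, [path])

    def stage_adjust(self):
        plots = self.state.get("plots")
        if plots is None:
            logger.warning("no phenotypes; skipping stage-1 adjustment")
            return
        frames, h2s = [], {}
        for env in plots["env"].unique():
            res = gxe.stage1_adjusted_means(plots, trial=env)
            df = res.adjusted_means.copy()
            df["env"] = env
            frames.append(df)
            h2s[env] = res.h2
        adj = pd.concat(frames, ignore_index=True)
        checks = plots.loc[plots.get("is_check", False), "genotype"] \
            if "is_check" in plots.columns else pd.Series([], dtype=object)
        adj = adj[~adj["genotype"].isin(set(checks))]
        self.state["adjusted"] = adj
        self.state["cell_means"] = adj.pivot(index="genotype", columns="env",
                                             values="mean")
        path = self.out / "adjusted_means.csv"
        adj.to_csv(path, index=False)
        h2path = self.out / "heritability.json"
        h2path.write_text(json.dumps(h2s, indent=1))
        self._manifest("adjust", {}, [path, h2path])

    def stage_gxe(self):
        plots = self.state.get("plots")
        if plots is None:
            return
        vc = gxe.fit_two_way_vc(plots)
        cm = self.state.get("cell_means")
        if cm is None:
            cm = gxe.cell_mean_matrix(plots)
        fw = gxe.finlay_wilkinson(cm)
        am = gxe.ammi(cm, n_axes=2, impute_missing=True)
        gg = gxe.gge(cm, n_axes=2, impute_missing=True)
        self.state.update(vc=vc, fw=fw, ammi=am, gge=gg)
        outputs = []
        p = self.out / "variance_components.json"
        p.write_text(json.dumps(vc, indent=1))
        outputs.append(p)
        p = self.out / "finlay_wilkinson.csv"
        fw.to_csv(p)
        outputs.append(p)
        p = self.out / "ammi_genotype_scores.csv"
        am.geno_scores.to_csv(p)
        outputs.append(p)
        p = self.out / "gge_genotype_scores.csv"
        gg.geno_scores.to_csv(p)
        outputs.append(p)
        self._manifest("gxe", {}, outputs)

    def stage_gwas(self):
        cm = self.state.get("cell_means")
        if cm is None:
            logger.warning("no cell means; skipping GWAS")
            return
        panel = self.state["panel"]
        cm = cm.loc[cm.index.isin(panel.line_ids)]
        sbc = gwas.structure_by_chromosome(
            panel, self.state["ld_profile"], alpha=self.cfg.structure.alpha,
            seed=self.cfg.seed, full_kinship=self.cfg.gwas.full_kinship,
        )
        res = gwas.scan_snps(cm, panel, sbc)
        path = self.out / "gwas_snps.tsv"
        res.table.to_csv(path, sep="\t", index=False)
        side = self.out / "gwas_thresholds.json"
        side.write_text(json.dumps(
            {"lambda_gc": res.lambda_gc, "m_eff": res.m_eff,
             "thresholds": {str(k): v for k, v in res.thresholds.items()}},
            indent=1))
        outputs = [path, side]
        self.state["gwas_snps"] = res
        if self.cfg.gwas.haplotype_scan and self.state.get("blockset"):
            hres = gwas.scan_haplotypes(
                cm, self.state["blockset"], sbc,
                min_carriers=self.cfg.gwas.min_carriers, panel=panel,
                m_eff=res.m_eff,
            )
            hpath = self.out / "gwas_haplotypes.tsv"
            hres.table.to_csv(hpath, sep="\t", index=False)
            outputs.append(hpath)
            self.state["gwas_haplotypes"] = hres
        self._manifest("gwas", self.cfg.gwas.model_dump(), outputs)


def run_pipeline(cfg: PipelineConfig | str | Path | dict) -> Path:
    if not isinstance(cfg, PipelineConfig):
        cfg = validate_config(cfg)
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), 20))
    return PipelineRunner(cfg).run()
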