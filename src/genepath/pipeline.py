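"""End-to-end orchestration: config, staged run, report export, manifest.

A run proceeds load/simulate -> QC -> SNP-gene mapping -> subgroup PCA with
Tracy-Widom component count -> covariate matrix -> per-phenotype GBST and
SMA -> Bonferroni / BH selection -> gene ranking (single and joint) ->
permutation pathway enrichment -> TSV reports plus a JSON manifest with a
config hash and per-stage counts.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import tomllib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import io as gio
from .assoc import run_gbst, run_sma
from .containers import GeneAnnotation, GenotypeMatrix, PathwayCollection, PhenotypeTable
from .enrichment import permutation_null, permutation_null_joint, rank_pathways
from .multitest import bh_select, bonferroni_select
from .simulate import SimulationConfig, simulate_cohort, write_cohort
from .structure import build_covariate_matrix, genotype_pca, tracy_widom_count

log = logging.getLogger("genepath")


@dataclass
class RunConfig:
    """Everything one analysis run needs; see ``RunConfig.from_toml``."""

    # file inputs (exactly one of `inputs` / `synthetic` must be set)
    inputs: dict | None = None  # genotypes, genotype_format, phenotypes, genes, pathways
    synthetic: dict | None = None  # SimulationConfig keyword arguments
    min_call_rate: float = 0.95
    min_maf: float = 0.05
    flank: int = 5000
    min_pathway_genes: int = 5
    n_components: int | str = "auto"  # or an explicit count
    tw_alpha: float = 0.01
    drop_first_component: bool = True
    include_study_indicator: bool = False
    phenotype_columns: list = field(default_factory=list)  # e.g. ["nefa_T2"]
    compute_ratios: bool = True
    log_scale_traits: tuple = ("nefa",)
    alpha: float = 0.05
    fdr_q: float = 0.05
    enrichment_methods: tuple = ("wkst", "wrst")
    n_perm: int = 1000
    top_k: int = 5
    joint: bool = False
    run_sma: bool = True
    seed: int = 0
    output_dir: str = "genepath_run"

    def __post_init__(self):
        if (self.inputs is None) == (self.synthetic is None):
            raise ValueError("exactly one of 'inputs' and 'synthetic' must be set")

    @classmethod
    def from_toml(cls, path) -> "RunConfig":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        return cls(**raw)

    def hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class RunResult:
    config: RunConfig
    genotypes: GenotypeMatrix
    phenotypes: PhenotypeTable
    genes: GeneAnnotation
    pathways: PathwayCollection
    gene_map: dict
    covariates: object
    n_significant_components: int
    gbst: dict  # phenotype column -> DataFrame
    sma: dict
    selection: dict  # phenotype column -> {bonferroni, fdr}
    enrichment: pd.DataFrame | None
    truth: object | None = None


def _load_inputs(config: RunConfig):
    if config.synthetic is not None:
        sim = SimulationConfig(**{**config.synthetic, "seed": config.seed})
        cohort = simulate_cohort(sim)
        return (cohort.genotypes, cohort.phenotypes, cohort.genes,
                cohort.pathways, cohort.truth)
    inputs = config.inputs
    genotypes = gio.read_genotypes(
        inputs["genotypes"], inputs.get("genotype_format", "ped_map"),
        map_path=inputs.get("map"),
    )
    phenotypes = gio.read_phenotypes(inputs["phenotypes"])
    genes = gio.read_gene_bed(inputs["genes"])
    pathways = gio.read_pathways(inputs["pathways"], genes,
                                 min_genes=config.min_pathway_genes)
    return genotypes, phenotypes, genes, pathways, None


def run_analysis(config: RunConfig) -> RunResult:
    """Execute every stage; raises with the stage name on failure."""
    stage = "load"
    try:
        genotypes, phenotypes, genes, pathways, truth = _load_inputs(config)
        log.info("loaded %d samples x %d SNPs, %d genes, %d pathways",
                 genotypes.n_samples, genotypes.n_snps, len(genes), len(pathways))

        if config.compute_ratios:
            phenotypes = gio.compute_ratio_phenotypes(
                phenotypes, log_scale_traits=config.log_scale_traits
            )
        columns = config.phenotype_columns or phenotypes.trait_columns
        missing = [c for c in columns if c not in phenotypes.frame.columns]
        if missing:
            raise ValueError(f"phenotype columns not found: {missing}")

        stage = "qc"
        genotypes, qc_report = gio.qc_filter(
            genotypes, min_call_rate=config.min_call_rate,
            min_maf=config.min_maf, impute=True,
        )
        log.info("QC kept %d/%d SNPs", qc_report.n_kept, qc_report.n_input)

        stage = "map"
        gene_map = gio.map_snps_to_genes(genotypes, genes, flank=config.flank)
        log.info("%d genes carry at least one SNP", len(gene_map))

        stage = "pca"
        group = phenotypes.frame["group"].to_numpy()
        g1 = group == 0  # the larger subgroup by convention
        if g1.sum() < genotypes.n_samples - g1.sum():
            g1 = ~g1
        pca = genotype_pca(genotypes, sample_subset=np.flatnonzero(g1))
        if config.n_components == "auto":
            n_comp = tracy_widom_count(pca, alpha=config.tw_alpha)
        else:
            n_comp = int(config.n_components)
        log.info("%d significant principal components", n_comp)

        stage = "covariates"
        study = phenotypes.frame.get("study")
        Z = build_covariate_matrix(
            genotypes.n_samples,
            g1.astype(float),
            pca=pca,
            n_components=n_comp,
            drop_first_component=config.drop_first_component,
            include_study_indicator=config.include_study_indicator,
            study_indicator=None if study is None else study.to_numpy(),
        )

        stage = "association"
        gbst = {}
        sma = {}
        selection = {}
        for col in columns:
            mask, values = phenotypes.analysis_set(col)
            rows = np.flatnonzero(mask)
            sub = genotypes.dosage[rows, :]
            Zsub = Z.values[rows, :]
            table = run_gbst(sub, gene_map, values, Zsub, genes=genes)
            gbst[col] = table
            pv = table.set_index("gene_id")["p_asymptotic"]
            selection[col] = {
                "bonferroni": bonferroni_select(pv, alpha=config.alpha),
                "fdr": bh_select(pv, q=config.fdr_q),
            }
            if config.run_sma:
                sma_table = run_sma(sub, values, Zsub)
                sma_table.insert(1, "chromosome",
                                 genotypes.snps["chromosome"].to_numpy())
                sma_table.insert(2, "position",
                                 genotypes.snps["position"].to_numpy())
                sma[col] = sma_table
            log.info("%s: %d genes tested, %d FDR-selected", col,
                     len(table), selection[col]["fdr"].n_selected)

        stage = "enrichment"
        enrichment = None
        if len(pathways) and config.n_perm > 0:
            positions = genes.table.set_index("gene_id")
            frames = []
            for col in columns:
                mask, values = phenotypes.analysis_set(col)
                rows = np.flatnonzero(mask)
                res = permutation_null(
                    values, genotypes.dosage[rows, :], Z.values[rows, :],
                    gene_map, pathways, positions=positions,
                    n_perm=config.n_perm, seed=config.seed,
                    methods=tuple(config.enrichment_methods),
                )
                res.insert(0, "phenotype", col)
                frames.append(res)
            if config.joint and len(columns) >= 2:
                masks = [phenotypes.analysis_set(c)[0] for c in columns]
                shared = np.logical_and.reduce(masks)
                rows = np.flatnonzero(shared)
                ys = {
                    c: phenotypes.frame[c].to_numpy(dtype=float)[rows]
                    for c in columns
                }
                res = permutation_null_joint(
                    ys, genotypes.dosage[rows, :], Z.values[rows, :],
                    gene_map, pathways, positions=positions,
                    n_perm=config.n_perm, seed=config.seed,
                    methods=tuple(config.enrichment_methods),
                )
                res.insert(0, "phenotype", "joint")
                frames.append(res)
            enrichment = pd.concat(frames, ignore_index=True)

        return RunResult(
            config=config, genotypes=genotypes, phenotypes=phenotypes,
            genes=genes, pathways=pathways, gene_map=gene_map,
            covariates=Z, n_significant_components=n_comp,
            gbst=gbst, sma=sma, selection=selection,
            enrichment=enrichment, truth=truth,
        )
    except Exception as err:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {err}") from err


def export_reports(result: RunResult, directory) -> dict:
    """Write all result tables as TSV plus a JSON manifest; returns paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    cfg_hash = result.config.hash()
    header = f"# genepath {__version__} config={cfg_hash} seed={result.config.seed}\n"
    paths = {}

    def write_tsv(name: str, frame: pd.DataFrame):
        path = directory / name
        with open(path, "w") as fh:
            fh.write(header)
            frame.to_csv(fh, sep="\t", index=False)
        paths[name] = path

    summary_rows = []
    for col, table in result.gbst.items():
        sel = result.selection[col]
        bon, fdr = sel["bonferroni"], sel["fdr"]
        out = table.copy()
        out["selected_bonferroni"] = out["gene_id"].isin(bon.selected)
        out["selected_fdr"] = out["gene_id"].isin(fdr.selected)
        write_tsv(f"gbst_{col}.tsv", out)
        # plot-ready Manhattan table with constant threshold columns
        man = out[["gene_id", "chromosome"]].copy()
        man["midpoint"] = (table["start"] + table["end"]) // 2
        with np.errstate(divide="ignore"):
            man["neg_log10_p"] = -np.log10(out["p_asymptotic"])
        man["bonferroni_line"] = -np.log10(bon.threshold)
        man["fdr_line"] = (
            -np.log10(fdr.threshold) if fdr.n_selected else np.nan
        )
        write_tsv(f"manhattan_{col}.tsv", man)
        summary_rows.append(
            {
                "phenotype": col,
                "n_genes": len(table),
                "n_bonferroni": bon.n_selected,
                "n_fdr": fdr.n_selected,
            }
        )
        if col in result.sma:
            write_tsv(f"sma_{col}.tsv", result.sma[col])
    write_tsv("summary.tsv", pd.DataFrame(summary_rows))

    if result.enrichment is not None:
        write_tsv("enrichment.tsv", result.enrichment)
        write_tsv(
            f"enrichment_top{result.config.top_k}.tsv",
            rank_pathways(result.enrichment, top_k=result.config.top_k),
        )

    manifest = {
        "package_version": __version__,
        "config_hash": cfg_hash,
        "seed": result.config.seed,
        "versions": {
            "python": sys.version.split()[0],
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "counts": {
            "samples": result.genotypes.n_samples,
            "snps_after_qc": result.genotypes.n_snps,
            "genes_mapped": len(result.gene_map),
            "pathways": len(result.pathways),
            "significant_components": result.n_significant_components,
        },
        "files": {
            name: hashlib.sha256(Path(p).read_bytes()).hexdigest()
            for name, p in paths.items()
        },
    }
    manifest_path = directory / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
    paths["manifest.json"] = manifest_path
    return paths
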