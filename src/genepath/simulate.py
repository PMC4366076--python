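"""Synthetic dairy-cohort generator.

Produces desk-scale cohorts with the statistical structure the analysis
assumes, so every downstream stage is testable without external data:

* **Stratification** — two (or more) breed-like groups whose allele
  frequencies diverge around a shared ancestral frequency under the
  Balding–Nichols model with a single FST parameter.
* **Linkage disequilibrium** — within each gene-sized block, haplotypes
  arise from a latent AR(1)-correlated Gaussian thresholded at the allele
  frequency quantile; two independent haplotypes are summed per animal.
* **Phenotypes** — the linear model ``y = Z theta + X beta + eps`` with
  planted causal SNPs concentrated in chosen genes and a causal pathway,
  realised at three time points (pre-calving T1, early-lactation T2,
  late-lactation T3) so ratio phenotypes are computable.

Everything is deterministic given the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import GeneAnnotation, GenotypeMatrix, PathwayCollection, PhenotypeTable
from . import io as gio

#: per-trait time-point means loosely matching transition-cow metabolite
#: summaries (NEFA on the log scale, BHBA and glucose in mmol/L)
DEFAULT_TRAIT_MEANS = {
    "nefa": (4.27, 5.62, 4.64),
    "bhba": (0.58, 1.35, 0.77),
    "glucose": (3.72, 3.15, 3.70),
}

TIME_POINTS = ("T1", "T2", "T3")


@dataclass
class SimulationConfig:
    """Cohort design: sample sizes, genome layout, effects and noise.

    Effect sizes are expressed in units of ``noise_sd`` (approximately
    phenotype SD units, since the genetic contribution is small).
    ``causal_genes`` is a tuple of ``(gene_index, n_causal_snps,
    per_snp_effect)`` triples.
    """

    n_samples: int = 244
    n_groups: int = 2
    group_sizes: tuple | None = None  # defaults to a 178/66-style split
    fst: float = 0.05
    n_genes: int = 100
    snps_per_gene: tuple = (5, 25)
    intergenic_snps: int = 200
    maf_range: tuple = (0.05, 0.5)
    ld_rho: float = 0.5
    causal_genes: tuple = ()
    causal_pathway_index: int | None = None
    n_pathways: int = 10
    genes_per_pathway: tuple = (5, 15)
    noise_sd: float = 1.0
    covariate_effects: tuple = (0.5, 0.0)  # group, management/study
    traits: tuple = ("nefa", "bhba", "glucose")
    causal_traits: tuple | None = None  # default: all traits
    time_multipliers: tuple = (1.0, 1.0, 1.0)
    trait_means: dict = field(default_factory=lambda: dict(DEFAULT_TRAIT_MEANS))
    missing_rate: float = 0.0
    n_chromosomes: int = 5
    seed: int = 0

    def resolved_group_sizes(self) -> tuple:
        if self.group_sizes is not None:
            return tuple(self.group_sizes)
        if self.n_groups == 2:
            # mirror the 178:66 two-breed split proportionally
            n1 = int(round(self.n_samples * 178 / 244))
            return (n1, self.n_samples - n1)
        base = self.n_samples // self.n_groups
        sizes = [base] * self.n_groups
        for i in range(self.n_samples - base * self.n_groups):
            sizes[i] += 1
        return tuple(sizes)

    def validate(self) -> None:
        if self.n_samples <= 0 or self.n_genes <= 0 or self.n_groups <= 0:
            raise ValueError("counts must be positive")
        sizes = self.resolved_group_sizes()
        if len(sizes) != self.n_groups or any(s <= 0 for s in sizes):
            raise ValueError("group_sizes must give one positive count per group")
        if sum(sizes) != self.n_samples:
            raise ValueError(
                f"group_sizes sum to {sum(sizes)}, expected n_samples={self.n_samples}"
            )
        if not (0 <= self.fst < 1):
            raise ValueError("fst must lie in [0, 1)")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if not (0 <= self.ld_rho < 1):
            raise ValueError("ld_rho must lie in [0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.snps_per_gene[0] < 0 or self.snps_per_gene[0] > self.snps_per_gene[1]:
            raise ValueError("snps_per_gene must be a non-negative (min, max) range")
        for gene_idx, n_causal, _ in self.causal_genes:
            if not (0 <= gene_idx < self.n_genes):
                raise ValueError(f"causal gene index {gene_idx} out of range")
            if n_causal < 1:
                raise ValueError("causal SNP count must be >= 1")
        if self.n_pathways > 0:
            if self.genes_per_pathway[0] < 5:
                raise ValueError("pathways must have at least 5 genes")
            if self.n_pathways * self.genes_per_pathway[0] > self.n_genes:
                raise ValueError("not enough genes to fill all pathways")
            if self.causal_pathway_index is not None and not (
                0 <= self.causal_pathway_index < self.n_pathways
            ):
                raise ValueError("causal_pathway_index out of range")


@dataclass
class TruthRecord:
    """Ground truth planted by the generator."""

    causal_snps: dict  # snp_id -> beta (on the noise_sd scale)
    causal_genes: tuple
    causal_pathway: str | None
    heritable_fraction: float


@dataclass
class SimulatedCohort:
    config: SimulationConfig
    genotypes: GenotypeMatrix
    phenotypes: PhenotypeTable
    genes: GeneAnnotation
    pathways: PathwayCollection
    truth: TruthRecord


# ---------------------------------------------------------------------------
# genome layout

_GENE_SPACING = 50_000  # bp between consecutive gene intervals (> 2x flank)
_SNP_SPACING = 1_000


def _layout(config: SimulationConfig):
    """Deterministic genome layout shared by genotype and annotation builders.

    Returns (snp table without stats, per-gene SNP index arrays, gene table,
    per-block column index lists).  Gene g occupies a block of
    ``snps_per_gene`` SNPs spaced 1 kb apart; intergenic SNPs sit mid-gap,
    more than one flank away from any gene.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    lo, hi = config.snps_per_gene
    gene_sizes = rng.integers(lo, hi + 1, size=config.n_genes)
    genes_per_chrom = int(np.ceil(config.n_genes / config.n_chromosomes))

    records = []  # (snp_id, chrom, pos)
    gene_rows = []
    blocks = []  # column-index groups sharing one latent AR(1) process
    gene_cols = {}
    inter_slots = []  # candidate (chrom, pos) for intergenic SNPs
    col = 0
    for g in range(config.n_genes):
        chrom = str(g // genes_per_chrom + 1)
        slot = g % genes_per_chrom
        start = 100_000 + slot * _GENE_SPACING
        m = int(gene_sizes[g])
        cols = []
        for j in range(m):
            pos = start + j * _SNP_SPACING
            records.append((f"snp_g{g:04d}_{j:03d}", chrom, pos))
            cols.append(col)
            col += 1
        gene_rows.append(
            (f"GENE{g:04d}", chrom, start, start + max(m - 1, 0) * _SNP_SPACING)
        )
        if m:
            blocks.append(cols)
            gene_cols[f"GENE{g:04d}"] = np.array(cols, dtype=int)
        # late-gap slot, > 5 kb from both flanking gene intervals for the
        # default block sizes
        inter_slots.append((chrom, start + 37_000))

    for k in range(config.intergenic_snps):
        chrom, pos = inter_slots[k % len(inter_slots)]
        records.append((f"snp_i{k:04d}", chrom, pos + (k // len(inter_slots)) * 7))
        blocks.append([col])
        col += 1

    snps = pd.DataFrame(records, columns=["snp_id", "chromosome", "position"])
    genes = pd.DataFrame(gene_rows, columns=["gene_id", "chromosome", "start", "end"])
    return snps, gene_cols, genes, blocks, gene_sizes


# ---------------------------------------------------------------------------
# genotypes


def simulate_genotypes(config: SimulationConfig) -> GenotypeMatrix:
    """Draw a stratified, LD-structured dosage matrix.

    Group allele frequencies follow Balding–Nichols around uniform ancestral
    frequencies in ``maf_range``; haplotypes within a gene block come from a
    latent AR(1) Gaussian thresholded at each SNP's frequency quantile.
    Columns are re-oriented afterwards so that dosage counts the realized
    minor allele, matching what the PED/MAP reader reconstructs.
    """
    config.validate()
    snps, _, _, blocks, _ = _layout(config)
    m = len(snps)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    sizes = config.resolved_group_sizes()

    p_anc = rng.uniform(config.maf_range[0], config.maf_range[1], size=m)
    if config.fst > 0:
        f = config.fst
        a = p_anc * (1 - f) / f
        b = (1 - p_anc) * (1 - f) / f
        p_group = np.clip(rng.beta(a[None, :], b[None, :], size=(config.n_groups, m)),
                          1e-3, 1 - 1e-3)
    else:
        p_group = np.tile(p_anc, (config.n_groups, 1))

    dosage = np.empty((config.n_samples, m))
    row = 0
    for g_idx, n_g in enumerate(sizes):
        thresh = stats.norm.ppf(p_group[g_idx])  # allele=1 iff latent < quantile
        for cols in blocks:
            cols = np.asarray(cols)
            k = len(cols)
            eps = rng.standard_normal((2 * n_g, k))
            z = np.empty_like(eps)
            z[:, 0] = eps[:, 0]
            rho = config.ld_rho if k > 1 else 0.0
            scale = np.sqrt(1 - rho**2)
            for j in range(1, k):
                z[:, j] = rho * z[:, j - 1] + scale * eps[:, j]
            hap = (z < thresh[cols]).astype(float)
            dosage[row : row + n_g, cols] = hap[:n_g] + hap[n_g:]
        row += n_g

    if config.missing_rate > 0:
        miss = rng.random(dosage.shape) < config.missing_rate
        dosage[miss] = np.nan

    # orient every column to the realized minor allele (ties untouched)
    with np.errstate(invalid="ignore"):
        freq = np.nanmean(dosage, axis=0) / 2.0
    flip = freq > 0.5
    dosage[:, flip] = 2.0 - dosage[:, flip]

    snps = snps.assign(call_rate=np.nan, maf=np.nan)[
        ["snp_id", "chromosome", "position", "call_rate", "maf"]
    ]
    ids = [f"cow{i:04d}" for i in range(config.n_samples)]
    out = GenotypeMatrix(ids, snps, dosage)
    out.recompute_snp_stats()
    return out


# ---------------------------------------------------------------------------
# phenotypes


def _group_labels(config: SimulationConfig) -> np.ndarray:
    sizes = config.resolved_group_sizes()
    return np.repeat(np.arange(config.n_groups), sizes)


def simulate_phenotypes(genotypes: GenotypeMatrix, config: SimulationConfig):
    """Realize ``y = Z theta + X beta + eps`` at the three time points.

    The genetic term ``X beta`` is shared across time points, scaled by
    ``time_multipliers``; noise is drawn independently per trait and time.
    Returns ``(PhenotypeTable, TruthRecord)``.
    """
    config.validate()
    if genotypes.n_samples != config.n_samples:
        raise ValueError("genotype sample count does not match config")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    _, gene_cols, _, _, _ = _layout(config)

    snp_ids = list(genotypes.snps["snp_id"])
    betas = {}
    causal_gene_ids = []
    for gene_idx, n_causal, effect in config.causal_genes:
        gid = f"GENE{gene_idx:04d}"
        cols = gene_cols.get(gid)
        if cols is None or len(cols) < n_causal:
            raise ValueError(
                f"causal gene {gid} has fewer than {n_causal} SNPs"
            )
        chosen = rng.choice(cols, size=n_causal, replace=False)
        for c in np.sort(chosen):
            sid = snp_ids[c]
            if c >= genotypes.n_snps:
                raise ValueError(f"causal SNP {sid} missing from genotypes")
            betas[sid] = effect * config.noise_sd
        causal_gene_ids.append(gid)

    col_of = genotypes.snp_index()
    genetic = np.zeros(config.n_samples)
    if betas:
        idx = [col_of[s] for s in betas]
        X = genotypes.dosage[:, idx]
        X = np.where(np.isfinite(X), X, np.nanmean(X, axis=0))
        genetic = X @ np.array(list(betas.values()))

    var_g = float(np.var(genetic))
    h2 = var_g / (var_g + config.noise_sd**2)

    group = _group_labels(config)
    study = (rng.random(config.n_samples) < 0.5).astype(int)
    theta_group, theta_mgmt = (tuple(config.covariate_effects) + (0.0, 0.0))[:2]
    fixed = (
        theta_group * config.noise_sd * (group == 0).astype(float)
        + theta_mgmt * config.noise_sd * study
    )

    causal_traits = config.causal_traits or config.traits
    data = {"group": group, "study": study}
    for trait in config.traits:
        means = config.trait_means.get(trait, (0.0, 0.0, 0.0))
        for t_idx, tp in enumerate(TIME_POINTS):
            eps = rng.normal(0.0, config.noise_sd, size=config.n_samples)
            y = means[t_idx] + fixed + eps
            if trait in causal_traits:
                y = y + config.time_multipliers[t_idx] * genetic
            data[f"{trait}_{tp}"] = y

    frame = pd.DataFrame(
        data, index=pd.Index([f"cow{i:04d}" for i in range(config.n_samples)],
                             name="sample_id")
    )
    truth = TruthRecord(
        causal_snps=betas,
        causal_genes=tuple(causal_gene_ids),
        causal_pathway=(
            f"PW{config.causal_pathway_index:03d}"
            if config.causal_pathway_index is not None
            else None
        ),
        heritable_fraction=h2,
    )
    return PhenotypeTable(frame), truth


# ---------------------------------------------------------------------------
# annotations


def build_annotations(genotypes: GenotypeMatrix, config: SimulationConfig):
    """Gene intervals covering each block plus a pathway partition.

    Genes whose block contains no SNP are omitted (a gene must carry at
    least one intragenic SNP).  Pathways partition the emitted genes into
    ``n_pathways`` sets of at least five genes; all causal genes are placed
    into the causal pathway when one is configured.
    """
    config.validate()
    _, gene_cols, gene_table, _, gene_sizes = _layout(config)
    keep = gene_table["gene_id"].isin(gene_cols.keys())
    genes = GeneAnnotation(gene_table[keep].reset_index(drop=True))

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    gene_ids = genes.gene_ids
    pathways = PathwayCollection()
    if config.n_pathways > 0:
        causal_ids = [f"GENE{idx:04d}" for idx, _, _ in config.causal_genes]
        causal_ids = [g for g in causal_ids if g in gene_cols]
        pool = [g for g in gene_ids if g not in causal_ids]
        rng.shuffle(pool)
        lo = config.genes_per_pathway[0]
        sizes = np.full(config.n_pathways, lo)
        extra = len(gene_ids) - sizes.sum()
        hi = config.genes_per_pathway[1]
        # distribute remaining genes round-robin up to the max size, then
        # spill anything left onto the last pathway so the partition covers
        # every gene
        i = 0
        while extra > 0:
            if sizes[i % config.n_pathways] < hi:
                sizes[i % config.n_pathways] += 1
                extra -= 1
            i += 1
            if i > 10 * config.n_pathways * (hi + 1):
                sizes[-1] += extra
                extra = 0
        members = {}
        cursor = 0
        for p in range(config.n_pathways):
            pid = f"PW{p:03d}"
            take = int(sizes[p])
            if config.causal_pathway_index == p:
                chosen = list(causal_ids)
                take = max(take - len(chosen), 0)
            else:
                chosen = []
            chosen += pool[cursor : cursor + take]
            cursor += take
            members[pid] = sorted(chosen)
        # any unassigned leftovers go to the last pathway
        if cursor < len(pool):
            members[f"PW{config.n_pathways - 1:03d}"] = sorted(
                members[f"PW{config.n_pathways - 1:03d}"] + pool[cursor:]
            )
        if config.causal_pathway_index is None and causal_ids:
            # no designated causal pathway: spread causal genes at the end
            members[f"PW{config.n_pathways - 1:03d}"] = sorted(
                members[f"PW{config.n_pathways - 1:03d}"] + causal_ids
            )
        pathways = PathwayCollection(
            members=members,
            descriptions={pid: f"synthetic pathway {pid}" for pid in members},
        )
    return genes, pathways


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Full cohort: genotypes, phenotypes, annotations, ground truth."""
    genotypes = simulate_genotypes(config)
    phenotypes, truth = simulate_phenotypes(genotypes, config)
    genes, pathways = build_annotations(genotypes, config)
    return SimulatedCohort(
        config=config,
        genotypes=genotypes,
        phenotypes=phenotypes,
        genes=genes,
        pathways=pathways,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# persistence


def write_cohort(cohort: SimulatedCohort, directory) -> dict:
    """Write the cohort as PED/MAP + TSV dosage + TSV phenotypes + BED + GMT.

    Returns a dict of logical name -> path.  All files round-trip through
    the readers in :mod:`genepath.io` losslessly.
    """
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "ped": directory / "genotypes.ped",
        "map": directory / "genotypes.map",
        "dosage": directory / "dosage.tsv",
        "phenotypes": directory / "phenotypes.tsv",
        "genes": directory / "genes.bed",
        "pathways": directory / "pathways.gmt",
        "truth": directory / "truth.tsv",
    }
    gio.write_ped_map(cohort.genotypes, directory / "genotypes")
    gio.write_dosage_tsv(cohort.genotypes, paths["dosage"])
    gio.write_phenotypes(cohort.phenotypes, paths["phenotypes"])
    gio.write_gene_bed(cohort.genes, paths["genes"])
    gio.write_gmt(cohort.pathways, paths["pathways"])
    with open(paths["truth"], "w") as fh:
        fh.write("kind\tid\tvalue\n")
        for sid, beta in cohort.truth.causal_snps.items():
            fh.write(f"causal_snp\t{sid}\t{beta:.6g}\n")
        for gid in cohort.truth.causal_genes:
            fh.write(f"causal_gene\t{gid}\t\n")
        if cohort.truth.causal_pathway is not None:
            fh.write(f"causal_pathway\t{cohort.truth.causal_pathway}\t\n")
        fh.write(f"heritable_fraction\t\t{cohort.truth.heritable_fraction:.6g}\n")
    return paths
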