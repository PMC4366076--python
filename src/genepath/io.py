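"""Readers, writers, QC and annotation mapping for cohort files.

Supported formats (all plain text):

* PED/MAP — PLINK text genotypes, one allele pair per SNP.  Dosage is
  re-derived on read as the count of the *minor* allele, computed from the
  data itself; ties at frequency 0.5 count the lexicographically later
  allele so that reading is deterministic.
* TSV dosage — samples x SNPs matrix, header row of SNP ids, first column
  sample id; SNP coordinates come from a sibling MAP file when given.
* BED — gene intervals, 0-based half-open on disk, converted to 1-based
  inclusive in memory.
* GMT — ``pathway_id <TAB> description <TAB> gene ...`` one pathway per line.
* TSV phenotypes — ``sample_id``, ``group``, optional ``study`` and one
  numeric column per trait/time point.

QC follows the conventional inclusive rules: SNPs are kept when
call rate >= 0.95 and MAF >= 0.05; surviving missing calls are filled with
the SNP's modal dosage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (
    RATIO_PAIRS,
    GeneAnnotation,
    GenotypeMatrix,
    PathwayCollection,
    PhenotypeTable,
)

MISSING_ALLELE = "0"


# ---------------------------------------------------------------------------
# genotypes


def _dosage_from_alleles(a1: np.ndarray, a2: np.ndarray, snp_id: str) -> np.ndarray:
    """Minor-allele dosage for one SNP from two allele columns."""
    obs = (a1 != MISSING_ALLELE) & (a2 != MISSING_ALLELE)
    half_missing = (a1 != MISSING_ALLELE) ^ (a2 != MISSING_ALLELE)
    if half_missing.any():
        raise ValueError(f"SNP {snp_id!r}: half-missing genotype call")
    alleles = sorted(set(a1[obs]) | set(a2[obs]))
    if len(alleles) > 2:
        raise ValueError(f"SNP {snp_id!r} is not biallelic: alleles {alleles}")
    dosage = np.full(a1.shape, np.nan)
    if not alleles:
        return dosage
    # count the minor allele; at an exact 0.5 tie count the later-sorting one
    counted = alleles[-1]
    if len(alleles) == 2:
        n_last = (a1[obs] == alleles[1]).sum() + (a2[obs] == alleles[1]).sum()
        if n_last > obs.sum():  # frequency > 0.5
            counted = alleles[0]
    dosage[obs] = (a1[obs] == counted).astype(float) + (a2[obs] == counted).astype(float)
    return dosage


def _read_map(path: Path) -> pd.DataFrame:
    rows = []
    for i, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) < 4:
            raise ValueError(f"{path}:{i}: MAP line has {len(parts)} fields, expected 4")
        rows.append((parts[0], parts[1], int(parts[3])))
    return pd.DataFrame(rows, columns=["chromosome", "snp_id", "position"])


def read_genotypes(path, format: str, map_path=None) -> GenotypeMatrix:
    """Read a genotype matrix.

    Parameters
    ----------
    path
        For ``ped_map``: the PED file or a prefix (``.ped``/``.map`` are
        appended).  For ``tsv_dosage``: the dosage TSV.
    format
        ``"ped_map"`` or ``"tsv_dosage"`` (no sniffing).
    map_path
        Optional MAP file carrying SNP coordinates for ``tsv_dosage``.
    """
    path = Path(path)
    if format == "ped_map":
        ped = path if path.suffix == ".ped" else path.with_suffix(".ped")
        mp = Path(map_path) if map_path else ped.with_suffix(".map")
        snps = _read_map(mp)
        m = len(snps)
        sample_ids = []
        a1 = []
        a2 = []
        for i, line in enumerate(ped.read_text().splitlines(), start=1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 6 + 2 * m:
                raise ValueError(
                    f"{ped}:{i}: {len(parts)} fields, expected {6 + 2 * m} "
                    f"for {m} MAP SNPs"
                )
            sample_ids.append(parts[1])
            a1.append(parts[6::2])
            a2.append(parts[7::2])
        a1 = np.asarray(a1, dtype=object)
        a2 = np.asarray(a2, dtype=object)
        dosage = np.column_stack(
            [
                _dosage_from_alleles(a1[:, j], a2[:, j], snps["snp_id"].iloc[j])
                for j in range(m)
            ]
        ) if m else np.empty((len(sample_ids), 0))
    elif format == "tsv_dosage":
        frame = pd.read_csv(path, sep="\t", index_col=0)
        sample_ids = [str(s) for s in frame.index]
        dosage = frame.to_numpy(dtype=float)
        if map_path is not None:
            snps = _read_map(Path(map_path))
            if list(snps["snp_id"]) != list(frame.columns):
                raise ValueError("MAP SNP order does not match dosage TSV header")
        else:
            snps = pd.DataFrame(
                {
                    "chromosome": "0",
                    "snp_id": list(frame.columns),
                    "position": np.arange(1, frame.shape[1] + 1),
                }
            )
    else:
        raise ValueError(f"unknown genotype format {format!r}")

    snps = snps.assign(call_rate=np.nan, maf=np.nan)[
        ["snp_id", "chromosome", "position", "call_rate", "maf"]
    ]
    g = GenotypeMatrix(sample_ids, snps, dosage)
    g.recompute_snp_stats()
    return g


def write_ped_map(genotypes: GenotypeMatrix, prefix) -> None:
    """Write PLINK text PED/MAP with A/B allele coding (B = counted allele)."""
    prefix = Path(prefix)
    with open(prefix.with_suffix(".map"), "w") as fh:
        for _, s in genotypes.snps.iterrows():
            fh.write(f"{s.chromosome}\t{s.snp_id}\t0\t{int(s.position)}\n")
    codes = {0.0: "A A", 1.0: "A B", 2.0: "B B"}
    with open(prefix.with_suffix(".ped"), "w") as fh:
        for i, sid in enumerate(genotypes.sample_ids):
            row = genotypes.dosage[i]
            geno = " ".join(
                codes[d] if np.isfinite(d) else "0 0" for d in row
            )
            fh.write(f"{sid} {sid} 0 0 0 -9 {geno}\n")


def write_dosage_tsv(genotypes: GenotypeMatrix, path) -> None:
    frame = pd.DataFrame(
        genotypes.dosage,
        index=pd.Index(genotypes.sample_ids, name="sample_id"),
        columns=list(genotypes.snps["snp_id"]),
    )
    frame.to_csv(path, sep="\t", float_format="%g")


# ---------------------------------------------------------------------------
# QC


@dataclass
class QcReport:
    n_input: int
    n_removed_call_rate: int
    n_removed_maf: int
    n_imputed: int

    @property
    def n_kept(self) -> int:
        return self.n_input - self.n_removed_call_rate - self.n_removed_maf


def qc_filter(
    genotypes: GenotypeMatrix,
    min_call_rate: float = 0.95,
    min_maf: float = 0.05,
    impute: bool = True,
):
    """Drop SNPs failing call-rate/MAF thresholds; mode-impute the rest.

    Thresholds are inclusive: call rate >= ``min_call_rate`` and
    MAF >= ``min_maf`` are kept.  Returns ``(filtered, QcReport)``.
    """
    if not (0 <= min_call_rate <= 1 and 0 <= min_maf <= 1):
        raise ValueError("QC thresholds must lie in [0, 1]")
    genotypes.recompute_snp_stats()
    cr = genotypes.snps["call_rate"].to_numpy()
    maf = genotypes.snps["maf"].to_numpy()
    fail_cr = cr < min_call_rate
    fail_maf = ~fail_cr & (np.isnan(maf) | (maf < min_maf))
    keep = ~(fail_cr | fail_maf)
    report = QcReport(
        n_input=genotypes.n_snps,
        n_removed_call_rate=int(fail_cr.sum()),
        n_removed_maf=int(fail_maf.sum()),
        n_imputed=0,
    )
    if not keep.any():
        warnings.warn("QC removed every SNP; returning an empty matrix")
    out = genotypes.subset_snps(np.flatnonzero(keep))
    if impute:
        miss = ~np.isfinite(out.dosage)
        report.n_imputed = int(miss.sum())
        if report.n_imputed:
            for j in np.flatnonzero(miss.any(axis=0)):
                col = out.dosage[:, j]
                obs = col[np.isfinite(col)]
                # modal dosage; ties -> smaller dosage value
                vals, counts = np.unique(obs, return_counts=True)
                mode = vals[np.argmax(counts)]
                col[~np.isfinite(col)] = mode
        out.recompute_snp_stats()
    return out, report


# ---------------------------------------------------------------------------
# gene / pathway annotation


def read_gene_bed(path) -> GeneAnnotation:
    """Read gene intervals from BED (0-based half-open -> 1-based inclusive)."""
    rows = []
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t")
        if len(parts) < 4:
            raise ValueError(f"{path}:{i}: BED line needs chrom,start,end,name")
        chrom, start0, end0, name = parts[0], int(parts[1]), int(parts[2]), parts[3]
        rows.append((name, chrom, start0 + 1, end0))
    return GeneAnnotation(
        pd.DataFrame(rows, columns=["gene_id", "chromosome", "start", "end"])
    )


def write_gene_bed(genes: GeneAnnotation, path) -> None:
    with open(path, "w") as fh:
        for _, g in genes.table.iterrows():
            fh.write(f"{g.chromosome}\t{g.start - 1}\t{g.end}\t{g.gene_id}\n")


def map_snps_to_genes(
    genotypes: GenotypeMatrix, genes: GeneAnnotation, flank: int = 5000
) -> dict:
    """Assign SNPs to genes within ``flank`` bp of the gene interval.

    A SNP belongs to gene G iff its position lies in
    ``[start - flank, end + flank]`` on the same chromosome; SNPs may be
    assigned to several overlapping genes.  Genes with no assigned SNP are
    dropped.  Returns ``{gene_id: array of SNP column indices}`` with genes
    in chromosome/start order.
    """
    by_chrom = {}
    for chrom, sub in genotypes.snps.groupby("chromosome", sort=False):
        pos = sub["position"].to_numpy()
        order = np.argsort(pos, kind="stable")
        by_chrom[chrom] = (pos[order], sub.index.to_numpy()[order])
    mapping = {}
    table = genes.table.sort_values(["chromosome", "start"], kind="stable")
    for _, g in table.iterrows():
        if g.chromosome not in by_chrom:
            continue
        pos, idx = by_chrom[g.chromosome]
        lo = np.searchsorted(pos, g.start - flank, side="left")
        hi = np.searchsorted(pos, g.end + flank, side="right")
        if hi > lo:
            mapping[g.gene_id] = np.sort(idx[lo:hi])
    return mapping


def read_pathways(path_gmt, genes: GeneAnnotation | None = None, min_genes: int = 5):
    """Read a GMT file; keep pathways with >= ``min_genes`` annotated members."""
    members = {}
    descriptions = {}
    for i, line in enumerate(Path(path_gmt).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path_gmt}:{i}: GMT line needs id, description, genes")
        pid = parts[0]
        if pid in members:
            raise ValueError(f"{path_gmt}:{i}: duplicate pathway id {pid!r}")
        members[pid] = [g for g in parts[2:] if g]
        descriptions[pid] = parts[1]
    collection = PathwayCollection(members=members, descriptions=descriptions)
    if not members:
        warnings.warn("empty GMT file: no pathways read")
        return collection
    if genes is not None:
        collection = collection.restrict(genes.gene_ids, min_genes=min_genes)
    return collection


def write_gmt(pathways: PathwayCollection, path) -> None:
    with open(path, "w") as fh:
        for pid, genes in pathways.members.items():
            desc = pathways.descriptions.get(pid, "")
            fh.write("\t".join([pid, desc, *genes]) + "\n")


# ---------------------------------------------------------------------------
# phenotypes


def read_phenotypes(path) -> PhenotypeTable:
    """Read the TSV phenotype table (sample_id, group[, study], traits...)."""
    frame = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in frame.columns:
        raise ValueError("phenotype table needs a 'sample_id' column")
    dup = frame["sample_id"].duplicated()
    if dup.any():
        raise ValueError(f"duplicated sample id: {frame['sample_id'][dup].iloc[0]!r}")
    frame = frame.set_index("sample_id")
    for col in frame.columns:
        if col in PhenotypeTable.META_COLUMNS:
            continue
        coerced = pd.to_numeric(frame[col], errors="coerce")
        bad = coerced.isna() & frame[col].notna() & (frame[col].astype(str).str.strip() != "")
        if bad.any():
            row = frame.index[bad][0]
            raise ValueError(f"non-numeric value in column {col!r}, sample {row!r}")
        frame[col] = coerced
    return PhenotypeTable(frame)


def write_phenotypes(table: PhenotypeTable, path) -> None:
    table.frame.to_csv(path, sep="\t", index_label="sample_id")


def compute_ratio_phenotypes(
    table: PhenotypeTable,
    traits=None,
    log_scale_traits=(),
    log_ratio: bool = False,
) -> PhenotypeTable:
    """Add between-time-point ratio phenotypes (T2/T1, T3/T1, T3/T2).

    Ratios are later-time over earlier-time concentration on the raw scale.
    For traits measured on the log scale the stored single-time values are
    log concentrations, so the raw-scale ratio is ``exp(later - earlier)``;
    with ``log_ratio=True`` the log-difference itself is stored instead.
    Samples with a zero or negative denominator are excluded from that
    ratio with a warning.
    """
    frame = table.frame.copy()
    if traits is None:
        traits = sorted(
            {
                c.rsplit("_", 1)[0]
                for c in table.trait_columns
                if c.rsplit("_", 1)[-1] in ("T1", "T2", "T3") and "_over_" not in c
            }
        )
    for trait in traits:
        for later, earlier in RATIO_PAIRS:
            num_col, den_col = f"{trait}_{later}", f"{trait}_{earlier}"
            if num_col not in frame.columns or den_col not in frame.columns:
                continue
            num = frame[num_col].astype(float)
            den = frame[den_col].astype(float)
            if trait in log_scale_traits:
                diff = num - den
                ratio = diff if log_ratio else np.exp(diff)
            else:
                bad = den <= 0
                if bad.any():
                    n = int((bad & num.notna()).sum())
                    if n:
                        warnings.warn(
                            f"{trait} {later}/{earlier}: excluded {n} samples "
                            f"with non-positive denominator"
                        )
                ratio = num / den.where(~bad)
            frame[f"{trait}_{later}_over_{earlier}"] = ratio
    return PhenotypeTable(frame)
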