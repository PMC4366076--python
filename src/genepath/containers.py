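"""In-memory containers shared across the pipeline.

Genotypes are held as a dense samples x SNPs dosage matrix with values in
{0, 1, 2} (count of the minor allele) and NaN for missing calls.  Phenotypes
are a plain :class:`pandas.DataFrame` wrapper with one column per
trait/time-point combination.  Gene and pathway annotations are small
metadata tables; the SNP-to-gene mapping itself is computed on demand
(see :func:`genepath.io.map_snps_to_genes`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SNP_COLUMNS = ("snp_id", "chromosome", "position", "call_rate", "maf")

RATIO_PAIRS = (("T2", "T1"), ("T3", "T1"), ("T3", "T2"))


class GenotypeMatrix:
    """Samples x SNPs dosage matrix plus per-SNP metadata.

    Parameters
    ----------
    sample_ids
        Sample labels, one per row of ``dosage``.
    snps
        Per-SNP metadata with columns ``snp_id, chromosome, position,
        call_rate, maf`` (1-based positions).  Row order matches the
        columns of ``dosage``.
    dosage
        Float array of shape ``(n_samples, n_snps)`` with values in
        {0, 1, 2} and NaN for missing genotypes.
    """

    def __init__(self, sample_ids, snps: pd.DataFrame, dosage: np.ndarray):
        dosage = np.asarray(dosage, dtype=float)
        sample_ids = list(sample_ids)
        if dosage.ndim != 2:
            raise ValueError("dosage must be a 2-D samples x SNPs array")
        if dosage.shape[0] != len(sample_ids):
            raise ValueError(
                f"dosage has {dosage.shape[0]} rows but {len(sample_ids)} sample ids"
            )
        if dosage.shape[1] != len(snps):
            raise ValueError(
                f"dosage has {dosage.shape[1]} columns but {len(snps)} SNP records"
            )
        missing = [c for c in SNP_COLUMNS if c not in snps.columns]
        if missing:
            raise ValueError(f"snps table lacks columns: {missing}")
        finite = dosage[np.isfinite(dosage)]
        if finite.size and not np.isin(finite, (0.0, 1.0, 2.0)).all():
            raise ValueError("dosage values must be in {0, 1, 2} or NaN")
        self.sample_ids = sample_ids
        self.snps = snps.reset_index(drop=True)
        self.dosage = dosage

    @property
    def n_samples(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosage.shape[1]

    def snp_index(self) -> dict:
        """Map snp_id -> column index."""
        return {s: i for i, s in enumerate(self.snps["snp_id"])}

    def subset_snps(self, cols) -> "GenotypeMatrix":
        cols = np.asarray(cols)
        return GenotypeMatrix(
            self.sample_ids,
            self.snps.iloc[cols].reset_index(drop=True),
            self.dosage[:, cols],
        )

    def subset_samples(self, rows) -> "GenotypeMatrix":
        rows = np.asarray(rows)
        ids = [self.sample_ids[i] for i in rows]
        return GenotypeMatrix(ids, self.snps.copy(), self.dosage[rows, :])

    def recompute_snp_stats(self) -> None:
        """Refresh per-SNP call rate and minor-allele frequency in place."""
        d = self.dosage
        obs = np.isfinite(d)
        n_obs = obs.sum(axis=0)
        with np.errstate(invalid="ignore"):
            freq = np.nansum(d, axis=0) / (2.0 * np.maximum(n_obs, 1))
        maf = np.minimum(freq, 1.0 - freq)
        maf[n_obs == 0] = np.nan
        self.snps = self.snps.assign(call_rate=n_obs / d.shape[0], maf=maf)

    def __repr__(self) -> str:  # pragma: no cover
        return f"GenotypeMatrix({self.n_samples} samples x {self.n_snps} SNPs)"


class PhenotypeTable:
    """Per-sample trait values at time points T1/T2/T3 plus ratio phenotypes.

    The underlying frame is indexed by sample id and carries a ``group``
    column (0/1 subgroup label), an optional ``study`` column (0/1 study
    origin) and one numeric column per trait/time combination, named
    ``<trait>_<time>`` (e.g. ``nefa_T2``).  Ratio phenotypes use
    ``<trait>_<later>_over_<earlier>``.
    """

    META_COLUMNS = ("group", "study")

    def __init__(self, frame: pd.DataFrame):
        if frame.index.has_duplicates:
            dup = frame.index[frame.index.duplicated()][0]
            raise ValueError(f"duplicated sample id: {dup!r}")
        self.frame = frame

    @property
    def sample_ids(self):
        return list(self.frame.index)

    @property
    def trait_columns(self):
        return [c for c in self.frame.columns if c not in self.META_COLUMNS]

    def analysis_set(self, column: str):
        """Non-missing samples for one phenotype column.

        Returns (boolean mask over rows, float values of the retained rows).
        Missing-phenotype exclusion is per column, not global.
        """
        if column not in self.frame.columns:
            raise KeyError(f"unknown phenotype column {column!r}")
        vals = pd.to_numeric(self.frame[column], errors="coerce")
        mask = vals.notna().to_numpy()
        return mask, vals.to_numpy()[mask]

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"PhenotypeTable({len(self.frame)} samples, "
            f"{len(self.trait_columns)} phenotype columns)"
        )


@dataclass
class GeneAnnotation:
    """Gene intervals (1-based, inclusive) on named chromosomes."""

    table: pd.DataFrame  # gene_id, chromosome, start, end

    def __post_init__(self):
        need = {"gene_id", "chromosome", "start", "end"}
        missing = need - set(self.table.columns)
        if missing:
            raise ValueError(f"gene table lacks columns: {sorted(missing)}")
        bad = self.table["start"] > self.table["end"]
        if bad.any():
            g = self.table.loc[bad, "gene_id"].iloc[0]
            raise ValueError(f"gene {g!r} has start > end")
        self.table = self.table.reset_index(drop=True)

    @property
    def gene_ids(self):
        return list(self.table["gene_id"])

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class PathwayCollection:
    """Pathway id -> member gene ids, with free-text descriptions."""

    members: dict = field(default_factory=dict)
    descriptions: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.members)

    def restrict(self, gene_universe, min_genes: int = 5) -> "PathwayCollection":
        """Intersect memberships with a gene universe, drop small pathways."""
        universe = set(gene_universe)
        members = {}
        for pid, genes in self.members.items():
            kept = [g for g in genes if g in universe]
            if len(kept) >= min_genes:
                members[pid] = kept
        desc = {pid: self.descriptions.get(pid, "") for pid in members}
        return PathwayCollection(members=members, descriptions=desc)
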