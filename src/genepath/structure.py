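"""Population-stratification correction.

Genotype PCA with binomial standardization, a Tracy-Widom test counting
the significant leading components, and construction of the covariate
matrix Z used by the association models.

The covariate matrix follows the two-breed-group design: an intercept, a
0/1 subgroup indicator, and principal components computed *within* the
large subgroup, zero-padded for animals outside it.  Two variants exist:

* ``Z``  = (1, I_G1, PC2 ... PCk)           -- the default,
* ``Z*`` = (1, I_E, I_G1, PC1, PC2 ... PCk) -- adds a study-origin
  indicator and the first component.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .containers import GenotypeMatrix

#: Chiani's shifted-gamma fit to the Tracy-Widom GOE (beta=1) distribution:
#: TW1 ~ Gamma(k, theta) - alpha.  Accurate to ~1e-3 in the CDF over the
#: whole support, including the upper tail used here.
_TW1_GAMMA_K = 46.44604884387132
_TW1_GAMMA_THETA = 0.18605402228279347
_TW1_GAMMA_ALPHA = 9.848007781128567


def tw1_sf(x: float) -> float:
    """Upper tail of the Tracy-Widom (GOE) distribution."""
    return float(stats.gamma.sf(x + _TW1_GAMMA_ALPHA, _TW1_GAMMA_K,
                                scale=_TW1_GAMMA_THETA))


@dataclass
class PcaResult:
    """Eigenvalues (descending), per-sample component scores, bookkeeping."""

    eigenvalues: np.ndarray
    scores: np.ndarray  # len(sample_rows) x n_components
    variance_fraction: np.ndarray
    sample_rows: np.ndarray  # row indices (into the cohort) the PCA used
    n_skipped_snps: int


def genotype_pca(genotypes: GenotypeMatrix, sample_subset=None) -> PcaResult:
    """PCA of binomially standardized genotypes.

    Each SNP column is mean-centered and scaled by sqrt(p(1-p)) of its
    allele frequency; eigenvalues are those of the sample covariance of the
    standardized matrix (normalized by the SNP count).  Zero-variance SNPs
    are skipped and counted.  Component signs are fixed by making each
    component's largest-magnitude loading positive.
    """
    if sample_subset is None:
        rows = np.arange(genotypes.n_samples)
    else:
        rows = np.asarray(sample_subset)
        if rows.dtype == bool:
            rows = np.flatnonzero(rows)
    if len(rows) < 2:
        raise ValueError("PCA needs at least two samples")
    d = genotypes.dosage[rows, :]
    d = np.where(np.isfinite(d), d, np.nan)
    mean = np.nanmean(d, axis=0)
    p_hat = mean / 2.0
    sd = np.sqrt(p_hat * (1.0 - p_hat))
    ok = sd > 0
    n_skipped = int((~ok).sum())
    if ok.sum() < 2:
        raise ValueError("PCA needs at least two polymorphic SNPs")
    x = (d[:, ok] - mean[ok]) / sd[ok]
    x = np.where(np.isfinite(x), x, 0.0)  # residual missing -> mean

    m_snps = x.shape[1]
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    eig = s**2 / m_snps
    # sign convention: largest-|loading| entry of each component positive
    for k in range(vt.shape[0]):
        j = np.argmax(np.abs(vt[k]))
        if vt[k, j] < 0:
            vt[k] *= -1
            u[:, k] *= -1
    scores = u * s
    # trailing zero eigenvalue from centering is kept out of the spectrum
    keep = eig > 1e-12 * max(eig[0], 1.0)
    return PcaResult(
        eigenvalues=eig[keep],
        scores=scores[:, keep],
        variance_fraction=eig[keep] / eig.sum(),
        sample_rows=rows,
        n_skipped_snps=n_skipped,
    )


def tracy_widom_count(pca: PcaResult, alpha: float = 0.01, max_components=None) -> int:
    """Count significant leading principal components.

    Sequential top-down testing in the Patterson style: at each step the
    leading remaining eigenvalue is normalized using centering/scaling
    constants built from an effective marker number estimated from the
    remaining spectrum, and compared with the Tracy-Widom (GOE) upper-tail
    quantile at ``alpha``.  Testing stops at the first non-significant
    component.
    """
    eig = np.asarray(pca.eigenvalues, dtype=float)
    eig = eig[eig > 0]
    limit = len(eig) - 1 if max_components is None else min(max_components, len(eig) - 1)
    count = 0
    for k in range(max(limit, 0)):
        lam = eig[k:]
        p = len(lam)
        if p < 3:
            break
        s1 = lam.sum()
        s2 = (lam**2).sum()
        denom = p * s2 - s1**2
        if denom <= 0:
            break
        # effective marker number from the first two spectral moments; the
        # moment identities are those of a Wishart with p variables, so the
        # estimator is unbiased for independent markers in either aspect
        # ratio regime
        n_eff = ((p + 2) * s1**2) / denom
        if n_eff <= 1:
            break
        ell = p * lam[0] / s1
        nsq = np.sqrt(n_eff - 1)
        psq = np.sqrt(p)
        mu = (nsq + psq) ** 2 / n_eff
        sigma = (nsq + psq) / n_eff * (1.0 / nsq + 1.0 / psq) ** (1.0 / 3.0)
        x = (ell - mu) / sigma
        if tw1_sf(x) <= alpha:
            count += 1
        else:
            break
    return count


@dataclass
class CovariateMatrix:
    """Labeled covariate matrix Z with an intercept first column."""

    columns: list
    values: np.ndarray  # n_samples x n_columns
    n_components: int

    def __post_init__(self):
        if not np.allclose(self.values[:, 0], 1.0):
            raise ValueError("first covariate column must be the intercept")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]


def build_covariate_matrix(
    n_samples: int,
    group_indicator,
    pca: PcaResult | None = None,
    n_components: int = 0,
    drop_first_component: bool = True,
    include_study_indicator: bool = False,
    study_indicator=None,
) -> CovariateMatrix:
    """Assemble Z (or Z*) from the group split and subgroup PCA.

    Component columns carry the subgroup scores and exact zeros for samples
    outside the subgroup the PCA was run on.  With
    ``drop_first_component=True`` components 2..n_components enter (the
    default Z); ``include_study_indicator=True`` adds the study-origin
    column and component 1 (the Z* variant).
    """
    group = np.asarray(group_indicator, dtype=float)
    if group.shape != (n_samples,):
        raise ValueError("group_indicator must have one entry per sample")
    cols = [np.ones(n_samples)]
    labels = ["intercept"]
    if include_study_indicator:
        if study_indicator is None:
            raise ValueError("study indicator requested but not provided")
        cols.append(np.asarray(study_indicator, dtype=float))
        labels.append("I_E")
    cols.append(group)
    labels.append("I_G1")

    if n_components > 0:
        if pca is None:
            raise ValueError("n_components > 0 requires a PcaResult")
        avail = pca.scores.shape[1]
        first = 1 if (drop_first_component and not include_study_indicator) else 0
        for k in range(first, min(n_components, avail)):
            col = np.zeros(n_samples)
            col[pca.sample_rows] = pca.scores[:, k]
            cols.append(col)
            labels.append(f"PC{k + 1}")

    values = np.column_stack(cols)
    rank = np.linalg.matrix_rank(values)
    if rank < values.shape[1]:
        # name the columns involved in the collinearity via QR pivoting
        _, r = np.linalg.qr(values)
        bad = [labels[j] for j in range(values.shape[1])
               if abs(r[j, j]) < 1e-8 * abs(r[0, 0])] if r.shape[0] >= values.shape[1] else labels
        raise ValueError(f"covariate matrix is rank deficient; check columns {bad}")
    return CovariateMatrix(columns=labels, values=values,
                           n_components=max(n_components, 0))
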