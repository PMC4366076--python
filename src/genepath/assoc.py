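"""Gene-based and single-marker association testing.

The gene-based score test (GBST) tests H0: beta = 0 in the linear model
``y = Z theta + X beta + eps`` for the ``m`` SNPs of one gene jointly,
using the sum-of-squared-score statistic

    U   = X^t (y - P_Z y) / sigma_hat,
    C   = (X - P_Z X)^t (X - P_Z X),
    SSU = U^t Diag(C)^{-1} U,

where ``P_Z`` is the hat matrix of the covariates and ``sigma_hat`` the
maximum-likelihood scale under H0.  Under H0, SSU is approximately a
weighted sum of independent chi-square(1) variables with weights given by
the eigenvalues of ``Diag(C)^{-1/2} C Diag(C)^{-1/2}``; p-values come from
a three-cumulant chi-square match, with a phenotype-permutation estimate
available as the exact-by-construction alternative.

The single-marker analysis (SMA) is the same linear model with one SNP at
a time and a two-sided t-test on the SNP coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .structure import CovariateMatrix

_DEGENERATE_DIAG = 1e-10


def _as_matrix(Z) -> np.ndarray:
    if isinstance(Z, CovariateMatrix):
        return Z.values
    return np.asarray(Z, dtype=float)


def _orthonormal_basis(Z: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the column space of Z (rank-revealing)."""
    q, r = np.linalg.qr(Z)
    diag = np.abs(np.diag(r))
    keep = diag > 1e-10 * max(diag.max(), 1.0)
    if not keep.all():
        # re-orthogonalize without the dependent columns
        q, _ = np.linalg.qr(Z[:, keep])
    return q


@dataclass
class ProjectionFit:
    """Covariate projection of a phenotype: residuals and ML scale."""

    residuals: np.ndarray  # y - P_Z y
    sigma2: float  # ML estimate of sigma^2 under H0 (divides by n)
    n: int
    rank: int  # column rank of Z (k+1)
    basis: np.ndarray  # orthonormal basis Q of span(Z)

    @property
    def sigma(self) -> float:
        return float(np.sqrt(self.sigma2))


def project_out_covariates(y, Z) -> ProjectionFit:
    """Project the covariates out of ``y``; estimate the H0 scale.

    ``sigma2 = ||y - P_Z y||^2 / n`` (maximum likelihood, not REML).  The
    projection is applied through an orthogonal decomposition of Z, never
    via an explicit inverse of ``Z^t Z``.
    """
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("phenotype vector contains non-finite values")
    Zm = _as_matrix(Z)
    if Zm.shape[0] != y.shape[0]:
        raise ValueError("phenotype and covariate sample sizes differ")
    q = _orthonormal_basis(Zm)
    if y.shape[0] <= q.shape[1]:
        raise ValueError("need more samples than covariate rank")
    resid = y - q @ (q.T @ y)
    sigma2 = float(resid @ resid) / y.shape[0]
    if sigma2 <= 1e-12 * max(float(y @ y) / y.shape[0], 1.0):
        raise ValueError("phenotype lies in the covariate span (sigma_hat = 0)")
    return ProjectionFit(residuals=resid, sigma2=sigma2, n=y.shape[0],
                         rank=q.shape[1], basis=q)


def chi2_quadform_pvalue(q: float, lambdas) -> float:
    """Upper-tail p for a weighted chi-square sum via cumulant matching.

    Matches the first three cumulants ``c_k = sum(lambda_i^k)`` of
    ``sum lambda_i z_i^2`` to a shifted, scaled chi-square: with
    ``a = c3/c2``, ``b = c1 - c2^2/c3``, ``d = c2^3/c3^2`` the p-value is
    the chi-square(d) upper tail at ``(q - b)/a``.  When the third cumulant
    vanishes the two-moment Satterthwaite match (scale ``c2/c1``, df
    ``c1^2/c2``) is used instead.
    """
    lam = np.asarray(lambdas, dtype=float)
    if lam.size == 0:
        raise ValueError("empty eigenvalue list")
    if q < 0:
        raise ValueError("quadratic-form statistic must be non-negative")
    c1 = lam.sum()
    c2 = (lam**2).sum()
    c3 = (lam**3).sum()
    if c2 <= 0:
        raise ValueError("eigenvalues must not all be zero")
    if c3 <= 1e-12:
        p = stats.chi2.sf(q / (c2 / c1), c1**2 / c2)
    else:
        a = c3 / c2
        b = c1 - c2**2 / c3
        d = c2**3 / c3**2
        p = stats.chi2.sf((q - b) / a, d)
    return float(min(max(p, 0.0), 1.0))


@dataclass
class GeneTestResult:
    gene_id: str
    m: int  # SNPs retained
    n_dropped: int  # degenerate columns removed
    u: np.ndarray
    c_diag: np.ndarray
    ssu: float
    lambdas: np.ndarray
    c1: float
    c2: float
    c3: float
    p_asymptotic: float | None
    p_permutation: float | None = None
    note: str = ""


def ssu_test(fit: ProjectionFit, X, gene_id: str = "") -> GeneTestResult:
    """SSU score test for one gene's genotype block.

    SNP columns that are constant after covariate projection
    (``C_ii <= 1e-10``) are dropped before inverting the diagonal; their
    count is recorded.  If every column is degenerate the p-value is
    missing with a reason code.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 1 and fit.n > 1:
        X = X.T
    if X.shape[0] != fit.n:
        raise ValueError("genotype block and projection fit sample sizes differ")
    q = fit.basis
    Xp = X - q @ (q.T @ X)
    C = Xp.T @ Xp
    diag = np.diag(C).copy()
    keep = diag > _DEGENERATE_DIAG
    n_dropped = int((~keep).sum())
    if not keep.any():
        return GeneTestResult(
            gene_id=gene_id, m=0, n_dropped=n_dropped,
            u=np.empty(0), c_diag=np.empty(0), ssu=np.nan,
            lambdas=np.empty(0), c1=np.nan, c2=np.nan, c3=np.nan,
            p_asymptotic=None, note="all SNP columns degenerate after projection",
        )
    # X^t r equals Xp^t r because the residuals are orthogonal to span(Z)
    u = (Xp[:, keep].T @ fit.residuals) / fit.sigma
    d = diag[keep]
    ssu = float(np.sum(u**2 / d))
    scale = 1.0 / np.sqrt(d)
    R = C[np.ix_(keep, keep)] * scale[:, None] * scale[None, :]
    lam = np.clip(np.linalg.eigvalsh(R), 0.0, None)[::-1]
    c1, c2, c3 = lam.sum(), (lam**2).sum(), (lam**3).sum()
    p = chi2_quadform_pvalue(ssu, lam)
    return GeneTestResult(
        gene_id=gene_id, m=int(keep.sum()), n_dropped=n_dropped,
        u=u, c_diag=d, ssu=ssu, lambdas=lam,
        c1=float(c1), c2=float(c2), c3=float(c3), p_asymptotic=p,
    )


def ssu_permutation_pvalue(
    y, X, Z, n_perm: int = 1000, seed: int = 0,
    residual_permutation: bool = False,
) -> float:
    """Permutation p-value for the SSU statistic of one gene.

    Phenotype entries are permuted uniformly; the projection, score vector
    and SSU are recomputed per permutation (the projected genotype
    covariance does not depend on y and is reused).  Returns the
    bias-corrected estimate ``(1 + #{SSU_perm >= SSU_obs}) / (1 + n_perm)``.
    With ``residual_permutation=True`` the covariate-adjusted residuals are
    permuted instead of the raw phenotypes.
    """
    if n_perm < 100:
        raise ValueError("use at least 100 permutations")
    y = np.asarray(y, dtype=float)
    fit = project_out_covariates(y, Z)
    obs = ssu_test(fit, X)
    if obs.p_asymptotic is None:
        return float("nan")
    q = fit.basis
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 1 and fit.n > 1:
        X = X.T
    Xp = X - q @ (q.T @ X)
    diag = np.einsum("ij,ij->j", Xp, Xp)
    keep = diag > _DEGENERATE_DIAG
    Xp = Xp[:, keep]
    d = diag[keep]
    base = fit.residuals if residual_permutation else y
    rng = np.random.default_rng(seed)
    n_ge = 0
    n = fit.n
    for _ in range(n_perm):
        yp = base[rng.permutation(n)]
        r = yp - q @ (q.T @ yp)
        sigma2 = (r @ r) / n
        u2 = (Xp.T @ r) ** 2 / sigma2
        if float(np.sum(u2 / d)) >= obs.ssu - 1e-12:
            n_ge += 1
    return (1 + n_ge) / (1 + n_perm)


# ---------------------------------------------------------------------------
# cohort-level engines


class GbstEngine:
    """Precomputed per-gene quantities for fast repeated GBST evaluation.

    The projected genotype covariance ``C`` of every gene is invariant
    under phenotype permutation, so its diagonal and eigenvalues are
    computed once; evaluating all gene p-values for a (permuted) phenotype
    then costs one projection and one matrix product.
    """

    def __init__(self, dosage: np.ndarray, gene_map: dict, Z):
        Zm = _as_matrix(Z)
        self.q = _orthonormal_basis(Zm)
        self.n = dosage.shape[0]
        if self.n != Zm.shape[0]:
            raise ValueError("dosage and covariate sample sizes differ")
        X = np.asarray(dosage, dtype=float)
        if not np.all(np.isfinite(X)):
            raise ValueError("dosage must be imputed before association testing")
        self.Xp = X - self.q @ (self.q.T @ X)
        self.gene_ids = []
        self.gene_cols = []  # retained column indices per gene
        self.gene_diag = []
        self.gene_abd = []  # (a, b, d) chi-square match constants
        self.gene_dropped = []
        for gid, cols in gene_map.items():
            cols = np.asarray(cols, dtype=int)
            Xg = self.Xp[:, cols]
            C = Xg.T @ Xg
            diag = np.diag(C).copy()
            keep = diag > _DEGENERATE_DIAG
            self.gene_ids.append(gid)
            self.gene_dropped.append(int((~keep).sum()))
            if not keep.any():
                self.gene_cols.append(cols[:0])
                self.gene_diag.append(diag[:0])
                self.gene_abd.append(None)
                continue
            d = diag[keep]
            scale = 1.0 / np.sqrt(d)
            R = C[np.ix_(keep, keep)] * scale[:, None] * scale[None, :]
            lam = np.clip(np.linalg.eigvalsh(R), 0.0, None)
            c1, c2, c3 = lam.sum(), (lam**2).sum(), (lam**3).sum()
            if c3 <= 1e-12:
                abd = (c2 / c1, 0.0, c1**2 / c2)
            else:
                abd = (c3 / c2, c1 - c2**2 / c3, c2**3 / c3**2)
            self.gene_cols.append(cols[keep])
            self.gene_diag.append(d)
            self.gene_abd.append(abd)

    def statistics(self, y: np.ndarray):
        """(SSU, asymptotic p) per gene for one phenotype vector."""
        y = np.asarray(y, dtype=float)
        r = y - self.q @ (self.q.T @ y)
        sigma2 = (r @ r) / self.n
        if sigma2 <= 0:
            raise ValueError("phenotype lies in the covariate span")
        scores = (self.Xp.T @ r) ** 2 / sigma2
        ssu = np.full(len(self.gene_ids), np.nan)
        pvals = np.full(len(self.gene_ids), np.nan)
        for i, (cols, diag, abd) in enumerate(
            zip(self.gene_cols, self.gene_diag, self.gene_abd)
        ):
            if abd is None:
                continue
            s = float(np.sum(scores[cols] / diag))
            a, b, dof = abd
            ssu[i] = s
            pvals[i] = stats.chi2.sf((s - b) / a, dof)
        return ssu, np.clip(pvals, 0.0, 1.0)


def run_gbst(
    genotypes, gene_map: dict, y, Z,
    genes=None, n_perm: int = 0, seed: int = 0,
) -> pd.DataFrame:
    """GBST over all mapped genes; one row per gene with >= 1 retained SNP.

    Rows are ordered by chromosome then gene start position.  Per-gene
    failures (all columns degenerate) are recorded with a missing p-value
    and the run continues.  ``n_perm > 0`` adds permutation p-values.
    """
    from .containers import GenotypeMatrix

    dosage = genotypes.dosage if isinstance(genotypes, GenotypeMatrix) else np.asarray(genotypes)
    engine = GbstEngine(dosage, gene_map, Z)
    y = np.asarray(y, dtype=float)
    ssu, pvals = engine.statistics(y)
    rows = []
    meta = None
    if genes is not None:
        meta = genes.table.set_index("gene_id")
    for i, gid in enumerate(engine.gene_ids):
        chrom, start, end = "", -1, -1
        if meta is not None and gid in meta.index:
            chrom = meta.loc[gid, "chromosome"]
            start = int(meta.loc[gid, "start"])
            end = int(meta.loc[gid, "end"])
        rows.append(
            {
                "gene_id": gid,
                "chromosome": chrom,
                "start": start,
                "end": end,
                "n_snps": len(engine.gene_cols[i]),
                "n_dropped": engine.gene_dropped[i],
                "ssu": ssu[i],
                "p_asymptotic": pvals[i] if np.isfinite(pvals[i]) else np.nan,
            }
        )
    out = pd.DataFrame(rows)
    if n_perm > 0:
        perms = []
        for i, gid in enumerate(engine.gene_ids):
            cols = engine.gene_cols[i]
            if len(cols) == 0:
                perms.append(np.nan)
                continue
            perms.append(
                ssu_permutation_pvalue(y, dosage[:, cols], Z, n_perm=n_perm,
                                       seed=seed + i)
            )
        out["p_permutation"] = perms
    if meta is not None:
        out = out.sort_values(["chromosome", "start"], kind="stable").reset_index(drop=True)
    return out


def run_sma(genotypes, y, Z) -> pd.DataFrame:
    """Single-marker regression t-tests with the same covariates Z.

    Implemented through the partialled-out regression, which yields the
    identical t statistic and p-value as refitting the full model per SNP:
    residualize y and each SNP on Z, regress residual on residual with
    ``n - rank(Z) - 1`` degrees of freedom.
    """
    from .containers import GenotypeMatrix

    if isinstance(genotypes, GenotypeMatrix):
        dosage = genotypes.dosage
        snp_ids = list(genotypes.snps["snp_id"])
    else:
        dosage = np.asarray(genotypes, dtype=float)
        snp_ids = [f"snp{j}" for j in range(dosage.shape[1])]
    if not np.all(np.isfinite(dosage)):
        raise ValueError("dosage must be imputed before association testing")
    y = np.asarray(y, dtype=float)
    Zm = _as_matrix(Z)
    q = _orthonormal_basis(Zm)
    n = y.shape[0]
    df = n - q.shape[1] - 1
    if df <= 0:
        raise ValueError("not enough samples for the single-marker t-test")
    ry = y - q @ (q.T @ y)
    Xp = dosage - q @ (q.T @ dosage)
    sxx = np.einsum("ij,ij->j", Xp, Xp)
    sxy = Xp.T @ ry
    syy = float(ry @ ry)
    ok = sxx > _DEGENERATE_DIAG
    beta = np.full(len(snp_ids), np.nan)
    tstat = np.full(len(snp_ids), np.nan)
    pvals = np.full(len(snp_ids), np.nan)
    beta[ok] = sxy[ok] / sxx[ok]
    rss = syy - beta[ok] ** 2 * sxx[ok]
    rss = np.clip(rss, 0.0, None)
    se = np.sqrt(rss / df / sxx[ok])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta[ok] / se
    tstat[ok] = t
    pvals[ok] = 2.0 * stats.t.sf(np.abs(t), df)
    return pd.DataFrame(
        {
            "snp_id": snp_ids,
            "beta": beta,
            "t": tstat,
            "p": pvals,
            "note": np.where(ok, "", "degenerate after projection"),
        }
    )


def contrast_genotype_groups(values, group_a_mask, group_b_mask):
    """Welch two-sample t-test between two genotype-defined groups.

    Returns ``(t, df, p)`` with the Welch-Satterthwaite degrees of freedom
    and a two-sided p-value.
    """
    values = np.asarray(values, dtype=float)
    a = values[np.asarray(group_a_mask, dtype=bool)]
    b = values[np.asarray(group_b_mask, dtype=bool)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both groups need at least two samples")
    if np.var(a) == 0 and np.var(b) == 0:
        if np.mean(a) == np.mean(b):
            return 0.0, float(len(a) + len(b) - 2), 1.0
        raise ValueError("zero within-group variance with unequal means")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)
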