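"""Kinship-corrected association scan for quantitative traits.

The model is the standard single-variance-component linear mixed model
y = W a + x b + u + e with u ~ MVN(0, lambda/tau * K) and e ~ MVN(0, I/tau),
where K is the SNP-derived relatedness matrix. The variance ratio lambda is
estimated once by maximum likelihood on the null (no-SNP) model using the
eigendecomposition of K, then held fixed while every SNP is tested by
generalized least squares in the rotated space with a 1-df Wald test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)


@dataclass
class GenotypeTable:
    """Dosage genotypes (0/1/2 copies of the minor allele, NaN = missing)."""

    samples: list[str]
    snps: pd.DataFrame  # columns: snp, contig, pos
    matrix: np.ndarray  # (n_samples, n_snps) float

    def __post_init__(self) -> None:
        if self.matrix.shape != (len(self.samples), len(self.snps)):
            raise ValueError("genotype matrix shape inconsistent with labels")


def qc_filter(
    gt: GenotypeTable,
    sample_miss: float = 0.10,
    snp_miss: float = 0.10,
    maf: float = 0.05,
    dr2: np.ndarray | None = None,
    min_dr2: float = 0.8,
) -> GenotypeTable:
    """Quality-control filter: drop samples with missingness > ``sample_miss``
    first, then SNPs with minor allele frequency < ``maf`` or missingness >
    ``snp_miss``. An imputation-quality hook drops SNPs with ``dr2 <=
    min_dr2`` when a DR2 vector is supplied (inert on complete data without
    one). Removal counts are logged.
    """
    X = gt.matrix
    miss_s = np.isnan(X).mean(axis=1)
    keep_s = miss_s <= sample_miss
    if not keep_s.any():
        raise ValueError("QC removed every sample")
    X = X[keep_s]
    with np.errstate(invalid="ignore"):
        p = np.nanmean(X, axis=0) / 2.0
    maf_arr = np.minimum(p, 1 - p)
    miss_v = np.isnan(X).mean(axis=0)
    keep_v = (maf_arr >= maf) & (miss_v <= snp_miss) & np.isfinite(maf_arr)
    if dr2 is not None:
        keep_v &= np.asarray(dr2) > min_dr2
    log.info(
        "QC removed %d/%d samples and %d/%d SNPs",
        int((~keep_s).sum()), len(keep_s), int((~keep_v).sum()), len(keep_v),
    )
    return GenotypeTable(
        samples=[s for s, k in zip(gt.samples, keep_s) if k],
        snps=gt.snps[keep_v].reset_index(drop=True),
        matrix=X[:, keep_v],
    )


def mean_impute(X: np.ndarray) -> np.ndarray:
    """Replace missing dosages by the per-SNP mean."""
    X = X.copy()
    means = np.nanmean(X, axis=0)
    idx = np.where(np.isnan(X))
    X[idx] = means[idx[1]]
    return X


def kinship_matrix(gt: GenotypeTable, standardize: bool = False) -> np.ndarray:
    """Centered (optionally standardized) genotype cross-product K = XX'/p.

    Missing dosages are mean-imputed per SNP; zero-variance SNPs are excluded.
    The result is symmetric positive semi-definite up to rounding.
    """
    X = mean_impute(gt.matrix)
    X = X - X.mean(axis=0)
    var = X.var(axis=0)
    X = X[:, var > 0]
    if X.shape[1] == 0:
        raise ValueError("no polymorphic SNP left for the kinship matrix")
    if standardize:
        X = X / np.sqrt(X.var(axis=0))
    K = X @ X.T / X.shape[1]
    return (K + K.T) / 2.0


def _null_ml_lambda(
    ty: np.ndarray, tW: np.ndarray, s: np.ndarray,
    grid: tuple[float, float, int] = (-5.0, 5.0, 61),
) -> float:
    """ML estimate of the variance ratio lambda on the null model, maximized
    over a log10 grid with golden-section refinement."""
    n = len(ty)

    def negloglik(log10_lam: float) -> float:
        lam = 10.0**log10_lam
        d = lam * s + 1.0
        w = 1.0 / d
        WtW = tW.T @ (tW * w[:, None])
        beta = np.linalg.solve(WtW, tW.T @ (ty * w))
        resid = ty - tW @ beta
        rss = float(np.sum(w * resid**2))
        sigma2 = rss / n
        return 0.5 * (n * np.log(2 * np.pi * sigma2) + float(np.sum(np.log(d))) + n)

    lo, hi, n_grid = grid
    xs = np.linspace(lo, hi, n_grid)
    vals = [negloglik(x) for x in xs]
    k = int(np.argmin(vals))
    a = xs[max(k - 1, 0)]
    b = xs[min(k + 1, n_grid - 1)]
    # golden-section refinement on [a, b]
    invphi = (np.sqrt(5) - 1) / 2
    c = b - invphi * (b - a)
    d_ = a + invphi * (b - a)
    fc, fd = negloglik(c), negloglik(d_)
    for _ in range(40):
        if fc < fd:
            b, d_, fd = d_, c, fc
            c = b - invphi * (b - a)
            fc = negloglik(c)
        else:
            a, c, fc = c, d_, fd
            d_ = a + invphi * (b - a)
            fd = negloglik(d_)
    return 10.0 ** ((a + b) / 2)


def lmm_scan(
    y: np.ndarray,
    W: np.ndarray,
    X: np.ndarray,
    K: np.ndarray,
    snps: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-SNP linear-mixed-model association scan.

    Parameters
    ----------
    y : trait vector (n,), finite values only.
    W : covariate matrix (n, c) including the intercept column.
    X : dosage matrix (n, m), complete (mean-impute beforehand).
    K : (n, n) relatedness matrix from :func:`kinship_matrix`.
    snps : optional SNP metadata (one row per column of X) carried through.

    Returns a table with beta, se, the 1-df Wald statistic and its chi-square
    P value per SNP; degenerate SNPs (no residual variance after covariates)
    get NaN.
    """
    y = np.asarray(y, dtype=np.float64)
    n = len(y)
    if n < 10:
        raise ValueError("need at least 10 samples")
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite trait values")
    W = np.asarray(W, dtype=np.float64)
    if np.linalg.matrix_rank(W) < W.shape[1]:
        raise ValueError("singular covariate matrix")
    X = np.asarray(X, dtype=np.float64)

    s, U = np.linalg.eigh(np.asarray(K, dtype=np.float64))
    s = np.clip(s, 0.0, None)
    ty = U.T @ y
    tW = U.T @ W
    tX = U.T @ X

    lam = _null_ml_lambda(ty, tW, s)
    d = lam * s + 1.0
    w = 1.0 / d

    Ww = tW * w[:, None]
    WtW = tW.T @ Ww
    coef_y = np.linalg.solve(WtW, Ww.T @ ty)
    ry = ty - tW @ coef_y
    coef_X = np.linalg.solve(WtW, Ww.T @ tX)
    RX = tX - tW @ coef_X
    sxx = np.einsum("i,ij,ij->j", w, RX, RX)
    sxy = np.einsum("i,ij,i->j", w, RX, ry)
    syy = float(np.sum(w * ry**2))
    ok = sxx > 1e-12
    beta = np.full(X.shape[1], np.nan)
    se = np.full(X.shape[1], np.nan)
    beta[ok] = sxy[ok] / sxx[ok]
    dof = n - W.shape[1] - 1
    rss = syy - beta[ok] ** 2 * sxx[ok]
    sigma2 = np.maximum(rss, 0.0) / dof
    se[ok] = np.sqrt(sigma2 / sxx[ok])
    wald = (beta / se) ** 2
    p = stats.chi2.sf(wald, df=1)
    out = pd.DataFrame(
        {"beta": beta, "se": se, "wald": wald, "p": p, "n": n, "lambda_": lam}
    )
    if snps is not None:
        out = pd.concat([snps.reset_index(drop=True), out], axis=1)
    return out


def bonferroni_threshold(alpha: float = 0.05, m: int = 1) -> float:
    """Family-wise significance cutoff alpha/m, to 3 significant figures."""
    if m < 1:
        raise ValueError("m must be at least 1")
    return float(f"{alpha / m:.3g}")


def assoc_scan(
    gt: GenotypeTable,
    phenotypes: pd.DataFrame,
    trait: str,
    covariates: list[str] | None = None,
    alpha: float = 0.05,
    qc: bool = True,
) -> pd.DataFrame:
    """End-to-end GWAS: QC, kinship, LMM scan and Bonferroni flag."""
    if qc:
        gt = qc_filter(gt)
    phen = phenotypes.set_index("sample").loc[gt.samples]
    y = phen[trait].to_numpy(dtype=np.float64)
    cols = [np.ones(len(gt.samples))]
    for c in covariates or []:
        cols.append(phen[c].to_numpy(dtype=np.float64))
    W = np.column_stack(cols)
    X = mean_impute(gt.matrix)
    K = kinship_matrix(gt)
    res = lmm_scan(y, W, X, K, snps=gt.snps)
    res["significant"] = res["p"] < bonferroni_threshold(alpha, len(res))
    return res
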