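"""PCA-based selection outlier scan.

Mirrors the pcadapt approach: PCA of the scaled genotype matrix, per-SNP
multiple regression of the scaled dosages on the top K score vectors, a
robust Mahalanobis distance of the K z-scores, genomic-inflation-factor
recalibration against the chi-square(K) null, and Benjamini-Hochberg FDR
thresholding of the resulting p-values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .genotypes import MISSING, GenotypeMatrix

__all__ = ["ScanResult", "genotype_pca", "snp_zscores",
           "mahalanobis_outliers", "pca_scan", "expand_windows"]


@dataclass
class ScanResult:
    """Per-SNP scan output aligned to the (possibly reduced) SNP index."""

    snp_index: np.ndarray      # column index into the input matrix
    z: np.ndarray              # (n_snp, K)
    d2: np.ndarray             # Mahalanobis distances
    p_value: np.ndarray
    q_value: np.ndarray
    lambda_gif: float
    K: int

    def outliers(self, fdr: float = 0.01) -> np.ndarray:
        return self.snp_index[self.q_value < fdr]


def _scaled_matrix(g: GenotypeMatrix):
    """Mean-imputed, centered dosage matrix scaled by the binomial SD
    sqrt(p(1-p)); monomorphic SNPs are dropped."""
    d = g.dosages.astype(np.float64)
    miss = d == MISSING
    d[miss] = np.nan
    p = np.nanmean(d, axis=0) / 2.0
    keep = (p > 0) & (p < 1)
    d = d[:, keep]
    p = p[keep]
    mu = 2 * p
    sd = np.sqrt(p * (1 - p))
    x = (d - mu) / sd
    x[np.isnan(x)] = 0.0           # mean imputation after centering
    return x, np.flatnonzero(keep)


def genotype_pca(g: GenotypeMatrix, K: int):
    """Top-K principal components of the scaled genotype matrix.

    Returns ``(scores, loadings, snp_index)``: scores are (n_ind, K),
    loadings (n_snp_kept, K); deterministic up to sign. Missing dosages are
    mean-imputed per SNP; monomorphic SNPs are dropped (their index is
    absent from ``snp_index``).
    """
    x, kept = _scaled_matrix(g)
    if not 0 < K < min(x.shape):
        raise ValueError("K must satisfy 0 < K < min(n_ind, n_snp)")
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    scores = u[:, :K] * s[:K]
    loadings = vt[:K].T
    return scores, loadings, kept


def snp_zscores(g: GenotypeMatrix, scores: np.ndarray,
                snp_index: np.ndarray | None = None) -> np.ndarray:
    """z-statistics of each SNP's regression on the K PC score vectors.

    Multiple linear regression of the scaled dosages on the scores (with
    intercept); z = coefficient / standard error. SNPs with (numerically)
    zero residual variance get NaN rows and are excluded downstream.
    """
    x, kept = _scaled_matrix(g)
    if snp_index is not None and not np.array_equal(kept, snp_index):
        raise ValueError("scores were computed on a different SNP set")
    n, K = scores.shape
    A = np.column_stack([np.ones(n), scores])
    coef, _, _, _ = np.linalg.lstsq(A, x, rcond=None)
    resid = x - A @ coef
    dof = n - (K + 1)
    if dof <= 0:
        raise ValueError("not enough individuals for K components")
    sigma2 = (resid ** 2).sum(axis=0) / dof
    xtx_inv = np.linalg.inv(A.T @ A)
    se = np.sqrt(np.outer(np.diag(xtx_inv)[1:], sigma2))
    z = coef[1:] / se
    bad = sigma2 < 1e-12
    z[:, bad] = np.nan
    return z.T                     # (n_snp, K)


def mahalanobis_outliers(z: np.ndarray, snp_index: np.ndarray | None = None,
                         fdr: float = 0.01) -> ScanResult:
    """Robust Mahalanobis distances of z-vectors with GIF recalibration.

    The covariance of the z-vectors is estimated robustly (correlation
    shape from the full data, per-component scale from the median absolute
    deviation), D2 follows chi-square(K) under neutrality after division by
    the genomic inflation factor lambda = median(D2) / chi2_K(0.5);
    q-values are Benjamini-Hochberg.
    """
    z = np.atleast_2d(np.asarray(z, dtype=np.float64))
    if z.shape[1] > z.shape[0]:
        raise ValueError("need more SNPs than components")
    ok = np.isfinite(z).all(axis=1)
    zc = z[ok]
    K = z.shape[1]
    if zc.shape[0] < 2 * K:
        raise ValueError("need at least 2K finite z-vectors")
    # robust scatter: MAD scales on normalized correlation structure
    mad = np.median(np.abs(zc - np.median(zc, axis=0)), axis=0) / 0.6745
    if (mad <= 0).any():
        raise ValueError("degenerate z distribution; try a smaller K")
    zs = (zc - np.median(zc, axis=0)) / mad
    corr = np.corrcoef(zs, rowvar=False) if K > 1 else np.ones((1, 1))
    cov = corr * np.outer(mad, mad)
    try:
        cov_inv = np.linalg.inv(cov)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular z covariance; try a smaller K") from exc
    center = np.median(zc, axis=0)
    dev = zc - center
    d2 = np.einsum("ij,jk,ik->i", dev, cov_inv, dev)
    lam = float(np.median(d2) / sps.chi2.ppf(0.5, K))
    if lam <= 0:
        raise ValueError("nonpositive inflation factor")
    p = sps.chi2.sf(d2 / lam, K)
    q = multipletests(p, method="fdr_bh")[1]
    idx = (np.asarray(snp_index)[ok] if snp_index is not None
           else np.flatnonzero(ok))
    return ScanResult(idx, zc, d2, p, q, lam, K)


def pca_scan(g: GenotypeMatrix, K: int, fdr: float = 0.01) -> ScanResult:
    """Full scan: PCA -> per-SNP z-scores -> recalibrated Mahalanobis."""
    scores, _, kept = genotype_pca(g, K)
    z = snp_zscores(g, scores)
    return mahalanobis_outliers(z, snp_index=kept, fdr=fdr)


def expand_windows(chrom: np.ndarray, pos: np.ndarray, hits: np.ndarray,
                   flank_bp: int = 150_000):
    """BED-style (chrom, start, end) intervals of +/- ``flank_bp`` around
    candidate SNPs (half-open, 0-based starts), merged per chromosome."""
    ivs: dict[str, list[list[int]]] = {}
    for i in hits:
        c = chrom[i]
        start = max(0, int(pos[i]) - 1 - flank_bp)
        end = int(pos[i]) + flank_bp
        ivs.setdefault(c, []).append([start, end])
    out = []
    for c in sorted(ivs):
        merged: list[list[int]] = []
        for s, e in sorted(ivs[c]):
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        out.extend((c, s, e) for s, e in merged)
    return out
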