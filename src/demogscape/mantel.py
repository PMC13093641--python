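"""Mantel and partial Mantel permutation tests on distance matrices.

The Mantel statistic is the Pearson (optionally Spearman) correlation of the
lower-triangle entries of two distance matrices; its null distribution comes
from simultaneous row/column permutations, which respect the exchangeability
of the underlying objects. The partial test correlates the residuals of X
and Y after linear removal of a covariate matrix Z and permutes the
residualized Y (Legendre's residual-permutation method).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .stats import DistanceMatrix

__all__ = ["MantelResult", "mantel", "partial_mantel"]


@dataclass
class MantelResult:
    r: float
    p: float
    n_perm: int
    tail: str
    seed: int


def _as_matrix(m) -> np.ndarray:
    if isinstance(m, DistanceMatrix):
        return m.values
    m = np.asarray(m, dtype=np.float64)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("expected a square distance matrix")
    return m


def _tri(m: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(m.shape[0], k=1)
    return m[iu]


def _check(x: np.ndarray, name: str) -> None:
    if x.std() == 0:
        raise ValueError(f"{name} matrix is constant; correlation undefined")


def _pvalue(r_obs: float, r_perm: np.ndarray, tail: str) -> float:
    if tail == "greater":
        hits = (r_perm >= r_obs).sum()
    elif tail == "less":
        hits = (r_perm <= r_obs).sum()
    elif tail == "two-sided":
        hits = (np.abs(r_perm) >= abs(r_obs)).sum()
    else:
        raise ValueError(f"unknown tail {tail!r}")
    return (1 + int(hits)) / (1 + r_perm.size)


def mantel(X, Y, n_perm: int = 10_000, tail: str = "greater",
           seed: int = 0, method: str = "pearson") -> MantelResult:
    """Mantel test of matrix correlation.

    Permutes rows and columns of ``Y`` simultaneously. ``method`` may be
    "pearson" (default) or "spearman" (ranks taken once, then Pearson).
    """
    xm, ym = _as_matrix(X), _as_matrix(Y)
    if xm.shape != ym.shape:
        raise ValueError("matrix shapes differ")
    n = xm.shape[0]
    if n < 4:
        raise ValueError("need at least 4 objects")
    iu = np.triu_indices(n, k=1)
    xv = xm[iu]
    if method == "spearman":
        xv = rankdata(xv)
    _check(xv, "X")
    rng = np.random.default_rng(seed)

    def corr_with(ymat):
        yv = ymat[iu]
        if method == "spearman":
            yv = rankdata(yv)
        return np.corrcoef(xv, yv)[0, 1]

    _check(_tri(ym) if method == "pearson" else rankdata(_tri(ym)), "Y")
    r_obs = corr_with(ym)
    r_perm = np.empty(n_perm)
    for k in range(n_perm):
        p = rng.permutation(n)
        r_perm[k] = corr_with(ym[np.ix_(p, p)])
    return MantelResult(float(r_obs), _pvalue(r_obs, r_perm, tail),
                        n_perm, tail, seed)


def _residualize(v: np.ndarray, z: np.ndarray) -> np.ndarray:
    """Residuals of v on [1, z] by least squares."""
    A = np.column_stack([np.ones_like(z), z])
    beta, *_ = np.linalg.lstsq(A, v, rcond=None)
    return v - A @ beta


def partial_mantel(X, Y, Z, n_perm: int = 10_000, tail: str = "greater",
                   seed: int = 0) -> MantelResult:
    """Partial Mantel test of X vs Y controlling for Z.

    Pearson correlation of the lower-triangle residuals of X|Z and Y|Z;
    the null permutes the residualized Y entries as a matrix (rows/columns
    together). Degenerate residuals (Z collinear with X or Y) are an error.
    """
    xm, ym, zm = _as_matrix(X), _as_matrix(Y), _as_matrix(Z)
    if not xm.shape == ym.shape == zm.shape:
        raise ValueError("matrix shapes differ")
    n = xm.shape[0]
    if n < 4:
        raise ValueError("need at least 4 objects")
    iu = np.triu_indices(n, k=1)
    zv = zm[iu]
    rx = _residualize(xm[iu], zv)
    ry_vec = _residualize(ym[iu], zv)
    if rx.std() < 1e-12 * (abs(xm[iu]).mean() + 1) or \
            ry_vec.std() < 1e-12 * (abs(ym[iu]).mean() + 1):
        raise ValueError("residuals degenerate: covariate collinear with "
                         "X or Y")
    # rebuild the residual matrix of Y so permutations act on objects
    rym = np.zeros_like(ym)
    rym[iu] = ry_vec
    rym = rym + rym.T
    rng = np.random.default_rng(seed)
    r_obs = np.corrcoef(rx, ry_vec)[0, 1]
    r_perm = np.empty(n_perm)
    for k in range(n_perm):
        p = rng.permutation(n)
        r_perm[k] = np.corrcoef(rx, rym[np.ix_(p, p)][iu])[0, 1]
    return MantelResult(float(r_obs), _pvalue(r_obs, r_perm, tail),
                        n_perm, tail, seed)
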