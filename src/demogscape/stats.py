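"""Summary statistics: nucleotide diversity, Weir-Cockerham F_ST, joint SFS
with hypergeometric projection, and individual Euclidean genetic distances."""

from __future__ import annotations

from dataclasses import dataclass
from math import comb
from pathlib import Path

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix

__all__ = [
    "JointSFS",
    "FstComponents",
    "DistanceMatrix",
    "site_pi",
    "wc_fst",
    "joint_sfs",
    "projection_weights",
    "euclidean_genetic_distance",
]


@dataclass
class JointSFS:
    """2-D site-frequency spectrum over two populations.

    ``counts[i, j]`` is the (possibly fractional, after projection) number of
    sites with ``i`` ALT copies among ``n1`` sampled chromosomes of pop 1 and
    ``j`` among ``n2`` of pop 2. Folding re-indexes by the minor allele:
    cells with total count above ``(n1+n2)/2`` are added onto their mirror,
    exactly-half cells are averaged with their mirror.
    """

    counts: np.ndarray
    n1: int
    n2: int
    folded: bool = False
    monomorphic_included: bool = True

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.float64)
        if self.counts.shape != (self.n1 + 1, self.n2 + 1):
            raise ValueError("counts shape must be (n1+1, n2+1)")
        if (self.counts < -1e-9).any():
            raise ValueError("negative SFS entry")

    def fold(self) -> "JointSFS":
        if self.folded:
            return self
        c = self.counts
        mirror = c[::-1, ::-1]
        total = np.add.outer(np.arange(self.n1 + 1), np.arange(self.n2 + 1))
        half = (self.n1 + self.n2) / 2
        out = np.where(total < half, c + mirror,
                       np.where(total == half, (c + mirror) / 2, 0.0))
        return JointSFS(out, self.n1, self.n2, folded=True,
                        monomorphic_included=self.monomorphic_included)

    def polymorphic_mask(self) -> np.ndarray:
        """Cells that can hold segregating sites (excludes fixed corners)."""
        m = np.ones_like(self.counts, dtype=bool)
        m[0, 0] = False
        m[self.n1, self.n2] = False
        if self.folded:
            total = np.add.outer(np.arange(self.n1 + 1), np.arange(self.n2 + 1))
            m &= total <= (self.n1 + self.n2) / 2
        return m

    def n_segregating(self) -> float:
        return float(self.counts[self.polymorphic_mask()].sum())

    def normalized(self) -> "JointSFS":
        """Probability-normalized spectrum over polymorphic cells."""
        m = self.polymorphic_mask()
        tot = self.counts[m].sum()
        if tot <= 0:
            raise ValueError("no polymorphic mass to normalize")
        out = np.where(m, self.counts / tot, 0.0)
        return JointSFS(out, self.n1, self.n2, folded=self.folded,
                        monomorphic_included=False)

    # dadi/fastsimcoal-style flat text: one header line with dimensions and
    # folding flag, then the row-major counts.
    def to_file(self, path) -> None:
        with Path(path).open("w") as fh:
            fold = "folded" if self.folded else "unfolded"
            fh.write(f"{self.n1 + 1} {self.n2 + 1} {fold}\n")
            fh.write(" ".join(f"{v:.10g}" for v in self.counts.ravel()) + "\n")

    @classmethod
    def from_file(cls, path) -> "JointSFS":
        lines = Path(path).read_text().split("\n")
        d1, d2, fold = lines[0].split()
        counts = np.fromstring(lines[1], sep=" ").reshape(int(d1), int(d2))
        return cls(counts, int(d1) - 1, int(d2) - 1, folded=fold == "folded")


@dataclass
class FstComponents:
    """Per-site Weir-Cockerham (1984) variance components and the ratio
    estimator theta-hat = sum(a) / sum(a+b+c) over usable sites."""

    a: np.ndarray
    b: np.ndarray
    c: np.ndarray

    @property
    def theta_hat(self) -> float:
        denom = self.a + self.b + self.c
        use = np.isfinite(denom) & (denom != 0)
        if not use.any():
            raise ValueError("F_ST undefined: no site with nonzero denominator")
        return float(self.a[use].sum() / denom[use].sum())


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray
    kind: str = "genetic"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix not symmetric")
        if not np.allclose(np.diag(v), 0):
            raise ValueError("distance matrix diagonal must be 0")
        if (v < -1e-12).any():
            raise ValueError("negative distance")
        self.values = v

    def condensed(self) -> np.ndarray:
        iu = np.triu_indices(len(self.labels), k=1)
        return self.values[iu]

    def to_csv(self, path) -> None:
        pd.DataFrame(self.values, index=self.labels,
                     columns=self.labels).to_csv(path)

    @classmethod
    def from_csv(cls, path, kind: str = "genetic") -> "DistanceMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(list(df.index.astype(str)), df.to_numpy(dtype=float), kind)


# ---------------------------------------------------------------------------


def site_pi(g: GenotypeMatrix, pop=None, total_sites: int | None = None):
    """Per-site nucleotide diversity and its mean.

    pi at a site with ``n`` called chromosomes and ALT frequency ``p`` is
    ``n/(n-1) * 2 p (1-p)`` (the mean pairwise difference). Sites with fewer
    than two called chromosomes are NaN and excluded. The mean divides the
    site-sum by ``total_sites`` when given (so callers can include an
    invariant-site denominator), else by the number of usable sites.
    """
    if pop is not None:
        g = g.take_individuals(g.individuals_in(pop))
    an = g.called_chromosomes().astype(float)
    ac = g.alt_count().astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = ac / an
        pi = np.where(an >= 2, an / np.maximum(an - 1, 1) * 2 * p * (1 - p),
                      np.nan)
    usable = np.isfinite(pi)
    denom = total_sites if total_sites is not None else int(usable.sum())
    mean = float(np.nansum(pi) / denom) if denom else float("nan")
    return pi, mean


def _pop_freqs(g: GenotypeMatrix, pop):
    sub = g.take_individuals(g.individuals_in(pop))
    called = sub.called_mask()
    n = called.sum(axis=0).astype(float)                       # individuals
    d = np.where(called, sub.dosages, 0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = d.sum(axis=0) / (2 * n)
        h = ((sub.dosages == 1) & called).sum(axis=0) / n      # obs het freq
    return n, p, h


def wc_fst(g: GenotypeMatrix, popA, popB) -> FstComponents:
    """Weir & Cockerham (1984) two-population variance components.

    Returns per-site a (among populations), b (among individuals within
    populations) and c (within individuals); the multi-locus estimator is the
    ratio of sums. Sites with fewer than two called individuals in either
    population are excluded (NaN components).
    """
    n1, p1, h1 = _pop_freqs(g, popA)
    n2, p2, h2 = _pop_freqs(g, popB)
    r = 2.0
    ok = (n1 >= 2) & (n2 >= 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        nbar = (n1 + n2) / r
        nc = (r * nbar - (n1 ** 2 + n2 ** 2) / (r * nbar)) / (r - 1)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2
                                 - hbar / 4) / (nbar - 1))
        b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2
                                   - (2 * nbar - 1) / (4 * nbar) * hbar)
        c = hbar / 2
    bad = ~ok
    for arr in (a, b, c):
        arr[bad] = np.nan
    return FstComponents(a, b, c)


def projection_weights(n: int, i: int, m: int) -> np.ndarray:
    """Hypergeometric mass over ALT counts j when downsampling a site with
    ``i`` ALT of ``n`` called chromosomes to ``m`` chromosomes."""
    if m > n:
        raise ValueError("cannot project up")
    j = np.arange(m + 1)
    w = np.zeros(m + 1)
    denom = comb(n, m)
    for jj in j:
        if jj <= i and m - jj <= n - i:
            w[jj] = comb(i, jj) * comb(n - i, m - jj) / denom
    return w


def joint_sfs(g: GenotypeMatrix, popA, popB, project_to: tuple[int, int],
              folded: bool = False) -> JointSFS:
    """Joint SFS of two populations with exact hypergeometric projection.

    Each site contributes the outer product of its per-population projection
    masses (accumulated as real numbers, easySFS-style); sites with fewer
    called chromosomes than the projection size in either population are
    dropped. Orientation is ALT-allele counts; fold afterwards for
    minor-allele indexing.
    """
    m1, m2 = project_to
    idxA = g.individuals_in(popA)
    idxB = g.individuals_in(popB)
    subA, subB = g.take_individuals(idxA), g.take_individuals(idxB)
    nA, nB = subA.called_chromosomes(), subB.called_chromosomes()
    iA, iB = subA.alt_count(), subB.alt_count()
    counts = np.zeros((m1 + 1, m2 + 1))
    n_dropped = 0
    # cache projection vectors; ddRAD matrices reuse few (n, i) combinations
    cache: dict[tuple[int, int, int], np.ndarray] = {}

    def w(n, i, m):
        key = (n, i, m)
        if key not in cache:
            cache[key] = projection_weights(n, i, m)
        return cache[key]

    for s in range(g.n_sites):
        if nA[s] < m1 or nB[s] < m2:
            n_dropped += 1
            continue
        counts += np.outer(w(int(nA[s]), int(iA[s]), m1),
                           w(int(nB[s]), int(iB[s]), m2))
    sfs = JointSFS(counts, m1, m2, folded=False)
    sfs.n_dropped = n_dropped  # type: ignore[attr-defined]
    return sfs.fold() if folded else sfs


def euclidean_genetic_distance(g: GenotypeMatrix) -> DistanceMatrix:
    """Pairwise Euclidean distance between individuals' dosage vectors.

    Computed over jointly called sites and rescaled by
    ``sqrt(S / S_joint)`` so missingness does not shrink distances in
    expectation. A pair with no joint site is an error.
    """
    n = g.n_individuals
    S = g.n_sites
    d = g.dosages.astype(np.float64)
    called = g.called_mask()
    vals = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            joint = called[i] & called[j]
            sj = int(joint.sum())
            if sj == 0:
                raise ValueError(
                    f"no jointly called site for pair "
                    f"({g.sample_ids[i]}, {g.sample_ids[j]})")
            diff = d[i, joint] - d[j, joint]
            vals[i, j] = vals[j, i] = np.sqrt((diff ** 2).sum() * S / sj)
    return DistanceMatrix(list(g.sample_ids), vals, kind="genetic")
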