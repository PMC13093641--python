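"""Structured-coalescent simulator for a two-deme history with an ancestral
merger, piecewise-constant sizes and epoch-switched asymmetric migration.

The process runs backward in time as a Markov jump chain: within an epoch a
deme holding ``k`` lineages coalesces at rate ``C(k,2)/(2N)`` per generation
(diploid ``N``), and each lineage in deme ``d`` jumps to deme ``e`` at the
backward migration rate ``m[d -> e]``; at the divergence time every lineage
moves into the ancestral deme. Infinite-sites mutations are laid down as a
Poisson process along branches. The continuous-time exponential approximation
to discrete Wright-Fisher generations is used throughout (error O(1/N)).

Backward-rate convention: the migration matrix entries are the per-generation
probabilities that a lineage's ancestor came from the other deme, matching
the MIG-matrix convention of SFS-based inference tools, so printed rates can
be used directly. A helper converts forward fractions under conservative
migration if needed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._core import branch_sfs, leaf_sets, poisson_mutations, sim_genealogy
from .genotypes import GenotypeMatrix
from .stats import JointSFS

__all__ = [
    "Epoch",
    "DemographicModel",
    "Genealogy",
    "simulate_genealogy",
    "sprinkle_mutations",
    "simulate_dataset",
    "simulate_haplotypes",
    "branch_sfs_mc",
    "locus_seeds",
]

DEME_NAMES = ("north", "south")


@dataclass
class Epoch:
    """One backward-time interval of constant sizes and migration.

    ``start_time`` is in generations before present; ``sizes`` are per-deme
    effective sizes; ``migration[d][e]`` is the backward per-lineage rate of
    moving from deme ``d`` into deme ``e``.
    """

    start_time: float
    sizes: tuple[float, float]
    migration: np.ndarray = field(
        default_factory=lambda: np.zeros((2, 2)))

    def __post_init__(self) -> None:
        self.migration = np.asarray(self.migration, dtype=np.float64)
        if self.migration.shape != (2, 2):
            raise ValueError("migration must be 2x2")


@dataclass
class DemographicModel:
    """Event-based two-deme history consumed by the simulator and inference.

    Times are generations before present; sizes are effective population
    sizes in the units of ``size_units`` ("diploid" individuals by default,
    "haploid" meaning gene copies). ``sample_sizes`` are haploid counts per
    deme at time 0.
    """

    sample_sizes: tuple[int, int]
    epochs: list[Epoch]
    divergence_time: float
    n_anc: float
    mutation_rate: float = 2.38e-9
    locus_length: int = 300
    n_loci: int = 2000
    size_units: str = "diploid"
    demes: tuple[str, str] = DEME_NAMES

    def __post_init__(self) -> None:
        if self.size_units not in ("diploid", "haploid"):
            raise ValueError("size_units must be diploid or haploid")
        if self.divergence_time <= 0:
            raise ValueError("divergence_time must be > 0")
        if self.n_anc <= 0 or self.mutation_rate <= 0:
            raise ValueError("n_anc and mutation_rate must be > 0")
        starts = [e.start_time for e in self.epochs]
        if not starts or starts[0] != 0:
            raise ValueError("first epoch must start at time 0")
        if any(t2 <= t1 for t1, t2 in zip(starts, starts[1:])):
            raise ValueError("epoch start times must be strictly increasing")
        for e in self.epochs:
            if min(e.sizes) <= 0:
                raise ValueError("deme sizes must be > 0")
            if (e.migration < 0).any() or (e.migration >= 1).any():
                raise ValueError("migration rates must be in [0, 1)")

    # arrays for the jitted kernel ------------------------------------
    def _arrays(self):
        eps = [e for e in self.epochs if e.start_time < self.divergence_time]
        starts = np.array([e.start_time for e in eps], dtype=np.float64)
        scale = 2.0 if self.size_units == "diploid" else 1.0
        two_n = np.array([[scale * e.sizes[0], scale * e.sizes[1]]
                          for e in eps], dtype=np.float64)
        migs = np.stack([e.migration for e in eps]).astype(np.float64)
        return starts, two_n, migs, float(self.divergence_time), \
            float(scale * self.n_anc)

    def theta_per_locus(self) -> float:
        return self.mutation_rate * self.locus_length

    def rescaled(self, c: float) -> "DemographicModel":
        """All sizes and times scaled by ``c``, mutation rate by ``1/c``
        (leaves the expected SFS invariant)."""
        eps = [Epoch(e.start_time * c, (e.sizes[0] * c, e.sizes[1] * c),
                     e.migration / c) for e in self.epochs]
        return DemographicModel(
            self.sample_sizes, eps, self.divergence_time * c, self.n_anc * c,
            self.mutation_rate / c, self.locus_length, self.n_loci,
            self.size_units, self.demes)


def forward_to_backward_migration(m_forward: np.ndarray, sizes) -> np.ndarray:
    """Convert forward fractions m[d->e] (share of deme e replaced by
    migrants from d each generation) to backward lineage-jump rates under
    conservative migration: a lineage in e jumps to d at rate m[d->e]."""
    m = np.asarray(m_forward, dtype=np.float64)
    return m.T.copy()


@dataclass
class Genealogy:
    """Coalescent tree as parent pointers with node times (generations).

    Leaves are nodes ``0..n-1`` (time 0); internal nodes are created in
    coalescence order so parents always have larger ids. ``n1`` leading
    leaves were sampled in the first deme.
    """

    parent: np.ndarray
    node_time: np.ndarray
    n1: int
    n2: int

    @property
    def n_leaves(self) -> int:
        return self.n1 + self.n2

    @property
    def n_nodes(self) -> int:
        return self.parent.shape[0]

    @property
    def root(self) -> int:
        return self.n_nodes - 1

    def branch_length(self, v: int) -> float:
        p = self.parent[v]
        return 0.0 if p < 0 else float(self.node_time[p] - self.node_time[v])

    def total_branch_length(self) -> float:
        return float(sum(self.branch_length(v) for v in range(self.n_nodes)))

    def tmrca(self) -> float:
        return float(self.node_time[self.root])

    def validate(self) -> None:
        if (self.parent[:-1] <= np.arange(self.n_nodes - 1)).any():
            raise ValueError("parent ids must exceed child ids")
        for v in range(self.n_nodes - 1):
            if self.node_time[self.parent[v]] < self.node_time[v]:
                raise ValueError("child older than parent")


def simulate_genealogy(model: DemographicModel, rng_seed: int) -> Genealogy:
    """One genealogy of all sampled lineages under ``model``."""
    n1, n2 = model.sample_sizes
    starts, two_n, migs, t_div, two_n_anc = model._arrays()
    parent, node_time = sim_genealogy(
        np.uint32(rng_seed), n1, n2, starts, two_n, migs, t_div, two_n_anc)
    return Genealogy(parent, node_time, n1, n2)


def sprinkle_mutations(tree: Genealogy, mu: float, L: int, rng_seed: int
                       ) -> np.ndarray:
    """Infinite-sites mutation: Poisson(mu*L*branch length) per branch, each
    mutation a new segregating site. Returns a (n_sites, n_leaves) boolean
    derived-allele matrix (haploid)."""
    muts = poisson_mutations(np.uint32(rng_seed), tree.parent, tree.node_time,
                             mu * L)
    total = int(muts.sum())
    if total == 0:
        return np.zeros((0, tree.n_leaves), dtype=bool)
    below = leaf_sets(tree.parent, tree.n_leaves)
    rows = []
    for v in range(tree.n_nodes - 1):
        for _ in range(int(muts[v])):
            rows.append(below[v])
    return np.array(rows, dtype=bool)


def locus_seeds(seed: int, n_loci: int) -> np.ndarray:
    """Counter-mode per-locus seed streams: locus ``i`` gets the same seed
    regardless of ``n_loci``, so extending a simulation keeps earlier loci."""
    ss = np.random.SeedSequence(int(seed))
    return ss.generate_state(2 * n_loci, dtype=np.uint32).reshape(n_loci, 2)


def branch_sfs_mc(model: DemographicModel, n_sims: int, seed: int,
                  folded: bool = False) -> JointSFS:
    """Monte-Carlo mean joint SFS over genealogies, with the mutational
    expectation taken analytically (branch lengths x mu*L), giving a
    lower-variance estimate than sprinkling mutations."""
    n1, n2 = model.sample_sizes
    starts, two_n, migs, t_div, two_n_anc = model._arrays()
    out = np.zeros((n1 + 1, n2 + 1))
    seeds = locus_seeds(seed, n_sims)
    for i in range(n_sims):
        parent, node_time = sim_genealogy(
            seeds[i, 0], n1, n2, starts, two_n, migs, t_div, two_n_anc)
        branch_sfs(parent, node_time, n1, n2, out)
    out *= model.theta_per_locus() / n_sims
    out[0, 0] = 0.0
    out[n1, n2] = 0.0
    sfs = JointSFS(out, n1, n2, folded=False)
    return sfs.fold() if folded else sfs


def simulate_haplotypes(model: DemographicModel, rng_seed: int,
                        chrom_prefix: str = "L"):
    """Haploid derived-allele matrix over all loci.

    Returns ``(haps, chrom, pos)``: an int8 matrix of shape
    ``(n1+n2, n_sites)`` (deme-0 haplotypes first), per-site locus names
    (``<prefix><locus index>``) and 1-based positions drawn uniformly
    without replacement within each locus. Deterministic for a given seed.
    """
    n1, n2 = model.sample_sizes
    starts, two_n, migs, t_div, two_n_anc = model._arrays()
    seeds = locus_seeds(rng_seed, model.n_loci)
    hap_cols = []
    site_chrom, site_pos = [], []
    for i in range(model.n_loci):
        parent, node_time = sim_genealogy(
            seeds[i, 0], n1, n2, starts, two_n, migs, t_div, two_n_anc)
        tree = Genealogy(parent, node_time, n1, n2)
        derived = sprinkle_mutations(tree, model.mutation_rate,
                                     model.locus_length, seeds[i, 1])
        if derived.shape[0] > model.locus_length:
            derived = derived[:model.locus_length]
        rng = np.random.default_rng(seeds[i, 1] + 1)
        pos = np.sort(rng.choice(model.locus_length, size=derived.shape[0],
                                 replace=False)) + 1
        for k, row in enumerate(derived):
            hap_cols.append(row)
            site_chrom.append(f"{chrom_prefix}{i:06d}")
            site_pos.append(int(pos[k]))
    haps = (np.array(hap_cols, dtype=np.int8).T if hap_cols
            else np.zeros((n1 + n2, 0), dtype=np.int8))
    return haps, np.array(site_chrom, dtype=object), np.array(site_pos,
                                                              dtype=np.int64)


def simulate_dataset(model: DemographicModel, rng_seed: int,
                     emit: str = "sfs", diploid_pairing_seed: int | None = None):
    """Simulate ``model.n_loci`` independent loci (no intra-locus
    recombination) and emit either a mutation-tallied :class:`JointSFS`
    (``emit="sfs"``) or a diploid :class:`GenotypeMatrix`
    (``emit="genotypes"``, haplotypes paired randomly within deme).

    Deterministic for a given seed; per-locus streams are independent of
    ``n_loci``.
    """
    if emit not in ("sfs", "genotypes"):
        raise ValueError("emit must be 'sfs' or 'genotypes'")
    n1, n2 = model.sample_sizes
    starts, two_n, migs, t_div, two_n_anc = model._arrays()
    seeds = locus_seeds(rng_seed, model.n_loci)
    theta = model.theta_per_locus()

    if emit == "sfs":
        counts = np.zeros((n1 + 1, n2 + 1))
        for i in range(model.n_loci):
            parent, node_time = sim_genealogy(
                seeds[i, 0], n1, n2, starts, two_n, migs, t_div, two_n_anc)
            tree = Genealogy(parent, node_time, n1, n2)
            derived = sprinkle_mutations(tree, model.mutation_rate,
                                         model.locus_length, seeds[i, 1])
            for row in derived:
                counts[int(row[:n1].sum()), int(row[n1:].sum())] += 1
        counts[0, 0] = 0
        counts[n1, n2] = 0
        return JointSFS(counts, n1, n2, folded=False)

    if n1 % 2 or n2 % 2:
        raise ValueError("haploid sample sizes must be even for diploids")
    haps, site_chrom, site_pos = simulate_haplotypes(model, rng_seed)
    n_sites = haps.shape[1]
    rng = np.random.default_rng(
        diploid_pairing_seed if diploid_pairing_seed is not None
        else np.random.SeedSequence(int(rng_seed)).generate_state(3)[2])
    perm1 = rng.permutation(n1)
    perm2 = n1 + rng.permutation(n2)
    order = np.concatenate([perm1, perm2])
    haps = haps[order]
    dosages = haps[0::2] + haps[1::2]
    n_ind = (n1 + n2) // 2
    labels = ([DEME_NAMES[0]] * (n1 // 2)) + ([DEME_NAMES[1]] * (n2 // 2))
    ids = [f"{lab}_{i:03d}" for i, lab in enumerate(labels)]
    ref = np.array(["A"] * n_sites, dtype=object)
    alt = np.array(["T"] * n_sites, dtype=object)
    return GenotypeMatrix(dosages, ids, labels,
                          np.array(site_chrom, dtype=object),
                          np.array(site_pos), ref, alt)
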