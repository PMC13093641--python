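import numpy as np
import pytest

from demogscape.coalescent import DemographicModel, Epoch
from demogscape.genotypes import GenotypeMatrix


def make_genotypes(dosages, pops=None, chrom=None, pos=None):
    """GenotypeMatrix from a plain list/array; one contig by default."""
    d = np.asarray(dosages, dtype=np.int8)
    n_ind, n_sites = d.shape
    pops = pops if pops is not None else ["other"] * n_ind
    chrom = (np.array(chrom, dtype=object) if chrom is not None
             else np.array(["chr1"] * n_sites, dtype=object))
    pos = (np.asarray(pos, dtype=np.int64) if pos is not None
           else np.arange(1, n_sites + 1, dtype=np.int64))
    return GenotypeMatrix(
        d, [f"ind{i}" for i in range(n_ind)], list(pops), chrom, pos,
        np.array(["A"] * n_sites, dtype=object),
        np.array(["T"] * n_sites, dtype=object))


def single_pop_model(N, n, mu=1e-6, L=300, n_loci=100):
    """Effectively panmictic model: immediate merger into size-N ancestor."""
    return DemographicModel((n, 0), [Epoch(0.0, (N, N))],
                            divergence_time=1e-9, n_anc=N, mutation_rate=mu,
                            locus_length=L, n_loci=n_loci)


def island_model(N, m, n1, n2, mu=2e-6, L=300, n_loci=1000,
                 t_div=2_000_000.0):
    """Two constant demes with symmetric migration and a very deep merger."""
    mig = np.array([[0.0, m], [m, 0.0]])
    return DemographicModel((n1, n2), [Epoch(0.0, (N, N), mig)],
                            divergence_time=t_div, n_anc=N,
                            mutation_rate=mu, locus_length=L, n_loci=n_loci)


@pytest.fixture
def toy_two_pop():
    """Ten diploids in two populations with a strongly differentiated SNP."""
    rng = np.random.default_rng(42)
    n, s = 10, 40
    d = rng.integers(0, 3, size=(n, s)).astype(np.int8)
    d[:5, 0] = 0
    d[5:, 0] = 2
    return make_genotypes(d, pops=["north"] * 5 + ["south"] * 5)
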