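"""Summary statistics: pi, Weir-Cockerham F_ST, SFS projection, distances."""

import itertools

import numpy as np
import pytest

from demogscape.genotypes import MISSING
from demogscape.stats import (DistanceMatrix, JointSFS,
                              euclidean_genetic_distance, joint_sfs,
                              projection_weights, site_pi, wc_fst)

from conftest import make_genotypes


class TestSitePi:
    def test_monomorphic_zero(self):
        pi, mean = site_pi(make_genotypes([[0], [0], [0]]))
        assert pi[0] == 0 and mean == 0

    def test_single_het_two_chromosomes(self):
        pi, _ = site_pi(make_genotypes([[1]]))
        assert pi[0] == pytest.approx(1.0)

    def test_matches_pairwise_difference_oracle(self):
        # n=4 chromosomes, one ALT copy: mean pairwise difference over all
        # C(4,2) haplotype pairs
        alleles = [1, 0, 0, 0]
        diffs = [a != b for a, b in itertools.combinations(alleles, 2)]
        expected = np.mean(diffs)
        pi, _ = site_pi(make_genotypes([[1], [0]]))
        assert pi[0] == pytest.approx(expected) == pytest.approx(0.5)

    def test_explicit_denominator(self):
        g = make_genotypes([[1, 0], [1, 0]])
        _, mean = site_pi(g, total_sites=100)
        pi, _ = site_pi(g)
        assert mean == pytest.approx(np.nansum(pi) / 100)

    def test_uncalled_site_excluded(self):
        d = np.array([[MISSING], [MISSING]], dtype=np.int8)
        pi, _ = site_pi(make_genotypes(d))
        assert np.isnan(pi[0])

    def test_one_called_diploid_still_defined(self):
        # a single called heterozygote is two chromosomes: pi = 1
        d = np.array([[1], [MISSING]], dtype=np.int8)
        pi, _ = site_pi(make_genotypes(d))
        assert pi[0] == pytest.approx(1.0)


def _wc_oracle(n1, p1, h1, n2, p2, h2):
    """Literal per-site transcription of the 1984 two-population estimator."""
    r = 2
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    a = nbar / nc * (s2 - 1 / (nbar - 1)
                     * (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4))
    b = nbar / (nbar - 1) * (pbar * (1 - pbar) - (r - 1) / r * s2
                             - (2 * nbar - 1) / (4 * nbar) * hbar)
    c = hbar / 2
    return a, b, c


class TestWcFst:
    def test_matches_independent_oracle(self):
        rng = np.random.default_rng(7)
        d = rng.choice([0, 1, 2, MISSING], size=(24, 50),
                       p=[0.45, 0.3, 0.15, 0.1]).astype(np.int8)
        pops = ["north"] * 12 + ["south"] * 12
        g = make_genotypes(d, pops=pops)
        comp = wc_fst(g, "north", "south")
        num = den = 0.0
        for s in range(50):
            stats = []
            for sl in (slice(0, 12), slice(12, 24)):
                col = d[sl, s]
                called = col != MISSING
                n = called.sum()
                p = col[called].sum() / (2 * n)
                h = (col[called] == 1).mean()
                stats.extend([n, p, h])
            a, b, c = _wc_oracle(*stats)
            if np.isfinite(a + b + c) and (a + b + c) != 0:
                num += a
                den += a + b + c
        assert comp.theta_hat == pytest.approx(num / den, abs=1e-12)

    def test_near_zero_when_identical_pops(self):
        # identical frequencies/heterozygosities: theta-hat ~ 0 up to the
        # finite-sample correction, which shrinks with n
        col = np.array([0, 1, 2, 1] * 25, dtype=np.int8).reshape(-1, 1)
        d = np.vstack([col, col])
        g = make_genotypes(d, pops=["a"] * 100 + ["b"] * 100)
        assert wc_fst(g, "a", "b").theta_hat == pytest.approx(0.0, abs=0.02)

    def test_fixed_difference_near_one(self):
        d = np.array([[0]] * 50 + [[2]] * 50, dtype=np.int8)
        g = make_genotypes(d, pops=["a"] * 50 + ["b"] * 50)
        assert wc_fst(g, "a", "b").theta_hat > 0.98

    def test_label_swap_invariance(self, toy_two_pop):
        t1 = wc_fst(toy_two_pop, "north", "south").theta_hat
        t2 = wc_fst(toy_two_pop, "south", "north").theta_hat
        assert t1 == pytest.approx(t2, abs=1e-14)

    def test_monomorphic_only_is_error(self):
        g = make_genotypes(np.zeros((8, 2), dtype=np.int8),
                           pops=["a"] * 4 + ["b"] * 4)
        with pytest.raises(ValueError):
            wc_fst(g, "a", "b").theta_hat


class TestJointSfs:
    def test_exact_hypergeometric_mass(self):
        w = projection_weights(4, 2, 2)
        assert np.allclose(w, [1 / 6, 4 / 6, 1 / 6])

    def test_identity_projection_equals_tally(self):
        rng = np.random.default_rng(3)
        d = rng.integers(0, 3, size=(8, 30)).astype(np.int8)
        pops = ["a"] * 4 + ["b"] * 4
        g = make_genotypes(d, pops=pops)
        sfs = joint_sfs(g, "a", "b", (8, 8))
        direct = np.zeros((9, 9))
        for s in range(30):
            direct[d[:4, s].sum(), d[4:, s].sum()] += 1
        assert np.allclose(sfs.counts, direct)

    def test_projection_preserves_total(self):
        rng = np.random.default_rng(4)
        d = rng.choice([0, 1, 2, MISSING], size=(10, 40),
                       p=[0.4, 0.3, 0.2, 0.1]).astype(np.int8)
        g = make_genotypes(d, pops=["a"] * 5 + ["b"] * 5)
        sfs = joint_sfs(g, "a", "b", (6, 6))
        assert sfs.counts.sum() + 0 == pytest.approx(40 - sfs.n_dropped)

    def test_fold_oracle_by_index_mapping(self):
        rng = np.random.default_rng(5)
        counts = rng.random((5, 7))
        counts[0, 0] = counts[4, 6] = 0
        sfs = JointSFS(counts, 4, 6)
        folded = sfs.fold()
        expected = np.zeros_like(counts)
        for i in range(5):
            for j in range(7):
                tot = i + j
                mi, mj = 4 - i, 6 - j
                if tot < 5:
                    expected[i, j] = counts[i, j] + counts[mi, mj]
                elif tot == 5:
                    expected[i, j] = (counts[i, j] + counts[mi, mj]) / 2
        assert np.allclose(folded.counts, expected)
        assert folded.counts.sum() == pytest.approx(counts.sum())

    def test_low_call_sites_dropped(self):
        d = np.array([[1, MISSING], [0, MISSING], [1, 0], [0, 1]],
                     dtype=np.int8)
        g = make_genotypes(d, pops=["a", "a", "b", "b"])
        sfs = joint_sfs(g, "a", "b", (4, 4))
        assert sfs.n_dropped == 1


class TestGeneticDistance:
    def test_identical_individuals_zero(self):
        g = make_genotypes([[1, 2, 0], [1, 2, 0]])
        assert euclidean_genetic_distance(g).values[0, 1] == 0

    def test_single_site_dosage_two_apart(self):
        g = make_genotypes([[0, 1, 1], [2, 1, 1]])
        assert euclidean_genetic_distance(g).values[0, 1] == \
            pytest.approx(2.0)

    def test_missing_rescaling_unbiased(self):
        """Masked-and-rescaled distances match full-data distances in
        expectation (Monte-Carlo over random missingness masks)."""
        rng = np.random.default_rng(8)
        d_full = rng.integers(0, 3, size=(2, 400)).astype(np.int8)
        g_full = make_genotypes(d_full)
        d0 = euclidean_genetic_distance(g_full).values[0, 1]
        sq = []
        for rep in range(300):
            d = d_full.copy()
            d[rng.random(d.shape) < 0.3] = MISSING
            sq.append(euclidean_genetic_distance(
                make_genotypes(d)).values[0, 1] ** 2)
        se = np.std(sq) / np.sqrt(len(sq))
        assert abs(np.mean(sq) - d0 ** 2) < 3 * se

    def test_no_joint_sites_error(self):
        d = np.array([[1, MISSING], [MISSING, 1]], dtype=np.int8)
        with pytest.raises(ValueError, match="jointly"):
            euclidean_genetic_distance(make_genotypes(d))


class TestDistanceMatrix:
    def test_csv_round_trip(self, tmp_path):
        rng = np.random.default_rng(2)
        a = rng.random((4, 4))
        v = (a + a.T) / 2
        np.fill_diagonal(v, 0)
        dm = DistanceMatrix(["w", "x", "y", "z"], v)
        dm.to_csv(tmp_path / "d.csv")
        back = DistanceMatrix.from_csv(tmp_path / "d.csv")
        assert back.labels == dm.labels
        assert np.allclose(back.values, dm.values)

    def test_asymmetry_rejected(self):
        with pytest.raises(ValueError):
            DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [2.0, 0.0]]))


class TestSfsSerialization:
    def test_file_round_trip(self, tmp_path):
        rng = np.random.default_rng(6)
        c = rng.random((4, 5))
        c[0, 0] = c[3, 4] = 0
        sfs = JointSFS(c, 3, 4)
        sfs.to_file(tmp_path / "s.sfs")
        back = JointSFS.from_file(tmp_path / "s.sfs")
        assert back.n1 == 3 and back.n2 == 4 and not back.folded
        assert np.allclose(back.counts, c)
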