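"""Weir-Cockerham theta against an independent brute-force oracle,
permutation significance, Bonferroni, and Mantel tests."""

import numpy as np
import pytest

from gartergen import (
    GenotypeMatrix,
    WrightFisherConfig,
    bonferroni_alpha,
    mantel_test,
    simulate_wright_fisher,
    theta_permutation_test,
    wc_theta,
)
from gartergen.genotype_io import GenotypeValidationError


def brute_force_theta(pop_dosages):
    """Textbook two-level variance-component FST estimator, written
    independently with explicit loops (oracle for wc_theta)."""
    r = len(pop_dosages)
    num = 0.0
    den = 0.0
    n_loci = pop_dosages[0].shape[1]
    for locus in range(n_loci):
        n = []
        p = []
        h = []
        for d in pop_dosages:
            col = [x for x in d[:, locus] if x >= 0]
            if not col:
                n, p, h = [], [], []
                break
            n.append(len(col))
            p.append(sum(col) / (2 * len(col)))
            h.append(sum(1 for x in col if x == 1) / len(col))
        if not n:
            continue
        nbar = sum(n) / r
        if nbar <= 1:
            continue
        ntot = sum(n)
        nc = (ntot - sum(v * v for v in n) / ntot) / (r - 1)
        pbar = sum(ni * pi for ni, pi in zip(n, p)) / ntot
        if pbar <= 0 or pbar >= 1:
            continue
        s2 = sum(ni * (pi - pbar) ** 2 for ni, pi in zip(n, p)) / ((r - 1) * nbar)
        hbar = sum(ni * hi for ni, hi in zip(n, h)) / ntot
        inner = pbar * (1 - pbar) - (r - 1) / r * s2
        a = nbar / nc * (s2 - (inner - hbar / 4) / (nbar - 1))
        b = nbar / (nbar - 1) * (inner - (2 * nbar - 1) / (4 * nbar) * hbar)
        c = hbar / 2
        num += a
        den += a + b + c
    return num / den


def _two_pops(d1, d2):
    d = np.vstack([d1, d2]).astype(np.int16)
    n1, n2 = d1.shape[0], d2.shape[0]
    return GenotypeMatrix(
        [f"i{k}" for k in range(n1 + n2)],
        [f"L{j}" for j in range(d.shape[1])],
        d,
        ["A"] * n1 + ["B"] * n2,
    )


class TestThetaOracle:
    def test_fixed_difference_is_one(self):
        g = _two_pops(np.full((10, 1), 2), np.zeros((10, 1)))
        assert wc_theta(g).theta.loc["A", "B"] == pytest.approx(1.0)

    def test_duplicated_population_not_positive(self):
        rng = np.random.default_rng(0)
        block = rng.integers(0, 3, size=(10, 30))
        g = _two_pops(block, block)  # same individuals under two labels
        assert wc_theta(g).theta.loc["A", "B"] <= 1e-9

    def test_toy_matches_brute_force(self):
        d1 = np.array([[2], [2], [1], [1], [0]])
        d2 = np.array([[0], [0], [0], [1], [1]])
        g = _two_pops(d1, d2)
        expected = brute_force_theta([d1, d2])
        assert wc_theta(g).theta.loc["A", "B"] == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("seed", range(4))
    def test_random_matrices_match_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        d1 = rng.integers(0, 3, size=(8, 15))
        d2 = rng.integers(0, 3, size=(11, 15))
        d1[rng.random(d1.shape) < 0.1] = -1
        g = _two_pops(d1, d2)
        assert wc_theta(g).theta.loc["A", "B"] == pytest.approx(
            brute_force_theta([d1, d2]), abs=1e-12
        )

    def test_invariances(self):
        rng = np.random.default_rng(5)
        d1 = rng.integers(0, 3, size=(9, 25))
        d2 = rng.integers(0, 3, size=(9, 25))
        g = _two_pops(d1, d2)
        base = wc_theta(g).theta.loc["A", "B"]
        # allele-label swap
        swapped = _two_pops(2 - d1, 2 - d2)
        assert wc_theta(swapped).theta.loc["A", "B"] == pytest.approx(base)
        # individual order
        perm = np.random.default_rng(1).permutation(18)
        g2 = g.take_individuals(perm)
        assert wc_theta(g2).theta.loc["A", "B"] == pytest.approx(base)

    def test_single_polymorphic_locus_equals_ratio(self):
        # only locus 0 polymorphic: multi-locus ratio-of-sums == that locus alone
        d1 = np.hstack([np.array([[2], [1], [1], [0]]), np.full((4, 3), 2)])
        d2 = np.hstack([np.array([[0], [0], [1], [0]]), np.full((4, 3), 2)])
        multi = wc_theta(_two_pops(d1, d2)).theta.loc["A", "B"]
        single = wc_theta(_two_pops(d1[:, :1], d2[:, :1])).theta.loc["A", "B"]
        assert multi == pytest.approx(single, abs=1e-12)

    def test_no_shared_polymorphism_errors(self):
        g = _two_pops(np.ones((5, 2)) * 2, np.ones((5, 2)) * 2)
        with pytest.raises(GenotypeValidationError):
            wc_theta(g)


class TestPermutationTest:
    def test_fixed_difference_minimal_p(self):
        g = _two_pops(np.full((8, 5), 2), np.zeros((8, 5)))
        p = theta_permutation_test(g, ["A", "B"], n_perm=999, seed=0)
        assert p == pytest.approx(1 / 1000)

    def test_minimum_permutations_enforced(self, two_pop_matrix):
        with pytest.raises(GenotypeValidationError):
            theta_permutation_test(two_pop_matrix, ["A", "B"], n_perm=50)

    def test_add_one_floor(self, two_pop_matrix):
        p = theta_permutation_test(two_pop_matrix, ["A", "B"], n_perm=99, seed=1)
        assert p >= 1 / 100


class TestBonferroni:
    @pytest.mark.parametrize(
        "n, alpha, expected",
        [(36, 0.05, 0.00139), (1, 0.05, 0.05), (28, 0.05, 0.00179)],
    )
    def test_values(self, n, alpha, expected):
        assert bonferroni_alpha(n, alpha) == pytest.approx(expected, abs=5e-6)


class TestMantel:
    def _sym(self, rng, n):
        m = rng.random((n, n))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        return m

    def test_identical_matrices_r_one(self):
        rng = np.random.default_rng(0)
        m = self._sym(rng, 6)
        res = mantel_test(m, m, n_perm=99, seed=0)
        assert res.r == pytest.approx(1.0)
        assert res.r_squared == pytest.approx(1.0)

    def test_negated_matrix_r_minus_one(self):
        rng = np.random.default_rng(1)
        m = self._sym(rng, 6)
        res = mantel_test(-m + m.max(), m, n_perm=99, seed=0)
        np.fill_diagonal(m, 0)
        assert res.r == pytest.approx(-1.0)

    def test_too_few_populations(self):
        with pytest.raises(GenotypeValidationError):
            mantel_test(np.zeros((2, 2)), np.zeros((2, 2)))

    def test_matches_skbio(self):
        """Cross-check r and permutation p against an independent library."""
        from skbio.stats.distance import DistanceMatrix, mantel

        rng = np.random.default_rng(9)
        a, b = self._sym(rng, 7), self._sym(rng, 7)
        ours = mantel_test(a, b, n_perm=999, seed=0)
        r_ref, p_ref, _ = mantel(
            DistanceMatrix(a), DistanceMatrix(b), method="pearson",
            permutations=999, alternative="two-sided",
        )
        assert ours.r == pytest.approx(float(r_ref), abs=1e-12)
        assert ours.p_value == pytest.approx(float(p_ref), abs=0.06)


def test_island_model_theta_decreases_with_migration():
    """Symmetric two-deme island model: equilibrium differentiation
    shrinks as migration grows (panmixia limit near zero)."""
    thetas = []
    for m in (0.002, 0.02, 0.5):
        cfg = WrightFisherConfig(
            deme_sizes=[100, 100], n_loci=400, generations=150, migration=m,
            sampling=[(150, 0, 30), (150, 1, 30)], seed=123, mode="frequency",
        )
        out = simulate_wright_fisher(cfg)
        from gartergen.genotype_io import concat_individuals

        g = concat_individuals(out[(150, 0)], out[(150, 1)])
        thetas.append(wc_theta(g).theta.iloc[0, 1])
    assert thetas[0] > thetas[1] > thetas[2]
    assert thetas[2] < 0.02
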