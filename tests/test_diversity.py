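"""Diversity statistics against closed forms and brute-force oracles."""

import itertools

import numpy as np
import pytest

import pollenflow as pf
from pollenflow import diversity as div

from conftest import random_genotypes


class TestHeterozygosity:
    def test_all_heterozygous(self):
        gm = pf.GenotypeMatrix(["a", "b"], ["l1"], np.ones((2, 1), np.int8))
        ho, he = div.heterozygosity(gm)
        assert ho == 1.0

    def test_matches_brute_force(self, rng):
        gm = random_genotypes(rng, n=20, L=40)
        ho, he = div.heterozygosity(gm)
        hos, hes = [], []
        for j in range(gm.n_loci):
            col = gm.calls[:, j][gm.calls[:, j] != pf.MISSING]
            if len(col) < 2:
                continue
            n = len(col)
            p = col.sum() / (2 * n)
            hos.append((col == 1).mean())
            hes.append(2 * p * (1 - p) * n / (n - 1))
        assert ho == pytest.approx(np.mean(hos))
        assert he == pytest.approx(np.mean(hes))


class TestPic:
    def test_closed_forms(self):
        assert div.pic(0.5) == pytest.approx(0.375)
        assert div.pic(0.0) == 0.0
        p = 0.1
        assert div.pic(p) == pytest.approx(1 - (p**2 + 0.9**2) - 2 * p**2 * 0.9**2)

    def test_bounds_relative_to_he(self):
        p = np.linspace(0.01, 0.99, 97)
        he = 2 * p * (1 - p)
        picv = div.pic(p)
        assert np.all(picv < he) and np.all(he < 2 * picv)


class TestHwe:
    def test_exact_proportions_not_deviating(self):
        # 16 AA, 48 Aa, 36 aa: exactly HW at p=0.6 (alt allele)
        calls = np.array([0] * 16 + [1] * 48 + [2] * 36, np.int8)[:, None]
        gm = pf.GenotypeMatrix([f"i{k}" for k in range(100)], ["l"], calls)
        dev, pvals, n = div.hwe_test(gm)
        assert not dev[0] and pvals[0] == pytest.approx(1.0)

    def test_all_heterozygotes_deviate(self):
        calls = np.ones((100, 1), np.int8)
        gm = pf.GenotypeMatrix([f"i{k}" for k in range(100)], ["l"], calls)
        dev, pvals, n = div.hwe_test(gm)
        assert dev[0] and pvals[0] < 1e-20


class TestNonExclusion:
    def test_monomorphic_locus_excludes_nobody(self):
        ne, excl = div.non_exclusion_second_parent([1e-9])
        assert excl[0] == pytest.approx(0.0, abs=1e-6)
        assert ne == pytest.approx(1.0, abs=1e-6)

    def test_independent_loci_multiply(self):
        ne1, e1 = div.non_exclusion_second_parent([0.3])
        ne2, e2 = div.non_exclusion_second_parent([0.4])
        ne12, _ = div.non_exclusion_second_parent([0.3, 0.4])
        assert ne12 == pytest.approx(ne1 * ne2)

    def test_matches_full_trio_enumeration(self):
        # enumerate mother x true-father x offspring x candidate at p = 0.5
        for p in (0.5, 0.3, 0.1):
            prior = np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2])

            def trans(gm_, gd_, go_):
                tot = 0.0
                for am in (0, 1):
                    for ad in (0, 1):
                        if am + ad == go_:
                            tot += ((gm_ / 2 if am else 1 - gm_ / 2)
                                    * (gd_ / 2 if ad else 1 - gd_ / 2))
                return tot

            excl_prob = 0.0
            for gm_ in range(3):
                for gd_ in range(3):  # true father
                    for go_ in range(3):
                        pr = prior[gm_] * prior[gd_] * trans(gm_, gd_, go_)
                        if pr == 0:
                            continue
                        # probability a random candidate is excluded
                        p_excl = sum(prior[gc] for gc in range(3)
                                     if trans(gm_, gc, go_) == 0)
                        excl_prob += pr * p_excl
            _, excl = div.non_exclusion_second_parent([p])
            assert excl[0] == pytest.approx(excl_prob, abs=1e-12)


class TestFst:
    def test_fixed_alternate_alleles(self):
        a = np.zeros((20, 5), np.int8)
        b = np.full((20, 5), 2, np.int8)
        gm = pf.GenotypeMatrix([f"a{k}" for k in range(20)]
                               + [f"b{k}" for k in range(20)],
                               [f"l{j}" for j in range(5)], np.vstack([a, b]))
        theta, mean = div.weir_cockerham_fst(
            gm, {"A": [f"a{k}" for k in range(20)],
                 "B": [f"b{k}" for k in range(20)]})
        assert mean == pytest.approx(1.0)

    def test_hand_computed_small_instance(self):
        # 2 groups x 4 individuals, one locus; components written out longhand
        ga = np.array([0, 1, 1, 2], np.int8)[:, None]
        gb = np.array([0, 0, 1, 0], np.int8)[:, None]
        gm = pf.GenotypeMatrix(["a1", "a2", "a3", "a4", "b1", "b2", "b3", "b4"],
                               ["l"], np.vstack([ga, gb]))
        theta, mean = div.weir_cockerham_fst(
            gm, {"A": ["a1", "a2", "a3", "a4"], "B": ["b1", "b2", "b3", "b4"]})
        # independent longhand arithmetic (Weir & Cockerham 1984 defs)
        r, n1 = 2, 4.0
        p1, p2 = 4 / 8, 1 / 8
        h1, h2 = 2 / 4, 1 / 4
        nbar = 4.0
        nc = (8 - (16 + 16) / 8) / (r - 1)
        pbar = (4 * p1 + 4 * p2) / 8
        s2 = (4 * (p1 - pbar) ** 2 + 4 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (4 * h1 + 4 * h2) / 8
        a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2
                                 - hbar / 4) / (nbar - 1))
        b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2
                                   - (2 * nbar - 1) / (4 * nbar) * hbar)
        c = hbar / 2
        assert theta[0] == pytest.approx(a / (a + b + c))


class TestNei:
    def test_identity_and_symmetry(self):
        f = np.array([0.2, 0.6, 0.4])
        assert div.nei_distance(f, f) == pytest.approx(0.0)
        g = np.array([0.3, 0.5, 0.1])
        assert div.nei_distance(f, g) == pytest.approx(div.nei_distance(g, f))

    def test_two_locus_toy_direct_formula(self):
        fA, fB = np.array([0.2, 0.7]), np.array([0.4, 0.6])
        jA = np.mean(fA**2 + (1 - fA) ** 2)
        jB = np.mean(fB**2 + (1 - fB) ** 2)
        jAB = np.mean(fA * fB + (1 - fA) * (1 - fB))
        expected = -np.log(jAB / np.sqrt(jA * jB))
        assert div.nei_distance(fA, fB) == pytest.approx(expected)


class TestShannonRarefaction:
    def test_shannon_closed_forms(self):
        assert div.shannon_index([7]) == 0.0
        assert div.shannon_index([3, 3, 3, 3]) == pytest.approx(np.log(4))
        c = np.array([5, 3, 2]) / 10
        assert div.shannon_index([5, 3, 2]) == pytest.approx(-(c * np.log(c)).sum())
        with pytest.raises(ValueError):
            div.shannon_index([0, 0])

    def test_rarefaction_limits(self):
        assert div.rarefaction_richness([4, 3, 1], 1) == pytest.approx(1.0)
        assert div.rarefaction_richness([4, 3, 1], 8) == pytest.approx(3.0)
        with pytest.raises(ValueError):
            div.rarefaction_richness([4, 3, 1], 9)

    def test_rarefaction_exhaustive_enumeration(self):
        # counts [4,3,1], depth 4: average richness over all C(8,4) subsets
        items = [0] * 4 + [1] * 3 + [2] * 1
        vals = [len(set(c)) for c in itertools.combinations(range(8), 4)]
        labels = [set(items[i] for i in c)
                  for c in itertools.combinations(range(8), 4)]
        expected = np.mean([len(s) for s in labels])
        assert div.rarefaction_richness([4, 3, 1], 4) == pytest.approx(expected)


class TestGrmPca:
    def test_duplicate_individuals_and_symmetry(self, rng):
        gm = random_genotypes(rng, n=6, L=60, miss=0.0)
        calls = np.vstack([gm.calls, gm.calls[:1]])  # duplicate first
        gm2 = pf.GenotypeMatrix([f"i{k}" for k in range(7)], gm.loci, calls)
        G = div.grm_vanraden(gm2)
        np.testing.assert_allclose(G, G.T)
        assert G[0, 6] == pytest.approx(G[0, 0])

    def test_ibs_toy_hand_count(self):
        calls = np.array([[0, 1, 2], [2, 1, 0], [0, 0, 2], [1, 1, 1]], np.int8)
        gm = pf.GenotypeMatrix(list("abcd"), ["l1", "l2", "l3"], calls)
        P, mean = div.ibs_dissimilarity(gm)
        assert P[0, 1] == pytest.approx((1 + 0 + 1) / 3)
        assert P[0, 2] == pytest.approx((0 + 0.5 + 0) / 3)
        assert P[0, 3] == pytest.approx((0.5 + 0 + 0.5) / 3)

    def test_pca_rank_one_and_orthogonality(self, rng):
        base = rng.binomial(2, 0.4, size=30).astype(np.int8)
        calls = np.vstack([base * 0, base, base * 0, base])
        gm = pf.GenotypeMatrix(list("abcd"), [f"l{j}" for j in range(30)], calls)
        scores, frac = div.pca_scores(gm, k=2)
        assert frac[0] == pytest.approx(1.0)
        gm2 = random_genotypes(rng, n=15, L=40, miss=0.0)
        scores, frac = div.pca_scores(gm2, k=3)
        prods = scores.T @ scores
        np.testing.assert_allclose(prods - np.diag(np.diag(prods)), 0, atol=1e-8)
        # spectral oracle: fractions equal eigenvalue ratios
        X = gm2.calls - gm2.calls.mean(axis=0)
        ev = np.sort(np.linalg.eigvalsh(X @ X.T))[::-1]
        np.testing.assert_allclose(frac, ev[:3] / ev[ev > 1e-9].sum(), atol=1e-8)

    def test_group_statistics_order_invariant(self, rng):
        gm = random_genotypes(rng, n=12, L=30)
        ids = list(gm.ids)
        perm = list(np.random.default_rng(1).permutation(ids))
        assert div.heterozygosity(gm, ids) == div.heterozygosity(gm, perm)
        _, m1 = div.ibs_dissimilarity(gm, ids)
        _, m2 = div.ibs_dissimilarity(gm, perm)
        assert m1 == pytest.approx(m2)


from hypothesis import given, settings, strategies as st


@settings(deadline=None, derandomize=True, max_examples=50)
@given(st.lists(st.integers(min_value=1, max_value=30), min_size=1, max_size=8))
def test_shannon_bounded_by_log_categories(counts):
    h = div.shannon_index(counts)
    assert -1e-12 <= h <= np.log(len(counts)) + 1e-12


@settings(deadline=None, derandomize=True, max_examples=50)
@given(st.lists(st.integers(min_value=1, max_value=20), min_size=2, max_size=6),
       st.data())
def test_rarefaction_monotone_in_depth(counts, data):
    n = sum(counts)
    d = data.draw(st.integers(min_value=1, max_value=n - 1))
    assert (div.rarefaction_richness(counts, d)
            <= div.rarefaction_richness(counts, d + 1) + 1e-12)
    assert div.rarefaction_richness(counts, n) == pytest.approx(len(counts))


@settings(deadline=None, derandomize=True, max_examples=40)
@given(st.floats(min_value=0.01, max_value=0.99))
def test_pic_between_half_and_full_heterozygosity(p):
    he = 2 * p * (1 - p)
    v = float(div.pic(p))
    assert he / 2 < v < he
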