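"""LOD machinery, calibration, assignment and paternal summaries."""

import numpy as np
import pandas as pd
import pytest

import pollenflow as pf
from pollenflow import paternity as pat


def enum_trio(go, gm, gd, p, eps, pool=False):
    """Exhaustive sum over true-genotype configurations under the error model."""
    prior = np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2])
    E = np.full((3, 3), eps / 2)
    np.fill_diagonal(E, 1 - eps)

    def trans(tm, td, to):
        tot = 0.0
        for am in (0, 1):
            for ad in (0, 1):
                if am + ad == to:
                    tot += ((tm / 2 if am else 1 - tm / 2)
                            * (td / 2 if ad else 1 - td / 2))
        return tot

    def post(obs):
        w = prior * E[obs]
        return w / w.sum()

    total = 0.0
    for tm in range(3):
        wm = post(gm)[tm]
        if pool:
            for to in range(3):
                tp = sum((tm / 2 if am else 1 - tm / 2) * (p if ad else 1 - p)
                         for am in (0, 1) for ad in (0, 1) if am + ad == to)
                total += wm * tp * E[go, to]
        else:
            for td in range(3):
                wd = post(gd)[td]
                for to in range(3):
                    total += wm * wd * trans(tm, td, to) * E[go, to]
    return total


class TestTrioProb:
    def test_mendelian_limits_without_error(self):
        assert pat.trio_genotype_prob(1, 1, 1, 0.3, 0.0) == pytest.approx(0.5)
        assert pat.trio_genotype_prob(2, 0, 0, 0.3, 0.0) == 0.0
        assert pat.trio_genotype_prob(0, 0, 0, 0.3, 0.0) == pytest.approx(1.0)

    @pytest.mark.parametrize("go,gm,gd,p,eps", [
        (1, 0, 2, 0.2, 0.1), (0, 1, 2, 0.4, 0.1), (2, 2, 1, 0.1, 0.05),
        (1, 1, 0, 0.3, 0.02),
    ])
    def test_matches_enumeration(self, go, gm, gd, p, eps):
        assert pat.trio_genotype_prob(go, gm, gd, p, eps) == pytest.approx(
            enum_trio(go, gm, gd, p, eps), abs=1e-12)
        assert pat.trio_genotype_prob(go, gm, None, p, eps, pool=True) == \
            pytest.approx(enum_trio(go, gm, None, p, eps, pool=True), abs=1e-12)

    def test_missing_calls_contribute_one(self):
        assert pat.trio_genotype_prob(pf.MISSING, 1, 1, 0.3, 0.1) == 1.0


class TestLodScore:
    def test_single_locus_composition(self):
        p, eps = 0.3, 0.1
        model = pat.LodModel(np.array([p]), error_rate=eps, min_loci=1)
        for go in range(3):
            for gmom in range(3):
                for gdad in range(3):
                    lod, n = pat.lod_score(np.array([go]), np.array([gmom]),
                                           np.array([gdad]), model)
                    num = pat.trio_genotype_prob(go, gmom, gdad, p, eps)
                    den = pat.trio_genotype_prob(go, gmom, None, p, eps, pool=True)
                    assert n == 1
                    if num > 0:
                        assert lod == pytest.approx(np.log(num / den))
                    else:
                        assert np.isneginf(lod)

    def test_additivity_over_loci(self, rng):
        p = rng.uniform(0.1, 0.4, size=30)
        model = pat.LodModel(p, error_rate=0.05, min_loci=1)
        go = rng.integers(0, 3, 30).astype(np.int8)
        gmom = rng.integers(0, 3, 30).astype(np.int8)
        gdad = rng.integers(0, 3, 30).astype(np.int8)
        total, n = pat.lod_score(go, gmom, gdad, model)
        per_locus = []
        for j in range(30):
            m1 = pat.LodModel(p[j:j + 1], error_rate=0.05, min_loci=1)
            per_locus.append(pat.lod_score(go[j:j + 1], gmom[j:j + 1],
                                           gdad[j:j + 1], m1)[0])
        assert total == pytest.approx(sum(per_locus), rel=1e-9)

    def test_opposing_homozygote_infinite_at_zero_error(self):
        model0 = pat.LodModel(np.array([0.3] * 5), error_rate=0.0, min_loci=1)
        go = np.array([2, 0, 0, 0, 0], np.int8)
        gmom = np.array([1, 0, 0, 0, 0], np.int8)
        gdad = np.array([0, 0, 0, 0, 0], np.int8)  # opposing at locus 0
        lod, n = pat.lod_score(go, gmom, gdad, model0)
        assert np.isneginf(lod)
        model1 = pat.LodModel(np.array([0.3] * 5), error_rate=0.05, min_loci=1)
        lod1, _ = pat.lod_score(go, gmom, gdad, model1)
        assert np.isfinite(lod1)

    def test_identical_candidate_ties_true_father(self, mini_nursery):
        founders = mini_nursery["founders"]
        progeny = mini_nursery["progeny"]
        truth, fams = mini_nursery["truth"], mini_nursery["families"]
        model = pat.LodModel(founders.allele_frequencies(), error_rate=0.01,
                             min_loci=10)
        fidx = {g: i for i, g in enumerate(founders.ids)}
        pid = next(p for p, f in truth.true_father.items() if f != pf.SELF)
        j = progeny.ids.index(pid)
        dad = founders.calls[fidx[truth.true_father[pid]]]
        mom = founders.calls[fidx[fams.mother_of[pid]]]
        lod_true, _ = pat.lod_score(progeny.calls[j], mom, dad, model)
        lod_clone, _ = pat.lod_score(progeny.calls[j], mom, dad.copy(), model)
        assert lod_clone == lod_true


class TestCalibration:
    def test_determinism_and_ordering(self, mini_nursery):
        founders = mini_nursery["founders"]
        model = pat.LodModel(founders.allele_frequencies(), error_rate=0.05,
                             min_loci=50)
        t1 = pat.calibrate_confidence(founders, model, n_offspring=500, seed=4)
        t2 = pat.calibrate_confidence(founders, model, n_offspring=500, seed=4)
        assert t1.lod_strict == t2.lod_strict
        assert t1.lod_strict >= t1.lod_relaxed

    def test_higher_error_does_not_lower_strict_threshold(self, mini_nursery):
        founders = mini_nursery["founders"]
        freqs = founders.allele_frequencies()
        thr = {}
        for eps in (0.0, 0.1):
            model = pat.LodModel(freqs, error_rate=max(eps, 1e-6), min_loci=50)
            thr[eps] = pat.calibrate_confidence(
                founders, model, n_offspring=800, error_rate=eps, seed=7
            ).lod_strict
        assert thr[0.1] >= thr[0.0]

    def test_zero_error_full_sampling_accuracy_by_construction(self, mini_nursery):
        founders = mini_nursery["founders"]
        model = pat.LodModel(founders.allele_frequencies(), error_rate=1e-6,
                             min_loci=50)
        t = pat.calibrate_confidence(founders, model, n_offspring=500,
                                     prop_candidates_sampled=1.0, seed=1)
        assert t.achieved["accuracy_at_strict"] >= 0.95


@pytest.fixture(scope="module")
def assigned(mini_nursery):
    founders = mini_nursery["founders"]
    model = pat.LodModel(founders.allele_frequencies(), error_rate=0.01,
                         min_loci=50)
    thr = pat.calibrate_confidence(founders, model, n_offspring=1000,
                                   prop_candidates_sampled=1.0, seed=2)
    table = pat.assign_paternity(mini_nursery["progeny"],
                                 mini_nursery["families"], founders,
                                 model, thr)
    return table, model, thr


class TestAssignment:
    def test_error_free_fixture_recovers_all_fathers(self, assigned, mini_nursery):
        table, _, _ = assigned
        truth = mini_nursery["truth"]
        strict = table[table.confidence == "strict95"]
        assert len(strict) == len(table)  # all assigned on clean data
        for r in strict.itertuples():
            assert truth.true_father[r.progeny_id] == r.father_id

    def test_no_self_assignment_when_outcrossed(self, assigned):
        table, _, _ = assigned
        assert not table.is_self.any()

    def test_min_loci_rule_forces_unassigned(self, mini_nursery, assigned):
        _, model, thr = assigned
        founders = mini_nursery["founders"]
        progeny = mini_nursery["progeny"]
        sparse = progeny.calls.copy()
        sparse[0, 40:] = pf.MISSING  # progeny 0 typed at only 40 < 50 loci
        gm = pf.GenotypeMatrix(list(progeny.ids), list(progeny.loci), sparse)
        table = pat.assign_paternity(gm, mini_nursery["families"], founders,
                                     model, thr)
        assert table.iloc[0].confidence == "unassigned"
        assert table.iloc[0].father_id is None

    def test_selfing_recovery(self):
        cfg = pf.SimConfig(
            n_candidates=56, n_families=8, family_size=7, n_mothers_sampled=3,
            progeny_per_mother=(8, 10), n_loci=200, genotyping_error=0.0,
            missing_rate=0.0, selfing_rate=1.0, seed=5)
        founders, fm, progeny, fams, truth = pf.simulate_nursery(cfg)
        model = pat.LodModel(founders.allele_frequencies(), error_rate=0.01,
                             min_loci=50)
        thr = pat.ConfidenceThresholds(0.0, 0.0, {})
        table = pat.assign_paternity(progeny, fams, founders, model, thr)
        assigned = table[table.father_id.notna()]
        assert (assigned.is_self.mean()) > 0.9  # mother is her own best match


class TestSummaries:
    def test_degenerate_single_father(self):
        table = pd.DataFrame({
            "progeny_id": [f"p{i}" for i in range(6)],
            "mother_id": ["m"] * 6, "father_id": ["f"] * 6,
            "lod": 10.0, "n_loci_compared": 100,
            "confidence": "strict95", "is_self": False, "tie": False,
        })
        s = pat.paternity_summary(table)
        assert s["unique_fathers"] == 1
        assert s["mean_progeny_per_father"] == 6

    def test_counts_match_brute_force_grouping(self, mini_nursery):
        founders = mini_nursery["founders"]
        model = pat.LodModel(founders.allele_frequencies(), error_rate=0.01,
                             min_loci=50)
        thr = pat.ConfidenceThresholds(0.0, 0.0, {})
        table = pat.assign_paternity(mini_nursery["progeny"],
                                     mini_nursery["families"], founders,
                                     model, thr)
        s = pat.paternity_summary(table)
        assigned = table.dropna(subset=["father_id"])
        assert s["n_assigned"] == len(assigned)
        assert s["unique_fathers"] == len(set(assigned.father_id))
        per_mother = {m: len(set(g.father_id))
                      for m, g in assigned.groupby("mother_id")}
        assert s["mean_fathers_per_mother"] == pytest.approx(
            np.mean(list(per_mother.values())))
        pair_sizes = assigned.groupby(["mother_id", "father_id"]).size()
        assert s["max_progeny_per_pair"] == pair_sizes.max()


class TestNielsen:
    def test_exact_values(self):
        assert pat.nielsen_effective_fathers([5])["effective_fathers"] == 1.0
        res = pat.nielsen_effective_fathers([2, 2])
        assert res["Q"] == pytest.approx(1 / 3)
        assert res["effective_fathers"] == pytest.approx(3.0)
        assert pat.nielsen_effective_fathers([1, 1])["unbounded"]
        with pytest.raises(ValueError):
            pat.nielsen_effective_fathers([1])


class TestKs:
    def test_limits(self):
        d, p = pat.ks_progeny_vs_distance([1, 2, 3], [1, 2, 3])
        assert d == 0.0
        d, p = pat.ks_progeny_vs_distance([1, 2], [10, 20])
        assert d == 1.0

    def test_matches_ecdf_brute_force(self, rng):
        a = rng.exponential(3.0, size=50)
        b = rng.uniform(0, 15, size=80)
        d, _ = pat.ks_progeny_vs_distance(a, b)
        grid = np.concatenate([a, b])
        sup = max(abs((a <= x).mean() - (b <= x).mean()) for x in grid)
        assert d == pytest.approx(sup, abs=1e-12)
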