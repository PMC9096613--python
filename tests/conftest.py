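import numpy as np
import pytest

import pollenflow as pf


@pytest.fixture(scope="session")
def mini_nursery():
    """Deterministic miniature nursery: 56 candidates, 200 loci, error-free."""
    founders, fieldmap, progeny, families, truth = pf.make_fixtures(seed=1)
    return {
        "founders": founders, "fieldmap": fieldmap, "progeny": progeny,
        "families": families, "truth": truth,
    }


@pytest.fixture(scope="session")
def noisy_nursery():
    """Mid-size nursery with genotyping error and missingness."""
    cfg = pf.SimConfig(
        n_candidates=150, n_families=20, family_size=7, n_mothers_sampled=5,
        progeny_per_mother=(20, 30), n_loci=600, genotyping_error=0.01,
        missing_rate=0.05, selfing_rate=0.0, seed=3,
    )
    founders, fieldmap, progeny, families, truth = pf.simulate_nursery(cfg)
    return {
        "cfg": cfg, "founders": founders, "fieldmap": fieldmap,
        "progeny": progeny, "families": families, "truth": truth,
        "freqs": founders.allele_frequencies(),
    }


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_genotypes(rng, n=20, L=50, miss=0.1, ids_prefix="I"):
    """Small random matrix helper shared across test modules."""
    p = rng.uniform(0.05, 0.5, size=L)
    calls = rng.binomial(2, p[None, :] * np.ones((n, 1))).astype(np.int8)
    calls[rng.random(calls.shape) < miss] = pf.MISSING
    return pf.GenotypeMatrix(
        [f"{ids_prefix}{i:03d}" for i in range(n)],
        [f"L{j:03d}" for j in range(L)], calls,
    )
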