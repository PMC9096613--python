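"""Population-genetic summary statistics for biallelic dosage matrices.

Heterozygosity, PIC, Hardy-Weinberg tests, second-parent non-exclusion
probability, Weir-Cockerham F_ST, Nei's standard distance, Shannon
diversity, hypergeometric rarefaction, VanRaden relationships / IBS
dissimilarity, and PCA of centered dosages.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .genotype_io import MISSING, GenotypeMatrix

__all__ = [
    "heterozygosity",
    "pic",
    "hwe_test",
    "non_exclusion_second_parent",
    "weir_cockerham_fst",
    "nei_distance",
    "shannon_index",
    "rarefaction_richness",
    "grm_vanraden",
    "ibs_dissimilarity",
    "pca_scores",
    "diversity_summary",
]


def _group_calls(gm: GenotypeMatrix, group) -> np.ndarray:
    calls = gm.calls if group is None else gm.calls[gm.index_of(group)]
    if calls.shape[0] == 0:
        raise ValueError("empty group")
    return calls


def heterozygosity(gm: GenotypeMatrix, group=None):
    """Mean observed and expected heterozygosity over loci.

    H_o per locus is the heterozygote fraction among non-missing calls;
    H_e = 2p(1-p) with the small-sample correction n/(n-1).  Loci with
    fewer than 2 genotyped individuals are excluded from the means.
    """
    calls = _group_calls(gm, group)
    ok = calls != MISSING
    n = ok.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        ho = ((calls == 1) & ok).sum(axis=0) / n
        p = np.where(ok, calls, 0).sum(axis=0) / (2.0 * n)
        he = 2.0 * p * (1.0 - p) * n / (n - 1.0)
    valid = n >= 2
    return float(np.nanmean(ho[valid])), float(np.nanmean(he[valid]))


def pic(freqs) -> np.ndarray:
    """Biallelic polymorphism information content 1 - (p²+q²) - 2p²q²."""
    p = np.asarray(freqs, dtype=float)
    q = 1.0 - p
    return 1.0 - (p**2 + q**2) - 2.0 * p**2 * q**2


def hwe_test(gm: GenotypeMatrix, group=None, alpha: float = 0.05,
             min_n: int = 5):
    """Per-locus 1-df chi-square goodness of fit to Hardy-Weinberg.

    Loci with < ``min_n`` genotyped individuals or no polymorphism are
    skipped (NaN p-value, not deviating).  Returns ``(deviating mask,
    p-values, n_deviating)``.
    """
    calls = _group_calls(gm, group)
    ok = calls != MISSING
    n = ok.sum(axis=0)
    n0 = ((calls == 0) & ok).sum(axis=0).astype(float)
    n1 = ((calls == 1) & ok).sum(axis=0).astype(float)
    n2 = ((calls == 2) & ok).sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = (n1 + 2 * n2) / (2.0 * n)
        e0, e1, e2 = n * (1 - p) ** 2, n * 2 * p * (1 - p), n * p**2
        chi2 = (n0 - e0) ** 2 / e0 + (n1 - e1) ** 2 / e1 + (n2 - e2) ** 2 / e2
    testable = (n >= min_n) & (p > 0) & (p < 1)
    pvals = np.full(calls.shape[1], np.nan)
    pvals[testable] = stats.chi2.sf(chi2[testable], df=1)
    deviating = np.zeros(calls.shape[1], dtype=bool)
    deviating[testable] = pvals[testable] < alpha
    return deviating, pvals, int(deviating.sum())


def non_exclusion_second_parent(freqs) -> tuple:
    """Combined second-parent non-exclusion probability, mother known.

    Per-locus exclusion power uses the codominant-locus closed form with
    one parent known (Jamieson-Taylor sums over allele frequencies a_i):
    P2 = 1 - 2Σa² + Σa³ + 2Σa⁴ - 3Σa⁵ - 2(Σa²)² + 3Σa²Σa³.
    Combined N_E = Π(1 - P2_l).  Returns ``(N_E, per-locus exclusion)``.
    """
    p = np.asarray(freqs, dtype=float)
    p = p[np.isfinite(p)]
    a2 = p**2 + (1 - p) ** 2
    a3 = p**3 + (1 - p) ** 3
    a4 = p**4 + (1 - p) ** 4
    a5 = p**5 + (1 - p) ** 5
    excl = (1.0 - 2.0 * a2 + a3 + 2.0 * a4 - 3.0 * a5
            - 2.0 * a2**2 + 3.0 * a2 * a3)
    excl = np.clip(excl, 0.0, 1.0)
    ne = float(np.exp(np.sum(np.log1p(-excl))))
    return ne, excl


def weir_cockerham_fst(gm: GenotypeMatrix, groups: dict):
    """Weir-Cockerham θ from genotype counts per group.

    ``groups`` maps group name -> list of individual ids (>= 2 groups).
    Per-locus variance components a, b, c are computed from sample sizes,
    allele frequencies and heterozygote fractions; the mean over loci is
    the ratio-of-sums Σa / Σ(a+b+c).  Loci monomorphic across all groups
    (or with any group under 2 genotyped individuals) are excluded.
    Returns ``(per-locus θ, mean θ)``.
    """
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    mats = [_group_calls(gm, ids) for ids in groups.values()]
    r = len(mats)
    L = gm.n_loci
    ni = np.zeros((r, L))
    pi = np.zeros((r, L))
    hi = np.zeros((r, L))
    for k, calls in enumerate(mats):
        ok = calls != MISSING
        ni[k] = ok.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            pi[k] = np.where(ok, calls, 0).sum(axis=0) / (2.0 * ni[k])
            hi[k] = ((calls == 1) & ok).sum(axis=0) / ni[k]

    nsum = ni.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        nbar = nsum / r
        nc = (nsum - (ni**2).sum(axis=0) / nsum) / (r - 1.0)
        pbar = (ni * pi).sum(axis=0) / nsum
        s2 = (ni * (pi - pbar) ** 2).sum(axis=0) / ((r - 1.0) * nbar)
        hbar = (ni * hi).sum(axis=0) / nsum
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1.0) / r * s2 - hbar / 4.0) / (nbar - 1.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1 - pbar) - (r - 1.0) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2.0
        theta = a / (a + b + c)

    valid = (ni >= 2).all(axis=0) & (pbar > 0) & (pbar < 1)
    theta = np.where(valid, theta, np.nan)
    denom = np.where(valid, a + b + c, 0.0).sum()
    mean_theta = float(np.where(valid, a, 0.0).sum() / denom) if denom > 0 else np.nan
    return theta, mean_theta


def _nei_j(freqA, freqB):
    """Per-locus allele-identity sums for two biallelic frequency vectors."""
    jA = freqA**2 + (1 - freqA) ** 2
    jB = freqB**2 + (1 - freqB) ** 2
    jAB = freqA * freqB + (1 - freqA) * (1 - freqB)
    return jA, jB, jAB


def nei_distance(freqA, freqB) -> float:
    """Nei's standard genetic distance D = -ln(J_AB / sqrt(J_A J_B)).

    Inputs are per-locus allele frequencies of the two groups; J terms are
    means over the shared loci.  Identity 0 gives +inf.
    """
    freqA = np.asarray(freqA, float)
    freqB = np.asarray(freqB, float)
    ok = np.isfinite(freqA) & np.isfinite(freqB)
    if not ok.any():
        raise ValueError("no shared genotyped loci")
    jA, jB, jAB = _nei_j(freqA[ok], freqB[ok])
    I = jAB.mean() / np.sqrt(jA.mean() * jB.mean())
    if I <= 0:
        return float("inf")
    return float(-np.log(min(I, 1.0)))


def nei_distance_groups(gm: GenotypeMatrix, groupA, groupB) -> float:
    """Nei's standard D between two groups of individuals."""
    return nei_distance(gm.allele_frequencies(groupA),
                        gm.allele_frequencies(groupB))


def mean_pairwise_nei(gm: GenotypeMatrix, group) -> float:
    """Mean pairwise Nei's D among individuals (each as a 1-genet 'population')."""
    calls = _group_calls(gm, group).astype(float)
    calls[calls == MISSING] = np.nan
    freqs = calls / 2.0
    n = freqs.shape[0]
    if n < 2:
        return float("nan")
    vals = []
    for i in range(n):
        for j in range(i + 1, n):
            ok = np.isfinite(freqs[i]) & np.isfinite(freqs[j])
            if ok.any():
                jA, jB, jAB = _nei_j(freqs[i][ok], freqs[j][ok])
                I = jAB.mean() / np.sqrt(jA.mean() * jB.mean())
                vals.append(-np.log(I) if I > 0 else np.inf)
    return float(np.mean(vals))


def shannon_index(category_counts) -> float:
    """Shannon diversity H = -Σ p_i ln p_i over positive categories."""
    c = np.asarray(category_counts, dtype=float)
    if (c < 0).any():
        raise ValueError("negative counts")
    c = c[c > 0]
    if c.size == 0:
        raise ValueError("all counts zero")
    p = c / c.sum()
    return float(-(p * np.log(p)).sum())


def rarefaction_richness(category_counts, depth: int) -> float:
    """Expected distinct categories in a subsample of ``depth`` draws.

    Hypergeometric expectation E[S] = Σ_i [1 - C(N - N_i, d) / C(N, d)].
    """
    c = np.asarray(category_counts, dtype=float)
    c = c[c > 0]
    N = c.sum()
    if depth > N:
        raise ValueError(f"depth {depth} exceeds total count {int(N)}")
    if depth < 1:
        raise ValueError("depth must be >= 1")
    # log-gamma form avoids overflow for large counts
    def logC(n, k):
        from scipy.special import gammaln
        return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)

    terms = np.where(
        N - c >= depth,
        1.0 - np.exp(logC(N - c, depth) - logC(N, depth)),
        1.0,
    )
    return float(terms.sum())


def grm_vanraden(gm: GenotypeMatrix, group=None, ref_freqs=None):
    """VanRaden method-1 genomic relationship matrix.

    G = ZZ' / (2 Σ p(1-p)) with Z the dosage matrix centered at 2p from a
    declared reference frequency set (defaults to the group itself).
    Missing calls are centered to zero (mean imputation).
    """
    calls = _group_calls(gm, group)
    if ref_freqs is None:
        ok = calls != MISSING
        n = ok.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            ref_freqs = np.where(ok, calls, 0).sum(axis=0) / (2.0 * n)
    p = np.asarray(ref_freqs, dtype=float)
    usable = np.isfinite(p) & (p > 0) & (p < 1)
    denom = 2.0 * (p[usable] * (1 - p[usable])).sum()
    if denom == 0:
        raise ValueError("all loci monomorphic: zero VanRaden denominator")
    Z = np.where(calls == MISSING, 2 * p[None, :], calls)[:, usable] - 2 * p[usable]
    return Z @ Z.T / denom


def ibs_dissimilarity(gm: GenotypeMatrix, group=None):
    """Mean pairwise allele-sharing dissimilarity (1 - IBS fraction).

    Per pair and locus the dissimilarity is |g1 - g2| / 2 over loci typed
    in both; returns ``(pairwise matrix, mean over off-diagonal pairs)``.
    """
    calls = _group_calls(gm, group).astype(float)
    n = calls.shape[0]
    ok = calls != MISSING
    X = np.where(ok, calls, 0.0)
    M = ok.astype(float)
    # |g1-g2| = g1+g2 - 2*min; compute via expansion over dosage indicators
    D = np.zeros((n, n))
    C = np.zeros((n, n))
    for a in range(3):
        Ia = (calls == a) * 1.0
        for b in range(3):
            Ib = (calls == b) * 1.0
            D += (abs(a - b) / 2.0) * (Ia @ Ib.T)
    C = M @ M.T
    with np.errstate(invalid="ignore", divide="ignore"):
        P = D / C
    if n < 2:
        return P, float("nan")
    iu = np.triu_indices(n, k=1)
    return P, float(np.nanmean(P[iu]))


def pca_scores(gm: GenotypeMatrix, k: int = 2, group=None):
    """PCA of mean-centered dosages (missing mean-imputed).

    Returns ``(scores (n, k), variance fraction per axis)``.
    """
    calls = _group_calls(gm, group).astype(float)
    if calls.shape[0] < k:
        raise ValueError("fewer individuals than requested components")
    calls[calls == MISSING] = np.nan
    mu = np.nanmean(calls, axis=0)
    X = np.where(np.isnan(calls), mu, calls) - mu
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    var = s**2
    frac = var / var.sum() if var.sum() > 0 else np.zeros_like(var)
    return U[:, :k] * s[:k], frac[:k]


def diversity_summary(gm: GenotypeMatrix, group=None, hwe_alpha: float = 0.05) -> dict:
    """One-group digest: A, H_o, H_e, PIC, N_E, HWE-deviating count."""
    calls = _group_calls(gm, group)
    ok = calls != MISSING
    n = ok.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(ok, calls, 0).sum(axis=0) / (2.0 * n)
    poly = (p > 0) & (p < 1)
    A = float(np.where(n > 0, np.where(poly, 2.0, 1.0), np.nan)[n > 0].mean())
    ho, he = heterozygosity(gm, group)
    mean_pic = float(np.nanmean(pic(p[np.isfinite(p)])))
    ne, _ = non_exclusion_second_parent(p)
    _, _, n_dev = hwe_test(gm, group, alpha=hwe_alpha)
    return {
        "A": A, "H_o": ho, "H_e": he, "PIC": mean_pic,
        "N_E": ne, "hwe_deviating": n_dev,
    }
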