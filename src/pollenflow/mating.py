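"""Mixed-mating maximum-likelihood estimation from half-sib progeny arrays.

Each progeny of a known mother is modeled as a mixture: with probability
``s`` it is a self, with probability ``1 - s`` an outcross sired by a
random draw from the pollen pool (plug-in allele frequencies of the
candidate population).  The selfing indicator is shared across loci, which
makes the multilocus likelihood; per-locus maximization gives the
single-locus rate.  Reported parameters follow the standard mixed-mating
notation: multilocus outcrossing rate t_m = 1 - ŝ, single-locus rate t_s
(mean of per-locus estimates), biparental inbreeding t_m - t_s, and
correlated paternity r_p (probability two outcrossed sibs share a father).
Spread comes from bootstrap resampling of maternal families.

Observed genotypes enter through the same symmetric dosage-flip error
mixture as the paternity likelihood; the mother's true genotype is
integrated per progeny against its posterior (a composite-likelihood
treatment of the shared mother).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .genotype_io import MISSING, GenotypeMatrix, FamilyTable
from .paternity import _error_matrix, _hwe_prior, _T, _MISS_CODE

logger = logging.getLogger(__name__)

__all__ = [
    "MatingSystemEstimate",
    "pollen_pool_frequencies",
    "family_log_likelihood",
    "estimate_outcrossing",
    "correlated_paternity",
]


@dataclass
class MatingSystemEstimate:
    """Point estimates with family-bootstrap spread."""

    t_m: float
    t_s: float
    r_p: float = float("nan")
    bootstrap_sd: dict = field(default_factory=dict)
    n_bootstrap: int = 0
    rp_p_value: float = float("nan")
    rp_direct: float = float("nan")

    @property
    def biparental(self) -> float:
        return self.t_m - self.t_s


def pollen_pool_frequencies(gm: GenotypeMatrix, candidate_ids=None) -> np.ndarray:
    """Plug-in allele frequencies of the pollen-donor population."""
    return gm.allele_frequencies(candidate_ids)


# ---------------------------------------------------------------------------
# per-family probability tables
# ---------------------------------------------------------------------------

def _family_tables(mother_calls, freqs, eps):
    """Per-locus P(offspring call | self) and P(offspring call | outcross).

    Returns ``(a, b)`` of shape (L, 4): column = offspring call code
    (0-2 dosage, 3 missing -> probability 1).
    """
    L = len(freqs)
    E = _error_matrix(eps)  # (4,3)
    prior = _hwe_prior(freqs)
    p = np.clip(np.asarray(freqs, float), 1e-6, 1 - 1e-6)
    mc = np.where(mother_calls == MISSING, _MISS_CODE, mother_calls).astype(int)
    post_m = prior * E[mc]  # (L,3) unnormalized
    norm = post_m.sum(axis=1, keepdims=True)
    post_m = np.where(norm > 0, post_m / norm, prior)

    # self: both gametes from the mother's true genotype
    Tself = _T[np.arange(3), np.arange(3)]  # (3 true mom, 3 true off)
    a = np.einsum("lm,mt,ot->lo", post_m, Tself, E)  # (L,4)

    # outcross: maternal gamete x pollen allele Bernoulli(p)
    gam = np.stack([1 - p, p], axis=1)
    Tout = np.zeros((L, 3, 3))
    for tm in range(3):
        pm = tm / 2.0
        for am in (0, 1):
            w = pm if am else 1 - pm
            Tout[:, tm, am] += w * gam[:, 0]
            Tout[:, tm, am + 1] += w * gam[:, 1]
    b = np.einsum("lm,lmt,ot->lo", post_m, Tout, E)
    a[:, 3] = 1.0
    b[:, 3] = 1.0
    return a, b


def _per_progeny_probs(families: FamilyTable, gm_progeny: GenotypeMatrix,
                       mother_gm: GenotypeMatrix, freqs, eps):
    """Stack per-progeny per-locus self/outcross probabilities.

    Returns ``(A, B, fam_index, fam_names)`` with A, B of shape
    (L, n_progeny): P(obs call | self) and P(obs call | outcross).
    """
    fam_names = families.mothers
    mother_idx = {m: i for i, m in enumerate(mother_gm.ids)}
    prog_idx = {p: i for i, p in enumerate(gm_progeny.ids)}
    cols_A, cols_B, fam_of_col = [], [], []
    for fi, m in enumerate(fam_names):
        if m not in mother_idx:
            raise KeyError(f"mother {m!r} not genotyped")
        a, b = _family_tables(mother_gm.calls[mother_idx[m]], freqs, eps)
        pids = [p for p in families.progeny_of(m) if p in prog_idx]
        if not pids:
            continue
        oc = np.where(gm_progeny.calls[[prog_idx[p] for p in pids]] == MISSING,
                      _MISS_CODE, gm_progeny.calls[[prog_idx[p] for p in pids]]).astype(int)
        L = a.shape[0]
        lidx = np.arange(L)
        cols_A.append(a[lidx[None, :], oc].T)  # (L, n_f)
        cols_B.append(b[lidx[None, :], oc].T)
        fam_of_col.extend([fi] * len(pids))
    A = np.concatenate(cols_A, axis=1)
    B = np.concatenate(cols_B, axis=1)
    return A, B, np.asarray(fam_of_col), fam_names


def family_log_likelihood(progeny_calls, mother_calls, s: float,
                          freqs, eps: float) -> float:
    """Multilocus mixed-mating log-likelihood of one family at rate ``s``.

    Per progeny P = s Π_l P_self(g_l) + (1-s) Π_l P_out(g_l); the log sum
    over progeny is returned.  Zero-probability progeny under both
    hypotheses (possible only at ε = 0) raise a flagging error.
    """
    a, b = _family_tables(mother_calls, freqs, eps)
    oc = np.where(progeny_calls == MISSING, _MISS_CODE, progeny_calls).astype(int)
    lidx = np.arange(a.shape[0])
    with np.errstate(divide="ignore"):
        lnA = np.log(a[lidx[None, :], oc]).sum(axis=1)
        lnB = np.log(b[lidx[None, :], oc]).sum(axis=1)
    if np.any(np.isneginf(lnA) & np.isneginf(lnB)):
        raise ValueError("progeny genotype inconsistent with mother at eps=0")
    return float(_mix_loglik(lnA - lnB, np.ones(len(lnA)), s) +
                 (lnB * 1.0).sum())


def _mix_loglik(d, w, s):
    """Σ w ln((1-s) + s e^d), stable for large |d|; d may be -inf."""
    d = np.clip(d, -745.0, 745.0)
    if s <= 0.0:
        return 0.0 if s == 0.0 else -np.inf
    if s >= 1.0:
        return float((w * d).sum()) if s == 1.0 else -np.inf
    return float((w * np.logaddexp(np.log1p(-s), np.log(s) + d)).sum())


def _opt_mixture(d, w, lo=0.0, hi=1.0):
    """Maximize Σ w ln((1-s) + s e^d) over s in [lo, hi].

    Newton-Raphson from the interior with a bounded Brent fallback
    (scipy's golden-section-based scalar minimizer).
    """
    from scipy.optimize import minimize_scalar

    d = np.clip(np.asarray(d, float), -745.0, 745.0)
    u = np.exp(d)

    def nll(s):
        return -_mix_loglik(d, w, s)

    def grad_hess(s):
        denom = (1 - s) + s * u
        r = (u - 1) / denom
        return float((w * r).sum()), float(-(w * r**2).sum())

    s = 0.5 * (lo + hi)
    converged = False
    for _ in range(60):
        g, h = grad_hess(s)
        if h >= 0:
            break
        step = -g / h
        s_new = min(max(s + step, lo + 1e-12 if lo == 0 else lo), hi - 1e-12)
        if abs(s_new - s) < 1e-12:
            s = s_new
            converged = True
            break
        s = s_new
    if not converged:
        res = minimize_scalar(nll, bounds=(lo, hi), method="bounded",
                              options={"xatol": 1e-10})
        if nll(res.x) <= nll(s):
            s = float(res.x)
    # boundary check
    for edge in (lo, hi):
        if nll(edge) < nll(s):
            s = edge
    return float(s)


def _per_locus_ts(A, B, w, max_iter: int = 60, s0=None, s_min: float = -0.5):
    """Vectorized per-locus ML selfing rates (Newton, bound-clipped).

    ``A, B``: (L, J) self/outcross probabilities; ``w``: per-progeny
    weights (bootstrap family multiplicities).  The per-locus estimate is
    allowed below zero (down to a feasibility-limited ``s_min``) so that
    sampling noise cancels instead of truncating when the estimates are
    averaged into t_s; bounding at zero would bias t_s downward.
    """
    L = A.shape[0]
    with np.errstate(divide="ignore", invalid="ignore"):
        U = A / B  # likelihood ratio per (locus, progeny); B > 0 always
    U = np.where(w[None, :] > 0, U, 1.0)  # zero-weight progeny are inert
    # mixture prob (1-s) + s*u must stay positive: s > -1/(max_u - 1)
    umax = U.max(axis=1)
    with np.errstate(divide="ignore"):
        lo = np.where(umax > 1, np.maximum(s_min, -0.95 / (umax - 1)), s_min)
    s = np.full(L, 0.05) if s0 is None else np.clip(np.asarray(s0, float), lo, 1 - 1e-9)
    for _ in range(max_iter):
        denom = (1 - s[:, None]) + s[:, None] * U
        R = (U - 1) / denom
        g = (R * w[None, :]).sum(axis=1)
        h = -((R**2) * w[None, :]).sum(axis=1)
        step = np.where(h < 0, -g / np.where(h < 0, h, -1.0), 0.0)
        s_new = np.clip(s + step, lo, 1 - 1e-9)
        if np.max(np.abs(s_new - s)) < 1e-10:
            s = s_new
            break
        s = s_new
    return s


# ---------------------------------------------------------------------------
# main estimators
# ---------------------------------------------------------------------------

def estimate_outcrossing(families: FamilyTable, progeny_gm: GenotypeMatrix,
                         mother_gm: GenotypeMatrix, freqs, eps: float = 0.01,
                         n_bootstrap: int = 1000, seed=0,
                         allow_negative_s: bool = False,
                         compute_rp: bool = True,
                         paternity_table=None) -> MatingSystemEstimate:
    """Multilocus and single-locus outcrossing with family bootstrap.

    Point estimates use the full data; bootstrap resamples the maternal
    families with replacement (deterministic given ``seed``).  ``t_m`` is
    bounded to [0, 1] by default; ``allow_negative_s`` permits s down to
    -0.05 (t_m up to 1.05) to mimic the upward multilocus bias reported
    for progeny-array estimators.
    """
    if len(families.mothers) < 2 and n_bootstrap > 0:
        raise ValueError("need >= 2 families for a family bootstrap")
    A, B, fam_idx, fam_names = _per_progeny_probs(
        families, progeny_gm, mother_gm, freqs, eps)
    nfam = len(fam_names)
    with np.errstate(divide="ignore"):
        d = np.log(A).sum(axis=0) - np.log(B).sum(axis=0)  # per progeny
    lo = -0.05 if allow_negative_s else 0.0
    w_full = np.ones(A.shape[1])

    s_hat = _opt_mixture(d, w_full, lo=lo, hi=1.0)
    s_loc = _per_locus_ts(A, B, w_full)
    t_m = 1.0 - s_hat
    t_s = float(1.0 - s_loc.mean())

    rp, rp_direct, d_pairs, pair_fam = float("nan"), float("nan"), None, None
    if compute_rp:
        rp, d_pairs, pair_fam = _rp_ml(families, progeny_gm, mother_gm, freqs,
                                       eps, s_hat, A, B, fam_idx)
        if paternity_table is not None:
            rp_direct = _rp_direct(paternity_table)

    sds, rp_p = {}, float("nan")
    if n_bootstrap > 0:
        rng = np.random.default_rng(seed)
        tms, tss, rps = [], [], []
        for _ in range(n_bootstrap):
            pick = rng.integers(0, nfam, size=nfam)
            mult = np.bincount(pick, minlength=nfam).astype(float)
            w = mult[fam_idx]
            if w.sum() == 0:
                continue
            tms.append(1.0 - _opt_mixture(d, w, lo=lo, hi=1.0))
            s_b = _per_locus_ts(A, B, w, max_iter=6, s0=s_loc)
            tss.append(1.0 - s_b.mean())
            if compute_rp and d_pairs is not None and len(d_pairs):
                wp = mult[pair_fam]
                if wp.sum() > 0:
                    rps.append(_opt_mixture(d_pairs, wp, lo=0.0, hi=1.0))
        tms, tss = np.asarray(tms), np.asarray(tss)
        sds = {"t_m": float(tms.std(ddof=1)), "t_s": float(tss.std(ddof=1)),
               "biparental": float((tms - tss).std(ddof=1))}
        if compute_rp and rps:
            rps = np.asarray(rps)
            sds["r_p"] = float(rps.std(ddof=1))
            rp_p = float(np.mean(rps <= 0.0))  # bootstrap percentile test
    est = MatingSystemEstimate(t_m=float(t_m), t_s=t_s, r_p=rp,
                               bootstrap_sd=sds, n_bootstrap=n_bootstrap,
                               rp_p_value=rp_p, rp_direct=rp_direct)
    logger.info("mating system: t_m=%.3f t_s=%.3f t_m-t_s=%.3f r_p=%.3f",
                est.t_m, est.t_s, est.biparental, est.r_p)
    return est


def _rp_ml(families, progeny_gm, mother_gm, freqs, eps, s_hat, A, B, fam_idx):
    """ML correlated paternity from outcrossed sib pairs.

    Pair likelihood mixture: r_p x full sibs (one father integrated over
    the pool) + (1 - r_p) x half sibs (independent fathers).  Returns
    ``(r_p, per-pair log-ratios, pair family index)``.
    """
    E = _error_matrix(eps)
    prior = _hwe_prior(freqs)
    # C[tm, td, offcode] reused from the trio machinery
    C = np.einsum("mdt,ot->mdo", _T, E)
    mother_idx = {m: i for i, m in enumerate(mother_gm.ids)}
    prog_idx = {p: i for i, p in enumerate(progeny_gm.ids)}
    with np.errstate(divide="ignore"):
        lnA_cols = np.log(A)
        lnB_cols = np.log(B)
    d_prog = lnA_cols.sum(axis=0) - lnB_cols.sum(axis=0)
    # posterior self probability per progeny at the fitted s
    with np.errstate(over="ignore"):
        post_self = s_hat * np.exp(np.clip(d_prog, -745, 745))
        post_self = post_self / (post_self + (1 - s_hat))

    d_pairs, pair_fam = [], []
    col = 0
    for fi, m in enumerate(families.mothers):
        pids = [p for p in families.progeny_of(m) if p in prog_idx]
        nf = len(pids)
        if nf == 0:
            continue
        cols = np.arange(col, col + nf)
        col += nf
        keep = post_self[cols] < 0.5  # outcrossed sibs only
        pids = [p for p, k in zip(pids, keep) if k]
        cols = cols[keep]
        if len(pids) < 2:
            continue
        mc = np.where(mother_gm.calls[mother_idx[m]] == MISSING, _MISS_CODE,
                      mother_gm.calls[mother_idx[m]]).astype(int)
        post_m = prior * E[mc]
        norm = post_m.sum(axis=1, keepdims=True)
        post_m = np.where(norm > 0, post_m / norm, prior)
        # F[l, g1, g2]: shared-father pair probability given this mother
        F = np.einsum("lm,ld,mdg,mdh->lgh", post_m, prior, C, C)
        oc = np.where(progeny_gm.calls[[prog_idx[p] for p in pids]] == MISSING,
                      _MISS_CODE,
                      progeny_gm.calls[[prog_idx[p] for p in pids]]).astype(int)
        lidx = np.arange(F.shape[0])
        lnb = lnB_cols[:, cols]  # (L, nf)
        i1, i2 = np.triu_indices(len(pids), k=1)
        with np.errstate(divide="ignore"):
            lnF = np.log(F[lidx[None, :], oc[i1], oc[i2]]).sum(axis=1)
        d_pairs.extend(lnF - lnb[:, i1].sum(axis=0) - lnb[:, i2].sum(axis=0))
        pair_fam.extend([fi] * len(i1))
    if not d_pairs:
        raise ValueError("no eligible outcrossed sib pairs for r_p")
    d_pairs = np.asarray(d_pairs)
    pair_fam = np.asarray(pair_fam)
    rp = _opt_mixture(d_pairs, np.ones(len(d_pairs)), lo=0.0, hi=1.0)
    return float(rp), d_pairs, pair_fam


def _rp_direct(paternity_table) -> float:
    """Identity-probability estimate from assigned fathers, mean over families."""
    vals = []
    assigned = paternity_table[paternity_table.father_id.notna()
                               & ~paternity_table.is_self]
    for m, sub in assigned.groupby("mother_id"):
        x = sub.groupby("father_id").size().to_numpy(float)
        n = x.sum()
        if n >= 2:
            vals.append(float((x * (x - 1)).sum() / (n * (n - 1))))
    return float(np.mean(vals)) if vals else float("nan")


def correlated_paternity(families: FamilyTable, progeny_gm: GenotypeMatrix,
                         mother_gm: GenotypeMatrix, freqs, eps: float = 0.01,
                         s_hat: float = 0.0, paternity_table=None) -> dict:
    """Standalone r_p: ML on sib pairs, plus the direct estimate if a
    paternity table is supplied (cross-validation of the two routes)."""
    A, B, fam_idx, _ = _per_progeny_probs(families, progeny_gm, mother_gm,
                                          freqs, eps)
    rp, d_pairs, pair_fam = _rp_ml(families, progeny_gm, mother_gm, freqs,
                                   eps, s_hat, A, B, fam_idx)
    out = {"r_p_ml": rp, "n_pairs": int(len(d_pairs))}
    if paternity_table is not None:
        out["r_p_direct"] = _rp_direct(paternity_table)
    return out
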