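"""Categorical LOD-based paternity assignment with known mothers.

The LOD score of a candidate father for a progeny with known mother is the
natural-log likelihood ratio, summed over loci typed in all three
individuals, of "the candidate is the father" versus "the father is a
random draw from the pollen pool".  Observed genotypes enter through a
symmetric dosage-flip error mixture: each call is true with probability
1 - ε, otherwise one of the two wrong dosages (ε/2 each); the likelihood
integrates over true genotypes with Hardy-Weinberg priors at the pollen
pool frequencies.  Confidence thresholds are calibrated by simulating
offspring from the candidate pool, exactly in the spirit of the
categorical-assignment programs used for SNP parentage.

Implementation note: per-locus log-ratio tables are precomputed for every
(mother call, offspring call, father call) combination, so scoring a batch
of progeny against all candidates reduces to three matrix products against
one-hot candidate dosage indicators.  Log 0 is floored at ``LOG_FLOOR``;
any LOD below ``NEG_INF_CUTOFF`` is reported as -inf by the scalar API.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix, FamilyTable

logger = logging.getLogger(__name__)

LOG_FLOOR = -1e7
NEG_INF_CUTOFF = -1e6
_MISS_CODE = 3  # internal 4-state call code

__all__ = [
    "LodModel",
    "ConfidenceThresholds",
    "trio_genotype_prob",
    "lod_score",
    "calibrate_confidence",
    "assign_paternity",
    "paternity_summary",
    "headline_ratios",
    "nielsen_effective_fathers",
    "ks_progeny_vs_distance",
]


# ---------------------------------------------------------------------------
# probability tables
# ---------------------------------------------------------------------------

def _mendel_cube() -> np.ndarray:
    """T[gm, gd, go]: Mendelian transmission for diploid dosages."""
    T = np.zeros((3, 3, 3))
    for gm in range(3):
        for gd in range(3):
            pm, pdd = gm / 2.0, gd / 2.0
            gam_m = np.array([1 - pm, pm])
            gam_d = np.array([1 - pdd, pdd])
            for am in (0, 1):
                for ad in (0, 1):
                    T[gm, gd, am + ad] += gam_m[am] * gam_d[ad]
    return T


_T = _mendel_cube()


def _error_matrix(eps: float) -> np.ndarray:
    """E[obs, true] for the symmetric dosage-flip model; obs 3 = missing -> 1."""
    E = np.full((4, 3), eps / 2.0)
    for g in range(3):
        E[g, g] = 1.0 - eps
    E[3, :] = 1.0  # missing call: contributes probability 1
    return E


def _hwe_prior(freqs: np.ndarray) -> np.ndarray:
    p = np.clip(np.asarray(freqs, float), 1e-6, 1 - 1e-6)
    return np.stack([(1 - p) ** 2, 2 * p * (1 - p), p**2], axis=1)  # (L, 3)


@dataclass
class LodModel:
    """Likelihood model: pollen-pool frequencies, error rate, locus rule."""

    freqs: np.ndarray
    error_rate: float = 0.10
    min_loci: int = 300

    def __post_init__(self):
        if not 0.0 <= self.error_rate < 0.5:
            raise ValueError("error_rate must be in [0, 0.5)")
        if self.min_loci < 1:
            raise ValueError("min_loci must be >= 1")
        self.freqs = np.asarray(self.freqs, dtype=float)

    # cached tables -----------------------------------------------------
    _tables: dict = field(default=None, repr=False, compare=False)

    def tables(self) -> dict:
        """Precompute per-locus numerator/denominator log tables.

        W[l, mom_code, off_code, dad_code] = ln P(off | mom, dad) -
        ln P(off | mom, pool); codes 0-2 dosage, 3 missing (-> 0 weight).
        """
        if self._tables is not None:
            return self._tables
        E = _error_matrix(self.error_rate)  # (4,3)
        prior = _hwe_prior(self.freqs)  # (L,3)
        p = np.clip(self.freqs, 1e-6, 1 - 1e-6)
        # posterior over true genotype given an observed call
        post = prior[:, None, :] * E[None, :, :]  # (L, obs4, true3)
        post[:, :3, :] /= post[:, :3, :].sum(axis=2, keepdims=True)
        post[:, 3, :] = prior  # missing call -> prior

        # pool transmission: Tpool[l, tm, to] with pollen allele Bernoulli(p)
        gam = np.stack([1 - p, p], axis=1)  # (L,2)
        Tpool = np.zeros((len(p), 3, 3))
        for tm in range(3):
            pm = tm / 2.0
            for am in (0, 1):
                w_m = pm if am else 1 - pm
                for ad in (0, 1):
                    Tpool[:, tm, am + ad] += w_m * gam[:, ad]

        # C[tm, td, off_code] = Σ_to T[tm,td,to] E[off_code,to]
        C = np.einsum("mdt,ot->mdo", _T, E)  # (3,3,4)
        # numerator N[l, momc, dadc, offc]
        N = np.einsum("lam,lbd,mdo->labo", post, post, C)
        # denominator D[l, momc, offc] = Σ_tm post_m Σ_to Tpool E
        D = np.einsum("lam,lmt,ot->lao", post, Tpool, E)
        with np.errstate(divide="ignore", invalid="ignore"):
            W = np.log(N) - np.log(D)[:, :, None, :]
        W = np.nan_to_num(W, neginf=LOG_FLOOR, posinf=LOG_FLOOR)
        # skipped loci: any missing among mother/offspring -> 0; dad missing -> 0
        W[:, 3, :, :] = 0.0
        W[:, :, 3, :] = 0.0
        W[:, :, :, 3] = 0.0
        # reorder to (L, momc, offc, dadc) for the batch gather
        W = np.transpose(W, (0, 1, 3, 2)).copy()
        self._tables = {"W": W, "post": post, "Tpool": Tpool, "C": C, "E": E,
                        "prior": prior}
        return self._tables


@dataclass
class ConfidenceThresholds:
    """Simulation-calibrated LOD cutoffs (natural-log units)."""

    lod_strict: float
    lod_relaxed: float
    sim_params: dict
    achieved: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.lod_strict < self.lod_relaxed:
            raise ValueError("lod_strict must be >= lod_relaxed")


# ---------------------------------------------------------------------------
# scalar API
# ---------------------------------------------------------------------------

def _code(g) -> int:
    return _MISS_CODE if g == MISSING else int(g)


def trio_genotype_prob(g_off, g_mom, g_dad, freq: float, eps: float,
                       pool: bool = False) -> float:
    """P(observed offspring call | observed mother, observed father or pool).

    ``pool=True`` replaces the named father by a random pollen-pool draw at
    frequency ``freq``.  Missing calls contribute probability 1.
    """
    if g_off == MISSING:
        return 1.0
    model = LodModel(np.array([freq]), error_rate=eps, min_loci=1)
    t = model.tables()
    mc, oc = _code(g_mom), _code(g_off)
    post_m = t["post"][0, mc]  # (3,)
    E = t["E"]
    if pool:
        return float(np.einsum("m,mt,t->", post_m, t["Tpool"][0], E[oc]))
    dc = _code(g_dad)
    post_d = t["post"][0, dc]
    return float(np.einsum("m,d,md->", post_m, post_d, t["C"][:, :, oc]))


def lod_score(progeny_calls, mother_calls, candidate_calls,
              model: LodModel) -> tuple:
    """LOD and loci-compared count for one progeny-mother-candidate trio.

    Natural-log units, summed over loci typed in all three.  Returns
    ``(-inf, n)`` when an opposing-homozygote mismatch is impossible under
    the model (ε = 0).
    """
    W = model.tables()["W"]
    oc = np.where(progeny_calls == MISSING, _MISS_CODE, progeny_calls).astype(int)
    mc = np.where(mother_calls == MISSING, _MISS_CODE, mother_calls).astype(int)
    dc = np.where(candidate_calls == MISSING, _MISS_CODE, candidate_calls).astype(int)
    L = np.arange(len(oc))
    lod = float(W[L, mc, oc, dc].sum())
    n = int(((oc != _MISS_CODE) & (mc != _MISS_CODE) & (dc != _MISS_CODE)).sum())
    if n == 0:
        return float("nan"), 0
    if lod < NEG_INF_CUTOFF:
        return float("-inf"), n
    return lod, n


# ---------------------------------------------------------------------------
# batch engine
# ---------------------------------------------------------------------------

def _batch_lods(off_calls, mom_calls, cand_calls, model: LodModel,
                batch: int = 1000):
    """LOD matrix (progeny x candidates) and loci-compared counts.

    ``mom_calls`` is per-progeny (same shape as ``off_calls``).  Uses the
    precomputed W tables; candidates enter through one-hot dosage masks so
    the locus sum is three float32 matrix products.
    """
    W = model.tables()["W"].astype(np.float32)
    J, L = off_calls.shape
    C = cand_calls.shape[0]
    oc = np.where(off_calls == MISSING, _MISS_CODE, off_calls).astype(np.int8)
    mc = np.where(mom_calls == MISSING, _MISS_CODE, mom_calls).astype(np.int8)
    H = [np.ascontiguousarray((cand_calls == d).astype(np.float32)) for d in range(3)]
    typed_c = np.ascontiguousarray((cand_calls != MISSING).astype(np.float32))
    lods = np.empty((J, C), dtype=np.float32)
    nloci = np.empty((J, C), dtype=np.int32)
    lidx = np.arange(L)
    for s in range(0, J, batch):
        e = min(s + batch, J)
        B = W[lidx[None, :], mc[s:e], oc[s:e], :]  # (b, L, 4)
        acc = B[:, :, 0] @ H[0].T
        acc += B[:, :, 1] @ H[1].T
        acc += B[:, :, 2] @ H[2].T
        lods[s:e] = acc
        typed_po = ((oc[s:e] != _MISS_CODE) & (mc[s:e] != _MISS_CODE)).astype(np.float32)
        nloci[s:e] = np.rint(typed_po @ typed_c.T).astype(np.int32)
    return lods, nloci


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

def _threshold_for(lods: np.ndarray, correct: np.ndarray, rate: float) -> float:
    """Smallest LOD cutoff whose accepted set is >= ``rate`` correct."""
    order = np.argsort(-lods, kind="stable")
    cum_acc = np.cumsum(correct[order]) / np.arange(1, len(order) + 1)
    ok = np.flatnonzero(cum_acc >= rate)
    if ok.size == 0:
        return float(lods.max()) + 1.0
    return float(lods[order[ok[-1]]])


def calibrate_confidence(candidates: GenotypeMatrix, model: LodModel,
                         n_offspring: int = 10000,
                         prop_candidates_sampled: float = 749 / 771,
                         prop_loci_typed: float = None,
                         error_rate: float = None,
                         seed=0) -> ConfidenceThresholds:
    """Simulate offspring from the candidate pool to set LOD cutoffs.

    Random mother x father pairs are drawn from the candidates; offspring
    genotypes are Mendelian draws degraded by the typing model (error rate
    defaults to the LOD model's ε, typed fraction to the candidates'
    observed mean).  With probability ``1 - prop_candidates_sampled`` the
    true father is hidden from the scored set.  Strict (95%) and relaxed
    (80%) thresholds are the smallest cutoffs whose accepted assignments
    reach those correctness rates.  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    Cn = candidates.n_individuals
    if Cn < 3:
        raise ValueError("need at least 3 candidates to calibrate")
    eps_sim = model.error_rate if error_rate is None else error_rate
    if prop_loci_typed is None:
        prop_loci_typed = float((candidates.calls != MISSING).mean())
    L = candidates.n_loci
    p = np.clip(model.freqs, 1e-6, 1 - 1e-6)

    mom_i = rng.integers(0, Cn, size=n_offspring)
    dad_i = rng.integers(0, Cn - 1, size=n_offspring)
    dad_i[dad_i >= mom_i] += 1  # father != mother
    sampled = rng.random(n_offspring) < prop_candidates_sampled

    gm_calls = candidates.calls[mom_i].astype(np.int8)
    gd_calls = candidates.calls[dad_i].astype(np.int8)
    # unobserved parental calls: draw a true genotype from the pool prior
    for calls in (gm_calls, gd_calls):
        miss = calls == MISSING
        if miss.any():
            draw = rng.binomial(2, np.broadcast_to(p, calls.shape)[miss])
            calls[miss] = draw.astype(np.int8)
    off = ((rng.random((n_offspring, L)) < gm_calls / 2.0).astype(np.int8)
           + (rng.random((n_offspring, L)) < gd_calls / 2.0).astype(np.int8))
    # typing model on the offspring calls
    if eps_sim > 0:
        flip = rng.random(off.shape) < eps_sim
        off[flip] = ((off[flip] + rng.integers(1, 3, size=int(flip.sum()))) % 3
                     ).astype(np.int8)
    off[rng.random(off.shape) > prop_loci_typed] = MISSING

    mom_obs = candidates.calls[mom_i]  # score against observed mother calls
    lods, nloci = _batch_lods(off, mom_obs, candidates.calls, model)
    lods[np.arange(n_offspring), mom_i] = -np.inf  # mother not her own mate here
    hidden = ~sampled
    lods[hidden, dad_i[hidden]] = -np.inf
    ok_loci = nloci >= model.min_loci
    lods = np.where(ok_loci, lods, -np.inf)
    best = np.argmax(lods, axis=1)
    best_lod = lods[np.arange(n_offspring), best]
    usable = np.isfinite(best_lod)
    correct = (best == dad_i) & sampled & usable
    strict = _threshold_for(best_lod[usable], correct[usable], 0.95)
    relaxed = _threshold_for(best_lod[usable], correct[usable], 0.80)
    relaxed = min(relaxed, strict)
    acc = {
        "n_usable": int(usable.sum()),
        "accuracy_at_strict": float(correct[usable][best_lod[usable] >= strict].mean())
        if (best_lod[usable] >= strict).any() else float("nan"),
        "assign_rate_at_strict": float((best_lod[usable] >= strict).mean()),
    }
    logger.info("calibrated thresholds: strict=%.2f relaxed=%.2f (%s)",
                strict, relaxed, acc)
    return ConfidenceThresholds(strict, relaxed, {
        "n_offspring": n_offspring, "n_candidates": Cn,
        "prop_candidates_sampled": prop_candidates_sampled,
        "prop_loci_typed": prop_loci_typed, "error_rate": eps_sim,
        "seed": int(seed),
    }, acc)


# ---------------------------------------------------------------------------
# assignment
# ---------------------------------------------------------------------------

def assign_paternity(progeny: GenotypeMatrix, families: FamilyTable,
                     candidates: GenotypeMatrix, model: LodModel,
                     thresholds: ConfidenceThresholds) -> pd.DataFrame:
    """Score every progeny against every candidate and assign the best.

    The mother herself is scored too, so selfing shows up as a
    self-assignment.  A progeny is assigned at strict/relaxed confidence
    when its best LOD clears the corresponding threshold and the trio
    shares at least ``model.min_loci`` typed loci.  Exact LOD ties are
    broken by the larger loci-compared count; unresolved ties are left
    unassigned with ``tie=True``.

    Returns the paternity table: one row per progeny with columns
    progeny_id, mother_id, father_id, lod, delta, n_loci_compared,
    confidence, is_self, tie.  (delta = LOD gap to the runner-up; computed
    for completeness but never used for assignment, because half-sib
    candidate structures make it misleading.)
    """
    known = [pid for pid in progeny.ids if pid in families.mother_of]
    skipped = set(progeny.ids) - set(known)
    if skipped:
        logger.warning("%d progeny without known mother skipped", len(skipped))
    cand_index = {g: i for i, g in enumerate(candidates.ids)}
    prog = progeny.subset_individuals(known)
    mom_ids = [families.mother_of[pid] for pid in known]
    try:
        mom_rows = np.array([cand_index[m] for m in mom_ids])
    except KeyError as e:
        raise KeyError(f"mother {e.args[0]!r} not among candidates") from None
    mom_calls = candidates.calls[mom_rows]
    lods, nloci = _batch_lods(prog.calls, mom_calls, candidates.calls, model)

    rows = []
    for j, pid in enumerate(known):
        lj = lods[j]
        order = np.argsort(-lj, kind="stable")
        b0 = order[0]
        tie = False
        if len(order) > 1 and lj[order[1]] == lj[b0]:
            tied = order[lj[order] == lj[b0]]
            nl = nloci[j, tied]
            if (nl == nl.max()).sum() > 1:
                tie = True
            b0 = tied[np.argmax(nl)]
        runner = order[1] if len(order) > 1 else b0
        delta = float(lj[b0] - lj[runner])
        best_lod = float(lj[b0])
        n = int(nloci[j, b0])
        if tie or n < model.min_loci or not np.isfinite(best_lod):
            conf, father = "unassigned", None
        elif best_lod >= thresholds.lod_strict:
            conf, father = "strict95", candidates.ids[b0]
        elif best_lod >= thresholds.lod_relaxed:
            conf, father = "relaxed80", candidates.ids[b0]
        else:
            conf, father = "unassigned", None
        rows.append({
            "progeny_id": pid, "mother_id": mom_ids[j], "father_id": father,
            "lod": best_lod, "delta": delta, "n_loci_compared": n,
            "confidence": conf, "is_self": father == mom_ids[j] and father is not None,
            "tie": tie,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def paternity_summary(table: pd.DataFrame, fieldmap=None) -> dict:
    """Paternal-contribution counts from an assignment table.

    Half-sib fathers (sharing the mother's family) need a ``fieldmap``.
    """
    if table.empty:
        raise ValueError("empty paternity table")
    assigned = table[table.father_id.notna()]
    per_mother = assigned.groupby("mother_id").father_id.nunique()
    pair_counts = assigned.groupby(["mother_id", "father_id"]).size()
    father_counts = assigned.groupby("father_id").size()
    out = {
        "n_progeny": int(len(table)),
        "n_assigned": int(len(assigned)),
        "n_unassigned": int(len(table) - len(assigned)),
        "assignment_rate": float(len(assigned) / len(table)),
        "total_fathers": int(per_mother.sum()),  # father-mother combinations
        "unique_fathers": int(assigned.father_id.nunique()),
        "mean_fathers_per_mother": float(per_mother.mean()),
        "unique_parent_pairs": int(len(pair_counts)),
        "mean_progeny_per_pair": float(pair_counts.mean()),
        "max_progeny_per_pair": int(pair_counts.max()),
        "mean_progeny_per_father": float(father_counts.mean()),
        "n_self": int(assigned.is_self.sum()),
        "per_mother_father_counts": per_mother.to_dict(),
        "per_father_progeny_counts": father_counts.to_dict(),
    }
    if fieldmap is not None:
        hs = [
            fieldmap.family_of(r.father_id) == fieldmap.family_of(r.mother_id)
            and r.father_id != r.mother_id
            for r in assigned.itertuples()
        ]
        out["half_sib_father_fraction"] = float(np.mean(hs)) if hs else 0.0
    return out


def headline_ratios(n_progeny: int, n_assigned: int, total_fathers: int,
                    unique_parent_pairs: int, n_mothers: int,
                    n_unique_fathers: int) -> dict:
    """Derived summary ratios from headline counts.

    Pure arithmetic on reported tallies: assignment percentage, mean
    assigned/unassigned progeny per mother, mean fathers per mother, and
    mean progeny per parent pair / per unique father.
    """
    return {
        "assignment_pct": 100.0 * n_assigned / n_progeny,
        "mean_assigned_per_mother": n_assigned / n_mothers,
        "mean_unassigned_per_mother": (n_progeny - n_assigned) / n_mothers,
        "mean_fathers_per_mother": total_fathers / n_mothers,
        "mean_progeny_per_pair": n_assigned / unique_parent_pairs,
        "mean_progeny_per_father": n_assigned / n_unique_fathers,
    }


def nielsen_effective_fathers(counts) -> dict:
    """Unbiased effective paternity number from per-father progeny counts.

    Q̂ = Σ x_i (x_i - 1) / (n (n - 1)) estimates the probability of
    paternal identity of two random progeny; the effective number of
    fathers is 1 / Q̂.  Q̂ <= 0 is reported as unbounded.
    """
    x = np.asarray(counts, dtype=float)
    n = x.sum()
    if n < 2:
        raise ValueError("need at least 2 progeny")
    q = float((x * (x - 1)).sum() / (n * (n - 1)))
    return {
        "Q": q,
        "effective_fathers": float(1.0 / q) if q > 0 else float("inf"),
        "unbounded": q <= 0,
    }


def ks_progeny_vs_distance(realized_distances, available_distances) -> tuple:
    """Two-sample Kolmogorov-Smirnov test of realized vs available distances.

    D = sup |ECDF_realized - ECDF_available| with the asymptotic p-value;
    a large D means pollination success depends on distance.
    """
    from scipy import stats

    a = np.asarray(realized_distances, float)
    b = np.asarray(available_distances, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty sample")
    res = stats.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)
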