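"""Forward simulator of a wind-pollinated spaced-plant breeding nursery.

Emulates the statistical structure of an intermediate-wheatgrass selection
nursery: half-sib families of candidates planted adjacently on a square
grid (default 0.91 m spacing), a remainder of bi-parental F1 genets,
mothers sampled away from the borders, progeny sired through a
distance-decaying pollen dispersal kernel with optional selfing, and
genotype calls degraded by a symmetric dosage-flip error and missingness.
Ground truth (true father, realized distance, kernel, founder allele
frequencies) is recorded so every downstream stage can be verified by
parameter recovery.

Genotypes are simulated as diploid biallelic dosages: the species is
hexaploid, but the genotype calls this pipeline consumes (and every
downstream likelihood) treat loci as diploid SNPs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from .genotype_io import MISSING, GenotypeMatrix, FieldMap, FamilyTable

SELF = "SELF"

__all__ = [
    "SELF",
    "SimConfig",
    "NurseryTruth",
    "simulate_founders",
    "simulate_matings",
    "simulate_traits",
    "simulate_nursery",
]


@dataclass
class SimConfig:
    """Nursery simulation parameters.

    Defaults mirror the study nursery: 749 candidate genets (73 half-sib
    families of 9 plus bi-parental F1s filling the remainder) on a 0.91 m
    grid, 15 sampled mothers with 44-72 progeny each, 2,500 biallelic loci
    with founder MAF drawn uniformly on [0.04, 0.25], near-complete
    outcrossing, and an exponential dispersal kernel.
    """

    n_candidates: int = 749
    n_families: int = 73
    family_size: int = 9
    grid_spacing_m: float = 0.91
    n_mothers_sampled: int = 15
    progeny_per_mother: tuple = (44, 72)
    n_loci: int = 2500
    maf_law: tuple = (0.04, 0.25)  # uniform bounds for founder minor allele freq
    kernel: dict = field(
        default_factory=lambda: {"family": "exponential", "scale_m": 3.5, "shape": 1.0}
    )
    selfing_rate: float = 0.0
    genotyping_error: float = 0.01
    missing_rate: float = 0.05
    trait_h2: float = 0.5
    seed: int = 0

    def __post_init__(self):
        for name in ("selfing_rate", "genotyping_error", "missing_rate", "trait_h2"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.grid_spacing_m <= 0:
            raise ValueError("grid_spacing_m must be > 0")
        if self.n_loci < 1:
            raise ValueError("n_loci must be >= 1")
        lo, hi = self.maf_law
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_law bounds must satisfy 0 < lo <= hi <= 0.5")
        if self.kernel["family"] not in ("exponential", "exponential-power", "uniform"):
            raise ValueError(f"unknown kernel family {self.kernel['family']!r}")
        if self.kernel.get("scale_m", 1.0) <= 0:
            raise ValueError("kernel scale_m must be > 0")
        lo, hi = self.progeny_per_mother
        if not (1 <= lo <= hi):
            raise ValueError("invalid progeny_per_mother range")
        if self.n_candidates < self.n_mothers_sampled:
            raise ValueError("fewer candidates than sampled mothers")

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["progeny_per_mother"] = list(d["progeny_per_mother"])
        d["maf_law"] = list(d["maf_law"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if "progeny_per_mother" in d:
            d["progeny_per_mother"] = tuple(d["progeny_per_mother"])
        if "maf_law" in d:
            d["maf_law"] = tuple(d["maf_law"])
        return cls(**d)


@dataclass
class NurseryTruth:
    """Simulator ground truth enabling recovery tests."""

    true_father: dict  # progeny_id -> candidate_id or SELF
    realized_distance_m: dict  # progeny_id -> meters (0 for selfing)
    kernel_params: dict
    selfing_events: int
    founder_freqs: np.ndarray

    def __post_init__(self):
        if set(self.true_father) != set(self.realized_distance_m):
            raise ValueError("truth maps cover different progeny sets")
        for pid, f in self.true_father.items():
            d = self.realized_distance_m[pid]
            if d < 0:
                raise ValueError(f"negative realized distance for {pid}")
            if f == SELF and d != 0:
                raise ValueError(f"selfed progeny {pid} has nonzero distance")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "true_father": self.true_father,
                    "realized_distance_m": self.realized_distance_m,
                    "kernel_params": self.kernel_params,
                    "selfing_events": self.selfing_events,
                    "founder_freqs": list(map(float, self.founder_freqs)),
                },
                fh,
            )

    @classmethod
    def from_json(cls, path) -> "NurseryTruth":
        with open(path) as fh:
            d = json.load(fh)
        d["founder_freqs"] = np.asarray(d["founder_freqs"])
        return cls(**d)


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _gamete(dosages: np.ndarray, rng) -> np.ndarray:
    """One allele per locus from a diploid parent: Bernoulli(dosage / 2)."""
    return (rng.random(dosages.shape) < dosages / 2.0).astype(np.int8)


def _degrade(calls: np.ndarray, eps: float, miss: float, rng) -> np.ndarray:
    """Symmetric dosage-flip error then missingness, in place on a copy."""
    out = calls.copy()
    if eps > 0:
        flip = rng.random(out.shape) < eps
        # uniformly one of the two wrong dosages
        shift = rng.integers(1, 3, size=out.shape)
        out[flip] = ((out[flip] + shift[flip]) % 3).astype(np.int8)
    if miss > 0:
        out[rng.random(out.shape) < miss] = MISSING
    return out


def kernel_weights(distances: np.ndarray, kernel: dict) -> np.ndarray:
    """Unnormalized pollination success weight at each distance."""
    d = np.asarray(distances, dtype=float)
    fam = kernel["family"]
    if fam == "uniform":
        return np.ones_like(d)
    scale = float(kernel["scale_m"])
    if fam == "exponential":
        return np.exp(-d / scale)
    if fam == "exponential-power":
        return np.exp(-((d / scale) ** float(kernel.get("shape", 1.0))))
    raise ValueError(f"unknown kernel family {fam!r}")


# ---------------------------------------------------------------------------
# founders
# ---------------------------------------------------------------------------

def simulate_founders(cfg: SimConfig, rng=None):
    """Simulate candidate genets, their grid positions, and family labels.

    Returns ``(GenotypeMatrix, FieldMap)``.  Members of one half-sib family
    share a simulated dam (independent sires), so realized half-sib
    relatedness exceeds that of unrelated pairs; families occupy adjacent
    grid positions, filled row-major.  The remainder beyond
    ``n_families * family_size`` is bi-parental F1 genets from crosses
    among 8 extra founders.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    L = cfg.n_loci
    lo, hi = cfg.maf_law
    freqs = rng.uniform(lo, hi, size=L)

    n_hs = cfg.n_families * cfg.family_size
    if n_hs > cfg.n_candidates:
        raise ValueError(
            f"n_families*family_size={n_hs} exceeds n_candidates={cfg.n_candidates}"
        )
    n_f1 = cfg.n_candidates - n_hs

    ids, fam_ids, rows = [], [], []
    for f in range(cfg.n_families):
        dam = rng.binomial(2, freqs).astype(np.int8)
        for k in range(cfg.family_size):
            sire = rng.binomial(2, freqs).astype(np.int8)
            rows.append(_gamete(dam, rng) + _gamete(sire, rng))
            ids.append(f"G{f * cfg.family_size + k:04d}")
            fam_ids.append(f"F{f:03d}")
    if n_f1 > 0:
        f1_parents = rng.binomial(2, freqs[None, :] * np.ones((8, 1))).astype(np.int8)
        for k in range(n_f1):
            i, j = rng.choice(8, size=2, replace=False)
            rows.append(_gamete(f1_parents[i], rng) + _gamete(f1_parents[j], rng))
            ids.append(f"X{k:04d}")
            fam_ids.append(f"F1_{i}x{j}")

    calls = np.stack(rows).astype(np.int8)
    gm = GenotypeMatrix(ids, [f"L{j:05d}" for j in range(L)], calls,
                        chrom=np.array([f"Chr{1 + j % 21:02d}" for j in range(L)]),
                        pos=np.arange(1, L + 1) * 1000)

    # grid: near-square, family blocks contiguous row-major
    ncols = int(np.ceil(np.sqrt(cfg.n_candidates)))
    nrows = int(np.ceil(cfg.n_candidates / ncols))
    if nrows * ncols < cfg.n_candidates:
        raise ValueError("grid too small for n_candidates")
    import pandas as pd

    pos = np.arange(cfg.n_candidates)
    grid_row, grid_col = pos // ncols, pos % ncols
    fm = FieldMap(pd.DataFrame({
        "genet_id": ids,
        "family_id": fam_ids,
        "role": "candidate",
        "grid_row": grid_row,
        "grid_col": grid_col,
        "x_m": grid_col * cfg.grid_spacing_m,
        "y_m": grid_row * cfg.grid_spacing_m,
    }))
    return gm, fm


def _pick_mothers(fm: FieldMap, cfg: SimConfig, rng) -> list:
    """Mothers from distinct half-sib families, positioned off the borders."""
    t = fm.table
    margin = 1 if min(t.grid_row.max(), t.grid_col.max()) < 6 else 2
    interior = t[
        (t.grid_row >= margin) & (t.grid_row <= t.grid_row.max() - margin)
        & (t.grid_col >= margin) & (t.grid_col <= t.grid_col.max() - margin)
        & t.family_id.str.startswith("F") & ~t.family_id.str.startswith("F1_")
    ]
    fams = list(dict.fromkeys(interior.family_id))
    if len(fams) < cfg.n_mothers_sampled:
        raise ValueError("not enough interior families to sample mothers from")
    chosen_fams = rng.choice(fams, size=cfg.n_mothers_sampled, replace=False)
    mothers = []
    for f in chosen_fams:
        members = interior[interior.family_id == f].genet_id.tolist()
        mothers.append(members[rng.integers(len(members))])
    return mothers


# ---------------------------------------------------------------------------
# matings
# ---------------------------------------------------------------------------

def simulate_matings(founders: GenotypeMatrix, fm: FieldMap, cfg: SimConfig,
                     rng, mothers=None):
    """Sire progeny for each sampled mother through the dispersal kernel.

    Each progeny's father is SELF with probability ``selfing_rate``, else a
    candidate drawn with probability proportional to
    ``kernel(distance(mother, candidate))`` (the mother herself excluded
    from the outcross pool).  Progeny genotypes are Mendelian draws from
    the parental dosages, then degraded by the error/missingness model.

    Returns ``(progeny GenotypeMatrix, FamilyTable, NurseryTruth)``.
    """
    if mothers is None:
        mothers = _pick_mothers(fm, cfg, rng)
    for m in mothers:
        if m not in fm._xy:
            raise KeyError(f"mother {m!r} absent from field map")
    cand_ids = founders.ids
    cand_idx = {g: i for i, g in enumerate(cand_ids)}
    founder_freqs = founders.allele_frequencies()

    prog_rows, prog_ids, mother_of = [], [], {}
    true_father, realized = {}, {}
    n_self = 0
    lo, hi = cfg.progeny_per_mother
    for m in mothers:
        mi = cand_idx[m]
        others = [g for g in cand_ids if g != m]
        dists = fm.distances_from(m, others)
        w = kernel_weights(dists, cfg.kernel)
        if w.sum() <= 0:
            raise ValueError("kernel assigns zero weight to every candidate")
        w = w / w.sum()
        n_prog = int(rng.integers(lo, hi + 1))
        father_draw = rng.choice(len(others), size=n_prog, p=w)
        selfed = rng.random(n_prog) < cfg.selfing_rate
        for k in range(n_prog):
            pid = f"P_{m}_{k:03d}"
            if selfed[k]:
                fid, d, fi = SELF, 0.0, mi
                n_self += 1
            else:
                fid = others[father_draw[k]]
                d = float(dists[father_draw[k]])
                fi = cand_idx[fid]
            g = _gamete(founders.calls[mi], rng) + _gamete(founders.calls[fi], rng)
            prog_rows.append(g)
            prog_ids.append(pid)
            mother_of[pid] = m
            true_father[pid] = fid
            realized[pid] = d

    calls = _degrade(np.stack(prog_rows).astype(np.int8),
                     cfg.genotyping_error, cfg.missing_rate, rng)
    progeny = GenotypeMatrix(prog_ids, list(founders.loci), calls,
                             chrom=founders.chrom.copy(), pos=founders.pos.copy())
    truth = NurseryTruth(true_father, realized, dict(cfg.kernel), n_self, founder_freqs)
    return progeny, FamilyTable(mother_of), truth


# ---------------------------------------------------------------------------
# traits
# ---------------------------------------------------------------------------

def simulate_traits(founders: GenotypeMatrix, progeny: GenotypeMatrix,
                    cfg: SimConfig, rng, n_traits: int = 1, trait_names=None):
    """Additive traits: dosage x i.i.d. normal effects + noise scaled to h2.

    Phenotypes are generated for the founders (the training set); true
    genetic values are returned for both founders and progeny.  Missing
    progeny calls are treated as the founder mean dosage when computing
    true genetic values.

    Returns ``(phenotypes DataFrame, truth dict)`` where truth has per-trait
    marker effects and true genetic values.
    """
    import pandas as pd

    h2 = cfg.trait_h2
    if not 0.0 <= h2 <= 1.0:
        raise ValueError("trait_h2 outside [0, 1]")
    if trait_names is None:
        trait_names = [f"trait{t + 1}" for t in range(n_traits)]
    L = founders.n_loci
    mean_dos = 2.0 * founders.allele_frequencies()
    Zf = np.where(founders.calls == MISSING, mean_dos[None, :], founders.calls)
    Zp = np.where(progeny.calls == MISSING, mean_dos[None, :], progeny.calls)

    pheno = {}
    truth = {}
    for name in trait_names:
        beta = rng.normal(0.0, 1.0, size=L) / np.sqrt(L)
        g_f = Zf @ beta
        g_p = Zp @ beta
        var_g = g_f.var()
        if h2 == 1.0 or var_g == 0.0:
            noise = np.zeros_like(g_f)
            if h2 == 0.0 and var_g == 0.0:
                noise = rng.normal(0.0, 1.0, size=len(g_f))
        elif h2 == 0.0:
            noise = rng.normal(0.0, np.sqrt(max(var_g, 1.0)), size=len(g_f))
            g_f = np.zeros_like(g_f)  # h2=0: phenotype carries no genetic signal
        else:
            var_e = var_g * (1.0 - h2) / h2
            noise = rng.normal(0.0, np.sqrt(var_e), size=len(g_f))
        pheno[name] = g_f + noise
        truth[name] = {"effects": beta, "gv_founders": Zf @ beta, "gv_progeny": g_p}
    df = pd.DataFrame(pheno, index=founders.ids)
    df.index.name = "id"
    return df, truth


def simulate_nursery(cfg: SimConfig):
    """One-call convenience: founders + matings (+ truth) from a SimConfig.

    Returns ``(founders_gm, fieldmap, progeny_gm, family_table, truth)``;
    deterministic given ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    founders, fm = simulate_founders(cfg, rng)
    progeny, fams, truth = simulate_matings(founders, fm, cfg, rng)
    return founders, fm, progeny, fams, truth
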