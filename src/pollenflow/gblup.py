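"""Single-environment GBLUP / ridge-regression genomic prediction.

Fits y = mu + Zb + e with b ~ N(0, sigma_b^2 I) on training-set-centered
marker dosages, variance components by REML profiled over the ratio
delta = sigma_e^2 / sigma_u^2 using one eigendecomposition of the VanRaden
relationship matrix.  Marker effects are back-solved so that predictions
via the relationship-matrix form and the marker-effect form coincide.
The genotype-by-environment genomic-selection machinery used in breeding
programs is deliberately out of scope here: this module's job is to supply
progeny trait predictions for distance-bin comparisons.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .genotype_io import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)

__all__ = ["TraitModel", "fit_gblup", "predict_gebv", "per_bin_trait_table"]


@dataclass
class TraitModel:
    """Fitted ridge/GBLUP model for one trait."""

    trait: str
    locus_ids: list
    effects: np.ndarray  # per-locus additive effect
    intercept: float
    train_freqs: np.ndarray  # centering frequencies
    delta: float  # sigma_e^2 / sigma_u^2 on the K scale
    sigma_u2: float
    sigma_e2: float
    fitted: np.ndarray
    train_ids: list

    def __post_init__(self):
        if len(self.effects) != len(self.locus_ids):
            raise ValueError("effect vector length != locus count")


def _center(calls: np.ndarray, freqs: np.ndarray) -> np.ndarray:
    Z = np.where(calls == MISSING, 2.0 * freqs[None, :], calls.astype(float))
    return Z - 2.0 * freqs[None, :]


def fit_gblup(train: GenotypeMatrix, phenotypes, trait: str = "trait",
              delta_bounds=(1e-6, 1e6)) -> TraitModel:
    """REML-fitted GBLUP from a training genotype matrix and phenotypes.

    ``phenotypes`` is a Series/array aligned to ``train.ids``.  Requires
    >= 30 training individuals and finite phenotypes.  Degenerate marker
    matrices trigger a shrinkage floor with a warning rather than an error.
    """
    y = np.asarray(phenotypes, dtype=float)
    if len(y) != train.n_individuals:
        raise ValueError("phenotype length != training individuals")
    if not np.isfinite(y).all():
        raise ValueError("non-finite phenotypes")
    n = len(y)
    if n < 30:
        raise ValueError("need >= 30 training individuals")

    p = train.allele_frequencies()
    usable = np.isfinite(p) & (p > 0) & (p < 1)
    c = 2.0 * (p[usable] * (1 - p[usable])).sum()
    Z = _center(train.calls, np.where(np.isfinite(p), p, 0.0))[:, usable]
    K = Z @ Z.T / c

    xi, U = np.linalg.eigh(K)
    yt = U.T @ y
    ones_t = U.T @ np.ones(n)

    def neg_reml(log_delta):
        delta = np.exp(log_delta)
        v = xi + delta
        # GLS intercept
        w = ones_t / v
        mu = (w @ yt) / (w @ ones_t)
        r = yt - mu * ones_t
        quad = (r**2 / v).sum()
        sigma_u2 = quad / (n - 1)
        return ((n - 1) * np.log(sigma_u2) + np.log(v).sum()
                + np.log((ones_t**2 / v).sum()))

    res = minimize_scalar(neg_reml, bounds=tuple(np.log(delta_bounds)),
                          method="bounded", options={"xatol": 1e-8})
    delta = float(np.exp(res.x))
    if not res.success or delta >= delta_bounds[1] * 0.99:
        logger.warning("REML at shrinkage bound (delta=%.3g); applying floor", delta)
    v = xi + delta
    w = ones_t / v
    mu = float((w @ yt) / (w @ ones_t))
    r = yt - mu * ones_t
    sigma_u2 = float((r**2 / v).sum() / (n - 1))
    sigma_e2 = float(delta * sigma_u2)

    # V^{-1} r in original coordinates, then marker effects beta = Z' V^{-1} r / c
    Vinv_r = U @ (r / v)
    beta_use = Z.T @ Vinv_r / c
    effects = np.zeros(train.n_loci)
    effects[usable] = beta_use
    fitted = mu + (Z @ beta_use)
    return TraitModel(
        trait=trait, locus_ids=list(train.loci), effects=effects,
        intercept=mu, train_freqs=np.where(np.isfinite(p), p, 0.0),
        delta=delta, sigma_u2=sigma_u2, sigma_e2=sigma_e2,
        fitted=fitted, train_ids=list(train.ids),
    )


def predict_gebv(model: TraitModel, gm: GenotypeMatrix) -> np.ndarray:
    """Genome-estimated trait values: intercept + centered dosage x effects.

    Loci are aligned by id intersection (a warning reports any loss);
    missing calls are centered to zero.
    """
    pos = {l: i for i, l in enumerate(model.locus_ids)}
    shared = [l for l in gm.loci if l in pos]
    if not shared:
        raise ValueError("no overlapping loci between model and genotypes")
    if len(shared) < len(model.locus_ids):
        logger.warning("predicting with %d of %d model loci",
                       len(shared), len(model.locus_ids))
    gm_pos = {l: i for i, l in enumerate(gm.loci)}
    gm_idx = [gm_pos[l] for l in shared]
    mod_idx = [pos[l] for l in shared]
    Z = _center(gm.calls[:, gm_idx], model.train_freqs[mod_idx])
    return model.intercept + Z @ model.effects[mod_idx]


def per_bin_trait_table(predictions: dict, binned, alpha: float = 0.05):
    """Per-bin trait means/sd with LSD letters.

    ``predictions`` maps trait -> Series indexed by progeny id; ``binned``
    is the record table from ``bin_by_distance``.  Progeny without a
    prediction are dropped; empty bins are excluded with a note.
    """
    import pandas as pd
    from .dispersal import lsd_test

    rows = []
    letters_all = {}
    for trait, pred in predictions.items():
        pred = pd.Series(pred)
        sub = binned[binned.progeny_id.isin(pred.index)]
        groups = {
            str(lbl): pred[g.progeny_id].to_numpy()
            for lbl, g in sub.groupby("bin_label", sort=False)
        }
        res = lsd_test(groups, alpha=alpha)
        letters_all[trait] = res
        for lbl in groups:
            rows.append({
                "trait": trait, "bin_label": lbl,
                "n": res["n"][lbl], "mean": res["means"][lbl],
                "sd": float(np.std(groups[lbl], ddof=1)) if res["n"][lbl] > 1 else 0.0,
                "letters": res["letters"][lbl],
            })
    return pd.DataFrame(rows), letters_all
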