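"""Distance and direction statistics of realized pollination events.

Builds per-progeny dispersal records (mother-father distance, compass
bearing, half-sib flag) from a paternity table and the field map, then
derives the axial dispersal spread sigma_pollen = sqrt(M/2) (M = mean
squared parent-pair distance), 16-sector compass summaries, 3 m distance
bins with per-bin diversity statistics, LSD mean-separation letters, and
paternal trait/success correlations.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .genotype_io import GenotypeMatrix, FieldMap, FamilyTable
from . import diversity

logger = logging.getLogger(__name__)

SECTOR_NAMES = [
    "N", "NNE", "NE", "ENE", "E", "ESE", "SE", "SSE",
    "S", "SSW", "SW", "WSW", "W", "WNW", "NW", "NNW",
]

__all__ = [
    "build_dispersal_records",
    "axial_sigma",
    "sector_analysis",
    "bin_by_distance",
    "per_bin_diversity",
    "lsd_test",
    "father_trait_correlations",
    "half_sib_profile",
    "dispersal_summary",
]


def build_dispersal_records(paternity_table: pd.DataFrame, fieldmap: FieldMap,
                            families: FamilyTable = None) -> pd.DataFrame:
    """One record per assigned progeny: distance, bearing, sector, flags.

    Bearing is degrees clockwise from North (mother -> father).  Selfing
    records get distance 0 and no bearing.  Unassigned progeny are
    excluded; a missing coordinate skips the record with a warning.
    """
    rows = []
    assigned = paternity_table[paternity_table.father_id.notna()]
    for r in assigned.itertuples():
        try:
            xm, ym = fieldmap.coords(r.mother_id)
            xf, yf = fieldmap.coords(r.father_id)
        except KeyError as e:
            logger.warning("skipping %s: %s", r.progeny_id, e)
            continue
        dx, dy = xf - xm, yf - ym
        dist = float(np.hypot(dx, dy))
        if r.is_self:
            bearing, sector = np.nan, None
        else:
            bearing = float(np.degrees(np.arctan2(dx, dy)) % 360.0)
            sector = SECTOR_NAMES[int(((bearing + 11.25) % 360.0) // 22.5)]
        fam_m = fieldmap.family_of(r.mother_id)
        fam_f = fieldmap.family_of(r.father_id)
        rows.append({
            "progeny_id": r.progeny_id, "mother_id": r.mother_id,
            "father_id": r.father_id, "distance_m": dist,
            "bearing_deg": bearing, "sector": sector,
            "is_half_sib_father": bool(fam_m == fam_f) and not r.is_self,
            "is_self": bool(r.is_self),
        })
    return pd.DataFrame(rows)


def axial_sigma(distances) -> tuple:
    """Axial dispersal spread: M = mean squared distance, sigma = sqrt(M/2)."""
    d = np.asarray(distances, dtype=float)
    if d.size == 0:
        raise ValueError("no distances")
    M = float((d**2).mean())
    return M, float(np.sqrt(M / 2.0))


def sector_analysis(records: pd.DataFrame) -> dict:
    """Per-sector father counts and the distance-direction correlation.

    Pearson r between the sector index (0-15 clockwise from North) and
    pollination distance, over outcross records.
    """
    out_rec = records[~records.is_self & records.sector.notna()]
    if out_rec.empty:
        raise ValueError("no outcross records")
    counts = out_rec.sector.value_counts().reindex(SECTOR_NAMES, fill_value=0)
    sector_idx = out_rec.sector.map({s: i for i, s in enumerate(SECTOR_NAMES)})
    if sector_idx.nunique() > 1 and out_rec.distance_m.nunique() > 1:
        r, p = stats.pearsonr(sector_idx, out_rec.distance_m)
    else:
        r, p = float("nan"), float("nan")
    return {"sector_counts": counts.to_dict(), "pearson_r": float(r),
            "p_value": float(p)}


def bin_by_distance(records: pd.DataFrame, width_m: float = 3.0) -> pd.DataFrame:
    """Assign each outcross record to a left-closed bin [k·w, (k+1)·w)."""
    if width_m <= 0:
        raise ValueError("bin width must be > 0")
    rec = records[~records.is_self].copy()
    k = np.floor(rec.distance_m / width_m).astype(int)
    rec["bin_index"] = k
    rec["bin_label"] = [f"{i * width_m:g}-{(i + 1) * width_m:g}" for i in k]
    return rec


def per_bin_diversity(binned: pd.DataFrame, gm: GenotypeMatrix,
                      rarefaction_depth: int = None) -> pd.DataFrame:
    """Table-2-style per-bin diversity statistics.

    Per bin: progeny count, mean pairwise IBS genetic distance, mean
    pairwise Nei's D among progeny, and Shannon H / rarefaction richness
    on the per-father progeny-count community.  The rarefaction reference
    depth defaults to the smallest bin's progeny count.  Bins with < 2
    progeny get NaN for the pairwise statistics.
    """
    groups = binned.groupby("bin_index")
    if rarefaction_depth is None:
        rarefaction_depth = max(1, int(groups.size().min()))
    rows = []
    for b, sub in groups:
        pids = [p for p in sub.progeny_id if p in set(gm.ids)]
        father_counts = sub.groupby("father_id").size().to_numpy()
        row = {
            "bin_index": b, "bin_label": sub.bin_label.iloc[0],
            "n_progeny": len(sub),
            "n_fathers": int(sub.father_id.nunique()),
            "shannon_H": diversity.shannon_index(father_counts),
            "rarefaction_E": diversity.rarefaction_richness(
                father_counts, min(rarefaction_depth, int(father_counts.sum()))),
        }
        if len(pids) >= 2:
            _, ibs = diversity.ibs_dissimilarity(gm, pids)
            row["genetic_distance"] = ibs
            row["nei_D"] = diversity.mean_pairwise_nei(gm, pids)
        else:
            row["genetic_distance"] = float("nan")
            row["nei_D"] = float("nan")
        rows.append(row)
    return pd.DataFrame(rows).sort_values("bin_index").reset_index(drop=True)


# ---------------------------------------------------------------------------
# LSD mean separation
# ---------------------------------------------------------------------------

def lsd_test(groups: dict, alpha: float = 0.05) -> dict:
    """Fisher's least-significant-difference test with letter display.

    ``groups`` maps group label -> 1-D array of observations.  One-way
    ANOVA residual variance feeds pairwise t comparisons (no multiple-
    testing correction); groups sharing a letter are not significantly
    different.  Singleton groups are carried but flagged.
    """
    labels = list(groups)
    data = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    ns = {k: len(v) for k, v in data.items()}
    if len(labels) < 2:
        raise ValueError("need >= 2 groups")
    means = {k: float(v.mean()) for k, v in data.items()}
    N = sum(ns.values())
    df_err = N - len(labels)
    sse = sum(((v - means[k]) ** 2).sum() for k, v in data.items())
    mse = sse / df_err if df_err > 0 else 0.0

    sig = {}
    if mse == 0.0:
        for i, a in enumerate(labels):
            for b in labels[i + 1:]:
                sig[(a, b)] = means[a] != means[b]
    else:
        tcrit = stats.t.ppf(1 - alpha / 2, df_err)
        for i, a in enumerate(labels):
            for b in labels[i + 1:]:
                lsd = tcrit * np.sqrt(mse * (1.0 / ns[a] + 1.0 / ns[b]))
                sig[(a, b)] = abs(means[a] - means[b]) > lsd

    letters = _letter_display(labels, means, sig)
    return {
        "means": means, "n": ns, "mse": mse, "df_error": df_err,
        "significant": sig, "letters": letters,
        "singletons": [k for k, n in ns.items() if n < 2],
    }


def _letter_display(labels, means, sig) -> dict:
    """Compact letter display: insert-and-absorb over mean-sorted groups."""
    order = sorted(labels, key=lambda k: -means[k])

    def differs(a, b):
        return sig.get((a, b), sig.get((b, a), False))

    runs = []
    for i in range(len(order)):
        j = i
        while j + 1 < len(order) and not any(
            differs(order[a], order[b])
            for a in range(i, j + 2) for b in range(a + 1, j + 2)
        ):
            j += 1
        runs.append(set(order[i:j + 1]))
    # absorb runs contained in earlier ones
    kept = []
    for r in runs:
        if not any(r <= k for k in kept):
            kept.append(r)
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {k: "" for k in labels}
    for idx, r in enumerate(kept):
        for k in order:
            if k in r:
                out[k] += alphabet[idx % 26]
    return out


def father_trait_correlations(per_father: pd.DataFrame,
                              phenotypes: pd.DataFrame) -> pd.DataFrame:
    """Pearson r of paternal traits vs pollination success and distance.

    ``per_father`` needs columns father_id, n_progeny, mean_distance_m;
    ``phenotypes`` is indexed by genet id with one column per trait.
    Constant vectors yield NaN (flagged undefined).
    """
    merged = per_father.set_index("father_id").join(phenotypes, how="inner")
    if len(merged) < 3:
        raise ValueError("need >= 3 fathers with phenotypes")
    rows = []
    for trait in phenotypes.columns:
        for target in ("n_progeny", "mean_distance_m"):
            x, y = merged[trait], merged[target]
            if x.nunique() < 2 or y.nunique() < 2:
                r, p = float("nan"), float("nan")
            else:
                r, p = stats.pearsonr(x, y)
            rows.append({"trait": trait, "against": target,
                         "r": float(r), "p_value": float(p)})
    return pd.DataFrame(rows)


def half_sib_profile(records: pd.DataFrame, cutoffs=(0.91, 1.8, 10.0)) -> dict:
    """Distance profile of half-sib vs other fathers.

    Fractions are over unique (mother, father) pairs, mirroring the
    father-centric reading of the nursery maps.
    """
    out_rec = records[~records.is_self]
    pairs = out_rec.drop_duplicates(["mother_id", "father_id"])
    hs = pairs[pairs.is_half_sib_father]
    other = pairs[~pairs.is_half_sib_father]
    res = {
        "n_fathers": int(len(pairs)),
        "n_half_sib_fathers": int(len(hs)),
        "half_sib_fraction": float(len(hs) / len(pairs)) if len(pairs) else 0.0,
        "half_sib_distances": hs.distance_m.tolist(),
        "other_distances": other.distance_m.tolist(),
    }
    for c in cutoffs:
        res[f"half_sib_within_{c:g}m"] = (
            float((hs.distance_m <= c).mean()) if len(hs) else 0.0)
    return res


def dispersal_summary(records: pd.DataFrame, ks: tuple = None) -> dict:
    """Headline distance statistics over outcross records."""
    d = records.loc[~records.is_self, "distance_m"].to_numpy()
    if d.size == 0:
        raise ValueError("no outcross records")
    M, sigma = axial_sigma(d)
    out = {
        "n_events": int(d.size),
        "mean_m": float(d.mean()), "median_m": float(np.median(d)),
        "min_m": float(d.min()), "max_m": float(d.max()),
        "M_m2": M, "sigma_pollen_m": sigma,
        "fraction_within_5m": float((d <= 5.0).mean()),
        "fraction_within_10m": float((d <= 10.0).mean()),
        "n_self": int(records.is_self.sum()),
    }
    if ks is not None:
        out["ks_D"], out["ks_p"] = ks
    return out
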