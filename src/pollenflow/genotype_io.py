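"""Genotype matrices, field maps and family tables: the shared data model.

Genotypes are diploid biallelic dosage calls (0, 1, 2; ``-1`` = missing),
stored as a dense ``int8`` matrix of individuals x loci.  Two on-disk
dialects are supported: a TSV dosage matrix and minimal VCF 4.2 (GT only).
Field maps carry genet coordinates in meters on the nursery grid; family
tables map each sampled progeny to its known mother.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING: int = -1

__all__ = [
    "MISSING",
    "GenotypeMatrix",
    "FieldMap",
    "FamilyTable",
    "read_genotypes",
    "write_genotypes",
    "filter_loci",
    "subsample_loci",
    "allele_frequencies",
]


class GenotypeParseError(ValueError):
    """Raised for malformed genotype files (message carries the line/record)."""


@dataclass
class GenotypeMatrix:
    """Individuals x biallelic loci dosage matrix.

    Parameters
    ----------
    ids : list of str
        Individual identifiers (unique, order preserved).
    loci : list of str
        Locus identifiers (unique, order preserved).
    calls : ndarray of int8, shape (n_individuals, n_loci)
        Alternate-allele dosage in {0, 1, 2} or ``MISSING``.
    chrom : ndarray of str, optional
        Chromosome label per locus.
    pos : ndarray of int, optional
        Physical position per locus (1-based).
    """

    ids: list
    loci: list
    calls: np.ndarray
    chrom: np.ndarray | None = None
    pos: np.ndarray | None = None
    _freq_cache: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.ids), len(self.loci)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.ids)} individuals x {len(self.loci)} loci"
            )
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate individual ids")
        if len(set(self.loci)) != len(self.loci):
            raise ValueError("duplicate locus ids")
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError(f"invalid dosage values: {np.unique(self.calls[bad])}")
        if self.chrom is None:
            self.chrom = np.array(["1"] * len(self.loci))
        if self.pos is None:
            self.pos = np.arange(1, len(self.loci) + 1)

    # -- basic accessors -------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return len(self.ids)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def index_of(self, ids) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.ids)}
        try:
            return np.array([lookup[g] for g in ids], dtype=int)
        except KeyError as e:
            raise KeyError(f"unknown individual id {e.args[0]!r}") from None

    def subset_individuals(self, ids) -> "GenotypeMatrix":
        idx = self.index_of(ids)
        return GenotypeMatrix(
            list(ids), list(self.loci), self.calls[idx],
            chrom=self.chrom.copy(), pos=self.pos.copy(),
        )

    def subset_loci(self, mask_or_idx) -> "GenotypeMatrix":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeMatrix(
            list(self.ids), [self.loci[i] for i in idx], self.calls[:, idx],
            chrom=self.chrom[idx], pos=self.pos[idx],
        )

    # -- statistics ------------------------------------------------------
    def allele_frequencies(self, individuals=None, use_cache: bool = True) -> np.ndarray:
        """Alternate-allele frequency per locus among non-missing calls.

        Loci with no data get NaN.  The full-matrix result is cached.
        """
        if individuals is None and use_cache and self._freq_cache is not None:
            return self._freq_cache
        calls = self.calls if individuals is None else self.calls[self.index_of(individuals)]
        ok = calls != MISSING
        n = ok.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            freq = np.where(ok, calls, 0).sum(axis=0) / (2.0 * n)
        freq = np.where(n == 0, np.nan, freq)
        if individuals is None:
            self._freq_cache = freq
        return freq

    def missing_fraction(self) -> np.ndarray:
        return (self.calls == MISSING).mean(axis=0)

    def minor_allele_frequencies(self, individuals=None) -> np.ndarray:
        p = self.allele_frequencies(individuals)
        return np.minimum(p, 1.0 - p)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.calls.astype(float), index=self.ids, columns=self.loci)
        return df.replace(float(MISSING), np.nan)


@dataclass
class FieldMap:
    """Genet coordinates in meters plus family membership and role.

    Backed by a DataFrame with columns ``genet_id, family_id, role,
    grid_row, grid_col, x_m, y_m``; role is one of candidate / mother /
    border (mothers are also candidates unless explicitly excluded).
    """

    table: pd.DataFrame

    REQUIRED = ("genet_id", "family_id", "role", "grid_row", "grid_col", "x_m", "y_m")

    def __post_init__(self):
        missing_cols = set(self.REQUIRED) - set(self.table.columns)
        if missing_cols:
            raise ValueError(f"field map missing columns: {sorted(missing_cols)}")
        if self.table["genet_id"].duplicated().any():
            raise ValueError("duplicate genet_id in field map")
        if not np.isfinite(self.table[["x_m", "y_m"]].to_numpy(float)).all():
            raise ValueError("non-finite coordinates in field map")
        self.table = self.table.reset_index(drop=True)
        self._xy = {
            r.genet_id: (float(r.x_m), float(r.y_m)) for r in self.table.itertuples()
        }
        self._family = dict(zip(self.table["genet_id"], self.table["family_id"]))

    def coords(self, genet_id) -> tuple:
        try:
            return self._xy[genet_id]
        except KeyError:
            raise KeyError(f"genet {genet_id!r} not in field map") from None

    def family_of(self, genet_id):
        return self._family[genet_id]

    def distance(self, a, b) -> float:
        xa, ya = self.coords(a)
        xb, yb = self.coords(b)
        return float(np.hypot(xa - xb, ya - yb))

    def distances_from(self, genet_id, others) -> np.ndarray:
        x0, y0 = self.coords(genet_id)
        xy = np.array([self._xy[g] for g in others], dtype=float)
        return np.hypot(xy[:, 0] - x0, xy[:, 1] - y0)

    @property
    def genet_ids(self) -> list:
        return list(self.table["genet_id"])

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "FieldMap":
        fm = cls(pd.read_csv(path))
        logger.info("read field map: %d genets from %s", len(fm.table), path)
        return fm


@dataclass
class FamilyTable:
    """Progeny -> known mother mapping."""

    mother_of: dict

    def __post_init__(self):
        self.mother_of = dict(self.mother_of)

    @property
    def progeny_ids(self) -> list:
        return list(self.mother_of)

    @property
    def mothers(self) -> list:
        seen = []
        for m in self.mother_of.values():
            if m not in seen:
                seen.append(m)
        return seen

    def progeny_of(self, mother) -> list:
        return [p for p, m in self.mother_of.items() if m == mother]

    def validate_against(self, fieldmap: FieldMap) -> None:
        absent = [m for m in self.mothers if m not in fieldmap._xy]
        if absent:
            raise ValueError(f"mothers absent from field map: {absent[:5]}")

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"progeny_id": list(self.mother_of), "mother_id": list(self.mother_of.values())}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "FamilyTable":
        df = pd.read_csv(path)
        if df["progeny_id"].duplicated().any():
            raise ValueError("duplicate progeny_id in family table")
        ft = cls(dict(zip(df["progeny_id"], df["mother_id"])))
        logger.info("read family table: %d progeny from %s", len(df), path)
        return ft


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_genotypes(path, dialect: str = "tsv") -> GenotypeMatrix:
    """Read a genotype matrix from ``tsv`` (dosage) or ``vcf`` (GT field).

    The TSV dialect is rows = individuals, columns = loci, cells in
    {0, 1, 2, NA}.  VCF reading uses cyvcf2 and rejects multi-allelic
    records.
    """
    if dialect == "tsv":
        return _read_tsv(path)
    if dialect == "vcf":
        return _read_vcf(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_tsv(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    vals = df.to_numpy(float)
    bad = ~(np.isnan(vals) | np.isin(vals, (0.0, 1.0, 2.0)))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise GenotypeParseError(
            f"{path}: invalid dosage {vals[i, j]!r} at row {i + 2} column {df.columns[j]!r}"
        )
    calls = np.where(np.isnan(vals), MISSING, vals).astype(np.int8)
    gm = GenotypeMatrix(list(df.index), list(df.columns), calls)
    logger.info("read %d individuals x %d loci (tsv) from %s", *calls.shape, path)
    return gm


def _read_vcf(path) -> GenotypeMatrix:
    from cyvcf2 import VCF  # optional dependency

    vcf = VCF(str(path), gts012=True)
    ids = list(vcf.samples)
    loci, chroms, poss, rows = [], [], [], []
    for i, var in enumerate(vcf):
        if len(var.ALT) != 1:
            raise GenotypeParseError(
                f"{path}: multi-allelic record at {var.CHROM}:{var.POS} (record {i + 1})"
            )
        loci.append(var.ID if var.ID not in (None, ".") else f"{var.CHROM}_{var.POS}")
        chroms.append(var.CHROM)
        poss.append(var.POS)
        gt = np.asarray(var.gt_types)  # gts012: 0/1/2 dosage, 3 unknown
        rows.append(np.where(gt == 3, MISSING, gt).astype(np.int8))
    calls = np.stack(rows, axis=1) if rows else np.zeros((len(ids), 0), np.int8)
    gm = GenotypeMatrix(ids, loci, calls, chrom=np.array(chroms), pos=np.array(poss))
    logger.info("read %d individuals x %d loci (vcf) from %s", *calls.shape, path)
    return gm


def write_genotypes(gm: GenotypeMatrix, path, dialect: str = "tsv") -> None:
    """Write ``tsv`` dosage matrix or minimal diploid VCF ("./." missing)."""
    if dialect == "tsv":
        df = pd.DataFrame(gm.calls.astype(object), index=gm.ids, columns=gm.loci)
        df = df.where(df != MISSING, "NA")
        df.to_csv(path, sep="\t", index_label="id")
        return
    if dialect == "vcf":
        gt_str = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
            fh.write("\t".join(str(s) for s in gm.ids) + "\n")
            for j, locus in enumerate(gm.loci):
                cells = "\t".join(gt_str[int(c)] for c in gm.calls[:, j])
                fh.write(
                    f"{gm.chrom[j]}\t{int(gm.pos[j])}\t{locus}\tA\tG\t.\tPASS\t.\tGT\t{cells}\n"
                )
        return
    raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# filtering / subsampling
# ---------------------------------------------------------------------------

def filter_loci(gm: GenotypeMatrix, maf_min: float = 0.03, max_missing: float = 0.10):
    """Drop loci with MAF < ``maf_min`` or missing fraction > ``max_missing``.

    Both statistics are computed over all individuals in ``gm`` (parents and
    progeny pooled).  The missingness rule is strict (> threshold drops, ==
    threshold keeps).  Returns ``(filtered, report)`` where report counts
    drops per rule (a locus failing both is counted under both).
    """
    if gm.n_loci == 0:
        raise ValueError("empty genotype matrix")
    maf = gm.minor_allele_frequencies()
    miss = gm.missing_fraction()
    fail_maf = ~(maf >= maf_min)  # NaN (no data) fails
    fail_miss = miss > max_missing
    keep = ~(fail_maf | fail_miss)
    report = {
        "n_input": gm.n_loci,
        "n_dropped_maf": int(fail_maf.sum()),
        "n_dropped_missing": int(fail_miss.sum()),
        "n_retained": int(keep.sum()),
    }
    if report["n_retained"] == 0:
        logger.warning("filter_loci removed every locus")
    logger.info("filter_loci: %(n_input)d -> %(n_retained)d loci", report)
    return gm.subset_loci(keep), report


def subsample_loci(gm: GenotypeMatrix, n: int = 2500, seed=None) -> GenotypeMatrix:
    """Uniform random locus subset without replacement; original order kept."""
    if n > gm.n_loci:
        raise ValueError(f"cannot subsample {n} of {gm.n_loci} loci")
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(gm.n_loci, size=n, replace=False))
    return gm.subset_loci(idx)


def allele_frequencies(gm: GenotypeMatrix, individuals=None) -> np.ndarray:
    """Counted-allele frequency per locus; NaN where a locus has no data."""
    return gm.allele_frequencies(individuals)
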