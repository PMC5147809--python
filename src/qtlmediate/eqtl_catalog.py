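"""eQTL catalog: cis/trans classification, hotspot profiling, genotype effects.

An expression QTL is *cis* when its peak lies near the encoding gene —
within 2.5 cM or ~5 Mbp on the same chromosome — and *trans* otherwise.
A *trans*-eQTL hotspot is a locus where many transcripts' trans-eQTLs
co-map; it is profiled here by counting, at every grid locus, the traits
whose significant peak's 1.5-LOD support interval covers the locus.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError, InvalidArgumentError
from .markers import MarkerMap
from .qtl_scan import QtlPeak

CIS_WINDOW_CM = 2.5
CIS_WINDOW_MBP = 5.0


@dataclass(frozen=True)
class EqtlRecord:
    """One trait's per-chromosome peak with its gene location and class."""

    trait: str
    gene_chrom: str | None
    gene_Mbp: float
    gene_cM: float
    peak: QtlPeak
    regulation: str            # "cis" | "trans"
    is_gwas_candidate: bool


def classify_cis_trans(peak: QtlPeak, gene_chrom, gene_cm: float, gene_mbp: float,
                       window_cm: float = CIS_WINDOW_CM,
                       window_mbp: float = CIS_WINDOW_MBP) -> str:
    """cis iff the peak is on the gene's chromosome within either window.

    The genetic (cM) and physical (Mbp) windows are alternatives: meeting
    either one suffices, so classification still works when only one
    coordinate system is available for the gene.
    """
    if gene_chrom is None or (isinstance(gene_chrom, float) and np.isnan(gene_chrom)):
        raise DataError(f"trait {peak.trait!r}: gene location missing, unclassifiable")
    if str(gene_chrom) != str(peak.chrom):
        return "trans"
    near_cm = not np.isnan(gene_cm) and abs(peak.pos_cM - gene_cm) <= window_cm
    near_mbp = not np.isnan(gene_mbp) and abs(peak.pos_Mbp - gene_mbp) <= window_mbp
    return "cis" if (near_cm or near_mbp) else "trans"


def build_catalog(peaks_by_trait: dict[str, list[QtlPeak]], annot: pd.DataFrame,
                  significant_only: bool = True) -> list[EqtlRecord]:
    """EqtlRecords from per-trait peak lists and a gene annotation table.

    Traits without a genomic location (clinical traits) are skipped; they
    are QTL, not eQTL.  With ``significant_only`` (default) only peaks at
    or above the significance threshold enter the catalog, matching the
    usual definition of "an eQTL".
    """
    records = []
    for trait, peaks in peaks_by_trait.items():
        if trait not in annot.index:
            raise DataError(f"trait {trait!r} has no annotation row")
        row = annot.loc[trait]
        if pd.isna(row["chrom"]):
            continue
        for pk in peaks:
            if significant_only and not pk.significant:
                continue
            records.append(EqtlRecord(
                trait=trait, gene_chrom=str(row["chrom"]),
                gene_Mbp=float(row["Mbp"]), gene_cM=float(row["cM"]), peak=pk,
                regulation=classify_cis_trans(pk, row["chrom"], row["cM"], row["Mbp"]),
                is_gwas_candidate=bool(row["is_gwas_candidate"])))
    return records


@dataclass
class HotspotProfile:
    """Per-locus count of traits whose significant eQTL interval covers the locus."""

    grid: MarkerMap
    counts: np.ndarray
    subset: str

    def max_on(self, chrom: str) -> int:
        sub = self.grid.chromosome(chrom)
        return int(self.counts[sub.index.to_numpy()].max())

    def to_frame(self) -> pd.DataFrame:
        out = self.grid.table[["chrom", "marker", "cM", "Mbp"]].copy()
        out["count"] = self.counts
        return out


def hotspot_profile(records: list[EqtlRecord], grid: MarkerMap,
                    subset: str = "all") -> HotspotProfile:
    """Count co-mapping significant eQTLs at every grid locus.

    For each locus, the count is the number of traits (in the subset:
    "all", "gwas", or "trans") with a significant peak on that chromosome
    whose 1.5-LOD support interval covers the locus; each trait counts at
    most once per locus.
    """
    if subset not in ("all", "gwas", "trans"):
        raise InvalidArgumentError(f"unknown subset {subset!r}")
    counts = np.zeros(len(grid), dtype=int)
    gtab = grid.table
    chrom_arr = gtab["chrom"].to_numpy()
    cm_arr = gtab["cM"].to_numpy()
    covered_by_trait: dict[str, np.ndarray] = {}
    for rec in records:
        if not rec.peak.significant:
            continue
        if subset == "gwas" and not rec.is_gwas_candidate:
            continue
        if subset == "trans" and rec.regulation != "trans":
            continue
        mask = ((chrom_arr == rec.peak.chrom)
                & (cm_arr >= rec.peak.ci_lo_cM) & (cm_arr <= rec.peak.ci_hi_cM))
        prev = covered_by_trait.get(rec.trait)
        covered_by_trait[rec.trait] = mask if prev is None else (prev | mask)
    for mask in covered_by_trait.values():
        counts += mask
    return HotspotProfile(grid=grid, counts=counts, subset=subset)


@dataclass(frozen=True)
class GenotypeEffect:
    """Per-genotype trait summaries at one typed marker."""

    trait: str
    marker: str
    n: tuple[int, int, int]
    mean: tuple[float, float, float]
    sem: tuple[float, float, float]
    fold_change: float          # base^(mean_homA − mean_homB), linear scale


def genotype_effect_summary(y, geno_at_locus, trait: str = "", marker: str = "",
                            linear_scale_base: float = 10.0) -> GenotypeEffect:
    """Per-genotype n/mean/SEM and the homozygote fold change.

    ``y`` is on a log scale (log10 sample/reference ratio by default), so
    the fold change between the homozygote classes on the linear scale is
    base^(mean_class0 − mean_class2).  Mice with a missing trait value or
    missing genotype are dropped; an empty class is reported with n = 0
    and NaN summaries.
    """
    y = np.asarray(y, dtype=float)
    g = np.asarray(geno_at_locus, dtype=float)
    keep = ~np.isnan(y) & ~np.isnan(g)
    y, g = y[keep], g[keep]
    ns, means, sems = [], [], []
    for cls in (0, 1, 2):
        v = y[g == cls]
        ns.append(int(len(v)))
        if len(v) == 0:
            means.append(float("nan"))
            sems.append(float("nan"))
        else:
            means.append(float(v.mean()))
            sems.append(float(v.std(ddof=1) / np.sqrt(len(v))) if len(v) > 1 else float("nan"))
    fold = float(linear_scale_base ** (means[0] - means[2]))
    return GenotypeEffect(trait=trait, marker=marker, n=tuple(ns),
                          mean=tuple(means), sem=tuple(sems), fold_change=fold)


def catalog_frame(records: list[EqtlRecord]) -> pd.DataFrame:
    """Catalog as a flat table (one row per record)."""
    rows = [{
        "trait": r.trait, "gene_chr": r.gene_chrom, "gene_Mbp": r.gene_Mbp,
        "gene_cM": r.gene_cM, "peak_chr": r.peak.chrom, "peak_cM": r.peak.pos_cM,
        "peak_Mbp": r.peak.pos_Mbp, "lod": r.peak.lod,
        "ci_lo_cM": r.peak.ci_lo_cM, "ci_hi_cM": r.peak.ci_hi_cM,
        "class": r.regulation, "is_gwas_candidate": r.is_gwas_candidate,
    } for r in records]
    return pd.DataFrame(rows)
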