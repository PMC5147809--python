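"""Synthetic B6-type × BTBR-type F2 intercross generator.

Generates crosses with a known mediated-trans-regulation architecture so
that every downstream stage (genotype probabilities, genome scans, hotspot
profiling, mediation ranking) can be verified against ground truth:

* a *driver* transcript with a strong cis-eQTL on a designated hotspot
  chromosome (default allelic effect: a 2-fold expression difference
  between the parental homozygotes, on a log10-ratio scale),
* *mediated* trans targets whose expression is a linear function of the
  driver's expression plus noise — no direct genotype term, so
  conditioning on the driver d-separates them from the locus,
* *direct* trans targets linked to the hotspot locus without mediation,
* *decoy* cis-regulated genes scattered along the hotspot chromosome
  (stand-ins for the cis-eQTL transcription factors a mediation analysis
  must rank below the true driver),
* pure-noise null transcripts, and
* one clinical trait (insulin-like) downstream of the driver.

Meiosis follows the Haldane no-interference model: crossovers on a gamete
form a Poisson process along the chromosome (inter-crossover distances
exponential with mean 100 cM), which makes the gamete allele sequence at
the markers a two-state Markov chain with switch probability equal to the
Haldane recombination fraction of each inter-marker interval.  Genotypes
are coded 0 = homozygous B6, 1 = heterozygous, 2 = homozygous BTBR,
missing = NaN.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import InvalidDesignError
from .genoprob import haldane_r
from .markers import MarkerMap

# mouse autosome lengths, approximate standard genetic (cM) and physical (Mbp)
_MOUSE_AUTOSOME_CM = [98, 103, 82, 89, 90, 79, 89, 76, 75, 77,
                      88, 64, 67, 66, 59, 57, 61, 59, 57]
_MOUSE_AUTOSOME_MBP = [195, 182, 160, 157, 152, 150, 145, 130, 124, 131,
                       122, 120, 120, 125, 104, 98, 95, 91, 61]

GENO_B6, GENO_HET, GENO_BTBR = 0, 1, 2

TRUTH_LABELS = ("driver", "mediated", "direct", "decoy_cis", "null", "clinical")


@dataclass(frozen=True)
class ChromSpec:
    """One simulated autosome: label, genetic length, physical length, marker count."""
    chrom: str
    len_cM: float
    len_Mbp: float
    n_markers: int


def default_chromosomes(n_markers_total: int = 2000) -> list[ChromSpec]:
    """Nineteen mouse-like autosomes with markers allotted proportional to cM length."""
    total_cm = sum(_MOUSE_AUTOSOME_CM)
    chroms = []
    for i, (cm, mbp) in enumerate(zip(_MOUSE_AUTOSOME_CM, _MOUSE_AUTOSOME_MBP), start=1):
        n = max(2, round(n_markers_total * cm / total_cm))
        chroms.append(ChromSpec(str(i), float(cm), float(mbp), n))
    return chroms


@dataclass
class SimDesign:
    """Parameters of a synthetic F2 cross.

    The defaults emulate the study design this package targets: 19
    autosomes carrying ~2,000 informative markers, 491 mice, one
    cis-regulated driver at two-thirds of the hotspot chromosome with an
    additive effect of half of log10(2) per allele (a 2-fold difference
    between parental homozygotes), 50 mediated and 10 direct trans targets
    flagged as GWAS candidates, 36 decoy cis genes on the hotspot
    chromosome, 200 null transcripts, and one insulin-like clinical trait.
    Expression units are log10 sample/reference ratios throughout.
    """

    n_mice: int = 491
    chromosomes: list[ChromSpec] = field(default_factory=default_chromosomes)

    # driver: cis-regulated transcript at the hotspot
    hotspot_chrom: str = "2"
    driver_pos_cM: float | None = None          # None -> 2/3 of chromosome length
    driver_additive: float = -math.log10(2) / 2  # B6 homozygote higher by log10(2)
    driver_dominance: float = 0.015
    driver_sd: float = 0.10

    # mediated trans targets: y_j = b_j * y_driver + noise
    n_mediated: int = 50
    mediation_coef_range: tuple[float, float] = (0.8, 1.2)
    mediated_sd: float = 0.30

    # direct (non-mediated) trans targets linked at the driver locus
    n_direct: int = 10
    direct_additive: float = 0.075
    direct_sd: float = 0.15

    # decoy cis genes along the hotspot chromosome
    n_decoy_cis: int = 36
    decoy_additive: float = 0.10
    decoy_sd: float = 0.12

    n_null: int = 200
    null_sd: float = 0.12

    # clinical trait downstream of the driver
    clinical_coef: float = 0.8
    clinical_sd: float = 0.25

    # nuisance structure
    genotyping_error_rate: float = 0.002
    missing_rate: float = 0.02
    n_batches: int = 4
    batch_sd: float = 0.02
    sex_effect: float = 0.01

    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_mice < 1:
            raise InvalidDesignError("n_mice must be >= 1")
        for name in ("driver_sd", "mediated_sd", "direct_sd", "decoy_sd",
                     "null_sd", "clinical_sd", "batch_sd"):
            if getattr(self, name) < 0:
                raise InvalidDesignError(f"{name} must be >= 0")
        for name in ("genotyping_error_rate", "missing_rate"):
            v = getattr(self, name)
            if not (0 <= v < 0.5):
                raise InvalidDesignError(f"{name} must lie in [0, 0.5)")
        for name in ("n_mediated", "n_direct", "n_decoy_cis", "n_null"):
            if getattr(self, name) < 0:
                raise InvalidDesignError(f"{name} must be >= 0")
        if self.n_batches < 1:
            raise InvalidDesignError("n_batches must be >= 1")
        if not any(c.chrom == self.hotspot_chrom for c in self.chromosomes):
            raise InvalidDesignError(
                f"hotspot chromosome {self.hotspot_chrom!r} not among simulated chromosomes")

    @property
    def driver_chrom_spec(self) -> ChromSpec:
        return next(c for c in self.chromosomes if c.chrom == self.hotspot_chrom)

    def resolved_driver_pos(self) -> float:
        if self.driver_pos_cM is not None:
            return self.driver_pos_cM
        return 2.0 / 3.0 * self.driver_chrom_spec.len_cM


@dataclass
class F2CrossData:
    """Genotypes, phenotypes, covariates and gene annotations for one cross.

    geno:   mice × markers, float codes {0, 1, 2, NaN}.
    pheno:  mice × traits, log10-ratio expression plus clinical traits.
    covar:  mice × {sex (0/1), batch (0..n_batches-1)}.
    annot:  one row per trait: chrom/Mbp/cM (NaN for clinical traits),
            is_gwas_candidate flag, truth_label for simulated data.
    """

    marker_map: MarkerMap
    geno: pd.DataFrame
    pheno: pd.DataFrame
    covar: pd.DataFrame
    annot: pd.DataFrame

    def __post_init__(self) -> None:
        vals = self.geno.to_numpy(dtype=float)
        ok = np.isnan(vals) | np.isin(vals, [0.0, 1.0, 2.0])
        if not ok.all():
            raise InvalidDesignError("genotype codes must be in {0, 1, 2, NaN}")
        missing_annot = self.pheno.columns.difference(self.annot.index)
        if len(missing_annot):
            raise InvalidDesignError(
                f"traits without annotation rows: {list(missing_annot)[:5]}")

    @property
    def mice(self) -> pd.Index:
        return self.geno.index

    def expression_traits(self) -> list[str]:
        """Traits with a genomic location (clinical traits excluded)."""
        has_pos = self.annot["chrom"].notna()
        return [t for t in self.pheno.columns if has_pos.get(t, False)]


# --------------------------------------------------------------------------- #
# map and genotype simulation
# --------------------------------------------------------------------------- #

def make_marker_map(chromosomes: Sequence[ChromSpec], seed: int = 0) -> MarkerMap:
    """Evenly spaced markers along each chromosome.

    Markers sit at equal cM intervals from 0 to the chromosome length, and
    physical positions scale proportionally.  Deterministic given the
    chromosome list (the seed is accepted for interface symmetry with the
    stochastic stages; even spacing needs no randomness).
    """
    rows = []
    for spec in chromosomes:
        if spec.len_cM <= 0 or spec.len_Mbp <= 0:
            raise InvalidDesignError(f"chromosome {spec.chrom}: non-positive length")
        if spec.n_markers < 2:
            raise InvalidDesignError(f"chromosome {spec.chrom}: need >= 2 markers")
        cm = np.linspace(0.0, spec.len_cM, spec.n_markers)
        mbp = cm / spec.len_cM * spec.len_Mbp
        for j, (p, q) in enumerate(zip(cm, mbp), start=1):
            rows.append((spec.chrom, f"c{spec.chrom}m{j:03d}", p, q, False))
    return MarkerMap(pd.DataFrame(rows, columns=["chrom", "marker", "cM", "Mbp", "pseudo"]))


def _simulate_gametes(cm: np.ndarray, n_gametes: int, rng: np.random.Generator) -> np.ndarray:
    """Gamete alleles (0/1) at marker positions under the Haldane model.

    The crossover Poisson process restricted to the marker positions is a
    Markov chain whose switch probability over an interval of d cM is the
    Haldane recombination fraction r(d)."""
    n_loci = len(cm)
    alleles = np.empty((n_gametes, n_loci), dtype=np.int8)
    alleles[:, 0] = rng.random(n_gametes) < 0.5
    r = haldane_r(np.diff(cm))
    switches = rng.random((n_gametes, n_loci - 1)) < r[None, :]
    # cumulative XOR of switch indicators propagates the allele down the chromosome
    flips = np.cumsum(switches, axis=1) % 2
    alleles[:, 1:] = (alleles[:, [0]] + flips) % 2
    return alleles


def simulate_f2_genotypes(marker_map: MarkerMap, n_mice: int, seed: int = 0) -> pd.DataFrame:
    """True (error-free) F2 genotypes: sum of two independent gametes per chromosome."""
    if n_mice < 1:
        raise InvalidDesignError("n_mice must be >= 1")
    rng = np.random.default_rng(seed)
    cols = []
    for chrom in marker_map.chromosomes:
        sub = marker_map.chromosome(chrom)
        cm = sub["cM"].to_numpy()
        g1 = _simulate_gametes(cm, n_mice, rng)
        g2 = _simulate_gametes(cm, n_mice, rng)
        cols.append(pd.DataFrame(g1 + g2, columns=sub["marker"].to_numpy()))
    geno = pd.concat(cols, axis=1).astype(float)
    geno.index = pd.Index([f"M{i + 1:04d}" for i in range(n_mice)], name="mouse")
    return geno


def corrupt_genotypes(geno: pd.DataFrame, error_rate: float, missing_rate: float,
                      seed: int = 0) -> pd.DataFrame:
    """Apply genotyping error and missingness to a clean genotype matrix.

    Each call is independently set missing with probability ``missing_rate``,
    or replaced by one of the two other codes (uniformly) with probability
    ``error_rate``; otherwise it is passed through unchanged.
    """
    for name, v in (("error_rate", error_rate), ("missing_rate", missing_rate)):
        if not (0 <= v < 0.5):
            raise InvalidDesignError(f"{name} must lie in [0, 0.5)")
    rng = np.random.default_rng(seed)
    vals = geno.to_numpy(dtype=float).copy()
    u = rng.random(vals.shape)
    vals[u < missing_rate] = np.nan
    flip = (u >= missing_rate) & (u < missing_rate + error_rate) & ~np.isnan(vals)
    # uniformly one of the two other codes: shift by 1 or 2 mod 3
    shift = rng.integers(1, 3, size=vals.shape)
    vals[flip] = (vals[flip] + shift[flip]) % 3
    return pd.DataFrame(vals, index=geno.index, columns=geno.columns)


# --------------------------------------------------------------------------- #
# phenotype simulation
# --------------------------------------------------------------------------- #

def _nearest_marker(marker_map: MarkerMap, chrom: str, pos_cm: float) -> tuple[str, float, float]:
    sub = marker_map.chromosome(chrom)
    i = int((sub["cM"] - pos_cm).abs().to_numpy().argmin())
    row = sub.iloc[i]
    return str(row["marker"]), float(row["cM"]), float(row["Mbp"])


def _signed_dosage(codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(s, h): signed allele dosage in {-1, 0, +1} and heterozygosity indicator."""
    s = codes - 1.0
    h = (codes == 1).astype(float)
    return s, h


def simulate_phenotypes(geno: pd.DataFrame, marker_map: MarkerMap,
                        design: SimDesign) -> F2CrossData:
    """Expression and clinical traits over true genotypes, per the design.

    ``geno`` must be the clean (error-free) genotype matrix: trait values are
    functions of the true genotype, not of the observed calls.  Truth labels
    and gene locations are recorded in the annotation table.
    """
    n = len(geno)
    if n != design.n_mice:
        raise InvalidDesignError("genotype matrix does not match design.n_mice")
    ss = np.random.SeedSequence(design.seed)
    # independent substreams per stage so each is reproducible in isolation
    (rng_cov, rng_drv, rng_med, rng_dir, rng_dec, rng_null, rng_clin,
     rng_place) = [np.random.default_rng(s) for s in ss.spawn(8)]

    sex = (rng_cov.random(n) < 0.5).astype(int)
    batch = np.arange(n) % design.n_batches          # round-robin batches
    batch_effects = rng_cov.normal(0.0, design.batch_sd, size=design.n_batches)

    drv_pos = design.resolved_driver_pos()
    drv_marker, drv_cm, drv_mbp = _nearest_marker(marker_map, design.hotspot_chrom, drv_pos)
    s_drv, h_drv = _signed_dosage(geno[drv_marker].to_numpy())

    pheno: dict[str, np.ndarray] = {}
    annot_rows: list[tuple] = []

    def add(name, values, chrom, mbp, cm, gwas, label):
        pheno[name] = values
        annot_rows.append((name, chrom, mbp, cm, gwas, label))

    y_drv = (design.driver_additive * s_drv + design.driver_dominance * h_drv
             + batch_effects[batch] + design.sex_effect * sex
             + rng_drv.normal(0.0, design.driver_sd, size=n))
    add("driver", y_drv, design.hotspot_chrom, drv_mbp, drv_cm, False, "driver")

    other_chroms = [c for c in marker_map.chromosomes if c != design.hotspot_chrom]

    def random_location(rng):
        chrom = other_chroms[rng.integers(len(other_chroms))]
        sub = marker_map.chromosome(chrom)
        lo, hi = float(sub["cM"].iloc[0]), float(sub["cM"].iloc[-1])
        cm = float(rng.uniform(lo, hi))
        mbp = float(np.interp(cm, sub["cM"], sub["Mbp"]))
        return chrom, mbp, cm

    # mediated targets: driven only through the driver's expression
    signs = np.where(np.arange(design.n_mediated) % 2 == 0, 1.0, -1.0)
    lo, hi = design.mediation_coef_range
    coefs = signs * rng_med.uniform(lo, hi, size=design.n_mediated)
    for j in range(design.n_mediated):
        y = coefs[j] * y_drv + rng_med.normal(0.0, design.mediated_sd, size=n)
        chrom, mbp, cm = random_location(rng_place)
        add(f"med{j + 1:03d}", y, chrom, mbp, cm, True, "mediated")

    # direct trans targets: their own genotype effect at a non-hotspot locus,
    # unlinked to the driver, so conditioning on the driver leaves them intact
    for j in range(design.n_direct):
        sign = 1.0 if j % 2 == 0 else -1.0
        qtl_chrom = other_chroms[j % len(other_chroms)]
        qsub = marker_map.chromosome(qtl_chrom)
        qpos = float(rng_place.uniform(qsub["cM"].iloc[0], qsub["cM"].iloc[-1]))
        mk, _, _ = _nearest_marker(marker_map, qtl_chrom, qpos)
        s_loc, _ = _signed_dosage(geno[mk].to_numpy())
        y = (sign * design.direct_additive * s_loc
             + rng_dir.normal(0.0, design.direct_sd, size=n))
        chrom, mbp, cm = random_location(rng_place)
        add(f"dir{j + 1:02d}", y, chrom, mbp, cm, True, "direct")

    # decoy cis genes spread along the hotspot chromosome
    hs = marker_map.chromosome(design.hotspot_chrom)
    hs_len = float(hs["cM"].iloc[-1])
    decoy_pos = np.linspace(0.05, 0.95, design.n_decoy_cis) * hs_len if design.n_decoy_cis else []
    for j, pos in enumerate(decoy_pos):
        mk, cm, mbp = _nearest_marker(marker_map, design.hotspot_chrom, float(pos))
        s_k, _ = _signed_dosage(geno[mk].to_numpy())
        sign = 1.0 if j % 2 == 0 else -1.0
        y = sign * design.decoy_additive * s_k + rng_dec.normal(0.0, design.decoy_sd, size=n)
        add(f"cisTF{j + 1:02d}", y, design.hotspot_chrom, mbp, cm, False, "decoy_cis")

    for j in range(design.n_null):
        y = rng_null.normal(0.0, design.null_sd, size=n)
        chrom, mbp, cm = random_location(rng_place)
        add(f"null{j + 1:03d}", y, chrom, mbp, cm, False, "null")

    y_ins = design.clinical_coef * y_drv + rng_clin.normal(0.0, design.clinical_sd, size=n)
    add("insulin", y_ins, None, np.nan, np.nan, False, "clinical")

    pheno_df = pd.DataFrame(pheno, index=geno.index)
    covar = pd.DataFrame({"sex": sex, "batch": batch}, index=geno.index)
    annot = pd.DataFrame(
        annot_rows,
        columns=["trait", "chrom", "Mbp", "cM", "is_gwas_candidate", "truth_label"],
    ).set_index("trait")
    return F2CrossData(marker_map=marker_map, geno=geno, pheno=pheno_df,
                       covar=covar, annot=annot)


def simulate_cross(design: SimDesign) -> F2CrossData:
    """End-to-end cross: map, meiosis, phenotypes, then genotype corruption.

    One global seed fans out to per-stage substreams, so each stage is
    individually reproducible and the whole cross is bit-identical across
    runs with the same design.
    """
    ss = np.random.SeedSequence(design.seed)
    seed_geno, seed_corrupt = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(2)]
    marker_map = make_marker_map(design.chromosomes, seed=design.seed)
    clean = simulate_f2_genotypes(marker_map, design.n_mice, seed=seed_geno)
    cross = simulate_phenotypes(clean, marker_map, design)
    observed = corrupt_genotypes(clean, design.genotyping_error_rate,
                                 design.missing_rate, seed=seed_corrupt)
    return F2CrossData(marker_map=marker_map, geno=observed, pheno=cross.pheno,
                       covar=cross.covar, annot=cross.annot)
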