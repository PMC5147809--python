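"""Cross-file I/O, pipeline configuration, and the end-to-end driver.

The cross file follows the de-facto mouse-QTL "cross CSV" dialect:

* row 1 — phenotype names followed by marker names,
* row 2 — blank under phenotypes, chromosome id under each marker,
* row 3 — blank under phenotypes, genetic position (cM) under each marker,
* remaining rows — one mouse each: phenotype values then genotype codes
  (default alphabet B/H/T for homozygous B6-type, heterozygous,
  homozygous BTBR-type; "-" for missing).

Gene annotations and covariates travel in two side-car CSVs.  A pipeline
run is described by a :class:`PipelineConfig` (YAML/JSON-loadable) and
executed by :func:`run_pipeline`: simulate or load → genotype
probabilities → quantile transform → genome scans → eQTL catalog and
hotspot profile → mediation ranking → CSV outputs plus a JSON manifest.
"""

from __future__ import annotations

import csv
import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, DataError, MapError
from .eqtl_catalog import build_catalog, catalog_frame, hotspot_profile
from .genoprob import calc_genoprob
from .markers import MarkerMap
from .mediation import candidate_summary_score, rank_candidates, ranking_frame
from .qtl_scan import best_per_chromosome, encode_covariates, normal_quantile_transform, scanone
from .synthetic_cross import F2CrossData, SimDesign, simulate_cross

log = logging.getLogger("qtlmediate")

DEFAULT_ALPHABET = {0.0: "B", 1.0: "H", 2.0: "T"}
DEFAULT_MISSING = "-"


# --------------------------------------------------------------------------- #
# cross CSV
# --------------------------------------------------------------------------- #

def write_cross(cross: F2CrossData, path, alphabet: dict | None = None,
                missing: str = DEFAULT_MISSING) -> None:
    """Write genotypes + phenotypes in the cross CSV dialect."""
    alphabet = alphabet or DEFAULT_ALPHABET
    typed = cross.marker_map.typed_only()
    markers = list(typed.marker_names)
    tab = typed.table.set_index("marker")
    traits = list(cross.pheno.columns)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["id"] + traits + markers)
        w.writerow(["", *[""] * len(traits)] + [str(tab.loc[m, "chrom"]) for m in markers])
        w.writerow(["", *[""] * len(traits)] + [repr(float(tab.loc[m, "cM"])) for m in markers])
        geno = cross.geno[markers].to_numpy(dtype=float)
        pheno = cross.pheno.to_numpy(dtype=float)
        for i, mouse in enumerate(cross.geno.index):
            prow = [repr(float(v)) if not np.isnan(v) else "" for v in pheno[i]]
            grow = [missing if np.isnan(v) else alphabet[v] for v in geno[i]]
            w.writerow([str(mouse)] + prow + grow)


def read_cross(path, annot_path=None, covar_path=None, mbp_per_cm: float | None = None,
               alphabet: dict | None = None, missing: str = DEFAULT_MISSING) -> F2CrossData:
    """Read a cross CSV (plus optional annotation/covariate side-cars).

    Columns whose chromosome row is blank are phenotypes; the rest are
    markers.  Physical positions for markers are taken from the annotation
    file when a marker row is present there, otherwise scaled from cM by
    ``mbp_per_cm`` (default 1.5 Mbp/cM, a mouse-genome-average fallback).
    """
    inv = {v: k for k, v in (alphabet or DEFAULT_ALPHABET).items()}
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    if len(rows) < 4:
        raise DataError(f"{path}: not a cross CSV (fewer than 4 rows)")
    header, chrom_row, pos_row = rows[0], rows[1], rows[2]
    if header[0] != "id":
        raise DataError(f"{path}: first column must be 'id'")
    is_marker = [c != "" for c in chrom_row]
    is_marker[0] = False
    traits = [h for h, m in zip(header[1:], is_marker[1:]) if not m]
    markers = [h for h, m in zip(header, is_marker) if m]
    chroms = [c for c, m in zip(chrom_row, is_marker) if m]
    try:
        cms = [float(p) for p, m in zip(pos_row, is_marker) if m]
    except ValueError as e:
        raise MapError(f"{path}: bad cM position: {e}") from e

    mice, pheno_rows, geno_rows = [], [], []
    for r, row in enumerate(rows[3:], start=4):
        mice.append(row[0])
        pvals, gvals = [], []
        for c, (val, mk) in enumerate(zip(row[1:], is_marker[1:]), start=2):
            if mk:
                if val == missing:
                    gvals.append(np.nan)
                elif val in inv:
                    gvals.append(inv[val])
                else:
                    raise DataError(
                        f"{path}: unknown genotype symbol {val!r} at row {r}, column {c}")
            else:
                pvals.append(float(val) if val != "" else np.nan)
        pheno_rows.append(pvals)
        geno_rows.append(gvals)

    annot = read_annotations(annot_path) if annot_path else None
    scale = 1.5 if mbp_per_cm is None else mbp_per_cm
    mbps = []
    for mk, cm in zip(markers, cms):
        if annot is not None and mk in annot.index and not pd.isna(annot.loc[mk, "Mbp"]):
            mbps.append(float(annot.loc[mk, "Mbp"]))
        else:
            mbps.append(cm * scale)
    marker_map = MarkerMap(pd.DataFrame(
        {"chrom": chroms, "marker": markers, "cM": cms, "Mbp": mbps, "pseudo": False}))

    idx = pd.Index(mice, name="mouse")
    geno = pd.DataFrame(geno_rows, index=idx, columns=markers, dtype=float)
    pheno = pd.DataFrame(pheno_rows, index=idx, columns=traits, dtype=float)
    covar = read_covariates(covar_path).loc[idx] if covar_path else \
        pd.DataFrame(index=idx)
    if annot is None:
        annot = pd.DataFrame(
            {"chrom": pd.Series([None] * len(traits), dtype=object),
             "Mbp": np.nan, "cM": np.nan,
             "is_gwas_candidate": False, "truth_label": "unknown"},
            index=pd.Index(traits, name="trait"))
    else:
        annot = annot.loc[[t for t in traits if t in annot.index]]
        missing_traits = [t for t in traits if t not in annot.index]
        if missing_traits:
            filler = pd.DataFrame(
                {"chrom": pd.Series([None] * len(missing_traits), dtype=object),
                 "Mbp": np.nan, "cM": np.nan,
                 "is_gwas_candidate": False, "truth_label": "unknown"},
                index=pd.Index(missing_traits, name="trait"))
            annot = pd.concat([annot, filler])
    return F2CrossData(marker_map=marker_map, geno=geno, pheno=pheno,
                       covar=covar, annot=annot)


_ANNOT_SCHEMA = ["trait", "chrom", "Mbp", "cM", "is_gwas_candidate", "truth_label"]
_COVAR_SCHEMA = ["mouse", "sex", "batch"]


def write_annotations(annot: pd.DataFrame, path) -> None:
    out = annot.reset_index()
    out.columns = _ANNOT_SCHEMA
    _write_schema_csv(out, path, _ANNOT_SCHEMA)


def read_annotations(path) -> pd.DataFrame:
    df = _read_schema_csv(path, _ANNOT_SCHEMA, dtype={"chrom": str}).set_index("trait")
    df["chrom"] = df["chrom"].astype(object).where(df["chrom"].notna(), None)
    df["is_gwas_candidate"] = df["is_gwas_candidate"].astype(bool)
    return df


def write_covariates(covar: pd.DataFrame, path) -> None:
    out = covar.reset_index()
    out.columns = _COVAR_SCHEMA[:out.shape[1]]
    _write_schema_csv(out, path, list(out.columns))


def read_covariates(path) -> pd.DataFrame:
    return _read_schema_csv(path, None).set_index("mouse")


def _write_schema_csv(df: pd.DataFrame, path, schema: list[str]) -> None:
    with open(path, "w") as fh:
        fh.write("# schema: " + ",".join(schema) + "\n")
        df.to_csv(fh, index=False)


def _read_schema_csv(path, schema: list[str] | None, dtype=None) -> pd.DataFrame:
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("# schema:"):
            raise DataError(f"{path}: missing schema header comment")
        declared = first.split(":", 1)[1].strip().split(",")
        if schema is not None and declared != schema:
            raise DataError(f"{path}: schema drift: {declared} != {schema}")
        # only empty cells are missing ("null" is a legitimate truth label)
        return pd.read_csv(fh, keep_default_na=False, na_values=[""], dtype=dtype)


# --------------------------------------------------------------------------- #
# configuration
# --------------------------------------------------------------------------- #

@dataclass
class PipelineConfig:
    """Everything needed to run the pipeline end to end.

    Exactly one of (cross_path) or (simulate=True + design) drives a run.
    """

    outdir: str = "results"
    cross_path: str | None = None
    annot_path: str | None = None
    covar_path: str | None = None
    simulate: bool = False
    design: SimDesign | None = None

    step_cm: float = 2.0
    error_rate: float = 0.002
    lod_threshold: float = 5.0
    lod_drop: float = 1.5
    cis_window_cm: float = 2.5
    cis_window_mbp: float = 5.0

    hotspot_chrom: str = "2"
    candidates: list[str] | str = "auto"     # "auto" = significant cis-eQTLs on hotspot chrom
    gwas_flag_column: str = "is_gwas_candidate"

    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        has_paths = self.cross_path is not None
        if has_paths == self.simulate:
            raise ConfigError("exactly one of cross_path or simulate must drive a run")
        if self.simulate and self.design is None:
            self.design = SimDesign(seed=self.seed)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        design_raw = raw.pop("design", None)
        cfg = cls(**raw)
        if design_raw is not None:
            cfg.design = SimDesign(**design_raw)
        return cfg


# --------------------------------------------------------------------------- #
# pipeline
# --------------------------------------------------------------------------- #

def _file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis and write peaks/hotspot/mediation CSVs.

    Returns a dict with the in-memory results (cross, peaks table, hotspot
    profile, mediation ranking, manifest) for programmatic use; the same
    tables are written under ``config.outdir``.
    """
    logging.basicConfig(level=config.log_level)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()

    if config.simulate:
        cross = simulate_cross(config.design)
        input_hash = hashlib.sha256(
            repr(dataclasses.asdict(config.design)).encode()).hexdigest()
    else:
        cross = read_cross(config.cross_path, config.annot_path, config.covar_path)
        input_hash = _file_sha256(config.cross_path)
    log.info("cross ready: %d mice, %d markers, %d traits (%.1fs)",
             len(cross.geno), cross.marker_map.n_markers, cross.pheno.shape[1],
             time.perf_counter() - t0)

    gp = calc_genoprob(cross.geno, cross.marker_map, step_cm=config.step_cm,
                       error_rate=config.error_rate)
    log.info("genotype probabilities on %d grid loci (%.1fs)",
             len(gp.grid), time.perf_counter() - t0)

    addcovar, intcovar = encode_covariates(cross.covar) if len(cross.covar.columns) \
        else (None, None)
    transformed = pd.DataFrame(
        {t: normal_quantile_transform(cross.pheno[t]) for t in cross.pheno.columns},
        index=cross.pheno.index)

    curves = scanone(gp, transformed, addcovar=addcovar, intcovar=intcovar)
    peaks_by_trait = {c.trait: best_per_chromosome(c, config.lod_threshold, config.lod_drop)
                      for c in curves}
    log.info("scans done for %d traits (%.1fs)", len(curves), time.perf_counter() - t0)

    records = build_catalog(peaks_by_trait, cross.annot)
    profile = hotspot_profile(records, gp.grid, subset="gwas")

    # candidate pool: significant cis-eQTLs on the hotspot chromosome
    if config.candidates == "auto":
        candidates = sorted({r.trait for r in records
                             if r.regulation == "cis"
                             and r.peak.chrom == config.hotspot_chrom
                             and r.peak.significant})
    else:
        candidates = list(config.candidates)
    targets = [t for t in cross.pheno.columns
               if bool(cross.annot.loc[t, config.gwas_flag_column])]

    ranking = pd.DataFrame()
    results = []
    if candidates and targets:
        results = [candidate_summary_score(
            c, targets, cross.pheno, gp, addcovar=addcovar, intcovar=intcovar,
            chrom=config.hotspot_chrom, threshold=config.lod_threshold)
            for c in candidates]
        results = rank_candidates(results)
        ranking = ranking_frame(results)
    log.info("mediation: %d candidates × %d targets (%.1fs)",
             len(candidates), len(targets), time.perf_counter() - t0)

    peaks_rows = [{
        "trait": pk.trait, "chr": pk.chrom, "pos_cM": pk.pos_cM, "pos_Mbp": pk.pos_Mbp,
        "lod": pk.lod, "ci_lo_cM": pk.ci_lo_cM, "ci_hi_cM": pk.ci_hi_cM,
        "significant": pk.significant,
    } for pks in peaks_by_trait.values() for pk in pks if pk.significant]
    peaks_df = pd.DataFrame(peaks_rows)
    catalog_df = catalog_frame(records)
    hotspot_df = profile.to_frame()

    _write_schema_csv(peaks_df, outdir / "peaks.csv", list(peaks_df.columns))
    _write_schema_csv(catalog_df, outdir / "catalog.csv", list(catalog_df.columns))
    _write_schema_csv(hotspot_df, outdir / "hotspot.csv", list(hotspot_df.columns))
    if len(ranking):
        _write_schema_csv(ranking, outdir / "mediation.csv", list(ranking.columns))

    manifest = {
        "seed": config.seed,
        "step_cm": config.step_cm, "error_rate": config.error_rate,
        "lod_threshold": config.lod_threshold, "lod_drop": config.lod_drop,
        "hotspot_chrom": config.hotspot_chrom,
        "n_mice": int(len(cross.geno)), "n_markers": int(cross.marker_map.n_markers),
        "n_traits": int(cross.pheno.shape[1]),
        "n_candidates": len(candidates), "n_targets": len(targets),
        "input_sha256": input_hash,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    log.info("pipeline complete (%.1fs)", time.perf_counter() - t0)

    return {"cross": cross, "genoprob": gp, "curves": curves,
            "peaks": peaks_df, "catalog": catalog_df, "records": records,
            "hotspot": profile, "mediation": results, "ranking": ranking,
            "manifest": manifest}
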