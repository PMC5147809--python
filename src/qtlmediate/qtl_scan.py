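"""Single-QTL genome scans by regression on expected genotype dosages.

Traits are first mapped to normal quantiles; at every grid locus the trait
is regressed on the additive dosage s = P(BB) − P(AA) and the dominance
dosage h = P(AB) (the regression-on-probabilities approximation to
interval mapping, exact at fully informative markers), together with any
additive covariates and covariate × QTL interactions.  The evidence for a
QTL is the LOD score

    LOD = (n/2) · log10(RSS0 / RSS1),

the log10 likelihood ratio of the QTL model against the covariate-only
null under Gaussian errors.  Peaks are summarized one per chromosome with
a 1.5-LOD support interval and a trait-wise significance threshold
(default LOD ≥ 5).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .errors import AlignmentError, DegenerateTraitError, InvalidArgumentError
from .genoprob import GenoProbTensor
from .markers import MarkerMap

LOD_CAP = 9999.0
_RSS_FLOOR_FACTOR = 1e-12


# --------------------------------------------------------------------------- #
# trait transformation
# --------------------------------------------------------------------------- #

def normal_quantile_transform(y) -> np.ndarray:
    """Rank-based transform of a trait to standard-normal quantiles.

    Non-missing values are replaced by Phi^-1((rank − 1/2) / m) where m is
    the number of non-missing values; tied observations receive the average
    of their ranks' quantiles; missing values stay missing.
    """
    y = np.asarray(y, dtype=float)
    out = np.full(y.shape, np.nan)
    obs = ~np.isnan(y)
    m = int(obs.sum())
    if m < 3:
        raise DegenerateTraitError("need at least 3 non-missing values")
    v = y[obs]
    if np.all(v == v[0]):
        raise DegenerateTraitError("constant trait cannot be quantile-transformed")
    order = np.argsort(v, kind="stable")
    q_sorted = stats.norm.ppf((np.arange(1, m + 1) - 0.5) / m)
    q = np.empty(m)
    q[order] = q_sorted
    # ties: average the quantiles assigned within each tied group
    uniq, inv = np.unique(v, return_inverse=True)
    sums = np.bincount(inv, weights=q)
    counts = np.bincount(inv)
    q = (sums / counts)[inv]
    out[obs] = q
    return out


# --------------------------------------------------------------------------- #
# result containers
# --------------------------------------------------------------------------- #

@dataclass
class LodCurve:
    """Genome-scan LOD profile for one trait on a marker/pseudomarker grid."""

    trait: str
    grid: MarkerMap
    lod: np.ndarray
    model: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.lod = np.asarray(self.lod, dtype=float)
        if len(self.lod) != len(self.grid):
            raise InvalidArgumentError("lod length does not match grid length")
        if np.nanmin(self.lod) < -1e-9:
            raise InvalidArgumentError("negative lod score")
        self.lod = np.maximum(self.lod, 0.0)

    def chromosome_max(self, chrom: str) -> float:
        sub = self.grid.chromosome(chrom)
        return float(np.max(self.lod[sub.index.to_numpy()]))


@dataclass(frozen=True)
class QtlPeak:
    """Per-chromosome LOD maximum with its 1.5-LOD support interval."""

    trait: str
    chrom: str
    pos_cM: float
    pos_Mbp: float
    lod: float
    ci_lo_cM: float
    ci_hi_cM: float
    ci_lo_Mbp: float
    ci_hi_Mbp: float
    significant: bool


# --------------------------------------------------------------------------- #
# regression core
# --------------------------------------------------------------------------- #

def _as_matrix(x, n: int, what: str) -> np.ndarray:
    if x is None:
        return np.empty((n, 0))
    arr = x.to_numpy(dtype=float) if hasattr(x, "to_numpy") else np.asarray(x, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    if arr.shape[0] != n:
        raise AlignmentError(f"{what} has {arr.shape[0]} rows, expected {n}")
    return arr


def _proj_rss(X: np.ndarray, Y: np.ndarray, yty: np.ndarray) -> tuple[np.ndarray, int]:
    """Residual sums of squares of Y on span(X), rank-aware via pivoted QR."""
    Q, R, _ = linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag[0] * max(X.shape) * np.finfo(float).eps if diag.size and diag[0] > 0 else 0.0
    rank = int((diag > tol).sum())
    coefs = Q[:, :rank].T @ Y
    rss = yty - np.einsum("ij,ij->j", coefs, coefs)
    return np.maximum(rss, 0.0), rank


def _lod_matrix(S: np.ndarray, H: np.ndarray, Y: np.ndarray,
                A: np.ndarray, I: np.ndarray) -> np.ndarray:
    """LOD scores (n_loci × n_traits) for complete-case trait block Y.

    S, H: (n, L) additive/dominance dosages; A: additive covariates
    (without intercept); I: interactive covariates (also added to both
    models additively; their products with s and h enter the QTL model).
    """
    n, L = S.shape
    ones = np.ones((n, 1))
    X0 = np.hstack([ones, A, I])
    yty = np.einsum("ij,ij->j", Y, Y)
    tss = yty - (Y.sum(axis=0) ** 2) / n
    floor = np.maximum(_RSS_FLOOR_FACTOR * tss, np.finfo(float).tiny)
    rss0, _ = _proj_rss(X0, Y, yty)
    lod = np.empty((L, Y.shape[1]))
    for l in range(L):
        s, h = S[:, l][:, None], H[:, l][:, None]
        parts = [X0, s, h]
        if I.shape[1]:
            parts += [I * s, I * h]
        rss1, _ = _proj_rss(np.hstack(parts), Y, yty)
        lod[l] = 0.5 * n * np.log10(np.maximum(rss0, floor) / np.maximum(rss1, floor))
    return np.clip(lod, 0.0, LOD_CAP)


def fit_lod(probs_at_locus, y, addcovar=None, intcovar=None) -> float:
    """LOD at one locus from 3-state genotype probability rows.

    Mice with a missing trait or covariate value are dropped listwise.
    A rank-deficient design triggers a warning and the offending columns
    are dropped (pivoted QR); an essentially perfect fit is capped at a
    LOD of 9999.
    """
    P = np.asarray(probs_at_locus, dtype=float)
    y = np.asarray(y, dtype=float)
    n_all = len(y)
    A = _as_matrix(addcovar, n_all, "addcovar")
    I = _as_matrix(intcovar, n_all, "intcovar")
    keep = ~np.isnan(y)
    if A.size:
        keep &= ~np.isnan(A).any(axis=1)
    if I.size:
        keep &= ~np.isnan(I).any(axis=1)
    P, y, A, I = P[keep], y[keep], A[keep], I[keep]
    n = len(y)
    if n < 3:
        raise DegenerateTraitError("fewer than 3 complete observations")
    s = (P[:, 2] - P[:, 0])[:, None]
    h = P[:, 1][:, None]
    parts = [np.ones((n, 1)), A, I, s, h]
    if I.shape[1]:
        parts += [I * s, I * h]
    X1 = np.hstack(parts)
    yty = float(y @ y)
    tss = yty - y.sum() ** 2 / n
    floor = max(_RSS_FLOOR_FACTOR * tss, np.finfo(float).tiny)
    Y = y[:, None]
    rss0, _ = _proj_rss(np.hstack([np.ones((n, 1)), A, I]), Y, np.array([yty]))
    rss1, rank1 = _proj_rss(X1, Y, np.array([yty]))
    if rank1 < X1.shape[1]:
        warnings.warn("rank-deficient QTL design; redundant columns dropped",
                      stacklevel=2)
    if rss1[0] < floor:
        warnings.warn("near-perfect fit; LOD capped", stacklevel=2)
    lod = 0.5 * n * np.log10(max(rss0[0], floor) / max(rss1[0], floor))
    return float(np.clip(lod, 0.0, LOD_CAP))


# --------------------------------------------------------------------------- #
# genome scan
# --------------------------------------------------------------------------- #

def scanone(gp: GenoProbTensor, pheno, addcovar=None, intcovar=None,
            chrom: str | None = None) -> list[LodCurve]:
    """Genome (or single-chromosome) scan of one or many traits.

    Parameters
    ----------
    gp:
        genotype probabilities; its mouse index must overlap the phenotype
        index (scans run on the intersection, in tensor order).
    pheno:
        Series, DataFrame, or array of traits (already transformed as
        desired — this function does not quantile-transform).
    addcovar, intcovar:
        additive and interactive covariate matrices aligned with pheno.
        Interactive covariates are included additively in both models;
        their products with the QTL dosages enter only the QTL model.
    chrom:
        restrict the scan to one chromosome.

    Missingness is handled per trait by listwise deletion; traits sharing
    a missingness pattern are fit in one batched pass.
    """
    if isinstance(pheno, pd.Series):
        pheno = pheno.to_frame()
    elif not isinstance(pheno, pd.DataFrame):
        arr = np.asarray(pheno, dtype=float)
        if arr.ndim == 1:
            arr = arr[:, None]
        pheno = pd.DataFrame(arr, index=gp.mice,
                             columns=[f"trait{i}" for i in range(arr.shape[1])])

    common = gp.mice.intersection(pheno.index)
    if len(common) == 0:
        raise AlignmentError("no mice shared between genotype probabilities and phenotypes")
    rows = pd.Index(gp.mice).get_indexer(common)

    if chrom is None:
        grid = gp.grid
        probs = gp.probs[rows]
    else:
        sub = gp.grid.chromosome(chrom)
        grid = MarkerMap(sub.reset_index(drop=True))
        probs = gp.probs[np.ix_(rows, sub.index.to_numpy())]

    Yfull = pheno.loc[common].to_numpy(dtype=float)
    A = _as_matrix(None if addcovar is None else
                   (addcovar.loc[common] if hasattr(addcovar, "loc") else addcovar),
                   len(common), "addcovar")
    I = _as_matrix(None if intcovar is None else
                   (intcovar.loc[common] if hasattr(intcovar, "loc") else intcovar),
                   len(common), "intcovar")
    covar_ok = np.ones(len(common), dtype=bool)
    if A.size:
        covar_ok &= ~np.isnan(A).any(axis=1)
    if I.size:
        covar_ok &= ~np.isnan(I).any(axis=1)

    S = probs[:, :, 2] - probs[:, :, 0]
    H = probs[:, :, 1]

    n_traits = Yfull.shape[1]
    lod_all = np.empty((len(grid), n_traits))
    n_used = np.empty(n_traits, dtype=int)
    miss = np.isnan(Yfull) | ~covar_ok[:, None]
    patterns, inverse = np.unique(miss, axis=1, return_inverse=True)
    for p in range(patterns.shape[1]):
        cols = np.flatnonzero(inverse == p)
        keep = ~patterns[:, p]
        if keep.sum() < 3:
            raise DegenerateTraitError(
                f"trait(s) {list(pheno.columns[cols])}: fewer than 3 complete observations")
        lod_all[:, cols] = _lod_matrix(S[keep], H[keep], Yfull[np.ix_(keep, cols)],
                                       A[keep], I[keep])
        n_used[cols] = int(keep.sum())

    model = {"addcovar": _names(addcovar), "intcovar": _names(intcovar)}
    return [
        LodCurve(trait=str(t), grid=grid, lod=lod_all[:, j],
                 model={**model, "n_mice": int(n_used[j])})
        for j, t in enumerate(pheno.columns)
    ]


def _names(x) -> list[str]:
    if x is None:
        return []
    if hasattr(x, "columns"):
        return [str(c) for c in x.columns]
    if hasattr(x, "name"):
        return [str(x.name)]
    arr = np.asarray(x)
    k = 1 if arr.ndim == 1 else arr.shape[1]
    return [f"covar{i}" for i in range(k)]


def encode_covariates(covar: pd.DataFrame, additive=("batch",), interactive=("sex",)
                      ) -> tuple[pd.DataFrame | None, pd.DataFrame | None]:
    """Design matrices from a covariate table.

    Categorical columns (e.g. batch) are one-hot encoded dropping the first
    level; numeric columns pass through.  Returns (addcovar, intcovar),
    either possibly None.
    """
    def build(cols):
        parts = []
        for c in cols:
            if c not in covar.columns:
                continue
            col = covar[c]
            if col.dtype.kind in "ifu" and col.nunique() > 2:
                parts.append(col.to_frame())
            elif col.nunique() <= 2 and col.dtype.kind in "ifu":
                parts.append(col.to_frame())
            else:
                parts.append(pd.get_dummies(col, prefix=c, drop_first=True, dtype=float))
        if not parts:
            return None
        return pd.concat(parts, axis=1).astype(float)

    # batch is categorical no matter its dtype
    add_parts = []
    for c in additive:
        if c not in covar.columns:
            continue
        if c == "batch" or covar[c].dtype.kind not in "if":
            add_parts.append(pd.get_dummies(covar[c], prefix=c, drop_first=True, dtype=float))
        else:
            add_parts.append(covar[c].to_frame().astype(float))
    addmat = pd.concat(add_parts, axis=1) if add_parts else None
    intmat = build(interactive)
    return addmat, intmat


# --------------------------------------------------------------------------- #
# peaks and support intervals
# --------------------------------------------------------------------------- #

def lod_support_interval(curve: LodCurve, chrom: str, drop: float = 1.5
                         ) -> tuple[float, float]:
    """Conservative 1.5-LOD support interval (cM) on one chromosome.

    Returns the outermost grid positions whose LOD is within ``drop`` of
    the chromosome maximum; internal dips are spanned.
    """
    sub = curve.grid.chromosome(chrom)
    lods = curve.lod[sub.index.to_numpy()]
    cm = sub["cM"].to_numpy()
    peak = lods.max()
    inside = np.flatnonzero(lods >= peak - drop)
    return float(cm[inside[0]]), float(cm[inside[-1]])


def best_per_chromosome(curve: LodCurve, threshold: float = 5.0,
                        drop: float = 1.5) -> list[QtlPeak]:
    """One candidate peak per chromosome (ties broken leftmost)."""
    peaks = []
    for chrom in curve.grid.chromosomes:
        sub = curve.grid.chromosome(chrom)
        idx = sub.index.to_numpy()
        lods = curve.lod[idx]
        k = int(np.argmax(lods))          # argmax returns the first (leftmost) max
        lo_cm, hi_cm = lod_support_interval(curve, chrom, drop)
        cm = sub["cM"].to_numpy()
        mbp = sub["Mbp"].to_numpy()
        lo_mbp = float(np.interp(lo_cm, cm, mbp))
        hi_mbp = float(np.interp(hi_cm, cm, mbp))
        peaks.append(QtlPeak(
            trait=curve.trait, chrom=chrom,
            pos_cM=float(cm[k]), pos_Mbp=float(mbp[k]), lod=float(lods[k]),
            ci_lo_cM=lo_cm, ci_hi_cM=hi_cm, ci_lo_Mbp=lo_mbp, ci_hi_Mbp=hi_mbp,
            significant=bool(lods[k] >= threshold)))
    return peaks


# --------------------------------------------------------------------------- #
# closed-form one-way ANOVA LOD from printed group statistics
# --------------------------------------------------------------------------- #

def lod_from_group_stats(means, sems, ns) -> float:
    """One-way ANOVA LOD from per-genotype means, SEMs and group sizes.

    Reconstructs the sufficient statistics: within-group sd = SEM·sqrt(n),
    RSS_within = sum (n_i − 1)·sd_i², between-group SS from the group means
    about the grand mean, and LOD = (N/2)·log10(TSS / RSS_within).  This is
    what a fully informative single-marker regression computes, so printed
    per-genotype summaries suffice to recover the LOD.
    """
    means = np.asarray(means, dtype=float)
    sems = np.asarray(sems, dtype=float)
    ns = np.asarray(ns, dtype=float)
    if means.shape != sems.shape or means.shape != ns.shape:
        raise InvalidArgumentError("means, sems, ns must have equal length")
    sds = sems * np.sqrt(ns)
    rss_within = float(np.sum((ns - 1) * sds ** 2))
    N = ns.sum()
    grand = float(np.sum(ns * means) / N)
    between = float(np.sum(ns * (means - grand) ** 2))
    tss = rss_within + between
    return float(0.5 * N * np.log10(tss / rss_within))


def synthesize_group_data(means, sds, ns) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic per-mouse data with exact group means and sds.

    Returns (genotype codes 0/1/2, trait values); within each genotype
    class the values are an affinely standardized ramp, so the sample mean
    and sd (ddof=1) match the requested values exactly.  Useful for
    reconstructing a dataset from printed per-genotype summaries.
    """
    codes, values = [], []
    for g, (m, sd, n) in enumerate(zip(means, sds, ns)):
        base = np.linspace(-1.0, 1.0, int(n))
        base = base - base.mean()
        denom = base.std(ddof=1)
        vals = m + (sd / denom) * base if denom > 0 else np.full(int(n), m)
        codes.append(np.full(int(n), g))
        values.append(vals)
    return np.concatenate(codes).astype(float), np.concatenate(values)
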