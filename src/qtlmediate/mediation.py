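"""Conditional scans and candidate-mediator ranking.

The mediation question: does the expression of a cis-regulated candidate
gene explain the trans-eQTLs co-mapping at a hotspot?  Operationally, each
target trait is rescanned with the candidate's (quantile-transformed)
expression appended to the additive covariates.  If the candidate mediates
the genotype → target path, conditioning removes the signal and the
target's LOD collapses; if the target is linked directly, the LOD barely
moves.  Each candidate receives a summary score

    score = (# targets significant after) − (# targets significant before)

restricted to the hotspot chromosome; the most negative score marks the
strongest mediator, and candidates are ranked accordingly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DegenerateTraitError, InvalidArgumentError
from .genoprob import GenoProbTensor
from .qtl_scan import LodCurve, normal_quantile_transform, scanone


@dataclass
class MediationResult:
    """Per-candidate conditional-scan outcome over a set of target traits."""

    candidate: str
    table: pd.DataFrame          # target, lod_before, lod_after, lod_drop, sig flags
    score: int
    mean_lod_drop: float
    rank: int | None = None
    self_conditioning: bool = field(default=False)


def _aligned_series(x, mice) -> pd.Series:
    if isinstance(x, pd.Series):
        return x.loc[mice]
    return pd.Series(np.asarray(x, dtype=float), index=mice)


def conditional_scan(gp: GenoProbTensor, target, mediator, addcovar=None,
                     intcovar=None, chrom: str | None = None,
                     transform: bool = True) -> LodCurve:
    """Genome/chromosome scan of a target with a mediator regressed out.

    Mice missing the mediator are dropped; both target and mediator are
    quantile-transformed after that subsetting (so the transform reflects
    the mice actually scanned) unless ``transform`` is disabled.  The
    mediator enters the additive covariates only — mediation adjustment is
    an additive correction, not an interaction.
    """
    target = _aligned_series(target, gp.mice)
    mediator = _aligned_series(mediator, gp.mice)
    keep = mediator.notna()
    mice = gp.mice[keep.to_numpy()]
    t = target.loc[mice]
    m = mediator.loc[mice]
    if np.allclose(t.fillna(np.inf), m.fillna(np.inf)):
        warnings.warn("conditioning a trait on itself; LOD will be ~0", stacklevel=2)
    tv = normal_quantile_transform(t) if transform else t.to_numpy(dtype=float)
    mv = _transform_mediator(m) if transform else m.to_numpy(dtype=float)

    A = _covar_subset(addcovar, mice)
    Aplus = np.hstack([A, mv[:, None]]) if A is not None else mv[:, None]
    I = _covar_subset(intcovar, mice)
    curve = scanone(gp, pd.DataFrame({target.name or "target": tv}, index=mice),
                    addcovar=pd.DataFrame(Aplus, index=mice),
                    intcovar=None if I is None else pd.DataFrame(I, index=mice),
                    chrom=chrom)[0]
    return curve


def _transform_mediator(m: pd.Series) -> np.ndarray:
    """Quantile-transform a mediator; a constant mediator passes through.

    A zero-variance mediator column is rank-deficient against the intercept
    and is dropped inside the regression, making the conditional scan equal
    the unconditional one."""
    try:
        return normal_quantile_transform(m)
    except DegenerateTraitError:
        return m.to_numpy(dtype=float)


def _covar_subset(x, mice):
    if x is None:
        return None
    sub = x.loc[mice] if hasattr(x, "loc") else pd.DataFrame(np.asarray(x, dtype=float))
    arr = sub.to_numpy(dtype=float) if hasattr(sub, "to_numpy") else np.asarray(sub)
    if arr.ndim == 1:
        arr = arr[:, None]
    return arr


def candidate_summary_score(candidate: str, gwas_targets: list[str],
                            pheno: pd.DataFrame, gp: GenoProbTensor,
                            addcovar=None, intcovar=None, chrom: str = "2",
                            threshold: float = 5.0) -> MediationResult:
    """Conditional-dependence summary of one candidate over GWAS targets.

    For every target, the chromosome-restricted maximum LOD is computed
    before and after conditioning on the candidate's expression.  Both
    scans run on the same mice (those with a non-missing candidate value)
    with traits quantile-transformed after subsetting, so the two LODs are
    nested-model comparable.  If the candidate itself appears among the
    targets its trivially self-conditioned row is flagged and excluded
    from the score.
    """
    if len(gwas_targets) == 0:
        raise InvalidArgumentError("empty target list")
    if candidate not in pheno.columns:
        raise InvalidArgumentError(f"candidate {candidate!r} not among traits")
    mediator = pheno[candidate]
    keep = mediator.notna()
    mice = pheno.index[keep]
    common = gp.mice.intersection(mice)
    mv = normal_quantile_transform(mediator.loc[common])

    Y = pheno.loc[common, gwas_targets]
    Yt = pd.DataFrame({t: normal_quantile_transform(Y[t]) for t in gwas_targets},
                      index=common)

    A = _covar_subset(addcovar, common)
    I = _covar_subset(intcovar, common)
    A_df = None if A is None else pd.DataFrame(A, index=common)
    I_df = None if I is None else pd.DataFrame(I, index=common)
    Aplus = mv[:, None] if A is None else np.hstack([A, mv[:, None]])
    Aplus_df = pd.DataFrame(Aplus, index=common)

    before = scanone(gp, Yt, addcovar=A_df, intcovar=I_df, chrom=chrom)
    after = scanone(gp, Yt, addcovar=Aplus_df, intcovar=I_df, chrom=chrom)

    rows = []
    for cb, ca in zip(before, after):
        lod_b, lod_a = float(cb.lod.max()), float(ca.lod.max())
        rows.append({
            "target": cb.trait, "lod_before": lod_b, "lod_after": lod_a,
            "lod_drop": lod_b - lod_a,
            "sig_before": lod_b >= threshold, "sig_after": lod_a >= threshold,
            "is_self": cb.trait == candidate,
        })
    table = pd.DataFrame(rows)
    scored = table[~table["is_self"]]
    score = int(scored["sig_after"].sum() - scored["sig_before"].sum())
    mean_drop = float(scored["lod_drop"].mean()) if len(scored) else 0.0
    return MediationResult(candidate=candidate, table=table, score=score,
                           mean_lod_drop=mean_drop,
                           self_conditioning=bool(table["is_self"].any()))


def rank_candidates(results: list[MediationResult]) -> list[MediationResult]:
    """Order candidates by mediation strength and assign ranks.

    Ascending summary score (most negative — the strongest mediator —
    first); ties broken by larger mean LOD drop, then by label.
    """
    if len(results) == 0:
        raise InvalidArgumentError("no candidates to rank")
    ordered = sorted(results, key=lambda r: (r.score, -r.mean_lod_drop, r.candidate))
    for i, r in enumerate(ordered, start=1):
        r.rank = i
    return ordered


def ranking_frame(results: list[MediationResult]) -> pd.DataFrame:
    """Candidate ranking as a flat table (one row per candidate)."""
    return pd.DataFrame([{
        "candidate": r.candidate, "score": r.score, "rank": r.rank,
        "mean_lod_drop": r.mean_lod_drop,
        "n_sig_before": int(r.table.loc[~r.table["is_self"], "sig_before"].sum()),
        "n_sig_after": int(r.table.loc[~r.table["is_self"], "sig_after"].sum()),
    } for r in results])
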