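"""Hidden-Markov genotype probabilities for an F2 intercross.

At each locus an F2 animal carries one of three genotypes — AA, AB, BB
(A = the B6-type allele, B = the BTBR-type allele) — with stationary
distribution (1/4, 1/2, 1/4).  Along a chromosome the true genotypes form
a Markov chain whose transition probabilities are functions of the
recombination fraction between adjacent loci under the Haldane
no-interference map function.  Observed genotype calls are noisy
emissions: a call equals the true genotype with probability 1 − ε and
each of the other two codes with probability ε/2; missing calls carry no
information.  :func:`calc_genoprob` runs forward–backward smoothing over
this chain, per mouse and chromosome, on a grid of markers plus inserted
pseudomarkers, yielding posterior genotype probabilities everywhere —
the substrate for regression-based QTL scans.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError, InvalidArgumentError, MapError
from .markers import MarkerMap

_PRIOR = np.array([0.25, 0.5, 0.25])


def haldane_r(d_cm):
    """Recombination fraction for a genetic distance in cM: r = (1 − e^(−2d/100))/2."""
    d = np.asarray(d_cm, dtype=float)
    if np.any(d < 0):
        raise InvalidArgumentError("genetic distance must be non-negative")
    r = 0.5 * (1.0 - np.exp(-2.0 * d / 100.0))
    return r if r.ndim else float(r)


def f2_transition_matrix(r: float) -> np.ndarray:
    """One-step genotype transition matrix of the F2 chain.

    Each of the two gametes recombines independently with probability r,
    giving e.g. AA→AA = (1−r)², AA→AB = 2r(1−r), AA→BB = r².  The matrix
    is stochastic and preserves the 1:2:1 stationary distribution.
    """
    if not (0.0 <= r <= 0.5):
        raise InvalidArgumentError("recombination fraction must lie in [0, 0.5]")
    s, t = 1.0 - r, r
    return np.array([
        [s * s, 2 * s * t, t * t],
        [s * t, s * s + t * t, s * t],
        [t * t, 2 * s * t, s * s],
    ])


def insert_pseudomarkers(marker_map: MarkerMap, step_cm: float) -> MarkerMap:
    """Grid of markers plus evenly spaced pseudomarkers, max gap ≤ step.

    Each inter-marker interval wider than ``step_cm`` is subdivided evenly
    into the smallest number of equal pieces not exceeding the step.
    Pseudomarkers are named by chromosome and position; physical positions
    are interpolated linearly between the flanking markers.
    """
    if step_cm <= 0:
        raise InvalidArgumentError("pseudomarker step must be positive")
    rows = []
    for chrom in marker_map.chromosomes:
        sub = marker_map.chromosome(chrom)
        cm = sub["cM"].to_numpy()
        mbp = sub["Mbp"].to_numpy()
        for i in range(len(sub)):
            rows.append((chrom, sub["marker"].iloc[i], cm[i], mbp[i],
                         bool(sub["pseudo"].iloc[i])))
            if i + 1 < len(sub):
                gap = cm[i + 1] - cm[i]
                n_add = int(np.ceil(gap / step_cm - 1e-9)) - 1
                for k in range(1, n_add + 1):
                    p = cm[i] + gap * k / (n_add + 1)
                    q = float(np.interp(p, cm, mbp))
                    rows.append((chrom, f"c{chrom}.loc{p:.4f}", p, q, True))
    return MarkerMap(pd.DataFrame(rows, columns=["chrom", "marker", "cM", "Mbp", "pseudo"]))


@dataclass
class GenoProbTensor:
    """Posterior genotype probabilities on a marker + pseudomarker grid.

    probs has shape (n_mice, n_loci, 3) over states (AA, AB, BB); every
    state vector is a probability distribution.
    """

    grid: MarkerMap
    probs: np.ndarray
    mice: pd.Index
    error_rate: float
    step_cm: float

    def locus(self, marker: str) -> np.ndarray:
        """(n_mice, 3) probabilities at one named grid locus."""
        return self.probs[:, self.grid.locus_index(marker), :]

    def chromosome_slice(self, chrom: str) -> tuple[np.ndarray, pd.DataFrame]:
        sub = self.grid.chromosome(chrom)
        return self.probs[:, sub.index.to_numpy(), :], sub.reset_index(drop=True)

    def expected_dosages(self) -> tuple[np.ndarray, np.ndarray]:
        """(s, h): signed additive dosage P(BB) − P(AA) and heterozygosity P(AB),
        each (n_mice, n_loci)."""
        return self.probs[:, :, 2] - self.probs[:, :, 0], self.probs[:, :, 1]


def _emission(obs: np.ndarray, eps: float) -> np.ndarray:
    """Emission likelihoods (n_mice, 3) for one marker's observed codes."""
    n = len(obs)
    e = np.ones((n, 3))
    typed = ~np.isnan(obs)
    codes = obs[typed].astype(int)
    block = np.full((typed.sum(), 3), eps / 2.0)
    block[np.arange(len(codes)), codes] = 1.0 - eps
    e[typed] = block
    return e


def calc_genoprob(geno: pd.DataFrame, marker_map: MarkerMap, step_cm: float = 2.0,
                  error_rate: float = 0.002) -> GenoProbTensor:
    """Forward–backward smoothing of F2 genotype probabilities.

    Parameters
    ----------
    geno:
        mice × markers observed codes {0, 1, 2, NaN}; columns must match the
        genotyped markers of ``marker_map`` in order.
    step_cm:
        maximum pseudomarker gap of the evaluation grid (cM).
    error_rate:
        genotyping error probability ε of the emission model.

    Chromosomes and mice are independent; each posterior state vector sums
    to one.  Forward and backward messages are renormalized per locus so
    the recursion never underflows; posteriors are invariant to that
    scaling.
    """
    if not (0.0 <= error_rate < 0.5):
        raise InvalidArgumentError("error rate must lie in [0, 0.5)")
    typed = marker_map.typed_only()
    if list(geno.columns) != list(typed.marker_names):
        raise DataError("genotype columns do not align with the marker map")
    vals = geno.to_numpy(dtype=float)
    bad = ~(np.isnan(vals) | np.isin(vals, [0.0, 1.0, 2.0]))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise DataError(
            f"invalid genotype code {vals[i, j]!r} at mouse {geno.index[i]!r}, "
            f"marker {geno.columns[j]!r}")

    grid = insert_pseudomarkers(typed, step_cm)
    n_mice, n_loci = len(geno), len(grid)
    probs = np.empty((n_mice, n_loci, 3))

    gtab = grid.table
    marker_col = {m: k for k, m in enumerate(geno.columns)}
    for chrom in grid.chromosomes:
        sub = gtab[gtab["chrom"] == chrom]
        idx = sub.index.to_numpy()
        cm = sub["cM"].to_numpy()
        L = len(idx)
        # emissions: uniform at pseudomarkers, noisy-call model at markers
        emis = np.ones((L, n_mice, 3))
        for k, (locus, is_pseudo) in enumerate(zip(sub["marker"], sub["pseudo"])):
            if not is_pseudo:
                emis[k] = _emission(vals[:, marker_col[locus]], error_rate)
        trans = [f2_transition_matrix(haldane_r(d)) for d in np.diff(cm)]

        fwd = np.empty((L, n_mice, 3))
        f = _PRIOR[None, :] * emis[0]
        fwd[0] = f / f.sum(axis=1, keepdims=True)
        for k in range(1, L):
            f = (fwd[k - 1] @ trans[k - 1]) * emis[k]
            fwd[k] = f / f.sum(axis=1, keepdims=True)

        bwd = np.empty((L, n_mice, 3))
        bwd[-1] = 1.0
        for k in range(L - 2, -1, -1):
            b = (emis[k + 1] * bwd[k + 1]) @ trans[k].T
            bwd[k] = b / b.sum(axis=1, keepdims=True)

        post = fwd * bwd
        post /= post.sum(axis=2, keepdims=True)
        probs[:, idx, :] = np.transpose(post, (1, 0, 2))

    return GenoProbTensor(grid=grid, probs=probs, mice=geno.index,
                          error_rate=error_rate, step_cm=step_cm)
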