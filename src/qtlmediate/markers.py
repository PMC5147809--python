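"""Ordered marker maps for an F2 cross.

A :class:`MarkerMap` holds, for every locus, a chromosome label, a marker
name, a genetic position in centimorgans (cM), a physical position in
megabase pairs (Mbp), and a flag marking pseudomarkers (grid positions
inserted between genotyped markers at which genotype probabilities are
inferred but no genotypes are observed).

Positions must be strictly increasing within a chromosome.  Markers typed
at identical genetic positions are resolved deterministically by adding a
1e-6 cM jitter in input order, so the hidden-Markov chain over loci is
well defined.  Genetic and physical coordinates are required to be
co-monotone within a chromosome.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import MapError

#: jitter applied to duplicated cM positions, in input order
_TIE_JITTER_CM = 1e-6

_COLUMNS = ["chrom", "marker", "cM", "Mbp", "pseudo"]


class MarkerMap:
    """Ordered markers (and optionally pseudomarkers) across chromosomes.

    Parameters
    ----------
    table:
        DataFrame with columns ``chrom`` (label), ``marker`` (unique name),
        ``cM`` (genetic position), ``Mbp`` (physical position) and
        optionally ``pseudo`` (bool, default False).  Rows may arrive in
        any order within a chromosome; they are sorted by position.
        Chromosome blocks keep their input order.
    """

    def __init__(self, table: pd.DataFrame):
        df = table.copy()
        if "pseudo" not in df.columns:
            df["pseudo"] = False
        missing = [c for c in _COLUMNS if c not in df.columns]
        if missing:
            raise MapError(f"marker table missing columns: {missing}")
        if len(df) == 0:
            raise MapError("marker map is empty")
        if df["marker"].duplicated().any():
            dup = df.loc[df["marker"].duplicated(), "marker"].iloc[0]
            raise MapError(f"duplicated marker name: {dup!r}")

        df["chrom"] = df["chrom"].astype(str)
        # keep chromosome blocks in first-appearance order
        chrom_order = list(dict.fromkeys(df["chrom"]))
        parts = []
        for c in chrom_order:
            block = df[df["chrom"] == c].copy()
            block = block.sort_values("cM", kind="stable")
            cm = block["cM"].to_numpy(dtype=float)
            # deterministic tie-resolution: bump duplicates by 1e-6 in order
            for i in range(1, len(cm)):
                if cm[i] <= cm[i - 1]:
                    if cm[i] < cm[i - 1] - _TIE_JITTER_CM:
                        raise MapError(f"non-monotone cM on chromosome {c}")
                    cm[i] = cm[i - 1] + _TIE_JITTER_CM
            block["cM"] = cm
            mbp = block["Mbp"].to_numpy(dtype=float)
            if np.any(np.diff(mbp) < 0):
                raise MapError(
                    f"genetic and physical positions not co-monotone on chromosome {c}"
                )
            parts.append(block)
        self._df = pd.concat(parts, ignore_index=True)[_COLUMNS]
        self._chrom_order = chrom_order

    # -- basic container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self._df)

    def __eq__(self, other) -> bool:
        return isinstance(other, MarkerMap) and self._df.equals(other._df)

    @property
    def table(self) -> pd.DataFrame:
        """The underlying locus table (copy-safe view)."""
        return self._df

    @property
    def chromosomes(self) -> list[str]:
        """Chromosome labels in map order."""
        return list(self._chrom_order)

    @property
    def marker_names(self) -> pd.Index:
        return pd.Index(self._df["marker"])

    @property
    def n_markers(self) -> int:
        """Number of genotyped (non-pseudo) markers."""
        return int((~self._df["pseudo"]).sum())

    def chromosome(self, chrom: str) -> pd.DataFrame:
        """Locus table restricted to one chromosome, with original row index."""
        sub = self._df[self._df["chrom"] == str(chrom)]
        if len(sub) == 0:
            raise MapError(f"chromosome {chrom!r} not in map")
        return sub

    def typed_only(self) -> "MarkerMap":
        """Map restricted to genotyped markers (drops pseudomarkers)."""
        return MarkerMap(self._df[~self._df["pseudo"]].reset_index(drop=True))

    def locus_index(self, marker: str) -> int:
        """Row position of a locus by name."""
        idx = np.flatnonzero(self._df["marker"].to_numpy() == marker)
        if len(idx) == 0:
            raise MapError(f"marker {marker!r} not in map")
        return int(idx[0])


def interpolate_mbp(cm: np.ndarray, anchor_cm: np.ndarray, anchor_mbp: np.ndarray) -> np.ndarray:
    """Physical positions for grid points, linear in cM between flanking markers."""
    return np.interp(cm, anchor_cm, anchor_mbp)


def concat_maps(maps: Iterable[MarkerMap]) -> MarkerMap:
    return MarkerMap(pd.concat([m.table for m in maps], ignore_index=True))
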