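"""GC-aware depth normalization of raw repeat counts.

Raw scanner counts scale with sequencing depth, and depth itself is biased
by local GC content.  Counts are therefore divided by the median per-base
depth of the GC bin matching the motif's own GC fraction, which
approximates the copy number per 1x coverage ("copy number" downstream).
Bins are {0-0.3, 0.3-0.35, 0.35-0.4, 0.4-0.45, 0.45-0.5, 0.5-0.55,
0.55-0.6, 0.6-1}: wider at the extremes where few genomic bases fall.

This normalization deliberately reproduces a known overcorrection: reads
that overlap an array with less than the detection span contribute nothing
to the count but still contribute to depth, so e.g. a homopolymer array of
exactly 50 bp normalizes to fewer than 50 copies.  The artifact is kept for
comparability with prior repeat-content estimates, not corrected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .scanner import KmerCountTable, Motif

__all__ = [
    "GC_BIN_EDGES",
    "GC_BIN_LABELS",
    "GCBinning",
    "NormalizedProfile",
    "MissingFactorError",
    "gc_bin",
    "normalization_factors",
    "normalize_counts",
]

GC_BIN_EDGES = (0.0, 0.3, 0.35, 0.4, 0.45, 0.5, 0.55, 0.6, 1.0)
GC_BIN_LABELS = tuple(
    f"{lo:g}-{hi:g}" for lo, hi in zip(GC_BIN_EDGES[:-1], GC_BIN_EDGES[1:])
)
N_BINS = len(GC_BIN_LABELS)


class MissingFactorError(ValueError):
    """Raised when a motif's GC bin has no usable normalization factor."""


def gc_bin(gc: float) -> int:
    """Index of the GC bin containing ``gc``.

    Bins are half-open [lo, hi) except the last, which is closed [0.6, 1].
    """
    if not 0.0 <= gc <= 1.0:
        raise ValueError(f"GC fraction must lie in [0, 1], got {gc}")
    idx = int(np.searchsorted(GC_BIN_EDGES, gc, side="right")) - 1
    return min(idx, N_BINS - 1)


@dataclass
class GCBinning:
    """Median per-base depth per GC bin (the normalization factors).

    ``factors[i]`` is the median depth (reads per base) over genomic bases
    whose local GC falls in bin i, or NaN if the bin contained no bases
    (flagged unusable; dividing a motif in such a bin raises
    :class:`MissingFactorError`).
    """

    factors: np.ndarray  # shape (8,); NaN = unusable bin
    n_bases: np.ndarray = field(
        default_factory=lambda: np.zeros(N_BINS, dtype=int)
    )

    def factor_for(self, motif: Motif) -> float:
        f = self.factors[gc_bin(motif.gc)]
        if np.isnan(f):
            raise MissingFactorError(
                f"no depth observations in GC bin "
                f"{GC_BIN_LABELS[gc_bin(motif.gc)]} (motif {motif.unit})"
            )
        return float(f)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"gc_bin": GC_BIN_LABELS, "median_depth": self.factors, "n_bases": self.n_bases}
        )


@dataclass
class NormalizedProfile:
    """Depth-normalized copy numbers (copies per 1x coverage) for one line."""

    line_id: str
    copy_number: Dict[Motif, float]
    binning: Optional[GCBinning] = None

    def __getitem__(self, motif) -> float:
        if isinstance(motif, str):
            from .scanner import canonical_motif

            motif = canonical_motif(motif)
        return self.copy_number.get(motif, 0.0)

    def total_kmer_bp(self) -> float:
        """Total repeat base pairs per 1x coverage."""
        return sum(m.k * c for m, c in self.copy_number.items())


def normalization_factors(depth_table: pd.DataFrame) -> GCBinning:
    """Median per-base depth within each GC bin of a depth table.

    ``depth_table`` needs columns ``depth`` and ``gc`` (one row per uniquely
    mappable base; ``contig``/``pos`` columns are ignored here).  The median
    of an even number of values is the mean of the two central values.
    """
    if len(depth_table) == 0:
        raise ValueError("depth table is empty")
    gc = np.asarray(depth_table["gc"], dtype=float)
    if gc.min() < 0 or gc.max() > 1:
        raise ValueError("gc column contains values outside [0, 1]")
    depth = np.asarray(depth_table["depth"], dtype=float)
    idx = np.minimum(np.searchsorted(GC_BIN_EDGES, gc, side="right") - 1, N_BINS - 1)
    factors = np.full(N_BINS, np.nan)
    n_bases = np.zeros(N_BINS, dtype=int)
    for b in range(N_BINS):
        mask = idx == b
        n_bases[b] = int(mask.sum())
        if n_bases[b]:
            factors[b] = np.median(depth[mask])
    factors[factors <= 0] = np.nan  # zero-coverage bins are unusable divisors
    return GCBinning(factors=factors, n_bases=n_bases)


def normalize_counts(raw: KmerCountTable, binning: GCBinning) -> NormalizedProfile:
    """Divide each motif's raw count by its GC-matched median depth.

    Raises
    ------
    MissingFactorError
        Listing every motif whose GC bin has no factor.
    """
    missing: List[str] = []
    copy_number: Dict[Motif, float] = {}
    for motif, count in raw.counts.items():
        f = binning.factors[gc_bin(motif.gc)]
        if np.isnan(f):
            missing.append(motif.unit)
            continue
        copy_number[motif] = count / f
    if missing:
        raise MissingFactorError(
            "no normalization factor for motifs in empty GC bins: "
            + ", ".join(sorted(missing))
        )
    return NormalizedProfile(line_id=raw.line_id, copy_number=copy_number, binning=binning)
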