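"""Mutation-rate estimation from mutation-accumulation line designs.

Each starting genotype contributes one sequenced ancestor (SC, the starting
control), a set of MA lines propagated by single-progeny descent for g_i
generations, and large-population extant controls (EC) in which selection
can purge copy-number changes.  For motif j in line i the genomic mutation
rate is the net copy-number change per generation,

    U_ij = (c_ij - c_SC,j) / g_i          [copies / generation]

and the per-copy rate divides out the mutational target size,

    u_ij = U_ij / c_SC,j                  [copies / copy / generation].

Both are *net* rates: a positive value means gains outweighed losses summed
over every array of that motif in the genome, not that only expansions
occurred.  Genotype-level rates U_j, u_j are plain means over the
genotype's MA lines; |u|_j averages |u_ij| and measures the magnitude of
change irrespective of direction.  EC lines are processed identically but
aggregated separately, never mixed into MA means.

Motifs enter the analysis only if sufficiently abundant: at least 6 copies
in the SC line and at least 2 copies in every MA line (and, by default,
every EC line) of the genotype.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set

import numpy as np
import pandas as pd

from .normalization import NormalizedProfile
from .scanner import Motif

__all__ = [
    "LineMeta",
    "RateTable",
    "filter_kmers",
    "genomic_rate",
    "per_copy_rate",
    "genotype_aggregate",
    "bp_change_per_generation",
    "ec_generations",
    "estimate_rates",
    "SC_MIN_COPIES",
    "LINE_MIN_COPIES",
]

SC_MIN_COPIES = 6.0
LINE_MIN_COPIES = 2.0

ROLES = ("SC", "MA", "EC")


@dataclass(frozen=True)
class LineMeta:
    """Identity and design metadata for one sequenced line."""

    line_id: str
    genotype: str
    population: str
    role: str  # "SC", "MA" or "EC"
    generations: float = 0.0  # elapsed generations; 0 for the SC itself

    def __post_init__(self):
        if self.role not in ROLES:
            raise ValueError(f"role must be one of {ROLES}, got {self.role!r}")
        if self.role != "SC" and self.generations <= 0:
            raise ValueError(
                f"{self.role} line {self.line_id} must have generations > 0"
            )


@dataclass
class RateTable:
    """Per-line and per-genotype mutation-rate estimates for one genotype.

    ``per_line`` has one row per (line, motif) with columns
    line_id/role/motif/k/gc/c_sc/c_line/generations/U/u;
    ``per_genotype`` one row per motif with U_j/u_j/abs_u_j averaged over MA
    lines (EC aggregates, when present, live in ``per_genotype_ec``);
    ``bp_change`` one row per line with the summed bp change per generation.
    """

    genotype: str
    per_line: pd.DataFrame
    per_genotype: pd.DataFrame
    per_genotype_ec: pd.DataFrame
    bp_change: pd.DataFrame


def filter_kmers(
    profiles: Mapping[str, NormalizedProfile],
    meta: Sequence[LineMeta],
    sc_min: float = SC_MIN_COPIES,
    line_min: float = LINE_MIN_COPIES,
    filter_ec: bool = True,
) -> Set[Motif]:
    """Motifs abundant enough for rate estimation in one genotype.

    Keeps motifs with copy number >= ``sc_min`` in the SC line and
    >= ``line_min`` in every MA line and (if ``filter_ec``) every EC line.
    Thresholds apply to the real-valued normalized copy numbers, no
    rounding.
    """
    sc = [m for m in meta if m.role == "SC"]
    if len(sc) != 1:
        raise ValueError(f"expected exactly one SC line, found {len(sc)}")
    ma = [m for m in meta if m.role == "MA"]
    if not ma:
        raise ValueError("no MA lines in genotype")
    required = ma + ([m for m in meta if m.role == "EC"] if filter_ec else [])
    sc_prof = profiles[sc[0].line_id]
    kept: Set[Motif] = set()
    for motif, c_sc in sc_prof.copy_number.items():
        if c_sc < sc_min:
            continue
        if all(profiles[m.line_id][motif] >= line_min for m in required):
            kept.add(motif)
    return kept


def genomic_rate(c_ij: float, c_sc_j: float, g_i: float) -> float:
    """Net copy-number change per generation, U_ij = (c_ij - c_SC,j) / g_i."""
    if g_i <= 0:
        raise ValueError(f"generations must be positive, got {g_i}")
    return (c_ij - c_sc_j) / g_i


def per_copy_rate(U_ij: float, c_sc_j: float) -> float:
    """Per-copy rate u_ij = U_ij / c_SC,j (copies per initial copy per generation)."""
    if c_sc_j <= 0:
        raise ValueError(f"ancestral copy number must be positive, got {c_sc_j}")
    return U_ij / c_sc_j


def bp_change_per_generation(
    profile_i: NormalizedProfile, profile_sc: NormalizedProfile, g_i: float
) -> float:
    """Total repeat base-pair change per generation across all motifs.

    sum_m k(m) * (c_i,m - c_SC,m) / g_i over the union of motifs; a motif
    absent from either profile counts as 0 copies there.
    """
    if g_i <= 0:
        raise ValueError(f"generations must be positive, got {g_i}")
    motifs = set(profile_i.copy_number) | set(profile_sc.copy_number)
    return sum(m.k * (profile_i[m] - profile_sc[m]) for m in motifs) / g_i


def ec_generations(experiment_days: float = 830.0, generation_time_days: float = 10.0) -> float:
    """Generations elapsed in an extant control kept for ``experiment_days``."""
    if generation_time_days <= 0:
        raise ValueError(
            f"generation time must be positive, got {generation_time_days}"
        )
    return experiment_days / generation_time_days


def genotype_aggregate(per_line: pd.DataFrame) -> pd.DataFrame:
    """Per-motif means of U, u and |u| across lines (unweighted).

    Input rows are per (line, motif) entries of a single role; output has
    one row per motif with U_j, u_j, abs_u_j and the number of lines.
    """
    grouped = per_line.groupby("motif", sort=True)
    out = grouped.agg(
        k=("k", "first"),
        gc=("gc", "first"),
        c_sc=("c_sc", "first"),
        U_j=("U", "mean"),
        u_j=("u", "mean"),
        n_lines=("line_id", "nunique"),
    )
    out["abs_u_j"] = grouped["u"].apply(lambda s: s.abs().mean())
    return out.reset_index()


def estimate_rates(
    profiles: Mapping[str, NormalizedProfile],
    meta: Sequence[LineMeta],
    filter_ec: bool = True,
    sc_min: float = SC_MIN_COPIES,
    line_min: float = LINE_MIN_COPIES,
) -> Dict[str, RateTable]:
    """Full rate estimation for every genotype in a line-metadata set.

    Returns one :class:`RateTable` per genotype: per-line U_ij/u_ij for MA
    and EC lines over the filtered motif set, per-genotype MA and EC
    aggregates, and per-line total bp change per generation.
    """
    tables: Dict[str, RateTable] = {}
    genotypes = sorted({m.genotype for m in meta})
    for genotype in genotypes:
        gmeta = [m for m in meta if m.genotype == genotype]
        kept = filter_kmers(
            profiles, gmeta, sc_min=sc_min, line_min=line_min, filter_ec=filter_ec
        )
        sc_meta = next(m for m in gmeta if m.role == "SC")
        sc_prof = profiles[sc_meta.line_id]
        rows = []
        bp_rows = []
        for m in gmeta:
            if m.role == "SC":
                continue
            prof = profiles[m.line_id]
            for motif in sorted(kept, key=lambda mo: (mo.k, mo.unit)):
                c_sc = sc_prof[motif]
                U = genomic_rate(prof[motif], c_sc, m.generations)
                rows.append(
                    {
                        "line_id": m.line_id,
                        "role": m.role,
                        "motif": motif.unit,
                        "k": motif.k,
                        "gc": motif.gc,
                        "c_sc": c_sc,
                        "c_line": prof[motif],
                        "generations": m.generations,
                        "U": U,
                        "u": per_copy_rate(U, c_sc),
                    }
                )
            bp_rows.append(
                {
                    "line_id": m.line_id,
                    "role": m.role,
                    "generations": m.generations,
                    "bp_per_generation": bp_change_per_generation(
                        prof, sc_prof, m.generations
                    ),
                }
            )
        per_line = pd.DataFrame(rows)
        ma_rows = per_line[per_line["role"] == "MA"] if len(per_line) else per_line
        ec_rows = per_line[per_line["role"] == "EC"] if len(per_line) else per_line
        tables[genotype] = RateTable(
            genotype=genotype,
            per_line=per_line,
            per_genotype=genotype_aggregate(ma_rows) if len(ma_rows) else pd.DataFrame(),
            per_genotype_ec=genotype_aggregate(ec_rows) if len(ec_rows) else pd.DataFrame(),
            bp_change=pd.DataFrame(bp_rows),
        )
    return tables
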