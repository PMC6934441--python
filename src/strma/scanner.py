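"""Tandem-repeat detection directly from sequencing reads.

Scans each read for arrays of 1-20 bp motifs that repeat tandemly over at
least a minimum span (default 50 bp), allowing one mismatched base per
repeat unit, and aggregates total copy counts per canonical motif across a
whole library.  Motifs are collapsed over rotations and reverse complements
so that, e.g., ``TA``, ``AT`` and their complements all count toward the
canonical unit ``AT``.

Because an array must span ``min_span`` bp to be detected, the minimum
number of repeat units required scales inversely with unit length: a
homopolymer needs 50 copies at the default span while a 5-mer needs only 10.
Counts are genome-wide totals per motif, not per-locus genotypes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Iterator, List, Sequence, Tuple

__all__ = [
    "Motif",
    "RepeatArray",
    "KmerCountTable",
    "canonical_motif",
    "min_units_for_detection",
    "scan_read",
    "quantify_library",
    "reverse_complement",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

DEFAULT_MIN_SPAN = 50
DEFAULT_MAX_K = 20


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (A<->T, C<->G; N stays N)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Motif:
    """A canonical microsatellite repeat unit.

    ``unit`` is primitive (not a whole-number repeat of a shorter string)
    and lexicographically minimal over all rotations of itself and of its
    reverse complement.  ``k`` is the unit length, ``gc`` the exact G+C
    fraction of the unit.
    """

    unit: str

    @property
    def k(self) -> int:
        return len(self.unit)

    @property
    def gc(self) -> float:
        u = self.unit
        return (u.count("G") + u.count("C")) / len(u)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.unit


@dataclass(frozen=True)
class RepeatArray:
    """One detected tandem array on one read.

    ``start`` is a 0-based inclusive offset; ``span_bp`` the array length on
    the read (complete units plus any exactly-matching trailing partial
    unit); ``units`` the number of complete unit windows.
    """

    read_id: str
    start: int
    span_bp: int
    motif: Motif
    units: int


@dataclass
class KmerCountTable:
    """Total repeat-unit counts per canonical motif for one sequencing library."""

    line_id: str
    counts: Dict[Motif, int]

    def __getitem__(self, motif) -> int:
        if isinstance(motif, str):
            motif = canonical_motif(motif)
        return self.counts.get(motif, 0)

    def total_kmer_bp(self) -> int:
        """Total base pairs contained in counted repeat units."""
        return sum(m.k * c for m, c in self.counts.items())


class InvalidMotifError(ValueError):
    """Raised for motif strings outside the 1-20 bp ACGT space."""


def _primitive_root(unit: str) -> str:
    """Shortest string whose whole-number repetition equals ``unit``."""
    n = len(unit)
    for d in range(1, n + 1):
        if n % d == 0 and unit[:d] * (n // d) == unit:
            return unit[:d]
    return unit


def _is_primitive(unit: str) -> bool:
    return _primitive_root(unit) == unit


def canonical_motif(unit: str, max_k: int = DEFAULT_MAX_K) -> Motif:
    """Collapse a repeat unit over rotations and strands to its canonical form.

    The canonical representative is the lexicographically smallest string
    among all rotations of the primitive root and all rotations of its
    reverse complement.  Idempotent: the canonical unit of a canonical unit
    is itself.

    Raises
    ------
    InvalidMotifError
        If ``unit`` is empty, longer than ``max_k``, or contains characters
        outside ``{A, C, G, T}``.
    """
    if not unit or len(unit) > max_k:
        raise InvalidMotifError(
            f"motif length must be 1-{max_k}, got {len(unit)} ({unit!r})"
        )
    unit = unit.upper()
    if any(ch not in "ACGT" for ch in unit):
        raise InvalidMotifError(f"motif contains non-ACGT characters: {unit!r}")
    root = _primitive_root(unit)
    k = len(root)
    rc = reverse_complement(root)
    best = min(
        min(root[i:] + root[:i] for i in range(k)),
        min(rc[i:] + rc[:i] for i in range(k)),
    )
    return Motif(best)


def min_units_for_detection(k: int, min_span: int = DEFAULT_MIN_SPAN) -> int:
    """Smallest number of complete units whose span reaches ``min_span``.

    ceil(min_span / k): 50 units for 1-mers and 10 units for 5-mers at the
    default 50 bp span.
    """
    if k <= 0:
        raise ValueError(f"unit length must be positive, got {k}")
    if min_span < k:
        raise ValueError(f"min_span ({min_span}) must be >= unit length ({k})")
    return -(-min_span // k)


def _extend_candidate(
    seq: str, start: int, k: int, mismatch_per_unit: int
) -> Tuple[int, int, int]:
    """Extend a seed-framed array rightward; return (units, span_bp, mismatches).

    The seed unit is the first k bases at ``start``.  Each subsequent
    non-overlapping k-window counts as one unit if its Hamming distance to
    the seed is <= ``mismatch_per_unit`` and it contains no N.  A trailing
    partial unit extends the span only while it matches the seed prefix
    exactly.
    """
    n = len(seq)
    seed = seq[start : start + k]
    # a unit cannot be pure mismatch: budget capped at k - 1, so 1-mers
    # tolerate no mismatch at all
    mismatch_per_unit = min(mismatch_per_unit, k - 1)
    pos = start + k
    units = 1
    total_mism = 0
    while pos + k <= n:
        window = seq[pos : pos + k]
        mism = 0
        ok = True
        for a, b in zip(window, seed):
            if a == "N" or a != b:
                if a == "N":
                    ok = False
                    break
                mism += 1
                if mism > mismatch_per_unit:
                    ok = False
                    break
        if not ok:
            break
        units += 1
        total_mism += mism
        pos += k
    span = pos - start
    # exact-match trailing partial unit: counts toward span, not units
    i = 0
    while pos + i < n and i < k - 1 and seq[pos + i] == seed[i]:
        i += 1
    return units, span + i, total_mism


def scan_read(
    sequence: str,
    min_span: int = DEFAULT_MIN_SPAN,
    max_k: int = DEFAULT_MAX_K,
    mismatch_per_unit: int = 1,
    read_id: str = "",
) -> List[RepeatArray]:
    """Detect all tandem repeat arrays spanning at least ``min_span`` bp.

    Candidate arrays are seeded at every start position for every primitive
    unit length (k ascending), extended maximally rightward under the
    per-unit mismatch tolerance, then filtered to span >= ``min_span``.
    Overlapping candidates are resolved deterministically: most matched
    bases (span minus mismatches) wins — so the true unit of an array beats
    a shorter unit that only survives by spending its mismatch budget every
    window — with ties broken by fewest mismatches, smaller k, lexicographic
    canonical unit, then leftmost start.  N bases never match and terminate
    extension.
    The effective mismatch budget per unit is min(mismatch_per_unit, k - 1):
    a unit window cannot consist entirely of mismatches, so homopolymer
    arrays must match exactly.

    Reads are scanned in their lexicographically smaller orientation (the
    read or its reverse complement, whichever compares smaller), which
    makes detection — and therefore library quantification — exactly
    strand-invariant.  Reported ``start`` offsets refer to the scanned
    orientation.
    """
    seq = sequence.upper()
    rc = reverse_complement(seq)
    if rc < seq:
        seq = rc
    n = len(seq)
    candidates: List[Tuple[int, int, int, str, int]] = []
    for start in range(n):
        if n - start < min_span:
            break
        for k in range(1, min(max_k, n - start) + 1):
            seed = seq[start : start + k]
            if "N" in seed or not _is_primitive(seed):
                continue
            # cheap prune: the window right after the seed must be tolerable
            if start + 2 * k <= n:
                w = seq[start + k : start + 2 * k]
                mism = sum(1 for a, b in zip(w, seed) if a != b or a == "N")
                if ("N" in w) or mism > min(mismatch_per_unit, k - 1):
                    if k * 1 + (k - 1) < min_span:  # single unit cannot reach span
                        continue
            units, span, mism = _extend_candidate(seq, start, k, mismatch_per_unit)
            if span >= min_span:
                canon = canonical_motif(seed, max_k=max_k).unit
                candidates.append((start, span, units, canon, k, mism))
    # overlap resolution: most matched bases, then fewest mismatches (the
    # purer framing of the same region), smaller k, lexicographic canonical
    # unit, leftmost start
    candidates.sort(key=lambda c: (-(c[1] - c[5]), c[5], c[4], c[3], c[0]))
    chosen: List[Tuple[int, int, int, str, int, int]] = []
    occupied: List[Tuple[int, int]] = []
    for cand in candidates:
        s, span = cand[0], cand[1]
        e = s + span
        if any(s < oe and os_ < e for os_, oe in occupied):
            continue
        occupied.append((s, e))
        chosen.append(cand)
    chosen.sort(key=lambda c: c[0])
    return [
        RepeatArray(read_id=read_id, start=s, span_bp=span, motif=Motif(canon), units=units)
        for s, span, units, canon, _k, _m in chosen
    ]


def quantify_library(
    reads: Iterable[Tuple[str, str]],
    line_id: str = "",
    min_span: int = DEFAULT_MIN_SPAN,
    max_k: int = DEFAULT_MAX_K,
    mismatch_per_unit: int = 1,
) -> KmerCountTable:
    """Aggregate total repeat-unit counts per canonical motif over a library.

    ``reads`` yields ``(read_id, sequence)`` pairs (see
    :func:`strma.io.read_fastq`).  The count for motif m is the sum of
    complete units over every detected array with that motif, across all
    reads; it is strand- and rotation-collapsed and deterministic for a
    fixed input and configuration.
    """
    counts: Dict[Motif, int] = {}
    for read_id, seq in reads:
        for arr in scan_read(
            seq,
            min_span=min_span,
            max_k=max_k,
            mismatch_per_unit=mismatch_per_unit,
            read_id=read_id,
        ):
            counts[arr.motif] = counts.get(arr.motif, 0) + arr.units
    return KmerCountTable(line_id=line_id, counts=counts)
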