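"""Independent brute-force oracles used by the test suite.

These deliberately re-derive results with naive enumeration (no shared code
with the package beyond the documented contracts) so they can stand as
independent checks.
"""

from __future__ import annotations

from typing import Dict, List, Tuple


def rc(seq: str) -> str:
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    return "".join(comp[c] for c in reversed(seq))


def brute_canonical(unit: str) -> str:
    """Canonical motif by exhaustive enumeration of divisors and rotations."""
    n = len(unit)
    root = unit
    for d in range(1, n):
        if n % d == 0 and unit == unit[:d] * (n // d):
            root = unit[:d]
            break
    variants = []
    for s in (root, rc(root)):
        for i in range(len(s)):
            variants.append(s[i:] + s[:i])
    return min(variants)


def _is_primitive(unit: str) -> bool:
    n = len(unit)
    return all(not (n % d == 0 and unit == unit[:d] * (n // d)) for d in range(1, n))


def brute_force_scan(
    seq: str, min_span: int = 50, max_k: int = 4, mismatch_per_unit: int = 1
) -> List[Tuple[str, int]]:
    """Enumerate every (start, k) seed window and apply the detection rules.

    Returns the sorted (canonical motif, units) list of selected arrays.
    Rules: the read is scanned in its lexicographically smaller orientation
    (read vs reverse complement); seed = first k bases (primitive, N-free);
    each later k-window
    must have Hamming distance <= min(mismatch_per_unit, k - 1) to the seed
    with N never matching; a trailing partial unit extends span while it
    matches the seed prefix exactly; arrays need span >= min_span; among
    overlapping candidates the one with the most matched bases wins, ties
    resolved by fewest mismatches, smaller k, lexicographic canonical unit,
    leftmost start.
    """
    rev = rc(seq)
    if rev < seq:
        seq = rev  # strand-invariant orientation: scan the smaller strand
    n = len(seq)
    cands = []
    for start in range(n):
        for k in range(1, max_k + 1):
            seed = seq[start : start + k]
            if len(seed) < k or "N" in seed or not _is_primitive(seed):
                continue
            budget = min(mismatch_per_unit, k - 1)
            units = 1
            mism = 0
            pos = start + k
            while pos + k <= n:
                w = seq[pos : pos + k]
                if "N" in w:
                    break
                d = sum(1 for a, b in zip(w, seed) if a != b)
                if d > budget:
                    break
                units += 1
                mism += d
                pos += k
            span = pos - start
            partial = 0
            while (
                pos + partial < n
                and partial < k - 1
                and seq[pos + partial] == seed[partial]
            ):
                partial += 1
            span += partial
            if span >= min_span:
                cands.append(
                    {
                        "start": start,
                        "span": span,
                        "units": units,
                        "mism": mism,
                        "k": k,
                        "canon": brute_canonical(seed),
                    }
                )
    cands.sort(
        key=lambda c: (
            -(c["span"] - c["mism"]),
            c["mism"],
            c["k"],
            c["canon"],
            c["start"],
        )
    )
    taken: List[Tuple[int, int]] = []
    out = []
    for c in cands:
        s, e = c["start"], c["start"] + c["span"]
        if any(s < te and ts < e for ts, te in taken):
            continue
        taken.append((s, e))
        out.append((c["canon"], c["units"]))
    return sorted(out)


def random_read(rng, length: int, max_k: int = 4) -> str:
    """A read that mixes uniform background with a planted, mutated repeat
    half of the time, so detection rules actually fire."""
    bases = "ACGT"
    seq = [bases[i] for i in rng.integers(0, 4, size=length)]
    if rng.random() < 0.5:
        k = int(rng.integers(1, max_k + 1))
        unit = "".join(bases[i] for i in rng.integers(0, 4, size=k))
        reps = int(rng.integers(3, length // k + 1))
        arr = list(unit * reps)
        for i in range(len(arr)):  # sprinkle mutations
            if rng.random() < 0.02:
                arr[i] = bases[int(rng.integers(0, 4))]
        start = int(rng.integers(0, max(1, length - len(arr) + 1)))
        seq[start : start + len(arr)] = arr[: length - start]
    return "".join(seq[:length])
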