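"""Synthetic mutation-accumulation experiments with known ground truth.

Everything the pipeline consumes can be generated here: genomes with
planted tandem arrays in non-repetitive background, error-prone reads with
a matching per-base depth/GC table, and whole MA experiment designs — a
panel of starting genotypes (SC) from several populations, each with
replicate MA lines propagated 2-26 generations and large-population extant
controls (EC) in which selection damps copy-number change.

The copy-number mutation model is a compound Poisson birth-death process:
each generation a motif gains Pois(lambda_gain) and loses Pois(lambda_loss)
copies, with the two intensities sharing a symmetric churn component and a
signed bias so the expected net change per generation is u* x (reference
copy number).  With ``reference="initial"`` the expectation per generation
is anchored at the ancestral copy number, so the net-change estimator
(c_g - c_0) / (g c_0) targets u* exactly; ``reference="current"`` compounds
multiplicatively (expected copy number c_0 (1 + u*)^g).  EC mode filters
proposed generations by a rejection step whose acceptance probability
decays with the magnitude of the proposed change, attenuating realized
rates without modelling a specific selective mechanism.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .normalization import NormalizedProfile
from .rates import LineMeta, ec_generations
from .scanner import Motif, canonical_motif, scan_read

__all__ = [
    "GenotypeProfile",
    "SimulationTruth",
    "Experiment",
    "make_genome",
    "make_reads",
    "evolve_lineage",
    "make_experiment",
    "make_rate_recovery_dataset",
    "DEFAULT_MOTIF_POOL",
]

# Pool of canonical motifs used for default landscapes: the field's usual
# suspects (A/AT-rich short units, the telomeric 5-mer, some GC-carrying
# longer units) spanning k = 1..10 and the full GC range.
DEFAULT_MOTIF_POOL = (
    "A", "C",
    "AT", "AC", "AG", "CG",
    "AAT", "AAC", "AAG", "ACC", "AGG", "ACG",
    "AAAT", "AAAC", "AATG", "ACAT", "AGAT", "ACGC",
    "AACCT", "AATAT", "AGAGG", "AACAG",
    "AACCCT", "AATGGC",
    "AAATAAT", "AAACCTC",
    "AATAATAG", "AACGATGC",
    "AAATAATAT",
    "AACCTAACGT",
)


@dataclass
class GenotypeProfile:
    """A genotype's planted motif landscape (copy numbers per haploid genome)."""

    genotype: str
    population: str
    landscape: Dict[str, float]  # canonical unit -> planted copy number


@dataclass
class SimulationTruth:
    """Ground truth of one simulated lineage."""

    line_id: str
    generations: float
    u_star: Dict[str, float]  # canonical unit -> planted per-copy rate
    initial: Dict[str, float]
    final: Dict[str, float]
    seed: int

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "line_id": self.line_id,
                "motif": m,
                "u_star": self.u_star.get(m, 0.0),
                "c_initial": self.initial[m],
                "c_final": self.final[m],
                "generations": self.generations,
            }
            for m in sorted(self.initial)
        ]
        return pd.DataFrame(rows)


@dataclass
class Experiment:
    """A complete simulated design: profiles, metadata and truth."""

    profiles: Dict[str, NormalizedProfile]
    meta: List[LineMeta]
    truth: pd.DataFrame
    genotypes: List[GenotypeProfile]
    seed: int


def _random_background(rng: np.random.Generator, length: int, min_span: int, max_k: int) -> str:
    """Random sequence verified (by the scanner itself) to contain no
    detectable tandem array; regenerated on the rare rejection."""
    for _ in range(50):
        seq = "".join(rng.choice(list("ACGT"), size=length))
        if not scan_read(seq, min_span=min_span, max_k=max_k):
            return seq
    raise RuntimeError("could not generate repeat-free background")


def make_genome(
    profile: Mapping[str, int],
    genome_length: int,
    seed: int,
    min_span: int = 50,
    max_k: int = 20,
    flank: int = 200,
) -> Tuple[str, pd.DataFrame]:
    """A single contig with one planted array per motif, plus a BED-style manifest.

    Each motif's total planted copies are laid down at one locus, separated
    from neighbours by ``flank`` bp of verified repeat-free background.
    Manifest coordinates are 0-based half-open (columns contig, start, end,
    motif, units, span_bp).
    """
    rng = np.random.default_rng(seed)
    items = sorted(profile.items())
    spans = {m: len(m) * int(units) for m, units in items}
    needed = sum(spans.values()) + flank * (len(items) + 1)
    if needed > genome_length:
        raise ValueError(
            f"genome_length {genome_length} too small: need >= {needed} bp "
            f"for {len(items)} arrays with {flank} bp flanks"
        )
    slack = genome_length - needed
    extra = [slack // (len(items) + 1)] * (len(items) + 1)
    extra[-1] += slack - sum(extra)
    for unit, _units in items:
        canon = canonical_motif(unit, max_k=max_k)
        if canon.unit != unit:
            raise ValueError(f"landscape motif {unit!r} is not canonical ({canon.unit})")

    planted = {unit: int(units) for unit, units in items}
    for _attempt in range(20):
        pieces: List[str] = []
        rows = []
        pos = 0
        for i, (unit, units) in enumerate(items):
            bg = _random_background(rng, flank + extra[i], min_span, max_k)
            pieces.append(bg)
            pos += len(bg)
            array = unit * int(units)
            rows.append(
                {
                    "contig": "chr1",
                    "start": pos,
                    "end": pos + len(array),
                    "motif": unit,
                    "units": int(units),
                    "span_bp": len(array),
                }
            )
            pieces.append(array)
            pos += len(array)
        pieces.append(_random_background(rng, flank + extra[-1], min_span, max_k))
        genome = list("".join(pieces))
        # break periodicity at array boundaries: the base before an array
        # must not extend it leftward, and the 2k flank bases after it must
        # mismatch every frame's continuation so no shifted seed can pick
        # up an extra window within its mismatch budget
        for r in rows:
            unit = r["motif"]
            k = len(unit)
            left, right = r["start"] - 1, r["end"]
            if genome[left] == unit[-1]:
                genome[left] = next(b for b in "CGTA" if b not in (unit[-1], unit[0]))
            frame = r["span_bp"] % k
            for j in range(2 * k):
                exp = unit[(frame + j) % k]
                if genome[right + j] == exp:
                    genome[right + j] = next(b for b in "CGTA" if b != exp)
        seq = "".join(genome)
        # rejection check with the scanner itself: a quasi-periodic flank
        # can still legitimately extend an array; redraw until the planted
        # (motif, units) multiset is recovered exactly
        found: Dict[str, int] = {}
        for a in scan_read(seq, min_span=min_span, max_k=max_k):
            found[a.motif.unit] = found.get(a.motif.unit, 0) + a.units
        if found == planted:
            return seq, pd.DataFrame(rows)
    raise RuntimeError("could not assemble a genome recovering the planted arrays")


def _local_gc(genome: np.ndarray, window: int = 150) -> np.ndarray:
    """Per-base GC fraction in a centered window (clipped at contig ends)."""
    is_gc = np.isin(genome, [b"G", b"C"]).astype(float)
    half = window // 2
    csum = np.concatenate([[0.0], np.cumsum(is_gc)])
    n = len(genome)
    lo = np.clip(np.arange(n) - half, 0, n)
    hi = np.clip(np.arange(n) + half + 1, 0, n)
    return (csum[hi] - csum[lo]) / (hi - lo)


def make_reads(
    genome: str,
    coverage: float,
    read_len: int = 150,
    error_rate: float = 0.0,
    seed: int = 0,
    gc_window: int = 150,
    gc_bias: Optional[callable] = None,
) -> Tuple[List[Tuple[str, str]], pd.DataFrame]:
    """Uniform (optionally GC-biased) single-end reads plus a depth/GC table.

    Read starts are uniform over the contig; ``gc_bias`` maps a read's mean
    local GC to a relative sampling weight in (0, 1].  Sequencing errors
    are uniform substitutions at ``error_rate`` per base.  The returned
    depth table has one row per base (contig, pos 1-based, depth, gc) with
    depth counted from the reads actually emitted, so normalization sees
    exactly the coverage the scanner saw.
    """
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    L = len(genome)
    if read_len > L:
        raise ValueError("read_len exceeds contig length")
    rng = np.random.default_rng(seed)
    arr = np.frombuffer(genome.encode(), dtype="S1")
    gc = _local_gc(arr, window=gc_window)
    n_reads = int(round(coverage * L / read_len))
    starts = rng.integers(0, L - read_len + 1, size=n_reads)
    if gc_bias is not None:
        read_gc = np.array([gc[s : s + read_len].mean() for s in starts])
        keep = rng.random(n_reads) < np.clip([gc_bias(g) for g in read_gc], 0, 1)
        starts = starts[keep]
    depth = np.zeros(L + 1)
    np.add.at(depth, starts, 1)
    np.add.at(depth, starts + read_len, -1)
    depth = np.cumsum(depth[:-1])
    bases = np.array(list("ACGT"))
    reads: List[Tuple[str, str]] = []
    for i, s in enumerate(starts):
        seq = list(genome[s : s + read_len])
        if error_rate > 0:
            errs = np.nonzero(rng.random(read_len) < error_rate)[0]
            for e in errs:
                seq[e] = rng.choice(bases[bases != seq[e]])
        reads.append((f"read_{i}_{s}", "".join(seq)))
    table = pd.DataFrame(
        {
            "contig": "chr1",
            "pos": np.arange(1, L + 1),
            "depth": depth.astype(int),
            "gc": gc,
        }
    )
    return reads, table


def evolve_lineage(
    landscape: Mapping[str, float],
    u_star: Mapping[str, float],
    generations: int,
    mode: str = "MA",
    seed: int = 0,
    reference: str = "initial",
    churn: float = 0.01,
    ec_strength: float = 3.0,
    line_id: str = "line",
) -> Tuple[Dict[str, float], SimulationTruth]:
    """Evolve a motif landscape for ``generations`` under planted rates.

    Per generation and motif, gains ~ Pois(b(churn + max(u*, 0))) and
    losses ~ Pois(b(churn + max(-u*, 0))) where b is the reference copy
    number (ancestral for ``reference="initial"``, current for
    ``"current"``), so the expected net change is u* b.  Copy number is
    floored at 0.  ``mode="EC"`` accepts each generation's proposed change
    with probability exp(-ec_strength |delta| / (1 + sd)), sd the Poisson
    scale, which attenuates realized rates toward 0.
    """
    if generations < 1:
        raise ValueError("generations must be >= 1")
    if mode not in ("MA", "EC"):
        raise ValueError(f"mode must be MA or EC, got {mode!r}")
    if reference not in ("initial", "current"):
        raise ValueError(f"reference must be 'initial' or 'current', got {reference!r}")
    rng = np.random.default_rng(seed)
    current = {m: float(c) for m, c in landscape.items()}
    initial = dict(current)
    for _ in range(int(generations)):
        for m in current:
            u = u_star.get(m, 0.0)
            base = initial[m] if reference == "initial" else current[m]
            lam_gain = base * (churn + max(u, 0.0))
            lam_loss = base * (churn + max(-u, 0.0))
            delta = float(rng.poisson(lam_gain)) - float(rng.poisson(lam_loss))
            if mode == "EC" and delta != 0:
                sd = math.sqrt(lam_gain + lam_loss)
                if rng.random() >= math.exp(-ec_strength * abs(delta) / (1.0 + sd)):
                    continue  # selection rejects this generation's change
            current[m] = max(current[m] + delta, 0.0)
    truth = SimulationTruth(
        line_id=line_id,
        generations=float(generations),
        u_star={m: u_star.get(m, 0.0) for m in landscape},
        initial=initial,
        final=dict(current),
        seed=seed,
    )
    return current, truth


def _measurement_noise(
    profile: Mapping[str, float], rng: np.random.Generator, sd: float
) -> Dict[Motif, float]:
    """Mean-one lognormal multiplicative noise, emulating residual
    depth-normalization error."""
    out = {}
    for m, c in profile.items():
        f = rng.lognormal(-0.5 * sd**2, sd) if sd > 0 else 1.0
        out[Motif(m)] = c * f
    return out


def _draw_generations(rng: np.random.Generator, lo: int, hi: int, mean: float) -> int:
    """Integer generation count in [lo, hi] with the requested mean,
    via a Beta(2, b) stretch of the interval."""
    frac = (mean - lo) / (hi - lo)
    a = 2.0
    b = a * (1.0 - frac) / frac
    return int(round(lo + (hi - lo) * rng.beta(a, b)))


def make_experiment(
    seed: int = 0,
    n_populations: int = 3,
    genotypes_per_pop: int = 2,
    ma_lines_per_genotype: Optional[Sequence[int]] = None,
    ec_lines_per_genotype: int = 2,
    generations_range: Tuple[int, int] = (2, 26),
    generations_mean: float = 12.4,
    n_motifs: int = 30,
    base_abundance_log_mean: float = 5.0,
    base_abundance_log_sd: float = 1.0,
    population_offset_sd: float = 1.2,
    genotype_offset_sd: float = 1.2,
    u_sd: float = 0.02,
    u_line_sd: float = 0.02,
    churn: float = 0.01,
    measurement_noise_sd: float = 0.02,
    ec_generation_time_days: float = 10.0,
    ec_strength: float = 3.0,
) -> Experiment:
    """Simulate a full MA design: populations x genotypes x (SC + MA + EC).

    Defaults emulate the study layout this pipeline targets: 3 populations
    x 2 genotypes, ~47 MA lines total ([8,8,8,8,8,7] split), 2 EC per
    genotype, MA generations in [2, 26] with mean 12.4, EC generations =
    830 days / 10-day generation time.  Landscapes are lognormal around a
    shared base with population- and genotype-level multiplicative offsets;
    per-copy mutation rates u* are drawn per genotype x motif from
    N(0, u_sd).  Returns measured (noise-perturbed) profiles, line
    metadata, and a truth table for recovery checks.  Deterministic for a
    fixed seed.
    """
    rng = np.random.default_rng(seed)
    n_geno = n_populations * genotypes_per_pop
    if ma_lines_per_genotype is None:
        ma_lines_per_genotype = [8, 8, 8, 8, 8, 7][:n_geno]
        while len(ma_lines_per_genotype) < n_geno:
            ma_lines_per_genotype.append(8)
    motifs = list(DEFAULT_MOTIF_POOL[:n_motifs])
    base = {
        m: float(np.exp(rng.normal(base_abundance_log_mean, base_abundance_log_sd)))
        for m in motifs
    }
    pop_names = ["Finland", "Germany", "Israel", "Pop4", "Pop5", "Pop6"][:n_populations]
    geno_letters = "ACBDEFGH"  # second genotype of a population is "C" by convention
    geno_names = []
    for pi, pop in enumerate(pop_names):
        prefix = pop[0] if pi < 3 else f"P{pi + 1}"
        for gi in range(genotypes_per_pop):
            geno_names.append((f"{prefix}{geno_letters[gi]}", pop))

    genotypes: List[GenotypeProfile] = []
    profiles: Dict[str, NormalizedProfile] = {}
    meta: List[LineMeta] = []
    truth_frames: List[pd.DataFrame] = []
    ec_gens = ec_generations(830.0, ec_generation_time_days)

    pop_offsets = {
        pop: {m: rng.lognormal(0.0, population_offset_sd) for m in motifs}
        for pop in pop_names
    }
    for g_idx, (geno, pop) in enumerate(geno_names):
        landscape = {
            m: base[m] * pop_offsets[pop][m] * rng.lognormal(0.0, genotype_offset_sd)
            for m in motifs
        }
        genotypes.append(GenotypeProfile(genotype=geno, population=pop, landscape=landscape))
        u_star = {m: float(rng.normal(0.0, u_sd)) for m in motifs}

        sc_id = f"{geno}_SC"
        profiles[sc_id] = NormalizedProfile(
            line_id=sc_id, copy_number=_measurement_noise(landscape, rng, measurement_noise_sd)
        )
        meta.append(LineMeta(sc_id, geno, pop, "SC", 0.0))

        for i in range(ma_lines_per_genotype[g_idx]):
            line_id = f"{geno}_MA{i + 1}"
            g_i = _draw_generations(rng, *generations_range, generations_mean)
            sub_seed = int(rng.integers(0, 2**31 - 1))
            # lines of one genotype mutate idiosyncratically around the
            # genotype-level rate (rates vary even among sibling lines)
            u_line = {m: u + rng.normal(0.0, u_line_sd) for m, u in u_star.items()}
            evolved, truth = evolve_lineage(
                landscape, u_line, g_i, mode="MA", seed=sub_seed,
                churn=churn, line_id=line_id,
            )
            profiles[line_id] = NormalizedProfile(
                line_id=line_id,
                copy_number=_measurement_noise(evolved, rng, measurement_noise_sd),
            )
            meta.append(LineMeta(line_id, geno, pop, "MA", float(g_i)))
            tf = truth.to_frame()
            tf["genotype"] = geno
            tf["role"] = "MA"
            truth_frames.append(tf)

        for i in range(ec_lines_per_genotype):
            line_id = f"{geno}_EC{i + 1}"
            sub_seed = int(rng.integers(0, 2**31 - 1))
            u_line = {m: u + rng.normal(0.0, u_line_sd) for m, u in u_star.items()}
            evolved, truth = evolve_lineage(
                landscape, u_line, int(round(ec_gens)), mode="EC", seed=sub_seed,
                churn=churn, ec_strength=ec_strength, line_id=line_id,
            )
            profiles[line_id] = NormalizedProfile(
                line_id=line_id,
                copy_number=_measurement_noise(evolved, rng, measurement_noise_sd),
            )
            meta.append(LineMeta(line_id, geno, pop, "EC", ec_gens))
            tf = truth.to_frame()
            tf["genotype"] = geno
            tf["role"] = "EC"
            truth_frames.append(tf)

    return Experiment(
        profiles=profiles,
        meta=meta,
        truth=pd.concat(truth_frames, ignore_index=True),
        genotypes=genotypes,
        seed=seed,
    )


def make_rate_recovery_dataset(
    n_lines: int = 200,
    u_values: Sequence[float] = (-0.1, -0.02, -0.005, 0.005, 0.02, 0.1),
    generations_range: Tuple[int, int] = (2, 8),
    generations_mean: float = 5.0,
    seed: int = 0,
    churn: float = 0.01,
    n_motifs_per_rate: int = 4,
) -> Tuple[Dict[str, NormalizedProfile], List[LineMeta], Dict[str, float]]:
    """One genotype with many replicate MA lines and known per-copy rates.

    Plants ``n_motifs_per_rate`` motifs per value of u* with ancestral copy
    numbers log-spaced over ~20-4000, evolves ``n_lines`` MA lines, and
    returns (profiles, meta, u* per motif) — the harness for estimator
    bias/correlation checks.  Lineages are short (default 2-8 generations)
    because a net per-copy loss of 0.1/generation drives a motif toward
    extinction — and below the abundance filter — over longer horizons.
    """
    rng = np.random.default_rng(seed)
    pool = [m for m in DEFAULT_MOTIF_POOL]
    needed = len(u_values) * n_motifs_per_rate
    if needed > len(pool):
        raise ValueError(f"motif pool too small for {needed} motifs")
    motifs = pool[:needed]
    copy_numbers = np.geomspace(20, 4000, needed)
    perm = rng.permutation(needed)
    landscape = {m: float(copy_numbers[perm[i]]) for i, m in enumerate(motifs)}
    u_star = {
        m: float(u_values[i // n_motifs_per_rate]) for i, m in enumerate(motifs)
    }
    sc_prof = NormalizedProfile("SC", {Motif(m): c for m, c in landscape.items()})
    profiles = {"SC": sc_prof}
    meta = [LineMeta("SC", "G1", "SimPop", "SC", 0.0)]
    for i in range(n_lines):
        g_i = _draw_generations(rng, *generations_range, generations_mean)
        evolved, _ = evolve_lineage(
            landscape, u_star, g_i, mode="MA",
            seed=int(rng.integers(0, 2**31 - 1)), churn=churn, line_id=f"MA{i + 1}",
        )
        profiles[f"MA{i + 1}"] = NormalizedProfile(
            f"MA{i + 1}", {Motif(m): c for m, c in evolved.items()}
        )
        meta.append(LineMeta(f"MA{i + 1}", "G1", "SimPop", "MA", float(g_i)))
    return profiles, meta, u_star
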