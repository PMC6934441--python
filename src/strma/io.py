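"""Readers, writers and pipeline configuration.

All tabular interchange is TSV ('.' decimal, tab delimiter, UTF-8, no
quoting).  Motif strings in any table must already be canonical; readers
validate and reject non-canonical rows so strand/rotation variants can
never be double counted.  FASTQ/FASTA input goes through Biopython with
gzip auto-detected from magic bytes.
"""

from __future__ import annotations

import gzip
import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, Iterator, List, Mapping, Optional, Sequence, Tuple

import pandas as pd
import yaml
from Bio import SeqIO

from .normalization import (
    GCBinning,
    NormalizedProfile,
    normalization_factors,
    normalize_counts,
)
from .rates import LineMeta, RateTable, estimate_rates
from .scanner import KmerCountTable, Motif, canonical_motif, quantify_library

__all__ = [
    "PipelineConfig",
    "read_fastq",
    "read_fasta",
    "write_fastq",
    "read_depth_table",
    "read_counts",
    "write_counts",
    "read_profiles",
    "write_profiles",
    "read_meta",
    "write_meta",
    "run_pipeline",
    "FastqParseError",
]

logger = logging.getLogger("strma")


class FastqParseError(ValueError):
    """Raised for malformed FASTQ records, naming the failing record index."""


_KNOWN_CONFIG_KEYS = {
    "min_span",
    "max_k",
    "mismatch_per_unit",
    "gc_window",
    "filter_ec",
    "k_grid",
    "n_pcs",
    "pca_log",
    "restarts",
    "seed",
    "sc_min_copies",
    "line_min_copies",
    "ec_generation_time_days",
}


@dataclass
class PipelineConfig:
    """Validated knobs for every pipeline stage.

    ``min_span`` is the detection span threshold (50 bp default; 10 bp for
    the short-locus variant); ``max_k`` the longest repeat unit considered;
    ``gc_window`` the width of the local-GC window in the depth table;
    ``filter_ec`` whether EC lines participate in the abundance filter.
    """

    min_span: int = 50
    max_k: int = 20
    mismatch_per_unit: int = 1
    gc_window: int = 150
    filter_ec: bool = True
    k_grid: List[int] = field(default_factory=lambda: list(range(2, 13)))
    n_pcs: int = 10
    pca_log: bool = True  # cluster on log10(x+1) copy numbers
    restarts: int = 20
    seed: int = 0
    sc_min_copies: float = 6.0
    line_min_copies: float = 2.0
    ec_generation_time_days: float = 10.0

    def __post_init__(self):
        if self.min_span < 1 or self.max_k < 1 or self.max_k > 20:
            raise ValueError("min_span must be >= 1 and max_k in [1, 20]")
        if self.n_pcs < 1:
            raise ValueError("n_pcs must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - _KNOWN_CONFIG_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:12]


def _open_maybe_gzip(path):
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_fastq(path) -> Iterator[Tuple[str, str]]:
    """Stream (read_id, sequence) pairs from FASTQ or FASTQ.gz.

    Constant memory in the number of reads.  A malformed record raises
    :class:`FastqParseError` naming the 0-based record index.
    """
    handle = _open_maybe_gzip(path)
    idx = 0
    try:
        for rec in SeqIO.parse(handle, "fastq"):
            yield rec.id, str(rec.seq).upper()
            idx += 1
    except ValueError as exc:
        raise FastqParseError(f"malformed FASTQ record at index {idx}: {exc}") from exc
    finally:
        handle.close()


def write_fastq(path, reads: Sequence[Tuple[str, str]]) -> None:
    """Write (read_id, sequence) pairs as 4-line FASTQ with uniform quality."""
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")


def read_fasta(path) -> Dict[str, str]:
    """Contig name -> sequence from FASTA (gzip auto-detected)."""
    handle = _open_maybe_gzip(path)
    try:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(handle, "fasta")}
    finally:
        handle.close()


def read_depth_table(path) -> pd.DataFrame:
    """Per-base depth table: contig, pos (1-based), depth, gc."""
    df = pd.read_csv(path, sep="\t")
    missing = {"contig", "pos", "depth", "gc"} - set(df.columns)
    if missing:
        raise ValueError(f"depth table missing columns: {sorted(missing)}")
    return df


def _validate_canonical(motifs: Sequence[str], where: str) -> None:
    dupes = pd.Series(motifs).duplicated()
    if dupes.any():
        dup = pd.Series(motifs)[dupes].iloc[0]
        raise ValueError(f"duplicate motif row {dup!r} in {where}")
    for i, m in enumerate(motifs):
        if canonical_motif(m).unit != m:
            raise ValueError(
                f"non-canonical motif {m!r} at row {i} of {where} "
                f"(canonical form: {canonical_motif(m).unit})"
            )


def write_counts(path, tables: Sequence[KmerCountTable]) -> None:
    """Motif x line matrix of raw unit counts (integers; absent = 0)."""
    motifs = sorted({m.unit for t in tables for m in t.counts})
    df = pd.DataFrame(
        {t.line_id: [t[Motif(m)] for m in motifs] for t in tables}, index=motifs
    )
    df.index.name = "motif"
    df.to_csv(path, sep="\t")


def read_counts(path) -> List[KmerCountTable]:
    df = pd.read_csv(path, sep="\t", index_col="motif", float_precision="round_trip")
    _validate_canonical(list(df.index), str(path))
    return [
        KmerCountTable(
            line_id=col,
            counts={
                Motif(m): int(v) for m, v in df[col].items() if v > 0
            },
        )
        for col in df.columns
    ]


def write_profiles(path, profiles: Mapping[str, NormalizedProfile]) -> None:
    """Motif x line matrix of normalized copy numbers (copies per 1x coverage)."""
    motifs = sorted({m.unit for p in profiles.values() for m in p.copy_number})
    df = pd.DataFrame(
        {lid: [p[Motif(m)] for m in motifs] for lid, p in profiles.items()},
        index=motifs,
    )
    df.index.name = "motif"
    # %.17g guarantees float round-trip through text
    df.to_csv(path, sep="\t", float_format="%.17g")


def read_profiles(path) -> Dict[str, NormalizedProfile]:
    df = pd.read_csv(path, sep="\t", index_col="motif", float_precision="round_trip")
    _validate_canonical(list(df.index), str(path))
    return {
        col: NormalizedProfile(
            line_id=col,
            copy_number={Motif(m): float(v) for m, v in df[col].items() if v > 0},
        )
        for col in df.columns
    }


def write_meta(path, meta: Sequence[LineMeta]) -> None:
    pd.DataFrame(
        [
            {
                "line_id": m.line_id,
                "genotype": m.genotype,
                "population": m.population,
                "role": m.role,
                "generations": m.generations,
            }
            for m in meta
        ]
    ).to_csv(path, sep="\t", index=False)


def read_meta(path) -> List[LineMeta]:
    df = pd.read_csv(path, sep="\t")
    return [
        LineMeta(
            line_id=str(r.line_id),
            genotype=str(r.genotype),
            population=str(r.population),
            role=str(r.role),
            generations=float(r.generations),
        )
        for r in df.itertuples()
    ]


def run_pipeline(
    config: PipelineConfig,
    fastq_by_line: Mapping[str, Sequence],
    depth_by_line: Mapping[str, pd.DataFrame],
    meta: Sequence[LineMeta],
    out_dir,
) -> Dict[str, Path]:
    """Scan -> normalize -> rates -> landscape over a set of lines.

    Each stage writes its TSV outputs under ``out_dir``; the resolved
    configuration is written alongside for provenance.  Stages run in
    order and abort naming the failing stage.  Deterministic: all
    randomness flows from ``config.seed``.
    """
    from .landscape import build_shared_matrix, kmedoids_select, pca_scores

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.resolved.yaml")
    outputs: Dict[str, Path] = {"config": out / "config.resolved.yaml"}
    missing_depth = [lid for lid in fastq_by_line if lid not in depth_by_line]
    if missing_depth:
        raise ValueError(f"no depth table for lines: {missing_depth}")

    stage = "scan"
    try:
        tables = []
        for line_id, reads in fastq_by_line.items():
            tables.append(
                quantify_library(
                    reads,
                    line_id=line_id,
                    min_span=config.min_span,
                    max_k=config.max_k,
                    mismatch_per_unit=config.mismatch_per_unit,
                )
            )
        write_counts(out / "counts.tsv", tables)
        outputs["counts"] = out / "counts.tsv"

        stage = "normalize"
        profiles: Dict[str, NormalizedProfile] = {}
        for t in tables:
            binning = normalization_factors(depth_by_line[t.line_id])
            profiles[t.line_id] = normalize_counts(t, binning)
        write_profiles(out / "profiles.tsv", profiles)
        outputs["profiles"] = out / "profiles.tsv"

        stage = "rates"
        tables_by_geno = estimate_rates(
            profiles,
            meta,
            filter_ec=config.filter_ec,
            sc_min=config.sc_min_copies,
            line_min=config.line_min_copies,
        )
        per_line = pd.concat(
            [t.per_line for t in tables_by_geno.values() if len(t.per_line)],
            ignore_index=True,
        )
        per_line.to_csv(out / "rates_per_line.tsv", sep="\t", index=False)
        per_geno = pd.concat(
            [
                t.per_genotype.assign(genotype=g)
                for g, t in tables_by_geno.items()
                if len(t.per_genotype)
            ],
            ignore_index=True,
        )
        per_geno.to_csv(out / "rates_per_genotype.tsv", sep="\t", index=False)
        outputs["rates_per_line"] = out / "rates_per_line.tsv"
        outputs["rates_per_genotype"] = out / "rates_per_genotype.tsv"

        stage = "landscape"
        if len(profiles) >= 3:
            shared = build_shared_matrix(profiles)
            scores, var = pca_scores(
                shared.matrix, n_pcs=config.n_pcs, log_transform=config.pca_log
            )
            scores.to_csv(out / "pc_scores.tsv", sep="\t")
            k_grid = [k for k in config.k_grid if k < len(profiles)]
            result = kmedoids_select(
                scores, k_grid=k_grid, seed=config.seed, restarts=config.restarts
            )
            pd.DataFrame(
                {"k": list(result.silhouette_by_k), "silhouette": list(result.silhouette_by_k.values())}
            ).to_csv(out / "silhouette_by_k.tsv", sep="\t", index=False)
            result.assignments.to_csv(out / "clusters.tsv", sep="\t")
            outputs["pc_scores"] = out / "pc_scores.tsv"
            outputs["clusters"] = out / "clusters.tsv"
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    logger.info("pipeline complete (config %s)", config.digest())
    return outputs
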