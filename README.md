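# strma — short tandem repeat landscapes and mutation-accumulation rates

`strma` quantifies microsatellite (short tandem repeat) content directly
from unassembled sequencing reads and estimates genome-wide copy-number
mutation rates from mutation-accumulation (MA) experiments. It is aimed at
groups running MA designs in clonally propagated organisms: a sequenced
ancestor per genotype (the starting control, SC), replicate MA lines
propagated by single-progeny descent for *g* generations, and large
extant-control populations (EC) in which selection purges most changes.

## What it computes

**Detection.** Tandem arrays of 1–20 bp units are detected on each read
when they span at least 50 bp (configurable down to 10 bp), allowing one
mismatched base per repeat unit. Units are collapsed over rotations and
reverse complements to a canonical, primitive motif (`TTAGG` → `AACCT`),
and per-motif unit counts are totalled over the library.

**Normalization.** Raw counts are divided by the median per-base depth of
the GC bin matching the motif's GC fraction (bins
{0–0.3, 0.3–0.35, …, 0.55–0.6, 0.6–1}), giving copy number per 1×
coverage. This reproduces — deliberately — the known overcorrection for
borderline-length arrays.

**Rates.** For motif *j* in line *i*, the genomic mutation rate is the net
copy-number change per generation

```
U_ij = (c_ij − c_SC,j) / g_i            [copies / generation]
u_ij = U_ij / c_SC,j                    [copies / copy / generation]
```

with motifs filtered to ≥ 6 copies in the SC and ≥ 2 copies in every
MA (and, by default, EC) line. Genotype-level rates `U_j`, `u_j` and the
magnitude `|u|_j` are means over MA lines; EC lines are aggregated
separately. Per-line total bp change per generation is
`Σ_m k(m)·(c_im − c_SC,m)/g_i`.

**Landscapes.** The motifs present in every line form a shared matrix that
is summarized by PCA and clustered by k-medoids (PAM), with the cluster
count chosen by maximum average silhouette. Motif-feature analyses relate
per-copy rates to unit length (OLS), GC content (top/bottom-10 |u_j|
contrast, two-way ANOVA), and compare genotypes (Kruskal–Wallis, pairwise
correlations).

**Simulation.** A fully self-contained generator produces genomes with
planted arrays and a BED manifest, reads with a matching depth/GC table,
and whole MA/SC/EC experiments with known per-copy rates, for end-to-end
validation.

## Worked example

```bash
strma simulate --seed 5 --out simdata/
strma rates --profiles simdata/profiles.tsv --meta simdata/lines.tsv --out rates/
strma landscape --profiles simdata/profiles.tsv --seed 0 --out landscape/
```

The `simulate` step prints

```
simulated 65 lines into simdata
```

— the default design: 6 genotypes from 3 populations, each with 1 SC,
2 EC and 7–8 MA lines (65 lines total). `rates` writes per-line and
per-genotype TSVs (`wrote rate tables for 6 genotypes to rates`), and
`landscape` prints

```
19 shared motifs; best k = 6 (silhouette 0.762)
```

meaning 19 motifs had nonzero copy number in all 65 lines and the
silhouette-selected k-medoids partition has six clusters — each containing
exactly one genotype's SC line with all of its MA and EC descendants, so
the copy-number landscape alone recovers the experiment's genotype
structure.

Scanning reads directly:

```bash
strma scan --fastq reads.fastq.gz --line-id L1 --min-span 50 --out counts.tsv
strma normalize --counts counts.tsv --depth depth.tsv --out profile.tsv
```

where `depth.tsv` is a per-base table (`contig`, `pos`, `depth`, `gc`)
produced upstream from alignments; normalization factors are written to a
sidecar TSV for audit.

## Layout

| Module | Role |
| --- | --- |
| `strma.scanner` | canonical motifs, per-read array detection, library counts |
| `strma.normalization` | GC-binned median-depth normalization |
| `strma.rates` | abundance filter, U/u estimators, genotype aggregation |
| `strma.landscape` | shared-motif matrix, PCA, PAM + silhouette, motif-feature statistics |
| `strma.simulate` | genomes, reads, lineage evolution, full experiment designs |
| `strma.io` / `strma.cli` | TSV/FASTQ/FASTA IO, configuration, pipeline driver |

See `docs/methods.md` for the model assumptions, parameter defaults and
known limitations.
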