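# qtl-atlas

Align quantitative trait loci (QTLs) for seed yield and yield-related traits
from many *Brassica napus* mapping populations onto one physical reference
map, and mine the aligned map for stable loci, candidate genes and hub genes.

QTLs published by different studies live on incompatible linkage maps; the
only coordinates they share are their flanking STS markers' primer
sequences. This package makes those QTLs comparable by:

1. **Marker placement (in-silico PCR).** Each flanking marker's primer pair
   is searched against the genome assembly: a hit is a locus where the
   forward primer matches one strand and the reverse primer the opposite
   strand facing inward, with an amplicon of plausible size, allowing at
   most *k* substitutions per primer and an exact 3'-terminal anchor.
   Markers are labelled *unique*, *ambiguous* or *unplaced*.
2. **QTL projection.** A QTL reported with flanking markers at midpoints
   m₁ ≤ m₂ is projected to the physical interval
   [m₁ − W/2, m₂ + W/2), where W = `window_cm` × `cm_to_bp` is a uniform
   genetic window (1 cM by default) — so a QTL can be placed even when only
   one flanking marker survives placement. Unprojectable QTLs are reported
   with a reason (no placed marker / ambiguous only / markers on discordant
   chromosomes).
3. **Overlap atlas.** Within each (chromosome, trait) stratum, projected
   intervals are clustered into connected components of the overlap graph
   (half-open arithmetic; abutting intervals do not overlap). Components
   supported by ≥ 2 distinct (population, study) signals become
   overlapping-QTL regions; member QTLs are *fixed*, all others
   *specified*. Regions are classified as environment-fixed (all member
   populations from one country) or mixed, and a second pass over region
   spans finds multi-trait loci where regions of ≥ 2 traits coincide.
4. **Candidate genes.** *B. napus* homologs of curated *A. thaliana* yield
   genes are positioned via the GFF3 annotation (homologs missing from the
   annotation are reported as unplaced) and intersected with region spans;
   a candidate's trait labels come from its containing regions, with the
   homology source trait kept as provenance.
5. **Interaction network.** An undirected graph over the candidates'
   *A. thaliana* orthologs is built from a scored edge table (STRING-style
   export, score ≥ 0.4 by default). "Degree layout" (DL) is the raw
   incident-edge count; genes with DL ≥ `dl_min` (20 by convention) are the
   influential hubs, and functional-category cluster composition is
   tallied.

A first-class synthetic-data module generates genomes, marker tables, QTL
studies, annotations, homolog maps and networks with planted ground truth
(known marker positions, region spans and classes, candidates, hub
degrees), so the entire pipeline is testable with exact set-equality
recovery and no downloads.

## Worked example

Generate a synthetic study and run the whole pipeline:

```
$ qtl-atlas simulate --out-dir study --seed 1
wrote 8 files to study

$ qtl-atlas run-all --config config.yaml
aligned 33/33 QTLs; 6 overlap regions; 12 candidate genes; 2 influential genes
```

where `config.yaml` points at the eight generated files plus the
scaled-down window parameters the generator used (`cm_to_bp: 20000`,
`window_cm: 1.0`, `dl_min: 6`). The atlas directory then contains, among
others, `regions.tsv`:

```
region_id  chrom  trait  start   end     ... env_class
R001       A01    FT     29637   51837   ... fixed:China
R002       A02    FT     152167  174367  ... fixed:Germany
R003       A03    SW     14809   38109   ... mixed:America+China
```

and `summary_totals.tsv`:

```
aligned_qtls       33
fixed_qtls         13
specified_qtls     20
overlap_regions    6
env_fixed_regions  3
mixed_regions      3
multitrait_loci    1
```

Reading: all 33 QTLs projected; 13 of them replicate across populations in
6 regions (3 of those regions are environment-fixed, e.g. both member
populations Chinese); one genomic span on C02 carries overlapping regions
of two different traits. The same numbers appear in `manifest.json`
together with input checksums and all parameters, and match the planted
truth in `study/truth.json` exactly.

The same stages are available as library calls (`place_markers`,
`project_all`, `detect_overlap_regions`, `find_candidates`, `build_graph`,
…) and as individual subcommands (`place`, `project`, `overlaps`,
`candidates`, `network`).

## Layout

```
src/qtlatlas/
  placement.py   in-silico PCR marker placement
  projection.py  QTL -> physical interval projection
  atlas.py       overlap regions, environment classes, multi-trait loci
  candidates.py  homolog positioning and candidate-gene intersection
  network.py     interaction graph, degree layout, functional clusters
  synthetic.py   synthetic studies with planted ground truth
  pipeline.py    end-to-end orchestration and manifests
  io.py          FASTA / TSV / GFF3 / BED / track-file boundary
  cli.py         `qtl-atlas` command-line interface
```

See `docs/methods.md` for the modelling assumptions, parameter defaults
and known limitations.
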