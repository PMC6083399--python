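# Methods

## Problem and approach

QTL studies in *Brassica napus* report loci on population-specific linkage
maps. The transferable information in each report is the flanking markers'
primer sequences and the trait/population/environment metadata. This
package aligns such QTLs onto a single physical reference by placing the
primers with in-silico PCR, delimiting each QTL with a uniform genetic
window, and then analysing the aligned map: replicated ("fixed") loci,
environment composition, multi-trait coincidence, candidate genes by
homology, and hub genes by interaction-network degree.

## Marker placement (in-silico PCR)

A hit requires the forward primer to match one strand and the reverse
primer the opposite strand facing inward, with the amplicon length inside
configured bounds. Both product orientations are searched, since a pair
may amplify the minus strand of the assembly.

Matching is ungapped substitution-counting. Defaults: at most **1
mismatch per primer**, an **exact 3'-terminal anchor of 3 bases** (a 3'
mismatch would abort polymerase extension), amplicon bounds **[sum of
primer lengths, 2000 bp]**, overridden to **expected_size ± 20 %** when the
marker carries a published product size. These mirror common STS-search
practice; no single canonical parameterisation exists for this tool
family, so all of them are exposed in the configuration. `N` in the genome
never matches; IUPAC ambiguity codes other than `N` in primers are
rejected rather than expanded (documented limitation — degenerate primers
are rare in the STS tables this pipeline consumes).

Markers are classified **unique** (exactly one hit — usable), **ambiguous**
(several hits — excluded, on the conservative view that a marker that
cannot be located unambiguously should not anchor a QTL), or **unplaced**.
The scanner seeds on exact anchor matches and verifies candidates with a
vectorised comparison; its output is property-tested for equality against
an exhaustive per-offset scan, for strand symmetry (reverse-complementing
the genome mirrors every hit), and for monotonicity in the mismatch
allowance.

## QTL projection

The marker position is the **amplicon midpoint** (a single well-defined
point per placement). With placed marker midpoints m₁ ≤ m₂ (m₁ = m₂ for a
single usable marker) and window W = `window_cm` × `cm_to_bp`, the QTL
interval is [m₁ − ⌊W/2⌋, m₂ + ⌈W/2⌉), clipped to the chromosome. The
uniform window is applied to two-marker and one-marker QTLs alike: the
symmetric extension is the minimal assumption consistent with delimiting
every QTL by one fixed genetic width, and setting `window_cm = 0` recovers
the bare marker span for two-marker QTLs. A degenerate zero-window
single-marker projection collapses to a 1 bp interval.

`cm_to_bp` defaults to **500 000 bp/cM**, the order of magnitude of the
*B. napus* assembly length divided by its total genetic length. It is an
explicit surrogate for a conversion the underlying mapping literature
leaves unstated, configurable globally (the synthetic default study uses
20 000 bp/cM, matching its shrunken chromosomes).

Failure reasons are exhaustive and disjoint: `no_placed_marker`,
`ambiguous_only`, `discordant_chromosomes` (flanking markers placed on
different chromosomes). A marker name absent from the marker table is an
input error, not a placement failure. Aligned + failed always partitions
the input, and projection is order-independent.

## Overlap atlas

Overlap regions are computed **per (chromosome, trait) stratum** as
connected components of the interval-overlap graph. Overlap requires
strictly positive intersection under half-open arithmetic — abutting
intervals do not overlap; this makes the boundary rule exact and
testable. Components are found by a sorted sweep, verified against an
all-pairs union-find oracle.

A component is a region only with **≥ 2 members from ≥ 2 distinct
(population, source-study) combinations**: the same cross re-phenotyped in
two studies counts as replication, duplicate QTLs within one study do
not. Region span is the union of member intervals; the core
(intersection) is also reported and may be empty for chained components.
Member QTLs are **fixed**, all others **specified**.

Environment classification uses a population → countries map derived from
the QTL table (a population may carry several country labels, e.g. a cross
developed in two countries; it contributes all of them). A region is
`fixed:<country>` only when the union of member-population countries is a
single label, else `mixed:<c1>+<c2>…`.

**Multi-trait loci** are a second pass: connected components of span
overlap across the per-trait regions of one chromosome, kept when ≥ 2
distinct traits participate (transitive closure — trait A and trait C join
one locus through trait B even if their spans do not touch). Computing
regions per trait and loci as a second pass is the only reading that lets
a region count and a separately reported multi-trait count coexist.

Summaries tabulate regions per chromosome, per trait, per
populations-per-region, per environment class and per subgenome (A vs C by
chromosome-name prefix), plus fixed/specified totals; each table is a
partition of the same total, asserted in tests.

## Candidate genes

Homolog records (*A. thaliana* source gene, its curated trait(s), *B.
napus* homolog ID) are positioned by joining against gene IDs in the GFF3
annotation; records whose IDs are absent are reported as **unplaced**
rather than dropped. A positioned gene is a candidate when its span
(GFF3's 1-based closed coordinates converted to half-open at the I/O
boundary) has positive intersection with ≥ 1 region span, strand ignored;
a gene straddling a region edge counts as inside — the weaker, documented
choice. A gene hitting several regions is listed once with all region IDs;
its trait set is the union of the containing regions' traits, and the
homology source trait is carried as provenance only, because a homolog
curated for one trait can land in a QTL region of another. Alongside the
candidate list the atlas-side statistics are reported: regions containing
≥ 1 candidate, and the member QTLs of those regions.

## Interaction network

The graph is built from a user-supplied scored edge table over the
candidates' *A. thaliana* orthologs rather than a live database query —
reproducible, offline, and independent of interaction-database versioning.
Edges below `score_min` (default 0.4, the usual medium-confidence cut) are
dropped, duplicate unordered pairs collapse to the maximum score,
self-loops are discarded, edges naming genes outside the whitelist are
dropped with a warning, and isolated whitelist genes keep degree 0.
Degree layout (DL) is the raw unweighted incident-edge count; influential
genes are those with DL ≥ `dl_min` (default 20), sorted by DL descending
then name. Functional clusters are an input mapping (ten categories; genes
without a mapping fall into "unknown"); within/between-category edge
counts are reported. The handshake identity and an adjacency-matrix degree
oracle are asserted in tests.

## Synthetic studies and what they do (not) show

The generator plants every structure the pipeline is supposed to find:

* **Genome** — i.i.d. bases at a target GC (0.37, rapeseed-like), subgenome
  chromosome naming (A01… / C01…). Default desk scale: six chromosomes of
  200 kb with 20 000 bp/cM, a uniform shrink (~4000×) of the real problem
  that preserves all proportions (window vs chromosome, gene vs region);
  these sizes keep a full 20-seed recovery sweep under a minute per seed
  on one CPU with wide margin.
* **Markers** — primer pairs cut from the genome itself, rejection-sampled
  to genome-wide uniqueness on both strands, so placement ambiguity is an
  opt-in scenario, not noise.
* **QTL study** — planted overlap regions (n same-trait QTLs from chosen
  countries whose projected intervals are guaranteed to overlap; coincident
  centers plant multi-trait loci; a dual-country population exercises the
  mixed classifier) plus background QTLs forced disjoint within each trait
  so truth counts are exact. The recorded truth spans are computed with
  the same window rule the projector applies, so recovery is bit-exact.
* **Annotation/homologs** — candidates planted strictly inside region
  spans, background genes strictly outside all spans, and a deterministic
  fraction (default 10 %) of homolog records pointing at IDs absent from
  the annotation to exercise the unplaced path.
* **Network** — hubs wired to a guaranteed minimum degree, noise edges
  capped below the hub threshold, so hub recovery at the study's `dl_min`
  is exact.

All randomness flows from one seed through per-stage child seeds; written
studies are byte-identical across runs. Because every planted structure is
clean by construction, passing recovery tests demonstrates the *logic* of
each stage (boundary rules, classification, set algebra), not robustness
to real-data pathology: real marker tables contain primers that place
ambiguously or not at all, real intervals overlap partially across traits
in ways no ground truth certifies, and real interaction tables are
version-bound. Those behaviours are covered separately by the failure-mode
and oracle tests, not by the recovery surface.

## Numerical and degenerate-input choices

* Coordinates are 0-based half-open internally; GFF3 (1-based closed) is
  converted at the I/O boundary; BED and track files are half-open.
* Window halves use floor/ceil so the added width is exactly W for odd W.
* Region IDs are deterministic: sorted by (chromosome, span start, span
  end, trait), numbered `R001…`.
* Ties in influential-gene ranking break alphabetically; equal-degree
  genes are all retained.
* Empty genome → empty hit list; empty edge table → isolated whitelist;
  zero markers → empty tables, not errors.
* The pipeline manifest records SHA-256 checksums of every input, all
  parameters and per-stage counts; identical configuration ⇒ identical
  outputs, asserted byte-for-byte in tests.

## Known limitations

* No gapped alignment, primer thermodynamics or genome indexing; the
  scanner is designed for marker tables against assemblies up to tens of
  megabases, not for chromosome-scale speed.
* The uniform-window projection ignores local recombination-rate
  variation; per-chromosome `cm_to_bp` values can be supplied but no
  genetic-map interpolation is performed, and source studies' confidence
  intervals are not re-derived.
* Homology itself is an input (no orthology inference), as are interaction
  scores and functional categories; the package intersects and counts, it
  does not re-derive them.
* Reproducing any particular published atlas additionally requires that
  study's own supplementary tables and reference assembly; the window
  parameters needed to match an under-specified published delimiting rule
  are exposed (`cm_to_bp`, `window_cm`) rather than fixed.
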