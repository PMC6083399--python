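"""Candidate genes: homologs of curated yield genes inside overlap regions.

The homolog map links curated *A. thaliana* yield genes (each annotated with
the trait(s) it was curated for) to their *B. napus* homologs.  Homologs are
positioned via the genome annotation; those whose IDs are absent from the
annotation cannot be placed and are reported separately.  A positioned gene
is a candidate when its span has strictly positive intersection with at
least one overlap-region span (a gene straddling a region edge counts).

Trait assignment follows the *containing region's* trait; the A. thaliana
source trait is retained as provenance only, since a homolog of, say, a
branch-number gene may fall into a flowering-time region.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Sequence

import pandas as pd
from intervaltree import IntervalTree

from .atlas import OverlapRegion
from .errors import InputError

HOMOLOG_COLUMNS = ("at_gene", "at_traits", "bn_gene")


@dataclass(frozen=True)
class CandidateGene:
    """An annotated gene intersecting >= 1 overlap region."""

    bn_gene: str
    chrom: str
    start: int
    end: int
    regions: tuple[str, ...]          # region ids, sorted
    traits: frozenset[str]            # union of containing regions' traits
    at_source: tuple[str, ...]        # A. thaliana gene(s) it descends from
    at_traits: frozenset[str]         # provenance trait(s) of the source gene

    @property
    def trait_label(self) -> str:
        return "/".join(sorted(self.traits))


@dataclass
class MappedHomologs:
    """Homolog records split into positioned and unplaced."""

    positioned: pd.DataFrame  # at_gene, at_traits, bn_gene, chrom, start, end
    unplaced: pd.DataFrame    # at_gene, at_traits, bn_gene

    @property
    def n_positioned(self) -> int:
        return int(self.positioned["bn_gene"].nunique())

    @property
    def n_unplaced(self) -> int:
        return int(self.unplaced["bn_gene"].nunique())


def map_homologs(homologs: pd.DataFrame, genes: pd.DataFrame) -> MappedHomologs:
    """Attach annotation coordinates to homolog records.

    ``homologs`` must carry columns (at_gene, at_traits, bn_gene), one row
    per A. thaliana gene / B. napus homolog pair; ``genes`` carries
    (gene_id, chrom, start, end) with 0-based half-open coordinates as
    produced by the GFF3 reader.  A homolog whose ``bn_gene`` is missing
    from the annotation is unplaced.
    """
    missing = set(HOMOLOG_COLUMNS) - set(homologs.columns)
    if missing:
        raise InputError(f"homolog table lacks column(s) {sorted(missing)}")
    coords = genes.set_index("gene_id")[["chrom", "start", "end"]]
    merged = homologs.merge(
        coords, left_on="bn_gene", right_index=True, how="left"
    )
    placed_mask = merged["chrom"].notna()
    positioned = merged[placed_mask].copy()
    positioned["start"] = positioned["start"].astype(int)
    positioned["end"] = positioned["end"].astype(int)
    unplaced = merged.loc[~placed_mask, list(HOMOLOG_COLUMNS)].copy()
    return MappedHomologs(
        positioned=positioned.reset_index(drop=True),
        unplaced=unplaced.reset_index(drop=True),
    )


def find_candidates(
    regions: Sequence[OverlapRegion], positioned: pd.DataFrame
) -> list[CandidateGene]:
    """Intersect positioned homologs with region spans (strand-ignorant).

    A gene hitting several regions is reported once, listing all of them;
    its trait set is the union of those regions' traits.  Results are sorted
    by (chrom, start, gene id).
    """
    trees: dict[str, IntervalTree] = {}
    for r in regions:
        trees.setdefault(r.chrom, IntervalTree())[r.start : r.end] = r

    by_gene: dict[str, dict] = {}
    for row in positioned.itertuples(index=False):
        rec = by_gene.setdefault(
            row.bn_gene,
            {
                "chrom": row.chrom, "start": int(row.start),
                "end": int(row.end), "at": set(), "at_traits": set(),
            },
        )
        rec["at"].add(row.at_gene)
        rec["at_traits"].update(
            t.strip() for t in str(row.at_traits).split(",") if t.strip()
        )

    out: list[CandidateGene] = []
    for gene, rec in by_gene.items():
        tree = trees.get(rec["chrom"])
        if tree is None:
            continue
        hits = tree.overlap(rec["start"], rec["end"])  # half-open, positive overlap
        if not hits:
            continue
        regs = sorted((h.data for h in hits), key=lambda r: r.region_id)
        out.append(
            CandidateGene(
                bn_gene=gene, chrom=rec["chrom"], start=rec["start"],
                end=rec["end"],
                regions=tuple(r.region_id for r in regs),
                traits=frozenset(r.trait for r in regs),
                at_source=tuple(sorted(rec["at"])),
                at_traits=frozenset(rec["at_traits"]),
            )
        )
    out.sort(key=lambda c: (c.chrom, c.start, c.bn_gene))
    return out


@dataclass
class CandidateSummary:
    """Tallies over the candidate set (per trait combination, chromosome, …).

    ``regions_with_candidates`` / ``qtls_in_candidate_regions`` are the
    atlas-side statistics that correspond to a candidate search: how many
    overlap regions contain at least one candidate, and how many member
    QTLs those regions carry.
    """

    per_trait_combination: pd.Series
    per_single_trait: pd.Series     # a gene counts toward each of its traits
    per_chromosome: pd.Series
    n_candidates: int
    regions_with_candidates: int
    qtls_in_candidate_regions: int


def summarize_candidates(
    candidates: Sequence[CandidateGene], regions: Sequence[OverlapRegion]
) -> CandidateSummary:
    combo = Counter(c.trait_label for c in candidates)
    single: Counter = Counter()
    for c in candidates:
        single.update(c.traits)
    per_chrom = Counter(c.chrom for c in candidates)
    hit_region_ids = {rid for c in candidates for rid in c.regions}
    qtl_ids = {
        qid
        for r in regions
        if r.region_id in hit_region_ids
        for qid in r.member_ids
    }
    return CandidateSummary(
        per_trait_combination=pd.Series(dict(sorted(combo.items())), dtype=int),
        per_single_trait=pd.Series(dict(sorted(single.items())), dtype=int),
        per_chromosome=pd.Series(dict(sorted(per_chrom.items())), dtype=int),
        n_candidates=len(candidates),
        regions_with_candidates=len(hit_region_ids),
        qtls_in_candidate_regions=len(qtl_ids),
    )


def candidates_frame(candidates: Sequence[CandidateGene]) -> pd.DataFrame:
    rows = [
        {
            "bn_gene": c.bn_gene, "chrom": c.chrom, "start": c.start,
            "end": c.end, "regions": ",".join(c.regions),
            "traits": "/".join(sorted(c.traits)),
            "at_source": ",".join(c.at_source),
            "at_traits": "/".join(sorted(c.at_traits)),
        }
        for c in candidates
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "bn_gene", "chrom", "start", "end", "regions", "traits",
            "at_source", "at_traits",
        ],
    )
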