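"""Overlapping-QTL regions, environment classes and multi-trait loci.

Within each (chromosome, trait) stratum, projected QTL intervals are grouped
into connected components of the interval-overlap graph (half-open
arithmetic: abutting intervals do **not** overlap).  A component is reported
as an overlap region only when it is supported by at least two distinct
(population, source) combinations — a signal replicated within a single
study is treated as one observation, not as replication.

QTLs that belong to some region are "fixed"; the rest are "specified".
Regions whose member populations were all developed in one country are
environment-fixed for that country; otherwise the region is mixed and its
country combination is recorded.  A second pass over region spans (all
traits together, per chromosome) yields multi-trait loci: genomic spans
where regions of two or more distinct traits coincide.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .projection import QTLInterval


@dataclass(frozen=True)
class OverlapRegion:
    """A maximal cluster of mutually/transitively overlapping same-trait QTLs.

    ``span`` (start, end) is the union of member intervals; ``core`` is their
    common intersection, or None when the chain has no common point.
    """

    region_id: str
    chrom: str
    trait: str
    start: int
    end: int
    core: tuple[int, int] | None
    members: tuple[QTLInterval, ...]
    populations: frozenset[str]
    countries: frozenset[str]
    env_class: str

    @property
    def member_ids(self) -> tuple[str, ...]:
        return tuple(m.qtl_id for m in self.members)

    @property
    def n_populations(self) -> int:
        return len(self.populations)


@dataclass(frozen=True)
class MultiTraitLocus:
    chrom: str
    start: int
    end: int
    traits: frozenset[str]
    region_ids: tuple[str, ...]


def _components(intervals: Sequence[QTLInterval]) -> list[list[QTLInterval]]:
    """Connected components of the overlap graph by a sorted sweep."""
    ivs = sorted(intervals, key=lambda iv: (iv.start, iv.end, iv.qtl_id))
    comps: list[list[QTLInterval]] = []
    cur: list[QTLInterval] = []
    cur_end = -1
    for iv in ivs:
        if cur and iv.start < cur_end:
            cur.append(iv)
            cur_end = max(cur_end, iv.end)
        else:
            if cur:
                comps.append(cur)
            cur = [iv]
            cur_end = iv.end
    if cur:
        comps.append(cur)
    return comps


def classify_region_environment(
    populations: Iterable[str], pop_to_countries: Mapping[str, frozenset[str]]
) -> tuple[str, frozenset[str]]:
    """(env_class, countries) for a set of member populations.

    A population developed in several countries (e.g. a cross grown both in
    China and Germany) contributes all of its labels, so a region containing
    it can never be environment-fixed for a single country.
    """
    countries: set[str] = set()
    for pop in populations:
        countries |= pop_to_countries.get(pop, frozenset())
    countries_f = frozenset(countries)
    if len(countries_f) == 1:
        return f"fixed:{next(iter(countries_f))}", countries_f
    return "mixed:" + "+".join(sorted(countries_f)), countries_f


def population_country_map(
    intervals: Iterable[QTLInterval],
) -> dict[str, frozenset[str]]:
    """Derive population → countries from the QTL records themselves."""
    out: dict[str, set[str]] = {}
    for iv in intervals:
        out.setdefault(iv.qtl.population, set()).update(iv.qtl.countries)
    return {p: frozenset(c) for p, c in out.items()}


def detect_overlap_regions(
    intervals: Sequence[QTLInterval],
    pop_to_countries: Mapping[str, frozenset[str]] | None = None,
) -> list[OverlapRegion]:
    """Overlap regions across all (chromosome, trait) strata.

    Region ids are deterministic: regions are sorted by
    (chrom, span start, span end, trait) and numbered R001, R002, ...
    Input order never affects the result.
    """
    if pop_to_countries is None:
        pop_to_countries = population_country_map(intervals)
    strata: dict[tuple[str, str], list[QTLInterval]] = {}
    for iv in intervals:
        strata.setdefault((iv.chrom, iv.trait), []).append(iv)

    raw: list[tuple[str, str, list[QTLInterval]]] = []
    for (chrom, trait), ivs in strata.items():
        for comp in _components(ivs):
            if len(comp) < 2:
                continue
            signals = {(iv.qtl.population, iv.qtl.source) for iv in comp}
            if len(signals) < 2:
                continue
            raw.append((chrom, trait, comp))

    raw.sort(key=lambda t: (t[0], min(iv.start for iv in t[2]),
                            max(iv.end for iv in t[2]), t[1]))
    regions: list[OverlapRegion] = []
    for i, (chrom, trait, comp) in enumerate(raw, start=1):
        start = min(iv.start for iv in comp)
        end = max(iv.end for iv in comp)
        core_start = max(iv.start for iv in comp)
        core_end = min(iv.end for iv in comp)
        core = (core_start, core_end) if core_start < core_end else None
        pops = frozenset(iv.qtl.population for iv in comp)
        env_class, countries = classify_region_environment(pops, pop_to_countries)
        members = tuple(sorted(comp, key=lambda iv: (iv.start, iv.end, iv.qtl_id)))
        regions.append(
            OverlapRegion(
                region_id=f"R{i:03d}", chrom=chrom, trait=trait,
                start=start, end=end, core=core, members=members,
                populations=pops, countries=countries, env_class=env_class,
            )
        )
    return regions


CLASS_FIXED = "fixed"
CLASS_SPECIFIED = "specified"


def classify_qtls(
    intervals: Sequence[QTLInterval], regions: Sequence[OverlapRegion]
) -> dict[str, str]:
    """fixed (member of an overlap region) vs specified, per QTL id."""
    fixed = {qid for r in regions for qid in r.member_ids}
    return {
        iv.qtl_id: (CLASS_FIXED if iv.qtl_id in fixed else CLASS_SPECIFIED)
        for iv in intervals
    }


def detect_multitrait_loci(
    regions: Sequence[OverlapRegion],
) -> list[MultiTraitLocus]:
    """Spans where per-trait regions of >= 2 distinct traits coincide.

    Connected components of the span-overlap graph per chromosome, closed
    transitively (A overlaps B, B overlaps C puts A and C in one locus even
    if they do not touch).
    """
    by_chrom: dict[str, list[OverlapRegion]] = {}
    for r in regions:
        by_chrom.setdefault(r.chrom, []).append(r)
    loci: list[MultiTraitLocus] = []
    for chrom in sorted(by_chrom):
        regs = sorted(by_chrom[chrom], key=lambda r: (r.start, r.end, r.region_id))
        comp: list[OverlapRegion] = []
        cur_end = -1
        comps: list[list[OverlapRegion]] = []
        for r in regs:
            if comp and r.start < cur_end:
                comp.append(r)
                cur_end = max(cur_end, r.end)
            else:
                if comp:
                    comps.append(comp)
                comp = [r]
                cur_end = r.end
        if comp:
            comps.append(comp)
        for comp in comps:
            traits = frozenset(r.trait for r in comp)
            if len(traits) < 2:
                continue
            loci.append(
                MultiTraitLocus(
                    chrom=chrom,
                    start=min(r.start for r in comp),
                    end=max(r.end for r in comp),
                    traits=traits,
                    region_ids=tuple(r.region_id for r in comp),
                )
            )
    return loci


@dataclass
class AtlasSummary:
    """The headline tallies of an overlap atlas."""

    per_chromosome: pd.Series
    per_trait: pd.Series
    populations_per_region: pd.Series
    env_classes: pd.Series
    genome_split: pd.Series  # regions on the A vs C subgenome
    totals: dict[str, int]

    def to_frames(self) -> dict[str, pd.DataFrame]:
        out = {
            "per_chromosome": self.per_chromosome.rename("n_regions").rename_axis("chrom").reset_index(),
            "per_trait": self.per_trait.rename("n_regions").rename_axis("trait").reset_index(),
            "populations_per_region": self.populations_per_region.rename("n_regions").rename_axis("n_populations").reset_index(),
            "env_classes": self.env_classes.rename("n_regions").rename_axis("env_class").reset_index(),
            "genome_split": self.genome_split.rename("n_regions").rename_axis("subgenome").reset_index(),
            "totals": pd.DataFrame(
                sorted(self.totals.items()), columns=["quantity", "value"]
            ),
        }
        return out


def summarize_atlas(
    regions: Sequence[OverlapRegion],
    loci: Sequence[MultiTraitLocus],
    intervals: Sequence[QTLInterval],
) -> AtlasSummary:
    """Per-chromosome / per-trait / per-environment tallies plus totals.

    The A/C subgenome split uses the chromosome-name prefix convention
    (A01–A10 vs C01–C09); other prefixes are tallied under "other".
    """
    classes = classify_qtls(intervals, regions)
    n_fixed = sum(1 for v in classes.values() if v == CLASS_FIXED)
    per_chrom = Counter(r.chrom for r in regions)
    per_trait = Counter(r.trait for r in regions)
    pops_hist = Counter(r.n_populations for r in regions)
    env = Counter(r.env_class for r in regions)
    split = Counter(
        r.chrom[0] if r.chrom[:1] in ("A", "C") else "other" for r in regions
    )
    totals = {
        "aligned_qtls": len(intervals),
        "fixed_qtls": n_fixed,
        "specified_qtls": len(intervals) - n_fixed,
        "overlap_regions": len(regions),
        "env_fixed_regions": sum(
            1 for r in regions if r.env_class.startswith("fixed:")
        ),
        "mixed_regions": sum(
            1 for r in regions if r.env_class.startswith("mixed")
        ),
        "multitrait_loci": len(loci),
    }
    return AtlasSummary(
        per_chromosome=pd.Series(dict(sorted(per_chrom.items())), dtype=int),
        per_trait=pd.Series(dict(sorted(per_trait.items())), dtype=int),
        populations_per_region=pd.Series(dict(sorted(pops_hist.items())), dtype=int),
        env_classes=pd.Series(dict(sorted(env.items())), dtype=int),
        genome_split=pd.Series(dict(sorted(split.items())), dtype=int),
        totals=totals,
    )
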