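"""Synthetic study generator with planted, machine-readable ground truth.

Every downstream stage of the atlas (marker placement, QTL projection,
overlap detection, candidate calling, network degree analysis) is testable
without any download: this module fabricates a genome, an STS marker table,
a multi-population QTL study, a gene annotation with a homolog map, and a
scored interaction edge table — all with the intended answers recorded in a
:class:`SyntheticTruth` object.

Design choices that make truth recovery exact rather than probabilistic:

* planted primer sites are rejection-sampled to genome-wide uniqueness, so
  placement ambiguity is an opt-in scenario, not background noise;
* background QTL intervals are forced disjoint from planted regions and
  from each other (within a trait), so ground-truth overlap counts are
  exact;
* background genes are placed outside every planted region span, so the
  candidate set equals the planted candidates;
* noise edges in the interaction graph are capped so that no non-hub node
  reaches the hub degree threshold.

Country labels are drawn from {China, America, Germany, Canada}, the label
space of the multi-country rapeseed populations this generator emulates.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import GenerationError, ParameterError
from .placement import reverse_complement
from .projection import TRAIT_CODES

CHROM_NAME_CONVENTION = tuple(
    [f"A{i:02d}" for i in range(1, 11)] + [f"C{i:02d}" for i in range(1, 10)]
)

COUNTRIES = ("China", "America", "Germany", "Canada")

FUNCTIONAL_CATEGORIES = (
    "cell", "transport", "signaling", "hormone metabolism", "RNA regulation",
    "development", "protein metabolism", "others", "miscellaneous", "unknown",
)


# ---------------------------------------------------------------------------
# truth containers


@dataclass(frozen=True)
class PlantedRegion:
    chrom: str
    start: int
    end: int
    trait: str
    members: tuple[str, ...]       # QTL ids
    env_class: str                 # "fixed:<country>" | "mixed:<c1>+<c2>..."


@dataclass(frozen=True)
class PlantedCandidate:
    gene_id: str
    chrom: str
    start: int
    end: int
    traits: frozenset[str]         # traits of every planted region it hits


@dataclass
class SyntheticTruth:
    """Planted ground truth for one synthetic study."""

    seed: int
    marker_positions: dict[str, tuple[str, int, int, str]] = field(default_factory=dict)
    regions: list[PlantedRegion] = field(default_factory=list)
    loci: list[tuple[str, frozenset[str]]] = field(default_factory=list)
    candidates: list[PlantedCandidate] = field(default_factory=list)
    hubs: dict[str, int] = field(default_factory=dict)

    def to_json(self) -> str:
        def enc(o):
            if isinstance(o, frozenset):
                return sorted(o)
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            raise TypeError(type(o))

        payload = {
            "seed": self.seed,
            "marker_positions": {
                m: list(v) for m, v in sorted(self.marker_positions.items())
            },
            "regions": [dataclasses.asdict(r) for r in self.regions],
            "loci": [[c, sorted(t)] for c, t in self.loci],
            "candidates": [
                {**dataclasses.asdict(c), "traits": sorted(c.traits)}
                for c in self.candidates
            ],
            "hubs": dict(sorted(self.hubs.items())),
        }
        return json.dumps(payload, indent=2, sort_keys=True, default=enc)


# ---------------------------------------------------------------------------
# genome


def generate_genome(
    n_chroms: int,
    lengths: Sequence[int],
    gc: float = 0.37,
    seed: int = 0,
    names: Sequence[str] | None = None,
) -> dict[str, str]:
    """Random chromosomes at a target GC content.

    Chromosome names follow the A01..A10 / C01..C09 subgenome convention
    when ``n_chroms`` <= 19 (or pass ``names`` explicitly).
    """
    if len(lengths) != n_chroms:
        raise ParameterError("lengths must have n_chroms entries")
    if any(l <= 0 for l in lengths):
        raise ParameterError("chromosome lengths must be positive")
    if not 0 < gc < 1:
        raise ParameterError("gc must be in (0, 1)")
    if names is None:
        if n_chroms <= len(CHROM_NAME_CONVENTION):
            names = CHROM_NAME_CONVENTION[:n_chroms]
        else:
            names = tuple(f"chr{i:02d}" for i in range(1, n_chroms + 1))
    rng = np.random.default_rng(seed)
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return {
        name: rng.choice(bases, size=length, p=p).tobytes().decode("ascii")
        for name, length in zip(names, lengths)
    }


# ---------------------------------------------------------------------------
# marker planting


def _count_occurrences(genome: Mapping[str, str], sub: str) -> int:
    """Overlapping occurrences of ``sub`` on either strand, genome-wide."""
    rc = reverse_complement(sub)
    total = 0
    for seq in genome.values():
        for pat in {sub, rc}:
            start = 0
            while True:
                i = seq.find(pat, start)
                if i < 0:
                    break
                total += 1
                start = i + 1
    return total


class _MarkerPlanter:
    """Stateful helper that carves unique primer sites out of a genome."""

    def __init__(self, genome: Mapping[str, str], rng: np.random.Generator,
                 primer_len: int):
        self.genome = genome
        self.rng = rng
        self.primer_len = primer_len
        self.occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in genome}

    def _free(self, chrom: str, start: int, end: int) -> bool:
        return all(end <= s or start >= e for s, e in self.occupied[chrom])

    def try_plant(self, name: str, chrom: str, start: int, amp_len: int):
        """Plant one marker amplicon at [start, start+amp_len); returns the
        marker row + position, or None if the site is unusable."""
        seq = self.genome[chrom]
        end = start + amp_len
        if start < 0 or end > len(seq) or not self._free(chrom, start, end):
            return None
        fwd = seq[start : start + self.primer_len]
        rev = reverse_complement(seq[end - self.primer_len : end])
        if "N" in fwd or "N" in rev:
            return None
        if _count_occurrences(self.genome, fwd) != 1:
            return None
        if _count_occurrences(self.genome, rev) != 1:
            return None
        self.occupied[chrom].append((start, end))
        row = {
            "marker": name, "fwd": fwd, "rev": rev, "expected_size": amp_len,
        }
        return row, (chrom, start, end, "+")

    def plant_near(self, name: str, chrom: str, target_start: int,
                   amp_len: int, jitter: int = 60, attempts: int = 200):
        """Plant at/near a target start, shifting a little when the exact
        site collides or is non-unique."""
        out = self.try_plant(name, chrom, target_start, amp_len)
        if out is not None:
            return out
        for _ in range(attempts):
            shift = int(self.rng.integers(-jitter, jitter + 1))
            out = self.try_plant(name, chrom, target_start + shift, amp_len)
            if out is not None:
                return out
        raise GenerationError(
            f"could not plant marker {name!r} near {chrom}:{target_start}"
        )

    def plant_random(self, name: str, amp_range: tuple[int, int],
                     attempts: int = 500):
        lo, hi = amp_range
        eligible = [c for c, s in self.genome.items() if len(s) >= hi]
        if not eligible:
            raise GenerationError(
                f"genome too short for amplicons of up to {hi} bp"
            )
        lens = np.array([len(self.genome[c]) for c in eligible], dtype=float)
        for _ in range(attempts):
            chrom = eligible[int(self.rng.choice(len(eligible), p=lens / lens.sum()))]
            amp_len = int(self.rng.integers(lo, hi + 1))
            start = int(self.rng.integers(0, len(self.genome[chrom]) - amp_len + 1))
            out = self.try_plant(name, chrom, start, amp_len)
            if out is not None:
                return out
        raise GenerationError(f"could not plant marker {name!r} after {attempts} tries")


def plant_markers(
    genome: Mapping[str, str],
    n_markers: int,
    primer_len: int = 20,
    amplicon_range: tuple[int, int] = (200, 600),
    seed: int = 0,
    prefix: str = "M",
) -> tuple[pd.DataFrame, dict[str, tuple[str, int, int, str]]]:
    """Plant ``n_markers`` STS markers at unique random sites.

    Each marker's forward primer is a genome substring and its reverse
    primer is the reverse complement of the amplicon's 3' end, so an exact
    E-PCR search recovers every marker at its recorded coordinates.
    """
    if amplicon_range[0] < 2 * primer_len:
        raise ParameterError("amplicon_range must fit two primers")
    rng = np.random.default_rng(seed)
    planter = _MarkerPlanter(genome, rng, primer_len)
    rows, positions = [], {}
    for i in range(n_markers):
        row, pos = planter.plant_random(f"{prefix}{i + 1:04d}", amplicon_range)
        rows.append(row)
        positions[row["marker"]] = pos
    df = pd.DataFrame(rows, columns=["marker", "fwd", "rev", "expected_size"])
    return df, positions


# ---------------------------------------------------------------------------
# QTL study


@dataclass(frozen=True)
class OverlapSpec:
    """One planted overlap region: ``n_qtls`` same-trait QTLs from the given
    countries whose projected intervals are guaranteed to overlap.

    ``center`` pins the region midpoint (bp); give two specs the same
    center on one chromosome to plant a multi-trait locus.  ``countries``
    entries may carry multiple labels joined by '+' (a population developed
    in two countries).
    """

    trait: str
    chrom: str
    n_qtls: int
    countries: tuple[str, ...]
    center: int | None = None

    def __post_init__(self) -> None:
        if self.trait not in TRAIT_CODES:
            raise ParameterError(f"unknown trait {self.trait!r}")
        if self.n_qtls < 2:
            raise ParameterError("a planted region needs >= 2 QTLs")
        if len(self.countries) != self.n_qtls:
            raise ParameterError("countries must list one entry per QTL")


def _env_class(countries: Sequence[str]) -> str:
    labels: set[str] = set()
    for c in countries:
        labels.update(x.strip() for x in c.split("+") if x.strip())
    if len(labels) == 1:
        return f"fixed:{next(iter(labels))}"
    return "mixed:" + "+".join(sorted(labels))


def _interval(mid_lo: int, mid_hi: int, window: int, clen: int) -> tuple[int, int]:
    # mirror of the projection rule, used to record exact expected spans
    start = max(0, mid_lo - window // 2)
    end = min(clen, mid_hi + (window - window // 2))
    return start, end


def generate_qtl_study(
    genome: Mapping[str, str],
    truth: SyntheticTruth,
    planted_overlap_spec: Sequence[OverlapSpec],
    n_background_qtls: int = 20,
    cm_to_bp: float = 20_000,
    window_cm: float = 1.0,
    primer_len: int = 20,
    amplicon_range: tuple[int, int] = (200, 600),
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fabricate a QTL table (and its markers) with planted overlap regions.

    Returns (qtl table, marker table); ``truth`` is extended in place with
    the planted marker positions, region spans/members/classes, and the
    multi-trait loci implied by coincident region spans.  Background QTLs
    are disjoint from every planted region and from each other within a
    trait, and each comes from its own population, so they can never form a
    region.
    """
    rng = np.random.default_rng(seed)
    planter = _MarkerPlanter(genome, rng, primer_len)
    # planted sites must stay unique against markers planted earlier
    window = int(round(window_cm * cm_to_bp))
    amp_len = (amplicon_range[0] + amplicon_range[1]) // 2
    # member amplicons fan out from the region centre; the step exceeds the
    # amplicon length so neighbouring planted sites never collide
    spread_step = amp_len + 150

    marker_rows: list[dict] = []
    qtl_rows: list[dict] = []
    # per (chrom, trait): intervals already claimed, to keep things disjoint
    claimed: dict[tuple[str, str], list[tuple[int, int]]] = {}
    # per chrom: planted region spans (all traits) for locus truth and for
    # keeping background genes out later
    new_regions: list[PlantedRegion] = []

    used_centers: dict[str, list[tuple[int, int]]] = {c: [] for c in genome}
    # specs sharing a centre (planted multi-trait loci) interleave their
    # members: each member takes the next free offset slot at that centre
    center_slots: dict[tuple[str, int], int] = {}

    def _region_halfwidth(n: int) -> int:
        return window // 2 + n * spread_step + amp_len + 200

    for k, spec in enumerate(planted_overlap_spec):
        clen = len(genome[spec.chrom])
        slots_taken = (
            center_slots.get((spec.chrom, spec.center), 0)
            if spec.center is not None
            else 0
        )
        half = _region_halfwidth(slots_taken + spec.n_qtls)
        if 2 * half >= clen:
            raise GenerationError(
                f"spec {k}: chromosome {spec.chrom} too short for a planted "
                f"region of ~{2 * half} bp"
            )
        if spec.center is not None:
            center = spec.center
            if not half <= center <= clen - half:
                raise GenerationError(f"spec {k}: center too close to a chromosome end")
        else:
            center = None
            for _ in range(500):
                cand = int(rng.integers(half, clen - half + 1))
                # keep distinct planted regions well apart unless pinned
                if all(
                    abs(cand - c0) > 2 * (half + h0)
                    for c0, h0 in used_centers[spec.chrom]
                ):
                    center = cand
                    break
            if center is None:
                raise GenerationError(
                    f"spec {k}: no room left on {spec.chrom} for another region"
                )
        used_centers[spec.chrom].append((center, half))

        member_ids, member_intervals = [], []
        for i in range(spec.n_qtls):
            slot = center_slots.get((spec.chrom, center), 0)
            center_slots[(spec.chrom, center)] = slot + 1
            d = (slot + 1) * spread_step
            left_name = f"mk_{spec.trait}{k}_{i}L"
            right_name = f"mk_{spec.trait}{k}_{i}R"
            rowL, posL = planter.plant_near(
                left_name, spec.chrom, center - d - amp_len // 2, amp_len
            )
            rowR, posR = planter.plant_near(
                right_name, spec.chrom, center + d - amp_len // 2, amp_len
            )
            marker_rows += [rowL, rowR]
            truth.marker_positions[left_name] = posL
            truth.marker_positions[right_name] = posR
            midL = (posL[1] + posL[2]) // 2
            midR = (posR[1] + posR[2]) // 2
            iv = _interval(min(midL, midR), max(midL, midR), window, clen)
            qid = f"q{spec.trait}{k}.{i + 1}"
            pop = f"Pop_{spec.trait}{k}_{i + 1}"
            qtl_rows.append(
                {
                    "qtl_id": qid, "trait": spec.trait, "population": pop,
                    "country": spec.countries[i],
                    "marker_left": left_name, "marker_right": right_name,
                    "source": f"Study_{spec.trait}{k}_{i + 1}",
                }
            )
            member_ids.append(qid)
            member_intervals.append(iv)
        span = (min(s for s, _ in member_intervals), max(e for _, e in member_intervals))
        claimed.setdefault((spec.chrom, spec.trait), []).append(span)
        new_regions.append(
            PlantedRegion(
                chrom=spec.chrom, start=span[0], end=span[1], trait=spec.trait,
                members=tuple(member_ids), env_class=_env_class(spec.countries),
            )
        )

    truth.regions.extend(new_regions)
    truth.loci = _expected_loci(truth.regions)

    # background QTLs: disjoint singletons
    traits_pool = [s.trait for s in planted_overlap_spec] or ["FT"]
    all_traits = tuple(dict.fromkeys(list(traits_pool) + ["SW", "PH", "SY", "SN"]))
    for j in range(n_background_qtls):
        trait = all_traits[int(rng.integers(0, len(all_traits)))]
        placed = False
        for _ in range(300):
            chrom = list(genome)[int(rng.integers(0, len(genome)))]
            clen = len(genome[chrom])
            margin = window // 2 + amp_len + 100
            if clen <= 2 * margin:
                continue
            mid = int(rng.integers(margin, clen - margin))
            iv = _interval(mid, mid, window, clen)
            others = claimed.get((chrom, trait), [])
            if any(iv[0] < e and s < iv[1] for s, e in others):
                continue
            name = f"mk_bg{j}"
            try:
                row, pos = planter.plant_near(name, chrom, mid - amp_len // 2, amp_len)
            except GenerationError:
                continue
            marker_rows.append(row)
            truth.marker_positions[name] = pos
            actual_mid = (pos[1] + pos[2]) // 2
            iv = _interval(actual_mid, actual_mid, window, clen)
            if any(iv[0] < e and s < iv[1] for s, e in others):
                planter.occupied[chrom].remove((pos[1], pos[2]))
                marker_rows.pop()
                del truth.marker_positions[name]
                continue
            claimed.setdefault((chrom, trait), []).append(iv)
            qtl_rows.append(
                {
                    "qtl_id": f"qbg{j + 1}", "trait": trait,
                    "population": f"BgPop{j + 1}",
                    "country": COUNTRIES[int(rng.integers(0, len(COUNTRIES)))],
                    "marker_left": name, "marker_right": "",
                    "source": f"BgStudy{j + 1}",
                }
            )
            placed = True
            break
        if not placed:
            raise GenerationError(f"could not place background QTL {j}")

    qtl_df = pd.DataFrame(
        qtl_rows,
        columns=[
            "qtl_id", "trait", "population", "country", "marker_left",
            "marker_right", "source",
        ],
    )
    marker_df = pd.DataFrame(
        marker_rows, columns=["marker", "fwd", "rev", "expected_size"]
    )
    return qtl_df, marker_df


def _expected_loci(
    regions: Sequence[PlantedRegion],
) -> list[tuple[str, frozenset[str]]]:
    """Ground-truth multi-trait loci from planted spans: transitive closure
    of pairwise span overlap per chromosome, kept at >= 2 distinct traits.
    Computed by brute-force union-find over the (few) planted regions."""
    idx = list(range(len(regions)))
    parent = dict(zip(idx, idx))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in idx:
        for j in idx:
            if i < j and regions[i].chrom == regions[j].chrom:
                if regions[i].start < regions[j].end and regions[j].start < regions[i].end:
                    parent[find(i)] = find(j)
    groups: dict[int, list[PlantedRegion]] = {}
    for i in idx:
        groups.setdefault(find(i), []).append(regions[i])
    loci = []
    for grp in groups.values():
        traits = frozenset(r.trait for r in grp)
        if len(traits) >= 2:
            loci.append((grp[0].chrom, traits))
    loci.sort(key=lambda t: (t[0], tuple(sorted(t[1]))))
    return loci


# ---------------------------------------------------------------------------
# annotation + homologs


def generate_annotation_and_homologs(
    genome: Mapping[str, str],
    truth: SyntheticTruth,
    n_genes: int = 80,
    planted_candidates_per_region: int = 2,
    unplaced_fraction: float = 0.1,
    background_homolog_fraction: float = 0.3,
    gene_length_range: tuple[int, int] = (500, 3000),
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Gene annotation plus a homolog map with planted candidates.

    * ``planted_candidates_per_region`` genes are placed strictly inside
      each planted region span and linked to distinct A. thaliana source
      genes (the provenance trait is drawn independently of the region
      trait, emulating homologs curated for one trait landing in a QTL
      region of another).
    * The remaining genes are placed outside every region span; a fraction
      of them also appear in the homolog map (positioned non-candidates).
    * An extra block of homolog records points at gene IDs absent from the
      annotation: the unplaced path.  Its size is chosen so unplaced
      records make up ``unplaced_fraction`` of all homolog records, with
      deterministic rounding.

    Returns (genes table, homolog table); ``truth.candidates`` is filled
    with the planted genes and, for each, the full trait set implied by
    every planted region span it intersects.
    """
    if not 0 <= unplaced_fraction < 1:
        raise ParameterError("unplaced_fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    glo, ghi = gene_length_range
    gene_rows: list[dict] = []
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in genome}
    region_spans: dict[str, list[tuple[int, int, str]]] = {}
    for r in truth.regions:
        region_spans.setdefault(r.chrom, []).append((r.start, r.end, r.trait))

    def free(chrom, s, e):
        return all(e <= a or s >= b for a, b in occupied[chrom])

    planted: list[tuple[dict, str]] = []  # (gene row, region trait)
    for r in truth.regions:
        for _ in range(planted_candidates_per_region):
            ok = False
            for _ in range(300):
                length = int(rng.integers(glo, ghi + 1))
                if r.end - r.start <= length + 2:
                    length = max(50, (r.end - r.start) // 3)
                s = int(rng.integers(r.start + 1, r.end - length))
                if free(r.chrom, s, s + length):
                    ok = True
                    break
            if not ok:
                raise GenerationError(
                    f"no room for a candidate gene inside region "
                    f"{r.chrom}:{r.start}-{r.end}"
                )
            row = {"chrom": r.chrom, "start": s, "end": s + length}
            occupied[r.chrom].append((s, s + length))
            planted.append((row, r.trait))

    n_background = max(0, n_genes - len(planted))
    background: list[dict] = []
    chrom_list = list(genome)
    for _ in range(n_background):
        for _ in range(500):
            chrom = chrom_list[int(rng.integers(0, len(chrom_list)))]
            clen = len(genome[chrom])
            length = int(rng.integers(glo, ghi + 1))
            if clen <= length + 2:
                continue
            s = int(rng.integers(0, clen - length))
            spans = region_spans.get(chrom, [])
            if any(s < e0 and s0 < s + length for s0, e0, _ in spans):
                continue
            if not free(chrom, s, s + length):
                continue
            background.append({"chrom": chrom, "start": s, "end": s + length})
            occupied[chrom].append((s, s + length))
            break
        else:
            raise GenerationError("no room left for background genes")

    # assign IDs in chromosomal order, Darmor-bzh naming style
    all_rows = [dict(r) for r, _ in planted] + [dict(b) for b in background]
    order = sorted(range(len(all_rows)), key=lambda i: (all_rows[i]["chrom"], all_rows[i]["start"]))
    counters: dict[str, int] = {}
    for rank, i in enumerate(order):
        chrom = all_rows[i]["chrom"]
        counters[chrom] = counters.get(chrom, 0) + 1
        all_rows[i]["gene_id"] = f"Bna{chrom}g{counters[chrom] * 10:05d}D"
    genes_df = pd.DataFrame(
        [all_rows[i] for i in order],
        columns=["chrom", "start", "end", "gene_id"],
    )[["gene_id", "chrom", "start", "end"]]

    # homolog map: planted candidates + a slice of background + unplaced
    hom_rows: list[dict] = []
    at_serial = 0

    def next_at() -> str:
        nonlocal at_serial
        at_serial += 1
        return f"AT{(at_serial % 5) + 1}G{at_serial:05d}"

    for i, (row, region_trait) in enumerate(planted):
        gid = all_rows[i]["gene_id"]
        at_trait = TRAIT_CODES[int(rng.integers(0, 8))]  # provenance, may differ
        hom_rows.append(
            {"at_gene": next_at(), "at_traits": at_trait, "bn_gene": gid}
        )
        spans = region_spans.get(row["chrom"], [])
        traits = frozenset(
            t for s0, e0, t in spans if row["start"] < e0 and s0 < row["end"]
        )
        truth.candidates.append(
            PlantedCandidate(
                gene_id=gid, chrom=row["chrom"], start=row["start"],
                end=row["end"], traits=traits,
            )
        )

    n_bg_hom = int(round(background_homolog_fraction * len(background)))
    for i in range(n_bg_hom):
        gid = all_rows[len(planted) + i]["gene_id"]
        hom_rows.append(
            {
                "at_gene": next_at(),
                "at_traits": TRAIT_CODES[int(rng.integers(0, 8))],
                "bn_gene": gid,
            }
        )

    n_placed_hom = len(hom_rows)
    n_total = int(round(n_placed_hom / (1 - unplaced_fraction)))
    n_unplaced = n_total - n_placed_hom
    for j in range(n_unplaced):
        hom_rows.append(
            {
                "at_gene": next_at(),
                "at_traits": TRAIT_CODES[int(rng.integers(0, 8))],
                "bn_gene": f"BnaUnkg{j + 1:05d}D",
            }
        )
    homologs_df = pd.DataFrame(hom_rows, columns=["at_gene", "at_traits", "bn_gene"])
    return genes_df, homologs_df


# ---------------------------------------------------------------------------
# interaction network


def generate_network(
    genes: Sequence[str],
    hub_spec: Mapping[str, int],
    n_noise_edges: int = 0,
    seed: int = 0,
    score_range: tuple[float, float] = (0.5, 0.99),
    max_nonhub_degree: int | None = None,
) -> pd.DataFrame:
    """Scored edge table with planted hubs.

    Each hub is wired to at least its specified number of distinct partners;
    noise edges are then added between random pairs, never duplicating an
    unordered pair or creating a self-loop.  With ``max_nonhub_degree`` set,
    noise edges that would lift a non-hub past that degree are rejected, so
    hub membership at a threshold above it is exact by construction.
    """
    genes = list(genes)
    n = len(genes)
    for g, d in hub_spec.items():
        if g not in genes:
            raise ParameterError(f"hub {g!r} not in the gene list")
        if d > n - 1:
            raise ParameterError(
                f"hub {g!r}: requested degree {d} exceeds n_genes - 1 = {n - 1}"
            )
    rng = np.random.default_rng(seed)
    edges: set[frozenset[str]] = set()
    degree: dict[str, int] = {g: 0 for g in genes}

    def add(a: str, b: str) -> bool:
        key = frozenset((a, b))
        if a == b or key in edges:
            return False
        edges.add(key)
        degree[a] += 1
        degree[b] += 1
        return True

    for hub in sorted(hub_spec):
        want = hub_spec[hub]
        others = [g for g in genes if g != hub]
        partners = list(rng.permutation(others))
        for p in partners:
            if degree[hub] >= want:
                break
            add(hub, p)
        if degree[hub] < want:
            raise GenerationError(f"could not reach degree {want} for hub {hub!r}")

    hubs = set(hub_spec)
    attempts = 0
    added_noise = 0
    while added_noise < n_noise_edges:
        attempts += 1
        if attempts > 200 * max(1, n_noise_edges):
            raise GenerationError("could not place all requested noise edges")
        i, j = rng.choice(n, size=2, replace=False)
        a, b = genes[int(i)], genes[int(j)]
        if max_nonhub_degree is not None:
            if a not in hubs and degree[a] + 1 > max_nonhub_degree:
                continue
            if b not in hubs and degree[b] + 1 > max_nonhub_degree:
                continue
        if add(a, b):
            added_noise += 1

    lo, hi = score_range
    rows = []
    for key in sorted(edges, key=lambda k: tuple(sorted(k))):
        a, b = sorted(key)
        rows.append(
            {"gene_a": a, "gene_b": b,
             "score": round(float(rng.uniform(lo, hi)), 3)}
        )
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "score"])


# ---------------------------------------------------------------------------
# full study orchestration


@dataclass(frozen=True)
class StudyConfig:
    """Desk-scale defaults for a complete synthetic study.

    The physical scale is a uniform shrink of a rapeseed-sized problem: six
    chromosomes from both subgenomes at 200 kb each, and 20 kb per cM so
    the uniform 1 cM QTL window spans 20 kb (the real genome is ~4000x
    larger; all proportions — window vs chromosome, genes vs regions — are
    preserved).
    """

    chrom_names: tuple[str, ...] = ("A01", "A02", "A03", "C01", "C02", "C03")
    chrom_length: int = 200_000
    gc: float = 0.37
    cm_to_bp: float = 20_000
    window_cm: float = 1.0
    primer_len: int = 20
    amplicon_range: tuple[int, int] = (200, 600)
    n_background_qtls: int = 20
    n_genes: int = 60
    planted_candidates_per_region: int = 2
    unplaced_fraction: float = 0.1
    hub_degree: int = 8
    n_hubs: int = 2
    n_noise_edges: int = 6
    max_nonhub_degree: int = 5
    dl_min: int = 6
    score_min: float = 0.4


def default_overlap_specs(cfg: StudyConfig) -> list[OverlapSpec]:
    """The planted study layout: environment-fixed and mixed regions, one
    dual-country population, and a coincident two-trait locus on C02."""
    locus_center = cfg.chrom_length // 2
    return [
        OverlapSpec("FT", "A01", 2, ("China", "China")),
        OverlapSpec("FT", "A02", 2, ("Germany", "Germany")),
        OverlapSpec("SW", "A03", 3, ("China", "America", "America")),
        OverlapSpec("SY", "C01", 2, ("China+Germany", "China")),
        OverlapSpec("PH", "C02", 2, ("China", "Germany"), center=locus_center),
        OverlapSpec("SN", "C02", 2, ("America", "America"), center=locus_center),
    ]


@dataclass
class SyntheticStudy:
    """All inputs of one synthetic study plus its planted truth."""

    config: StudyConfig
    genome: dict[str, str]
    markers: pd.DataFrame
    qtls: pd.DataFrame
    genes: pd.DataFrame
    homologs: pd.DataFrame
    edges: pd.DataFrame
    categories: pd.DataFrame
    truth: SyntheticTruth

    def chrom_lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.genome.items()}

    def write(self, out_dir: str | os.PathLike) -> dict[str, str]:
        """Write every input file (plus the truth as JSON); byte-identical
        for identical (config, seed)."""
        from . import io as qio

        os.makedirs(out_dir, exist_ok=True)
        paths = {
            "genome": os.path.join(out_dir, "genome.fa"),
            "markers": os.path.join(out_dir, "markers.tsv"),
            "qtls": os.path.join(out_dir, "qtls.tsv"),
            "genes": os.path.join(out_dir, "genes.gff3"),
            "homologs": os.path.join(out_dir, "homologs.tsv"),
            "edges": os.path.join(out_dir, "edges.tsv"),
            "categories": os.path.join(out_dir, "categories.tsv"),
            "truth": os.path.join(out_dir, "truth.json"),
        }
        qio.write_fasta(self.genome, paths["genome"])
        params = {"seed": self.truth.seed}
        qio.write_tsv(self.markers, paths["markers"], params)
        qio.write_tsv(self.qtls, paths["qtls"], params)
        qio.write_gff3(self.genes, paths["genes"])
        qio.write_tsv(self.homologs, paths["homologs"], params)
        qio.write_tsv(self.edges, paths["edges"], params)
        qio.write_tsv(self.categories, paths["categories"], params)
        with open(paths["truth"], "w") as fh:
            fh.write(self.truth.to_json() + "\n")
        return paths


def simulate_study(
    config: StudyConfig | None = None,
    seed: int = 0,
    overlap_specs: Sequence[OverlapSpec] | None = None,
) -> SyntheticStudy:
    """Generate a complete, internally consistent synthetic study.

    All randomness flows from ``seed`` through independent child seeds per
    stage, so the study (and every file it writes) is reproducible
    bit-for-bit.
    """
    cfg = config or StudyConfig()
    specs = list(overlap_specs) if overlap_specs is not None else default_overlap_specs(cfg)
    root = np.random.default_rng(seed)
    sub = [int(s) for s in root.integers(0, 2**31 - 1, size=5)]

    genome = generate_genome(
        len(cfg.chrom_names), [cfg.chrom_length] * len(cfg.chrom_names),
        gc=cfg.gc, seed=sub[0], names=cfg.chrom_names,
    )
    truth = SyntheticTruth(seed=seed)
    qtls, markers = generate_qtl_study(
        genome, truth, specs,
        n_background_qtls=cfg.n_background_qtls,
        cm_to_bp=cfg.cm_to_bp, window_cm=cfg.window_cm,
        primer_len=cfg.primer_len, amplicon_range=cfg.amplicon_range,
        seed=sub[1],
    )
    genes, homologs = generate_annotation_and_homologs(
        genome, truth, n_genes=cfg.n_genes,
        planted_candidates_per_region=cfg.planted_candidates_per_region,
        unplaced_fraction=cfg.unplaced_fraction, seed=sub[2],
    )
    # network over the candidates' A. thaliana orthologs
    planted_ids = {c.gene_id for c in truth.candidates}
    ortho = homologs[homologs["bn_gene"].isin(planted_ids)]["at_gene"].tolist()
    ortho = sorted(set(ortho))
    hubs = {g: cfg.hub_degree for g in ortho[: cfg.n_hubs]}
    edges = generate_network(
        ortho, hubs, n_noise_edges=cfg.n_noise_edges, seed=sub[3],
        max_nonhub_degree=cfg.max_nonhub_degree,
    )
    truth.hubs = dict(hubs)
    # a stray edge to a non-whitelist gene exercises the drop-with-warning path
    edges = pd.concat(
        [
            edges,
            pd.DataFrame(
                [{"gene_a": ortho[0], "gene_b": "AT9G99999", "score": 0.9}]
            ),
        ],
        ignore_index=True,
    )
    cats = []
    for i, g in enumerate(ortho):
        cats.append({"gene": g, "category": FUNCTIONAL_CATEGORIES[i % (len(FUNCTIONAL_CATEGORIES) - 1)]})
    categories = pd.DataFrame(cats, columns=["gene", "category"])
    if len(categories) > 1:  # leave one gene unmapped: the "unknown" path
        categories = categories.iloc[:-1].reset_index(drop=True)
    return SyntheticStudy(
        config=cfg, genome=genome, markers=markers, qtls=qtls, genes=genes,
        homologs=homologs, edges=edges, categories=categories, truth=truth,
    )
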