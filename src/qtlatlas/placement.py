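"""Electronic PCR: place STS marker primer pairs on a genome assembly.

A marker is defined by a primer pair.  A placement (hit) is a locus where the
forward primer matches one strand and the reverse primer matches the opposite
strand facing inward, producing an amplicon of plausible size.  Both product
orientations are searched: the pair may amplify the plus strand (forward
primer on the left) or the minus strand (reverse primer on the left, with the
reverse-complemented forward primer on the right).

Matching is ungapped.  Up to ``max_mismatches`` substitutions are tolerated
per primer, except over the 3'-terminal ``anchor_3prime`` bases which must
match exactly — polymerase extension initiates at the 3' end, so a mismatch
there would abort amplification.  ``N`` in the genome never counts as a
match; IUPAC ambiguity codes other than ``N`` are rejected in primers.

Coordinates are 0-based half-open throughout this module.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InputError, ParameterError

_PRIMER_ALPHABET = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: default upper amplicon bound (bp) when the marker carries no expected size
DEFAULT_AMPLICON_MAX = 2000

#: expected_size tolerance: bounds become expected_size * (1 +/- tol)
DEFAULT_SIZE_TOLERANCE = 0.20

MIN_PRIMER_LEN = 12


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (``N`` maps to ``N``)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class PrimerPair:
    """An STS marker: name plus forward/reverse primers (both written 5'→3').

    ``expected_size`` is the published amplicon length in bp, when known; it
    narrows the acceptable amplicon-size window during placement.
    """

    name: str
    fwd: str
    rev: str
    expected_size: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "fwd", self.fwd.upper())
        object.__setattr__(self, "rev", self.rev.upper())
        for label, seq in (("forward", self.fwd), ("reverse", self.rev)):
            if len(seq) < MIN_PRIMER_LEN:
                raise InputError(
                    f"marker {self.name!r}: {label} primer shorter than "
                    f"{MIN_PRIMER_LEN} bp"
                )
            bad = set(seq) - _PRIMER_ALPHABET
            if bad:
                raise InputError(
                    f"marker {self.name!r}: {label} primer contains "
                    f"unsupported characters {sorted(bad)} (only A/C/G/T/N "
                    "are accepted; IUPAC ambiguity codes are not expanded)"
                )
        if self.expected_size is not None and self.expected_size <= 0:
            raise InputError(f"marker {self.name!r}: non-positive expected_size")


@dataclass(frozen=True, order=True)
class MarkerHit:
    """One placement of a primer pair: the amplicon span on a chromosome."""

    chrom: str
    start: int
    end: int
    orientation: str  # "plus" | "minus"
    marker: str = field(compare=False)
    fwd_mismatches: int = field(compare=False)
    rev_mismatches: int = field(compare=False)

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class PlacementParams:
    """E-PCR search settings.

    The underlying tool family is conventionally run with a small
    substitution allowance and an exact 3' anchor; these defaults mirror that
    practice and are all configurable.
    """

    max_mismatches: int = 1
    anchor_3prime: int = 3
    amplicon_max: int = DEFAULT_AMPLICON_MAX
    size_tolerance: float = DEFAULT_SIZE_TOLERANCE

    def __post_init__(self) -> None:
        if self.max_mismatches < 0:
            raise ParameterError("max_mismatches must be >= 0")
        if self.anchor_3prime < 0:
            raise ParameterError("anchor_3prime must be >= 0")
        if self.amplicon_max <= 0:
            raise ParameterError("amplicon_max must be positive")
        if not 0 <= self.size_tolerance < 1:
            raise ParameterError("size_tolerance must be in [0, 1)")


# ---------------------------------------------------------------------------
# low-level scanning


def _encode_genome_seq(seq: str) -> np.ndarray:
    """Byte-encode a chromosome; anything outside A/C/G/T becomes a sentinel
    byte that matches no primer base (so genomic N never matches)."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8).copy()
    valid = (
        (arr == ord("A")) | (arr == ord("C")) | (arr == ord("G")) | (arr == ord("T"))
    )
    arr[~valid] = 0
    return arr


def _encode_pattern(seq: str) -> np.ndarray:
    # primer N is kept as the byte 'N', which equals no genome byte: a primer
    # N therefore always counts as a mismatch (and never satisfies an anchor)
    return np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)


def _scan(
    seq: np.ndarray,
    pattern: np.ndarray,
    max_mismatches: int,
    anchor_len: int,
    anchor_at_start: bool,
) -> tuple[np.ndarray, np.ndarray]:
    """All start offsets where ``pattern`` matches ``seq`` with at most
    ``max_mismatches`` substitutions and an exact match over the anchor.

    Returns (starts, mismatch_counts), both sorted by start.  The anchor is
    the first ``anchor_len`` pattern positions when ``anchor_at_start`` else
    the last.  Anchored positions are used as a seed filter: candidate
    offsets are verified in one vectorised gather.
    """
    m = len(pattern)
    n = len(seq) - m + 1
    empty = (np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int32))
    if n <= 0:
        return empty
    if anchor_len > 0:
        idx = range(anchor_len) if anchor_at_start else range(m - anchor_len, m)
        ok = np.ones(n, dtype=bool)
        for t in idx:
            ok &= seq[t : t + n] == pattern[t]
        cand = np.nonzero(ok)[0]
        if cand.size == 0:
            return empty
        window = seq[cand[:, None] + np.arange(m)]
        mm = (window != pattern).sum(axis=1).astype(np.int32)
        keep = mm <= max_mismatches
        return cand[keep].astype(np.int64), mm[keep]
    mm_all = np.zeros(n, dtype=np.int32)
    for t in range(m):
        mm_all += seq[t : t + n] != pattern[t]
    starts = np.nonzero(mm_all <= max_mismatches)[0]
    return starts.astype(np.int64), mm_all[starts]


def _amplicon_bounds(
    pair: PrimerPair, params: PlacementParams, override: tuple[int, int] | None
) -> tuple[int, int]:
    floor = len(pair.fwd) + len(pair.rev)
    if override is not None:
        lo, hi = override
        if lo < floor:
            raise ParameterError(
                f"amplicon lower bound {lo} below total primer length {floor}"
            )
        return lo, hi
    if pair.expected_size is not None:
        tol = params.size_tolerance
        lo = max(floor, int(np.ceil(pair.expected_size * (1 - tol))))
        hi = int(np.floor(pair.expected_size * (1 + tol)))
        return lo, max(lo, hi)
    return floor, max(floor, params.amplicon_max)


def find_primer_hits(
    genome: Mapping[str, str],
    pair: PrimerPair,
    params: PlacementParams = PlacementParams(),
    amplicon_bounds: tuple[int, int] | None = None,
    _encoded: Mapping[str, np.ndarray] | None = None,
) -> list[MarkerHit]:
    """All loci where ``pair`` would amplify a product on ``genome``.

    Both orientations are searched.  Hits are sorted by
    (chrom, start, end, orientation).  An empty genome yields an empty list.
    """
    a = params.anchor_3prime
    if a > min(len(pair.fwd), len(pair.rev)):
        raise ParameterError(
            f"marker {pair.name!r}: anchor_3prime={a} exceeds a primer length"
        )
    lo, hi = _amplicon_bounds(pair, params, amplicon_bounds)
    k = params.max_mismatches

    hits: list[MarkerHit] = []
    for chrom in genome:
        seq = _encoded[chrom] if _encoded is not None else _encode_genome_seq(genome[chrom])
        # (left pattern, right pattern, orientation); the left primer's 3'
        # end is its last bases, the right pattern is a reverse complement so
        # its source primer's 3' end sits at the pattern start.
        layouts = (
            (pair.fwd, reverse_complement(pair.rev), "plus"),
            (pair.rev, reverse_complement(pair.fwd), "minus"),
        )
        for left, right, orientation in layouts:
            l_starts, l_mm = _scan(seq, _encode_pattern(left), k, a, anchor_at_start=False)
            if l_starts.size == 0:
                continue
            r_starts, r_mm = _scan(seq, _encode_pattern(right), k, a, anchor_at_start=True)
            if r_starts.size == 0:
                continue
            len_r = len(right)
            for i, lmm in zip(l_starts, l_mm):
                # amplicon end = r_start + len_r; size constraint lo..hi
                j_lo = np.searchsorted(r_starts, i + lo - len_r, side="left")
                j_hi = np.searchsorted(r_starts, i + hi - len_r, side="right")
                for j in range(j_lo, j_hi):
                    rs, rmm = int(r_starts[j]), int(r_mm[j])
                    if orientation == "plus":
                        fmm, vmm = int(lmm), rmm
                    else:
                        fmm, vmm = rmm, int(lmm)
                    hits.append(
                        MarkerHit(
                            chrom=chrom,
                            start=int(i),
                            end=rs + len_r,
                            orientation=orientation,
                            marker=pair.name,
                            fwd_mismatches=fmm,
                            rev_mismatches=vmm,
                        )
                    )
    hits.sort(key=lambda h: (h.chrom, h.start, h.end, h.orientation))
    return hits


# ---------------------------------------------------------------------------
# marker-set placement


STATUS_UNIQUE = "unique"
STATUS_AMBIGUOUS = "ambiguous"
STATUS_UNPLACED = "unplaced"


@dataclass
class PlacementResult:
    """Outcome of placing a marker set: per-marker status and hits.

    Only markers with status ``unique`` carry a usable placement; ambiguous
    markers (several candidate loci) and unplaced markers (none) are listed
    in the diagnostics and excluded from projection by default.
    """

    statuses: dict[str, str]
    hits: dict[str, list[MarkerHit]]

    @property
    def unique(self) -> dict[str, MarkerHit]:
        return {
            m: self.hits[m][0]
            for m, s in self.statuses.items()
            if s == STATUS_UNIQUE
        }

    def counts(self) -> dict[str, int]:
        out = {STATUS_UNIQUE: 0, STATUS_AMBIGUOUS: 0, STATUS_UNPLACED: 0}
        for s in self.statuses.values():
            out[s] += 1
        return out

    def diagnostics(self) -> pd.DataFrame:
        """One row per non-unique marker with the reason it was excluded."""
        rows = []
        for m, s in sorted(self.statuses.items()):
            if s == STATUS_UNIQUE:
                continue
            n = len(self.hits[m])
            reason = (
                f"{n} candidate loci" if s == STATUS_AMBIGUOUS else "no amplifiable locus"
            )
            rows.append({"marker": m, "status": s, "n_hits": n, "reason": reason})
        return pd.DataFrame(rows, columns=["marker", "status", "n_hits", "reason"])

    def hits_table(self) -> pd.DataFrame:
        """Every marker as rows: one per hit, plus a coordinate-free row for
        unplaced markers, so the table is a complete placement record."""
        rows = []
        for m, s in sorted(self.statuses.items()):
            if not self.hits[m]:
                rows.append(
                    {
                        "marker": m, "status": s, "chrom": "", "start": "",
                        "end": "", "orientation": "", "fwd_mismatches": "",
                        "rev_mismatches": "",
                    }
                )
            for h in self.hits[m]:
                rows.append(
                    {
                        "marker": m, "status": s, "chrom": h.chrom,
                        "start": h.start, "end": h.end,
                        "orientation": h.orientation,
                        "fwd_mismatches": h.fwd_mismatches,
                        "rev_mismatches": h.rev_mismatches,
                    }
                )
        return pd.DataFrame(
            rows,
            columns=[
                "marker", "status", "chrom", "start", "end", "orientation",
                "fwd_mismatches", "rev_mismatches",
            ],
        )


def place_markers(
    genome: Mapping[str, str],
    markers: Sequence[PrimerPair] | Iterable[PrimerPair],
    params: PlacementParams = PlacementParams(),
) -> PlacementResult:
    """Place every marker, labelling each unique / ambiguous / unplaced."""
    markers = list(markers)
    names = [m.name for m in markers]
    dupes = {n for n, grp in itertools.groupby(sorted(names)) if len(list(grp)) > 1}
    if dupes:
        raise InputError(f"duplicate marker names: {sorted(dupes)}")
    encoded = {c: _encode_genome_seq(s) for c, s in genome.items()}
    statuses: dict[str, str] = {}
    hits: dict[str, list[MarkerHit]] = {}
    for pair in markers:
        h = find_primer_hits(genome, pair, params, _encoded=encoded)
        hits[pair.name] = h
        if len(h) == 1:
            statuses[pair.name] = STATUS_UNIQUE
        elif len(h) > 1:
            statuses[pair.name] = STATUS_AMBIGUOUS
        else:
            statuses[pair.name] = STATUS_UNPLACED
    return PlacementResult(statuses=statuses, hits=hits)
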