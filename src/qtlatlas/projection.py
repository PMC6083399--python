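"""Project QTL records onto physical chromosome intervals.

Each source study reports a QTL by one or two flanking markers.  Once the
markers are placed on the assembly, the QTL is delimited by a uniform window
of ``window_cm`` centimorgans (converted to bp by ``cm_to_bp``) around the
marker span — so a QTL can be located even when only one flanking marker is
available.  The window is applied symmetrically: half upstream of the left
marker midpoint, half downstream of the right one (for a single marker, both
halves around its midpoint).

A QTL whose markers land on different chromosomes, or whose markers are all
ambiguous or unplaced, is reported as a projection failure with a reason
rather than silently dropped.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .errors import InputError, ParameterError
from .placement import STATUS_AMBIGUOUS, STATUS_UNIQUE, PlacementResult

#: the closed trait vocabulary (26 yield and yield-related trait codes)
TRAIT_CODES = (
    "FT", "SW", "PH", "SY", "MT", "SN", "NPB", "PN", "BY", "PY", "SL", "TW",
    "SPUA", "FEBN", "BH", "LMI", "SB", "SID", "ST", "PNMI", "SV", "SD", "BN",
    "DTS", "FBH", "NRV",
)
_TRAIT_SET = frozenset(TRAIT_CODES)

#: default genome-wide physical-per-genetic distance surrogate (bp per cM)
DEFAULT_CM_TO_BP = 500_000
DEFAULT_WINDOW_CM = 1.0

FAIL_NO_PLACED_MARKER = "no_placed_marker"
FAIL_DISCORDANT_CHROMOSOMES = "discordant_chromosomes"
FAIL_AMBIGUOUS_ONLY = "ambiguous_only"


@dataclass(frozen=True)
class QTLRecord:
    """One QTL as reported by a source mapping study."""

    qtl_id: str
    trait: str
    population: str
    country: str  # may carry several labels joined by '+'
    markers: tuple[str, ...]
    source: str = ""

    def __post_init__(self) -> None:
        if self.trait not in _TRAIT_SET:
            raise InputError(
                f"QTL {self.qtl_id!r}: unknown trait code {self.trait!r}"
            )
        if not 1 <= len(self.markers) <= 2:
            raise InputError(
                f"QTL {self.qtl_id!r}: expected 1 or 2 flanking markers, "
                f"got {len(self.markers)}"
            )

    @property
    def countries(self) -> frozenset[str]:
        return frozenset(c.strip() for c in self.country.split("+") if c.strip())


@dataclass(frozen=True)
class QTLInterval:
    """A QTL projected onto the assembly (0-based half-open span)."""

    qtl: QTLRecord
    chrom: str
    start: int
    end: int
    basis: str  # "two_markers" | "one_marker"
    window_bp: int

    @property
    def qtl_id(self) -> str:
        return self.qtl.qtl_id

    @property
    def trait(self) -> str:
        return self.qtl.trait


@dataclass(frozen=True)
class ProjectionFailure:
    qtl_id: str
    reason: str


def project_qtl(
    record: QTLRecord,
    placements: PlacementResult,
    chrom_lengths: Mapping[str, int],
    cm_to_bp: float = DEFAULT_CM_TO_BP,
    window_cm: float = DEFAULT_WINDOW_CM,
) -> QTLInterval | ProjectionFailure:
    """Project one QTL; returns an interval or a failure with a reason.

    Marker positions are amplicon midpoints of *unique* placements only.
    A marker name absent from the placement run altogether is an input error
    (the record references a marker that was never searched), distinct from
    a marker that was searched but could not be placed.
    """
    if cm_to_bp <= 0:
        raise ParameterError("cm_to_bp must be positive")
    if window_cm < 0:
        raise ParameterError("window_cm must be >= 0")
    unknown = [m for m in record.markers if m not in placements.statuses]
    if unknown:
        raise InputError(
            f"QTL {record.qtl_id!r}: marker(s) {unknown} absent from the "
            "marker table"
        )
    usable = [
        placements.hits[m][0]
        for m in record.markers
        if placements.statuses[m] == STATUS_UNIQUE
    ]
    if not usable:
        if any(
            placements.statuses[m] == STATUS_AMBIGUOUS for m in record.markers
        ):
            return ProjectionFailure(record.qtl_id, FAIL_AMBIGUOUS_ONLY)
        return ProjectionFailure(record.qtl_id, FAIL_NO_PLACED_MARKER)
    chroms = {h.chrom for h in usable}
    if len(chroms) > 1:
        return ProjectionFailure(record.qtl_id, FAIL_DISCORDANT_CHROMOSOMES)
    chrom = usable[0].chrom
    mids = sorted(h.midpoint for h in usable)
    window = int(round(window_cm * cm_to_bp))
    start = mids[0] - window // 2
    end = mids[-1] + (window - window // 2)
    basis = "two_markers" if len(usable) == 2 else "one_marker"
    clen = chrom_lengths[chrom]
    start = max(0, start)
    end = min(clen, end)
    if end <= start:  # degenerate zero window around a single marker
        start = max(0, min(mids[0], clen - 1))
        end = start + 1
    return QTLInterval(
        qtl=record, chrom=chrom, start=start, end=end, basis=basis,
        window_bp=window,
    )


@dataclass
class ProjectionReport:
    """Partition of the input into aligned intervals and reasoned failures."""

    aligned: list[QTLInterval]
    failures: list[ProjectionFailure]

    @property
    def n_input(self) -> int:
        return len(self.aligned) + len(self.failures)

    def per_trait_counts(self) -> Counter:
        return Counter(iv.trait for iv in self.aligned)

    def per_population_counts(self) -> Counter:
        return Counter(iv.qtl.population for iv in self.aligned)

    def failure_reasons(self) -> Counter:
        return Counter(f.reason for f in self.failures)


def project_all(
    records: Sequence[QTLRecord] | Iterable[QTLRecord],
    placements: PlacementResult,
    chrom_lengths: Mapping[str, int],
    cm_to_bp: float = DEFAULT_CM_TO_BP,
    window_cm: float = DEFAULT_WINDOW_CM,
) -> ProjectionReport:
    """Project every record; aligned + failed always partitions the input."""
    aligned: list[QTLInterval] = []
    failures: list[ProjectionFailure] = []
    for rec in records:
        out = project_qtl(rec, placements, chrom_lengths, cm_to_bp, window_cm)
        if isinstance(out, QTLInterval):
            aligned.append(out)
        else:
            failures.append(out)
    return ProjectionReport(aligned=aligned, failures=failures)
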