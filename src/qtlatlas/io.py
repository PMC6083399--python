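"""File-format boundary: FASTA, TSV tables, GFF3, BED.

Internal coordinates are 0-based half-open everywhere; GFF3 (1-based closed)
is converted at this boundary.  Output tables are TSV with a leading comment
line recording the tool version and the parameters that produced them.
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__
from .errors import Gff3ParseError, InputError
from .placement import PrimerPair
from .projection import QTLInterval, QTLRecord

# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Mapping[str, str], path: str | os.PathLike) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# TSV plumbing


def _params_comment(params: Mapping[str, object] | None) -> str:
    body = " ".join(f"{k}={v}" for k, v in (params or {}).items())
    return f"# qtl-atlas v{__version__}" + (f" | {body}" if body else "")


def write_tsv(
    df: pd.DataFrame,
    path: str | os.PathLike,
    params: Mapping[str, object] | None = None,
) -> None:
    with open(path, "w") as fh:
        fh.write(_params_comment(params) + "\n")
        df.to_csv(fh, sep="\t", index=False)


def read_tsv(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


# ---------------------------------------------------------------------------
# markers and QTL tables

MARKER_COLUMNS = ("marker", "fwd", "rev", "expected_size")
QTL_COLUMNS = (
    "qtl_id", "trait", "population", "country", "marker_left", "marker_right",
    "source",
)


def read_markers(path: str | os.PathLike) -> list[PrimerPair]:
    df = read_tsv(path)
    missing = set(MARKER_COLUMNS[:3]) - set(df.columns)
    if missing:
        raise InputError(f"marker table lacks column(s) {sorted(missing)}")
    pairs = []
    for row in df.itertuples(index=False):
        size = getattr(row, "expected_size", None)
        size = None if pd.isna(size) else int(size)
        pairs.append(
            PrimerPair(name=str(row.marker), fwd=str(row.fwd), rev=str(row.rev),
                       expected_size=size)
        )
    return pairs


def read_qtls(path: str | os.PathLike) -> list[QTLRecord]:
    df = read_tsv(path)
    missing = set(QTL_COLUMNS) - set(df.columns) - {"marker_right"}
    if missing:
        raise InputError(f"QTL table lacks column(s) {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        markers = [str(row.marker_left)]
        right = getattr(row, "marker_right", None)
        if right is not None and not pd.isna(right) and str(right):
            markers.append(str(right))
        records.append(
            QTLRecord(
                qtl_id=str(row.qtl_id), trait=str(row.trait),
                population=str(row.population), country=str(row.country),
                markers=tuple(markers), source=str(row.source),
            )
        )
    return records


# ---------------------------------------------------------------------------
# GFF3 (1-based closed on disk <-> 0-based half-open in memory)


def write_gff3(genes: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write a gene-level GFF3.  ``genes`` columns: gene_id, chrom, start,
    end (0-based half-open)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        ordered = genes.sort_values(["chrom", "start", "gene_id"])
        for row in ordered.itertuples(index=False):
            fh.write(
                f"{row.chrom}\tqtl-atlas\tgene\t{int(row.start) + 1}\t"
                f"{int(row.end)}\t.\t+\t.\tID={row.gene_id}\n"
            )


def read_gff3_genes(path: str | os.PathLike) -> pd.DataFrame:
    """Gene records from a GFF3 file as (gene_id, chrom, start, end) with
    0-based half-open coordinates.  Malformed lines raise
    :class:`Gff3ParseError` with the offending line number."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise Gff3ParseError(lineno, f"expected 9 fields, got {len(fields)}")
            chrom, _src, ftype, start_s, end_s, _score, _strand, _phase, attrs = fields
            if ftype != "gene":
                continue
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError:
                raise Gff3ParseError(lineno, "non-integer coordinates") from None
            if start1 < 1 or end1 < start1:
                raise Gff3ParseError(lineno, f"invalid span {start1}..{end1}")
            gene_id = None
            for item in attrs.split(";"):
                if item.startswith("ID="):
                    gene_id = item[3:]
                    break
            if not gene_id:
                raise Gff3ParseError(lineno, "gene record without ID attribute")
            rows.append(
                {"gene_id": gene_id, "chrom": chrom, "start": start1 - 1, "end": end1}
            )
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end"])


# ---------------------------------------------------------------------------
# BED and interval tables


def write_intervals_bed(
    intervals: Sequence[QTLInterval], path: str | os.PathLike
) -> None:
    """Aligned QTL intervals as BED6+ (name=qtl_id; extra columns trait,
    population, country, basis)."""
    with open(path, "w") as fh:
        for iv in sorted(intervals, key=lambda v: (v.chrom, v.start, v.qtl_id)):
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.qtl_id}\t0\t.\t"
                f"{iv.trait}\t{iv.qtl.population}\t{iv.qtl.country}\t{iv.basis}\n"
            )


def intervals_frame(intervals: Sequence[QTLInterval]) -> pd.DataFrame:
    rows = [
        {
            "qtl_id": iv.qtl_id, "chrom": iv.chrom, "start": iv.start,
            "end": iv.end, "trait": iv.trait,
            "population": iv.qtl.population, "country": iv.qtl.country,
            "source": iv.qtl.source, "basis": iv.basis,
            "window_bp": iv.window_bp,
        }
        for iv in intervals
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "qtl_id", "chrom", "start", "end", "trait", "population",
            "country", "source", "basis", "window_bp",
        ],
    )


def intervals_from_frame(df: pd.DataFrame) -> list[QTLInterval]:
    """Rebuild projected intervals from the table written by the projection
    stage (the CLI hand-off format)."""
    out = []
    for row in df.itertuples(index=False):
        rec = QTLRecord(
            qtl_id=str(row.qtl_id), trait=str(row.trait),
            population=str(row.population), country=str(row.country),
            markers=("NA",), source=str(row.source),
        )
        out.append(
            QTLInterval(
                qtl=rec, chrom=str(row.chrom), start=int(row.start),
                end=int(row.end), basis=str(row.basis),
                window_bp=int(row.window_bp),
            )
        )
    return out


def write_regions_bed(regions, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for r in regions:
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\t{r.region_id}\t"
                f"{len(r.members)}\t.\t{r.trait}\t{r.env_class}\n"
            )


def regions_frame(regions) -> pd.DataFrame:
    rows = [
        {
            "region_id": r.region_id, "chrom": r.chrom, "trait": r.trait,
            "start": r.start, "end": r.end,
            "core_start": r.core[0] if r.core else "",
            "core_end": r.core[1] if r.core else "",
            "n_members": len(r.members),
            "members": ",".join(r.member_ids),
            "populations": ",".join(sorted(r.populations)),
            "countries": ",".join(sorted(r.countries)),
            "env_class": r.env_class,
        }
        for r in regions
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "region_id", "chrom", "trait", "start", "end", "core_start",
            "core_end", "n_members", "members", "populations", "countries",
            "env_class",
        ],
    )


def loci_frame(loci) -> pd.DataFrame:
    rows = [
        {
            "chrom": l.chrom, "start": l.start, "end": l.end,
            "traits": "/".join(sorted(l.traits)),
            "regions": ",".join(l.region_ids),
        }
        for l in loci
    ]
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "traits", "regions"])


def failures_frame(failures) -> pd.DataFrame:
    return pd.DataFrame(
        [{"qtl_id": f.qtl_id, "reason": f.reason} for f in failures],
        columns=["qtl_id", "reason"],
    )


# ---------------------------------------------------------------------------
# Circos-style plain-text tracks


def write_karyotype(
    chrom_lengths: Mapping[str, int], path: str | os.PathLike
) -> None:
    """Karyotype track: one ``chr`` record per chromosome."""
    with open(path, "w") as fh:
        for i, (chrom, length) in enumerate(sorted(chrom_lengths.items()), 1):
            fh.write(f"chr - {chrom} {chrom} 0 {length} chr{i}\n")


def write_highlight_tracks(
    regions, out_dir: str | os.PathLike
) -> dict[str, str]:
    """One highlight file per trait; every region lands in exactly one."""
    os.makedirs(out_dir, exist_ok=True)
    by_trait: dict[str, list] = {}
    for r in regions:
        by_trait.setdefault(r.trait, []).append(r)
    paths = {}
    for trait in sorted(by_trait):
        path = os.path.join(out_dir, f"highlight_{trait}.txt")
        with open(path, "w") as fh:
            for r in sorted(by_trait[trait], key=lambda r: (r.chrom, r.start)):
                fh.write(f"{r.chrom} {r.start} {r.end} fill_color=trait_{trait.lower()}\n")
        paths[trait] = path
    return paths


def write_text_tracks(
    intervals: Sequence[QTLInterval], out_dir: str | os.PathLike
) -> dict[str, str]:
    """One QTL-label text track per population."""
    os.makedirs(out_dir, exist_ok=True)
    by_pop: dict[str, list[QTLInterval]] = {}
    for iv in intervals:
        by_pop.setdefault(iv.qtl.population, []).append(iv)
    paths = {}
    for pop in sorted(by_pop):
        safe = "".join(ch if ch.isalnum() else "_" for ch in pop)
        path = os.path.join(out_dir, f"text_{safe}.txt")
        with open(path, "w") as fh:
            for iv in sorted(by_pop[pop], key=lambda v: (v.chrom, v.start)):
                fh.write(f"{iv.chrom} {iv.start} {iv.end} {iv.qtl_id}\n")
        paths[pop] = path
    return paths
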