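"""End-to-end orchestration: place → project → overlaps → candidates → network.

:func:`analyze` runs the whole analysis on in-memory objects and returns
every stage's result; :func:`run_pipeline` wraps it with file I/O, writing
all tables, track files and a manifest (input checksums, parameters,
per-stage counts).  The pipeline is a pure function of (inputs,
configuration): re-running the same configuration reproduces every output
byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import pandas as pd
import yaml

from . import __version__, io as qio
from .atlas import (
    AtlasSummary,
    MultiTraitLocus,
    OverlapRegion,
    detect_multitrait_loci,
    detect_overlap_regions,
    summarize_atlas,
)
from .candidates import (
    CandidateGene,
    CandidateSummary,
    MappedHomologs,
    candidates_frame,
    find_candidates,
    map_homologs,
    summarize_candidates,
)
from .errors import InputError, ParameterError
from .network import (
    DEFAULT_DL_MIN,
    DEFAULT_SCORE_MIN,
    ClusterSummary,
    build_graph,
    cluster_summary,
    graph_tables,
    influential_genes,
)
from .placement import PlacementParams, PlacementResult, PrimerPair, place_markers
from .projection import (
    DEFAULT_CM_TO_BP,
    DEFAULT_WINDOW_CM,
    ProjectionReport,
    QTLRecord,
    project_all,
)


@dataclass
class AnalysisResult:
    """Every stage's output for one full analysis run."""

    placement: PlacementResult
    projection: ProjectionReport
    regions: list[OverlapRegion]
    loci: list[MultiTraitLocus]
    atlas_summary: AtlasSummary
    mapped_homologs: MappedHomologs
    candidates: list[CandidateGene]
    candidate_summary: CandidateSummary
    graph: nx.Graph
    influential: list[tuple[str, int]]
    clusters: ClusterSummary

    def counts(self) -> dict[str, int]:
        """The manifest count block."""
        out = {f"markers_{k}": v for k, v in self.placement.counts().items()}
        out.update(
            markers_total=len(self.placement.statuses),
            qtls_input=self.projection.n_input,
            qtls_aligned=len(self.projection.aligned),
            qtls_failed=len(self.projection.failures),
            overlap_regions=len(self.regions),
            fixed_qtls=self.atlas_summary.totals["fixed_qtls"],
            specified_qtls=self.atlas_summary.totals["specified_qtls"],
            env_fixed_regions=self.atlas_summary.totals["env_fixed_regions"],
            mixed_regions=self.atlas_summary.totals["mixed_regions"],
            multitrait_loci=len(self.loci),
            homolog_genes=self.mapped_homologs.n_positioned
            + self.mapped_homologs.n_unplaced,
            homologs_positioned=self.mapped_homologs.n_positioned,
            homologs_unplaced=self.mapped_homologs.n_unplaced,
            candidate_genes=len(self.candidates),
            regions_with_candidates=self.candidate_summary.regions_with_candidates,
            qtls_in_candidate_regions=self.candidate_summary.qtls_in_candidate_regions,
            network_nodes=self.graph.number_of_nodes(),
            network_edges=self.graph.number_of_edges(),
            influential_genes=len(self.influential),
        )
        return out


def analyze(
    genome: Mapping[str, str],
    markers: Sequence[PrimerPair],
    records: Sequence[QTLRecord],
    genes: pd.DataFrame,
    homologs: pd.DataFrame,
    edges: pd.DataFrame,
    categories: Mapping[str, str],
    placement_params: PlacementParams = PlacementParams(),
    cm_to_bp: float = DEFAULT_CM_TO_BP,
    window_cm: float = DEFAULT_WINDOW_CM,
    score_min: float = DEFAULT_SCORE_MIN,
    dl_min: int = DEFAULT_DL_MIN,
) -> AnalysisResult:
    """Run all five stages on in-memory inputs.

    The network whitelist is derived from the analysis itself: the
    A. thaliana source genes of the discovered candidates.
    """
    placement = place_markers(genome, markers, placement_params)
    chrom_lengths = {c: len(s) for c, s in genome.items()}
    report = project_all(records, placement, chrom_lengths, cm_to_bp, window_cm)
    regions = detect_overlap_regions(report.aligned)
    loci = detect_multitrait_loci(regions)
    summary = summarize_atlas(regions, loci, report.aligned)
    mapped = map_homologs(homologs, genes)
    cands = find_candidates(regions, mapped.positioned)
    csum = summarize_candidates(cands, regions)
    whitelist = sorted({at for c in cands for at in c.at_source})
    G = build_graph(edges, whitelist, score_min)
    hubs = influential_genes(G, dl_min)
    clusters = cluster_summary(G, categories)
    return AnalysisResult(
        placement=placement, projection=report, regions=regions, loci=loci,
        atlas_summary=summary, mapped_homologs=mapped, candidates=cands,
        candidate_summary=csum, graph=G, influential=hubs, clusters=clusters,
    )


def analyze_study(study, dl_min: int | None = None) -> AnalysisResult:
    """Run :func:`analyze` on a :class:`~qtlatlas.synthetic.SyntheticStudy`,
    taking every parameter from the study's own configuration (the
    generator-matched policy)."""
    cfg = study.config
    markers = [
        PrimerPair(str(r.marker), str(r.fwd), str(r.rev), int(r.expected_size))
        for r in study.markers.itertuples(index=False)
    ]
    records = [
        QTLRecord(
            qtl_id=str(r.qtl_id), trait=str(r.trait),
            population=str(r.population), country=str(r.country),
            markers=tuple(m for m in (str(r.marker_left), str(r.marker_right)) if m),
            source=str(r.source),
        )
        for r in study.qtls.itertuples(index=False)
    ]
    categories = dict(
        zip(study.categories["gene"].astype(str), study.categories["category"].astype(str))
    )
    return analyze(
        study.genome, markers, records, study.genes, study.homologs,
        study.edges, categories,
        cm_to_bp=cfg.cm_to_bp, window_cm=cfg.window_cm,
        score_min=cfg.score_min,
        dl_min=cfg.dl_min if dl_min is None else dl_min,
    )


# ---------------------------------------------------------------------------
# file-based pipeline


@dataclass
class PipelineConfig:
    """Paths and parameters for one pipeline run."""

    genome: str
    markers: str
    qtls: str
    gff3: str
    homologs: str
    edges: str
    categories: str
    out_dir: str
    cm_to_bp: float = DEFAULT_CM_TO_BP
    window_cm: float = DEFAULT_WINDOW_CM
    placement: PlacementParams = field(default_factory=PlacementParams)
    score_min: float = DEFAULT_SCORE_MIN
    dl_min: int = DEFAULT_DL_MIN
    seed: int = 0

    _INPUT_KEYS = ("genome", "markers", "qtls", "gff3", "homologs", "edges", "categories")

    def validate(self) -> None:
        for key in self._INPUT_KEYS:
            path = getattr(self, key)
            if not os.path.isfile(path):
                raise InputError(f"input file for {key!r} not found: {path}")
        if self.cm_to_bp <= 0 or self.window_cm < 0:
            raise ParameterError("cm_to_bp must be > 0 and window_cm >= 0")
        if self.dl_min < 0:
            raise ParameterError("dl_min must be >= 0")

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        placement = PlacementParams(**raw.pop("placement", {}))
        return cls(placement=placement, **raw)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage(name: str, fn):
    try:
        return fn()
    except Exception as exc:
        exc.args = (f"[stage {name}] {exc}",)
        raise


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage from files, write all outputs, return the manifest.

    Aborts before writing anything when an input path is missing; a data
    problem inside a stage propagates with the stage name attached.
    """
    config.validate()

    genome = _stage("place", lambda: qio.read_fasta(config.genome))
    markers = _stage("place", lambda: qio.read_markers(config.markers))
    records = _stage("project", lambda: qio.read_qtls(config.qtls))
    genes = _stage("candidates", lambda: qio.read_gff3_genes(config.gff3))
    homologs = _stage("candidates", lambda: qio.read_tsv(config.homologs))
    edges = _stage("network", lambda: qio.read_tsv(config.edges))
    cat_df = _stage("network", lambda: qio.read_tsv(config.categories))
    categories = dict(zip(cat_df["gene"].astype(str), cat_df["category"].astype(str)))

    result = analyze(
        genome, markers, records, genes, homologs, edges, categories,
        placement_params=config.placement, cm_to_bp=config.cm_to_bp,
        window_cm=config.window_cm, score_min=config.score_min,
        dl_min=config.dl_min,
    )

    os.makedirs(config.out_dir, exist_ok=True)
    out = lambda name: os.path.join(config.out_dir, name)  # noqa: E731
    pp = {"cm_to_bp": config.cm_to_bp, "window_cm": config.window_cm}

    qio.write_tsv(result.placement.hits_table(), out("hits.tsv"), pp)
    qio.write_tsv(result.placement.diagnostics(), out("placement_diagnostics.tsv"), pp)
    with open(out("unique_placements.bed"), "w") as fh:
        for m, h in sorted(result.placement.unique.items()):
            fh.write(f"{h.chrom}\t{h.start}\t{h.end}\t{m}\t0\t+\n")

    qio.write_tsv(qio.intervals_frame(result.projection.aligned), out("aligned.tsv"), pp)
    qio.write_intervals_bed(result.projection.aligned, out("aligned.bed"))
    qio.write_tsv(qio.failures_frame(result.projection.failures), out("failures.tsv"), pp)

    qio.write_tsv(qio.regions_frame(result.regions), out("regions.tsv"), pp)
    qio.write_regions_bed(result.regions, out("regions.bed"))
    qio.write_tsv(qio.loci_frame(result.loci), out("multitrait_loci.tsv"), pp)
    for name, frame in result.atlas_summary.to_frames().items():
        qio.write_tsv(frame, out(f"summary_{name}.tsv"), pp)

    qio.write_tsv(candidates_frame(result.candidates), out("candidates.tsv"), pp)
    qio.write_tsv(result.mapped_homologs.unplaced, out("unplaced_homologs.tsv"), pp)
    qio.write_tsv(
        result.candidate_summary.per_trait_combination.rename("n_candidates")
        .rename_axis("traits").reset_index(),
        out("candidates_per_trait.tsv"), pp,
    )

    nodes_df, edges_df = graph_tables(result.graph, categories)
    qio.write_tsv(nodes_df, out("network_nodes.tsv"), pp)
    qio.write_tsv(edges_df, out("network_edges.tsv"), pp)
    hub_names = [g for g, _ in result.influential]
    qio.write_tsv(
        nodes_df[nodes_df["gene"].isin(hub_names)]
        .sort_values(["degree", "gene"], ascending=[False, True])
        .reset_index(drop=True),
        out("influential_genes.tsv"), pp,
    )

    chrom_lengths = {c: len(s) for c, s in genome.items()}
    export_figure_tracks(
        chrom_lengths, result.regions, result.projection.aligned, out("tracks")
    )

    manifest = {
        "tool": f"qtl-atlas v{__version__}",
        "inputs": {k: _sha256(getattr(config, k)) for k in config._INPUT_KEYS},
        "params": {
            "cm_to_bp": config.cm_to_bp,
            "window_cm": config.window_cm,
            "placement": dataclasses.asdict(config.placement),
            "score_min": config.score_min,
            "dl_min": config.dl_min,
            "seed": config.seed,
        },
        "counts": result.counts(),
    }
    with open(out("manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


def export_figure_tracks(chrom_lengths, regions, intervals, out_dir) -> dict:
    """Circular-plot text tracks: karyotype, per-trait region highlights,
    per-population QTL label tracks."""
    os.makedirs(out_dir, exist_ok=True)
    qio.write_karyotype(chrom_lengths, os.path.join(out_dir, "karyotype.txt"))
    highlights = qio.write_highlight_tracks(regions, out_dir)
    texts = qio.write_text_tracks(intervals, out_dir)
    return {"karyotype": os.path.join(out_dir, "karyotype.txt"),
            "highlights": highlights, "texts": texts}
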