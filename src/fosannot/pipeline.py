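"""End-to-end annotation pipeline and report bundle.

One insert at a time: cluster homology hits into gene sites, infer
codons, categorize, flag truncations, tier ESTs and classify coverage,
add EST-only sites, build gene models where the evidence permits, scan
SSRs and merge operational loci, and detect tandem duplications and
microsynteny. Study level: an insert inventory, a per-model
reconciliation table, an SSR summary, and the density summary. Every
output is deterministic given the inputs; per-insert failures are
recorded and do not halt the run.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, field
from typing import Optional, Sequence

import pandas as pd
import yaml

from . import __version__
from .densities import DensitySummary, build_density_summary
from .est_support import (
    GeneModel,
    IncompleteEvidenceError,
    SpliceConflictError,
    TierParams,
    build_gene_model,
    classify_coverage,
    find_est_only_sites,
    intron_stats,
    tier_est,
)
from .gene_inference import (
    EvidenceParams,
    categorize_site,
    cluster_hits_to_sites,
    detect_tandem_duplicates,
    flag_truncation,
    infer_start_stop,
)
from .microsynteny import (
    ReferenceGeneOrder,
    SyntenyPair,
    detect_synteny,
    pairs_to_frame,
)
from .prediction_compare import (
    ReconciliationReport,
    reports_to_frame,
    summarize_models,
)
from .records import ESTAlignment, FosmidRecord, GeneSite, HomologyHit, PredictionTrack
from .sequence_io import read_blast_tab, read_fasta, read_gff_track
from .ssr import (
    GenomeContext,
    SSRLocus,
    SSRScanParams,
    SSRSummary,
    SSRTract,
    merge_operational_loci,
    scan_ssrs,
    summarize_ssrs,
    tracts_to_frame,
)


@dataclass
class PipelineParams:
    evidence: EvidenceParams = field(default_factory=EvidenceParams)
    ssr: SSRScanParams = field(default_factory=SSRScanParams)
    tiers: TierParams = field(default_factory=TierParams)
    genome_size_bp: int = 206_000_000
    map_length_cM: float = 424.0
    synteny_max_step: int = 3
    synteny_max_intervening: int = 2
    tandem_max_intervening: int = 1


@dataclass
class InsertAnnotation:
    """All per-insert stage outputs (the five-panel structure, tabular)."""

    record: FosmidRecord
    sites: list[GeneSite]  # homology sites then EST-only sites
    tracts: list[SSRTract]
    loci: list[SSRLocus]
    coverage: dict[str, str]  # site_id -> complete | partial | none
    models: dict[str, GeneModel]
    model_errors: dict[str, str]
    tandem_pairs: list[tuple[GeneSite, GeneSite, str]]
    synteny_pairs: list[SyntenyPair]
    ests: list[ESTAlignment]

    @property
    def homology_sites(self) -> list[GeneSite]:
        return [s for s in self.sites if s.category != "est_only"]


@dataclass
class StudyResult:
    annotations: dict[str, InsertAnnotation]
    reports: list[ReconciliationReport]
    ssr_summary: SSRSummary
    density: DensitySummary
    errors: dict[str, str] = field(default_factory=dict)

    def sites_by_insert(self) -> dict[str, list[GeneSite]]:
        return {iid: a.sites for iid, a in self.annotations.items()}


def annotate_insert(
    record: FosmidRecord,
    hits: Sequence[HomologyHit],
    ests: Sequence[ESTAlignment],
    tracks: Sequence[PredictionTrack],
    probes: Sequence[tuple[str, str]] = (),
    params: Optional[PipelineParams] = None,
    locus_map: Optional[dict[str, str]] = None,
    reference_order: Optional[ReferenceGeneOrder] = None,
) -> InsertAnnotation:
    """Annotate one insert from its evidence files."""
    params = params or PipelineParams()
    insert_id = record.insert_id
    sites = cluster_hits_to_sites(hits, params.evidence, insert_id=insert_id)
    for site in sites:
        infer_start_stop(site, record, ests, params.tiers.top_tier_min)
        site.category = categorize_site(
            site, probes, te_keywords=params.evidence.te_keywords
        )
        flag_truncation(site, record, params=params.evidence)
        if locus_map and site.best_subject:
            site.best_locus = locus_map.get(site.best_subject.subject_id)

    est_only = find_est_only_sites(
        ests,
        sites,
        tracks,
        insert_id,
        insert_length=record.frame_length,
        params=params.tiers,
        boundary_margin=params.evidence.boundary_margin,
    )

    top_ests = [e for e in ests if tier_est(e, params.tiers) == "top"]
    coverage: dict[str, str] = {}
    models: dict[str, GeneModel] = {}
    model_errors: dict[str, str] = {}
    for site in sites:
        if site.start_codon is not None and site.stop_codon is not None:
            if site.strand == "+":
                extent = (site.start_codon, site.stop_codon + 2)
            else:
                extent = (site.stop_codon - 2, site.start_codon)
        else:
            extent = (site.start, site.end)
        coverage[site.site_id] = classify_coverage(site, extent, top_ests)
        if (
            coverage[site.site_id] == "complete"
            and site.start_codon is not None
            and site.stop_codon is not None
            and site.category != "te_related"
        ):
            try:
                models[site.site_id] = build_gene_model(site, ests, params.tiers)
            except (IncompleteEvidenceError, SpliceConflictError) as exc:
                model_errors[site.site_id] = str(exc)

    tracts = scan_ssrs(record.sequence, params.ssr, insert_id=insert_id)
    loci = merge_operational_loci(tracts, params.ssr.merge_gap)

    tandem = detect_tandem_duplicates(
        sites, max_intervening=params.tandem_max_intervening
    )
    synteny_sites = [s for s in sites if s.best_locus]
    synteny = (
        detect_synteny(
            sites,
            order=reference_order,
            max_step=params.synteny_max_step,
            max_intervening=params.synteny_max_intervening,
        )
        if synteny_sites
        else []
    )
    return InsertAnnotation(
        record=record,
        sites=sites + est_only,
        tracts=tracts,
        loci=loci,
        coverage=coverage,
        models=models,
        model_errors=model_errors,
        tandem_pairs=tandem,
        synteny_pairs=synteny,
        ests=list(ests),
    )


def run_study(
    records: Sequence[FosmidRecord],
    hits: dict[str, list[HomologyHit]],
    tracks: Sequence[PredictionTrack],
    ests: dict[str, list[ESTAlignment]],
    probes: Sequence[tuple[str, str]] = (),
    params: Optional[PipelineParams] = None,
    locus_map: Optional[dict[str, str]] = None,
    reference_order: Optional[ReferenceGeneOrder] = None,
) -> StudyResult:
    """Run every stage over a set of inserts and assemble study tables.

    A failing insert is recorded under ``errors`` (keyed by insert id and
    stage) and the remaining inserts are still processed.
    """
    params = params or PipelineParams()
    annotations: dict[str, InsertAnnotation] = {}
    errors: dict[str, str] = {}
    for record in records:
        try:
            annotations[record.insert_id] = annotate_insert(
                record,
                hits.get(record.insert_id, []),
                ests.get(record.insert_id, []),
                tracks,
                probes=probes,
                params=params,
                locus_map=locus_map,
                reference_order=reference_order,
            )
        except Exception as exc:  # keep going; report per-insert failure
            errors[record.insert_id] = f"annotate: {exc}"
    good_records = [r for r in records if r.insert_id in annotations]
    total_bp = sum(r.total_length for r in good_records)
    ctx = GenomeContext(
        total_analyzed_bp=total_bp,
        genome_size_bp=params.genome_size_bp,
        map_length_cM=params.map_length_cM,
    )
    all_tracts = [t for a in annotations.values() for t in a.tracts]
    all_loci = [l for a in annotations.values() for l in a.loci]
    ssr_summary = summarize_ssrs(all_tracts, all_loci, ctx)
    sites_by_insert = {iid: a.sites for iid, a in annotations.items()}
    reports = (
        summarize_models(tracks, sites_by_insert) if tracks else []
    )
    density = build_density_summary(
        sites_by_insert, ssr_summary, ctx, records=good_records
    )
    return StudyResult(
        annotations=annotations,
        reports=reports,
        ssr_summary=ssr_summary,
        density=density,
        errors=errors,
    )


# ------------------------------------------------------------- reporting


def sites_to_frame(annotation: InsertAnnotation) -> pd.DataFrame:
    rows = []
    for s in annotation.sites:
        rows.append(
            {
                "site_id": s.site_id,
                "insert_id": s.insert_id,
                "start": s.start,
                "end": s.end,
                "strand": s.strand,
                "category": s.category,
                "tier": s.confidence_tier or "",
                "start_codon": s.start_codon if s.start_codon is not None else "",
                "stop_codon": s.stop_codon if s.stop_codon is not None else "",
                "truncation": ",".join(sorted(s.truncation)),
                "best_subject": s.best_subject.subject_id if s.best_subject else "",
                "e_value": s.best_subject.e_value if s.best_subject else "",
                "description": s.best_subject.description if s.best_subject else "",
                "coverage": annotation.coverage.get(s.site_id, ""),
                "best_locus": s.best_locus or "",
            }
        )
    return pd.DataFrame(rows)


def write_report_bundle(
    result: StudyResult,
    outdir: str,
    manifest_extra: Optional[dict] = None,
) -> None:
    """Write the per-insert summaries and study tables under ``outdir``.

    Fixed file names; re-running on identical inputs reproduces identical
    bytes. A machine-readable manifest records inputs and parameters.
    """
    os.makedirs(outdir, exist_ok=True)
    inventory = pd.DataFrame(
        [
            {
                "insert_id": a.record.insert_id,
                "accession": a.record.accession or "",
                "insert_length_bp": a.record.total_length,
                "n_contigs": len(a.record.contigs),
                "n_gene_sites": len(a.homology_sites),
                "n_est_only_sites": len(a.sites) - len(a.homology_sites),
                "n_ssr_tracts": len(a.tracts),
                "n_ssr_loci": len(a.loci),
            }
            for a in result.annotations.values()
        ]
    )
    inventory.to_csv(os.path.join(outdir, "inventory.tsv"), sep="\t", index=False)

    if result.reports:
        reports_to_frame(result.reports).to_csv(
            os.path.join(outdir, "reconciliation.tsv"), sep="\t", index=False
        )

    result.ssr_summary.per_class.to_csv(
        os.path.join(outdir, "ssr_classes.tsv"), sep="\t", index=False
    )
    result.ssr_summary.per_unit_length.to_csv(
        os.path.join(outdir, "ssr_unit_lengths.tsv"), sep="\t", index=False
    )
    with open(os.path.join(outdir, "density_summary.json"), "w") as fh:
        fh.write(result.density.to_json() + "\n")

    all_sites = pd.concat(
        [sites_to_frame(a) for a in result.annotations.values()],
        ignore_index=True,
    )
    all_sites.to_csv(os.path.join(outdir, "gene_sites.tsv"), sep="\t", index=False)

    all_tracts = pd.concat(
        [
            tracts_to_frame(a.tracts, a.loci)
            for a in result.annotations.values()
        ],
        ignore_index=True,
    )
    all_tracts.to_csv(os.path.join(outdir, "ssr_tracts.tsv"), sep="\t", index=False)

    synteny_frames = [
        pairs_to_frame(a.synteny_pairs)
        for a in result.annotations.values()
        if a.synteny_pairs
    ]
    if synteny_frames:
        pd.concat(synteny_frames, ignore_index=True).to_csv(
            os.path.join(outdir, "synteny.tsv"), sep="\t", index=False
        )

    models_rows = []
    for a in result.annotations.values():
        for site_id, m in a.models.items():
            models_rows.append(
                {
                    "site_id": site_id,
                    "cds_start": m.cds_start,
                    "cds_end": m.cds_end,
                    "n_exons": len(m.exons),
                    "n_introns": m.intron_count,
                    "exons": ";".join(f"{s}-{e}" for s, e in m.exons),
                    "introns": ";".join(f"{s}-{e}" for s, e in m.introns),
                }
            )
    pd.DataFrame(
        models_rows,
        columns=[
            "site_id",
            "cds_start",
            "cds_end",
            "n_exons",
            "n_introns",
            "exons",
            "introns",
        ],
    ).to_csv(os.path.join(outdir, "gene_models.tsv"), sep="\t", index=False)

    all_models = [m for a in result.annotations.values() for m in a.models.values()]
    if all_models:
        stats = intron_stats(all_models)
        with open(os.path.join(outdir, "intron_stats.json"), "w") as fh:
            json.dump(asdict(stats), fh, indent=2)
            fh.write("\n")

    # per-insert five-panel neighborhood summaries
    insert_dir = os.path.join(outdir, "inserts")
    os.makedirs(insert_dir, exist_ok=True)
    for iid, a in sorted(result.annotations.items()):
        lines = [f"# Neighborhood summary for insert {iid}", ""]
        lines.append("## A. Ab initio prediction tracks")
        lines.append("(see reconciliation.tsv for per-model totals)")
        lines.append("")
        lines.append("## B. Homology hits -> gene sites")
        for s in a.homology_sites:
            lines.append(
                f"{s.site_id}\t{s.start}-{s.end}\t{s.strand}\t{s.category}\t"
                f"{s.confidence_tier}\t{s.best_subject.subject_id if s.best_subject else ''}"
            )
        lines.append("")
        lines.append("## C. EST support")
        for e in sorted(a.ests, key=lambda e: (e.start, e.est_id)):
            lines.append(
                f"{e.est_id}\t{e.start}-{e.end}\t{e.pct_identity:.1f}\t"
                f"{tier_est(e)}"
            )
        lines.append("")
        lines.append("## D. Annotated sites (with EST-only)")
        for s in a.sites:
            lines.append(
                f"{s.site_id}\t{s.start}-{s.end}\t{s.strand}\t{s.category}\t"
                f"coverage={a.coverage.get(s.site_id, 'n/a')}"
            )
        lines.append("")
        lines.append("## E. SSR loci")
        for li, locus in enumerate(a.loci, start=1):
            motifs = ",".join(
                f"({t.motif}){t.repeat_count}" for t in locus.tracts
            )
            lines.append(f"L{li}\t{locus.start}-{locus.end}\t{motifs}")
        lines.append("")
        with open(os.path.join(insert_dir, f"{iid}.txt"), "w") as fh:
            fh.write("\n".join(lines))

    manifest = {
        "tool": "fosannot",
        "version": __version__,
        "n_inserts": len(result.annotations),
        "errors": result.errors,
    }
    if manifest_extra:
        manifest.update(manifest_extra)
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")


# -------------------------------------------------------- file-based run


def load_config(path: str) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("pipeline config must be a YAML mapping")
    return cfg


def run_pipeline(config: dict, outdir: str) -> StudyResult:
    """Run the pipeline from a file-based configuration.

    Expected keys: ``inserts`` (list of {id, fasta, accession?}; a
    multi-record FASTA is treated as ordered contigs), ``hits`` (combined
    12(+1)-column tabular file, query id = insert id), ``ests`` (GFF3),
    ``tracks`` (list of {model, gff}), optional ``probes`` (list of
    {name, pattern}), ``locus_map`` (TSV: subject, locus),
    ``reference_order`` (TSV: locus, chromosome, rank), ``gap_pad``, and
    parameter overrides under ``params``.
    """
    gap_pad = int(config.get("gap_pad", 100))
    records = []
    for entry in config["inserts"]:
        contigs = read_fasta(entry["fasta"])
        rec = FosmidRecord(
            insert_id=entry["id"],
            contigs=contigs,
            accession=entry.get("accession"),
            gap_pad=gap_pad,
        )
        records.append(rec)

    hits_by_insert: dict[str, list[HomologyHit]] = {r.insert_id: [] for r in records}
    if config.get("hits"):
        for hit in read_blast_tab(config["hits"]):
            hits_by_insert.setdefault(hit.query_id, []).append(hit)

    ests_by_insert: dict[str, list[ESTAlignment]] = {}
    if config.get("ests"):
        for est in read_gff_track(config["ests"], kind="est"):
            ests_by_insert.setdefault(est.insert_id, []).append(est)

    tracks = []
    for entry in config.get("tracks", []):
        track = read_gff_track(
            entry["gff"], kind="prediction", model_name=entry["model"]
        )
        tracks.append(track)

    probes = [
        (p["name"], p.get("pattern", p["name"]))
        for p in config.get("probes", [])
    ]
    locus_map = None
    if config.get("locus_map"):
        df = pd.read_csv(config["locus_map"], sep="\t")
        locus_map = dict(zip(df["subject"], df["locus"]))
    reference_order = None
    if config.get("reference_order"):
        reference_order = ReferenceGeneOrder.from_table(config["reference_order"])

    params = PipelineParams()
    overrides = config.get("params", {})
    if "evidence" in overrides:
        params.evidence = EvidenceParams(**overrides["evidence"])
    if "ssr" in overrides:
        params.ssr = SSRScanParams(**overrides["ssr"])
    if "tiers" in overrides:
        params.tiers = TierParams(**overrides["tiers"])
    for key in ("genome_size_bp", "map_length_cM", "synteny_max_step",
                "synteny_max_intervening", "tandem_max_intervening"):
        if key in overrides:
            setattr(params, key, overrides[key])

    result = run_study(
        records,
        hits_by_insert,
        tracks,
        ests_by_insert,
        probes=probes,
        params=params,
        locus_map=locus_map,
        reference_order=reference_order,
    )
    write_report_bundle(result, outdir, manifest_extra={"config": config})
    return result
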