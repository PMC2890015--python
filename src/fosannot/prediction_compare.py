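"""Reconciliation of ab initio prediction tracks against evidence-based
gene sites.

Each predicted gene is matched to the gene sites it overlaps on the same
strand (>= ``min_overlap`` bp, default 1). A prediction overlapping no
site is *unsupported*; one spanning two or more distinct sites is a *gene
merger* (the classic under-prediction failure); two or more predictions
tiling one site constitute a *split*. Predicted translation starts/stops
are *validated* when they coincide exactly with the homology-inferred
codon of an overlapped site. EST-only sites count as support but, like
TE-related sites by default, are not tallied in mergers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .records import GeneSite, PredictedGene, PredictionTrack


@dataclass
class ReconciliationReport:
    """Per-model reconciliation counts."""

    model_name: str
    predicted_genes: int
    unsupported: int
    mergers: int
    genes_merged: int
    splits: int
    validated_starts: int
    validated_stops: int

    @property
    def validated_total(self) -> int:
        return self.validated_starts + self.validated_stops


@dataclass
class Assignment:
    """Overlap maps and per-prediction classifications for one insert."""

    prediction_sites: dict[str, list[str]]  # gene_id -> overlapped site ids
    site_predictions: dict[str, list[str]]  # site_id -> overlapping gene ids
    classification: dict[str, str]  # gene_id -> unsupported|merger|split|simple
    mergers: list[tuple[str, tuple[str, ...]]]  # (gene_id, merged site ids)
    splits: list[tuple[str, tuple[str, ...]]]  # (site_id, prediction ids)


def _overlap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    return max(0, min(a_end, b_end) - max(a_start, b_start) + 1)


def assign_predictions(
    predictions: Sequence[PredictedGene],
    sites: Sequence[GeneSite],
    min_overlap: int = 1,
    insert_length: Optional[int] = None,
    count_te_in_mergers: bool = False,
) -> Assignment:
    """Match one insert's predictions to its gene sites.

    Support requires same-strand overlap of at least ``min_overlap`` bp.
    Merger takes precedence over split when both patterns touch the same
    prediction. Merger tallies count only non-TE, non-EST-only sites
    unless ``count_te_in_mergers`` is set; EST-only sites still provide
    support against the *unsupported* classification.
    """
    if insert_length is not None:
        for g in predictions:
            if g.end > insert_length or g.start < 1:
                raise ValueError(
                    f"prediction {g.gene_id} at {g.start}-{g.end} lies outside "
                    f"the insert coordinate frame (length {insert_length})"
                )
    pred_sites: dict[str, list[str]] = {g.gene_id: [] for g in predictions}
    site_preds: dict[str, list[str]] = {s.site_id: [] for s in sites}
    for g in predictions:
        for s in sites:
            if g.strand != s.strand:
                continue
            if _overlap(g.start, g.end, s.start, s.end) >= min_overlap:
                pred_sites[g.gene_id].append(s.site_id)
                site_preds[s.site_id].append(g.gene_id)

    site_by_id = {s.site_id: s for s in sites}

    def merger_eligible(site_id: str) -> bool:
        cat = site_by_id[site_id].category
        if cat == "est_only":
            return False
        if cat == "te_related" and not count_te_in_mergers:
            return False
        return True

    classification: dict[str, str] = {}
    mergers: list[tuple[str, tuple[str, ...]]] = []
    for g in predictions:
        overlapped = pred_sites[g.gene_id]
        if not overlapped:
            classification[g.gene_id] = "unsupported"
            continue
        eligible = [sid for sid in overlapped if merger_eligible(sid)]
        if len(eligible) >= 2:
            classification[g.gene_id] = "merger"
            mergers.append((g.gene_id, tuple(eligible)))
            continue
        if any(len(site_preds[sid]) >= 2 for sid in overlapped):
            classification[g.gene_id] = "split"
        else:
            classification[g.gene_id] = "simple"

    splits = []
    for s in sites:
        preds = site_preds[s.site_id]
        # a site carved up by >=2 predictions that are not themselves mergers
        carvers = [p for p in preds if classification.get(p) != "merger"]
        if len(carvers) >= 2:
            splits.append((s.site_id, tuple(carvers)))

    return Assignment(
        prediction_sites=pred_sites,
        site_predictions=site_preds,
        classification=classification,
        mergers=mergers,
        splits=splits,
    )


def validate_codons(
    predictions: Sequence[PredictedGene],
    sites: Sequence[GeneSite],
    tolerance: int = 0,
) -> tuple[int, int]:
    """Count homology-inferred start/stop codons matched exactly by an
    overlapping same-strand prediction.

    Counting is per *site* (a site's codon is validated by at least one
    prediction), so a split cannot double-count one codon. Sites with
    undetermined codons contribute nothing.
    """
    starts = stops = 0
    for s in sites:
        overlapping = [
            g
            for g in predictions
            if g.strand == s.strand and _overlap(g.start, g.end, s.start, s.end) > 0
        ]
        if s.start_codon is not None and any(
            g.predicted_start_codon is not None
            and abs(g.predicted_start_codon - s.start_codon) <= tolerance
            for g in overlapping
        ):
            starts += 1
        if s.stop_codon is not None and any(
            g.predicted_stop_codon is not None
            and abs(g.predicted_stop_codon - s.stop_codon) <= tolerance
            for g in overlapping
        ):
            stops += 1
    return starts, stops


def summarize_models(
    tracks: Sequence[PredictionTrack],
    sites_by_insert: dict[str, list[GeneSite]],
    min_overlap: int = 1,
    count_te_in_mergers: bool = False,
) -> list[ReconciliationReport]:
    """One reconciliation report per model, in the given track order."""
    if not tracks:
        raise ValueError("need at least one prediction track")
    reports = []
    for track in tracks:
        unsupported = mergers = genes_merged = splits = 0
        starts = stops = 0
        predicted = 0
        insert_ids = sorted(set(track.genes) | set(sites_by_insert))
        for insert_id in insert_ids:
            preds = track.for_insert(insert_id)
            sites = sites_by_insert.get(insert_id, [])
            predicted += len(preds)
            assignment = assign_predictions(
                preds,
                sites,
                min_overlap=min_overlap,
                count_te_in_mergers=count_te_in_mergers,
            )
            unsupported += sum(
                1 for v in assignment.classification.values() if v == "unsupported"
            )
            mergers += len(assignment.mergers)
            genes_merged += sum(len(sids) for _, sids in assignment.mergers)
            splits += len(assignment.splits)
            st, sp = validate_codons(preds, sites)
            starts += st
            stops += sp
        reports.append(
            ReconciliationReport(
                model_name=track.model_name,
                predicted_genes=predicted,
                unsupported=unsupported,
                mergers=mergers,
                genes_merged=genes_merged,
                splits=splits,
                validated_starts=starts,
                validated_stops=stops,
            )
        )
    return reports


def reports_to_frame(reports: Sequence[ReconciliationReport]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "model": r.model_name,
                "predicted_genes": r.predicted_genes,
                "unsupported_predictions": r.unsupported,
                "gene_mergers": r.mergers,
                "genes_merged": r.genes_merged,
                "splits": r.splits,
                "validated_starts": r.validated_starts,
                "validated_stops": r.validated_stops,
                "validated_starts_plus_stops": r.validated_total,
            }
            for r in reports
        ]
    )
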