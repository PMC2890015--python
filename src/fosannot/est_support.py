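"""EST support tiering, coverage classification, and gene-model building.

EST-to-genomic matches are tiered by percent identity: *top-tier* at >= 95%
(strong evidence the locus is transcribed in this species) and
*second-tier* in the 85-94.999% band (likely a related species or a
paralogous transcript). A gene's coding extent is *completely* covered
when the union of top-tier EST segments tiles every base of it; complete
coverage plus determined start/stop codons licenses a spliced gene model
whose introns are the gaps between merged EST segments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from statistics import mean
from typing import Optional, Sequence

from .records import (
    ESTAlignment,
    GeneSite,
    PredictionTrack,
    merge_intervals,
)


@dataclass(frozen=True)
class TierParams:
    top_tier_min: float = 95.0
    second_tier_min: float = 85.0

    def __post_init__(self) -> None:
        if not self.second_tier_min < self.top_tier_min:
            raise ValueError("second_tier_min must be < top_tier_min")


class SpliceConflictError(ValueError):
    """Two ESTs imply contradictory intron/exon structure for one site."""


class IncompleteEvidenceError(ValueError):
    """Gene-model construction attempted without its evidence prerequisites."""


@dataclass
class GeneModel:
    """An EST-defined exon/intron model of a gene's coding region."""

    site_id: str
    exons: list[tuple[int, int]]
    introns: list[tuple[int, int]]
    cds_start: int
    cds_end: int

    def __post_init__(self) -> None:
        if len(self.introns) != len(self.exons) - 1:
            raise ValueError("intron count must be exon count - 1")
        for s, e in self.introns:
            if e - s + 1 < 1:
                raise ValueError("introns must be at least 1 bp")

    @property
    def intron_count(self) -> int:
        return len(self.introns)

    @property
    def intron_lengths(self) -> list[int]:
        return [e - s + 1 for s, e in self.introns]


def tier_est(alignment: ESTAlignment, params: TierParams = TierParams()) -> str:
    """Tier label: ``top``, ``second``, or ``unclassified``."""
    ident = alignment.pct_identity
    if not 0 <= ident <= 100:
        raise ValueError("pct_identity must lie in [0, 100]")
    if ident >= params.top_tier_min:
        return "top"
    if ident >= params.second_tier_min:
        return "second"
    return "unclassified"


def classify_coverage(
    site: GeneSite,
    model_extent: tuple[int, int],
    top_ests: Sequence[ESTAlignment],
) -> str:
    """Coverage of the coding extent by the union of top-tier ESTs.

    Coverage is judged at the transcript level: a spliced EST represents
    the transcript across its whole genomic envelope (its internal gaps
    are spliced-out introns), so each EST contributes its envelope
    ``[start, end]``. ``complete`` when the union of envelopes covers
    every base of ``model_extent`` (several ESTs may tile it),
    ``partial`` when the overlap is nonzero, else ``none``. Exon/intron
    structure still comes from the segments (see
    :func:`build_gene_model`).
    """
    lo, hi = model_extent
    if lo > hi:
        raise ValueError("model extent start must be <= end")
    envelopes = [
        (max(est.start, lo), min(est.end, hi))
        for est in top_ests
        if est.start <= hi and est.end >= lo
    ]
    if not envelopes:
        return "none"
    union = merge_intervals(envelopes)
    covered = sum(e - s + 1 for s, e in union)
    if covered == hi - lo + 1:
        return "complete"
    return "partial"


def find_est_only_sites(
    ests: Sequence[ESTAlignment],
    sites: Sequence[GeneSite],
    predictions: Sequence[PredictionTrack],
    insert_id: str,
    insert_length: Optional[int] = None,
    params: TierParams = TierParams(),
    boundary_margin: int = 50,
) -> list[GeneSite]:
    """Top-tier ESTs overlapping no homology site and no predicted gene
    define new gene sites of category ``est_only``.

    Overlapping qualifying ESTs are clustered into one site whose extent
    is the cluster envelope; sites within ``boundary_margin`` of an insert
    end are flagged artifactual.
    """
    predicted_spans = [
        (g.start, g.end)
        for track in predictions
        for g in track.for_insert(insert_id)
    ]
    site_spans = [(s.start, s.end) for s in sites]

    def overlaps_any(lo: int, hi: int, spans: list[tuple[int, int]]) -> bool:
        return any(lo <= e and hi >= s for s, e in spans)

    qualifying = [
        e
        for e in ests
        if tier_est(e, params) == "top"
        and not overlaps_any(e.start, e.end, site_spans)
        and not overlaps_any(e.start, e.end, predicted_spans)
    ]
    qualifying.sort(key=lambda e: (e.start, e.end))
    clusters: list[list[ESTAlignment]] = []
    for est in qualifying:
        if clusters and est.start <= max(e.end for e in clusters[-1]):
            clusters[-1].append(est)
        else:
            clusters.append([est])
    new_sites = []
    for i, cluster in enumerate(clusters, start=1):
        lo = min(e.start for e in cluster)
        hi = max(e.end for e in cluster)
        site = GeneSite(
            site_id=f"{insert_id}.est{i}",
            insert_id=insert_id,
            start=lo,
            end=hi,
            strand=cluster[0].strand,
            category="est_only",
        )
        if insert_length is not None:
            if lo - 1 <= boundary_margin:
                site.truncation.add("artifactual_5p" if site.strand == "+" else "artifactual_3p")
            if insert_length - hi <= boundary_margin:
                site.truncation.add("artifactual_3p" if site.strand == "+" else "artifactual_5p")
        new_sites.append(site)
    return new_sites


def build_gene_model(
    site: GeneSite,
    spliced: Sequence[ESTAlignment],
    params: TierParams = TierParams(),
) -> GeneModel:
    """Build an exon/intron model from complete top-tier EST coverage.

    Exons are the merged union of top-tier EST segments clipped to the
    span between the determined start and stop codons; introns are the
    gaps between consecutive exons. An EST whose internal gap contradicts
    the pooled intron set (one EST says intron where another says exon)
    raises :class:`SpliceConflictError` rather than being silently
    resolved.
    """
    if site.start_codon is None or site.stop_codon is None:
        raise IncompleteEvidenceError(
            f"site {site.site_id}: start/stop codons undetermined"
        )
    if site.strand == "+":
        cds_lo, cds_hi = site.start_codon, site.stop_codon + 2
    else:
        cds_lo, cds_hi = site.stop_codon - 2, site.start_codon
    top = [e for e in spliced if tier_est(e, params) == "top"]
    coverage = classify_coverage(site, (cds_lo, cds_hi), top)
    if coverage != "complete":
        raise IncompleteEvidenceError(
            f"site {site.site_id}: EST coverage is {coverage}, not complete"
        )
    clipped = [
        (max(s, cds_lo), min(e, cds_hi))
        for est in top
        for s, e in est.segments
        if s <= cds_hi and e >= cds_lo
    ]
    exons = merge_intervals(clipped)
    introns = [
        (prev_end + 1, next_start - 1)
        for (_, prev_end), (next_start, _) in zip(exons, exons[1:])
    ]
    intron_set = set(introns)
    for est in top:
        segs = [
            (max(s, cds_lo), min(e, cds_hi))
            for s, e in est.segments
            if s <= cds_hi and e >= cds_lo
        ]
        for (_, e0), (s1, _) in zip(segs, segs[1:]):
            gap = (e0 + 1, s1 - 1)
            if gap[0] > gap[1]:
                continue
            if gap not in intron_set:
                raise SpliceConflictError(
                    f"site {site.site_id}: EST {est.est_id} implies intron "
                    f"{gap} conflicting with the pooled exon structure"
                )
    return GeneModel(
        site_id=site.site_id,
        exons=exons,
        introns=introns,
        cds_start=cds_lo,
        cds_end=cds_hi,
    )


@dataclass(frozen=True)
class IntronStats:
    n_genes: int
    total_introns: int
    mean_per_gene: float
    min_per_gene: int
    max_per_gene: int
    mean_intron_length: Optional[int]
    n_below_threshold: int
    n_below_mean_length: int


def mean_introns_per_gene(total_introns: int, n_genes: int) -> float:
    """Mean intron count per modeled gene, to 2 decimals."""
    if n_genes <= 0:
        raise ValueError("n_genes must be positive")
    return round(total_introns / n_genes, 2)


def intron_stats(
    models: Sequence[GeneModel], length_threshold: int = 150
) -> IntronStats:
    """Summary statistics over the introns of a set of gene models."""
    if not models:
        raise ValueError("need at least one gene model")
    counts = [m.intron_count for m in models]
    lengths = [length for m in models for length in m.intron_lengths]
    mean_len = round(mean(lengths)) if lengths else None
    return IntronStats(
        n_genes=len(models),
        total_introns=sum(counts),
        mean_per_gene=mean_introns_per_gene(sum(counts), len(models)),
        min_per_gene=min(counts),
        max_per_gene=max(counts),
        mean_intron_length=mean_len,
        n_below_threshold=sum(1 for length in lengths if length < length_threshold),
        n_below_mean_length=(
            sum(1 for length in lengths if length < mean_len) if lengths else 0
        ),
    )
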