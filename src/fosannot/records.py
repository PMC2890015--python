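"""Shared record types for insert annotation.

Coordinates are uniformly 1-based and inclusive (GenBank/GFF3 convention);
orientation is carried by a ``strand`` field in ``{"+", "-"}``, never by
reversed coordinates. Multi-contig inserts live in a single concatenated
coordinate frame with 'N' padding between ordered contigs; the padding is
bookkept by gap sentinels and excluded from the insert's ``total_length``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

VALID_BASES = frozenset("ACGTN")
STRANDS = ("+", "-")


@dataclass(frozen=True)
class GapSentinel:
    """An inter-contig gap: padding start in the concatenated frame plus a
    nominal (unsequenced) gap length in bp."""

    position: int  # 1-based start of the padding in the concatenated frame
    nominal_length: int


@dataclass
class FosmidRecord:
    """One sequenced insert: ordered contigs in a single coordinate frame."""

    insert_id: str
    contigs: list[tuple[str, str]]
    accession: Optional[str] = None
    gap_pad: int = 100

    def __post_init__(self) -> None:
        if not self.contigs:
            raise ValueError("an insert needs at least one contig")
        if self.gap_pad < 0:
            raise ValueError("gap_pad must be >= 0")
        for cid, seq in self.contigs:
            bad = set(seq) - VALID_BASES
            if bad:
                raise ValueError(
                    f"contig {cid!r} contains illegal characters: {sorted(bad)}"
                )

    @property
    def total_length(self) -> int:
        """Sum of contig sequence lengths, excluding gap padding."""
        return sum(len(seq) for _, seq in self.contigs)

    @property
    def sequence(self) -> str:
        """Concatenated frame: contigs joined by ``gap_pad`` 'N' characters."""
        return ("N" * self.gap_pad).join(seq for _, seq in self.contigs)

    @property
    def frame_length(self) -> int:
        return self.total_length + self.gap_pad * (len(self.contigs) - 1)

    @property
    def gap_positions(self) -> list[GapSentinel]:
        """Gap sentinels at contig junctions, in frame coordinates."""
        sentinels = []
        offset = 0
        for _, seq in self.contigs[:-1]:
            offset += len(seq)
            sentinels.append(GapSentinel(position=offset + 1, nominal_length=self.gap_pad))
            offset += self.gap_pad
        return sentinels

    def spans_gap(self, start: int, end: int) -> bool:
        """True when [start, end] crosses or touches an inter-contig gap."""
        for gap in self.gap_positions:
            gap_lo = gap.position
            gap_hi = gap.position + max(self.gap_pad, 1) - 1
            if self.gap_pad == 0:
                # zero-width junction between gap_lo-1 and gap_lo
                if start < gap_lo <= end:
                    return True
            elif start <= gap_hi and end >= gap_lo:
                return True
        return False


@dataclass
class HomologyHit:
    """A translated-homology (blastx-style) hit in insert coordinates."""

    query_id: str
    subject_id: str
    pct_identity: float
    query_start: int
    query_end: int
    strand: str
    e_value: float
    bit_score: float
    frame: Optional[int] = None
    description: Optional[str] = None
    subject_start: Optional[int] = None
    subject_end: Optional[int] = None
    aln_length: Optional[int] = None

    def __post_init__(self) -> None:
        if self.query_start > self.query_end:
            raise ValueError("query_start must be <= query_end (strand carries orientation)")
        if self.e_value < 0:
            raise ValueError("e_value must be >= 0")
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}")

    @property
    def length(self) -> int:
        return self.query_end - self.query_start + 1


@dataclass
class ESTAlignment:
    """A spliced EST-to-genomic alignment (segments in insert coordinates)."""

    est_id: str
    pct_identity: float
    segments: list[tuple[int, int]]
    strand: str = "+"
    insert_id: Optional[str] = None
    source_genus: Optional[str] = None
    covers_cds_start: Optional[bool] = None
    covers_cds_end: Optional[bool] = None

    def __post_init__(self) -> None:
        if not 0 <= self.pct_identity <= 100:
            raise ValueError("pct_identity must lie in [0, 100]")
        segs = sorted(self.segments)
        for s, e in segs:
            if s > e:
                raise ValueError("segment start must be <= end")
        for (_, e0), (s1, _) in zip(segs, segs[1:]):
            if s1 <= e0:
                raise ValueError("EST segments must be non-overlapping")
        self.segments = segs

    @property
    def start(self) -> int:
        return self.segments[0][0]

    @property
    def end(self) -> int:
        return self.segments[-1][1]

    def covered_bases(self) -> int:
        return sum(e - s + 1 for s, e in self.segments)


@dataclass
class BestSubject:
    subject_id: str
    description: str
    e_value: float


@dataclass
class GeneSite:
    """An evidence-inferred gene locus on an insert.

    ``category`` is one of targeted / known / unknown / te_related /
    est_only; ``confidence_tier`` records whether the best supporting hit
    clears the strict or only the relaxed E-value cutoff. Codon positions
    are the genomic coordinate of the codon's first base in transcript
    orientation (for a minus-strand site that is the codon's highest
    genomic coordinate); ``None`` means undetermined.
    """

    site_id: str
    insert_id: str
    start: int
    end: int
    strand: str
    category: str = "known"
    best_subject: Optional[BestSubject] = None
    supporting_hits: list[HomologyHit] = field(default_factory=list)
    start_codon: Optional[int] = None
    stop_codon: Optional[int] = None
    truncation: set[str] = field(default_factory=set)
    confidence_tier: Optional[str] = None
    best_locus: Optional[str] = None
    family: Optional[str] = None
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("site start must be <= end")
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other_start: int, other_end: int) -> int:
        """Overlap in bp with [other_start, other_end] (0 when disjoint)."""
        return max(0, min(self.end, other_end) - max(self.start, other_start) + 1)


@dataclass
class PredictedGene:
    """One ab initio predicted gene with exon structure and codon calls."""

    gene_id: str
    start: int
    end: int
    strand: str
    exons: list[tuple[int, int]] = field(default_factory=list)
    predicted_start_codon: Optional[int] = None
    predicted_stop_codon: Optional[int] = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("gene start must be <= end")
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}")
        self.exons = sorted(self.exons)


@dataclass
class PredictionTrack:
    """One ab initio model's predicted genes for a set of inserts.

    ``genes`` maps insert_id -> list of PredictedGene sorted by start.
    """

    model_name: str
    genes: dict[str, list[PredictedGene]] = field(default_factory=dict)

    def for_insert(self, insert_id: str) -> list[PredictedGene]:
        return sorted(self.genes.get(insert_id, []), key=lambda g: (g.start, g.end))

    @property
    def n_genes(self) -> int:
        return sum(len(v) for v in self.genes.values())


def merge_intervals(intervals: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of 1-based inclusive intervals as a sorted, disjoint list."""
    merged: list[tuple[int, int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def interval_union_size(intervals: Sequence[tuple[int, int]]) -> int:
    return sum(e - s + 1 for s, e in merge_intervals(intervals))


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]
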