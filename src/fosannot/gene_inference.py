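"""Homology-based gene-site inference.

Protein-homology hits against an insert are clustered into gene sites at a
relaxed E-value cutoff (default 1e-5), with each site tiered *strict* when
its best hit clears the conservative cutoff (default 1e-10). Sites are
categorized from their best subject description (TE-related keywords,
"unknown protein", probe-targeted, or known), start/stop codons are
located by scanning the reading frame outward from the homology region,
and truncation flags distinguish artifacts of the insert boundary or a
contig gap from biologically shortened (pseudogene-like) coding regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .records import (
    BestSubject,
    ESTAlignment,
    FosmidRecord,
    GeneSite,
    HomologyHit,
    reverse_complement,
)

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

DEFAULT_TE_KEYWORDS = (
    "reverse transcriptase",
    "transposase",
    "polyprotein",
    "retrotransposon",
    "retroelement",
    "transposon",
    "gag",
    "pol protein",
)

UNKNOWN_KEYWORDS = ("unknown protein", "hypothetical")


@dataclass(frozen=True)
class EvidenceParams:
    """Cutoffs and geometry knobs for homology-based inference."""

    e_strict: float = 1e-10
    e_relaxed: float = 1e-5
    max_chain_gap: int = 2000
    same_site_overlap: float = 0.5
    boundary_margin: int = 50
    biological_truncation_ratio: float = 0.7
    te_keywords: tuple[str, ...] = DEFAULT_TE_KEYWORDS

    def __post_init__(self) -> None:
        if self.e_strict > self.e_relaxed:
            raise ValueError("e_strict must be <= e_relaxed")
        if not 0 < self.same_site_overlap <= 1:
            raise ValueError("same_site_overlap must lie in (0, 1]")


def cluster_hits_to_sites(
    hits: Sequence[HomologyHit],
    params: EvidenceParams = EvidenceParams(),
    insert_id: Optional[str] = None,
) -> list[GeneSite]:
    """Cluster homology hits into gene sites.

    Hits above ``e_relaxed`` are discarded. Same-subject, same-strand hits
    whose query-coordinate gap is at most ``max_chain_gap`` are chained
    into one site (exons of one gene). Chains from *different* subjects
    are merged when their intervals overlap by at least
    ``same_site_overlap`` of the shorter one on the same strand
    (paralogous subjects hitting the same physical site). Each site is
    tiered ``strict`` or ``relaxed`` by its best E-value.
    """
    kept = [h for h in hits if h.e_value <= params.e_relaxed]
    if insert_id is None:
        insert_id = kept[0].query_id if kept else "insert"
    if any(h.query_id != insert_id for h in kept):
        raise ValueError("hits from multiple inserts mixed")
    # chain per (subject, strand)
    chains: list[dict] = []
    groups: dict[tuple[str, str], list[HomologyHit]] = {}
    for h in kept:
        groups.setdefault((h.subject_id, h.strand), []).append(h)
    for (subject, strand), members in sorted(groups.items()):
        members.sort(key=lambda h: (h.query_start, h.query_end))
        current: list[HomologyHit] = []
        for h in members:
            if current and h.query_start - max(m.query_end for m in current) - 1 > params.max_chain_gap:
                chains.append({"strand": strand, "hits": current})
                current = []
            current.append(h)
        if current:
            chains.append({"strand": strand, "hits": current})
    for c in chains:
        c["start"] = min(h.query_start for h in c["hits"])
        c["end"] = max(h.query_end for h in c["hits"])

    # merge overlapping chains (union-find by the overlap criterion)
    n = len(chains)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    order = sorted(range(n), key=lambda i: (chains[i]["start"], chains[i]["end"]))
    for a in range(n):
        for b in range(a + 1, n):
            i, j = order[a], order[b]
            ci, cj = chains[i], chains[j]
            if cj["start"] > ci["end"]:
                break
            if ci["strand"] != cj["strand"]:
                continue
            ov = min(ci["end"], cj["end"]) - max(ci["start"], cj["start"]) + 1
            shorter = min(
                ci["end"] - ci["start"] + 1, cj["end"] - cj["start"] + 1
            )
            if ov >= params.same_site_overlap * shorter:
                union(i, j)

    clusters: dict[int, list[int]] = {}
    for i in range(n):
        clusters.setdefault(find(i), []).append(i)

    sites = []
    for members in clusters.values():
        all_hits = sorted(
            (h for i in members for h in chains[i]["hits"]),
            key=lambda h: (h.e_value, -h.bit_score, h.query_start),
        )
        best = all_hits[0]
        site = GeneSite(
            site_id="",
            insert_id=insert_id,
            start=min(chains[i]["start"] for i in members),
            end=max(chains[i]["end"] for i in members),
            strand=chains[members[0]]["strand"],
            best_subject=BestSubject(
                subject_id=best.subject_id,
                description=best.description or "",
                e_value=best.e_value,
            ),
            supporting_hits=sorted(all_hits, key=lambda h: h.query_start),
            confidence_tier="strict" if best.e_value <= params.e_strict else "relaxed",
        )
        sites.append(site)
    sites.sort(key=lambda s: (s.start, s.end))
    for i, site in enumerate(sites, start=1):
        site.site_id = f"{insert_id}.g{i}"
    return sites


def categorize_site(
    site: GeneSite,
    target_probes: Sequence[tuple[str, str]] = (),
    te_keywords: Iterable[str] = DEFAULT_TE_KEYWORDS,
    probe_min_identity: float = 98.0,
) -> str:
    """Category from the best-subject description and probe matches.

    Order of precedence: TE-related keyword, "unknown protein"/
    "hypothetical", probe-targeted (subject/description matches a probe
    pattern with >= ``probe_min_identity`` percent identity), else known.
    """
    if site.best_subject is None:
        return site.category
    desc = site.best_subject.description.lower()
    if any(kw.lower() in desc for kw in te_keywords):
        return "te_related"
    if any(kw in desc for kw in UNKNOWN_KEYWORDS):
        return "unknown"
    best_ident = max(
        (h.pct_identity for h in site.supporting_hits), default=0.0
    )
    for _, pattern in target_probes:
        pat = pattern.lower()
        if (
            pat in desc or pat in site.best_subject.subject_id.lower()
        ) and best_ident >= probe_min_identity:
            return "targeted"
    return "known"


def _codon_at(seq: str, pos: int, strand: str) -> Optional[str]:
    """Codon whose first transcript base sits at frame position ``pos``.

    ``pos`` is 1-based in the concatenated frame. For '+' the codon is
    seq[pos..pos+2]; for '-' it is the reverse complement of
    seq[pos-2..pos]. Returns None when the codon leaves the sequence or
    touches an 'N'.
    """
    if strand == "+":
        lo, hi = pos, pos + 2
    else:
        lo, hi = pos - 2, pos
    if lo < 1 or hi > len(seq):
        return None
    codon = seq[lo - 1 : hi]
    if "N" in codon:
        return None
    return codon if strand == "+" else reverse_complement(codon)


def infer_start_stop(
    site: GeneSite,
    insert: FosmidRecord,
    ests: Sequence[ESTAlignment] = (),
    top_tier_min: float = 95.0,
) -> GeneSite:
    """Locate start and stop codons by scanning outward from the homology
    region in steps of one codon.

    The stop codon is the first in-frame TAA/TAG/TGA at or 3' of the
    homology region's 3' end, anchored on the 3'-most supporting hit. The
    start codon is the in-frame ATG at or 5' of the homology 5' end that
    begins the longest open stretch reaching the region without an
    intervening in-frame stop. A top-tier EST spanning a boundary bounds
    the outward scan at its own extent (the EST-implied boundary takes
    precedence over an unbounded frame scan). Codons are left undetermined
    when the scan exits the insert or hits a contig gap; a site
    overlapping a gap sentinel gets both codons undetermined and a
    ``contig_break`` flag.
    """
    seq = insert.sequence
    if insert.spans_gap(site.start, site.end):
        site.start_codon = None
        site.stop_codon = None
        site.truncation.add("contig_break")
        return site

    top_ests = [
        e
        for e in ests
        if e.pct_identity >= top_tier_min
        and max(0, min(site.end, e.end) - max(site.start, e.start) + 1) > 0
    ]
    est_lo = min((e.start for e in top_ests), default=None)
    est_hi = max((e.end for e in top_ests), default=None)

    if site.strand == "+":
        five_prime, three_prime = site.start, site.end
        step_out_5p, step_out_3p = -3, +3
        first_stop_pos = three_prime + 1
    else:
        five_prime, three_prime = site.end, site.start
        step_out_5p, step_out_3p = +3, -3
        first_stop_pos = three_prime - 1  # codon covers [start-3, start-1]

    # ---- stop codon: first in-frame stop at/3' of the homology 3' end
    stop_codon = None
    pos = first_stop_pos
    while True:
        codon = _codon_at(seq, pos, site.strand)
        if codon is None:
            break  # ran off the insert or into a gap: undetermined
        if codon in STOP_CODONS:
            stop_codon = pos
            break
        if est_hi is not None:
            # do not scan past the transcript extent implied by EST support
            if site.strand == "+" and pos + 2 > est_hi and pos > site.end:
                break
            if site.strand == "-" and pos - 2 < est_lo and pos < site.start:
                break
        pos += step_out_3p

    # ---- start codon: most 5' ATG with an open stretch into the region
    start_codon = None
    pos = five_prime
    while True:
        codon = _codon_at(seq, pos, site.strand)
        if codon is None:
            break
        if codon in STOP_CODONS:
            break
        if codon == "ATG":
            start_codon = pos
        if est_lo is not None:
            if site.strand == "+" and pos - 3 < est_lo and pos < site.start:
                break
            if site.strand == "-" and pos + 3 > est_hi and pos > site.end:
                break
        pos += step_out_5p

    site.start_codon = start_codon
    site.stop_codon = stop_codon
    return site


def flag_truncation(
    site: GeneSite,
    insert: FosmidRecord,
    homolog_len_aa: Optional[int] = None,
    predicted_len_aa: Optional[int] = None,
    params: EvidenceParams = EvidenceParams(),
) -> set[str]:
    """Truncation flags for a placed site.

    ``artifactual_5p``/``artifactual_3p`` when the transcript-orientation
    5'/3' edge lies within ``boundary_margin`` of an insert end;
    ``contig_break`` when a gap sentinel intersects the site;
    ``biological`` when the predicted protein is substantially shorter
    than its homolog (< ``biological_truncation_ratio``) and no
    artifactual flag explains it.
    """
    flags: set[str] = set()
    frame_len = insert.frame_length
    near_left = site.start - 1 <= params.boundary_margin
    near_right = frame_len - site.end <= params.boundary_margin
    if site.strand == "+":
        if near_left:
            flags.add("artifactual_5p")
        if near_right:
            flags.add("artifactual_3p")
    else:
        if near_right:
            flags.add("artifactual_5p")
        if near_left:
            flags.add("artifactual_3p")
    if insert.spans_gap(site.start, site.end):
        flags.add("contig_break")
    if (
        not flags
        and homolog_len_aa
        and predicted_len_aa is not None
        and predicted_len_aa / homolog_len_aa < params.biological_truncation_ratio
    ):
        flags.add("biological")
    site.truncation |= flags
    return flags


def detect_tandem_duplicates(
    sites: Sequence[GeneSite],
    max_intervening: int = 1,
    subject_match: str = "same_subject",
) -> list[tuple[GeneSite, GeneSite, str]]:
    """Find tandemly duplicated gene pairs on one insert.

    Non-overlapping site pairs with the same best subject (or the same
    configured family when ``subject_match='same_family'``), separated by
    at most ``max_intervening`` other sites, are reported with their
    orientation: head_to_tail (same strand), head_to_head (leftmost on
    minus, divergent), or tail_to_tail (leftmost on plus, convergent).
    """
    if subject_match not in ("same_subject", "same_family"):
        raise ValueError("subject_match must be same_subject or same_family")
    ordered = sorted(sites, key=lambda s: (s.start, s.end))
    if len({s.insert_id for s in ordered}) > 1:
        raise ValueError("sites from multiple inserts mixed")
    pairs = []
    for i, a in enumerate(ordered):
        for j in range(i + 1, min(i + 2 + max_intervening, len(ordered))):
            b = ordered[j]
            if j - i - 1 > max_intervening:
                break
            if a.overlaps(b.start, b.end):
                continue
            if subject_match == "same_subject":
                if (
                    a.best_subject is None
                    or b.best_subject is None
                    or a.best_subject.subject_id != b.best_subject.subject_id
                ):
                    continue
            else:
                if a.family is None or a.family != b.family:
                    continue
            if a.strand == b.strand:
                orientation = "head_to_tail"
            elif a.strand == "-":
                orientation = "head_to_head"
            else:
                orientation = "tail_to_tail"
            pairs.append((a, b, orientation))
    return pairs
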