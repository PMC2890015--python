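"""Seed-reproducible synthetic fosmid-like inserts with full ground truth.

The generator emulates the study conditions end to end: 29-45 kb inserts
carrying multi-exon protein-coding genes (intact ORFs with start/stop
codons and an in-frame upstream stop guard so codon inference is exact),
perfect SSR tracts drawn from the observed motif-class spectrum,
TE-keyword gene sites, optional 2-3-contig assemblies with 'N' gap
padding, EST-only transcribed loci, homology hit tables, six ab initio
prediction tracks corrupted by configurable merge/split/miss/spurious/
codon-jitter events, and spliced EST alignments with configurable
identity and coverage completeness. Background sequence is scrubbed of
accidental qualifying SSRs so planted-feature recovery is exact rather
than statistical, and every planted feature and corruption event is
recorded in a ground-truth object sufficient to compute the expected
output of every downstream stage without re-simulation.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .records import (
    ESTAlignment,
    FosmidRecord,
    HomologyHit,
    PredictedGene,
    PredictionTrack,
    reverse_complement,
)
from .ssr import SSRScanParams, scan_ssrs

BASES = "ACGT"
STOPS = ("TAA", "TAG", "TGA")
SENSE_CODONS = [
    "".join(c) for c in itertools.product(BASES, repeat=3) if "".join(c) not in STOPS
]

DEFAULT_MODELS = ("At", "Mt", "Mo", "Nt", "Le", "Vv")

# motif-class weights proportional to the observed study spectrum
DEFAULT_MOTIF_WEIGHTS = {
    "AG": 58,
    "AT": 48,
    "AC": 17,
    "AGG": 5,
    "ACC": 2,
    "ATT": 4,
    "AAG": 14,
    "GTT": 4,
    "ACT": 4,
    "AGT": 2,
}

TE_DESCRIPTIONS = (
    "putative reverse transcriptase",
    "transposase-like protein",
    "retroviral polyprotein-like",
    "retrotransposon gag-pol protein",
)


@dataclass(frozen=True)
class CorruptionParams:
    """Per-model prediction corruption rates."""

    p_merge: float = 0.08
    p_split: float = 0.08
    p_miss: float = 0.05
    spurious_per_insert: float = 1.0
    p_codon_jitter: float = 0.25


@dataclass
class SimConfig:
    """Study-condition parameters of the synthetic generator."""

    seed: int = 0
    n_inserts: int = 20
    insert_length_range: tuple[int, int] = (29_000, 45_000)
    genes_per_insert_mean: float = 6.6  # ~ one gene per 5.9 kb
    intron_count_mean: float = 2.87
    intron_count_range: tuple[int, int] = (0, 9)
    intron_length_range: tuple[int, int] = (84, 933)
    exon_codon_range: tuple[int, int] = (30, 100)
    ssr_per_insert_mean: float = 8.0  # ~ one tract per 4.5 kb
    ssr_motif_weights: dict = field(
        default_factory=lambda: dict(DEFAULT_MOTIF_WEIGHTS)
    )
    repeat_count_range: tuple[int, int] = (5, 38)
    multi_tract_locus_rate: float = 0.09  # fraction of loci with 2 tracts
    te_site_rate: float = 0.65  # expected TE gene sites per insert
    unknown_gene_rate: float = 0.15
    relaxed_tier_rate: float = 0.06
    paralog_hit_rate: float = 0.10
    p_contig_break: float = 0.35  # 7/20 inserts are multi-contig
    gap_pad: int = 100
    tandem_dup_rate: float = 0.25
    tandem_separation: tuple[int, int] = (2_100, 2_600)
    syntenic_insert_rate: float = 0.5
    est_only_per_insert: float = 0.4  # 8 EST-only sites across 20 inserts
    coverage_probs: tuple[float, float, float] = (15 / 131, 40 / 131, 76 / 131)
    second_tier_est_rate: float = 0.5
    min_separation: int = 500
    end_margin: int = 300
    corruption: dict = field(
        default_factory=lambda: {m: CorruptionParams() for m in DEFAULT_MODELS}
    )


@dataclass
class PlantedGene:
    gene_id: str
    insert_id: str
    start: int  # genomic CDS span (including the stop codon)
    end: int
    strand: str
    exons: list[tuple[int, int]]  # genomic CDS exons, stop codon included
    start_codon: int  # transcript-first-base convention
    stop_codon: int
    site_start: int  # expected homology-site extent (CDS minus stop codon)
    site_end: int
    subject_id: str
    description: str
    category: str  # targeted | known | unknown | te_related
    e_value: float
    pct_identity: float
    tier: str  # strict | relaxed
    best_locus: Optional[str]
    family: Optional[str]
    coverage_class: str  # complete | partial | none
    targeted: bool
    homolog_len_aa: int
    has_paralog_hit: bool = False

    @property
    def intron_count(self) -> int:
        return len(self.exons) - 1

    @property
    def introns(self) -> list[tuple[int, int]]:
        return [
            (e0 + 1, s1 - 1)
            for (_, e0), (s1, _) in zip(self.exons, self.exons[1:])
        ]


@dataclass
class PlantedSSR:
    start: int
    end: int
    motif: str
    unit_length: int
    repeat_count: int
    canonical: str
    locus_index: int


@dataclass
class InsertTruth:
    insert_id: str
    frame_length: int
    contig_lengths: list[int]
    gap_positions: list[int]  # frame coordinate where each N-pad starts
    genes: list[PlantedGene] = field(default_factory=list)
    ssr_tracts: list[PlantedSSR] = field(default_factory=list)
    est_only_loci: list[tuple[int, int]] = field(default_factory=list)

    def expected_loci(self) -> list[list[PlantedSSR]]:
        groups: dict[int, list[PlantedSSR]] = {}
        for t in self.ssr_tracts:
            groups.setdefault(t.locus_index, []).append(t)
        return [sorted(g, key=lambda t: t.start) for _, g in sorted(groups.items())]


@dataclass
class TrackEvents:
    """Corruption events applied to one model's track on one insert."""

    merges: list[tuple[str, str]] = field(default_factory=list)
    splits: list[str] = field(default_factory=list)
    missed: list[str] = field(default_factory=list)
    spurious: list[tuple[int, int]] = field(default_factory=list)
    jittered_starts: set[str] = field(default_factory=set)
    jittered_stops: set[str] = field(default_factory=set)


@dataclass
class StudyTruth:
    inserts: dict[str, InsertTruth] = field(default_factory=dict)
    track_events: dict[str, dict[str, TrackEvents]] = field(default_factory=dict)

    def all_genes(self) -> list[PlantedGene]:
        return [g for t in self.inserts.values() for g in t.genes]

    def expected_report(self, model: str) -> dict[str, int]:
        """The Table-2-style cells this model's corrupted track must yield."""
        events = self.track_events[model]
        predicted = unsupported = mergers = genes_merged = splits = 0
        validated_starts = validated_stops = 0
        for insert_id, truth in self.inserts.items():
            ev = events[insert_id]
            gene_by_id = {g.gene_id: g for g in truth.genes}
            merged_ids = {gid for pair in ev.merges for gid in pair}
            n_genes = len(truth.genes)
            predicted += (
                n_genes
                - len(ev.missed)
                - len(ev.merges)  # each merge collapses 2 genes into 1
                + len(ev.splits)  # each split adds 1 extra prediction
                + len(ev.spurious)
            )
            unsupported += len(ev.spurious)
            mergers += len(ev.merges)
            genes_merged += 2 * len(ev.merges)
            splits += len(ev.splits)
            for g in truth.genes:
                if g.gene_id in ev.missed:
                    continue
                start_kept = stop_kept = True
                if g.gene_id in merged_ids:
                    pair = next(p for p in ev.merges if g.gene_id in p)
                    a, b = (gene_by_id[pair[0]], gene_by_id[pair[1]])
                    if a.start > b.start:
                        a, b = b, a
                    five_prime = b if g.strand == "-" else a
                    three_prime = a if g.strand == "-" else b
                    start_kept = g.gene_id == five_prime.gene_id
                    stop_kept = g.gene_id == three_prime.gene_id
                else:
                    start_kept = g.gene_id not in ev.jittered_starts
                    stop_kept = g.gene_id not in ev.jittered_stops
                if start_kept:
                    validated_starts += 1
                if stop_kept:
                    validated_stops += 1
        return {
            "predicted_genes": predicted,
            "unsupported": unsupported,
            "mergers": mergers,
            "genes_merged": genes_merged,
            "splits": splits,
            "validated_starts": validated_starts,
            "validated_stops": validated_stops,
        }


@dataclass
class SimulatedStudy:
    config: SimConfig
    records: list[FosmidRecord]
    truth: StudyTruth
    hits: dict[str, list[HomologyHit]]
    tracks: list[PredictionTrack]
    ests: dict[str, list[ESTAlignment]]
    probes: list[tuple[str, str]]

    @property
    def total_bp(self) -> int:
        return sum(r.total_length for r in self.records)


# ----------------------------------------------------------------- helpers


def _random_seq(rng: np.random.Generator, n: int) -> list[str]:
    return [BASES[i] for i in rng.integers(0, 4, size=n)]


def _pick_weighted(rng: np.random.Generator, weights: dict[str, float]) -> str:
    keys = sorted(weights)
    w = np.array([weights[k] for k in keys], dtype=float)
    return keys[rng.choice(len(keys), p=w / w.sum())]


def _rotate(motif: str, r: int) -> str:
    return motif[r:] + motif[:r]


@dataclass
class _GeneLayout:
    """A gene cassette in forward (transcript) layout, before placement."""

    cassette: str  # guard stop + CDS with introns (stop codon included)
    exons_fwd: list[tuple[int, int]]  # 1-based cassette coords of CDS exons
    n_codons: int


def _build_gene_cassette(cfg: SimConfig, rng: np.random.Generator) -> _GeneLayout:
    lo_i, hi_i = cfg.intron_count_range
    n_introns = int(min(max(rng.poisson(cfg.intron_count_mean), lo_i), hi_i))
    n_exons = n_introns + 1
    exon_codons = rng.integers(
        cfg.exon_codon_range[0], cfg.exon_codon_range[1] + 1, size=n_exons
    )
    total_codons = int(exon_codons.sum())
    codons = [SENSE_CODONS[i] for i in rng.integers(0, len(SENSE_CODONS), total_codons)]
    codons[0] = "ATG"
    codons[-1] = STOPS[rng.integers(0, 3)]
    cds = "".join(codons)
    guard = STOPS[rng.integers(0, 3)]
    parts = [guard]
    exons_fwd = []
    pos = len(guard)  # 0-based cursor in cassette
    cds_cursor = 0
    for i, ncod in enumerate(exon_codons):
        exon_seq = cds[cds_cursor : cds_cursor + int(ncod) * 3]
        cds_cursor += int(ncod) * 3
        parts.append(exon_seq)
        exons_fwd.append((pos + 1, pos + len(exon_seq)))
        pos += len(exon_seq)
        if i < n_exons - 1:
            ilen = int(
                rng.integers(cfg.intron_length_range[0], cfg.intron_length_range[1] + 1)
            )
            parts.append("".join(_random_seq(rng, ilen)))
            pos += ilen
    return _GeneLayout(
        cassette="".join(parts), exons_fwd=exons_fwd, n_codons=total_codons
    )


def _place_gene(
    gene_id: str,
    insert_id: str,
    layout: _GeneLayout,
    p: int,
    strand: str,
) -> dict:
    """Map a forward cassette placed with its first base at frame position
    ``p`` (1-based) to genomic coordinates under the given strand."""
    Lc = len(layout.cassette)
    if strand == "+":
        exons = [(p + a - 1, p + b - 1) for a, b in layout.exons_fwd]
        start_codon = p + 3
        stop_codon = p + Lc - 3
        span = (p + 3, p + Lc - 1)
        site = (p + 3, p + Lc - 4)
    else:
        exons = sorted((p + Lc - b, p + Lc - a) for a, b in layout.exons_fwd)
        start_codon = p + Lc - 4
        stop_codon = p + 2
        span = (p, p + Lc - 4)
        site = (p + 3, p + Lc - 4)
    return {
        "exons": exons,
        "start_codon": start_codon,
        "stop_codon": stop_codon,
        "span": span,
        "site": site,
    }


def _scrub_sequence(
    seq: list[str],
    rng: np.random.Generator,
    planted: set[tuple[int, int, int]],
    protected: set[int],
    params: SSRScanParams,
    max_rounds: int = 60,
) -> None:
    """Mutate bases until the only qualifying SSR tracts are the planted
    ones. ``planted`` holds (start, end, unit_length) keys; ``protected``
    holds 1-based positions that must not be altered."""
    for _ in range(max_rounds):
        found = scan_ssrs("".join(seq), params)
        rogue = [
            t for t in found if (t.start, t.end, t.unit_length) not in planted
        ]
        if not rogue:
            return
        for t in rogue:
            candidates = [
                pos
                for pos in range(t.start + 1, t.end + 1)
                if pos not in protected
            ]
            if not candidates:  # cannot happen for tracts >= 10 bp
                continue
            pos = candidates[len(candidates) // 2]
            current = seq[pos - 1]
            replacement = rng.permutation([b for b in BASES if b != current])[0]
            seq[pos - 1] = str(replacement)
    raise RuntimeError("SSR scrubbing did not converge")


# ------------------------------------------------------------ generation


def generate_insert(
    cfg: SimConfig,
    rng: np.random.Generator,
    insert_index: int,
) -> tuple[FosmidRecord, InsertTruth, list[HomologyHit], list[tuple[str, str]]]:
    """Generate one insert with its ground truth and homology hit table.

    Returns ``(record, truth, hits, probes)`` where probes holds the
    (name, pattern) pair for the insert's targeted gene.
    """
    insert_id = f"SYN{insert_index + 1:02d}"
    lo, hi = cfg.insert_length_range
    total_bp = int(rng.integers(lo, hi + 1))

    n_contigs = 1
    if rng.random() < cfg.p_contig_break:
        n_contigs = 2 if rng.random() < 2 / 7 else 3
    n_gaps = n_contigs - 1
    frame_length = total_bp + n_gaps * cfg.gap_pad

    n_genes = max(1, int(rng.poisson(cfg.genes_per_insert_mean)))
    n_te = int(rng.poisson(cfg.te_site_rate))
    n_est_only = int(rng.poisson(cfg.est_only_per_insert))
    n_ssr = int(rng.poisson(cfg.ssr_per_insert_mean))

    # ---- build feature payloads
    features: list[dict] = []
    probe_name = f"PRB{insert_index + 1:02d}"
    tandem = rng.random() < cfg.tandem_dup_rate
    gene_counter = 0

    def new_gene_feature(category: str, targeted: bool = False) -> dict:
        nonlocal gene_counter
        gene_counter += 1
        layout = _build_gene_cassette(cfg, rng)
        strand = "+" if rng.random() < 0.5 else "-"
        return {
            "kind": "gene",
            "length": len(layout.cassette),
            "layout": layout,
            "strand": strand,
            "category": category,
            "targeted": targeted,
            "local_id": gene_counter,
        }

    target_feature = new_gene_feature("targeted", targeted=True)
    if tandem:
        dup = new_gene_feature("targeted", targeted=True)
        dup["strand"] = target_feature["strand"] if rng.random() < 0.6 else (
            "-" if target_feature["strand"] == "+" else "+"
        )
        sep = int(rng.integers(*cfg.tandem_separation))
        features.append(
            {
                "kind": "tandem_pair",
                "length": target_feature["length"] + sep + dup["length"],
                "members": [target_feature, dup],
                "sep": sep,
            }
        )
        n_genes = max(0, n_genes - 2)
    else:
        features.append(target_feature)
        n_genes = max(0, n_genes - 1)

    for _ in range(n_genes):
        category = "unknown" if rng.random() < cfg.unknown_gene_rate else "known"
        features.append(new_gene_feature(category))
    for _ in range(n_te):
        features.append(new_gene_feature("te_related"))
    for _ in range(n_est_only):
        features.append(
            {"kind": "est_only", "length": int(rng.integers(400, 801))}
        )

    # SSR loci: group planned tracts into 1- or 2-tract loci
    ssr_plan: list[list[dict]] = []
    remaining = n_ssr
    while remaining > 0:
        pair = remaining >= 2 and rng.random() < cfg.multi_tract_locus_rate
        members = []
        for _ in range(2 if pair else 1):
            canonical = _pick_weighted(rng, cfg.ssr_motif_weights)
            unit = _rotate(canonical, int(rng.integers(0, len(canonical))))
            r_lo, r_hi = cfg.repeat_count_range
            repeats = int(min(r_lo + rng.geometric(0.25) - 1, r_hi))
            members.append({"unit": unit, "repeats": repeats, "canonical": canonical})
        ssr_plan.append(members)
        remaining -= len(members)
    for members in ssr_plan:
        length = sum(len(m["unit"]) * m["repeats"] for m in members)
        if len(members) == 2:
            members_gap = int(rng.integers(3, 100))
            length += members_gap
            features.append(
                {"kind": "ssr_locus", "length": length, "members": members,
                 "gap": members_gap}
            )
        else:
            features.append(
                {"kind": "ssr_locus", "length": length, "members": members, "gap": 0}
            )

    for _ in range(n_gaps):
        features.append({"kind": "gap", "length": cfg.gap_pad})

    # ---- fit features into the frame; drop trailing genes if oversized
    def required(feats: list[dict]) -> int:
        return (
            sum(f["length"] for f in feats)
            + (len(feats) - 1) * cfg.min_separation
            + 2 * cfg.end_margin
        )

    order = list(rng.permutation(len(features)))
    feats = [features[i] for i in order]
    while required(feats) > frame_length and len(feats) > 1:
        droppable = [
            i
            for i, f in enumerate(feats)
            if f["kind"] in ("gene", "est_only", "ssr_locus")
            and not f.get("targeted")
        ]
        if not droppable:
            break
        feats.pop(droppable[-1])
    if required(feats) > frame_length:
        raise ValueError("infeasible packing: features exceed insert length")

    slack = frame_length - required(feats)
    cuts = rng.multinomial(slack, np.ones(len(feats) + 1) / (len(feats) + 1))
    positions = []
    cursor = cfg.end_margin + int(cuts[0])
    for i, f in enumerate(feats):
        positions.append(cursor + 1)  # 1-based start
        cursor += f["length"]
        if i < len(feats) - 1:
            cursor += cfg.min_separation + int(cuts[i + 1])

    # ---- write the frame sequence
    seq = _random_seq(rng, frame_length)
    truth = InsertTruth(
        insert_id=insert_id,
        frame_length=frame_length,
        contig_lengths=[],
        gap_positions=[],
    )
    hits: list[HomologyHit] = []
    protected: set[int] = set()
    planted_keys: set[tuple[int, int, int]] = set()
    subject_counter = itertools.count(1)
    est_counter = itertools.count(1)
    syntenic = rng.random() < cfg.syntenic_insert_rate
    chrom = str(int(rng.integers(1, 6)))
    base_code = int(rng.integers(100, 5000)) * 10
    locus_cursor = itertools.count(0)

    def write(seg: str, start: int) -> None:
        seq[start - 1 : start - 1 + len(seg)] = list(seg)

    def plant_gene(
        f: dict,
        p: int,
        shared_subject: Optional[str] = None,
        shared_locus: Optional[str] = None,
    ) -> PlantedGene:
        layout: _GeneLayout = f["layout"]
        cassette = layout.cassette
        if f["strand"] == "-":
            write(reverse_complement(cassette), p)
        else:
            write(cassette, p)
        placed = _place_gene("", insert_id, layout, p, f["strand"])
        # protect guard, start codon, stop codon from scrubbing
        if f["strand"] == "+":
            protected.update(range(p, p + 7))  # guard + ATG
            protected.update(range(p + len(cassette) - 3, p + len(cassette)))
        else:
            protected.update(range(p + len(cassette) - 7, p + len(cassette) + 1))
            protected.update(range(p, p + 3))
        category = f["category"]
        if category == "te_related":
            desc = TE_DESCRIPTIONS[int(rng.integers(0, len(TE_DESCRIPTIONS)))]
        elif category == "unknown":
            desc = "unknown protein"
        elif f.get("targeted"):
            desc = f"{probe_name} target protein"
        else:
            desc = f"synthetic conserved protein {next(subject_counter):03d}"
        subject = shared_subject or f"SYNP{insert_index:02d}{f['local_id']:03d}"
        relaxed = rng.random() < cfg.relaxed_tier_rate and not f.get("targeted")
        if relaxed:
            e_value = 10.0 ** -float(rng.uniform(5.2, 9.8))
            tier = "relaxed"
        else:
            e_value = 10.0 ** -float(rng.uniform(15, 60))
            tier = "strict"
        identity = (
            float(rng.uniform(98.0, 99.9))
            if f.get("targeted")
            else float(rng.uniform(60, 95))
        )
        if shared_subject is not None:
            # a tandem duplicate is a family cluster: same reference locus
            locus = shared_locus
        elif category == "te_related" or not syntenic:
            locus = None
        else:
            locus = f"At{chrom}g{base_code + 10 * next(locus_cursor):05d}"
        gene = PlantedGene(
            gene_id=f"{insert_id}.t{f['local_id']}",
            insert_id=insert_id,
            start=placed["span"][0],
            end=placed["span"][1],
            strand=f["strand"],
            exons=placed["exons"],
            start_codon=placed["start_codon"],
            stop_codon=placed["stop_codon"],
            site_start=placed["site"][0],
            site_end=placed["site"][1],
            subject_id=subject,
            description=desc,
            category="targeted" if f.get("targeted") else category,
            e_value=e_value,
            pct_identity=identity,
            tier=tier,
            best_locus=locus,
            family=subject if f.get("targeted") else None,
            coverage_class="none",
            targeted=bool(f.get("targeted")),
            homolog_len_aa=layout.n_codons - 1,
            has_paralog_hit=rng.random() < cfg.paralog_hit_rate,
        )
        truth.genes.append(gene)
        return gene

    for f, p in zip(feats, positions):
        if f["kind"] == "gene":
            plant_gene(f, p)
        elif f["kind"] == "tandem_pair":
            a, b = f["members"]
            g1 = plant_gene(a, p)
            plant_gene(
                b,
                p + a["length"] + f["sep"],
                shared_subject=g1.subject_id,
                shared_locus=g1.best_locus,
            )
        elif f["kind"] == "est_only":
            truth.est_only_loci.append((p, p + f["length"] - 1))
        elif f["kind"] == "gap":
            write("N" * cfg.gap_pad, p)
            truth.gap_positions.append(p)
        elif f["kind"] == "ssr_locus":
            cursor_p = p
            locus_index = len(truth.expected_loci())
            for m_i, m in enumerate(f["members"]):
                unit, repeats = m["unit"], m["repeats"]
                k = len(unit)
                tract = unit * repeats
                write(tract, cursor_p)
                s, e = cursor_p, cursor_p + len(tract) - 1
                # flank guards: break whole-unit extension on both sides
                left = [b for b in BASES if b != unit[-1]]
                right = [b for b in BASES if b != unit[0]]
                if s - 1 >= 1:
                    seq[s - 2] = left[int(rng.integers(0, len(left)))]
                    protected.add(s - 1)
                if e + 1 <= frame_length:
                    seq[e] = right[int(rng.integers(0, len(right)))]
                    protected.add(e + 1)
                protected.update(range(s, e + 1))
                truth.ssr_tracts.append(
                    PlantedSSR(
                        start=s,
                        end=e,
                        motif=unit,
                        unit_length=k,
                        repeat_count=repeats,
                        canonical=m["canonical"],
                        locus_index=locus_index,
                    )
                )
                planted_keys.add((s, e, k))
                cursor_p = e + 1 + f["gap"]

    truth.ssr_tracts.sort(key=lambda t: t.start)
    truth.genes.sort(key=lambda g: g.start)
    truth.est_only_loci.sort()

    # ---- scrub accidental SSRs (planted tracts and key codons protected)
    scan_params = SSRScanParams()
    _scrub_sequence(seq, rng, planted_keys, protected, scan_params)

    # ---- cut the frame into contigs at the gap zones
    frame = "".join(seq)
    gap_starts = sorted(truth.gap_positions)
    contigs = []
    prev = 1
    for i, gs in enumerate(gap_starts):
        contigs.append((f"{insert_id}.c{i + 1}", frame[prev - 1 : gs - 1]))
        prev = gs + cfg.gap_pad
    contigs.append((f"{insert_id}.c{len(gap_starts) + 1}", frame[prev - 1 :]))
    truth.contig_lengths = [len(s) for _, s in contigs]
    record = FosmidRecord(
        insert_id=insert_id, contigs=contigs, gap_pad=cfg.gap_pad
    )
    assert record.sequence == frame
    assert record.total_length == total_bp

    # ---- homology hit table
    for g in truth.genes:
        exon_hits = list(g.exons)
        if g.strand == "+":
            s, e = exon_hits[-1]
            exon_hits[-1] = (s, e - 3)  # the stop codon is not protein-coding
        else:
            s, e = exon_hits[0]
            exon_hits[0] = (s + 3, e)
        subj_cursor = 1
        for (hs, he) in exon_hits:
            aa = (he - hs + 1) // 3
            hit = HomologyHit(
                query_id=insert_id,
                subject_id=g.subject_id,
                pct_identity=g.pct_identity,
                query_start=hs,
                query_end=he,
                strand=g.strand,
                e_value=g.e_value,
                bit_score=round(200 - np.log10(g.e_value + 1e-300), 1),
                description=g.description,
                subject_start=subj_cursor,
                subject_end=subj_cursor + aa - 1,
                aln_length=aa,
            )
            subj_cursor += aa
            hits.append(hit)
            if g.has_paralog_hit:
                hits.append(
                    HomologyHit(
                        query_id=insert_id,
                        subject_id=g.subject_id + "p",
                        pct_identity=max(40.0, g.pct_identity - 10),
                        query_start=hs,
                        query_end=he,
                        strand=g.strand,
                        e_value=min(1e-5, g.e_value * 1e3),
                        bit_score=150.0,
                        description=g.description + " (paralog)",
                        subject_start=subj_cursor,
                        subject_end=subj_cursor + aa - 1,
                        aln_length=aa,
                    )
                )
    hits.sort(key=lambda h: (h.query_start, h.query_end, h.subject_id))
    probes = [(probe_name, probe_name)]
    return record, truth, hits, probes


def corrupt_predictions(
    truth: StudyTruth,
    cfg: SimConfig,
    rng: np.random.Generator,
) -> list[PredictionTrack]:
    """Derive the six ab initio tracks from truth, with seeded corruption.

    Merge events span the merged genes' envelope and keep the pair's
    outermost codons; split events partition a multi-intron gene at an
    intron boundary, each part keeping its outer codon; spurious
    predictions land in feature-free background; codon jitter shifts a
    retained codon by one codon (+-3 bp). Every event is logged.
    """
    tracks = []
    for model in cfg.corruption:
        params: CorruptionParams = cfg.corruption[model]
        track = PredictionTrack(model_name=model)
        truth.track_events.setdefault(model, {})
        for insert_id, ins in truth.inserts.items():
            ev = TrackEvents()
            truth.track_events[model][insert_id] = ev
            genes = sorted(ins.genes, key=lambda g: g.start)
            kept = [g for g in genes if rng.random() >= params.p_miss]
            ev.missed = [g.gene_id for g in genes if g not in kept]
            order_index = {g.gene_id: i for i, g in enumerate(genes)}
            preds: list[PredictedGene] = []
            i = 0
            pid = itertools.count(1)
            while i < len(kept):
                g = kept[i]
                nxt = kept[i + 1] if i + 1 < len(kept) else None
                if (
                    nxt is not None
                    # only merge genes that are true neighbors, so the merged
                    # envelope spans exactly the two evidence sites and does
                    # not swallow an EST-only locus between them
                    and order_index[nxt.gene_id] == order_index[g.gene_id] + 1
                    and not any(
                        s > g.end and e < nxt.start
                        for s, e in ins.est_only_loci
                    )
                    and g.strand == nxt.strand
                    and g.category != "te_related"
                    and nxt.category != "te_related"
                    and rng.random() < params.p_merge
                ):
                    five, three = (nxt, g) if g.strand == "-" else (g, nxt)
                    preds.append(
                        PredictedGene(
                            gene_id=f"{insert_id}.{model}.p{next(pid)}",
                            start=g.start,
                            end=nxt.end,
                            strand=g.strand,
                            exons=g.exons + nxt.exons,
                            predicted_start_codon=five.start_codon,
                            predicted_stop_codon=three.stop_codon,
                        )
                    )
                    ev.merges.append((g.gene_id, nxt.gene_id))
                    i += 2
                    continue
                if g.intron_count >= 1 and rng.random() < params.p_split:
                    cut = int(rng.integers(0, g.intron_count))
                    left_exons = g.exons[: cut + 1]
                    right_exons = g.exons[cut + 1 :]
                    left = PredictedGene(
                        gene_id=f"{insert_id}.{model}.p{next(pid)}",
                        start=left_exons[0][0],
                        end=left_exons[-1][1],
                        strand=g.strand,
                        exons=left_exons,
                    )
                    right = PredictedGene(
                        gene_id=f"{insert_id}.{model}.p{next(pid)}",
                        start=right_exons[0][0],
                        end=right_exons[-1][1],
                        strand=g.strand,
                        exons=right_exons,
                    )
                    if g.strand == "+":
                        left.predicted_start_codon = g.start_codon
                        right.predicted_stop_codon = g.stop_codon
                    else:
                        right.predicted_start_codon = g.start_codon
                        left.predicted_stop_codon = g.stop_codon
                    preds.extend([left, right])
                    ev.splits.append(g.gene_id)
                    i += 1
                    continue
                start_codon, stop_codon = g.start_codon, g.stop_codon
                if rng.random() < params.p_codon_jitter:
                    start_codon += 3 * int(rng.choice([-1, 1]))
                    ev.jittered_starts.add(g.gene_id)
                if rng.random() < params.p_codon_jitter:
                    stop_codon += 3 * int(rng.choice([-1, 1]))
                    ev.jittered_stops.add(g.gene_id)
                preds.append(
                    PredictedGene(
                        gene_id=f"{insert_id}.{model}.p{next(pid)}",
                        start=g.start,
                        end=g.end,
                        strand=g.strand,
                        exons=g.exons,
                        predicted_start_codon=start_codon,
                        predicted_stop_codon=stop_codon,
                    )
                )
                i += 1
            # spurious predictions in feature-free background
            n_spurious = int(rng.poisson(params.spurious_per_insert))
            occupied = (
                [(g.start - 60, g.end + 60) for g in genes]
                + [(s - 60, e + 60) for s, e in ins.est_only_loci]
                + [(t.start - 60, t.end + 60) for t in ins.ssr_tracts]
                + [
                    (gp - 60, gp + cfg.gap_pad + 60)
                    for gp in ins.gap_positions
                ]
            )
            free = _free_intervals(ins.frame_length, occupied)
            for _ in range(n_spurious):
                length = int(rng.integers(300, 901))
                slots = [(s, e) for s, e in free if e - s + 1 >= length]
                if not slots:
                    continue
                s, e = slots[int(rng.integers(0, len(slots)))]
                start = int(rng.integers(s, e - length + 2))
                preds.append(
                    PredictedGene(
                        gene_id=f"{insert_id}.{model}.sp{len(ev.spurious) + 1}",
                        start=start,
                        end=start + length - 1,
                        strand="+" if rng.random() < 0.5 else "-",
                        exons=[(start, start + length - 1)],
                    )
                )
                ev.spurious.append((start, start + length - 1))
            preds.sort(key=lambda g: (g.start, g.end))
            track.genes[insert_id] = preds
        tracks.append(track)
    return tracks


def _free_intervals(
    frame_length: int, occupied: list[tuple[int, int]]
) -> list[tuple[int, int]]:
    free = []
    cursor = 1
    for s, e in sorted(occupied):
        if s > cursor:
            free.append((cursor, min(s - 1, frame_length)))
        cursor = max(cursor, e + 1)
    if cursor <= frame_length:
        free.append((cursor, frame_length))
    return [(max(1, s), e) for s, e in free if e >= s]


def simulate_ests(
    truth: StudyTruth,
    cfg: SimConfig,
    rng: np.random.Generator,
) -> dict[str, list[ESTAlignment]]:
    """Spliced EST alignments realizing each gene's coverage class.

    Complete-class genes receive top-tier ESTs whose segment union tiles
    the coding extent exactly along planted exon boundaries; partial-class
    genes get a sub-covering subset; none-class genes get no top-tier EST
    (second-tier ESTs may still overlap them).
    """
    ests: dict[str, list[ESTAlignment]] = {}
    counter = itertools.count(1)
    p_complete, p_partial, p_none = cfg.coverage_probs
    for insert_id, ins in truth.inserts.items():
        out: list[ESTAlignment] = []
        for g in ins.genes:
            if g.category == "te_related":
                g.coverage_class = "none"
                continue
            u = rng.random()
            if u < p_complete:
                g.coverage_class = "complete"
                exons = list(g.exons)
                if len(exons) >= 3 and rng.random() < 0.5:
                    j = int(rng.integers(1, len(exons)))
                    groups = [exons[:j], exons[j - 1 :]]  # overlap one exon
                else:
                    groups = [exons]
                for segs in groups:
                    out.append(
                        ESTAlignment(
                            est_id=f"FVEST{next(counter):05d}",
                            pct_identity=float(rng.uniform(95.0, 99.9)),
                            segments=segs,
                            strand=g.strand,
                            insert_id=insert_id,
                            source_genus="Fragaria",
                        )
                    )
            elif u < p_complete + p_partial:
                g.coverage_class = "partial"
                # cDNA truncation: the EST misses a terminal portion
                exons = list(g.exons)
                if len(exons) >= 2:
                    segs = exons[1:] if rng.random() < 0.5 else exons[:-1]
                else:
                    s, e = exons[0]
                    segs = [(s + 10, e)] if rng.random() < 0.5 else [(s, e - 10)]
                out.append(
                    ESTAlignment(
                        est_id=f"FVEST{next(counter):05d}",
                        pct_identity=float(rng.uniform(95.0, 99.9)),
                        segments=segs,
                        strand=g.strand,
                        insert_id=insert_id,
                        source_genus="Fragaria",
                    )
                )
            else:
                g.coverage_class = "none"
            if rng.random() < cfg.second_tier_est_rate:
                s, e = g.exons[0]
                out.append(
                    ESTAlignment(
                        est_id=f"ROEST{next(counter):05d}",
                        pct_identity=float(rng.uniform(85.0, 94.9)),
                        segments=[(s, e)],
                        strand=g.strand,
                        insert_id=insert_id,
                        source_genus=("Malus", "Prunus", "Rosa")[
                            int(rng.integers(0, 3))
                        ],
                    )
                )
        for (s, e) in ins.est_only_loci:
            out.append(
                ESTAlignment(
                    est_id=f"FVEST{next(counter):05d}",
                    pct_identity=float(rng.uniform(95.0, 99.9)),
                    segments=[(s, e)],
                    strand="+",
                    insert_id=insert_id,
                    source_genus="Fragaria",
                )
            )
        out.sort(key=lambda a: (a.start, a.end, a.est_id))
        ests[insert_id] = out
    return ests


def simulate_study(cfg: Optional[SimConfig] = None) -> SimulatedStudy:
    """Generate the full synthetic study: inserts, truth, homology hits,
    six corrupted prediction tracks, and EST alignments."""
    cfg = cfg or SimConfig()
    rng = np.random.default_rng(cfg.seed)
    truth = StudyTruth()
    records = []
    hits: dict[str, list[HomologyHit]] = {}
    probes: list[tuple[str, str]] = []
    for i in range(cfg.n_inserts):
        record, ins_truth, ins_hits, ins_probes = generate_insert(cfg, rng, i)
        records.append(record)
        truth.inserts[record.insert_id] = ins_truth
        hits[record.insert_id] = ins_hits
        probes.extend(ins_probes)
    tracks = corrupt_predictions(truth, cfg, rng)
    ests = simulate_ests(truth, cfg, rng)
    return SimulatedStudy(
        config=cfg,
        records=records,
        truth=truth,
        hits=hits,
        tracks=tracks,
        ests=ests,
        probes=probes,
    )


# ------------------------------------------------------------ file output


def write_study_files(study: SimulatedStudy, outdir: str) -> str:
    """Emit the simulated study in the formats the readers consume.

    Writes per-insert FASTA (ordered contigs), a combined homology hit
    table, a combined EST GFF3, one prediction GFF3 per model, the
    subject-to-locus map and reference gene order TSVs, a ground-truth
    JSON, and a ready-to-run pipeline configuration YAML. Returns the
    path of the configuration file.
    """
    import os

    import yaml

    from .sequence_io import write_blast_tab, write_fasta, write_gff_track

    os.makedirs(outdir, exist_ok=True)
    insert_entries = []
    for record in study.records:
        fasta = os.path.join(outdir, f"{record.insert_id}.fasta")
        write_fasta(fasta, record.contigs)
        insert_entries.append({"id": record.insert_id, "fasta": fasta})

    hits_path = os.path.join(outdir, "hits.tsv")
    write_blast_tab(
        hits_path, [h for iid in sorted(study.hits) for h in study.hits[iid]]
    )

    ests_path = os.path.join(outdir, "ests.gff3")
    write_gff_track(
        ests_path,
        "est",
        [e for iid in sorted(study.ests) for e in study.ests[iid]],
    )

    track_entries = []
    for track in study.tracks:
        path = os.path.join(outdir, f"track_{track.model_name}.gff3")
        write_gff_track(path, "prediction", track)
        track_entries.append({"model": track.model_name, "gff": path})

    genes = study.truth.all_genes()
    locus_path = os.path.join(outdir, "locus_map.tsv")
    with open(locus_path, "w") as fh:
        fh.write("subject\tlocus\n")
        seen = set()
        for g in genes:
            if g.best_locus and g.subject_id not in seen:
                fh.write(f"{g.subject_id}\t{g.best_locus}\n")
                seen.add(g.subject_id)

    order_path = os.path.join(outdir, "reference_order.tsv")
    loci = sorted({g.best_locus for g in genes if g.best_locus})
    with open(order_path, "w") as fh:
        fh.write("locus\tchromosome\trank\n")
        from .microsynteny import ReferenceGeneOrder

        order = ReferenceGeneOrder.from_codes(loci)
        for locus in loci:
            chrom, rank, _ = order.entries[locus]
            fh.write(f"{locus}\t{chrom}\t{rank}\n")

    truth_path = os.path.join(outdir, "truth.json")
    with open(truth_path, "w") as fh:
        json.dump(_truth_to_dict(study.truth), fh, indent=1)
        fh.write("\n")

    config = {
        "inserts": insert_entries,
        "hits": hits_path,
        "ests": ests_path,
        "tracks": track_entries,
        "probes": [{"name": n, "pattern": p} for n, p in study.probes],
        "locus_map": locus_path,
        "reference_order": order_path,
        "gap_pad": study.config.gap_pad,
    }
    config_path = os.path.join(outdir, "pipeline.yaml")
    with open(config_path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
    return config_path


def _truth_to_dict(truth: StudyTruth) -> dict:
    def gene_dict(g: PlantedGene) -> dict:
        d = dict(g.__dict__)
        d["exons"] = [list(x) for x in g.exons]
        return d

    return {
        "inserts": {
            iid: {
                "insert_id": ins.insert_id,
                "frame_length": ins.frame_length,
                "contig_lengths": ins.contig_lengths,
                "gap_positions": ins.gap_positions,
                "genes": [gene_dict(g) for g in ins.genes],
                "ssr_tracts": [dict(t.__dict__) for t in ins.ssr_tracts],
                "est_only_loci": [list(x) for x in ins.est_only_loci],
            }
            for iid, ins in truth.inserts.items()
        },
        "track_events": {
            model: {
                iid: {
                    "merges": [list(p) for p in ev.merges],
                    "splits": ev.splits,
                    "missed": ev.missed,
                    "spurious": [list(p) for p in ev.spurious],
                    "jittered_starts": sorted(ev.jittered_starts),
                    "jittered_stops": sorted(ev.jittered_stops),
                }
                for iid, ev in per_insert.items()
            }
            for model, per_insert in truth.track_events.items()
        },
    }
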