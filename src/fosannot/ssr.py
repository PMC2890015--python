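"""Perfect microsatellite (SSR) detection and operational-locus statistics.

The scanner reports every *maximal* uninterrupted tract of a *primitive*
repeat unit (unit length 2-5 bp by default) repeated at least
``min_repeats`` times — SSRIT-style semantics in which a single mismatch
base terminates a tract, so e.g. (TCC)6 TCT (TCC)5 counts as two SSRs.
Tracts lying within ``merge_gap`` bp of each other (strictly less than,
default 100) are chained into a single *operational SSR locus*: the unit a
single primer pair would genotype. Density helpers extrapolate per-Mb and
per-cM marker densities from a genome size and genetic map length.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from .records import reverse_complement

CANONICAL_MODES = ("rotation", "rotation_rc", "per_unit_length")


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class SSRScanParams:
    """Scan parameters (defaults reproduce SSRIT with 5x2..5x5 settings)."""

    min_unit: int = 2
    max_unit: int = 5
    min_repeats: int = 5
    merge_gap: int = 100  # exclusive: a gap of exactly merge_gap does not merge
    canonical_mode: str = "per_unit_length"

    def __post_init__(self) -> None:
        if not (1 <= self.min_unit <= self.max_unit <= 5):
            raise ValueError("require 1 <= min_unit <= max_unit <= 5")
        if self.min_repeats < 2:
            raise ValueError("min_repeats must be >= 2")
        if self.merge_gap < 0:
            raise ValueError("merge_gap must be >= 0")
        if self.canonical_mode not in CANONICAL_MODES:
            raise ValueError(f"canonical_mode must be one of {CANONICAL_MODES}")


@dataclass(frozen=True)
class SSRTract:
    """A maximal perfect repeat tract (1-based inclusive coordinates)."""

    insert_id: str
    start: int
    end: int
    motif: str
    canonical_motif: str
    unit_length: int
    repeat_count: int

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != self.unit_length * self.repeat_count:
            raise ValueError("tract span must equal unit_length * repeat_count")


@dataclass
class SSRLocus:
    """One or more nearby tracts genotyped as a single marker locus."""

    insert_id: str
    tracts: list[SSRTract]

    @property
    def start(self) -> int:
        return min(t.start for t in self.tracts)

    @property
    def end(self) -> int:
        return max(t.end for t in self.tracts)


@dataclass(frozen=True)
class GenomeContext:
    """Study-level context for density extrapolation."""

    total_analyzed_bp: int
    genome_size_bp: int
    map_length_cM: float

    def __post_init__(self) -> None:
        if min(self.total_analyzed_bp, self.genome_size_bp, self.map_length_cM) <= 0:
            raise ValueError("all genome-context quantities must be positive")


def is_primitive(motif: str) -> bool:
    """True when the motif is not itself a repetition of a shorter unit."""
    n = len(motif)
    for d in range(1, n):
        if n % d == 0 and motif[:d] * (n // d) == motif:
            return False
    return True


def canonical_motif(motif: str, mode: str = "per_unit_length") -> str:
    """Canonical class label for a repeat unit.

    ``rotation``: lexicographically smallest cyclic rotation.
    ``rotation_rc``: smallest over rotations of the motif and of its
    reverse complement (so CT folds into AG).
    ``per_unit_length``: rotation_rc for unit length <= 2 and rotation-only
    for unit length >= 3, the mixed grouping conventional for dinucleotide
    vs trinucleotide class tables (ACT and AGT stay distinct).
    """
    if mode not in CANONICAL_MODES:
        raise ValueError(f"mode must be one of {CANONICAL_MODES}")
    if not motif or not 1 <= len(motif) <= 5:
        raise ValueError("motif length must lie in [1, 5]")
    if not is_primitive(motif):
        raise ValueError(f"motif {motif!r} is not primitive")
    if mode == "per_unit_length":
        mode = "rotation_rc" if len(motif) <= 2 else "rotation"
    rotations = [motif[i:] + motif[:i] for i in range(len(motif))]
    if mode == "rotation_rc":
        rc = reverse_complement(motif)
        rotations += [rc[i:] + rc[:i] for i in range(len(rc))]
    return min(rotations)


def scan_ssrs(
    sequence: str,
    params: SSRScanParams = SSRScanParams(),
    insert_id: str = "seq",
) -> list[SSRTract]:
    """Report all maximal perfect repeat tracts in ``sequence``.

    Tracts are maximal (not extendable by one full unit on either side),
    reported under their primitive unit only, never contain 'N', and are
    returned sorted by start. Only whole repeat units count toward a
    tract's span; a trailing partial unit is outside the tract. Exactly
    one tract is reported per maximal periodic region and unit length,
    anchored at the region's left edge (phase-shifted readings of the
    same region are not separate tracts).
    """
    seq = sequence.upper()
    n = len(seq)
    tracts: list[SSRTract] = []
    valid = [c in "ACGT" for c in seq]
    for k in range(params.min_unit, params.max_unit + 1):
        i = 0
        while i + k * params.min_repeats <= n:
            if not valid[i]:
                i += 1
                continue
            # extend the period-k match run starting at i
            j = i
            while j + k < n and valid[j + k] and seq[j] == seq[j + k]:
                j += 1
            run = j - i + k  # length of the periodic region [i, i+run-1]
            repeats = run // k
            if repeats >= params.min_repeats:
                motif = seq[i : i + k]
                if is_primitive(motif):
                    tracts.append(
                        SSRTract(
                            insert_id=insert_id,
                            start=i + 1,
                            end=i + repeats * k,
                            motif=motif,
                            canonical_motif=canonical_motif(
                                motif, params.canonical_mode
                            ),
                            unit_length=k,
                            repeat_count=repeats,
                        )
                    )
            # any start inside this periodic region yields a phase-shifted
            # sub-tract of the same region; skip to the next region start
            i += run - k + 1
    tracts.sort(key=lambda t: (t.start, t.unit_length))
    return tracts


def merge_operational_loci(
    tracts: list[SSRTract], merge_gap: int = 100
) -> list[SSRLocus]:
    """Chain tracts into operational loci by single linkage.

    Consecutive tracts whose inter-tract gap (``next.start - prev.end - 1``)
    is strictly less than ``merge_gap`` join one locus; the chain is
    transitive.
    """
    if not tracts:
        return []
    insert_ids = {t.insert_id for t in tracts}
    if len(insert_ids) > 1:
        raise ValueError(f"tracts from multiple inserts mixed: {sorted(insert_ids)}")
    ordered = sorted(tracts, key=lambda t: (t.start, t.end))
    loci = [SSRLocus(insert_id=ordered[0].insert_id, tracts=[ordered[0]])]
    for t in ordered[1:]:
        prev_end = max(m.end for m in loci[-1].tracts)
        gap = t.start - prev_end - 1
        if gap < merge_gap:
            loci[-1].tracts.append(t)
        else:
            loci.append(SSRLocus(insert_id=t.insert_id, tracts=[t]))
    return loci


def ssr_density_per_Mb(count: int, total_bp: int) -> int:
    """Tracts per megabase, rounded to the nearest integer."""
    if total_bp <= 0:
        raise ValueError("total_bp must be > 0")
    return _round_half_up(count * 1e6 / total_bp)


def kb_per_cM(ctx: GenomeContext) -> int:
    """Physical-to-genetic distance ratio, in kb per cM (nearest integer)."""
    if ctx.map_length_cM <= 0:
        raise ValueError("map length must be > 0")
    return _round_half_up(ctx.genome_size_bp / ctx.map_length_cM / 1000)


def loci_per_cM(locus_count: int, total_bp: int, ctx: GenomeContext) -> tuple[float, int]:
    """Extrapolated marker loci per cM of map distance.

    Returns ``(loci_per_cM, kb_per_cM)`` where the first term is
    ``(locus_count / total_bp) * (genome_size_bp / map_length_cM)``.
    """
    if locus_count <= 0 or total_bp <= 0:
        raise ValueError("locus_count and total_bp must be positive")
    density = locus_count / total_bp * (ctx.genome_size_bp / ctx.map_length_cM)
    return density, kb_per_cM(ctx)


UNIT_CLASS_NAMES = {
    1: "Mono-nucleotide",
    2: "Di-nucleotide",
    3: "Tri-nucleotide",
    4: "Tetra-nucleotide",
    5: "Penta-nucleotide",
}


@dataclass
class SSRSummary:
    """Study-level SSR summary (per-class counts and densities)."""

    per_class: pd.DataFrame  # canonical_motif, unit_length, count, per_Mb
    per_unit_length: pd.DataFrame  # unit class subtotals
    total_tracts: int
    total_loci: int
    total_bp: int
    kb_per_tract: Optional[float]
    kb_per_locus: Optional[float]
    loci_per_cM: Optional[float] = None
    kb_per_cM: Optional[int] = None


def summarize_ssrs(
    tracts: list[SSRTract],
    loci: list[SSRLocus],
    ctx: GenomeContext,
) -> SSRSummary:
    """Per-class counts/densities, unit-length subtotals, and spacings.

    Spacings are reported in kb rounded to 0.1; with zero tracts or loci
    the corresponding spacing is ``None`` rather than a division error.
    """
    total_bp = ctx.total_analyzed_bp
    rows = []
    by_class: dict[tuple[int, str], int] = {}
    for t in tracts:
        by_class[(t.unit_length, t.canonical_motif)] = (
            by_class.get((t.unit_length, t.canonical_motif), 0) + 1
        )
    for (unit_length, motif), count in sorted(by_class.items()):
        rows.append(
            {
                "canonical_motif": motif,
                "unit_length": unit_length,
                "count": count,
                "per_Mb": ssr_density_per_Mb(count, total_bp),
            }
        )
    per_class = pd.DataFrame(
        rows, columns=["canonical_motif", "unit_length", "count", "per_Mb"]
    )
    unit_rows = []
    for unit_length in range(1, 6):
        count = sum(c for (k, _), c in by_class.items() if k == unit_length)
        unit_rows.append(
            {
                "unit_class": UNIT_CLASS_NAMES[unit_length],
                "unit_length": unit_length,
                "count": count,
                "per_Mb": ssr_density_per_Mb(count, total_bp),
            }
        )
    per_unit_length = pd.DataFrame(
        unit_rows, columns=["unit_class", "unit_length", "count", "per_Mb"]
    )
    n_tracts, n_loci = len(tracts), len(loci)
    summary = SSRSummary(
        per_class=per_class,
        per_unit_length=per_unit_length,
        total_tracts=n_tracts,
        total_loci=n_loci,
        total_bp=total_bp,
        kb_per_tract=round(total_bp / n_tracts / 1000, 1) if n_tracts else None,
        kb_per_locus=round(total_bp / n_loci / 1000, 1) if n_loci else None,
    )
    if n_loci:
        density, ratio = loci_per_cM(n_loci, total_bp, ctx)
        summary.loci_per_cM = density
        summary.kb_per_cM = ratio
    return summary


def tracts_to_frame(tracts: list[SSRTract], loci: list[SSRLocus]) -> pd.DataFrame:
    """Flat per-tract table with locus membership, for TSV output."""
    locus_of = {}
    for li, locus in enumerate(loci, start=1):
        for t in locus.tracts:
            locus_of[(t.insert_id, t.start, t.end, t.unit_length)] = (
                f"{locus.insert_id}.L{li}"
            )
    rows = [
        {
            "insert_id": t.insert_id,
            "start": t.start,
            "end": t.end,
            "motif": t.motif,
            "canonical_motif": t.canonical_motif,
            "unit_length": t.unit_length,
            "repeat_count": t.repeat_count,
            "locus_id": locus_of.get((t.insert_id, t.start, t.end, t.unit_length), ""),
        }
        for t in tracts
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "insert_id",
            "start",
            "end",
            "motif",
            "canonical_motif",
            "unit_length",
            "repeat_count",
            "locus_id",
        ],
    )
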