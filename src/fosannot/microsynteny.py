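"""Microsynteny detection against a reference genome's gene order.

Gene sites on an insert carry the reference locus of their best protein
hit, identified by an AGI-style code (e.g. At3g54340) whose numeric part
encodes ordered position along a chromosome at nominal steps of 10. Two
near-adjacent insert sites whose reference loci are close on one
reference chromosome are *colinear* (strictly adjacent homologs, locus
step 1, nothing between them on the insert) or in *conserved
microsynteny* (near-adjacent with interruptions on either genome). An
externally supplied gene-order table overrides code-derived ordering.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .records import GeneSite

AGI_PATTERN = re.compile(r"^At([1-5CM])g(\d{5})$", re.IGNORECASE)


def parse_agi(locus: str) -> tuple[str, int]:
    """Parse an AGI locus code into (chromosome, numeric code)."""
    m = AGI_PATTERN.match(locus.strip())
    if not m:
        raise ValueError(f"malformed AGI locus code: {locus!r}")
    return m.group(1).upper(), int(m.group(2))


@dataclass
class ReferenceGeneOrder:
    """Ordered reference loci: code -> (chromosome, ordinal, numeric code).

    Built either from an explicit table (chromosome + rank) or inferred
    from AGI numeric codes at their nominal step of 10.
    """

    entries: dict[str, tuple[str, int, int]]

    @classmethod
    def from_codes(cls, loci: Sequence[str]) -> "ReferenceGeneOrder":
        parsed = {locus: parse_agi(locus) for locus in loci}
        entries: dict[str, tuple[str, int, int]] = {}
        by_chrom: dict[str, list[tuple[int, str]]] = {}
        for locus, (chrom, code) in parsed.items():
            by_chrom.setdefault(chrom, []).append((code, locus))
        for chrom, pairs in by_chrom.items():
            for ordinal, (code, locus) in enumerate(sorted(pairs), start=1):
                entries[locus] = (chrom, ordinal, code)
        return cls(entries=entries)

    @classmethod
    def from_table(cls, path: str) -> "ReferenceGeneOrder":
        """Read a TSV with columns locus, chromosome, rank."""
        df = pd.read_csv(path, sep="\t", dtype={"locus": str, "chromosome": str})
        entries = {}
        for row in df.itertuples(index=False):
            try:
                _, code = parse_agi(row.locus)
            except ValueError:
                code = int(row.rank) * 10
            entries[row.locus] = (str(row.chromosome), int(row.rank), code)
        return cls(entries=entries)

    def locus_step(self, locus_a: str, locus_b: str) -> Optional[int]:
        """Rank distance between two loci; None when on different
        chromosomes or absent from the table."""
        if locus_a not in self.entries or locus_b not in self.entries:
            raise KeyError(
                f"locus absent from the reference order table: "
                f"{locus_a if locus_a not in self.entries else locus_b}"
            )
        chrom_a, _, code_a = self.entries[locus_a]
        chrom_b, _, code_b = self.entries[locus_b]
        if chrom_a != chrom_b:
            return None
        return abs(code_a - code_b) // 10


@dataclass(frozen=True)
class SyntenyPair:
    """Two insert gene sites with near-adjacent reference homologs."""

    site_a: str
    site_b: str
    locus_a: str
    locus_b: str
    intervening_insert_genes: int
    locus_step: int
    klass: str
    family_cluster: bool = False


def detect_synteny(
    sites: Sequence[GeneSite],
    order: Optional[ReferenceGeneOrder] = None,
    max_step: int = 3,
    max_intervening: int = 2,
) -> list[SyntenyPair]:
    """Report colinear and conserved-microsynteny site pairs on one insert.

    Sites must carry their best reference locus (``best_locus``);
    TE-related and EST-only sites are skipped. A pair qualifies when at
    most ``max_intervening`` eligible sites lie between the two on the
    insert and their loci share a chromosome with rank step
    <= ``max_step``. Classification: ``colinear`` iff nothing intervenes
    and the step is exactly 1; ``conserved_microsynteny`` iff the step is
    within bounds and either something intervenes or the step exceeds 1.
    Several sites sharing one best locus (a multigene-family cluster) are
    annotated ``family_cluster``.
    """
    eligible = [
        s
        for s in sorted(sites, key=lambda s: (s.start, s.end))
        if s.category not in ("te_related", "est_only") and s.best_locus
    ]
    if order is None:
        order = ReferenceGeneOrder.from_codes(
            sorted({s.best_locus for s in eligible})
        )
    locus_counts: dict[str, int] = {}
    for s in eligible:
        locus_counts[s.best_locus] = locus_counts.get(s.best_locus, 0) + 1
    pairs = []
    for i, a in enumerate(eligible):
        for j in range(i + 1, min(i + 2 + max_intervening, len(eligible))):
            b = eligible[j]
            intervening = j - i - 1
            step = order.locus_step(a.best_locus, b.best_locus)
            if step is None or step > max_step:
                continue
            if intervening == 0 and step == 1:
                klass = "colinear"
            elif intervening > 0 or step > 1:
                klass = "conserved_microsynteny"
            else:
                continue  # same locus, adjacent: a tandem array, not synteny
            pairs.append(
                SyntenyPair(
                    site_a=a.site_id,
                    site_b=b.site_id,
                    locus_a=a.best_locus,
                    locus_b=b.best_locus,
                    intervening_insert_genes=intervening,
                    locus_step=step,
                    klass=klass,
                    family_cluster=(
                        locus_counts[a.best_locus] > 1
                        or locus_counts[b.best_locus] > 1
                    ),
                )
            )
    return pairs


def pairs_to_frame(pairs: Sequence[SyntenyPair]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "site_a": p.site_a,
                "site_b": p.site_b,
                "locus_a": p.locus_a,
                "locus_b": p.locus_b,
                "intervening_insert_genes": p.intervening_insert_genes,
                "locus_step": p.locus_step,
                "klass": p.klass,
                "family_cluster": p.family_cluster,
            }
            for p in pairs
        ]
    )
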