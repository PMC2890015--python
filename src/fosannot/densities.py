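"""Study-level density and extrapolation arithmetic.

Pure integer/float arithmetic over counts: insert totals, mean insert
length, gene spacing in kb, SSR tract and operational-locus spacings,
per-Mb densities, and the physical-to-genetic extrapolation (kb/cM and
marker loci per cM). Rounding follows the conventions of printed summary
tables: spacings to 0.1 kb, per-Mb densities and kb/cM to the nearest
integer.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from typing import Optional, Sequence

from .records import FosmidRecord, GeneSite
from .ssr import GenomeContext, SSRSummary, kb_per_cM, loci_per_cM


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass
class DensitySummary:
    total_bp: int
    n_inserts: int
    mean_insert_bp: int
    n_gene_sites_non_te: int
    kb_per_gene: float
    ssr_tracts: int
    ssr_per_Mb: int
    ssr_loci: int
    kb_per_ssr_locus: Optional[float]
    kb_per_cM: int
    loci_per_cM: Optional[float]

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


def insert_totals(records: Sequence[FosmidRecord]) -> tuple[int, int, int]:
    """(total_bp, n_inserts, mean_bp); total exact, mean to nearest bp."""
    if not records:
        raise ValueError("need at least one insert")
    total = sum(r.total_length for r in records)
    n = len(records)
    return total, n, _round_half_up(total / n)


def gene_spacing_kb(n_sites_non_te: int, total_bp: int) -> float:
    """Average kb of insert sequence per (non-TE) gene site, to 0.1 kb."""
    if n_sites_non_te <= 0 or total_bp <= 0:
        raise ValueError("counts must be positive")
    return round(total_bp / n_sites_non_te / 1000, 1)


def build_density_summary(
    sites_by_insert: dict[str, list[GeneSite]],
    ssr_summary: SSRSummary,
    ctx: GenomeContext,
    records: Optional[Sequence[FosmidRecord]] = None,
) -> DensitySummary:
    """Assemble the study-level density summary.

    TE-related and EST-only sites are excluded from the gene-spacing
    denominator (it counts protein-encoding genes and pseudogenes). With
    zero SSR loci the per-locus spacing and per-cM density are reported
    as ``None`` rather than raising.
    """
    if records is not None:
        missing = set(sites_by_insert) - {r.insert_id for r in records}
        if missing:
            raise ValueError(f"sites reference unknown inserts: {sorted(missing)}")
        total_bp, n, mean_bp = insert_totals(records)
        if total_bp != ctx.total_analyzed_bp:
            raise ValueError(
                "GenomeContext.total_analyzed_bp disagrees with the insert set"
            )
    else:
        total_bp = ctx.total_analyzed_bp
        n = len(sites_by_insert)
        mean_bp = _round_half_up(total_bp / n) if n else 0
    n_non_te = sum(
        1
        for sites in sites_by_insert.values()
        for s in sites
        if s.category not in ("te_related", "est_only")
    )
    n_loci = ssr_summary.total_loci
    density = None
    if n_loci:
        density, _ = loci_per_cM(n_loci, total_bp, ctx)
    return DensitySummary(
        total_bp=total_bp,
        n_inserts=n,
        mean_insert_bp=mean_bp,
        n_gene_sites_non_te=n_non_te,
        kb_per_gene=gene_spacing_kb(n_non_te, total_bp) if n_non_te else float("nan"),
        ssr_tracts=ssr_summary.total_tracts,
        ssr_per_Mb=(
            _round_half_up(ssr_summary.total_tracts * 1e6 / total_bp)
        ),
        ssr_loci=n_loci,
        kb_per_ssr_locus=(
            round(total_bp / n_loci / 1000, 1) if n_loci else None
        ),
        kb_per_cM=kb_per_cM(ctx),
        loci_per_cM=density,
    )
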