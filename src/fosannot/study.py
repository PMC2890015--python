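"""Published inventory of the 20-insert *Fragaria vesca* targeted-fosmid
set, and the study-level genome context used for density extrapolation.

These are inputs to the summary arithmetic: the GenBank accession, clone
number, total insert length (bp), contig count, target gene, and probe
name of each sequenced fosmid, together with the diploid strawberry
genome size (206 Mb), its genetic map length (424 cM), and the headline
evidence counts established for this insert set (gene sites, SSR tracts,
operational loci, modeled genes and their introns).
"""

from __future__ import annotations

from .ssr import GenomeContext

# (accession, clone, insert length bp, contigs, target gene, probe)
FOSMID_INVENTORY: list[tuple[str, str, int, int, str, str]] = [
    ("EU024823", "01I13", 40_701, 2, "HY5", "HY5"),
    ("EU024826", "08G19", 38_293, 1, "APETALA 3", "AP3"),
    ("EU024827", "10B08", 35_178, 1, "LEAFY", "LFY"),
    ("EU024831", "13I24", 33_654, 1, "NBS-LRR resistance-like", "gRGA2"),
    ("EU024832", "14K06", 36_024, 1, "ALCOHOL DEHYDROGENASE", "ADH"),
    ("EU024837", "19H07", 32_060, 3, "SUPPRESSOR OF CONSTANS I", "SOC"),
    ("EU024838", "19M24", 32_776, 1, "NBS-LRR resistance-like", "gRGA1"),
    ("EU024845", "32L07", 32_968, 1, "NBS-LRR resistance-like", "gRGA2"),
    ("EU024847", "34E24", 36_278, 1, "NBS-LRR resistance-like", "gRGA1"),
    ("EU024852", "41O22", 32_997, 1, "TERPENE SYNTHASE", "TPS"),
    ("EU024856", "48I08", 38_603, 3, "CHALCONE ISOMERASE", "CHI"),
    ("EU024859", "49M15", 42_209, 3, "LRR resistance-like", "gLRR"),
    ("EU024860", "51F10", 29_623, 1, "PHYTOCHROME A", "PHY"),
    ("EU024861", "52B01", 29_916, 1, "CONSTANS", "CO"),
    ("EU024863", "52I20", 42_439, 1, "GRANULE-BOUND STARCH SYNTHASE-I", "GBSSI"),
    ("EU024864", "53J04", 32_846, 2, "TERPENE SYNTHASE", "TPS"),
    ("EU024865", "53O08", 31_107, 3, "DIHYDROFLAVONOL 4-REDUCTASE", "DFR"),
    ("EU024868", "73I22", 33_392, 1, "CHALCONE SYNTHASE", "CHS"),
    ("EU024870", "76C08", 44_532, 3, "REGULATOR OF ANTHOCYANIN SYNTHESIS", "RAN"),
    ("EU024871", "76K13", 32_767, 1, "PISTILLATA", "PIST"),
]

INSERT_LENGTHS_BP = [row[2] for row in FOSMID_INVENTORY]

STUDY_CONTEXT = GenomeContext(
    total_analyzed_bp=sum(INSERT_LENGTHS_BP),
    genome_size_bp=206_000_000,
    map_length_cM=424.0,
)

# headline evidence counts for this insert set
N_GENE_SITES_BLASTX = 131  # homology-supported sites at the relaxed cutoff
N_GENE_SITES_STRICT = 123  # sites already supported at the strict cutoff
N_TE_RELATED_SITES = 11
N_GENE_SITES_NON_TE = N_GENE_SITES_BLASTX - N_TE_RELATED_SITES  # 120
N_SSR_TRACTS = 158
N_SSR_LOCI = 144
N_MODELED_GENES = 15
N_INTRONS_IN_MODELS = 43
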