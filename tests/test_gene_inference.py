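"""Hit clustering, site categorization, codon inference, truncation flags,
and tandem-duplication detection."""

import pytest

from fosannot.gene_inference import (
    EvidenceParams,
    categorize_site,
    cluster_hits_to_sites,
    detect_tandem_duplicates,
    flag_truncation,
    infer_start_stop,
)
from fosannot.records import (
    BestSubject,
    FosmidRecord,
    GeneSite,
    HomologyHit,
    reverse_complement,
)


def hit(qs, qe, subject="s1", strand="+", e=1e-30, ident=90.0, desc="some protein"):
    return HomologyHit(
        query_id="ins",
        subject_id=subject,
        pct_identity=ident,
        query_start=qs,
        query_end=qe,
        strand=strand,
        e_value=e,
        bit_score=100.0,
        description=desc,
    )


class TestClustering:
    def test_single_strict_hit_forms_strict_site(self):
        (site,) = cluster_hits_to_sites([hit(100, 400, e=2.3e-39)])
        assert site.confidence_tier == "strict"
        assert (site.start, site.end) == (100, 400)

    def test_relaxed_only_hit_dropped_above_cutoff(self):
        sites = cluster_hits_to_sites([hit(100, 400, e=1e-7)])
        assert [s.confidence_tier for s in sites] == ["relaxed"]
        assert cluster_hits_to_sites([hit(100, 400, e=1e-4)]) == []

    def test_same_subject_chaining_and_strand_separation(self):
        chained = cluster_hits_to_sites([hit(100, 400), hit(900, 1200)])
        assert len(chained) == 1
        assert (chained[0].start, chained[0].end) == (100, 1200)
        split = cluster_hits_to_sites(
            [hit(100, 400), hit(900, 1200, strand="-")]
        )
        assert len(split) == 2

    def test_chain_gap_limit(self):
        params = EvidenceParams(max_chain_gap=2000)
        far = cluster_hits_to_sites([hit(100, 400), hit(2600, 2900)], params)
        assert len(far) == 2

    def test_paralog_subjects_merged_by_overlap(self):
        sites = cluster_hits_to_sites(
            [hit(100, 400, subject="a", e=1e-40), hit(150, 420, subject="b", e=1e-20)]
        )
        assert len(sites) == 1
        assert sites[0].best_subject.subject_id == "a"

    def test_strict_relaxed_partition(self):
        hits = [
            hit(100, 400, subject="a", e=1e-40),
            hit(1000, 1400, subject="b", e=1e-7),
            hit(2000, 2400, subject="c", e=1e-12),
        ]
        sites = cluster_hits_to_sites(hits)
        tiers = [s.confidence_tier for s in sites]
        assert tiers.count("strict") + tiers.count("relaxed") == len(sites)
        assert tiers == ["strict", "relaxed", "strict"]


class TestCategorize:
    def _site(self, desc, ident=90.0):
        s = GeneSite(
            site_id="x",
            insert_id="ins",
            start=1,
            end=100,
            strand="+",
            best_subject=BestSubject("sub", desc, 1e-30),
            supporting_hits=[hit(1, 100, ident=ident, desc=desc)],
        )
        return s

    @pytest.mark.parametrize(
        "desc",
        [
            "retroviral polyprotein-like",
            "putative reverse transcriptase",
            "transposase family protein",
        ],
    )
    def test_te_keywords(self, desc):
        assert categorize_site(self._site(desc)) == "te_related"

    def test_unknown_protein(self):
        assert categorize_site(self._site("unknown protein")) == "unknown"
        assert categorize_site(self._site("hypothetical protein")) == "unknown"

    def test_targeted_requires_high_identity(self):
        probes = [("CHS", "chalcone synthase")]
        high = self._site("chalcone synthase", ident=98.5)
        low = self._site("chalcone synthase", ident=92.0)
        assert categorize_site(high, probes) == "targeted"
        assert categorize_site(low, probes) == "known"

    def test_default_known(self):
        assert categorize_site(self._site("protein kinase")) == "known"


def build_plus_gene(pad5=60, pad3=60, n_codons=40):
    """A plus-strand single-exon gene with an upstream in-frame stop guard.

    Returns (record, site, start_codon, stop_codon).
    """
    body = "GCT" * (n_codons - 2)
    cds = "ATG" + body + "TGA"
    seq = "C" * pad5 + "TAA" + cds + "C" * pad3
    start = pad5 + 3 + 1
    stop = start + len(cds) - 3
    rec = FosmidRecord(insert_id="ins", contigs=[("c", seq)], gap_pad=100)
    site = GeneSite(
        site_id="g",
        insert_id="ins",
        start=start,
        end=stop - 1,  # homology covers the CDS minus the stop codon
        strand="+",
    )
    return rec, site, start, stop


class TestInferStartStop:
    def test_plus_strand_recovery(self):
        rec, site, start, stop = build_plus_gene()
        infer_start_stop(site, rec)
        assert (site.start_codon, site.stop_codon) == (start, stop)

    def test_minus_strand_recovery(self):
        rec, site, start, stop = build_plus_gene()
        rc = reverse_complement(rec.sequence)
        L = len(rc)
        rec2 = FosmidRecord(insert_id="ins", contigs=[("c", rc)], gap_pad=100)
        site2 = GeneSite(
            site_id="g",
            insert_id="ins",
            start=L - (site.end - 1),
            end=L - (site.start - 1),
            strand="-",
        )
        infer_start_stop(site2, rec2)
        assert site2.start_codon == L - (start - 1)
        assert site2.stop_codon == L - (stop - 1)

    def test_homology_region_anchored_on_atg(self):
        # the degenerate case: homology begins exactly at an in-frame ATG
        # with a guard stop immediately upstream picks that ATG
        rec, site, start, _ = build_plus_gene(pad5=0)
        # pad5=0 puts the guard at positions 1-3 and ATG at 4
        assert start == 4
        infer_start_stop(site, rec)
        assert site.start_codon == 4

    def test_most_upstream_open_atg_chosen(self):
        # two in-frame ATGs with no stop between: the 5'-most wins
        cds = "ATG" + "GCT" * 10 + "TGA"
        seq = "C" * 30 + "TAA" + "ATG" + "GCC" * 4 + cds + "C" * 30
        rec = FosmidRecord(insert_id="i", contigs=[("c", seq)], gap_pad=100)
        inner_start = 30 + 3 + 3 + 12 + 1
        site = GeneSite(
            site_id="g", insert_id="i", start=inner_start,
            end=inner_start + len(cds) - 4, strand="+",
        )
        infer_start_stop(site, rec)
        assert site.start_codon == 30 + 3 + 1

    def test_truncated_by_insert_end_leaves_stop_undetermined(self):
        body = "GCT" * 20
        seq = "C" * 30 + "TAA" + "ATG" + body  # runs off the end, no stop
        rec = FosmidRecord(insert_id="i", contigs=[("c", seq)], gap_pad=100)
        site = GeneSite(
            site_id="g", insert_id="i", start=34, end=len(seq), strand="+"
        )
        infer_start_stop(site, rec)
        assert site.start_codon == 34
        assert site.stop_codon is None

    def test_site_over_contig_gap_undetermined_with_flag(self):
        rec = FosmidRecord(
            insert_id="i", contigs=[("a", "A" * 200), ("b", "C" * 200)], gap_pad=50
        )
        site = GeneSite(site_id="g", insert_id="i", start=150, end=300, strand="+")
        infer_start_stop(site, rec)
        assert site.start_codon is None and site.stop_codon is None
        assert "contig_break" in site.truncation

    def test_planted_genes_recovered_exactly(self, study, result):
        for iid, ins in study.truth.inserts.items():
            sites = result.annotations[iid].homology_sites
            assert len(sites) == len(ins.genes)
            for g, s in zip(ins.genes, sites):
                assert (s.start, s.end) == (g.site_start, g.site_end)
                assert s.strand == g.strand
                assert s.start_codon == g.start_codon
                assert s.stop_codon == g.stop_codon
                assert s.confidence_tier == g.tier
                assert s.category == g.category


class TestTruncationFlags:
    def _rec(self, n=10_000):
        return FosmidRecord(insert_id="i", contigs=[("c", "A" * n)], gap_pad=100)

    def test_site_near_insert_end_plus_strand(self):
        rec = self._rec()
        site = GeneSite(
            site_id="g", insert_id="i", start=9000, end=9990, strand="+"
        )
        assert flag_truncation(site, rec) == {"artifactual_3p"}

    def test_site_near_insert_end_minus_strand_is_5p(self):
        rec = self._rec()
        site = GeneSite(
            site_id="g", insert_id="i", start=9000, end=9990, strand="-"
        )
        assert flag_truncation(site, rec) == {"artifactual_5p"}

    def test_biological_truncation_for_interior_short_protein(self):
        rec = self._rec()
        site = GeneSite(site_id="g", insert_id="i", start=4000, end=5000, strand="+")
        flags = flag_truncation(site, rec, homolog_len_aa=450, predicted_len_aa=200)
        assert flags == {"biological"}

    def test_full_length_interior_site_unflagged(self):
        rec = self._rec()
        site = GeneSite(site_id="g", insert_id="i", start=4000, end=5000, strand="+")
        assert flag_truncation(site, rec, homolog_len_aa=300, predicted_len_aa=300) == set()


class TestTandemDuplicates:
    def _site(self, i, start, end, strand, subject):
        return GeneSite(
            site_id=f"g{i}",
            insert_id="ins",
            start=start,
            end=end,
            strand=strand,
            best_subject=BestSubject(subject, "x", 1e-30),
        )

    def test_head_to_tail_same_minus_strand(self):
        a = self._site(1, 100, 1000, "-", "CHS")
        b = self._site(2, 3500, 4400, "-", "CHS")
        ((sa, sb, orient),) = detect_tandem_duplicates([a, b])
        assert orient == "head_to_tail"

    def test_head_to_head_divergent(self):
        a = self._site(1, 100, 1000, "-", "ADH")
        b = self._site(2, 3500, 4400, "+", "ADH")
        ((_, _, orient),) = detect_tandem_duplicates([a, b])
        assert orient == "head_to_head"

    def test_tail_to_tail_convergent(self):
        a = self._site(1, 100, 1000, "+", "TPS")
        b = self._site(2, 3500, 4400, "-", "TPS")
        ((_, _, orient),) = detect_tandem_duplicates([a, b])
        assert orient == "tail_to_tail"

    def test_unrelated_subjects_not_paired(self):
        a = self._site(1, 100, 1000, "+", "TPS")
        b = self._site(2, 3500, 4400, "+", "PPR")
        assert detect_tandem_duplicates([a, b]) == []

    def test_max_intervening_respected(self):
        a = self._site(1, 100, 1000, "+", "X")
        m1 = self._site(2, 2000, 2500, "+", "A")
        m2 = self._site(3, 3000, 3500, "+", "B")
        b = self._site(4, 4000, 5000, "+", "X")
        assert detect_tandem_duplicates([a, m1, m2, b], max_intervening=1) == []
        assert len(detect_tandem_duplicates([a, m1, m2, b], max_intervening=2)) == 1

    def test_planted_tandem_pairs_detected(self, study, result):
        for iid, ins in study.truth.inserts.items():
            planted_pairs = set()
            genes = ins.genes
            for i, g in enumerate(genes):
                for j in range(i + 1, min(i + 3, len(genes))):
                    if genes[j].subject_id == g.subject_id:
                        planted_pairs.add((g.gene_id, genes[j].gene_id))
            got = result.annotations[iid].tandem_pairs
            assert len(got) == len(planted_pairs)
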