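"""EST tiering, coverage classification, EST-only sites, gene models,
and intron statistics."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fosannot.est_support import (
    GeneModel,
    IncompleteEvidenceError,
    SpliceConflictError,
    TierParams,
    build_gene_model,
    classify_coverage,
    find_est_only_sites,
    intron_stats,
    mean_introns_per_gene,
    tier_est,
)
from fosannot.records import ESTAlignment, GeneSite, PredictedGene, PredictionTrack


def est(segments, ident=97.0, est_id="e1", strand="+"):
    return ESTAlignment(
        est_id=est_id, pct_identity=ident, segments=segments, strand=strand
    )


def site(start, end, strand="+", start_codon=None, stop_codon=None, sid="s1"):
    s = GeneSite(
        site_id=sid, insert_id="ins", start=start, end=end, strand=strand
    )
    s.start_codon = start_codon
    s.stop_codon = stop_codon
    return s


class TestTiering:
    @pytest.mark.parametrize(
        "identity,expected",
        [
            (95.08, "top"),  # the marginal top-tier case
            (95.0, "top"),
            (94.999, "second"),
            (94.0, "second"),
            (85.0, "second"),
            (84.9, "unclassified"),
        ],
    )
    def test_tier_bands(self, identity, expected):
        assert tier_est(est([(1, 100)], ident=identity)) == expected

    def test_identity_outside_range_rejected(self):
        with pytest.raises(ValueError):
            ESTAlignment(est_id="e", pct_identity=101.0, segments=[(1, 10)])

    @given(st.floats(min_value=0, max_value=100, allow_nan=False))
    @settings(max_examples=120, deadline=None, derandomize=True)
    def test_tiering_is_a_partition(self, identity):
        tiers = [tier_est(est([(1, 10)], ident=identity))]
        assert tiers[0] in ("top", "second", "unclassified")


class TestCoverage:
    def test_two_ests_tiling_full_cds(self):
        ests = [est([(100, 250)], est_id="a"), est([(251, 400)], est_id="b")]
        assert classify_coverage(site(100, 400), (100, 400), ests) == "complete"

    def test_spliced_est_covers_across_introns(self):
        # transcript-level: the EST's internal gap is a spliced intron
        spliced = est([(100, 200), (500, 700)])
        assert classify_coverage(site(100, 700), (100, 700), [spliced]) == "complete"

    def test_ends_only_coverage_is_partial(self):
        ests = [est([(100, 150)], est_id="a"), est([(380, 400)], est_id="b")]
        assert classify_coverage(site(100, 400), (100, 400), ests) == "partial"

    def test_no_overlap_is_none(self):
        assert classify_coverage(site(100, 400), (100, 400), [est([(900, 990)])]) == "none"

    def test_adding_an_est_never_demotes(self):
        extent = (100, 400)
        base = [est([(100, 200)], est_id="a")]
        more = base + [est([(180, 400)], est_id="b")]
        order = {"none": 0, "partial": 1, "complete": 2}
        assert (
            order[classify_coverage(site(*extent), extent, more)]
            >= order[classify_coverage(site(*extent), extent, base)]
        )


class TestEstOnlySites:
    def _track(self, spans):
        track = PredictionTrack(model_name="At")
        track.genes["ins"] = [
            PredictedGene(gene_id=f"p{i}", start=s, end=e, strand="+")
            for i, (s, e) in enumerate(spans)
        ]
        return track

    def test_unmatched_top_tier_est_creates_site(self):
        sites = find_est_only_sites(
            [est([(5000, 5600)])], [site(100, 400)], [self._track([(100, 400)])],
            "ins", insert_length=10_000,
        )
        assert len(sites) == 1
        assert sites[0].category == "est_only"
        assert (sites[0].start, sites[0].end) == (5000, 5600)

    def test_est_inside_existing_site_ignored(self):
        assert (
            find_est_only_sites(
                [est([(150, 300)])], [site(100, 400)], [], "ins", 10_000
            )
            == []
        )

    def test_second_tier_est_ignored(self):
        assert (
            find_est_only_sites(
                [est([(5000, 5600)], ident=90.0)], [site(100, 400)], [], "ins", 10_000
            )
            == []
        )

    def test_overlapping_ests_cluster_into_one_site(self):
        ests = [
            est([(5000, 5600)], est_id="a"),
            est([(5400, 5900)], est_id="b"),
            est([(8000, 8400)], est_id="c"),
        ]
        sites = find_est_only_sites(ests, [], [], "ins", 10_000)
        assert [(s.start, s.end) for s in sites] == [(5000, 5900), (8000, 8400)]

    def test_boundary_site_flagged_artifactual(self):
        (s,) = find_est_only_sites([est([(10, 300)])], [], [], "ins", 10_000)
        assert s.truncation == {"artifactual_5p"}

    def test_planted_est_only_loci_recovered(self, study, result):
        for iid, ins in study.truth.inserts.items():
            got = [
                (s.start, s.end)
                for s in result.annotations[iid].sites
                if s.category == "est_only"
            ]
            assert got == list(ins.est_only_loci)


class TestGeneModel:
    def _complete_site(self):
        # cds 100..400 (+), one intron 201..299
        s = site(100, 400, start_codon=100, stop_codon=398)
        ests = [est([(100, 200), (300, 400)])]
        return s, ests

    def test_single_intron_model(self):
        s, ests = self._complete_site()
        model = build_gene_model(s, ests)
        assert model.exons == [(100, 200), (300, 400)]
        assert model.introns == [(201, 299)]
        assert model.intron_count == 1

    def test_two_intron_model(self):
        s = site(100, 700, start_codon=100, stop_codon=698)
        ests = [est([(100, 200), (300, 400), (500, 700)])]
        model = build_gene_model(s, ests)
        assert model.intron_count == 2
        assert model.intron_lengths == [99, 99]

    def test_single_exon_model_has_zero_introns(self):
        s = site(100, 400, start_codon=100, stop_codon=398)
        model = build_gene_model(s, [est([(100, 400)])])
        assert model.intron_count == 0

    def test_incomplete_coverage_refused(self):
        s = site(100, 400, start_codon=100, stop_codon=398)
        with pytest.raises(IncompleteEvidenceError, match="partial"):
            build_gene_model(s, [est([(100, 250)])])

    def test_undetermined_codons_refused(self):
        s = site(100, 400)
        with pytest.raises(IncompleteEvidenceError, match="undetermined"):
            build_gene_model(s, [est([(100, 400)])])

    def test_conflicting_splice_boundaries_reported(self):
        s = site(100, 400, start_codon=100, stop_codon=398)
        conflicting = [
            est([(100, 200), (300, 400)], est_id="a"),  # intron 201-299
            est([(100, 250), (320, 400)], est_id="b"),  # says 251-319
        ]
        with pytest.raises(SpliceConflictError, match="implies intron"):
            build_gene_model(s, conflicting)

    def test_planted_models_recovered_exactly(self, study, result):
        n_checked = 0
        for iid, ins in study.truth.inserts.items():
            ann = result.annotations[iid]
            for g, s in zip(ins.genes, ann.homology_sites):
                if g.coverage_class != "complete":
                    continue
                model = ann.models[s.site_id]
                assert model.exons == g.exons
                assert model.introns == g.introns
                n_checked += 1
        assert n_checked > 0


class TestIntronStats:
    def _model(self, intron_lengths, sid="m"):
        exons = []
        cursor = 1
        introns = []
        for length in intron_lengths:
            exons.append((cursor, cursor + 99))
            introns.append((cursor + 100, cursor + 100 + length - 1))
            cursor += 100 + length
        exons.append((cursor, cursor + 99))
        return GeneModel(
            site_id=sid,
            exons=exons,
            introns=introns,
            cds_start=1,
            cds_end=exons[-1][1],
        )

    def test_study_scale_mean(self):
        assert mean_introns_per_gene(43, 15) == 2.87

    def test_stats_over_models(self):
        models = [self._model([100, 200]), self._model([500]), self._model([])]
        stats = intron_stats(models, length_threshold=150)
        assert stats.total_introns == 3
        assert stats.mean_per_gene == 1.0
        assert (stats.min_per_gene, stats.max_per_gene) == (0, 2)
        assert stats.mean_intron_length == round((100 + 200 + 500) / 3)
        assert stats.n_below_threshold == 1
        assert stats.n_below_mean_length == 2

    def test_zero_intron_degenerate(self):
        stats = intron_stats([self._model([])])
        assert stats.mean_per_gene == 0.0
        assert stats.mean_intron_length is None

    def test_empty_model_list_rejected(self):
        with pytest.raises(ValueError):
            intron_stats([])
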