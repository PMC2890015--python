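"""SSR scanning, motif canonicalization, locus merging, and densities."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fosannot.ssr import (
    GenomeContext,
    SSRScanParams,
    SSRTract,
    canonical_motif,
    is_primitive,
    kb_per_cM,
    loci_per_cM,
    merge_operational_loci,
    scan_ssrs,
    ssr_density_per_Mb,
    summarize_ssrs,
)

STUDY_CTX = GenomeContext(
    total_analyzed_bp=708_363, genome_size_bp=206_000_000, map_length_cM=424.0
)


def brute_force_ssrs(seq, min_unit=2, max_unit=5, min_repeats=5):
    """Quadratic enumerator over every (position, unit_length) pair.

    Reports left-aligned whole-unit maximal tracts of primitive units,
    one per maximal periodic region, exactly like the scanner's contract
    but computed by direct substring comparison.
    """
    n = len(seq)
    out = []
    for k in range(min_unit, max_unit + 1):
        for a in range(n - k * min_repeats + 1):
            unit = seq[a : a + k]
            if any(c not in "ACGT" for c in unit):
                continue
            if not is_primitive(unit):
                continue
            r = 1
            while seq[a + r * k : a + (r + 1) * k] == unit:
                r += 1
            if r < min_repeats:
                continue
            # a must start its periodic region: the period-k match must
            # fail just before it
            if a > 0 and seq[a - 1] in "ACGT" and seq[a - 1] == seq[a - 1 + k]:
                continue
            out.append((a + 1, a + r * k, k, r))
    return sorted(out)


class TestScan:
    def test_interrupted_tract_counts_as_two(self):
        seq = "TCCTCCTCCTCCTCCTCCTCTTCCTCCTCCTCCTCC"
        tracts = scan_ssrs(seq)
        assert [(t.motif, t.repeat_count) for t in tracts] == [("TCC", 6), ("TCC", 5)]
        gap = tracts[1].start - tracts[0].end - 1
        assert gap == 3

    def test_no_qualifying_repeat(self):
        assert scan_ssrs("ACGTACGCATG") == []

    def test_tract_terminated_by_n(self):
        assert scan_ssrs("AG" * 4 + "N" + "AG" * 4) == []
        (t,) = scan_ssrs("AG" * 5 + "N" + "AG" * 4)
        assert (t.start, t.end) == (1, 10)

    def test_mononucleotide_runs_excluded(self):
        assert scan_ssrs("A" * 30) == []

    def test_composite_unit_not_double_reported(self):
        tracts = scan_ssrs("AT" * 10)
        assert [(t.unit_length, t.repeat_count) for t in tracts] == [(2, 10)]

    def test_partial_trailing_unit_outside_tract(self):
        (t,) = scan_ssrs("G" + "CAT" * 6 + "CA" + "G" * 3)
        assert (t.start, t.end, t.repeat_count) == (2, 19, 6)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_on_random_sequences(self, seed):
        rng = np.random.default_rng(seed)
        # repeat-rich alphabet choices stress phase and composite handling
        alphabet = ["ACGT", "AT", "ACG", "ACGTN"][seed % 4]
        seq = "".join(
            alphabet[i] for i in rng.integers(0, len(alphabet), 2000)
        )
        got = [(t.start, t.end, t.unit_length, t.repeat_count) for t in scan_ssrs(seq)]
        assert got == brute_force_ssrs(seq)


class TestCanonical:
    def test_dinucleotide_folds_reverse_complement(self):
        assert canonical_motif("CT", "rotation_rc") == "AG"
        assert canonical_motif("GA", "rotation_rc") == "AG"
        assert canonical_motif("TA", "rotation_rc") == "AT"

    def test_trinucleotide_rotation_only(self):
        assert canonical_motif("GAA", "rotation") == "AAG"
        assert canonical_motif("AGA", "rotation") == "AAG"
        # ACT and AGT are reverse complements but stay distinct classes
        assert canonical_motif("ACT", "per_unit_length") != canonical_motif(
            "AGT", "per_unit_length"
        )

    def test_non_primitive_motif_rejected(self):
        for mode in ("rotation", "rotation_rc", "per_unit_length"):
            with pytest.raises(ValueError, match="primitive"):
                canonical_motif("ATAT", mode)

    @given(
        motif=st.text(alphabet="ACGT", min_size=2, max_size=5),
        rot=st.integers(0, 4),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_rotation_invariance(self, motif, rot):
        if not is_primitive(motif):
            return
        rotated = motif[rot % len(motif):] + motif[: rot % len(motif)]
        for mode in ("rotation", "rotation_rc", "per_unit_length"):
            assert canonical_motif(motif, mode) == canonical_motif(rotated, mode)


def _tract(start, unit, repeats, insert_id="i"):
    return SSRTract(
        insert_id=insert_id,
        start=start,
        end=start + len(unit) * repeats - 1,
        motif=unit,
        canonical_motif=canonical_motif(unit),
        unit_length=len(unit),
        repeat_count=repeats,
    )


class TestLocusMerging:
    def test_close_pair_is_one_locus(self):
        tracts = scan_ssrs("TCCTCCTCCTCCTCCTCCTCTTCCTCCTCCTCCTCC")
        (locus,) = merge_operational_loci(tracts, 100)
        assert len(locus.tracts) == 2

    def test_gap_of_exactly_merge_gap_does_not_merge(self):
        a = _tract(1, "AG", 5)
        b = _tract(a.end + 1 + 100, "AT", 5)
        assert len(merge_operational_loci([a, b], 100)) == 2
        c = _tract(a.end + 1 + 99, "AT", 5)
        assert len(merge_operational_loci([a, c], 100)) == 1

    def test_transitive_chain(self):
        a = _tract(1, "AG", 5)
        b = _tract(a.end + 51, "AT", 5)
        c = _tract(b.end + 51, "AC", 5)
        (locus,) = merge_operational_loci([a, b, c], 100)
        assert len(locus.tracts) == 3
        assert (locus.start, locus.end) == (a.start, c.end)

    def test_mixed_inserts_rejected(self):
        with pytest.raises(ValueError, match="multiple inserts"):
            merge_operational_loci([_tract(1, "AG", 5, "a"), _tract(500, "AG", 5, "b")])

    @given(st.data())
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_monotonicity_in_merge_gap(self, data):
        starts = sorted(
            data.draw(
                st.lists(st.integers(1, 3000), min_size=1, max_size=8, unique=True)
            )
        )
        tracts = []
        cursor = 0
        for s in starts:
            start = max(s, cursor + 1)
            t = _tract(start, "AG", 5)
            tracts.append(t)
            cursor = t.end
        g1 = data.draw(st.integers(0, 200))
        g2 = data.draw(st.integers(0, 200))
        lo, hi = sorted((g1, g2))
        assert len(merge_operational_loci(tracts, hi)) <= len(
            merge_operational_loci(tracts, lo)
        )


class TestDensities:
    @pytest.mark.parametrize(
        "count,total,expected",
        [(158, 708_363, 223), (123, 708_363, 174), (35, 708_363, 49), (0, 1000, 0)],
    )
    def test_per_mb_density(self, count, total, expected):
        assert ssr_density_per_Mb(count, total) == expected

    def test_kb_per_cm_ratio(self):
        assert kb_per_cM(STUDY_CTX) == 486

    def test_loci_per_cm(self):
        density, ratio = loci_per_cM(144, 708_363, STUDY_CTX)
        assert ratio == 486
        assert round(density, 1) == 98.8

    def test_unit_locus_density(self):
        ctx = GenomeContext(
            total_analyzed_bp=485_849,
            genome_size_bp=206_000_000,
            map_length_cM=424.0,
        )
        density, _ = loci_per_cM(1, 485_849, ctx)
        assert round(density, 2) == 1.0


class TestSummary:
    def test_summary_totals_and_spacing(self):
        rng = np.random.default_rng(0)
        tracts = []
        cursor = 1
        for _ in range(20):
            unit = ["AG", "AT", "AAG"][rng.integers(0, 3)]
            t = _tract(cursor, unit, int(rng.integers(5, 12)))
            tracts.append(t)
            cursor = t.end + 200
        loci = merge_operational_loci(tracts, 100)
        ctx = GenomeContext(
            total_analyzed_bp=90_000, genome_size_bp=206_000_000, map_length_cM=424.0
        )
        summary = summarize_ssrs(tracts, loci, ctx)
        assert summary.total_tracts == 20
        assert summary.per_class["count"].sum() == 20
        assert summary.per_unit_length["count"].sum() == 20
        assert summary.kb_per_tract == round(90_000 / 20 / 1000, 1)

    def test_study_scale_spacings(self):
        # printed-count arithmetic: 158 tracts and 144 loci in 708,363 bp
        assert round(708_363 / 158 / 1000, 1) == 4.5
        assert round(708_363 / 144 / 1000, 1) == 4.9

    def test_empty_inputs_give_zero_table(self):
        summary = summarize_ssrs([], [], STUDY_CTX)
        assert summary.total_tracts == 0
        assert summary.kb_per_tract is None
        assert summary.loci_per_cM is None


class TestPlantedRecovery:
    def test_every_planted_tract_recovered_exactly(self, study, result):
        for iid, ins in study.truth.inserts.items():
            found = {
                (t.start, t.end, t.motif, t.repeat_count)
                for t in result.annotations[iid].tracts
            }
            planted = {
                (t.start, t.end, t.motif, t.repeat_count) for t in ins.ssr_tracts
            }
            assert found == planted

    def test_operational_loci_match_planted_groups(self, study, result):
        for iid, ins in study.truth.inserts.items():
            got = [
                tuple((t.start, t.end) for t in locus.tracts)
                for locus in result.annotations[iid].loci
            ]
            expected = sorted(
                tuple((t.start, t.end) for t in group)
                for group in ins.expected_loci()
            )
            assert sorted(got) == expected

    def test_motif_classes_match_planted(self, study, result):
        for iid, ins in study.truth.inserts.items():
            got = {(t.start, t.canonical_motif) for t in result.annotations[iid].tracts}
            planted = {(t.start, t.canonical) for t in ins.ssr_tracts}
            assert got == planted
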