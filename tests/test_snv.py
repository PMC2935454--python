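"""Unit and property tests for the tiered SNV classifier."""

from __future__ import annotations

import io
import random
from collections import Counter

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aviangen import snv
from aviangen.snv import (
    GAP,
    LONG_READ_PLATFORM,
    SHORT_READ_PLATFORM,
    PileupColumn,
    PileupError,
    ReadObservation,
    SNVThresholds,
)
from conftest import make_column, oracle_classify, random_column


class TestGapQuality:
    @pytest.mark.parametrize(
        "flanks,expected",
        [((20, 35), 20), ((30, 30), 30), ((25, None), 25), ((None, 25), 25)],
    )
    def test_minimum_of_available_flanks(self, flanks, expected):
        col = make_column([("A", 30)])
        obs = ReadObservation(GAP, 0, SHORT_READ_PLATFORM, "g", flanks)
        assert snv.assign_gap_quality(col, obs) == expected

    def test_gap_without_flanks_is_unusable(self):
        col = make_column([("A", 30)])
        obs = ReadObservation(GAP, 0, SHORT_READ_PLATFORM, "g", (None, None))
        with pytest.raises(PileupError):
            snv.assign_gap_quality(col, obs)

    def test_non_gap_rejected(self):
        col = make_column([("A", 30)])
        with pytest.raises(PileupError):
            snv.assign_gap_quality(col, col.observations[0])


class TestHomopolymerPredicate:
    def test_deletion_in_run(self):
        col = make_column([("A", 30), (GAP, 30)], consensus="A", left="CAA", right="AAG")
        assert snv.is_homopolymer_indel(col, min_run=2)

    def test_insertion_between_different_bases(self):
        col = make_column([("C", 30), (GAP, 30)], consensus="C", left="GA", right="GT")
        assert not snv.is_homopolymer_indel(col, min_run=2)

    @pytest.mark.parametrize("min_run", [2, 3, 4, 5])
    def test_run_length_boundary(self, min_run):
        # run of exactly min_run-1 fails, exactly min_run passes; enumerate
        # left/right splits of the surrounding run
        for total in (min_run - 1, min_run):
            hit_any = False
            for n_left in range(total):
                n_right = total - 1 - n_left
                col = make_column(
                    [("A", 30), (GAP, 30)],
                    consensus="A",
                    left="C" + "A" * n_left,
                    right="A" * n_right + "C",
                )
                got = snv.is_homopolymer_indel(col, min_run=min_run)
                assert got == (total >= min_run)
                hit_any = True
            assert hit_any


class TestVariantEvidence:
    def test_two_alleles_tallied(self):
        col = make_column([("A", 30)] * 4 + [("G", 25)] * 3)
        ev = snv.variant_evidence(col)
        assert [(e.allele, e.support) for e in ev] == [("A", 4), ("G", 3)]

    def test_uniform_column_single_entry(self):
        ev = snv.variant_evidence(make_column([("T", 20)] * 6))
        assert len(ev) == 1 and ev[0].support == 6

    def test_n_observations_excluded(self):
        ev = snv.variant_evidence(make_column([("A", 30), ("N", 30), ("N", 30)]))
        assert [e.allele for e in ev] == ["A"]

    def test_supports_match_exhaustive_tally(self):
        rng = random.Random(7)
        for _ in range(200):
            col = random_column(rng)
            counts = Counter(o.symbol for o in col.observations if o.symbol != "N")
            ev = snv.variant_evidence(col)
            assert {e.allele: e.support for e in ev} == dict(counts)
            # sorted by support desc, allele asc
            keys = [(-e.support, e.allele) for e in ev]
            assert keys == sorted(keys)


class TestClassifyColumn:
    def test_strong_when_all_criteria_met(self, thresholds):
        col = make_column([("A", 30)] * 10 + [("G", 28)] * 6, consensus="A")
        assert col.depth == 16
        assert snv.classify_column(col, thresholds) == "strong"

    def test_depth_cap_demotes_to_weak(self, thresholds):
        col = make_column(
            [("A", 30)] * 22 + [("G", 28)] * 13, consensus="A"
        )  # depth 35 > 30
        assert snv.classify_column(col, thresholds) == "weak"

    def test_homopolymer_indel_needs_short_read_support(self, thresholds):
        # gap allele only ever seen on the long-read platform -> no tier
        obs = [("A", 30, SHORT_READ_PLATFORM)] * 8 + [(GAP, 30, LONG_READ_PLATFORM)] * 5
        col = make_column(obs, consensus="A", left="CAA", right="AG")
        assert snv.classify_column(col, thresholds) == "none"
        # one short-read gap observation rescues it
        rescued = obs + [(GAP, 30, SHORT_READ_PLATFORM)]
        col2 = make_column(rescued, consensus="A", left="CAA", right="AG")
        assert snv.classify_column(col2, thresholds) == "strong"

    def test_matches_brute_force_oracle(self, thresholds):
        rng = random.Random(42)
        for _ in range(2000):
            col = random_column(rng)
            assert snv.classify_column(col, thresholds) == oracle_classify(col, thresholds)

    def test_bad_thresholds_rejected(self):
        with pytest.raises(PileupError):
            SNVThresholds(strong_min_support=0)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        seed=st.integers(0, 10_000),
        extra_quality=st.integers(0, 45),
    )
    def test_extra_supporting_read_never_demotes_to_none(self, seed, extra_quality):
        """Adding a read behind an existing allele only adds evidence: a
        weak/strong column never drops to none (the strong depth cap may
        demote strong to weak, which is allowed)."""
        rng = random.Random(seed)
        col = random_column(rng)
        before = snv.classify_column(col)
        if before == "none":
            return
        target = snv.variant_evidence(col)[0].allele
        flanks = (extra_quality, extra_quality) if target == GAP else (None, None)
        extra = ReadObservation(
            target, extra_quality, SHORT_READ_PLATFORM, "extra", flanks
        )
        bigger = PileupColumn(
            col.contig,
            col.position,
            col.consensus,
            col.observations + [extra],
            col.left_context,
            col.right_context,
        )
        assert snv.classify_column(bigger) != "none"


class TestCallSnvs:
    def test_concordant_columns_yield_nothing(self):
        cols = [make_column([("A", 30)] * 10, position=i) for i in range(5)]
        assert snv.call_snvs(cols) == []

    def test_multiallelic_flag(self):
        col = make_column([("A", 30)] * 5 + [("C", 30)] * 5 + [("G", 30)] * 5)
        calls = snv.call_snvs([col])
        assert len(calls) == 1 and calls[0].multiallelic

    def test_unsorted_input_rejected(self):
        cols = [make_column([("A", 30)], position=5), make_column([("A", 30)], position=2)]
        with pytest.raises(PileupError):
            snv.call_snvs(cols)

    def test_indel_kind(self):
        col = make_column(
            [("A", 30)] * 5 + [(GAP, 30)] * 5, consensus="A", left="CG", right="GC"
        )
        (call,) = snv.call_snvs([col])
        assert call.kind == "indel" and call.tier == "strong"


class TestSubstitutionClass:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ("A", "G", "transition"),
            ("C", "T", "transition"),
            ("A", "C", "transversion"),
            ("G", "T", "transversion"),
        ],
    )
    def test_classes(self, a, b, expected):
        assert snv.substitution_class(a, b) == expected
        assert snv.substitution_class(b, a) == expected

    def test_invalid_inputs(self):
        with pytest.raises(PileupError):
            snv.substitution_class("A", "A")
        with pytest.raises(PileupError):
            snv.substitution_class("A", "N")


class TestSummary:
    def test_simple_ratio(self):
        calls = [
            snv.call_snvs([make_column([("A", 30)] * 5 + [("G", 30)] * 5, position=i)])[0]
            for i in range(2)
        ] + snv.call_snvs([make_column([("A", 30)] * 5 + [("C", 30)] * 5, position=2)])
        summary = snv.summarize_calls(calls)
        assert (summary.transitions, summary.transversions) == (2, 1)
        assert summary.ts_tv == 2.0

    def test_empty_input(self):
        summary = snv.summarize_calls([])
        assert summary.n_total == 0 and summary.ts_tv is None
        assert not summary.ratio_defined
        assert summary.depth_mean is None

    def test_permutation_invariance(self):
        cols = [
            make_column([("A", 30)] * 5 + [("G", 30)] * 4, position=i) for i in range(6)
        ]
        calls = snv.call_snvs(cols)
        shuffled = list(reversed(calls))
        a, b = snv.summarize_calls(calls), snv.summarize_calls(shuffled)
        assert a == b


class TestWattersonTheta:
    def test_zero_segregating_sites(self):
        assert snv.watterson_theta(0, 1000, 5).theta == 0.0

    def test_two_sequences(self):
        est = snv.watterson_theta(5, 1000, 2)
        assert est.a == 1.0 and est.theta == pytest.approx(0.005)

    def test_harmonic_normalizer(self):
        est = snv.watterson_theta(11, 1000, 4)
        assert est.a == pytest.approx(11 / 6)
        assert est.theta == pytest.approx(0.006)

    @given(s=st.integers(0, 100), k=st.integers(2, 10))
    @settings(deadline=None, derandomize=True)
    def test_linear_in_s(self, s, k):
        base = snv.watterson_theta(s, 500, 6).theta
        scaled = snv.watterson_theta(s * k, 500, 6).theta
        assert scaled == pytest.approx(base * k)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            snv.watterson_theta(1, 0, 2)
        with pytest.raises(ValueError):
            snv.watterson_theta(1, 10, 1)


class TestVcf:
    reference = {"c1": "GATTACAAAGT"}

    def test_empty_calls_header_only(self):
        text = snv.write_vcf([], self.reference)
        body = [l for l in text.splitlines() if l and not l.startswith("#")]
        assert body == []

    def test_substitution_coordinate_shift(self):
        col = make_column(
            [("T", 30)] * 5 + [("G", 30)] * 5, consensus="T", position=9, contig="c1"
        )
        calls = snv.call_snvs([col])
        rec = snv.read_vcf(snv.write_vcf(calls, self.reference))[0]
        assert rec["pos0"] == 9 and rec["ref"] == "G"  # reference base at index 9

    def test_deletion_left_normalized(self):
        # deleting any A of the AAA run at indices 6-8 normalizes to the run
        # start, anchored on the C at index 5
        col = make_column(
            [("A", 30)] * 5 + [(GAP, 30)] * 5,
            consensus="A",
            position=8,
            contig="c1",
            left="ACAA",
            right="GT",
        )
        calls = snv.call_snvs([col])
        line = [
            l for l in snv.write_vcf(calls, self.reference).splitlines()
            if not l.startswith("#")
        ][0]
        chrom, pos, _, ref, alt = line.split("\t")[:5]
        assert (pos, ref, alt) == ("6", "CA", "C")

    def test_round_trip_preserves_call_fields(self):
        cols = [
            make_column([("T", 30)] * 6 + [("G", 28)] * 4, consensus="T", position=2,
                        contig="c1"),
            make_column([("A", 30)] * 3 + [("C", 20)] * 2, consensus="A", position=4,
                        contig="c1"),
        ]
        calls = snv.call_snvs(cols)
        recs = snv.read_vcf(snv.write_vcf(calls, self.reference))
        assert len(recs) == len(calls)
        for call, rec in zip(calls, recs):
            assert rec["tier"] == call.tier
            assert rec["kind"] == call.kind
            assert rec["depth"] == call.depth
            assert rec["supports"] == [a.support for a in call.alleles]
            assert rec["multiallelic"] == call.multiallelic

    def test_pysam_parses_output(self, tmp_path):
        pysam = pytest.importorskip("pysam")
        col = make_column(
            [("T", 30)] * 5 + [("G", 30)] * 5, consensus="T", position=9, contig="c1"
        )
        path = tmp_path / "calls.vcf"
        path.write_text(snv.write_vcf(snv.call_snvs([col]), self.reference))
        with pysam.VariantFile(str(path)) as vf:
            recs = list(vf)
        assert len(recs) == 1
        assert recs[0].pos == 10  # 1-based
        assert recs[0].info["TIER"] == "strong"

    def test_position_outside_reference(self):
        col = make_column([("T", 30)] * 5 + [("G", 30)] * 5, position=99, contig="c1")
        with pytest.raises(PileupError):
            snv.write_vcf(snv.call_snvs([col]), self.reference)


class TestPileupIO:
    def test_tsv_round_trip(self):
        rng = random.Random(3)
        cols = [random_column(rng, position=i) for i in range(20)]
        buf = io.StringIO()
        snv.write_pileup_tsv(cols, buf)
        buf.seek(0)
        back = snv.read_pileup_tsv(buf)
        assert len(back) == len(cols)
        for a, b in zip(cols, back):
            assert (a.contig, a.position, a.consensus) == (b.contig, b.position, b.consensus)
            assert a.left_context == b.left_context
            # classification is invariant under the round trip (gap
            # qualities were materialized at write time)
            assert snv.classify_column(a) == snv.classify_column(b)

    def test_sam_adapter_builds_columns(self, tmp_path):
        pytest.importorskip("pysam")
        ref = {"c1": "ACGTACGTAA"}
        sam = "\n".join(
            [
                "@HD\tVN:1.6\tSO:coordinate",
                "@SQ\tSN:c1\tLN:10",
                "@RG\tID:ill\tPL:short-read",
                # read2 carries a deletion of the base at 0-based position 4
                "r1\t0\tc1\t1\t60\t8M\t*\t0\t0\tACGTACGT\tIIIIIIII\tRG:Z:ill",
                "r2\t0\tc1\t1\t60\t4M1D3M\t*\t0\t0\tACGTCGT\tIIIIIII\tRG:Z:ill",
            ]
        )
        path = tmp_path / "toy.sam"
        path.write_text(sam + "\n")
        cols = snv.columns_from_alignment(str(path), ref)
        by_pos = {c.position: c for c in cols}
        gap_obs = [o for o in by_pos[4].observations if o.symbol == GAP]
        assert len(gap_obs) == 1
        assert snv.assign_gap_quality(by_pos[4], gap_obs[0]) == 40  # 'I' = Q40
        assert by_pos[0].depth == 2
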