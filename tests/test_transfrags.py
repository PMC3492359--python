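import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from isncrna.annotation import AnnotatedGenome, AnnotationRecord, GenomicInterval
from isncrna.coverage import CoverageTrack
from isncrna.transfrags import (
    DetectionReport,
    Transfrag,
    call_transfrags,
    detection_rate,
    filter_novel,
    merge_novel,
    tss_profile,
)
from conftest import brute_force_runs


def _track(values, chrom="c", strand="+", sample_id="s1", length=None):
    track = CoverageTrack({chrom: length or len(values)}, sample_id=sample_id)
    track.array(chrom, strand)[: len(values)] = values
    return track


def _plain_genome(length=1000, records=()):
    return AnnotatedGenome({"c": length}, records)


class TestCallTransfrags:
    def test_two_runs_with_statistics(self):
        tfs = call_transfrags(_track([0, 0, 5, 5, 5, 0, 7, 7, 0]))
        assert [(t.interval.start, t.interval.end) for t in tfs] == [(2, 5), (6, 8)]
        assert [t.length for t in tfs] == [3, 2]
        assert [t.mean_coverage for t in tfs] == [5.0, 7.0]
        assert tfs[0].sample_ids == ("s1",)

    def test_zero_track_empty(self):
        assert call_transfrags(_track([0.0] * 10)) == []

    def test_single_gap_breaks_run(self):
        tfs = call_transfrags(_track([1, 1, 0, 1, 1]))
        assert len(tfs) == 2

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 10, allow_nan=False), min_size=1, max_size=80))
    def test_matches_brute_force_run_scan(self, values):
        vec = np.array(values)
        tfs = call_transfrags(_track(vec))
        expected = brute_force_runs(vec)
        got = [
            (t.interval.start, t.interval.end, t.mean_coverage, t.max_coverage) for t in tfs
        ]
        assert len(got) == len(expected)
        for g, e in zip(got, expected):
            assert g[:2] == e[:2]
            assert g[2] == pytest.approx(e[2])
            assert g[3] == pytest.approx(e[3])


class TestFilterNovel:
    def test_low_coverage_boundary(self):
        genome = _plain_genome()
        tfs = call_transfrags(_track([5.99] * 50, length=1000))
        assert filter_novel(tfs, genome)[0].status == "rejected_low_coverage"
        tfs = call_transfrags(_track([6.0] * 50, length=1000))
        assert filter_novel(tfs, genome)[0].status == "novel_retained"

    def test_short_boundary(self):
        genome = _plain_genome()
        tfs = call_transfrags(_track([10.0] * 35, length=1000))
        assert filter_novel(tfs, genome)[0].status == "rejected_short"
        tfs = call_transfrags(_track([10.0] * 36, length=1000))
        assert filter_novel(tfs, genome)[0].status == "novel_retained"

    @pytest.mark.parametrize("strand", "+-")
    def test_retained_short_transfrag_extended_downstream(self, strand):
        genome = _plain_genome()
        track = CoverageTrack({"c": 1000})
        track.array("c", strand)[500:540] = 6.0
        (tf,) = filter_novel(call_transfrags(track), genome)
        assert tf.status == "novel_retained"
        assert tf.length == 70
        if strand == "+":
            assert (tf.interval.start, tf.interval.end) == (500, 570)
        else:
            assert (tf.interval.start, tf.interval.end) == (470, 540)
        # coverage statistics refer to the pre-extension run
        assert tf.mean_coverage == 6.0
        assert tf.source_interval.start == 500 and tf.source_interval.end == 540

    def test_extension_clipped_at_chromosome_end(self):
        genome = _plain_genome(length=560)
        track = CoverageTrack({"c": 560})
        track.array("c", "+")[520: 560] = 8.0
        (tf,) = filter_novel(call_transfrags(track), genome)
        assert tf.interval.end == 560  # clipped

    def test_same_strand_ncrna_overlap_rejected_antisense_kept(self):
        rec = AnnotationRecord(
            GenomicInterval("c", 100, 160, "+"), "ncRNA", "n1", ncrna_class="snoRNA"
        )
        genome = _plain_genome(records=[rec])
        for strand, expected in (("+", "rejected_annotated"), ("-", "novel_retained")):
            track = CoverageTrack({"c": 1000})
            track.array("c", strand)[120:200] = 10.0
            (tf,) = filter_novel(call_transfrags(track), genome)
            assert tf.status == expected

    def test_exon_and_intron_overlap_survive(self):
        records = [
            AnnotationRecord(GenomicInterval("c", 100, 200, "+"), "exon", "e1"),
            AnnotationRecord(GenomicInterval("c", 200, 400, "+"), "intron", "i1"),
        ]
        genome = _plain_genome(records=records)
        track = CoverageTrack({"c": 1000})
        track.array("c", "+")[150:300] = 10.0
        (tf,) = filter_novel(call_transfrags(track), genome)
        assert tf.status == "novel_retained"

    def test_idempotent_and_order_independent(self, rng):
        genome = _plain_genome()
        track = CoverageTrack({"c": 1000})
        arr = track.array("c", "+")
        for s in (10, 100, 300, 600, 900):
            arr[s : s + int(rng.integers(20, 80))] = float(rng.uniform(3, 12))
        once = filter_novel(call_transfrags(track), genome)
        twice = filter_novel(once, genome)
        assert [(t.interval, t.status, t.mean_coverage) for t in once] == [
            (t.interval, t.status, t.mean_coverage) for t in twice
        ]
        shuffled = list(once)
        rng.shuffle(shuffled)
        again = filter_novel(shuffled, genome)
        assert {(t.interval, t.status) for t in again} == {(t.interval, t.status) for t in once}

    def test_max_coverage_statistic_config(self):
        genome = _plain_genome()
        vec = [0.0] * 10 + [2.0] * 49 + [10.0]
        tfs = call_transfrags(_track(vec, length=1000))
        assert filter_novel(tfs, genome)[0].status == "rejected_low_coverage"
        assert filter_novel(tfs, genome, coverage_stat="max")[0].status == "novel_retained"


class TestMergeNovel:
    def test_overlapping_novels_merge_across_samples(self):
        a = Transfrag(GenomicInterval("c", 100, 200, "+"), 8.0, 9.0, ("s1",), "novel_retained")
        b = Transfrag(GenomicInterval("c", 150, 260, "+"), 6.0, 7.0, ("s2",), "novel_retained")
        c = Transfrag(GenomicInterval("c", 400, 500, "+"), 6.0, 7.0, ("s2",), "novel_retained")
        rej = Transfrag(GenomicInterval("c", 100, 200, "+"), 1.0, 1.0, ("s3",), "rejected_low_coverage")
        merged = merge_novel([a, b, c, rej])
        assert len(merged) == 2
        first = merged[0]
        assert (first.interval.start, first.interval.end) == (100, 260)
        assert first.sample_ids == ("s1", "s2")

    def test_opposite_strands_never_merge(self):
        a = Transfrag(GenomicInterval("c", 100, 200, "+"), 8.0, 9.0, ("s1",), "novel_retained")
        b = Transfrag(GenomicInterval("c", 150, 260, "-"), 6.0, 7.0, ("s1",), "novel_retained")
        assert len(merge_novel([a, b])) == 2


class TestDetectionRate:
    def _genome(self):
        records = [
            AnnotationRecord(GenomicInterval("c", 100, 180, "+"), "ncRNA", "a", ncrna_class="snoRNA"),
            AnnotationRecord(GenomicInterval("c", 300, 380, "+"), "ncRNA", "b", ncrna_class="snoRNA"),
            AnnotationRecord(GenomicInterval("c", 500, 560, "-"), "ncRNA", "d", ncrna_class="miRNA"),
        ]
        return _plain_genome(records=records)

    def test_same_strand_any_overlap(self):
        genome = self._genome()
        tfs = [
            Transfrag(GenomicInterval("c", 170, 220, "+"), 3.0, 3.0),  # overlaps a
            Transfrag(GenomicInterval("c", 300, 380, "-"), 3.0, 3.0),  # antisense to b
        ]
        report = detection_rate(tfs, genome)
        assert report.rate_of("snoRNA") == 50.0
        assert report.rate_of("miRNA") == 0.0
        # the intermediate-size total excludes the miRNA row
        row = report.frame[report.frame["ncrna_class"] == "all"].iloc[0]
        assert (row["n_known"], row["n_detected"]) == (2, 1)
        assert tfs[0].status == "known_overlap"
        assert tfs[1].status is None

    def test_min_fraction_threshold(self):
        genome = self._genome()
        tfs = [Transfrag(GenomicInterval("c", 170, 220, "+"), 3.0, 3.0)]  # covers 10/80
        assert detection_rate(tfs, genome, min_fraction_covered=0.5).rate_of("snoRNA") == 0.0

    def test_no_transfrags_gives_zero_rates(self):
        report = detection_rate([], self._genome())
        assert (report.frame["rate_percent"] == 0.0).all()

    def test_from_counts_rounding(self):
        report = DetectionReport.from_counts([("x", 965, 879), ("y", 135, 125)])
        assert report.rate_of("x") == 91.09
        assert report.rate_of("y") == 92.59
        with pytest.raises(ValueError):
            DetectionReport.from_counts([("bad", 10, 11)])


class TestTssProfile:
    def _genome(self):
        records = [
            AnnotationRecord(GenomicInterval("c", 100, 180, "+"), "ncRNA", "p", ncrna_class="snoRNA"),
            AnnotationRecord(GenomicInterval("c", 400, 460, "-"), "ncRNA", "m", ncrna_class="snRNA"),
        ]
        return _plain_genome(records=records)

    def test_offset_and_coverage_flags(self):
        genome = self._genome()
        tfs = [
            Transfrag(GenomicInterval("c", 60, 180, "+"), 9.0, 9.0),  # 40 bp upstream of p
            Transfrag(GenomicInterval("c", 400, 440, "-"), 9.0, 9.0),  # 5' end at 439, TSS 459
        ]
        profile = tss_profile(tfs, genome)
        rows = profile.frame.set_index("locus_id")
        assert rows.loc["p", "offset"] == -40
        assert bool(rows.loc["p", "covered_at_tss"])
        assert rows.loc["m", "offset"] == 20  # 459 - 439 downstream on minus strand
        assert not bool(rows.loc["m", "covered_at_tss"])

    def test_exact_tss_start(self):
        genome = self._genome()
        tfs = [Transfrag(GenomicInterval("c", 100, 150, "+"), 9.0, 9.0)]
        profile = tss_profile(tfs, genome)
        row = profile.frame.iloc[0]
        assert row["offset"] == 0 and bool(row["covered_at_tss"])

    def test_low_coverage_transfrags_excluded(self):
        genome = self._genome()
        tfs = [Transfrag(GenomicInterval("c", 100, 150, "+"), 5.0, 5.0)]
        assert tss_profile(tfs, genome).frame.empty

    def test_histogram_and_mode(self):
        genome = self._genome()
        tfs = [Transfrag(GenomicInterval("c", 60, 180, "+"), 9.0, 9.0)]
        profile = tss_profile(tfs, genome)
        counts, edges = profile.histogram(bin_width=10)
        assert counts.sum() == 1
        assert profile.mode_offset(bin_width=10) == -35.0
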