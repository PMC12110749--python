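"""Depth tracks, copy-number arithmetic and recovery, anomaly scanning."""

import numpy as np
import pytest

from conftest import align_scenario, tandem_scenario

from editaudit.config import default_config
from editaudit.coverage import (
    CoverageAnomaly,
    DepthTrack,
    copies_per_diploid,
    copy_number,
    depth_track,
    scan_anomalies,
)
from editaudit.hybridref import ReferenceSet
from editaudit.seqio import AlignedRead, Interval, SeqRecord


class TestDepthTrack:
    def test_single_read_covers_its_span(self):
        refs = ReferenceSet([SeqRecord("chr1", "A" * 1_000)])
        read = AlignedRead("r", 0, "chr1", 1, 60, [("M", 150)], seq="A" * 150)
        track = depth_track([read], refs)
        d = track.depths["chr1"]
        assert d[:150].tolist() == [1] * 150 and d[150:].sum() == 0

    def test_overlap_counted_twice_deletion_not_covered(self):
        refs = ReferenceSet([SeqRecord("chr1", "A" * 1_000)])
        reads = [
            AlignedRead("a", 0, "chr1", 1, 60, [("M", 100)], seq="A" * 100),
            AlignedRead("b", 0, "chr1", 51, 60, [("M", 20), ("D", 10), ("M", 70)], seq="A" * 90),
        ]
        d = depth_track(reads, refs).depths["chr1"]
        assert d[60] == 2          # overlap
        assert d[72] == 1          # inside b's deletion: only a covers
        assert d[120] == 1

    def test_secondary_alignments_excluded(self):
        refs = ReferenceSet([SeqRecord("chr1", "A" * 500)])
        reads = [
            AlignedRead("a", 0, "chr1", 1, 60, [("M", 100)], seq="A" * 100),
            AlignedRead("a", 0x100, "chr1", 201, 0, [("M", 100)], seq="A" * 100),
        ]
        d = depth_track(reads, refs).depths["chr1"]
        assert d[250] == 0

    def test_simulated_depth_near_target(self, multi_edit_small):
        assert abs(multi_edit_small.track.genome_mean - 10) / 10 < 0.05

    def test_matches_naive_counting_oracle(self, multi_edit_small):
        rng = np.random.default_rng(0)
        reads = [r for r in multi_edit_small.index.all_primary if r.ref_id == "chr1"]
        picks = rng.choice(len(reads), size=200, replace=False)
        naive = np.zeros(len(multi_edit_small.hybrid["chr1"]), dtype=int)
        subset = [reads[i] for i in picks]
        for r in subset:
            pos = r.ref_start
            for op, n in r.cigar:
                if op in "M=X":
                    naive[pos : pos + n] += 1
                    pos += n
                elif op in "DN":
                    pos += n
        track = depth_track(subset, multi_edit_small.hybrid)
        assert (track.depths["chr1"] == naive).all()


class TestCopyNumber:
    @pytest.mark.parametrize(
        "mean_cov,expected",
        [(5.12919, 1.0), (8.85867, 1.8), (10.3415, 2.1), (20.769, 4.2)],
    )
    def test_reported_table_arithmetic(self, mean_cov, expected, cfg):
        assert copies_per_diploid(mean_cov, 9.97527, cfg) == expected

    def test_equal_coverage_is_diploid(self, cfg):
        assert copies_per_diploid(9.97527, 9.97527, cfg) == 2.0

    def test_half_up_rounding(self, cfg):
        assert copies_per_diploid(1.25, 2.0, cfg) == 1.3  # 1.25 rounds up

    def test_zero_genome_mean_rejected(self, cfg):
        with pytest.raises(ValueError):
            copies_per_diploid(5.0, 0.0, cfg)

    def test_copy_number_over_track_interval(self, cfg):
        refs = ReferenceSet([SeqRecord("chr1", "A" * 1_000)])
        track = DepthTrack({"chr1": np.full(1_000, 10, dtype=np.int32)}, ["chr1"])
        est = copy_number(track, Interval("chr1", 100, 200, ".", "roi"), cfg)
        assert est.copies_per_diploid == 2.0 and est.name == "roi"


class TestCopyRecovery:
    @pytest.mark.parametrize("copies", [1, 2, 4, 8])
    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_tandem_copies_recovered(self, copies, seed, cfg):
        """A c-copy tandem integration reads out c +/- 0.3c at 10x."""
        sc = tandem_scenario(copies, seed)
        aligned = align_scenario(sc, cfg)
        orf = Interval("plasmid1", 500 + cfg.plasmid_overhang, 2_500 + cfg.plasmid_overhang, ".", "orf")
        est = copy_number(aligned.track, orf, cfg)
        assert abs(est.copies_per_diploid - copies) <= 0.3 * copies


def _make_track(depths: np.ndarray) -> DepthTrack:
    return DepthTrack({"chr1": depths.astype(np.int32)}, ["chr1"])


def oracle_runs(depths, predicate, min_len):
    """Direct per-base scan for maximal runs satisfying a predicate."""
    runs = []
    start = None
    for i, d in enumerate(depths):
        if predicate(d):
            if start is None:
                start = i
        elif start is not None:
            if i - start >= min_len:
                runs.append((start, i))
            start = None
    if start is not None and len(depths) - start >= min_len:
        runs.append((start, len(depths)))
    return runs


from hypothesis import given, settings
from hypothesis import strategies as st


@given(st.lists(st.sampled_from([0, 3, 55]), min_size=1, max_size=400))
@settings(derandomize=True, max_examples=60, deadline=None)
def test_scan_anomalies_matches_oracle_on_arbitrary_tracks(depths):
    """Property: scanner output equals the direct per-base scan for any track."""
    cfg = default_config()
    arr = np.array(depths)
    got = scan_anomalies(_make_track(arr), [], cfg)
    zero = [(a.interval.start, a.interval.end) for a in got if a.type == "zero"]
    high = [(a.interval.start, a.interval.end) for a in got if a.type == "high"]
    assert zero == oracle_runs(arr, lambda d: d == 0, cfg.anomaly_min_len)
    assert high == oracle_runs(arr, lambda d: d > cfg.anomaly_high_depth, cfg.anomaly_min_len)


class TestScanAnomalies:
    def test_constant_coverage_yields_nothing(self, cfg):
        track = _make_track(np.full(5_000, 10))
        assert scan_anomalies(track, [], cfg) == []

    def test_planted_zero_run_reported_with_exact_boundaries(self, cfg):
        depths = np.full(5_000, 10)
        depths[100:125] = 0
        (a,) = scan_anomalies(_make_track(depths), [], cfg)
        assert (a.type, a.interval.start, a.interval.end) == ("zero", 100, 125)

    def test_19nt_run_below_threshold_ignored(self, cfg):
        depths = np.full(5_000, 10)
        depths[100:119] = 0
        assert scan_anomalies(_make_track(depths), [], cfg) == []

    def test_high_run_strictly_above_50(self, cfg):
        depths = np.full(5_000, 10)
        depths[200:240] = 51
        depths[300:340] = 50  # not strictly above: ignored
        (a,) = scan_anomalies(_make_track(depths), [], cfg)
        assert (a.type, a.interval.start, a.interval.end) == ("high", 200, 240)

    def test_equivalence_with_direct_scan_oracle(self, cfg):
        rng = np.random.default_rng(5)
        depths = rng.choice([0, 1, 10, 60], size=20_000, p=[0.05, 0.1, 0.7, 0.15])
        got = scan_anomalies(_make_track(depths), [], cfg)
        zero = [(a.interval.start, a.interval.end) for a in got if a.type == "zero"]
        high = [(a.interval.start, a.interval.end) for a in got if a.type == "high"]
        assert zero == oracle_runs(depths, lambda d: d == 0, 20)
        assert high == oracle_runs(depths, lambda d: d > 50, 20)

    def test_run_boundaries_are_maximal(self, cfg):
        rng = np.random.default_rng(6)
        depths = rng.choice([0, 10], size=10_000, p=[0.1, 0.9])
        for a in scan_anomalies(_make_track(depths), [], cfg):
            s, e = a.interval.start, a.interval.end
            if s > 0:
                assert depths[s - 1] != 0
            if e < len(depths):
                assert depths[e] != 0

    def test_cds_overlap_annotated_and_graze_flagged_artifact(self, cfg):
        depths = np.full(5_000, 10)
        depths[1_000:1_100] = 0
        annotation = [
            Interval("chr1", 500, 1_002, "+", "grazed_gene"),
            Interval("chr1", 2_000, 2_200, "+", "elsewhere"),
        ]
        (a,) = scan_anomalies(_make_track(depths), annotation, cfg)
        assert a.cds_names == ["grazed_gene"]
        assert a.likely_artifact  # only 2 coding nt at zero depth

    def test_deep_cds_overlap_not_artifact(self, cfg):
        depths = np.full(5_000, 10)
        depths[1_000:1_100] = 0
        annotation = [Interval("chr1", 900, 1_080, "+", "hit_gene")]
        (a,) = scan_anomalies(_make_track(depths), annotation, cfg)
        assert a.cds_names == ["hit_gene"] and not a.likely_artifact
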