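"""Insertion detection from clips + discordant pairs, masking, microhomology."""

import pytest

from conftest import align_scenario

from editaudit.config import default_config
from editaudit.fixtures import (
    EditEvent,
    Scenario,
    apply_edits,
    make_references,
    simulate_reads,
)
from editaudit.microalign import extract_gapped_inserts, extract_softclips
from editaudit.rearrange import (
    InsertionCall,
    cluster_breakpoints,
    collect_discordant_pairs,
    headline_calls,
    junction_microhomology,
)
from editaudit.seqio import Interval


def _rearrange(aligned):
    clips = extract_softclips(aligned.alignments, aligned.cfg.min_clip_len) + extract_gapped_inserts(
        aligned.alignments, aligned.cfg.min_clip_len
    )
    pairs = collect_discordant_pairs(aligned.alignments)
    calls = cluster_breakpoints(clips, pairs, aligned.mask, aligned.cfg, aligned.hybrid)
    return clips, pairs, calls


class TestDiscordantPairs:
    def test_unedited_genome_has_no_cross_reference_pairs(self, cfg):
        refs = make_references(1, 30_000, 1, 4_000, 6_000, 0, seed=41)
        haps, _ = apply_edits(refs, [])
        pairs = simulate_reads(haps, 150, 5, 400, 40, 0.0, seed=42)
        aligned = align_scenario(Scenario(refs, [], [], haps, None, [], pairs), cfg)
        assert collect_discordant_pairs(aligned.alignments) == []

    def test_integration_produces_host_plasmid_pairs(self, multi_edit_small):
        pairs = collect_discordant_pairs(multi_edit_small.alignments)
        refs = {"chr1"}
        assert any(
            {a.ref_id, b.ref_id} == {"chr1", "plasmid1"} for a, b in pairs
        )

    def test_unmapped_mates_excluded(self):
        from editaudit.seqio import AlignedRead

        a = AlignedRead("p", 0x1 | 0x40, "chr1", 100, 60, [("M", 50)], seq="A" * 50)
        b = AlignedRead("p", 0x1 | 0x80 | 0x4, None, 0, 0, [], seq="A" * 50)
        assert collect_discordant_pairs([a, b]) == []


class TestClusterBreakpoints:
    def test_planted_contaminant_insert_called_at_breakpoint(self, multi_edit_small):
        sc = multi_edit_small.scenario
        _clips, _pairs, calls = _rearrange(multi_edit_small)
        for ev in sc.truth.events:
            if ev.kind != "foreign_insertion" or ev.hap != 0:
                continue
            near = [
                c for c in calls
                if c.source_id == "contaminant"
                and abs(c.host_breakpoint.start - ev.pre_start) <= 5
            ]
            assert near, f"no call near planted insert at {ev.pre_start}"
            call = near[0]
            assert not call.in_mask
            # the junction end is ambiguous up to chance base matches, so the
            # recovered source interval may overshoot by a few bases
            src = call.source_interval
            assert abs(src.start - ev.payload_source.start) <= 1
            assert 0 <= src.end - ev.payload_source.end <= multi_edit_small.cfg.max_microhomology

    def test_tandem_integration_called_with_plasmid_source(self, multi_edit_small):
        sc = multi_edit_small.scenario
        (tandem,) = [e for e in sc.events if e.kind == "tandem_integration"]
        _c, _p, calls = _rearrange(multi_edit_small)
        hits = [
            c for c in calls
            if c.source_id == "plasmid1"
            and abs(c.host_breakpoint.start - tandem.locus.start) <= 5
        ]
        assert hits and hits[0].support >= 2

    def test_no_evidence_gives_no_calls(self, cfg):
        refs = make_references(1, 20_000, 0, 0, 0, 0, seed=43)
        assert cluster_breakpoints([], [], [], cfg, refs) == []

    def test_unedited_specificity(self, cfg):
        """No non-masked calls from an unedited genome at zero error rate."""
        refs = make_references(1, 30_000, 1, 4_000, 6_000, 0, seed=44)
        haps, _ = apply_edits(refs, [])
        pairs = simulate_reads(haps, 150, 5, 400, 40, 0.0, seed=45)
        aligned = align_scenario(Scenario(refs, [], [], haps, None, [], pairs), cfg)
        _c, _p, calls = _rearrange(aligned)
        assert headline_calls(calls) == []


class TestDetectionPower:
    @pytest.mark.parametrize("seed", [1, 2, 3, 4, 5])
    def test_inserts_down_to_30nt_called_within_5nt(self, seed, cfg):
        """Homozygous foreign inserts >= 30 nt are located to +/- 5 nt at 10x."""
        refs = make_references(1, 40_000, 0, 0, 10_000, 0, seed)
        cont = refs["contaminant"].sequence
        spots = [10_000, 20_000, 30_000]
        lens = [30, 80, 200]
        events = [
            EditEvent(
                "foreign_insertion",
                Interval("chr1", at, at + 1),
                haplotypes=(0, 1),
                payload_source=Interval("contaminant", 500 + 1_000 * i, 500 + 1_000 * i + ln),
                payload_len=ln,
            )
            for i, (at, ln) in enumerate(zip(spots, lens))
        ]
        haps, _ = apply_edits(refs, events)
        pairs = simulate_reads(haps, 150, 10 / 2, 400, 40, 0.0, seed + 70)
        aligned = align_scenario(Scenario(refs, [], events, haps, None, [], pairs), cfg)
        _c, _p, calls = _rearrange(aligned)
        for at in spots:
            near = [
                c for c in calls
                if c.source_id == "contaminant" and abs(c.host_breakpoint.start - at) <= 5
            ]
            assert near, f"seed {seed}: insert at {at} not recovered"


class TestMaskEffectiveness:
    def test_homology_trap_evidence_flagged_in_mask(self, cfg):
        """Reads carrying only vector-borne host sequence yield >= 90%
        mask-flagged evidence and an empty headline report."""
        refs = make_references(1, 40_000, 1, 5_000, 0, 1_200, seed=46)
        # episomal plasmid: reads derive from the vector alone
        pairs = simulate_reads(
            [refs["plasmid1"]], 150, 20, 400, 40, 0.0, seed=47
        )
        aligned = align_scenario(Scenario(refs, [], [], [], None, [], pairs), cfg)
        clips, dpairs, calls = _rearrange(aligned)
        evidence = len(dpairs) + len(clips)
        assert evidence >= 10
        masked = sum(
            1
            for a, b in dpairs
            for host_side in (a if a.ref_id == "chr1" else b,)
            if any(
                m.seq_id == "chr1" and host_side.ref_start < m.end and host_side.ref_end > m.start
                for m in aligned.mask
            )
        )
        masked += sum(
            1 for c in clips
            if c.read.ref_id != "chr1" or any(
                m.seq_id == "chr1" and m.start - 10 <= c.position <= m.end + 10
                for m in aligned.mask
            )
        )
        assert masked / evidence >= 0.9
        assert headline_calls(calls) == []


class TestJunctionMicrohomology:
    def test_planted_direct_repeats_measured_exactly(self, multi_edit_small):
        sc = multi_edit_small.scenario
        _c, _p, calls = _rearrange(multi_edit_small)
        expected = {
            e.pre_start: e.microhomology_len
            for e in sc.truth.events
            if e.kind == "foreign_insertion" and e.hap == 0
        }
        assert sorted(expected.values()) == [3, 4]
        for at, mh in expected.items():
            (call,) = [
                c for c in calls
                if c.source_id == "contaminant" and abs(c.host_breakpoint.start - at) <= 5
            ]
            assert call.microhomology_len == mh

    def test_blunt_junction_measures_zero(self, cfg):
        refs = make_references(1, 5_000, 0, 0, 2_000, 0, seed=48)
        host = refs["chr1"].sequence
        cont = refs["contaminant"].sequence
        bp = 2_500
        # choose a source whose end shares no terminal bases with the host flank
        end = next(
            e for e in range(300, 1_500)
            if cont[e - 1] != host[bp - 1]
        )
        call = InsertionCall(
            host_breakpoint=Interval("chr1", bp, bp + 1),
            source_id="contaminant",
            source_interval=Interval("contaminant", end - 200, end),
            orientation="+",
            clip_support=3,
            pair_support=0,
        )
        assert junction_microhomology(call, refs, 10) == 0

    def test_cap_semantics(self, cfg):
        refs = make_references(1, 5_000, 0, 0, 2_000, 0, seed=49)
        host = refs["chr1"].sequence
        bp = 2_500
        call = InsertionCall(
            host_breakpoint=Interval("chr1", bp, bp + 1),
            source_id="contaminant",
            source_interval=None,
            orientation="+",
            clip_support=3,
            pair_support=0,
            insert_end_seq="X" * 20 + host[bp - 7 : bp],  # 7 shared terminal bases
        )
        assert junction_microhomology(call, refs, max_mh=5) == 5
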