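"""On-target allele reconstruction: guide placement, allele recovery, WT certificate."""

import pytest

from conftest import align_scenario, indel_ladder_scenario

from editaudit.config import default_config
from editaudit.fixtures import EditEvent, apply_edits, make_references, simulate_reads, Scenario
from editaudit.hybridref import ReferenceSet
from editaudit.ontarget import call_alleles, discordant_span_support, locate_guides
from editaudit.seqio import Interval, SeqRecord, revcomp


class TestLocateGuides:
    def _genome_with_guide(self, proto, pam, at=500, length=3_000, seed=11):
        refs = make_references(1, length, 0, 0, 0, 0, seed)
        seq = refs["chr1"].sequence
        seq = seq[:at] + proto + pam + seq[at + 23 :]
        return ReferenceSet([SeqRecord("chr1", seq)])

    PROTO = "GATTACAGATTACAGATTAC"

    def test_plus_strand_cut_between_17_and_18(self, cfg):
        refs = self._genome_with_guide(self.PROTO, "AGG")
        (locus,) = locate_guides(refs, [("g", self.PROTO)], cfg)
        assert locus.strand == "+" and locus.cut_pos == 517

    def test_minus_strand_cut_mirrored(self, cfg):
        # embed the reverse complement of protospacer+PAM at position 500:
        # on the forward strand the (rc) PAM occupies [500,503) and the
        # rc protospacer [503,523), so the mirrored cut is at 503+3
        base = make_references(1, 3_000, 0, 0, 0, 0, seed=11)["chr1"].sequence
        seq = base[:500] + revcomp(self.PROTO + "AGG") + base[523:]
        refs = ReferenceSet([SeqRecord("chr1", seq)])
        (locus,) = locate_guides(refs, [("g", self.PROTO)], default_config())
        assert locus.strand == "-" and locus.cut_pos == 506

    def test_protospacer_without_pam_not_reported(self, cfg):
        refs = self._genome_with_guide(self.PROTO, "ATT")
        with pytest.raises(ValueError, match="g"):
            locate_guides(refs, [("g", self.PROTO)], cfg)


def _locus(aligned, guide_id):
    loci = locate_guides(aligned.hybrid, aligned.scenario.guides, aligned.cfg)
    return [l for l in loci if l.guide_id == guide_id][0]


class TestCallAlleles:
    def test_two_deletion_alleles_and_zero_wt(self, multi_edit_small):
        """The first locus carries 8- and 10-nt deletions on the two alleles."""
        alleles, wt = call_alleles(
            multi_edit_small.index, _locus(multi_edit_small, "bak1"), multi_edit_small.cfg, multi_edit_small.hybrid
        )
        assert wt == 0
        del_lens = sorted(e[2] for a in alleles for e in a.signature if e[1] == "del")
        assert del_lens == [8, 10]

    def test_single_insertion_allele_on_both_haplotypes(self, multi_edit_small):
        alleles, wt = call_alleles(
            multi_edit_small.index, _locus(multi_edit_small, "bax"), multi_edit_small.cfg, multi_edit_small.hybrid
        )
        assert wt == 0
        assert len(alleles) == 1
        (entry,) = alleles[0].signature
        assert entry[1] == "ins" and entry[2] == 1
        assert alleles[0].fraction > 0.9  # same signature on both alleles

    def test_foreign_and_distal_alleles_at_one_locus(self, multi_edit_small):
        alleles, wt = call_alleles(
            multi_edit_small.index, _locus(multi_edit_small, "glul"), multi_edit_small.cfg, multi_edit_small.hybrid
        )
        assert wt == 0
        kinds = {e[1] for a in alleles for e in a.signature}
        assert "foreign" in kinds and "distal_junction" in kinds
        foreign = [a for a in alleles if any(e[1] == "foreign" for e in a.signature)][0]
        assert foreign.source.seq_id == "contaminant"
        distal = [a for a in alleles if any(e[1] == "distal_junction" for e in a.signature)][0]
        distance = [e[2] for e in distal.signature if e[1] == "distal_junction"][0]
        assert abs(distance - 575) <= 10

    def test_unedited_locus_is_pure_wt(self, cfg):
        refs = make_references(1, 30_000, 0, 0, 0, 0, seed=21)
        haps, _ = apply_edits(refs, [])
        pairs = simulate_reads(haps, 150, 5, 400, 40, 0.0, seed=22)
        sc = Scenario(refs, [], [], haps, None, [], pairs)
        from editaudit.fixtures import _find_guide_site

        cut, proto = _find_guide_site(refs["chr1"].sequence, 15_000, [], refs["chr1"].sequence)
        sc.guides = [("g", proto)]
        aligned = align_scenario(sc, cfg)
        alleles, wt = call_alleles(aligned.index, _locus(aligned, "g"), cfg, aligned.hybrid)
        assert alleles == [] and wt > 0

    def test_zero_coverage_locus_raises_not_assessable(self, multi_edit_small, cfg):
        # a guide placed inside the big homozygous deletion has no informative reads
        sc = multi_edit_small.scenario
        bigdel = [e for e in sc.events if e.kind == "deletion" and len(e.locus) == 300][0]
        host = multi_edit_small.hybrid["chr1"].sequence
        start = bigdel.locus.start + 100
        proto = host[start : start + 20]
        from editaudit.ontarget import GuideLocus

        locus = GuideLocus(
            "dead", proto, "chr1", "+",
            Interval("chr1", start, start + 20),
            Interval("chr1", start + 20, start + 23),
            start + 17,
            Interval("chr1", start + 7, start + 27),
        )
        with pytest.raises(ValueError, match="not assessable"):
            call_alleles(multi_edit_small.index, locus, cfg, multi_edit_small.hybrid)


class TestIndelLadder:
    @pytest.mark.parametrize("seed", [1, 2, 3, 4, 5])
    def test_planted_indel_lengths_recovered_exactly(self, seed, cfg):
        """Indels of 1-50 nt are recovered with their exact lengths at 10x."""
        sc = indel_ladder_scenario(seed)
        aligned = align_scenario(sc, cfg)
        loci = locate_guides(aligned.hybrid, sc.guides, cfg)
        for locus in loci:
            kind, length = sc.expected_indels[locus.guide_id]
            alleles, wt = call_alleles(aligned.index, locus, cfg, aligned.hybrid)
            assert wt == 0, f"{locus.guide_id}: wild-type reads at a homozygous edit"
            found = {(e[1], e[2]) for a in alleles for e in a.signature}
            assert (kind, length) in found, f"{locus.guide_id}: {found}"


class TestHeterozygousFraction:
    def test_het_edit_gives_half_wt(self, cfg):
        """One edited haplotype leaves a wild-type fraction of 0.5 +/- 0.1."""
        refs = make_references(1, 30_000, 0, 0, 0, 0, seed=31)
        from editaudit.fixtures import _find_guide_site

        chrom = refs["chr1"].sequence
        taken = []
        cuts = []
        for near in (8_000, 15_000, 22_000):
            cut, proto = _find_guide_site(chrom, near, taken, chrom)
            taken.append((cut - 1000, cut + 1000))
            cuts.append((cut, proto))
        events = [
            EditEvent("deletion", Interval("chr1", cut - 4, cut + 4), haplotypes=(0,))
            for cut, _ in cuts
        ]
        haps, _ = apply_edits(refs, events)
        pairs = simulate_reads(haps, 150, 5, 400, 40, 0.0, seed=32)
        sc = Scenario(refs, [(f"g{i}", p) for i, (_, p) in enumerate(cuts)], events, haps, None, [], pairs)
        aligned = align_scenario(sc, cfg)
        fractions = []
        for locus in locate_guides(aligned.hybrid, sc.guides, cfg):
            alleles, wt = call_alleles(aligned.index, locus, cfg, aligned.hybrid)
            total = wt + sum(a.supporting_reads for a in alleles)
            fractions.append(wt / total)
            # per-locus binomial noise at ~20 informative reads
            assert abs(fractions[-1] - 0.5) <= 0.25
        assert abs(sum(fractions) / len(fractions) - 0.5) <= 0.1


class TestDiscordantSpans:
    def test_distal_junction_supported_by_long_templates(self, multi_edit_small):
        locus = _locus(multi_edit_small, "glul")
        spans = discordant_span_support(multi_edit_small.index, locus, 5_000, multi_edit_small.cfg)
        assert len(spans) >= 1
        assert all(400 + 575 - 250 <= s <= 400 + 575 + 250 for _pair, s in spans)

    def test_unedited_locus_has_none(self, multi_edit_small):
        locus = _locus(multi_edit_small, "bax")  # 1-nt insertion: template lengths normal
        assert discordant_span_support(multi_edit_small.index, locus, 5_000, multi_edit_small.cfg) == []

    def test_zero_max_dist_empty(self, multi_edit_small):
        locus = _locus(multi_edit_small, "glul")
        assert discordant_span_support(multi_edit_small.index, locus, 0, multi_edit_small.cfg) == []
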