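"""Off-target enumeration (vs a brute-force oracle) and locus screening."""

import numpy as np
import pytest

from conftest import align_scenario

from editaudit.config import default_config
from editaudit.fixtures import EditEvent, Scenario, apply_edits, make_references, simulate_reads
from editaudit.hybridref import ReferenceSet
from editaudit.offtarget import audit_offtargets, enumerate_sites, pileup_scan
from editaudit.ontarget import AlignmentIndex, iupac_match
from editaudit.seqio import Interval, SeqRecord, revcomp


# ---------------------------------------------------------------------------
# independent oracle: positionwise scan in pure Python
# ---------------------------------------------------------------------------


_SCAN_CACHE: dict = {}


def brute_force_scan(genome: str, proto: str):
    """Every candidate (site_start, strand, mismatches, pam) with mm <= 4,
    by direct positionwise comparison (no PAM filter applied yet)."""
    key = (hash(genome), proto)
    if key in _SCAN_CACHE:
        return _SCAN_CACHE[key]
    out = []
    rc = revcomp(proto)
    L = len(genome)
    for i in range(L - 19):
        window = genome[i : i + 20]
        mm = sum(a != b for a, b in zip(window, proto))
        if mm <= 4 and i + 23 <= L:
            out.append((i, "+", mm, genome[i + 20 : i + 23]))
        mm = sum(a != b for a, b in zip(window, rc))
        if mm <= 4 and i >= 3:
            out.append((i - 3, "-", mm, revcomp(genome[i - 3 : i])))
    _SCAN_CACHE[key] = out
    return out


def brute_force_sites(genome: str, proto: str, budget: int, pams: list[str]):
    """Oracle hit set for one budget and PAM set."""
    return {
        (start, strand, mm)
        for start, strand, mm, pam in brute_force_scan(genome, proto)
        if mm <= budget and any(iupac_match(p, pam) for p in pams)
    }


def _decoy_genome(seed: int, length: int = 50_000):
    """Random genome with planted near-matches of a guide at 0-4 mismatches."""
    refs = make_references(1, length, 0, 0, 0, 0, seed)
    seq = refs["chr1"].sequence
    rng = np.random.default_rng(seed + 50)
    proto = seq[1_000 : 1_020]
    pos = 1_020
    seq = seq[:pos] + "AGG" + seq[pos + 3 :]  # on-target PAM
    for k, (at, pam) in enumerate(
        [(9_000, "TGG"), (17_000, "GAG"), (25_000, "CGG"), (33_000, "AAG"), (41_000, "ATT")]
    ):
        decoy = list(proto)
        for j in rng.choice(20, size=k, replace=False):
            decoy[j] = {"A": "C", "C": "G", "G": "T", "T": "A"}[decoy[j]]
        ins = "".join(decoy) + pam
        seq = seq[:at] + ins + seq[at + len(ins) :]
    return ReferenceSet([SeqRecord("chr1", seq)]), proto


class TestEnumerateSites:
    def test_exact_site_found_with_zero_budget(self):
        refs, proto = _decoy_genome(seed=1)
        cfg = default_config()
        cfg.mismatch_budget = 0
        hits = enumerate_sites(refs, ("g", proto), cfg)
        assert any(h.mismatches == 0 for h in hits)

    @pytest.mark.parametrize("seed", [1, 2, 3, 4, 5])
    @pytest.mark.parametrize("pams", [["NGG", "NAG"], ["NGG"]])
    def test_equivalent_to_brute_force_scan(self, seed, pams):
        """Identical to the positionwise oracle for budgets 0-4, both PAM sets."""
        refs, proto = _decoy_genome(seed)
        genome = refs["chr1"].sequence
        cfg = default_config()
        cfg.pam_patterns = pams
        for budget in range(5):
            cfg.mismatch_budget = budget
            got = {
                (h.site.start, h.strand, h.mismatches)
                for h in enumerate_sites(refs, ("g", proto), cfg)
            }
            assert got == brute_force_sites(genome, proto, budget, pams)

    def test_hits_monotone_in_budget(self):
        refs, proto = _decoy_genome(seed=2)
        cfg = default_config()
        prev = set()
        for budget in range(5):
            cfg.mismatch_budget = budget
            cur = {(h.site.start, h.strand) for h in enumerate_sites(refs, ("g", proto), cfg)}
            assert prev <= cur
            prev = cur


class TestPileupScan:
    def _aligned_decoy(self):
        refs, proto = _decoy_genome(seed=7, length=40_000)
        # 2-nt deletion at the 2-mismatch decoy site (planted at 17,000)
        events = [EditEvent("deletion", Interval("chr1", 17_008, 17_010))]
        haps, _ = apply_edits(refs, events)
        pairs = simulate_reads(haps, 150, 5, 400, 40, 0.0, seed=8)
        sc = Scenario(refs, [("g", proto)], events, haps, None, [], pairs)
        return align_scenario(sc), proto

    def test_matching_reads_give_no_variants(self):
        aligned, _ = self._aligned_decoy()
        window = Interval("chr1", 30_000, 30_100)
        assert pileup_scan(aligned.index, window, aligned.hybrid, aligned.cfg) == []

    def test_planted_hom_deletion_called(self):
        aligned, _ = self._aligned_decoy()
        window = Interval("chr1", 16_980, 17_043)
        variants = pileup_scan(aligned.index, window, aligned.hybrid, aligned.cfg)
        dels = [v for v in variants if len(v.ref_allele) > len(v.alt_allele)]
        assert len(dels) == 1
        assert dels[0].genotype_class == "hom_alt"
        assert len(dels[0].ref_allele) - len(dels[0].alt_allele) == 2

    def test_het_snp_counted(self, cfg):
        # hand-built pileup: half of the reads carry one substitution
        from editaudit.seqio import AlignedRead

        refs = ReferenceSet([SeqRecord("chr1", "ACGT" * 1000)])
        ref_seq = refs["chr1"].sequence
        reads = []
        for i in range(20):
            seq = ref_seq[100:250]
            if i < 10:
                seq = seq[:50] + ("G" if seq[50] != "G" else "T") + seq[51:]
            reads.append(AlignedRead(f"r{i}", 0, "chr1", 101, 60, [("M", 150)], seq=seq))
        variants = pileup_scan(reads, Interval("chr1", 140, 160), refs, cfg)
        assert len(variants) == 1
        v = variants[0]
        assert v.pos == 151 and v.alt_support == 10 and v.genotype_class == "het"


@pytest.fixture(scope="module")
def audited():
    refs, proto = _decoy_genome(seed=7, length=40_000)
    events = [
        EditEvent("deletion", Interval("chr1", 17_008, 17_010)),  # edit at 2-mm decoy
        EditEvent("deletion", Interval("chr1", 24_800, 25_500)),  # buries the 3-mm decoy
    ]
    haps, _ = apply_edits(refs, events)
    pairs = simulate_reads(haps, 150, 5, 400, 40, 0.0, seed=8)
    annotation = [Interval("chr1", 16_900, 17_400, "+", "abcc4_like")]
    sc = Scenario(refs, [("g", proto)], events, haps, None, annotation, pairs)
    aligned = align_scenario(sc)
    hits, summary = audit_offtargets(
        aligned.hybrid, aligned.index, sc.guides, annotation, aligned.cfg, aligned.track
    )
    return hits, summary


class TestAuditOfftargets:
    def test_only_edited_decoy_reported_with_changes(self, audited):
        hits, summary = audited
        changed = [h for h in hits if h.variants]
        assert len(changed) == 1
        assert changed[0].site.start == 17_000
        assert summary.loc[0, "n_with_changes"] == 1

    def test_zero_coverage_site_not_assessable(self, audited):
        hits, _ = audited
        buried = [h for h in hits if h.site.start == 25_000]
        assert buried and not buried[0].assessable
        assert buried[0].variants == []

    def test_annotation_name_attached(self, audited):
        hits, summary = audited
        changed = [h for h in hits if h.variants][0]
        assert "abcc4_like" in changed.affected_annotation
        assert "abcc4_like" in summary.loc[0, "affected_genes"]

    def test_no_changes_in_unedited_sites(self, audited):
        """False-positive guard: error-free reads produce no spurious variants."""
        hits, _ = audited
        for h in hits:
            if h.assessable and h.site.start not in (17_000,):
                assert h.variants == []
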