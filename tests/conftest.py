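"""Shared fixtures: aligned synthetic scenarios reused across the suite."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

from editaudit.config import AuditConfig, default_config
from editaudit.coverage import DepthTrack, depth_track
from editaudit.fixtures import (
    EditEvent,
    ReadPair,
    Scenario,
    Truth,
    _find_guide_site,
    apply_edits,
    make_references,
    scenario_multi_edit,
    simulate_reads,
)
from editaudit.hybridref import ReferenceSet, build_reference, compute_homology_mask
from editaudit.microalign import Scoring, align_reads, build_index, extract_softclips
from editaudit.ontarget import AlignmentIndex
from editaudit.seqio import AlignedRead, Interval, SeqRecord


@dataclass
class AlignedScenario:
    """A scenario taken through reference building and alignment."""

    scenario: Scenario
    hybrid: ReferenceSet
    mask: list[Interval]
    alignments: list[AlignedRead]
    index: AlignmentIndex
    track: DepthTrack
    cfg: AuditConfig


def align_scenario(sc: Scenario, cfg: AuditConfig | None = None) -> AlignedScenario:
    cfg = cfg or default_config()
    hybrid = build_reference(
        sc.refs.host,
        sc.refs.by_provenance("plasmid"),
        sc.refs.by_provenance("contaminant"),
        cfg.plasmid_overhang,
    )
    mask = compute_homology_mask(hybrid, cfg.mask_min_match)
    seed_index = build_index(hybrid)
    alignments = align_reads(sc.pairs, seed_index, hybrid, Scoring())
    index = AlignmentIndex(alignments)
    track = depth_track(index.all_primary, hybrid)
    return AlignedScenario(sc, hybrid, mask, alignments, index, track, cfg)


@pytest.fixture(scope="session")
def cfg() -> AuditConfig:
    return default_config()


@pytest.fixture(scope="session")
def multi_edit_small() -> AlignedScenario:
    """The canned multi-edit scenario on a 60 kb host at 10x, aligned."""
    sc = scenario_multi_edit(seed=1, host_len=60_000, target_depth=10)
    return align_scenario(sc)


def indel_ladder_scenario(
    seed: int,
    del_lens: tuple[int, ...] = (1, 8, 20, 35, 50),
    ins_lens: tuple[int, ...] = (1, 10, 28, 45),
    host_len: int = 60_000,
    depth: float = 10.0,
) -> Scenario:
    """Homozygous indels of each length, one per guide locus."""
    refs = make_references(1, host_len, 0, 0, 0, 0, seed)
    chrom = refs["chr1"].sequence
    rng = np.random.default_rng(seed + 13)
    n = len(del_lens) + len(ins_lens)
    taken: list[tuple[int, int]] = []
    cuts: list[tuple[int, str]] = []
    for i in range(n):
        near = int((i + 1) * host_len / (n + 2))
        cut, proto = _find_guide_site(chrom, near, taken, chrom, min_gap=1500)
        taken.append((cut - 800, cut + 800))
        cuts.append((cut, proto))
    events = []
    guides = []
    expected: dict[str, tuple[str, int]] = {}
    for i, d in enumerate(del_lens):
        cut, proto = cuts[i]
        gid = f"del{d}"
        guides.append((gid, proto))
        events.append(EditEvent("deletion", Interval("chr1", cut - d // 2, cut - d // 2 + d)))
        expected[gid] = ("del", d)
    for j, d in enumerate(ins_lens):
        cut, proto = cuts[len(del_lens) + j]
        gid = f"ins{d}"
        guides.append((gid, proto))
        payload = "ACGT" [int(rng.integers(0, 4))] if d == 1 else "".join(
            "ACGT"[b] for b in rng.integers(0, 4, size=d)
        )
        events.append(
            EditEvent("insertion", Interval("chr1", cut, cut + 1), payload_seq=payload)
        )
        expected[gid] = ("ins", d)
    haplotypes, truth = apply_edits(refs, events)
    pairs = simulate_reads(haplotypes, 150, depth / 2, 400, 40, 0.0, seed + 7)
    sc = Scenario(refs, guides, events, haplotypes, truth, [], pairs)
    sc.expected_indels = expected  # type: ignore[attr-defined]
    return sc


def tandem_scenario(copies: int, seed: int, host_len: int = 30_000, plasmid_len: int = 3_000) -> Scenario:
    """A c-copy tandem plasmid integration on one haplotype, no homology trap."""
    refs = make_references(1, host_len, 1, plasmid_len, 0, 0, seed)
    locus = int(0.5 * host_len)
    events = [
        EditEvent(
            "tandem_integration",
            Interval("chr1", locus, locus + 1),
            haplotypes=(0,),
            payload_source=Interval("plasmid1", 0, plasmid_len),
            copy_count=copies,
        )
    ]
    haplotypes, truth = apply_edits(refs, events)
    pairs = simulate_reads(haplotypes, 150, 10 / 2, 400, 40, 0.0, seed + 7)
    return Scenario(refs, [], events, haplotypes, truth, [], pairs)
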