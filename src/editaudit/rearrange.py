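"""Genome-wide foreign-DNA insertion detection and junction reconstruction.

Evidence comes from two read classes: soft-clipped reads whose clipped tail
matches another reference sequence, and read pairs whose mates map to
different reference sequences (host-plasmid or host-contaminant pairs).
Clips within a few nt on the host are merged into breakpoints, clipped
sequences are re-searched (exact, then 1-mismatch) against the whole
reference set to assign the insert's source, and nearby cross-reference
pairs corroborate each call.  Pair-only evidence yields region-level calls
with breakpoint uncertainty of one library-fragment standard deviation.

Calls whose entire support lies inside the plasmid-host homology mask are
flagged ``in_mask`` and excluded from the headline report: reads from a
host region that is also carried on a vector produce abundant artefactual
cross-reference evidence that says nothing about integration.

Junction microhomology is the longest direct repeat shared by the host
sequence immediately upstream of the breakpoint and the insert's
junction-adjacent end, a signature of microhomology-driven recombination.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable

from .config import AuditConfig, default_config
from .hybridref import ReferenceSet
from .microalign import SoftClip
from .ontarget import ClipMatch, search_clip, split_clip
from .seqio import AlignedRead, Interval, revcomp

logger = logging.getLogger(__name__)

__all__ = [
    "InsertionCall",
    "collect_discordant_pairs",
    "cluster_breakpoints",
    "junction_microhomology",
    "headline_calls",
]


@dataclass
class InsertionCall:
    """A reconstructed foreign/distal DNA junction on the host genome."""

    host_breakpoint: Interval  # 1-nt for clip-resolved, wider for pair-only
    source_id: str  # reference the insert matches, or "ambiguous"/"unknown"
    source_interval: Interval | None
    orientation: str
    clip_support: int
    pair_support: int
    microhomology_len: int = 0
    in_mask: bool = False
    weak: bool = False
    #: observed insert sequence adjacent to the downstream junction
    insert_end_seq: str = ""
    #: observed insert sequence adjacent to the upstream junction
    insert_start_seq: str = ""
    #: observed clip boundaries on the host (None if that side is unseen)
    left_bp: int | None = None
    right_bp: int | None = None

    @property
    def support(self) -> int:
        return self.clip_support + self.pair_support


@dataclass
class _JunctionObs:
    """One clip normalized into host coordinates."""

    seq_id: str
    bp: int
    upstream: bool  # True: junction seen from the upstream (5') host side
    partner_id: str | None
    partner_start: int
    partner_end: int
    partner_strand: str
    ambiguous: bool
    clip_seq: str


@dataclass
class ClipMatchShim:
    """A clip match with a corrected source interval."""

    base: object
    start: int
    end: int


def collect_discordant_pairs(
    alignments: Iterable[AlignedRead],
) -> list[tuple[AlignedRead, AlignedRead]]:
    """Primary-alignment pairs whose mates map to different references."""
    first: dict[str, AlignedRead] = {}
    out: list[tuple[AlignedRead, AlignedRead]] = []
    for read in alignments:
        if read.is_secondary or read.is_unmapped:
            continue
        mate = first.pop(read.read_id, None)
        if mate is None:
            first[read.read_id] = read
            continue
        if mate.ref_id != read.ref_id:
            pair = (mate, read) if mate.is_read1 else (read, mate)
            out.append(pair)
    return out


def _in_mask(seq_id: str, start: int, end: int, mask: list[Interval]) -> bool:
    return any(m.seq_id == seq_id and start < m.end and end > m.start for m in mask)


def cluster_breakpoints(
    softclips: list[SoftClip],
    discordant_pairs: list[tuple[AlignedRead, AlignedRead]],
    mask: list[Interval] | None = None,
    config: AuditConfig | None = None,
    refs: ReferenceSet | None = None,
) -> list[InsertionCall]:
    """Merge clip evidence into breakpoints, assign sources, attach pairs.

    Only host-side evidence defines breakpoints.  Calls with all support
    inside the homology mask get ``in_mask=True``; calls below the support
    threshold are flagged ``weak``.  Output is sorted by total support.
    """
    cfg = config or default_config()
    mask = mask or []
    if refs is None:
        raise ValueError("cluster_breakpoints requires the reference set")
    host_ids = {r.id for r in refs.host}

    # --- normalize every clip into a host-side junction observation -------
    # A junction is seen from either side: a host-anchored read clips the
    # insert, or an insert-anchored read clips its host tail.  Both are
    # mapped onto (host sequence, breakpoint, upstream/downstream side).
    observations: list[_JunctionObs] = []
    for clip in softclips:
        if len(clip.seq) < cfg.min_clip_len:
            continue
        match = search_clip(clip.seq, clip.side, refs, cfg)
        if clip.read.ref_id in host_ids:
            bp = clip.position
            upstream = clip.side == "right"
            if match is None:
                # short insert: the clip spans it entirely and rejoins the
                # host; split at the rejoin point and locate the insert alone
                split = split_clip(
                    clip.seq, clip.side, bp, refs[clip.read.ref_id].sequence, cfg
                )
                if split is not None:
                    ins_len, ins_seq = split
                    if ins_len >= 15:
                        for rec in refs.records:
                            if rec.id == clip.read.ref_id:
                                continue
                            for strand, q in (("+", ins_seq), ("-", revcomp(ins_seq))):
                                p = rec.sequence.find(q)
                                if p >= 0:
                                    match = ClipMatch(
                                        rec.id, rec.provenance, p, p + ins_len, strand, 0
                                    )
                                    break
                            if match is not None:
                                break
            partner = match
            # a chance match between the insert start and the host bases just
            # past the junction drags the clip boundary into the insert;
            # walk it back so the breakpoint is exact
            if (
                upstream
                and match is not None
                and match.strand == "+"
                and not match.ambiguous
            ):
                host_seq = refs[clip.read.ref_id].sequence
                src_seq = refs[match.seq_id].sequence
                s0 = match.start
                shift = 0
                while (
                    shift < cfg.max_microhomology
                    and s0 - shift - 1 >= 0
                    and bp - shift - 1 >= 0
                    and src_seq[s0 - shift - 1] == host_seq[bp - shift - 1]
                ):
                    shift += 1
                bp -= shift
                partner = ClipMatchShim(match, match.start - shift, match.end)
            observations.append(
                _JunctionObs(
                    seq_id=clip.read.ref_id,
                    bp=bp,
                    upstream=upstream,
                    partner_id=match.seq_id if match else None,
                    partner_start=partner.start if partner else 0,
                    partner_end=partner.end if partner else 0,
                    partner_strand=match.strand if match else ".",
                    ambiguous=bool(match.ambiguous) if match else False,
                    clip_seq=clip.seq,
                )
            )
        elif match is not None and match.seq_id in host_ids and not match.ambiguous:
            # insert-anchored read: the clipped tail is host sequence
            if clip.side == "left":
                bp = match.end
                upstream = True
            else:
                bp = match.start
                upstream = False
            observations.append(
                _JunctionObs(
                    seq_id=match.seq_id,
                    bp=bp,
                    upstream=upstream,
                    partner_id=clip.read.ref_id,
                    partner_start=clip.read.ref_start,
                    partner_end=clip.read.ref_end,
                    partner_strand="-" if clip.read.is_reverse else "+",
                    ambiguous=False,
                    clip_seq="",
                )
            )

    observations.sort(key=lambda o: (o.seq_id, o.bp))
    clusters: list[list[_JunctionObs]] = []
    for obs in observations:
        if (
            clusters
            and clusters[-1][-1].seq_id == obs.seq_id
            and obs.bp - clusters[-1][-1].bp <= cfg.breakpoint_merge_dist
        ):
            clusters[-1].append(obs)
        else:
            clusters.append([obs])

    calls: list[InsertionCall] = []
    for cluster in clusters:
        seq_id = cluster[0].seq_id
        sources: dict[str, int] = {}
        ambiguous = any(o.ambiguous for o in cluster)
        for o in cluster:
            if o.partner_id is not None:
                sources[o.partner_id] = sources.get(o.partner_id, 0) + 1

        def _mode(vals: list[int]) -> int | None:
            if not vals:
                return None
            counts: dict[int, int] = {}
            for v in vals:
                counts[v] = counts.get(v, 0) + 1
            return sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[0][0]

        right_bp = _mode([o.bp for o in cluster if o.upstream])
        left_bp = _mode([o.bp for o in cluster if not o.upstream])
        insert_start_seq = max(
            (o.clip_seq for o in cluster if o.upstream), key=len, default=""
        )
        insert_end_seq = max(
            (o.clip_seq for o in cluster if not o.upstream), key=len, default=""
        )
        if not sources:
            source_id = "unknown"
            src_iv = None
            orientation = "."
        else:
            ranked = sorted(sources.items(), key=lambda kv: (-kv[1], kv[0]))
            if ambiguous or (len(ranked) > 1 and ranked[0][1] == ranked[1][1]):
                source_id = "ambiguous"
                src_iv = None
                orientation = "."
            else:
                source_id = ranked[0][0]
                obs_src = [o for o in cluster if o.partner_id == source_id]
                src_iv = Interval(
                    source_id,
                    min(o.partner_start for o in obs_src),
                    max(o.partner_end for o in obs_src),
                )
                orientation = obs_src[0].partner_strand
        bp = right_bp if right_bp is not None else left_bp
        support_in_mask = all(
            _in_mask(seq_id, o.bp, o.bp + 1, mask) for o in cluster
        )
        calls.append(
            InsertionCall(
                host_breakpoint=Interval(seq_id, bp, bp + 1),
                source_id=source_id,
                source_interval=src_iv,
                orientation=orientation,
                clip_support=len(cluster),
                pair_support=0,
                in_mask=support_in_mask,
                insert_start_seq=insert_start_seq,
                insert_end_seq=insert_end_seq,
                left_bp=left_bp,
                right_bp=right_bp,
            )
        )

    # --- attach discordant pairs to the nearest breakpoint ----------------
    assign_dist = int(cfg.insert_mean + 4 * cfg.insert_sd)
    orphan_pairs: dict[tuple[str, str], list[tuple[int, int, bool]]] = {}
    for a, b in discordant_pairs:
        host_side = a if a.ref_id in host_ids else b if b.ref_id in host_ids else None
        other = b if host_side is a else a
        if host_side is None or other.ref_id in host_ids:
            continue  # host-host or foreign-foreign pairs carry no insertion signal
        pos = host_side.ref_end if not host_side.is_reverse else host_side.ref_start
        masked = _in_mask(host_side.ref_id, host_side.ref_start, host_side.ref_end, mask)
        best = None
        for call in calls:
            if call.host_breakpoint.seq_id != host_side.ref_id:
                continue
            d = abs(call.host_breakpoint.start - pos)
            if d <= assign_dist and (best is None or d < best[0]):
                best = (d, call)
        if best is not None:
            best[1].pair_support += 1
            if not masked:
                best[1].in_mask = False
        else:
            orphan_pairs.setdefault((host_side.ref_id, other.ref_id), []).append(
                (host_side.ref_start, host_side.ref_end, masked)
            )

    # --- region-level calls from pair-only evidence ------------------------
    for (host_id, other_id), items in orphan_pairs.items():
        items.sort()
        group: list[tuple[int, int, bool]] = []
        groups: list[list[tuple[int, int, bool]]] = []
        for it in items:
            if group and it[0] - group[-1][0] > assign_dist:
                groups.append(group)
                group = []
            group.append(it)
        if group:
            groups.append(group)
        for g in groups:
            mid = g[len(g) // 2][0]
            sd = int(cfg.insert_sd)
            start = max(0, mid - sd)
            calls.append(
                InsertionCall(
                    host_breakpoint=Interval(host_id, start, mid + sd + 1),
                    source_id=other_id,
                    source_interval=None,
                    orientation=".",
                    clip_support=0,
                    pair_support=len(g),
                    in_mask=all(m for _s, _e, m in g),
                )
            )

    for call in calls:
        call.weak = call.support < cfg.min_junction_support
        if refs is not None and call.source_interval is not None:
            call.microhomology_len = junction_microhomology(call, refs, cfg.max_microhomology)
    calls.sort(key=lambda c: -c.support)
    return calls


def headline_calls(calls: list[InsertionCall]) -> list[InsertionCall]:
    """Calls worth reporting: not mask artefacts, not below support threshold."""
    return [c for c in calls if not c.in_mask and not c.weak]


def junction_microhomology(
    call: InsertionCall, refs: ReferenceSet, max_mh: int = 10
) -> int:
    """Longest direct repeat between host upstream of the breakpoint and the
    insert's junction end (0 if none), capped at ``max_mh``.

    When both junction sides were observed, the repeat length is the offset
    between them: the aligner absorbs a junction duplication into the host
    alignment of downstream-anchored reads, so their clip boundary sits
    exactly ``mh`` nt upstream of the true breakpoint.  With one side only,
    falls back to comparing host context with the observed insert end.
    """
    if call.left_bp is not None and call.right_bp is not None:
        return max(0, min(max_mh, call.right_bp - call.left_bp))
    if call.source_interval is None and not call.insert_end_seq:
        return 0
    host_seq = refs[call.host_breakpoint.seq_id].sequence
    bp = call.host_breakpoint.start
    if call.insert_end_seq:
        insert_end = call.insert_end_seq
    else:
        src = call.source_interval
        seq = refs[src.seq_id].sequence[src.start : src.end]
        insert_end = seq if call.orientation != "-" else revcomp(seq)
    best = 0
    for l in range(1, max_mh + 1):
        if l > len(insert_end) or bp - l < 0:
            break
        if host_seq[bp - l : bp] == insert_end[-l:]:
            best = l
    return best
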