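"""On-target allele reconstruction and complete-editing certification.

For each guide the pipeline locates the protospacer+PAM on the host genome,
computes the blunt cut position 3 bp PAM-proximal of the protospacer end,
and classifies every informative read overlapping the cut window as
wild-type or as carrying a variant signature derived from its CIGAR and
soft clips.  Clips are re-searched against the full reference set:

* a clip matching a plasmid or the contaminant genome → ``foreign`` allele
  (vector / cloning-strain DNA at the cut);
* a clip matching host sequence within the distal window → either a plain
  deletion (short distances) or a ``distal_junction`` allele with the
  distance recorded;
* I/D CIGAR operations → insertion / deletion signatures.

Signatures are clustered by exact identity; a locus where every informative
read carries a signature (zero wild-type reads) is certified completely
edited.  Reads anchored on the far side of a junction whose clip maps back
into the cut window also support the junction allele.
"""

from __future__ import annotations

import logging
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .config import AuditConfig, default_config
from .hybridref import ReferenceSet
from .seqio import AlignedRead, Interval, revcomp

logger = logging.getLogger(__name__)

__all__ = [
    "GuideLocus",
    "AlleleCall",
    "locate_guides",
    "call_alleles",
    "discordant_span_support",
    "AlignmentIndex",
    "search_clip",
]

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def iupac_match(pattern: str, seq: str) -> bool:
    return len(pattern) == len(seq) and all(b in _IUPAC[p] for p, b in zip(pattern, seq))


@dataclass(frozen=True)
class GuideLocus:
    """One exact protospacer+PAM occurrence with its cut position."""

    guide_id: str
    protospacer: str
    seq_id: str
    strand: str
    site: Interval  # protospacer span, forward coordinates
    pam_pos: Interval
    cut_pos: int  # 0-based: cut falls between cut_pos-1 and cut_pos
    window: Interval

    @property
    def pam(self) -> str:
        return ""


def locate_guides(
    refs: ReferenceSet,
    guides: Sequence[tuple[str, str]],
    config: AuditConfig | None = None,
) -> list[GuideLocus]:
    """Exact protospacer+PAM placements of every guide on the host genome.

    The cut position is the blunt SpCas9 cut between protospacer positions
    17 and 18 (3 bp from the PAM), mirrored on the minus strand.  A guide
    whose protospacer never occurs with an adjacent PAM raises ValueError.
    """
    cfg = config or default_config()
    loci: list[GuideLocus] = []
    for guide_id, proto in guides:
        proto = proto.upper()
        if len(proto) != 20:
            raise ValueError(f"guide {guide_id!r}: protospacer must be 20 nt")
        found = []
        rc = revcomp(proto)
        for rec in refs.host:
            seq = rec.sequence
            # + strand: protospacer then PAM
            p = seq.find(proto)
            while p != -1:
                pam = seq[p + 20 : p + 23]
                if len(pam) == 3 and any(iupac_match(pp, pam) for pp in cfg.pam_patterns):
                    cut = p + 17
                    found.append((rec.id, "+", p, cut, Interval(rec.id, p + 20, p + 23)))
                p = seq.find(proto, p + 1)
            # - strand: PAM (revcomp) immediately 5' of the rc protospacer
            p = seq.find(rc)
            while p != -1:
                pam_fwd = seq[max(0, p - 3) : p]
                if len(pam_fwd) == 3:
                    pam = revcomp(pam_fwd)
                    if any(iupac_match(pp, pam) for pp in cfg.pam_patterns):
                        cut = p + 3
                        found.append((rec.id, "-", p, cut, Interval(rec.id, p - 3, p)))
                p = seq.find(rc, p + 1)
        if not found:
            raise ValueError(f"guide {guide_id!r}: protospacer not found with an adjacent PAM")
        for seq_id, strand, p, cut, pam_iv in found:
            loci.append(
                GuideLocus(
                    guide_id=guide_id,
                    protospacer=proto,
                    seq_id=seq_id,
                    strand=strand,
                    site=Interval(seq_id, p, p + 20, strand),
                    pam_pos=pam_iv,
                    cut_pos=cut,
                    window=Interval(seq_id, cut - cfg.cut_flank, cut + cfg.cut_flank),
                )
            )
    return loci


# ---------------------------------------------------------------------------
# alignment position index (shared with other screening stages)
# ---------------------------------------------------------------------------


class AlignmentIndex:
    """Primary alignments sorted by position for fast window queries."""

    def __init__(self, alignments: Iterable[AlignedRead], max_span: int = 500):
        self.by_ref: dict[str, tuple[list[int], list[AlignedRead]]] = {}
        self.max_span = max_span
        buckets: dict[str, list[AlignedRead]] = {}
        self.all_primary: list[AlignedRead] = []
        for read in alignments:
            if read.is_unmapped or read.is_secondary:
                continue
            self.all_primary.append(read)
            buckets.setdefault(read.ref_id, []).append(read)
        for ref_id, reads in buckets.items():
            reads.sort(key=lambda r: r.ref_start)
            self.by_ref[ref_id] = ([r.ref_start for r in reads], reads)

    def overlapping(self, seq_id: str, start: int, end: int) -> list[AlignedRead]:
        if seq_id not in self.by_ref:
            return []
        starts, reads = self.by_ref[seq_id]
        lo = bisect_left(starts, start - self.max_span)
        hi = bisect_right(starts, end)
        return [r for r in reads[lo:hi] if r.ref_end > start and r.ref_start < end]


# ---------------------------------------------------------------------------
# clip re-search
# ---------------------------------------------------------------------------


def _find_1mm(hay: str, needle: str) -> int:
    """First position of an exact-or-1-mismatch occurrence; -1 if none."""
    n = len(needle)
    # anchor on the exact half that must be error-free
    half = n // 2
    for anchor, shift in ((needle[:half], 0), (needle[half:], half)):
        p = hay.find(anchor)
        while p != -1:
            s = p - shift
            if 0 <= s <= len(hay) - n:
                mm = sum(1 for a, b in zip(hay[s : s + n], needle) if a != b)
                if mm <= 1:
                    return s
            p = hay.find(anchor, p + 1)
    return -1


@dataclass
class ClipMatch:
    seq_id: str
    provenance: str
    start: int  # match interval on the reference, forward coordinates
    end: int
    strand: str
    trimmed: int  # junction-end bases trimmed before the match was found
    ambiguous: bool = False


def search_clip(
    clip_seq: str,
    side: str,
    refs: ReferenceSet,
    config: AuditConfig | None = None,
) -> ClipMatch | None:
    """Locate a clipped sequence in the reference set.

    Tries an exact match first, then a 1-mismatch match.  Up to
    ``max_microhomology`` bases are trimmed from the junction-adjacent end
    of the clip (the aligned-boundary side), because a junction duplication
    is not part of the inserted source sequence.  A clip matching more than
    one reference sequence equally is flagged ambiguous.
    """
    cfg = config or default_config()
    for trimmed in range(0, cfg.max_microhomology + 1):
        if side == "left":
            sub = clip_seq[: len(clip_seq) - trimmed] if trimmed else clip_seq
        else:
            sub = clip_seq[trimmed:]
        if len(sub) < cfg.min_clip_len:
            break
        matches: list[ClipMatch] = []
        for rec in refs.records:
            for strand, query in (("+", sub), ("-", revcomp(sub))):
                p = rec.sequence.find(query)
                if p != -1:
                    matches.append(
                        ClipMatch(rec.id, rec.provenance, p, p + len(sub), strand, trimmed)
                    )
                    if rec.sequence.find(query, p + 1) != -1:
                        matches.append(
                            ClipMatch(rec.id, rec.provenance, p, p + len(sub), strand, trimmed)
                        )
        if matches:
            ids = {m.seq_id for m in matches}
            best = matches[0]
            best.ambiguous = len(matches) > 1 and len(ids) > 1
            return best
        # 1-mismatch fallback
        for rec in refs.records:
            for strand, query in (("+", sub), ("-", revcomp(sub))):
                p = _find_1mm(rec.sequence, query)
                if p != -1:
                    return ClipMatch(rec.id, rec.provenance, p, p + len(sub), strand, trimmed)
    return None


def split_clip(
    clip_seq: str,
    side: str,
    bp: int,
    ref_seq: str,
    config: AuditConfig | None = None,
) -> tuple[int, str] | None:
    """Split a junction-spanning clip at the point where host sequence resumes.

    For an insertion at ``bp`` the host continues unchanged on both sides, so
    a right-side clip is insert + host[bp:] and a left-side clip is
    host[:bp]-tail + insert.  Returns (insert_length, insert_sequence) for
    the shortest insert leaving at least ``min_split_anchor`` host bases, or
    None if the clip never rejoins the host.
    """
    cfg = config or default_config()
    n = len(clip_seq)
    anchor = cfg.min_split_anchor
    if side == "right":
        for ins_len in range(1, n - anchor + 1):
            if clip_seq[ins_len:] == ref_seq[bp : bp + n - ins_len]:
                return ins_len, clip_seq[:ins_len]
    else:
        for ins_len in range(1, n - anchor + 1):
            h = n - ins_len
            if bp - h >= 0 and clip_seq[:h] == ref_seq[bp - h : bp]:
                return ins_len, clip_seq[h:]
    return None


# ---------------------------------------------------------------------------
# allele calling
# ---------------------------------------------------------------------------


@dataclass
class AlleleCall:
    """One reconstructed allele at a cut site."""

    guide_id: str
    signature: tuple  # ordered (offset_from_cut, kind, length, detail) entries
    supporting_reads: int
    fraction: float
    source: Interval | None = None  # aggregated source interval for foreign alleles

    @property
    def kinds(self) -> set[str]:
        return {entry[1] for entry in self.signature}


def _read_events(
    read: AlignedRead,
    locus: GuideLocus,
    refs: ReferenceSet,
    cfg: AuditConfig,
) -> tuple[list[tuple], bool, bool, list[Interval]]:
    """Classify one read: (signature entries, covers_window, is_wt, foreign sources)."""
    cut = locus.cut_pos
    w = cfg.cut_flank
    ref_seq = refs[locus.seq_id].sequence
    entries: list[tuple] = []
    sources: list[Interval] = []

    # walk the CIGAR
    rpos = read.ref_start
    qpos = 0
    mismatch_in_window = False
    for i, (op, n) in enumerate(read.cigar):
        if op in "M=X":
            lo = max(rpos, cut - w)
            hi = min(rpos + n, cut + w)
            if lo < hi and read.seq:
                seg_q = read.seq[qpos + (lo - rpos) : qpos + (hi - rpos)]
                if seg_q != ref_seq[lo:hi]:
                    mismatch_in_window = True
            rpos += n
            qpos += n
        elif op == "I":
            if cut - w <= rpos <= cut + w:
                entries.append((rpos - cut, "ins", n, read.seq[qpos : qpos + n]))
            qpos += n
        elif op in "DN":
            if rpos + n > cut - w and rpos < cut + w:
                entries.append((rpos - cut, "del", n, ""))
            rpos += n
        elif op == "S":
            side = "left" if i == 0 else "right"
            bp = read.ref_start if side == "left" else read.ref_end
            if n < cfg.min_clip_len:
                qpos += n
                continue
            clip_seq = read.seq[:n] if side == "left" else read.seq[-n:]
            match = search_clip(clip_seq, side, refs, cfg)
            qpos += n
            if match is None:
                # the clip spans the whole insert and rejoins host sequence:
                # split it at the rejoin point to recover the exact insert
                if cut - w <= bp <= cut + w:
                    split = split_clip(clip_seq, side, bp, ref_seq, cfg)
                    if split is None:
                        entries.append((bp - cut, "unresolved_clip", n, ""))
                    else:
                        ins_len, ins_seq = split
                        src = None
                        if ins_len >= 15:
                            for rec in refs.records:
                                if rec.provenance == "host":
                                    continue
                                p = rec.sequence.find(ins_seq)
                                if p < 0:
                                    p_rc = rec.sequence.find(revcomp(ins_seq))
                                    p = p_rc
                                if p >= 0:
                                    src = rec
                                    entries.append((bp - cut, "foreign", 0, rec.id))
                                    sources.append(Interval(rec.id, p, p + ins_len))
                                    break
                        if src is None:
                            entries.append((bp - cut, "ins", ins_len, ins_seq))
                continue
            if match.provenance in ("plasmid", "contaminant"):
                # junction coordinate of the insert on the source
                if cut - w <= bp <= cut + w:
                    entries.append((bp - cut, "foreign", 0, match.seq_id))
                    sources.append(Interval(match.seq_id, match.start, match.end))
            elif match.seq_id == locus.seq_id:
                partner = match.end if side == "left" else match.start
                anchor = bp
                dist = abs(partner - anchor)
                j_lo, j_hi = min(anchor, partner), max(anchor, partner)
                # the junction must touch the cut window on at least one side
                if not (cut - w <= anchor <= cut + w or cut - w <= partner <= cut + w):
                    continue
                if dist < cfg.min_distal_distance:
                    entries.append((j_lo - cut, "del", dist, ""))
                elif dist <= cfg.max_distal_distance:
                    entries.append((j_lo - cut, "distal_junction", dist, ""))
        elif op == "H":
            pass
    entries.sort()
    covers = read.ref_start <= cut - w and read.ref_end >= cut + w
    is_wt = covers and not entries and not mismatch_in_window and all(
        op in "M=X" or (op == "S" and n < cfg.min_clip_len) for op, n in read.cigar
    )
    return entries, covers, is_wt, sources


def _entries_compatible(a: tuple, b: tuple, cfg: AuditConfig) -> bool:
    """Whether two junction signatures describe the same allele.

    Exact-CIGAR events (del/ins) must match exactly; clip-resolved junction
    events tolerate breakpoint shifts up to the merge distance, because a
    chance base match at a junction moves the observed clip boundary.
    """
    if len(a) != len(b):
        return False
    for ea, eb in zip(a, b):
        if ea[1] != eb[1]:
            return False
        kind = ea[1]
        if kind == "del":
            if ea[:3] != eb[:3]:
                return False
        elif kind == "ins":
            # a chance base match at the junction trades one unit of offset
            # for one of length; offset+length is the invariant
            if (
                ea[0] + ea[2] != eb[0] + eb[2]
                or abs(ea[0] - eb[0]) > cfg.breakpoint_merge_dist
            ):
                return False
        elif kind == "foreign":
            if ea[3] != eb[3] or abs(ea[0] - eb[0]) > cfg.breakpoint_merge_dist:
                return False
        else:  # distal_junction, unresolved_clip
            if (
                abs(ea[0] - eb[0]) > cfg.breakpoint_merge_dist
                or abs(ea[2] - eb[2]) > cfg.breakpoint_merge_dist
            ):
                return False
    return True


def _merge_compatible_signatures(
    sig_support: dict[tuple, int],
    sig_sources: dict[tuple, list[Interval]],
    cfg: AuditConfig,
) -> tuple[dict[tuple, int], dict[tuple, list[Interval]]]:
    """Greedily merge junction signatures shifted by breakpoint ambiguity."""
    order = sorted(sig_support, key=lambda k: (-sig_support[k], k))
    groups: list[list] = []  # [representative, support, sources]
    for key in order:
        placed = False
        for grp in groups:
            if _entries_compatible(grp[0], key, cfg):
                grp[1] += sig_support[key]
                grp[2].extend(sig_sources.get(key, []))
                placed = True
                break
        if not placed:
            groups.append([key, sig_support[key], list(sig_sources.get(key, []))])
    support = {g[0]: g[1] for g in groups}
    sources = {g[0]: g[2] for g in groups if g[2]}
    return support, sources


def call_alleles(
    alignments: Iterable[AlignedRead] | AlignmentIndex,
    locus: GuideLocus,
    config: AuditConfig | None = None,
    refs: ReferenceSet | None = None,
) -> tuple[list[AlleleCall], int]:
    """Cluster informative reads at a cut site into alleles; count WT reads.

    Returns (alleles, wt_read_count).  Raises if the locus has zero
    informative reads (not assessable).  Alleles supported by fewer than
    ``min_junction_support`` reads are suppressed from the return value but
    logged.
    """
    if refs is None:
        raise ValueError("call_alleles requires the reference set")
    cfg = config or default_config()
    index = alignments if isinstance(alignments, AlignmentIndex) else AlignmentIndex(alignments)
    cut = locus.cut_pos
    # pull reads near the locus, wide enough to catch far-side junction anchors
    reads = index.overlapping(
        locus.seq_id, cut - cfg.max_distal_distance, cut + cfg.max_distal_distance
    )
    sig_support: dict[tuple, int] = {}
    sig_sources: dict[tuple, list[Interval]] = {}
    wt = 0
    informative = 0
    for read in reads:
        near = read.ref_start <= cut + cfg.cut_flank and read.ref_end >= cut - cfg.cut_flank
        has_clip = any(op == "S" and n >= cfg.min_clip_len for op, n in read.cigar)
        if not near and not has_clip:
            continue
        entries, covers, is_wt, sources = _read_events(read, locus, refs, cfg)
        if not entries:
            if is_wt:
                wt += 1
                informative += 1
            continue
        informative += 1
        key = tuple(entries)
        sig_support[key] = sig_support.get(key, 0) + 1
        if sources:
            sig_sources.setdefault(key, []).extend(sources)
    # insert-anchored junction reads: a read whose longer half lies on a
    # plasmid/contaminant aligns there and clips its host tail; if that tail
    # maps into the cut window it supports a foreign allele at this locus
    host_ids = {r.id for r in refs.host}
    for ref_rec in refs.records:
        if ref_rec.provenance == "host" or ref_rec.id not in index.by_ref:
            continue
        for read in index.by_ref[ref_rec.id][1]:
            for i, (op, n) in enumerate(read.cigar):
                if op != "S" or n < cfg.min_clip_len:
                    continue
                side = "left" if i == 0 else "right"
                clip_seq = read.seq[:n] if side == "left" else read.seq[-n:]
                m = search_clip(clip_seq, side, refs, cfg)
                if m is None or m.seq_id != locus.seq_id:
                    continue
                bp = m.end if side == "left" else m.start
                if not (cut - cfg.cut_flank <= bp <= cut + cfg.cut_flank):
                    continue
                key = ((bp - cut, "foreign", 0, ref_rec.id),)
                informative += 1
                sig_support[key] = sig_support.get(key, 0) + 1
                sig_sources.setdefault(key, []).append(
                    Interval(ref_rec.id, read.ref_start, read.ref_end)
                )
    if informative == 0:
        raise ValueError(
            f"locus {locus.guide_id}@{locus.seq_id}:{cut} not assessable: no informative reads"
        )
    sig_support, sig_sources = _merge_compatible_signatures(sig_support, sig_sources, cfg)
    alleles: list[AlleleCall] = []
    for key, support in sorted(sig_support.items(), key=lambda kv: -kv[1]):
        src = None
        if key in sig_sources:
            ivs = sig_sources[key]
            src = Interval(ivs[0].seq_id, min(i.start for i in ivs), max(i.end for i in ivs))
        call = AlleleCall(
            guide_id=locus.guide_id,
            signature=key,
            supporting_reads=support,
            fraction=support / informative,
            source=src,
        )
        if support >= cfg.min_junction_support:
            alleles.append(call)
        else:
            logger.info(
                "suppressed allele at %s:%d (%d read(s) < min_junction_support): %s",
                locus.seq_id, cut, support, key,
            )
    return alleles, wt


def discordant_span_support(
    alignments: Iterable[AlignedRead] | AlignmentIndex,
    locus: GuideLocus,
    max_dist: int,
    config: AuditConfig | None = None,
) -> list[tuple[tuple[AlignedRead, AlignedRead], int]]:
    """FR pairs over the cut window with an implied template length far above
    the library distribution (mean + 4 sd of all proper pairs), capped at
    ``max_dist``; evidence for a junction to distant sequence."""
    index = alignments if isinstance(alignments, AlignmentIndex) else AlignmentIndex(alignments)
    if max_dist <= 0:
        return []
    spans = [abs(r.template_len) for r in index.all_primary if r.is_proper and r.template_len > 0]
    if not spans:
        return []
    n = len(spans)
    mean = sum(spans) / n
    var = sum((s - mean) ** 2 for s in spans) / n
    threshold = mean + 4 * var**0.5
    pairs: dict[str, list[AlignedRead]] = {}
    for read in index.all_primary:
        if read.ref_id == locus.seq_id == read.mate_ref_id:
            pairs.setdefault(read.read_id, []).append(read)
    out = []
    w = locus.window
    for reads in pairs.values():
        if len(reads) != 2:
            continue
        a, b = sorted(reads, key=lambda r: r.ref_start)
        if a.is_reverse or not b.is_reverse:
            continue  # require FR orientation
        span = b.ref_end - a.ref_start
        if span <= threshold or span > max_dist:
            continue
        if a.ref_start < w.end and b.ref_end > w.start:
            out.append(((a, b), span))
    return out
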