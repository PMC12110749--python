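"""Desk-scale paired-end seed-and-extend aligner.

Produces the alignment behaviors the audit depends on — soft clips at
sequence junctions and cross-reference mate placement — without requiring an
external aligner.  Reads are seeded with exact k-mers against a sorted-array
index, candidate loci are voted by seed diagonals, and each candidate is
scored either by an exact full-length match (the common case for error-free
reads) or by a local affine-gap alignment whose unaligned read ends become
soft clips.  Equal-best hits are emitted as secondary alignments and kept
downstream.  Externally produced SAM text with the same conventions is a
drop-in replacement (see ``docs/methods.md`` for the conformance list).

Scoring prefers clipping over forcing very long gapped extensions, so
junction-spanning reads clip rather than stretch across foreign sequence,
while mid-size indels (up to the band width) stay gapped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from numba import njit

from .hybridref import ReferenceSet
from .seqio import (
    FLAG_MATE_REVERSE,
    FLAG_MATE_UNMAPPED,
    FLAG_PAIRED,
    FLAG_PROPER,
    FLAG_READ1,
    FLAG_READ2,
    FLAG_REVERSE,
    FLAG_SECONDARY,
    FLAG_UNMAPPED,
    AlignedRead,
    Interval,
    revcomp,
)

__all__ = ["Scoring", "SeedIndex", "build_index", "align_pair", "align_reads", "extract_softclips", "SoftClip"]

_ENC = np.zeros(256, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENC[_b] = _i


@dataclass
class Scoring:
    """Alignment scoring and pairing parameters."""

    match: float = 1.0
    mismatch: float = -4.0
    gap_open: float = -6.0
    gap_extend: float = -0.5
    #: window padding around a candidate locus; bounds the longest gapped indel
    band: int = 60
    #: spacing of seed k-mers along the read
    seed_step: int = 25
    #: candidate loci evaluated per read orientation
    max_candidates: int = 4
    #: score margin below which the best hit is called ambiguous (mapq 30)
    mapq_margin: float = 20.0
    #: template length beyond which a same-reference FR pair is not "proper"
    proper_max_tlen: int = 1000


def _encode(seq: str) -> np.ndarray:
    return _ENC[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _rolling_codes(arr: np.ndarray, k: int) -> np.ndarray:
    """2-bit k-mer codes at every offset (int64; exact for k <= 31)."""
    n = arr.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    code = np.zeros(n, dtype=np.int64)
    for j in range(k):
        code = code * 4 + arr[j : j + n]
    return code


@dataclass
class SeedIndex:
    """Sorted-array exact k-mer index over the forward strand of every reference.

    Reverse-strand hits are found by querying the reverse complement of the
    read, which is equivalent to indexing both strands.
    """

    k: int
    ref_names: list[str]
    ref_lengths: list[int]
    codes: np.ndarray  # sorted k-mer codes
    ref_idx: np.ndarray  # parallel: which reference
    offsets: np.ndarray  # parallel: forward-strand offset

    @property
    def n_positions(self) -> int:
        return int(self.codes.size)

    @property
    def n_distinct(self) -> int:
        return int(np.unique(self.codes).size)

    def lookup_code(self, code: int) -> tuple[np.ndarray, np.ndarray]:
        lo = int(np.searchsorted(self.codes, code, side="left"))
        hi = int(np.searchsorted(self.codes, code, side="right"))
        return self.ref_idx[lo:hi], self.offsets[lo:hi]

    def lookup(self, kmer: str) -> list[tuple[str, int, str]]:
        """All (ref_id, forward offset, strand) occurrences of a k-mer."""
        if len(kmer) != self.k:
            raise ValueError(f"query length {len(kmer)} != k={self.k}")
        out: list[tuple[str, int, str]] = []
        for strand, seq in (("+", kmer), ("-", revcomp(kmer))):
            code = int(_rolling_codes(_encode(seq), self.k)[0])
            ridx, offs = self.lookup_code(code)
            out.extend((self.ref_names[r], int(o), strand) for r, o in zip(ridx, offs))
        return out


def build_index(refs: ReferenceSet, k: int = 21) -> SeedIndex:
    """Index every forward-strand k-mer position of every reference."""
    if k < 11:
        raise ValueError("k must be >= 11")
    if k > min(refs.lengths.values()):
        raise ValueError("k exceeds the shortest reference sequence")
    all_codes, all_ref, all_off = [], [], []
    for i, rec in enumerate(refs.records):
        codes = _rolling_codes(_encode(rec.sequence), k)
        all_codes.append(codes)
        all_ref.append(np.full(codes.size, i, dtype=np.uint32))
        all_off.append(np.arange(codes.size, dtype=np.uint32))
    codes = np.concatenate(all_codes)
    ref_idx = np.concatenate(all_ref)
    offsets = np.concatenate(all_off)
    order = np.argsort(codes, kind="stable")
    return SeedIndex(
        k=k,
        ref_names=refs.ids,
        ref_lengths=[refs.lengths[n] for n in refs.ids],
        codes=codes[order],
        ref_idx=ref_idx[order],
        offsets=offsets[order],
    )


# ---------------------------------------------------------------------------
# local affine-gap alignment (numba-jitted)
# ---------------------------------------------------------------------------


@njit(cache=True)
def _sw_core(read, ref, match, mismatch, gap_open, gap_extend):  # pragma: no cover
    n = read.size
    m = ref.size
    NEG = np.float32(-1e30)
    H = np.zeros((n + 1, m + 1), dtype=np.float32)
    E = np.full((n + 1, m + 1), NEG, dtype=np.float32)
    F = np.full((n + 1, m + 1), NEG, dtype=np.float32)
    best = np.float32(0.0)
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            e = H[i, j - 1] + gap_open
            e2 = E[i, j - 1] + gap_extend
            if e2 > e:
                e = e2
            E[i, j] = e
            f = H[i - 1, j] + gap_open
            f2 = F[i - 1, j] + gap_extend
            if f2 > f:
                f = f2
            F[i, j] = f
            s = match if read[i - 1] == ref[j - 1] else mismatch
            h = H[i - 1, j - 1] + s
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0.0:
                h = 0.0
            H[i, j] = h
            if h > best:
                best = h
                bi = i
                bj = j
    # traceback: ops 0=M, 1=I (read-only), 2=D (ref-only)
    ops = np.empty(n + m, dtype=np.uint8)
    nops = 0
    i, j = bi, bj
    while i > 0 and j > 0 and H[i, j] > 0.0:
        h = H[i, j]
        s = match if read[i - 1] == ref[j - 1] else mismatch
        if h == H[i - 1, j - 1] + s:
            ops[nops] = 0
            nops += 1
            i -= 1
            j -= 1
        elif h == E[i, j]:
            # consume ref (deletion from the read's perspective)
            while True:
                ops[nops] = 2
                nops += 1
                stop = E[i, j] == H[i, j - 1] + gap_open
                j -= 1
                if stop or j == 0:
                    break
        elif h == F[i, j]:
            while True:
                ops[nops] = 1
                nops += 1
                stop = F[i, j] == H[i - 1, j] + gap_open
                i -= 1
                if stop or i == 0:
                    break
        else:  # numerical safety: treat as match step
            ops[nops] = 0
            nops += 1
            i -= 1
            j -= 1
    return best, i, j, bi, bj, ops[:nops]


_OP_CHARS = "MID"


def _sw_align(read_arr: np.ndarray, ref_arr: np.ndarray, sc: Scoring):
    """Local alignment; returns (score, read_start, read_end, ref_start, ref_end, cigar_core)."""
    best, i0, j0, i1, j1, ops = _sw_core(
        read_arr,
        ref_arr,
        np.float32(sc.match),
        np.float32(sc.mismatch),
        np.float32(sc.gap_open),
        np.float32(sc.gap_extend),
    )
    if best <= 0 or i1 == i0:
        return None
    cigar: list[tuple[str, int]] = []
    for op in ops[::-1]:
        ch = _OP_CHARS[op]
        if cigar and cigar[-1][0] == ch:
            cigar[-1] = (ch, cigar[-1][1] + 1)
        else:
            cigar.append((ch, 1))
    return float(best), i0, i1, j0, j1, cigar


# ---------------------------------------------------------------------------
# candidate generation and per-read alignment
# ---------------------------------------------------------------------------


@dataclass
class _Hit:
    score: float
    ref_i: int
    orient: int  # 0 = forward, 1 = reverse
    pos: int  # 0-based leftmost on the reference
    cigar: list[tuple[str, int]]


def _candidate_clusters(
    seq_arr: np.ndarray, index: SeedIndex, sc: Scoring
) -> list[tuple[int, int, int]]:
    """Candidate (ref_i, start_pos, votes) for one read orientation."""
    L = seq_arr.size
    k = index.k
    if L < k:
        return []
    codes = _rolling_codes(seq_arr, k)
    seed_offs = list(range(0, L - k + 1, sc.seed_step))
    if seed_offs[-1] != L - k:
        seed_offs.append(L - k)
    q = codes[np.array(seed_offs)]
    lo = np.searchsorted(index.codes, q, side="left")
    hi = np.searchsorted(index.codes, q, side="right")
    votes: dict[tuple[int, int], int] = {}
    for s_i, off in enumerate(seed_offs):
        for t in range(lo[s_i], hi[s_i]):
            key = (int(index.ref_idx[t]), int(index.offsets[t]) - off)
            votes[key] = votes.get(key, 0) + 1
    if not votes:
        return []
    # merge nearby diagonals (within the band) into clusters
    items = sorted(votes.items(), key=lambda kv: (kv[0][0], kv[0][1]))
    clusters: list[list[int]] = []  # [ref_i, votes, best_pos, best_votes, last_pos]
    for (ref_i, pos), v in items:
        if clusters and clusters[-1][0] == ref_i and pos - clusters[-1][4] <= sc.band:
            c = clusters[-1]
            c[1] += v
            c[4] = pos
            if v > c[3]:
                c[2], c[3] = pos, v
        else:
            clusters.append([ref_i, v, pos, v, pos])
    clusters.sort(key=lambda c: (-c[1], c[0], c[2]))
    return [(c[0], c[2], c[1]) for c in clusters[: sc.max_candidates]]


def _align_orientation(
    seq: str, seq_arr: np.ndarray, orient: int, index: SeedIndex, refs: ReferenceSet, sc: Scoring
) -> list[_Hit]:
    hits: list[_Hit] = []
    L = len(seq)
    for ref_i, pos, _votes in _candidate_clusters(seq_arr, index, sc):
        ref_seq = refs.records[ref_i].sequence
        if 0 <= pos and pos + L <= len(ref_seq) and ref_seq[pos : pos + L] == seq:
            hits.append(_Hit(sc.match * L, ref_i, orient, pos, [("M", L)]))
            continue
        w_start = max(0, pos - sc.band)
        w_end = min(len(ref_seq), pos + L + sc.band)
        window = _encode(ref_seq[w_start:w_end])
        res = _sw_align(seq_arr, window, sc)
        if res is None:
            continue
        score, r0, r1, g0, g1, core = res
        cigar: list[tuple[str, int]] = []
        if r0 > 0:
            cigar.append(("S", r0))
        cigar.extend(core)
        if L - r1 > 0:
            cigar.append(("S", L - r1))
        hits.append(_Hit(score, ref_i, orient, w_start + g0, cigar))
    return hits


def _align_single(read_seq: str, index: SeedIndex, refs: ReferenceSet, sc: Scoring) -> list[_Hit]:
    """All hits for one read, best first; ties by (reference order, position)."""
    fwd = read_seq
    rev = revcomp(read_seq)
    hits = _align_orientation(fwd, _encode(fwd), 0, index, refs, sc)
    hits += _align_orientation(rev, _encode(rev), 1, index, refs, sc)
    # deduplicate identical placements
    seen: set[tuple[int, int, int]] = set()
    uniq: list[_Hit] = []
    for h in sorted(hits, key=lambda h: (-h.score, h.ref_i, h.pos, h.orient)):
        key = (h.ref_i, h.orient, h.pos)
        if key not in seen:
            seen.add(key)
            uniq.append(h)
    return uniq


def _mapq(hits: list[_Hit], sc: Scoring) -> int:
    if not hits:
        return 0
    if len(hits) == 1:
        return 60
    if hits[1].score == hits[0].score:
        return 0
    if hits[0].score - hits[1].score < sc.mapq_margin:
        return 30
    return 60


def _records_for_read(
    read_id: str,
    raw_seq: str,
    qual: str,
    hits: list[_Hit],
    refs: ReferenceSet,
    sc: Scoring,
    mate_bit: int,
) -> list[AlignedRead]:
    base_flag = FLAG_PAIRED | mate_bit
    if not hits:
        return [
            AlignedRead(read_id, base_flag | FLAG_UNMAPPED, None, 0, 0, [], seq=raw_seq, qual=qual)
        ]
    mapq = _mapq(hits, sc)
    records: list[AlignedRead] = []
    n_secondary = sum(1 for h in hits[1:] if h.score == hits[0].score)
    for rank, hit in enumerate(hits[: 1 + n_secondary]):
        flag = base_flag
        if hit.orient:
            flag |= FLAG_REVERSE
        if rank > 0:
            flag |= FLAG_SECONDARY
        seq = raw_seq if not hit.orient else revcomp(raw_seq)
        records.append(
            AlignedRead(
                read_id=read_id,
                flag=flag,
                ref_id=refs.records[hit.ref_i].id,
                pos=hit.pos + 1,
                mapq=mapq if rank == 0 else 0,
                cigar=list(hit.cigar),
                seq=seq,
                qual=qual if not hit.orient else qual[::-1],
            )
        )
    return records


def align_pair(
    read1: str,
    read2: str,
    index: SeedIndex,
    refs: ReferenceSet,
    scoring: Scoring | None = None,
    read_id: str = "pair",
    qual1: str = "",
    qual2: str = "",
) -> tuple[list[AlignedRead], list[AlignedRead]]:
    """Align both mates independently, then set pairing flags.

    Returns the records for each mate, primary first (secondaries follow for
    equal-best placements).  A pair is flagged proper when both primaries map
    to the same reference in FR orientation within the template bound.
    """
    sc = scoring or Scoring()
    if not read1 or not read2:
        raise ValueError("reads must be non-empty")
    qual1 = qual1 or "?" * len(read1)
    qual2 = qual2 or "?" * len(read2)
    hits1 = _align_single(read1, index, refs, sc)
    hits2 = _align_single(read2, index, refs, sc)
    recs1 = _records_for_read(read_id, read1, qual1, hits1, refs, sc, FLAG_READ1)
    recs2 = _records_for_read(read_id, read2, qual2, hits2, refs, sc, FLAG_READ2)
    _set_mate_fields(recs1[0], recs2[0], sc)
    for extra in recs1[1:]:
        extra.mate_ref_id, extra.mate_pos = recs2[0].ref_id, recs2[0].pos
    for extra in recs2[1:]:
        extra.mate_ref_id, extra.mate_pos = recs1[0].ref_id, recs1[0].pos
    return recs1, recs2


def _set_mate_fields(a: AlignedRead, b: AlignedRead, sc: Scoring) -> None:
    for rec, mate in ((a, b), (b, a)):
        rec.mate_ref_id = mate.ref_id
        rec.mate_pos = mate.pos
        if mate.is_unmapped:
            rec.flag |= FLAG_MATE_UNMAPPED
        elif mate.is_reverse:
            rec.flag |= FLAG_MATE_REVERSE
    if a.is_unmapped or b.is_unmapped or a.ref_id != b.ref_id:
        return
    left, right = (a, b) if a.ref_start <= b.ref_start else (b, a)
    tlen = right.ref_end - left.ref_start
    proper = (
        not left.is_reverse
        and right.is_reverse
        and 0 < tlen <= sc.proper_max_tlen
    )
    left.template_len = tlen
    right.template_len = -tlen
    if proper:
        a.flag |= FLAG_PROPER
        b.flag |= FLAG_PROPER


def align_reads(
    pairs: Iterable,
    index: SeedIndex,
    refs: ReferenceSet,
    scoring: Scoring | None = None,
) -> list[AlignedRead]:
    """Align an iterable of read pairs (ReadPair or (id, seq1, seq2) tuples)."""
    sc = scoring or Scoring()
    out: list[AlignedRead] = []
    for p in pairs:
        if hasattr(p, "seq1"):
            rid, s1, s2 = p.read_id, p.seq1, p.seq2
        else:
            rid, s1, s2 = p
        recs1, recs2 = align_pair(s1, s2, index, refs, sc, read_id=rid)
        out.extend(recs1)
        out.extend(recs2)
    return out


# ---------------------------------------------------------------------------
# soft-clip extraction
# ---------------------------------------------------------------------------


@dataclass
class SoftClip:
    """One soft-clipped read end with its reference breakpoint."""

    read: AlignedRead
    side: str  # "left" | "right"
    seq: str
    breakpoint: Interval  # 1-nt interval at the clip boundary (0-based)

    @property
    def position(self) -> int:
        return self.breakpoint.start


def extract_gapped_inserts(
    alignments: Iterable[AlignedRead], min_ins_len: int = 20
) -> list[SoftClip]:
    """Large insertion CIGAR operations as synthetic right-side clips.

    Inserts short enough to fit in the alignment band are gapped rather than
    clipped, so they leave no soft-clip evidence; representing the read tail
    from the insertion onward as a clip lets junction clustering treat both
    evidence classes identically.
    """
    out: list[SoftClip] = []
    for read in alignments:
        if read.is_unmapped or read.is_secondary or not read.seq:
            continue
        rpos, qpos = read.ref_start, 0
        for op, n in read.cigar:
            if op in "M=X":
                rpos += n
                qpos += n
            elif op == "I":
                if n >= min_ins_len:
                    out.append(
                        SoftClip(read, "right", read.seq[qpos:], Interval(read.ref_id, rpos, rpos + 1))
                    )
                qpos += n
            elif op in "DN":
                rpos += n
            elif op == "S":
                qpos += n
    return out


def extract_softclips(alignments: Iterable[AlignedRead], min_clip_len: int = 20) -> list[SoftClip]:
    """One entry per primary-alignment clip of at least ``min_clip_len`` nt.

    The breakpoint of a left clip is the alignment start; of a right clip,
    the alignment end (0-based half-open), i.e. the reference coordinate at
    which the read stops matching.
    """
    if min_clip_len < 1:
        raise ValueError("min_clip_len must be >= 1")
    out: list[SoftClip] = []
    for read in alignments:
        if read.is_unmapped or read.is_secondary or not read.cigar:
            continue
        op0, n0 = read.cigar[0]
        if op0 == "S" and n0 >= min_clip_len:
            bp = read.ref_start
            out.append(
                SoftClip(read, "left", read.seq[:n0], Interval(read.ref_id, bp, bp + 1))
            )
        opn, nn = read.cigar[-1]
        if len(read.cigar) > 1 and opn == "S" and nn >= min_clip_len:
            bp = read.ref_end
            out.append(
                SoftClip(read, "right", read.seq[-nn:], Interval(read.ref_id, bp, bp + 1))
            )
    return out
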