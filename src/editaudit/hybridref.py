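"""Hybrid audit reference: host genome + linearized plasmids + contaminant.

Foreign-derived reads (vector backbone, cloning-strain DNA) only map cleanly
when the foreign sequences are part of the reference, so the audit aligns
against a hybrid: the host chromosomes with each plasmid and the contaminant
genome appended as extra sequences.  Circular plasmids are linearized at
position 0 with wrap-around overhangs so that reads spanning the circular
junction still map contiguously.

Host regions that occur verbatim inside a plasmid (e.g. a host promoter
cloned into the vector) attract floods of artefactual cross-reference pairs
and clips; :func:`compute_homology_mask` finds them declaratively by shared
k-mer seeding extended to maximal exact matches, so downstream stages can
flag evidence falling inside them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .seqio import Interval, SeqRecord, revcomp

__all__ = ["ReferenceSet", "build_reference", "compute_homology_mask"]

_SEED_K = 31


@dataclass
class ReferenceSet:
    """Ordered references with provenance and an optional homology mask."""

    records: list[SeqRecord]
    homology_mask: list[Interval] = field(default_factory=list)
    plasmid_mask: list[Interval] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate sequence ids in reference set")
        self._by_id = {r.id: r for r in self.records}

    def __getitem__(self, seq_id: str) -> SeqRecord:
        return self._by_id[seq_id]

    def __contains__(self, seq_id: str) -> bool:
        return seq_id in self._by_id

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    @property
    def lengths(self) -> dict[str, int]:
        return {r.id: len(r) for r in self.records}

    def by_provenance(self, provenance: str) -> list[SeqRecord]:
        return [r for r in self.records if r.provenance == provenance]

    @property
    def host(self) -> list[SeqRecord]:
        return self.by_provenance("host")


def build_reference(
    host: list[SeqRecord],
    plasmids: list[SeqRecord],
    contaminant: list[SeqRecord] | None = None,
    overhang: int = 75,
) -> ReferenceSet:
    """Assemble the hybrid reference.

    Each plasmid of length L is appended as a single sequence of length
    L + 2*overhang: the last `overhang` nt of the circle are prepended and
    the first `overhang` nt appended (circular linearization at position 0).
    The contaminant genome is appended unchanged; host sequences unchanged.
    """
    records: list[SeqRecord] = [SeqRecord(r.id, r.sequence, "host") for r in host]
    for p in plasmids:
        if overhang >= len(p):
            raise ValueError(f"overhang {overhang} >= plasmid {p.id!r} length {len(p)}")
        seq = p.sequence[-overhang:] + p.sequence + p.sequence[:overhang] if overhang else p.sequence
        records.append(SeqRecord(p.id, seq, "plasmid"))
    for c in contaminant or []:
        records.append(SeqRecord(c.id, c.sequence, "contaminant"))
    return ReferenceSet(records)


def _merge_intervals(intervals: list[Interval]) -> list[Interval]:
    merged: list[Interval] = []
    for iv in sorted(intervals, key=lambda i: (i.seq_id, i.start, i.end)):
        if merged and merged[-1].seq_id == iv.seq_id and iv.start <= merged[-1].end:
            last = merged[-1]
            if iv.end > last.end:
                merged[-1] = Interval(last.seq_id, last.start, iv.end, last.strand, last.name)
        else:
            merged.append(iv)
    return merged


def compute_homology_mask(refs: ReferenceSet, min_match_len: int = 100) -> list[Interval]:
    """Host intervals sharing an exact match of >= min_match_len nt with any plasmid.

    Seeds with shared 31-mers, extends each to a maximal exact match, then
    merges overlapping host intervals.  Both plasmid strands are searched.
    The symmetric plasmid-side intervals are stored on refs.plasmid_mask.
    """
    if min_match_len < 30:
        raise ValueError("min_match_len must be >= 30")
    k = _SEED_K
    host_index: dict[str, list[tuple[str, int]]] = {}
    for rec in refs.host:
        seq = rec.sequence
        for i in range(len(seq) - k + 1):
            host_index.setdefault(seq[i : i + k], []).append((rec.id, i))

    host_hits: list[Interval] = []
    plasmid_hits: list[Interval] = []
    for plasmid in refs.by_provenance("plasmid"):
        for strand, pseq in (("+", plasmid.sequence), ("-", revcomp(plasmid.sequence))):
            p = 0
            while p <= len(pseq) - k:
                positions = host_index.get(pseq[p : p + k])
                if not positions:
                    p += 1
                    continue
                best_len = 0
                for host_id, h in positions:
                    hseq = refs[host_id].sequence
                    # extend left
                    left = 0
                    while p - left - 1 >= 0 and h - left - 1 >= 0 and pseq[p - left - 1] == hseq[h - left - 1]:
                        left += 1
                    # extend right
                    right = k
                    while (
                        p + right < len(pseq)
                        and h + right < len(hseq)
                        and pseq[p + right] == hseq[h + right]
                    ):
                        right += 1
                    match_len = left + right
                    if match_len >= min_match_len:
                        host_hits.append(Interval(host_id, h - left, h + right, "+", plasmid.id))
                        ps, pe = p - left, p + right
                        if strand == "-":
                            ps, pe = len(pseq) - pe, len(pseq) - ps
                        plasmid_hits.append(Interval(plasmid.id, ps, pe, strand, host_id))
                    best_len = max(best_len, match_len)
                # skip ahead past the extended region to avoid quadratic rescans
                p += max(1, best_len - k + 1) if best_len else 1

    mask = _merge_intervals(host_hits)
    refs.homology_mask = mask
    refs.plasmid_mask = _merge_intervals(plasmid_hits)
    return mask
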