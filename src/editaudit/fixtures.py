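"""Synthetic-data generator: references, planted edits, and read simulation.

The generator builds a random host genome, plasmids carrying a shared host
segment (the "homology trap", emulating a host promoter cloned into the
expression vectors), and a contaminant genome (emulating cloning-strain
DNA).  Edits are applied per haplotype — every host chromosome is diploid —
and ground truth (realized coordinates plus a pre->post lift-over map) is
recorded so downstream stages can be scored against it.

Reads are paired-end with a truncated-normal fragment length, mate 2
reverse-complemented, i.i.d. substitution errors only, and constant Q30
base qualities.  Error-free reads are exact substrings of the (edited)
genome or its reverse complement.

The canned ``multi_edit`` scenario plants one instance of every event class the
audit must recover:

* two deletion alleles (8 and 10 nt) at one cut site,
* a 1-nt insertion on both haplotypes at a second site,
* a 184-nt contaminant insert with a 3-nt junction duplication plus, on the
  other haplotype, a junction to host sequence 575 nt away,
* a contaminant insert whose junction carries a 4-nt direct repeat,
* a tandem two-copy plasmid integration,
* a 300-nt homozygous deletion (a zero-coverage anomaly).
"""

from __future__ import annotations

import json
import math
from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .hybridref import ReferenceSet
from .seqio import Interval, SeqRecord, revcomp, write_fasta, write_fastq, write_gff

__all__ = [
    "EditEvent",
    "Truth",
    "ReadPair",
    "Scenario",
    "make_references",
    "apply_edits",
    "simulate_reads",
    "scenario_multi_edit",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

EVENT_KINDS = {"deletion", "insertion", "foreign_insertion", "distal_junction", "tandem_integration"}


@dataclass
class EditEvent:
    """One planted edit on the pre-edit host genome.

    ``locus`` is the affected pre-edit interval: the deleted span for
    deletions, the span [start, start+distance) severed by a distal
    junction, and a nominal 1-nt interval whose *start* is the insertion
    point for the insertion kinds.  ``haplotypes`` lists which of the two
    haplotypes carry the event.
    """

    kind: str
    locus: Interval
    haplotypes: tuple[int, ...] = (0, 1)
    payload_source: Interval | None = None
    payload_len: int = 0
    payload_seq: str | None = None  # untemplated bases for kind="insertion"
    microhomology_len: int = 0
    copy_count: int = 1

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.copy_count < 1:
            raise ValueError("copy_count must be >= 1")
        if self.microhomology_len < 0 or (
            self.payload_len and self.microhomology_len > self.payload_len
        ):
            raise ValueError("microhomology_len must be in [0, payload_len]")
        if self.kind == "foreign_insertion" and self.payload_source is None:
            raise ValueError("foreign_insertion requires payload_source")
        if self.kind == "tandem_integration" and self.payload_source is None:
            raise ValueError("tandem_integration requires payload_source")
        if self.kind == "insertion" and not self.payload_seq:
            raise ValueError("insertion requires payload_seq")

    @property
    def length_change(self) -> int:
        if self.kind == "deletion":
            return -len(self.locus)
        if self.kind == "insertion":
            return len(self.payload_seq or "")
        if self.kind == "foreign_insertion":
            return self.payload_len + self.microhomology_len
        if self.kind == "distal_junction":
            return -self.payload_len
        if self.kind == "tandem_integration":
            return self.copy_count * len(self.payload_source or ())  # set in apply
        return 0

    def span(self) -> tuple[int, int]:
        """Pre-edit footprint used for the non-overlap check."""
        if self.kind in ("deletion",):
            return self.locus.start, self.locus.end
        if self.kind == "distal_junction":
            return self.locus.start, self.locus.start + self.payload_len
        return self.locus.start, self.locus.start + 1


@dataclass
class RealizedEvent:
    """Where an event landed on the edited genome (one haplotype)."""

    kind: str
    seq_id: str
    hap: int
    pre_start: int
    post_start: int
    post_end: int
    inserted_seq: str = ""
    payload_source: Interval | None = None
    microhomology_len: int = 0
    distance: int = 0
    copy_count: int = 1

    def to_dict(self) -> dict:
        d = {
            "kind": self.kind,
            "seq_id": self.seq_id,
            "hap": self.hap,
            "pre_start": self.pre_start,
            "post_start": self.post_start,
            "post_end": self.post_end,
            "microhomology_len": self.microhomology_len,
            "distance": self.distance,
            "copy_count": self.copy_count,
        }
        if self.payload_source is not None:
            d["payload_source"] = {
                "seq_id": self.payload_source.seq_id,
                "start": self.payload_source.start,
                "end": self.payload_source.end,
            }
        return d


@dataclass
class Truth:
    """Ground truth: edited haplotypes, realized events, pre->post lift-over."""

    haplotypes: list[SeqRecord]
    events: list[RealizedEvent]
    #: per (seq_id, hap): kept pre-edit segments as (pre_start, pre_end, post_start)
    liftover: dict[tuple[str, int], list[tuple[int, int, int]]]

    def hap_id(self, seq_id: str, hap: int) -> str:
        return f"{seq_id}|hap{hap}"

    def lift(self, seq_id: str, hap: int, pre_pos: int) -> int | None:
        """Map a pre-edit coordinate to the edited haplotype; None if deleted."""
        segs = self.liftover[(seq_id, hap)]
        starts = [s[0] for s in segs]
        i = bisect_right(starts, pre_pos) - 1
        if i < 0:
            return None
        pre_start, pre_end, post_start = segs[i]
        if pre_pos >= pre_end:
            return None
        return post_start + (pre_pos - pre_start)

    def verify(self, host: list[SeqRecord]) -> None:
        """Internal consistency: lift-over monotone, kept segments identical."""
        host_by_id = {r.id: r for r in host}
        hap_by_id = {r.id: r for r in self.haplotypes}
        for (seq_id, hap), segs in self.liftover.items():
            pre = host_by_id[seq_id].sequence
            post = hap_by_id[self.hap_id(seq_id, hap)].sequence
            last_post = -1
            for pre_start, pre_end, post_start in segs:
                if post_start <= last_post:
                    raise AssertionError("lift-over not monotone")
                last_post = post_start
                if pre[pre_start:pre_end] != post[post_start : post_start + pre_end - pre_start]:
                    raise AssertionError("lift-over segment mismatch")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "haplotypes": {r.id: len(r) for r in self.haplotypes},
            "events": [e.to_dict() for e in self.events],
            "liftover": {
                f"{sid}|hap{h}": segs for (sid, h), segs in self.liftover.items()
            },
        }
        Path(path).write_text(json.dumps(payload, indent=1))


# ---------------------------------------------------------------------------
# reference construction
# ---------------------------------------------------------------------------


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode()


def make_references(
    n_host_seqs: int,
    host_len: int,
    n_plasmids: int,
    plasmid_len: int,
    contaminant_len: int,
    shared_homology_len: int,
    seed: int,
) -> ReferenceSet:
    """Random host/plasmid/contaminant references with a planted homology trap.

    Each plasmid contains one exact copy of the same host subsequence of
    length ``shared_homology_len`` (a promoter-like region shared between
    vector and host).  Deterministic under ``seed``.  The planted trap
    coordinates are recorded on the returned set as ``homology_truth``:
    a list of (host Interval, plasmid Interval) pairs.
    """
    if min(n_host_seqs, host_len) < 1 or contaminant_len < 0 or n_plasmids < 0:
        raise ValueError("lengths and counts must be positive")
    if n_plasmids and shared_homology_len >= min(plasmid_len, host_len):
        raise ValueError("shared_homology_len must be < min(plasmid_len, host_len)")
    rng = np.random.default_rng(seed)
    records: list[SeqRecord] = []
    for i in range(n_host_seqs):
        records.append(SeqRecord(f"chr{i + 1}", _random_seq(rng, host_len), "host"))
    trap_truth: list[tuple[Interval, Interval]] = []
    trap_host: Interval | None = None
    if n_plasmids and shared_homology_len:
        # one shared host region, copied into every plasmid (as with a host
        # promoter driving each vector's expression cassette)
        h_start = int(rng.integers(0, host_len - shared_homology_len))
        trap_host = Interval("chr1", h_start, h_start + shared_homology_len, "+", "homology_trap")
    for j in range(n_plasmids):
        seq = _random_seq(rng, plasmid_len)
        if trap_host is not None:
            shared = records[0].sequence[trap_host.start : trap_host.end]
            p_start = int(rng.integers(0, plasmid_len - shared_homology_len))
            seq = seq[:p_start] + shared + seq[p_start + shared_homology_len :]
            trap_truth.append(
                (trap_host, Interval(f"plasmid{j + 1}", p_start, p_start + shared_homology_len))
            )
        records.append(SeqRecord(f"plasmid{j + 1}", seq, "plasmid"))
    if contaminant_len:
        records.append(SeqRecord("contaminant", _random_seq(rng, contaminant_len), "contaminant"))
    refs = ReferenceSet(records)
    refs.homology_truth = trap_truth  # type: ignore[attr-defined]
    return refs


# ---------------------------------------------------------------------------
# edit application
# ---------------------------------------------------------------------------


def apply_edits(refs: ReferenceSet, events: list[EditEvent]) -> tuple[list[SeqRecord], Truth]:
    """Apply planted events per haplotype; return edited haplotypes + truth.

    Two haplotypes are emitted per host chromosome.  Events must be
    non-overlapping on the pre-edit host (per haplotype).  Inserted foreign
    payloads are followed by a duplicated copy of the ``microhomology_len``
    host bases immediately upstream of the insertion point, so the direct
    repeat flanks the insert.
    """
    host = refs.host
    by_hap: dict[tuple[str, int], list[EditEvent]] = {}
    for ev in events:
        if ev.locus.seq_id not in {r.id for r in host}:
            raise ValueError(f"event locus on unknown host sequence {ev.locus.seq_id!r}")
        for h in ev.haplotypes:
            by_hap.setdefault((ev.locus.seq_id, h), []).append(ev)
    for (seq_id, h), evs in by_hap.items():
        evs.sort(key=lambda e: e.span())
        for a, b in zip(evs, evs[1:]):
            if a.span()[1] > b.span()[0]:
                raise ValueError(
                    f"overlapping events on {seq_id} hap{h}: "
                    f"{a.kind}@{a.locus.start} and {b.kind}@{b.locus.start}"
                )

    haplotypes: list[SeqRecord] = []
    realized: list[RealizedEvent] = []
    liftover: dict[tuple[str, int], list[tuple[int, int, int]]] = {}
    for rec in host:
        for h in (0, 1):
            evs = sorted(by_hap.get((rec.id, h), []), key=lambda e: e.span())
            pieces: list[str] = []
            segs: list[tuple[int, int, int]] = []
            cur = 0
            post = 0
            for ev in evs:
                start = ev.locus.start
                if start > cur:
                    pieces.append(rec.sequence[cur:start])
                    segs.append((cur, start, post))
                    post += start - cur
                ins = ""
                distance = 0
                src: Interval | None = ev.payload_source
                if ev.kind == "deletion":
                    cur = ev.locus.end
                elif ev.kind == "distal_junction":
                    distance = ev.payload_len
                    cur = start + distance
                elif ev.kind == "insertion":
                    ins = ev.payload_seq or ""
                    cur = start
                elif ev.kind == "foreign_insertion":
                    assert src is not None
                    payload = refs[src.seq_id].sequence[src.start : src.end]
                    if src.strand == "-":
                        payload = revcomp(payload)
                    mh = ev.microhomology_len
                    dup = rec.sequence[start - mh : start] if mh else ""
                    ins = payload + dup
                    cur = start
                elif ev.kind == "tandem_integration":
                    assert src is not None
                    unit = refs[src.seq_id].sequence[src.start : src.end]
                    ins = unit * ev.copy_count
                    cur = start
                post_start = post
                pieces.append(ins)
                post += len(ins)
                realized.append(
                    RealizedEvent(
                        kind=ev.kind,
                        seq_id=rec.id,
                        hap=h,
                        pre_start=start,
                        post_start=post_start,
                        post_end=post,
                        inserted_seq=ins,
                        payload_source=src,
                        microhomology_len=ev.microhomology_len,
                        distance=distance if ev.kind == "distal_junction" else 0,
                        copy_count=ev.copy_count,
                    )
                )
            if cur < len(rec):
                pieces.append(rec.sequence[cur:])
                segs.append((cur, len(rec), post))
                post += len(rec) - cur
            edited = "".join(pieces)
            expected = len(rec) + sum(
                e.length_change
                if e.kind != "tandem_integration"
                else e.copy_count * len(e.payload_source)  # type: ignore[arg-type]
                for e in evs
            )
            if len(edited) != expected:
                raise AssertionError("edited length does not match algebraic event sum")
            haplotypes.append(SeqRecord(f"{rec.id}|hap{h}", edited, "host"))
            liftover[(rec.id, h)] = segs
    truth = Truth(haplotypes, realized, liftover)
    truth.verify(host)
    return haplotypes, truth


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------


@dataclass
class ReadPair:
    read_id: str
    seq1: str
    seq2: str
    origin_id: str
    frag_start: int
    frag_end: int


def simulate_reads(
    genome: list[SeqRecord],
    read_len: int = 150,
    target_depth: float = 10.0,
    insert_mean: float = 400.0,
    insert_sd: float = 40.0,
    error_rate: float = 0.0,
    seed: int = 1,
) -> list[ReadPair]:
    """Simulate paired-end reads at the requested mean depth.

    Pair count is ceil(target_depth * total_len / (2 * read_len)); fragments
    start uniformly on a length-weighted random sequence; fragment length is
    truncated-normal; mate 2 is the reverse complement of the fragment end.
    Substitution errors are i.i.d. at ``error_rate``; no indel errors.
    """
    if insert_mean < read_len:
        raise ValueError("insert_mean must be >= read_len")
    if not (0 <= error_rate < 1):
        raise ValueError("error_rate must be in [0, 1)")
    min_len = min(len(r) for r in genome)
    if min_len < insert_mean + 4 * insert_sd:
        raise ValueError("genome sequence shorter than insert_mean + 4*insert_sd")
    rng = np.random.default_rng(seed)
    lengths = np.array([len(r) for r in genome], dtype=float)
    total = lengths.sum()
    n_pairs = math.ceil(target_depth * total / (2 * read_len))
    seq_choice = rng.choice(len(genome), size=n_pairs, p=lengths / total)
    frag_lens = np.clip(
        np.rint(rng.normal(insert_mean, insert_sd, size=n_pairs)).astype(int),
        read_len,
        int(insert_mean + 4 * insert_sd),
    )
    starts = np.floor(
        rng.random(n_pairs) * (lengths[seq_choice] - frag_lens + 1)
    ).astype(int)

    pairs: list[ReadPair] = []
    for i in range(n_pairs):
        rec = genome[seq_choice[i]]
        s, fl = int(starts[i]), int(frag_lens[i])
        frag = rec.sequence[s : s + fl]
        r1 = frag[:read_len]
        r2 = revcomp(frag[-read_len:])
        pairs.append(ReadPair(f"sim{i}", r1, r2, rec.id, s, s + fl))
    if error_rate > 0:
        for pair in pairs:
            for attr in ("seq1", "seq2"):
                seq = np.frombuffer(getattr(pair, attr).encode(), dtype=np.uint8).copy()
                hit = rng.random(seq.size) < error_rate
                if hit.any():
                    shift = rng.integers(1, 4, size=int(hit.sum()))
                    idx = {65: 0, 67: 1, 71: 2, 84: 3}
                    cur = np.array([idx[b] for b in seq[hit]])
                    seq[hit] = _BASES[(cur + shift) % 4]
                    setattr(pair, attr, seq.tobytes().decode())
    return pairs


def write_reads(pairs: list[ReadPair], r1_path: str | Path, r2_path: str | Path, qual_char: str = "?") -> None:
    """Write pairs as two FASTQ files with constant Q30 qualities."""
    write_fastq(((p.read_id, p.seq1, qual_char * len(p.seq1)) for p in pairs), r1_path)
    write_fastq(((p.read_id, p.seq2, qual_char * len(p.seq2)) for p in pairs), r2_path)


# ---------------------------------------------------------------------------
# canned scenarios
# ---------------------------------------------------------------------------


@dataclass
class Scenario:
    """A complete synthetic study: references, guides, events, reads, truth."""

    refs: ReferenceSet
    guides: list[tuple[str, str]]
    events: list[EditEvent]
    haplotypes: list[SeqRecord]
    truth: Truth
    annotation: list[Interval]
    pairs: list[ReadPair] = field(default_factory=list)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(self.refs.host, outdir / "host.fa")
        write_fasta(self.refs.by_provenance("plasmid"), outdir / "plasmids.fa")
        write_fasta(self.refs.by_provenance("contaminant"), outdir / "contaminant.fa")
        write_gff(self.annotation, outdir / "annotation.gff3")
        with open(outdir / "guides.tsv", "w") as fh:
            for gid, proto in self.guides:
                fh.write(f"{gid}\t{proto}\n")
        self.truth.to_json(outdir / "truth.json")
        write_reads(self.pairs, outdir / "reads_1.fastq", outdir / "reads_2.fastq")


def _find_guide_site(
    seq: str, near: int, taken: list[tuple[int, int]], genome_cat: str, min_gap: int = 3000
) -> tuple[int, str]:
    """Find a cut position >= near whose protospacer is unique with an NGG PAM.

    Returns (cut_pos, protospacer).  Cut falls between protospacer offsets
    17 and 18 (3 nt from the PAM).
    """
    pos = near
    while pos < len(seq) - 30:
        # PAM 'NGG' occupying [pos+? ...]: protospacer p..p+20, PAM p+20..p+23
        p = pos
        pam = seq[p + 20 : p + 23]
        proto = seq[p : p + 20]
        cut = p + 17
        clear = all(not (a - min_gap < cut < b + min_gap) for a, b in taken)
        if (
            pam[1:] == "GG"
            and "N" not in proto
            and clear
            and genome_cat.count(proto) == 1
            and revcomp(proto) not in genome_cat
        ):
            return cut, proto
        pos += 1
    raise RuntimeError("no suitable guide site found")


def _payload_interval(
    cont: str, cont_id: str, host: str, cut: int, mh: int, payload_len: int, start_hint: int
) -> Interval:
    """Pick a contaminant interval for a foreign insert with exact ``mh``
    terminal microhomology.

    Two bases are constrained so the planted repeat is unambiguous: the
    payload may not end with the base that would extend the direct repeat by
    one, and the contaminant base preceding the payload may not equal the
    host base preceding the cut (which would blur the upstream junction)."""
    forbidden_end = host[cut - mh - 1]
    forbidden_pre = host[cut - 1]
    i = max(start_hint, 1)
    while i < len(cont) - payload_len:
        payload = cont[i : i + payload_len]
        if (
            payload[-1] != forbidden_end
            and cont[i - 1] != forbidden_pre
            and "N" not in payload
        ):
            return Interval(cont_id, i, i + payload_len)
        i += 1
    raise RuntimeError("no payload interval found")


def scenario_multi_edit(
    seed: int = 1,
    host_len: int = 300_000,
    plasmid_len: int = 5_000,
    contaminant_len: int = 20_000,
    shared_homology_len: int = 1_200,
    target_depth: float = 10.0,
    read_len: int = 150,
    insert_mean: float = 400.0,
    insert_sd: float = 40.0,
    error_rate: float = 0.0,
    simulate: bool = True,
) -> Scenario:
    """The canned multi-edit scenario: every event class at one locus each."""
    refs = make_references(1, host_len, 2, plasmid_len, contaminant_len, shared_homology_len, seed)
    chrom = refs["chr1"].sequence
    cont = refs["contaminant"].sequence
    genome_cat = chrom + "#" + cont + "#" + "#".join(
        r.sequence for r in refs.by_provenance("plasmid")
    )
    trap_host = refs.homology_truth[0][0] if refs.homology_truth else None  # type: ignore[attr-defined]
    taken: list[tuple[int, int]] = []
    if trap_host is not None:
        taken.append((trap_host.start - 2000, trap_host.end + 2000))

    def claim(near: int) -> tuple[int, str]:
        cut, proto = _find_guide_site(chrom, near, taken, genome_cat)
        taken.append((cut - 1000, cut + 1000))
        return cut, proto

    cut_bak1, g_bak1 = claim(int(0.10 * host_len))
    cut_bax, g_bax = claim(int(0.20 * host_len))
    cut_glul, g_glul = claim(int(0.30 * host_len))
    cut_dhfr, g_dhfr = claim(int(0.40 * host_len))
    tandem_pos = int(0.60 * host_len)
    bigdel_start = int(0.70 * host_len)
    taken += [(tandem_pos - 1000, tandem_pos + 1000), (bigdel_start - 1000, bigdel_start + 1000)]

    rng = np.random.default_rng(seed + 101)
    one_nt = "ACGT"[int(rng.integers(0, 4))]

    events = [
        # two deletion alleles at the first cut site
        EditEvent("deletion", Interval("chr1", cut_bak1 - 4, cut_bak1 + 4), haplotypes=(0,)),
        EditEvent("deletion", Interval("chr1", cut_bak1 - 5, cut_bak1 + 5), haplotypes=(1,)),
        # 1-nt insertion on both haplotypes
        EditEvent(
            "insertion", Interval("chr1", cut_bax, cut_bax + 1), haplotypes=(0, 1), payload_seq=one_nt
        ),
        # 184-nt contaminant insert with 3-nt junction duplication
        EditEvent(
            "foreign_insertion",
            Interval("chr1", cut_glul, cut_glul + 1),
            haplotypes=(0,),
            payload_source=_payload_interval(cont, "contaminant", chrom, cut_glul, 3, 184, 2_000),
            payload_len=184,
            microhomology_len=3,
        ),
        # junction to host sequence 575 nt downstream on the other haplotype
        EditEvent(
            "distal_junction", Interval("chr1", cut_glul, cut_glul + 575), haplotypes=(1,), payload_len=575
        ),
        # contaminant insert with 4-nt direct repeat at the junction
        EditEvent(
            "foreign_insertion",
            Interval("chr1", cut_dhfr, cut_dhfr + 1),
            haplotypes=(0,),
            payload_source=_payload_interval(cont, "contaminant", chrom, cut_dhfr, 4, 250, 8_000),
            payload_len=250,
            microhomology_len=4,
        ),
        # 5-nt deletion on the other allele of the same gene
        EditEvent("deletion", Interval("chr1", cut_dhfr - 2, cut_dhfr + 3), haplotypes=(1,)),
        # two-copy tandem plasmid integration on one haplotype
        EditEvent(
            "tandem_integration",
            Interval("chr1", tandem_pos, tandem_pos + 1),
            haplotypes=(0,),
            payload_source=Interval("plasmid1", 0, plasmid_len),
            copy_count=2,
        ),
        # homozygous 300-nt deletion: a zero-coverage anomaly
        EditEvent("deletion", Interval("chr1", bigdel_start, bigdel_start + 300), haplotypes=(0, 1)),
    ]
    haplotypes, truth = apply_edits(refs, events)

    annotation = [
        Interval("chr1", cut_bak1 - 200, cut_bak1 + 400, "+", "bak1"),
        Interval("chr1", cut_bax - 200, cut_bax + 400, "+", "bax"),
        Interval("chr1", cut_glul - 200, cut_glul + 400, "+", "glul"),
        Interval("chr1", cut_dhfr - 200, cut_dhfr + 400, "+", "dhfr"),
        # CDS ending 2 nt inside the big deletion: a likely depth artifact
        Interval("chr1", bigdel_start - 500, bigdel_start + 2, "+", "sympk_like"),
        Interval("chr1", int(0.83 * host_len), int(0.83 * host_len) + 900, "+", "bystander"),
    ]
    guides = [("bak1", g_bak1), ("bax", g_bax), ("glul", g_glul), ("dhfr", g_dhfr)]
    pairs: list[ReadPair] = []
    if simulate:
        # reads are drawn from both haplotypes, so the per-sequence depth is
        # half the collapsed (diploid) target depth
        pairs = simulate_reads(
            haplotypes, read_len, target_depth / 2, insert_mean, insert_sd, error_rate, seed + 7
        )
    return Scenario(refs, guides, events, haplotypes, truth, annotation, pairs)
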