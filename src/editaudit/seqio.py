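"""Readers and writers for the standard formats the pipeline touches.

This module is the coordinate-convention firewall: everything inside the
package uses 0-based half-open intervals, and conversion to the 1-based
conventions of SAM/GFF happens here and only here.  The one deliberate
exception is :class:`AlignedRead.pos`, which mirrors the SAM dialect
(1-based leftmost) because alignment records are passed around in that
dialect; use :attr:`AlignedRead.ref_start` for the internal convention.

FASTA goes through Biopython, alignment text through pysam (SAM dialect,
plain text, no BAM), annotation through small dialect-aware converters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Literal

import pysam
from Bio import SeqIO as _BioSeqIO
from Bio.Seq import Seq as _BioSeq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

logger = logging.getLogger(__name__)

DNA_ALPHABET = frozenset("ACGTN")

#: CIGAR operations that consume query sequence
QUERY_OPS = frozenset("MIS=X")
#: CIGAR operations that consume reference
REF_OPS = frozenset("MD=XN")

Provenance = Literal["host", "plasmid", "contaminant"]


class FormatError(ValueError):
    """A file violated its declared format."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class SeqRecord:
    """A named DNA sequence with provenance (host / plasmid / contaminant)."""

    id: str
    sequence: str
    provenance: Provenance = "host"

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise ValueError(f"sequence {self.id!r} is empty")
        bad = set(self.sequence) - DNA_ALPHABET
        if bad:
            raise FormatError(f"sequence {self.id!r} has non-IUPAC characters {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Interval:
    """0-based half-open interval on a named sequence."""

    seq_id: str
    start: int
    end: int
    strand: str = "."
    name: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end}) on {self.seq_id}")
        if self.strand not in "+-.":
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        return (
            self.seq_id == other.seq_id
            and self.start < other.end
            and other.start < self.end
        )


# SAM flag bits
FLAG_PAIRED = 0x1
FLAG_PROPER = 0x2
FLAG_UNMAPPED = 0x4
FLAG_MATE_UNMAPPED = 0x8
FLAG_REVERSE = 0x10
FLAG_MATE_REVERSE = 0x20
FLAG_READ1 = 0x40
FLAG_READ2 = 0x80
FLAG_SECONDARY = 0x100


@dataclass
class AlignedRead:
    """One read alignment in the SAM dialect (pos is 1-based leftmost)."""

    read_id: str
    flag: int
    ref_id: str | None
    pos: int  # 1-based leftmost; 0 for unmapped
    mapq: int
    cigar: list[tuple[str, int]]
    mate_ref_id: str | None = None
    mate_pos: int = 0
    template_len: int = 0
    seq: str = ""
    qual: str = ""

    # -- flag accessors ----------------------------------------------------
    @property
    def is_paired(self) -> bool:
        return bool(self.flag & FLAG_PAIRED)

    @property
    def is_proper(self) -> bool:
        return bool(self.flag & FLAG_PROPER)

    @property
    def is_unmapped(self) -> bool:
        return bool(self.flag & FLAG_UNMAPPED)

    @property
    def mate_unmapped(self) -> bool:
        return bool(self.flag & FLAG_MATE_UNMAPPED)

    @property
    def is_reverse(self) -> bool:
        return bool(self.flag & FLAG_REVERSE)

    @property
    def is_secondary(self) -> bool:
        return bool(self.flag & FLAG_SECONDARY)

    @property
    def is_read1(self) -> bool:
        return bool(self.flag & FLAG_READ1)

    # -- coordinates -------------------------------------------------------
    @property
    def ref_start(self) -> int:
        """0-based leftmost reference coordinate."""
        return self.pos - 1

    @property
    def ref_end(self) -> int:
        """0-based half-open reference end (ref_start + reference span)."""
        return self.ref_start + sum(n for op, n in self.cigar if op in REF_OPS)

    @property
    def query_length(self) -> int:
        return sum(n for op, n in self.cigar if op in QUERY_OPS)

    def validate(self) -> None:
        if self.seq and self.cigar:
            qlen = self.query_length
            if qlen != len(self.seq):
                raise FormatError(
                    f"read {self.read_id!r}: CIGAR consumes {qlen} query bases "
                    f"but sequence has {len(self.seq)}"
                )
        if not self.is_unmapped and self.pos < 1:
            raise FormatError(f"read {self.read_id!r}: mapped but pos={self.pos}")

    def cigar_string(self) -> str:
        return "".join(f"{n}{op}" for op, n in self.cigar) if self.cigar else "*"


@dataclass
class VariantRecord:
    """A small variant (SNP or indel) in the VCF dialect, pos 1-based."""

    seq_id: str
    pos: int
    ref_allele: str
    alt_allele: str
    depth: int
    alt_support: int
    genotype_class: Literal["hom_ref", "het", "hom_alt"]

    def __post_init__(self) -> None:
        if self.alt_support > self.depth:
            raise ValueError("alt_support cannot exceed depth")
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref and alt alleles must differ")


# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path, provenance: Provenance = "host") -> list[SeqRecord]:
    """Read a FASTA file; lowercase is uppercased, non-IUPAC letters rejected."""
    records: list[SeqRecord] = []
    for rec in _BioSeqIO.parse(str(path), "fasta"):
        if not rec.id:
            raise FormatError(f"{path}: record with empty header")
        records.append(SeqRecord(rec.id, str(rec.seq), provenance))
    if not records:
        logger.warning("%s: no FASTA records found", path)
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
    return records


def write_fasta(records: Iterable[SeqRecord], path: str | Path, width: int = 70) -> None:
    bio = [
        _BioSeqRecord(_BioSeq(r.sequence), id=r.id, description="")
        for r in records
    ]
    with open(path, "w") as fh:
        writer = _BioSeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


def write_fastq(reads: Iterable[tuple[str, str, str]], path: str | Path) -> None:
    """Write (id, sequence, quality-string) triples as FASTQ."""
    with open(path, "w") as fh:
        for rid, seq, qual in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


def read_fastq(path: str | Path) -> Iterator[tuple[str, str, str]]:
    for rec in _BioSeqIO.parse(str(path), "fastq"):
        qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
        yield rec.id, str(rec.seq), qual


# ---------------------------------------------------------------------------
# SAM-dialect alignment text
# ---------------------------------------------------------------------------


def _from_segment(seg: pysam.AlignedSegment, header: pysam.AlignmentHeader) -> AlignedRead:
    cigar = []
    if seg.cigartuples:
        ops = "MIDNSHP=X"
        cigar = [(ops[op], n) for op, n in seg.cigartuples]
    read = AlignedRead(
        read_id=seg.query_name or "",
        flag=seg.flag,
        ref_id=seg.reference_name if seg.reference_id >= 0 else None,
        pos=(seg.reference_start + 1) if seg.reference_start is not None and seg.reference_start >= 0 else 0,
        mapq=seg.mapping_quality,
        cigar=cigar,
        mate_ref_id=seg.next_reference_name if seg.next_reference_id >= 0 else None,
        mate_pos=(seg.next_reference_start + 1) if seg.next_reference_start >= 0 else 0,
        template_len=seg.template_length,
        seq=seg.query_sequence or "",
        qual="".join(chr(q + 33) for q in seg.query_qualities) if seg.query_qualities is not None else "",
    )
    read.validate()
    return read


def _to_segment(read: AlignedRead, header: pysam.AlignmentHeader) -> pysam.AlignedSegment:
    read.validate()
    seg = pysam.AlignedSegment(header)
    seg.query_name = read.read_id
    seg.flag = read.flag
    seg.reference_id = header.get_tid(read.ref_id) if read.ref_id else -1
    seg.reference_start = read.pos - 1 if read.pos >= 1 else -1
    seg.mapping_quality = read.mapq
    if read.cigar:
        seg.cigarstring = read.cigar_string()
    seg.next_reference_id = header.get_tid(read.mate_ref_id) if read.mate_ref_id else -1
    seg.next_reference_start = read.mate_pos - 1 if read.mate_pos >= 1 else -1
    seg.template_length = read.template_len
    if read.seq:
        seg.query_sequence = read.seq
        if read.qual:
            seg.query_qualities = pysam.qualitystring_to_array(read.qual)
    return seg


def read_alignments(path: str | Path) -> Iterator[AlignedRead]:
    """Stream AlignedRead records from SAM text; order preserved.

    Records whose CIGAR does not consume the full query, or whose reference
    is not declared in the header, raise :class:`FormatError` naming the read.
    """
    path = str(path)
    header = None
    with open(path) as fh:
        header_lines = []
        for line in fh:
            if line.startswith("@"):
                header_lines.append(line)
            else:
                break
        header = pysam.AlignmentHeader.from_text("".join(header_lines))
    declared = set(header.references)
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("@"):
                continue
            read_id = line.split("\t", 1)[0]
            try:
                seg = pysam.AlignedSegment.fromstring(line, header)
            except Exception as exc:  # htslib parse error
                raise FormatError(f"read {read_id!r}: malformed alignment record ({exc})")
            read = _from_segment(seg, header)
            if read.ref_id is not None and read.ref_id not in declared:
                raise FormatError(f"read {read_id!r}: undeclared reference {read.ref_id!r}")
            yield read


def make_header(ref_names: list[str], ref_lengths: list[int]) -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [{"SN": n, "LN": int(l)} for n, l in zip(ref_names, ref_lengths)],
        }
    )


def write_alignments(
    reads: Iterable[AlignedRead],
    path: str | Path,
    ref_names: list[str],
    ref_lengths: list[int],
) -> None:
    header = make_header(ref_names, ref_lengths)
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for read in reads:
            out.write(_to_segment(read, header))


# ---------------------------------------------------------------------------
# variants (VCF dialect)
# ---------------------------------------------------------------------------

_GT = {"hom_ref": "0/0", "het": "0/1", "hom_alt": "1/1"}


def write_variants(variants: Iterable[VariantRecord], path: str | Path) -> None:
    """Write variants as minimal VCF text (CHROM/POS/REF/ALT, INFO DP & AD)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Total depth">\n')
        fh.write('##INFO=<ID=AD,Number=1,Type=Integer,Description="Alt support">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tsample\n")
        for v in variants:
            fh.write(
                f"{v.seq_id}\t{v.pos}\t.\t{v.ref_allele}\t{v.alt_allele}\t.\tPASS\t"
                f"DP={v.depth};AD={v.alt_support}\tGT\t{_GT[v.genotype_class]}\n"
            )


# ---------------------------------------------------------------------------
# annotation (BED / GFF3)
# ---------------------------------------------------------------------------


def read_annotation(path: str | Path, dialect: Literal["BED", "GFF"]) -> list[Interval]:
    """Read intervals from BED (0-based half-open) or GFF3 (1-based inclusive).

    GFF coordinates are converted to the internal 0-based half-open
    convention at this boundary (start-1, end).
    """
    if dialect not in ("BED", "GFF"):
        raise ValueError(f"unknown annotation dialect {dialect!r}")
    intervals: list[Interval] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#") or (dialect == "BED" and line.startswith(("track", "browser"))):
            continue
        fields = line.split("\t")
        try:
            if dialect == "BED":
                seq_id, start, end = fields[0], int(fields[1]), int(fields[2])
                name = fields[3] if len(fields) > 3 else ""
                strand = fields[5] if len(fields) > 5 else "."
            else:
                if len(fields) < 8:
                    raise FormatError(f"{path}:{lineno}: GFF line with {len(fields)} fields")
                seq_id = fields[0]
                start, end = int(fields[3]) - 1, int(fields[4])
                strand = fields[6] if fields[6] in "+-" else "."
                name = ""
                if len(fields) > 8:
                    attrs = dict(
                        kv.split("=", 1) for kv in fields[8].split(";") if "=" in kv
                    )
                    name = attrs.get("Name", attrs.get("ID", ""))
        except (IndexError, ValueError) as exc:
            if isinstance(exc, FormatError):
                raise
            raise FormatError(f"{path}:{lineno}: malformed {dialect} line ({exc})")
        if end <= start:
            raise FormatError(f"{path}:{lineno}: end <= start after conversion")
        intervals.append(Interval(seq_id, start, end, strand, name))
    return intervals


def write_bed(intervals: Iterable[Interval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.seq_id}\t{iv.start}\t{iv.end}\t{iv.name}\t0\t{iv.strand}\n")


def write_gff(intervals: Iterable[Interval], path: str | Path, feature: str = "CDS") -> None:
    """Write intervals as GFF3 (converting back to 1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for iv in intervals:
            strand = iv.strand if iv.strand in "+-" else "."
            fh.write(
                f"{iv.seq_id}\teditaudit\t{feature}\t{iv.start + 1}\t{iv.end}\t.\t"
                f"{strand}\t.\tID={iv.name};Name={iv.name}\n"
            )


# ---------------------------------------------------------------------------
# small sequence utilities shared across stages
# ---------------------------------------------------------------------------

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]
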