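"""Per-base depth, transgene copy number, and coverage-anomaly scanning.

Depth counts primary mapped alignments only: multi-mapped reads are kept for
rearrangement evidence elsewhere, but double-counting them here would
corrupt the copy-number ratio.  The genome mean is taken over host sequences
only, because transgene dosage is normalized against host coverage.

Copy number per diploid genome is ``diploid_factor * mean_cov / genome_mean``
rounded half-up to one decimal.  Anomalies are maximal runs of exactly-zero
depth (putative deletions) or depth strictly above the high threshold
(putative amplifications) at least ``anomaly_min_len`` nt long; zero runs
that only graze a coding sequence by a couple of bases are flagged as likely
depth artifacts rather than real deletions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable

import numpy as np

from .config import AuditConfig, default_config
from .hybridref import ReferenceSet
from .seqio import AlignedRead, Interval

__all__ = [
    "DepthTrack",
    "CopyNumberEstimate",
    "CoverageAnomaly",
    "depth_track",
    "copy_number",
    "copies_per_diploid",
    "scan_anomalies",
]


@dataclass
class DepthTrack:
    """Per-base depth arrays per reference sequence."""

    depths: dict[str, np.ndarray]
    host_ids: list[str]

    @property
    def genome_mean(self) -> float:
        """Mean depth over host sequences only."""
        total = sum(int(self.depths[h].sum()) for h in self.host_ids)
        length = sum(self.depths[h].size for h in self.host_ids)
        return total / length if length else 0.0

    def mean_over(self, interval: Interval) -> float:
        arr = self.depths[interval.seq_id]
        return float(arr[interval.start : interval.end].mean())


def depth_track(alignments: Iterable[AlignedRead], refs: ReferenceSet) -> DepthTrack:
    """Depth per base: primary mapped reads, M/=/X columns only (not D or S)."""
    deltas = {r.id: np.zeros(len(r) + 1, dtype=np.int32) for r in refs.records}
    for read in alignments:
        if read.is_unmapped or read.is_secondary:
            continue
        arr = deltas[read.ref_id]
        pos = read.ref_start
        for op, n in read.cigar:
            if op in "M=X":
                arr[pos] += 1
                arr[pos + n] -= 1
                pos += n
            elif op in "DN":
                pos += n
        # I/S/H consume no reference
    depths = {rid: np.cumsum(d[:-1]).astype(np.int32) for rid, d in deltas.items()}
    return DepthTrack(depths, [r.id for r in refs.host])


def _round_half_up(value: float, ndigits: int = 1) -> float:
    return float(Decimal(repr(value)).quantize(Decimal(f"1e-{ndigits}"), rounding=ROUND_HALF_UP))


@dataclass
class CopyNumberEstimate:
    name: str
    mean_cov: float
    copies_per_diploid: float


def copies_per_diploid(
    mean_cov: float, genome_mean: float, config: AuditConfig | None = None
) -> float:
    """Copies per diploid genome from an interval's mean coverage."""
    cfg = config or default_config()
    if genome_mean <= 0:
        raise ValueError("genome mean depth is zero; copy number undefined")
    return _round_half_up(cfg.diploid_factor * mean_cov / genome_mean, 1)


def copy_number(
    track: DepthTrack, interval: Interval, config: AuditConfig | None = None
) -> CopyNumberEstimate:
    mean_cov = track.mean_over(interval)
    return CopyNumberEstimate(
        name=interval.name or f"{interval.seq_id}:{interval.start}-{interval.end}",
        mean_cov=mean_cov,
        copies_per_diploid=copies_per_diploid(mean_cov, track.genome_mean, config),
    )


@dataclass
class CoverageAnomaly:
    interval: Interval
    type: str  # "zero" | "high"
    cds_names: list[str] = field(default_factory=list)
    likely_artifact: bool = False

    @property
    def length(self) -> int:
        return len(self.interval)


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal [start, end) runs of True."""
    if not mask.any():
        return []
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return list(zip(edges[0::2], edges[1::2]))


def scan_anomalies(
    track: DepthTrack,
    annotation: list[Interval] | None = None,
    config: AuditConfig | None = None,
    seq_ids: list[str] | None = None,
) -> list[CoverageAnomaly]:
    """Maximal zero/high-depth runs of at least the configured length.

    Each anomaly is annotated with any-overlap CDS names; zero runs whose
    CDS overlap is <= 2 nt are flagged ``likely_artifact`` (coverage gaps
    that barely touch a gene are more plausibly depth fluctuations than real
    deletions).
    """
    cfg = config or default_config()
    annotation = annotation or []
    out: list[CoverageAnomaly] = []
    for seq_id in seq_ids or track.host_ids:
        arr = track.depths[seq_id]
        for kind, mask in (
            ("zero", arr == cfg.anomaly_zero_depth),
            ("high", arr > cfg.anomaly_high_depth),
        ):
            for start, end in _runs(mask):
                if end - start < cfg.anomaly_min_len:
                    continue
                iv = Interval(seq_id, int(start), int(end), ".", kind)
                overlaps = [a for a in annotation if a.overlaps(iv)]
                max_olap = max(
                    (min(a.end, iv.end) - max(a.start, iv.start) for a in overlaps),
                    default=0,
                )
                out.append(
                    CoverageAnomaly(
                        interval=iv,
                        type=kind,
                        cds_names=[a.name for a in overlaps],
                        likely_artifact=kind == "zero" and bool(overlaps) and max_olap <= 2,
                    )
                )
    return out
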