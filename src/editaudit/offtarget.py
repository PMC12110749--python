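"""Off-target candidate enumeration and screening.

Candidate loci are every genomic position, on either strand, whose 20-mer is
within the mismatch budget of the guide protospacer (substitutions only, no
bulges) with an adjacent PAM 3-mer.  Enumeration is a vectorized
positionwise Hamming scan, so it is exhaustive by construction.

Each candidate is then screened against the alignment: its mean depth over
the 23-nt site decides assessability, a minimal pileup caller reports
SNPs/indels within the site +/- 20 nt, and overlapping annotation intervals
(any overlap) name the potentially affected genes.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .config import AuditConfig, default_config
from .coverage import DepthTrack, depth_track
from .hybridref import ReferenceSet
from .ontarget import AlignmentIndex, _IUPAC
from .seqio import AlignedRead, Interval, VariantRecord, revcomp

__all__ = ["GuideHit", "enumerate_sites", "pileup_scan", "audit_offtargets"]

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_ENC = np.full(256, 4, dtype=np.uint8)
for _b, _c in _CODE.items():
    _ENC[ord(_b)] = _c


@dataclass
class GuideHit:
    """A candidate off-target locus for one guide."""

    guide_id: str
    site: Interval  # 23-nt protospacer+PAM span, forward coordinates
    strand: str
    mismatches: int
    pam: str  # 3-mer as read on the protospacer strand
    mean_depth: float = 0.0
    assessable: bool = False
    variants: list[VariantRecord] = field(default_factory=list)
    affected_annotation: list[str] = field(default_factory=list)

    @property
    def protospacer_interval(self) -> Interval:
        if self.strand == "+":
            return Interval(self.site.seq_id, self.site.start, self.site.end - 3, "+")
        return Interval(self.site.seq_id, self.site.start + 3, self.site.end, "-")


def _pam_ok(arr: np.ndarray, patterns: list[str], offset_starts: np.ndarray, rc: bool) -> np.ndarray:
    """Vectorized IUPAC PAM test at each start offset (3-mer)."""
    ok = np.zeros(offset_starts.size, dtype=bool)
    for pat in patterns:
        pat_eff = revcomp(pat) if rc else pat
        this = np.ones(offset_starts.size, dtype=bool)
        for j, p in enumerate(pat_eff):
            allowed = _IUPAC[p]
            col = arr[offset_starts + j]
            m = np.zeros(offset_starts.size, dtype=bool)
            for b in allowed:
                m |= col == _CODE[b]
            this &= m
        ok |= this
    return ok


def enumerate_sites(
    refs: ReferenceSet,
    guide: tuple[str, str],
    config: AuditConfig | None = None,
) -> list[GuideHit]:
    """All host loci within the mismatch budget of the guide, PAM-adjacent.

    Exhaustive positionwise Hamming scan of both strands; each position is
    reported exactly once.  Bulged (indel) matches are out of scope.
    """
    cfg = config or default_config()
    guide_id, proto = guide
    proto = proto.upper()
    if len(proto) != 20:
        raise ValueError("protospacer must be 20 nt")
    g_fwd = np.array([_CODE[b] for b in proto], dtype=np.uint8)
    g_rc = np.array([_CODE[b] for b in revcomp(proto)], dtype=np.uint8)
    hits: list[GuideHit] = []
    for rec in refs.host:
        arr = _ENC[np.frombuffer(rec.sequence.encode(), dtype=np.uint8)]
        L = arr.size
        n = L - 20 + 1
        if n <= 0:
            continue
        # + strand: protospacer at [i, i+20), PAM at [i+20, i+23)
        mm = np.zeros(n, dtype=np.int16)
        for j in range(20):
            mm += arr[j : j + n] != g_fwd[j]
        cand = np.flatnonzero(mm <= cfg.mismatch_budget)
        cand = cand[cand + 23 <= L]
        if cand.size:
            ok = _pam_ok(arr, cfg.pam_patterns, cand + 20, rc=False)
            for i in cand[ok]:
                i = int(i)
                hits.append(
                    GuideHit(
                        guide_id,
                        Interval(rec.id, i, i + 23),
                        "+",
                        int(mm[i]),
                        rec.sequence[i + 20 : i + 23],
                    )
                )
        # - strand: forward 20-mer equals revcomp(protospacer), PAM revcomp
        # immediately 5' of it
        mm = np.zeros(n, dtype=np.int16)
        for j in range(20):
            mm += arr[j : j + n] != g_rc[j]
        cand = np.flatnonzero(mm <= cfg.mismatch_budget)
        cand = cand[cand >= 3]
        if cand.size:
            ok = _pam_ok(arr, cfg.pam_patterns, cand - 3, rc=True)
            for i in cand[ok]:
                i = int(i)
                hits.append(
                    GuideHit(
                        guide_id,
                        Interval(rec.id, i - 3, i + 20),
                        "-",
                        int(mm[i]),
                        revcomp(rec.sequence[i - 3 : i]),
                    )
                )
    hits.sort(key=lambda h: (h.site.seq_id, h.site.start, h.strand))
    return hits


# ---------------------------------------------------------------------------
# minimal pileup caller
# ---------------------------------------------------------------------------


def pileup_scan(
    alignments: Iterable[AlignedRead] | AlignmentIndex,
    site_window: Interval,
    refs: ReferenceSet,
    config: AuditConfig | None = None,
) -> list[VariantRecord]:
    """Minimal pileup over a window: per-column base counts from M/=/X and
    indel events from I/D CIGAR operations (primary alignments only).

    A variant is emitted when alt support and alt fraction clear the
    configured thresholds; genotype is hom_alt at or above the homozygous
    fraction, het otherwise.
    """
    cfg = config or default_config()
    index = alignments if isinstance(alignments, AlignmentIndex) else AlignmentIndex(alignments)
    ref_seq = refs[site_window.seq_id].sequence
    lo, hi = site_window.start, site_window.end
    width = hi - lo
    base_counts = np.zeros((width, 4), dtype=np.int32)
    depth = np.zeros(width, dtype=np.int32)
    indels: Counter = Counter()  # (pos0, ref, alt) -> support
    for read in index.overlapping(site_window.seq_id, lo, hi):
        rpos, qpos = read.ref_start, 0
        for op, n in read.cigar:
            if op in "M=X":
                a = max(rpos, lo)
                b = min(rpos + n, hi)
                if a < b and read.seq:
                    seg = read.seq[qpos + (a - rpos) : qpos + (b - rpos)]
                    codes = _ENC[np.frombuffer(seg.encode(), dtype=np.uint8)]
                    cols = np.arange(a - lo, b - lo)
                    valid = codes < 4
                    base_counts[cols[valid], codes[valid]] += 1
                    depth[a - lo : b - lo] += 1
                rpos += n
                qpos += n
            elif op == "I":
                if lo < rpos <= hi and rpos > 0:
                    anchor = rpos - 1
                    ref_b = ref_seq[anchor]
                    indels[(anchor, ref_b, ref_b + read.seq[qpos : qpos + n])] += 1
                qpos += n
            elif op in "DN":
                if lo <= rpos - 1 < hi and rpos > 0:
                    anchor = rpos - 1
                    ref_b = ref_seq[anchor : rpos + n]
                    indels[(anchor, ref_b, ref_seq[anchor])] += 1
                rpos += n
            elif op == "S":
                qpos += n
    variants: list[VariantRecord] = []
    bases = "ACGT"
    for col in range(width):
        d = int(depth[col])
        if d == 0:
            continue
        ref_b = ref_seq[lo + col]
        ref_code = _CODE.get(ref_b, 4)
        for code in range(4):
            if code == ref_code:
                continue
            support = int(base_counts[col, code])
            if support >= cfg.pileup_min_support and support / d >= cfg.pileup_min_fraction:
                frac = support / d
                variants.append(
                    VariantRecord(
                        site_window.seq_id,
                        lo + col + 1,
                        ref_b,
                        bases[code],
                        d,
                        support,
                        "hom_alt" if frac >= cfg.homalt_fraction else "het",
                    )
                )
    for (anchor, ref_a, alt_a), support in sorted(indels.items()):
        d = int(depth[anchor - lo]) if lo <= anchor < hi else support
        d = max(d, support)
        if support >= cfg.pileup_min_support and support / d >= cfg.pileup_min_fraction:
            frac = support / d
            variants.append(
                VariantRecord(
                    site_window.seq_id,
                    anchor + 1,
                    ref_a,
                    alt_a,
                    d,
                    support,
                    "hom_alt" if frac >= cfg.homalt_fraction else "het",
                )
            )
    variants.sort(key=lambda v: (v.pos, v.alt_allele))
    return variants


# ---------------------------------------------------------------------------
# full off-target audit
# ---------------------------------------------------------------------------


def audit_offtargets(
    refs: ReferenceSet,
    alignments: Sequence[AlignedRead] | AlignmentIndex,
    guides: Sequence[tuple[str, str]],
    annotation: list[Interval] | None = None,
    config: AuditConfig | None = None,
    track: DepthTrack | None = None,
) -> tuple[list[GuideHit], pd.DataFrame]:
    """Enumerate and screen candidate loci for every guide.

    Completes each hit with mean depth over the 23-nt site, the assessable
    flag (depth strictly above the configured minimum), pileup variants
    within site +/- 20 nt, and any-overlap annotation names.  Returns the
    completed hits and a per-guide summary table (guide, sequence, n_sites,
    n_assessable, n_with_changes, affected_genes).
    """
    cfg = config or default_config()
    annotation = annotation or []
    index = alignments if isinstance(alignments, AlignmentIndex) else AlignmentIndex(alignments)
    if track is None:
        track = depth_track(index.all_primary, refs)
    rows = []
    all_hits: list[GuideHit] = []
    for guide_id, proto in guides:
        hits = enumerate_sites(refs, (guide_id, proto), cfg)
        n_assessable = 0
        n_changed = 0
        genes: list[str] = []
        for hit in hits:
            site = hit.site
            hit.mean_depth = track.mean_over(site)
            hit.assessable = hit.mean_depth > cfg.min_locus_depth
            hit.affected_annotation = sorted(
                {a.name for a in annotation if a.overlaps(site) and a.name}
            )
            if hit.assessable:
                n_assessable += 1
                window = Interval(
                    site.seq_id,
                    max(0, site.start - 20),
                    min(len(refs[site.seq_id]), site.end + 20),
                )
                hit.variants = pileup_scan(index, window, refs, cfg)
                if hit.variants:
                    n_changed += 1
                    genes.extend(hit.affected_annotation)
        all_hits.extend(hits)
        rows.append(
            {
                "guide": guide_id,
                "sequence": proto,
                "n_sites": len(hits),
                "n_assessable": n_assessable,
                "n_with_changes": n_changed,
                "affected_genes": ",".join(sorted(set(genes))) or "-",
            }
        )
    return all_hits, pd.DataFrame(rows)
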