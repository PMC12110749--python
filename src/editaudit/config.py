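"""Audit configuration: every numeric threshold the pipeline uses.

All stages read their cutoffs from :class:`AuditConfig`; no stage hard-codes a
threshold.  Defaults reflect the audit conditions of a ~10x paired-end 150+150
whole-genome run of a multiplex-edited CHO-like cell line:

* off-target candidates are genomic 20-mers within 4 mismatches of the guide
  with an adjacent SpCas9 PAM (NGG/NAG),
* a candidate locus is assessable when its mean depth exceeds 5x,
* coverage anomalies are runs of 0x (putative deletion) or >50x (putative
  amplification) depth at least 20 nt long,
* circular plasmids are linearized with 75-nt wrap-around overhangs,
* transgene dosage is reported per diploid genome (factor 2).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["AuditConfig", "default_config", "load_config", "save_config"]


@dataclass
class AuditConfig:
    """Numeric thresholds and conventions shared by all pipeline stages."""

    #: mismatches allowed between the 20-nt guide and a genomic protospacer
    mismatch_budget: int = 4
    #: IUPAC 3-mers accepted as PAM, on the PAM-proximal (3') side
    pam_patterns: list[str] = field(default_factory=lambda: ["NGG", "NAG"])
    #: mean depth (x) at or below which an off-target locus is "not assessable"
    min_locus_depth: float = 5.0
    #: minimum length (nt) of a reportable coverage anomaly
    anomaly_min_len: int = 20
    #: depth defining a "zero coverage" run (exact equality)
    anomaly_zero_depth: int = 0
    #: depth above which (strictly) a run counts as amplified
    anomaly_high_depth: int = 50
    #: nt of wrap-around sequence appended to each end of a linearized plasmid
    plasmid_overhang: int = 75
    #: copies are reported per diploid genome: 2 x (interval depth / genome depth)
    diploid_factor: float = 2.0
    #: reads required before an insertion junction is reported as solid
    min_junction_support: int = 2
    #: read length (nt) of the paired-end run
    read_len: int = 150
    #: target mean sequencing depth (x)
    target_depth: float = 10.0
    #: master seed for every stochastic stage
    rng_seed: int = 1
    #: simulated / expected library fragment length (mean, sd), nt
    insert_mean: float = 400.0
    insert_sd: float = 40.0
    #: half-width (nt) of the informative window around a cut site
    cut_flank: int = 10
    #: clip-resolved junctions nearer than this are treated as plain deletions
    min_distal_distance: int = 100
    #: maximum distance (nt) for a host-host junction to count as "distal"
    max_distal_distance: int = 5000
    #: soft clips shorter than this are ignored by junction detection
    min_clip_len: int = 20
    #: longest direct repeat searched at an insertion junction
    max_microhomology: int = 10
    #: clips within this many nt are merged into one breakpoint
    breakpoint_merge_dist: int = 10
    #: host bases a clip must retain across a junction for split resolution
    min_split_anchor: int = 10
    #: pileup caller: min alt reads and min alt fraction to emit a variant
    pileup_min_support: int = 2
    pileup_min_fraction: float = 0.2
    #: alt fraction at or above which a variant is called homozygous
    homalt_fraction: float = 0.8
    #: minimum exact plasmid/host match length for the homology mask
    mask_min_match: int = 100

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.mismatch_budget < 0:
            raise ValueError("mismatch_budget must be >= 0")
        if self.anomaly_min_len < 1:
            raise ValueError("anomaly_min_len must be >= 1")
        if self.anomaly_high_depth <= self.anomaly_zero_depth:
            raise ValueError("anomaly_high_depth must exceed anomaly_zero_depth")
        if self.plasmid_overhang < 0:
            raise ValueError("plasmid_overhang must be >= 0")
        for name in ("min_locus_depth", "anomaly_zero_depth", "target_depth"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for pam in self.pam_patterns:
            if len(pam) != 3:
                raise ValueError(f"PAM pattern {pam!r} is not a 3-mer")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def default_config() -> AuditConfig:
    """Return the default audit configuration (documented on the class)."""
    return AuditConfig()


def load_config(path: str | Path) -> AuditConfig:
    """Load a config from YAML; unknown keys are rejected."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = {f.name for f in dataclasses.fields(AuditConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return AuditConfig(**raw)


def save_config(config: AuditConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))
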