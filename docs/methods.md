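# Methods

## The audit model

A multiplex-edited clonal cell line is sequenced once with paired-end
150+150 reads at ~10× mean depth.  All inference is read-level and
reference-based against a *hybrid reference*: the host chromosomes plus
every plasmid used for editing/selection plus a potential contaminant
genome (the plasmid cloning strain), appended as extra sequences.  Four
read classes carry the audit signal:

1. reads spanning a cut site with I/D CIGAR operations (small indels),
2. soft-clipped reads whose clipped tail belongs to another sequence
   (insertion/rearrangement junctions),
3. read pairs whose mates map to different reference sequences
   (corroborating insertions), and
4. per-base depth (dosage and deletions/amplifications).

The package treats all thresholds as configuration (`AuditConfig`); stage
code contains no numeric literals for decisions.

## Key parameters (defaults)

| parameter | default | meaning |
|---|---|---|
| `mismatch_budget` | 4 | max protospacer mismatches for an off-target candidate |
| `pam_patterns` | NGG, NAG | accepted SpCas9 PAMs, 3′ of the protospacer |
| `min_locus_depth` | 5× | below/at this mean depth a locus is "not assessable" |
| `anomaly_zero_depth` / `anomaly_high_depth` | 0× / 50× | depth predicates (zero is exact, high is strict `>`) |
| `anomaly_min_len` | 20 nt | minimum reportable anomaly run |
| `plasmid_overhang` | 75 nt | wrap-around linearization overhang per plasmid end |
| `diploid_factor` | 2 | copy number is reported per diploid genome |
| `min_junction_support` | 2 reads | below this a call/allele is suppressed (logged) or flagged weak; set to 1 to accept single-read junctions |
| `read_len` / `target_depth` | 150 / 10× | sequencing-run geometry |
| `insert_mean` / `insert_sd` | 400 / 40 nt | library fragment length model |
| `cut_flank` | 10 nt | informative window half-width around a cut |
| `min_clip_len` | 20 nt | shortest clip used as junction evidence |
| `min_distal_distance` / `max_distal_distance` | 100 / 5000 nt | host-host junction classified as deletion vs "distal junction" |
| `max_microhomology` | 10 nt | longest direct repeat searched at a junction |
| `mask_min_match` | 100 nt | minimum exact plasmid-host match entering the homology mask |

## Conventions and numerical choices

**Coordinates.** Everything internal is 0-based half-open; conversion to
1-based SAM/GFF happens only in `seqio`.  `AlignedRead.pos` keeps the SAM
convention (1-based) because those records travel in the SAM dialect.

**Cut position.** Blunt cut between protospacer positions 17 and 18 (3 bp
from the PAM), mirrored on the minus strand — the standard SpCas9 geometry.

**Aligner.** A seed-and-extend aligner (21-mer sorted-array index, seeds
every 25 nt, diagonal voting) with a local affine-gap extension
(match +1, mismatch −4, gap open −6, gap extend −0.5) over a ±60-nt
window.  Unaligned read ends become soft clips at zero cost, so junction
reads clip rather than stretch across foreign sequence, while indels up to
the band stay gapped.  The extension penalty is deliberately mild so that
insertions up to ~50 nt are still preferred over clipping.  Equal-best
placements are emitted as secondary alignments and retained downstream;
ties break on (reference order, position).  mapq is a three-level 0/30/60
heuristic (tie / within 20 points / unique) and nothing downstream
thresholds on finer values.  Externally produced SAM text is accepted as a
drop-in replacement provided it populates: soft clips, mate reference/
position, the paired/reverse/secondary/unmapped flags, and sequence for
clipped records.

**Junction normalization.** A junction is observed from either side — a
host-anchored read clipping into the insert, or an insert-anchored read
clipping its host tail — and both are mapped onto (host sequence,
breakpoint, upstream/downstream).  Two corrections make breakpoints exact:
a chance match between the insert's first bases and the host just past the
junction drags the upstream clip boundary into the insert, and is walked
back by comparing source and host bases; a junction *duplication* (direct
repeat) is absorbed into the host alignment of downstream-anchored reads,
so the downstream boundary sits exactly `mh` nt upstream of the true
breakpoint.  Microhomology is therefore measured as
`right_boundary − left_boundary` when both sides are seen, which recovers
planted repeats exactly; with one side only, the observed insert end is
compared with the host flank directly.

**Insert representation in the simulator.** A foreign insertion with
microhomology `m` is realized as `host[:cut] + payload + host[cut−m:cut] +
host[cut:]` — the payload followed by a duplicated copy of the `m`
upstream host bases, so the direct repeat flanks the insert and the total
length change is `payload_len + m`.

**Short and novel inserts.** Inserts that fit in the alignment band appear
as I operations, not clips; large insertion operations are converted into
synthetic right-side clips so clustering sees one evidence stream.  A clip
that matches nothing is split at the point where host sequence resumes
(requiring a ≥10-nt host anchor), recovering the exact inserted length for
untemplated insertions and the exact source interval for short templated
ones.

**Signature clustering.** On-target allele signatures cluster by exact
identity, then compatible junction signatures are merged: breakpoint
shifts up to 10 nt for clip-resolved events, and for insertions the
invariant `offset + length` (a chance junction base trades one unit of
offset for one of length).  CIGAR-exact deletions never merge across
lengths — two deletion alleles of 8 and 10 nt stay distinct.

**Depth and copy number.** Depth counts primary mapped alignments only
(M/=/X columns; deletions and clips do not cover).  Multi-mapped reads are
kept for junction evidence but excluded from depth, because double-counting
would corrupt the dosage ratio.  The genome mean is host-only.  Copy number
is `diploid_factor × mean/genome_mean` rounded *half-up* to one decimal
(`decimal.Decimal`, not banker's rounding).  Note that when a vector
carries host sequence, reads from that region map preferentially to the
host copy, so whole-plasmid intervals underestimate dosage — dosage should
be read over vector-unique regions (ORFs), which is how the copy-number
recovery is tested.

**Anomaly scan.** Maximal runs with `depth == 0` or `depth > 50`, length
≥ 20 nt, annotated with any-overlap CDS names; zero runs overlapping a CDS
by ≤ 2 nt are flagged "likely depth artifact" rather than a real deletion.

**Pileup caller.** Deliberately minimal: per-column base counts from M/=/X
and indel events keyed by anchor base; a variant needs ≥ 2 alt reads and
alt fraction ≥ 0.2; genotype is hom_alt at fraction ≥ 0.8, het otherwise.
It is a screening device for "possible off-target changes", not a general
variant caller.

## The synthetic-data generator

`fixtures` emulates the study conditions: a uniform-random diploid host
(two explicit haplotype sequences per chromosome), plasmids carrying one
exact copy of a shared 1.2-kb host segment (the homology trap), a random
contaminant genome, paired-end 150+150 reads at 10× collapsed diploid
depth (5× per haplotype), truncated-normal fragment lengths (400 ± 40 nt),
substitution-only errors (default 0), constant Q30 qualities.  The canned
`multi_edit` scenario plants per-haplotype deletions of 8 and 10 nt, a 1-nt
insertion on both haplotypes, a 184-nt contaminant insert with a 3-nt
junction duplication, a 575-nt distal junction on the sister allele, a
250-nt insert with a 4-nt direct repeat, a two-copy tandem plasmid
integration, and a 300-nt homozygous deletion; `truth.json` records every
realized coordinate and a pre→post lift-over map.

What it does **not** emulate: repetitive/low-complexity genome content, GC
and PCR-duplicate bias, indel sequencing errors, quality-score variation,
chimeric library artifacts.  Passing tests therefore demonstrate that the
*logic* of the audit is correct under clean, fully-known conditions; on
real data the same stages face multi-mapping and noise that the
configuration (support thresholds, mapq levels, mask) is designed to
absorb but that these tests do not measure.

## Problem sizes

The test suite runs the scenario at 60-kb host scale for module tests and
300 kb for the end-to-end recovery suite; copy-number recovery uses 30-kb
hosts with 3-kb plasmids at 1/2/4/8 tandem copies (seeds 1–3); off-target
enumeration is checked against a pure-Python positionwise oracle on 50-kb
genomes with planted 0–4-mismatch decoys (seeds 1–5); indel recovery plants
ladders of 1–50-nt deletions and insertions (seeds 1–5).  These sizes keep
the full suite under a minute while every code path is the one a full-size
genome would use.

## Known limitations

- No bulge-tolerant (indel) off-target matching and no cleavage-activity
  scores; the enumeration is substitution-Hamming only, by design.
- Insert *internal* structure is not assembled; calls report breakpoints
  and source intervals only, so a rearranged or chimeric insert appears as
  its junction fragments.
- Junction end-coordinates are ambiguous up to chance base matches between
  source and host (bounded by `max_microhomology`); recovered source
  intervals can overshoot by a few bases.
- The aligner is not a BWA replacement: no split/supplementary records, no
  base-quality awareness, three-level mapq only.
- Copy-number estimation assumes uniform coverage; no GC correction or
  segmentation-based CNV calling.
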