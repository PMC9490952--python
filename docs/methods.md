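# Methods

## Scope and model

The package infers piRNA clusters from gonadal small-RNA sequencing of a fish
population segregating a supernumerary (B) chromosome, locates B-resident loci
by comparative read depth, characterizes the transposable-element (TE)
divergence landscape of the two genome states, and quantifies gene dosage and
expression from qPCR Cq tables.  The organism model is a contig-level Illumina
assembly: the B chromosome is built largely from duplicated A-complement
sequence and cannot be assembled separately, so B residency is inferred from
carrier/non-carrier coverage ratios rather than from assembly.

## Small-RNA preprocessing

Reads are length-filtered to 24–35 nt, the mature piRNA range; miRNAs
(21–22 nt) fall below the window and drop out before cluster calling.  Reads
are collapsed to unique sequence tags carrying per-library counts.  U is
normalized to T on input and reads containing N are discarded so tag identity
is unambiguous.  Base-call quality is ignored throughout; adapter removal is
assumed done upstream, with an optional exact 3′-adapter match for raw input.

## Tag placement and multi-mapper weighting

Tags are placed by exact substring search over both strands using a seed
k-mer index (k = 12, reduced for toy genomes); with `max_mismatch=1` a
two-seed pigeonhole lookup adds the one-mismatch stratum, and only the best
stratum (fewest mismatches) is reported.  A tag with `n` placements
contributes `total_count / n` weight to each, so summed weight per tag equals
its read count exactly.  Tags with more than 100 placements (configurable) are
dropped as hyper-repetitive.  Alignments from an external aligner can be
imported from SAM/BAM under the same contract, with `n` taken as the number of
records per query name.  Coordinates are 0-based half-open internally and
1-based inclusive in all human-facing tables.

## Cluster calling

Candidate loci are maximal runs of placements on a contig whose consecutive
start positions are at most `max_gap = 500` bp apart, subject to at least
`min_tags = 10` distinct tags and `min_weight = 20` summed weight.  Candidates
are accepted iff all three criteria hold (equality passes, since the
thresholds are minima):

* span ≥ 1000 bp;
* weighted fraction of member reads whose 5′ base is T or whose 10th base is
  A ≥ 0.75 (primary piRNAs carry 5′U; ping-pong secondaries carry 10A);
* weighted fraction with length in [24, 35] nt ≥ 0.75.

Directionality is `mono:+`/`mono:-` when the weighted main-strand fraction is
≥ 0.75, else `bi`; bidirectional clusters are reported as single intervals.  A
cluster is "expressed" in a library when its weighted mass there reaches
`min_expr = 5`.  Overlapping accepted clusters from parameter re-runs can be
union-merged, taking per-library weights as the member maximum (the runs
re-count the same reads).

**Known limitation.**  The scanner is deliberately simple: it exposes the
published acceptance criteria behind explicit, logged parameters instead of a
density/p-value model.  Its weakness is boundary inflation under uniform
background: once background placements are spaced more densely than
`max_gap`, runs bridge across true cluster boundaries, and although
background-only candidates are reliably rejected by the 1U/10A filter
(random sequence yields ≈ 0.44, far below 0.75), a cluster candidate extended
by background keeps its signature and is accepted with an inflated span.
Recovery benchmarks therefore run with background-free libraries; with
background present the caller still finds every planted cluster but its
reported spans grow toward run boundaries.  A density-aware scanner would be
the natural extension.

## B-chromosome localization

Per-contig depth is `depth[i] = number of reads covering position i`.  The
B+/B− ratio is normalized by library-wide total mapped bases,

    ratio = (mean_B+ / total_bases_B+) / (mean_B− / total_bases_B−),

and a contig is flagged B-resident when ratio > 2 (strict).  The ratio is a
qualitative indicator, not a copy-number estimate.

Normalizing by total mapped bases makes the rule robust to unequal sequencing
depth but couples every contig's ratio to the B content of the library: if
B-resident contigs make up a fraction f of B+ mapped bases beyond the
A complement, all ratios shrink by (1 − f)-ish.  With realistic assemblies the
B-blocks are a small minority of contigs and the skew is negligible; the
calibration study here uses 1 multiplier-3 contig among 20 × 20 kb (skew
0.91), where unit-copy contigs sit at 0.91 and multiplier-3 contigs at 2.73.
In a deliberately B-heavy layout (2 of 10 contigs at multiplier 3) unit
contigs fall to ≈ 0.71 and B contigs to ≈ 2.14 — still on the correct side of
the strict > 2 rule, but close to it; users flagging heavily duplicated
genomes should prefer a robust (e.g. median-depth) normalization.

B-specific SNPs are sites where both pileups reach `min_depth = 5`, the B+
alternate-allele frequency is ≥ 0.2 and the B− alternate frequency is ≤ 0.02;
sites polymorphic in both samples are population SNPs and are excluded.  The
frequency thresholds are pragmatic defaults (the original procedure was
manual inspection) and are exposed as flags.

## Kimura divergence and landscapes

For an aligned copy/consensus pair, gap columns are stripped pairwise, CpG
positions of the consensus may optionally be masked (exclusion only — no
reweighting), and transitions/transversions are counted over positions where
both bases are ACGT, giving p and q as exact counted proportions.  The
two-parameter distance is

    K = −½ ln((1 − 2p − q) · √(1 − 2q)),

valid for 1−2p−q > 0 and 1−2q > 0; beyond that domain the estimator raises a
saturation error rather than extrapolating.  Landscapes bin each copy's
aligned bp at `floor(100·K)` (1% bins, clamped at 50%), so binned mass equals
summed copy length exactly.  Landscapes can alternatively be built directly
from the divergence column of a RepeatMasker `.out` file, trusted as-is.
B−/B+ comparison normalizes each landscape to its total bp and flags bins
where B+ exceeds 1.5× the B− mass with at least 50 bp of raw B+ mass (a
small-noise floor chosen once; both knobs configurable).

## Colocalization

A contig is classed miRNA-only / piRNA-only / both; "both" contigs are
superposed when any miRNA–cluster pair overlaps by ≥ 1 bp, strand-agnostic
(annotated miRNAs occur in either orientation inside clusters).  BED input is
0-based half-open, GFF3 1-based inclusive; conversion happens in the readers.
The packaged fixture table stores printed 1-based intervals for 16 contigs
carrying both annotation types (13 superposed); one row's transcription
strand is missing in the source and is stored empty.

## qPCR quantification

Replicate Cq values are averaged arithmetically before ΔCq = Cq_target −
Cq_reference.  Relative quantity is E^−(ΔCq_sample − ΔCq_calibrator) with
amplification efficiency E = 2 by default (exposed as a parameter).  Gene-dose
ratios use the non-carrier group's mean ΔCq as calibrator, so carrier samples
with one extra copy against a single-copy reference center at GDR = 2 and the
calibrator group has geometric mean exactly 1.

Group effects are tested with a two-sided permutation test on the difference
of group means: p = (1 + #{permuted |Δ| ≥ observed}) / (1 + n_perm), seeded
and vectorized; an exhaustive mode enumerates all assignments for small
cohorts.  This replaces a parametric gamma GLM by design — it preserves the
significance decision without distributional assumptions, at the cost of not
estimating covariate effects jointly.

## Synthetic-data generator

The generator emulates the study design: four gonadal small-RNA libraries
(FB−, FB+, MB−, MB+), a piRNA length profile peaking at 28–29 nt (support
26–31), 5′U probability 0.9 and 10A probability 0.5, mono- and bidirectional
planted clusters (main-strand fraction 0.95 for mono), B-exclusive clusters
on contigs with copy multiplier ≥ 2, miRNA loci emitting 21–22 nt reads,
B−/B+ WGS with per-contig expected depth `mean_depth × multiplier` for B+,
and B-specific SNPs whose alternate allele rides on (m−1)/m of B+ reads for
multiplier m (all B-resident copies descend from one founder).  Base biases
are realized by start-position choice (rejection sampling), never by editing
bases, so every simulated read is an exact genomic substring and maps back at
zero mismatches; the realized 5′U fraction is therefore slightly above the
nominal probability (forced fraction plus background base composition).
TE copies are mutated from consensus with exactly `round(rate × length)`
transitions/transversions and no back-mutation, so realized (p, q) are exact.
SNP sites are kept ≥ 300 bp apart so no short read spans two sites.
Sequencing error defaults to 0 (configurable) to isolate method behavior from
error-model choices; genomes are ACGT-only; each operation takes an explicit
seed and identical calls are byte-identical.

What the generator does **not** emulate — quality-score structure, adapter
contamination, PCR duplicates, indels, paired ends, genuine degraded-RNA
background with its own base biases, and repeat-induced multi-mapping between
near-identical contigs.  Passing recovery tests therefore demonstrates the
correctness of the inference chain under its stated model, not robustness to
real library artifacts.

Library depth is 2×10⁵ reads per library by default (the real per-library
depths are not constrained by the design; this value keeps tag diversity high
at desk scale) and WGS depth 20×.  The standard benchmark study uses 10
contigs × 50 kb with 5 planted clusters (3 mono, 2 bi; the 2 bi ones
B-exclusive on multiplier-3 contigs), the coverage-ratio calibration 20
contigs × 20 kb with one multiplier-3 contig, and the qPCR cohort 8 samples
per B group (four of each sex), matching the study's qPCR design.

## Numerical and design choices

* Thresholds are minima: equality at 0.75 (fractions) or 1000 bp (size)
  accepts; the coverage-ratio rule is strict (> 2).
* TE-class assignment tie-break: largest overlap, then leftmost annotation —
  deterministic output.
* Multi-placement WGS reads take the first placement in sorted
  (contig, position, strand) order — deterministic, and irrelevant for the
  distinct-contig genomes simulated here.
* Mean depth over the whole contig (not the cluster interval) decides the
  B flag, matching the contig-level procedure; per-interval tracks are
  exportable as BedGraph for inspection.
* `coverage_ratio` reports +∞ with a distinct marker when the B− mean is
  zero; pileup sites with non-ACGT reference are skipped.
* The pipeline logs every parameter value and the SHA-256 of every output,
  and derives all stage seeds from the single run seed.
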