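# Methods

This note documents the models, conventions and numerical choices behind
`mavecall`, and what the synthetic-data generator does and does not
emulate.

## Coordinates and reference model

All internal coordinates are 0-based half-open. VCF input/output is
1-based; BED and bedgraph stay 0-based half-open. The reference is a
single transcript (`TranscriptReference`) with explicit CDS bounds; the
CDS length must be a positive multiple of 3 and the sequence must be
unambiguous A/C/G/T (ambiguity codes in *reads* are tolerated but an
N can never support a call). Codon translation uses the standard genetic
code. The NNK mutagenesis signature is evaluated on the **alternate**
codon only: NNK library construction replaces the whole codon, so the
reference third base is irrelevant; a variant matches when it alters
exactly one codon and that codon's third base is G or T. Multi-codon
variants never match and never raise.

## Spike-in simulation (`sim`)

Planning is per *fragment* (read pair), not per pileup read: truth
counts are fragment counts, and one edit consumes one fragment. For each
requested variant the number of fragments to edit is

    round_half_away_from_zero(target_frequency × fragment coverage at POS),

floored at 1 when coverage is non-zero; an explicit `target_count`
overrides this when an exact design (e.g. 10 pairs per variant) is
wanted. Eligible fragments must (a) cover every edited position in at
least one mate — a mate partially covering an MNP is edited on the
covered subset, so mates never disagree with the planned allele; (b)
carry no pre-existing mismatch within `conversion_buffer` nt of any
edited position, in either mate (default 3 nt, matching the caller's MNP
merge window; 0 disables the prohibition); and (c) not already be
claimed by another variant, which also gives variants at the same
coordinate disjoint fragment sets. Sampling among eligible fragments is
uniform without replacement from a seeded generator over a canonically
sorted fragment list, so the same (variants, alignments, seed) triple is
byte-reproducible. Variants that cannot reach their count are reported
*unplaceable* with the achieved count — never silently truncated.

Edited reads preserve base qualities and are emitted in sequencer
orientation; untouched reads pass through verbatim. Re-alignment of the
edited FASTQ uses the same external aligner as the calling pipeline.

## External tools

Adapter/quality trimming and alignment are delegated, as is standard for
this kind of pipeline. The default aligner is `bwa mem` behind a single
command-template configuration (`AlignerConfig`); any aligner emitting
SAM on stdout can be substituted. `bwa mem` is a local aligner, so
terminal mismatch clusters can in principle be soft-clipped; the
validation dataset therefore places variants ≥ 10 nt from fragment ends,
where a tri-nt mismatch cluster still scores better aligned than
clipped under the default penalties. Trimming is an optional hook
(`trim_cmd`), disabled by default because the synthetic libraries carry
no adapters.

## Preprocessing

**UMI extraction** moves a fixed-length R1 5′ UMI (given as a length or
an anchored pattern such as `(?P<umi_1>[ATCGN]{16})`) into both read
names with an underscore delimiter, before trimming and alignment.
Pairs shorter than the UMI are dropped and counted.

**Primer base-quality masking** assigns each mate its *originating*
primers: (1) same strand — the read 5′ end lies within the primer's
aligned coordinates or within a buffer upstream of the primer 5′ end
(relative to strand); (2) opposite strand — the read 3′ end stops within
the primer, or within the same buffer upstream of that primer's 5′ end.
The buffer is 15 nt for amplicon designs and 3 nt for RACE-like designs.
Read segments overlapping originating primers get BQ set to exactly 0;
base calls are never changed and the original qualities are retained in
the mask report, so masking is lossless. Masked bases are excluded from
both variant calling and fragment-coverage enumeration. Reads whose 5′
end lies beyond the buffer (readthrough coverage from an adjacent tile)
are deliberately not masked — that coverage is what makes variants under
primers callable. Each mate is masked independently by its own
originating primers.

**Consensus deduplication** groups pairs by (UMI, R1 leftmost aligned
position) with the directional-adjacency rule: within a stratum, UMIs at
Hamming distance 1 link A→B when count(A) ≥ 2·count(B) − 1, and
connected components are seeded from the highest-count UMIs. Grouping is
order-invariant (canonical sort first). Consensus is a per-reference-
position majority vote among the duplicates covering that position
(positions absent from a duplicate's alignment abstain); two-way ties
resolve by reference match, then higher base quality, then seeded random
choice. The consensus base quality is the **maximum** quality among
duplicates supporting the chosen base — the most defensible single-read
proxy given that duplicate qualities are not independent; this choice is
not dictated by the method's definition and is documented here for that
reason. Singleton groups pass through unchanged. Pipeline order is
alignment → deduplication (if requested) → masking → calling.

## Calling

A pair is discarded whole when either mate's edit distance (NM as
aligned, including InDel lengths; recomputed from the reference when the
tag is absent) exceeds `max_nm` — the filter is deliberately applied to
raw NM, not NM minus the candidate variant, keeping the feature
identical to what the error model sees. Mismatches require strict mate
concordance: both mates aligned across the position, identical
non-reference call, both BQs ≥ `min_bq`, neither masked. Positions
covered by one mate only are uncallable by construction; on fully
overlapping designs this costs nothing, and on partial-overlap designs
the uncallable fraction is visible in the coverage track. InDels are
never called; reads containing them are retained (subject to the NM
filter).

Merging is greedy left-to-right with a hard 3-nt reference-span cap:
mismatches at positions *i*, *j* merge iff *j − i ≤ 2*, so reported
alleles are exactly SNPs, di-nt and tri-nt MNPs. Gap positions inside a
merged allele take the reference base (equal to the read base, since no
mismatch was observed there). When four or more mismatches cluster, the
greedy scan takes maximal leftmost components; an optimal partition is
not attempted — the choice only matters for pathological clusters and
determinism is worth more than an arbitrary optimality criterion.

Aggregation counts identical (POS, REF, ALT) components once per
fragment, drops calls below `min_count`, and computes frequency against
fragment coverage at the variant's leftmost position. Per-call feature
summaries are per-mate medians of supporting base quality, read
position and edit distance; even-count medians resolve to the lower
middle value (determinism over convention). RACE-like runs additionally
track sample-strand (R1 orientation) counts. Outputs: VCF v4 with the
annotations in INFO; a per-mismatch summary table with one row per
mismatch participating in a primary variant call (a tri-nt MNP
supported by 10 fragments contributes 30 rows); and a bedgraph of
fragment coverage.

## Error model

The negative-control library estimates the background error process.
The balanced truth set samples variant specs — SNP fraction 0.25 by
default, di/tri splitting the remainder evenly, frequencies resampled
from a mutagenized library's empirical distribution (calls < 0.3) —
until cumulative component mismatches (SNP = 1, di = 2, tri = 3) exactly
equal the NC's false-positive mismatch count at `min_count` 1. The truth
set is spiked into the NC alignments, the caller re-run, and each call
labeled by truth-VCF membership; calls outside the target region or with
frequency ≥ 0.3 are excluded.

Features (amplicon): log₁₀ frequency; variant type (3 levels); NNK
signature; substitution class (6 strand-collapsed levels, an MNP classed
by its first mismatched base); upstream and downstream reference nt; R1
and R2 median supporting BQ; R2 median read position and edit distance
(R1 read position/NM are omitted for collinearity with R2). RACE-like
adds the per-sample-strand BQ/read-position/NM variants plus the strand
count difference; strata with no observations yield NaN, imputed by
per-feature median rough-fix. Categoricals are one-hot encoded against a
fixed schema stored in the model bundle; scoring refuses on schema
mismatch, naming the missing/extra columns.

Training is nested stratified 10-fold CV: within each fold, 20% of the
training split selects hyperparameters from a small grid (kept small
deliberately — random-forest `max_features`, GBM learning rate, GLM C,
kNN k, SVC C — enough to exercise the protocol without dominating run
time), accuracy is measured on the held-out fold, and the final model is
refit on all examples with the same tuning protocol. kNN additionally
selects 3–10 design columns by greedy forward selection under 5-fold CV
(a practical stand-in for exhaustive best-subset search, which is
combinatorial on a one-hot design). Random forests report permutation
importances under accuracy scoring — the mean-decrease-in-accuracy
definition. The default probability cutoff is 0.5 for scoring
(`score_and_filter`), and the replicate-aware mode removes a variant
only when predicted an error in *all* replicates.

## Post-filtering

Background subtraction records `log10(f_mut) − log10(f_nc)` for variants
with an identical-allele NC call (flagged `nc_dominated` when the NC
frequency is at least the call frequency — fully explained by background
when equal) and flags variants absent from the NC `nc_absent` with
adjustment 0. The filter chain applies the seven criteria in their
stated order — target region; NNK signature; single-codon; SNP count
≥ 2 / MNP count ≥ 1; strand count difference ≤ 64 (RACE-like only);
classifier false-positive verdict in all replicates at cutoff 0.49;
presence in all replicates — logging per-criterion attrition that sums
exactly to input minus output. The order is part of the method; it is
asserted, not assumed. Downstream differential-abundance statistics are
out of scope: the chain ends at clean per-replicate tables plus a
generic count-matrix exporter.

## Synthetic data

The generator emulates: amplicon-tiled fragments (fragment = tile,
primers at both ends) and RACE-like fragments (one gene-specific primer
anchoring the 5′ end, truncated-normal fragment lengths 150–250 nt);
2×150 reads; UMIs; PCR duplication (1 + Poisson copies); and three error
channels. *Fragment*-level substitutions (the RT/PCR analogue) are
shared by both mates and therefore survive mate concordance — without
this channel a concordance-based caller would see no false positives at
all; *read*-level substitutions model sequencer miscalls and are removed
by concordance; *primer*-channel substitutions fall only on synthetic
primer-derived segments, the artifact class masking suppresses. Default
fragment rates follow the empirically observed bias of Illumina
negative-control libraries — (C>A, G>T) and (C>T, G>A) elevated roughly
an order of magnitude over the other four classes, at a total per-base
rate of order 10⁻⁴–10⁻³. Error bases draw base qualities from a lower
distribution (mean Q31 vs. Q38 with mild per-cycle decay), reflecting
the weak BQ signal real miscalls carry; this is what makes BQ features
informative to the classifiers.

What the generator does **not** emulate: InDel errors, platform quality
binning, GC/coverage bias, adapter read-through, duplex UMIs, and any
correlation structure between errors beyond the fragment/read split.
Passing tests on this data therefore demonstrate the *logic* of the
pipeline (concordance, merging, masking, dedup, balancing, CV protocol)
and its behaviour under a realistic error magnitude and bias — not
performance on any particular instrument's artifact spectrum.

The validation dataset is a single primer-free full-overlap 150-nt
window inside the CDS: every fragment spans the same window, so fragment
coverage is exactly the pair count at every position, both mates cover
every variant, and the planted 10/10,000 design yields frequency
exactly 10⁻³. Variants are drawn distinct with minimal alleles (first
and last allele base differ from the reference, so the caller's variant
key matches the spec exactly) and placed ≥ 10 nt from fragment ends
(see External tools). Default problem sizes — 10,000 pairs / 187
variants for the validation round trip, 4,000 fragments for the
error-model demonstration, 1,000 fragments for the simulator property
scans — were chosen as the smallest sizes at which the designs'
stated conditions (coverage, counts, balanced labels in the hundreds)
are met with comfortable margin.

## Known limitations

* Single transcript, substitutions only: no splicing, no InDel calling,
  no multi-codon haplotypes, no barcode-sequencing designs.
* Strict concordance makes mate-nonoverlapping positions uncallable;
  partially overlapping designs lose sensitivity there by construction.
* The directional-adjacency implementation is quadratic per (UMI, R1
  position) stratum; fine for targeted designs, not tuned for
  genome-scale UMI counts.
* `bwa mem` has no end-to-end mode; extreme-end mismatch clusters in
  user data (as opposed to the validation design) can be soft-clipped
  and lost. Supplying a custom `AlignerConfig` with an end-to-end
  aligner removes the caveat.
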