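# mavecall

Low-frequency SNP/MNP simulation and calling for saturation-mutagenesis
(MAVE) targeted sequencing.

Multiplexed assays of variant effect (MAVEs) quantify thousands of
engineered variants in a target gene by deep sequencing of pooled
libraries. Individual variants sit at frequencies of 10⁻³–10⁻⁴ —
at or below the error rate of the PCR/RT/sequencing pipeline — so the
variant caller must distinguish a real allele supported by a handful of
fragments from a recurrent artifact. `mavecall` provides both halves of
the problem:

* **`sim`** — a deterministic spike-in simulator that edits
  user-specified SNPs and 2–3-nt MNPs into *existing* paired-end
  alignments at target frequencies, emitting edited FASTQ plus a truth
  VCF with realized counts. Fragments are edited at most once, and a
  configurable buffer prohibits editing next to pre-existing mismatches
  so a planted variant can never merge with a neighbouring error into a
  spurious higher-order allele (*variant conversion*).
* **`call`** — an end-to-end caller: external local alignment to the
  transcript reference, optional UMI consensus deduplication
  (directional-adjacency grouping keyed by UMI × R1 position), optional
  primer base-quality masking (BQ→0 over synthetic primer segments),
  then variant calling that requires **mate concordance** (both reads of
  a pair must call the same non-reference base), greedily merges phased
  mismatches within a 3-nt reference span into di-/tri-nt MNPs, and
  reports counts and frequencies against *fragment* coverage.
* **`errormodel`** — classifier-based error correction: spike a balanced
  truth set into a negative-control (non-mutagenized) library, re-call,
  label calls by truth membership, train a random forest (or GBM,
  elastic-net GLM, kNN, SVC) on the caller's quality features under
  nested 10-fold CV, and strip predicted errors from real call sets.
* **`postprocess`** — NC log₁₀-frequency background subtraction and the
  sequential seven-criterion filter chain (target region, NNK signature,
  single-codon, count thresholds, strand bias, classifier verdict,
  replicate presence).
* **`synthdata`** — a synthetic-library generator (amplicon tiles or
  RACE-like layouts, substitution-biased errors, UMIs, PCR duplicates,
  NNK variant libraries) with a full provenance ledger, so every
  workflow is testable without downloads.

## The calling model

For a proper pair with per-mate edit distances ≤ *e*, a mismatch at
reference position *i* is emitted iff both mates align across *i*, call
the same non-reference base, and both base qualities are ≥ *q* (masked
BQ-0 bases never participate). Per pair, mismatches at positions
*i ≤ j* merge into one MNP while *j − i ≤ 2* (total reference span ≤ 3
nt; gap positions take the reference base); no haplotype beyond 3 nt is
ever called. Identical (POS, REF, ALT) components are counted once per
fragment, calls below *m* supporting fragments are dropped, and

    frequency = supporting fragments / fragment coverage at POS,

where fragment coverage counts read pairs (not reads) with ≥ 1 unmasked
base across the position. The defaults mirror the standard analysis
configuration `-m 2 -q 30 -e 10 -s NNK`, where the NNK signature flags
variants whose alternate codon ends in G/T (K), the hallmark of NNK
codon mutagenesis.

## Worked example

Build a small error-free validation set (25 variants, each edited into
10 of 2,000 read pairs) and call it back:

```python
from mavecall import synthdata, vcfio
from mavecall.call import CallFilters, run_call

ds = synthdata.build_validation_dataset("example_out", seed=1,
                                        n_pairs=2000, n_variants=25)
result = run_call(ds.reference, "example_out/call",
                  fastq_r1=ds.fastq_r1, fastq_r2=ds.fastq_r2,
                  filters=CallFilters(min_count=2, min_bq=30, max_nm=10))
truth = vcfio.read_truth_entries(ds.truth_vcf)
called = {c.key for c in result.calls}
print(f"truth variants: {len(truth)}")
print(f"calls:          {len(result.calls)}")
print(f"recall:         {len(called & set(truth)) / len(truth):.3f}")
```

prints

```
truth variants: 25
calls:          25
recall:         1.000
```

and the first recovered call, a di-nt MNP planted at 10/2,000 fragments,
reads

```
example call:   pos 67 GA>AC type di_nt_MNP count 10 freq 0.0050 aa p.Glu17Thr
```

i.e. transcript position 67, alternate allele `AC`, supported by exactly
the 10 edited fragments (frequency 10/2000 = 0.005), changing codon 17
from Glu to Thr. The same objects are written as `calls.vcf`, a
per-mismatch `summary.txt` (one row per mismatch participating in a
primary variant call — do not count rows as variants), and a
fragment-coverage `coverage.bedgraph`.

The equivalent shell pipeline is available as `mavecall synth`,
`mavecall sim`, `mavecall call`, `mavecall train-error-model`,
`mavecall score-calls` and `mavecall filter`; see `mavecall --help`.

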