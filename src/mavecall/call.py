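"""Low-frequency SNP/MNP calling from paired-end alignments.

The caller iterates over filtered read pairs, emits mismatches only where
both mates concordantly call the same non-reference base, greedily merges
mismatches within a 3-nt reference span into di-/tri-nt MNPs (no haplotype
calls beyond 3 nt), aggregates per-fragment components into variant calls
with frequencies against fragment coverage, and writes VCF, a per-mismatch
summary table and a fragment-coverage bedgraph.

Filters mirror the tool's command line: ``-m`` minimum supporting
fragments, ``-q`` minimum base quality of both mates, ``-e`` maximum
per-mate edit distance, ``-s`` optional NNK mutagenesis signature.
"""

from __future__ import annotations

import os
from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import vcfio
from .align import AlignerConfig, StageLog, align_pairs
from .pairs import Fragment, load_fragments
from .refdata import (
    VARIANT_TYPES,
    ReferenceMismatchError,
    TranscriptReference,
    VariantAnnotation,
    annotate_variant,
    matches_nnk,
)
from .synthdata import PrimerInterval

MNP_MAX_SPAN = 3


@dataclass(frozen=True)
class CallFilters:
    """Variant-calling thresholds (CLI: -m, -q, -e, -s)."""

    min_count: int = 2
    min_bq: int = 30
    max_nm: int = 10
    signature: str | None = None  # "NNK" or None
    drop_nonsignature: bool = False

    def __post_init__(self) -> None:
        if self.min_count < 1 or self.min_bq < 0 or self.max_nm < 0:
            raise ValueError("invalid filter thresholds")
        if self.signature not in (None, "NNK"):
            raise ValueError("signature must be None or 'NNK'")


@dataclass(frozen=True)
class MismatchObservation:
    """One concordant read-pair mismatch with its quality features."""

    ref_pos: int  # 0-based
    ref_base: str
    alt_base: str
    r1_bq: int
    r2_bq: int
    r1_read_pos: int
    r2_read_pos: int
    r1_nm: int
    r2_nm: int
    fragment_id: str
    sample_strand: str = "+"


@dataclass
class PairComponent:
    """A per-pair variant component: one SNP or merged <=3-nt MNP."""

    start0: int  # 0-based reference start
    ref_allele: str
    alt_allele: str
    observations: list[MismatchObservation]

    @property
    def key(self) -> tuple[int, str, str]:
        return (self.start0 + 1, self.ref_allele, self.alt_allele)


@dataclass
class VariantCall:
    annotation: VariantAnnotation
    supporting_count: int
    fragment_coverage: int
    frequency: float
    fragment_ids: list[str]
    matches_signature: bool
    summaries: dict[str, float]
    strand_counts: dict[str, int] = field(default_factory=dict)
    components: list[PairComponent] = field(default_factory=list)

    @property
    def key(self) -> tuple[int, str, str]:
        return (self.annotation.pos, self.annotation.ref_allele, self.annotation.alt_allele)


def sample_strand_of(frag: Fragment) -> str:
    """Sample strand of a fragment: '+' when R1 aligns forward."""
    if frag.r1 is not None and not frag.r1.is_unmapped:
        return "-" if frag.r1.is_reverse else "+"
    return "+"


def enumerate_concordant_mismatches(
    frag: Fragment, ref: TranscriptReference, filters: CallFilters
) -> list[MismatchObservation]:
    """Mismatches supported concordantly by both mates of a proper pair.

    The pair is discarded entirely when either mate's edit distance exceeds
    ``max_nm``. A mismatch is emitted only where both mates align across
    the position, call the same non-reference, non-N base, and both base
    qualities are >= ``min_bq``. Masked bases (BQ 0) never participate;
    soft-clipped segments and positions covered by one mate only yield
    nothing.
    """
    if not frag.is_proper():
        return []
    refseq = ref.sequence
    r1, r2 = frag.r1, frag.r2
    for mate in (r1, r2):
        if mate.query_qualities is None or mate.cigartuples is None:
            raise ValueError(f"read {frag.name} lacks base qualities or CIGAR")
    p1 = frag.profile(r1, refseq)
    p2 = frag.profile(r2, refseq)
    if p1.nm > filters.max_nm or p2.nm > filters.max_nm:
        return []

    strand = sample_strand_of(frag)
    out: list[MismatchObservation] = []
    shared = p1.mismatches & p2.mismatches
    for rpos in sorted(shared):
        q1pos = p1.posmap[rpos]
        q2pos = p2.posmap[rpos]
        b1 = r1.query_sequence[q1pos]
        b2 = r2.query_sequence[q2pos]
        if b1 != b2 or b1 == "N":
            continue
        bq1 = r1.query_qualities[q1pos]
        bq2 = r2.query_qualities[q2pos]
        if bq1 == 0 or bq2 == 0:  # primer-masked
            continue
        if bq1 < filters.min_bq or bq2 < filters.min_bq:
            continue
        out.append(
            MismatchObservation(
                ref_pos=rpos,
                ref_base=refseq[rpos],
                alt_base=b1,
                r1_bq=int(bq1),
                r2_bq=int(bq2),
                r1_read_pos=q1pos,
                r2_read_pos=q2pos,
                r1_nm=p1.nm,
                r2_nm=p2.nm,
                fragment_id=frag.name,
                sample_strand=strand,
            )
        )
    return out


def merge_mnps(
    observations: list[MismatchObservation], refseq: str
) -> list[PairComponent]:
    """Greedy left-to-right merge of per-pair mismatches into <=3-nt MNPs.

    Consecutive mismatches merge while the total reference span of the
    component stays <= 3 nt (positions i and j merge iff j - i <= 2). Gap
    positions inside a merged allele take the reference base — which is by
    construction also the read base, since no mismatch was observed there.
    """
    if not observations:
        return []
    obs = sorted(observations, key=lambda o: o.ref_pos)
    components: list[PairComponent] = []
    group: list[MismatchObservation] = [obs[0]]
    for o in obs[1:]:
        if o.ref_pos - group[0].ref_pos <= MNP_MAX_SPAN - 1:
            group.append(o)
        else:
            components.append(_component_from(group, refseq))
            group = [o]
    components.append(_component_from(group, refseq))
    return components


def _component_from(group: list[MismatchObservation], refseq: str) -> PairComponent:
    start = group[0].ref_pos
    end = group[-1].ref_pos + 1
    ref_allele = refseq[start:end]
    alt = list(ref_allele)
    for o in group:
        alt[o.ref_pos - start] = o.alt_base
    return PairComponent(
        start0=start, ref_allele=ref_allele, alt_allele="".join(alt), observations=group
    )


def compute_fragment_coverage(
    fragments: list[Fragment], ref: TranscriptReference
) -> list[tuple[str, int, int, int]]:
    """Per-position fragment depth as merged bedgraph intervals.

    A fragment covers a position when at least one mate has an unmasked
    (BQ > 0) base aligned across it; both mates of a pair count once.
    """
    depth = np.zeros(len(ref.sequence), dtype=np.int64)
    for frag in fragments:
        covered: set[int] = set()
        for mate in frag.mates:
            quals = mate.query_qualities
            for qpos, rpos in mate.get_aligned_pairs(matches_only=True):
                if quals[qpos] > 0:
                    covered.add(rpos)
        for p in covered:
            depth[p] += 1
    return _depth_to_bedgraph(depth, ref.transcript_id)


def _depth_to_bedgraph(depth: np.ndarray, contig: str) -> list[tuple[str, int, int, int]]:
    track: list[tuple[str, int, int, int]] = []
    start = 0
    for i in range(1, len(depth) + 1):
        if i == len(depth) or depth[i] != depth[start]:
            if depth[start] > 0:
                track.append((contig, start, i, int(depth[start])))
            start = i
    return track


def depth_at(track: list[tuple[str, int, int, int]], pos0: int) -> int:
    for _, s, e, d in track:
        if s <= pos0 < e:
            return d
    return 0


def _lower_median(values: list[int]) -> float:
    """Median with even counts resolved to the lower middle (deterministic)."""
    s = sorted(values)
    return float(s[(len(s) - 1) // 2])


def _annotate(
    ref: TranscriptReference, pos: int, ref_allele: str, alt_allele: str
) -> VariantAnnotation:
    """Codon-resolved annotation, degrading gracefully outside the CDS."""
    try:
        return annotate_variant(ref, pos, ref_allele, alt_allele)
    except ReferenceMismatchError:
        raise
    except ValueError:
        return VariantAnnotation(
            pos=pos,
            cds_pos=0,
            ref_allele=ref_allele,
            alt_allele=alt_allele,
            variant_type=VARIANT_TYPES[len(ref_allele)],
            ref_codons=(),
            alt_codons=(),
            aa_change="p.?",
            multi_codon=False,
        )


def aggregate_variants(
    components_by_fragment: dict[str, list[PairComponent]],
    coverage: list[tuple[str, int, int, int]],
    filters: CallFilters,
    ref: TranscriptReference,
) -> list[VariantCall]:
    """Aggregate per-pair components into variant calls.

    Identical (POS, REF, ALT) components count once per fragment. Calls
    below ``min_count`` supporting fragments are dropped. Frequency is
    supporting count over fragment coverage at the variant's leftmost
    position. When an NNK signature filter is configured, calls are
    flagged (and optionally dropped) by :func:`matches_nnk`.
    """
    by_key: dict[tuple[int, str, str], list[PairComponent]] = defaultdict(list)
    for comps in components_by_fragment.values():
        seen: set[tuple[int, str, str]] = set()
        for comp in comps:
            if comp.key in seen:  # defensive: one count per fragment
                continue
            seen.add(comp.key)
            by_key[comp.key].append(comp)

    calls: list[VariantCall] = []
    for (pos, ref_allele, alt_allele), comps in sorted(by_key.items()):
        count = len(comps)
        if count < filters.min_count:
            continue
        cov = depth_at(coverage, pos - 1)
        assert cov > 0, f"zero coverage at called position {pos}"
        ann = _annotate(ref, pos, ref_allele, alt_allele)
        sig = bool(ann.alt_codons) and matches_nnk(ref, ann)
        if filters.signature == "NNK" and filters.drop_nonsignature and not sig:
            continue
        obs = [o for c in comps for o in c.observations]
        summaries = {
            "R1BQ": _lower_median([o.r1_bq for o in obs]),
            "R2BQ": _lower_median([o.r2_bq for o in obs]),
            "R1RP": _lower_median([o.r1_read_pos for o in obs]),
            "R2RP": _lower_median([o.r2_read_pos for o in obs]),
            "R1NM": _lower_median([o.r1_nm for o in obs]),
            "R2NM": _lower_median([o.r2_nm for o in obs]),
        }
        strand_counts = {
            "+": sum(1 for c in comps if c.observations[0].sample_strand == "+"),
            "-": sum(1 for c in comps if c.observations[0].sample_strand == "-"),
        }
        calls.append(
            VariantCall(
                annotation=ann,
                supporting_count=count,
                fragment_coverage=cov,
                frequency=count / cov,
                fragment_ids=sorted(c.observations[0].fragment_id for c in comps),
                matches_signature=sig,
                summaries=summaries,
                strand_counts=strand_counts,
                components=comps,
            )
        )
    return calls


def call_fragments(
    fragments: list[Fragment],
    ref: TranscriptReference,
    filters: CallFilters,
) -> tuple[list[VariantCall], list[tuple[str, int, int, int]]]:
    """Enumerate -> merge -> aggregate over in-memory fragments."""
    coverage = compute_fragment_coverage(fragments, ref)
    components: dict[str, list[PairComponent]] = {}
    for frag in fragments:
        obs = enumerate_concordant_mismatches(frag, ref, filters)
        if obs:
            components[frag.name] = merge_mnps(obs, ref.sequence)
    calls = aggregate_variants(components, coverage, filters, ref)
    return calls, coverage


def summary_table(calls: list[VariantCall]) -> pd.DataFrame:
    """One row per mismatch participating in a primary variant call.

    A di-/tri-nt MNP contributes one row per component mismatch per
    supporting fragment; consumers must not treat rows as variant counts.
    """
    rows = []
    for call in calls:
        ann = call.annotation
        for comp in call.components:
            for o in comp.observations:
                rows.append(
                    dict(
                        var_pos=ann.pos,
                        var_ref=ann.ref_allele,
                        var_alt=ann.alt_allele,
                        var_type=ann.variant_type,
                        mismatch_pos=o.ref_pos + 1,
                        mismatch_ref=o.ref_base,
                        mismatch_alt=o.alt_base,
                        fragment_id=o.fragment_id,
                        r1_bq=o.r1_bq,
                        r2_bq=o.r2_bq,
                        r1_read_pos=o.r1_read_pos,
                        r2_read_pos=o.r2_read_pos,
                        r1_nm=o.r1_nm,
                        r2_nm=o.r2_nm,
                        sample_strand=o.sample_strand,
                    )
                )
    columns = [
        "var_pos", "var_ref", "var_alt", "var_type",
        "mismatch_pos", "mismatch_ref", "mismatch_alt", "fragment_id",
        "r1_bq", "r2_bq", "r1_read_pos", "r2_read_pos", "r1_nm", "r2_nm",
        "sample_strand",
    ]
    return pd.DataFrame(rows, columns=columns)


@dataclass
class CallResult:
    calls: list[VariantCall]
    coverage: list[tuple[str, int, int, int]]
    vcf_path: str | None
    summary_path: str | None
    bedgraph_path: str | None
    stage_log: StageLog
    fragments: list[Fragment] = field(repr=False, default_factory=list)


def run_call(
    ref: TranscriptReference,
    out_dir: str,
    fastq_r1: str | None = None,
    fastq_r2: str | None = None,
    bam_path: str | None = None,
    filters: CallFilters | None = None,
    primers: list[PrimerInterval] | str | None = None,
    method: str = "amplicon",
    umi_pattern: str | int | None = None,
    dedup: bool = False,
    seed: int = 0,
    aligner_config: AlignerConfig | None = None,
    keep_fragments: bool = False,
) -> CallResult:
    """The end-to-end calling pipeline.

    Stages: [UMI extraction] -> alignment (external, local) -> [consensus
    deduplication] -> [primer BQ masking] -> concordant mismatch
    enumeration -> <=3-nt MNP merging -> aggregation/annotation -> VCF +
    per-mismatch summary + fragment-coverage bedgraph. Each stage logs the
    surviving read-pair count.
    """
    from . import preprocess
    from .synthdata import read_primer_bed

    filters = filters or CallFilters()
    os.makedirs(out_dir, exist_ok=True)
    log = StageLog()
    ref_fasta = os.path.join(out_dir, f"{ref.transcript_id}.fa")

    if bam_path is None:
        if fastq_r1 is None or fastq_r2 is None:
            raise ValueError("provide either a FASTQ pair or a BAM")
        if umi_pattern is not None:
            umi_r1 = os.path.join(out_dir, "umi_R1.fastq.gz")
            umi_r2 = os.path.join(out_dir, "umi_R2.fastq.gz")
            counts = preprocess.extract_umis(fastq_r1, fastq_r2, umi_r1, umi_r2, umi_pattern)
            log.record("umi_extraction", counts["pairs_out"])
            fastq_r1, fastq_r2 = umi_r1, umi_r2
        ref.to_fasta(ref_fasta)
        bam_path = align_pairs(
            fastq_r1, fastq_r2, ref_fasta, os.path.join(out_dir, "aligned.bam"),
            aligner_config,
        )

    fragments, _ = load_fragments(bam_path)
    log.record("aligned_pairs", len(fragments))

    if dedup:
        fragments, groups = preprocess.deduplicate(fragments, ref, seed=seed)
        log.record("dedup_groups", len(groups))

    if primers is not None:
        if isinstance(primers, str):
            primers = read_primer_bed(primers)
        preprocess.mask_primers(fragments, primers, method=method)
        log.record("masked_pairs", len(fragments))

    proper = [f for f in fragments if f.is_proper()]
    log.record("proper_pairs", len(proper))

    calls, coverage = call_fragments(proper, ref, filters)
    log.record("variant_calls", len(calls))

    cmd = (
        f"call -m {filters.min_count} -q {filters.min_bq} -e {filters.max_nm}"
        + (f" -s {filters.signature}" if filters.signature else "")
    )
    vcf_path = vcfio.write_calls_vcf(calls, ref, os.path.join(out_dir, "calls.vcf"), cmd)
    summary_path = os.path.join(out_dir, "summary.txt")
    summary_table(calls).to_csv(summary_path, sep="\t", index=False)
    bedgraph_path = vcfio.write_bedgraph(coverage, os.path.join(out_dir, "coverage.bedgraph"))
    return CallResult(
        calls=calls,
        coverage=coverage,
        vcf_path=vcf_path,
        summary_path=summary_path,
        bedgraph_path=bedgraph_path,
        stage_log=log,
        fragments=proper if keep_fragments else [],
    )
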