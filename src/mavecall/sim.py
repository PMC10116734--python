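"""Deterministic spike-in of low-frequency SNPs/MNPs into existing alignments.

Variants are edited into real (or synthetic) aligned read pairs at target
frequencies and re-emitted as FASTQ, along with a truth VCF of realized
counts and frequencies. Three guarantees drive the design:

* a fragment is edited at most once across all variants (no double edits);
* with ``conversion_buffer`` b > 0, no edited fragment carries a
  pre-existing mismatch within b nt of an edited base, preventing *variant
  conversion* — the merging of a planted variant with a neighbouring error
  into a spurious higher-order allele;
* editing is per-fragment, uniform without replacement, and fully seeded,
  so the same (variants, alignments, seed) triple always produces
  byte-identical output.
"""

from __future__ import annotations

import gzip
import math
import os
from dataclasses import dataclass, field

import numpy as np
import pysam

from .pairs import Fragment, load_fragments, revcomp
from .refdata import TranscriptReference
from . import vcfio


@dataclass(frozen=True)
class VariantSpec:
    """A requested spike-in: POS/REF/ALT plus a target frequency.

    ``pos`` is 1-based (VCF convention). ``target_count`` overrides the
    frequency-derived fragment count when an exact number of edited pairs is
    wanted (as in the 10-pairs-per-variant validation design).
    """

    pos: int
    ref_allele: str
    alt_allele: str
    target_frequency: float
    target_count: int | None = None

    def __post_init__(self) -> None:
        if len(self.ref_allele) != len(self.alt_allele):
            raise ValueError("REF/ALT length mismatch (substitutions only)")
        if not 1 <= len(self.ref_allele) <= 3:
            raise ValueError("allele length must be 1-3 nt")
        if self.ref_allele == self.alt_allele:
            raise ValueError("ALT equals REF")
        if not 0.0 < self.target_frequency < 1.0:
            raise ValueError("target_frequency must be in (0,1)")

    @property
    def positions0(self) -> range:
        return range(self.pos - 1, self.pos - 1 + len(self.ref_allele))

    @property
    def key(self) -> tuple[int, str, str]:
        return (self.pos, self.ref_allele, self.alt_allele)


@dataclass
class EditTarget:
    fragment_id: str
    # mate ("R1"/"R2") -> list of (query_pos, replacement_base) in aligned orientation
    mate_edits: dict[str, list[tuple[int, str]]]


@dataclass
class TruthRecord:
    spec: VariantSpec
    realized_count: int
    fragment_coverage: int
    unplaceable: bool = False

    @property
    def realized_frequency(self) -> float:
        if self.fragment_coverage == 0:
            return 0.0
        return self.realized_count / self.fragment_coverage


@dataclass
class EditPlan:
    targets: dict[tuple[int, str, str], list[EditTarget]]
    truth_records: list[TruthRecord]
    seed: int
    conversion_buffer: int

    def edited_fragments(self) -> set[str]:
        return {t.fragment_id for ts in self.targets.values() for t in ts}


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def plan_edits(
    specs: list[VariantSpec],
    alignments: str | list[Fragment],
    ref: TranscriptReference,
    seed: int,
    conversion_buffer: int = 3,
) -> EditPlan:
    """Choose fragments to edit for each variant.

    The number of fragments per variant is round(target_frequency x fragment
    coverage at POS), floored at 1 (or the explicit ``target_count``).
    Eligible fragments must (a) cover all edited positions in at least one
    mate, (b) when ``conversion_buffer`` > 0, carry no pre-existing mismatch
    within that many nt of any edited position in either mate, and (c) not
    be claimed by another variant. Variants that cannot reach their count
    are reported unplaceable with the achieved count — never silently
    truncated.
    """
    if conversion_buffer < 0:
        raise ValueError("conversion_buffer must be >= 0")
    if isinstance(alignments, str):
        fragments, _ = load_fragments(alignments, require_sorted=True)
    else:
        fragments = alignments
    refseq = ref.sequence
    rng = np.random.default_rng(seed)

    coverage = np.zeros(len(refseq) + 1, dtype=np.int64)
    for frag in fragments:
        covered = frag.covered_positions(refseq)
        if covered:
            for p in covered:
                coverage[p] += 1

    claimed: set[str] = set()
    targets: dict[tuple[int, str, str], list[EditTarget]] = {}
    truth: list[TruthRecord] = []
    order = sorted(range(len(fragments)), key=lambda i: fragments[i].name)

    for spec in specs:
        positions = list(spec.positions0)
        if positions[-1] >= len(refseq):
            raise ValueError(f"variant at {spec.pos} outside the reference")
        observed = refseq[positions[0] : positions[-1] + 1]
        if observed != spec.ref_allele:
            raise ValueError(
                f"REF mismatch for variant at {spec.pos}: reference has {observed}"
            )
        cov = int(coverage[positions[0]])
        if spec.target_count is not None:
            needed = spec.target_count
        else:
            needed = max(1, _round_half_away(spec.target_frequency * cov)) if cov else 0

        eligible: list[Fragment] = []
        for i in order:
            frag = fragments[i]
            if frag.name in claimed:
                continue
            full_cover = False
            near_error = False
            for mate in frag.mates:
                prof = frag.profile(mate, refseq)
                if all(p in prof.posmap for p in positions):
                    full_cover = True
                if conversion_buffer > 0 and prof.mismatches:
                    for m in prof.mismatches:
                        if any(abs(m - p) <= conversion_buffer for p in positions):
                            near_error = True
                            break
                if near_error:
                    break
            if full_cover and not near_error:
                eligible.append(frag)

        chosen_idx = rng.permutation(len(eligible))[:needed]
        chosen = [eligible[i] for i in sorted(chosen_idx)]
        unplaceable = len(chosen) < max(needed, 1)
        spec_targets: list[EditTarget] = []
        for frag in chosen:
            mate_edits: dict[str, list[tuple[int, str]]] = {}
            for label, mate in (("R1", frag.r1), ("R2", frag.r2)):
                if mate is None or mate.is_unmapped:
                    continue
                prof = frag.profile(mate, refseq)
                edits = [
                    (prof.posmap[p], spec.alt_allele[j])
                    for j, p in enumerate(positions)
                    if p in prof.posmap
                ]
                if edits:
                    mate_edits[label] = edits
            spec_targets.append(EditTarget(frag.name, mate_edits))
            claimed.add(frag.name)
        targets[spec.key] = spec_targets
        truth.append(
            TruthRecord(
                spec=spec,
                realized_count=len(spec_targets),
                fragment_coverage=cov,
                unplaceable=unplaceable,
            )
        )

    return EditPlan(
        targets=targets,
        truth_records=truth,
        seed=seed,
        conversion_buffer=conversion_buffer,
    )


def _open_fq(path: str):
    return gzip.open(path, "wt") if path.endswith(".gz") else open(path, "w")


def _emit_fastq(read: pysam.AlignedSegment, edits, fh) -> None:
    seq = read.query_sequence
    quals = read.query_qualities
    if edits:
        seq_l = list(seq)
        for qpos, base in edits:
            if not 0 <= qpos < len(seq_l):
                raise ValueError(
                    f"edit position {qpos} outside read {read.query_name} "
                    f"(length {len(seq_l)})"
                )
            seq_l[qpos] = base
        seq = "".join(seq_l)
    if read.is_reverse:
        seq = revcomp(seq)
        quals = quals[::-1]
    qual_str = "".join(chr(q + 33) for q in quals)
    fh.write(f"@{read.query_name}\n{seq}\n+\n{qual_str}\n")


def apply_edits(
    plan: EditPlan,
    alignments: str | list[Fragment],
    ref: TranscriptReference,
    out_fastq_r1: str,
    out_fastq_r2: str,
    truth_vcf: str | None = None,
) -> list[TruthRecord]:
    """Substitute planned ALT bases into targeted mates and write FASTQ.

    Base qualities are preserved; non-targeted reads pass through with
    sequence and qualities untouched. Reads are emitted in their original
    (sequencer) orientation.
    """
    if isinstance(alignments, str):
        fragments, _ = load_fragments(alignments)
    else:
        fragments = alignments

    edits_by_fragment: dict[str, dict[str, list[tuple[int, str]]]] = {}
    for spec_targets in plan.targets.values():
        for tgt in spec_targets:
            slot = edits_by_fragment.setdefault(tgt.fragment_id, {"R1": [], "R2": []})
            for label, edits in tgt.mate_edits.items():
                slot[label].extend(edits)

    with _open_fq(out_fastq_r1) as fq1, _open_fq(out_fastq_r2) as fq2:
        for frag in sorted(fragments, key=lambda f: f.name):
            frag_edits = edits_by_fragment.get(frag.name, {})
            if frag.r1 is not None:
                _emit_fastq(frag.r1, frag_edits.get("R1"), fq1)
            if frag.r2 is not None:
                _emit_fastq(frag.r2, frag_edits.get("R2"), fq2)

    if truth_vcf is not None:
        vcfio.write_truth_vcf(plan.truth_records, ref, truth_vcf)
    return plan.truth_records


def realign_edited(
    fastq_r1: str,
    fastq_r2: str,
    ref: TranscriptReference,
    out_bam: str,
    work_dir: str | None = None,
    aligner_config=None,
) -> str:
    """Re-align edited reads so downstream tools see valid CIGAR/MD/NM."""
    from .align import align_pairs

    work_dir = work_dir or os.path.dirname(os.path.abspath(out_bam))
    ref_fasta = os.path.join(work_dir, f"{ref.transcript_id}.fa")
    if not os.path.exists(ref_fasta):
        ref.to_fasta(ref_fasta)
    return align_pairs(fastq_r1, fastq_r2, ref_fasta, out_bam, aligner_config)


def run_sim(
    specs: list[VariantSpec],
    bam_path: str,
    ref: TranscriptReference,
    out_dir: str,
    seed: int,
    conversion_buffer: int = 3,
    realign: bool = False,
    aligner_config=None,
) -> tuple[list[TruthRecord], str, str, str]:
    """Plan + apply + (optionally) re-align; the full spike-in workflow."""
    os.makedirs(out_dir, exist_ok=True)
    plan = plan_edits(specs, bam_path, ref, seed=seed, conversion_buffer=conversion_buffer)
    fq1 = os.path.join(out_dir, "edited_R1.fastq.gz")
    fq2 = os.path.join(out_dir, "edited_R2.fastq.gz")
    truth_vcf = os.path.join(out_dir, "truth.vcf")
    truth = apply_edits(plan, bam_path, ref, fq1, fq2, truth_vcf)
    if realign:
        realign_edited(fq1, fq2, ref, os.path.join(out_dir, "edited.bam"),
                       work_dir=out_dir, aligner_config=aligner_config)
    return truth, fq1, fq2, truth_vcf
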