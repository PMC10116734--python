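"""Read preprocessing between FASTQ and variant calling.

Covers UMI extraction to the read header, primer base-quality masking, UMI
directional-adjacency grouping keyed by (UMI, R1 position), and majority-
vote consensus deduplication. Adapter/3' quality trimming and alignment are
delegated to external tools (see :mod:`mavecall.align`).
"""

from __future__ import annotations

import gzip
import re
import warnings
from collections import Counter, defaultdict
from dataclasses import dataclass, field

import numpy as np
import pysam

from .pairs import Fragment, load_fragments
from .refdata import TranscriptReference
from .synthdata import PrimerInterval

UMI_DELIMITER = "_"

#: masking buffer (nt) upstream of the primer 5' end, by library method
MASK_BUFFERS = {"amplicon": 15, "race_like": 3}


# ---------------------------------------------------------------------------
# UMI extraction
# ---------------------------------------------------------------------------

def _open_fq(path: str, mode: str = "rt"):
    return gzip.open(path, mode) if path.endswith(".gz") else open(path, mode.rstrip("t"))


def _umi_length_from_pattern(pattern: str | int) -> int:
    """Accept an anchored UMI regex like ``(?P<umi_1>[ATCGN]{16})`` or a length."""
    if isinstance(pattern, int):
        return pattern
    m = re.search(r"\{(\d+)\}", pattern)
    if m:
        return int(m.group(1))
    raise ValueError(f"cannot determine UMI length from pattern {pattern!r}")


def extract_umis(
    fastq_r1: str,
    fastq_r2: str,
    out_r1: str,
    out_r2: str,
    umi_pattern: str | int,
) -> dict[str, int]:
    """Move a fixed-length R1 5' UMI from sequence to the read names.

    The UMI (and its qualities) is removed from R1 and appended to both
    mates' names with ``_``. Pairs whose R1 is shorter than the UMI are
    dropped and counted. A zero-length pattern copies input to output.
    """
    umi_len = _umi_length_from_pattern(umi_pattern)
    counts = {"pairs_in": 0, "pairs_out": 0, "pairs_dropped_short": 0}
    with _open_fq(fastq_r1) as in1, _open_fq(fastq_r2) as in2, \
            _open_fq(out_r1, "wt") as o1, _open_fq(out_r2, "wt") as o2:
        while True:
            rec1 = [in1.readline() for _ in range(4)]
            rec2 = [in2.readline() for _ in range(4)]
            if not rec1[0] and not rec2[0]:
                break
            if not rec1[0] or not rec2[0]:
                raise ValueError("R1/R2 FASTQ files are not the same length")
            counts["pairs_in"] += 1
            seq1 = rec1[1].rstrip("\n")
            if len(seq1) < umi_len:
                counts["pairs_dropped_short"] += 1
                continue
            if umi_len == 0:
                o1.writelines(rec1)
                o2.writelines(rec2)
                counts["pairs_out"] += 1
                continue
            umi = seq1[:umi_len]
            name1 = rec1[0].rstrip("\n").split()[0]
            name2 = rec2[0].rstrip("\n").split()[0]
            if name1.lstrip("@") != name2.lstrip("@"):
                raise ValueError(f"unpaired records: {name1} vs {name2}")
            new_name = f"{name1}{UMI_DELIMITER}{umi}"
            o1.write(f"{new_name}\n{seq1[umi_len:]}\n+\n{rec1[3].rstrip()[umi_len:]}\n")
            o2.write(f"{name2}{UMI_DELIMITER}{umi}\n{rec2[1]}+\n{rec2[3]}")
            counts["pairs_out"] += 1
    return counts


def umi_from_name(name: str) -> str | None:
    if UMI_DELIMITER not in name:
        return None
    candidate = name.rsplit(UMI_DELIMITER, 1)[1]
    return candidate if candidate and set(candidate) <= set("ACGTN") else None


# ---------------------------------------------------------------------------
# Primer base-quality masking
# ---------------------------------------------------------------------------

@dataclass
class MaskedSegment:
    read_name: str
    mate: str  # R1 | R2
    primer_name: str
    read_positions: list[int]
    original_quals: list[int]


@dataclass
class MaskReport:
    segments: list[MaskedSegment] = field(default_factory=list)

    def masked_bases(self, read_name: str, mate: str) -> int:
        return sum(
            len(s.read_positions)
            for s in self.segments
            if s.read_name == read_name and s.mate == mate
        )

    def originating_primers(self, read_name: str, mate: str) -> set[str]:
        return {
            s.primer_name
            for s in self.segments
            if s.read_name == read_name and s.mate == mate
        }


def _read_5p(read: pysam.AlignedSegment) -> int:
    return read.reference_end - 1 if read.is_reverse else read.reference_start


def _read_3p(read: pysam.AlignedSegment) -> int:
    return read.reference_start if read.is_reverse else read.reference_end - 1


def _originating_primers(
    read: pysam.AlignedSegment, primers: list[PrimerInterval], buffer: int
) -> list[PrimerInterval]:
    """Primers a read segment originates from.

    Criterion 1 (same strand): the read 5' end lies within the primer's
    aligned coordinates, or within ``buffer`` nt upstream of the primer 5'
    end (upstream relative to strand). Criterion 2 (opposite strand): the
    read 3' end stops within the primer's aligned coordinates, or within
    ``buffer`` nt upstream of that primer's 5' end.
    """
    strand = "-" if read.is_reverse else "+"
    p5 = _read_5p(read)
    p3 = _read_3p(read)
    out = []
    for primer in primers:
        if primer.strand == strand:
            if primer.strand == "+":
                hit = primer.start - buffer <= p5 < primer.end
            else:
                hit = primer.start <= p5 < primer.end + buffer
            if hit:
                out.append(primer)
        else:
            if primer.strand == "+":
                hit = primer.start - buffer <= p3 < primer.end
            else:
                hit = primer.start <= p3 < primer.end + buffer
            if hit:
                out.append(primer)
    return out


def mask_primers(
    fragments: list[Fragment],
    primers: list[PrimerInterval],
    method: str = "amplicon",
) -> MaskReport:
    """Set base qualities to 0 over read segments deriving from primers.

    Mutates the alignments in place and returns a report recording, per
    mate, the originating primers and the masked positions with their
    original qualities (so masking is reversible). Base calls are never
    changed. Buffer: 15 nt (amplicon) or 3 nt (RACE-like).
    """
    if method not in MASK_BUFFERS:
        raise ValueError(f"unknown method {method!r}")
    buffer = MASK_BUFFERS[method]
    report = MaskReport()
    if not primers:
        return report
    for frag in fragments:
        for label, mate in (("R1", frag.r1), ("R2", frag.r2)):
            if mate is None or mate.is_unmapped:
                continue
            if mate.query_qualities is None:
                raise ValueError(f"read {mate.query_name} has no base qualities")
            origins = _originating_primers(mate, primers, buffer)
            if not origins:
                continue
            quals = np.array(mate.query_qualities, dtype=int)
            pos_pairs = mate.get_aligned_pairs(matches_only=True)
            for primer in origins:
                qpositions = [q for q, r in pos_pairs if primer.start <= r < primer.end]
                if not qpositions:
                    continue
                report.segments.append(
                    MaskedSegment(
                        read_name=mate.query_name,
                        mate=label,
                        primer_name=primer.name,
                        read_positions=qpositions,
                        original_quals=[int(quals[q]) for q in qpositions],
                    )
                )
                quals[qpositions] = 0
            mate.query_qualities = pysam.qualitystring_to_array(
                "".join(chr(q + 33) for q in quals)
            )
        frag.clear_cache()
    return report


def unmask(fragments: list[Fragment], report: MaskReport) -> None:
    """Restore the original base qualities recorded in a MaskReport."""
    by_read = {(f.name, "R1"): f.r1 for f in fragments} | {
        (f.name, "R2"): f.r2 for f in fragments
    }
    for seg in report.segments:
        mate = by_read.get((seg.read_name, seg.mate))
        if mate is None:
            continue
        quals = list(mate.query_qualities)
        for qpos, q in zip(seg.read_positions, seg.original_quals):
            quals[qpos] = q
        mate.query_qualities = quals


# ---------------------------------------------------------------------------
# UMI directional-adjacency grouping
# ---------------------------------------------------------------------------

@dataclass
class UmiGroup:
    group_id: str
    umi: str  # seed (highest-count) UMI of the group
    r1_pos: int
    members: list[str]  # fragment names, duplicates included

    @property
    def size(self) -> int:
        return len(self.members)


def _hamming1(a: str, b: str) -> bool:
    if len(a) != len(b):
        return False
    diff = 0
    for x, y in zip(a, b):
        if x != y:
            diff += 1
            if diff > 1:
                return False
    return diff == 1


def group_umis_directional(fragments: list[Fragment]) -> list[UmiGroup]:
    """Group read pairs from a common molecule by (UMI, R1 position).

    Within each R1-position stratum, UMIs at Hamming distance 1 are linked
    A -> B when count(A) >= 2 x count(B) - 1; connected components are
    seeded from the highest-count UMIs (the directional adjacency method).
    Grouping is invariant to input order: fragments are canonically sorted
    before graph construction. Pairs without a UMI in the read name are
    excluded with a warning.
    """
    strata: dict[int, dict[str, list[str]]] = defaultdict(lambda: defaultdict(list))
    skipped = 0
    for frag in sorted(fragments, key=lambda f: f.name):
        if frag.r1 is None or frag.r1.is_unmapped:
            skipped += 1
            continue
        umi = umi_from_name(frag.name)
        if umi is None:
            skipped += 1
            continue
        r1_pos = frag.r1.reference_start
        strata[r1_pos][umi].append(frag.name)

    groups: list[UmiGroup] = []
    for r1_pos in sorted(strata):
        by_umi = strata[r1_pos]
        counts = {u: len(v) for u, v in by_umi.items()}
        order = sorted(counts, key=lambda u: (-counts[u], u))
        assigned: set[str] = set()
        for seed_umi in order:
            if seed_umi in assigned:
                continue
            component = [seed_umi]
            assigned.add(seed_umi)
            queue = [seed_umi]
            while queue:
                cur = queue.pop(0)
                for other in order:
                    if other in assigned:
                        continue
                    if _hamming1(cur, other) and counts[cur] >= 2 * counts[other] - 1:
                        assigned.add(other)
                        component.append(other)
                        queue.append(other)
            members = [name for u in component for name in by_umi[u]]
            groups.append(
                UmiGroup(
                    group_id=f"G{len(groups):06d}{UMI_DELIMITER}{seed_umi}",
                    umi=seed_umi,
                    r1_pos=r1_pos,
                    members=sorted(members),
                )
            )
    if skipped:
        warnings.warn(f"{skipped} read pair(s) without a UMI excluded from grouping")
    return groups


# ---------------------------------------------------------------------------
# Consensus deduplication
# ---------------------------------------------------------------------------

def _consensus_mate(
    mates: list[pysam.AlignedSegment],
    refseq: str,
    rng: np.random.Generator,
) -> pysam.AlignedSegment:
    """Majority-vote consensus of duplicate alignments of one mate.

    Votes are taken per aligned reference position among the duplicates
    covering it (positions absent from a duplicate's alignment abstain).
    Two-way ties resolve by (i) reference match, (ii) higher base quality,
    (iii) seeded random choice. The consensus base quality is the maximum
    quality among duplicates supporting the chosen base.
    """
    votes: dict[int, list[tuple[str, int]]] = defaultdict(list)
    for mate in mates:
        seq = mate.query_sequence
        quals = mate.query_qualities
        for qpos, rpos in mate.get_aligned_pairs(matches_only=True):
            votes[rpos].append((seq[qpos], quals[qpos]))

    positions = sorted(votes)
    bases: list[str] = []
    quals_out: list[int] = []
    for rpos in positions:
        calls = votes[rpos]
        tally = Counter(b for b, _ in calls)
        top = tally.most_common()
        best, best_n = top[0]
        tied = [b for b, n in top if n == best_n]
        if len(tied) > 1:
            ref_base = refseq[rpos]
            if ref_base in tied:
                best = ref_base
            else:
                bq = {b: max(q for bb, q in calls if bb == b) for b in tied}
                maxq = max(bq.values())
                top_bq = sorted(b for b, q in bq.items() if q == maxq)
                best = top_bq[0] if len(top_bq) == 1 else top_bq[rng.integers(0, len(top_bq))]
        bases.append(best)
        quals_out.append(max(q for b, q in calls if b == best))

    proto = mates[0]
    out = pysam.AlignedSegment(header=proto.header)
    out.query_name = proto.query_name
    out.flag = proto.flag
    out.reference_id = proto.reference_id
    out.reference_start = positions[0]
    out.mapping_quality = proto.mapping_quality
    # interior positions covered by no duplicate are filled from the
    # reference at quality 0 (masked), keeping the consensus contiguous
    full_seq: list[str] = []
    full_quals: list[int] = []
    cursor = positions[0]
    for rpos, base, q in zip(positions, bases, quals_out):
        while cursor < rpos:
            full_seq.append(refseq[cursor])
            full_quals.append(0)
            cursor += 1
        full_seq.append(base)
        full_quals.append(q)
        cursor = rpos + 1
    out.cigartuples = [(0, len(full_seq))]
    out.query_sequence = "".join(full_seq)
    out.query_qualities = full_quals
    nm = sum(1 for i, b in enumerate(full_seq) if b != refseq[positions[0] + i])
    out.set_tag("NM", nm)
    return out


def consensus_deduplicate(
    groups: list[UmiGroup],
    fragments: list[Fragment],
    ref: TranscriptReference,
    seed: int = 0,
) -> list[Fragment]:
    """One consensus read pair per UMI group.

    Singleton groups pass their read pair through unchanged; multi-member
    groups are collapsed by per-position majority vote (see
    :func:`_consensus_mate`).
    """
    rng = np.random.default_rng(seed)
    by_name = {f.name: f for f in fragments}
    out: list[Fragment] = []
    for group in groups:
        members = [by_name[n] for n in group.members if n in by_name]
        assert members, f"group {group.group_id} has no members"
        if len(members) == 1:
            out.append(members[0])
            continue
        r1s = [m.r1 for m in members if m.r1 is not None and not m.r1.is_unmapped]
        r2s = [m.r2 for m in members if m.r2 is not None and not m.r2.is_unmapped]
        cons = Fragment(name=group.group_id)
        if r1s:
            cons.r1 = _consensus_mate(r1s, ref.sequence, rng)
            cons.r1.query_name = group.group_id
            cons.r1.set_tag("GS", len(members))
        if r2s:
            cons.r2 = _consensus_mate(r2s, ref.sequence, rng)
            cons.r2.query_name = group.group_id
            cons.r2.set_tag("GS", len(members))
        out.append(cons)
    return out


def deduplicate(
    fragments: list[Fragment], ref: TranscriptReference, seed: int = 0
) -> tuple[list[Fragment], list[UmiGroup]]:
    groups = group_umis_directional(fragments)
    return consensus_deduplicate(groups, fragments, ref, seed=seed), groups
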