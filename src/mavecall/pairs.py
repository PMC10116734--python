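"""In-memory representation of aligned read pairs (fragments).

The caller and simulator both operate on *fragments*: the two primary
alignments of a read pair. Mates are matched by query name. Secondary and
supplementary alignments are dropped on load.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

import pysam


@dataclass
class MateProfile:
    """Per-mate view of an alignment against the reference.

    ``posmap`` maps 0-based reference position -> 0-based query position for
    aligned (non-clipped, non-indel) bases. ``mismatches`` holds reference
    positions where the read base differs from the reference (N bases are
    treated as mismatching the reference but can never support a call).
    """

    posmap: dict[int, int]
    mismatches: set[int]
    nm: int


@dataclass
class Fragment:
    name: str
    r1: pysam.AlignedSegment | None = None
    r2: pysam.AlignedSegment | None = None
    _profiles: dict = field(default_factory=dict, repr=False)

    @property
    def mates(self) -> list[pysam.AlignedSegment]:
        return [m for m in (self.r1, self.r2) if m is not None and not m.is_unmapped]

    def is_proper(self) -> bool:
        return (
            self.r1 is not None
            and self.r2 is not None
            and not self.r1.is_unmapped
            and not self.r2.is_unmapped
        )

    def profile(self, mate: pysam.AlignedSegment, refseq: str) -> MateProfile:
        key = 1 if mate is self.r1 else 2
        if key not in self._profiles:
            self._profiles[key] = mate_profile(mate, refseq)
        return self._profiles[key]

    def covered_positions(self, refseq: str) -> set[int]:
        """Union of reference positions aligned by either mate."""
        out: set[int] = set()
        for m in self.mates:
            out.update(self.profile(m, refseq).posmap)
        return out

    def clear_cache(self) -> None:
        self._profiles.clear()


def mate_profile(read: pysam.AlignedSegment, refseq: str) -> MateProfile:
    posmap: dict[int, int] = {}
    mismatches: set[int] = set()
    seq = read.query_sequence
    indel_len = 0
    for ct, ln in read.cigartuples or []:
        if ct in (1, 2):  # I, D
            indel_len += ln
    for qpos, rpos in read.get_aligned_pairs(matches_only=True):
        posmap[rpos] = qpos
        if seq[qpos] != refseq[rpos]:
            mismatches.add(rpos)
    return MateProfile(posmap=posmap, mismatches=mismatches, nm=len(mismatches) + indel_len)


def load_fragments(
    source: str | Iterable[pysam.AlignedSegment],
    require_sorted: bool = False,
) -> tuple[list[Fragment], pysam.AlignmentHeader | None]:
    """Group primary alignments into fragments by query name.

    ``source`` is a BAM/SAM path or an iterable of segments. Returns
    fragments in order of first appearance plus the header when available.
    """
    header = None
    if isinstance(source, str):
        af = pysam.AlignmentFile(source, check_sq=False)
        header = af.header
        if require_sorted and header.get("HD", {}).get("SO") != "coordinate":
            raise ValueError(f"{source} is not coordinate-sorted")
        reads: Iterator[pysam.AlignedSegment] = af
    else:
        reads = iter(source)

    frags: dict[str, Fragment] = {}
    for read in reads:
        if read.is_secondary or read.is_supplementary:
            continue
        frag = frags.get(read.query_name)
        if frag is None:
            frag = frags[read.query_name] = Fragment(read.query_name)
        if read.is_read2:
            frag.r2 = read
        else:
            frag.r1 = read
    return list(frags.values()), header


def nm_of(read: pysam.AlignedSegment, refseq: str) -> int:
    """Edit distance of a mate: the NM tag when present, else recomputed."""
    if read.has_tag("NM"):
        return int(read.get_tag("NM"))
    return mate_profile(read, refseq).nm


_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]
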