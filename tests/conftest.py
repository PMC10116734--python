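"""Shared fixtures: a small transcript reference, an in-memory read-pair
builder, and independent brute-force oracles for the caller."""

from __future__ import annotations

from collections import Counter, defaultdict

import pysam
import pytest

from mavecall.pairs import Fragment
from mavecall.refdata import TranscriptReference

# 10-codon CDS (ATG ... TAA) with 6-nt UTRs; 42 nt total
TOY_SEQ = "ACGTAC" + "ATG" + "GCT" + "AAA" + "CCG" + "TTC" + "GGA" + "TAC" + "CAT" + "ATG" + "TAA" + "GTACGT"


@pytest.fixture(scope="session")
def toy_ref() -> TranscriptReference:
    return TranscriptReference("toy_tx", TOY_SEQ, 6, 36)


@pytest.fixture(scope="session")
def toy_header(toy_ref) -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_references(
        [toy_ref.transcript_id], [len(toy_ref.sequence)]
    )


def build_mate(
    header: pysam.AlignmentHeader,
    refseq: str,
    name: str,
    start: int,
    end: int,
    is_read2: bool,
    is_reverse: bool,
    muts: dict[int, str] | None = None,
    qual: int = 37,
    qual_at: dict[int, int] | None = None,
) -> pysam.AlignedSegment:
    """Ungapped aligned mate over [start, end) with reference-position
    mutations ``muts`` and per-reference-position quality overrides."""
    seg = pysam.AlignedSegment(header=header)
    seg.query_name = name
    seq = list(refseq[start:end])
    quals = [qual] * len(seq)
    for rpos, base in (muts or {}).items():
        seq[rpos - start] = base
    for rpos, q in (qual_at or {}).items():
        quals[rpos - start] = q
    seg.query_sequence = "".join(seq)
    seg.query_qualities = quals
    seg.reference_id = 0
    seg.reference_start = start
    seg.cigartuples = [(0, end - start)]
    seg.mapping_quality = 60
    seg.is_paired = True
    seg.is_proper_pair = True
    seg.is_read2 = is_read2
    seg.is_read1 = not is_read2
    seg.is_reverse = is_reverse
    seg.mate_is_reverse = not is_reverse
    return seg


@pytest.fixture(scope="session")
def pair_builder(toy_header, toy_ref):
    """Factory for fully-overlapping (or offset) read pairs on the toy
    reference. ``both_muts`` edits both mates (concordant), ``r1_muts`` /
    ``r2_muts`` one mate only."""

    def build(
        name: str,
        start: int = 0,
        end: int | None = None,
        both_muts: dict[int, str] | None = None,
        r1_muts: dict[int, str] | None = None,
        r2_muts: dict[int, str] | None = None,
        r1_span: tuple[int, int] | None = None,
        r2_span: tuple[int, int] | None = None,
        qual: int = 37,
        r1_qual_at: dict[int, int] | None = None,
        r2_qual_at: dict[int, int] | None = None,
        refseq: str | None = None,
        header: pysam.AlignmentHeader | None = None,
    ) -> Fragment:
        refseq = refseq if refseq is not None else toy_ref.sequence
        header = header if header is not None else toy_header
        end = end if end is not None else len(refseq)
        s1, e1 = r1_span or (start, end)
        s2, e2 = r2_span or (start, end)
        m1 = dict(both_muts or {})
        m1.update(r1_muts or {})
        m2 = dict(both_muts or {})
        m2.update(r2_muts or {})
        r1 = build_mate(header, refseq, name, s1, e1, False, False,
                        {p: b for p, b in m1.items() if s1 <= p < e1}, qual, r1_qual_at)
        r2 = build_mate(header, refseq, name, s2, e2, True, True,
                        {p: b for p, b in m2.items() if s2 <= p < e2}, qual, r2_qual_at)
        return Fragment(name=name, r1=r1, r2=r2)

    return build


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------

def oracle_merge_positions(positions: list[int], max_span: int = 3) -> list[list[int]]:
    """Recursive leftmost-maximal grouping of sorted mismatch positions:
    the first group takes as many positions as fit within the span cap,
    then recurse on the remainder."""
    if not positions:
        return []
    take = 1
    while take < len(positions) and positions[take] - positions[0] <= max_span - 1:
        take += 1
    return [positions[:take]] + oracle_merge_positions(positions[take:], max_span)


def oracle_pair_mismatches(frag: Fragment, refseq: str, min_bq: int, max_nm: int):
    """Concordant mismatch positions of one pair, by direct scanning."""
    r1, r2 = frag.r1, frag.r2
    maps = []
    for mate in (r1, r2):
        posmap = {r: q for q, r in mate.get_aligned_pairs(matches_only=True)}
        nm = sum(
            1 for r, q in posmap.items() if mate.query_sequence[q] != refseq[r]
        ) + sum(l for op, l in mate.cigartuples if op in (1, 2))
        maps.append((posmap, nm))
    if maps[0][1] > max_nm or maps[1][1] > max_nm:
        return {}
    out = {}
    for rpos in sorted(set(maps[0][0]) & set(maps[1][0])):
        b1 = r1.query_sequence[maps[0][0][rpos]]
        b2 = r2.query_sequence[maps[1][0][rpos]]
        q1 = r1.query_qualities[maps[0][0][rpos]]
        q2 = r2.query_qualities[maps[1][0][rpos]]
        if b1 == b2 != refseq[rpos] and b1 != "N" and min(q1, q2) >= max(min_bq, 1):
            out[rpos] = b1
    return out


def oracle_calls(
    fragments: list[Fragment], refseq: str, min_bq: int, max_nm: int, min_count: int
) -> dict[tuple[int, str, str], int]:
    """Brute-force caller: per-pair concordant scan + recursive merge +
    per-fragment counting. Returns {(1-based pos, ref, alt): count}."""
    counts: Counter = Counter()
    for frag in fragments:
        if frag.r1 is None or frag.r2 is None:
            continue
        mm = oracle_pair_mismatches(frag, refseq, min_bq, max_nm)
        seen = set()
        for group in oracle_merge_positions(sorted(mm)):
            start, end = group[0], group[-1] + 1
            ref_allele = refseq[start:end]
            alt = list(ref_allele)
            for p in group:
                alt[p - start] = mm[p]
            key = (start + 1, ref_allele, "".join(alt))
            if key not in seen:
                seen.add(key)
                counts[key] += 1
    return {k: n for k, n in counts.items() if n >= min_count}
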