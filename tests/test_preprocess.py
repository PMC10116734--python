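"""UMI extraction, primer masking, directional-adjacency grouping and
consensus deduplication."""

import copy

import pytest

from mavecall import preprocess
from mavecall.preprocess import (
    UmiGroup,
    consensus_deduplicate,
    extract_umis,
    group_umis_directional,
    mask_primers,
    unmask,
)
from mavecall.synthdata import PrimerInterval


def write_fastq(path, records):
    with open(path, "w") as fh:
        for name, seq, qual in records:
            fh.write(f"@{name}\n{seq}\n+\n{qual}\n")


class TestExtractUmis:
    def test_sixteen_nt_pattern_moves_prefix_to_header(self, tmp_path):
        umi = "ACGTACGTACGTACGT"
        write_fastq(tmp_path / "r1.fq", [("p1", umi + "GGGG", "I" * 20)])
        write_fastq(tmp_path / "r2.fq", [("p1", "CCCC", "I" * 4)])
        counts = extract_umis(
            str(tmp_path / "r1.fq"), str(tmp_path / "r2.fq"),
            str(tmp_path / "o1.fq"), str(tmp_path / "o2.fq"),
            "(?P<umi_1>[ATCGN]{16})",
        )
        assert counts == {"pairs_in": 1, "pairs_out": 1, "pairs_dropped_short": 0}
        lines1 = open(tmp_path / "o1.fq").read().splitlines()
        lines2 = open(tmp_path / "o2.fq").read().splitlines()
        assert lines1[0] == f"@p1_{umi}"
        assert lines1[1] == "GGGG" and lines1[3] == "IIII"
        assert lines2[0] == f"@p1_{umi}"
        assert lines2[1] == "CCCC"

    def test_zero_length_pattern_is_identity(self, tmp_path):
        recs = [("p1", "ACGT", "IIII"), ("p2", "GGGG", "JJJJ")]
        write_fastq(tmp_path / "r1.fq", recs)
        write_fastq(tmp_path / "r2.fq", recs)
        extract_umis(
            str(tmp_path / "r1.fq"), str(tmp_path / "r2.fq"),
            str(tmp_path / "o1.fq"), str(tmp_path / "o2.fq"), 0,
        )
        assert open(tmp_path / "o1.fq").read() == open(tmp_path / "r1.fq").read()

    def test_short_read_drops_pair(self, tmp_path):
        write_fastq(tmp_path / "r1.fq", [("p1", "ACGTACGTAC", "I" * 10)])
        write_fastq(tmp_path / "r2.fq", [("p1", "CCCC", "IIII")])
        counts = extract_umis(
            str(tmp_path / "r1.fq"), str(tmp_path / "r2.fq"),
            str(tmp_path / "o1.fq"), str(tmp_path / "o2.fq"), 16,
        )
        assert counts["pairs_dropped_short"] == 1
        assert counts["pairs_out"] == 0


@pytest.fixture
def forward_primer(toy_ref):
    return PrimerInterval(toy_ref.transcript_id, 5, 15, "+", "fwd")


class TestMaskPrimers:
    def test_read_starting_at_primer_start_masked_over_span(
        self, pair_builder, forward_primer
    ):
        frag = pair_builder("p1", start=5, end=30)
        report = mask_primers([frag], [forward_primer], method="amplicon")
        # R1 (+ strand) originates from the + primer: bases over [5,15) -> BQ 0
        assert list(frag.r1.query_qualities[:10]) == [0] * 10
        assert all(q > 0 for q in frag.r1.query_qualities[10:])
        assert report.originating_primers("p1", "R1") == {"fwd"}

    def test_buffer_distinguishes_amplicon_from_race(self, pair_builder, forward_primer):
        # read starts 10 nt upstream of the primer 5' end
        for method, masked in (("amplicon", True), ("race_like", False)):
            frag = pair_builder("p1", start=0, end=30)
            mask_primers([frag], [forward_primer], method=method)
            r1_masked = any(q == 0 for q in frag.r1.query_qualities)
            assert r1_masked is masked  # 10 <= 15 buffer, 10 > 3 buffer

    def test_readthrough_read_never_masked(self, pair_builder, toy_ref):
        """A read whose 5' end lies downstream of the primer span (readthrough
        coverage from an adjacent tile) is not masked over that primer."""
        primer = PrimerInterval(toy_ref.transcript_id, 0, 10, "+", "tile_F")
        # + strand read starting 20 nt downstream of the primer 5' end
        frag = pair_builder("p1", start=20, end=42)
        report = mask_primers([frag], [primer], method="amplicon")
        assert all(q > 0 for q in frag.r1.query_qualities)
        assert not report.segments

    def test_opposite_strand_three_prime_stop_masked(self, pair_builder, toy_ref):
        """Criterion 2: a + strand read whose 3' end stops inside a - strand
        primer (the opposite end of the amplicon) is masked over it."""
        rev_primer = PrimerInterval(toy_ref.transcript_id, 32, 42, "-", "rev")
        frag = pair_builder("p1", start=0, end=42)
        mask_primers([frag], [rev_primer], method="amplicon")
        assert list(frag.r1.query_qualities[32:]) == [0] * 10
        assert all(q > 0 for q in frag.r1.query_qualities[:32])

    def test_masking_changes_no_base_calls_and_is_lossless(
        self, pair_builder, forward_primer
    ):
        frag = pair_builder("p1", start=5, end=30)
        seq_before = frag.r1.query_sequence
        quals_before = list(frag.r1.query_qualities)
        report = mask_primers([frag], [forward_primer], method="amplicon")
        assert frag.r1.query_sequence == seq_before
        unmask([frag], report)
        assert list(frag.r1.query_qualities) == quals_before

    def test_empty_primer_list_is_noop(self, pair_builder):
        frag = pair_builder("p1")
        report = mask_primers([frag], [], method="amplicon")
        assert not report.segments
        assert all(q > 0 for q in frag.r1.query_qualities)

    def test_missing_qualities_error(self, pair_builder, forward_primer):
        frag = pair_builder("p1", start=5, end=30)
        frag.r1.query_qualities = None
        with pytest.raises(ValueError, match="base qualities"):
            mask_primers([frag], [forward_primer], method="amplicon")


def make_umi_fragments(pair_builder, spec):
    """spec: {umi: count}; all fragments share R1 position 0."""
    frags = []
    for umi, count in spec.items():
        for i in range(count):
            frags.append(pair_builder(f"{umi}read{i}_{umi}"))
    return frags


class TestDirectionalAdjacency:
    def test_single_umi_single_group(self, pair_builder):
        frags = make_umi_fragments(pair_builder, {"AAAA": 7})
        groups = group_umis_directional(frags)
        assert len(groups) == 1
        assert groups[0].size == 7

    def test_count_10_vs_3_merges(self, pair_builder):
        # 10 >= 2*3 - 1: AAAT is absorbed into AAAA's group
        frags = make_umi_fragments(pair_builder, {"AAAA": 10, "AAAT": 3})
        groups = group_umis_directional(frags)
        assert len(groups) == 1
        assert groups[0].umi == "AAAA"
        assert groups[0].size == 13

    def test_count_10_vs_6_stays_separate(self, pair_builder):
        # 10 < 2*6 - 1: two distinct molecules
        frags = make_umi_fragments(pair_builder, {"AAAA": 10, "AAAT": 6})
        groups = group_umis_directional(frags)
        assert sorted(g.size for g in groups) == [6, 10]

    def test_distinct_r1_positions_never_group(self, pair_builder):
        frags = [
            pair_builder("a_AAAA", start=0),
            pair_builder("b_AAAA", start=1, end=42),
        ]
        groups = group_umis_directional(frags)
        assert len(groups) == 2

    def test_grouping_invariant_to_input_order(self, pair_builder):
        frags = make_umi_fragments(
            pair_builder, {"AAAA": 5, "AAAT": 2, "GGGG": 4, "GGGT": 4}
        )
        forward = group_umis_directional(frags)
        backward = group_umis_directional(list(reversed(frags)))
        key = lambda gs: sorted((g.umi, tuple(g.members)) for g in gs)
        assert key(forward) == key(backward)

    def test_hamming_distance_two_never_linked(self, pair_builder):
        frags = make_umi_fragments(pair_builder, {"AAAA": 10, "AATT": 1})
        groups = group_umis_directional(frags)
        assert len(groups) == 2


class TestConsensusDedup:
    def grouped(self, frags):
        return [
            UmiGroup("G0", "AAAA", 0, [f.name for f in frags]),
        ]

    def test_strict_majority_wins(self, pair_builder, toy_ref):
        frags = [
            pair_builder("a", both_muts={12: "A"}),
            pair_builder("b", both_muts={12: "A"}),
            pair_builder("c", both_muts={12: "G"}),
        ]
        out = consensus_deduplicate(self.grouped(frags), frags, toy_ref, seed=0)
        assert len(out) == 1
        assert out[0].r1.query_sequence[12] == "A"

    def test_two_way_tie_prefers_reference(self, pair_builder, toy_ref):
        # ref base at 0-based 12 is A; duplicates call A and G
        frags = [pair_builder("a"), pair_builder("b", both_muts={12: "G"})]
        out = consensus_deduplicate(self.grouped(frags), frags, toy_ref, seed=0)
        assert out[0].r1.query_sequence[12] == "A"

    def test_tie_without_reference_uses_higher_bq(self, pair_builder, toy_ref):
        frags = [
            pair_builder("a", both_muts={12: "C"}, r1_qual_at={12: 30}, r2_qual_at={12: 30}),
            pair_builder("b", both_muts={12: "G"}, r1_qual_at={12: 20}, r2_qual_at={12: 20}),
        ]
        out = consensus_deduplicate(self.grouped(frags), frags, toy_ref, seed=0)
        assert out[0].r1.query_sequence[12] == "C"

    def test_tie_final_fallback_is_seeded_random(self, pair_builder, toy_ref):
        frags = [
            pair_builder("a", both_muts={12: "C"}),
            pair_builder("b", both_muts={12: "G"}),
        ]
        picks = {
            consensus_deduplicate(self.grouped(frags), frags, toy_ref, seed=s)[0]
            .r1.query_sequence[12]
            for s in range(20)
        }
        assert picks <= {"C", "G"}
        assert len(picks) == 2  # both outcomes reachable across seeds
        one = consensus_deduplicate(self.grouped(frags), frags, toy_ref, seed=5)
        two = consensus_deduplicate(self.grouped(frags), frags, toy_ref, seed=5)
        assert one[0].r1.query_sequence == two[0].r1.query_sequence

    def test_consensus_bq_is_max_of_supporting(self, pair_builder, toy_ref):
        frags = [
            pair_builder("a", both_muts={12: "A"}, r1_qual_at={12: 20}),
            pair_builder("b", both_muts={12: "A"}, r1_qual_at={12: 35}),
            pair_builder("c", both_muts={12: "G"}, r1_qual_at={12: 41}),
        ]
        out = consensus_deduplicate(self.grouped(frags), frags, toy_ref, seed=0)
        assert out[0].r1.query_qualities[12] == 35  # max over A-supporting only

    def test_singleton_group_passes_through_unchanged(self, pair_builder, toy_ref):
        frag = pair_builder("solo", both_muts={12: "G"})
        out = consensus_deduplicate(
            [UmiGroup("G0", "AAAA", 0, ["solo"])], [frag], toy_ref, seed=0
        )
        assert out[0] is frag

    def test_dedup_count_equals_group_count(self, pair_builder, toy_ref):
        frags = make_umi_fragments(pair_builder, {"AAAA": 4, "CCCC": 3, "GGGG": 1})
        deduped, groups = preprocess.deduplicate(frags, toy_ref, seed=0)
        assert len(deduped) == len(groups) == 3
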