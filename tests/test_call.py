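"""Concordant mismatch enumeration, MNP merging, aggregation, coverage."""

import itertools

import numpy as np
import pytest

from conftest import oracle_calls, oracle_merge_positions
from mavecall.call import (
    CallFilters,
    MismatchObservation,
    call_fragments,
    compute_fragment_coverage,
    depth_at,
    enumerate_concordant_mismatches,
    merge_mnps,
)

LOOSE = CallFilters(min_count=1, min_bq=0, max_nm=10)


def obs_at(positions_bases, refseq, fragment_id="f0"):
    return [
        MismatchObservation(
            ref_pos=p, ref_base=refseq[p], alt_base=b, r1_bq=37, r2_bq=37,
            r1_read_pos=p, r2_read_pos=p, r1_nm=1, r2_nm=1, fragment_id=fragment_id,
        )
        for p, b in positions_bases
    ]


class TestConcordance:
    def test_perfect_pair_yields_nothing(self, pair_builder, toy_ref):
        assert enumerate_concordant_mismatches(pair_builder("f"), toy_ref, LOOSE) == []

    def test_single_mate_mismatch_is_discordant(self, pair_builder, toy_ref):
        frag = pair_builder("f", r1_muts={12: "G"})
        assert enumerate_concordant_mismatches(frag, toy_ref, LOOSE) == []

    def test_mates_disagreeing_on_alt_base_yield_nothing(self, pair_builder, toy_ref):
        frag = pair_builder("f", r1_muts={12: "G"}, r2_muts={12: "C"})
        assert enumerate_concordant_mismatches(frag, toy_ref, LOOSE) == []

    def test_concordant_mismatch_with_features(self, pair_builder, toy_ref):
        filters = CallFilters(min_count=1, min_bq=30, max_nm=10)
        frag = pair_builder("f", both_muts={12: "G"},
                            r1_qual_at={12: 35}, r2_qual_at={12: 33})
        (obs,) = enumerate_concordant_mismatches(frag, toy_ref, filters)
        assert (obs.ref_pos, obs.ref_base, obs.alt_base) == (12, "A", "G")
        assert (obs.r1_bq, obs.r2_bq) == (35, 33)
        assert obs.r1_nm == obs.r2_nm == 1

    def test_low_bq_on_either_mate_filters(self, pair_builder, toy_ref):
        filters = CallFilters(min_count=1, min_bq=30, max_nm=10)
        frag = pair_builder("f", both_muts={12: "G"}, r2_qual_at={12: 29})
        assert enumerate_concordant_mismatches(frag, toy_ref, filters) == []

    def test_high_nm_discards_whole_pair(self, pair_builder, toy_ref):
        filters = CallFilters(min_count=1, min_bq=0, max_nm=2)
        muts = {6: "C", 12: "G", 18: "A"}  # NM 3 > 2
        frag = pair_builder("f", both_muts=muts)
        assert enumerate_concordant_mismatches(frag, toy_ref, filters) == []

    def test_masked_bases_never_participate(self, pair_builder, toy_ref):
        frag = pair_builder("f", both_muts={12: "G"}, r1_qual_at={12: 0})
        assert enumerate_concordant_mismatches(frag, toy_ref, LOOSE) == []

    def test_non_overlapping_region_uncallable(self, pair_builder, toy_ref):
        frag = pair_builder("f", r1_span=(0, 20), r2_span=(20, 42),
                            r1_muts={12: "G"}, r2_muts={30: "A"})
        assert enumerate_concordant_mismatches(frag, toy_ref, LOOSE) == []

    def test_n_base_never_called(self, pair_builder, toy_ref):
        frag = pair_builder("f", both_muts={12: "N"})
        assert enumerate_concordant_mismatches(frag, toy_ref, LOOSE) == []


class TestMergeMnps:
    def test_span_three_merges_with_reference_gap_base(self, toy_ref):
        refseq = toy_ref.sequence
        obs = obs_at([(5, "G"), (7, "A")], refseq)  # span 3, gap at 6
        (comp,) = merge_mnps(obs, refseq)
        assert comp.start0 == 5
        assert comp.ref_allele == refseq[5:8]
        assert comp.alt_allele == "G" + refseq[6] + "A"

    def test_span_five_stays_two_snps(self, toy_ref):
        obs = obs_at([(5, "G"), (9, "A")], toy_ref.sequence)
        comps = merge_mnps(obs, toy_ref.sequence)
        assert [(c.start0, c.alt_allele) for c in comps] == [(5, "G"), (9, "A")]

    def test_three_adjacent_mismatches_one_tri_mnp(self, toy_ref):
        obs = obs_at([(5, "G"), (6, "T"), (7, "A")], toy_ref.sequence)
        (comp,) = merge_mnps(obs, toy_ref.sequence)
        assert comp.alt_allele == "GTA"
        assert len(comp.observations) == 3

    def test_exhaustive_against_recursive_oracle(self, toy_ref):
        """All mismatch placements of up to 4 mismatches in a 10-nt window
        produce exactly the oracle's leftmost-maximal <=3-nt components."""
        refseq = toy_ref.sequence
        for k in range(1, 5):
            for positions in itertools.combinations(range(10), k):
                alts = [
                    "A" if refseq[p] != "A" else "C" for p in positions
                ]
                obs = obs_at(list(zip(positions, alts)), refseq)
                comps = merge_mnps(obs, refseq)
                expected = oracle_merge_positions(list(positions))
                assert [
                    [o.ref_pos for o in c.observations] for c in comps
                ] == expected
                for comp in comps:
                    assert len(comp.ref_allele) <= 3  # span cap, always


class TestCoverage:
    def test_fragment_counted_once_despite_two_mates(self, pair_builder, toy_ref):
        track = compute_fragment_coverage([pair_builder("f")], toy_ref)
        assert track == [(toy_ref.transcript_id, 0, 42, 1)]

    def test_tiled_pairs_give_stepped_track(self, pair_builder, toy_ref):
        frags = [
            pair_builder("a", start=0, end=30),
            pair_builder("b", start=15, end=42),
        ]
        track = compute_fragment_coverage(frags, toy_ref)
        tid = toy_ref.transcript_id
        assert track == [(tid, 0, 15, 1), (tid, 15, 30, 2), (tid, 30, 42, 1)]

    def test_masked_span_has_zero_depth(self, pair_builder, toy_ref):
        frag = pair_builder("f")
        for mate in (frag.r1, frag.r2):
            quals = list(mate.query_qualities)
            quals[:20] = [0] * 20
            mate.query_qualities = quals
        track = compute_fragment_coverage([frag], toy_ref)
        assert track == [(toy_ref.transcript_id, 20, 42, 1)]

    def test_depth_width_conservation(self, pair_builder, toy_ref):
        frags = [
            pair_builder("a", start=0, end=30),
            pair_builder("b", start=10, end=42),
            pair_builder("c", start=5, end=25),
        ]
        track = compute_fragment_coverage(frags, toy_ref)
        total = sum((e - s) * d for _, s, e, d in track)
        covered_bases = sum(len(f.covered_positions(toy_ref.sequence)) for f in frags)
        assert total == covered_bases


class TestAggregation:
    def test_min_count_threshold_drops_singletons(self, pair_builder, toy_ref):
        frags = [pair_builder("a", both_muts={12: "G"}), pair_builder("b")]
        calls, _ = call_fragments(frags, toy_ref, CallFilters(min_count=2, min_bq=0))
        assert calls == []
        calls, _ = call_fragments(frags, toy_ref, CallFilters(min_count=1, min_bq=0))
        assert len(calls) == 1

    def test_frequency_is_count_over_fragment_coverage(self, pair_builder, toy_ref):
        frags = [pair_builder(f"v{i}", both_muts={12: "G"}) for i in range(2)]
        frags += [pair_builder(f"b{i}") for i in range(18)]
        (call,), _ = call_fragments(frags, toy_ref, CallFilters(min_count=2, min_bq=0))
        assert call.supporting_count == 2
        assert call.fragment_coverage == 20
        assert call.frequency == pytest.approx(0.1)

    def test_snp_and_containing_mnp_are_distinct_alleles(self, pair_builder, toy_ref):
        frags = [pair_builder(f"s{i}", both_muts={12: "G"}) for i in range(3)]
        frags.append(pair_builder("m", both_muts={12: "G", 13: "C"}))
        calls, _ = call_fragments(frags, toy_ref, CallFilters(min_count=1, min_bq=0))
        by_key = {c.key: c.supporting_count for c in calls}
        assert by_key[(13, "A", "G")] == 3
        assert by_key[(13, "AA", "GC")] == 1

    def test_supporting_count_matches_fragment_ids(self, pair_builder, toy_ref):
        frags = [pair_builder(f"v{i}", both_muts={12: "G"}) for i in range(4)]
        (call,), _ = call_fragments(frags, toy_ref, CallFilters(min_count=2, min_bq=0))
        assert call.supporting_count == len(set(call.fragment_ids)) == 4

    def test_median_features_use_lower_median(self, pair_builder, toy_ref):
        quals = [31, 33, 35, 41]
        frags = [
            pair_builder(f"v{i}", both_muts={12: "G"}, r1_qual_at={12: q})
            for i, q in enumerate(quals)
        ]
        (call,), _ = call_fragments(frags, toy_ref, CallFilters(min_count=2, min_bq=0))
        assert call.summaries["R1BQ"] == 33  # lower middle of even count


class TestOracleEquivalence:
    @pytest.mark.parametrize("trial", range(12))
    def test_random_toy_sets_match_brute_force(self, pair_builder, toy_ref, trial):
        """On random <=20-pair toy sets with concordant/discordant/low-BQ/
        high-NM reads, the caller reproduces the brute-force oracle."""
        rng = np.random.default_rng(100 + trial)
        filters = CallFilters(min_count=max(1, trial % 3), min_bq=30, max_nm=3)
        frags = []
        for i in range(int(rng.integers(3, 21))):
            n_mut = int(rng.integers(0, 5))
            positions = rng.choice(np.arange(2, 40), size=n_mut, replace=False)
            both, r1_only = {}, {}
            qual_overrides = {}
            for p in positions:
                p = int(p)
                base = "ACGT"[int(rng.integers(0, 4))]
                if base == toy_ref.sequence[p]:
                    continue
                if rng.random() < 0.75:
                    both[p] = base
                else:
                    r1_only[p] = base
                if rng.random() < 0.2:
                    qual_overrides[p] = int(rng.integers(0, 31))
            frags.append(
                pair_builder(
                    f"t{trial}f{i}", both_muts=both, r1_muts=r1_only,
                    r1_qual_at=qual_overrides,
                )
            )
        calls, _ = call_fragments(frags, toy_ref, filters)
        got = {c.key: c.supporting_count for c in calls}
        expected = oracle_calls(
            frags, toy_ref.sequence, filters.min_bq, filters.max_nm, filters.min_count
        )
        assert got == expected
        # uniqueness + span cap on everything reported
        assert len(got) == len(set(got))
        assert all(len(ref) <= 3 for (_, ref, _) in got)


def test_depth_at_outside_track_is_zero(toy_ref):
    assert depth_at([(toy_ref.transcript_id, 0, 10, 5)], 15) == 0
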