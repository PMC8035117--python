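import math

import pytest
from hypothesis import given, settings, strategies as st

from procliq.patterns import ActionPattern
from procliq.similarity import (
    LCSAlignment,
    compute_lcs,
    importance,
    pairwise_similarities,
    read_edge_list,
    sim_timing_modified,
    sim_timing_original,
    similarity,
    write_edge_list,
)

from conftest import lcs_length_oracle

seqs = st.lists(
    st.sampled_from("ABCD"), min_size=1, max_size=8
).map(tuple)

pattern_st = st.builds(
    lambda actions, times: ActionPattern(
        "x", actions, tuple(times[: len(actions)])
    ),
    seqs,
    st.lists(
        st.floats(min_value=0.01, max_value=100.0, allow_nan=False),
        min_size=8,
        max_size=8,
    ),
)


class TestComputeLCS:
    def test_worked_example_alignment(self, p1_p2):
        p1, p2 = p1_p2
        al = compute_lcs(p1.actions, p2.actions)
        assert al.lcs == ("A", "B", "C")
        assert al.map_i == (0, 1, 2)
        assert al.map_j == (0, 2, 4)

    def test_identical_sequences_self_align(self):
        al = compute_lcs(("A", "B", "A"), ("A", "B", "A"))
        assert al.lcs == ("A", "B", "A")
        assert al.map_i == al.map_j == (0, 1, 2)

    def test_disjoint_alphabets_empty(self):
        assert len(compute_lcs(("A", "B"), ("C", "D"))) == 0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            compute_lcs((), ("A",))

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(a=seqs, b=seqs)
    def test_length_matches_exhaustive_oracle(self, a, b):
        """DP length equals the brute-force maximum over all subsequences."""
        al = compute_lcs(a, b)
        assert len(al) == lcs_length_oracle(a, b)

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(a=seqs, b=seqs)
    def test_index_maps_valid(self, a, b):
        al = compute_lcs(a, b)
        assert all(
            a[x] == b[y] == s
            for x, y, s in zip(al.map_i, al.map_j, al.lcs)
        )
        assert list(al.map_i) == sorted(set(al.map_i))
        assert list(al.map_j) == sorted(set(al.map_j))


class TestTimingMeasures:
    def test_worked_example_original(self, p1_p2):
        p1, p2 = p1_p2
        al = compute_lcs(p1.actions, p2.actions)
        val = sim_timing_original(al, p1.times, p2.times)
        assert val == pytest.approx((1 / 1.5 + 1.5 / 2 + 1.0) / 3)
        assert round(val, 3) == 0.806  # paper truncates to 0.805

    def test_equal_times_give_one(self):
        al = compute_lcs(("A", "B"), ("A", "B"))
        assert sim_timing_original(al, (1.0, 2.0), (1.0, 2.0)) == 1.0
        assert sim_timing_modified(al, (1.0, 2.0), (1.0, 2.0)) == 1.0

    def test_both_zero_policy(self):
        al = compute_lcs(("A", "B"), ("A", "B"))
        assert sim_timing_original(al, (0.0, 1.0), (0.0, 2.0)) == \
            pytest.approx((1 + 0.5) / 2)
        assert sim_timing_modified(al, (0.0, 0.0), (0.0, 0.0)) == 1.0

    def test_modified_is_minmax_of_sums(self):
        al = compute_lcs(("A", "B"), ("A", "B"))
        assert sim_timing_modified(al, (1.0, 1.0), (4.0, 4.0)) == 0.25
        assert sim_timing_modified(al, (2.0, 3.0), (3.0, 3.0)) == \
            pytest.approx(5 / 6)

    def test_empty_alignment_errors(self):
        empty = LCSAlignment((), (), ())
        with pytest.raises(ValueError):
            sim_timing_original(empty, (), ())
        with pytest.raises(ValueError):
            sim_timing_modified(empty, (), ())

    def test_original_equals_modified_under_proportional_times(self):
        """Both timing measures reduce to min(c, 1/c) when t_j = c * t_i."""
        al = compute_lcs(("A", "B", "C"), ("A", "B", "C"))
        t = (1.0, 2.5, 0.5)
        for c in (1.0, 2.0):
            tc = tuple(c * x for x in t)
            orig = sim_timing_original(al, t, tc)
            mod = sim_timing_modified(al, t, tc)
            assert orig == pytest.approx(mod) == pytest.approx(min(c, 1 / c))


class TestImportance:
    def test_worked_example(self, p1_p2):
        p1, p2 = p1_p2
        al = compute_lcs(p1.actions, p2.actions)
        assert importance(al, p1, p2) == pytest.approx(math.sqrt(5 / 7))
        assert round(importance(al, p1, p2), 3) == 0.845

    def test_full_coverage_gives_one(self):
        p = ActionPattern("p", ("A", "B"), (1.0, 2.0))
        q = ActionPattern("q", ("A", "B"), (3.0, 4.0))
        al = compute_lcs(p.actions, q.actions)
        assert importance(al, p, q) == 1.0

    def test_empty_alignment_gives_zero(self):
        p = ActionPattern("p", ("A",), (1.0,))
        q = ActionPattern("q", ("B",), (1.0,))
        al = compute_lcs(p.actions, q.actions)
        assert importance(al, p, q) == 0.0

    def test_zero_total_time_errors(self):
        p = ActionPattern("p", ("A",), (0.0,))
        q = ActionPattern("q", ("A",), (1.0,))
        al = compute_lcs(p.actions, q.actions)
        with pytest.raises(ValueError):
            importance(al, p, q)


class TestSimilarity:
    def test_worked_example_all_kinds(self, p1_p2):
        p1, p2 = p1_p2
        assert round(similarity(p1, p2, "original"), 3) == 0.681
        assert round(similarity(p1, p2, "modified"), 3) == 0.704
        assert similarity(p1, p2, "action_only") == \
            pytest.approx(math.sqrt(3 / 5))

    @pytest.mark.parametrize("kind", ["original", "modified", "action_only"])
    def test_self_similarity_is_exactly_one(self, kind, p1_p2):
        for p in p1_p2:
            assert similarity(p, p, kind) == 1.0

    def test_disjoint_patterns_zero(self):
        p = ActionPattern("p", ("A",), (1.0,))
        q = ActionPattern("q", ("B",), (1.0,))
        for kind in ("original", "modified", "action_only"):
            assert similarity(p, q, kind) == 0.0

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(p=pattern_st, q=pattern_st)
    @pytest.mark.parametrize("kind", ["original", "modified", "action_only"])
    def test_range_and_symmetry(self, kind, p, q):
        s = similarity(p, q, kind)
        assert 0.0 <= s <= 1.0
        assert similarity(q, p, kind) == pytest.approx(s, abs=1e-12)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(p=pattern_st, q=pattern_st, c=st.floats(0.1, 10.0))
    @pytest.mark.parametrize("kind", ["original", "modified", "action_only"])
    def test_scale_invariance(self, kind, p, q, c):
        """Rescaling both patterns' times by a common factor changes nothing."""
        ps = ActionPattern(p.person_id, p.actions, tuple(c * t for t in p.times))
        qs = ActionPattern(q.person_id, q.actions, tuple(c * t for t in q.times))
        assert similarity(ps, qs, kind) == \
            pytest.approx(similarity(p, q, kind), abs=1e-9)


class TestEdgeList:
    def test_pairwise_covers_each_unordered_pair_once(self, p1_p2):
        p1, p2 = p1_p2
        p3 = ActionPattern("3", ("A", "C"), (1.0, 1.0))
        df = pairwise_similarities([p1, p2, p3], "modified")
        assert len(df) == 3
        assert set(map(frozenset, zip(df["i"], df["j"]))) == {
            frozenset({"1", "2"}), frozenset({"1", "3"}), frozenset({"2", "3"})
        }

    def test_duplicate_ids_rejected(self, p1_p2):
        p1, _ = p1_p2
        with pytest.raises(ValueError):
            pairwise_similarities([p1, p1])

    def test_tsv_round_trip_preserves_measure(self, tmp_path, p1_p2):
        df = pairwise_similarities(list(p1_p2), "original")
        path = tmp_path / "edges.tsv"
        write_edge_list(df, path)
        back = read_edge_list(path)
        assert back.attrs["measure"] == "original"
        assert back["s"].tolist() == pytest.approx(df["s"].tolist())
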