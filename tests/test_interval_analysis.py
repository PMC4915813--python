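import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chromregime.io_formats import GeneAnnotation, GenomicInterval, ReadTag
from chromregime.interval_analysis import (
    assign_targets,
    intersect_any,
    overlap_summary,
    promoter_counts,
    select_promoter,
    tss_windows,
)
from oracles import brute_force_intersections


def iv(start, end, chrom="c", name=""):
    return GenomicInterval(chrom, start, end, ".", 0.0, name)


class TestIntersectAny:
    def test_single_base_overlap_counts(self):
        assert intersect_any([iv(0, 100)], [iv(99, 150)])[0]

    def test_abutting_intervals_do_not_overlap(self):
        assert not intersect_any([iv(0, 100)], [iv(100, 150)])[0]

    def test_empty_query_set_gives_all_false(self):
        assert not intersect_any([iv(0, 100), iv(5, 9)], []).any()

    def test_chromosomes_are_respected(self):
        assert not intersect_any([iv(0, 100, "c1")], [iv(0, 100, "c2")])[0]

    interval_lists = st.lists(
        st.tuples(
            st.sampled_from(["c1", "c2"]), st.integers(0, 300), st.integers(1, 50)
        ),
        min_size=0,
        max_size=200,
    )

    @given(a=interval_lists, b=interval_lists)
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_sweep_equals_brute_force(self, a, b):
        a = [iv(s, s + w, c) for c, s, w in a]
        b = [iv(s, s + w, c) for c, s, w in b]
        assert np.array_equal(intersect_any(a, b), brute_force_intersections(a, b))


class TestOverlapSummary:
    def test_worked_example(self):
        a = [iv(0, 100), iv(200, 300), iv(400, 500)]
        b = [iv(90, 110), iv(450, 460)]
        summary = overlap_summary(a, b)
        assert summary.n_a_overlapping == 2 and summary.n_b_overlapping == 2
        assert summary.pct_a == pytest.approx(66.7, abs=0.05)
        assert summary.pct_b == pytest.approx(100.0)

    def test_identical_sets_fully_overlap(self):
        a = [iv(0, 10), iv(50, 60)]
        summary = overlap_summary(a, list(a))
        assert summary.pct_a == 100.0 and summary.pct_b == 100.0

    def test_disjoint_sets(self):
        summary = overlap_summary([iv(0, 10)], [iv(20, 30)])
        assert summary.pct_a == 0.0 and summary.pct_b == 0.0

    def test_empty_set_error_names_the_set(self):
        with pytest.raises(ValueError, match="lhs"):
            overlap_summary([], [iv(0, 10)], name_a="lhs")

    def test_invariant_under_shuffling(self):
        rng = np.random.default_rng(8)
        a = [iv(int(s), int(s) + 10) for s in rng.integers(0, 500, 30)]
        b = [iv(int(s), int(s) + 10) for s in rng.integers(0, 500, 30)]
        ref = overlap_summary(a, b)
        perm = list(rng.permutation(len(a)))
        shuffled = overlap_summary([a[i] for i in perm], b)
        assert shuffled.n_a_overlapping == ref.n_a_overlapping


def annotation(rows):
    return GeneAnnotation(
        pd.DataFrame(rows, columns=["gene_id", "chrom", "tss", "strand"])
    )


class TestTssWindows:
    def test_inclusive_flank(self):
        (w,) = tss_windows(annotation([("g", "c", 5_000, "+")]), flank=1500)
        assert (w.start, w.end) == (3_500, 6_501)
        assert w.name == "g"

    def test_clamped_at_chromosome_start(self):
        (w,) = tss_windows(annotation([("g", "c", 1_000, "+")]), flank=1500)
        assert (w.start, w.end) == (0, 2_501)

    def test_zero_flank_is_single_base(self):
        (w,) = tss_windows(annotation([("g", "c", 42, "-")]), flank=0)
        assert (w.start, w.end) == (42, 43)

    def test_strand_does_not_change_geometry(self):
        plus = tss_windows(annotation([("g", "c", 5_000, "+")]))
        minus = tss_windows(annotation([("g", "c", 5_000, "-")]))
        assert (plus[0].start, plus[0].end) == (minus[0].start, minus[0].end)


class TestAssignTargets:
    def test_boundary_peak_at_plus_1500_hits(self):
        windows = tss_windows(annotation([("g", "c", 5_000, "+")]))
        hits, _ = assign_targets([iv(6_500, 6_600, name="p")], windows)
        assert hits == {"g"}

    def test_boundary_peak_at_plus_1501_misses(self):
        windows = tss_windows(annotation([("g", "c", 5_000, "+")]))
        hits, _ = assign_targets([iv(6_501, 6_600)], windows)
        assert hits == set()

    def test_no_peaks_gives_empty_set(self):
        windows = tss_windows(annotation([("g", "c", 5_000, "+")]))
        assert assign_targets([], windows)[0] == set()

    def test_matches_brute_force_on_toy_annotation(self):
        rng = np.random.default_rng(4)
        rows = [(f"g{i}", "c", int(t), "+")
                for i, t in enumerate(rng.integers(2_000, 50_000, 30))]
        windows = tss_windows(annotation(rows), flank=1500)
        peaks = [iv(int(s), int(s) + 300, name=f"p{j}")
                 for j, s in enumerate(rng.integers(0, 52_000, 25))]
        hits, support = assign_targets(peaks, windows)
        expected = {
            g for (g, _, t, _) in rows
            if any(p.start < t + 1501 and max(t - 1500, 0) < p.end for p in peaks)
        }
        assert hits == expected
        assert set(support) == expected

    def test_monotone_under_added_peaks(self):
        rows = [("g1", "c", 5_000, "+"), ("g2", "c", 9_000, "-")]
        windows = tss_windows(annotation(rows))
        base, _ = assign_targets([iv(5_100, 5_200)], windows)
        grown, _ = assign_targets([iv(5_100, 5_200), iv(9_000, 9_100)], windows)
        assert base <= grown

    def test_any_tss_window_suffices_for_multi_tss_gene(self):
        rows = [("g", "c", 5_000, "+"), ("g", "c", 50_000, "+")]
        windows = tss_windows(annotation(rows))
        hits, _ = assign_targets([iv(50_100, 50_200)], windows)
        assert hits == {"g"}


class TestSelectPromoter:
    def test_argmax_per_gene(self):
        ann = annotation([("g", "c", 100, "+"), ("g", "c", 900, "+")])
        chosen = select_promoter(ann, [0.2, 0.7])
        assert chosen["tss"].iloc[0] == 900

    def test_single_tss_gene(self):
        ann = annotation([("g", "c", 100, "+")])
        assert select_promoter(ann, [0.3])["tss"].iloc[0] == 100

    def test_tie_goes_to_smaller_coordinate(self):
        ann = annotation([("g", "c", 900, "+"), ("g", "c", 100, "+")])
        chosen = select_promoter(ann, [0.5, 0.5])
        assert chosen["tss"].iloc[0] == 100

    def test_unscored_tss_error_names_gene(self):
        ann = annotation([("gX", "c", 100, "+")])
        with pytest.raises(ValueError, match="gX"):
            select_promoter(ann, [np.nan])


class TestPromoterCounts:
    def test_direct_count(self):
        windows = [iv(1_000, 2_000, name="g")]
        chip = [ReadTag("c", p, "+") for p in (1_100, 1_500, 1_999, 2_000)]
        ctrl = [ReadTag("c", p, "+") for p in (1_000, 1_001)]
        frame = promoter_counts(chip, ctrl, windows)
        assert frame.loc[0, "s"] == 3 and frame.loc[0, "r"] == 2

    def test_empty_window(self):
        frame = promoter_counts([], [], [iv(0, 10, name="g")])
        assert (frame.loc[0, "s"], frame.loc[0, "r"]) == (0, 0)

    def test_overlapping_windows_count_independently(self):
        windows = [iv(0, 100, name="g1"), iv(50, 150, name="g2")]
        chip = [ReadTag("c", 75, "+")]
        frame = promoter_counts(chip, [], windows)
        assert list(frame["s"]) == [1, 1]
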