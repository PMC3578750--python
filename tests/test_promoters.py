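"""Tests of unique-TSS selection, promoter windows and timing summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from replitime import (
    find_unique_tss,
    make_promoter_windows,
    probes_in_promoter,
    summarize_promoter_timing,
)

from conftest import make_annotation, make_track


def brute_force_unique(annotation, max_dist=1000):
    """O(n^2) all-pairs oracle for the uniqueness filter."""
    keep = []
    for i, row in annotation.iterrows():
        alone = True
        for j, other in annotation.iterrows():
            if i == j:
                continue
            if row["chrom"] == other["chrom"] and abs(
                row["tss"] - other["tss"]
            ) <= max_dist:
                alone = False
                break
        keep.append(alone)
    kept = annotation[np.asarray(keep, dtype=bool)]
    return set(kept["gene_id"])


class TestFindUniqueTss:
    def test_single_tss_retained(self):
        out = find_unique_tss(make_annotation([10_000]))
        assert len(out) == 1

    def test_pair_within_window_both_removed(self):
        out = find_unique_tss(make_annotation([10_000, 10_900]))
        assert len(out) == 0

    def test_distant_triplet_all_retained(self):
        out = find_unique_tss(make_annotation([10_000, 11_200, 50_000]))
        assert len(out) == 3

    def test_boundary_distance_exactly_1000_disqualifies(self):
        out = find_unique_tss(make_annotation([10_000, 11_000]))
        assert len(out) == 0

    def test_duplicate_positions_mutually_disqualify(self):
        out = find_unique_tss(make_annotation([5_000, 5_000, 20_000]))
        assert list(out["tss"]) == [20_000]

    def test_same_position_different_chromosome_is_fine(self):
        annot = make_annotation([("chr1", 5_000), ("chr2", 5_000)])
        assert len(find_unique_tss(annot)) == 2

    def test_empty_annotation_gives_empty_result(self):
        out = find_unique_tss(make_annotation([]))
        assert len(out) == 0

    def test_result_independent_of_input_order(self, rng):
        pos = rng.integers(0, 100_000, size=60)
        annot = make_annotation(pos)
        shuffled = annot.sample(frac=1.0, random_state=4).reset_index(drop=True)
        a = find_unique_tss(annot)
        b = find_unique_tss(shuffled)
        pd.testing.assert_frame_equal(a, b)

    def test_idempotent(self, rng):
        annot = make_annotation(rng.integers(0, 50_000, size=80))
        once = find_unique_tss(annot)
        twice = find_unique_tss(once)
        pd.testing.assert_frame_equal(once, twice)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        positions=st.lists(
            st.integers(min_value=0, max_value=30_000), min_size=0, max_size=30
        )
    )
    def test_agrees_with_all_pairs_oracle(self, positions):
        annot = make_annotation(positions)
        out = find_unique_tss(annot)
        assert set(out["gene_id"]) == brute_force_unique(annot)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        positions=st.lists(
            st.integers(min_value=0, max_value=20_000),
            min_size=1,
            max_size=15,
            unique=True,
        ),
        extra=st.integers(min_value=50_000, max_value=80_000),
    )
    def test_far_tss_never_changes_existing_status(self, positions, extra):
        annot = make_annotation(positions)
        before = set(find_unique_tss(annot)["gene_id"])
        grown = make_annotation(positions + [extra])
        after = set(find_unique_tss(grown)["gene_id"])
        assert before == after - {f"g{len(positions) + 1:03d}"}

    def test_invalid_strand_raises(self):
        annot = make_annotation([1000])
        annot.loc[0, "strand"] = "*"
        with pytest.raises(ValueError, match="strand"):
            find_unique_tss(annot)


class TestMakePromoterWindows:
    def test_window_arithmetic(self):
        out = make_promoter_windows(make_annotation([10_000]))
        assert (out["start"].iloc[0], out["end"].iloc[0]) == (9_500, 10_500)

    def test_boundary_tss_at_500(self):
        out = make_promoter_windows(make_annotation([500]))
        assert (out["start"].iloc[0], out["end"].iloc[0]) == (0, 1_000)

    def test_tss_below_half_window_skipped_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            out = make_promoter_windows(make_annotation([499, 10_000]))
        assert len(out) == 1
        assert "skipping" in caplog.text

    def test_all_windows_are_1kb(self, rng):
        annot = make_annotation(rng.integers(500, 1_000_000, size=100))
        out = make_promoter_windows(annot)
        assert ((out["end"] - out["start"]) == 1000).all()
        assert ((out["tss"] >= out["start"]) & (out["tss"] < out["end"])).all()

    def test_window_symmetric_regardless_of_strand(self):
        plus = make_promoter_windows(make_annotation([10_000], strand="+"))
        minus = make_promoter_windows(make_annotation([10_000], strand="-"))
        assert plus["start"].iloc[0] == minus["start"].iloc[0]
        assert plus["end"].iloc[0] == minus["end"].iloc[0]


class TestProbesInPromoter:
    PROMOTER = {"chrom": "chr1", "start": 9_500, "end": 10_500}

    def test_probe_flush_with_start_included(self):
        track = make_track([(9_500, 9_536, 1.0)])
        assert len(probes_in_promoter(self.PROMOTER, track)) == 1

    def test_partially_overlapping_probe_excluded(self):
        track = make_track([(9_480, 9_516, 1.0), (10_490, 10_526, 2.0)])
        assert len(probes_in_promoter(self.PROMOTER, track)) == 0

    def test_other_chromosome_excluded(self):
        track = make_track([(9_600, 9_636, 1.0)], chrom="chr2")
        assert len(probes_in_promoter(self.PROMOTER, track)) == 0

    def test_matches_brute_force_on_random_track(self, rng):
        starts = rng.integers(9_000, 11_000, size=50)
        track = make_track([(s, s + 36, float(v)) for s, v in
                            zip(starts, rng.normal(size=50))])
        got = probes_in_promoter(self.PROMOTER, track)
        expected = [
            i
            for i, row in track.iterrows()
            if row["start"] >= 9_500 and row["end"] <= 10_500
        ]
        assert list(got.index) == expected


class TestSummarizePromoterTiming:
    def _promoters(self):
        return make_promoter_windows(make_annotation([10_000]))

    def _track_with_values(self, values, start=9_500, width=36, gap=40):
        return make_track(
            [(start + i * gap, start + i * gap + width, float(v))
             for i, v in enumerate(values)]
        )

    def test_constant_probes_give_constant_median(self):
        track = self._track_with_values([1.5] * 10)
        out = summarize_promoter_timing(self._promoters(), track)
        assert out["replication_timing"].iloc[0] == 1.5
        assert not out["discarded"].iloc[0]

    def test_median_of_eleven_values(self):
        track = self._track_with_values(range(1, 12))
        out = summarize_promoter_timing(self._promoters(), track)
        assert out["replication_timing"].iloc[0] == 6.0

    def test_even_count_averages_central_values(self):
        track = self._track_with_values(range(1, 13))
        out = summarize_promoter_timing(self._promoters(), track)
        assert out["replication_timing"].iloc[0] == 6.5

    def test_nine_probes_discards_promoter(self):
        track = self._track_with_values([1.0] * 9)
        out = summarize_promoter_timing(self._promoters(), track)
        assert out["discarded"].iloc[0]
        assert np.isnan(out["replication_timing"].iloc[0])

    def test_non_finite_probes_do_not_count(self):
        values = [1.0] * 9 + [np.nan]
        track = self._track_with_values(values)
        out = summarize_promoter_timing(self._promoters(), track)
        assert out["n_probes"].iloc[0] == 9
        assert out["discarded"].iloc[0]

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(perm_seed=st.integers(min_value=0, max_value=10_000))
    def test_median_is_permutation_invariant(self, perm_seed):
        values = list(np.random.default_rng(99).normal(size=15))
        track = self._track_with_values(values)
        shuffled = track.sample(frac=1.0, random_state=perm_seed).reset_index(
            drop=True
        )
        a = summarize_promoter_timing(self._promoters(), track)
        b = summarize_promoter_timing(self._promoters(), shuffled)
        assert a["replication_timing"].iloc[0] == pytest.approx(
            b["replication_timing"].iloc[0]
        )
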