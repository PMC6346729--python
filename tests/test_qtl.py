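import numpy as np
import pandas as pd
import pytest

from introscan.qtl import (
    TRAIT_GROUPS,
    circular_permutation_test,
    count_in_regions,
    dedup_and_peaks,
    exact_rotation_counts,
    filter_qtls,
    peak_window_indices,
)
from introscan.windows import GenomeLayout, window_grid


def qtl_frame(rows):
    return pd.DataFrame(
        rows, columns=["qtl_id", "trait", "trait_group", "method", "chrom", "start", "end"]
    )


LAYOUT = GenomeLayout(
    names=("SSC1", "SSC2", "X"), lengths=(2_000_000, 2_000_000, 1_000_000),
    autosome=(True, True, False),
)


class TestFilter:
    def test_two_stage_bookkeeping(self):
        records = qtl_frame(
            [
                ("q1", "t", "health", "association", "SSC1", 0, 500_000),
                ("q2", "t", "health", "linkage", "SSC1", 0, 10_000),
                ("q3", "t", "health", "association", "X", 0, 10_000),
                ("q4", "t", "health", "association", "SSC2", 0, 1_200_000),
                ("q5", "t", "health", "association", "chrUn", 0, 10_000),
            ]
        )
        kept, audit = filter_qtls(records, LAYOUT)
        assert kept["qtl_id"].tolist() == ["q1"]
        assert audit["n_dropped_linkage"] == 1
        assert audit["n_after_linkage"] == 4
        assert audit["n_dropped_location_or_span"] == 3
        assert audit["n_dropped_non_autosome"] == 2  # X and unknown chrUn
        assert audit["n_dropped_span"] == 1
        assert audit["n_input"] - audit["n_dropped_linkage"] - audit[
            "n_dropped_location_or_span"
        ] == audit["n_output"]

    def test_exactly_max_span_kept(self):
        records = qtl_frame(
            [("q1", "t", "health", "association", "SSC1", 0, 1_000_000)]
        )
        kept, _ = filter_qtls(records, LAYOUT)
        assert len(kept) == 1


class TestDedup:
    def test_same_group_same_interval_collapse(self):
        records = qtl_frame(
            [
                ("q1", "weaning weight", "reproduction", "association", "SSC1", 100, 300),
                ("q2", "litter size", "reproduction", "association", "SSC1", 100, 300),
            ]
        )
        deduped, audit = dedup_and_peaks(records)
        assert len(deduped) == 1
        assert audit["n_collapsed"] == 1

    def test_same_interval_different_groups_both_kept(self):
        records = qtl_frame(
            [
                ("q1", "t1", "reproduction", "association", "SSC1", 100, 300),
                ("q2", "t2", "health", "association", "SSC1", 100, 300),
            ]
        )
        deduped, audit = dedup_and_peaks(records)
        assert len(deduped) == 2
        assert audit["n_output_interval_key"] == 1  # group-agnostic tally reported too

    def test_peak_is_midpoint(self):
        records = qtl_frame([("q1", "t", "health", "association", "SSC1", 100, 300)])
        deduped, _ = dedup_and_peaks(records)
        assert deduped["peak"].iloc[0] == 200


class TestCountInRegions:
    def regions(self):
        return pd.DataFrame(
            {"chrom": ["SSC1", "SSC2"], "start": [100_000, 0], "end": [200_000, 50_000]}
        )

    def test_boundary_conventions(self):
        peaks = pd.DataFrame(
            {
                "chrom": ["SSC1", "SSC1", "SSC1"],
                "peak": [100_000, 199_999, 200_000],
                "trait_group": ["health"] * 3,
            }
        )
        counts = count_in_regions(peaks, self.regions())
        assert counts["all"] == 2  # start inclusive, end exclusive

    def test_matches_brute_force_double_loop(self):
        rng = np.random.default_rng(12)
        regions = pd.DataFrame(
            {
                "chrom": rng.choice(["SSC1", "SSC2"], 8),
                "start": np.sort(rng.choice(np.arange(0, 1_900_000, 100_000), 8, replace=False)),
            }
        )
        regions["end"] = regions["start"] + 50_000
        peaks = pd.DataFrame(
            {
                "chrom": rng.choice(["SSC1", "SSC2"], 300),
                "peak": rng.integers(0, 2_000_000, 300),
                "trait_group": rng.choice(TRAIT_GROUPS, 300),
            }
        )
        counts = count_in_regions(peaks, regions)
        brute = 0
        for _, p in peaks.iterrows():
            for _, r in regions.iterrows():
                if p["chrom"] == r["chrom"] and r["start"] <= p["peak"] < r["end"]:
                    brute += 1
                    break
        assert counts["all"] == brute
        assert sum(counts[g] for g in TRAIT_GROUPS) == counts["all"]


def small_layout(n_windows=10, size=50_000):
    return GenomeLayout(names=("SSC1",), lengths=(n_windows * size,))


def peaks_in_windows(window_ids, size=50_000, group="health"):
    return pd.DataFrame(
        {
            "chrom": "SSC1",
            "peak": [w * size + size // 2 for w in window_ids],
            "trait_group": group,
        }
    )


class TestPermutation:
    def test_all_windows_candidate_gives_p_one(self):
        layout = small_layout()
        grid = window_grid(layout)
        peaks = peaks_in_windows([0, 3, 7])
        res = circular_permutation_test(np.arange(10), peaks, grid, layout, n_perm=50, seed=1)
        assert res["all"].p_value == 1.0
        assert (res["all"].null_counts == res["all"].observed).all()

    def test_zero_peaks_gives_p_one(self):
        layout = small_layout()
        grid = window_grid(layout)
        peaks = peaks_in_windows([])
        res = circular_permutation_test(np.array([0, 1]), peaks, grid, layout, n_perm=20, seed=1)
        assert res["all"].observed == 0
        assert res["all"].p_value == 1.0

    def test_empty_candidate_set_undefined(self):
        layout = small_layout()
        grid = window_grid(layout)
        res = circular_permutation_test(
            np.array([], dtype=int), peaks_in_windows([1]), grid, layout, n_perm=10, seed=0
        )
        assert res["all"].p_value is None
        assert res["all"].reason == "empty candidate set"

    def test_invalid_n_perm_rejected(self):
        layout = small_layout()
        with pytest.raises(ValueError):
            circular_permutation_test(
                np.array([0]), peaks_in_windows([1]), window_grid(layout), layout, n_perm=0
            )

    def test_offset_zero_reproduces_observed_count(self):
        layout = small_layout()
        grid = window_grid(layout)
        peaks = peaks_in_windows([0, 1, 5])
        slots = np.array([0, 1])
        pw = peak_window_indices(peaks, grid, layout)
        hist = np.bincount(pw, minlength=10)
        counts = exact_rotation_counts(slots, hist)
        res = circular_permutation_test(slots, peaks, grid, layout, n_perm=100, seed=3)
        assert counts[0] == res["all"].observed == 2

    def test_monte_carlo_agrees_with_enumeration(self):
        # 10-window circle, candidates {0,1}, peaks in windows {0,1,5}
        layout = small_layout()
        grid = window_grid(layout)
        peaks = peaks_in_windows([0, 1, 5])
        slots = np.array([0, 1])
        pw = peak_window_indices(peaks, grid, layout)
        hist = np.bincount(pw, minlength=10)
        counts = exact_rotation_counts(slots, hist)
        observed = counts[0]
        exact_p = (counts[1:] >= observed).mean()  # identity offset excluded
        res = circular_permutation_test(slots, peaks, grid, layout, n_perm=10_000, seed=5)
        mc_p = res["all"].p_value
        bound = 3 * np.sqrt(exact_p * (1 - exact_p) / 10_000)
        assert abs(mc_p - exact_p) <= max(bound, 1e-12)

    def test_two_seeds_agree_within_monte_carlo_error(self):
        rng = np.random.default_rng(9)
        layout = small_layout(40)
        grid = window_grid(layout)
        peaks = peaks_in_windows(rng.choice(40, size=25).tolist())
        slots = np.array([2, 3, 17])
        r1 = circular_permutation_test(slots, peaks, grid, layout, n_perm=10_000, seed=1)
        r2 = circular_permutation_test(slots, peaks, grid, layout, n_perm=10_000, seed=2)
        p1, p2 = r1["all"].p_value, r2["all"].p_value
        se = np.sqrt(max(p1, 1e-4) * (1 - min(p1, 1 - 1e-4)) / 10_000)
        assert abs(p1 - p2) <= 6 * se

    def test_shared_offsets_across_scopes(self):
        # per-group null counts must sum to the all-traits null at every draw
        rng = np.random.default_rng(4)
        layout = small_layout(30)
        grid = window_grid(layout)
        peaks = pd.DataFrame(
            {
                "chrom": "SSC1",
                "peak": rng.integers(0, 30 * 50_000, 60),
                "trait_group": rng.choice(TRAIT_GROUPS, 60),
            }
        )
        res = circular_permutation_test(
            np.array([1, 2, 9]), peaks, grid, layout, n_perm=200, seed=7
        )
        total = sum(res[g].null_counts for g in TRAIT_GROUPS)
        np.testing.assert_array_equal(total, res["all"].null_counts)

    def test_non_autosomes_excluded_from_circle(self):
        layout = GenomeLayout(
            names=("SSC1", "X"), lengths=(500_000, 500_000), autosome=(True, False)
        )
        grid = window_grid(layout)
        peaks = peaks_in_windows([0])
        res = circular_permutation_test(
            np.array([0]), peaks, grid, layout, n_perm=50, seed=0
        )
        # circle has 10 autosomal windows; X windows are invalid candidates
        with pytest.raises(ValueError):
            circular_permutation_test(np.array([12]), peaks, grid, layout, n_perm=50, seed=0)
        assert res["all"].observed == 1
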