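"""Common-grid binning, frequency tables and bin grouping."""

import numpy as np
import pandas as pd
import pytest

from kna.grouping import (
    FrequencyTable,
    GridSpec,
    GroupAssignment,
    assemble_frequency_table,
    assign_localisation_groups,
    bin_localisations,
    build_grid,
    cluster_bins_hierarchical,
    filter_common_bins,
    nine_group_scheme,
)


class TestGrid:
    def test_single_image_range_split_into_equal_bins(self):
        coords = np.column_stack(
            [np.linspace(0, 5, 11), np.linspace(-1, 1, 11), np.linspace(-1, 1, 11)]
        )
        grid = build_grid([coords], n_bins=50)
        assert grid.mins[0] == 0.0 and grid.maxs[0] == 5.0
        width = (grid.maxs[0] - grid.mins[0]) / grid.n_bins
        assert width == pytest.approx(0.1)

    def test_pooled_range_over_images(self):
        a = np.array([[0.0, 0.0, 0.0], [1.0, 1.0, 1.0]])
        b = np.array([[2.0, 2.0, 2.0], [3.0, 3.0, 3.0]])
        grid = build_grid([a, b])
        assert grid.mins == (0.0, 0.0, 0.0)
        assert grid.maxs == (3.0, 3.0, 3.0)

    def test_interior_image_leaves_grid_unchanged(self):
        a = np.array([[0.0, -1.0, -1.0], [10.0, 1.0, 1.0]])
        inner = np.array([[5.0, 0.0, 0.0]])
        assert build_grid([a]) == build_grid([a, inner])

    def test_degenerate_axis_rejected(self):
        with pytest.raises(ValueError):
            build_grid([np.array([[0.0, 1.0, 0.0], [1.0, 1.0, 1.0]])])

    def test_value_at_axis_max_falls_in_last_bin(self):
        grid = GridSpec((0, 0, 0), (1, 1, 1), n_bins=10)
        assert grid.axis_index(0, np.array([1.0]))[0] == 9

    def test_flat_index_convention(self):
        grid = GridSpec((0, 0, 0), (1, 1, 1), n_bins=50)
        idx = grid.flat_index(np.array([0.0]), np.array([0.0]), np.array([0.0]))
        assert idx[0] == 0
        # one step along each axis
        w = 1 / 50
        idx = grid.flat_index(np.array([1.5 * w]), np.array([2.5 * w]), np.array([3.5 * w]))
        assert idx[0] == 1 * 2500 + 2 * 50 + 3


class TestBinning:
    def test_counts_conserve_localisations(self, rng):
        grid = GridSpec((0, -1, -1), (1, 1, 1), n_bins=10)
        coords = np.column_stack(
            [rng.uniform(0, 1, 500), rng.uniform(-1, 1, 500), rng.uniform(-1, 1, 500)]
        )
        counts, flat = bin_localisations(coords, grid)
        assert sum(counts.values()) == 500
        assert (flat >= 0).all()

    def test_manual_two_bin_assignment(self):
        grid = GridSpec((0, 0, 0), (1, 1, 1), n_bins=2)
        coords = np.array([[0.1, 0.1, 0.1], [0.9, 0.1, 0.1], [0.9, 0.9, 0.9]])
        counts, flat = bin_localisations(coords, grid)
        assert flat.tolist() == [0, 4, 7]
        assert counts == {0: 1, 4: 1, 7: 1}

    def test_nan_rows_get_sentinel_index(self):
        grid = GridSpec((0, 0, 0), (1, 1, 1), n_bins=2)
        counts, flat = bin_localisations(np.array([[np.nan, 0.5, 0.5]]), grid)
        assert flat.tolist() == [-1]
        assert counts == {}

    def test_out_of_range_clamped_with_warning(self):
        grid = GridSpec((0, 0, 0), (1, 1, 1), n_bins=2)
        with pytest.warns(UserWarning, match="clamped"):
            _, flat = bin_localisations(np.array([[2.0, 0.1, 0.1]]), grid)
        assert flat[0] == 4  # last density bin, first pc bins


class TestFrequencyTable:
    def test_normalised_rows_sum_to_one(self):
        table = assemble_frequency_table({"a": {0: 3, 5: 1}, "b": {5: 2}})
        np.testing.assert_allclose(table.normalised.sum(axis=1), 1.0, atol=1e-12)

    def test_duplicated_image_duplicates_row(self):
        table = assemble_frequency_table({"a": {0: 3, 5: 1}, "b": {0: 3, 5: 1}})
        np.testing.assert_array_equal(
            table.counts.loc["a"].to_numpy(), table.counts.loc["b"].to_numpy()
        )

    def test_empty_image_rejected(self):
        with pytest.raises(ValueError, match="no binned"):
            assemble_frequency_table({"a": {0: 1}, "b": {}})

    def test_filter_common_bins(self):
        table = assemble_frequency_table(
            {"a": {0: 1, 1: 2, 2: 3, 9: 1}, "b": {0: 4, 1: 5, 2: 6}}
        )
        filtered, leftover = filter_common_bins(table)
        assert filtered.bin_indices.tolist() == [0, 1, 2]
        assert leftover.tolist() == [9]

    def test_identical_images_leave_no_leftover(self):
        table = assemble_frequency_table({"a": {0: 1, 1: 2}, "b": {0: 9, 1: 1}})
        _, leftover = filter_common_bins(table)
        assert leftover.size == 0

    def test_no_common_bins_is_error(self):
        table = assemble_frequency_table({"a": {0: 1}, "b": {1: 1}})
        with pytest.raises(ValueError, match="no bin"):
            filter_common_bins(table)


class TestHierarchical:
    def test_identical_columns_merge_first(self):
        table = assemble_frequency_table(
            {"a": {0: 5, 1: 5, 2: 1}, "b": {0: 5, 1: 5, 2: 9}}
        )
        groups = cluster_bins_hierarchical(table, 2).group_members()
        assert [0, 1] in groups.values()

    def test_two_well_separated_pairs(self):
        # columns 0,1 peak in image a; columns 2,3 peak in image b
        table = assemble_frequency_table(
            {
                "a": {0: 100, 1: 98, 2: 2, 3: 3},
                "b": {0: 2, 1: 3, 2: 100, 3: 97},
            }
        )
        groups = cluster_bins_hierarchical(table, 2).group_members()
        assert sorted(groups.values()) == [[0, 1], [2, 3]]

    def test_singleton_cut(self):
        table = assemble_frequency_table({"a": {0: 1, 1: 2, 2: 3}, "b": {0: 3, 1: 2, 2: 1}})
        assignment = cluster_bins_hierarchical(table, 3)
        assert assignment.n_groups == 3

    def test_too_many_groups_rejected(self):
        table = assemble_frequency_table({"a": {0: 1, 1: 2}, "b": {0: 3, 1: 2}})
        with pytest.raises(ValueError):
            cluster_bins_hierarchical(table, 3)


def constructed_nine_group_fixture():
    """Four k-means clusters (three straddling SNPC1=0) plus leftover bins.

    Designed so the scheme forms 4 + 2 = 6 clusters before splitting and
    exactly three of them straddle SNPC1 = 0, yielding 9 groups.
    """
    grid = GridSpec((0.0, -1.0, -1.0), (1.0, 1.0, 1.0), n_bins=50)

    def flat(iden, ipc1, ipc2):
        return iden * 2500 + ipc1 * 50 + ipc2

    images = ["i0", "i1", "i2", "i3"]
    cluster_bins = {}
    for c in range(4):
        if c < 3:  # straddle PC1 = 0 (bins 20 -> centre<0, 30 -> centre>0)
            bins = [flat(5 + c, 20, 10), flat(5 + c, 20, 11),
                    flat(5 + c, 30, 10), flat(5 + c, 30, 11)]
        else:      # entirely on the positive PC1 side
            bins = [flat(5 + c, 30, 20), flat(5 + c, 31, 20),
                    flat(5 + c, 35, 20), flat(5 + c, 36, 20)]
        cluster_bins[c] = bins
    leftover = [flat(2, 30, 5), flat(2, 30, 6), flat(45, 30, 5), flat(45, 30, 6)]

    counts = {}
    for i, image in enumerate(images):
        c = {}
        for cl, bins in cluster_bins.items():
            for b in bins:
                c[b] = 200 if cl == i else 10
        for b in leftover:
            if i != 0:  # absent from image 0 -> not common
                c[b] = 30
        counts[image] = c
    return grid, assemble_frequency_table(counts), cluster_bins, leftover


class TestNineGroupScheme:
    def test_reference_configuration_yields_nine_groups(self):
        grid, table, cluster_bins, leftover_truth = constructed_nine_group_fixture()
        filtered, leftover = filter_common_bins(table)
        assert sorted(leftover.tolist()) == sorted(leftover_truth)
        assignment = nine_group_scheme(filtered, leftover, grid, seed=0)
        prov = assignment.provenance
        assert prov["n_clusters_before_split"] == 6
        assert len(prov["split_cluster_ids"]) == 3
        assert assignment.n_groups == 9
        # partition: every occupied bin labelled exactly once
        occupied = set(table.bin_indices.tolist())
        assert set(assignment.bin_to_group) == occupied

    def test_stable_across_kmeans_restarts(self):
        grid, table, *_ = constructed_nine_group_fixture()
        filtered, leftover = filter_common_bins(table)
        a = nine_group_scheme(filtered, leftover, grid, seed=0)
        b = nine_group_scheme(filtered, leftover, grid, seed=99)
        # well-separated profiles: the partition is seed-independent
        members_a = {frozenset(v) for v in a.group_members().values()}
        members_b = {frozenset(v) for v in b.group_members().values()}
        assert members_a == members_b

    def test_no_straddling_cluster_keeps_six_groups(self):
        grid, table, cluster_bins, _ = constructed_nine_group_fixture()
        filtered, leftover = filter_common_bins(table)
        assignment = nine_group_scheme(
            filtered, leftover, grid, split_min_frac=0.6, seed=0
        )
        # 50/50 straddles fail a 60% per-side requirement: nothing splits
        assert assignment.n_groups == 6

    def test_kmeans_k_exceeding_bins_rejected(self):
        grid, table, *_ = constructed_nine_group_fixture()
        filtered, leftover = filter_common_bins(table)
        with pytest.raises(ValueError):
            nine_group_scheme(filtered, leftover, grid, k_kmeans=100)


class TestAssignGroups:
    def test_labels_inherit_bin_group(self):
        assignment = GroupAssignment({3: 1, 7: 2})
        labels = assign_localisation_groups(np.array([3, 7, 3, -1]), assignment)
        assert labels.tolist() == [1, 2, 1, 0]

    def test_unassigned_bin_is_error(self):
        with pytest.raises(KeyError):
            assign_localisation_groups(np.array([5]), GroupAssignment({3: 1}))

    def test_group_frequencies_aggregate_bin_frequencies(self):
        grid, table, *_ = constructed_nine_group_fixture()
        filtered, leftover = filter_common_bins(table)
        assignment = nine_group_scheme(filtered, leftover, grid, seed=0)
        norm = table.normalised
        for image in norm.index:
            by_group = {}
            for b, g in assignment.bin_to_group.items():
                by_group[g] = by_group.get(g, 0.0) + norm.loc[image].get(b, 0.0)
            assert sum(by_group.values()) == pytest.approx(1.0, abs=1e-12)


class TestEndToEndSeparation:
    def test_large_clusters_and_noise_in_different_groups(self, ensemble_run):
        """Localisations from large clusters vs background noise should be
        separated by the group partition (majority-group rule)."""
        patterns = ensemble_run["patterns"]
        labels = ensemble_run["results"]["localisation_groups"]
        large, noise = [], []
        for iid, pat in patterns.items():
            lab = labels[iid]
            large.append(lab[(pat.N_clus >= 60) & (lab > 0)])
            noise.append(lab[pat.is_noise & (lab > 0)])
        large = np.concatenate(large)
        noise = np.concatenate(noise)
        groups = np.unique(np.concatenate([large, noise]))
        correct = 0
        for g in groups:
            nl = (large == g).sum() / large.size
            nn = (noise == g).sum() / noise.size
            # assign the bin-group to whichever population dominates it
            if nl >= nn:
                correct += (large == g).sum()
            else:
                correct += (noise == g).sum()
        separation = correct / (large.size + noise.size)
        assert separation >= 0.70
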