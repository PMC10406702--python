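import numpy as np
import pandas as pd
import pytest

from axsi.connectome import (ConnectomeMatrix, SECTION_NAMES,
                             build_connectome, cc_section_stats,
                             group_average_connectome, mad_outlier_mask,
                             node_mean_add, weight_streamlines,
                             witelson_sections, WeightedTractogram)


def line(p0, p1, n=20):
    t = np.linspace(0, 1, n)[:, None]
    return np.asarray(p0) * (1 - t) + np.asarray(p1) * t


class TestWeightStreamlines:
    affine = np.eye(4)

    def test_mean_of_traversed_voxel_values(self):
        emad = np.full((3, 1, 1), np.nan)
        emad[:, 0, 0] = [2.0, 4.0, 6.0]
        wt = weight_streamlines([line([0, 0, 0], [2, 0, 0])], emad,
                                self.affine)
        assert wt.add[0] == pytest.approx(4.0)

    def test_revisiting_a_voxel_counts_once(self):
        emad = np.full((3, 1, 1), np.nan)
        emad[:, 0, 0] = [2.0, 4.0, 100.0]
        fwd = line([0, 0, 0], [1, 0, 0])
        zigzag = np.vstack([fwd] * 10)
        w1 = weight_streamlines([fwd], emad, self.affine).add[0]
        w2 = weight_streamlines([zigzag], emad, self.affine).add[0]
        assert w1 == pytest.approx(w2)

    def test_corridor_streamline_reads_corridor_value(self):
        emad = np.full((10, 5, 3), 2.0)
        emad[:, 2, 1] = 8.0  # corridor
        wt = weight_streamlines([line([0, 2, 1], [9, 2, 1], n=40)], emad,
                                self.affine)
        assert wt.add[0] == pytest.approx(8.0)

    def test_streamline_outside_volume_gets_nan(self):
        emad = np.full((3, 3, 3), 5.0)
        wt = weight_streamlines([line([50, 50, 50], [60, 50, 50])], emad,
                                self.affine)
        assert np.isnan(wt.add[0])
        assert wt.n_outside == 1

    def test_undefined_voxels_ignored_in_average(self):
        emad = np.full((3, 1, 1), np.nan)
        emad[0, 0, 0] = 6.0
        wt = weight_streamlines([line([0, 0, 0], [2, 0, 0])], emad,
                                self.affine)
        assert wt.add[0] == pytest.approx(6.0)


@pytest.fixture
def two_blob_setup():
    """Atlas with labels 1 and 2 at opposite x-ends of a 10-voxel box."""
    atlas = np.zeros((10, 3, 3), dtype=int)
    atlas[:2] = 1
    atlas[-2:] = 2
    affine = np.eye(4)
    sls = [line([0, 1, 1], [9, 1, 1]) for _ in range(3)]
    return atlas, affine, sls


class TestBuildConnectome:
    def test_hand_enumerated_add_and_count(self, two_blob_setup):
        atlas, affine, sls = two_blob_setup
        wt = WeightedTractogram(streamlines=sls,
                                add=np.array([1.0, 2.0, 3.0]))
        conn = build_connectome(wt, atlas, affine)
        i, j = 0, 1  # labels 1, 2
        assert conn.count_weight[i, j] == 3
        assert conn.add_weight[i, j] == pytest.approx(2.0)
        assert np.array_equal(conn.count_weight, conn.count_weight.T)

    def test_nan_weight_streamline_counted_but_not_averaged(self,
                                                            two_blob_setup):
        atlas, affine, sls = two_blob_setup
        wt = WeightedTractogram(streamlines=sls,
                                add=np.array([2.0, np.nan, 4.0]))
        conn = build_connectome(wt, atlas, affine)
        assert conn.count_weight[0, 1] == 3
        assert conn.add_weight[0, 1] == pytest.approx(3.0)

    def test_unconnected_pair_has_zero_count_nan_add(self, two_blob_setup):
        atlas, affine, _ = two_blob_setup
        atlas[4:6, 0, 0] = 3  # a third, never-touched label
        wt = WeightedTractogram(streamlines=[line([0, 1, 1], [9, 1, 1])],
                                add=np.array([2.0]))
        conn = build_connectome(wt, atlas, affine)
        k = list(conn.labels).index(3)
        assert conn.count_weight[0, k] == 0
        assert np.isnan(conn.add_weight[0, k])

    def test_streamline_conservation(self, two_blob_setup):
        atlas, affine, sls = two_blob_setup
        lost = line([5, 1, 1], [5.5, 1, 1])  # both endpoints unlabeled
        wt = WeightedTractogram(streamlines=sls + [lost],
                                add=np.array([1.0, 2.0, 3.0, 9.0]))
        conn = build_connectome(wt, atlas, affine, tolerance_mm=0.5)
        assigned = conn.count_weight[np.triu_indices(len(conn.labels))].sum()
        assert assigned + conn.n_unassigned == 4

    def test_permuting_streamline_order_changes_nothing(self,
                                                        two_blob_setup):
        atlas, affine, sls = two_blob_setup
        add = np.array([1.0, 2.0, 3.0])
        c1 = build_connectome(
            WeightedTractogram(streamlines=sls, add=add), atlas, affine)
        c2 = build_connectome(
            WeightedTractogram(streamlines=sls[::-1], add=add[::-1]),
            atlas, affine)
        assert np.array_equal(c1.count_weight, c2.count_weight)
        assert np.allclose(c1.add_weight, c2.add_weight, equal_nan=True)


class TestMadOutlierMask:
    def test_planted_outlier_excluded_by_degenerate_rule(self):
        keep = mad_outlier_mask(np.array([1.0, 1.0, 1.0, 1.0, 100.0]), 2.5)
        assert list(keep) == [True, True, True, True, False]

    def test_all_equal_values_kept(self):
        assert mad_outlier_mask(np.array([3.0, 3.0, 3.0])).all()

    def test_symmetric_triple_kept_at_default_threshold(self):
        assert mad_outlier_mask(np.array([-1.0, 0.0, 1.0]), 2.5).all()

    def test_fewer_than_three_finite_keeps_all_finite(self, caplog):
        import logging
        with caplog.at_level(logging.WARNING):
            keep = mad_outlier_mask(np.array([1.0, np.nan]))
        assert list(keep) == [True, False]

    def test_moderate_outlier_excluded(self):
        vals = np.array([10.0, 10.5, 9.5, 10.2, 9.8, 25.0])
        keep = mad_outlier_mask(vals, 2.5)
        assert not keep[-1]
        assert keep[:-1].all()


def conn_of(add, count, labels=(1, 2, 3)):
    return ConnectomeMatrix(labels=np.array(labels),
                            add_weight=np.asarray(add, dtype=float),
                            count_weight=np.asarray(count))


class TestGroupAverage:
    def base(self, a12):
        add = np.full((3, 3), np.nan)
        add[0, 1] = add[1, 0] = a12
        count = np.zeros((3, 3), dtype=int)
        count[0, 1] = count[1, 0] = 5
        return conn_of(add, count)

    def test_single_subject_is_identity(self):
        c = self.base(4.0)
        g = group_average_connectome([c])
        assert np.allclose(g.add_weight, c.add_weight, equal_nan=True)

    def test_edge_defined_in_no_subject_stays_undefined(self):
        g = group_average_connectome([self.base(4.0), self.base(5.0)])
        assert np.isnan(g.add_weight[0, 2])

    def test_wild_subject_value_excluded_from_edge_mean(self):
        subjects = [self.base(v) for v in [4.0, 4.1, 3.9, 4.05, 50.0]]
        g = group_average_connectome(subjects)
        assert g.add_weight[0, 1] == pytest.approx(
            np.mean([4.0, 4.1, 3.9, 4.05]))


class TestNodeMeanAdd:
    def test_equal_count_incident_edges_average(self):
        add = np.full((3, 3), np.nan)
        add[0, 1] = add[1, 0] = 2.0
        add[0, 2] = add[2, 0] = 4.0
        count = (~np.isnan(add)).astype(int)
        out = node_mean_add(conn_of(add, count))
        assert out[0] == pytest.approx(3.0)

    def test_isolated_node_undefined(self):
        add = np.full((3, 3), np.nan)
        add[0, 1] = add[1, 0] = 2.0
        out = node_mean_add(conn_of(add, (~np.isnan(add)).astype(int)))
        assert np.isnan(out[2])

    def test_count_weighted_mode_matches_streamline_level_mean(self):
        add = np.full((3, 3), np.nan)
        add[0, 1] = add[1, 0] = 2.0
        add[0, 2] = add[2, 0] = 5.0
        count = np.zeros((3, 3), dtype=int)
        count[0, 1] = count[1, 0] = 3
        count[0, 2] = count[2, 0] = 1
        out = node_mean_add(conn_of(add, count), count_weighted=True)
        assert out[0] == pytest.approx((3 * 2.0 + 1 * 5.0) / 4)

    def test_self_connection_excluded(self):
        add = np.full((3, 3), np.nan)
        add[0, 0] = 9.0
        add[0, 1] = add[1, 0] = 2.0
        count = (~np.isnan(add)).astype(int)
        assert node_mean_add(conn_of(add, count))[0] == pytest.approx(2.0)


class TestWitelsonSections:
    def test_100_voxel_mask_proportions(self):
        mask = np.zeros((1, 100, 1), dtype=bool)
        mask[0, :, 0] = True
        labels = witelson_sections(mask, ap_axis=1,
                                   anterior_is_high_index=False)
        # boundaries at fractions 1/3, 1/2, 2/3, 4/5 of the 0..99 extent,
        # boundary voxels (e.g. 66/99 = 2/3) going to the posterior side
        counts = [int((labels == k).sum()) for k in range(1, 6)]
        assert counts == [33, 17, 16, 14, 20]
        assert [c / 100 for c in counts] == pytest.approx(
            [1 / 3, 1 / 6, 1 / 6, 2 / 15, 1 / 5], abs=0.015)

    def test_exactly_five_labels_partition_the_mask(self, rng):
        mask = rng.random((3, 40, 2)) > 0.3
        mask[:, ::7, :] = True  # guarantee AP coverage
        labels = witelson_sections(mask, ap_axis=1)
        assert set(np.unique(labels[mask])) == {1, 2, 3, 4, 5}
        assert np.all(labels[~mask] == 0)
        assert np.all(labels[mask] > 0)

    def test_boundary_voxel_falls_on_posterior_side(self):
        # 7 voxels: fractional positions 0, 1/6, 2/6, 3/6=1/2, ...
        mask = np.zeros((1, 7, 1), dtype=bool)
        mask[0, :, 0] = True
        labels = witelson_sections(mask, ap_axis=1,
                                   anterior_is_high_index=False)
        # position 3 is exactly the 1/2 boundary -> mid body (label 3)
        assert labels[0, 3, 0] == 3

    def test_ap_axis_read_from_affine(self):
        mask = np.zeros((1, 1, 30), dtype=bool)
        mask[0, 0, :] = True
        affine = np.zeros((4, 4))
        affine[0, 0] = 2.0   # x <- i
        affine[1, 2] = 2.0   # y (anterior) <- k
        affine[2, 1] = 2.0
        affine[3, 3] = 1.0
        labels = witelson_sections(mask, affine=affine)
        # anterior = high k index -> genu (label 1) at the far end
        assert labels[0, 0, -1] == 1
        assert labels[0, 0, 0] == 5

    def test_thin_mask_rejected(self):
        mask = np.zeros((1, 4, 1), dtype=bool)
        mask[0, :, 0] = True
        with pytest.raises(ValueError, match="5"):
            witelson_sections(mask, ap_axis=1)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            witelson_sections(np.zeros((2, 9, 2), dtype=bool), ap_axis=1)


class TestCcSectionStats:
    def make_table(self, rng, shift=0.0, n=12):
        base = rng.normal(5.0, 0.3, size=(n, 5))
        base[:, 1:4] += shift  # body sections
        return pd.DataFrame(base, columns=list(SECTION_NAMES))

    def test_ten_posthoc_pairs_for_five_sections(self, rng):
        stats = cc_section_stats(self.make_table(rng, shift=1.0))
        assert len(stats.pairwise) == 10
        assert stats.pairwise["p_bonferroni"].max() <= 1.0
        assert np.all(stats.pairwise["p_bonferroni"]
                      >= stats.pairwise["p_raw"] - 1e-15)

    def test_identical_columns_give_null_result(self):
        table = pd.DataFrame(np.tile([[4.0, 4.0, 4.0, 4.0, 4.0]], (8, 1)),
                             columns=list(SECTION_NAMES))
        stats = cc_section_stats(table)
        assert stats.f_value == pytest.approx(0.0, abs=1e-10)
        assert np.all(stats.pairwise["p_bonferroni"] == 1.0)

    def test_injected_body_shift_gives_correct_t_signs(self, rng):
        stats = cc_section_stats(self.make_table(rng, shift=2.0))
        pw = stats.pairwise.set_index(["section_a", "section_b"])
        assert pw.loc[("Genu", "Mid Body"), "t"] < 0
        assert pw.loc[("Mid Body", "Splenium"), "t"] > 0
        assert pw.loc[("Anterior Body", "Splenium"), "t"] > 0
        assert stats.f_value > 10

    def test_incomplete_table_rejected(self, rng):
        table = self.make_table(rng)
        table.iloc[0, 0] = np.nan
        with pytest.raises(ValueError):
            cc_section_stats(table)
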