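"""Magnitude thresholding, 8-connected clustering, annotation."""

import numpy as np
import pandas as pd
import pytest
from conftest import floodfill_label_oracle, single_vein_scene

from veinpulse.segmentation import (VesselClusterMap, annotate_clusters,
                                    cluster_size_summary, label_clusters,
                                    threshold_mask, time_average_magnitude)
from veinpulse.synthetic import random_scene_config, render_scene


class TestTimeAverage:
    def test_constant_stack(self, noiseless_scene):
        series, _ = noiseless_scene
        const = series.magnitude * 0 + 3.0
        series2 = type(series)(magnitude=const, phase=series.phase,
                               venc=10.0, phase_duration=23.1)
        assert np.allclose(time_average_magnitude(series2), 3.0)

    def test_alternating_phases_average(self, noiseless_scene):
        series, _ = noiseless_scene
        mag = np.zeros_like(series.magnitude)
        mag[..., 1::2] = 2.0
        series2 = type(series)(magnitude=mag, phase=series.phase,
                               venc=10.0, phase_duration=23.1)
        assert np.allclose(time_average_magnitude(series2), 1.0)

    def test_vessels_brighter_than_background(self):
        series, truth = single_vein_scene(noise_sd_phase=0.02,
                                          noise_sd_mag=5.0)
        avg = time_average_magnitude(series)
        vessel = truth.label_image > 0
        assert avg[vessel].min() > avg[~vessel].mean()


class TestThresholdMask:
    def test_uniform_image_empty(self):
        assert not threshold_mask(np.ones((10, 10))).any()

    def test_single_bright_voxel_oracle(self):
        """101 voxels: 100 zeros and one 100; direct mean/SD arithmetic says
        only the bright voxel exceeds mean + 2 SD."""
        img = np.zeros(101)
        img[57] = 100.0
        cut = img.mean() + 2 * img.std()
        assert 0 < cut < 100
        mask = threshold_mask(img.reshape(1, -1), k=2.0)
        assert mask.sum() == 1 and mask[0, 57]

    def test_roi_restricts_statistics_and_mask(self):
        img = np.zeros((10, 10))
        img[:, 5:] = 50.0    # bright half
        img[2, 2] = 10.0     # modest voxel, bright relative to left half only
        roi = np.zeros((10, 10), dtype=bool)
        roi[:, :5] = True
        mask = threshold_mask(img, k=2.0, roi=roi)
        assert mask[2, 2]
        assert not mask[:, 5:].any()  # outside ROI excluded

    def test_empty_roi_is_error(self):
        with pytest.raises(ValueError, match="roi"):
            threshold_mask(np.ones((5, 5)), roi=np.zeros((5, 5), bool))

    def test_default_contrast_covers_full_volume_vessels(self):
        cfg = random_scene_config(21, grid_size=96)
        series, truth = render_scene(cfg)
        mask = threshold_mask(time_average_magnitude(series))
        assert np.all(mask[truth.label_image > 0])


class TestLabelClusters:
    def test_diagonal_touch_joins(self):
        mask = np.zeros((5, 5), bool)
        mask[1, 1] = mask[2, 2] = True
        assert label_clusters(mask).n_clusters == 1

    def test_one_voxel_gap_separates(self):
        mask = np.zeros((5, 5), bool)
        mask[2, 1] = mask[2, 3] = True
        cmap = label_clusters(mask)
        assert cmap.n_clusters == 2

    def test_empty_mask(self):
        cmap = label_clusters(np.zeros((6, 6), bool))
        assert cmap.n_clusters == 0
        assert len(cmap.clusters) == 0

    def test_label_completeness(self, rng):
        mask = rng.random((30, 30)) < 0.35
        cmap = label_clusters(mask)
        assert (cmap.label_image > 0).sum() == mask.sum()
        assert int(cmap.clusters["size"].sum()) == int(mask.sum())

    def test_raster_order_ids(self):
        mask = np.zeros((6, 6), bool)
        mask[4, 0] = True   # later in raster order
        mask[0, 4] = True   # earlier
        cmap = label_clusters(mask)
        assert cmap.label_image[0, 4] == 1
        assert cmap.label_image[4, 0] == 2

    def test_matches_floodfill_oracle_on_random_masks(self, rng):
        """Partition equivalence (and identical ids, both raster-ordered)
        against a brute-force BFS flood fill on random 12x12 masks."""
        for density in (0.2, 0.4, 0.6):
            for _ in range(60):
                mask = rng.random((12, 12)) < density
                ours = label_clusters(mask).label_image
                theirs = floodfill_label_oracle(mask)
                assert np.array_equal(ours, theirs)

    def test_partition_invariant_to_transposition(self, rng):
        """Relabelling voxel order (transpose) permutes ids but preserves
        the partition into clusters."""
        mask = rng.random((15, 15)) < 0.4
        a = label_clusters(mask).label_image
        b = label_clusters(mask.T).label_image.T
        # same partition: co-membership matrices agree
        fa, fb = a.ravel(), b.ravel()
        on = fa > 0
        pairs_a = fa[on, None] == fa[None, on]
        pairs_b = fb[on, None] == fb[None, on]
        assert np.array_equal(pairs_a, pairs_b)


class TestAnnotate:
    def _two_cluster_map(self):
        mask = np.zeros((8, 8), bool)
        mask[1, 1:3] = True
        mask[5, 5] = True
        return label_clusters(mask)

    def test_legend_direct_assignment(self):
        cmap = self._two_cluster_map()
        legend = pd.DataFrame([{"cluster_id": 2, "class_label": "small_vein",
                                "territory": "PCA"}])
        out = annotate_clusters(cmap, legend=legend)
        assert out.clusters.set_index("cluster_id").loc[2, "class_label"] \
            == "small_vein"
        assert out.clusters.set_index("cluster_id").loc[1, "class_label"] \
            == "unclassified"

    def test_unknown_class_rejected(self):
        cmap = self._two_cluster_map()
        legend = pd.DataFrame([{"cluster_id": 1, "class_label": "capillary",
                                "territory": "ACA"}])
        with pytest.raises(ValueError, match="capillary"):
            annotate_clusters(cmap, legend=legend)

    def test_two_class_overlap_discarded(self):
        """A cluster overlapping both a vein and an artery reference mask
        is discarded rather than guessed."""
        cmap = self._two_cluster_map()
        ref = np.zeros((8, 8), int)
        ref[1, 1] = 1   # vein
        ref[1, 2] = 2   # artery
        table = pd.DataFrame([
            {"cluster_id": 1, "class_label": "small_vein", "territory": "ACA"},
            {"cluster_id": 2, "class_label": "artery", "territory": "ACA"}])
        out = annotate_clusters(cmap, reference_labels=ref,
                                reference_table=table)
        assert out.clusters.set_index("cluster_id").loc[1, "class_label"] \
            == "discard"

    def test_scene_truth_recovered_exactly(self):
        cfg = random_scene_config(13, grid_size=96)
        series, truth = render_scene(cfg)
        cmap = label_clusters(threshold_mask(time_average_magnitude(series)))
        out = annotate_clusters(cmap, reference_labels=truth.label_image,
                                reference_table=truth.class_table)
        truth_classes = truth.class_table.set_index("cluster_id")
        recovered = 0
        for _, row in out.clusters.iterrows():
            vox = out.voxels(int(row["cluster_id"]))
            hits = truth.label_image[vox[:, 0], vox[:, 1]]
            hits = hits[hits > 0]
            if len(set(hits)) == 1:
                tid = hits[0]
                assert row["class_label"] == \
                    truth_classes.loc[tid, "class_label"]
                recovered += 1
        assert recovered > 0


class TestSizeSummary:
    def _map_with_sizes(self, sizes, cls="small_vein"):
        rows = [{"cluster_id": i + 1, "size": s, "class_label": cls,
                 "territory": "none"} for i, s in enumerate(sizes)]
        label = np.zeros((40, 40), int)
        col = 0
        for i, s in enumerate(sizes):
            label[2 * i, col:col + s] = i + 1
        return VesselClusterMap(label_image=label,
                                clusters=pd.DataFrame(rows))

    def test_singleton(self):
        out = cluster_size_summary(self._map_with_sizes([5]))
        row = out.iloc[0]
        assert row["median"] == row["p10"] == row["p90"] == 5

    def test_order_statistics(self):
        out = cluster_size_summary(self._map_with_sizes([1, 2, 9]))
        assert out.iloc[0]["median"] == 2

    def test_absent_class_missing_not_error(self):
        out = cluster_size_summary(self._map_with_sizes([3, 4]))
        assert "artery" not in set(out["class_label"])
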