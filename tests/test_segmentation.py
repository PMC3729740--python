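"""Segmentation correctness against generator ground truth and contracts."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import ndimage

from gliaquant.segmentation import (
    LabeledMask,
    assign_nuclei_to_cells,
    estimate_background,
    segment_microglia,
    segment_nuclei,
    threshold_channel,
)
from gliaquant.synthetic import CultureParams, FieldImage, draw_disk, generate_field
from gliaquant.validation import cell_iou_table, match_nuclei_to_truth


def _field_from(channels: dict[str, np.ndarray]) -> FieldImage:
    return FieldImage(channels=channels, field_id="synthetic_test")


class TestSegmentNuclei:
    def test_constant_background_image(self):
        rng = np.random.default_rng(0)
        img = (400 + rng.normal(0, 30, (128, 128))).astype(np.uint16)
        field = _field_from({"nuclei": img})
        assert segment_nuclei(field).n_objects == 0
        flat = _field_from({"nuclei": np.full((64, 64), 500, np.uint16)})
        assert segment_nuclei(flat).n_objects == 0

    def test_missing_channel_named_in_error(self):
        field = _field_from({"surface": np.zeros((32, 32), np.uint16)})
        with pytest.raises(KeyError, match="nuclei"):
            segment_nuclei(field)

    def test_count_and_centroid_recovery(self, high_snr_field):
        """Well-separated synthetic nuclei: every nucleus found within 3 px
        of its true centre."""
        fimg, truth, _ = high_snr_field
        nuclei = segment_nuclei(fimg)
        assert nuclei.n_objects == len(truth)
        matches = match_nuclei_to_truth(nuclei, truth, max_dist=3.0)
        assert (matches.nucleus_label > 0).all()

    def test_watershed_splits_touching_nuclei(self):
        img = np.full((64, 64), 400.0)
        # two disks of radius 8 at 30% overlap (centres 1.4 r apart)
        draw_disk(img, (32, 24), 8, 6000.0)
        draw_disk(img, (32, 24 + 11.2), 8, 6000.0)
        field = _field_from({"nuclei": img.astype(np.uint16)})
        nuclei = segment_nuclei(field, min_area=25, max_area=500)
        assert nuclei.n_objects == 2

    def test_labels_consecutive(self, high_snr_field):
        fimg, _, _ = high_snr_field
        labels = segment_nuclei(fimg).labels
        ids = np.unique(labels)
        assert ids[0] == 0
        assert np.array_equal(ids[1:], np.arange(1, len(ids)))


class TestSegmentMicroglia:
    def test_zero_signal_channel(self):
        rng = np.random.default_rng(1)
        img = (400 + rng.normal(0, 30, (128, 128))).clip(0).astype(np.uint16)
        field = _field_from({"surface": img})
        assert segment_microglia(field).n_objects == 0

    def test_body_recovery_iou(self, high_snr_field):
        fimg, truth, params = high_snr_field
        cells = segment_microglia(fimg)
        assert cells.n_objects == int(truth.is_microglia.sum())
        ious = cell_iou_table(cells, truth, params.superellipse_exponent)
        assert (ious.iou >= 0.8).all()

    def test_rotation_symmetry(self, high_snr_field):
        fimg, _, _ = high_snr_field
        n0 = segment_microglia(fimg).n_objects
        rot = FieldImage(
            channels={"surface": np.rot90(fimg.channels["surface"])},
            field_id="rot",
        )
        assert segment_microglia(rot).n_objects == n0

    def test_threshold_scale_invariance(self, high_snr_field):
        """Multiplying a channel by a positive constant changes nothing
        (normalized-threshold contract)."""
        fimg, _, _ = high_snr_field
        chan = fimg.channels["surface"].astype(np.float64)
        m1 = threshold_channel(chan)
        m2 = threshold_channel(chan * 7.3)
        assert np.array_equal(m1, m2)

    def test_label_partition(self, high_snr_field):
        """Every foreground pixel belongs to exactly one label and the
        result is identical on re-run (order-stable relabeling)."""
        fimg, _, _ = high_snr_field
        a = segment_microglia(fimg).labels
        b = segment_microglia(fimg).labels
        assert np.array_equal(a, b)
        n_fg = int((a > 0).sum())
        assert sum(int((a == i).sum()) for i in range(1, a.max() + 1)) == n_fg


class TestAssignment:
    @staticmethod
    def _mask(arr, kind):
        return LabeledMask(np.asarray(arr, dtype=np.int32), kind)

    def test_disjoint_masks(self):
        nuc = np.zeros((10, 10), int)
        nuc[1:3, 1:3] = 1
        cel = np.zeros((10, 10), int)
        cel[6:9, 6:9] = 1
        res = assign_nuclei_to_cells(self._mask(nuc, "nuclei"), self._mask(cel, "cells"))
        assert (res.table.cell_id == 0).all()
        assert list(res.empty_cells) == [1]

    def test_max_overlap_wins(self):
        nuc = np.zeros((10, 10), int)
        nuc[4, 0:10] = 1  # nucleus strip across two cells
        cel = np.zeros((10, 10), int)
        cel[:, 0:6] = 1  # 60% overlap
        cel[:, 6:10] = 2  # 40% overlap
        res = assign_nuclei_to_cells(self._mask(nuc, "nuclei"), self._mask(cel, "cells"))
        assert res.table.cell_id.tolist() == [1]

    def test_tie_breaks_to_smaller_cell_id(self):
        nuc = np.zeros((10, 10), int)
        nuc[4, 1:9] = 1  # 4 px in each cell
        cel = np.zeros((10, 10), int)
        cel[:, 1:5] = 2
        cel[:, 5:9] = 1
        res = assign_nuclei_to_cells(self._mask(nuc, "nuclei"), self._mask(cel, "cells"))
        assert res.table.cell_id.tolist() == [1]

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            assign_nuclei_to_cells(
                self._mask(np.zeros((4, 4), int), "nuclei"),
                self._mask(np.zeros((5, 5), int), "cells"),
            )

    def test_ground_truth_pairing(self, high_snr_field):
        """Each microglial nucleus is assigned to its own body."""
        fimg, truth, params = high_snr_field
        nuclei = segment_nuclei(fimg)
        cells = segment_microglia(fimg)
        res = assign_nuclei_to_cells(nuclei, cells)
        assert len(res.assigned) == int(truth.is_microglia.sum())
        assert len(res.empty_cells) == 0
        # assigned nuclei sit at microglial centroids
        matches = match_nuclei_to_truth(nuclei, truth)
        merged = matches.merge(truth[["cell_id", "is_microglia"]], on="cell_id")
        mg_nuclei = set(merged[merged.is_microglia].nucleus_label)
        assert mg_nuclei == set(res.assigned.nucleus_id)


class TestBackground:
    def test_constant_image(self):
        img = np.full((32, 32), 123.0)
        assert estimate_background(img) == (123.0, 0.0)

    def test_recovers_generated_background(self, default_noise_field):
        fimg, _, params = default_noise_field
        for role in ("pu1", "cargo"):
            chan = fimg.channels[role].astype(float)
            fg = chan > 1500
            fg = ndimage.binary_dilation(fg, iterations=3)
            bg_mean, bg_sd = estimate_background(chan, fg)
            assert bg_mean == pytest.approx(params.intensity_levels[role][1], rel=0.02)
            assert bg_sd > 0

    def test_foreground_brightness_does_not_leak(self):
        """10x brighter foreground moves the masked estimate by < 1%."""
        rng = np.random.default_rng(5)
        base = 400 + rng.normal(0, 20, (128, 128))
        fg_mask = np.zeros((128, 128), bool)
        fg_mask[40:80, 40:80] = True
        img1 = base.copy()
        img1[fg_mask] = 3000
        img2 = base.copy()
        img2[fg_mask] = 30000
        m1, _ = estimate_background(img1, fg_mask)
        m2, _ = estimate_background(img2, fg_mask)
        assert abs(m2 - m1) / m1 < 0.01

    def test_all_foreground_raises(self):
        with pytest.raises(ValueError):
            estimate_background(np.ones((8, 8)), np.ones((8, 8), bool))


class TestCountRecoveryProperty:
    def test_high_snr_fixture_counts_within_2_percent(self, high_snr_fixture_set):
        true_nuc = got_nuc = true_mg = got_mg = 0
        for fimg, truth in high_snr_fixture_set[:8]:  # subset; full set in acceptance
            true_nuc += len(truth)
            true_mg += int(truth.is_microglia.sum())
            got_nuc += segment_nuclei(fimg).n_objects
            got_mg += segment_microglia(fimg).n_objects
        assert abs(got_nuc - true_nuc) / true_nuc <= 0.02
        assert abs(got_mg - true_mg) / true_mg <= 0.02
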