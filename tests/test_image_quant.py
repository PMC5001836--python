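import numpy as np
import pytest
from scipy import ndimage as ndi
from skimage import measure, morphology

from screenpolish.image_quant import (
    CellMeasurement,
    aggregate_well,
    build_rois,
    measure_cell,
    quantify_field,
    quantify_images,
    segment_nuclei,
)
from screenpolish.synthetic_screen import generate_field


def disk_image(radius, size=64, background=10.0, level=100.0, center=None):
    img = np.full((size, size), background)
    cy = cx = size // 2 if center is None else None
    if center is not None:
        cy, cx = center
    yy, xx = np.ogrid[:size, :size]
    img[(yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2] = level
    return img


class TestSegmentNuclei:
    def test_one_disk_one_label(self):
        labels = segment_nuclei(disk_image(8), min_area_px=30)
        assert labels.max() == 1

    def test_blank_image_zero_labels(self):
        labels = segment_nuclei(np.zeros((64, 64)))
        assert labels.max() == 0

    def test_border_touching_discarded(self):
        labels = segment_nuclei(disk_image(8, center=(3, 32)), min_area_px=10)
        assert labels.max() == 0

    def test_small_objects_discarded(self):
        labels = segment_nuclei(disk_image(2), min_area_px=30)
        assert labels.max() == 0

    def test_synthetic_field_centroids(self, noiseless_field):
        # oracle: the field's emitted ground truth
        nuclear, _, gt = noiseless_field
        labels = segment_nuclei(nuclear)
        assert labels.max() == gt.n_cells
        centroids = np.array([p.centroid for p in measure.regionprops(labels)])
        for center in gt.cell_centers:
            nearest = np.min(np.hypot(*(centroids - center).T))
            assert nearest < 2.0

    def test_rejects_negative_intensities(self):
        with pytest.raises(ValueError, match="nonnegative"):
            segment_nuclei(np.full((8, 8), -1.0))


class TestBuildRois:
    def test_disk_radius_10_default_geometry(self):
        # nuclear ROI ~ the circle two pixels inside; ring = 3-px annulus, no gap
        labels = (disk_image(10, size=64) > 50).astype(int)
        rois, flagged = build_rois(labels, erosion_px=2, ring_width_px=3, gap_px=0)
        assert flagged == []
        (roi,) = rois
        yy, xx = np.ogrid[:64, :64]
        r = np.hypot(yy - 32, xx - 32)
        ideal_nuc = r <= 8
        assert np.sum(roi.nuclear_mask ^ ideal_nuc) <= 12  # discretization slack
        # ring pixels sit just outside the stain disk, within ~3 px
        ring_r = r[roi.ring_mask]
        assert ring_r.min() > 10.0 - 0.01
        assert ring_r.max() <= 13.0 + 1.0
        # everything comfortably inside the annulus is covered
        assert np.all(roi.ring_mask[(r > 10.6) & (r <= 12.4)])

    def test_disk_one_pixel_gap(self):
        labels = (disk_image(10, size=64) > 50).astype(int)
        (roi,), _ = build_rois(labels, erosion_px=2, ring_width_px=3, gap_px=1)
        yy, xx = np.ogrid[:64, :64]
        r = np.hypot(yy - 32, xx - 32)
        ring_r = r[roi.ring_mask]
        assert ring_r.min() > 11.0 - 0.01
        assert ring_r.max() <= 14.0 + 1.0
        assert np.all(roi.ring_mask[(r > 11.6) & (r <= 13.4)])

    def test_tiny_nucleus_fully_eroded_is_flagged(self):
        labels = (disk_image(2, size=32) > 50).astype(int)
        rois, flagged = build_rois(labels, erosion_px=2)
        assert rois == []
        assert flagged == [1]

    def test_matches_morphological_construction(self, noiseless_field):
        # independent oracle: skimage dilation with a disk structuring element
        nuclear, _, _ = noiseless_field
        labels = segment_nuclei(nuclear)
        rois, _ = build_rois(labels, erosion_px=2, ring_width_px=3, gap_px=1)
        for roi in rois[:5]:
            mask = labels == roi.label
            expected_nuc = morphology.erosion(mask, morphology.disk(2))
            expected_ring = morphology.dilation(mask, morphology.disk(4)) & ~morphology.dilation(
                mask, morphology.disk(1)
            )
            expected_ring &= labels == 0
            assert np.array_equal(roi.nuclear_mask, expected_nuc)
            assert np.array_equal(roi.ring_mask, expected_ring)

    def test_roi_disjointness_and_ring_distance_invariants(self, noiseless_field):
        nuclear, _, _ = noiseless_field
        labels = segment_nuclei(nuclear)
        rois, _ = build_rois(labels, erosion_px=2, ring_width_px=3, gap_px=0)
        all_rings = np.zeros(labels.shape, int)
        for roi in rois:
            assert not np.any(roi.nuclear_mask & roi.ring_mask)
            d = ndi.distance_transform_edt(labels != roi.label)
            ring_d = d[roi.ring_mask]
            assert np.all(ring_d > 0)
            assert np.all(ring_d <= 3)
            all_rings[roi.ring_mask] += 1
        assert all_rings.max() <= 1  # no pixel measured twice

    def test_overlapping_rings_assigned_to_nearer_cell(self):
        # two disks 24 px apart: rings would overlap in between
        img = np.full((64, 96), 10.0)
        yy, xx = np.ogrid[:64, :96]
        img[(yy - 32) ** 2 + (xx - 36) ** 2 <= 100] = 100.0
        img[(yy - 32) ** 2 + (xx - 60) ** 2 <= 100] = 100.0
        labels = segment_nuclei(img, min_area_px=30)
        assert labels.max() == 2
        rois, _ = build_rois(labels, erosion_px=2, ring_width_px=3, gap_px=0)
        assert not np.any(rois[0].ring_mask & rois[1].ring_mask)
        d1 = ndi.distance_transform_edt(labels != rois[0].label)
        d2 = ndi.distance_transform_edt(labels != rois[1].label)
        assert np.all(d1[rois[0].ring_mask] <= d2[rois[0].ring_mask])
        assert np.all(d2[rois[1].ring_mask] <= d1[rois[1].ring_mask])

    def test_invalid_geometry(self):
        with pytest.raises(ValueError):
            build_rois(np.zeros((8, 8), int), erosion_px=-1)


class TestMeasureCell:
    def test_uniform_reporter_ratio_one(self, noiseless_field):
        nuclear, _, _ = noiseless_field
        labels = segment_nuclei(nuclear)
        rois, _ = build_rois(labels)
        uniform = np.full(nuclear.shape, 7.0)
        for roi in rois:
            assert measure_cell(roi, uniform).ratio == pytest.approx(1.0)

    def test_noiseless_ratio_recovery(self):
        nuclear, reporter, gt = generate_field(1, 2.0, 0.0, image_size=128, seed=2)
        cells = quantify_field(nuclear, reporter)
        assert len(cells) == 1
        assert abs(cells[0].ratio - 2.0) < 0.05

    def test_zero_nuclear_signal_ratio_zero(self, noiseless_field):
        nuclear, _, _ = noiseless_field
        labels = segment_nuclei(nuclear)
        rois, _ = build_rois(labels)
        reporter = np.ones(nuclear.shape)
        reporter[rois[0].nuclear_mask] = 0.0
        m = measure_cell(rois[0], reporter)
        assert m.ratio == 0.0
        assert not m.flagged

    def test_zero_ring_mean_flagged(self, noiseless_field):
        nuclear, _, _ = noiseless_field
        labels = segment_nuclei(nuclear)
        rois, _ = build_rois(labels)
        reporter = np.zeros(nuclear.shape)
        reporter[rois[0].nuclear_mask] = 5.0
        m = measure_cell(rois[0], reporter)
        assert m.flagged

    @pytest.mark.parametrize("k", [0.5, 3.0, 1000.0])
    def test_scale_equivariance(self, noiseless_field, k):
        nuclear, reporter, _ = noiseless_field
        base = quantify_field(nuclear, reporter)
        scaled = quantify_field(nuclear, reporter * k)
        for a, b in zip(base, scaled):
            assert b.ratio == pytest.approx(a.ratio, rel=1e-12)


def _cells(ratios):
    return [
        CellMeasurement(i, r, 1.0, r, 50, 60, flagged=False)
        for i, r in enumerate(ratios)
    ]


class TestAggregateWell:
    def test_median_of_three(self):
        agg = aggregate_well(_cells([1.0, 2.0, 3.0]), min_cells=1)
        assert agg.score == 2.0

    def test_identical_ratios(self):
        agg = aggregate_well(_cells([2.0] * 10), min_cells=1)
        assert agg.score == 2.0

    def test_min_cells_missing(self):
        agg = aggregate_well(_cells([2.0] * 19), min_cells=20)
        assert agg.missing
        assert np.isnan(agg.score)
        assert not aggregate_well(_cells([2.0] * 20), min_cells=20).missing

    def test_flagged_cells_excluded(self):
        cells = _cells([1.0, 2.0, 3.0])
        cells[2].flagged = True
        agg = aggregate_well(cells, min_cells=1)
        assert agg.score == 1.5
        assert agg.n_cells == 2

    def test_mean_and_pooled_modes(self):
        cells = _cells([1.0, 3.0])
        assert aggregate_well(cells, min_cells=1, mode="mean").score == 2.0
        pooled = aggregate_well(cells, min_cells=1, mode="pooled").score
        assert pooled == pytest.approx(2.0)  # equal pixel counts -> plain mean

    def test_unknown_mode(self):
        with pytest.raises(ValueError, match="mode"):
            aggregate_well(_cells([1.0]), min_cells=1, mode="max")


class TestQuantifyImages:
    def test_roundtrip_from_tiffs(self, tmp_path):
        import pandas as pd

        from screenpolish.synthetic_screen import write_field_images

        records = []
        expected = {}
        for i, (row, col) in enumerate([(0, 0), (0, 1), (1, 0)]):
            ratio = 1.5 + 0.5 * i
            nuclear, reporter, _ = generate_field(
                25, ratio, 0.0, image_size=512, seed=100 + i
            )
            write_field_images(tmp_path, 0, row, col, 0, nuclear, reporter)
            records.append(
                dict(plate=0, row=row, col=col, gene_id=f"g{i}", sirna_id=f"s{i}",
                     **{"class": "sample"})
            )
            expected[(row, col)] = ratio
        # a well with no images must come out missing
        records.append(dict(plate=0, row=5, col=5, gene_id="gx", sirna_id="sx",
                            **{"class": "sample"}))
        platemap = pd.DataFrame.from_records(records)
        wells = quantify_images(tmp_path, platemap, min_cells=20)
        assert len(wells) == 4
        for (row, col), ratio in expected.items():
            w = wells[(wells["row"] == row) & (wells["col"] == col)].iloc[0]
            assert w["n_cells"] == 25
            assert w["well_score"] == pytest.approx(ratio, abs=0.05)
        missing = wells[wells["row"] == 5].iloc[0]
        assert np.isnan(missing["well_score"])
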