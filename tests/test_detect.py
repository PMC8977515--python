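import numpy as np
import pytest
from scipy.spatial import cKDTree

from graftquant.detect import (Cell, CellDetectionSet, DoGConfig, MetConfig,
                               assign_compartments, compartment_areas_mm2,
                               compute_densities, detect_cells, detect_met_events,
                               dog_response)
from graftquant.geometry import RegionMask, compute_biopsy_mask
from graftquant.synthetic import SlideSpec, render_if_slide, render_ihc_slide


def _disk_image(value_core=40, value_bg=190, radius=3.5, size=64):
    img = np.full((size, size, 3), value_bg, dtype=np.uint8)
    yy, xx = np.mgrid[:size, :size]
    r = np.hypot(yy - size // 2, xx - size // 2)
    img[r <= radius] = value_core
    return img


class TestDogResponse:
    def test_constant_image_zero_response(self):
        img = np.full((32, 32, 3), 123, dtype=np.uint8)
        assert np.all(dog_response(img) == 0)

    def test_dark_disk_gives_positive_peak(self):
        img = _disk_image(value_core=40, value_bg=190)  # contrast 150
        resp = dog_response(img)
        assert resp[32, 32] > 10

    def test_bright_spot_not_detected(self):
        img = _disk_image(value_core=250, value_bg=100)
        resp = dog_response(img)
        assert resp[32, 32] == 0  # negative response clipped to 0
        assert len(detect_cells(img)) == 0


class TestDetectCells:
    def test_planting_oracle_exact_recovery(self, default_slide):
        img, gt = default_slide
        det = detect_cells(img, slide_id="s1", marker="CD3")
        planted = np.array([[x, y] for x, y, _ in gt.positive_cells])
        assert len(det) == len(planted) == 50
        dists, idx = cKDTree(planted).query(det.centroids())
        assert dists.max() <= 3.0
        assert len(set(idx.tolist())) == len(planted)  # one-to-one
        if gt.negative_cells:
            neg = np.array([[x, y] for x, y in gt.negative_cells])
            dneg, _ = cKDTree(neg).query(det.centroids())
            assert dneg.min() > 3.0  # no detection near a decoy

    def test_small_component_removed(self):
        # radius ~1.6 px -> thresholded DoG component below 10 px
        img = _disk_image(value_core=40, radius=1.0)
        cfg = DoGConfig()
        det_all = detect_cells(img, DoGConfig(min_component_area_px=1))
        det = detect_cells(img, cfg)
        assert len(det_all) == 1 and det_all.cells[0].area_px < 10
        assert len(det) == 0

    def test_darkness_filter_boundary(self):
        # darkest pixel exactly 100 -> removed; 99 -> kept
        img_at = _disk_image(value_core=100)
        img_below = _disk_image(value_core=99)
        assert len(detect_cells(img_at)) == 0
        assert len(detect_cells(img_below)) == 1

    def test_darkness_all_rule_stricter(self):
        img, _ = render_ihc_slide(SlideSpec(seed=11))
        n_any = len(detect_cells(img, DoGConfig(darkness_rule="any")))
        n_all = len(detect_cells(img, DoGConfig(darkness_rule="all")))
        assert n_all <= n_any

    @pytest.mark.parametrize("param,values", [
        ("response_threshold", [5, 10, 30, 80]),
        ("min_component_area_px", [5, 10, 20, 40]),
    ])
    def test_count_monotone_in_thresholds(self, default_slide, param, values):
        img, _ = default_slide
        counts = [len(detect_cells(img, DoGConfig(**{param: v}))) for v in values]
        assert counts == sorted(counts, reverse=True)

    def test_density_invariant_to_background_padding(self, small_slide):
        img, _ = small_slide
        det = detect_cells(img)
        padded = np.pad(img, ((30, 30), (30, 30), (0, 0)), constant_values=230)
        det_p = detect_cells(padded)
        assert len(det) == len(det_p)
        area = compute_biopsy_mask(img).total_px
        area_p = compute_biopsy_mask(padded).total_px
        assert area == area_p


class TestCompartments:
    def test_assignment_matches_planting(self, default_slide):
        img, gt = default_slide
        biopsy = compute_biopsy_mask(img)
        glom = gt.glomerulus_mask()
        det = assign_compartments(detect_cells(img), glom, biopsy)
        truth_glom = sum(1 for *_, c in gt.positive_cells if c == "glomerular")
        assert det.count("glomerular") == truth_glom
        assert det.count("glomerular") + det.count("non_glomerular") == len(det)

    def test_cell_on_background_dropped_and_logged(self):
        labels = np.zeros((20, 20), dtype=np.int32)
        labels[5:15, 5:15] = 1
        biopsy = RegionMask(labels=labels, px_per_micron=2.3)
        glom = RegionMask(labels=np.zeros((20, 20), np.int32), px_per_micron=2.3)
        det = CellDetectionSet("s", "CD3", cells=[Cell(1.0, 1.0, 12), Cell(8.0, 8.0, 12)])
        out = assign_compartments(det, glom, biopsy)
        assert len(out) == 1 and out.n_dropped_outside_tissue == 1

    def test_empty_glom_mask_all_non_glomerular(self):
        labels = np.ones((20, 20), dtype=np.int32)
        biopsy = RegionMask(labels=labels, px_per_micron=2.3)
        glom = RegionMask(labels=np.zeros((20, 20), np.int32), px_per_micron=2.3)
        det = CellDetectionSet("s", "CD3", cells=[Cell(3.0, 3.0, 12)])
        out = assign_compartments(det, glom, biopsy)
        assert out.count("non_glomerular") == 1

    def test_shape_mismatch_rejected(self):
        biopsy = RegionMask(labels=np.ones((20, 20), np.int32), px_per_micron=2.3)
        glom = RegionMask(labels=np.zeros((10, 10), np.int32), px_per_micron=2.3)
        with pytest.raises(ValueError, match="shape"):
            assign_compartments(CellDetectionSet("s", "CD3"), glom, biopsy)


class TestDensities:
    def test_simple_division(self):
        det = CellDetectionSet("s1", "CD3", cells=[
            Cell(float(i), 1.0, 12, "non_glomerular") for i in range(20)])
        df = compute_densities([det], {"s1": {"glomerular": 0.1, "non_glomerular": 0.5}})
        assert df.loc["s1", "CD3_non_glomerular"] == pytest.approx(40.0)
        assert df.loc["s1", "CD3_glomerular"] == 0.0

    def test_zero_area_with_count_raises(self):
        det = CellDetectionSet("s1", "CD3", cells=[Cell(1.0, 1.0, 12, "glomerular")])
        with pytest.raises(ValueError, match="zero-area"):
            compute_densities([det], {"s1": {"glomerular": 0.0, "non_glomerular": 0.5}})

    def test_compartment_areas_partition_biopsy(self, default_slide):
        img, gt = default_slide
        biopsy = compute_biopsy_mask(img)
        from graftquant.glomseg import prob_to_glomerulus_mask
        from graftquant.glomseg import oracle_probability_map

        glom = prob_to_glomerulus_mask(
            oracle_probability_map(gt.glomerulus_mask()), biopsy_mask=biopsy)
        areas = compartment_areas_mm2(glom, biopsy)
        from graftquant.geometry import mask_area_mm2

        total = mask_area_mm2(biopsy)
        assert areas["glomerular"] + areas["non_glomerular"] == pytest.approx(total)


class TestMetEvents:
    @pytest.mark.parametrize("coloc,expected", [(0.0, 0), (0.5, 20), (1.0, 40)])
    def test_planting_oracle(self, coloc, expected):
        img, gt = render_if_slide(SlideSpec(seed=9, n_positive_cells=40),
                                  coloc_fraction=coloc)
        n, _, _ = detect_met_events(img)
        assert n == expected
        assert len(gt.double_positive_cells) == expected

    def test_identical_channels_self_colocalize(self):
        img, _ = render_if_slide(SlideSpec(seed=4, n_positive_cells=30),
                                 coloc_fraction=0.0)
        doubled = np.stack([img[:, :, 0], img[:, :, 0]], axis=-1)
        n, d0, d1 = detect_met_events(doubled)
        assert n == len(d0) == len(d1)

    def test_channel_shape_checked(self):
        with pytest.raises(ValueError, match="two-channel"):
            detect_met_events(np.zeros((10, 10, 3), dtype=np.uint8))


class TestPropertyRandomSpecs:
    @pytest.mark.parametrize("seed", range(8))
    def test_perfect_precision_recall_over_random_specs(self, seed):
        """Detection on random in-contract slides: recall = precision = 1."""
        rng = np.random.default_rng(seed)
        spec = SlideSpec(
            seed=seed, width_px=int(rng.integers(700, 1000)),
            height_px=int(rng.integers(700, 1000)),
            n_positive_cells=int(rng.integers(20, 40)),
            n_negative_cells=int(rng.integers(20, 40)),
            n_glomeruli=int(rng.integers(1, 4)))
        img, gt = render_ihc_slide(spec)
        det = detect_cells(img)
        planted = np.array([[x, y] for x, y, _ in gt.positive_cells])
        assert len(det) == len(planted)
        dists, idx = cKDTree(planted).query(det.centroids())
        assert dists.max() <= 3.0 and len(set(idx.tolist())) == len(planted)
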