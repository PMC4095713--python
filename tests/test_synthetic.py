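"""Synthetic study generator: sampling, placement, rendering, determinism."""

import numpy as np
import pandas as pd
import pytest
from skimage.measure import label as sk_label

from pulpmorph.segmentation import DEFAULT_THRESHOLD, label_regions, remove_scrap, threshold_rgb
from pulpmorph.synthetic import (
    StageParams,
    generate_stage_records,
    generate_study,
    ground_truth_frame,
    place_cells,
    rasterize_polygon,
    render_study_image,
    sample_area_ff,
    stage_defaults,
)


def small_params(**overrides) -> StageParams:
    base = dict(
        stage="cap",
        mean_area=17.733,
        sd_area=7.328,
        mean_ff=0.289,
        sd_ff=0.130,
        cells_per_image=20,
    )
    base.update(overrides)
    return StageParams(**base)


class TestStageParams:
    def test_defaults_carry_published_group_means(self):
        stages = stage_defaults()
        assert set(stages) == {"cap", "early_bell", "late_bell"}
        assert stages["cap"].mean_area == pytest.approx(17.733)
        assert stages["early_bell"].mean_area == pytest.approx(25.187)
        assert stages["late_bell"].mean_area == pytest.approx(32.788)
        assert stages["cap"].mean_ff == pytest.approx(0.289)
        assert stages["early_bell"].mean_ff == pytest.approx(0.134)
        assert stages["late_bell"].mean_ff == pytest.approx(0.104)
        assert stages["cap"].shape_family == "star"
        assert stages["early_bell"].shape_family == "fusiform"

    def test_override_applies_to_every_stage(self):
        stages = stage_defaults(cells_per_image=12)
        assert all(p.cells_per_image == 12 for p in stages.values())

    def test_validation(self):
        with pytest.raises(ValueError):
            small_params(mean_area=-1.0)
        with pytest.raises(ValueError):
            small_params(mean_ff=1.5)
        with pytest.raises(ValueError):
            small_params(ff_area_coupling=1.0)


class TestStatisticalRecords:
    def test_zero_sd_gives_identical_records(self):
        params = small_params(sd_area=0.0, sd_ff=0.0)
        df = generate_stage_records(params, 10, np.random.default_rng(0))
        expected_p = np.sqrt(4.0 * np.pi * params.mean_area / params.mean_ff)
        assert (df["area"] == params.mean_area).all()
        assert (df["form_factor"] == params.mean_ff).all()
        assert df["perimeter"].to_numpy() == pytest.approx(expected_p)

    def test_circle_relation_at_ff_one(self):
        params = small_params(mean_ff=1.0, sd_ff=0.0)
        df = generate_stage_records(params, 50, np.random.default_rng(1))
        assert df["perimeter"].to_numpy() == pytest.approx(
            np.sqrt(4.0 * np.pi * df["area"].to_numpy())
        )

    def test_sample_mean_within_three_se(self):
        params = small_params()
        df = generate_stage_records(params, 500, np.random.default_rng(2))
        se = params.sd_area / np.sqrt(500)
        assert abs(df["area"].mean() - params.mean_area) < 3 * se

    def test_ff_respects_truncation_bounds(self):
        params = small_params()
        _, ff = sample_area_ff(params, 2000, np.random.default_rng(3))
        lo, hi = params.ff_bounds
        assert ff.min() >= lo and ff.max() <= hi

    def test_area_ff_negatively_coupled(self):
        """The copula couples big cells to low form factors."""
        area, ff = sample_area_ff(small_params(), 2000, np.random.default_rng(4))
        assert np.corrcoef(area, ff)[0, 1] < -0.5

    def test_perimeter_area_correlation_strong(self):
        df = generate_stage_records(small_params(), 500, np.random.default_rng(5))
        r = np.corrcoef(df["area"], df["perimeter"])[0, 1]
        assert r > 0.8

    def test_rejects_nonpositive_n(self):
        with pytest.raises(ValueError):
            sample_area_ff(small_params(), 0, np.random.default_rng(0))


class TestGroundTruth:
    def test_ff_identity_exact(self, rendered_cap_image):
        _, _, records, _ = rendered_cap_image
        for rec in records:
            ff = 4.0 * np.pi * rec.area_true / rec.perimeter_true**2
            assert ff == pytest.approx(rec.ff_true, rel=1e-12)
            assert 0.0 < rec.ff_true <= 1.0

    def test_frame_has_wkt_polygons(self, rendered_cap_image):
        _, _, records, _ = rendered_cap_image
        frame = ground_truth_frame(records)
        assert len(frame) == len(records)
        assert frame["polygon_wkt"].str.startswith("POLYGON").all()


class TestRasterizer:
    def test_translation_invariance(self):
        """The pixel set translates rigidly with integer polygon shifts."""
        from pulpmorph.geometry import ShapeSpec, generate_contour

        poly = generate_contour(ShapeSpec("star", 4.0, lobe_amplitude=0.6))
        rr0, cc0 = rasterize_polygon(poly, 0.25)
        base = np.sort(rr0 + 1j * cc0)
        for shift in ((17.0, -9.0), (-30.0, 3.0)):
            moved = poly + np.array(shift) * 0.25
            rr, cc = rasterize_polygon(moved, 0.25)
            expected = base + shift[1] + 1j * shift[0]
            assert np.array_equal(np.sort(rr + 1j * cc), expected)

    def test_disc_pixel_count_within_two_percent(self):
        from pulpmorph.geometry import ShapeSpec, generate_contour

        for radius_px in (20, 35, 60):
            poly = generate_contour(ShapeSpec("star", float(radius_px), vertex_count=512))
            rr, _ = rasterize_polygon(poly, 1.0)
            assert rr.size == pytest.approx(np.pi * radius_px**2, rel=0.02)

    def test_clips_to_image_shape(self):
        from pulpmorph.geometry import ShapeSpec, generate_contour

        poly = generate_contour(ShapeSpec("star", 10.0))  # centred on the origin
        rr, cc = rasterize_polygon(poly, 1.0, image_shape=(8, 8))
        assert rr.size > 0
        assert rr.min() >= 0 and cc.min() >= 0
        assert rr.max() < 8 and cc.max() < 8


class TestPlacementAndRendering:
    def test_zero_cells_renders_pure_background(self):
        params = small_params(cells_per_image=0, noise_sd=0.0)
        image, truth = render_study_image([], params, (64, 64), 0.25, np.random.default_rng(0))
        assert (truth == 0).all()
        assert (image == np.array(params.background_rgb, dtype=np.uint8)).all()
        mask = remove_scrap(threshold_rgb(image, DEFAULT_THRESHOLD), 5)
        assert label_regions(mask).count == 0

    def test_thirty_cells_thirty_components(self, rendered_cap_image):
        _, truth, records, _ = rendered_cap_image
        assert len(records) == 30
        n_components = int(sk_label(truth > 0, connectivity=2).max())
        assert n_components == 30

    def test_cells_disjoint_in_truth(self, rendered_cap_image):
        _, truth, records, _ = rendered_cap_image
        labels, counts = np.unique(truth[truth > 0], return_counts=True)
        assert len(labels) == len(records)
        assert (counts > 0).all()

    def test_placement_respects_bounds(self, rendered_cap_image):
        image, truth, _, _ = rendered_cap_image
        assert truth.shape == image.shape[:2]

    def test_placement_deterministic(self):
        params = small_params()
        recs1 = place_cells(params, (512, 512), 0.25, np.random.default_rng(42))
        recs2 = place_cells(params, (512, 512), 0.25, np.random.default_rng(42))
        assert len(recs1) == len(recs2)
        for a, b in zip(recs1, recs2):
            assert np.array_equal(a.polygon, b.polygon)


class TestGenerateStudy:
    def test_tree_layout_and_determinism(self, tmp_path):
        stages = stage_defaults(cells_per_image=8)
        kwargs = dict(
            stage_params=stages,
            n_cases=1,
            images_per_case=2,
            image_shape=(512, 512),
            calibration=0.125,
            seed=5,
        )
        root1 = generate_study(tmp_path / "s1", **kwargs)
        root2 = generate_study(tmp_path / "s2", **kwargs)
        pngs = sorted(p.relative_to(root1) for p in root1.rglob("*.png"))
        assert len(pngs) == 3 * 1 * 2  # groups x cases x images
        csv1 = (root1 / "ground_truth.csv").read_bytes()
        csv2 = (root2 / "ground_truth.csv").read_bytes()
        assert csv1 == csv2
        truth = pd.read_csv(root1 / "ground_truth.csv")
        assert set(truth.columns) >= {
            "case_id", "image_id", "cell_id", "area_true", "perimeter_true", "ff_true",
        }
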