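"""Similarity-transform fitting (with an independent cross-check), boundary
averaging, and consensus overlap maps."""

import numpy as np
import pytest
from shapely.geometry import LineString, box

from cortimap.geometry import FieldBoundary, RegionGeometry
from cortimap.quantify import movement_area
from cortimap.registration import (
    RegistrationError,
    Transform2D,
    average_geometry,
    consensus,
    fit_alignment,
    transform_case_map,
)
from cortimap.simulate import SimParams, simulate_case
from cortimap.tessellation import build_case_map


def named(points):
    return {f"L{i}": tuple(p) for i, p in enumerate(points)}


class TestTransform2D:
    def test_apply_then_invert_is_identity(self):
        t = Transform2D(rotation=0.3, scale=1.4, translation=(2.0, -1.0))
        pts = np.array([[0, 0], [1, 0], [1, 1], [0, 1], [0.3, 0.7]])
        back = t.inverse().apply(t.apply(pts))
        assert np.allclose(back, pts, atol=1e-9)

    def test_scale_must_be_positive(self):
        with pytest.raises(RegistrationError):
            Transform2D(scale=0.0)


class TestFitAlignment:
    def test_identity_when_src_equals_ref(self):
        pts = named([(0, 0), (3, 1), (1, 4)])
        t, residuals = fit_alignment(pts, pts)
        assert t.rotation == pytest.approx(0.0, abs=1e-12)
        assert t.scale == pytest.approx(1.0)
        assert t.translation == pytest.approx((0.0, 0.0), abs=1e-12)
        assert max(residuals.values()) <= 1e-9

    def test_pure_translation_recovered(self):
        src = named([(0, 0), (3, 1), (1, 4)])
        ref = {k: (x + 3, y - 1) for k, (x, y) in src.items()}
        t, residuals = fit_alignment(src, ref)
        assert t.translation == pytest.approx((3.0, -1.0))
        assert t.rotation == pytest.approx(0.0, abs=1e-12)
        assert t.scale == pytest.approx(1.0)
        assert max(residuals.values()) <= 1e-9

    def test_random_similarity_recovered_exactly(self):
        """Self-consistency: a planted similarity on 10 random landmarks is
        recovered with residual <= 1e-6."""
        rng = np.random.default_rng(31)
        for _ in range(20):
            pts = rng.uniform(-5, 5, size=(10, 2))
            planted = Transform2D(
                rotation=float(rng.uniform(-np.pi, np.pi)),
                scale=float(rng.uniform(0.5, 2.0)),
                translation=tuple(rng.uniform(-10, 10, 2)),
            )
            src = named(pts)
            ref = named(planted.apply(pts))
            t, residuals = fit_alignment(src, ref)
            assert max(residuals.values()) <= 1e-6
            assert t.scale == pytest.approx(planted.scale, abs=1e-9)
            # rotation compared on the circle
            dr = (t.rotation - planted.rotation + np.pi) % (2 * np.pi) - np.pi
            assert abs(dr) <= 1e-9

    def test_matches_independent_similarity_estimator(self):
        """Cross-check the closed-form fit against scikit-image's
        SimilarityTransform on a noisy correspondence set."""
        from skimage.transform import SimilarityTransform

        rng = np.random.default_rng(5)
        pts = rng.uniform(0, 10, size=(8, 2))
        target = Transform2D(0.4, 1.2, (1.0, -2.0)).apply(pts) + rng.normal(0, 0.1, (8, 2))
        t, _ = fit_alignment(named(pts), named(target))
        if hasattr(SimilarityTransform, "from_estimate"):
            sk = SimilarityTransform.from_estimate(pts, target)
        else:
            sk = SimilarityTransform()
            assert sk.estimate(pts, target)
        assert t.scale == pytest.approx(sk.scale, rel=1e-9)
        assert t.rotation == pytest.approx(sk.rotation, abs=1e-9)
        assert np.allclose(t.translation, sk.translation, atol=1e-9)

    def test_too_few_common_landmarks(self):
        with pytest.raises(RegistrationError, match=">= 2 common"):
            fit_alignment({"A": (0, 0)}, {"A": (0, 0), "B": (1, 1)})

    def test_coincident_landmarks_rejected(self):
        pts = {"A": (1.0, 1.0), "B": (1.0, 1.0)}
        with pytest.raises(RegistrationError, match="coincident"):
            fit_alignment(pts, {"A": (0, 0), "B": (2, 2)})


def geometry_with(boundaries=None, sulci=None, case_id="K1"):
    return RegionGeometry(
        case_id=case_id,
        field_boundaries={k: FieldBoundary(v) for k, v in (boundaries or {}).items()},
        sulci=sulci or {},
    )


class TestAverageGeometry:
    def test_identical_inputs_identical_output(self):
        # identity up to the arc-length resampling of the curves
        g = geometry_with(
            boundaries={"3b": box(0, 0, 2, 1)},
            sulci={"FS": LineString([(0, 0), (1, 2), (2, 2.5)])},
        )
        avg = average_geometry([g, g, g], n_points=400)
        assert avg.boundaries["3b"].area == pytest.approx(2.0, rel=1e-3)
        assert avg.boundaries["3b"].hausdorff_distance(box(0, 0, 2, 1)) < 0.01
        assert avg.sulci["FS"].hausdorff_distance(g.sulci["FS"]) < 0.01

    def test_parallel_lines_average_to_midline(self):
        a = geometry_with(sulci={"FS": LineString([(0, 0), (10, 0)])})
        b = geometry_with(sulci={"FS": LineString([(0, 2), (10, 2)])}, case_id="K2")
        avg = average_geometry([a, b])
        ys = np.asarray(avg.sulci["FS"].coords)[:, 1]
        assert np.allclose(ys, 1.0, atol=1e-9)

    def test_reversed_polyline_is_orientation_aligned(self):
        a = geometry_with(sulci={"FS": LineString([(0, 0), (10, 0)])})
        b = geometry_with(sulci={"FS": LineString([(10, 2), (0, 2)])}, case_id="K2")
        avg = average_geometry([a, b])
        ys = np.asarray(avg.sulci["FS"].coords)[:, 1]
        assert np.allclose(ys, 1.0, atol=1e-9)

    def test_jittered_curve_mean_near_truth(self):
        rng = np.random.default_rng(12)
        t = np.linspace(0, 2 * np.pi, 60)
        truth = np.column_stack([t, np.sin(t)])
        sigma = 0.2
        geoms = [
            geometry_with(
                sulci={"FS": LineString(truth + rng.normal(0, sigma, truth.shape))},
                case_id=f"K{i}",
            )
            for i in range(4)
        ]
        avg = average_geometry(geoms)
        truth_line = LineString(truth)
        from shapely.geometry import Point

        # every point of the averaged curve lies within 3 sigma/sqrt(n)
        # of the true curve
        for xy in np.asarray(avg.sulci["FS"].coords):
            assert truth_line.distance(Point(*xy)) <= 3 * sigma / np.sqrt(4)

    def test_curve_in_single_case_passed_through_with_flag(self):
        a = geometry_with(sulci={"FS": LineString([(0, 0), (1, 0)])})
        b = geometry_with(sulci={"IPS": LineString([(0, 0), (0, 1)])}, case_id="K2")
        avg = average_geometry([a, b])
        assert "FS" in avg.flags and "IPS" in avg.flags
        assert avg.sulci["FS"].equals(a.sulci["FS"])


@pytest.fixture(scope="module")
def sim_map():
    case = simulate_case(SimParams(seed=21, n_sites=80), 0)
    return build_case_map(case.sites, case.geometry)


class TestConsensus:
    def test_single_case_depth_one_on_labelled_cells(self, sim_map):
        cmap = consensus([sim_map], "tongue", resolution_mm=0.1)
        assert cmap.grid.max() == 1
        area = cmap.depth_weighted_area_mm2()
        assert area == pytest.approx(movement_area(sim_map, "tongue"), rel=0.02)

    def test_four_identical_cases_depth_four(self, sim_map):
        one = consensus([sim_map], "tongue", resolution_mm=0.1)
        four = consensus([sim_map] * 4, "tongue", resolution_mm=0.1)
        assert np.array_equal(four.grid, 4 * one.grid)
        assert four.n_cases == 4

    def test_disjoint_cases_additive(self, sim_map):
        shifted = transform_case_map(sim_map, Transform2D(translation=(100.0, 0.0)))
        cmap = consensus([sim_map, shifted], "tongue", resolution_mm=0.1)
        assert cmap.grid.max() == 1
        expected = movement_area(sim_map, "tongue") + movement_area(shifted, "tongue")
        assert cmap.depth_weighted_area_mm2() == pytest.approx(expected, rel=0.02)

    def test_depth_weighted_area_identity(self, small_study):
        from cortimap.registration import align_cases, mean_landmark_frame

        maps = [build_case_map(c.sites, c.geometry) for c in small_study.cases]
        geoms = [c.geometry for c in small_study.cases]
        fits = align_cases(geoms, mean_landmark_frame(geoms))
        aligned = [transform_case_map(m, t) for m, (t, _) in zip(maps, fits)]
        cmap = consensus(aligned, "shoulder", resolution_mm=0.05)
        expected = sum(movement_area(m, "shoulder") for m in aligned)
        assert cmap.depth_weighted_area_mm2() == pytest.approx(expected, rel=0.01)

    def test_equivariance_under_common_rigid_motion(self, sim_map):
        t = Transform2D(rotation=0.6, scale=1.0, translation=(3.0, -7.0))
        moved = transform_case_map(sim_map, t)
        a = consensus([sim_map], "shoulder", resolution_mm=0.05)
        b = consensus([moved], "shoulder", resolution_mm=0.05)
        assert b.depth_weighted_area_mm2() == pytest.approx(
            a.depth_weighted_area_mm2(), rel=0.01
        )

    def test_empty_selector_match_gives_zero_grid(self, sim_map):
        cmap = consensus([sim_map], "eye", resolution_mm=0.2)
        assert cmap.grid.max() <= 1  # eye is rare; may be absent entirely
        cmap2 = consensus([sim_map], lambda l: False, resolution_mm=0.5)
        assert cmap2.grid.max() == 0
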