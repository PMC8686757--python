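"""The 12-cone family, initial conification, and the nearest-cone fallback."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dpc12 import (
    CANONICAL_ORDER,
    CCP_CENTERS,
    Scene,
    SceneObject,
    build_family12,
    coverage_fraction,
    full_conify,
    initial_conify,
    recenter_scene,
    sample_uniform_ball,
)
from dpc12.conification import UNASSIGNED
from dpc12.geometry import point_to_cone_distance

from conftest import cap_union_solid_angle


class TestBuildFamily:
    def test_published_tf_center(self, family):
        assert tuple(family["TF"].center) == (0.0, 1.0, 1.68)
        assert family.labels == CANONICAL_ORDER

    def test_half_angles_in_expected_band(self, family):
        degs = [np.degrees(c.half_angle) for c in family]
        assert all(28.5 <= d <= 31.0 for d in degs)

    def test_sum_of_cap_fractions(self, family):
        # closed-form spherical caps from the published centers, R = 1:
        # 4 cones at ||c|| = 2.07, 6 at 1.9551, 2 at 2 -> 0.80496
        total = sum((1 - np.cos(c.half_angle)) / 2 for c in family)
        assert total == pytest.approx(0.80496, abs=1e-4)

    def test_radius_too_large_names_offending_label(self):
        with pytest.raises(ValueError, match="TF"):
            build_family12(sphere_radius=1.96)

    def test_exact_fcc_centers_are_a_touching_shell(self):
        fam = build_family12(centers="fcc")
        for cone in fam:
            assert np.linalg.norm(cone.center) == pytest.approx(2.0)
            assert cone.half_angle == pytest.approx(np.radians(30.0))

    def test_unknown_centers_option(self):
        with pytest.raises(ValueError):
            build_family12(centers="hcp")


class TestRecenter:
    def test_centroid_mode(self):
        scene = Scene([SceneObject("a", [(1, 1, 1), (3, 3, 3)])])
        shifted, anchor = recenter_scene(scene, "a", "centroid")
        assert np.allclose(anchor, (2, 2, 2))
        assert np.allclose(shifted["a"].points, [(-1, -1, -1), (1, 1, 1)])

    def test_explicit_origin_is_identity(self):
        scene = Scene([SceneObject("a", [(1, 2, 3)])])
        shifted, anchor = recenter_scene(scene, "a", np.zeros(3))
        assert np.allclose(shifted["a"].points, scene["a"].points)

    def test_object_anchor_mode(self):
        scene = Scene([SceneObject("a", [(1, 0, 0), (3, 0, 0)], anchor=(1, 0, 0))])
        shifted, anchor = recenter_scene(scene, "a", "object_anchor")
        assert np.allclose(anchor, (1, 0, 0))
        assert np.allclose(shifted["a"].points[0], (0, 0, 0))

    def test_missing_anchor_error(self):
        scene = Scene([SceneObject("a", [(1, 0, 0)])])
        with pytest.raises(ValueError, match="anchor"):
            recenter_scene(scene, "a", "object_anchor")

    def test_unknown_object_error(self):
        scene = Scene([SceneObject("a", [(1, 0, 0)])])
        with pytest.raises(KeyError):
            recenter_scene(scene, "b", "centroid")

    def test_m3ds_central_centroid_is_origin(self, m3ds_scene):
        shifted, _ = recenter_scene(m3ds_scene, "LE", "centroid")
        assert np.allclose(shifted["LE"].centroid(), 0.0, atol=1e-12)


class TestInitialConify:
    def test_generating_center_goes_to_its_own_cone(self, family):
        assert initial_conify(np.array([[0.0, 1.0, 1.68]]), family)[0] == "TF"

    def test_vertex_goes_to_first_canonical_label(self, family):
        # the vertex is on every cone's boundary; first-match picks TL
        assert initial_conify(np.zeros((1, 3)), family)[0] == "TL"

    def test_each_center_maps_to_its_label(self, family):
        pts = np.array([CCP_CENTERS[lab] for lab in CANONICAL_ORDER])
        assert list(initial_conify(pts, family)) == list(CANONICAL_ORDER)

    def test_coverage_matches_cap_union_oracle(self, family):
        pts = sample_uniform_ball(100_000, 1.0, seed=0)
        cov = coverage_fraction(initial_conify(pts, family))
        oracle = cap_union_solid_angle(
            [c.axis for c in family], [c.half_angle for c in family]
        )
        # membership depends only on direction, so ball coverage equals
        # the solid-angle fraction of the cap union (up to MC error)
        assert cov == pytest.approx(oracle, abs=0.005)

    def test_coverage_fraction_bounds(self, family):
        assigned = np.array(["TL", "TF"], dtype=object)
        assert coverage_fraction(assigned) == 1.0
        none = np.array([UNASSIGNED, UNASSIGNED], dtype=object)
        assert coverage_fraction(none) == 0.0
        with pytest.raises(ValueError):
            coverage_fraction(np.array([], dtype=object))

    def test_coverage_monotone_in_sphere_radius(self):
        pts = sample_uniform_ball(20_000, 1.0, seed=3)
        covs = [
            coverage_fraction(initial_conify(pts, build_family12(sphere_radius=r)))
            for r in (0.6, 0.8, 1.0, 1.2)
        ]
        assert covs == sorted(covs)

    @given(lam=st.floats(min_value=1e-3, max_value=1e3))
    @settings(max_examples=30, derandomize=True)
    def test_scale_invariance_of_assignments(self, lam):
        fam = build_family12()
        pts = np.random.default_rng(7).normal(size=(200, 3))
        a = initial_conify(pts, fam)
        b = initial_conify(lam * pts, fam)
        assert (a == b).all()


class TestFullConify:
    def test_no_unassigned_and_partition(self, m3ds_scene, family):
        con = full_conify(m3ds_scene, "H", "centroid", family)
        assert con.n_points == m3ds_scene.n_points
        assert not (con.cos_ids == UNASSIGNED).any()
        assert set(con.cos_ids) <= set(CANONICAL_ORDER)

    def test_fallback_fraction_matches_gap_solid_angle(self, family):
        # the fallback fraction equals the solid-angle fraction of the gaps
        # between cones (~0.1995); at this sample size the hard 20% bound is
        # within sampling noise, so compare against the quadrature oracle
        pts = sample_uniform_ball(100_000, 1.0, seed=0)
        cov = coverage_fraction(initial_conify(pts, family))
        gap = 1.0 - cap_union_solid_angle(
            [c.axis for c in family], [c.half_angle for c in family]
        )
        assert 1.0 - cov == pytest.approx(gap, abs=0.005)

    def test_idempotent_on_recentered_scene(self, m3ds_scene, family):
        shifted, _ = recenter_scene(m3ds_scene, "H", "centroid")
        con = full_conify(shifted, "H", np.zeros(3), family)
        assert np.array_equal(con.coords, shifted.all_points())

    def test_fallback_tie_breaks_to_first_canonical_label(self, family):
        # a direction between two equal-angle cones, outside both: the
        # assigned label must be the canonically first of the minimisers
        a1, a2 = family["TF"].axis, family["LF"].axis
        u = a1 + a2
        u = u / np.linalg.norm(u)
        con = full_conify(
            Scene([SceneObject("a", [u]), SceneObject("b", [(0, 0, 0.0)])]),
            "b",
            np.zeros(3),
            family,
        )
        label = con.cos_ids[0]
        dists = np.array([point_to_cone_distance(u, c) for c in family])
        minimisers = [
            lab
            for lab, d in zip(CANONICAL_ORDER, dists)
            if d <= dists.min() + 1e-12
        ]
        assert label == minimisers[0]

    def test_determinism(self, m3ds_scene, family):
        a = full_conify(m3ds_scene, "H", "centroid", family)
        b = full_conify(m3ds_scene, "H", "centroid", family)
        assert (a.cos_ids == b.cos_ids).all()
        assert np.array_equal(a.coords, b.coords)

    def test_five_parameters_per_point(self, m3ds_scene, family):
        con = full_conify(m3ds_scene, "H", "centroid", family)
        df = con.to_frame()
        assert list(df.columns) == ["x", "y", "z", "obj_id", "cos_id"]
        assert len(df) == m3ds_scene.n_points
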