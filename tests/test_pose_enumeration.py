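"""Grid primitives, anchor transforms, and the pose search."""

import math

import numpy as np
import pytest

from acedock.ace_energy import ScoringParams
from acedock.fragment_candidates import FragmentPair
from acedock.pose_enumeration import (AnchorPair, anchor_transform,
                                      axis_rotations, dball_grid, dock,
                                      enumerate_poses, filter_fragment_pairs,
                                      sphere_cap_grid)
from acedock.core_model import RigidTransform
from acedock.synthetic import make_planted_complex, make_toy_ace_table
from conftest import random_transform, toy_structure


class TestDballGrid:
    def test_step_two_d_leaves_only_center(self):
        pts = dball_grid(np.array([1.0, 2.0, 3.0]), d=2.0, step=4.0)
        np.testing.assert_array_equal(pts, [[1.0, 2.0, 3.0]])

    def test_unit_ball_has_seven_points(self):
        pts = dball_grid(np.zeros(3), d=1.0, step=1.0)
        assert len(pts) == 7
        norms = np.linalg.norm(pts, axis=1)
        assert set(np.round(norms, 9)) == {0.0, 1.0}

    def test_all_points_inside_ball_and_center_included(self, rng):
        for _ in range(10):
            center = rng.uniform(-5, 5, 3)
            d = float(rng.uniform(2, 8))
            step = float(rng.uniform(0.5, 1.5))
            pts = dball_grid(center, d, step)
            assert (np.linalg.norm(pts - center, axis=1) <= d + 1e-9).all()
            assert any(np.allclose(p, center) for p in pts)

    def test_matches_brute_force_cube_scan(self):
        center = np.array([0.3, -0.7, 1.1])
        d, step = 3.0, 0.9
        pts = dball_grid(center, d, step)
        reach = int(d / step) + 1
        expected = []
        for i in range(-reach, reach + 1):
            for j in range(-reach, reach + 1):
                for k in range(-reach, reach + 1):
                    p = center + step * np.array([i, j, k])
                    if np.linalg.norm(p - center) <= d + 1e-9:
                        expected.append(p)
        assert len(pts) == len(expected)


class TestSphereCapGrid:
    def test_center_on_sphere_makes_pole_equal_center(self):
        p = np.zeros(3)
        c = np.array([4.0, 0.0, 0.0])
        pts = sphere_cap_grid(p, r=4.0, c=c, d=2.0, step=1.0)
        assert len(pts) > 0
        np.testing.assert_allclose(pts[0], c, atol=1e-9)

    def test_disjoint_cases_are_empty(self):
        p = np.zeros(3)
        assert len(sphere_cap_grid(p, 2.0, np.array([10.0, 0, 0]), 2.0, 0.5)) == 0
        # ball entirely inside the sphere: no intersection either
        assert len(sphere_cap_grid(p, 8.0, np.array([1.0, 0, 0]), 2.0, 0.5)) == 0

    def test_membership_constraints_and_pole(self, rng):
        for _ in range(50):
            p = rng.uniform(-5, 5, 3)
            r = float(rng.uniform(1, 10))
            c = p + rng.normal(size=3) * rng.uniform(0.5, 4)
            d = float(rng.uniform(1, 6))
            step = float(rng.uniform(0.4, 1.2))
            pts = sphere_cap_grid(p, r, c, d, step)
            h = np.linalg.norm(c - p)
            disjoint = abs(h - r) > d
            if disjoint:
                assert len(pts) == 0
                continue
            assert len(pts) > 0
            np.testing.assert_allclose(np.linalg.norm(pts - p, axis=1), r, atol=1e-9)
            assert (np.linalg.norm(pts - c, axis=1) <= d + 1e-6).all()
            # first point is the cap pole: the sphere point nearest c
            pole = p + r * (c - p) / h
            np.testing.assert_allclose(pts[0], pole, atol=1e-9)
            # polar coverage reaches the cap boundary to within one ring step
            cos_max = np.clip((h * h + r * r - d * d) / (2 * r * h), -1, 1)
            phi_max = math.acos(cos_max)
            phis = np.arccos(np.clip((pts - p) @ ((c - p) / h) / r, -1, 1))
            assert phis.max() >= phi_max - step / r - 1e-9


class TestAnchorTransform:
    def test_identity_when_targets_equal_sources(self, rng):
        a_i, a_j = rng.uniform(-5, 5, 3), rng.uniform(-5, 5, 3)
        t = anchor_transform(a_i, a_j, a_i, a_j)
        np.testing.assert_allclose(t.rotation, np.eye(3), atol=1e-9)
        np.testing.assert_allclose(t.translation, np.zeros(3), atol=1e-9)

    def test_pure_shift_keeps_rotation_identity(self):
        a_i = np.array([1.0, 0.0, 0.0])
        a_j = np.array([2.0, 3.0, 0.0])
        shift = np.array([5.0, -2.0, 1.0])
        t = anchor_transform(a_i, a_j, a_i + shift, a_j + shift)
        np.testing.assert_allclose(t.rotation, np.eye(3), atol=1e-9)
        np.testing.assert_allclose(t.translation, shift, atol=1e-9)

    def test_contracts_on_random_instances(self, rng):
        for _ in range(100):
            a_i = rng.uniform(-10, 10, 3)
            a_j = rng.uniform(-10, 10, 3)
            if np.linalg.norm(a_j - a_i) < 0.5:
                continue
            g = random_transform(rng)
            p = rng.uniform(-10, 10, 3)
            q = p + g.rotation @ (a_j - a_i)
            t = anchor_transform(a_i, a_j, p, q)
            np.testing.assert_allclose(t.apply(a_i), p, atol=1e-9)
            np.testing.assert_allclose(t.apply(a_j), q, atol=1e-6)
            np.testing.assert_allclose(t.rotation.T @ t.rotation, np.eye(3), atol=1e-9)
            assert np.linalg.det(t.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_antiparallel_case(self):
        a_i, a_j = np.zeros(3), np.array([0.0, 0.0, 2.0])
        p, q = np.zeros(3), np.array([0.0, 0.0, -2.0])
        t = anchor_transform(a_i, a_j, p, q)
        np.testing.assert_allclose(t.apply(a_j), q, atol=1e-9)
        assert np.linalg.det(t.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            anchor_transform(np.zeros(3), np.array([1.0, 0, 0]),
                             np.zeros(3), np.array([2.0, 0, 0]))


class TestAxisRotations:
    def test_index_zero_is_base(self, rng):
        base = random_transform(rng)
        rots = axis_rotations(base, np.zeros(3), np.array([0.0, 0.0, 1.0]), 90.0)
        assert len(rots) == 4
        np.testing.assert_allclose(rots[0].rotation, base.rotation, atol=1e-12)
        np.testing.assert_allclose(rots[0].translation, base.translation, atol=1e-12)

    def test_axis_points_invariant(self, rng):
        p = rng.uniform(-5, 5, 3)
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        base = RigidTransform.identity()
        axis_pts = p + np.outer(np.linspace(-3, 3, 5), u)
        for t in axis_rotations(base, p, u, 45.0):
            np.testing.assert_allclose(t.apply(axis_pts), axis_pts, atol=1e-9)

    def test_off_axis_point_traces_circle(self, rng):
        p = np.zeros(3)
        u = np.array([0.0, 0.0, 1.0])
        x = np.array([2.0, 1.0, 5.0])
        images = [t.apply(x) for t in axis_rotations(RigidTransform.identity(), p, u, 30.0)]
        dists = [np.linalg.norm(im[:2]) for im in images]  # distance to the z axis
        np.testing.assert_allclose(dists, dists[0], atol=1e-9)


def coarse_pair(rng):
    """A tiny typed toy pair for counting/clash tests."""
    a = toy_structure(np.column_stack([np.zeros(6), np.zeros(6), np.arange(6) * 2.0]),
                      types=[0] * 6)
    b = toy_structure(rng.uniform(0, 5, (8, 3)), chain="B", types=[1] * 8)
    return a, b


class TestEnumeratePoses:
    def test_count_equals_product_of_grid_sizes(self, rng):
        a, b = coarse_pair(rng)
        params = ScoringParams(epsilon=0.75, rotation_step=120.0, clash_theta=0.17)
        anchors = AnchorPair(0, 5, 0, 7)
        table = make_toy_ace_table([(0, 1)])
        poses = list(enumerate_poses(a, b, anchors, params, table))
        d = params.contact_cutoff
        step = params.epsilon * d
        r = np.linalg.norm(a.coords[0] - a.coords[5])
        expected = 0
        for P in dball_grid(b.coords[0], d, step):
            expected += len(sphere_cap_grid(P, r, b.coords[7], d, step)) * 3
        assert len(poses) == expected
        # grid order is deterministic and lexicographic
        indices = [p.grid_index for p in poses]
        assert indices == sorted(indices)

    def test_engulfing_partner_leaves_no_clash_free_pose(self):
        # B is a dense cube completely filling the anchor region
        xs = np.arange(0.0, 9.0, 1.0)
        cube = np.array([[x, y, z] for x in xs for y in xs for z in xs])
        b = toy_structure(cube, chain="B", types=[1] * len(cube))
        a = toy_structure(np.column_stack([np.zeros(8), np.zeros(8), np.arange(8) * 2.0]),
                          types=[0] * 8)
        params = ScoringParams(epsilon=1.0, rotation_step=120.0)
        anchors = AnchorPair(0, 7, 0, len(cube) - 1)  # anchors across the cube
        table = make_toy_ace_table([(0, 1)])
        poses = list(enumerate_poses(a, b, anchors, params, table))
        assert poses, "enumeration should still yield candidate poses"
        assert all(p.clash for p in poses)

    def test_degenerate_anchors_yield_nothing(self, rng):
        a = toy_structure([[0.0, 0, 0], [0.5, 0, 0]], types=[0, 0])
        b = toy_structure(rng.uniform(0, 3, (4, 3)), chain="B", types=[1] * 4)
        params = ScoringParams(epsilon=0.5, rotation_step=120.0)
        table = make_toy_ace_table([(0, 1)])
        poses = list(enumerate_poses(a, b, AnchorPair(0, 1, 0, 1), params, table))
        assert poses == []


class TestFilterFragmentPairs:
    def _setup(self):
        cx = make_planted_complex(3)
        t0 = len(cx.subunit_a) - 16
        pair = FragmentPair(span_a=(t0, t0 + 14), span_b=(0, 14),
                            columns=[(t0 + i, i) for i in range(15)],
                            n_surface_a=15, n_surface_b=15)
        return cx, pair

    def test_planted_pair_survives_default_threshold(self):
        cx, pair = self._setup()
        kept = filter_fragment_pairs(cx.subunit_a, cx.subunit_b, [pair],
                                     cx.params, cx.table)
        assert len(kept) == 1
        frag, best = kept[0]
        assert frag is pair
        assert best.ace < 0 < cx.params.fragment_ace_threshold

    def test_threshold_extremes(self):
        import dataclasses
        cx, pair = self._setup()
        lax = dataclasses.replace(cx.params, fragment_ace_threshold=float("inf"))
        assert len(filter_fragment_pairs(cx.subunit_a, cx.subunit_b, [pair],
                                         lax, cx.table)) == 1
        strict = dataclasses.replace(cx.params, fragment_ace_threshold=float("-inf"))
        assert filter_fragment_pairs(cx.subunit_a, cx.subunit_b, [pair],
                                     strict, cx.table) == []


class TestDock:
    def test_recovers_planted_interface(self):
        cx = make_planted_complex(7)
        res = dock(cx.subunit_a, cx.subunit_b, cx.table, cx.params)
        assert res.ok
        assert res.interface.residue_pairs == cx.planted_interface.residue_pairs
        assert res.k_fragment_pairs >= 1
        # ranking is strictly by energy, all reported poses clash-free
        energies = [p.ace for p in res.poses]
        assert energies == sorted(energies)
        assert not any(p.clash for p in res.poses)

    def test_mutually_repulsive_pair_gives_no_prediction(self, rng):
        a = toy_structure(rng.uniform(0, 10, (20, 3)), types=[0] * 20)
        b = toy_structure(rng.uniform(0, 10, (20, 3)), chain="B", types=[1] * 20)
        table = make_toy_ace_table([(2, 3)])  # every A-B pair scores +1
        res = dock(a, b, table, ScoringParams(epsilon=0.5, rotation_step=120.0))
        assert not res.ok
        assert res.poses == []
        assert "filter" in res.reason or "threshold" in res.reason

    def test_dock_is_reproducible(self):
        cx = make_planted_complex(11)
        r1 = dock(cx.subunit_a, cx.subunit_b, cx.table, cx.params)
        r2 = dock(cx.subunit_a, cx.subunit_b, cx.table, cx.params)
        assert r1.best.ace == r2.best.ace
        assert r1.best.grid_index == r2.best.grid_index
        np.testing.assert_array_equal(r1.best.transform.rotation,
                                      r2.best.transform.rotation)
        assert r1.interface.residue_pairs == r2.interface.residue_pairs

    def test_frame_equivariance_under_lattice_translation(self):
        # translating B (and leaving A) by a whole-lattice vector must give
        # the same best energy and the same interface residue pairs
        from acedock.core_model import apply_transform
        cx = make_planted_complex(5)
        shift = np.array([7.0, -4.0, 3.0])
        t = RigidTransform(np.eye(3), shift)
        b_moved = apply_transform(cx.subunit_b, t)
        r0 = dock(cx.subunit_a, cx.subunit_b, cx.table, cx.params)
        r1 = dock(cx.subunit_a, b_moved, cx.table, cx.params)
        assert r0.ok and r1.ok
        assert r1.best.ace == pytest.approx(r0.best.ace, abs=1e-6)
        assert r0.interface.residue_pairs == r1.interface.residue_pairs
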