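"""Rigid superposition, screw-axis decomposition, axis classification and
point-group perception."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from intsymm.errors import DegenerateGeometryError
from intsymm.geometry import (
    RigidTransform,
    SymmetryAxis,
    axis_from_transform,
    classify_axis,
    combine_axes,
    detect_point_group,
    superimpose,
)
from intsymm.params import GeometryTolerances


def rot(axis, deg):
    return Rotation.from_rotvec(np.radians(deg) * np.asarray(axis, float)).as_matrix()


class TestSuperimpose:
    def test_identity_on_equal_sets(self):
        P = np.random.default_rng(0).normal(0, 5, (20, 3))
        T, rmsd = superimpose(P, P)
        assert rmsd < 1e-9
        assert np.allclose(T.rotation, np.eye(3), atol=1e-9)
        assert np.allclose(T.translation, 0, atol=1e-9)

    def test_recovers_known_rotation(self):
        P = np.random.default_rng(1).normal(0, 5, (30, 3))
        R = rot([0, 0, 1], 90)
        Q = P @ R.T
        T, rmsd = superimpose(P, Q)
        assert rmsd < 1e-9
        assert axis_from_transform(T).theta_deg == pytest.approx(90.0, abs=1e-6)

    def test_matches_independent_svd_oracle_on_noisy_data(self):
        rng = np.random.default_rng(2)
        P = rng.normal(0, 5, (50, 3))
        R = Rotation.random(random_state=rng).as_matrix()
        Q = P @ R.T + np.array([3.0, -1.0, 7.0]) + rng.normal(0, 0.5, (50, 3))
        T, rmsd = superimpose(P, Q)
        # oracle: scipy's orthogonal Procrustes about the centroids
        rot_o, _ = Rotation.align_vectors(Q - Q.mean(0), P - P.mean(0))
        Ro = rot_o.as_matrix()
        to = Q.mean(0) - Ro @ P.mean(0)
        rmsd_o = float(np.sqrt(np.mean(np.sum((P @ Ro.T + to - Q) ** 2, axis=1))))
        assert rmsd == pytest.approx(rmsd_o, abs=1e-9)
        assert np.allclose(T.rotation, Ro, atol=1e-9)

    def test_collinear_points_raise(self):
        P = np.stack([np.arange(10.0), np.zeros(10), np.zeros(10)], axis=1)
        with pytest.raises(DegenerateGeometryError):
            superimpose(P, P + 1.0)


class TestScrewAxis:
    def test_pure_rotation_about_z(self):
        T = RigidTransform(rot([0, 0, 1], 180), np.zeros(3))
        ax = axis_from_transform(T)
        assert abs(ax.direction[2]) == pytest.approx(1.0, abs=1e-9)
        assert ax.theta_deg == pytest.approx(180.0, abs=1e-9)
        assert ax.screw_t == pytest.approx(0.0, abs=1e-9)

    def test_screw_with_translation_along_axis(self):
        T = RigidTransform(rot([0, 0, 1], 120), np.array([0.0, 0.0, 5.0]))
        ax = axis_from_transform(T)
        assert ax.theta_deg == pytest.approx(120.0, abs=1e-9)
        assert abs(ax.screw_t) == pytest.approx(5.0, abs=1e-9)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_round_trip_reproduces_random_transforms(self, seed):
        rng = np.random.default_rng(seed)
        R = Rotation.random(random_state=rng).as_matrix()
        t = rng.normal(0, 10, 3)
        T = RigidTransform(R, t)
        back = axis_from_transform(T).to_transform()
        assert np.allclose(back.rotation, T.rotation, atol=1e-6)
        assert np.allclose(back.translation, T.translation, atol=1e-6)


class TestClassifyAxis:
    def axis(self, theta, t, direction=(0, 0, 1)):
        return SymmetryAxis(np.asarray(direction, float), np.zeros(3), theta, t)

    def test_closed_is_cyclic(self):
        assert classify_axis(self.axis(72.0, 0.0), 5, has_cp=True) == "C5"

    def test_open_screw_is_helical(self):
        assert classify_axis(self.axis(120.0, 4.8), 5, has_cp=False) == "H3"

    def test_open_pure_translation_is_r(self):
        assert classify_axis(self.axis(0.5, 10.0), 4, has_cp=False) == "R"

    def test_open_pure_rotation_is_r(self):
        assert classify_axis(self.axis(20.0, 0.5), 4, has_cp=False) == "R"

    def test_irregular_screw_is_superhelical(self):
        # 66 degrees is more than 5 degrees from every 360/n with n <= 8
        assert classify_axis(self.axis(66.0, 6.0), 5, has_cp=False) == "SH"


def asymmetric_blob(rng, n=20):
    return rng.normal(0, 3, (n, 3)) + np.array([12.0, 0.0, 0.0])


class TestPointGroup:
    def test_c4_square_of_repeats(self):
        rng = np.random.default_rng(0)
        base = asymmetric_blob(rng)
        reps = [base @ rot([0, 0, 1], 90 * r).T for r in range(4)]
        pg = detect_point_group(reps, rmsd_threshold=5.0)
        assert (pg.family, pg.order) == ("C", 4)

    def test_d2_fixture(self, d2_fixture):
        _, truth, trace = d2_fixture
        reps = [trace.coords[s:e + 1] for s, e in truth.repeat_ranges]
        pg = detect_point_group(reps, rmsd_threshold=5.0)
        assert (pg.family, pg.order) == ("D", 2)

    def test_two_unrelated_repeats_are_c1(self):
        rng = np.random.default_rng(3)
        a = asymmetric_blob(rng)
        b = rng.normal(0, 3, (20, 3)) + np.array([-5.0, 8.0, 3.0])
        pg = detect_point_group([a, b], rmsd_threshold=5.0)
        assert pg.label == "C1"

    def test_group_closure(self):
        """Composing any two accepted rotations lands on a group member."""
        rng = np.random.default_rng(1)
        base = asymmetric_blob(rng)
        reps = [base @ rot([0, 0, 1], 90 * r).T for r in range(4)]
        pg = detect_point_group(reps, rmsd_threshold=5.0)
        perms = {p: R for p, R in zip(pg.permutations, pg.rotations)}
        for pa, Ra in perms.items():
            for pb, Rb in perms.items():
                pc = tuple(pa[pb[i]] for i in range(len(pa)))
                assert pc in perms
                Rc = Ra @ Rb
                ang = np.degrees(
                    np.linalg.norm(Rotation.from_matrix(perms[pc].T @ Rc).as_rotvec())
                )
                assert ang < 10.0


class TestCombineAxes:
    def axis(self, direction, point=(0, 0, 0)):
        d = np.asarray(direction, float)
        return SymmetryAxis(d / np.linalg.norm(d), np.asarray(point, float), 180.0, 0.0)

    def test_collinear_two_folds_multiply(self):
        levels = [("C2", self.axis([0, 0, 1])), ("C2", self.axis([0, 0, 1]))]
        assert combine_axes(levels) == "C4"

    def test_orthogonal_two_fold_makes_dihedral(self):
        levels = [("C3", self.axis([0, 0, 1])), ("C2", self.axis([1, 0, 0]))]
        assert combine_axes(levels) == "D3"

    def test_skew_axes_stay_hierarchical(self):
        levels = [
            ("C2", self.axis([0, 0, 1])),
            ("C2", self.axis([0, 0, 1], point=(10, 0, 0))),
        ]
        assert combine_axes(levels) == "C2/C2"

    def test_empty_is_asymmetric(self):
        assert combine_axes([]) == "C1"
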