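import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import dixpol.geometry as geo
from oracles import quaternion_rmsd, screw_from_rotvec


def _rot_z(deg):
    t = math.radians(deg)
    return np.array(
        [[math.cos(t), -math.sin(t), 0], [math.sin(t), math.cos(t), 0], [0, 0, 1]]
    )


class TestSuperpose:
    def test_identical_sets_give_zero_rmsd_identity_rotation(self, rng):
        pts = rng.normal(size=(12, 3)) * 5
        res = geo.superpose(pts, pts)
        assert res.rmsd == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(res.rot, np.eye(3), atol=1e-9)

    def test_recovers_known_rotation(self, rng):
        pts = rng.normal(size=(15, 3)) * 6
        moved = pts @ _rot_z(90).T + np.array([3.0, -2.0, 7.0])
        res = geo.superpose(pts, moved)
        assert res.rmsd == pytest.approx(0.0, abs=1e-9)
        assert geo.rotation_angle_deg(res.rot) == pytest.approx(90.0, abs=1e-9)

    def test_matches_quaternion_oracle_on_noisy_clouds(self, rng):
        """Kabsch RMSD equals the quaternion-eigenvalue solution to 1e-9
        on 100 random 10-point clouds."""
        for _ in range(100):
            a = rng.normal(size=(10, 3)) * 4
            b = a @ _rot_z(rng.uniform(0, 360)).T + rng.normal(size=(10, 3)) * 0.5
            assert geo.superpose(a, b).rmsd == pytest.approx(
                quaternion_rmsd(a, b), abs=1e-9
            )

    def test_rmsd_is_symmetric(self, rng):
        a = rng.normal(size=(20, 3)) * 5
        b = a + rng.normal(size=(20, 3)) * 0.8
        assert geo.superpose(a, b).rmsd == pytest.approx(
            geo.superpose(b, a).rmsd, abs=1e-9
        )

    def test_rejects_degenerate_input(self, rng):
        line = np.outer(np.arange(5.0), [1.0, 0.0, 0.0])
        with pytest.raises(ValueError, match="collinear|degenerate"):
            geo.superpose(line, line)
        with pytest.raises(ValueError, match="3"):
            geo.superpose(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_reflection_is_corrected_to_proper_rotation(self, rng):
        a = rng.normal(size=(10, 3))
        b = a.copy()
        b[:, 2] *= -1  # mirrored cloud
        res = geo.superpose(a, b)
        assert np.linalg.det(res.rot) == pytest.approx(1.0, abs=1e-9)


class TestPairwiseRmsd:
    def test_identical_chains_mean_zero(self, single_helix):
        from dixpol.structure_model import select_coords

        _spec, structure, _ = single_helix
        sets = [select_coords(structure, c, atom_filter="CA-only") for c in "AB"]
        # subunits are rigid copies: pairwise CA RMSD is exactly zero
        mat, mean = geo.average_pairwise_rmsd(sets)
        assert mean == pytest.approx(0.0, abs=1e-9)
        assert mat.shape == (2, 2)

    def test_mean_matches_direct_computation(self, rng):
        base = rng.normal(size=(30, 3)) * 6
        sets = []
        for _k in range(3):
            noisy = base + rng.normal(size=base.shape) * 0.3
            sets.append(
                geo.CoordinateSet(
                    [(i + 1, "CA", noisy[i]) for i in range(len(noisy))]
                )
            )
        mat, mean = geo.average_pairwise_rmsd(sets)
        direct = [
            geo.superpose(sets[i].coords, sets[j].coords).rmsd
            for i in range(3)
            for j in range(i + 1, 3)
        ]
        assert mean == pytest.approx(np.mean(direct), abs=1e-12)
        np.testing.assert_allclose(mat, mat.T)
        assert np.all(np.diag(mat) == 0)


class TestScrew:
    def test_constructed_screw_recovered(self):
        sp = geo.screw_decompose(_rot_z(51.4286), [0.0, 0.0, 11.43])
        assert sp.angle == pytest.approx(51.4286, abs=1e-9)
        assert sp.rise == pytest.approx(11.43, abs=1e-9)
        np.testing.assert_allclose(sp.axis, [0, 0, 1], atol=1e-9)
        assert sp.handedness == "right"

    def test_two_fold_screw(self):
        """180 deg rotation + half-repeat translation: the classic 2_1 axis."""
        sp = geo.screw_decompose(_rot_z(180.0), [0.0, 0.0, 62.8])
        assert sp.angle == pytest.approx(180.0, abs=1e-6)
        assert sp.rise == pytest.approx(62.8, abs=1e-9)

    def test_matches_rotation_vector_oracle(self, rng):
        for _ in range(50):
            axis = rng.normal(size=3)
            axis /= np.linalg.norm(axis)
            angle = rng.uniform(5.0, 175.0)
            rise = rng.uniform(-20.0, 20.0)
            R, t = geo.screw_compose(angle, axis, rise, point=rng.normal(size=3) * 10)
            sp = geo.screw_decompose(R, t)
            o_angle, o_axis, o_rise, _ = screw_from_rotvec(R, t)
            assert sp.angle == pytest.approx(o_angle, abs=1e-9)
            assert sp.rise == pytest.approx(o_rise, abs=1e-9)
            np.testing.assert_allclose(sp.axis, o_axis, atol=1e-9)

    def test_pure_translation_rejected(self):
        with pytest.raises(ValueError, match="pure translation"):
            geo.screw_decompose(np.eye(3), [0, 0, 5.0])

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(
        angle=st.floats(1.0, 179.0),
        rise=st.floats(0.1, 25.0),
        ax=st.integers(0, 10_000),
    )
    def test_compose_decompose_round_trip(self, angle, rise, ax):
        """screw_decompose inverts screw_compose on (angle, axis, rise)."""
        rng = np.random.default_rng(ax)
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        R, t = geo.screw_compose(angle, axis, rise)
        sp = geo.screw_decompose(R, t)
        assert sp.angle == pytest.approx(angle, abs=1e-8)
        assert sp.rise == pytest.approx(rise, abs=1e-8)
        np.testing.assert_allclose(sp.axis, axis, atol=1e-7)


class TestHelixParameters:
    def _filament_coords(self, rise, twist, n, rng, sigma=0.0):
        base = rng.normal(size=(25, 3)) * 5 + np.array([12.0, 0.0, 0.0])
        out = []
        for k in range(n):
            R = _rot_z(twist * k)
            pts = base @ R.T + np.array([0, 0, rise * k])
            if sigma:
                pts = pts + rng.normal(size=pts.shape) * sigma
            out.append(pts)
        return out

    def test_ground_truth_recovery_left_handed(self, rng):
        coords = self._filament_coords(11.43, -51.4286, 8, rng)
        hp = geo.helix_parameters(coords)
        assert hp.rise == pytest.approx(11.43, abs=1e-9)
        assert hp.twist == pytest.approx(-51.4286, abs=1e-9)
        assert hp.pitch == pytest.approx(80.0, abs=1e-2)
        assert hp.subunits_per_turn == pytest.approx(7.0, abs=1e-4)
        assert hp.handedness == "left"

    def test_pitch_identity_holds(self, rng):
        coords = self._filament_coords(5.0, 60.0, 6, rng)
        hp = geo.helix_parameters(coords)
        assert hp.pitch == pytest.approx(hp.rise * 360.0 / abs(hp.twist), rel=1e-9)
        assert hp.subunits_per_turn == pytest.approx(360.0 / abs(hp.twist), rel=1e-9)

    def test_irregular_filament_rejected(self, rng):
        coords = self._filament_coords(10.0, 40.0, 3, rng)
        coords += self._filament_coords(10.0, 80.0, 3, rng)
        with pytest.raises(ValueError, match="not a regular helix"):
            geo.helix_parameters(coords)

    def test_needs_two_subunits(self, rng):
        with pytest.raises(ValueError, match="two"):
            geo.helix_parameters(self._filament_coords(10.0, 40.0, 1, rng))


class TestDimerRotation:
    def test_self_comparison_is_zero(self, rng):
        tail = rng.normal(size=(20, 3)) * 6
        head = rng.normal(size=(20, 3)) * 6 + np.array([15.0, 0, 0])
        assert geo.dimer_rotation_difference((tail, head), (tail, head)) == (
            pytest.approx(0.0, abs=1e-9)
        )

    @pytest.mark.parametrize("anchor", ["tail", "head"])
    def test_planted_head_rotation_recovered(self, rng, anchor):
        """Rotating one dimer's non-anchor subunit by 25 deg about its
        centroid is measured back exactly."""
        tail = rng.normal(size=(20, 3)) * 6
        head = rng.normal(size=(20, 3)) * 6 + np.array([15.0, 0, 0])
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        R, _ = geo.screw_compose(25.0, axis, 0.0)
        if anchor == "tail":
            head_b = (head - head.mean(0)) @ R.T + head.mean(0)
            dimer_b = (tail, head_b)
        else:
            tail_b = (tail - tail.mean(0)) @ R.T + tail.mean(0)
            dimer_b = (tail_b, head)
        got = geo.dimer_rotation_difference((tail, head), dimer_b, anchor=anchor)
        assert got == pytest.approx(25.0, abs=1e-6)
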