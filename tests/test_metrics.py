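"""Junction/pore geometry metrics against analytic and brute-force oracles."""
import math

import numpy as np
import pytest

from conftest import rigid_transform
from sheetkit.metrics import (
    HeightProfile,
    JunctionSpec,
    MetricSeries,
    analyze_height_profile,
    arm_axis,
    corner_plane_planarity,
    equilibrium_stats,
    inter_arm_angles,
    junction_planarity,
    junction_position,
    layer_count,
    planarity_dp,
    pore_internal_angles,
    pore_quadrilateral,
)
from sheetkit.oxdna import BasePairMap, Snapshot
from sheetkit.synthetic import (
    DistortionParams,
    generate_height_profile,
    generate_pore_snapshot,
)


def _dp_brute_force(j, e1, e2, e3):
    """Plane through the three tips via SVD null space, then point-plane
    distance — an independent route to d_p."""
    tips = np.array([j + e for e in (e1, e2, e3)])
    centered = tips - tips.mean(axis=0)
    _u, s, vt = np.linalg.svd(centered)
    normal = vt[-1]
    return abs(np.dot(normal, j - tips[0]))


class TestPlanarityDp:
    def test_coplanar_arms_are_flat(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            angles = np.sort(rng.uniform(0, 2 * np.pi, 3))
            if np.min(np.diff(angles)) < 0.1:
                continue
            es = [np.array([np.cos(a), np.sin(a), 0.0]) for a in angles]
            assert planarity_dp(np.zeros(3), *es) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("phi_deg", np.linspace(0, 80, 17))
    def test_uniform_tilt_gives_sin_phi(self, phi_deg):
        """d_p equals sin(tilt) exactly when all three arms share the same
        out-of-plane inclination, for any in-plane azimuths."""
        phi = math.radians(phi_deg)
        azimuths = (0.0, 2.0, 4.5)  # non-collinear in-plane arrangement
        es = [
            np.array(
                [math.cos(phi) * math.cos(a), math.cos(phi) * math.sin(a), math.sin(phi)]
            )
            for a in azimuths
        ]
        j = np.array([1.0, -2.0, 0.5])
        assert planarity_dp(j, *es) == pytest.approx(math.sin(phi), abs=1e-9)

    def test_against_brute_force_oracle_1000_tripods(self):
        rng = np.random.default_rng(123)
        n_checked = 0
        while n_checked < 1000:
            vecs = rng.normal(size=(3, 3))
            vecs /= np.linalg.norm(vecs, axis=1, keepdims=True)
            j = rng.normal(size=3)
            tips = j + vecs
            if np.linalg.norm(np.cross(tips[1] - tips[0], tips[2] - tips[0])) < 1e-6:
                continue
            got = planarity_dp(j, *vecs)
            assert got == pytest.approx(_dp_brute_force(j, *vecs), abs=1e-9)
            n_checked += 1

    def test_collinear_tips_rejected(self):
        e = np.array([1.0, 0.0, 0.0])
        with pytest.raises(ValueError, match="degenerate plane"):
            planarity_dp(np.zeros(3), e, e, e)


class TestInterArmAngles:
    def test_orthogonal_and_identical(self):
        ex, ey = np.array([1.0, 0, 0]), np.array([0, 1.0, 0])
        out = inter_arm_angles({"e1": ex, "e2": ey, "e3": ex})
        assert out["a12"] == pytest.approx(90.0, abs=1e-12)
        assert out["a13"] == pytest.approx(0.0, abs=1e-6)

    def test_non_unit_rejected(self):
        with pytest.raises(ValueError, match="unit"):
            inter_arm_angles({"e1": np.array([2.0, 0, 0]), "e2": np.array([0, 1.0, 0])})


class TestArmAxis:
    def _straight_arm(self, direction, n=16, noise=0.0, rng=None):
        direction = np.asarray(direction, float)
        mids = np.outer(np.arange(1, n + 1) * 0.4, direction)
        offs = np.array([0.5, 0.0, 0.0])
        if abs(direction[0]) > 0.9:
            offs = np.array([0.0, 0.5, 0.0])
        pos = np.empty((2 * n, 3))
        pos[:n] = mids + offs
        pos[n:] = mids - offs
        if noise:
            pos += rng.normal(0, noise, pos.shape)
        a1 = np.tile(-offs / np.linalg.norm(offs), (2 * n, 1))
        a1[n:] *= -1
        snap = Snapshot(
            time=0.0,
            box=np.full(3, 100.0),
            positions=pos,
            a1=a1,
            a3=np.tile(direction / np.linalg.norm(direction), (2 * n, 1)),
        )
        pairing = BasePairMap.from_pairs([(k, k + n) for k in range(n)])
        return snap, pairing, list(range(n))

    def test_exact_line_along_y(self):
        snap, pairing, arm = self._straight_arm([0, 1, 0])
        direction, _origin = arm_axis(snap, pairing, arm)
        np.testing.assert_allclose(direction, [0, 1, 0], atol=1e-12)

    def test_reversed_index_list_flips_sign(self):
        snap, pairing, arm = self._straight_arm([0, 1, 0])
        direction, _ = arm_axis(snap, pairing, arm[::-1])
        np.testing.assert_allclose(direction, [0, -1, 0], atol=1e-12)

    def test_noise_monte_carlo_within_3_degrees(self):
        rng = np.random.default_rng(7)
        hits = 0
        for _ in range(100):
            snap, pairing, arm = self._straight_arm(
                [0, 1, 0], noise=0.1, rng=rng
            )
            direction, _ = arm_axis(snap, pairing, arm)
            ang = math.degrees(math.acos(min(abs(direction[1]), 1.0)))
            hits += ang <= 3.0
        assert hits >= 99

    def test_too_short_arm(self):
        snap, pairing, arm = self._straight_arm([0, 1, 0])
        with pytest.raises(ValueError, match="at least 2"):
            arm_axis(snap, pairing, arm[:1])


class TestJunctionPosition:
    def test_centroid_of_proximal_midpoints(self):
        pos = np.array(
            [[0, 0, 0], [0, 0, 0], [1, 0, 0], [1, 0, 0], [0, 1, 0], [0, 1, 0],
             [2, 0, 0], [2, 0, 0], [2, 2, 0], [2, 2, 0], [0, 2, 0], [0, 2, 0]],
            dtype=float,
        )
        snap = Snapshot(
            time=0, box=np.full(3, 50.0), positions=pos,
            a1=np.tile([1.0, 0, 0], (12, 1)), a3=np.tile([0, 0, 1.0], (12, 1)),
        )
        pairing = BasePairMap.from_pairs([(k, k + 1) for k in range(0, 12, 2)])
        spec = JunctionSpec("j", arms=[[0, 6], [2, 8], [4, 10]])
        np.testing.assert_allclose(
            junction_position(snap, pairing, spec), [1 / 3, 1 / 3, 0], atol=1e-12
        )

    def test_translation_equivariance(self, funit_ideal):
        art = funit_ideal
        p0 = junction_position(art.snapshot, art.pairing, art.junctions[0])
        shifted = rigid_transform(art.snapshot, angles=(0, 0, 0), shift=np.array([1.0, 2.0, 3.0]))
        p1 = junction_position(shifted, art.pairing, art.junctions[0])
        np.testing.assert_allclose(p1 - p0, [1, 2, 3], atol=1e-9)

    def test_ground_truth_junction_recovered(self, funit_ideal):
        from sheetkit.constants import NM_PER_SU

        truth = np.asarray(funit_ideal.ground_truth.data["junctions_nm"][0])
        got = junction_position(
            funit_ideal.snapshot, funit_ideal.pairing, funit_ideal.junctions[0]
        ) * NM_PER_SU
        assert np.linalg.norm(got - truth) < 0.5


class TestEquilibriumStats:
    def test_constant_series(self):
        s = MetricSeries("c", np.arange(10.0), np.full(10, 4.2))
        mean, sd, window = equilibrium_stats(s)
        assert mean == pytest.approx(4.2) and sd == 0.0
        assert window == (5.0, 9.0)
        assert s.equilibrium_mean == mean

    def test_step_series_uses_trailing_window(self):
        vals = np.concatenate([np.ones(8), np.full(8, 3.0)])
        s = MetricSeries("step", np.arange(16.0), vals)
        mean, _sd, _w = equilibrium_stats(s, last_fraction=0.5)
        assert mean == pytest.approx(3.0)

    def test_too_few_frames(self):
        s = MetricSeries("x", np.arange(4.0), np.arange(4.0))
        with pytest.raises(ValueError, match="at least 4"):
            equilibrium_stats(s, last_fraction=0.5)


class TestPore:
    def test_ideal_pore_matches_closed_forms(self):
        art = generate_pore_snapshot()
        dxz, dyw, _ = pore_quadrilateral(art.snapshot, art.pairing, art.pore)
        assert dxz == pytest.approx(art.ground_truth.data["planar_diag_XZ_nm"], abs=1e-6)
        assert dyw == pytest.approx(art.ground_truth.data["planar_diag_YW_nm"], abs=1e-6)

    def test_internal_angles_alternate(self):
        art = generate_pore_snapshot(junction_angle_deg=80.0)
        out = pore_internal_angles(art.snapshot, art.pairing, art.pore)
        assert out["alpha"] == pytest.approx(80.0, abs=1e-6)
        assert out["beta"] == pytest.approx(100.0, abs=1e-6)
        assert out["gamma"] == pytest.approx(80.0, abs=1e-6)
        assert out["delta"] == pytest.approx(100.0, abs=1e-6)

    def test_square_pore_all_ninety(self):
        from sheetkit.design import FUnitDesign

        # equal side lengths at 90 deg: a square pore
        design = FUnitDesign(core_bp=0, arm_bp=16, se_bp=10)
        art = generate_pore_snapshot(design, junction_angle_deg=90.0)
        dxz, dyw, _ = pore_quadrilateral(art.snapshot, art.pairing, art.pore)
        assert dxz == pytest.approx(dyw, rel=1e-9)
        out = pore_internal_angles(art.snapshot, art.pairing, art.pore)
        assert all(v == pytest.approx(90.0, abs=1e-6) for v in out.values())

    def test_rigid_motion_invariance(self):
        art = generate_pore_snapshot(
            distortion=DistortionParams(positional_noise_nm=0.3, seed=5)
        )
        d0 = pore_quadrilateral(art.snapshot, art.pairing, art.pore)[:2]
        a0 = pore_internal_angles(art.snapshot, art.pairing, art.pore)
        moved = rigid_transform(art.snapshot)
        d1 = pore_quadrilateral(moved, art.pairing, art.pore)[:2]
        a1 = pore_internal_angles(moved, art.pairing, art.pore)
        np.testing.assert_allclose(d1, d0, atol=1e-9)
        for key in a0:
            assert a1[key] == pytest.approx(a0[key], abs=1e-9)

    def test_perturbed_angles_match_eigen_oracle(self):
        """Principal-axis computation via the covariance eigenproblem is an
        independent route to the TLS arm direction."""
        art = generate_pore_snapshot(
            distortion=DistortionParams(positional_noise_nm=0.2, seed=3)
        )
        partner = art.pairing.partner()
        got = pore_internal_angles(art.snapshot, art.pairing, art.pore)
        greek = dict(zip(("X", "Y", "Z", "W"), ("alpha", "beta", "gamma", "delta")))
        for label, spec in art.pore.corners.items():
            axes = []
            for arm in spec.arms:
                mids = np.array(
                    [
                        0.5 * (art.snapshot.positions[i] + art.snapshot.positions[partner[i]])
                        for i in arm
                    ]
                )
                c = mids - mids.mean(axis=0)
                w, v = np.linalg.eigh(c.T @ c)
                d = v[:, np.argmax(w)]
                if np.dot(d, mids[-1] - mids[0]) < 0:
                    d = -d
                axes.append(d)
            expected = math.degrees(
                math.acos(np.clip(np.dot(axes[0], axes[1]), -1, 1))
            )
            assert got[greek[label]] == pytest.approx(expected, abs=1e-9)


class TestCornerPlanes:
    def test_planar_quadrilateral_all_zero(self):
        pts = [(0, 0, 0), (2, 0, 0), (3, 2, 0), (-1, 2, 0)]
        out = corner_plane_planarity([np.array(p, float) for p in pts])
        assert all(v == pytest.approx(0.0, abs=1e-9) for v in out.values())

    def test_regular_tetrahedron_face_normals(self):
        pts = np.array(
            [[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float
        )
        out = corner_plane_planarity(pts)
        expected = math.degrees(math.acos(1 / 3))
        assert all(v == pytest.approx(expected, abs=1e-9) for v in out.values())

    def test_single_fold_matches_dihedral(self):
        """Folding one corner out of plane by a known dihedral about a
        diagonal reproduces the closed-form angle for the affected pair."""
        phi = math.radians(25.0)
        x, y, z = np.zeros(3), np.array([2.0, 0, 0]), np.array([2.0, 2.0, 0.0])
        w0 = np.array([0.0, 2.0, 0.0])
        # rotate W about the X-Z diagonal by phi
        axis = (z - x) / np.linalg.norm(z - x)
        c, s = math.cos(phi), math.sin(phi)
        k = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
        rot = c * np.eye(3) + s * k + (1 - c) * np.outer(axis, axis)
        w = rot @ w0
        out = corner_plane_planarity([x, y, z, w])
        # the Y and W corner planes are the two half-planes of the fold:
        # their normals close exactly the dihedral angle phi
        assert out["YW"] == pytest.approx(math.degrees(phi), abs=1e-9)

    def test_collinear_triple_rejected(self):
        pts = [(0, 0, 0), (1, 0, 0), (2, 0, 0), (1, 1, 0)]
        with pytest.raises(ValueError, match="collinear"):
            corner_plane_planarity([np.array(p, float) for p in pts])


class TestJunctionMetricInvariance:
    def test_dp_and_angles_invariant_under_rigid_motion(self, funit_tilted):
        art = funit_tilted
        dp0 = junction_planarity(art.snapshot, art.pairing, art.junctions[0])
        moved = rigid_transform(art.snapshot)
        dp1 = junction_planarity(moved, art.pairing, art.junctions[0])
        assert dp1 == pytest.approx(dp0, abs=1e-9)
        axes0 = {
            f"e{k+1}": arm_axis(art.snapshot, art.pairing, arm)[0]
            for k, arm in enumerate(art.junctions[0].arms)
        }
        axes1 = {
            f"e{k+1}": arm_axis(moved, art.pairing, arm)[0]
            for k, arm in enumerate(art.junctions[0].arms)
        }
        a0, a1 = inter_arm_angles(axes0), inter_arm_angles(axes1)
        for key in a0:
            assert a1[key] == pytest.approx(a0[key], abs=1e-9)


class TestHeightProfile:
    def test_spacing_recovered(self):
        profile, truth = generate_height_profile(
            spacing_nm=25.0, n_pores=8, noise_nm=0.1, seed=11
        )
        out = analyze_height_profile(profile)
        assert out.mean_spacing_nm == pytest.approx(25.0, abs=1.0)

    def test_layer_rounding_rule(self):
        assert layer_count(1.8) == 1
        assert layer_count(4.1) == 2
        assert layer_count(-0.3) == 0

    def test_multilayer_pattern_recovered(self):
        profile, _ = generate_height_profile(
            n_pores=2, layer_pattern=[1, 2, 1], noise_nm=0.0, seed=0
        )
        out = analyze_height_profile(profile)
        assert out.layer_counts == [1, 2, 1]

    def test_flat_profile_no_peaks(self):
        profile, _ = generate_height_profile(
            n_pores=0, layer_pattern=[0], noise_nm=0.0, seed=0
        )
        out = analyze_height_profile(profile)
        assert len(out.pore_positions_nm) == 0
        assert out.layer_counts == [0]

    def test_non_uniform_sampling_rejected(self):
        with pytest.raises(ValueError, match="non-uniform"):
            HeightProfile(positions=np.array([0.0, 1.0, 2.5]), heights=np.zeros(3))
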