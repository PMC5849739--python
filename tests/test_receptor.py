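"""Superposition, RMSD series, ionic lock and TM6 displacement."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from scipy.spatial.transform import Rotation

import memgate as mg
from memgate.core import AtomSet
from memgate.receptor import kabsch, match_atoms, rmsd, rmsd_series, \
    standard_selections
from memgate.synth import ReceptorSpec, make_path, make_receptor

from conftest import frame_of, toy_system
from oracles import quaternion_grid_rmsd

RNG = np.random.default_rng(20260901)


class TestKabsch:
    def test_identity_fit(self):
        pts = RNG.normal(size=(10, 3))
        sup = kabsch(pts, pts)
        assert sup.fit_rmsd == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(sup.rotation, np.eye(3), atol=1e-9)

    def test_pure_translation_removed(self):
        pts = RNG.normal(size=(8, 3))
        sup = kabsch(pts + [5.0, 0.0, 0.0], pts)
        assert sup.fit_rmsd == pytest.approx(0.0, abs=1e-12)

    def test_rotation_is_proper(self):
        for _ in range(20):
            a = RNG.normal(size=(6, 3))
            b = RNG.normal(size=(6, 3))
            sup = kabsch(a, b)
            assert np.linalg.det(sup.rotation) == pytest.approx(1.0,
                                                                abs=1e-9)

    def test_errors(self):
        with pytest.raises(mg.MemgateError, match="mismatch"):
            kabsch(RNG.normal(size=(5, 3)), RNG.normal(size=(6, 3)))
        with pytest.raises(mg.MemgateError, match="at least 3"):
            kabsch(RNG.normal(size=(2, 3)), RNG.normal(size=(2, 3)))
        line = np.outer(np.arange(5.0), [1.0, 0.0, 0.0])
        with pytest.raises(mg.MemgateError, match="collinear"):
            kabsch(line, line)

    def test_matches_scipy_align_vectors(self):
        """Independent cross-check against scipy's weighted Kabsch."""
        for _ in range(50):
            n = int(RNG.integers(4, 20))
            a = RNG.normal(size=(n, 3)) * 3
            b = RNG.normal(size=(n, 3)) * 3
            sup = kabsch(a, b)
            rot, rssd = Rotation.align_vectors(b - b.mean(0), a - a.mean(0))
            assert sup.fit_rmsd == pytest.approx(rssd / np.sqrt(n),
                                                 abs=1e-9)

    def test_matches_quaternion_grid_oracle(self):
        """Noisy rotated cloud: SVD answer equals direct minimisation."""
        for _ in range(10):
            n = int(RNG.integers(6, 21))
            ref = RNG.normal(size=(n, 3)) * 4
            rot = Rotation.random(random_state=int(RNG.integers(2**31)))
            mobile = ref @ rot.as_matrix().T + RNG.normal(0, 0.1, (n, 3))
            got = kabsch(mobile, ref).fit_rmsd
            oracle = quaternion_grid_rmsd(mobile, ref)
            assert got == pytest.approx(oracle, abs=1e-3)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(a=arrays(float, (9, 3), elements=st.floats(-30, 30)),
           b=arrays(float, (9, 3), elements=st.floats(-30, 30)))
    def test_fitted_never_exceeds_unfitted(self, a, b):
        """Superposition optimality: the fitted RMSD cannot be worse than
        the raw one."""
        try:
            sup = kabsch(a, b)
        except mg.MemgateError:
            return  # degenerate covariance: rotation under-determined
        assert sup.fit_rmsd <= rmsd(a, b) + 1e-9


class TestRmsdSeries:
    def test_self_reference_is_zero(self, receptor_inactive):
        system, frame, ann, _ = receptor_inactive
        sel = standard_selections(system, ann)
        traj = [mg.Frame(coords=frame.coords.copy(), time=4.0 * k)
                for k in range(5)]
        rs = rmsd_series(traj, system, frame, system,
                         (sel["tm_ca"], sel["tm_ca"]))
        np.testing.assert_allclose(rs.values, 0.0, atol=1e-12)
        assert list(rs.times) == [0.0, 4.0, 8.0, 12.0, 16.0]

    def test_linear_interpolation_linearity(self, receptor_inactive,
                                            receptor_active):
        """With the fit on an invariant core, the fitted RMSD of a linearly
        interpolated displacement is exactly linear in the fraction."""
        sys_i, fr_i, ann, _ = receptor_inactive
        _, fr_a, _, _ = receptor_active
        frames, fracs = make_path(fr_i, fr_a, 11)
        invariant = " ".join(str(s) for s in
                             ann.tm_residues([1, 2, 3, 4, 5, 8]))
        fit = mg.select(sys_i, f"resid {invariant} name CA", ann)
        measure = mg.select(
            sys_i, "resid "
            + " ".join(str(s) for s in ann.tm_residues([6])) + " name CA",
            ann)
        rs = rmsd_series(frames, sys_i, fr_i, sys_i, (fit, fit),
                         (measure, measure))
        np.testing.assert_allclose(rs.values, fracs * rs.values[-1],
                                   atol=1e-9)

    def test_npxxy_of_inactive_like_frame_is_below_threshold(
            self, receptor_inactive):
        system, frame, ann, _ = receptor_inactive
        sel = standard_selections(system, ann)
        rs = rmsd_series([frame], system, frame, system,
                         (sel["tm_ca"], sel["tm_ca"]),
                         (sel["npxxy_backbone"], sel["npxxy_backbone"]))
        assert rs.values[0] < mg.Thresholds().npxxy_inactive_max

    def test_empty_selection_raises(self, receptor_inactive):
        system, frame, ann, _ = receptor_inactive
        empty = AtomSet(np.array([], dtype=int), "empty")
        with pytest.raises(mg.MemgateError):
            rmsd_series([frame], system, frame, system, (empty, empty))


class TestIonicLock:
    def test_right_triangle_distance(self):
        sys = toy_system(2, names=["CA", "CA"], resseqs=[131, 268],
                         resnames=["ARG", "GLU"])
        ann = _mini_annotation()
        fr = frame_of([[0, 0, 0], [3, 4, 12]])
        assert mg.ionic_lock_distance(fr, sys, ann) == pytest.approx(13.0)

    def test_rigid_transform_invariance(self, receptor_active):
        system, frame, ann, _ = receptor_active
        d0 = mg.ionic_lock_distance(frame, system, ann)
        rot = Rotation.from_euler("xyz", [0.3, -1.1, 2.0]).as_matrix()
        moved = mg.Frame(coords=frame.coords @ rot.T + [7.0, -3.0, 11.0])
        assert mg.ionic_lock_distance(moved, system, ann) == \
            pytest.approx(d0, abs=1e-9)

    def test_missing_calpha_raises(self):
        sys = toy_system(2, names=["CB", "CA"], resseqs=[131, 268],
                         resnames=["ARG", "GLU"])
        with pytest.raises(mg.MemgateError):
            mg.ionic_lock_distance(frame_of([[0, 0, 0], [1, 1, 1]]),
                                   sys, _mini_annotation())


class TestSidechainPhosphate:
    def _system(self, nh_coords, lipid_blocks):
        names = ["CA", "NH1", "NH2"]
        resseqs = [131, 131, 131]
        resnames = ["ARG"] * 3
        roles = ["protein"] * 3
        lids = [-1] * 3
        coords = [[0, 0, 0]] + list(nh_coords)
        for k, block in enumerate(lipid_blocks):
            for nm, xyz in block:
                names.append(nm)
                resseqs.append(500 + k)
                resnames.append("DOPG")
                roles.append("lipid")
                lids.append(k)
                coords.append(xyz)
        sys = toy_system(len(names), names=names, resseqs=resseqs,
                         resnames=resnames, lipid_ids=lids)
        sys.roles = np.array(roles, dtype=object)
        return sys, np.array(coords, dtype=float)

    def test_min_over_terminal_atoms(self):
        sys, coords = self._system(
            [[10, 0, 0], [0, 10, 0]],
            [[("P", [15.0, 0.0, 0.0])]])  # 5 from NH1, ~18 from NH2
        d, lid = mg.sidechain_phosphate_distance(
            frame_of(coords, box=[200, 200, 200]), sys, _mini_annotation())
        assert d == pytest.approx(5.0)

    def test_closest_lipid_identity(self):
        sys, coords = self._system(
            [[0, 0, 0], [0, 0, 0]],
            [[("P", [12.0, 0.0, 0.0])], [("P", [4.0, 0.0, 0.0])]])
        d, lid = mg.sidechain_phosphate_distance(
            frame_of(coords, box=[200, 200, 200]), sys, _mini_annotation())
        assert d == pytest.approx(4.0)
        assert lid == 1

    def test_minimum_image_across_x_boundary(self):
        # NH at x=3, lipid P at x=43 in a 46 Å box: direct 40, imaged 6
        sys, coords = self._system(
            [[3, 0, 0], [3, 0, 0]],
            [[("P", [43.0, 0.0, 0.0])]])
        d, _ = mg.sidechain_phosphate_distance(
            frame_of(coords, box=[46, 46, 46]), sys, _mini_annotation())
        assert d == pytest.approx(6.0)

    def test_no_lipids_is_an_error(self):
        sys, coords = self._system([[1, 0, 0], [0, 1, 0]], [])
        with pytest.raises(mg.MemgateError):
            mg.sidechain_phosphate_distance(frame_of(coords), sys,
                                            _mini_annotation())


class TestTm6Displacement:
    def test_identical_structures(self, receptor_inactive):
        system, frame, ann, _ = receptor_inactive
        assert mg.tm6_displacement((system, frame), (system, frame), ann) \
            == pytest.approx(0.0, abs=1e-12)

    def test_prescribed_hinge_displacement_recovered(self):
        """A bundle built with a 10 Å TM6 tip swing measures as 10 Å."""
        spec = ReceptorSpec(tm6_tip_displacement=10.0, lock_active=17.0,
                            npxxy_shift=0.0)
        sys_i, fr_i, ann, _ = make_receptor(spec, "inactive")
        sys_a, fr_a, _, _ = make_receptor(spec, "active")
        d = mg.tm6_displacement((sys_a, fr_a), (sys_i, fr_i), ann)
        assert d == pytest.approx(10.0, abs=0.1)


def _mini_annotation():
    bw = {"3.40": 121, "3.50": 131, "5.50": 211, "6.25": 263, "6.29": 267,
          "6.30": 268, "6.32": 270, "6.35": 273, "6.44": 282, "7.49": 322,
          "7.50": 323, "7.51": 324, "7.52": 325, "7.53": 326}
    return mg.ReceptorAnnotation(
        bw_map=bw,
        tm_ranges={3: (103, 136), 6: (262, 298)},
        motifs={"ionic_lock": ["3.50", "6.30"]},
        chain="A")


def test_match_atoms_drops_unpaired(receptor_inactive):
    system, frame, ann, _ = receptor_inactive
    sel = standard_selections(system, ann)
    full = sel["tm_ca"]
    partial = AtomSet(full.indices[5:], "partial")
    ia, ib = match_atoms(system, full, system, partial)
    assert len(ia) == len(partial)
    np.testing.assert_array_equal(ia, ib)
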