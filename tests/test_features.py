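"""Dihedral, RMSD and axis-projection featurization checks."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from k2ptraj.features import (
    FeaturizationError,
    SFSelection,
    canonical_sf_selection,
    axial_coordinate,
    dihedral,
    dihedral_column_labels,
    extract_sf_dihedrals,
    sf_backbone_rmsd,
    sincos_expand,
    wrap_degrees,
    xy_distance,
)
from k2ptraj.io import AtomRecord, Trajectory
from k2ptraj.synthetic import SFGeometrySpec, build_filter_coordinates


def dihedral_oracle(p1, p2, p3, p4):
    """Independent torsion formula: project the outer bonds onto the plane
    perpendicular to the central bond and take the signed angle."""
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b0, b1, b2 = p1 - p2, p3 - p2, p4 - p3
    b1u = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1u) * b1u
    w = b2 - np.dot(b2, b1u) * b1u
    x = np.dot(v, w)
    y = np.dot(np.cross(b1u, v), w)
    return wrap_degrees(np.degrees(np.arctan2(y, x)))


finite_coord = st.floats(-50, 50, allow_nan=False, allow_infinity=False)
point = st.tuples(finite_coord, finite_coord, finite_coord)


class TestDihedral:
    def test_planar_cis_is_zero(self):
        assert dihedral((0, 0, 0), (1, 0, 0), (1, 1, 0), (0, 1, 0)) == pytest.approx(
            dihedral_oracle((0, 0, 0), (1, 0, 0), (1, 1, 0), (0, 1, 0)), abs=1e-12
        )
        assert dihedral((0, 0, 0), (1, 0, 0), (1, 1, 0), (0, 1, 0)) == pytest.approx(0.0, abs=1e-12)

    def test_planar_trans_is_180(self):
        ang = dihedral((0, 0, 0), (1, 0, 0), (1, 1, 0), (2, 1, 0))
        assert ang == pytest.approx(180.0, abs=1e-12)

    def test_right_handed_quarter_turn_is_positive(self):
        # clockwise-positive (IUPAC) sign convention
        ang = dihedral((0, 1, 0), (0, 0, 0), (1, 0, 0), (1, 0, 1))
        assert ang == pytest.approx(90.0, abs=1e-12)

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(p1=point, p2=point, p3=point, p4=point)
    def test_matches_oracle_with_symmetries(self, p1, p2, p3, p4):
        try:
            ang = dihedral(p1, p2, p3, p4)
        except FeaturizationError:
            return  # degenerate quadruple: no defined torsion to compare
        assert ang == pytest.approx(dihedral_oracle(p1, p2, p3, p4), abs=1e-4)
        # reversal symmetry: same angle
        assert dihedral(p4, p3, p2, p1) == pytest.approx(ang, abs=1e-4)
        # mirror (z -> -z): negated angle (+/-180 are the same point)
        mirrored = [np.array(p) * [1, 1, -1] for p in (p1, p2, p3, p4)]
        m = dihedral(*mirrored)
        assert min(abs(m + ang), abs(abs(m) - 180.0) + abs(abs(ang) - 180.0)) < 1e-4

    def test_collinear_rejected(self):
        with pytest.raises(FeaturizationError, match="collinear"):
            dihedral((0, 0, 0), (1, 0, 0), (2, 0, 0), (3, 1, 0))

    def test_coincident_rejected(self):
        with pytest.raises(FeaturizationError, match="coincident"):
            dihedral((0, 0, 0), (0, 0, 0), (1, 1, 0), (2, 1, 0))


class TestExtraction:
    def test_round_trip_against_oracle(self, filter_traj, sf_selection):
        matrix = extract_sf_dihedrals(filter_traj, sf_selection)
        assert matrix.shape == (1, 44)
        index = filter_traj.atom_index()
        frame = filter_traj.frames[0]

        def pos(c, r, n):
            return frame[index[(c, r, n)]]

        labels = dihedral_column_labels(sf_selection)
        for j, (chain, res, kind) in enumerate(labels):
            if kind == "phi":
                quad = (pos(chain, res - 1, "C"), pos(chain, res, "N"),
                        pos(chain, res, "CA"), pos(chain, res, "C"))
            elif kind == "psi":
                quad = (pos(chain, res, "N"), pos(chain, res, "CA"),
                        pos(chain, res, "C"), pos(chain, res + 1, "N"))
            else:
                quad = (pos(chain, res, "N"), pos(chain, res, "CA"),
                        pos(chain, res, "CB"), pos(chain, res, "OG1"))
            assert matrix[0, j] == pytest.approx(dihedral_oracle(*quad), abs=1e-6)

    def test_frame_count_preserved(self, filter_traj, sf_selection):
        frames = np.repeat(filter_traj.frames, 100, axis=0)
        traj = Trajectory(filter_traj.atom_table, frames, frame_interval=0.1)
        assert extract_sf_dihedrals(traj, sf_selection).shape == (100, 44)

    def test_three_ploop_selection_rejected(self):
        loops = canonical_sf_selection().ploops[:3]
        with pytest.raises(FeaturizationError, match="4 P-loops"):
            SFSelection(ploops=loops)

    def test_missing_atom_named(self, filter_traj, sf_selection):
        atoms = [a for a in filter_traj.atom_table
                 if a.key() != ("A", 131, "CA")]
        keep = [i for i, a in enumerate(filter_traj.atom_table)
                if a.key() != ("A", 131, "CA")]
        traj = Trajectory(atoms, filter_traj.frames[:, keep, :])
        with pytest.raises(FeaturizationError, match="chain A, residue 131, atom CA"):
            extract_sf_dihedrals(traj, sf_selection)


class TestSinCos:
    def test_interleaving_and_units(self):
        out = sincos_expand(np.array([[0.0, 90.0]]))
        np.testing.assert_allclose(out, [[0.0, 1.0, 1.0, 0.0]], atol=1e-15)

    def test_unit_circle_identity(self, rng):
        angles = rng.uniform(-180, 180, (50, 44))
        out = sincos_expand(angles)
        np.testing.assert_allclose(out[:, 0::2] ** 2 + out[:, 1::2] ** 2, 1.0,
                                   atol=1e-12)


class TestRMSD:
    def test_identity_is_zero(self, filter_traj, sf_selection):
        assert sf_backbone_rmsd(filter_traj, sf_selection)[0] == pytest.approx(0.0, abs=1e-9)

    def test_rigid_motion_is_zero(self, filter_traj, sf_selection):
        theta = np.radians(90.0)
        rot = np.array([[np.cos(theta), -np.sin(theta), 0],
                        [np.sin(theta), np.cos(theta), 0], [0, 0, 1]])
        moved = filter_traj.frames[0] @ rot.T + np.array([5.0, -3.0, 12.0])
        traj = Trajectory(filter_traj.atom_table,
                          np.stack([filter_traj.frames[0], moved]))
        assert sf_backbone_rmsd(traj, sf_selection)[1] == pytest.approx(0.0, abs=1e-6)

    def test_single_displacement_closed_form(self, filter_traj, sf_selection):
        # no-fit oracle: displacing one of n atoms by d gives RMSD d/sqrt(n);
        # the optimal fit can only reduce it, and for a symmetric 80-atom
        # ring the correction is O(1/n)
        d = 0.5
        n = 4 * 5 * 4  # ploops x residues x backbone atoms
        index = filter_traj.atom_index()
        moved = filter_traj.frames[0].copy()
        moved[index[("A", 131, "CA")]] += [0.0, 0.0, d]
        traj = Trajectory(filter_traj.atom_table,
                          np.stack([filter_traj.frames[0], moved]))
        rmsd = sf_backbone_rmsd(traj, sf_selection)[1]
        no_fit = d / np.sqrt(n)
        assert rmsd <= no_fit + 1e-12
        assert rmsd == pytest.approx(no_fit, rel=0.05)


class TestAxisProjections:
    def ion_traj(self, filter_traj, ion_positions):
        atoms = list(filter_traj.atom_table) + [
            AtomRecord("K", "K", 500, "I", tuple(ion_positions[0]))
        ]
        frames = np.concatenate(
            [np.repeat(filter_traj.frames, len(ion_positions), axis=0),
             np.asarray(ion_positions, dtype=float)[:, None, :]],
            axis=1,
        )
        return Trajectory(atoms, frames)

    def test_rigid_translation_invariance(self, filter_traj, sf_selection):
        traj = self.ion_traj(filter_traj, [[0.0, 0.0, 20.0], [0.0, 0.0, 20.0]])
        traj.frames[1] += np.array([7.0, -4.0, 11.0])
        z = axial_coordinate(traj, [("I", 500, "K")], sf_selection)
        assert z[0, 0] == pytest.approx(z[1, 0], abs=1e-9)
        xy = xy_distance(traj, [("I", 500, "K")], sf_selection)
        assert xy[0, 0] == pytest.approx(xy[1, 0], abs=1e-9)

    def test_axial_shift_by_five(self, filter_traj, sf_selection):
        traj = self.ion_traj(filter_traj,
                             [[0.0, 0.0, 10.0], [0.0, 0.0, 15.0]])
        z = axial_coordinate(traj, [("I", 500, "K")], sf_selection)
        assert z[1, 0] - z[0, 0] == pytest.approx(5.0, abs=1e-9)

    def test_xy_three_four_five(self, filter_traj, sf_selection):
        from k2ptraj.features import sf_axis_origin

        c = sf_axis_origin(filter_traj, sf_selection)[0]
        traj = self.ion_traj(filter_traj, [[c[0] + 3.0, c[1] + 4.0, 0.0], [c[0], c[1], 5.0]])
        xy = xy_distance(traj, [("I", 500, "K")], sf_selection)
        assert xy[0, 0] == pytest.approx(5.0, abs=1e-9)
        assert xy[1, 0] == pytest.approx(0.0, abs=1e-9)


class TestNoisyRoundTrip:
    def test_extraction_error_bounded_by_noise(self, sf_selection):
        clean = build_filter_coordinates(SFGeometrySpec(), seed=0)
        noisy = build_filter_coordinates(SFGeometrySpec(angular_noise=5.0), seed=0)
        a = extract_sf_dihedrals(clean, sf_selection)
        b = extract_sf_dihedrals(noisy, sf_selection)
        diff = np.abs(wrap_degrees(a - b))
        # only psi/chi1-adjacent carbonyl orientations move; bounded by a few sigma
        assert diff.max() < 45.0
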