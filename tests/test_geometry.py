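"""Geometric observables: centroids, distances, partners, angles, alignment."""

import numpy as np
import pytest

from gatelatch import (
    AtomRecord,
    Structure,
    Trajectory,
    align_structure,
    align_to_pore_axis,
    azimuthal_rotation,
    met_ring_distance,
    nearest_gate_partner,
    pore_diameter_proxy,
    radial_angle,
    ring_centroid,
)
from gatelatch.geometry import nearest_ring_partner
from gatelatch.structure import PHE_RING_ATOMS


def _atom(chain, resid, name, xyz, resname="PHE", element="C", mass=12.011):
    return AtomRecord(name, element, resname, resid, chain, np.asarray(xyz, float), mass)


def _hexagon(center, radius=1.39, plane="xy"):
    pts = []
    for a in np.radians(np.arange(0, 360, 60)):
        if plane == "xy":
            pts.append(center + radius * np.array([np.cos(a), np.sin(a), 0.0]))
        else:
            pts.append(center + radius * np.array([np.cos(a), 0.0, np.sin(a)]))
    return pts


def _ring_structure(center, chain="A", resid=171, extra=()):
    atoms = [
        _atom(chain, resid, nm, p) for nm, p in zip(PHE_RING_ATOMS, _hexagon(center))
    ]
    atoms.extend(extra)
    return Structure(atoms, subunit_ring=[chain])


class TestRingCentroid:
    def test_hexagon_at_origin(self):
        s = _ring_structure(np.zeros(3))
        np.testing.assert_allclose(
            ring_centroid(s, s.coordinates, "A", 171), [0, 0, 0], atol=1e-12
        )

    def test_translation_equivariance(self):
        s = _ring_structure(np.array([1.0, 2.0, 3.0]))
        np.testing.assert_allclose(
            ring_centroid(s, s.coordinates, "A", 171), [1, 2, 3], atol=1e-12
        )

    def test_distorted_hexagon_matches_hand_mean(self):
        pts = np.array(
            [[0.1, 0, 0], [1.2, 0.4, 0], [2.0, 1.5, 0.3],
             [1.1, 2.6, 0], [-0.2, 2.2, -0.1], [-0.6, 1.0, 0]]
        )
        atoms = [_atom("A", 171, nm, p) for nm, p in zip(PHE_RING_ATOMS, pts)]
        s = Structure(atoms, subunit_ring=["A"])
        np.testing.assert_allclose(
            ring_centroid(s, s.coordinates, "A", 171), pts.mean(axis=0), atol=1e-12
        )

    def test_atom_order_permutation_invariant(self, rng):
        pts = rng.normal(size=(6, 3))
        atoms = [_atom("A", 171, nm, p) for nm, p in zip(PHE_RING_ATOMS, pts)]
        s1 = Structure(atoms, subunit_ring=["A"])
        order = rng.permutation(6)
        s2 = Structure([atoms[i] for i in order], subunit_ring=["A"])
        np.testing.assert_allclose(
            ring_centroid(s1, s1.coordinates, "A", 171),
            ring_centroid(s2, s2.coordinates, "A", 171),
            atol=1e-12,
        )

    def test_missing_ring_atom_named(self):
        s = _ring_structure(np.zeros(3))
        atoms = [a for a in s.atoms if a.atom_name != "CZ"]
        s2 = Structure(atoms, subunit_ring=["A"])
        with pytest.raises(ValueError, match="CZ"):
            ring_centroid(s2, s2.coordinates, "A", 171)


class TestMetRingDistance:
    def test_sulfur_at_centroid(self):
        extra = [_atom("A", 173, "SD", [0, 0, 0], "MET", "S", 32.065)]
        s = _ring_structure(np.zeros(3), extra=extra)
        assert met_ring_distance(s, s.coordinates, "A", 173, "SD", "A", 171) == pytest.approx(0.0, abs=1e-12)

    def test_axial_offset(self):
        extra = [_atom("A", 173, "SD", [0, 0, 5.0], "MET", "S", 32.065)]
        s = _ring_structure(np.zeros(3), extra=extra)
        assert met_ring_distance(s, s.coordinates, "A", 173, "SD", "A", 171) == pytest.approx(5.0)

    def test_missing_atom_errors(self):
        s = _ring_structure(np.zeros(3))
        with pytest.raises(ValueError, match="SD"):
            met_ring_distance(s, s.coordinates, "A", 173, "SD", "A", 171)


def _partner_fixture(d_succ, d_pred):
    """Three-subunit ring: A's Met between B (successor) and C (predecessor)."""
    atoms = [_atom("A", 173, "CB", [0, 0, 0], "MET")]
    atoms += [_atom("A", 1, "CA", [0, -5, 0], "ALA")]
    atoms += [_atom("B", 1, "CA", [20, 0, 0], "ALA")]
    atoms += [_atom("C", 1, "CA", [-20, 0, 0], "ALA")]
    atoms += [_atom("B", 171, nm, p) for nm, p in zip(PHE_RING_ATOMS, _hexagon(np.array([d_succ, 0, 0]), plane="xz"))]
    atoms += [_atom("C", 171, nm, p) for nm, p in zip(PHE_RING_ATOMS, _hexagon(np.array([-d_pred, 0, 0]), plane="xz"))]
    return Structure(atoms, subunit_ring=["A", "B", "C"])


class TestNearestGatePartner:
    def test_successor_is_nearer(self):
        s = _partner_fixture(5.0, 9.0)
        chain, d = nearest_gate_partner(s, s.coordinates, "A", 173, 171, "CB")
        assert chain == "B"
        assert d == pytest.approx(5.0)

    def test_tie_breaks_to_successor(self):
        s = _partner_fixture(6.0, 6.0)
        chain, _ = nearest_gate_partner(s, s.coordinates, "A", 173, 171, "CB")
        assert chain == "B"

    def test_chain_not_in_ring_errors(self, toy_channel):
        with pytest.raises(ValueError, match="ring"):
            nearest_gate_partner(toy_channel, toy_channel.coordinates, "Z")

    def test_brute_force_over_neighbors(self, short_trajectory):
        """Returned distance never exceeds the other adjacent candidate."""
        traj, _ = short_trajectory
        topo = traj.topology
        for f in range(0, traj.n_frames, 10):
            coords = traj.coords[f]
            for chain in topo.subunit_ring:
                partner, d = nearest_gate_partner(topo, coords, chain, 173, 171, "SD")
                pred, succ = topo.ring_neighbors(chain)
                both = {
                    c: met_ring_distance(topo, coords, chain, 173, "SD", c, 171)
                    for c in (pred, succ)
                }
                assert d == pytest.approx(min(both.values()))
                assert partner in both

    def test_any_partner_is_global_minimum(self, toy_channel):
        coords = toy_channel.coordinates
        chain, d = nearest_ring_partner(toy_channel, coords, "A", 173, 259, "CB")
        all_d = [
            met_ring_distance(toy_channel, coords, "A", 173, "CB", c, 259)
            for c in toy_channel.subunit_ring
        ]
        assert d == pytest.approx(min(all_d))


def _radial_fixture(ca171_offset):
    """Seven CAs whose mean sits at vertex (5, 0, 5); CA171 at vertex+offset."""
    vertex = np.array([5.0, 0.0, 5.0])
    ca171 = vertex + np.asarray(ca171_offset, float)
    others = (7 * vertex - ca171) / 6
    atoms = [_atom("A", 171, "CA", ca171, "PHE")]
    for r in (168, 169, 170, 172, 173, 174):
        atoms.append(_atom("A", r, "CA", others + (r - 171) * 1e-9, "ALA"))
    return Structure(atoms, subunit_ring=["A"])


class TestRadialAngle:
    def test_toward_axis_is_zero(self):
        s = _radial_fixture([-2.0, 0.0, 0.0])  # toward the axis foot
        assert radial_angle(s, s.coordinates, "A") == pytest.approx(0.0, abs=1e-6)

    def test_outward_is_180(self):
        s = _radial_fixture([2.0, 0.0, 0.0])
        assert radial_angle(s, s.coordinates, "A") == pytest.approx(180.0, abs=1e-6)

    def test_tangential_is_90(self):
        s = _radial_fixture([0.0, 2.0, 0.0])
        assert radial_angle(s, s.coordinates, "A") == pytest.approx(90.0, abs=1e-4)

    def test_matches_hand_vector_formula(self, rng):
        for _ in range(100):
            off = rng.normal(size=3)
            if np.linalg.norm(off) < 0.1:
                continue
            s = _radial_fixture(off)
            got = radial_angle(s, s.coordinates, "A")
            vertex = np.array([5.0, 0.0, 5.0])
            r1 = np.array([0, 0, vertex[2]]) - vertex
            r2 = off
            want = np.degrees(
                np.arccos(r1 @ r2 / np.linalg.norm(r1) / np.linalg.norm(r2))
            )
            assert got == pytest.approx(want, abs=1e-4)
            assert 0.0 <= got <= 180.0

    def test_missing_window_residue_errors(self):
        s = _radial_fixture([1, 1, 0])
        atoms = [a for a in s.atoms if a.residue_number != 169]
        s2 = Structure(atoms, subunit_ring=["A"])
        with pytest.raises(ValueError, match="169"):
            radial_angle(s2, s2.coordinates, "A")


def _rotz(deg):
    t = np.radians(deg)
    c, s = np.cos(t), np.sin(t)
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1.0]])


class TestAzimuthalRotation:
    def test_identity_is_zero(self, toy_channel):
        assert azimuthal_rotation(
            toy_channel, toy_channel.coordinates, "A", 171, toy_channel
        ) == pytest.approx(0.0)

    def test_known_rotation_recovered(self, toy_channel):
        coords = toy_channel.coordinates @ _rotz(20.0).T
        assert azimuthal_rotation(toy_channel, coords, "A", 171, toy_channel) == pytest.approx(20.0, abs=1e-9)

    def test_wraps_to_signed_interval(self, toy_channel):
        coords = toy_channel.coordinates @ _rotz(190.0).T
        assert azimuthal_rotation(toy_channel, coords, "A", 171, toy_channel) == pytest.approx(-170.0, abs=1e-9)


class TestPoreDiameterProxy:
    def _six_rings(self, radii):
        atoms = []
        for k, (chain, r) in enumerate(zip("ABCDEF", radii)):
            center = _rotz(60 * k) @ np.array([r, 0.0, 0.0])
            atoms += [
                _atom(chain, 171, nm, p)
                for nm, p in zip(PHE_RING_ATOMS, _hexagon(center))
            ]
            atoms.append(_atom(chain, 1, "CA", center + [0, 0, 5], "ALA"))
        return Structure(atoms, subunit_ring=list("ABCDEF"))

    def test_uniform_circle(self):
        s = self._six_rings([4.0] * 6)
        assert pore_diameter_proxy(s, s.coordinates) == pytest.approx(8.0)

    def test_mixed_radii_mean(self):
        s = self._six_rings([3, 3, 3, 5, 5, 5])
        assert pore_diameter_proxy(s, s.coordinates) == pytest.approx(8.0)

    def test_on_axis_is_zero(self):
        s = self._six_rings([0.0] * 6)
        assert pore_diameter_proxy(s, s.coordinates) == pytest.approx(0.0, abs=1e-12)


def _rigid(coords, rng):
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    R = np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )
    t = rng.normal(scale=20.0, size=3)
    return coords @ R.T + t


class TestAlignment:
    def test_tilted_bundle_axis_recovered(self, toy_channel, rng):
        """A 30°-tilted channel aligns back to |axis·ẑ| ≥ 0.9999."""
        t = np.radians(30.0)
        Rx = np.array([[1, 0, 0], [0, np.cos(t), -np.sin(t)], [0, np.sin(t), np.cos(t)]])
        tilted = Trajectory(topology=toy_channel, coords=(toy_channel.coordinates @ Rx.T)[None])
        aligned = align_to_pore_axis(tilted)
        # independent principal-axis computation via SVD
        idx = [
            i
            for i, a in enumerate(toy_channel.atoms)
            if a.atom_name == "CA" and 141 <= a.residue_number <= 174
        ]
        pts = aligned.coords[0][idx]
        pts = pts - pts.mean(axis=0)
        _, _, vt = np.linalg.svd(pts, full_matrices=False)
        assert abs(vt[0] @ [0, 0, 1]) >= 0.9999
        np.testing.assert_allclose(pts.mean(axis=0), 0.0, atol=1e-9)

    def test_aligned_frame_changes_only_by_z_rotation(self, toy_channel):
        aligned = align_structure(toy_channel)
        again = align_structure(aligned)
        # radial and axial coordinates untouched by a z-rotation
        c1, c2 = aligned.coordinates, again.coordinates
        np.testing.assert_allclose(
            np.hypot(c1[:, 0], c1[:, 1]), np.hypot(c2[:, 0], c2[:, 1]), atol=1e-9
        )
        np.testing.assert_allclose(c1[:, 2], c2[:, 2], atol=1e-9)

    def test_rigid_motion_invariance_of_observables(self, short_trajectory, rng):
        """Distances and radial angles are identical after any rigid motion."""
        traj, _ = short_trajectory
        frame = traj.coords[0][None]
        ref = Trajectory(topology=traj.topology, coords=frame)
        moved = Trajectory(topology=traj.topology, coords=_rigid(frame[0], rng)[None])
        a1 = align_to_pore_axis(ref)
        a2 = align_to_pore_axis(moved)
        topo = traj.topology
        for chain in topo.subunit_ring:
            _, d1a = nearest_gate_partner(topo, a1.coords[0], chain, 173, 171, "SD")
            _, d1b = nearest_gate_partner(topo, a2.coords[0], chain, 173, 171, "SD")
            assert d1a == pytest.approx(d1b, abs=1e-6)
            ra = radial_angle(topo, a1.coords[0], chain)
            rb = radial_angle(topo, a2.coords[0], chain)
            assert ra == pytest.approx(rb, abs=1e-4)
        assert pore_diameter_proxy(topo, a1.coords[0]) == pytest.approx(
            pore_diameter_proxy(topo, a2.coords[0]), abs=1e-6
        )

    def test_reference_pins_azimuth(self, short_trajectory, rng):
        """With a reference, azimuthal rotation is rigid-motion invariant too."""
        traj, _ = short_trajectory
        ref = align_structure(traj.topology)
        frame = traj.coords[5][None]
        moved = _rigid(frame[0], rng)[None]
        a1 = align_to_pore_axis(
            Trajectory(topology=traj.topology, coords=frame), reference=ref
        )
        a2 = align_to_pore_axis(
            Trajectory(topology=traj.topology, coords=moved), reference=ref
        )
        for chain in traj.topology.subunit_ring:
            r1 = azimuthal_rotation(traj.topology, a1.coords[0], chain, 171, ref)
            r2 = azimuthal_rotation(traj.topology, a2.coords[0], chain, 171, ref)
            assert r1 == pytest.approx(r2, abs=1e-4)

    def test_too_few_atoms_degenerate(self):
        atoms = [
            _atom("A", r, "CA", [0, 0, r], "ALA") for r in (141, 142)
        ]
        s = Structure(atoms, subunit_ring=["A"])
        with pytest.raises(ValueError, match="degenerate"):
            align_to_pore_axis(Trajectory(topology=s, coords=s.coordinates[None]))
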