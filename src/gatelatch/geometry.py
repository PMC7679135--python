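"""Per-frame geometric observables around the hydrophobic gate.

All observables assume a pore-aligned frame: the principal axis of the TM1
pore-helix Cα atoms along +z, the pore-helix Cα centroid at the origin.
:func:`align_to_pore_axis` produces that frame; every other function then
reduces to elementary vector algebra.

Distance labels follow the convention used for Met-aromatic gate contacts in
hexameric channels:

=====  ===========  ====================================================
label  Met atom     aromatic partner
=====  ===========  ====================================================
d1     Sδ (M173)    F171 ring of the nearest ring-adjacent subunit
d2     Sδ (M173)    nearest F259 ring (any subunit)
d3     Cβ (M173)    F171 ring of the nearest ring-adjacent subunit
d4     Cβ (M173)    nearest F259 ring (any subunit)
=====  ===========  ====================================================

Ring positions are the mass-weighted centroid of the six phenylalanine ring
carbons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structure import PHE_RING_ATOMS, Structure, Trajectory, select_indices

__all__ = [
    "GeometryConstants",
    "DistanceSeries",
    "AngleSeries",
    "align_structure",
    "align_to_pore_axis",
    "ring_centroid",
    "met_ring_distance",
    "nearest_gate_partner",
    "nearest_ring_partner",
    "compute_distance_series",
    "radial_angle",
    "azimuthal_rotation",
    "pore_diameter_proxy",
]

DEFAULT_PORE_HELIX = range(141, 175)  # TM1 pore helix, dOrai numbering


@dataclass(frozen=True)
class GeometryConstants:
    """Geometry conventions for the gate-latch analysis.

    ``contact_cutoff`` — Met-Phe contact/non-contact split, Å.
    ``crystal_reference_angle`` — azimuthal orientation of the F171 side
    chain in the closed crystal structure, degrees.
    ``crystal_d3`` / ``crystal_d4`` — Cβ(M173)-ring distances in the closed
    crystal structure, Å.
    ``turn_window`` — residue half-width used for the "two helical turns"
    centred on the gate residue (±3 ≈ 1.9 turns).
    """

    contact_cutoff: float = 7.0
    crystal_reference_angle: float = 30.6
    crystal_d3: float = 7.3
    crystal_d4: float = 5.8
    turn_window: int = 3


@dataclass
class DistanceSeries:
    """Per-frame, per-subunit Met-to-ring distances (Å)."""

    label: str
    values: np.ndarray          # (n_frames, n_subunits)
    partner_subunit: np.ndarray  # (n_frames, n_subunits) chain ids
    chains: list[str]           # subunit order of the columns

    def pooled(self) -> np.ndarray:
        """All samples (frames × subunits) as a flat array."""
        return self.values.ravel()


@dataclass
class AngleSeries:
    """Per-frame, per-subunit angles (degrees)."""

    kind: str                   # "radial_angle" | "azimuthal_rotation"
    values: np.ndarray          # (n_frames, n_subunits)
    chains: list[str]
    reference: str = ""

    def pooled(self) -> np.ndarray:
        return self.values.ravel()


# ---------------------------------------------------------------------------
# alignment

def _pore_helix_ca_indices(topology: Structure, residues, chains) -> np.ndarray:
    idx: list[int] = []
    for c in chains:
        for i, a in enumerate(topology.atoms):
            if a.chain_id == c and a.atom_name == "CA" and a.residue_number in residues:
                idx.append(i)
    return np.asarray(idx, dtype=int)


def _principal_axis(points: np.ndarray) -> np.ndarray:
    centred = points - points.mean(axis=0)
    cov = centred.T @ centred
    w, v = np.linalg.eigh(cov)
    return v[:, -1]


def _rotation_to_z(axis: np.ndarray) -> np.ndarray:
    """Minimal rotation taking the unit vector ``axis`` onto +z."""
    a = axis / np.linalg.norm(axis)
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(a, z)
    s = np.linalg.norm(v)
    c = float(a @ z)
    if s < 1e-12:
        if c > 0:
            return np.eye(3)
        return np.diag([1.0, -1.0, -1.0])  # 180° about x
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * ((1 - c) / s**2)


def _align_frame(
    coords: np.ndarray,
    ca_idx: np.ndarray,
    lower_idx: np.ndarray,
    upper_idx: np.ndarray,
    ref_xy: np.ndarray | None,
) -> np.ndarray:
    pts = coords[ca_idx]
    axis = _principal_axis(pts)
    # orient the axis along the helix N→C direction so that flipped inputs
    # align identically
    direction = coords[upper_idx].mean(axis=0) - coords[lower_idx].mean(axis=0)
    if axis @ direction < 0:
        axis = -axis
    R = _rotation_to_z(axis)
    out = (coords - pts.mean(axis=0)) @ R.T
    if ref_xy is not None:
        p = out[ca_idx]
        A = float(ref_xy[:, 0] @ p[:, 0] + ref_xy[:, 1] @ p[:, 1])
        B = float(ref_xy[:, 1] @ p[:, 0] - ref_xy[:, 0] @ p[:, 1])
        theta = np.arctan2(B, A)
        ct, st = np.cos(theta), np.sin(theta)
        Rz = np.array([[ct, -st, 0.0], [st, ct, 0.0], [0.0, 0.0, 1.0]])
        out = out @ Rz.T
    return out


def align_to_pore_axis(
    traj: Trajectory,
    pore_helix_residues=DEFAULT_PORE_HELIX,
    reference: Structure | None = None,
    chains: list[str] | None = None,
) -> Trajectory:
    """Align every frame so the pore axis lies along +z.

    Per frame, the principal axis of the pore-helix Cα cloud (all ring
    chains) is rotated onto +z and the cloud's centroid is moved to the
    origin.  If ``reference`` is given (an already-aligned structure), an
    additional rotation about z minimises the in-plane RMSD of the pore-helix
    Cα atoms to the reference, pinning the azimuthal origin; without it the
    azimuth of each frame is left untouched (the minimal rotation is used).
    """
    topology = traj.topology
    chains = chains or topology.subunit_ring
    residues = set(pore_helix_residues)
    ca_idx = _pore_helix_ca_indices(topology, residues, chains)
    if len(ca_idx) < 3:
        raise ValueError(
            f"degenerate axis: only {len(ca_idx)} pore-helix CA atoms found"
        )
    med = np.median([topology.atoms[i].residue_number for i in ca_idx])
    lower = np.asarray([i for i in ca_idx if topology.atoms[i].residue_number <= med])
    upper = np.asarray([i for i in ca_idx if topology.atoms[i].residue_number > med])
    ref_xy = None
    if reference is not None:
        ref_xy = reference.coordinates[ca_idx][:, :2]
    aligned = np.stack(
        [_align_frame(traj.coords[f], ca_idx, lower, upper, ref_xy)
         for f in range(traj.n_frames)]
    )
    return Trajectory(
        topology=topology,
        coords=aligned,
        frame_spacing=traj.frame_spacing,
        repeat_id=traj.repeat_id,
        time_offset=traj.time_offset,
    )


def align_structure(
    structure: Structure,
    pore_helix_residues=DEFAULT_PORE_HELIX,
    reference: Structure | None = None,
    chains: list[str] | None = None,
) -> Structure:
    """Single-structure convenience wrapper around :func:`align_to_pore_axis`."""
    traj = Trajectory(topology=structure, coords=structure.coordinates[None])
    aligned = align_to_pore_axis(traj, pore_helix_residues, reference, chains)
    return structure.with_coordinates(aligned.coords[0])


# ---------------------------------------------------------------------------
# per-frame observables

def ring_centroid(
    topology: Structure, coords: np.ndarray, chain: str, residue: int
) -> np.ndarray:
    """Mass-weighted centroid of the six Phe ring carbons (Å).

    All six carbons have equal mass, so this is their arithmetic mean; a
    missing ring atom is an error naming the atom.
    """
    pos = []
    for name in PHE_RING_ATOMS:
        try:
            pos.append(coords[topology.index_of(chain, residue, name)])
        except KeyError:
            raise ValueError(
                f"ring atom {name} missing for {chain}/{residue}"
            ) from None
    return np.mean(pos, axis=0)


def met_ring_distance(
    topology: Structure,
    coords: np.ndarray,
    met_chain: str,
    met_residue: int,
    met_atom: str,
    phe_chain: str,
    phe_residue: int,
) -> float:
    """Distance from a Met atom (Sδ or Cβ) to a Phe ring centroid (Å)."""
    try:
        p = coords[topology.index_of(met_chain, met_residue, met_atom)]
    except KeyError:
        raise ValueError(
            f"atom {met_atom} missing for {met_chain}/{met_residue}"
        ) from None
    c = ring_centroid(topology, coords, phe_chain, phe_residue)
    return float(np.linalg.norm(p - c))


def nearest_gate_partner(
    topology: Structure,
    coords: np.ndarray,
    met_chain: str,
    met_residue: int = 173,
    candidate_residue: int = 171,
    met_atom: str = "SD",
) -> tuple[str, float]:
    """The nearer of the two ring-adjacent subunits' candidate rings.

    Returns ``(partner_chain, distance)``.  Ties break toward the
    ring-successor chain.
    """
    pred, succ = topology.ring_neighbors(met_chain)
    d_succ = met_ring_distance(
        topology, coords, met_chain, met_residue, met_atom, succ, candidate_residue
    )
    d_pred = met_ring_distance(
        topology, coords, met_chain, met_residue, met_atom, pred, candidate_residue
    )
    if d_succ <= d_pred:
        return succ, d_succ
    return pred, d_pred


def nearest_ring_partner(
    topology: Structure,
    coords: np.ndarray,
    met_chain: str,
    met_residue: int,
    candidate_residue: int,
    met_atom: str,
) -> tuple[str, float]:
    """Nearest candidate ring over all subunits (used for the F259 partner)."""
    best: tuple[str, float] | None = None
    for chain in topology.subunit_ring:
        d = met_ring_distance(
            topology, coords, met_chain, met_residue, met_atom, chain, candidate_residue
        )
        if best is None or d < best[1]:
            best = (chain, d)
    assert best is not None
    return best


_LABELS = {
    "d1": ("SD", 171, "adjacent"),
    "d2": ("SD", 259, "any"),
    "d3": ("CB", 171, "adjacent"),
    "d4": ("CB", 259, "any"),
}


def compute_distance_series(
    traj: Trajectory, label: str, met_residue: int = 173
) -> DistanceSeries:
    """Per-frame, per-subunit distance series for one of the labels d1–d4."""
    try:
        met_atom, partner_res, mode = _LABELS[label]
    except KeyError:
        raise ValueError(f"unknown distance label {label!r}; expected d1..d4") from None
    topology = traj.topology
    chains = topology.subunit_ring
    values = np.empty((traj.n_frames, len(chains)))
    partners = np.empty((traj.n_frames, len(chains)), dtype=object)
    for f in range(traj.n_frames):
        coords = traj.coords[f]
        for s, chain in enumerate(chains):
            if mode == "adjacent":
                p, d = nearest_gate_partner(
                    topology, coords, chain, met_residue, partner_res, met_atom
                )
            else:
                p, d = nearest_ring_partner(
                    topology, coords, chain, met_residue, partner_res, met_atom
                )
            values[f, s] = d
            partners[f, s] = p
    return DistanceSeries(label=label, values=values, partner_subunit=partners,
                          chains=list(chains))


def radial_angle(
    topology: Structure,
    coords: np.ndarray,
    chain: str,
    residue: int = 171,
    window: int = 3,
) -> float:
    """Angle (degrees, in [0, 180]) between the pore axis and the gate Cα.

    The vertex is the Cα centre of mass of the two helical turns centred on
    the residue (residues ``residue ± window``); ray 1 runs from the vertex
    to its perpendicular foot on the z axis, ray 2 from the vertex to the
    residue's Cα.  Requires a pore-aligned frame.
    """
    pos = []
    missing = []
    for r in range(residue - window, residue + window + 1):
        try:
            pos.append(coords[topology.index_of(chain, r, "CA")])
        except KeyError:
            missing.append(r)
    if missing:
        raise ValueError(f"missing CA atoms on chain {chain}: residues {missing}")
    vertex = np.mean(pos, axis=0)
    ray1 = np.array([0.0, 0.0, vertex[2]]) - vertex  # toward the axis foot
    if np.linalg.norm(ray1) < 1e-9:
        raise ValueError("vertex lies on the pore axis; radial direction undefined")
    ca = coords[topology.index_of(chain, residue, "CA")]
    ray2 = ca - vertex
    cosang = float(ray1 @ ray2 / (np.linalg.norm(ray1) * np.linalg.norm(ray2)))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def _wrap_deg(angle: float) -> float:
    """Wrap to (−180, 180]."""
    a = (angle + 180.0) % 360.0 - 180.0
    if a == -180.0:
        a = 180.0
    return a


def azimuthal_rotation(
    topology: Structure,
    coords: np.ndarray,
    chain: str,
    residue: int,
    reference: Structure,
) -> float:
    """Signed Cα azimuth change vs a reference structure, degrees.

    Both the frame and the reference must be pore-aligned (same azimuthal
    origin).  Positive values are counterclockwise viewed from the
    extracellular (+z) side; result wrapped to (−180, 180].
    """
    i = topology.index_of(chain, residue, "CA")
    p = coords[i]
    r = reference.coordinates[i]
    for v, who in ((p, "frame"), (r, "reference")):
        if np.hypot(v[0], v[1]) < 1e-9:
            raise ValueError(f"CA lies on the pore axis in the {who}")
    az = np.degrees(np.arctan2(p[1], p[0]) - np.arctan2(r[1], r[0]))
    return _wrap_deg(float(az))


def pore_diameter_proxy(
    topology: Structure, coords: np.ndarray, gate_residue: int = 171
) -> float:
    """Twice the mean xy-radius of the six gate-residue ring centroids (Å).

    A transparent stand-in for a pore-diameter metric; requires a
    pore-aligned frame and a complete gate ring in every subunit.
    """
    radii = []
    for chain in topology.subunit_ring:
        c = ring_centroid(topology, coords, chain, gate_residue)
        radii.append(np.hypot(c[0], c[1]))
    return float(2.0 * np.mean(radii))
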