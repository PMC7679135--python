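"""Axial occupancy analysis of the pore.

Water / ion histograms are accumulated inside a cylinder of radius 10 Å
around the pore axis, with axial coordinates measured relative to the centre
of mass of the pore-helix Cα atoms (residues 141–174 over all six chains).
Per-bin quantities are mean counts per frame; error bars are standard errors
over independent simulation repeats.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .ensemble import welch_two_sided
from .structure import Structure, Trajectory

__all__ = [
    "AxialHistogram",
    "axial_reference",
    "cylinder_axial_histogram",
    "repeat_axial_histogram",
    "water_count_at_z",
    "calpha_axial_distribution",
]

DEFAULT_CYLINDER_RADIUS = 10.0  # Å
DEFAULT_BIN_WIDTH = 1.0  # Å
DEFAULT_Z_RANGE = (-30.0, 30.0)  # Å relative to the pore-helix Cα COM
PORE_HELIX_RESIDUES = range(141, 175)

WATER_RESNAMES = {"HOH", "SOL", "WAT", "TIP3", "TIP"}
_SPECIES_DEFAULTS = {
    "water": {"residues": WATER_RESNAMES, "atoms": {"O", "OW", "OH2"}},
    "Na+": {"residues": {"NA", "SOD"}, "atoms": {"NA", "SOD"}},
    "Cl-": {"residues": {"CL", "CLA"}, "atoms": {"CL", "CLA"}},
}


@dataclass
class AxialHistogram:
    """Mean per-frame occupancy along the pore axis."""

    species: str
    bin_edges: np.ndarray
    mean_counts: np.ndarray
    sem: np.ndarray | None
    cylinder_radius: float
    n_frames: int = 0
    n_repeats: int = 1

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


def axial_reference(
    topology: Structure,
    coords: np.ndarray,
    residues=PORE_HELIX_RESIDUES,
    chains: Sequence[str] | None = None,
) -> float:
    """z of the pore-helix Cα centre of mass; the axial origin downstream."""
    chains = chains or topology.subunit_ring
    residues = set(residues)
    zs, missing = [], set(residues)
    for i, a in enumerate(topology.atoms):
        if a.atom_name == "CA" and a.chain_id in chains and a.residue_number in residues:
            zs.append(coords[i][2])
            missing.discard(a.residue_number)
    if missing:
        raise ValueError(f"pore-helix residues missing CA atoms: {sorted(missing)}")
    return float(np.mean(zs))


def _species_indices(
    topology: Structure, species: str, species_map: dict | None
) -> np.ndarray:
    spec = dict(_SPECIES_DEFAULTS.get(species, {}))
    if species_map and species in species_map:
        spec = species_map[species]
    if not spec:
        raise ValueError(f"unknown species {species!r} and no override supplied")
    res = {r.upper() for r in spec.get("residues", set())}
    names = {n.upper() for n in spec.get("atoms", set())}
    return np.asarray(
        [
            i
            for i, a in enumerate(topology.atoms)
            if a.residue_name.upper() in res and a.atom_name.upper() in names
        ],
        dtype=int,
    )


def cylinder_axial_histogram(
    traj: Trajectory,
    species: str = "water",
    radius: float = DEFAULT_CYLINDER_RADIUS,
    bin_width: float = DEFAULT_BIN_WIDTH,
    z_range: tuple[float, float] = DEFAULT_Z_RANGE,
    species_map: dict | None = None,
) -> AxialHistogram:
    """Mean per-frame count of a species in axial bins of a pore cylinder.

    Atoms with xy-radius ≤ ``radius`` are binned by z relative to
    :func:`axial_reference` of the same frame.  Frames are assumed aligned
    (and the trajectory equilibration-trimmed by the caller).
    """
    if traj.n_frames == 0:
        raise ValueError("trajectory has no frames")
    idx = _species_indices(traj.topology, species, species_map)
    lo, hi = z_range
    nbins = int(round((hi - lo) / bin_width))
    edges = lo + bin_width * np.arange(nbins + 1)
    counts = np.zeros(nbins)
    for f in range(traj.n_frames):
        coords = traj.coords[f]
        z0 = axial_reference(traj.topology, coords)
        if idx.size:
            pts = coords[idx]
            inside = np.hypot(pts[:, 0], pts[:, 1]) <= radius
            c, _ = np.histogram(pts[inside, 2] - z0, bins=edges)
            counts += c
    return AxialHistogram(
        species=species,
        bin_edges=edges,
        mean_counts=counts / traj.n_frames,
        sem=None,
        cylinder_radius=radius,
        n_frames=traj.n_frames,
    )


def repeat_axial_histogram(
    repeats: Sequence[Trajectory], species: str = "water", **kwargs
) -> AxialHistogram:
    """Mean over repeats of per-repeat mean counts, with SEM over repeats."""
    if len(repeats) == 0:
        raise ValueError("no repeats supplied")
    hists = [cylinder_axial_histogram(t, species, **kwargs) for t in repeats]
    stack = np.stack([h.mean_counts for h in hists])
    sem = None
    if len(hists) > 1:
        sem = stack.std(axis=0, ddof=1) / np.sqrt(len(hists))
    return AxialHistogram(
        species=species,
        bin_edges=hists[0].bin_edges,
        mean_counts=stack.mean(axis=0),
        sem=sem,
        cylinder_radius=hists[0].cylinder_radius,
        n_frames=sum(h.n_frames for h in hists),
        n_repeats=len(hists),
    )


def _bin_index(edges: np.ndarray, z: float) -> int:
    if not (edges[0] <= z < edges[-1]):
        raise ValueError(f"z = {z} Å outside the binned range [{edges[0]}, {edges[-1]})")
    return int(np.searchsorted(edges, z, side="right") - 1)


def water_count_at_z(
    hists_a: Sequence[AxialHistogram],
    hists_b: Sequence[AxialHistogram],
    z: float = 15.0,
) -> tuple[float, float, float]:
    """Compare mean water counts at one axial position across repeats.

    ``hists_a`` / ``hists_b`` are per-repeat histograms for the two variants;
    the sample for each repeat is its mean count in the bin containing ``z``.
    Returns ``(mean_a, mean_b, p)`` with a two-sided Welch p-value.
    """
    if len(hists_a) < 2 or len(hists_b) < 2:
        raise ValueError("need at least 2 repeats per variant")
    ia = _bin_index(hists_a[0].bin_edges, z)
    ib = _bin_index(hists_b[0].bin_edges, z)
    a = [h.mean_counts[ia] for h in hists_a]
    b = [h.mean_counts[ib] for h in hists_b]
    _, p = welch_two_sided(a, b)
    return float(np.mean(a)), float(np.mean(b)), p


def calpha_axial_distribution(
    traj: Trajectory,
    residues: Sequence[int],
    bin_width: float = 0.5,
    z_range: tuple[float, float] | None = None,
) -> dict[int, tuple[np.ndarray, np.ndarray]]:
    """Per-residue normalized histogram of Cα axial position.

    Pools frames and subunits; returns ``{residue: (bin_edges, probs)}``
    with each probability vector summing to 1.  Shared edges across residues.
    """
    if traj.n_frames == 0:
        raise ValueError("trajectory has no frames")
    topology = traj.topology
    per_res: dict[int, list[float]] = {r: [] for r in residues}
    for f in range(traj.n_frames):
        coords = traj.coords[f]
        z0 = axial_reference(topology, coords)
        for r in residues:
            for chain in topology.subunit_ring:
                try:
                    i = topology.index_of(chain, r, "CA")
                except KeyError:
                    raise ValueError(f"residue {r} has no CA on chain {chain}") from None
                per_res[r].append(coords[i][2] - z0)
    allz = np.concatenate([np.asarray(v) for v in per_res.values()])
    if z_range is None:
        lo = np.floor(allz.min() / bin_width) * bin_width - bin_width
        hi = np.ceil(allz.max() / bin_width) * bin_width + bin_width
    else:
        lo, hi = z_range
    edges = lo + bin_width * np.arange(int(round((hi - lo) / bin_width)) + 1)
    out = {}
    for r, zs in per_res.items():
        c, _ = np.histogram(zs, bins=edges)
        out[r] = (edges, c / c.sum())
    return out
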