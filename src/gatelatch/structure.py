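"""Structures, trajectories and atom selections.

The in-memory model is deliberately small: an ordered list of
:class:`AtomRecord` with author residue numbering (matching the closed-state
dOrai crystal structure), an optional box, and the cyclic order of the six
channel subunits around the pore.  Trajectories are a fixed topology plus an
``(n_frames, n_atoms, 3)`` coordinate array with a physical time per frame.

PDB parsing is delegated to :mod:`gemmi`; author numbering and chain labels
are preserved exactly as read.  Two trajectory containers are accepted, both
hand-writable in a text editor: multi-model PDB and a whitespace-delimited
frame table with columns ``frame chain resid atom x y z``.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np
import pandas as pd

__all__ = [
    "AtomRecord",
    "Structure",
    "Trajectory",
    "PHE_RING_ATOMS",
    "NUMBERING_OFFSET",
    "read_pdb",
    "write_pdb",
    "read_trajectory",
    "read_frame_table",
    "write_frame_table",
    "select_atoms",
    "select_indices",
    "map_residue_numbering",
]

#: The six ring carbons of a phenylalanine side chain.  Ring centroids are
#: computed over these atoms only; ring hydrogens are absent from crystal
#: structures and are excluded by convention.
PHE_RING_ATOMS: tuple[str, ...] = ("CG", "CD1", "CD2", "CE1", "CE2", "CZ")

#: dOrai residue number = hOrai1 residue number + 72 (e.g. hOrai1 F99 is
#: dOrai F171, hOrai1 M101 is dOrai M173).
NUMBERING_OFFSET: int = 72

_FALLBACK_MASSES = {"C": 12.011, "N": 14.007, "O": 15.999, "S": 32.065,
                    "H": 1.008, "NA": 22.990, "CL": 35.453, "P": 30.974}


@dataclass(frozen=True)
class AtomRecord:
    """One atom: identity plus coordinates (Å) and mass (amu)."""

    atom_name: str
    element: str
    residue_name: str
    residue_number: int
    chain_id: str
    coordinates: np.ndarray
    mass: float

    def __post_init__(self) -> None:
        xyz = np.asarray(self.coordinates, dtype=float)
        if xyz.shape != (3,) or not np.all(np.isfinite(xyz)):
            raise ValueError(f"atom {self.key} has non-finite coordinates")
        object.__setattr__(self, "coordinates", xyz)
        if not self.mass > 0:
            raise ValueError(f"atom {self.key} has non-positive mass")

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.residue_number, self.atom_name)


class Structure:
    """An ordered atom list with an explicit cyclic subunit order.

    Parameters
    ----------
    atoms:
        Atom records in file order.  ``(chain, residue_number, atom_name)``
        must be unique.
    box:
        Optional orthorhombic box lengths in Å.
    subunit_ring:
        Cyclic order of the channel subunits around the pore.  Defaults to
        the ascending chain ids of all chains that contain a CA atom, which
        for the hexameric channel use case yields the six protein chains and
        skips solvent.
    """

    def __init__(
        self,
        atoms: Sequence[AtomRecord],
        box: Sequence[float] | None = None,
        subunit_ring: Sequence[str] | None = None,
    ):
        self.atoms: list[AtomRecord] = list(atoms)
        self.box = None if box is None else tuple(float(b) for b in box)
        index: dict[tuple[str, int, str], int] = {}
        for i, a in enumerate(self.atoms):
            if a.key in index:
                raise ValueError(f"duplicate atom {a.key}")
            index[a.key] = i
        self._index = index
        if subunit_ring is None:
            subunit_ring = sorted(
                {a.chain_id for a in self.atoms if a.atom_name == "CA"}
            )
        self.subunit_ring: list[str] = list(subunit_ring)
        chains = {a.chain_id for a in self.atoms}
        missing = [c for c in self.subunit_ring if c not in chains]
        if missing:
            raise ValueError(f"subunit_ring chains absent from structure: {missing}")

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coordinates(self) -> np.ndarray:
        """``(n_atoms, 3)`` coordinate array (a copy)."""
        return np.array([a.coordinates for a in self.atoms], dtype=float)

    @property
    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms], dtype=float)

    def index_of(self, chain_id: str, residue_number: int, atom_name: str) -> int:
        return self._index[(chain_id, residue_number, atom_name)]

    def with_coordinates(self, coords: np.ndarray) -> "Structure":
        """A copy of this structure carrying new coordinates."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ValueError("coordinate array shape does not match atom count")
        atoms = [replace(a, coordinates=c) for a, c in zip(self.atoms, coords)]
        return Structure(atoms, box=self.box, subunit_ring=self.subunit_ring)

    def ring_neighbors(self, chain_id: str) -> tuple[str, str]:
        """(predecessor, successor) of ``chain_id`` in the cyclic ring order."""
        try:
            i = self.subunit_ring.index(chain_id)
        except ValueError:
            raise ValueError(f"chain {chain_id!r} not in subunit ring") from None
        n = len(self.subunit_ring)
        return self.subunit_ring[(i - 1) % n], self.subunit_ring[(i + 1) % n]


@dataclass
class Trajectory:
    """Ordered frames over a fixed topology.

    Frame ``i`` carries physical time ``time_offset + (i + 1) * frame_spacing``
    ns, i.e. a frame records the end of its sampling interval; a 400-frame
    trajectory at 1 ns spacing spans (0, 400] ns.
    """

    topology: Structure
    coords: np.ndarray
    frame_spacing: float = 1.0
    repeat_id: str = "rep0"
    time_offset: float = 0.0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[1:] != (len(self.topology), 3):
            raise ValueError(
                f"coords must be (n_frames, {len(self.topology)}, 3); "
                f"got {self.coords.shape}"
            )
        if not self.frame_spacing > 0:
            raise ValueError("frame_spacing must be positive")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def times(self) -> np.ndarray:
        """Per-frame time in ns."""
        return self.time_offset + self.frame_spacing * (np.arange(self.n_frames) + 1)

    def frame(self, i: int) -> np.ndarray:
        return self.coords[i]


def _atom_mass(atom: gemmi.Atom) -> float:
    w = atom.element.weight
    if w and w > 0:
        return float(w)
    guess = _FALLBACK_MASSES.get(atom.name[:1].upper())
    if guess is None:
        raise ValueError(f"cannot assign a mass to atom {atom.name!r}")
    return guess


def _records_from_model(model: gemmi.Model) -> list[AtomRecord]:
    records = []
    for chain in model:
        for residue in chain:
            for atom in residue:
                records.append(
                    AtomRecord(
                        atom_name=atom.name,
                        element=atom.element.name.upper(),
                        residue_name=residue.name,
                        residue_number=residue.seqid.num,
                        chain_id=chain.name,
                        coordinates=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                        mass=_atom_mass(atom),
                    )
                )
    return records


def _read_gemmi(path: str | Path) -> gemmi.Structure:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"cannot parse PDB file {path}: {exc}") from exc
    if len(st) == 0 or sum(1 for _ in _records_from_model(st[0])) == 0:
        raise ValueError(f"no ATOM/HETATM records found in {path}")
    return st


def read_pdb(path: str | Path, subunit_ring: Sequence[str] | None = None) -> Structure:
    """Read a PDB file into a :class:`Structure`.

    Author residue numbering and chain labels are preserved.  For multi-model
    files only the first model is read (use :func:`read_trajectory` for the
    rest).
    """
    st = _read_gemmi(path)
    box = None
    cell = st.cell
    if cell and cell.a > 1.0:
        box = (cell.a, cell.b, cell.c)
    return Structure(_records_from_model(st[0]), box=box, subunit_ring=subunit_ring)


def _format_pdb_atom_name(name: str, element: str) -> str:
    # Standard PDB alignment: 1-2 char element symbols right-justified in
    # columns 13-14; short names of single-letter elements start at col 14.
    if len(name) >= 4:
        return name[:4]
    if len(element) == 1:
        return f" {name:<3s}"
    return f"{name:<4s}"


def write_pdb(structure: Structure, path: str | Path) -> None:
    """Write a :class:`Structure` as PDB text (ATOM records, one model)."""
    with open(path, "w") as fh:
        if structure.box is not None:
            a, b, c = structure.box
            fh.write(
                f"CRYST1{a:9.3f}{b:9.3f}{c:9.3f}{90.0:7.2f}{90.0:7.2f}{90.0:7.2f} P 1           1\n"
            )
        for i, atom in enumerate(structure.atoms, start=1):
            x, y, z = atom.coordinates
            name = _format_pdb_atom_name(atom.atom_name, atom.element)
            fh.write(
                f"ATOM  {i % 100000:5d} {name}{'':1s}{atom.residue_name:>3s} "
                f"{atom.chain_id[:1]}{atom.residue_number:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}          "
                f"{atom.element:>2s}\n"
            )
        fh.write("END\n")


def _check_frame_identity(
    topology: Structure, keys: list[tuple[str, int, str]], where: str
) -> None:
    expected = [a.key for a in topology.atoms]
    if keys != expected:
        if len(keys) != len(expected):
            raise ValueError(
                f"{where}: atom count {len(keys)} does not match topology "
                f"({len(expected)} atoms)"
            )
        for i, (got, want) in enumerate(zip(keys, expected)):
            if got != want:
                raise ValueError(
                    f"{where}: atom {i} is {got}, topology expects {want} "
                    "(strict atom order is required)"
                )


def read_frame_table(path: str | Path, topology: Structure) -> np.ndarray:
    """Read a plain-text frame table into an ``(n_frames, n_atoms, 3)`` array.

    The table is whitespace-delimited with columns
    ``frame chain resid atom x y z`` (header optional); atoms within each
    frame must appear in topology order.
    """
    df = pd.read_csv(
        path,
        sep=r"\s+",
        comment="#",
        names=["frame", "chain", "resid", "atom", "x", "y", "z"],
        dtype={"chain": str, "atom": str},
    )
    if len(df) and str(df.iloc[0]["frame"]) == "frame":  # header row
        df = df.iloc[1:].reset_index(drop=True)
    df["frame"] = df["frame"].astype(int)
    df["resid"] = df["resid"].astype(int)
    frames = []
    for f, grp in df.groupby("frame", sort=True):
        keys = list(zip(grp["chain"], grp["resid"], grp["atom"]))
        _check_frame_identity(topology, keys, f"frame {f} of {path}")
        frames.append(grp[["x", "y", "z"]].to_numpy(dtype=float))
    if not frames:
        raise ValueError(f"no frames found in {path}")
    return np.stack(frames)


def write_frame_table(traj: Trajectory, path: str | Path) -> None:
    """Write a trajectory as a plain-text frame table (see read_frame_table)."""
    with open(path, "w") as fh:
        fh.write("frame chain resid atom x y z\n")
        for f in range(traj.n_frames):
            for a, (x, y, z) in zip(traj.topology.atoms, traj.coords[f]):
                fh.write(
                    f"{f} {a.chain_id} {a.residue_number} {a.atom_name} "
                    f"{x:.4f} {y:.4f} {z:.4f}\n"
                )


def read_trajectory(
    paths: str | Path | Sequence[str | Path],
    topology: Structure,
    frame_spacing: float = 1.0,
    repeat_id: str = "rep0",
) -> Trajectory:
    """Read frames from multi-model PDB files and/or frame tables.

    Frames are ordered by file order then model order.  Every frame must
    match the topology's atom identity sequence exactly.
    """
    if isinstance(paths, (str, Path)):
        paths = [paths]
    all_frames: list[np.ndarray] = []
    for path in paths:
        path = Path(path)
        with open(path) as fh:
            head = fh.read(4096)
        if any(head.lstrip().startswith(tag) for tag in ("ATOM", "HETATM", "MODEL",
                                                         "CRYST1", "REMARK", "HEADER")):
            st = _read_gemmi(path)
            for m, model in enumerate(st):
                recs = _records_from_model(model)
                keys = [r.key for r in recs]
                _check_frame_identity(topology, keys, f"model {m + 1} of {path}")
                all_frames.append(np.array([r.coordinates for r in recs]))
        else:
            all_frames.extend(read_frame_table(path, topology))
    if not all_frames:
        raise ValueError("no frames read")
    return Trajectory(
        topology=topology,
        coords=np.stack(all_frames),
        frame_spacing=frame_spacing,
        repeat_id=repeat_id,
    )


def select_atoms(
    structure: Structure,
    chain: str | None = None,
    residue: int | None = None,
    atom_names: Iterable[str] | None = None,
) -> list[AtomRecord]:
    """Atoms matching the given chain / residue number / atom-name set.

    Returns matches in topology order; an empty list is a valid result.
    """
    return [structure.atoms[i] for i in select_indices(structure, chain, residue, atom_names)]


def select_indices(
    structure: Structure,
    chain: str | None = None,
    residue: int | None = None,
    atom_names: Iterable[str] | None = None,
) -> np.ndarray:
    """Like :func:`select_atoms` but returns integer indices into the topology."""
    names = None if atom_names is None else set(atom_names)
    out = [
        i
        for i, a in enumerate(structure.atoms)
        if (chain is None or a.chain_id == chain)
        and (residue is None or a.residue_number == residue)
        and (names is None or a.atom_name in names)
    ]
    return np.asarray(out, dtype=int)


def map_residue_numbering(n: int, direction: str = "h_to_d") -> int:
    """Map between hOrai1 and dOrai author numbering (offset +72).

    ``direction`` is ``"h_to_d"`` (hOrai1 → dOrai, adds 72) or ``"d_to_h"``
    (subtracts 72).  hOrai1 F99 maps to dOrai F171.
    """
    if n <= 0:
        raise ValueError("residue number must be positive")
    if direction == "h_to_d":
        return n + NUMBERING_OFFSET
    if direction == "d_to_h":
        return n - NUMBERING_OFFSET
    raise ValueError(f"unknown direction {direction!r}")
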