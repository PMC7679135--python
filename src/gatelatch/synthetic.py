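"""Synthetic hexameric channels with known ground truth.

The generator emulates the statistical structure of a gate-latch MD
ensemble, not its physics: six idealized TM1-like Cα helices around a pore
axis carry a methionine (Cβ, Sδ) at position 173 and phenylalanine rings at
171 (gate) and 259 (TM3 anchor).  Each subunit's Met hops between a contact
and a non-contact rotamer state as a discrete-time two-state Markov chain of
prescribed stationary probability; conditional on the state, the Sδ-to-ring
separation is drawn from a truncated normal law confined to its side of the
7 Å contact cutoff, so the stationary contact probability is exactly the
probability of d < 7 Å and −RT ln[p/(1−p)] is the exact free-energy ground
truth.  The gate ring (and its Cα) of the partner subunit is rotated
azimuthally when held by a latch, coupling rotation to contact as in open
channels.  Solvent is an inhomogeneous Poisson gas: bulk density everywhere,
multiplied by a dewetting factor inside the gate z-window.

Everything is deterministic under a seed; per-repeat seeds are derived from
one master seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .structure import AtomRecord, Structure, Trajectory

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "build_toy_channel",
    "simulate_gate_dynamics",
    "populate_solvent",
    "make_repeat_set",
]

_MASS = {"C": 12.011, "S": 32.065, "O": 15.999, "NA": 22.990, "CL": 35.453}
_RING_NAMES = ("CG", "CD1", "CD2", "CE1", "CE2", "CZ")
_RING_RADIUS = 1.39  # Å, benzene C-C circumradius
_CHAIN_IDS = "ABCDEF"

# idealized helix parameters
_HELIX_RADIUS = 2.3      # Å, Cα circumradius of an α-helix
_RISE_PER_RES = 1.5      # Å
_TWIST_PER_RES = 100.0   # degrees
_PORE_RADIUS = 10.0      # Å, distance of each helix axis from the pore axis


@dataclass
class SyntheticConfig:
    """Ground-truth parameters of the synthetic channel ensemble.

    The defaults describe a WT-like closed channel: stationary contact
    probability 4/9 (contact : non-contact ratio 0.8), production length
    400 ns at 1 ns spacing with the first 100 ns discarded downstream,
    contact/non-contact Sδ-ring laws peaked at 5.0 / 8.5 Å straddling the
    7 Å cutoff, and a partially dewetted gate (factor 0.3) in a 10–20 Å
    axial window at bulk water density 0.0334 Å⁻³.
    """

    n_subunits: int = 6
    n_frames: int = 400
    frame_spacing: float = 1.0           # ns
    p_contact_target: float = 0.8 / 1.8  # stationary P(contact); ratio 0.8
    switch_rate: float = 0.2             # per ns total switching propensity
    contact_mu: float = 5.0              # Å
    contact_sigma: float = 0.6
    noncontact_mu: float = 8.5
    noncontact_sigma: float = 0.8
    contact_cutoff: float = 7.0          # Å; also the truncation boundary
    noncontact_max: float = 12.0         # Å; keeps the partner unambiguous
    gate_angle_contact: float = 20.0     # deg, azimuthal gate rotation when latched
    gate_angle_noncontact: float = 0.0
    d3_static: float = 7.3               # Å, closed-crystal Cβ→F171 calibration
    d4_static: float = 5.8               # Å, closed-crystal Cβ→F259 calibration
    jitter_sigma: float = 0.05           # Å thermal jitter on protein atoms
    include_solvent: bool = False
    solvent_bulk_density: float = 0.0334  # water O per Å³
    ion_density: float = 9e-5             # Na+ and Cl− per Å³ (~150 mM)
    gate_dewetting_factor: float = 0.3
    gate_z_window: tuple[float, float] = (10.0, 20.0)  # Å, axial
    solvent_half_width: float = 12.0     # Å, xy half-width of the solvent slab
    solvent_z_range: tuple[float, float] = (-30.0, 30.0)
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 <= self.p_contact_target <= 1.0):
            raise ValueError("p_contact_target must lie in [0, 1]")
        if self.contact_sigma <= 0 or self.noncontact_sigma <= 0:
            raise ValueError("state sigmas must be positive")
        if self.contact_mu <= _RING_RADIUS:
            raise ValueError(
                f"contact_mu = {self.contact_mu} Å is inside the ring "
                f"(radius {_RING_RADIUS} Å); unreachable geometry"
            )
        if self.solvent_bulk_density < 0 or self.ion_density < 0:
            raise ValueError("densities must be non-negative")
        if not (0.0 <= self.gate_dewetting_factor <= 1.0):
            raise ValueError("gate_dewetting_factor must lie in [0, 1]")
        if self.n_subunits != len(_CHAIN_IDS):
            raise ValueError("the toy channel is hexameric (n_subunits = 6)")

    def expected_delta_g(self, temperature: float = 298.15) -> float:
        """Exact ground-truth per-contact ΔG = −RT ln[p/(1−p)], kcal/mol."""
        from .free_energy import delta_g_contact

        p = self.p_contact_target
        if p <= 0 or p >= 1:
            raise ValueError("delta G undefined for degenerate p_contact_target")
        return delta_g_contact(p / (1 - p), temperature)


@dataclass
class GroundTruth:
    """Realized states and the exact expectations implied by the config."""

    config: SyntheticConfig
    states: np.ndarray  # (n_frames, n_subunits) 1 = contact
    expected_p_contact: float

    @property
    def realized_p_contact(self) -> float:
        return float(self.states.mean())


def _rotz(deg: float) -> np.ndarray:
    t = np.radians(deg)
    c, s = np.cos(t), np.sin(t)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _ring_atoms(centroid: np.ndarray, normal: np.ndarray) -> list[np.ndarray]:
    n = normal / np.linalg.norm(normal)
    probe = np.array([0.0, 0.0, 1.0])
    if abs(n @ probe) > 0.9:
        probe = np.array([1.0, 0.0, 0.0])
    e1 = np.cross(n, probe)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(n, e1)
    return [
        centroid + _RING_RADIUS * (np.cos(a) * e1 + np.sin(a) * e2)
        for a in np.radians(np.arange(0, 360, 60))
    ]


def _chain_template(config: SyntheticConfig) -> dict[str, np.ndarray]:
    """Key positions of chain A; other chains are 60° rotations of these."""
    # TM1-like Cα helix, residues 141..174, axially centred at z = 0
    ca = {}
    for i in range(141, 175):
        a = np.radians(_TWIST_PER_RES * (i - 141))
        ca[i] = np.array(
            [
                _PORE_RADIUS + _HELIX_RADIUS * np.cos(a),
                _HELIX_RADIUS * np.sin(a),
                _RISE_PER_RES * (i - 157.5),
            ]
        )
    ca173 = ca[173]
    u_in = -np.array([ca173[0], ca173[1], 0.0])
    u_in /= np.linalg.norm(u_in)
    cb = ca173 + 1.53 * u_in
    u_out = -u_in
    c259 = cb + config.d4_static * u_out
    # gate ring of the ring-successor chain, placed tangentially at the
    # closed-crystal Cβ separation from this chain's Met Cβ
    u_t = _rotz(60.0) @ cb - cb
    u_t /= np.linalg.norm(u_t)
    c171_succ = cb + config.d3_static * u_t
    sd = cb + 2.8 * (c259 - cb) / np.linalg.norm(c259 - cb)
    # ring atoms are laid out in the template and rotated with the chain so
    # the whole structure is exactly six-fold symmetric atom for atom
    u_out259 = np.array([c259[0], c259[1], 0.0])
    u_out259 /= np.linalg.norm(u_out259)
    return {
        "ca": ca,
        "cb": cb,
        "sd": sd,
        "c259": c259,
        "c259_ca": c259 + 1.5 * u_out259,
        "ring259": _ring_atoms(c259, u_out259),
        "c171_succ": c171_succ,
        "ring171_succ": _ring_atoms(c171_succ, np.array([0.0, 0.0, 1.0])),
    }


def build_toy_channel(config: SyntheticConfig | None = None) -> Structure:
    """Six-fold symmetric toy channel in the closed-crystal calibration.

    Residues 141–174 are Cα-only (ALA) except F171 (Cα + six ring carbons)
    and M173 (Cα, Cβ, Sδ); residue 259 carries the TM3 Phe ring.  The gate
    rings sit exactly ``d3_static`` from the preceding subunit's Met Cβ and
    the F259 rings exactly ``d4_static`` from their own Met Cβ, mirroring
    the closed-state crystal separations.
    """
    config = config or SyntheticConfig()
    config.validate()
    tpl = _chain_template(config)
    atoms: list[AtomRecord] = []

    def add(chain: str, resname: str, resid: int, name: str, element: str,
            pos: np.ndarray) -> None:
        atoms.append(
            AtomRecord(
                atom_name=name, element=element, residue_name=resname,
                residue_number=resid, chain_id=chain,
                coordinates=np.asarray(pos, dtype=float), mass=_MASS[element],
            )
        )

    n = config.n_subunits
    for k in range(n):
        R = _rotz(360.0 * k / n)
        chain = _CHAIN_IDS[k]
        # gate ring of chain k is defined from the predecessor's template
        Rpred = _rotz(360.0 * ((k - 1) % n) / n)
        for i in range(141, 175):
            resname = "PHE" if i == 171 else ("MET" if i == 173 else "ALA")
            add(chain, resname, i, "CA", "C", R @ tpl["ca"][i])
            if i == 171:
                for name, pos in zip(_RING_NAMES, tpl["ring171_succ"]):
                    add(chain, "PHE", 171, name, "C", Rpred @ pos)
            if i == 173:
                add(chain, "MET", 173, "CB", "C", R @ tpl["cb"])
                add(chain, "MET", 173, "SD", "S", R @ tpl["sd"])
        add(chain, "PHE", 259, "CA", "C", R @ tpl["c259_ca"])
        for name, pos in zip(_RING_NAMES, tpl["ring259"]):
            add(chain, "PHE", 259, name, "C", R @ pos)
    return Structure(atoms, subunit_ring=list(_CHAIN_IDS[:n]))


# ---------------------------------------------------------------------------
# solvent

def _solvent_counts(config: SyntheticConfig) -> tuple[int, int, int]:
    L = 2 * config.solvent_half_width
    z0, z1 = config.solvent_z_range
    v_box = L * L * (z1 - z0)
    g0, g1 = config.gate_z_window
    g0, g1 = max(g0, z0), min(g1, z1)
    v_gate = L * L * max(0.0, g1 - g0)
    f = config.gate_dewetting_factor
    n_w = int(round(config.solvent_bulk_density * (v_box - (1 - f) * v_gate)))
    n_ion = int(round(config.ion_density * v_box))
    return n_w, n_ion, n_ion


def populate_solvent(
    config: SyntheticConfig, rng: np.random.Generator, counts: tuple[int, int, int] | None = None
) -> dict[str, np.ndarray]:
    """One frame of solvent coordinates.

    Water oxygens follow a piecewise-uniform density: the bulk value outside
    the gate z-window and ``gate_dewetting_factor`` times it inside.  Ions
    are uniform at their bulk density.  Counts are fixed (the trajectory
    topology must not change between frames) at the integer mean of the
    corresponding Poisson intensity; positions are redrawn every frame.
    """
    if counts is None:
        counts = _solvent_counts(config)
    n_w, n_na, n_cl = counts
    h = config.solvent_half_width
    z0, z1 = config.solvent_z_range
    g0, g1 = config.gate_z_window
    g0, g1 = max(g0, z0), min(g1, z1)
    f = config.gate_dewetting_factor
    len_gate = max(0.0, g1 - g0)
    len_out = (z1 - z0) - len_gate

    def sample_z(n: int) -> np.ndarray:
        w_gate = f * len_gate
        w_out = len_out
        total = w_gate + w_out
        if total <= 0:
            return np.empty(0)
        in_gate = rng.random(n) < (w_gate / total)
        z = np.empty(n)
        z[in_gate] = rng.uniform(g0, g1, size=int(in_gate.sum()))
        u = rng.uniform(0.0, len_out, size=int((~in_gate).sum()))
        # map uniform on the non-gate length onto [z0,g0) ∪ (g1,z1]
        below = u < (g0 - z0)
        zz = np.where(below, z0 + u, g1 + (u - (g0 - z0)))
        z[~in_gate] = zz
        return z

    def xy(n: int) -> np.ndarray:
        return rng.uniform(-h, h, size=(n, 2))

    water = np.column_stack([xy(n_w), sample_z(n_w)]) if n_w else np.empty((0, 3))
    na = (
        np.column_stack([xy(n_na), rng.uniform(z0, z1, n_na)])
        if n_na else np.empty((0, 3))
    )
    cl = (
        np.column_stack([xy(n_cl), rng.uniform(z0, z1, n_cl)])
        if n_cl else np.empty((0, 3))
    )
    return {"water": water, "Na+": na, "Cl-": cl}


def _solvent_records(counts: tuple[int, int, int]) -> list[AtomRecord]:
    n_w, n_na, n_cl = counts
    records = []
    for i in range(n_w):
        records.append(AtomRecord("O", "O", "HOH", i + 1, "W", np.zeros(3), _MASS["O"]))
    for i in range(n_na):
        records.append(AtomRecord("NA", "NA", "NA", i + 1, "I", np.zeros(3), _MASS["NA"]))
    for i in range(n_cl):
        records.append(
            AtomRecord("CL", "CL", "CL", n_na + i + 1, "I", np.zeros(3), _MASS["CL"])
        )
    return records


# ---------------------------------------------------------------------------
# dynamics

def _truncnorm(mu: float, sigma: float, lo: float, hi: float):
    return stats.truncnorm((lo - mu) / sigma, (hi - mu) / sigma, loc=mu, scale=sigma)


def _simulate_states(config: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    """Two-state Markov chain per subunit; 1 = contact."""
    p = config.p_contact_target
    s = min(1.0, config.switch_rate * config.frame_spacing)
    a, b = s * p, s * (1 - p)  # 0→1 and 1→0 probabilities; stationary P(1) = p
    states = np.empty((config.n_frames, config.n_subunits), dtype=np.int8)
    states[0] = (rng.random(config.n_subunits) < p).astype(np.int8)
    for f in range(1, config.n_frames):
        u = rng.random(config.n_subunits)
        prev = states[f - 1]
        flip = np.where(prev == 0, u < a, u < b)
        states[f] = np.where(flip, 1 - prev, prev)
    return states


def simulate_gate_dynamics(
    config: SyntheticConfig | None = None, seed: int | None = None
) -> tuple[Trajectory, GroundTruth]:
    """Generate a synthetic trajectory with exact two-state ground truth.

    Per frame and subunit, the Met Sδ is placed on the line from the
    (possibly rotated) successor gate-ring centroid toward the Met Cβ at a
    distance drawn from the state-conditional truncated normal law, so the
    nearest-adjacent-subunit Sδ-ring distance d1 realizes the law exactly.
    Identical seeds give identical output.
    """
    config = config or SyntheticConfig()
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)

    base = build_toy_channel(config)
    counts = _solvent_counts(config) if config.include_solvent else (0, 0, 0)
    atoms = list(base.atoms) + (_solvent_records(counts) if config.include_solvent else [])
    topology = Structure(atoms, subunit_ring=base.subunit_ring)
    n_protein = len(base.atoms)
    base_coords = base.coordinates

    chains = topology.subunit_ring
    n = len(chains)
    ring_idx = {
        c: [topology.index_of(c, 171, nm) for nm in _RING_NAMES] for c in chains
    }
    ca171_idx = {c: topology.index_of(c, 171, "CA") for c in chains}
    cb_idx = {c: topology.index_of(c, 173, "CB") for c in chains}
    sd_idx = {c: topology.index_of(c, 173, "SD") for c in chains}

    law_contact = _truncnorm(
        config.contact_mu, config.contact_sigma, _RING_RADIUS + 0.1, config.contact_cutoff
    )
    law_noncontact = _truncnorm(
        config.noncontact_mu, config.noncontact_sigma, config.contact_cutoff,
        config.noncontact_max,
    )

    states = _simulate_states(config, rng)
    coords = np.empty((config.n_frames, len(topology), 3))
    for f in range(config.n_frames):
        frame = np.zeros((len(topology), 3))
        frame[:n_protein] = base_coords
        if config.jitter_sigma > 0:
            frame[:n_protein] += rng.normal(
                0.0, config.jitter_sigma, size=(n_protein, 3)
            )
        # state-coupled gate rotation: a latched Met rotates the partner
        # (ring-successor) subunit's gate ring and Cα azimuthally
        for k, chain in enumerate(chains):
            succ = chains[(k + 1) % n]
            angle = (
                config.gate_angle_contact
                if states[f, k]
                else config.gate_angle_noncontact
            )
            if angle:
                R = _rotz(angle)
                for i in ring_idx[succ] + [ca171_idx[succ]]:
                    frame[i] = R @ frame[i]
        # place each Sδ at the drawn state-conditional ring separation
        for k, chain in enumerate(chains):
            succ = chains[(k + 1) % n]
            centroid = frame[ring_idx[succ]].mean(axis=0)
            law = law_contact if states[f, k] else law_noncontact
            d = float(law.rvs(random_state=rng))
            u = frame[cb_idx[chain]] - centroid
            u /= np.linalg.norm(u)
            frame[sd_idx[chain]] = centroid + d * u
        if config.include_solvent:
            sol = populate_solvent(config, rng, counts)
            frame[n_protein:] = np.concatenate(
                [sol["water"], sol["Na+"], sol["Cl-"]], axis=0
            )
        coords[f] = frame

    traj = Trajectory(
        topology=topology,
        coords=coords,
        frame_spacing=config.frame_spacing,
        repeat_id=f"seed{config.seed if seed is None else seed}",
    )
    truth = GroundTruth(
        config=config, states=states, expected_p_contact=config.p_contact_target
    )
    return traj, truth


def make_repeat_set(
    config: SyntheticConfig, n_repeats: int, seed: int = 0
) -> tuple[list[Trajectory], list[GroundTruth]]:
    """Independent repeats with per-repeat seeds derived from one master seed."""
    child_seeds = np.random.SeedSequence(seed).generate_state(n_repeats) % (2**31)
    trajs, truths = [], []
    for i, s in enumerate(child_seeds):
        t, g = simulate_gate_dynamics(config, seed=int(s))
        t.repeat_id = f"rep{i}"
        trajs.append(t)
        truths.append(g)
    return trajs, truths
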