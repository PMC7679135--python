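import numpy as np
import pytest

from gatelatch import SyntheticConfig, build_toy_channel, simulate_gate_dynamics


@pytest.fixture(scope="session")
def toy_channel():
    """Closed-crystal-calibrated hexameric toy structure."""
    return build_toy_channel()


@pytest.fixture(scope="session")
def short_trajectory():
    """Small deterministic gate-dynamics trajectory (no solvent)."""
    cfg = SyntheticConfig(n_frames=60, seed=7)
    traj, truth = simulate_gate_dynamics(cfg)
    return traj, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(20250925)


THREE_ATOM_PDB = """\
ATOM      1  CA  ALA A   1       1.000   2.000   3.000  1.00  0.00           C
ATOM      2  CB  ALA A   1       1.500   2.500   3.500  1.00  0.00           C
ATOM      3  CA  GLY B   2      -1.250   0.000   9.125  1.00  0.00           C
END
"""


@pytest.fixture()
def three_atom_pdb(tmp_path):
    path = tmp_path / "three.pdb"
    path.write_text(THREE_ATOM_PDB)
    return path
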