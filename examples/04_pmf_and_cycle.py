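"""From distance distributions to the per-channel gating free energy.

Builds closed-like (ratio 0.8) and open-like (ratio 3) synthetic ensembles,
Boltzmann-inverts the d1 distributions into PMFs, discretizes them at the
7 Å cutoff, and closes the thermodynamic cycle: ΔΔG = ΔG2 − ΔG1 is the
stabilization of the Met-Phe contact upon opening, and six latches give the
per-channel estimate.
"""

import numpy as np

from gatelatch import (
    SyntheticConfig,
    align_to_pore_axis,
    compute_distance_series,
    contact_ratio,
    delta_g_contact,
    distance_distribution,
    pmf_boltzmann,
    simulate_gate_dynamics,
    thermo_cycle,
    trim_equilibration,
)

dgs = {}
for name, ratio in (("closed (WT-like)", 0.8), ("open (H206C-like)", 3.0)):
    cfg = SyntheticConfig(
        n_frames=400, p_contact_target=ratio / (1 + ratio), seed=21
    )
    traj, _ = simulate_gate_dynamics(cfg)
    traj = trim_equilibration(align_to_pore_axis(traj), 100.0)
    d1 = compute_distance_series(traj, "d1").pooled()
    dist = distance_distribution(d1, bin_width=0.2)
    pmf = pmf_boltzmann(dist)  # T = 298.15 K, minimum at the mode
    stats = contact_ratio(dist, cutoff=7.0)
    dg = delta_g_contact(stats.ratio)
    dgs[name] = dg
    wmax = np.nanmax(pmf.w)
    print(
        f"{name:18s} ratio = {stats.ratio:.2f}  "
        f"dG = {dg:+.2f} kcal/mol  (PMF min at {pmf.d0:.1f} A, "
        f"barrier span {wmax:.2f} kcal/mol)"
    )

res = thermo_cycle(dgs["closed (WT-like)"], dgs["open (H206C-like)"])
print(f"\nddG (open - closed) = {res.ddg:+.2f} kcal/mol per contact")
print(f"per channel ({res.n_sub} latches, additive) = {res.per_channel:+.2f} kcal/mol")
print("The published ratios 0.8 and 3 give dG1 = +0.13 and dG2 = -0.65,")
print("i.e. |ddG| ~ 0.8 kcal/mol per contact and ~5 kcal/mol per channel.")
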