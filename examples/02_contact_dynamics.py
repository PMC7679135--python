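"""Gate-latch contact dynamics in a synthetic open-like ensemble.

Simulates two-state Met rotamer dynamics (contact/non-contact) at the
stationary contact probability of an open channel, then measures the d1
distance distribution (Met Sδ to neighboring F171 ring) and the fraction of
frames within the 7 Å sulfur-aromatic interaction range (contact AUC).
"""

import numpy as np

from gatelatch import (
    SyntheticConfig,
    align_to_pore_axis,
    compute_distance_series,
    contact_auc,
    distance_distribution,
    simulate_gate_dynamics,
    trim_equilibration,
)

# open-like channel: contact : non-contact ratio 3 (P_contact = 0.75)
cfg = SyntheticConfig(n_frames=400, p_contact_target=0.75, seed=11)
traj, truth = simulate_gate_dynamics(cfg)
traj = trim_equilibration(align_to_pore_axis(traj), t_eq=100.0)

d1 = compute_distance_series(traj, "d1")
dist = distance_distribution(d1.pooled(), bin_width=0.2, source_label="d1")
auc = contact_auc(dist, cutoff=7.0)

print(f"frames analyzed: {traj.n_frames} (after 100 ns equilibration trim)")
print(f"pooled samples:  {dist.n_samples} (frames x 6 subunits)")
print(f"mean d1 = {d1.pooled().mean():.2f} A")
mode = dist.bin_centers[np.argmax(dist.probabilities)]
print(f"distribution mode at {mode:.1f} A (sulfur-aromatic optimum is ~5 A)")
print(f"contact AUC (d1 < 7 A) = {auc:.3f}")
print(f"generator ground truth P_contact = {truth.expected_p_contact:.3f}")
print("The AUC estimates the stationary probability that the Met sulfur is")
print("latched onto the neighboring gate phenylalanine.")
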