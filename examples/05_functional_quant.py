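"""Functional quantification: current ratios, GOF calls and E-FRET.

Applies the electrophysiology and imaging formulas to small numeric inputs:
fractional inhibition of a current by a blocker, fold potentiation,
gain-of-function classification at the 2 pA/pF threshold, and three-cube
sensitized-emission FRET efficiency with measured bleed-through constants.
"""

from gatelatch import (
    CurrentPair,
    FretCalibration,
    FretTriplet,
    acceptor_donor_gate,
    classify_gof,
    efret,
    fold_change,
    fractional_inhibition,
)

# Cd2+ block of a double-cysteine mutant: current drops from -100 to -25 pA
inhib = fractional_inhibition(CurrentPair(i_b=-25.0, i_ctrl=-100.0))
print(f"fractional inhibition: {inhib:.2f} (1 = full block)")

# Cd2+ potentiation of a cysteine-bridged open channel
fold, _ = fold_change(i_post=-120.0, i_pre=-10.0)
print(f"fold potentiation: {fold:.1f}x over baseline")

for dens in (0.4, 2.0, 3.6):
    call = "GOF" if classify_gof(dens) else "not GOF"
    print(f"current density {dens:4.1f} pA/pF -> {call} (threshold: >2 strictly)")

cal = FretCalibration()  # a=0.12, b=0.008, c=0.002, d=0.33, G=1.85
t = FretTriplet(i_dd=100.0, i_aa=200.0, i_da=100.0)
e, below = efret(t, cal)
print(f"\nE-FRET of (I_DD, I_AA, I_DA) = (100, 200, 100): E = {e:.4f}")
ratio = t.i_aa / t.i_dd
ok = acceptor_donor_gate(ratio)
print(f"YFP/CFP ratio {ratio:.1f} -> {'kept' if ok else 'excluded'} (accept 2-6)")
print("E reports donor-acceptor proximity after bleed-through correction;")
print("cells outside the 2-6 expression window are excluded before averaging.")
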