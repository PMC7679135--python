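"""Functional-data formulas: current ratios, GOF calls and three-cube E-FRET.

Current conventions: inward currents are recorded as negative values;
magnitudes are used for all ratios while signed inputs are preserved by the
caller.  The E-FRET efficiency uses the standard three-cube
sensitized-emission form with bleed-through-corrected FRET signal

    F_c = I_DA − a·I_AA − d·I_DD,      E = F_c / (F_c + G·I_DD),

with calibration constants measured from donor-only / acceptor-only cells.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "CurrentPair",
    "FretCalibration",
    "FretTriplet",
    "fractional_inhibition",
    "fold_change",
    "classify_gof",
    "efret",
    "invert_efret",
    "acceptor_donor_gate",
    "GOF_THRESHOLD_PA_PF",
]

#: Current density above which a variant is called gain-of-function (strict).
GOF_THRESHOLD_PA_PF = 2.0


@dataclass(frozen=True)
class CurrentPair:
    """Currents before (``i_ctrl``) and during (``i_b``) blocker application."""

    i_b: float
    i_ctrl: float


@dataclass(frozen=True)
class FretCalibration:
    """Microscope bleed-through constants and G factor.

    ``b`` and ``c`` are measured alongside ``a`` and ``d`` but do not enter
    the implemented sensitized-emission formula; they are carried for
    completeness.
    """

    a: float = 0.12
    b: float = 0.008
    c: float = 0.002
    d: float = 0.33
    g_factor: float = 1.85

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d", "g_factor"):
            if getattr(self, name) < 0:
                raise ValueError(f"calibration constant {name} must be >= 0")


@dataclass(frozen=True)
class FretTriplet:
    """Background-subtracted CFP (``i_dd``), YFP (``i_aa``) and FRET
    (``i_da``) channel intensities."""

    i_dd: float
    i_aa: float
    i_da: float

    def __post_init__(self) -> None:
        for v in (self.i_dd, self.i_aa, self.i_da):
            if not math.isfinite(v):
                raise ValueError("intensities must be finite")


def fractional_inhibition(pair: CurrentPair) -> float:
    """Fractional block, 1 − |I_b| / |I_ctrl|."""
    if pair.i_ctrl == 0:
        raise ValueError("control current is zero; inhibition undefined")
    return 1.0 - abs(pair.i_b) / abs(pair.i_ctrl)


def fold_change(i_post: float, i_pre: float) -> tuple[float, bool]:
    """Fold change in current magnitude, |I_post| / |I_pre|.

    Returns ``(fold, sign_discordant)``; the flag marks inputs of opposite
    sign, for which the magnitude ratio is still reported.
    """
    if i_pre == 0:
        raise ValueError("baseline current is zero; fold change undefined")
    discordant = (i_post * i_pre) < 0
    return abs(i_post) / abs(i_pre), discordant


def classify_gof(current_density: float) -> bool:
    """Gain-of-function call: current density strictly exceeding 2 pA/pF."""
    if current_density < 0:
        raise ValueError("current density magnitude must be non-negative")
    return current_density > GOF_THRESHOLD_PA_PF


def efret(t: FretTriplet, cal: FretCalibration | None = None) -> tuple[float, bool]:
    """Apparent FRET efficiency E = F_c / (F_c + G·I_DD).

    Returns ``(E, below_zero)``; ``below_zero`` flags a negative corrected
    FRET signal F_c (reported as-is, not clipped).  Requires I_DD > 0.
    """
    cal = cal or FretCalibration()
    if t.i_dd <= 0:
        raise ValueError("donor intensity must be positive")
    f_c = t.i_da - cal.a * t.i_aa - cal.d * t.i_dd
    e = f_c / (f_c + cal.g_factor * t.i_dd)
    return e, f_c < 0


def invert_efret(
    e: float, i_dd: float, i_aa: float, cal: FretCalibration | None = None
) -> FretTriplet:
    """Intensities that produce efficiency ``e`` at the given I_DD, I_AA."""
    cal = cal or FretCalibration()
    if i_dd <= 0:
        raise ValueError("donor intensity must be positive")
    if not e < 1:
        raise ValueError("efficiency must be < 1")
    f_c = e * cal.g_factor * i_dd / (1.0 - e)
    return FretTriplet(i_dd=i_dd, i_aa=i_aa, i_da=f_c + cal.a * i_aa + cal.d * i_dd)


def acceptor_donor_gate(yfp_cfp_ratio: float) -> bool:
    """Keep only cells with YFP/CFP expression ratio in [2, 6] (inclusive)."""
    if yfp_cfp_ratio <= 0:
        raise ValueError("YFP/CFP ratio must be positive")
    return 2.0 <= yfp_cfp_ratio <= 6.0
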