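"""Isotope-dilution E values: the isotopically exchangeable Cu pool.

A soil suspension is spiked with a small amount of Cu enriched in 65Cu.
The spike equilibrates with whatever soil Cu is isotopically exchangeable,
so the measured 63Cu/65Cu ratio in solution falls between the spike ratio
and the natural ratio; how far it has moved back toward natural measures
the size of the exchangeable (labile) pool, the *E value* (mg Cu per kg
soil).  Subtracting the control-soil E value and dividing by the Cu dose
gives the labile fraction of the *added* Cu, the quantity the aging model
predicts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

__all__ = [
    "IsotopeMeasurement",
    "EValueResult",
    "IR_NAT_DEFAULT",
    "IR_SP_DEFAULT",
    "AM_CU_NAT",
    "AM_CU_65",
    "e_value",
    "added_e_fraction",
]

#: Natural 63Cu/65Cu abundance ratio (69.15 % / 30.85 %).  The measured
#: per-soil solution ratio may be supplied instead.
IR_NAT_DEFAULT = 69.15 / 30.85
#: 63Cu/65Cu ratio of the enriched spike solution (0.5 % / 99.5 %).
IR_SP_DEFAULT = 0.5 / 99.5
#: Atomic mass of natural-composition Cu, amu.
AM_CU_NAT = 63.546
#: Atomic mass of 65Cu, amu.
AM_CU_65 = 64.928


@dataclass(frozen=True)
class IsotopeMeasurement:
    """One isotope-dilution measurement.

    Attributes
    ----------
    spike_total : float
        Total 65Cu added to the soil, mg per kg soil (symbol R).
    ir_meas : float
        Measured 63/65 isotope-amount ratio in solution after equilibration.
    ir_nat : float
        Natural 63/65 ratio of the soil solution.
    ir_sp : float
        63/65 ratio of the enriched spike.
    am_nat, am_65 : float
        Atomic masses of natural Cu and of 65Cu, amu.
    """

    spike_total: float
    ir_meas: float
    ir_nat: float = IR_NAT_DEFAULT
    ir_sp: float = IR_SP_DEFAULT
    am_nat: float = AM_CU_NAT
    am_65: float = AM_CU_65

    def __post_init__(self) -> None:
        if self.spike_total <= 0:
            raise ValueError(f"spike_total must be > 0, got {self.spike_total}")
        for name in ("ir_meas", "ir_nat", "ir_sp", "am_nat", "am_65"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")


@dataclass(frozen=True)
class EValueResult:
    """An E value (mg/kg) and, when derivable, the added-Cu labile fraction."""

    e_mg_per_kg: float
    e_add_fraction: float | None = None


def e_value(m: IsotopeMeasurement) -> float:
    """Exchangeable Cu pool (mg/kg) from one isotope-dilution measurement.

    Implements the two-pool isotope mass balance

        E = R * (AM_nat / AM_65) * (IR_sp - IR_meas) / (IR_meas - IR_nat)
              * (IR_nat + 1)

    which inverts the mixing of the enriched spike with a natural-composition
    exchangeable pool.  Raises on IR_meas == IR_nat (no dilution detected:
    the exchangeable pool is unbounded); warns when IR_meas lies outside
    (IR_sp, IR_nat), where the result changes sign and is physically
    meaningless.
    """
    if m.ir_meas == m.ir_nat:
        raise ValueError(
            "ir_meas equals ir_nat: no isotope dilution detected "
            "(exchangeable pool unbounded)"
        )
    if not (min(m.ir_sp, m.ir_nat) <= m.ir_meas <= max(m.ir_sp, m.ir_nat)):
        warnings.warn(
            f"ir_meas={m.ir_meas} outside the spike-natural interval "
            f"({m.ir_sp}, {m.ir_nat}); E value sign is not meaningful",
            stacklevel=2,
        )
    return (
        m.spike_total
        * (m.am_nat / m.am_65)
        * (m.ir_sp - m.ir_meas)
        / (m.ir_meas - m.ir_nat)
        * (m.ir_nat + 1.0)
    )


def added_e_fraction(e_spiked: float, e_control: float, cu_added: float) -> float:
    """Labile fraction of added Cu: (E_spiked − E_control) / Cu_added.

    The control E value is the native exchangeable pool of the unamended
    soil.  Values outside [0, 1] are retained (clamping is a prediction
    concern, not a measurement one) but warned about for QC.
    """
    if cu_added <= 0:
        raise ValueError(f"cu_added must be > 0, got {cu_added}")
    frac = (e_spiked - e_control) / cu_added
    if not 0.0 <= frac <= 1.0:
        warnings.warn(
            f"added-Cu E fraction {frac:.4g} outside [0, 1]; "
            "check E values and dose",
            stacklevel=2,
        )
    return frac
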