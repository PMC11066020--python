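"""Unit conventions.

Internal unit system is CGS (cm, s, g), matching the conventional vascular
CFD fluid constants (viscosity in Poise = g cm^-1 s^-1, density in g/cm^3).
Velocities are cm/s, wall shear stress dyn/cm^2, resistance dyn s cm^-5 and
capacitance cm^5/dyn.  Pressures cross the API boundary in mmHg only and are
converted on entry/exit; nothing downstream ever sees mmHg.
"""

from dataclasses import dataclass

#: 1 mmHg expressed in dyn/cm^2 (barye).
MMHG_TO_DYN_PER_CM2 = 1333.22


def mmhg_to_cgs(p_mmhg):
    """Convert pressure from mmHg to dyn/cm^2."""
    return p_mmhg * MMHG_TO_DYN_PER_CM2


def cgs_to_mmhg(p_dyn_per_cm2):
    """Convert pressure from dyn/cm^2 to mmHg."""
    return p_dyn_per_cm2 / MMHG_TO_DYN_PER_CM2


@dataclass(frozen=True)
class UnitConventions:
    """Declarative record of the unit system, attachable to reports."""

    length: str = "cm"
    time: str = "s"
    velocity: str = "cm/s"
    pressure_io: str = "mmHg"
    pressure_internal: str = "dyn/cm^2"
    resistance: str = "dyn*s/cm^5"
    capacitance: str = "cm^5/dyn"
    mmhg_in_cgs: float = MMHG_TO_DYN_PER_CM2


DEFAULT_UNITS = UnitConventions()
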