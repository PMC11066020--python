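"""Subject-specific RCR Windkessel outlet boundary conditions.

Clinical inputs (pressures in mmHg, flows in mL/s) are converted to CGS at
this boundary: total resistance is MAP over mean flow, total capacitance is
stroke volume over pulse pressure, and outlet totals are distributed by
Murray's law with exponent 2.1 on the outlet diameters.  A 0D integrator
of the three-element model validates the resulting pressure response.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import FlowWaveform, FluidProperties, SubjectVitals
from .errors import ConsistencyWarning, IntegrationError, ParameterError
from .units import MMHG_TO_DYN_PER_CM2, mmhg_to_cgs


@dataclass(frozen=True)
class RCRConfig:
    murray_coefficient: float = 2.1     # exponent on outlet diameter
    proximal_fraction: float = 0.09     # Rp / (Rp + Rd)
    reference_pressure_mmhg: float = 0.0

    def __post_init__(self):
        if self.murray_coefficient <= 0:
            raise ParameterError("murray_coefficient must be positive")
        if not 0 < self.proximal_fraction < 1:
            raise ParameterError("proximal_fraction must be in (0, 1)")


@dataclass(frozen=True)
class RCRParameters:
    """Three-element Windkessel in CGS: resistances dyn s cm^-5,
    capacitance cm^5/dyn, reference pressure dyn/cm^2."""

    proximal_resistance: float
    capacitance: float
    distal_resistance: float
    reference_pressure: float = 0.0

    def __post_init__(self):
        if min(self.proximal_resistance, self.capacitance, self.distal_resistance) <= 0:
            raise ParameterError("Rp, C and Rd must be positive")

    @property
    def total_resistance(self) -> float:
        return self.proximal_resistance + self.distal_resistance

    def as_clinical_units(self):
        """Convenience dict in mmHg s/mL and mL/mmHg."""
        return {
            "Rp_mmHg_s_per_mL": self.proximal_resistance / MMHG_TO_DYN_PER_CM2,
            "Rd_mmHg_s_per_mL": self.distal_resistance / MMHG_TO_DYN_PER_CM2,
            "C_mL_per_mmHg": self.capacitance * MMHG_TO_DYN_PER_CM2,
        }


def mean_arterial_pressure(systolic, diastolic):
    """MAP = DBP + (SBP - DBP)/3 = (SBP + 2 DBP)/3, in mmHg."""
    if not systolic > diastolic:
        raise ParameterError("systolic pressure must exceed diastolic")
    return diastolic + (systolic - diastolic) / 3.0


def estimate_total_rcr(map_mmhg, mean_flow, stroke_volume, pulse_pressure,
                       config: RCRConfig = RCRConfig()) -> RCRParameters:
    """Total R = MAP / mean flow; total C = SV / pulse pressure (CGS)."""
    if mean_flow <= 0:
        raise ParameterError("mean flow must be positive")
    if min(map_mmhg, stroke_volume, pulse_pressure) <= 0:
        raise ParameterError("MAP, stroke volume and pulse pressure must be positive")
    r_total = map_mmhg / mean_flow * MMHG_TO_DYN_PER_CM2
    c_total = stroke_volume / pulse_pressure / MMHG_TO_DYN_PER_CM2
    return RCRParameters(
        proximal_resistance=config.proximal_fraction * r_total,
        capacitance=c_total,
        distal_resistance=(1.0 - config.proximal_fraction) * r_total,
        reference_pressure=mmhg_to_cgs(config.reference_pressure_mmhg),
    )


def murray_flow_fractions(outlet_diameters, config: RCRConfig = RCRConfig()):
    d = np.asarray(outlet_diameters, dtype=float)
    if len(d) == 0 or np.any(d <= 0):
        raise ParameterError("outlet diameters must be positive")
    w = d ** config.murray_coefficient
    return w / w.sum()


def distribute_outlets(totals: RCRParameters, outlet_diameters,
                       config: RCRConfig = RCRConfig()):
    """Split totals across outlets by Murray's law.

    Per-outlet resistance R_i = R_total / f_i (parallel combination
    recovers the total exactly) and capacitance C_i = f_i C_total.
    """
    f = murray_flow_fractions(outlet_diameters, config)
    out = []
    for fi in f:
        r_i = totals.total_resistance / fi
        out.append(
            RCRParameters(
                proximal_resistance=config.proximal_fraction * r_i,
                capacitance=fi * totals.capacitance,
                distal_resistance=(1.0 - config.proximal_fraction) * r_i,
                reference_pressure=totals.reference_pressure,
            )
        )
    return out


def rcr_pressure_response(waveform: FlowWaveform, rcr: RCRParameters,
                          n_cycles=5, dt=None):
    """Integrate the 0D three-element model over ``n_cycles`` cycles.

    C dP_d/dt = Q(t) - (P_d - P_ref)/Rd, P_in = P_d + Rp Q(t), starting
    from the steady estimate P_d(0) = P_ref + Rd Qbar, with classical RK4.
    Returns (times, P_in, P_d) over the final cycle, times within [0, T).
    """
    T = waveform.period
    if dt is None:
        dt = T / 400.0
    if dt > T / 100.0 + 1e-15:
        raise ParameterError("dt must be at most period/100")
    n_per = int(round(T / dt))
    dt = T / n_per
    Rp, Rd, C = rcr.proximal_resistance, rcr.distal_resistance, rcr.capacitance
    Pref = rcr.reference_pressure
    qbar = waveform.mean_flow

    # Q is mL/s = cm^3/s; with R, C in CGS the product R*Q is dyn/cm^2
    def f(t, pd):
        return (waveform(t) - (pd - Pref) / Rd) / C

    pd = Pref + Rd * qbar
    history = np.empty(n_per)
    for cyc in range(n_cycles):
        for i in range(n_per):
            t = i * dt
            k1 = f(t, pd)
            k2 = f(t + dt / 2, pd + dt / 2 * k1)
            k3 = f(t + dt / 2, pd + dt / 2 * k2)
            k4 = f(t + dt, pd + dt * k3)
            pd = pd + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
            if not np.isfinite(pd):
                raise IntegrationError("0D Windkessel integration diverged")
            if cyc == n_cycles - 1:
                history[i] = pd
    times = (np.arange(n_per) + 1) * dt
    times = np.mod(times, T)
    order = np.argsort(times)
    times = times[order]
    p_d = history[order]
    p_in = p_d + Rp * waveform(times)
    return times, p_in, p_d


def reynolds_number(mean_speed, diameter, fluid: FluidProperties = FluidProperties()):
    """Re = rho v D / mu (dimensionless)."""
    if mean_speed < 0 or diameter <= 0:
        raise ParameterError("speed must be >= 0 and diameter > 0")
    return fluid.density * mean_speed * diameter / fluid.viscosity


def rcr_from_subject(vitals: SubjectVitals, waveform: FlowWaveform,
                     outlet_diameters=None, config: RCRConfig = RCRConfig(),
                     mean_flow=None):
    """Estimate subject RCR parameters from vitals and inlet waveform.

    The mean flow comes from the waveform's time average; if an explicit
    ``mean_flow`` is also given and disagrees by more than 5%, a
    ConsistencyWarning is raised and the waveform value is used.
    """
    qbar = waveform.mean_flow
    if mean_flow is not None and abs(mean_flow - qbar) > 0.05 * qbar:
        warnings.warn(
            f"stated mean flow {mean_flow:.3g} mL/s differs from waveform "
            f"average {qbar:.3g} mL/s by more than 5%",
            ConsistencyWarning,
            stacklevel=2,
        )
    m = mean_arterial_pressure(vitals.systolic, vitals.diastolic)
    totals = estimate_total_rcr(
        m, qbar, vitals.stroke_volume, vitals.pulse_pressure, config
    )
    if outlet_diameters is None:
        return totals
    return distribute_outlets(totals, outlet_diameters, config)
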