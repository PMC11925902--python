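"""Arterial stiffness metrics: echo-tracking (QAS-style) report and pSWE.

The wall-tracking report is computed from the diastolic/systolic carotid
diameters and the brachial pressure endpoints with the standard
echo-tracking definitions (cross-sectional areas A = pi D^2 / 4):

* compliance coefficient   CC = dA / dP                 [mm^2/kPa]
* distensibility           DC = dA / (A_d dP)           [1/kPa]
* beta stiffness           beta = ln(Ps/Pd) / (dD/D_d)  [-]
* alpha stiffness          alpha = ln(Ps/Pd) / (dA/A_d) [-]
* pulse wave velocity      PWV = sqrt(1 / (rho DC))     [m/s] (Bramwell-Hill)

Point shear-wave elastography reports tissue Young's modulus from the
shear-wave group speed under the linear-elastic, incompressible,
homogeneous assumption E = 3 rho c_s^2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .synthetic import DiameterWaveform

BLOOD_DENSITY = 1050.0  # kg/m^3
TISSUE_DENSITY = 1000.0  # kg/m^3


@dataclass
class DistensionMeasure:
    """Cycle-averaged diastolic/systolic diameters (mm) and distension (um)."""

    diastolic_diameter: float
    systolic_diameter: float
    distension: float


@dataclass
class QASReport:
    """Echo-tracking stiffness report for one patient."""

    distension: float  # um
    diameter: float  # mm (diastolic)
    dc: float  # 1/kPa
    cc: float  # mm^2/kPa
    alpha: float
    beta: float
    pwv: float  # m/s
    defined: bool = True  # False when the diameter excursion is zero


def measure_distension(waveform: DiameterWaveform, n_average: int = 6) -> DistensionMeasure:
    """Average the per-cycle diameter extremes over six successive beats.

    The waveform's ``n_cycles`` metadata segments the trace into beats;
    each beat contributes its minimum (diastolic) and maximum (systolic)
    sample.
    """
    if waveform.n_cycles < n_average:
        raise ValueError(f"need at least {n_average} cycles, got {waveform.n_cycles}")
    segments = np.array_split(waveform.diameter, waveform.n_cycles)[:n_average]
    d_min = float(np.mean([s.min() for s in segments]))
    d_max = float(np.mean([s.max() for s in segments]))
    return DistensionMeasure(d_min, d_max, (d_max - d_min) * 1000.0)


def qas_report(
    diastolic_diameter: float,
    systolic_diameter: float,
    systolic_pressure: float,
    diastolic_pressure: float,
    blood_density: float = BLOOD_DENSITY,
) -> QASReport:
    """Compute the stiffness report from diameters (mm) and pressures (kPa).

    A zero diameter excursion yields DC = CC = 0 with alpha, beta and PWV
    flagged undefined (NaN) rather than raising.
    """
    d_d, d_s = diastolic_diameter, systolic_diameter
    ps, pd_ = systolic_pressure, diastolic_pressure
    if not (d_s >= d_d > 0):
        raise ValueError("require systolic >= diastolic diameter > 0")
    if not (ps > pd_ > 0):
        raise ValueError("require systolic > diastolic pressure > 0")
    a_d = math.pi * d_d**2 / 4.0
    a_s = math.pi * d_s**2 / 4.0
    dp = ps - pd_
    da = a_s - a_d
    distension_um = (d_s - d_d) * 1000.0
    if da == 0.0:
        return QASReport(0.0, d_d, 0.0, 0.0, math.nan, math.nan, math.nan, defined=False)
    cc = da / dp
    dc = da / (a_d * dp)
    beta = math.log(ps / pd_) / ((d_s - d_d) / d_d)
    alpha = math.log(ps / pd_) / (da / a_d)
    # DC is per kPa = per 1000 Pa; PWV in m/s needs DC per Pa
    pwv = math.sqrt(1000.0 / (blood_density * dc))
    return QASReport(distension_um, d_d, dc, cc, alpha, beta, pwv)


def swe_young_modulus(shear_speed: float, density: float = TISSUE_DENSITY) -> float:
    """Young's modulus (kPa) from shear-wave speed (m/s): E = 3 rho c^2."""
    if shear_speed < 0:
        raise ValueError("shear speed must be non-negative")
    if density <= 0:
        raise ValueError("density must be positive")
    return 3.0 * density * shear_speed**2 / 1000.0
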