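"""Arterial stiffness indices from diameters and pressures.

Three related indices of local aortic wall stiffness:

* fractional diameter change, 100 (Dmax - Dmin) / Dmin, in %;
* stiffness parameter beta = ln(SBP/DBP) / [(Dmax - Dmin) / Dmin], the slope
  of the (approximately exponential) pressure-distension relation, largely
  pressure-independent;
* local pulse wave velocity from the Bramwell-Hill relation
  PWV = sqrt(Ad PP / (rho dA)), with Ad the diastolic cross-sectional area,
  dA the systolic-diastolic area difference, PP the local pulse pressure in
  Pa and rho the blood density (1060 kg/m3 by default).

Cross-sections are assumed circular (one B-mode diameter is measured); all
aggregation across subjects should average per-subject values, never plug
group-mean diameters into these formulas.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import ParameterError
from .waveform_io import DiameterMeasurement, convert_units

#: default blood density, kg/m3
RHO_BLOOD_KG_M3 = 1060.0


@dataclass
class StiffnessIndices:
    """All stiffness outputs for one subject/condition."""

    beta: float
    diameter_change_pct: float
    pwv_m_s: float
    ad_m2: float
    delta_a_m2: float
    pp_pa: float
    rho_kg_m3: float = RHO_BLOOD_KG_M3


def diameter_change(d: DiameterMeasurement) -> float:
    """Percent diameter change 100 (Dmax - Dmin) / Dmin."""
    return 100.0 * (d.dmax_mm - d.dmin_mm) / d.dmin_mm


def stiffness_beta(sbp_mmhg: float, dbp_mmhg: float, d: DiameterMeasurement) -> float:
    """beta = ln(SBP/DBP) / [(Dmax - Dmin)/Dmin]; dimensionless."""
    if sbp_mmhg < dbp_mmhg or dbp_mmhg <= 0:
        raise ParameterError(
            f"need SBP >= DBP > 0, got SBP={sbp_mmhg}, DBP={dbp_mmhg}"
        )
    strain = (d.dmax_mm - d.dmin_mm) / d.dmin_mm
    if strain == 0:
        raise ParameterError("Dmax equals Dmin: diameter strain is zero")
    return math.log(sbp_mmhg / dbp_mmhg) / strain


def bramwell_hill_pwv(
    d: DiameterMeasurement, pp_mmhg: float, rho_kg_m3: float = RHO_BLOOD_KG_M3
) -> float:
    """Local PWV in m/s: sqrt(Ad PP / (rho dA)) with circular cross-sections."""
    if pp_mmhg <= 0:
        raise ParameterError(f"pulse pressure must be > 0, got {pp_mmhg}")
    if d.dmax_mm == d.dmin_mm:
        raise ParameterError("Dmax equals Dmin: area difference is zero")
    rmax_m = convert_units(d.dmax_mm, "mm", "m") / 2.0
    rmin_m = convert_units(d.dmin_mm, "mm", "m") / 2.0
    ad = math.pi * rmin_m**2
    delta_a = math.pi * (rmax_m**2 - rmin_m**2)
    pp_pa = convert_units(pp_mmhg, "mmHg", "Pa")
    return math.sqrt(ad * pp_pa / (rho_kg_m3 * delta_a))


def compute_stiffness_indices(
    sbp_mmhg: float,
    dbp_mmhg: float,
    d: DiameterMeasurement,
    rho_kg_m3: float = RHO_BLOOD_KG_M3,
) -> StiffnessIndices:
    """All three indices at once, sharing the circular-area intermediates."""
    rmax_m = convert_units(d.dmax_mm, "mm", "m") / 2.0
    rmin_m = convert_units(d.dmin_mm, "mm", "m") / 2.0
    pp_mmhg = sbp_mmhg - dbp_mmhg
    return StiffnessIndices(
        beta=stiffness_beta(sbp_mmhg, dbp_mmhg, d),
        diameter_change_pct=diameter_change(d),
        pwv_m_s=bramwell_hill_pwv(d, pp_mmhg, rho_kg_m3),
        ad_m2=math.pi * rmin_m**2,
        delta_a_m2=math.pi * (rmax_m**2 - rmin_m**2),
        pp_pa=convert_units(pp_mmhg, "mmHg", "Pa"),
        rho_kg_m3=rho_kg_m3,
    )
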