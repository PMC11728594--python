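"""Pathway-specific exposure models for the four groundwater routes.

Doses follow the standard contaminated-site guideline algebra: chronic daily
intake (CDI) for ingestion, a steady-state permeability-coefficient event
model for dermal contact, and time-averaged exposure concentrations (EC)
for indoor/outdoor inhalation of vapours volatilizing from the water table.
Volatilization factors (VF, mg/m³ air per mg/L water) use a Millington-Quirk
effective diffusion coefficient through the vadose zone feeding either an
ambient mixing box (outdoor) or a steady-state enclosed-space balance with
diffusive crack entry (indoor). The VF sub-model is pluggable via
:class:`VolatilizationModel` so an alternative formulation can be swapped in
without touching the risk engine.

All doses and ECs are homogeneous of degree 1 in the water concentration
``cw`` (mg/L) and linear in exposure duration at fixed averaging time.
"""

from __future__ import annotations

from enum import Enum
from typing import Protocol

from pydantic import BaseModel, ConfigDict, Field, model_validator

from .registry import ChemicalParams

__all__ = [
    "Averaging",
    "ExposureParams",
    "SiteParams",
    "VolatilizationModel",
    "DiffusiveVolatilization",
    "oral_cdi",
    "dermal_dose",
    "effective_diffusion",
    "vf_outdoor",
    "vf_indoor",
    "inhalation_ec",
]

#: Litres per cubic centimetre, the dermal volume conversion factor.
L_PER_CM3 = 1e-3


class Averaging(str, Enum):
    """Which averaging time applies: lifetime (cancer) or exposure period."""

    CARCINOGENIC = "carcinogenic"
    NONCARCINOGENIC = "noncarcinogenic"


class ExposureParams(BaseModel):
    """Receptor behaviour parameters.

    ``at_nc`` is an independent constant in days (365 × the default exposure
    duration), deliberately NOT recomputed when ``ed`` is varied: if the
    non-carcinogenic averaging time tracked ``ed``, the hazard quotient would
    be invariant to exposure duration, which contradicts the observed
    sensitivity of HQ to ED.
    """

    model_config = ConfigDict(frozen=True)

    gwcr: float = Field(default=2.5, gt=0, description="drinking-water intake, L/day")
    ef: float = Field(default=365.0, gt=0, le=365, description="exposure frequency, days/year")
    ed: float = Field(default=24.0, gt=0, description="exposure duration, years")
    bw: float = Field(default=60.0, gt=0, description="body weight, kg")
    at_c: float = Field(default=25550.0, gt=0, description="carcinogenic averaging time, days")
    at_nc: float = Field(default=8760.0, gt=0, description="non-carcinogenic averaging time, days")
    sa: float = Field(default=1000.0, gt=0, description="contacted skin area, cm^2")
    t_event: float = Field(default=0.1, gt=0, description="water-contact event duration, h")
    ev: float = Field(default=1.0, gt=0, description="contact events per day")
    et_in: float = Field(default=20.0, ge=0, description="indoor exposure time, h/day")
    et_out: float = Field(default=4.0, ge=0, description="outdoor exposure time, h/day")
    boil_reduction: float = Field(default=0.6, ge=0, lt=1,
                                  description="fraction of solute removed by boiling")

    @model_validator(mode="after")
    def _day_budget(self) -> "ExposureParams":
        if self.et_in + self.et_out > 24.0 + 1e-12:
            raise ValueError("et_in + et_out must not exceed 24 h/day")
        return self

    def averaging_time(self, averaging: Averaging | str) -> float:
        return self.at_c if Averaging(averaging) is Averaging.CARCINOGENIC else self.at_nc


class SiteParams(BaseModel):
    """Vadose-zone and building parameters driving the volatilization factors."""

    model_config = ConfigDict(frozen=True)

    theta_a: float = Field(default=0.28, gt=0, description="air-filled soil porosity")
    theta_w: float = Field(default=0.15, gt=0, description="water-filled soil porosity")
    theta_t: float = Field(default=0.43, gt=0, lt=1, description="total porosity")
    l_gw: float = Field(default=300.0, gt=0, description="depth to groundwater, cm")
    u_air: float = Field(default=200.0, gt=0, description="ambient mixing-zone wind speed, cm/s")
    delta_air: float = Field(default=200.0, gt=0, description="ambient mixing-zone height, cm")
    w: float = Field(default=1000.0, gt=0, description="source width along wind, cm")
    er: float = Field(default=0.00014, gt=0, description="indoor air exchange rate, 1/s")
    lb: float = Field(default=200.0, gt=0, description="building volume/infiltration-area ratio, cm")
    eta: float = Field(default=0.001, gt=0, lt=1, description="foundation crack area fraction")
    l_crack: float = Field(default=15.0, gt=0, description="foundation thickness, cm")

    @model_validator(mode="after")
    def _porosity_budget(self) -> "SiteParams":
        if self.theta_a + self.theta_w > self.theta_t + 1e-12:
            raise ValueError("theta_a + theta_w must not exceed theta_t")
        return self


def _require_nonnegative(cw: float) -> None:
    if cw < 0:
        raise ValueError(f"concentration must be non-negative, got {cw}")


def oral_cdi(cw: float, p: ExposureParams, averaging: Averaging | str) -> float:
    """Chronic daily intake from drinking, mg/kg·day.

    CDI = cw · GWCR · EF · ED / (BW · AT).
    """
    _require_nonnegative(cw)
    at = p.averaging_time(averaging)
    return cw * p.gwcr * p.ef * p.ed / (p.bw * at)


def dermal_dose(
    cw: float, chem: ChemicalParams, p: ExposureParams, averaging: Averaging | str
) -> float:
    """Dermally absorbed dose from water contact, mg/kg·day.

    Steady-state event model: DAD = cw · Kp · t_event · EV · SA · EF · ED · CF
    / (BW · AT), CF = 1e-3 L/cm³. No lag-time correction is applied; with
    dermal contributions below 0.2% of total risk the refinement is
    immaterial.
    """
    _require_nonnegative(cw)
    if chem.kp is None:
        raise UnsupportedPathwayError(
            f"{chem.name} has no dermal permeability coefficient"
        )
    at = p.averaging_time(averaging)
    return (
        cw * chem.kp * p.t_event * p.ev * p.sa * p.ef * p.ed * L_PER_CM3
        / (p.bw * at)
    )


class UnsupportedPathwayError(ValueError):
    """A pathway cannot be evaluated because a required parameter is absent."""


def effective_diffusion(chem: ChemicalParams, s: SiteParams) -> float:
    """Millington-Quirk effective vapour diffusion through the vadose zone, cm²/s.

    D_eff = D_air·θa^3.33/θt² + (D_water/H')·θw^3.33/θt².
    """
    if chem.henry_dimensionless <= 0:
        raise ValueError("henry_dimensionless must be positive")
    theta_t2 = s.theta_t**2
    air_term = chem.d_air * s.theta_a**3.33 / theta_t2
    water_term = (chem.d_water / chem.henry_dimensionless) * s.theta_w**3.33 / theta_t2
    return air_term + water_term


def vf_outdoor(chem: ChemicalParams, s: SiteParams) -> float:
    """Groundwater-to-ambient-air volatilization factor, (mg/m³)/(mg/L).

    Box model over the source: VF = 1000·H' / (1 + u·δ·L_gw/(D_eff·W)).
    Approaches the equilibrium limit 1000·H' as D_eff → ∞.
    """
    d_eff = effective_diffusion(chem, s)
    resistance = s.u_air * s.delta_air * s.l_gw / (d_eff * s.w)
    return 1000.0 * chem.henry_dimensionless / (1.0 + resistance)


def vf_indoor(chem: ChemicalParams, s: SiteParams) -> float:
    """Groundwater-to-enclosed-space volatilization factor, (mg/m³)/(mg/L).

    Steady-state enclosed-space balance with diffusive crack entry:
    VF = 1000·H'·r / (1 + r + (D_eff/L_gw)/(D_eff·η/L_crack)),
    r = (D_eff/L_gw)/(ER·LB). Under the packaged default site this exceeds
    the outdoor factor for every study compound, as expected for vapour
    accumulation in enclosed spaces.
    """
    d_eff = effective_diffusion(chem, s)
    r = (d_eff / s.l_gw) / (s.er * s.lb)
    crack_resistance = (d_eff / s.l_gw) / (d_eff * s.eta / s.l_crack)
    return 1000.0 * chem.henry_dimensionless * r / (1.0 + r + crack_resistance)


class VolatilizationModel(Protocol):
    """Pluggable groundwater-to-air sub-model consumed by the risk engine."""

    def indoor(self, chem: ChemicalParams, s: SiteParams) -> float: ...

    def outdoor(self, chem: ChemicalParams, s: SiteParams) -> float: ...


class DiffusiveVolatilization:
    """Default VF model: the diffusive closed forms above."""

    def indoor(self, chem: ChemicalParams, s: SiteParams) -> float:
        return vf_indoor(chem, s)

    def outdoor(self, chem: ChemicalParams, s: SiteParams) -> float:
        return vf_outdoor(chem, s)


DEFAULT_VF_MODEL = DiffusiveVolatilization()


def inhalation_ec(
    cw: float,
    vf: float,
    p: ExposureParams,
    which: str,
    averaging: Averaging | str,
) -> float:
    """Time-averaged inhalation exposure concentration, mg/m³.

    EC = cw · VF · ET · EF · ED / (24 · AT), with ET the indoor or outdoor
    exposure time. With continuous exposure (ET=24, EF=365, 365·ED=AT) the
    EC collapses to cw·VF.
    """
    _require_nonnegative(cw)
    if vf < 0:
        raise ValueError("volatilization factor must be non-negative")
    et = p.et_in if which == "indoor" else p.et_out if which == "outdoor" else None
    if et is None:
        raise ValueError(f"which must be 'indoor' or 'outdoor', got {which!r}")
    if not 0 <= et <= 24:
        raise ValueError("exposure time must lie in [0, 24] h/day")
    at = p.averaging_time(averaging)
    return cw * vf * et * p.ef * p.ed / (24.0 * at)
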