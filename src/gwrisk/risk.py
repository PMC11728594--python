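"""Carcinogenic risk (CR) and hazard quotient (HQ) engine.

Turns the pathway doses/exposure concentrations into risk metrics, sums them
across the four routes (ingestion, dermal, indoor and outdoor inhalation),
and produces the derived analyses: pathway contribution shares (which are
concentration-invariant), compound shares of the summed site risk,
unit-concentration standardization, boiled-water scenarios, and the
censored-sample survey statistics (detection rate, exceedance rate, maximum,
mean).

Conventions:
  * CR = CDI·SF (ingestion), DAD·SF/ABS_gi (dermal), EC·1000·IUR
    (inhalation; the factor 1000 converts mg/m³ to µg/m³ and is applied
    here and nowhere else).
  * HQ = CDI/RfD, DAD/(RfD·ABS_gi), EC/RfC.
  * A pathway lacking its toxicity parameter yields an absent metric
    (``None``), never a silent zero.
  * Boiling removes ``boil_reduction`` of the solute from drinking water
    and therefore rescales the ingestion pathway only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Optional, Sequence

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from .exposure import (
    DEFAULT_VF_MODEL,
    Averaging,
    ExposureParams,
    SiteParams,
    VolatilizationModel,
    dermal_dose,
    inhalation_ec,
    oral_cdi,
)
from .registry import ChemicalParams, ChemicalSet

__all__ = [
    "PATHWAYS",
    "CR_THRESHOLD",
    "HQ_THRESHOLD",
    "RiskResult",
    "RiskSummary",
    "SampleTable",
    "UndefinedShareError",
    "apply_boiling",
    "pathway_risks",
    "total_metric",
    "pathway_shares",
    "summarize",
    "standardized_risks",
    "compound_shares",
    "survey_stats",
]

PATHWAYS: tuple[str, ...] = (
    "ingestion",
    "dermal",
    "inhalation_indoor",
    "inhalation_outdoor",
)

#: Acceptability thresholds: risks at or above these flags are unacceptable.
CR_THRESHOLD = 1e-6
HQ_THRESHOLD = 1.0

Metric = Literal["cr", "hq"]


class RiskResult(BaseModel):
    """CR and HQ for one compound through one pathway."""

    model_config = ConfigDict(frozen=True)

    compound: str
    pathway: str
    cr: Optional[float] = Field(default=None, ge=0)
    hq: Optional[float] = Field(default=None, ge=0)
    boiled: bool = False

    def metric(self, which: Metric) -> Optional[float]:
        return self.cr if which == "cr" else self.hq


class UndefinedShareError(ValueError):
    """Raised when shares are requested but every metric is zero or absent."""


@dataclass(frozen=True)
class SampleTable:
    """Per-well censored concentration records.

    ``data`` columns: ``well, compound, conc_mg_L, censored``. Censored rows
    carry the detection limit as their value.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"well", "compound", "conc_mg_L", "censored"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"sample table lacks column(s): {sorted(missing)}")
        if len(self.data) == 0:
            raise ValueError("sample table is empty")
        if (self.data["conc_mg_L"] < 0).any():
            raise ValueError("sample concentrations must be non-negative")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def compounds(self) -> list[str]:
        return list(self.data["compound"].unique())


def apply_boiling(cw: float, p: ExposureParams) -> float:
    """Drinking-water concentration after boiling: cw·(1 − boil_reduction)."""
    if cw < 0:
        raise ValueError("concentration must be non-negative")
    return cw * (1.0 - p.boil_reduction)


def pathway_risks(
    cw: float,
    chem: ChemicalParams,
    p: ExposureParams,
    s: SiteParams,
    boiled: bool = False,
    vf_model: VolatilizationModel = DEFAULT_VF_MODEL,
) -> list[RiskResult]:
    """CR and HQ for one compound through all four pathways at ``cw`` mg/L."""
    if cw < 0:
        raise ValueError("concentration must be non-negative")

    cw_ing = apply_boiling(cw, p) if boiled else cw
    out: list[RiskResult] = []

    cdi_c = oral_cdi(cw_ing, p, Averaging.CARCINOGENIC)
    cdi_nc = oral_cdi(cw_ing, p, Averaging.NONCARCINOGENIC)
    out.append(
        RiskResult(
            compound=chem.name,
            pathway="ingestion",
            cr=None if chem.sf_oral is None else cdi_c * chem.sf_oral,
            hq=None if chem.rfd_oral is None else cdi_nc / chem.rfd_oral,
            boiled=boiled,
        )
    )

    if chem.kp is None:
        dermal = RiskResult(
            compound=chem.name, pathway="dermal", cr=None, hq=None, boiled=boiled
        )
    else:
        dad_c = dermal_dose(cw, chem, p, Averaging.CARCINOGENIC)
        dad_nc = dermal_dose(cw, chem, p, Averaging.NONCARCINOGENIC)
        dermal = RiskResult(
            compound=chem.name,
            pathway="dermal",
            cr=None if chem.sf_oral is None else dad_c * chem.sf_oral / chem.abs_gi,
            hq=None
            if chem.rfd_oral is None
            else dad_nc / (chem.rfd_oral * chem.abs_gi),
            boiled=boiled,
        )
    out.append(dermal)

    for which, pathway in (("indoor", "inhalation_indoor"), ("outdoor", "inhalation_outdoor")):
        vf = vf_model.indoor(chem, s) if which == "indoor" else vf_model.outdoor(chem, s)
        ec_c = inhalation_ec(cw, vf, p, which, Averaging.CARCINOGENIC)
        ec_nc = inhalation_ec(cw, vf, p, which, Averaging.NONCARCINOGENIC)
        out.append(
            RiskResult(
                compound=chem.name,
                pathway=pathway,
                cr=None if chem.iur is None else ec_c * 1000.0 * chem.iur,
                hq=None if chem.rfc is None else ec_nc / chem.rfc,
                boiled=boiled,
            )
        )
    return out


def total_metric(results: Iterable[RiskResult], metric: Metric) -> Optional[float]:
    """Sum a metric over pathways; ``None`` if no pathway carries it."""
    values = [r.metric(metric) for r in results if r.metric(metric) is not None]
    if not values:
        return None
    return float(sum(values))


def pathway_shares(
    results: Sequence[RiskResult], metric: Metric = "cr"
) -> dict[str, float]:
    """Fraction of a compound's total metric carried by each pathway.

    The shares are invariant to the water concentration (every pathway is
    linear in cw), so they characterize the compound itself.
    """
    total = total_metric(results, metric)
    if total is None or total == 0.0:
        raise UndefinedShareError(
            f"all {metric} values are zero or absent; shares are undefined"
        )
    return {
        r.pathway: r.metric(metric) / total
        for r in results
        if r.metric(metric) is not None
    }


@dataclass
class RiskSummary:
    """Risk breakdown for a set of compounds at given concentrations."""

    results: pd.DataFrame  # columns: compound, pathway, cr, hq, boiled
    total_cr: dict[str, float] = field(default_factory=dict)
    total_hq: dict[str, float] = field(default_factory=dict)
    pathway_shares: dict[str, dict[str, dict[str, float]]] = field(default_factory=dict)
    compound_shares: dict[str, dict[str, float]] = field(default_factory=dict)
    acceptable_cr: dict[str, bool] = field(default_factory=dict)
    acceptable_hq: dict[str, bool] = field(default_factory=dict)


def summarize(
    conc: Mapping[str, float],
    chems: ChemicalSet,
    p: ExposureParams,
    s: SiteParams,
    boiled: bool = False,
    vf_model: VolatilizationModel = DEFAULT_VF_MODEL,
) -> RiskSummary:
    """Full per-compound, per-pathway breakdown with totals, shares and flags."""
    if not conc:
        raise ValueError("no concentrations supplied")
    rows: list[dict] = []
    total_cr: dict[str, float] = {}
    total_hq: dict[str, float] = {}
    shares: dict[str, dict[str, dict[str, float]]] = {"cr": {}, "hq": {}}
    acceptable_cr: dict[str, bool] = {}
    acceptable_hq: dict[str, bool] = {}

    for name, cw in conc.items():
        chem = chems[name]
        results = pathway_risks(cw, chem, p, s, boiled=boiled, vf_model=vf_model)
        rows.extend(r.model_dump() for r in results)
        for metric, totals in (("cr", total_cr), ("hq", total_hq)):
            tot = total_metric(results, metric)
            if tot is not None:
                totals[name] = tot
                if tot > 0:
                    shares[metric][name] = pathway_shares(results, metric)
        if name in total_cr:
            acceptable_cr[name] = total_cr[name] < CR_THRESHOLD
        if name in total_hq:
            acceptable_hq[name] = total_hq[name] < HQ_THRESHOLD

    comp_shares: dict[str, dict[str, float]] = {}
    for metric, totals in (("cr", total_cr), ("hq", total_hq)):
        grand = sum(totals.values())
        if grand > 0:
            comp_shares[metric] = {k: v / grand for k, v in totals.items()}

    return RiskSummary(
        results=pd.DataFrame(rows),
        total_cr=total_cr,
        total_hq=total_hq,
        pathway_shares=shares,
        compound_shares=comp_shares,
        acceptable_cr=acceptable_cr,
        acceptable_hq=acceptable_hq,
    )


def standardized_risks(
    chems: ChemicalSet,
    p: ExposureParams,
    s: SiteParams,
    vf_model: VolatilizationModel = DEFAULT_VF_MODEL,
) -> RiskSummary:
    """Risk summary with every compound standardized to 1 mg/L (unboiled).

    Removes the influence of the measured concentrations so the compound
    shares reflect toxicity and volatility alone.
    """
    conc = {name: 1.0 for name in chems.names}
    return summarize(conc, chems, p, s, boiled=False, vf_model=vf_model)


def compound_shares(
    mean_conc: Mapping[str, float],
    chems: ChemicalSet,
    p: ExposureParams,
    s: SiteParams,
    boiled: bool = False,
    mode: Metric = "cr",
    vf_model: VolatilizationModel = DEFAULT_VF_MODEL,
) -> dict[str, float]:
    """Each compound's fraction of the summed site metric at mean concentrations."""
    if not mean_conc:
        raise ValueError("empty concentration table")
    if any(v < 0 for v in mean_conc.values()):
        raise ValueError("mean concentrations must be non-negative")
    summary = summarize(mean_conc, chems, p, s, boiled=boiled, vf_model=vf_model)
    if mode not in summary.compound_shares:
        raise UndefinedShareError(f"summed {mode} is zero; shares undefined")
    return summary.compound_shares[mode]


def survey_stats(
    samples: SampleTable,
    chems: ChemicalSet,
    substitution: Literal["zero", "half", "dl"] = "zero",
) -> pd.DataFrame:
    """Per-compound survey statistics from a censored sample table.

    detection_rate: fraction of rows uncensored; exceedance_rate: fraction
    of rows whose reported value exceeds the drinking-water standard limit;
    max/mean over reported values with censored rows substituted by 0
    (default), half the detection limit, or the detection limit. The zero
    default mirrors survey tables in which heavily censored compounds print
    a mean of 0.00.
    """
    subst_factor = {"zero": 0.0, "half": 0.5, "dl": 1.0}[substitution]
    records = []
    for compound, group in samples.data.groupby("compound", sort=False):
        if compound not in chems:
            raise KeyError(f"compound {compound!r} absent from registry")
        chem = chems[compound]
        censored = group["censored"].astype(bool)
        values = group["conc_mg_L"].where(
            ~censored, chem.detection_limit * subst_factor
        )
        detected = ~censored
        records.append(
            {
                "compound": compound,
                "detection_rate": float(detected.mean()),
                "exceedance_rate": float(
                    (group["conc_mg_L"].where(detected, 0.0) > chem.standard_limit).mean()
                ),
                "max": float(values.max()) if len(values) else math.nan,
                "mean": float(values.mean()),
            }
        )
    return pd.DataFrame.from_records(records).set_index("compound")
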