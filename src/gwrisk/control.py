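"""Risk-based back-calculation of control values.

Two inversions of the forward model, both exact because every pathway
metric is linear in the inverted variable:

* concentration control value — the water concentration at which the total
  CR (threshold 1e-6) or HQ (threshold 1) is reached;
* exposure-duration control value — the duration (years) at which the total
  metric reaches its threshold for a fixed (e.g. site-average) concentration,
  holding the averaging time fixed.

The closed forms are cross-checked against bisection on the forward model;
both are exposed via ``method=``. Control values use the total multi-pathway
metric by default; ``pathway_scope="ingestion"`` restricts to drinking
water alone.
"""

from __future__ import annotations

from typing import Literal, Optional

from pydantic import BaseModel, ConfigDict, Field
from scipy.optimize import brentq

from .exposure import DEFAULT_VF_MODEL, ExposureParams, SiteParams, VolatilizationModel
from .registry import ChemicalParams
from .risk import CR_THRESHOLD, HQ_THRESHOLD, Metric, pathway_risks

__all__ = ["ControlValue", "concentration_control", "duration_control"]

Mode = Literal["carcinogenic", "noncarcinogenic"]
Scope = Literal["all", "ingestion"]


class ControlValue(BaseModel):
    model_config = ConfigDict(frozen=True)

    compound: str
    mode: Mode
    variable: Literal["concentration", "duration"]
    value: float = Field(gt=0)
    threshold: float


def _metric_for_mode(mode: Mode) -> Metric:
    return "cr" if mode == "carcinogenic" else "hq"


def _threshold(mode: Mode) -> float:
    return CR_THRESHOLD if mode == "carcinogenic" else HQ_THRESHOLD


def _total(
    cw: float,
    chem: ChemicalParams,
    p: ExposureParams,
    s: SiteParams,
    mode: Mode,
    scope: Scope,
    vf_model: VolatilizationModel,
) -> Optional[float]:
    metric = _metric_for_mode(mode)
    results = pathway_risks(cw, chem, p, s, boiled=False, vf_model=vf_model)
    if scope == "ingestion":
        results = [r for r in results if r.pathway == "ingestion"]
    values = [r.metric(metric) for r in results if r.metric(metric) is not None]
    return float(sum(values)) if values else None


def concentration_control(
    chem: ChemicalParams,
    p: ExposureParams,
    s: SiteParams,
    mode: Mode,
    pathway_scope: Scope = "all",
    method: Literal["closed_form", "bisection"] = "closed_form",
    vf_model: VolatilizationModel = DEFAULT_VF_MODEL,
) -> ControlValue:
    """Concentration (mg/L) at which the total metric reaches its threshold.

    The total metric is strictly linear in cw, so the closed form is
    threshold / (metric at 1 mg/L); the bisection route solves the forward
    model directly and agrees to ~1e-12 relative.
    """
    threshold = _threshold(mode)
    unit = _total(1.0, chem, p, s, mode, pathway_scope, vf_model)
    if unit is None or unit <= 0.0:
        raise ValueError(
            f"{chem.name}: no {mode} toxicity data in scope; control value undefined"
        )
    closed = threshold / unit
    if method == "closed_form":
        value = closed
    else:
        value = brentq(
            lambda c: _total(c, chem, p, s, mode, pathway_scope, vf_model) - threshold,
            closed * 1e-6,
            closed * 1e6,
            xtol=closed * 1e-12,
            rtol=8.9e-16,
        )
    return ControlValue(
        compound=chem.name,
        mode=mode,
        variable="concentration",
        value=value,
        threshold=threshold,
    )


def duration_control(
    chem: ChemicalParams,
    cw_avg: float,
    p: ExposureParams,
    s: SiteParams,
    mode: Mode,
    pathway_scope: Scope = "all",
    method: Literal["closed_form", "bisection"] = "closed_form",
    vf_model: VolatilizationModel = DEFAULT_VF_MODEL,
) -> ControlValue:
    """Exposure duration (years) at which the metric reaches its threshold.

    Averaging times stay fixed while ed varies, so the metric is linear in
    ed and the closed form is threshold·ed_ref / metric(ed_ref).
    """
    if cw_avg <= 0:
        raise ValueError(
            f"{chem.name}: non-positive concentration never reaches the threshold"
        )
    threshold = _threshold(mode)

    def metric_at(ed: float) -> Optional[float]:
        p_ed = p.model_copy(update={"ed": ed})
        return _total(cw_avg, chem, p_ed, s, mode, pathway_scope, vf_model)

    ref = metric_at(p.ed)
    if ref is None or ref <= 0.0:
        raise ValueError(
            f"{chem.name}: no {mode} toxicity data in scope; control value undefined"
        )
    closed = threshold * p.ed / ref
    if method == "closed_form":
        value = closed
    else:
        value = brentq(
            lambda ed: metric_at(ed) - threshold,
            closed * 1e-6,
            closed * 1e6,
            xtol=closed * 1e-12,
            rtol=8.9e-16,
        )
    return ControlValue(
        compound=chem.name,
        mode=mode,
        variable="duration",
        value=value,
        threshold=threshold,
    )
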