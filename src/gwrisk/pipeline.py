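"""End-to-end assessment pipeline and report assembly.

``run_assessment`` chains the stages: survey statistics → per-compound
multi-pathway risks at the survey means (boiled and unboiled) → pathway and
compound contribution shares → unit-concentration standardization →
risk-based control values → Monte Carlo sensitivity under the drinking
pathway. The report bundle carries full provenance (config echo, seed,
package version) and serializes to CSV/JSON.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Any, Literal, Optional

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from . import __version__
from .control import concentration_control, duration_control
from .io import load_exposure, load_site, read_samples, sigfig, write_json
from .registry import default_chemicals, load_chemicals
from .risk import standardized_risks, summarize, survey_stats
from .synthetic import calibrate_config
from .uncertainty import default_specs, mc_risk, sample_inputs

__all__ = ["RunConfig", "StageError", "run_assessment", "write_report"]


class RunConfig(BaseModel):
    model_config = ConfigDict(frozen=True)

    sample_table: str
    chemical_table: Optional[str] = None
    exposure_config: Optional[str] = None
    site_config: Optional[str] = None
    censoring_substitution: Literal["zero", "half", "dl"] = "zero"
    pathway_scope: Literal["all", "ingestion"] = "ingestion"
    mc_iterations: int = Field(default=10000, ge=2)
    seed: int = 0


class StageError(RuntimeError):
    def __init__(self, stage: str, detail: str):
        super().__init__(f"stage {stage!r} failed: {detail}")
        self.stage = stage


def run_assessment(cfg: RunConfig) -> dict[str, Any]:
    """Execute the full pipeline; returns the report bundle."""
    chems = (
        load_chemicals(cfg.chemical_table) if cfg.chemical_table else default_chemicals()
    )
    exposure = load_exposure(cfg.exposure_config)
    site = load_site(cfg.site_config)

    def stage(name: str, fn):
        try:
            return fn()
        except Exception as exc:
            raise StageError(name, str(exc)) from exc

    samples = stage("read_samples", lambda: read_samples(cfg.sample_table))
    survey = stage(
        "survey_stats",
        lambda: survey_stats(samples, chems, substitution=cfg.censoring_substitution),
    )
    means = survey["mean"].to_dict()

    summaries = {
        boiled: stage(
            "pathway_risks",
            lambda b=boiled: summarize(means, chems, exposure, site, boiled=b),
        )
        for boiled in (False, True)
    }
    risks = pd.concat([s.results for s in summaries.values()], ignore_index=True)

    shares_rows = []
    for boiled, summary in summaries.items():
        for metric, per_compound in summary.pathway_shares.items():
            for compound, shares in per_compound.items():
                for pathway, share in shares.items():
                    shares_rows.append(
                        {
                            "compound": compound,
                            "metric": metric,
                            "pathway": pathway,
                            "boiled": boiled,
                            "share": share,
                        }
                    )
    pathway_share_table = pd.DataFrame(shares_rows)

    standardized = stage(
        "standardized_risks", lambda: standardized_risks(chems, exposure, site)
    )
    standardized_rows = [
        {"compound": c, "metric": m, "share": v}
        for m, shares in standardized.compound_shares.items()
        for c, v in shares.items()
    ]

    compound_share_rows = [
        {"compound": c, "metric": metric, "boiled": boiled, "share": v}
        for boiled, summary in summaries.items()
        for metric, shares in summary.compound_shares.items()
        for c, v in shares.items()
    ]

    control_rows = []
    for chem in chems:
        for mode in ("carcinogenic", "noncarcinogenic"):
            try:
                conc = concentration_control(
                    chem, exposure, site, mode, pathway_scope=cfg.pathway_scope
                )
            except ValueError:
                continue
            control_rows.append(conc.model_dump())
            mean = means.get(chem.name, 0.0)
            if mean > 0:
                control_rows.append(
                    duration_control(
                        chem, mean, exposure, site, mode,
                        pathway_scope=cfg.pathway_scope,
                    ).model_dump()
                )
    control_table = pd.DataFrame(control_rows)

    def run_sensitivity() -> pd.DataFrame:
        targets = {
            name: {
                "mean": survey.loc[name, "mean"],
                "max": survey.loc[name, "max"],
                "detection_rate": survey.loc[name, "detection_rate"],
            }
            for name in survey.index
        }
        sim = calibrate_config(targets, n_wells=max(len(samples.data), 1), chems=chems)
        rows = []
        for chem in chems:
            comp = sim.compounds.get(chem.name)
            if comp is None or survey.loc[chem.name, "detection_rate"] == 0:
                continue
            specs = default_specs(cw_mu=comp.log_mean, cw_sigma=comp.log_sd)
            draws = sample_inputs(specs, cfg.mc_iterations, cfg.seed)
            for metric in ("cr", "hq"):
                try:
                    result = mc_risk(
                        draws, chem, exposure, site,
                        mode=metric, pathway_scope=cfg.pathway_scope,
                    )
                except ValueError:
                    continue
                for parameter, value in result.sensitivity.items():
                    rows.append(
                        {
                            "compound": chem.name,
                            "metric": metric,
                            "parameter": parameter,
                            "contribution": value,
                        }
                    )
        return pd.DataFrame(rows)

    sensitivity = stage("sensitivity", run_sensitivity)

    return {
        "provenance": {
            "package": "gwrisk",
            "version": __version__,
            "seed": cfg.seed,
            "config": cfg.model_dump(),
        },
        "survey": survey.reset_index(),
        "risks": risks,
        "pathway_shares": pathway_share_table,
        "standardized_shares": pd.DataFrame(standardized_rows),
        "compound_shares": pd.DataFrame(compound_share_rows),
        "control_values": control_table,
        "sensitivity": sensitivity,
    }


def write_report(bundle: dict[str, Any], out_dir: str | Path) -> Path:
    """Write the bundle: one CSV per table plus a consolidated JSON report."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    consolidated: dict[str, Any] = {}
    for name, value in bundle.items():
        if isinstance(value, pd.DataFrame):
            frame = value.copy()
            for column in frame.columns:
                if frame[column].dtype.kind == "f":
                    frame[column] = frame[column].map(
                        lambda x: sigfig(x) if not math.isnan(x) else x
                    )
            frame.to_csv(out / f"{name}.csv", index=False)
            consolidated[name] = frame.to_dict(orient="records")
        else:
            consolidated[name] = value
    write_json(consolidated, out / "report.json")
    return out / "report.json"
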