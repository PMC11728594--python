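"""Synthetic per-well concentration tables with survey-realistic censoring.

The monitoring data behind the site survey are summarized only by
per-compound detection rates, exceedance rates, maxima and means, so the
generator emulates the concentration field as a zero-inflated lognormal:
with probability ``zero_inflation`` a well truly lacks the compound
(reported as a non-detect), otherwise the concentration is lognormal and is
censored at the analytical detection limit. Censored rows carry the
detection limit as their reported value. Wells are independent and
identically distributed — the published summaries carry no usable spatial
structure, and none of the downstream risk computations consume coordinates.

:func:`calibrate_config` inverts the censored moments: given a target
(censored) mean, detection rate and observed maximum it finds lognormal and
zero-inflation parameters by weighted least squares on three moment
equations (censored mean, detection probability, median of the sample
maximum). Mean and detection rate are matched tightly; the maximum is
down-weighted since a single order statistic is a noisy constraint.
"""

from __future__ import annotations

import math
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field
from scipy import optimize, special, stats

from .registry import ChemicalSet, _data_path
from .risk import SampleTable

__all__ = [
    "CompoundSim",
    "SiteSimConfig",
    "generate_site",
    "calibrate_config",
    "detection_probability",
    "censored_mean",
    "load_table1",
    "table1_site_config",
]


class CompoundSim(BaseModel):
    """Zero-inflated lognormal concentration model for one compound."""

    model_config = ConfigDict(frozen=True)

    log_mean: float
    log_sd: float = Field(gt=0)
    zero_inflation: float = Field(ge=0, le=1)
    detection_limit: float = Field(gt=0)


class SiteSimConfig(BaseModel):
    model_config = ConfigDict(frozen=True)

    compounds: dict[str, CompoundSim]
    n_wells: int = Field(default=76, ge=1)
    seed: int = 0


def detection_probability(sim: CompoundSim) -> float:
    """P(reported value uncensored) under the compound model."""
    z = (sim.log_mean - math.log(sim.detection_limit)) / sim.log_sd
    return (1.0 - sim.zero_inflation) * stats.norm.cdf(z)


def censored_mean(sim: CompoundSim) -> float:
    """Expected reported mean with non-detects substituted by zero."""
    mu, sd = sim.log_mean, sim.log_sd
    z = (mu + sd**2 - math.log(sim.detection_limit)) / sd
    return (1.0 - sim.zero_inflation) * math.exp(mu + sd**2 / 2) * stats.norm.cdf(z)


def generate_site(cfg: SiteSimConfig) -> SampleTable:
    """Draw a per-well sample table; reproducible given the config seed."""
    rng = np.random.default_rng(cfg.seed)
    rows = []
    wells = [f"W{i + 1:03d}" for i in range(cfg.n_wells)]
    for compound, sim in cfg.compounds.items():
        absent = rng.uniform(size=cfg.n_wells) < sim.zero_inflation
        conc = rng.lognormal(sim.log_mean, sim.log_sd, size=cfg.n_wells)
        censored = absent | (conc < sim.detection_limit)
        reported = np.where(censored, sim.detection_limit, conc)
        for well, value, flag in zip(wells, reported, censored):
            rows.append(
                {
                    "well": well,
                    "compound": compound,
                    "conc_mg_L": float(value),
                    "censored": bool(flag),
                }
            )
    return SampleTable(pd.DataFrame(rows))


def _calibrate_compound(
    mean: float,
    maximum: float,
    detection_rate: float,
    detection_limit: float,
    n_wells: int,
) -> CompoundSim:
    if detection_rate <= 0.0:
        # fully censored compound: any sub-detection-limit field works
        return CompoundSim(
            log_mean=math.log(detection_limit) - 3.0,
            log_sd=1.0,
            zero_inflation=1.0,
            detection_limit=detection_limit,
        )
    if mean > maximum > 0:
        raise ValueError(
            f"infeasible targets: mean {mean} exceeds maximum {maximum}"
        )

    n_det = max(int(round(detection_rate * n_wells)), 1)
    z_max = stats.norm.ppf(0.5 ** (1.0 / n_det))
    log_dl = math.log(detection_limit)
    have_mean = mean > 0.0

    def residuals(x: np.ndarray) -> np.ndarray:
        mu, log_sd, logit_p0 = x
        sd = math.exp(log_sd)
        p0 = special.expit(logit_p0)
        sim = CompoundSim(
            log_mean=mu,
            log_sd=sd,
            zero_inflation=p0,
            detection_limit=detection_limit,
        )
        r_det = (detection_probability(sim) - detection_rate) / max(detection_rate, 0.05)
        if have_mean:
            r_mean = (censored_mean(sim) - mean) / mean
        else:
            r_mean = log_sd - math.log(1.5)
        r_max = 0.3 * (mu + sd * z_max - math.log(maximum)) / max(
            1.0, abs(math.log(maximum))
        )
        return np.array([r_det, r_mean, r_max])

    sd0 = 1.5
    p0_0 = min(max((1.0 - detection_rate) / 2.0, 0.02), 0.9)
    if have_mean:
        mu0 = math.log(mean / (1.0 - p0_0)) - sd0**2 / 2.0
    else:
        mu0 = math.log(maximum) - sd0 * z_max
    x0 = np.array([mu0, math.log(sd0), special.logit(p0_0)])
    sol = optimize.least_squares(
        residuals,
        x0,
        bounds=([log_dl - 15.0, math.log(0.1), -12.0], [log_dl + 15.0, math.log(4.0), 12.0]),
        xtol=1e-12,
        ftol=1e-12,
    )
    mu, log_sd, logit_p0 = sol.x
    return CompoundSim(
        log_mean=float(mu),
        log_sd=float(math.exp(log_sd)),
        zero_inflation=float(special.expit(logit_p0)),
        detection_limit=detection_limit,
    )


def calibrate_config(
    targets: Mapping[str, Mapping[str, float]],
    n_wells: int = 76,
    chems: Optional[ChemicalSet] = None,
    seed: int = 0,
) -> SiteSimConfig:
    """Fit a :class:`SiteSimConfig` to per-compound survey targets.

    ``targets`` maps compound name to ``{"mean", "max", "detection_rate"}``
    (censored mean with non-detects at zero). Detection limits come from the
    registry when supplied, else from the packaged default table. A compound
    whose mean prints as zero (heavy censoring) is calibrated to its
    detection rate and maximum only, with the log-sd pinned at 1.5.
    """
    if chems is None:
        from .registry import default_chemicals

        chems = default_chemicals()
    compounds = {}
    for name, row in targets.items():
        compounds[name] = _calibrate_compound(
            mean=float(row["mean"]),
            maximum=float(row["max"]),
            detection_rate=float(row["detection_rate"]),
            detection_limit=chems[name].detection_limit,
            n_wells=n_wells,
        )
    return SiteSimConfig(compounds=compounds, n_wells=n_wells, seed=seed)


def load_table1() -> pd.DataFrame:
    """Packaged per-compound survey summary of the study site (indexed by compound)."""
    return pd.read_csv(_data_path("table1.csv")).set_index("compound")


def table1_site_config(
    n_wells: int = 76, chems: Optional[ChemicalSet] = None, seed: int = 0
) -> SiteSimConfig:
    """Site config calibrated to the packaged survey summary table."""
    table = load_table1()
    targets = {
        name: {
            "mean": row["mean_mg_L"],
            "max": row["max_mg_L"],
            "detection_rate": row["detection_rate"],
        }
        for name, row in table.iterrows()
    }
    return calibrate_config(targets, n_wells=n_wells, chems=chems, seed=seed)
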