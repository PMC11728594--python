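"""Monte Carlo uncertainty propagation and contribution-to-variance sensitivity.

Exposure inputs (water concentration cw, intake rate gwcr, frequency ef,
duration ed, body weight bw) are sampled independently from declared
distributions, pushed through the deterministic risk engine, and the output
spread is attributed to inputs by the signed, normalized squared Spearman
rank correlation — the "contribution to variance" measure popularized by
spreadsheet risk tools. A positive contribution means the input raises the
risk; the absolute contributions sum to one over the non-degenerate inputs.

Averaging times are fixed constants and are never sampled.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator
from scipy import stats

from .exposure import DEFAULT_VF_MODEL, ExposureParams, SiteParams, VolatilizationModel
from .registry import ChemicalParams
from .risk import Metric, pathway_risks

__all__ = [
    "SAMPLABLE_PARAMETERS",
    "DistributionSpec",
    "McResult",
    "specs_from_dict",
    "load_specs",
    "default_specs",
    "sample_inputs",
    "mc_risk",
    "contribution_to_variance",
]

SAMPLABLE_PARAMETERS: tuple[str, ...] = ("cw", "gwcr", "ef", "ed", "bw")

#: Hard validity bounds per target parameter (support must stay inside).
_PARAMETER_RANGE: dict[str, tuple[float, float]] = {
    "cw": (0.0, np.inf),
    "gwcr": (0.0, np.inf),
    "ef": (0.0, 365.0),
    "ed": (0.0, np.inf),
    "bw": (0.0, np.inf),
}

Family = Literal["lognormal", "normal_truncated", "triangular", "uniform", "point"]

_REQUIRED_PARAMS: dict[str, tuple[str, ...]] = {
    "lognormal": ("mu", "sigma"),
    "normal_truncated": ("mean", "sd", "lower", "upper"),
    "triangular": ("left", "mode", "right"),
    "uniform": ("lower", "upper"),
    "point": ("value",),
}


class DistributionSpec(BaseModel):
    """Distribution assigned to one exposure input."""

    model_config = ConfigDict(frozen=True)

    name: str
    family: Family
    params: dict[str, float]
    lower: Optional[float] = None
    upper: Optional[float] = None

    @model_validator(mode="after")
    def _validate(self) -> "DistributionSpec":
        if self.name not in SAMPLABLE_PARAMETERS:
            raise ValueError(
                f"parameter {self.name!r} is not samplable; "
                f"choose from {SAMPLABLE_PARAMETERS}"
            )
        missing = set(_REQUIRED_PARAMS[self.family]) - set(self.params)
        if missing:
            raise ValueError(f"{self.family} spec for {self.name} lacks {sorted(missing)}")
        if self.family == "lognormal" and self.params["sigma"] <= 0:
            raise ValueError("lognormal sigma must be positive")
        if self.family == "normal_truncated":
            if self.params["sd"] <= 0:
                raise ValueError("truncated normal sd must be positive")
            if self.params["lower"] >= self.params["upper"]:
                raise ValueError("truncation bounds must satisfy lower < upper")
        if self.family == "triangular":
            left, mode, right = (self.params[k] for k in ("left", "mode", "right"))
            if not left <= mode <= right or left == right:
                raise ValueError("triangular requires left <= mode <= right, left < right")
        if self.family == "uniform" and self.params["lower"] >= self.params["upper"]:
            raise ValueError("uniform requires lower < upper")
        lo, hi = self.support()
        rlo, rhi = _PARAMETER_RANGE[self.name]
        if lo < rlo or hi > rhi:
            raise ValueError(
                f"{self.name} support [{lo}, {hi}] exceeds valid range [{rlo}, {rhi}]"
            )
        return self

    def support(self) -> tuple[float, float]:
        if self.family == "point":
            v = self.params["value"]
            return v, v
        if self.family == "uniform":
            lo, hi = self.params["lower"], self.params["upper"]
        elif self.family == "triangular":
            lo, hi = self.params["left"], self.params["right"]
        elif self.family == "normal_truncated":
            lo, hi = self.params["lower"], self.params["upper"]
        else:  # lognormal
            lo, hi = 0.0, np.inf
        if self.lower is not None:
            lo = max(lo, self.lower)
        if self.upper is not None:
            hi = min(hi, self.upper)
        return lo, hi

    @property
    def is_point(self) -> bool:
        return self.family == "point"


def specs_from_dict(config: Mapping[str, Mapping[str, float]]) -> list[DistributionSpec]:
    """Build specs from a flat config: one block per parameter."""
    specs = []
    for name, block in config.items():
        block = dict(block)
        family = block.pop("family")
        if family == "normal_truncated":
            # lower/upper are the family's own truncation parameters
            lower = upper = None
        else:
            lower = block.pop("lower", None)
            upper = block.pop("upper", None)
        specs.append(
            DistributionSpec(
                name=name, family=family, params=block, lower=lower, upper=upper
            )
        )
    return specs


def load_specs(path) -> list[DistributionSpec]:
    with open(path) as fh:
        return specs_from_dict(yaml.safe_load(fh))


def default_specs(
    cw_mu: Optional[float] = None, cw_sigma: Optional[float] = None
) -> list[DistributionSpec]:
    """Packaged default distributions, optionally with a compound-specific
    lognormal concentration field (log-mean/log-sd, typically the calibrated
    site parameters)."""
    from .registry import _data_path

    specs = load_specs(_data_path("distributions.yaml"))
    if cw_mu is not None and cw_sigma is not None:
        specs = [s for s in specs if s.name != "cw"]
        specs.append(
            DistributionSpec(
                name="cw",
                family="lognormal",
                params={"mu": cw_mu, "sigma": cw_sigma},
            )
        )
    return specs


def _draw(spec: DistributionSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    if spec.family == "point":
        return np.full(n, spec.params["value"])
    if spec.family == "uniform":
        x = rng.uniform(spec.params["lower"], spec.params["upper"], size=n)
    elif spec.family == "triangular":
        x = rng.triangular(
            spec.params["left"], spec.params["mode"], spec.params["right"], size=n
        )
    elif spec.family == "normal_truncated":
        a = (spec.params["lower"] - spec.params["mean"]) / spec.params["sd"]
        b = (spec.params["upper"] - spec.params["mean"]) / spec.params["sd"]
        x = stats.truncnorm.rvs(
            a, b, loc=spec.params["mean"], scale=spec.params["sd"],
            size=n, random_state=rng,
        )
    else:  # lognormal
        x = rng.lognormal(spec.params["mu"], spec.params["sigma"], size=n)
    lo, hi = spec.support()
    if np.isfinite(lo) or np.isfinite(hi):
        # truncation by resampling out-of-bound draws
        bad = (x < lo) | (x > hi)
        while bad.any():
            x[bad] = _draw(
                spec.model_copy(update={"lower": None, "upper": None}),
                int(bad.sum()),
                rng,
            )
            x_bad = x[bad]
            still = (x_bad < lo) | (x_bad > hi)
            idx = np.flatnonzero(bad)
            bad = np.zeros_like(bad)
            bad[idx[still]] = True
    return x


def sample_inputs(
    specs: Sequence[DistributionSpec], n: int, seed: int
) -> pd.DataFrame:
    """Independent, reproducible draws for each declared parameter."""
    if n < 1:
        raise ValueError("n must be at least 1")
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise ValueError("overlapping distribution specs: each parameter once")
    rng = np.random.default_rng(seed)
    draws = pd.DataFrame({s.name: _draw(s, n, rng) for s in specs})
    draws.attrs["seed"] = seed
    return draws


@dataclass
class McResult:
    """Monte Carlo output bundle for one compound and metric."""

    n: int
    seed: Optional[int]
    draws: pd.DataFrame
    outputs: np.ndarray
    percentiles: dict[float, float]
    sensitivity: dict[str, float]


_PERCENTILES = (2.5, 5.0, 25.0, 50.0, 75.0, 95.0, 97.5)


def mc_risk(
    draws: pd.DataFrame,
    chem: ChemicalParams,
    p_base: ExposureParams,
    s: SiteParams,
    mode: Metric = "cr",
    pathway_scope: Literal["all", "ingestion"] = "ingestion",
    vf_model: VolatilizationModel = DEFAULT_VF_MODEL,
) -> McResult:
    """Push sampled inputs through the deterministic engine.

    Each draw overrides the base exposure parameters (and cw when sampled);
    the output is the total CR or HQ over the selected pathway scope.
    """
    if len(draws) == 0:
        raise ValueError("draws must be nonempty")
    outputs = np.empty(len(draws))
    exposure_cols = [c for c in draws.columns if c != "cw"]
    for i, row in enumerate(draws.itertuples(index=False)):
        record = dict(zip(draws.columns, row))
        cw = record.pop("cw", 1.0)
        p = p_base.model_copy(update=record) if exposure_cols else p_base
        results = pathway_risks(cw, chem, p, s, vf_model=vf_model)
        if pathway_scope == "ingestion":
            results = [r for r in results if r.pathway == "ingestion"]
        values = [r.metric(mode) for r in results if r.metric(mode) is not None]
        outputs[i] = sum(values) if values else np.nan
    if np.isnan(outputs).any():
        raise ValueError(f"{chem.name} lacks {mode} toxicity data in scope")
    sens = contribution_to_variance(draws, outputs)
    return McResult(
        n=len(draws),
        seed=draws.attrs.get("seed"),
        draws=draws,
        outputs=outputs,
        percentiles={q: float(np.percentile(outputs, q)) for q in _PERCENTILES},
        sensitivity=sens,
    )


def contribution_to_variance(
    draws: pd.DataFrame, outputs: np.ndarray
) -> dict[str, float]:
    """Signed normalized squared Spearman correlations.

    contribution_k = sign(r_k)·r_k² / Σ_j r_j² over parameters with at least
    two distinct sampled values; degenerate (point) parameters are excluded.
    """
    outputs = np.asarray(outputs, dtype=float)
    if np.ptp(outputs) == 0.0:
        raise ValueError("output variance is zero; contributions undefined")
    correlations: dict[str, float] = {}
    for column in draws.columns:
        x = draws[column].to_numpy()
        if np.ptp(x) == 0.0:
            continue
        r = stats.spearmanr(x, outputs).statistic
        correlations[column] = float(r)
    denom = sum(r * r for r in correlations.values())
    if denom == 0.0:
        raise ValueError("no parameter correlates with the output")
    return {
        name: float(np.sign(r) * r * r / denom) for name, r in correlations.items()
    }
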