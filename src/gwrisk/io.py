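"""Readers and writers: sample tables, parameter configs, report files.

Sample tables are CSV with header ``well,compound,conc_mg_L,censored``.
Exposure and site configs are flat YAML (key = field name, value = number).
All numeric report output is written with 6 significant digits.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Any, Optional

import pandas as pd
import yaml

from .exposure import ExposureParams, SiteParams
from .registry import _data_path
from .risk import SampleTable

__all__ = [
    "read_samples",
    "write_samples",
    "load_exposure",
    "load_site",
    "sigfig",
    "write_json",
]

_TRUE = {"true", "1", "yes"}
_FALSE = {"false", "0", "no"}


def read_samples(path: str | Path) -> SampleTable:
    """Parse a sample-table CSV; malformed rows are reported with line numbers."""
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    if len(raw) == 0:
        raise ValueError(f"{path}: sample table is empty")
    required = ["well", "compound", "conc_mg_L", "censored"]
    missing = [c for c in required if c not in raw.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")

    rows = []
    for idx, row in raw.iterrows():
        line = idx + 2  # header occupies line 1
        try:
            conc = float(row["conc_mg_L"])
        except ValueError as exc:
            raise ValueError(
                f"{path}:{line}: non-numeric concentration {row['conc_mg_L']!r}"
            ) from exc
        if not math.isfinite(conc) or conc < 0:
            raise ValueError(f"{path}:{line}: invalid concentration {conc}")
        flag = str(row["censored"]).strip().lower()
        if flag in _TRUE:
            censored = True
        elif flag in _FALSE:
            censored = False
        else:
            raise ValueError(f"{path}:{line}: invalid censored flag {row['censored']!r}")
        rows.append(
            {
                "well": row["well"],
                "compound": row["compound"],
                "conc_mg_L": conc,
                "censored": censored,
            }
        )
    return SampleTable(pd.DataFrame(rows))


def write_samples(table: SampleTable, path: str | Path) -> None:
    table.data.to_csv(path, index=False)


def load_exposure(path: Optional[str | Path] = None) -> ExposureParams:
    """Exposure parameters from flat YAML; packaged defaults when no path given."""
    with open(path or _data_path("exposure.yaml")) as fh:
        return ExposureParams(**yaml.safe_load(fh))


def load_site(path: Optional[str | Path] = None) -> SiteParams:
    """Site parameters from flat YAML; packaged defaults when no path given."""
    with open(path or _data_path("site.yaml")) as fh:
        return SiteParams(**yaml.safe_load(fh))


def sigfig(x: float, digits: int = 6) -> float:
    """Round to ``digits`` significant digits (report convention)."""
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, digits - 1 - int(math.floor(math.log10(abs(x)))))


def _roundtree(obj: Any) -> Any:
    if isinstance(obj, float):
        return sigfig(obj)
    if isinstance(obj, dict):
        return {k: _roundtree(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_roundtree(v) for v in obj]
    return obj


def write_json(obj: Any, path: str | Path) -> None:
    """Deterministic JSON: sorted keys, 6-significant-digit floats."""
    with open(path, "w") as fh:
        json.dump(_roundtree(obj), fh, indent=2, sort_keys=True)
        fh.write("\n")
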