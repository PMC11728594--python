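"""Per-compound physicochemical and toxicity parameter registry.

The ten study compounds are chlorinated hydrocarbons monitored in the site's
phreatic aquifer. Each carries the constants the downstream dose and risk
models consume: oral cancer slope factor (SF, (mg/kg·day)^-1), inhalation
unit risk (IUR, (µg/m³)^-1), oral reference dose (RfD, mg/kg·day),
inhalation reference concentration (RfC, mg/m³), dimensionless Henry
constant H' (air/water), free-air and free-water diffusivities (cm²/s),
dermal permeability coefficient Kp (cm/h), gastrointestinal absorption
fraction, analytical detection limit and drinking-water standard limit
(both mg/L).

Toxicity parameters are optional: a compound without an IUR simply has no
quantifiable inhalation cancer risk, and the risk engine reports that metric
as absent rather than zero. The packaged default table follows USEPA
IRIS/RSL values with Kp from the dermal guidance literature; every entry can
be overridden by loading a user table with :func:`load_chemicals`.
"""

from __future__ import annotations

import importlib.resources
import warnings
from pathlib import Path
from typing import Iterable, Iterator, Optional

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

__all__ = [
    "STUDY_COMPOUNDS",
    "ChemicalParams",
    "ChemicalSet",
    "RegistryCheck",
    "ValidationReport",
    "load_chemicals",
    "default_chemicals",
    "write_chemicals",
    "validate_registry",
]

#: Controlled vocabulary of the ten study compounds.
STUDY_COMPOUNDS: tuple[str, ...] = (
    "trichloromethane",
    "vinyl chloride",
    "trichloroethylene",
    "carbon tetrachloride",
    "1,1-dichloroethane",
    "1,2-dichloroethane",
    "1,1,2-trichloroethane",
    "1,1-dichloroethylene",
    "1,2-dichloroethylene",
    "tetrachloroethylene",
)

#: Column order of the chemical-table CSV interface.
CHEMICAL_COLUMNS: tuple[str, ...] = (
    "name",
    "cas",
    "sf_oral",
    "iur",
    "rfd_oral",
    "rfc",
    "henry_dimensionless",
    "d_air",
    "d_water",
    "kp",
    "abs_gi",
    "detection_limit",
    "standard_limit",
)

_OPTIONAL_FIELDS = ("sf_oral", "iur", "rfd_oral", "rfc")


class ChemicalParams(BaseModel):
    """Validated parameter record for one compound."""

    model_config = ConfigDict(frozen=True)

    name: str
    cas: str
    sf_oral: Optional[float] = Field(default=None, gt=0)
    iur: Optional[float] = Field(default=None, gt=0)
    rfd_oral: Optional[float] = Field(default=None, gt=0)
    rfc: Optional[float] = Field(default=None, gt=0)
    henry_dimensionless: float = Field(gt=0)
    d_air: float = Field(gt=0)
    d_water: float = Field(gt=0)
    kp: Optional[float] = Field(default=None, gt=0)
    abs_gi: float = Field(gt=0, le=1)
    detection_limit: float = Field(ge=0.0002, le=0.005)
    standard_limit: float = Field(gt=0)

    @model_validator(mode="after")
    def _known_compound(self) -> "ChemicalParams":
        if self.name not in STUDY_COMPOUNDS:
            raise ValueError(
                f"unknown compound {self.name!r}; expected one of the "
                f"{len(STUDY_COMPOUNDS)} study compounds"
            )
        return self


class ChemicalSet:
    """Ordered collection of :class:`ChemicalParams` keyed by compound name."""

    def __init__(self, chemicals: Iterable[ChemicalParams]):
        self._by_name: dict[str, ChemicalParams] = {}
        for chem in chemicals:
            if chem.name in self._by_name:
                raise ValueError(f"duplicate compound id {chem.name!r}")
            self._by_name[chem.name] = chem

    def __getitem__(self, name: str) -> ChemicalParams:
        return self._by_name[name]

    def __iter__(self) -> Iterator[ChemicalParams]:
        return iter(self._by_name.values())

    def __len__(self) -> int:
        return len(self._by_name)

    def __contains__(self, name: object) -> bool:
        return name in self._by_name

    @property
    def names(self) -> list[str]:
        return list(self._by_name)

    def to_frame(self) -> pd.DataFrame:
        rows = [chem.model_dump() for chem in self]
        return pd.DataFrame(rows, columns=list(CHEMICAL_COLUMNS))


def _data_path(filename: str) -> Path:
    return Path(str(importlib.resources.files("gwrisk.data") / filename))


def load_chemicals(source: str | Path | pd.DataFrame) -> ChemicalSet:
    """Load and validate a chemical parameter table.

    ``source`` is a CSV path (header row = :data:`CHEMICAL_COLUMNS`, empty
    cell = parameter absent) or an equivalent DataFrame. Raises ``ValueError``
    naming the offending row/column on any malformed entry; emits a warning
    if the table does not cover the full ten-compound study set.
    """
    if isinstance(source, pd.DataFrame):
        table = source.copy()
    else:
        table = pd.read_csv(source)

    unknown = set(table.columns) - set(CHEMICAL_COLUMNS)
    if unknown:
        raise ValueError(f"unknown chemical-table column(s): {sorted(unknown)}")
    missing = set(CHEMICAL_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"chemical table lacks column(s): {sorted(missing)}")

    chems: list[ChemicalParams] = []
    for idx, row in table.iterrows():
        record = {
            key: (None if pd.isna(value) else value) for key, value in row.items()
        }
        try:
            chems.append(ChemicalParams(**record))
        except Exception as exc:
            raise ValueError(
                f"invalid chemical table row {idx} ({record.get('name')!r}): {exc}"
            ) from exc

    chem_set = ChemicalSet(chems)
    if set(chem_set.names) != set(STUDY_COMPOUNDS):
        warnings.warn(
            f"chemical table covers {len(chem_set)} compounds; the default "
            f"study set has {len(STUDY_COMPOUNDS)}",
            stacklevel=2,
        )
    return chem_set


def default_chemicals() -> ChemicalSet:
    """The packaged default parameter table for the ten study compounds."""
    return load_chemicals(_data_path("chemicals.csv"))


def write_chemicals(chems: ChemicalSet, path: str | Path) -> None:
    """Serialize a chemical set to the CSV interface (round-trips losslessly)."""
    chems.to_frame().to_csv(path, index=False)


class RegistryCheck(BaseModel):
    name: str
    passed: bool
    detail: str


class ValidationReport(BaseModel):
    checks: list[RegistryCheck]
    warnings: list[str] = Field(default_factory=list)

    @property
    def passed(self) -> bool:
        return all(check.passed for check in self.checks)

    def failures(self) -> list[RegistryCheck]:
        return [check for check in self.checks if not check.passed]


def validate_registry(chems: ChemicalSet) -> ValidationReport:
    """Check the qualitative toxicity orderings the study site exhibits.

    On the packaged default table all three assertions hold: vinyl chloride
    and trichloroethylene carry the two largest oral slope factors,
    trichloroethylene has the smallest oral reference dose, and vinyl
    chloride shares its reference dose with 1,2-dichloroethylene.
    """
    checks: list[RegistryCheck] = []
    warns: list[str] = []

    if len(chems) != len(STUDY_COMPOUNDS):
        warns.append(
            f"registry holds {len(chems)} compounds (default study set: "
            f"{len(STUDY_COMPOUNDS)})"
        )

    with_sf = sorted(
        (c for c in chems if c.sf_oral is not None),
        key=lambda c: c.sf_oral,
        reverse=True,
    )
    top_two = {c.name for c in with_sf[:2]}
    # the top two must stand strictly above the rest (ties flag the check)
    distinct = len(with_sf) >= 2 and (
        len(with_sf) == 2 or with_sf[1].sf_oral > with_sf[2].sf_oral
    )
    checks.append(
        RegistryCheck(
            name="sf_oral_top_two",
            passed=distinct
            and top_two == {"vinyl chloride", "trichloroethylene"},
            detail=f"largest oral slope factors: {sorted(top_two)}",
        )
    )

    with_rfd = [c for c in chems if c.rfd_oral is not None]
    min_rfd = min(with_rfd, key=lambda c: c.rfd_oral) if with_rfd else None
    unique_min = min_rfd is not None and (
        sum(1 for c in with_rfd if c.rfd_oral == min_rfd.rfd_oral) == 1
    )
    checks.append(
        RegistryCheck(
            name="rfd_oral_minimum",
            passed=unique_min and min_rfd.name == "trichloroethylene",
            detail=f"minimum oral RfD: {min_rfd.name if min_rfd else 'n/a'}",
        )
    )

    try:
        vc = chems["vinyl chloride"].rfd_oral
        dce = chems["1,2-dichloroethylene"].rfd_oral
        equal = vc is not None and vc == dce
        detail = f"RfD vinyl chloride={vc}, 1,2-dichloroethylene={dce}"
    except KeyError:
        equal, detail = False, "compound(s) absent"
    checks.append(
        RegistryCheck(name="rfd_vc_equals_12dce", passed=equal, detail=detail)
    )

    return ValidationReport(checks=checks, warnings=warns)
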