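"""Assay designs and observation containers for microsomal inhibition experiments.

Two experiment families are represented:

* Reversible inhibition (RI): reaction velocities measured on a substrate
  concentration x inhibitor concentration grid, used to estimate a competitive
  inhibition constant Ki.
* Time-dependent inactivation (TDI): percent-remaining enzyme activity measured
  on an inhibitor concentration x pre-incubation time grid, used to estimate
  the inactivation constants kinact and KI.

CYP3A4 activity is isolated in CYP3A5*3/*3 (non-expresser) microsomes without
CYP3cide; CYP3A5 activity is isolated in *1/*3 microsomes with CYP3cide present
to silence CYP3A4.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, model_validator

from .errors import DataError, DesignError

RI_COLUMNS = ["substrate_um", "inhibitor_um", "replicate", "velocity"]
TDI_COLUMNS = ["inhibitor_um", "time_min", "replicate", "activity_pct"]


class EnzymeTarget(str, enum.Enum):
    CYP3A4 = "CYP3A4"
    CYP3A5 = "CYP3A5"


class MicrosomeGenotype(str, enum.Enum):
    """CYP3A5 genotype of the liver-microsome lot (*1 active, *3 inactive)."""

    HET = "*1/*3"
    NULL = "*3/*3"


def _check_strictly_increasing(values, name: str) -> None:
    arr = np.asarray(values, dtype=float)
    if arr.size and np.any(np.diff(arr) <= 0):
        raise ValueError(f"{name} must be strictly increasing")


class RIDesign(BaseModel):
    """Design of a reversible-inhibition velocity assay."""

    enzyme_target: EnzymeTarget
    microsome_genotype: MicrosomeGenotype
    cyp3cide_conc: float = 0.0  # uM; >0 only when isolating CYP3A5
    substrate_concs: list[float]
    inhibitor_concs: list[float]
    protein_conc: float = 0.2  # mg/mL
    incubation_time: float = 10.0  # min

    @model_validator(mode="after")
    def _validate(self) -> "RIDesign":
        if min(self.substrate_concs) <= 0:
            raise ValueError("substrate_concs must be strictly positive")
        _check_strictly_increasing(self.substrate_concs, "substrate_concs")
        if min(self.inhibitor_concs) < 0:
            raise ValueError("inhibitor_concs must be non-negative")
        if 0.0 not in self.inhibitor_concs:
            raise ValueError("inhibitor_concs must include 0 (control)")
        _check_strictly_increasing(self.inhibitor_concs, "inhibitor_concs")
        if self.enzyme_target is EnzymeTarget.CYP3A5:
            if self.microsome_genotype is not MicrosomeGenotype.HET:
                raise ValueError("CYP3A5 assays require *1/*3 microsomes")
            if self.cyp3cide_conc <= 0:
                raise ValueError("CYP3A5 assays require CYP3cide > 0")
        else:
            if self.microsome_genotype is not MicrosomeGenotype.NULL:
                raise ValueError("CYP3A4 assays require *3/*3 microsomes")
            if self.cyp3cide_conc != 0:
                raise ValueError("CYP3A4 assays require CYP3cide = 0")
        return self


class TDIDesign(BaseModel):
    """Design of a two-step dilution time-dependent-inactivation assay."""

    enzyme_target: EnzymeTarget
    inhibitor_concs: list[float]
    preincubation_times: list[float]
    dilution_factor: float = 10.0  # 20 uL primary into 180 uL secondary
    probe_substrate_conc: float = 200.0  # uM testosterone
    protein_conc: float = 0.5  # mg/mL
    cyp3cide_conc: float = 0.0  # uM

    @model_validator(mode="after")
    def _validate(self) -> "TDIDesign":
        if min(self.preincubation_times) < 0:
            raise ValueError("preincubation_times must be non-negative")
        if 0.0 not in self.preincubation_times:
            raise ValueError("preincubation_times must include 0")
        _check_strictly_increasing(self.preincubation_times, "preincubation_times")
        if 0.0 not in self.inhibitor_concs:
            raise ValueError("inhibitor_concs must include 0 (control)")
        _check_strictly_increasing(self.inhibitor_concs, "inhibitor_concs")
        if self.dilution_factor <= 1:
            raise ValueError("dilution_factor must exceed 1")
        return self


def _require_columns(table: pd.DataFrame, columns: list[str], kind: str) -> pd.DataFrame:
    missing = [c for c in columns if c not in table.columns]
    if missing:
        raise DataError(f"{kind} table is missing columns {missing}")
    return table.loc[:, columns].reset_index(drop=True)


@dataclass
class RIDataset:
    """Velocity observations (pmol/min/mg) on a substrate x inhibitor grid."""

    design: RIDesign
    velocities: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self.velocities = _require_columns(self.velocities, RI_COLUMNS, "RI")
        v = self.velocities
        if (v["velocity"] < 0).any():
            raise DataError("velocities must be non-negative")
        grid = {(s, i) for s in self.design.substrate_concs for i in self.design.inhibitor_concs}
        observed = set(map(tuple, v[["substrate_um", "inhibitor_um"]].to_numpy()))
        empty = grid - observed
        if empty:
            raise DesignError(f"grid cells without observations: {sorted(empty)[:5]}")
        extra = observed - grid
        if extra:
            raise DesignError(f"observations off the design grid: {sorted(extra)[:5]}")

    @property
    def n_replicates(self) -> int:
        return int(self.velocities.groupby(["substrate_um", "inhibitor_um"]).size().max())

    def control_subset(self) -> pd.DataFrame:
        """Rows at inhibitor concentration 0 (baseline Michaelis-Menten data)."""
        return self.velocities[self.velocities["inhibitor_um"] == 0.0]

    def to_csv(self, path: str | Path) -> None:
        self.velocities.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, csv_path: str | Path, design_path: str | Path) -> "RIDataset":
        design = RIDesign(**yaml.safe_load(Path(design_path).read_text()))
        return cls(design=design, velocities=pd.read_csv(csv_path))


@dataclass
class TDIDataset:
    """Percent-remaining activity on an inhibitor x pre-incubation-time grid."""

    design: TDIDesign
    activities: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self.activities = _require_columns(self.activities, TDI_COLUMNS, "TDI")
        a = self.activities
        bad = a[a["activity_pct"] <= 0]
        if not bad.empty:
            row = bad.iloc[0]
            raise DataError(
                "non-positive activity at inhibitor "
                f"{row['inhibitor_um']} uM, t={row['time_min']} min "
                "(log-linear regression requires activity > 0)"
            )
        grid = {(i, t) for i in self.design.inhibitor_concs for t in self.design.preincubation_times}
        observed = set(map(tuple, a[["inhibitor_um", "time_min"]].to_numpy()))
        empty = grid - observed
        if empty:
            raise DesignError(f"grid cells without observations: {sorted(empty)[:5]}")

    def to_csv(self, path: str | Path) -> None:
        self.activities.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, csv_path: str | Path, design_path: str | Path) -> "TDIDataset":
        design = TDIDesign(**yaml.safe_load(Path(design_path).read_text()))
        return cls(design=design, activities=pd.read_csv(csv_path))


def percent_of_control(
    rates: pd.DataFrame, mode: str = "matched_time"
) -> pd.DataFrame:
    """Convert raw probe formation rates into percent-remaining activity.

    ``rates`` carries columns inhibitor_um, time_min, replicate, rate.

    mode="matched_time" (default) normalises each cell to the mean 0 uM
    control rate at the same pre-incubation time, which cancels any
    inhibitor-independent loss of activity during pre-incubation.
    mode="t0" normalises to the mean rate of the same inhibitor level at t=0.
    """
    if mode not in {"matched_time", "t0"}:
        raise ValueError(f"unknown normalisation mode {mode!r}")
    rates = _require_columns(rates, ["inhibitor_um", "time_min", "replicate", "rate"], "rate")
    out = rates.copy()
    if mode == "matched_time":
        ref = (
            rates[rates["inhibitor_um"] == 0.0]
            .groupby("time_min")["rate"]
            .mean()
        )
        denom = out["time_min"].map(ref)
    else:
        ref = (
            rates[rates["time_min"] == 0.0]
            .groupby("inhibitor_um")["rate"]
            .mean()
        )
        denom = out["inhibitor_um"].map(ref)
    if denom.isna().any() or (denom <= 0).any():
        raise DataError("normalisation reference rates missing or non-positive")
    out["activity_pct"] = 100.0 * out["rate"] / denom
    return out.drop(columns="rate")
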