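"""Scenario orchestration: baseline and DDI simulations, report tables.

The default scenario grid mirrors the study design: a 2 mg oral victim dose
in CYP3A5 expresser and non-expresser Chinese populations, each perpetrator
given either as a single co-administered dose or twice daily for 13 days with
the victim co-dosed with the first perpetrator dose of day 13, and three
inhibition cases per cell — #1 reversible only, #2 time-dependent only,
#3 both.  Schisandrin A in non-expressers runs only the TDI-only case by
default: it shows no reversible inhibition of CYP3A4 and non-expressers have
no CYP3A5, so its RI and combined cells are mechanistically empty.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
from pydantic import BaseModel, Field

from . import presets
from .errors import CypddiError, DataError
from .metrics import aucr, compute_metrics, fold_error, round_half_even
from .pbpk import (
    CompoundSpec,
    DoseRegimen,
    GenotypeClass,
    MechanismCase,
    PopulationSpec,
    SolverSettings,
    simulate_pk,
)

__all__ = ["ScenarioConfig", "DDIResult", "DDIReport", "run_scenario_grid",
           "render_report", "verify_printed_aucr", "baseline_metrics"]

_CASES = (MechanismCase.RI_ONLY, MechanismCase.TDI_ONLY, MechanismCase.BOTH)

MULTIDOSE_VICTIM_START_H = 288.0  # first perpetrator dose of day 13 (BID from t=0)


class ScenarioConfig(BaseModel):
    """Configuration of the full DDI scenario grid."""

    victim_dose_mg: float = 2.0
    ethnicity: str = "Chinese"
    genotypes: list[str] = Field(default_factory=lambda: ["expresser", "non_expresser"])
    perpetrators: list[str] = Field(default_factory=lambda: ["STA", "SIA"])
    regimens: list[str] = Field(default_factory=lambda: ["single", "multidose"])
    multidose_days: int = 13
    force_all_cells: bool = False  # run mechanistically empty SIA cells anyway
    solver: SolverSettings = Field(default_factory=SolverSettings)


@dataclass
class DDIResult:
    scenario_id: str
    population: str
    perpetrator: str
    regimen: str
    case: str
    auc_alone: float
    auc_with: float
    aucr: float
    cmax_with: float
    tmax_with: float
    error: str | None = None


@dataclass
class DDIReport:
    results: list[DDIResult]
    baselines: dict[str, dict]  # genotype -> metrics dict
    config: ScenarioConfig
    profiles: dict[str, pd.DataFrame] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.__dict__ for r in self.results])


def _perpetrator(name: str) -> tuple[CompoundSpec, float]:
    if name.upper() == "STA":
        return presets.sta_compound(), presets.STA_DOSE_MG
    if name.upper() == "SIA":
        return presets.sia_compound(), presets.SIA_DOSE_MG
    raise CypddiError(f"unknown perpetrator {name!r}")


def _mechanistically_empty(perp: str, genotype: str, case: MechanismCase) -> bool:
    # SIA has no reversible CYP3A4 inhibition; without CYP3A5 its RI arm is empty
    return (perp.upper() == "SIA" and genotype == "non_expresser"
            and case is not MechanismCase.TDI_ONLY)


def baseline_metrics(
    genotype: str, dose_mg: float = 2.0, ethnicity: str = "Chinese",
    settings: Optional[SolverSettings] = None,
):
    """Victim-alone profile and metrics for one genotype population."""
    pop = presets.population(ethnicity, genotype)
    victim = presets.tacrolimus_compound(genotype)
    profile = simulate_pk(victim, DoseRegimen(dose_mg=dose_mg), pop,
                          settings=settings)
    return profile, compute_metrics(profile)


def run_scenario_grid(config: ScenarioConfig | None = None,
                      keep_profiles: bool = False) -> DDIReport:
    """Run the victim-alone baselines and every (perpetrator, regimen, case) cell."""
    config = config or ScenarioConfig()
    settings = config.solver
    results: list[DDIResult] = []
    baselines: dict[str, dict] = {}
    profiles: dict[str, pd.DataFrame] = {}

    for genotype in config.genotypes:
        pop = presets.population(config.ethnicity, genotype)
        victim = presets.tacrolimus_compound(genotype)
        base_profile, base = baseline_metrics(genotype, config.victim_dose_mg,
                                              config.ethnicity, settings)
        baselines[genotype] = {"auc": base.auc, "cmax": base.cmax, "tmax": base.tmax}
        if keep_profiles:
            profiles[f"baseline_{genotype}"] = base_profile.to_frame()

        for perp_name in config.perpetrators:
            perp, perp_dose = _perpetrator(perp_name)
            for regimen_name in config.regimens:
                if regimen_name == "single":
                    perp_reg = presets.single_dose(perp_dose)
                    victim_reg = DoseRegimen(dose_mg=config.victim_dose_mg)
                    start = 0.0
                else:
                    perp_reg = presets.multidose_bid(perp_dose, config.multidose_days)
                    start = 12.0 * (2 * config.multidose_days - 2)
                    victim_reg = DoseRegimen(dose_mg=config.victim_dose_mg,
                                             start_time_h=start)
                for case in _CASES:
                    sid = f"{genotype}/{perp_name}/{regimen_name}/{case.value}"
                    if not config.force_all_cells and \
                            _mechanistically_empty(perp_name, genotype, case):
                        continue
                    try:
                        profile = simulate_pk(victim, victim_reg, pop,
                                              perpetrator=(perp, perp_reg),
                                              mechanism_case=case, settings=settings)
                        m = compute_metrics(profile, start_time_h=start)
                        results.append(DDIResult(
                            scenario_id=sid, population=genotype,
                            perpetrator=perp_name, regimen=regimen_name,
                            case=case.value, auc_alone=base.auc, auc_with=m.auc,
                            aucr=aucr(m.auc, base.auc), cmax_with=m.cmax,
                            tmax_with=m.tmax,
                        ))
                        if keep_profiles:
                            profiles[sid.replace("/", "_")] = profile.to_frame()
                    except CypddiError as exc:
                        results.append(DDIResult(
                            scenario_id=sid, population=genotype,
                            perpetrator=perp_name, regimen=regimen_name,
                            case=case.value, auc_alone=base.auc, auc_with=float("nan"),
                            aucr=float("nan"), cmax_with=float("nan"),
                            tmax_with=float("nan"), error=str(exc),
                        ))
    return DDIReport(results=results, baselines=baselines, config=config,
                     profiles=profiles)


def verify_printed_aucr(auc_alone: float, auc_with: float, printed_aucr: float,
                        ndigits: int = 2) -> bool:
    """Check that a printed AUC ratio is consistent with its own AUC pair."""
    return round_half_even(aucr(auc_with, auc_alone), ndigits) == printed_aucr


def render_report(report: DDIReport, outdir: str | Path,
                  observed: dict | None = None) -> dict[str, Path]:
    """Write CSV/JSON/markdown report files; returns the paths written.

    ``observed`` maps (dose_mg, genotype) to observed metrics for the
    Table-1-style predicted-vs-observed sheet (fold-error cells >= 2 flagged).
    """
    if not report.results:
        raise DataError("no scenario results to render")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    frame = report.to_frame()
    table2 = frame.assign(
        aucr_2dp=frame["aucr"].map(lambda x: round_half_even(x) if x == x else x),
    )
    path2 = outdir / "table2_like.csv"
    table2.to_csv(path2, index=False, float_format="%.6g")
    written["table2"] = path2

    if observed:
        rows = []
        for (dose, genotype), obs in observed.items():
            base = report.baselines.get(genotype)
            if base is None:
                continue
            for metric in ("auc", "cmax", "tmax"):
                fe = fold_error(base[metric], obs[metric]).fold_error
                rows.append({
                    "dose_mg": dose, "population": genotype, "metric": metric,
                    "predicted": base[metric], "observed": obs[metric],
                    "fold_error": round_half_even(fe),
                    "exceeds_twofold": fe >= 2.0,
                })
        path1 = outdir / "table1_like.csv"
        pd.DataFrame(rows).to_csv(path1, index=False, float_format="%.6g")
        written["table1"] = path1

    prof_dir = outdir / "profiles"
    for name, prof in report.profiles.items():
        prof_dir.mkdir(exist_ok=True)
        p = prof_dir / f"{name}.csv"
        prof.to_csv(p, index=False, float_format="%.6g")
        written[f"profile_{name}"] = p

    config_json = report.config.model_dump_json()
    run = {
        "config": json.loads(config_json),
        "config_sha256": hashlib.sha256(config_json.encode()).hexdigest(),
        "baselines": report.baselines,
        "results": [r.__dict__ for r in report.results],
    }
    path_json = outdir / "run.json"
    path_json.write_text(json.dumps(run, indent=2, default=float))
    written["run"] = path_json

    lines = ["| scenario | AUC alone | AUC with | AUCR |", "|---|---|---|---|"]
    for r in report.results:
        if r.error:
            lines.append(f"| {r.scenario_id} | - | - | failed: {r.error} |")
        else:
            lines.append(
                f"| {r.scenario_id} | {round_half_even(r.auc_alone):.2f} "
                f"| {round_half_even(r.auc_with):.2f} "
                f"| {round_half_even(r.aucr):.2f} |"
            )
    path_md = outdir / "report.md"
    path_md.write_text("\n".join(lines) + "\n")
    written["markdown"] = path_md
    return written
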