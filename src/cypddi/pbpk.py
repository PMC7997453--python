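"""Reduced whole-body PBPK engine with CYP3A4/CYP3A5 genotype stratification.

The victim drug is followed through six compartments: gut lumen, enterocyte,
liver, central blood, adipose, and a lumped rest-of-body.  Absorption is
first-order from the lumen into the enterocyte, where villous blood flow
competes with gut-wall metabolism for the absorbed drug (first-pass-only gut
extraction); the enterocyte effluent joins the hepatic inflow, so first-pass
extraction arises mechanistically in both gut wall and liver.
Tissues are flow-limited with tissue:plasma partition coefficients Kp
(converted to tissue:blood with the blood:plasma ratio); the liver is
well-stirred with elimination fu_b * CLint,u acting on emergent venous blood.

Intrinsic clearance is scaled bottom-up from per-pmol enzyme kinetics:

    CLint,u(liver) = ISEF * sum(Vmax/Km,u) * abundance[pmol/mg] * MPPGL * liver mass
    CLint,u(gut)   = ISEF * sum(Vmax/Km,u) * total gut enzyme [nmol]

CYP3A5 non-expressers carry zero CYP3A5 in liver and gut, which is the sole
mechanistic difference between the genotype populations.

Perpetrator interactions act on each isoform's intrinsic clearance:

* reversible inhibition scales CLint by 1/(1 + Iu/Ki), with Iu the unbound
  perpetrator concentration local to the organ (liver venous blood for
  hepatic enzymes, enterocyte for gut enzymes);
* mechanism-based inactivation evolves the active-enzyme pool per organ and
  isoform by dE/dt = kdeg*(E0 - E) - kinact*Iu/(KI + Iu) * E, so exposure
  history, not instantaneous concentration, controls the loss of enzyme and
  its slow (kdeg-limited) recovery after washout.

The perpetrator's own disposition uses the same compartment structure with a
fixed hepatic intrinsic clearance; its profile is solved first and drives the
victim system as an interpolated forcing function.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator
from scipy.integrate import solve_ivp

from .errors import ConfigurationError, SolverError

__all__ = [
    "Isoform", "GenotypeClass", "Ethnicity", "MechanismCase",
    "Pathway", "EnzymeKinetics", "Physiology", "PopulationSpec",
    "IsoformInhibition", "InhibitorKinetics", "DoseRegimen", "CompoundSpec",
    "SolverSettings", "SimProfile",
    "build_population", "hepatic_clint_u", "gut_clint_u",
    "simulate_pk", "static_aucr", "kp_sensitivity_scan",
]

# CYP3A protein turnover (first-order degradation of active enzyme).
KDEG_LIVER_PER_H = 0.0193  # ~36 h half-life
KDEG_GUT_PER_H = 0.03  # ~23 h half-life


class Isoform(str, enum.Enum):
    CYP3A4 = "CYP3A4"
    CYP3A5 = "CYP3A5"


class GenotypeClass(str, enum.Enum):
    EXPRESSER = "expresser"  # carries >= 1 CYP3A5*1 allele
    NON_EXPRESSER = "non_expresser"  # CYP3A5*3/*3, no functional CYP3A5


class Ethnicity(str, enum.Enum):
    CHINESE = "Chinese"
    CAUCASIAN = "Caucasian"


class MechanismCase(str, enum.Enum):
    NONE = "none"
    RI_ONLY = "RI_only"
    TDI_ONLY = "TDI_only"
    BOTH = "both"


class Pathway(BaseModel):
    name: str
    vmax: float = Field(gt=0)  # pmol/min/pmol P450
    km_u: float = Field(gt=0)  # uM, unbound


class EnzymeKinetics(BaseModel):
    isoform: Isoform
    pathways: list[Pathway]
    isef: float = Field(default=0.24, gt=0)  # inter-system extrapolation factor

    @model_validator(mode="after")
    def _unique_pathways(self) -> "EnzymeKinetics":
        names = [p.name for p in self.pathways]
        if len(names) != len(set(names)):
            raise ValueError("pathway names must be unique")
        return self

    def clint_per_pmol(self) -> float:
        """ISEF-scaled sum of Vmax/Km,u over pathways, uL/min/pmol P450."""
        return self.isef * sum(p.vmax / p.km_u for p in self.pathways)


class Physiology(BaseModel):
    """Representative-individual physiology (volumes L, masses kg/g, flows L/h)."""

    liver_mass_g: float = Field(gt=0)
    mppgl: float = Field(default=40.0, gt=0)  # mg microsomal protein / g liver
    hepatic_blood_flow: float = Field(gt=0)  # total, L/h
    villous_blood_flow: float = Field(gt=0)  # enterocyte perfusion, L/h
    adipose_mass_kg: float = Field(gt=0)
    adipose_blood_flow: float = Field(gt=0)
    body_mass_kg: float = Field(gt=0)
    haematocrit: float = Field(default=0.45, gt=0, lt=1)
    blood_volume_l: float = Field(default=5.0, gt=0)
    enterocyte_volume_l: float = Field(default=0.3, gt=0)
    rest_blood_flow: float = Field(gt=0)  # L/h

    @property
    def liver_volume_l(self) -> float:
        return self.liver_mass_g / 1000.0  # unit density

    @property
    def adipose_volume_l(self) -> float:
        return self.adipose_mass_kg / 0.92  # adipose density ~0.92 kg/L

    @property
    def rest_volume_l(self) -> float:
        v = (self.body_mass_kg - self.adipose_mass_kg) - self.liver_volume_l \
            - self.blood_volume_l - self.enterocyte_volume_l
        return max(v, 1.0)


class PopulationSpec(BaseModel):
    ethnicity: Ethnicity
    genotype_class: GenotypeClass
    liver_abundance: dict[Isoform, float]  # pmol/mg microsomal protein
    gut_abundance: dict[Isoform, float]  # nmol total gut enzyme
    physiology: Physiology

    @model_validator(mode="after")
    def _validate(self) -> "PopulationSpec":
        if any(v < 0 for v in self.liver_abundance.values()):
            raise ValueError("abundances must be non-negative")
        if any(v < 0 for v in self.gut_abundance.values()):
            raise ValueError("abundances must be non-negative")
        if self.genotype_class is GenotypeClass.NON_EXPRESSER:
            if self.liver_abundance.get(Isoform.CYP3A5, 0) != 0 or \
               self.gut_abundance.get(Isoform.CYP3A5, 0) != 0:
                raise ValueError("non-expressers must have zero CYP3A5 abundance")
        return self


class IsoformInhibition(BaseModel):
    """Inhibition constants of a perpetrator against one isoform."""

    ki: Optional[float] = Field(default=None, gt=0)  # uM, reversible
    kinact: Optional[float] = Field(default=None, gt=0)  # min^-1
    ki_half: Optional[float] = Field(default=None, gt=0)  # KI, uM

    @model_validator(mode="after")
    def _validate(self) -> "IsoformInhibition":
        if (self.kinact is None) != (self.ki_half is None):
            raise ValueError("kinact and KI must be present or absent together")
        if self.ki is None and self.kinact is None:
            raise ValueError("at least one inhibition mechanism required")
        return self


class InhibitorKinetics(BaseModel):
    by_isoform: dict[Isoform, IsoformInhibition]


class DoseRegimen(BaseModel):
    dose_mg: float = Field(ge=0)
    interval_h: Optional[float] = Field(default=None, gt=0)
    n_doses: int = Field(default=1, ge=1)
    start_time_h: float = 0.0

    @model_validator(mode="after")
    def _validate(self) -> "DoseRegimen":
        if self.n_doses > 1 and self.interval_h is None:
            raise ValueError("interval_h required when n_doses > 1")
        return self

    @property
    def dose_times(self) -> np.ndarray:
        step = self.interval_h or 0.0
        return self.start_time_h + step * np.arange(self.n_doses)


class CompoundSpec(BaseModel):
    name: str
    role: str  # "victim" | "perpetrator"
    mw: float = Field(gt=0)  # g/mol
    fu_plasma: float = Field(gt=0, le=1)
    blood_to_plasma: float = Field(gt=0)
    fu_mic: float = Field(default=1.0, gt=0, le=1)
    fu_gut: float = Field(default=1.0, gt=0, le=1)
    ka: float = Field(gt=0)  # 1/h
    fa: float = Field(gt=0, le=1)
    kp: dict[str, float] = Field(default_factory=lambda: {"adipose": 1000.0, "rest": 1.0,
                                                          "liver": 1.0})
    cl_renal: float = Field(default=0.0, ge=0)  # L/h, blood
    elimination: list[EnzymeKinetics] = Field(default_factory=list)  # victims
    clint_hepatic_u: float = Field(default=0.0, ge=0)  # L/h unbound, perpetrators
    inhibition: Optional[InhibitorKinetics] = None

    @property
    def fu_blood(self) -> float:
        return self.fu_plasma / self.blood_to_plasma

    def kp_blood(self, tissue: str) -> float:
        """Tissue:blood partition coefficient (Kp is tissue:plasma)."""
        return self.kp.get(tissue, 1.0) / self.blood_to_plasma


class SolverSettings(BaseModel):
    rtol: float = 1e-7
    atol: float = 1e-9
    dt_out: float = 0.05  # h, fixed output grid
    horizon_h: Optional[float] = None  # default: last dose + washout
    washout_h: float = 400.0
    nonlinear_elimination: bool = False
    kdeg_liver: float = KDEG_LIVER_PER_H
    kdeg_gut: float = KDEG_GUT_PER_H


@dataclass
class SimProfile:
    """Simulated whole-blood profile with compartment and enzyme trajectories."""

    time_h: np.ndarray
    conc_blood_ng_ml: np.ndarray
    amounts: pd.DataFrame = field(repr=False)  # umol per compartment
    enzyme: pd.DataFrame = field(repr=False)  # active fractions, organ x isoform
    compound: str = ""

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"time_h": self.time_h,
                            "blood_conc_ng_ml": self.conc_blood_ng_ml})
        return pd.concat([out, self.amounts.reset_index(drop=True),
                          self.enzyme.reset_index(drop=True)], axis=1)


# --- populations ------------------------------------------------------------

# Liver pmol/mg microsomal protein; gut nmol total enzyme.
_ABUNDANCE = {
    Ethnicity.CAUCASIAN: {
        "liver": {Isoform.CYP3A4: 137.0, Isoform.CYP3A5: 103.0},
        "gut": {Isoform.CYP3A4: 66.2, Isoform.CYP3A5: 24.6},
    },
    Ethnicity.CHINESE: {
        "liver": {Isoform.CYP3A4: 120.0, Isoform.CYP3A5: 82.0},
        "gut": {Isoform.CYP3A4: 58.0, Isoform.CYP3A5: 21.5},
    },
}

_PHYSIOLOGY = {
    Ethnicity.CAUCASIAN: dict(
        liver_mass_g=1650.0, hepatic_blood_flow=90.0, villous_blood_flow=18.0,
        adipose_mass_kg=15.0, adipose_blood_flow=15.6, body_mass_kg=70.0,
        rest_blood_flow=230.0,
    ),
    Ethnicity.CHINESE: dict(
        liver_mass_g=1500.0, hepatic_blood_flow=80.0, villous_blood_flow=16.0,
        adipose_mass_kg=11.0, adipose_blood_flow=13.0, body_mass_kg=61.0,
        rest_blood_flow=210.0,
    ),
}


def build_population(
    ethnicity: Ethnicity | str,
    genotype_class: GenotypeClass | str,
    physiology_overrides: dict | None = None,
) -> PopulationSpec:
    """Assemble a virtual genotype population from the shipped abundance table."""
    ethnicity = Ethnicity(ethnicity)
    genotype_class = GenotypeClass(genotype_class)
    abundance = _ABUNDANCE[ethnicity]
    liver = dict(abundance["liver"])
    gut = dict(abundance["gut"])
    if genotype_class is GenotypeClass.NON_EXPRESSER:
        liver[Isoform.CYP3A5] = 0.0
        gut[Isoform.CYP3A5] = 0.0
    phys = dict(_PHYSIOLOGY[ethnicity])
    phys.update(physiology_overrides or {})
    return PopulationSpec(
        ethnicity=ethnicity, genotype_class=genotype_class,
        liver_abundance=liver, gut_abundance=gut, physiology=Physiology(**phys),
    )


# --- clearance scaling ------------------------------------------------------

_UL_MIN_TO_L_H = 60.0 / 1e6


def hepatic_clint_u(
    kinetics: Sequence[EnzymeKinetics], pop: PopulationSpec
) -> tuple[float, dict[Isoform, float]]:
    """Whole-liver unbound intrinsic clearance (L/h) and per-isoform shares."""
    phys = pop.physiology
    per_iso: dict[Isoform, float] = {}
    for ek in kinetics:
        if ek.isoform not in pop.liver_abundance:
            raise ConfigurationError(f"no liver abundance for {ek.isoform.value}")
        ul_min = ek.clint_per_pmol() * pop.liver_abundance[ek.isoform] \
            * phys.mppgl * phys.liver_mass_g
        per_iso[ek.isoform] = per_iso.get(ek.isoform, 0.0) + ul_min * _UL_MIN_TO_L_H
    total = sum(per_iso.values())
    shares = {iso: (v / total if total > 0 else 0.0) for iso, v in per_iso.items()}
    return total, shares


def gut_clint_u(
    kinetics: Sequence[EnzymeKinetics], pop: PopulationSpec
) -> tuple[float, dict[Isoform, float]]:
    """Total gut-wall unbound intrinsic clearance (L/h) and per-isoform shares."""
    per_iso: dict[Isoform, float] = {}
    for ek in kinetics:
        if ek.isoform not in pop.gut_abundance:
            raise ConfigurationError(f"no gut abundance for {ek.isoform.value}")
        pmol = pop.gut_abundance[ek.isoform] * 1000.0  # nmol -> pmol
        per_iso[ek.isoform] = per_iso.get(ek.isoform, 0.0) \
            + ek.clint_per_pmol() * pmol * _UL_MIN_TO_L_H
    total = sum(per_iso.values())
    shares = {iso: (v / total if total > 0 else 0.0) for iso, v in per_iso.items()}
    return total, shares


# --- core ODE machinery -----------------------------------------------------

_ISOFORMS = (Isoform.CYP3A4, Isoform.CYP3A5)


def _per_isoform_clint(kinetics, pop, organ: str) -> dict[Isoform, float]:
    fn = hepatic_clint_u if organ == "liver" else gut_clint_u
    out = {iso: 0.0 for iso in _ISOFORMS}
    for ek in kinetics:
        total, _ = fn([ek], pop)
        out[ek.isoform] = out.get(ek.isoform, 0.0) + total
    return out


class _Disposition:
    """Pre-computed constants for one compound in one population."""

    def __init__(self, compound: CompoundSpec, pop: PopulationSpec):
        phys = pop.physiology
        self.compound = compound
        self.v_blood = phys.blood_volume_l
        self.v_ent = phys.enterocyte_volume_l
        self.v_liver = phys.liver_volume_l
        self.v_adipose = phys.adipose_volume_l
        self.v_rest = phys.rest_volume_l
        self.kpb_liver = compound.kp_blood("liver")
        self.kpb_adipose = compound.kp_blood("adipose")
        self.kpb_rest = compound.kp_blood("rest")
        self.q_h = phys.hepatic_blood_flow
        self.q_v = phys.villous_blood_flow
        self.q_ad = phys.adipose_blood_flow
        self.q_rest = phys.rest_blood_flow
        self.ka = compound.ka
        self.fa = compound.fa
        self.fu_b = compound.fu_blood
        self.fu_gut = compound.fu_gut
        self.cl_renal = compound.cl_renal


def _dose_umol(dose_mg: float, mw: float) -> float:
    return dose_mg * 1000.0 / mw  # mg -> ug -> umol


def _segment_times(dose_times: np.ndarray, t_end: float) -> list[tuple[float, float]]:
    edges = sorted({0.0, *map(float, dose_times), float(t_end)})
    return [(a, b) for a, b in zip(edges[:-1], edges[1:]) if b > a]


def _integrate(rhs: Callable, y0: np.ndarray, dose_times: np.ndarray,
               dose_amount: float, lumen_index: int, t_end: float,
               settings: SolverSettings, dense: bool = False):
    """Piecewise LSODA integration with instantaneous lumen boluses at doses."""
    dose_set = {round(float(t), 9) for t in dose_times}
    segments = _segment_times(dose_times, t_end)
    sols, y = [], y0.copy()
    for t0, t1 in segments:
        if round(t0, 9) in dose_set:
            y = y.copy()
            y[lumen_index] += dose_amount
        sol = solve_ivp(rhs, (t0, t1), y, method="LSODA",
                        rtol=settings.rtol, atol=settings.atol, dense_output=True)
        if not sol.success:
            raise SolverError(f"ODE integration failed on [{t0}, {t1}]: {sol.message}",
                              state={"t": sol.t[-1] if len(sol.t) else t0,
                                     "y": list(map(float, y))})
        sols.append(sol)
        y = sol.y[:, -1]
    return sols, [s.t[-1] for s in sols]


class _PiecewiseSolution:
    """Evaluate a list of per-segment dense ODE solutions as one function."""

    def __init__(self, sols):
        self.sols = sols
        self.edges = np.array([s.t[0] for s in sols] + [sols[-1].t[-1]])

    def __call__(self, t: float) -> np.ndarray:
        idx = int(np.searchsorted(self.edges, t, side="right") - 1)
        idx = min(max(idx, 0), len(self.sols) - 1)
        sol = self.sols[idx]
        t = min(max(t, sol.t[0]), sol.t[-1])
        return sol.sol(t)


def _simulate_compound_alone(
    compound: CompoundSpec, regimen: DoseRegimen, pop: PopulationSpec,
    settings: SolverSettings, t_end: float,
) -> _PiecewiseSolution:
    """Disposition of a compound with fixed (non-enzyme-state) clearances."""
    d = _Disposition(compound, pop)
    if compound.role == "victim":
        clint_liver, _ = hepatic_clint_u(compound.elimination, pop)
        clint_gut, _ = gut_clint_u(compound.elimination, pop)
    else:
        clint_liver, clint_gut = compound.clint_hepatic_u, 0.0

    def rhs(_t, y):
        return _rhs_fixed(y, d, clint_liver, clint_gut)

    y0 = np.zeros(6)
    dose = _dose_umol(regimen.dose_mg, compound.mw) * d.fa
    sols, _ = _integrate(rhs, y0, regimen.dose_times, dose, 0, t_end, settings)
    return _PiecewiseSolution(sols)


def _rhs_fixed(y, d: _Disposition, clint_liver: float, clint_gut: float):
    a_lum, a_ent, a_liv, a_bld, a_adi, a_rst = y
    c_b = a_bld / d.v_blood
    c_ent = a_ent / d.v_ent
    c_liv = a_liv / (d.v_liver * d.kpb_liver)
    c_adi = a_adi / (d.v_adipose * d.kpb_adipose)
    c_rst = a_rst / (d.v_rest * d.kpb_rest)

    absorb = d.ka * a_lum
    gut_met = d.fu_gut * clint_gut * c_ent
    liv_met = d.fu_b * clint_liver * c_liv
    return [
        -absorb,
        absorb - d.q_v * c_ent - gut_met,
        d.q_h * c_b + d.q_v * c_ent - d.q_h * c_liv - liv_met,
        d.q_h * c_liv + d.q_ad * c_adi + d.q_rest * c_rst
        - (d.q_h + d.q_ad + d.q_rest) * c_b - d.cl_renal * c_b,
        d.q_ad * (c_b - c_adi),
        d.q_rest * (c_b - c_rst),
    ]


def _inhibition_terms(inhib: Optional[InhibitorKinetics], iso: Isoform,
                      iu: float, mechanism: MechanismCase,
                      fu_mic: float) -> tuple[float, float]:
    """Return (reversible CLint scale factor, inactivation rate lambda, 1/h)."""
    if inhib is None or mechanism is MechanismCase.NONE:
        return 1.0, 0.0
    entry = inhib.by_isoform.get(iso)
    if entry is None:
        return 1.0, 0.0
    ri = 1.0
    lam = 0.0
    if mechanism in (MechanismCase.RI_ONLY, MechanismCase.BOTH) and entry.ki is not None:
        ri = 1.0 / (1.0 + iu / (entry.ki * fu_mic))
    if mechanism in (MechanismCase.TDI_ONLY, MechanismCase.BOTH) and entry.kinact is not None:
        ki_half_u = entry.ki_half * fu_mic
        lam = 60.0 * entry.kinact * iu / (ki_half_u + iu)  # min^-1 -> h^-1
    return ri, lam


def simulate_pk(
    victim: CompoundSpec,
    regimen: DoseRegimen,
    pop: PopulationSpec,
    perpetrator: Optional[tuple[CompoundSpec, Optional[DoseRegimen]]] = None,
    mechanism_case: MechanismCase | str = MechanismCase.NONE,
    settings: Optional[SolverSettings] = None,
    constant_perpetrator_unbound: Optional[tuple[float, float]] = None,
) -> SimProfile:
    """Simulate the victim's whole-blood concentration-time profile.

    ``perpetrator`` is a (compound, regimen) pair whose disposition is solved
    first and drives enzyme inhibition/inactivation in the victim system.
    ``constant_perpetrator_unbound`` = (Iu_liver, Iu_gut) in uM bypasses the
    perpetrator simulation and clamps the driving unbound concentrations,
    which is the configuration used to compare against the mechanistic-static
    AUC-ratio formula.
    """
    settings = settings or SolverSettings()
    mechanism_case = MechanismCase(mechanism_case)
    d = _Disposition(victim, pop)

    clint_liver_iso = _per_isoform_clint(victim.elimination, pop, "liver")
    clint_gut_iso = _per_isoform_clint(victim.elimination, pop, "gut")

    last_victim_dose = float(regimen.dose_times[-1])
    t_end = settings.horizon_h
    perp_spec = perp_regimen = None
    if perpetrator is not None:
        perp_spec, perp_regimen = perpetrator
    if t_end is None:
        t_end = last_victim_dose + settings.washout_h
        if perp_regimen is not None:
            t_end = max(t_end, float(perp_regimen.dose_times[-1]) + settings.washout_h)

    inhib = perp_spec.inhibition if perp_spec is not None else None
    fu_mic = perp_spec.fu_mic if perp_spec is not None else 1.0

    if constant_perpetrator_unbound is not None:
        iu_liver_const, iu_gut_const = constant_perpetrator_unbound

        def perp_unbound(_t):
            return iu_liver_const, iu_gut_const
    elif perp_spec is not None and perp_regimen is not None and perp_regimen.dose_mg > 0 \
            and mechanism_case is not MechanismCase.NONE:
        perp_sol = _simulate_compound_alone(perp_spec, perp_regimen, pop, settings, t_end)
        dp = _Disposition(perp_spec, pop)

        def perp_unbound(t):
            yp = perp_sol(t)
            c_liv_out = yp[2] / (dp.v_liver * dp.kpb_liver)
            c_ent = yp[1] / dp.v_ent
            return dp.fu_b * c_liv_out, dp.fu_gut * c_ent
    else:
        def perp_unbound(_t):
            return 0.0, 0.0

    kdeg_l, kdeg_g = settings.kdeg_liver, settings.kdeg_gut

    def rhs(t, y):
        a_lum, a_ent, a_liv, a_bld, a_adi, a_rst = y[:6]
        e = y[6:10]  # E_liver_3A4, E_liver_3A5, E_gut_3A4, E_gut_3A5
        iu_liver, iu_gut = perp_unbound(t)

        cl_l = 0.0
        cl_g = 0.0
        de = np.zeros(4)
        for k, iso in enumerate(_ISOFORMS):
            ri_l, lam_l = _inhibition_terms(inhib, iso, iu_liver, mechanism_case, fu_mic)
            ri_g, lam_g = _inhibition_terms(inhib, iso, iu_gut, mechanism_case, fu_mic)
            cl_l += clint_liver_iso[iso] * e[k] * ri_l
            cl_g += clint_gut_iso[iso] * e[2 + k] * ri_g
            de[k] = kdeg_l * (1.0 - e[k]) - lam_l * e[k]
            de[2 + k] = kdeg_g * (1.0 - e[2 + k]) - lam_g * e[2 + k]

        c_b = a_bld / d.v_blood
        c_ent = a_ent / d.v_ent
        c_liv = a_liv / (d.v_liver * d.kpb_liver)
        c_adi = a_adi / (d.v_adipose * d.kpb_adipose)
        c_rst = a_rst / (d.v_rest * d.kpb_rest)

        absorb = d.ka * a_lum
        if settings.nonlinear_elimination:
            gut_met = _mm_rate(victim.elimination, pop, "gut", d.fu_gut * c_ent,
                               e[2:4], inhib, iu_gut, mechanism_case, fu_mic)
            liv_met = _mm_rate(victim.elimination, pop, "liver", d.fu_b * c_liv,
                               e[0:2], inhib, iu_liver, mechanism_case, fu_mic)
        else:
            gut_met = d.fu_gut * cl_g * c_ent
            liv_met = d.fu_b * cl_l * c_liv

        dy = np.empty(10)
        dy[0] = -absorb
        dy[1] = absorb - d.q_v * c_ent - gut_met
        dy[2] = d.q_h * c_b + d.q_v * c_ent - d.q_h * c_liv - liv_met
        dy[3] = d.q_h * c_liv + d.q_ad * c_adi + d.q_rest * c_rst \
            - (d.q_h + d.q_ad + d.q_rest) * c_b - d.cl_renal * c_b
        dy[4] = d.q_ad * (c_b - c_adi)
        dy[5] = d.q_rest * (c_b - c_rst)
        dy[6:10] = de
        return dy

    y0 = np.zeros(10)
    y0[6:10] = 1.0
    dose = _dose_umol(regimen.dose_mg, victim.mw) * d.fa
    sols, _ = _integrate(rhs, y0, regimen.dose_times, dose, 0, t_end, settings)
    piecewise = _PiecewiseSolution(sols)

    t_grid = np.arange(0.0, t_end + settings.dt_out / 2, settings.dt_out)
    states = np.column_stack([piecewise(t) for t in t_grid])
    if np.min(states[:6]) < -1e-6 * max(dose, 1.0):
        raise SolverError("negative compartment amount beyond tolerance",
                          state={"min_amount": float(np.min(states[:6]))})
    states[:6] = np.clip(states[:6], 0.0, None)

    conc_blood_um = states[3] / d.v_blood
    conc_ng_ml = conc_blood_um * victim.mw  # uM * g/mol = ug/L = ng/mL
    amounts = pd.DataFrame(
        states[:6].T,
        columns=["gut_lumen", "enterocyte", "liver", "blood", "adipose", "rest"],
    )
    enzyme = pd.DataFrame(
        np.clip(states[6:10].T, 0.0, 1.0),
        columns=["liver_CYP3A4", "liver_CYP3A5", "gut_CYP3A4", "gut_CYP3A5"],
    )
    return SimProfile(time_h=t_grid, conc_blood_ng_ml=conc_ng_ml,
                      amounts=amounts, enzyme=enzyme, compound=victim.name)


def _mm_rate(kinetics, pop, organ, cu, e_organ, inhib, iu, mechanism, fu_mic):
    """Full Michaelis-Menten elimination rate (umol/h) at unbound conc cu (uM)."""
    phys = pop.physiology
    rate = 0.0
    for ek in kinetics:
        if organ == "liver":
            pmol = pop.liver_abundance[ek.isoform] * phys.mppgl * phys.liver_mass_g
        else:
            pmol = pop.gut_abundance[ek.isoform] * 1000.0
        k = 0 if ek.isoform is Isoform.CYP3A4 else 1
        ri, _ = _inhibition_terms(inhib, ek.isoform, iu, mechanism, fu_mic)
        for p in ek.pathways:
            km_app = p.km_u / ri  # competitive inhibition raises apparent Km
            # pmol/min/pmol * pmol = pmol/min -> umol/h: * 60 / 1e6
            rate += ek.isef * p.vmax * pmol * e_organ[k] * cu / (km_app + cu) * 60e-6
    return rate


def static_aucr(
    fm_shares: dict[Isoform, float],
    iu: float,
    inhibition: InhibitorKinetics,
    kdeg_per_h: float = KDEG_LIVER_PER_H,
    mechanism_case: MechanismCase | str = MechanismCase.BOTH,
) -> float:
    """Mechanistic-static AUC ratio for systemic (hepatic) inhibition.

    AUCR = 1 / (sum_i fm_i / (RI_i * TDI_i) + (1 - sum_i fm_i)) with
    RI_i = 1 + Iu/Ki and TDI_i = 1 + kinact*Iu / (kdeg*(KI + Iu)).
    Serves as the closed-form oracle for the dynamic model in the
    constant-exposure, liver-only, low-extraction limit.
    """
    mechanism_case = MechanismCase(mechanism_case)
    fm_total = sum(fm_shares.values())
    if fm_total > 1 + 1e-9:
        raise ConfigurationError("fm shares must sum to <= 1")
    denom = 1.0 - fm_total
    for iso, fm in fm_shares.items():
        entry = inhibition.by_isoform.get(iso)
        ri = tdi = 1.0
        if entry is not None and mechanism_case is not MechanismCase.NONE:
            if entry.ki is not None and mechanism_case in (MechanismCase.RI_ONLY,
                                                           MechanismCase.BOTH):
                ri = 1.0 + iu / entry.ki
            if entry.kinact is not None and mechanism_case in (MechanismCase.TDI_ONLY,
                                                               MechanismCase.BOTH):
                tdi = 1.0 + (60.0 * entry.kinact) * iu / (kdeg_per_h * (entry.ki_half + iu))
        denom += fm / (ri * tdi)
    return 1.0 / denom


def kp_sensitivity_scan(
    victim: CompoundSpec,
    pop: PopulationSpec,
    kp_values: Sequence[float],
    regimen: Optional[DoseRegimen] = None,
    settings: Optional[SolverSettings] = None,
) -> pd.DataFrame:
    """Re-simulate the victim over a ladder of adipose Kp values.

    Returns one row per Kp with AUC(0-inf), Cmax and Tmax, plus monotonicity
    diagnostics in ``DataFrame.attrs``.
    """
    from .metrics import compute_metrics  # local import avoids a cycle

    if min(kp_values) <= 0:
        raise ConfigurationError("Kp values must be positive")
    regimen = regimen or DoseRegimen(dose_mg=2.0)
    rows = []
    for kp in kp_values:
        spec = victim.model_copy(deep=True)
        spec.kp["adipose"] = float(kp)
        profile = simulate_pk(spec, regimen, pop, settings=settings)
        m = compute_metrics(profile)
        rows.append((float(kp), m.auc, m.cmax, m.tmax))
    out = pd.DataFrame(rows, columns=["kp_adipose", "auc", "cmax", "tmax"])
    cmax = out.sort_values("kp_adipose")["cmax"].to_numpy()
    out.attrs["cmax_non_increasing"] = bool(np.all(np.diff(cmax) <= 1e-9 * cmax[:-1]))
    return out
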