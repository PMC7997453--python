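"""Named presets: assay designs, enzyme kinetics, populations and compounds.

Victim enzymology (per-pmol Vmax/Km,u per pathway and the ISEF) and the
genotype abundance table are the published tacrolimus inputs.  The victim's
binding/absorption constants (fu_plasma 0.013, blood:plasma 15, ka 2 /h,
Fa 0.95) are standard literature values for tacrolimus.  The perpetrator
(schisantherin A / schisandrin A) absorption and disposition parameters are
ILLUSTRATIVE placeholders — plausible for moderately cleared, moderately
bound dibenzocyclooctadiene lignans — because no public parameter set is
shipped with this package; their inhibition constants are the measured ones.
"""

from __future__ import annotations

from .datasets import EnzymeTarget, MicrosomeGenotype, RIDesign, TDIDesign
from .pbpk import (
    CompoundSpec,
    DoseRegimen,
    EnzymeKinetics,
    Ethnicity,
    GenotypeClass,
    InhibitorKinetics,
    Isoform,
    IsoformInhibition,
    Pathway,
    PopulationSpec,
    build_population,
)

__all__ = [
    "ri_design", "tdi_design", "tacrolimus_kinetics", "tacrolimus_compound",
    "sta_compound", "sia_compound", "population", "STA_INHIBITION",
    "SIA_INHIBITION", "RI_TRUE_KI", "TDI_TRUE_PARAMS", "OBSERVED_TACROLIMUS_PK",
    "STA_DOSE_MG", "SIA_DOSE_MG", "single_dose", "multidose_bid",
]

# --- assay designs ----------------------------------------------------------

_RI_SUBSTRATE_GRID = [0.2, 0.4, 0.8, 1.6]  # uM tacrolimus
_RI_INHIBITOR_GRIDS = {"STA": [0.0, 0.125, 0.25, 0.5], "SIA": [0.0, 2.4, 7.2, 12.0]}
_TDI_INHIBITOR_GRIDS = {"STA": [0.0, 0.25, 0.5, 1.0, 2.0], "SIA": [0.0, 2.0, 4.0, 8.0, 16.0]}
_TDI_TIMES = [0.0, 5.0, 10.0, 20.0, 30.0]  # min


def ri_design(inhibitor: str, enzyme: EnzymeTarget | str) -> RIDesign:
    """Reversible-inhibition assay design for STA or SIA on CYP3A4/CYP3A5."""
    enzyme = EnzymeTarget(enzyme)
    if enzyme is EnzymeTarget.CYP3A5:
        genotype, cyp3cide = MicrosomeGenotype.HET, 0.5
    else:
        genotype, cyp3cide = MicrosomeGenotype.NULL, 0.0
    return RIDesign(
        enzyme_target=enzyme, microsome_genotype=genotype, cyp3cide_conc=cyp3cide,
        substrate_concs=_RI_SUBSTRATE_GRID,
        inhibitor_concs=_RI_INHIBITOR_GRIDS[inhibitor.upper()],
        protein_conc=0.2, incubation_time=10.0,
    )


def tdi_design(inhibitor: str, enzyme: EnzymeTarget | str) -> TDIDesign:
    """Two-step dilution TDI assay design for STA or SIA."""
    enzyme = EnzymeTarget(enzyme)
    return TDIDesign(
        enzyme_target=enzyme,
        inhibitor_concs=_TDI_INHIBITOR_GRIDS[inhibitor.upper()],
        preincubation_times=_TDI_TIMES,
        dilution_factor=10.0, probe_substrate_conc=200.0, protein_conc=0.5,
        cyp3cide_conc=1.2 if enzyme is EnzymeTarget.CYP3A5 else 0.0,
    )


# measured inhibition constants (uM; min^-1 for kinact)
RI_TRUE_KI = {
    ("STA", "CYP3A4"): 0.15,
    ("STA", "CYP3A5"): 0.11,
    ("SIA", "CYP3A5"): 8.74,
}
TDI_TRUE_PARAMS = {
    ("STA", "CYP3A4"): (0.11, 2.45),
    ("SIA", "CYP3A4"): (0.019, 2.54),
    ("SIA", "CYP3A5"): (0.014, 2.07),
}

STA_INHIBITION = InhibitorKinetics(by_isoform={
    Isoform.CYP3A4: IsoformInhibition(ki=0.15, kinact=0.11, ki_half=2.45),
    Isoform.CYP3A5: IsoformInhibition(ki=0.11),
})
SIA_INHIBITION = InhibitorKinetics(by_isoform={
    # no reversible inhibition of CYP3A4 was detectable for SIA
    Isoform.CYP3A4: IsoformInhibition(kinact=0.019, ki_half=2.54),
    Isoform.CYP3A5: IsoformInhibition(ki=8.74, kinact=0.014, ki_half=2.07),
})

# --- victim enzymology ------------------------------------------------------

_ISEF = 0.24  # BD Supersomes inter-system extrapolation factor

_CYP3A4_PATHWAYS = [Pathway(name="13-DMT", vmax=8.0, km_u=0.21),
                    Pathway(name="12-HT", vmax=0.6, km_u=0.29)]
_CYP3A5_PATHWAYS = [Pathway(name="13-DMT", vmax=17.0, km_u=0.21),
                    Pathway(name="12-HT", vmax=1.4, km_u=0.35)]


def tacrolimus_kinetics(genotype: GenotypeClass | str) -> list[EnzymeKinetics]:
    """Per-isoform elimination kinetics of tacrolimus for a genotype class."""
    genotype = GenotypeClass(genotype)
    kin = [EnzymeKinetics(isoform=Isoform.CYP3A4, pathways=_CYP3A4_PATHWAYS, isef=_ISEF)]
    if genotype is GenotypeClass.EXPRESSER:
        kin.append(EnzymeKinetics(isoform=Isoform.CYP3A5, pathways=_CYP3A5_PATHWAYS,
                                  isef=_ISEF))
    return kin


def tacrolimus_compound(genotype: GenotypeClass | str = GenotypeClass.EXPRESSER,
                        kp_adipose: float = 1000.0) -> CompoundSpec:
    """Tacrolimus victim spec; adipose Kp defaults to the optimised value 1000."""
    return CompoundSpec(
        name="tacrolimus", role="victim", mw=804.0,
        fu_plasma=0.013, blood_to_plasma=15.0, fu_mic=1.0,
        ka=2.0, fa=0.95,
        kp={"adipose": kp_adipose, "rest": 1.0, "liver": 1.0},
        cl_renal=0.0,
        elimination=tacrolimus_kinetics(genotype),
    )


# --- perpetrators (disposition parameters illustrative, not measured) -------

STA_DOSE_MG = 7.325
SIA_DOSE_MG = 7.20


def sta_compound() -> CompoundSpec:
    return CompoundSpec(
        name="schisantherin A", role="perpetrator", mw=536.57,
        fu_plasma=0.10, blood_to_plasma=0.8, fu_mic=1.0,
        ka=1.5, fa=0.85,
        kp={"adipose": 2.0, "rest": 1.0, "liver": 1.0},
        clint_hepatic_u=300.0,
        inhibition=STA_INHIBITION,
    )


def sia_compound() -> CompoundSpec:
    return CompoundSpec(
        name="schisandrin A", role="perpetrator", mw=416.51,
        fu_plasma=0.08, blood_to_plasma=0.9, fu_mic=1.0,
        ka=1.2, fa=0.85,
        kp={"adipose": 2.0, "rest": 1.0, "liver": 1.0},
        clint_hepatic_u=200.0,
        inhibition=SIA_INHIBITION,
    )


def population(ethnicity: str = "Chinese", genotype: str = "expresser",
               **overrides) -> PopulationSpec:
    return build_population(Ethnicity(ethnicity), GenotypeClass(genotype),
                            physiology_overrides=overrides or None)


def single_dose(dose_mg: float, start_time_h: float = 0.0) -> DoseRegimen:
    return DoseRegimen(dose_mg=dose_mg, start_time_h=start_time_h)


def multidose_bid(dose_mg: float, days: int = 13) -> DoseRegimen:
    """Twice-daily dosing for ``days`` days starting at t = 0."""
    return DoseRegimen(dose_mg=dose_mg, interval_h=12.0, n_doses=2 * days)


# Observed clinical tacrolimus exposure after single oral doses, by genotype.
# Keys: (dose_mg, genotype) -> {cmax ng/mL, tmax h, auc ng/mL*h, n subjects}.
OBSERVED_TACROLIMUS_PK = {
    (1, "expresser"): {"cmax": 3.88, "tmax": 1.75, "auc": 19.34, "n": 16},
    (1, "non_expresser"): {"cmax": 5.52, "tmax": 1.5, "auc": 30.34, "n": 26},
    (2, "expresser"): {"cmax": 14.09, "tmax": 1.26, "auc": 60.83, "n": 31},
    (2, "non_expresser"): {"cmax": 24.28, "tmax": 1.35, "auc": 119.02, "n": 40},
    (5, "expresser"): {"cmax": 20.8, "tmax": 1.40, "auc": 90.40, "n": 12},
    (5, "non_expresser"): {"cmax": 27.90, "tmax": 1.30, "auc": 134.77, "n": 12},
}
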