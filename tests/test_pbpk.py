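"""PBPK engine: population assembly, clearance scaling, simulation properties."""

import numpy as np
import pytest

from cypddi import (
    CompoundSpec,
    DoseRegimen,
    GenotypeClass,
    InhibitorKinetics,
    Isoform,
    IsoformInhibition,
    MechanismCase,
    SolverSettings,
    build_population,
    compute_metrics,
    gut_clint_u,
    hepatic_clint_u,
    kp_sensitivity_scan,
    presets,
    simulate_pk,
    static_aucr,
)
from cypddi.errors import ConfigurationError
from cypddi.pbpk import KDEG_LIVER_PER_H

A4, A5 = Isoform.CYP3A4, Isoform.CYP3A5


class TestBuildPopulation:
    def test_chinese_expresser_liver_abundances(self):
        pop = build_population("Chinese", "expresser")
        assert pop.liver_abundance[A4] == 120.0
        assert pop.liver_abundance[A5] == 82.0

    def test_caucasian_non_expresser_has_no_cyp3a5(self):
        pop = build_population("Caucasian", "non_expresser")
        assert pop.liver_abundance[A5] == 0.0
        assert pop.gut_abundance[A5] == 0.0

    def test_chinese_gut_cyp3a4(self):
        pop = build_population("Chinese", "non_expresser")
        assert pop.gut_abundance[A4] == 58.0

    def test_caucasian_expresser_abundances(self):
        pop = build_population("Caucasian", "expresser")
        assert pop.liver_abundance[A4] == 137.0
        assert pop.gut_abundance[A4] == 66.2
        assert pop.gut_abundance[A5] == 24.6


class TestClearanceScaling:
    def test_non_expresser_cyp3a5_share_is_zero(self):
        pop = build_population("Chinese", "non_expresser")
        kin = presets.tacrolimus_kinetics("expresser")  # includes CYP3A5 entry
        _, shares = hepatic_clint_u(kin, pop)
        assert shares[A5] == 0.0

    def test_per_pmol_cyp3a5_exceeds_cyp3a4_twofold(self):
        kin = {ek.isoform: ek for ek in presets.tacrolimus_kinetics("expresser")}
        per_pmol_a4 = kin[A4].clint_per_pmol() / kin[A4].isef
        per_pmol_a5 = kin[A5].clint_per_pmol() / kin[A5].isef
        assert per_pmol_a4 == pytest.approx(8 / 0.21 + 0.6 / 0.29, rel=1e-12)
        assert per_pmol_a5 == pytest.approx(17 / 0.21 + 1.4 / 0.35, rel=1e-12)
        assert per_pmol_a5 > 2 * per_pmol_a4

    def test_clint_linear_in_abundance(self):
        pop = build_population("Chinese", "expresser")
        doubled = pop.model_copy(deep=True)
        doubled.liver_abundance = {k: 2 * v for k, v in pop.liver_abundance.items()}
        kin = presets.tacrolimus_kinetics("expresser")
        total, _ = hepatic_clint_u(kin, pop)
        total2, _ = hepatic_clint_u(kin, doubled)
        assert total2 == pytest.approx(2 * total, rel=1e-12)

    def test_missing_abundance_raises(self):
        pop = build_population("Chinese", "expresser")
        pop = pop.model_copy(update={"gut_abundance": {A4: 58.0}})
        with pytest.raises(ConfigurationError):
            gut_clint_u(presets.tacrolimus_kinetics("expresser"), pop)


@pytest.fixture(scope="module")
def pop_exp():
    return presets.population("Chinese", "expresser")


@pytest.fixture(scope="module")
def pop_non():
    return presets.population("Chinese", "non_expresser")


@pytest.fixture(scope="module")
def victim_exp():
    return presets.tacrolimus_compound("expresser")


class TestSimulatePk:
    def test_null_perpetrator_identity(self, victim_exp, pop_exp):
        reg = DoseRegimen(dose_mg=2.0)
        s = SolverSettings(washout_h=100.0)
        alone = simulate_pk(victim_exp, reg, pop_exp, settings=s)
        zero_perp = presets.sta_compound().model_copy(update={})
        with_zero = simulate_pk(
            victim_exp, reg, pop_exp,
            perpetrator=(zero_perp, DoseRegimen(dose_mg=0.0)),
            mechanism_case=MechanismCase.BOTH, settings=s)
        assert np.allclose(alone.conc_blood_ng_ml, with_zero.conc_blood_ng_ml,
                           rtol=1e-9, atol=1e-12)

    def test_mass_balance_with_elimination_off(self, pop_exp):
        inert = presets.tacrolimus_compound("expresser").model_copy(
            update={"elimination": [], "cl_renal": 0.0})
        s = SolverSettings(washout_h=200.0)
        prof = simulate_pk(inert, DoseRegimen(dose_mg=2.0), pop_exp, settings=s)
        dose_umol = 2.0 * 1000.0 / inert.mw * inert.fa
        total = prof.amounts.iloc[-1].sum()
        assert total == pytest.approx(dose_umol, rel=1e-4)

    def test_one_compartment_closed_form_auc(self, pop_exp):
        # all Kp = 1, no gut metabolism, enormous liver flow: AUC = F*Dose/CL
        victim = CompoundSpec(
            name="probe", role="victim", mw=500.0, fu_plasma=0.1,
            blood_to_plasma=1.0, ka=1.0, fa=1.0,
            kp={"adipose": 1.0, "rest": 1.0, "liver": 1.0},
            cl_renal=2.0, elimination=[],
        )
        pop = pop_exp.model_copy(deep=True)
        pop.physiology = pop.physiology.model_copy(
            update={"hepatic_blood_flow": 1e5, "villous_blood_flow": 1e4})
        prof = simulate_pk(victim, DoseRegimen(dose_mg=2.0), pop,
                           settings=SolverSettings(washout_h=400.0))
        m = compute_metrics(prof)
        auc_theory = 1.0 * 2e6 / (2.0 * 1000.0)  # ng/mL*h, F=1, CL=2 L/h
        assert m.auc == pytest.approx(auc_theory, rel=5e-3)

    def test_dose_linearity(self, victim_exp, pop_exp):
        s = SolverSettings(washout_h=400.0)
        aucs = []
        for dose in (1.0, 2.0, 5.0):
            prof = simulate_pk(victim_exp, DoseRegimen(dose_mg=dose), pop_exp,
                               settings=s)
            aucs.append(compute_metrics(prof).auc / dose)
        assert max(aucs) / min(aucs) - 1 < 1e-3

    def test_genotype_ordering(self, victim_exp, pop_exp, pop_non):
        s = SolverSettings(washout_h=400.0)
        reg = DoseRegimen(dose_mg=2.0)
        auc_exp = compute_metrics(simulate_pk(victim_exp, reg, pop_exp,
                                              settings=s)).auc
        vic_non = presets.tacrolimus_compound("non_expresser")
        auc_non = compute_metrics(simulate_pk(vic_non, reg, pop_non,
                                              settings=s)).auc
        assert auc_non > auc_exp

    def test_enzyme_recovery_after_washout(self, victim_exp, pop_exp):
        perp = presets.sta_compound()
        s = SolverSettings(washout_h=500.0)
        prof = simulate_pk(victim_exp, DoseRegimen(dose_mg=2.0), pop_exp,
                           perpetrator=(perp, DoseRegimen(dose_mg=presets.STA_DOSE_MG)),
                           mechanism_case=MechanismCase.BOTH, settings=s)
        final = prof.enzyme.iloc[-1]
        assert float(final.min()) > 0.99
        assert float(prof.enzyme.min().min()) < 0.99  # inactivation did happen

    def test_solver_tolerance_refinement(self, victim_exp, pop_exp):
        reg = DoseRegimen(dose_mg=2.0)
        coarse = SolverSettings(washout_h=200.0)
        fine = SolverSettings(rtol=5e-8, atol=5e-10, washout_h=200.0)
        auc1 = compute_metrics(simulate_pk(victim_exp, reg, pop_exp,
                                           settings=coarse)).auc
        auc2 = compute_metrics(simulate_pk(victim_exp, reg, pop_exp,
                                           settings=fine)).auc
        assert abs(auc1 / auc2 - 1) < 1e-3


class TestStaticAucr:
    STA = presets.STA_INHIBITION

    def test_no_inhibition_gives_unity(self):
        inhib = InhibitorKinetics(by_isoform={})
        assert static_aucr({A4: 0.6, A5: 0.4}, 1.0, inhib) == pytest.approx(1.0)

    def test_full_fm_pure_ri_algebra(self):
        inhib = InhibitorKinetics(by_isoform={A4: IsoformInhibition(ki=1.0)})
        assert static_aucr({A4: 1.0}, 1.0, inhib,
                           mechanism_case="RI_only") == pytest.approx(2.0)

    def test_dynamic_constant_infusion_matches_static(self, pop_exp):
        # liver-only low-extraction configuration at clamped unbound exposure
        victim = presets.tacrolimus_compound("expresser")
        victim = victim.model_copy(update={"fu_plasma": 1e-4})
        pop = pop_exp.model_copy(deep=True)
        pop.gut_abundance = {A4: 0.0, A5: 0.0}
        _, shares = hepatic_clint_u(victim.elimination, pop)
        iu = 0.05
        s = SolverSettings(washout_h=600.0)
        reg = DoseRegimen(dose_mg=2.0)
        perp = presets.sta_compound()
        base = compute_metrics(simulate_pk(victim, reg, pop, settings=s)).auc
        # enzyme pools start at baseline; hold exposure constant so they sit at
        # steady state within a fraction of the long elimination phase
        inhibited = compute_metrics(simulate_pk(
            victim, reg, pop, perpetrator=(perp, None),
            mechanism_case=MechanismCase.BOTH, settings=s,
            constant_perpetrator_unbound=(iu, 0.0))).auc
        dynamic = inhibited / base
        static = static_aucr(shares, iu, perp.inhibition)
        assert dynamic == pytest.approx(static, rel=0.05)

    def test_aucr_monotone_in_ki_and_kinact(self):
        ki_ladder = [0.05, 0.1, 0.5, 1.0]
        vals = [static_aucr({A4: 1.0}, 0.2,
                            InhibitorKinetics(by_isoform={A4: IsoformInhibition(ki=k)}))
                for k in ki_ladder]
        assert all(a > b for a, b in zip(vals, vals[1:]))
        kin_ladder = [0.01, 0.05, 0.1, 0.5]
        vals = [static_aucr(
            {A4: 1.0}, 0.2,
            InhibitorKinetics(by_isoform={A4: IsoformInhibition(kinact=k, ki_half=2.0)}))
            for k in kin_ladder]
        assert all(a < b for a, b in zip(vals, vals[1:]))


class TestKpScan:
    def test_cmax_non_increasing_in_kp(self, victim_exp, pop_exp):
        s = SolverSettings(washout_h=150.0)
        scan = kp_sensitivity_scan(victim_exp, pop_exp, [250.0, 500.0, 1000.0],
                                   settings=s)
        assert scan.attrs["cmax_non_increasing"]

    def test_duplicate_kp_rows_identical(self, victim_exp, pop_exp):
        s = SolverSettings(washout_h=100.0)
        scan = kp_sensitivity_scan(victim_exp, pop_exp, [500.0, 500.0], settings=s)
        assert scan.iloc[0].equals(scan.iloc[1])
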