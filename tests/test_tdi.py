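"""Time-dependent inactivation: kobs regression, (kinact, KI) fits, efficiency."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from cypddi import TDIDataset, efficiency, estimate_kobs, fit_inactivation, presets
from cypddi.datasets import percent_of_control
from cypddi.errors import DataError, DesignError, DomainError, FitError
from cypddi.synth import TDISynthSpec, gen_tdi_dataset


def _exact_decay_table(kobs_by_level, times=(0.0, 5.0, 10.0, 20.0, 30.0)):
    rows = [(i, t, 1, 100.0 * math.exp(-k * t))
            for i, k in kobs_by_level.items() for t in times]
    return pd.DataFrame(rows, columns=["inhibitor_um", "time_min",
                                       "replicate", "activity_pct"])


def _dataset(design, table):
    return TDIDataset(design=design, activities=table)


class TestEstimateKobs:
    def test_exact_log_linear_decay(self, tdi_design_sta_3a4):
        table = _exact_decay_table({i: 0.05 if i > 0 else 0.0
                                    for i in tdi_design_sta_3a4.inhibitor_concs})
        res = estimate_kobs(_dataset(tdi_design_sta_3a4, table))
        for i, k in res.kobs_map.items():
            assert k == pytest.approx(0.05 if i > 0 else 0.0, abs=1e-12)

    def test_constant_activity_gives_zero(self, tdi_design_sta_3a4):
        table = _exact_decay_table({i: 0.0 for i in tdi_design_sta_3a4.inhibitor_concs})
        res = estimate_kobs(_dataset(tdi_design_sta_3a4, table))
        assert all(k == 0.0 for k in res.kobs_map.values())

    def test_noisy_recovery_within_ten_percent(self, tdi_design_sta_3a4):
        design = tdi_design_sta_3a4
        rng = np.random.default_rng(11)
        rows = []
        for i in design.inhibitor_concs:
            k = 0.08 if i > 0 else 0.0
            for t in design.preincubation_times:
                for rep in range(3):
                    rows.append((i, t, rep + 1,
                                 100.0 * math.exp(-k * t) * math.exp(rng.normal(0, 0.03))))
        table = pd.DataFrame(rows, columns=["inhibitor_um", "time_min",
                                            "replicate", "activity_pct"])
        res = estimate_kobs(_dataset(design, table))
        for i, k in res.kobs_map.items():
            if i > 0:
                assert k == pytest.approx(0.08, rel=0.10)

    def test_non_positive_activity_names_cell(self, tdi_design_sta_3a4):
        table = _exact_decay_table({i: 0.01 for i in tdi_design_sta_3a4.inhibitor_concs})
        table.loc[(table["inhibitor_um"] == 2.0) & (table["time_min"] == 10.0),
                  "activity_pct"] = 0.0
        with pytest.raises(DataError, match="2.0"):
            _dataset(tdi_design_sta_3a4, table)

    def test_increasing_activity_clamped_with_flag(self, tdi_design_sta_3a4):
        table = _exact_decay_table({i: (-0.01 if i == 2.0 else 0.02)
                                    for i in tdi_design_sta_3a4.inhibitor_concs})
        res = estimate_kobs(_dataset(tdi_design_sta_3a4, table))
        row = res.table[res.table["inhibitor_um"] == 2.0].iloc[0]
        assert row["kobs"] == 0.0 and bool(row["clamped"])

    def test_activity_rescaling_invariance(self, exact_tdi_dataset):
        base = estimate_kobs(exact_tdi_dataset)
        scaled = exact_tdi_dataset.activities.assign(
            activity_pct=lambda d: d["activity_pct"] * 3.0)
        res = estimate_kobs(TDIDataset(design=exact_tdi_dataset.design,
                                       activities=scaled))
        for i in base.kobs_map:
            assert res.kobs_map[i] == pytest.approx(base.kobs_map[i], abs=1e-12)


class TestFitInactivation:
    def test_exact_closed_form_recovery(self):
        kinact, ki_half = 0.11, 2.45
        kobs = {i: kinact * i / (ki_half + i) for i in [0.25, 0.5, 1.0, 2.0]}
        fit = fit_inactivation(kobs)
        assert fit.kinact == pytest.approx(kinact, rel=1e-9)
        assert fit.ki_half == pytest.approx(ki_half, rel=1e-9)

    def test_half_saturation_property(self):
        kinact, ki_half = 0.014, 2.07
        assert kinact * ki_half / (ki_half + ki_half) == pytest.approx(kinact / 2)

    def test_reciprocal_and_nonlinear_agree_on_exact_data(self):
        kinact, ki_half = 0.014, 2.07
        kobs = {i: kinact * i / (ki_half + i) for i in [2.0, 4.0, 8.0, 16.0]}
        fit = fit_inactivation(kobs)
        assert fit.alternate["kinact"] == pytest.approx(fit.kinact, rel=1e-9)
        assert fit.alternate["KI"] == pytest.approx(fit.ki_half, rel=1e-9)

    def test_no_saturation_raises(self):
        # kobs linear in I: reciprocal line through the origin, intercept 0
        kobs = {i: 0.01 * i for i in [1.0, 2.0, 4.0]}
        with pytest.raises(FitError):
            fit_inactivation(kobs)

    def test_too_few_pairs_raises(self):
        with pytest.raises(DesignError):
            fit_inactivation({1.0: 0.05, 2.0: 0.08})

    @given(kinact=st.floats(0.01, 1.0), ki_half=st.floats(0.5, 20.0))
    def test_round_trip_recovery_property(self, kinact, ki_half):
        grid = [0.5, 1.0, 2.0, 4.0, 8.0]
        kobs = {i: kinact * i / (ki_half + i) for i in grid}
        fit = fit_inactivation(kobs)
        assert fit.kinact == pytest.approx(kinact, rel=1e-6)
        assert fit.ki_half == pytest.approx(ki_half, rel=1e-6)

    def test_pipeline_from_synthetic_dataset(self, exact_tdi_dataset):
        fit = fit_inactivation(estimate_kobs(exact_tdi_dataset))
        assert fit.kinact == pytest.approx(0.11, rel=1e-6)
        assert fit.ki_half == pytest.approx(2.45, rel=1e-6)

    def test_control_corrected_mode_removes_background(self, tdi_design_sta_3a4):
        spec = TDISynthSpec(design=tdi_design_sta_3a4, kinact=0.11, ki_half=2.45,
                            background_rate=0.005, cv=0.0, seed=0)
        res = estimate_kobs(gen_tdi_dataset(spec))
        fit = fit_inactivation(res, corrected=True)
        assert fit.kinact == pytest.approx(0.11, rel=1e-6)
        assert fit.ki_half == pytest.approx(2.45, rel=1e-6)


class TestEfficiency:
    @pytest.mark.parametrize("kinact, ki_half, expected", [
        (0.11, 2.45, 44.90),
        (0.019, 2.54, 7.48),
        (0.014, 2.07, 6.76),
    ])
    def test_reported_efficiencies(self, kinact, ki_half, expected):
        assert round(efficiency(kinact, ki_half), 2) == expected

    def test_homogeneity(self):
        assert efficiency(0.22, 4.90) == pytest.approx(efficiency(0.11, 2.45))

    def test_domain_errors(self):
        with pytest.raises(DomainError):
            efficiency(0.0, 1.0)
        with pytest.raises(DomainError):
            efficiency(0.1, -1.0)


class TestNormalisation:
    def test_matched_time_mode_cancels_background_loss(self):
        rows = []
        for i in [0.0, 2.0]:
            for t in [0.0, 10.0, 20.0]:
                rate = 50.0 * math.exp(-0.01 * t) * math.exp(-(0.05 if i else 0.0) * t)
                rows.append((i, t, 1, rate))
        rates = pd.DataFrame(rows, columns=["inhibitor_um", "time_min",
                                            "replicate", "rate"])
        pct = percent_of_control(rates, mode="matched_time")
        inh = pct[pct["inhibitor_um"] == 2.0].set_index("time_min")["activity_pct"]
        assert inh[10.0] == pytest.approx(100.0 * math.exp(-0.5))
        assert inh[20.0] == pytest.approx(100.0 * math.exp(-1.0))
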