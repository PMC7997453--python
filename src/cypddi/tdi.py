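"""Time-dependent inactivation kinetics: kobs per inhibitor level, kinact and KI.

Mechanism-based inactivation of a P450 follows pseudo-first-order loss of
active enzyme during pre-incubation with inhibitor and NADPH.  At inhibitor
concentration I the observed inactivation rate saturates as

    kobs(I) = kinact * I / (KI + I)

so kobs is estimated per inhibitor level as the negative slope of the
ordinary-least-squares regression of ln(percent remaining activity) on
pre-incubation time, and (kinact, KI) are recovered canonically from the
double-reciprocal line 1/kobs = (KI/kinact)(1/I) + 1/kinact, with a direct
nonlinear fit of the saturation form reported alongside as a cross-check.

The inactivation efficiency kinact/KI is reported in mL/min/umol
(1000 * kinact[min^-1] / KI[uM]).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .datasets import TDIDataset
from .errors import DesignError, DomainError, FitError

__all__ = ["KobsResult", "TDIFit", "estimate_kobs", "fit_inactivation", "efficiency"]


@dataclass
class KobsResult:
    """Per-inhibitor-level inactivation rates from log-linear regression."""

    table: pd.DataFrame = field(repr=False)
    # columns: inhibitor_um, kobs (min^-1), se, r_squared, clamped (bool)

    @property
    def kobs_map(self) -> dict[float, float]:
        return dict(zip(self.table["inhibitor_um"], self.table["kobs"]))

    @property
    def corrected_map(self) -> dict[float, float]:
        """kobs(I) - kobs(0): control-corrected inactivation rates."""
        k0 = float(self.table.loc[self.table["inhibitor_um"] == 0.0, "kobs"].iloc[0]) \
            if (self.table["inhibitor_um"] == 0.0).any() else 0.0
        return {i: k - k0 for i, k in self.kobs_map.items()}


@dataclass
class TDIFit:
    kinact: float  # min^-1
    ki_half: float  # KI, uM
    efficiency: float  # mL/min/umol, always 1000*kinact/ki_half
    method: str  # "double_reciprocal" | "nonlinear"
    kobs: KobsResult
    # cross-check estimates from the other estimator
    alternate: dict[str, float] = field(default_factory=dict)
    diagnostics: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "kinact_per_min": self.kinact,
            "KI_um": self.ki_half,
            "efficiency_ml_min_umol": self.efficiency,
            "method": self.method,
            "alternate": self.alternate,
            "kobs_table": self.kobs.table.to_dict(orient="records"),
            "diagnostics": self.diagnostics,
        }


def estimate_kobs(
    dataset: TDIDataset,
    include_t0: bool = True,
    positive_slope_tol: float = 1e-12,
) -> KobsResult:
    """OLS of ln(percent activity) on pre-incubation time, per inhibitor level.

    kobs is the negative regression slope; a slope that comes out positive
    (activity apparently increasing) is clamped to zero and flagged.
    """
    rows = []
    for i_level, grp in dataset.activities.groupby("inhibitor_um"):
        if not include_t0:
            grp = grp[grp["time_min"] > 0]
        t = grp["time_min"].to_numpy(float)
        if np.unique(t).size < 3:
            raise DesignError(
                f"kobs regression at I={i_level} uM needs >= 3 time points"
            )
        y = np.log(grp["activity_pct"].to_numpy(float))
        res = stats.linregress(t, y)
        kobs = -float(res.slope)
        clamped = False
        if kobs < -positive_slope_tol:
            kobs, clamped = 0.0, True
        elif kobs < 0:
            kobs = 0.0
        r2 = float(res.rvalue**2) if np.isfinite(res.rvalue) else 1.0
        rows.append((float(i_level), kobs, float(res.stderr or 0.0), r2, clamped))
    table = pd.DataFrame(
        rows, columns=["inhibitor_um", "kobs", "se", "r_squared", "clamped"]
    ).sort_values("inhibitor_um", ignore_index=True)
    return table_to_result(table)


def table_to_result(table: pd.DataFrame) -> KobsResult:
    return KobsResult(table=table)


def _as_pairs(kobs_map: dict[float, float] | KobsResult, corrected: bool):
    if isinstance(kobs_map, KobsResult):
        kobs_map = kobs_map.corrected_map if corrected else kobs_map.kobs_map
    pairs = [(i, k) for i, k in kobs_map.items() if i > 0 and k > 0]
    return np.array(sorted(pairs), dtype=float)


def fit_inactivation(
    kobs_map: dict[float, float] | KobsResult,
    corrected: bool = False,
) -> TDIFit:
    """Estimate (kinact, KI) from per-level kobs values.

    Canonical estimator: OLS of 1/kobs on 1/I (double-reciprocal), giving
    kinact = 1/intercept and KI = slope/intercept.  A direct nonlinear
    least-squares fit of kobs = kinact*I/(KI+I) is computed as a cross-check
    and reported under ``alternate``.

    ``corrected=True`` subtracts the 0 uM control kobs before fitting.
    """
    pairs = _as_pairs(kobs_map, corrected)
    if len(pairs) < 3:
        raise DesignError("inactivation fit needs >= 3 positive (I, kobs) pairs")
    i, kobs = pairs[:, 0], pairs[:, 1]

    res = stats.linregress(1.0 / i, 1.0 / kobs)
    intercept, slope = float(res.intercept), float(res.slope)
    if intercept <= 1e-9 * float(np.max(1.0 / kobs)):
        raise FitError(
            "double-reciprocal intercept <= 0: no saturation observed in kobs(I)",
            diagnostics={"intercept": intercept, "slope": slope},
        )
    kinact = 1.0 / intercept
    ki_half = slope / intercept
    if ki_half <= 0:
        raise FitError("negative KI from double-reciprocal fit",
                       diagnostics={"intercept": intercept, "slope": slope})

    def model(i_, kin, ki_):
        return kin * i_ / (ki_ + i_)

    try:
        popt, _ = optimize.curve_fit(
            model, i, kobs, p0=[kinact, ki_half],
            bounds=([0, 0], [np.inf, np.inf]), maxfev=20000, xtol=1e-14, ftol=1e-14,
        )
        alternate = {"kinact": float(popt[0]), "KI": float(popt[1]),
                     "efficiency": efficiency(float(popt[0]), float(popt[1]))}
    except RuntimeError:
        alternate = {}

    kobs_result = kobs_map if isinstance(kobs_map, KobsResult) else KobsResult(
        table=pd.DataFrame(
            {"inhibitor_um": list(kobs_map), "kobs": list(kobs_map.values()),
             "se": 0.0, "r_squared": 1.0, "clamped": False}
        )
    )
    return TDIFit(
        kinact=kinact, ki_half=ki_half, efficiency=efficiency(kinact, ki_half),
        method="double_reciprocal", kobs=kobs_result, alternate=alternate,
        diagnostics={"reciprocal_r_squared": float(res.rvalue**2)},
    )


def efficiency(kinact: float, ki_half: float) -> float:
    """Inactivation efficiency kinact/KI in mL/min/umol.

    kinact[min^-1] / KI[uM] has units L/min/umol; the factor 1000 converts
    to the conventional mL/min/umol.
    """
    if kinact <= 0 or ki_half <= 0:
        raise DomainError("efficiency requires kinact > 0 and KI > 0")
    return 1000.0 * kinact / ki_half
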