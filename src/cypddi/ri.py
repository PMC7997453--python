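"""Reversible (competitive) inhibition estimation from microsomal velocity grids.

The canonical Ki estimator is a global nonlinear least-squares fit of the
competitive Michaelis-Menten model

    v = Vmax * S / (Km * (1 + I/Ki) + S)

over every observation of the substrate x inhibitor grid.  The classical
Dixon construction (per-substrate lines of 1/v against I, which intersect at
I = -Ki for a competitive inhibitor) is provided as a diagnostic cross-check:
on exact data the two agree to numerical precision, and the Dixon intersection
is the field's traditional graphical read-out.

Inhibition presence is screened first: when velocities show neither a
significant negative trend in inhibitor concentration nor an appreciable drop
at the top inhibitor level, the compound is classified as a non-inhibitor of
that isoform (the pattern seen for schisandrin A on CYP3A4) and no Ki is
reported.
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .datasets import RIDataset
from .errors import DesignError, FitError

__all__ = [
    "InhibitionCall",
    "MMFit",
    "RIFit",
    "DixonResult",
    "fit_michaelis_menten",
    "fit_competitive_ki",
    "dixon_regression",
    "detect_inhibition",
]

# identifiability flags for the baseline Michaelis-Menten fit
_SATURATED = "saturated"  # Km indistinguishable from 0: v flat in S
_FIRST_ORDER = "first_order"  # Km far above the S grid: only Vmax/Km identified
_OK = "ok"


class InhibitionMode(str, enum.Enum):
    COMPETITIVE = "competitive"
    NONE = "none"


@dataclass
class InhibitionCall:
    """Outcome of the inhibition-presence screen."""

    call: str  # "inhibited" | "none"
    p_values: dict[float, float]  # substrate level -> two-sided trend p-value
    slopes: dict[float, float]
    max_mean_reduction: float  # fractional drop at the top inhibitor level
    heuristic: bool = False  # True when single replicates forced a slope-sign rule


@dataclass
class MMFit:
    vmax: float
    km: float
    se_vmax: float
    se_km: float
    rss: float
    r_squared: float
    identifiability: str = _OK


@dataclass
class RIFit:
    """Result of the competitive-inhibition fit (or the no-inhibition call)."""

    mode: InhibitionMode
    vmax: float
    km: float
    ki: float | None
    standard_errors: dict[str, float]
    rss: float
    r_squared: float
    method: str = "nonlinear"
    screen: InhibitionCall | None = None

    def to_dict(self) -> dict:
        return {
            "mode": self.mode.value,
            "Vmax": self.vmax,
            "Km": self.km,
            "Ki": self.ki,
            "standard_errors": self.standard_errors,
            "rss": self.rss,
            "r_squared": self.r_squared,
            "method": self.method,
        }


@dataclass
class DixonResult:
    ki: float
    lines: pd.DataFrame = field(repr=False)  # substrate_um, slope, intercept
    intersections: pd.DataFrame = field(repr=False)  # pairwise (I*, 1/v*)
    excluded_pairs: int = 0


def _maybe_average(table: pd.DataFrame, average: bool) -> pd.DataFrame:
    if not average:
        return table
    return (
        table.groupby(["substrate_um", "inhibitor_um"], as_index=False)["velocity"]
        .mean()
        .assign(replicate=1)
    )


def _r_squared(observed: np.ndarray, fitted: np.ndarray) -> float:
    ss_res = float(np.sum((observed - fitted) ** 2))
    ss_tot = float(np.sum((observed - observed.mean()) ** 2))
    return 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0


def fit_michaelis_menten(dataset: RIDataset) -> MMFit:
    """Fit v = Vmax*S/(Km+S) to the inhibitor-free rows of the grid."""
    control = dataset.control_subset()
    s = control["substrate_um"].to_numpy(float)
    v = control["velocity"].to_numpy(float)
    if np.unique(s).size < 3:
        raise DesignError("Michaelis-Menten fit needs >= 3 distinct substrate levels at I=0")

    def model(s_, vmax, km):
        return vmax * s_ / (km + s_)

    vmax0 = float(v.max()) * 1.2 or 1.0
    km0 = float(np.median(s))
    try:
        popt, pcov = optimize.curve_fit(
            model, s, v, p0=[vmax0, km0], bounds=([0, 0], [np.inf, np.inf]),
            maxfev=20000, xtol=1e-14, ftol=1e-14,
        )
    except RuntimeError as exc:  # pragma: no cover - scipy convergence failure
        raise FitError(f"Michaelis-Menten fit did not converge: {exc}") from exc
    vmax, km = map(float, popt)
    se = np.sqrt(np.clip(np.diag(pcov), 0, np.inf))
    fitted = model(s, vmax, km)
    rss = float(np.sum((v - fitted) ** 2))
    flag = _OK
    if km < 1e-3 * s.min():
        flag = _SATURATED  # velocities flat in S; Km at the 0 boundary
    elif km > 1e2 * s.max():
        flag = _FIRST_ORDER  # v ~ (Vmax/Km) * S; only the ratio is identified
    if vmax <= 0 or (flag == _OK and km <= 0):
        raise FitError("Michaelis-Menten estimates must be strictly positive",
                       diagnostics={"vmax": vmax, "km": km, "rss": rss})
    return MMFit(vmax, km, float(se[0]), float(se[1]), rss, _r_squared(v, fitted), flag)


def detect_inhibition(
    dataset: RIDataset,
    alpha: float = 0.05,
    reduction_threshold: float = 0.20,
) -> InhibitionCall:
    """Screen for any reversible inhibitory effect on the velocity grid.

    Classifies as "none" when no substrate level shows a statistically
    significant negative velocity trend in I (two-sided test on the OLS slope)
    AND the largest mean velocity reduction at the top inhibitor level stays
    below ``reduction_threshold``.
    """
    table = dataset.velocities
    inhibitor_levels = sorted(table["inhibitor_um"].unique())
    if len(inhibitor_levels) < 2:
        raise DesignError("inhibition screen needs >= 2 inhibitor levels")
    single_rep = dataset.n_replicates == 1
    top = inhibitor_levels[-1]

    p_values: dict[float, float] = {}
    slopes: dict[float, float] = {}
    reductions = []
    for s_level, grp in table.groupby("substrate_um"):
        x = grp["inhibitor_um"].to_numpy(float)
        y = grp["velocity"].to_numpy(float)
        if np.allclose(y, y[0]):
            slopes[s_level], p_values[s_level] = 0.0, 1.0
        else:
            res = stats.linregress(x, y)
            slopes[s_level] = float(res.slope)
            p_values[s_level] = float(res.pvalue) if np.isfinite(res.pvalue) else 1.0
        v0 = y[x == 0].mean()
        v_top = y[x == top].mean()
        reductions.append(1.0 - v_top / v0 if v0 > 0 else 0.0)
    max_reduction = float(max(reductions))

    if single_rep:
        # too few points for a meaningful trend test: slope-sign heuristic
        inhibited = max_reduction >= reduction_threshold and min(slopes.values()) < 0
        call = "inhibited" if inhibited else "none"
        return InhibitionCall(call, p_values, slopes, max_reduction, heuristic=True)

    significant_negative = any(
        slopes[s] < 0 and p_values[s] < alpha for s in slopes
    )
    if not significant_negative and max_reduction < reduction_threshold:
        call = "none"
    else:
        call = "inhibited"
    return InhibitionCall(call, p_values, slopes, max_reduction)


def fit_competitive_ki(
    dataset: RIDataset,
    average_replicates: bool = False,
    screen: bool = True,
    alpha: float = 0.05,
    reduction_threshold: float = 0.20,
) -> RIFit:
    """Global nonlinear fit of the competitive model over the full grid.

    When the inhibition screen classifies the data as uninhibited the result
    carries mode "none" and no Ki; the baseline Michaelis-Menten parameters
    are still reported.
    """
    call = None
    if screen:
        call = detect_inhibition(dataset, alpha=alpha, reduction_threshold=reduction_threshold)
        if call.call == "none":
            mm = fit_michaelis_menten(dataset)
            return RIFit(
                mode=InhibitionMode.NONE, vmax=mm.vmax, km=mm.km, ki=None,
                standard_errors={"Vmax": mm.se_vmax, "Km": mm.se_km},
                rss=mm.rss, r_squared=mm.r_squared, method="nonlinear", screen=call,
            )

    table = _maybe_average(dataset.velocities, average_replicates)
    s = table["substrate_um"].to_numpy(float)
    i = table["inhibitor_um"].to_numpy(float)
    v = table["velocity"].to_numpy(float)
    if np.unique(s).size < 3 or np.unique(i).size < 3:
        raise DesignError("competitive fit needs >= 3 substrate and >= 3 inhibitor levels")

    def model(x, vmax, km, ki):
        s_, i_ = x
        return vmax * s_ / (km * (1.0 + i_ / ki) + s_)

    mm = fit_michaelis_menten(dataset)
    ki0 = max(float(np.median(i[i > 0])), 1e-6)
    try:
        popt, pcov = optimize.curve_fit(
            model, (s, i), v, p0=[mm.vmax, mm.km, ki0],
            bounds=([0, 0, 0], [np.inf] * 3), maxfev=50000, xtol=1e-14, ftol=1e-14,
        )
    except RuntimeError as exc:
        raise FitError(f"competitive fit did not converge: {exc}") from exc
    vmax, km, ki = map(float, popt)
    se = np.sqrt(np.clip(np.diag(pcov), 0, np.inf))
    fitted = model((s, i), *popt)
    rss = float(np.sum((v - fitted) ** 2))
    return RIFit(
        mode=InhibitionMode.COMPETITIVE, vmax=vmax, km=km, ki=ki,
        standard_errors={"Vmax": float(se[0]), "Km": float(se[1]), "Ki": float(se[2])},
        rss=rss, r_squared=_r_squared(v, fitted), method="nonlinear", screen=call,
    )


def dixon_regression(
    dataset: RIDataset,
    average_replicates: bool = False,
    parallel_rtol: float = 1e-6,
) -> DixonResult:
    """Dixon-plot estimate: per-substrate OLS lines of 1/v on I.

    For a competitive inhibitor all lines cross at I = -Ki; the estimate is
    the median of -I* over all non-parallel line pairs.  Pairs whose slopes
    differ by less than ``parallel_rtol`` (relative to the largest slope
    magnitude) are treated as parallel and excluded.
    """
    table = _maybe_average(dataset.velocities, average_replicates)
    if (table["velocity"] <= 0).any():
        raise FitError("Dixon regression requires strictly positive velocities")
    lines = []
    for s_level, grp in table.groupby("substrate_um"):
        x = grp["inhibitor_um"].to_numpy(float)
        y = 1.0 / grp["velocity"].to_numpy(float)
        res = stats.linregress(x, y)
        lines.append((float(s_level), float(res.slope), float(res.intercept)))
    lines_df = pd.DataFrame(lines, columns=["substrate_um", "slope", "intercept"])

    scale = float(np.max(np.abs(lines_df["slope"]))) or 1.0
    rows, excluded = [], 0
    for (s1, m1, b1), (s2, m2, b2) in itertools.combinations(
        lines_df.itertuples(index=False), 2
    ):
        if abs(m1 - m2) <= parallel_rtol * scale + 1e-300:
            excluded += 1
            continue
        i_star = (b2 - b1) / (m1 - m2)
        rows.append((s1, s2, i_star, m1 * i_star + b1))
    if not rows:
        raise FitError("all Dixon line pairs are parallel: no intersection, Ki undefined")
    inter = pd.DataFrame(rows, columns=["substrate_a", "substrate_b", "i_star", "inv_v_star"])
    ki = float(np.median(-inter["i_star"]))
    return DixonResult(ki=ki, lines=lines_df, intersections=inter, excluded_pairs=excluded)
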