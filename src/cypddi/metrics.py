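"""Exposure metrics (AUC, Cmax, Tmax), fold error and AUC-ratio arithmetic."""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_EVEN, Decimal

import numpy as np
from scipy import stats

from .errors import DataError, DomainError
from .pbpk import SimProfile

__all__ = ["PKMetrics", "FoldError", "compute_metrics", "fold_error", "aucr",
           "round_half_even"]


@dataclass
class PKMetrics:
    auc: float  # ng/mL*h
    cmax: float  # ng/mL
    tmax: float  # h
    auc_last: float = 0.0
    extrapolated_fraction: float = 0.0
    lambda_z: float | None = None


@dataclass
class FoldError:
    predicted: float
    observed: float
    fold_error: float

    def __post_init__(self):
        assert self.fold_error >= 1.0


def round_half_even(x: float, ndigits: int = 2) -> float:
    """Banker's rounding on the decimal representation (report display rule)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_EVEN))


def _terminal_slope(t: np.ndarray, c: np.ndarray) -> float | None:
    """Log-linear terminal slope from the last third of the post-peak record."""
    i_max = int(np.argmax(c))
    mask = (np.arange(len(t)) > i_max) & (c > 0)
    t_post, c_post = t[mask], c[mask]
    if len(t_post) < 5:
        return None
    cut = t_post[0] + 2.0 / 3.0 * (t_post[-1] - t_post[0])
    sel = t_post >= cut
    if sel.sum() < 5:
        sel = np.zeros(len(t_post), bool)
        sel[-5:] = True
    res = stats.linregress(t_post[sel], np.log(c_post[sel]))
    lz = -float(res.slope)
    return lz if lz > 0 else None


def compute_metrics(
    profile: SimProfile, mode: str = "infinity", start_time_h: float = 0.0
) -> PKMetrics:
    """Linear-trapezoid AUC with optional lambda-z extrapolation to infinity.

    ``start_time_h`` restricts the analysis window, used when the victim dose
    is given late in a multidose perpetrator regimen: metrics are computed
    from the victim dose time onward.  Tmax is reported relative to
    ``start_time_h``; ties take the earliest time.
    """
    t = np.asarray(profile.time_h, float)
    c = np.asarray(profile.conc_blood_ng_ml, float)
    if len(t) == 0:
        raise DataError("empty profile")
    if np.any(np.diff(t) <= 0):
        raise DataError("time grid must be strictly increasing")
    sel = t >= start_time_h - 1e-12
    t, c = t[sel], c[sel]

    auc_last = float(np.trapezoid(c, t))
    cmax = float(c.max())
    tmax = float(t[int(np.argmax(c))] - start_time_h)
    if cmax == 0.0:
        return PKMetrics(0.0, 0.0, 0.0, 0.0, 0.0, None)

    if mode == "last":
        return PKMetrics(auc_last, cmax, tmax, auc_last, 0.0, None)
    if mode != "infinity":
        raise ValueError(f"unknown AUC mode {mode!r}")

    lz = _terminal_slope(t, c)
    extrap = float(c[-1] / lz) if lz else 0.0
    auc = auc_last + extrap
    return PKMetrics(auc, cmax, tmax, auc_last,
                     extrap / auc if auc > 0 else 0.0, lz)


def fold_error(predicted: float, observed: float) -> FoldError:
    """max(pred/obs, obs/pred); the model-fitness criterion is fold error < 2."""
    if predicted <= 0 or observed <= 0:
        raise DomainError("fold error requires strictly positive values")
    fe = max(predicted / observed, observed / predicted)
    return FoldError(predicted=predicted, observed=observed, fold_error=fe)


def aucr(auc_with: float, auc_alone: float) -> float:
    """Fold-increase in victim AUC caused by the perpetrator."""
    if auc_alone <= 0:
        raise DomainError("AUC without perpetrator must be positive")
    return auc_with / auc_alone
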