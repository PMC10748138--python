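"""Log-linear swelling law and the scale-gauge identity behind it.

The swelling curves MES(tau) are fitted with the two-parameter law

    MES(tau) = Mes0 * tau + alpha * ln(tau),

which is the gauge function phi = ln(rho) of the scale-resolution
transformation rho(tau) = tau**b * exp(a*tau) with the integration constant
fixed to zero, so (Mes0, alpha) identify with (a, b).  The law is linear in
its two coefficients, so fitting is ordinary least squares on the design
matrix [tau, ln tau] (no intercept).

Times are in hours from immersion.  The law is not closed under a change
of time unit (ln(c*tau) shifts by a constant), so a fit carries its time
unit and predictions convert input times into that unit.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "LogLinearFit",
    "GaugeModelParams",
    "fit_log_linear",
    "predict_log_linear",
    "gauge_consistency",
    "TIME_UNIT_HOURS",
]

logger = logging.getLogger(__name__)

#: Conversion factors into hours for the supported time units.
TIME_UNIT_HOURS = {"h": 1.0, "min": 1.0 / 60.0, "d": 24.0}


@dataclass(frozen=True)
class LogLinearFit:
    """Fitted coefficients of MES(tau) = mes0*tau + alpha*ln(tau).

    ``mes0`` is in g/g per time unit, ``alpha`` in g/g.  ``r_squared`` is
    the uncentered coefficient of determination (the model has no
    intercept).  ``time_unit`` records the unit of the training times.
    """

    mes0: float
    alpha: float
    se_mes0: float
    se_alpha: float
    r_squared: float
    n: int
    time_unit: str = "h"

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValueError("fit requires n >= 3 points")
        if not 0 <= self.r_squared <= 1:
            raise ValueError(f"r_squared={self.r_squared} outside [0, 1]")
        if self.se_mes0 < 0 or self.se_alpha < 0:
            raise ValueError("standard errors must be >= 0")


@dataclass(frozen=True)
class GaugeModelParams:
    """(a, b) of the resolution law rho(tau) = tau**b * exp(a*tau)."""

    a: float
    b: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.a) and np.isfinite(self.b)):
            raise ValueError("a and b must be finite")


def _design(times: np.ndarray) -> np.ndarray:
    return np.column_stack([times, np.log(times)])


def fit_log_linear(
    times,
    values,
    *,
    weights=None,
    window: tuple[float, float] | None = None,
    time_unit: str = "h",
    drop_zero_times: bool = True,
) -> LogLinearFit:
    """Least-squares fit of MES(tau) = mes0*tau + alpha*ln(tau).

    Parameters
    ----------
    times, values:
        Swelling observations; times strictly positive (tau = 0 rows are
        dropped with a warning when ``drop_zero_times`` is set, since
        experimental tables start at immersion).
    weights:
        Optional nonnegative weights (weighted least squares).
    window:
        Optional (t_min, t_max) restriction of the fit, e.g. to the first
        hour for compact fibers where the law holds only initially.
    time_unit:
        Unit the times are expressed in ('h', 'min' or 'd'); recorded on
        the fit so predictions can convert.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.shape != y.shape or t.ndim != 1:
        raise ValueError("times and values must be 1-D arrays of equal length")
    w = None if weights is None else np.asarray(weights, dtype=float)
    if w is not None and (w.shape != t.shape or np.any(w < 0)):
        raise ValueError("weights must be nonnegative, same length as times")
    if time_unit not in TIME_UNIT_HOURS:
        raise ValueError(f"unknown time_unit {time_unit!r}")

    keep = np.ones(t.size, dtype=bool)
    if window is not None:
        keep &= (t >= window[0]) & (t <= window[1])
    zeros = keep & (t == 0)
    if zeros.any():
        if not drop_zero_times:
            raise ValueError(
                f"time 0 at rows {np.nonzero(zeros)[0].tolist()}: ln(0) undefined"
            )
        warnings.warn(
            f"dropping {int(zeros.sum())} point(s) at tau=0 (ln 0 undefined)",
            stacklevel=2,
        )
        keep &= t > 0
    bad = keep & (t < 0)
    if bad.any():
        raise ValueError(f"negative time at rows {np.nonzero(bad)[0].tolist()}")
    t, y = t[keep], y[keep]
    if w is not None:
        w = w[keep]
    n = t.size
    if n < 3:
        raise ValueError(f"need >= 3 usable points, got {n}")
    if np.unique(t).size < 2:
        raise ValueError("rank-deficient design: all times equal")

    X = _design(t)
    if w is not None:
        sw = np.sqrt(w)
        Xw, yw = X * sw[:, None], y * sw
    else:
        Xw, yw = X, y
    beta, _, rank, _ = np.linalg.lstsq(Xw, yw, rcond=None)
    if rank < 2:
        raise ValueError("rank-deficient design matrix")
    resid = yw - Xw @ beta
    ssr = float(resid @ resid)
    tss = float(yw @ yw)
    r2 = 1.0 if tss == 0 else max(0.0, min(1.0, 1.0 - ssr / tss))
    dof = max(n - 2, 1)
    sigma2 = ssr / dof
    cov = sigma2 * np.linalg.inv(Xw.T @ Xw)
    se = np.sqrt(np.diag(cov))
    logger.debug("fit_log_linear: n=%d mes0=%g alpha=%g R2=%g", n, beta[0], beta[1], r2)
    return LogLinearFit(
        mes0=float(beta[0]),
        alpha=float(beta[1]),
        se_mes0=float(se[0]),
        se_alpha=float(se[1]),
        r_squared=r2,
        n=int(n),
        time_unit=time_unit,
    )


def predict_log_linear(fit: LogLinearFit, times, *, time_unit: str | None = None):
    """Evaluate mes0*tau + alpha*ln(tau) at strictly positive times.

    ``time_unit`` converts the input times into the fit's own unit first,
    so predictions do not depend on the unit the caller works in.
    """
    t = np.asarray(times, dtype=float)
    if np.any(t <= 0):
        raise ValueError("times must be > 0")
    if time_unit is not None and time_unit != fit.time_unit:
        factor = TIME_UNIT_HOURS[time_unit] / TIME_UNIT_HOURS[fit.time_unit]
        t = t * factor
    return fit.mes0 * t + fit.alpha * np.log(t)


def gauge_consistency(gmp: GaugeModelParams, tau_grid) -> float:
    """Max |ln(rho(tau)) - (a*tau + b*ln tau)| over the grid.

    The identity ln(tau**b * exp(a*tau)) = a*tau + b*ln(tau) links the
    resolution law to the fitted swelling form with A = a, B = b and zero
    integration constant; the discrepancy is zero to rounding.
    """
    tau = np.asarray(tau_grid, dtype=float)
    if np.any(tau <= 0):
        raise ValueError("tau_grid must be > 0")
    rho = tau**gmp.b * np.exp(gmp.a * tau)
    phi = gmp.a * tau + gmp.b * np.log(tau)
    return float(np.max(np.abs(np.log(rho) - phi)))
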