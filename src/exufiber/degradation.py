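"""Experimental degradation metrics: mass loss, equilibrium swelling, pH
programs and vapor-sorption summaries for electrospun fiber samples.

Mass loss and mass equilibrium swelling (MES) are the two gravimetric
observables of the degradation protocol:

    W_loss (%)  = (W0 - Wt) / W0 * 100
    MES (g/g)   = (Wt - W0) / W0

where W0 is the initial dry mass and Wt the (dry or swollen) mass at a
later time.  The pH schedule represents the wound-exudate pH trajectory as
a piecewise-constant program (media are replaced instantaneously), and the
sorption cycle holds one dynamic-vapor-sorption loop over stepped relative
humidity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

__all__ = [
    "FiberSample",
    "MassTimeSeries",
    "PHSchedule",
    "SorptionCycle",
    "SorptionSummary",
    "mass_loss_percent",
    "mes",
    "mass_loss_curve",
    "mes_curve",
    "ph_at",
    "sorption_summary",
    "DEFAULT_PH_SCHEDULE",
]

#: Canonical sample codes: neat chitosan (C), chitosan/quaternized-chitosan
#: blends at mass ratios 19/1 .. 1/1, and neat quaternized chitosan (Q).
CANONICAL_CODES = {
    "C": 0.0,
    "CQ19": 1 / 20,
    "CQ7": 1 / 8,
    "CQ3": 1 / 4,
    "CQ2": 1 / 3,
    "CQ1": 1 / 2,
    "Q": 1.0,
}


@dataclass(frozen=True)
class FiberSample:
    """A fiber composition: code plus quaternized-chitosan mass fraction."""

    code: str
    q_fraction: float

    def __post_init__(self) -> None:
        if not self.code:
            raise ValueError("sample code must be non-empty")
        if not 0 <= self.q_fraction <= 1:
            raise ValueError(f"q_fraction={self.q_fraction} outside [0, 1]")

    @classmethod
    def from_code(cls, code: str) -> "FiberSample":
        """Build a sample from a canonical code (C, CQ19 ... CQ1, Q)."""
        try:
            return cls(code, CANONICAL_CODES[code])
        except KeyError:
            raise ValueError(
                f"unknown sample code {code!r}; canonical codes: "
                f"{sorted(CANONICAL_CODES)}"
            ) from None


@dataclass
class MassTimeSeries:
    """Masses of one fiber sample in one medium over time.

    ``points`` is a list of (time_h, mass_mg) with strictly increasing
    times; ``w0`` is the initial dry mass in mg.  For swelling experiments
    the masses are swollen masses, for degradation experiments dry masses.
    """

    sample: FiberSample
    medium: str
    points: list[tuple[float, float]]
    w0: float

    def __post_init__(self) -> None:
        if self.w0 <= 0:
            raise ValueError("w0 must be > 0")
        times = [t for t, _ in self.points]
        masses = [m for _, m in self.points]
        if times and times[0] < 0:
            raise ValueError("first time must be >= 0")
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("times must be strictly increasing")
        if not all(np.isfinite(m) and m > 0 for m in masses):
            raise ValueError("masses must be finite and positive")

    @property
    def times(self) -> np.ndarray:
        return np.array([t for t, _ in self.points], dtype=float)

    @property
    def masses(self) -> np.ndarray:
        return np.array([m for _, m in self.points], dtype=float)


def mass_loss_percent(w0: float, wt: float, *, allow_gain: bool = False) -> float:
    """Percent mass loss (W0 - Wt)/W0 * 100.

    ``wt > w0`` (negative loss, i.e. mass gain) is flagged as inconsistent
    for a degradation series unless ``allow_gain`` is set.
    """
    if w0 <= 0:
        raise ValueError("w0 must be > 0")
    if wt < 0:
        raise ValueError("wt must be >= 0")
    if wt > w0 and not allow_gain:
        raise ValueError(
            f"wt={wt} > w0={w0}: mass gain is inconsistent with degradation "
            "(pass allow_gain=True to accept)"
        )
    return (w0 - wt) / w0 * 100.0


def mes(w0: float, wt: float) -> float:
    """Mass equilibrium swelling (Wt - W0)/W0 in g liquid per g fiber."""
    if w0 <= 0:
        raise ValueError("w0 must be > 0")
    if wt < 0:
        raise ValueError("wt must be >= 0")
    return (wt - w0) / w0


def mass_loss_curve(
    series: MassTimeSeries, *, allow_gain: bool = False
) -> list[tuple[float, float]]:
    """Elementwise mass loss of a series against its initial dry mass."""
    return [
        (t, mass_loss_percent(series.w0, m, allow_gain=allow_gain))
        for t, m in series.points
    ]


def mes_curve(series: MassTimeSeries) -> list[tuple[float, float]]:
    """Elementwise mass equilibrium swelling of a (swollen-mass) series."""
    return [(t, mes(series.w0, m)) for t, m in series.points]


@dataclass
class PHSchedule:
    """Piecewise-constant pH program, left-closed segments, last open-ended.

    Mimics the wound-exudate pH trajectory: alkaline during hemostasis and
    inflammation, trending acidic through granulation and remodeling.
    """

    breakpoints: list[tuple[float, float]]
    ph_range: tuple[float, float] = (3.0, 10.0)

    def __post_init__(self) -> None:
        if not self.breakpoints:
            raise ValueError("schedule needs at least one segment")
        starts = [s for s, _ in self.breakpoints]
        if starts[0] != 0:
            raise ValueError("first segment must start at time 0")
        if any(b <= a for a, b in zip(starts, starts[1:])):
            raise ValueError("segment start times must be strictly increasing")
        lo, hi = self.ph_range
        for _, ph in self.breakpoints:
            if not lo <= ph <= hi:
                raise ValueError(f"pH {ph} outside validated range [{lo}, {hi}]")


#: Degradation-protocol default: starts at the alkaline pH of the
#: inflammatory stage and steps down toward granulation/remodeling values.
#: Only the 8.5 start point is a protocol constant; the later steps are
#: configurable placeholders consistent with the described downward trend.
DEFAULT_PH_SCHEDULE = PHSchedule(
    breakpoints=[(0.0, 8.5), (24.0, 7.5), (72.0, 7.0), (120.0, 6.5), (168.0, 5.5)]
)


def ph_at(schedule: PHSchedule, time: float) -> float:
    """pH of the segment containing ``time`` (hours); left-closed convention."""
    if time < 0:
        raise ValueError("time must be >= 0")
    ph = schedule.breakpoints[0][1]
    for start, value in schedule.breakpoints:
        if time >= start:
            ph = value
        else:
            break
    return ph


@dataclass
class SorptionCycle:
    """One dynamic-vapor-sorption loop: ascending and descending RH branches.

    Each branch is a list of (relative_humidity %, uptake %); RH is within
    [0, 90], the ascending branch sorted increasing and the descending
    branch decreasing.  The two branches share their RH endpoints.
    """

    branch_up: list[tuple[float, float]]
    branch_down: list[tuple[float, float]]
    temperature_c: float = 25.0
    endpoint_tol: float = 1e-6

    def __post_init__(self) -> None:
        for name, branch, ascending in (
            ("branch_up", self.branch_up, True),
            ("branch_down", self.branch_down, False),
        ):
            rh = [p[0] for p in branch]
            up = [p[1] for p in branch]
            if any(not 0 <= v <= 90 for v in rh):
                raise ValueError(f"{name}: RH outside [0, 90]")
            if any(v < 0 for v in up):
                raise ValueError(f"{name}: uptake must be >= 0")
            diffs = [b - a for a, b in zip(rh, rh[1:])]
            if ascending and any(d <= 0 for d in diffs):
                raise ValueError("branch_up RH must be strictly increasing")
            if not ascending and any(d >= 0 for d in diffs):
                raise ValueError("branch_down RH must be strictly decreasing")
        if self.branch_up and self.branch_down:
            lo_up, hi_up = self.branch_up[0], self.branch_up[-1]
            hi_dn, lo_dn = self.branch_down[0], self.branch_down[-1]
            for (r1, u1), (r2, u2) in ((hi_up, hi_dn), (lo_up, lo_dn)):
                if abs(r1 - r2) > self.endpoint_tol or abs(u1 - u2) > self.endpoint_tol:
                    raise ValueError(
                        "branches must share their RH-extreme endpoints "
                        f"(got {(r1, u1)} vs {(r2, u2)})"
                    )


class SorptionSummary(NamedTuple):
    max_uptake: float        # % over both branches
    hysteresis_area: float   # %*RH, integral of |down - up| over shared RH
    monotone_up: bool        # uptake non-decreasing along ascending branch


def sorption_summary(cycle: SorptionCycle) -> SorptionSummary:
    """Summarise a sorption loop: peak uptake, hysteresis area, monotonicity.

    The hysteresis area is the trapezoidal integral of the absolute gap
    between the descending and ascending branches over their shared RH
    range, so it vanishes exactly when the branches coincide pointwise.
    """
    if len(cycle.branch_up) < 3 or len(cycle.branch_down) < 3:
        raise ValueError("each branch needs >= 3 points")
    rh_up = np.array([p[0] for p in cycle.branch_up])
    up = np.array([p[1] for p in cycle.branch_up])
    rh_dn = np.array([p[0] for p in cycle.branch_down])[::-1]
    dn = np.array([p[1] for p in cycle.branch_down])[::-1]

    max_uptake = float(max(up.max(), dn.max()))
    lo = max(rh_up[0], rh_dn[0])
    hi = min(rh_up[-1], rh_dn[-1])
    grid = np.union1d(rh_up, rh_dn)
    grid = grid[(grid >= lo) & (grid <= hi)]
    gap = np.abs(
        np.interp(grid, rh_dn, dn) - np.interp(grid, rh_up, up)
    )
    area = float(np.trapezoid(gap, grid))
    monotone = bool(np.all(np.diff(up) >= 0))
    return SorptionSummary(max_uptake=max_uptake, hysteresis_area=area, monotone_up=monotone)
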