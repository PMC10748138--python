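"""Seeded synthetic data with the statistical structure of the fiber
degradation study.

The generators emulate, without claiming mechanism:

* two-phase mass-loss curves — a fast leaching phase (soluble quaternized
  chitosan dissolving out within ~24 h) followed by a slower enzymatic
  phase, with the asymptotic loss scaling with the quaternized-chitosan
  fraction into the 15-55 % range;
* swelling curves following MES(tau) = mes0*tau + alpha*ln(tau) plus
  Gaussian noise;
* vapor sorption/desorption loops with maximum uptake rising from 30 % to
  60 % with quaternized-chitosan content, and a closed hysteresis loop;
* Gaussian fiber-diameter populations, optionally eroded by a
  multiplicative shrink factor.

Every generator is a pure function of its parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .degradation import (
    FiberSample,
    MassTimeSeries,
    PHSchedule,
    SorptionCycle,
    ph_at,
)
from .morphometry import DiameterSample, Stage

__all__ = [
    "DegradationGenParams",
    "SwellingGenParams",
    "gen_degradation_curve",
    "gen_swelling_curve",
    "gen_sorption_cycle",
    "gen_diameters",
]

#: Default pH -> enzymatic-rate multipliers: decomposition accelerates in
#: the acidic media of the granulation/remodeling stages.
DEFAULT_PH_RATE_MODIFIERS = ((7.0, 1.0), (-np.inf, 1.5))


@dataclass(frozen=True)
class DegradationGenParams:
    """Two-phase mass-loss emulator parameters.

    Mean loss (percent of initial dry mass) at time t hours:

        loss(t) = q_fraction * leach_plateau * (1 - exp(-k_leach * t))
                + enzymatic_plateau * m(pH(t)) * (1 - exp(-k_enz * t))

    with m the pH-band rate modifier.  Defaults place the asymptote at
    10 % for neat chitosan (q_fraction = 0) and 55 % for pure quaternized
    chitosan (q = 1), spanning the observed 15-55 % blend range; the leach
    rate (0.25 /h) is essentially complete within 24 h while the enzymatic
    rate (0.02 /h) acts over the 7-day horizon.
    """

    q_fraction: float
    medium: str = "lysozyme_PBS"
    leach_plateau_percent: float = 45.0
    enzymatic_plateau_percent: float = 10.0
    k_leach: float = 0.25
    k_enz: float = 0.02
    ph_rate_modifiers: tuple[tuple[float, float], ...] = DEFAULT_PH_RATE_MODIFIERS
    ph_schedule: PHSchedule | None = None
    noise_sd_percent: float = 1.0
    w0_mg: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.q_fraction <= 1:
            raise ValueError("q_fraction outside [0, 1]")
        if self.leach_plateau_percent < 0 or self.enzymatic_plateau_percent < 0:
            raise ValueError("plateaus must be >= 0")
        if self.leach_plateau_percent + self.enzymatic_plateau_percent > 100:
            raise ValueError("plateau sum exceeds 100 %")
        if self.k_leach <= 0 or self.k_enz <= 0:
            raise ValueError("rates must be > 0")
        if self.noise_sd_percent < 0:
            raise ValueError("noise_sd_percent must be >= 0")
        if self.w0_mg <= 0:
            raise ValueError("w0_mg must be > 0")

    def rate_modifier(self, ph: float) -> float:
        """Multiplier on k_enz for the pH band containing ``ph``."""
        for threshold, factor in self.ph_rate_modifiers:
            if ph >= threshold:
                return factor
        return self.ph_rate_modifiers[-1][1]


def mean_loss_percent(p: DegradationGenParams, times) -> np.ndarray:
    """Noise-free two-phase mean loss curve, percent."""
    t = np.asarray(times, dtype=float)
    if p.ph_schedule is None:
        modifier = np.ones_like(t)
    else:
        modifier = np.array([p.rate_modifier(ph_at(p.ph_schedule, ti)) for ti in t])
    leach = p.q_fraction * p.leach_plateau_percent * (1.0 - np.exp(-p.k_leach * t))
    enz = p.enzymatic_plateau_percent * modifier * (1.0 - np.exp(-p.k_enz * t))
    return np.minimum(leach + enz, 100.0)


def gen_degradation_curve(p: DegradationGenParams, times) -> MassTimeSeries:
    """Seeded two-phase mass-loss series W_t = W0 * (1 - loss/100).

    Gaussian noise is added to the mean loss and the trajectory is then
    clipped to stay non-decreasing in loss (washed-and-dried masses cannot
    increase) and within [0, 100) percent.
    """
    t = np.asarray(times, dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    if np.any(t < 0):
        raise ValueError("times must be >= 0")
    rng = np.random.default_rng(p.seed)
    loss = mean_loss_percent(p, t)
    loss = loss + rng.normal(0.0, p.noise_sd_percent, size=t.shape)
    loss = np.maximum.accumulate(np.clip(loss, 0.0, 99.999))
    masses = p.w0_mg * (1.0 - loss / 100.0)
    sample = FiberSample(code=f"synthQ{p.q_fraction:.2f}", q_fraction=p.q_fraction)
    return MassTimeSeries(
        sample=sample,
        medium=p.medium,
        points=list(zip(t.tolist(), masses.tolist())),
        w0=p.w0_mg,
    )


@dataclass(frozen=True)
class SwellingGenParams:
    """Log-linear swelling curve emulator: MES = mes0*tau + alpha*ln tau + noise."""

    mes0_true: float
    alpha_true: float
    times: tuple[float, ...]
    noise_sd: float = 0.0
    w0_mg: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        if t.size == 0 or np.any(t <= 0):
            raise ValueError("times must be > 0 (ln tau must exist)")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.w0_mg <= 0:
            raise ValueError("w0_mg must be > 0")


def gen_swelling_curve(
    p: SwellingGenParams, sample: FiberSample | None = None
) -> MassTimeSeries:
    """Seeded swollen-mass series with MES following the log-linear law.

    Masses are recovered through the swelling definition inverse,
    ``wt = w0 * (1 + MES)``; MES values are floored just above -1 so the
    masses stay positive under extreme noise draws.
    """
    t = np.asarray(p.times, dtype=float)
    rng = np.random.default_rng(p.seed)
    mes_vals = p.mes0_true * t + p.alpha_true * np.log(t)
    if p.noise_sd > 0:
        mes_vals = mes_vals + rng.normal(0.0, p.noise_sd, size=t.shape)
    mes_vals = np.maximum(mes_vals, -0.999)
    masses = p.w0_mg * (1.0 + mes_vals)
    if sample is None:
        sample = FiberSample(code="synth", q_fraction=0.5)
    return MassTimeSeries(
        sample=sample,
        medium="lysozyme_PBS",
        points=list(zip(t.tolist(), masses.tolist())),
        w0=p.w0_mg,
    )


def gen_sorption_cycle(
    q_fraction: float,
    seed: int = 0,
    *,
    rh_step: float = 10.0,
    jitter: bool = True,
    hysteresis: bool = True,
) -> SorptionCycle:
    """Seeded sorption/desorption loop over RH 0-90 % in fixed steps.

    The ascending branch is ``Umax * (RH/90)**gamma`` with
    ``Umax = 30 + 30*q_fraction`` percent (plus a seeded relative jitter of
    at most 5 % when ``jitter`` is set) and a seeded exponent gamma in
    [1, 2].  The descending branch uses a smaller exponent, which puts it
    at or above the ascending branch everywhere while sharing both RH
    endpoints (hysteresis loop closes).
    """
    if not 0 <= q_fraction <= 1:
        raise ValueError("q_fraction outside [0, 1]")
    rng = np.random.default_rng(seed)
    umax = 30.0 + 30.0 * q_fraction
    if jitter:
        umax *= 1.0 + rng.uniform(-0.05, 0.05)
    gamma = rng.uniform(1.0, 2.0)
    gamma_down = gamma * rng.uniform(0.6, 0.9) if hysteresis else gamma
    rh = np.arange(0.0, 90.0 + rh_step / 2, rh_step)
    up = umax * (rh / 90.0) ** gamma
    down = umax * (rh / 90.0) ** gamma_down
    branch_up = list(zip(rh.tolist(), up.tolist()))
    branch_down = list(zip(rh[::-1].tolist(), down[::-1].tolist()))
    return SorptionCycle(branch_up=branch_up, branch_down=branch_down)


def gen_diameters(
    mean_nm: float,
    sd_nm: float,
    n: int,
    seed: int = 0,
    erosion_factor: float = 0.8,
    *,
    erosion_jitter_sd: float = 0.02,
    sample_code: str = "synth",
) -> tuple[DiameterSample, DiameterSample]:
    """(initial, after-biodegradation) diameter populations.

    Initial diameters are Normal(mean, sd) truncated to > 0 by resampling;
    the after stage multiplies each fiber by ``erosion_factor`` with a
    small per-fiber lognormal-style jitter.  ``erosion_factor = 1`` means
    no erosion and reproduces the initial population exactly.
    """
    if mean_nm <= 0 or sd_nm <= 0:
        raise ValueError("mean_nm and sd_nm must be > 0")
    if n < 10:
        raise ValueError("n must be >= 10 (downstream statistics need it)")
    if not 0 < erosion_factor <= 1:
        raise ValueError("erosion_factor must be in (0, 1]")
    rng = np.random.default_rng(seed)
    d = rng.normal(mean_nm, sd_nm, size=n)
    while np.any(d <= 0):  # truncate at zero by resampling
        bad = d <= 0
        d[bad] = rng.normal(mean_nm, sd_nm, size=int(bad.sum()))
    if erosion_factor < 1.0 and erosion_jitter_sd > 0:
        jitter = np.exp(rng.normal(0.0, erosion_jitter_sd, size=n))
    else:
        jitter = np.ones(n)
    after = d * erosion_factor * jitter
    return (
        DiameterSample(sample_code, Stage.INITIAL, d),
        DiameterSample(sample_code, Stage.AFTER_BIODEGRADATION, after),
    )
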