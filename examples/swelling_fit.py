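"""Fitting the log-linear swelling law MES(tau) = Mes0*tau + alpha*ln(tau).

Generates a noisy synthetic swelling curve over 7 days, fits the law by
least squares, and verifies the gauge identity that motivates its form:
ln(tau^b e^{a tau}) = a*tau + b*ln(tau).
"""

import numpy as np

from exufiber import GaugeModelParams, fit_log_linear, gauge_consistency, mes_curve
from exufiber.synthetic import SwellingGenParams, gen_swelling_curve

truth = dict(mes0_true=0.05, alpha_true=1.5)
series = gen_swelling_curve(
    SwellingGenParams(**truth, times=tuple(np.linspace(1.0, 168.0, 50)),
                      noise_sd=0.2, seed=7)
)
curve = mes_curve(series)
fit = fit_log_linear([c[0] for c in curve], [c[1] for c in curve])
print(f"true   Mes0 = {truth['mes0_true']}, alpha = {truth['alpha_true']}")
print(f"fitted Mes0 = {fit.mes0:.4f} +/- {fit.se_mes0:.4f}, "
      f"alpha = {fit.alpha:.4f} +/- {fit.se_alpha:.4f}, R^2 = {fit.r_squared:.4f}")
# Mes0 is the linear swelling rate (g/g per hour), alpha the logarithmic
# early-time term; the estimates bracket the generating values.

gap = gauge_consistency(GaugeModelParams(a=fit.mes0, b=fit.alpha),
                        np.geomspace(1.0, 168.0, 50))
print(f"gauge identity max |ln rho - (a tau + b ln tau)| = {gap:.2e}  (zero to rounding)")
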