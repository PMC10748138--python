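"""Leaching-channel morphology fields and their dynamic regimes.

Evaluates M(Omega, t) = Re(a1 z + a2) on a grid and classifies the time
traces: slow oscillations (Omega ~ 1) show the double-period pattern of
leaching channels (bursts in close pairs separated by long gaps), fast ones
(Omega ~ 10) the intermittent bursting of a degrading lattice.
"""

import numpy as np

from exufiber import classify_regime, morphology_field
from exufiber.scale_model import morphology_amplitude, regime_features

for omega, r in [(1.0, 0.5), (10.0, 0.9)]:
    period = np.pi / omega
    t = np.linspace(0.0, 6 * period, 6 * 256, endpoint=False)
    fld = morphology_field(np.array([omega]), t, r)
    trace = fld.values[0]
    dt = float(t[1] - t[0])
    label = classify_regime(trace, dt)
    feats = regime_features(trace, dt)
    print(
        f"Omega={omega:5.1f} r={r}: peak={np.abs(trace).max():8.3f} "
        f"(theory {morphology_amplitude(r, omega):8.3f}), "
        f"burst rate={feats.burst_rate:5.2f}/unit-tau, "
        f"gap ratio={feats.gap_cluster_ratio:6.2f} -> {label.value}"
    )
# The burst rate ~2*Omega/pi is what separates the regimes; the gap ratio
# (long/short inter-burst interval) shows the double-period alternation.
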