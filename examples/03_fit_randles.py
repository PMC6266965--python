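"""Fit the Randles/CPE equivalent circuit to a spectrum.

Simulates a noiseless spectrum from the in-vivo hockey-stick fitted means
and refits it with the standard protocol (frequencies up to 10 kHz,
standard initial values and bounds).  The recovered parameters match the
generator to many digits, demonstrating that the fit window and weighting
identify Q, n and R_S from 21 frequencies.
"""

from eistrack import (
    ArrayType,
    Category,
    ExtendedParams,
    SessionMeta,
    SessionTime,
    default_grid,
    fit_randles,
    get_archetype,
    simulate_spectrum,
)
from eistrack.synthetic import Condition

archetype = get_archetype(ArrayType.IROX, Category.HOCKEY_STICK, Condition.IN_VIVO)
truth = archetype.params.base
meta = SessionMeta("demo", 1, ArrayType.IROX, SessionTime.week_(2))
s = simulate_spectrum(ExtendedParams.randles(truth), default_grid(), meta)

r = fit_randles(s)
print(f"fit used {r.n_points} frequencies (<= 10 kHz), converged={r.converged}")
print(f"weighted residual cost: {r.cost:.2e}")
print(f"{'param':>6}  {'true':>12}  {'recovered':>12}")
for name, t, got in [
    ("R_E", truth.R_E, r.params.R_E),
    ("Q", truth.Q, r.params.Q),
    ("n", truth.n, r.params.n),
    ("R_S", truth.R_S, r.params.R_S),
]:
    print(f"{name:>6}  {t:>12.5g}  {got:>12.5g}")
print("\nn ~ 0.64 marks a leaky-capacitor interface; R_S = 138 kOhm is the")
print("access-resistance plateau.  R_E barely influences the 1 Hz - 10 kHz")
print("window at these values, so its estimate is the least constrained.")
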