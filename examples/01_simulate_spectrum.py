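"""Simulate an impedance spectrum from an equivalent circuit.

Builds the Randles/CPE circuit of a healthy iridium-oxide electrode tip
(in-vivo hockey-stick archetype), evaluates it on the standard 31-point
1 Hz - 1 MHz grid, and prints a few rows plus the 1 kHz impedance that a
quick single-frequency check would report.
"""

from eistrack import (
    ArrayType,
    Category,
    SessionMeta,
    SessionTime,
    default_grid,
    f_peak,
    get_archetype,
    impedance_at_1khz,
    simulate_spectrum,
)
from eistrack.synthetic import Condition

archetype = get_archetype(ArrayType.IROX, Category.HOCKEY_STICK, Condition.IN_VIVO)
p = archetype.params.base
print(f"circuit: R_E={p.R_E:.3g} ohm, Q={p.Q:.3g} S*s^n, n={p.n}, R_S={p.R_S:.3g} ohm")

meta = SessionMeta("demo", 1, ArrayType.IROX, SessionTime.week_(2))
s = simulate_spectrum(archetype.params, default_grid(), meta)

print(f"\n{'f (Hz)':>10}  {'|Z| (ohm)':>12}  {'phase (deg)':>11}")
for k in (0, 5, 10, 15, 20, 25, 30):
    print(f"{s.frequencies[k]:>10.4g}  {s.zmag[k]:>12.4g}  {s.phase[k]:>11.2f}")

print(f"\n|Z| at 1 kHz: {impedance_at_1khz(s):.4g} ohm")
print(f"phase peak at f_peak = {f_peak(s):.4g} Hz (monotone rise: peak at grid top)")

# an aged electrode couples through its degraded insulation at high
# frequency; the added dielectric capacitance bends the phase back down,
# moving the peak to an interior frequency near 1 kHz
from eistrack import ExtendedParams

aged = ExtendedParams(base=p, C_d=5e-11)
s_aged = simulate_spectrum(aged, default_grid(), meta)
print(f"with C_d = 50 pF (aged): f_peak = {f_peak(s_aged):.4g} Hz")

print("\nThe magnitude falls steeply at low frequency (capacitive interface)")
print("and flattens onto the access-resistance plateau R_S at high frequency")
print("- the 'hockey-stick' signature of an intact low-impedance tip.")
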