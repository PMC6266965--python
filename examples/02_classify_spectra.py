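"""Rule-based classification of spectra into degradation categories.

Simulates one noisy spectrum per packaged archetype, extracts the band
statistics the decision rules test, and classifies each.  The printed
agreement with the generating category illustrates the classifier's
robustness at a realistic measurement-noise level.
"""

import numpy as np

from eistrack import (
    ArrayType,
    NoiseModel,
    SessionMeta,
    SessionTime,
    apply_noise,
    archetype_library,
    classify_spectrum,
    default_grid,
    extract_features,
    simulate_spectrum,
)

rng = np.random.default_rng(7)
grid = default_grid()
noise = NoiseModel(sigma_logmag=0.05, sigma_phase=3.0)

print(f"{'array':>5}  {'condition':>9}  {'generated as':>12}  {'classified as':>13}")
n_ok = 0
for a in archetype_library():
    meta = SessionMeta("demo", 1, a.array_type, SessionTime.week_(2))
    s = apply_noise(simulate_spectrum(a.params, grid, meta), noise, rng)
    label = classify_spectrum(extract_features(s), a.array_type)
    n_ok += label.category is a.category
    print(
        f"{a.array_type.value:>5}  {a.condition.value:>9}  "
        f"{a.category.value:>12}  {label.category.value:>13}"
    )
print(f"\n{n_ok}/10 noisy archetype spectra recovered their generating category.")
print("mean/max phase bands below 100 Hz and above 10/50 kHz, plus the")
print("low-frequency magnitude, are what the printed decision rules test.")
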