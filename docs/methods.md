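# Methods

## Data model

A spectrum is |Z| (Ω) and phase (degrees, negative = capacitive) on a
strictly increasing positive frequency grid, with (array, channel, session)
metadata. Phases are stored as given and never wrapped. Sessions are an
ordered categorical axis — in-vitro baseline < ~1 h post-op < week 2 <
week 3 < … — because the baseline and the post-op check are not points on
a numeric time line. The default grid is 31 points log-uniform over
1 Hz – 1 MHz (5 per decade); it contains 10^3 Hz exactly, and grids are
constructed from integer exponent steps so that decade frequencies carry
no floating-point error. Cohorts may mix grids; band statistics operate on
whatever frequencies exist.

Supported file formats: a fixed CSV dialect (columns `frequency_hz,
zmag_ohm, zphz_deg`, comma separator, `.` decimal — fixed to avoid locale
ambiguity) and a tab-delimited instrument-export text containing a single
ZCURVE table with `Freq, Zreal, Zimag, Zmod, Zphz` columns. On read,
magnitude/phase come from `Zmod`/`Zphz` when present; if `Zmod` disagrees
with √(Zreal²+Zimag²) by more than 1 % the magnitude is recomputed with a
warning. Values are written with `repr` (shortest round-tripping decimal),
so write → read → write is bit-identical.

## Circuit model

The electrode–electrolyte interface is the Randles circuit with a constant
phase element:

    Z_CPE(ω) = 1/(Q (jω)^n),    Z(ω) = R_S + R_E / (1 + R_E Q (jω)^n)

- ω is **angular frequency** (rad/s), ω = 2πf. CPE literature is split
  between per-rad/s and per-Hz conventions; switching rescales Q by (2π)^n
  and changes nothing else. This package fixes rad/s and documents every
  place the other convention appears (see archetype library below).
- The complex power uses the principal branch, j^n = exp(j n π/2), so the
  CPE phase is exactly −n·90°.
- Parameters: R_S (access/solution resistance, Ω) — the high-frequency
  resistive plateau set by electrolyte path and electrode geometry; R_E
  (charge-transfer resistance, Ω); Q (CPE admittance magnitude, S·s^n) and
  n ∈ [0, 1] (n = 1 ideal capacitor, n = 0 resistor).

Degraded electrodes add two conduction pathways, each placed **in parallel
with the whole Randles branch**:

    Z_ext(ω) = 1 / ( 1/Z(ω) + 1/R_p + jω C_d )

The parallel shunt R_p produces the flat low-frequency plateau of
ski-slope spectra once the electrode branch impedance exceeds it; the
parallel dielectric capacitance C_d produces the high-frequency phase
plunge of ski-slope spectra and bends the rising phase of aged
hockey-stick spectra back down, creating an interior phase maximum near
1 kHz. The published circuit sketches these pathways without equations;
the parallel topology is this package's choice, made because it
reproduces both morphologies with one formula and reduces *exactly*
(identical floating-point values) to the Randles circuit when R_p = ∞ and
C_d = 0.

## Classification rules

Band conventions: "<100 Hz", ">10 kHz", ">50 kHz" strict; "100 Hz–50 kHz"
and "100 Hz–10 kHz" closed (0.1 kHz = 100 Hz, matching the companion
"<100 Hz" band). Band means are arithmetic means over grid points in the
band; Δφ is the difference between phases at successive grid frequencies,
compared by absolute value — for a decreasing sigmoid the signed
difference is negative and a "max(Δφ) > 25°" test would never fire, so the
intended magnitude-of-slope reading is used. A band with no grid points
yields an unavailable (NaN) feature, and a rule needing it raises an error
naming the band.

Evaluation order (the published rules state no precedence): **outlier**
first — mean(|Z| < 100 Hz) above 2×10⁹ Ω (IrOx) or 1×10⁸ Ω (Pt) — because
the magnitude gate numerically dominates both shape rules; then
**hockey-stick** (iridium-oxide arrays only, all four printed conditions:
mean(|Z|<100 Hz) < 8×10⁶ Ω; −80° < mean(φ<100 Hz) < −40°;
max(φ, 100 Hz–50 kHz) > −30°; |max(φ, 100 Hz–10 kHz) − mean(φ<100 Hz)| >
25°); then **ski-slope** (mean(φ>10 kHz) < −80°, or all of
mean(φ<100 Hz) > −35°, mean(φ>50 kHz) < −70°, max|Δφ| > 25°); else
**mixed**. All comparisons are strict as printed. Hockey-stick is gated to
IrOx because that morphology belongs to low-impedance tips; the ski-slope
rule is applied to platinum too (broken Pt channels do occur) but such
labels carry a low-confidence note, since the rule was calibrated on
iridium oxide. All thresholds live in `ClassifierThresholds` and can be
changed without code edits for sensitivity analyses.

Manual overrides are applied from a (key, category, note) ledger;
overridden labels carry MANUAL provenance and the override fraction is
reported.

## Fit protocol

Only frequencies ≤ 10 kHz enter the fit (boundary inclusive): aged
electrodes show a high-frequency roll-off from dielectric coupling that
the plain Randles form cannot represent, and exclusion by window is the
only roll-off handling — the extended model is simulation-only. Initial
values: R_E = 6×10⁷ Ω, Q = 5×10⁻⁷ S·s^n, n = 0.8, R_S = Re Z at 10 kHz
(interpolated linearly in log-frequency if off-grid; a spectrum ending
below 10 kHz falls back to its highest frequency with a warning). Bounds:
R_E ∈ [10⁴, 10¹¹] Ω, Q ∈ [10⁻¹⁵, 10⁻⁵], n ∈ [0, 1], R_S ∈ [10, 10¹²] Ω —
the R_S upper bound is nominally unbounded; 10¹² Ω is the documented
surrogate.

Residuals: per retained frequency, (Re Ẑ − Re Z)/|Z| and
(Im Ẑ − Im Z)/|Z|. Modulus weighting is the package's choice (the original
fitting routine's weighting is not described anywhere): spectra span five
decades of magnitude and unweighted residuals would let the lowest
frequencies dominate. Unit weighting is available as a config option.

Optimizer: bound-constrained trust-region least squares
(`scipy.optimize.least_squares`, method `trf`) with R_E, Q, R_S optimised
as log10 values (they span many decades) and n in natural space, an
analytic Jacobian, tolerances 10⁻¹⁴, and one deterministic restart from a
perturbed initial point if the iteration budget (400 evaluations) is
exhausted. Estimates within 10⁻⁶ internal units of a bound are flagged
`at_bound` — fits of near-open channels routinely pin R_E at the 10¹¹ Ω
ceiling, and the flag distinguishes a pinned estimate from a converged
one. Degenerate inputs (e.g. a pure resistor) produce a best-effort fit
with bound flags rather than an error; fewer than 4 usable frequencies is
an error.

Identifiability: with the 1 Hz – 10 kHz window, Q, n and R_S are well
determined whenever each element contributes somewhere in the window; R_E
is identifiable only when the CPE does not block it at the lowest
frequency (roughly R_E·Q·ω_min^n < 10). Round-trip tests therefore assert
R_E recovery only under that condition.

## Longitudinal analytics

|Z|(1 kHz) is the exact grid sample when 1 kHz is on the grid, else
log-log linear interpolation (spectra are locally near power-law; linear
interpolation in linear coordinates would bias on a 5-per-decade grid).
f_peak is the grid argmax of the phase with ties broken toward the lowest
frequency; no sub-grid refinement, since peak tracking is across the
discrete measured grid. Population tables count categories per session
over a fixed channel roster, with channels lacking a spectrum counted
*unmeasured*; every table asserts that counts + unmeasured equal the
roster size. Group aggregates report mean and SEM only for groups with
more than three channels at a time point; SEM = sd/√count with the sample
standard deviation (ddof = 1; unspecified in the source convention, chosen
as the standard unbiased-variance estimator).

Area/unit helpers for cross-study comparison: areal CPE admittance ×
electrode area (µm² → mm²); access resistance divided by an area ratio;
and Q reported in s·Ω^(−1/n) units converted by raising to the power n.

## Synthetic cohorts

The generator emulates the *structure* of a chronic peripheral-nerve
implant study: 5 iridium-oxide and 6 platinum 16-channel arrays, sessions
in-vitro + ~1 h post-op + weeks 2–12, per-channel category scripts with
whole-array events (a global week-8 switch to ski-slope followed by
failure; a hockey-stick array whose channels all turn mixed at week 3;
stable platinum arrays with late outlier clusters; no outliers in vitro).
Transitions are *scripted, not mechanistic* — there is no tissue-response
model — and unmeasured sessions simply end a script.

**Archetype library.** One circuit per published fitted-means row (10 rows
carry data: 7 IrOx, 3 Pt). The four Randles fields are the published means
with two documented exceptions:

1. *CPE convention.* The published Q means only reproduce the category
   morphologies under the per-Hz CPE convention: read as rad/s quantities,
   the in-vivo hockey-stick means put the CPE/R_S crossover at ~23 Hz, the
   sub-100 Hz mean phase at ≈ −37° (outside the −80…−40° rule window) and
   no ~1 kHz phase peak; read as per-Hz and converted
   (Q_rad = Q_printed/(2π)^n, crossover ~150 Hz) the same row satisfies
   all four hockey-stick conditions and shows the interior peak. The
   library stores the converted values; n, R_E and R_S are
   convention-invariant.
2. *Outlier Q is chosen, not the published mean.* The outlier-row Q means
   are means of strongly skewed per-channel fits; simulated directly they
   give low-frequency magnitudes far below the outlier gates under either
   convention. The packaged outlier archetypes keep the published R_E, n,
   R_S and carry a chosen Q (2×10⁻¹¹ IrOx, 3×10⁻¹⁰ Pt) placing the
   simulated magnitude at the instrument-limit level the category
   describes.

The extended elements are never published quantitatively and are chosen so
each archetype's noiseless simulation satisfies its own category rule
(recorded per archetype in `chosen_elements`): ski-slope archetypes
R_p = 10⁷ Ω, C_d = 2 nF; the aged-mixed IrOx in-vivo archetype a milder
R_p = 10⁶ Ω (without it the mixed means satisfy all four hockey-stick
conditions); outlier archetypes no shunt — a parallel pathway would cap
the magnitude below the outlier gate of an isolated open-circuit failure.
Label closure — classify(simulate(archetype)) = archetype category for
every packaged archetype — is the central self-consistency property of
the package and is asserted in the test suite.

**Noise model.** |Z| → |Z|·10^ε with ε ~ N(0, σ_logmag) and phase → phase
+ N(0, σ_phase), independent, phases clipped to [−180°, 180°]; the
simplest law preserving |Z| > 0. Defaults σ_logmag = 0.05,
σ_phase = 3° — a realistic in-vivo repeat-measurement scatter of roughly
±12 % in magnitude. The median absolute log10-magnitude deviation is
0.6745·σ_logmag (half-normal), which the tests check against simulation.
All randomness flows from a single integer seed through one
`numpy.random.Generator`.

Simulating at class-mean parameters is an idealisation: real channels
scatter around the means and real spectra carry structured (not
independent per-frequency) noise, so classification-agreement and
benchmark numbers on synthetic cohorts characterise the pipeline's
self-consistency, not expected performance on measured data.

## SVM benchmark

Feature rows are per (spectrum, frequency): log10 f, log10 |Z|, phase,
channel number, session ordinal, labelled with the spectrum's category.
The classifier is an RBF-kernel SVC ("fine Gaussian": kernel scale
s = √P/4 with P = 5 predictors, i.e. K = exp(−‖x−y‖²/s²) on standardized
features; gamma = 1/s²), one-vs-one multiclass, C = 1, no hyperparameter
search — the benchmark gauges the categorisation, it does not chase
accuracy. Folds are stratified by label and seeded; the fold assignment is
a partition, so the pooled confusion matrix rows sum to the per-class
counts and overall accuracy = trace/total exactly. Row-level stratification
is the default; because noiseless rows repeat across channels, grouped
folds (by array/channel) would be the stricter leakage control and can be
obtained by pre-splitting the feature table. The SMO convergence tolerance
is 10⁻² (looser than the sklearn default): on this near-separable problem
the decision boundary is insensitive to it and the runtime is not. A
single-class input returns a degenerate accuracy-1.0 report with a
warning.

## Known limitations

- No Warburg/diffusion element, no inductive artifacts, no
  electrode-area microstructure: the circuit vocabulary is R_S, R_E, CPE,
  R_p, C_d.
- The extended (shunt/dielectric) model is forward-only; fitting always
  uses the plain Randles form, as the roll-off exclusion window makes the
  extra elements unidentifiable from ≤ 10 kHz data.
- Inferential statistics (ANOVA, Kruskal–Wallis, Wilcoxon with
  Holm–Bonferroni) are deliberately out of scope; users can run them with
  standard statistics packages on the exported tables.
- Threshold values are configuration, but no automatic threshold
  learning is provided.
- The binary instrument format is not read, only its text export.
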