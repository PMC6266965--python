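"""Rule-based classification of impedance spectra into degradation categories.

Each spectrum is reduced to a handful of band statistics of the magnitude
and phase and then assigned one of four categories:

hockey-stick
    The signature of an intact low-impedance (iridium-oxide-type) tip:
    magnitude steep at low frequency, flattening to the access-resistance
    plateau at high frequency; phase highly negative at low frequency and
    rising toward zero.
ski-slope
    Magnitude flat (resistive plateau) at low frequency and falling
    capacitively at high frequency — a parasitic leakage path through
    damaged encapsulation or a broken lead.
mixed
    The default category: monotonic magnitude with multiple small phase
    inflections, typical of platinum tips and aged iridium oxide.
outlier
    Very high low-frequency magnitude, an open-circuit-like failure
    isolated from the electrolyte.

All thresholds are configurable; the defaults are the published decision
rules.  The evaluation order is OUTLIER, then (iridium oxide only)
HOCKEY_STICK, then SKI_SLOPE, with MIXED as the fall-through; every
comparison is strict.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Tuple

import numpy as np

from .spectra import ArrayType, CohortDataset, ImpedanceSpectrum

__all__ = [
    "Category",
    "Provenance",
    "CategoryLabel",
    "SpectrumFeatures",
    "ClassifierThresholds",
    "ClassificationError",
    "CohortClassification",
    "OverrideResult",
    "extract_features",
    "classify_spectrum",
    "classify_cohort",
    "apply_overrides",
    "labels_to_frame",
]


class Category(str, enum.Enum):
    HOCKEY_STICK = "hockey-stick"
    SKI_SLOPE = "ski-slope"
    MIXED = "mixed"
    OUTLIER = "outlier"


class Provenance(str, enum.Enum):
    AUTO = "auto"
    MANUAL = "manual"


@dataclass(frozen=True)
class CategoryLabel:
    category: Category
    provenance: Provenance = Provenance.AUTO
    note: str = ""


@dataclass(frozen=True)
class SpectrumFeatures:
    """Band statistics the decision rules test.

    Band conventions: "<100 Hz", ">10 kHz" and ">50 kHz" are strict;
    "100 Hz - 50 kHz" and "100 Hz - 10 kHz" are closed intervals.
    ``max_abs_dphase`` is the largest absolute phase difference between
    successive grid frequencies (the discrete phase slope).  A feature whose
    band contains no grid point is NaN (unavailable).
    """

    mean_zmag_lt100: float
    mean_phase_lt100: float
    max_phase_100_50k: float
    max_phase_100_10k: float
    mean_phase_gt10k: float
    mean_phase_gt50k: float
    max_abs_dphase: float


class ClassificationError(ValueError):
    """A rule needed a band statistic that the spectrum cannot provide."""


@dataclass(frozen=True)
class ClassifierThresholds:
    """Decision thresholds, defaulting to the published rules.

    Hockey-stick (iridium oxide only) requires all of:
      (1) mean(|Z| < 100 Hz)  <  ``hs_zmag_max``            [8e6 ohm]
      (2) ``hs_phase_low_lo`` < mean(phase < 100 Hz) < ``hs_phase_low_hi``
                                                            [-80, -40 deg]
      (3) max(phase, 100 Hz - 50 kHz) > ``hs_phase_max_min`` [-30 deg]
      (4) |max(phase, 100 Hz - 10 kHz) - mean(phase < 100 Hz)|
                                        > ``hs_transition_min`` [25 deg]
    Ski-slope requires mean(phase > 10 kHz) < ``ss_phase_hf`` [-80 deg],
    or all of: mean(phase < 100 Hz) > ``ss_phase_low_min`` [-35 deg],
    mean(phase > 50 kHz) < ``ss_phase_50k_max`` [-70 deg] and
    max|dphase| > ``ss_dphase_min`` [25 deg].
    Outliers: mean(|Z| < 100 Hz) above ``outlier_zmag_pt`` [1e8 ohm] for
    platinum, ``outlier_zmag_irox`` [2e9 ohm] for iridium oxide.
    """

    hs_zmag_max: float = 8e6
    hs_phase_low_lo: float = -80.0
    hs_phase_low_hi: float = -40.0
    hs_phase_max_min: float = -30.0
    hs_transition_min: float = 25.0
    ss_phase_hf: float = -80.0
    ss_phase_low_min: float = -35.0
    ss_phase_50k_max: float = -70.0
    ss_dphase_min: float = 25.0
    outlier_zmag_irox: float = 2e9
    outlier_zmag_pt: float = 1e8


DEFAULT_THRESHOLDS = ClassifierThresholds()


def extract_features(s: ImpedanceSpectrum) -> SpectrumFeatures:
    """Compute the band statistics of one spectrum.

    Band means are arithmetic means over the grid points satisfying the
    band predicate; band maxima likewise.  Bands with no grid point yield
    NaN and the dependent rule will raise when evaluated.
    """
    f = s.frequencies
    if f.size == 0:
        raise ValueError("empty spectrum")
    phase = s.phase
    zmag = s.zmag

    def band_mean(values: np.ndarray, mask: np.ndarray) -> float:
        return float(values[mask].mean()) if mask.any() else math.nan

    def band_max(values: np.ndarray, mask: np.ndarray) -> float:
        return float(values[mask].max()) if mask.any() else math.nan

    lt100 = f < 100.0
    b_100_50k = (f >= 100.0) & (f <= 50_000.0)
    b_100_10k = (f >= 100.0) & (f <= 10_000.0)
    gt10k = f > 10_000.0
    gt50k = f > 50_000.0

    max_abs_dphase = float(np.abs(np.diff(phase)).max()) if f.size > 1 else 0.0

    return SpectrumFeatures(
        mean_zmag_lt100=band_mean(zmag, lt100),
        mean_phase_lt100=band_mean(phase, lt100),
        max_phase_100_50k=band_max(phase, b_100_50k),
        max_phase_100_10k=band_max(phase, b_100_10k),
        mean_phase_gt10k=band_mean(phase, gt10k),
        mean_phase_gt50k=band_mean(phase, gt50k),
        max_abs_dphase=max_abs_dphase,
    )


def _require(value: float, band: str) -> float:
    if math.isnan(value):
        raise ClassificationError(f"no grid frequencies in band {band}")
    return value


def classify_spectrum(
    features: SpectrumFeatures,
    array_type: ArrayType,
    thresholds: ClassifierThresholds = DEFAULT_THRESHOLDS,
) -> CategoryLabel:
    """Apply the decision rules to one feature vector.

    Evaluation order: OUTLIER first (its magnitude gate dominates both
    shape rules), then HOCKEY_STICK for iridium oxide arrays, then
    SKI_SLOPE, else MIXED.  Hockey-stick is never assigned to platinum
    arrays; ski-slope labels on platinum arrays are marked low-confidence
    because that rule was only ever calibrated on iridium oxide spectra.
    """
    array_type = ArrayType(array_type)
    t = thresholds

    gate = t.outlier_zmag_irox if array_type is ArrayType.IROX else t.outlier_zmag_pt
    if _require(features.mean_zmag_lt100, "<100 Hz") > gate:
        return CategoryLabel(Category.OUTLIER)

    if array_type is ArrayType.IROX:
        mean_phase_low = _require(features.mean_phase_lt100, "<100 Hz")
        if (
            features.mean_zmag_lt100 < t.hs_zmag_max
            and t.hs_phase_low_lo < mean_phase_low < t.hs_phase_low_hi
            and _require(features.max_phase_100_50k, "100 Hz-50 kHz") > t.hs_phase_max_min
            and abs(
                _require(features.max_phase_100_10k, "100 Hz-10 kHz") - mean_phase_low
            )
            > t.hs_transition_min
        ):
            return CategoryLabel(Category.HOCKEY_STICK)

    if _require(features.mean_phase_gt10k, ">10 kHz") < t.ss_phase_hf or (
        _require(features.mean_phase_lt100, "<100 Hz") > t.ss_phase_low_min
        and _require(features.mean_phase_gt50k, ">50 kHz") < t.ss_phase_50k_max
        and features.max_abs_dphase > t.ss_dphase_min
    ):
        note = (
            "low-confidence: ski-slope rule calibrated on iridium oxide"
            if array_type is ArrayType.PT
            else ""
        )
        return CategoryLabel(Category.SKI_SLOPE, note=note)

    return CategoryLabel(Category.MIXED)


@dataclass
class CohortClassification:
    """Per-spectrum labels plus any per-spectrum failures, never aborting."""

    labels: Dict[tuple, CategoryLabel] = field(default_factory=dict)
    errors: Dict[tuple, str] = field(default_factory=dict)

    def categories(self) -> Dict[tuple, Category]:
        return {k: v.category for k, v in self.labels.items()}


def classify_cohort(
    cohort: CohortDataset,
    thresholds: ClassifierThresholds = DEFAULT_THRESHOLDS,
) -> CohortClassification:
    """Classify every spectrum of a cohort; errors are collected, not raised."""
    result = CohortClassification()
    for key in sorted(cohort.spectra, key=lambda k: (k[0], k[1], k[2])):
        spectrum = cohort.spectra[key]
        try:
            features = extract_features(spectrum)
            result.labels[key] = classify_spectrum(
                features, spectrum.meta.array_type, thresholds
            )
        except (ClassificationError, ValueError) as exc:
            result.errors[key] = str(exc)
    return result


@dataclass(frozen=True)
class OverrideResult:
    labels: Dict[tuple, CategoryLabel]
    override_fraction: float


def apply_overrides(
    labels: Mapping[tuple, CategoryLabel],
    ledger: Iterable[Tuple[tuple, Category, str]],
) -> OverrideResult:
    """Apply manual corrections from a (key, category, note) ledger.

    Mirrors the supervised-correction workflow in which a reviewer inspects
    each automatic label and overrides the rare mistakes; overridden entries
    carry MANUAL provenance and the returned object reports the fraction of
    labels changed.
    """
    out = dict(labels)
    n_overridden = 0
    for key, category, note in ledger:
        if key not in out:
            raise ValueError(f"override for unknown key: {key}")
        out[key] = CategoryLabel(
            Category(category), provenance=Provenance.MANUAL, note=note
        )
        n_overridden += 1
    fraction = n_overridden / len(out) if out else 0.0
    return OverrideResult(labels=out, override_fraction=fraction)


def labels_to_frame(labels: Mapping[tuple, CategoryLabel]):
    """Labels as a tidy DataFrame (array_id, channel, session, category, ...)."""
    import pandas as pd

    rows = [
        {
            "array_id": key[0],
            "channel": key[1],
            "session": key[2].label(),
            "category": lab.category.value,
            "provenance": lab.provenance.value,
            "note": lab.note,
        }
        for key, lab in sorted(labels.items(), key=lambda kv: (kv[0][0], kv[0][1], kv[0][2]))
    ]
    return pd.DataFrame(rows, columns=["array_id", "channel", "session", "category", "provenance", "note"])
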