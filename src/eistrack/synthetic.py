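"""Synthetic labelled cohorts with the structure of a chronic-implant study.

Every other module in this package is testable without measured data via
this simulator.  It provides:

* an *archetype library*: one equivalent-circuit parameter set per
  (array type, category, condition) combination with published fitted
  means, extended where necessary with the parasitic-shunt / dielectric
  pathways so that the noiseless simulation of each archetype satisfies
  its own category's decision rule (label closure);
* a measurement noise model (log-normal on magnitude, additive Gaussian
  on phase — the simplest law preserving |Z| > 0);
* scripted longitudinal category transitions, including the whole-array
  ski-slope switches and failures observed before device loss, encoded as
  per-array session scripts;
* a cohort generator whose default configuration mirrors the study
  design: 5 iridium-oxide and 6 platinum 16-channel arrays measured in
  vitro, ~1 h post-op and weekly from week 2 to week 12, with ground-truth
  labels attached.

Archetype provenance: the four Randles fields come from the published
fitted means for the matching row, except where noted in
``chosen_elements`` — the shunt/dielectric elements are never published
quantitatively and are chosen here, and the outlier rows' CPE magnitude Q
is chosen (see docs/methods.md: the published fitted means for outliers
are means of strongly skewed per-channel fits and do not themselves
reproduce the outlier magnitude gate).

CPE unit convention: this package evaluates Z_CPE = 1/(Q*(j*w)^n) with w
in rad/s, but the published fitted Q means follow the per-Hz convention
of the original fitting tool — only under that reading do the
hockey-stick means reproduce the hockey-stick phase signature and the
~1 kHz phase peak.  The library therefore stores
``Q = Q_printed / (2*pi)**n``, which leaves the spectra (and the
convention-invariant n, R_E, R_S) exactly as printed.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .circuit import ExtendedParams, RandlesParams, simulate_spectrum
from .classify import Category
from .spectra import (
    ArrayType,
    CohortDataset,
    FrequencyGrid,
    ImpedanceSpectrum,
    SessionKind,
    SessionMeta,
    SessionTime,
    default_grid,
)

__all__ = [
    "Condition",
    "Archetype",
    "NoiseModel",
    "ArrayScript",
    "CohortConfig",
    "archetype_library",
    "get_archetype",
    "apply_noise",
    "simulate_channel_series",
    "simulate_cohort",
    "default_cohort_config",
    "study_sessions",
]


class Condition(str, enum.Enum):
    IN_VITRO = "IN_VITRO"
    IN_VIVO = "IN_VIVO"


@dataclass(frozen=True)
class Archetype:
    """Circuit parameters representative of one (array, category, condition)."""

    array_type: ArrayType
    category: Category
    condition: Condition
    params: ExtendedParams
    chosen_elements: frozenset = frozenset()  # fields not taken from fitted means


def _arch(
    array_type: ArrayType,
    category: Category,
    condition: Condition,
    R_E: float,
    Q: float,
    n: float,
    R_S: float,
    R_p: float = math.inf,
    C_d: float = 0.0,
    chosen: Sequence[str] = (),
) -> Archetype:
    return Archetype(
        array_type=array_type,
        category=category,
        condition=condition,
        params=ExtendedParams(
            base=RandlesParams(R_E=R_E, Q=Q, n=n, R_S=R_S), R_p=R_p, C_d=C_d
        ),
        chosen_elements=frozenset(chosen),
    )


def _q(q_printed: float, n: float) -> float:
    """Printed per-Hz CPE magnitude -> the package's rad/s convention."""
    return q_printed / (2.0 * math.pi) ** n


def archetype_library() -> List[Archetype]:
    """One archetype per fitted-means row with data (10 in total).

    The shunt resistance ``R_p`` and dielectric capacitance ``C_d`` are
    chosen (not published): ski-slope archetypes get R_p = 1e7 ohm and
    C_d = 2e-9 F so the low-frequency plateau and high-frequency phase
    plunge of that morphology appear; the aged-mixed iridium-oxide
    archetype gets a milder R_p = 1e6 ohm shunt, which keeps its phase at
    intermediate values across the spectrum; outlier archetypes carry a
    *chosen* Q (see module docstring) and no shunt — a parallel pathway
    would cap the magnitude below the outlier gate of an open-circuit-like
    failure.  Noiselessly simulated, every archetype classifies as its own
    category.
    """
    IROX, PT = ArrayType.IROX, ArrayType.PT
    HS, SS, MIX, OUT = (
        Category.HOCKEY_STICK,
        Category.SKI_SLOPE,
        Category.MIXED,
        Category.OUTLIER,
    )
    VITRO, VIVO = Condition.IN_VITRO, Condition.IN_VIVO
    return [
        _arch(IROX, HS, VITRO, R_E=2.0e10, Q=_q(22e-8, 0.81), n=0.81, R_S=2.17e3),
        _arch(IROX, HS, VIVO, R_E=6.2e10, Q=_q(30e-8, 0.64), n=0.64, R_S=138e3),
        _arch(
            IROX, SS, VITRO, R_E=2.1e10, Q=_q(7.4e-8, 0.68), n=0.68, R_S=156e3,
            R_p=1e7, C_d=2e-9, chosen=("R_p", "C_d"),
        ),
        _arch(
            IROX, SS, VIVO, R_E=1.0e10, Q=_q(1.1e-8, 0.85), n=0.85, R_S=76e3,
            R_p=1e7, C_d=2e-9, chosen=("R_p", "C_d"),
        ),
        _arch(IROX, MIX, VITRO, R_E=4.5e10, Q=_q(43e-8, 0.75), n=0.75, R_S=0.15e3),
        _arch(
            IROX, MIX, VIVO, R_E=3.0e10, Q=_q(11e-8, 0.61), n=0.61, R_S=59e3,
            R_p=1e6, chosen=("R_p",),
        ),
        _arch(
            IROX, OUT, VIVO, R_E=6.8e10, Q=2e-11, n=0.89, R_S=416e3,
            chosen=("Q",),
        ),
        _arch(PT, MIX, VITRO, R_E=0.46e10, Q=_q(0.72e-8, 0.74), n=0.74, R_S=7.3e3),
        _arch(PT, MIX, VIVO, R_E=5.0e10, Q=_q(11e-8, 0.55), n=0.55, R_S=25e3),
        _arch(
            PT, OUT, VIVO, R_E=1.1e10, Q=3e-10, n=0.96, R_S=93e3,
            C_d=2e-11, chosen=("Q", "C_d"),
        ),
    ]


_LIBRARY_INDEX: Optional[Dict[tuple, Archetype]] = None


def get_archetype(
    array_type: ArrayType, category: Category, condition: Condition
) -> Archetype:
    """Look up an archetype; falls back to IN_VIVO when no IN_VITRO row exists."""
    global _LIBRARY_INDEX
    if _LIBRARY_INDEX is None:
        _LIBRARY_INDEX = {
            (a.array_type, a.category, a.condition): a for a in archetype_library()
        }
    key = (ArrayType(array_type), Category(category), Condition(condition))
    if key not in _LIBRARY_INDEX:
        fallback = (key[0], key[1], Condition.IN_VIVO)
        if fallback in _LIBRARY_INDEX:
            return _LIBRARY_INDEX[fallback]
        raise KeyError(f"no archetype for {key}")
    return _LIBRARY_INDEX[key]


# ---------------------------------------------------------------------------
# noise model


@dataclass(frozen=True)
class NoiseModel:
    """Measurement noise: multiplicative log-normal on |Z|, Gaussian on phase.

    ``sigma_logmag`` is the standard deviation of the log10-magnitude
    perturbation (|Z| -> |Z| * 10**eps with eps ~ N(0, sigma_logmag)), so
    the median absolute log10 deviation is 0.6745 * sigma_logmag.
    ``sigma_phase`` is in degrees.  Magnitude and phase noise are
    independent.
    """

    sigma_logmag: float = 0.05
    sigma_phase: float = 3.0

    def __post_init__(self) -> None:
        if self.sigma_logmag < 0 or self.sigma_phase < 0:
            raise ValueError("noise standard deviations must be >= 0")

    @property
    def is_noiseless(self) -> bool:
        return self.sigma_logmag == 0.0 and self.sigma_phase == 0.0


NOISELESS = NoiseModel(0.0, 0.0)


def apply_noise(
    spectrum: ImpedanceSpectrum, noise: NoiseModel, rng: np.random.Generator
) -> ImpedanceSpectrum:
    if noise.is_noiseless:
        return spectrum
    n = len(spectrum)
    zmag = spectrum.zmag * 10.0 ** rng.normal(0.0, noise.sigma_logmag, n)
    phase = np.clip(spectrum.phase + rng.normal(0.0, noise.sigma_phase, n), -180.0, 180.0)
    return ImpedanceSpectrum(
        grid=spectrum.grid, zmag=zmag, phase=phase, meta=spectrum.meta
    )


# ---------------------------------------------------------------------------
# trajectory scripts


@dataclass(frozen=True)
class ArrayScript:
    """Per-array longitudinal script: which category each channel is in at
    each measured session.  Sessions absent from ``assignments`` are
    unmeasured (whole-array failure once measurements stop)."""

    array_id: str
    array_type: ArrayType
    assignments: Mapping[SessionTime, Tuple[Category, ...]]
    n_channels: int = 16

    def __post_init__(self) -> None:
        for session, cats in self.assignments.items():
            if len(cats) != self.n_channels:
                raise ValueError(
                    f"{self.array_id} {session.label()}: expected "
                    f"{self.n_channels} per-channel categories, got {len(cats)}"
                )

    def sessions(self) -> List[SessionTime]:
        return sorted(self.assignments)


@dataclass(frozen=True)
class CohortConfig:
    arrays: Tuple[ArrayScript, ...]
    noise: NoiseModel = NoiseModel()
    grid: FrequencyGrid = field(default_factory=default_grid)


def _condition_for(session: SessionTime) -> Condition:
    return (
        Condition.IN_VITRO
        if session.kind is SessionKind.IN_VITRO
        else Condition.IN_VIVO
    )


def simulate_channel_series(
    assignments: Sequence[Tuple[SessionTime, Archetype]],
    noise: NoiseModel,
    grid: FrequencyGrid,
    array_id: str,
    channel: int,
    array_type: ArrayType,
    rng: np.random.Generator,
) -> List[ImpedanceSpectrum]:
    """Simulate one channel across its measured sessions."""
    out = []
    for session, archetype in assignments:
        meta = SessionMeta(
            array_id=array_id, channel=channel, array_type=array_type, session=session
        )
        spectrum = simulate_spectrum(archetype.params, grid, meta)
        out.append(apply_noise(spectrum, noise, rng))
    return out


def simulate_cohort(config: CohortConfig, seed: int = 0) -> CohortDataset:
    """Generate a labelled cohort; deterministic for a fixed seed."""
    rng = np.random.default_rng(seed)
    cohort = CohortDataset()
    for script in sorted(config.arrays, key=lambda a: a.array_id):
        for channel in range(1, script.n_channels + 1):
            assignments = []
            for session in script.sessions():
                category = script.assignments[session][channel - 1]
                archetype = get_archetype(
                    script.array_type, category, _condition_for(session)
                )
                assignments.append((session, archetype))
            spectra = simulate_channel_series(
                assignments,
                config.noise,
                config.grid,
                script.array_id,
                channel,
                script.array_type,
                rng,
            )
            for (session, _), spectrum in zip(assignments, spectra):
                truth = script.assignments[session][channel - 1]
                cohort.add(spectrum, truth=truth.value)
    return cohort


# ---------------------------------------------------------------------------
# the default study-shaped cohort


def study_sessions(last_week: int = 12) -> List[SessionTime]:
    """In-vitro baseline, ~1 h post-op, then weekly from week 2."""
    return [SessionTime.in_vitro(), SessionTime.post_op()] + [
        SessionTime.week_(w) for w in range(2, last_week + 1)
    ]


def _fill(mapping: Mapping[int, Category], default: Category) -> Tuple[Category, ...]:
    """16 per-channel categories: ``default`` except channels in ``mapping``."""
    return tuple(mapping.get(ch, default) for ch in range(1, 17))


def default_cohort_config(noise: NoiseModel = NoiseModel()) -> CohortConfig:
    """The study-shaped default: 5 IrOx + 6 Pt arrays, 16 channels each,
    in-vitro + 1 h + weeks 2-12, with scripted failures.

    The scripts encode the reported longitudinal anecdotes: an IrOx array
    whose channels are hockey-stick until a global week-8 switch to
    ski-slope followed by failure; an IrOx array whose hockey-stick
    channels all become mixed at week 3 and fail after week 9; a more
    variable IrOx array measured through week 10; platinum arrays that are
    predominantly mixed, two of which turn globally to outliers at week 8;
    no outliers occur in vitro.
    """
    HS, SS, MIX, OUT = (
        Category.HOCKEY_STICK,
        Category.SKI_SLOPE,
        Category.MIXED,
        Category.OUTLIER,
    )
    vitro, postop = SessionTime.in_vitro(), SessionTime.post_op()
    week = SessionTime.week_

    def span(first: int, last: int) -> List[SessionTime]:
        return [week(w) for w in range(first, last + 1)]

    arrays: List[ArrayScript] = []

    # IrOx 1: 15/16 hockey-stick pre-implant; one outlier at implantation;
    # global ski-slope switch at week 8, unmeasured afterwards.
    a = {vitro: _fill({16: MIX}, HS)}
    for s in [postop] + span(2, 7):
        a[s] = _fill({15: OUT, 16: MIX}, HS)
    a[week(8)] = _fill({}, SS)
    arrays.append(ArrayScript("irox01", ArrayType.IROX, a))

    # IrOx 2: hockey-stick at 1 h, all 15 switch to mixed at week 3,
    # mixed until failure after week 9.
    a = {s: _fill({16: MIX}, HS) for s in [vitro, postop, week(2)]}
    for s in span(3, 9):
        a[s] = _fill({}, MIX)
    arrays.append(ArrayScript("irox02", ArrayType.IROX, a))

    # IrOx 3: variable; measured through week 10 (the last measured week).
    a = {vitro: _fill({}, HS), postop: _fill({}, HS)}
    for s in span(2, 4):
        a[s] = _fill({15: MIX, 16: MIX}, HS)
    for s in span(5, 9):
        a[s] = _fill({9: MIX, 10: MIX, 11: MIX, 12: MIX, 13: MIX, 14: OUT, 15: OUT, 16: OUT}, HS)
    a[week(10)] = _fill({}, HS)
    arrays.append(ArrayScript("irox03", ArrayType.IROX, a))

    # IrOx 4: varied categories from the start; fails after week 8.
    a = {}
    varied = _fill({7: MIX, 8: MIX, 9: MIX, 10: MIX, 11: MIX, 12: MIX,
                    13: SS, 14: SS, 15: SS, 16: SS}, HS)
    for s in [vitro, postop] + span(2, 4):
        a[s] = varied
    aged = _fill({4: MIX, 5: MIX, 6: MIX, 7: MIX, 8: MIX, 9: MIX, 10: MIX,
                  11: MIX, 12: MIX, 13: SS, 14: SS, 15: SS, 16: SS}, HS)
    for s in span(5, 8):
        a[s] = aged
    arrays.append(ArrayScript("irox04", ArrayType.IROX, a))

    # IrOx 5: varied, ages toward mixed with late outliers; fails after week 9.
    a = {}
    early = _fill({9: MIX, 10: MIX, 11: MIX, 12: MIX, 13: MIX, 14: MIX,
                   15: SS, 16: SS}, HS)
    for s in [vitro, postop] + span(2, 5):
        a[s] = early
    late = _fill({3: MIX, 4: MIX, 5: MIX, 6: MIX, 7: MIX, 8: MIX, 9: MIX,
                  10: MIX, 11: MIX, 12: MIX, 13: OUT, 14: OUT, 15: SS, 16: SS}, HS)
    for s in span(6, 9):
        a[s] = late
    arrays.append(ArrayScript("irox05", ArrayType.IROX, a))

    # Pt 1: all mixed until the global week-8 outlier switch; fails after week 10.
    a = {s: _fill({}, MIX) for s in [vitro, postop] + span(2, 7)}
    for s in span(8, 10):
        a[s] = _fill({}, OUT)
    arrays.append(ArrayScript("pt01", ArrayType.PT, a))

    # Pt 2: one channel an outlier from implantation; global outliers at week 8.
    a = {vitro: _fill({}, MIX)}
    for s in [postop] + span(2, 7):
        a[s] = _fill({16: OUT}, MIX)
    for s in span(8, 9):
        a[s] = _fill({}, OUT)
    arrays.append(ArrayScript("pt02", ArrayType.PT, a))

    # Pt 3 and 4: stable mixed for the full 12 weeks.
    a = {s: _fill({}, MIX) for s in study_sessions(12)}
    arrays.append(ArrayScript("pt03", ArrayType.PT, a))
    a = {vitro: _fill({}, MIX)}
    for s in [postop] + span(2, 12):
        a[s] = _fill({16: OUT}, MIX)
    arrays.append(ArrayScript("pt04", ArrayType.PT, a))

    # Pt 5: mixed with a late cluster of outliers.
    a = {s: _fill({}, MIX) for s in [vitro, postop] + span(2, 7)}
    for s in span(8, 12):
        a[s] = _fill({13: OUT, 14: OUT, 15: OUT, 16: OUT}, MIX)
    arrays.append(ArrayScript("pt05", ArrayType.PT, a))

    # Pt 6: mixed, half the channels failing at week 11.
    a = {s: _fill({}, MIX) for s in [vitro, postop] + span(2, 10)}
    for s in span(11, 12):
        a[s] = _fill({ch: OUT for ch in range(9, 17)}, MIX)
    arrays.append(ArrayScript("pt06", ArrayType.PT, a))

    return CohortConfig(arrays=tuple(arrays), noise=noise)
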