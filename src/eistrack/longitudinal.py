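"""Longitudinal failure-mode analytics for classified impedance cohorts.

Covers the study-level summaries that follow classification and fitting:
the 1 kHz impedance trajectory of each channel, the phase-peak frequency
``f_peak`` (which shifts to lower frequency as the access resistance
grows), category population tables over sessions (with an UNMEASURED
column for channels of failed arrays), group-wise mean/SEM aggregation
(reported only when more than three channels are present in a group at a
time point), and the area/unit conversion helpers used to compare CPE
parameters across electrode geometries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .classify import Category, CategoryLabel
from .spectra import CohortDataset, ImpedanceSpectrum, SessionTime

__all__ = [
    "ChannelTrajectory",
    "impedance_at_1khz",
    "f_peak",
    "channel_trajectories",
    "population_table",
    "aggregate_metric",
    "scale_areal_admittance",
    "scale_access_resistance",
    "convert_q_units",
]

UNMEASURED = "unmeasured"


def impedance_at_1khz(s: ImpedanceSpectrum) -> float:
    """|Z| at 1 kHz: the exact sample if 1 kHz is on the grid, else log-log
    linear interpolation of the magnitude between the bracketing points.

    Spectra are locally near power-law, so interpolation is linear in
    (log f, log |Z|) space.  A grid that does not bracket 1 kHz raises.
    """
    return _interp_zmag(s, 1000.0)


def _interp_zmag(s: ImpedanceSpectrum, f0: float) -> float:
    f = s.frequencies
    exact = np.isclose(f, f0, rtol=1e-12, atol=0.0)
    if exact.any():
        return float(s.zmag[int(np.argmax(exact))])
    if f[0] > f0 or f[-1] < f0:
        raise ValueError(f"grid [{f[0]:g}, {f[-1]:g}] Hz does not bracket {f0:g} Hz")
    logz = np.interp(math.log10(f0), np.log10(f), np.log10(s.zmag))
    return float(10.0 ** logz)


def f_peak(s: ImpedanceSpectrum) -> float:
    """Grid frequency at which the phase attains its maximum.

    A grid argmax with no sub-grid refinement — the published analysis
    tracks peak shifts across the discrete measured grid.  Ties break
    toward the lowest frequency.
    """
    if len(s) == 0:
        raise ValueError("empty spectrum")
    return float(s.frequencies[int(np.argmax(s.phase))])


@dataclass(frozen=True)
class ChannelTrajectory:
    """Longitudinal record of one channel: per-session label, |Z|(1 kHz), f_peak."""

    array_id: str
    channel: int
    points: Tuple[Tuple[SessionTime, Category, float, Optional[float]], ...]

    def __post_init__(self) -> None:
        sessions = [p[0] for p in self.points]
        if any(b <= a for a, b in zip(sessions, sessions[1:])):
            raise ValueError("trajectory sessions must be strictly increasing")


def channel_trajectories(
    cohort: CohortDataset, labels: Mapping[tuple, CategoryLabel]
) -> List[ChannelTrajectory]:
    """Assemble per-channel trajectories from a cohort and its labels.

    ``f_peak`` is recorded only for hockey-stick spectra (the published
    peak-tracking concerns that category's interior phase maximum); other
    categories carry None.
    """
    by_channel: Dict[tuple, list] = {}
    for key in sorted(cohort.spectra, key=lambda k: (k[0], k[1], k[2])):
        if key not in labels:
            continue
        spectrum = cohort.spectra[key]
        category = labels[key].category
        fp = f_peak(spectrum) if category is Category.HOCKEY_STICK else None
        by_channel.setdefault((key[0], key[1]), []).append(
            (key[2], category, impedance_at_1khz(spectrum), fp)
        )
    return [
        ChannelTrajectory(array_id=arr, channel=ch, points=tuple(points))
        for (arr, ch), points in sorted(by_channel.items())
    ]


def population_table(
    labels: Mapping[tuple, CategoryLabel],
    roster: Iterable[Tuple[str, int]],
    sessions: Sequence[SessionTime],
) -> pd.DataFrame:
    """Category counts per session, with unmeasured channels accounted for.

    ``roster`` lists every (array_id, channel) of the cohort; a roster
    channel with no label at a session (e.g. after whole-array failure)
    is counted in the UNMEASURED column, so each session's counts sum to
    the roster size.
    """
    roster = sorted(set(roster))
    columns = [c.value for c in Category] + [UNMEASURED]
    table = pd.DataFrame(
        0, index=[s.label() for s in sessions], columns=columns, dtype=int
    )
    for session in sessions:
        for arr, ch in roster:
            label = labels.get((arr, ch, session))
            col = label.category.value if label is not None else UNMEASURED
            table.loc[session.label(), col] += 1
    assert (table.sum(axis=1) == len(roster)).all(), "population not conserved"
    return table


MIN_GROUP_SIZE = 4  # mean/SEM reported only for more than three channels


def aggregate_metric(values: pd.DataFrame) -> pd.DataFrame:
    """Mean/SEM of a metric per (category, session) group.

    ``values`` needs columns ``category``, ``session`` and ``value`` (one
    row per channel).  Groups with three or fewer values report only their
    count — small groups would yield unstable error bars, matching the
    published aggregation rule.  SEM is sd/sqrt(count) with the sample
    standard deviation (ddof=1).
    """
    required = {"category", "session", "value"}
    if not required.issubset(values.columns):
        raise ValueError(f"values must have columns {sorted(required)}")
    rows = []
    for (category, session), group in values.groupby(
        ["category", "session"], sort=True
    ):
        v = group["value"].to_numpy(dtype=float)
        count = v.size
        if count >= MIN_GROUP_SIZE:
            mean = float(v.mean())
            sem = float(v.std(ddof=1) / math.sqrt(count))
        else:
            mean = math.nan
            sem = math.nan
        rows.append(
            {"category": category, "session": session, "count": count, "mean": mean, "sem": sem}
        )
    return pd.DataFrame(rows, columns=["category", "session", "count", "mean", "sem"])


# ---------------------------------------------------------------------------
# area / unit conversion helpers

UM2_PER_MM2 = 1.0e6


def scale_areal_admittance(q_areal: float, area_um2: float) -> float:
    """Convert an areal CPE admittance (S*s^n per mm^2) to an absolute one.

    ``q_areal * area`` with the electrode area given in um^2 (e.g. a
    4000 um^2 microelectrode tip).
    """
    if q_areal <= 0 or area_um2 <= 0:
        raise ValueError("inputs must be positive")
    return q_areal * (area_um2 / UM2_PER_MM2)


def scale_access_resistance(r: float, area_ref_um2: float, area_new_um2: float) -> float:
    """Rescale an access resistance between electrode areas.

    R_S varies inversely with geometric surface area, so a value reported
    for a reference area is divided by the ratio of the new to the
    reference area.
    """
    if r <= 0 or area_ref_um2 <= 0 or area_new_um2 <= 0:
        raise ValueError("inputs must be positive")
    return r / (area_new_um2 / area_ref_um2)


def convert_q_units(q_alt: float, n: float) -> float:
    """Convert a CPE magnitude reported in s*ohm^(-1/n) units to S*s^n.

    Raising to the power ``n`` maps between the two common CPE unit
    conventions.
    """
    if q_alt <= 0:
        raise ValueError("q_alt must be positive")
    if not 0.0 < n <= 1.0:
        raise ValueError("n must be in (0, 1]")
    return q_alt**n
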