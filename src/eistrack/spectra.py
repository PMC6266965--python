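"""Domain types and file I/O for electrode impedance spectra.

A *spectrum* is one broadband impedance measurement of a single electrode
channel: impedance magnitude |Z| (ohm) and phase (degrees, negative =
capacitive) sampled on a strictly increasing frequency grid.  Spectra are
organised into cohorts keyed by (array_id, channel, session), mirroring a
chronic-implant study in which each 16-channel array is measured in vitro,
~1 h post-op, and then weekly.

Two text formats are supported: a fixed CSV dialect (columns
``frequency_hz, zmag_ohm, zphz_deg``) and a tab-delimited instrument export
containing a ZCURVE table with ``Freq, Zreal, Zimag, Zmod, Zphz`` columns.
"""

from __future__ import annotations

import csv
import enum
import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, TextIO, Union

import numpy as np

__all__ = [
    "FormatError",
    "FrequencyGrid",
    "ArrayType",
    "SessionKind",
    "SessionTime",
    "SessionMeta",
    "ImpedanceSpectrum",
    "CohortDataset",
    "make_frequency_grid",
    "default_grid",
    "to_complex",
    "from_complex",
    "read_spectrum_csv",
    "write_spectrum_csv",
    "read_instrument_dta",
    "write_instrument_dta",
    "read_cohort",
    "write_cohort",
]


class FormatError(ValueError):
    """Raised when an input file violates the documented schema."""


# ---------------------------------------------------------------------------
# frequency grid


@dataclass(frozen=True)
class FrequencyGrid:
    """Strictly increasing, positive measurement frequencies in Hz."""

    values: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 1 or arr.size == 0:
            raise ValueError("frequency grid must be a non-empty 1-D array")
        if np.any(arr <= 0):
            raise ValueError("all grid frequencies must be > 0")
        if np.any(np.diff(arr) <= 0):
            raise ValueError("grid frequencies must be strictly increasing")
        object.__setattr__(self, "values", arr)

    def __len__(self) -> int:
        return int(self.values.size)

    def __iter__(self) -> Iterator[float]:
        return iter(self.values)

    @property
    def fmin(self) -> float:
        return float(self.values[0])

    @property
    def fmax(self) -> float:
        return float(self.values[-1])


def make_frequency_grid(
    points_per_decade: int, fmin: float, fmax: float
) -> FrequencyGrid:
    """Log-uniform grid from ``fmin`` to ``fmax`` inclusive.

    With integer decade spans the grid hits decade frequencies exactly:
    ``make_frequency_grid(5, 1, 1e6)`` has 31 points and contains 1000.0 Hz
    at index 15 with no floating-point error.
    """
    if fmin <= 0 or fmax <= 0:
        raise ValueError("frequency bounds must be positive")
    if fmin >= fmax:
        raise ValueError("fmin must be strictly less than fmax")
    if points_per_decade < 1:
        raise ValueError("points_per_decade must be >= 1")
    span = math.log10(fmax / fmin)
    n_intervals = round(points_per_decade * span)
    if not math.isclose(n_intervals, points_per_decade * span, rel_tol=1e-9):
        raise ValueError(
            "fmax/fmin must span an integer number of grid steps at the "
            "requested points_per_decade"
        )
    exponents = math.log10(fmin) + np.arange(n_intervals + 1) / points_per_decade
    values = 10.0 ** exponents
    # pin the endpoints so round-trips compare exactly
    values[0] = fmin
    values[-1] = fmax
    return FrequencyGrid(values)


def default_grid() -> FrequencyGrid:
    """The study's measurement grid: 31 points, 1 Hz to 1 MHz, 5 per decade."""
    return make_frequency_grid(5, 1.0, 1.0e6)


# ---------------------------------------------------------------------------
# session metadata


class ArrayType(str, enum.Enum):
    """Tip metallization of the array: iridium oxide or platinum."""

    IROX = "IROX"
    PT = "PT"


class SessionKind(str, enum.Enum):
    IN_VITRO = "IN_VITRO"
    POST_OP_1H = "POST_OP_1H"
    WEEK = "WEEK"


@dataclass(frozen=True, order=True)
class SessionTime:
    """A measurement session, ordered IN_VITRO < POST_OP_1H < WEEK 2 < WEEK 3 ...

    The in-vitro baseline and the ~1 h post-op check are categorical
    sessions, not points on a numeric time axis; ordering is by the
    ``sort_index`` computed below.
    """

    sort_index: float = field(init=False, repr=False)
    kind: SessionKind = field(compare=False)
    week: Optional[int] = field(default=None, compare=False)

    def __post_init__(self) -> None:
        kind = SessionKind(self.kind)
        object.__setattr__(self, "kind", kind)
        if kind is SessionKind.WEEK:
            if self.week is None or self.week < 2:
                raise ValueError("weekly sessions start at week 2")
            object.__setattr__(self, "sort_index", float(self.week))
        else:
            if self.week is not None:
                raise ValueError(f"week is only valid for WEEK sessions, not {kind}")
            object.__setattr__(
                self,
                "sort_index",
                -2.0 if kind is SessionKind.IN_VITRO else -1.0,
            )

    @classmethod
    def in_vitro(cls) -> "SessionTime":
        return cls(SessionKind.IN_VITRO)

    @classmethod
    def post_op(cls) -> "SessionTime":
        return cls(SessionKind.POST_OP_1H)

    @classmethod
    def week_(cls, week: int) -> "SessionTime":
        return cls(SessionKind.WEEK, week)

    def label(self) -> str:
        if self.kind is SessionKind.WEEK:
            return f"week{self.week:02d}"
        return {"IN_VITRO": "invitro", "POST_OP_1H": "postop1h"}[self.kind.value]

    @classmethod
    def from_label(cls, label: str) -> "SessionTime":
        if label == "invitro":
            return cls.in_vitro()
        if label == "postop1h":
            return cls.post_op()
        if label.startswith("week"):
            return cls.week_(int(label[4:]))
        raise ValueError(f"unrecognised session label: {label!r}")


@dataclass(frozen=True)
class SessionMeta:
    """Identity of one channel-session measurement."""

    array_id: str
    channel: int
    array_type: ArrayType
    session: SessionTime

    def __post_init__(self) -> None:
        if not 1 <= self.channel <= 16:
            raise ValueError("channel must be in 1..16")
        object.__setattr__(self, "array_type", ArrayType(self.array_type))

    @property
    def key(self) -> tuple:
        return (self.array_id, self.channel, self.session)


# ---------------------------------------------------------------------------
# spectrum


@dataclass(frozen=True)
class ImpedanceSpectrum:
    """|Z| (ohm) and phase (deg) on a frequency grid, with session metadata."""

    grid: FrequencyGrid
    zmag: np.ndarray
    phase: np.ndarray
    meta: SessionMeta

    def __post_init__(self) -> None:
        zmag = np.asarray(self.zmag, dtype=float)
        phase = np.asarray(self.phase, dtype=float)
        n = len(self.grid)
        if zmag.shape != (n,) or phase.shape != (n,):
            raise ValueError("zmag and phase must match the grid length")
        if np.any(zmag <= 0) or not np.all(np.isfinite(zmag)):
            raise ValueError("impedance magnitudes must be finite and > 0")
        if np.any(np.abs(phase) > 180) or not np.all(np.isfinite(phase)):
            raise ValueError("phases must be finite and within [-180, 180] degrees")
        object.__setattr__(self, "zmag", zmag)
        object.__setattr__(self, "phase", phase)

    def __len__(self) -> int:
        return len(self.grid)

    @property
    def frequencies(self) -> np.ndarray:
        return self.grid.values


def to_complex(spectrum: ImpedanceSpectrum) -> np.ndarray:
    """Complex impedance Z = |Z| * exp(j*phase), phase taken in degrees."""
    phi = np.deg2rad(spectrum.phase)
    return spectrum.zmag * (np.cos(phi) + 1j * np.sin(phi))


def from_complex(
    grid: FrequencyGrid, z: np.ndarray, meta: SessionMeta
) -> ImpedanceSpectrum:
    """Inverse of :func:`to_complex`: build a spectrum from complex impedances."""
    z = np.asarray(z, dtype=complex)
    return ImpedanceSpectrum(
        grid=grid,
        zmag=np.abs(z),
        phase=np.rad2deg(np.angle(z)),
        meta=meta,
    )


# ---------------------------------------------------------------------------
# CSV dialect

_CSV_COLUMNS = ("frequency_hz", "zmag_ohm", "zphz_deg")


def read_spectrum_csv(source: Union[TextIO, str, Path], meta: SessionMeta) -> ImpedanceSpectrum:
    """Read one spectrum from the documented CSV dialect.

    Rows may appear in any frequency order; the result is sorted ascending.
    Duplicate frequencies, missing columns and non-numeric cells raise
    :class:`FormatError` naming the offending row.
    """
    close = False
    if isinstance(source, (str, Path)):
        source = open(source, "r", newline="")
        close = True
    try:
        reader = csv.DictReader(source)
        if reader.fieldnames is None:
            raise FormatError("empty CSV: no header row")
        missing = [c for c in _CSV_COLUMNS if c not in reader.fieldnames]
        if missing:
            raise FormatError(f"missing column(s): {', '.join(missing)}")
        rows = []
        for i, row in enumerate(reader, start=2):  # header is line 1
            try:
                rows.append(tuple(float(row[c]) for c in _CSV_COLUMNS))
            except (TypeError, ValueError):
                raise FormatError(f"non-numeric cell at line {i}") from None
        if not rows:
            raise FormatError("CSV contains no data rows")
    finally:
        if close:
            source.close()
    rows.sort(key=lambda r: r[0])
    freqs = np.array([r[0] for r in rows])
    if np.any(np.diff(freqs) == 0):
        dup = freqs[np.where(np.diff(freqs) == 0)[0][0]]
        raise FormatError(f"duplicate frequency {dup} Hz")
    try:
        grid = FrequencyGrid(freqs)
        return ImpedanceSpectrum(
            grid=grid,
            zmag=np.array([r[1] for r in rows]),
            phase=np.array([r[2] for r in rows]),
            meta=meta,
        )
    except ValueError as exc:
        raise FormatError(str(exc)) from None


def write_spectrum_csv(spectrum: ImpedanceSpectrum, dest: Union[TextIO, str, Path]) -> None:
    close = False
    if isinstance(dest, (str, Path)):
        dest = open(dest, "w", newline="")
        close = True
    try:
        writer = csv.writer(dest)
        writer.writerow(_CSV_COLUMNS)
        for f, z, p in zip(spectrum.frequencies, spectrum.zmag, spectrum.phase):
            writer.writerow([repr(float(f)), repr(float(z)), repr(float(p))])
    finally:
        if close:
            dest.close()


# ---------------------------------------------------------------------------
# instrument (DTA-style) export

_ZMOD_TOL = 0.01  # relative disagreement between Zmod and sqrt(Zreal^2+Zimag^2)


def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


def read_instrument_dta(source: Union[TextIO, str, Path], meta: SessionMeta) -> ImpedanceSpectrum:
    """Read a tab-delimited instrument export containing one ZCURVE table.

    Magnitude and phase are taken from the ``Zmod``/``Zphz`` columns when
    present, else computed from ``Zreal``/``Zimag``.  If Zmod disagrees with
    sqrt(Zreal^2 + Zimag^2) by more than 1 % a warning is emitted and the
    magnitude is recomputed from the rectangular components.
    """
    close = False
    if isinstance(source, (str, Path)):
        source = open(source, "r")
        close = True
    try:
        lines = source.read().splitlines()
    finally:
        if close:
            source.close()

    start = None
    for i, line in enumerate(lines):
        if line.split("\t")[0].strip().upper() == "ZCURVE":
            start = i
            break
    if start is None:
        raise FormatError("no ZCURVE table found")

    # header row: first following line containing a Freq column
    header = None
    idx = start + 1
    while idx < len(lines):
        fields = [f.strip() for f in lines[idx].split("\t")]
        if any(f.lower() == "freq" for f in fields):
            header = fields
            idx += 1
            break
        idx += 1
    if header is None:
        raise FormatError("ZCURVE table has no header row with a Freq column")

    cols = {name.lower(): j for j, name in enumerate(header) if name}

    def col(name: str) -> Optional[int]:
        return cols.get(name.lower())

    # optional units row: skip if its Freq cell is not numeric
    if idx < len(lines):
        fields = lines[idx].split("\t")
        j = col("freq")
        if j is not None and (j >= len(fields) or not _is_number(fields[j].strip())):
            idx += 1

    rows = []
    for line in lines[idx:]:
        if not line.strip():
            break
        fields = line.split("\t")
        j = col("freq")
        if j is None or j >= len(fields) or not _is_number(fields[j].strip()):
            break

        def get(name: str) -> Optional[float]:
            k = col(name)
            if k is None or k >= len(fields):
                return None
            token = fields[k].strip()
            return float(token) if _is_number(token) else None

        rows.append(
            {
                "freq": get("freq"),
                "zreal": get("zreal"),
                "zimag": get("zimag"),
                "zmod": get("zmod"),
                "zphz": get("zphz"),
            }
        )
    if not rows:
        raise FormatError("ZCURVE table contains no data rows")

    freqs, zmags, phases = [], [], []
    for i, r in enumerate(rows):
        if r["freq"] is None:
            raise FormatError(f"ZCURVE row {i}: missing Freq")
        zr, zi = r["zreal"], r["zimag"]
        zmod, zphz = r["zmod"], r["zphz"]
        if zmod is None or zphz is None:
            if zr is None or zi is None:
                raise FormatError(
                    f"ZCURVE row {i}: needs Zmod/Zphz or Zreal/Zimag"
                )
            zmod = math.hypot(zr, zi)
            zphz = math.degrees(math.atan2(zi, zr))
        elif zr is not None and zi is not None:
            rect = math.hypot(zr, zi)
            if zmod > 0 and abs(rect - zmod) / zmod > _ZMOD_TOL:
                warnings.warn(
                    f"ZCURVE row {i}: Zmod={zmod:g} inconsistent with "
                    f"sqrt(Zreal^2+Zimag^2)={rect:g}; magnitude recomputed",
                    stacklevel=2,
                )
                zmod = rect
                zphz = math.degrees(math.atan2(zi, zr))
        freqs.append(r["freq"])
        zmags.append(zmod)
        phases.append(zphz)

    order = np.argsort(freqs)
    try:
        grid = FrequencyGrid(np.asarray(freqs)[order])
        return ImpedanceSpectrum(
            grid=grid,
            zmag=np.asarray(zmags)[order],
            phase=np.asarray(phases)[order],
            meta=meta,
        )
    except ValueError as exc:
        raise FormatError(str(exc)) from None


def write_instrument_dta(spectrum: ImpedanceSpectrum, dest: Union[TextIO, str, Path]) -> None:
    """Write the instrument-export dialect (single ZCURVE table)."""
    close = False
    if isinstance(dest, (str, Path)):
        dest = open(dest, "w", newline="")
        close = True
    try:
        z = to_complex(spectrum)
        dest.write("EXPLAIN\n")
        dest.write("TAG\tEISPOT\n")
        dest.write(f"ZCURVE\tTABLE\t{len(spectrum)}\n")
        dest.write("\tPt\tFreq\tZreal\tZimag\tZmod\tZphz\n")
        dest.write("\t#\tHz\tohm\tohm\tohm\t°\n")
        for i, (f, zi, m, p) in enumerate(
            zip(spectrum.frequencies, z, spectrum.zmag, spectrum.phase)
        ):
            dest.write(
                "\t%d\t%s\t%s\t%s\t%s\t%s\n"
                % (i, repr(float(f)), repr(zi.real), repr(zi.imag), repr(float(m)), repr(float(p)))
            )
    finally:
        if close:
            dest.close()


# ---------------------------------------------------------------------------
# cohort container


@dataclass
class CohortDataset:
    """All spectra of a study, keyed by (array_id, channel, session).

    ``truth_labels`` carries ground-truth category names for synthetic
    cohorts (values are plain strings so this module stays independent of
    the classifier); it is empty for measured data.
    """

    spectra: dict = field(default_factory=dict)
    truth_labels: dict = field(default_factory=dict)

    def add(self, spectrum: ImpedanceSpectrum, truth: Optional[str] = None) -> None:
        key = spectrum.meta.key
        if key in self.spectra:
            raise ValueError(f"duplicate cohort key: {key}")
        self.spectra[key] = spectrum
        if truth is not None:
            self.truth_labels[key] = truth

    def __len__(self) -> int:
        return len(self.spectra)

    def keys(self) -> Iterable[tuple]:
        return self.spectra.keys()

    def arrays(self) -> list:
        return sorted({k[0] for k in self.spectra})

    def sessions(self) -> list:
        return sorted({k[2] for k in self.spectra})

    def validate(self) -> None:
        for key in self.truth_labels:
            if key not in self.spectra:
                raise ValueError(f"truth label for unknown key {key}")


_MANIFEST_NAME = "manifest.json"


def write_cohort(
    cohort: CohortDataset, directory: Union[str, Path], file_format: str = "csv"
) -> Path:
    """Write a cohort as one directory per array plus a JSON manifest.

    Each channel-session spectrum becomes one file
    ``<array_id>/ch<CC>_<session>.<ext>``; the manifest maps files to their
    session metadata and optional ground-truth label.
    """
    if file_format not in ("csv", "dta"):
        raise ValueError("file_format must be 'csv' or 'dta'")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries = []
    writer = write_spectrum_csv if file_format == "csv" else write_instrument_dta
    for key in sorted(cohort.spectra, key=lambda k: (k[0], k[1], k[2])):
        spectrum = cohort.spectra[key]
        meta = spectrum.meta
        rel = Path(meta.array_id) / f"ch{meta.channel:02d}_{meta.session.label()}.{file_format}"
        (directory / rel).parent.mkdir(exist_ok=True)
        writer(spectrum, directory / rel)
        entry = {
            "path": str(rel),
            "array_id": meta.array_id,
            "channel": meta.channel,
            "array_type": meta.array_type.value,
            "session": meta.session.label(),
        }
        if key in cohort.truth_labels:
            entry["truth_label"] = cohort.truth_labels[key]
        entries.append(entry)
    manifest = {"format": file_format, "spectra": entries}
    with open(directory / _MANIFEST_NAME, "w") as fh:
        json.dump(manifest, fh, indent=1)
    return directory / _MANIFEST_NAME


def read_cohort(directory: Union[str, Path]) -> CohortDataset:
    """Read a cohort directory written by :func:`write_cohort`."""
    directory = Path(directory)
    manifest_path = directory / _MANIFEST_NAME
    if not manifest_path.exists():
        raise FormatError(f"no {_MANIFEST_NAME} in {directory}")
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    file_format = manifest.get("format", "csv")
    reader = read_spectrum_csv if file_format == "csv" else read_instrument_dta
    cohort = CohortDataset()
    for entry in manifest["spectra"]:
        meta = SessionMeta(
            array_id=entry["array_id"],
            channel=int(entry["channel"]),
            array_type=ArrayType(entry["array_type"]),
            session=SessionTime.from_label(entry["session"]),
        )
        spectrum = reader(directory / entry["path"], meta)
        cohort.add(spectrum, truth=entry.get("truth_label"))
    return cohort
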