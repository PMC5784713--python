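"""Plate geometry, array layouts, and plate-reader run files.

A *run* is one continuous reading session of a single plate: a strictly
increasing sequence of timepoints, each with one OD600 absorbance value per
well.  Runs are stored in a versioned CSV dialect (magic line
``# PLATEPHEN-RUN v1``) so that sessions taken at different times — including
the pre-print agar blank — can be re-read and combined into a single
:class:`ExperimentSeries` on an absolute timeline.

Reader absorbance saturates at 3.5, the hard ceiling of the FLUOstar-class
instruments this dialect models; no reading may exceed it.
"""

from __future__ import annotations

import csv
import io
import math
from dataclasses import dataclass, field
from datetime import datetime
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

#: Hard ceiling of the microplate reader's absorbance scale.
SATURATION_CEILING = 3.5

#: Supported plate densities mapped to (rows, columns).
GEOMETRIES = {96: (8, 12), 384: (16, 24), 1536: (32, 48)}

RUN_FILE_MAGIC = "# PLATEPHEN-RUN v1"


class PlatePhenError(Exception):
    """Base class for all package errors."""


class FormatError(PlatePhenError):
    """A file does not conform to its declared dialect."""


class GeometryError(PlatePhenError):
    """A label, index or label set is inconsistent with the plate geometry."""


class OrderingError(PlatePhenError):
    """Timepoints are not strictly increasing."""


class LayoutError(PlatePhenError):
    """An array layout file is internally inconsistent."""


class CombineError(PlatePhenError):
    """Runs cannot be combined (mismatched plates or clashing timestamps)."""


# ---------------------------------------------------------------------------
# Geometry and well labels
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlateGeometry:
    """Plate density and its fixed rectangular grid (96→8×12, 384→16×24, 1536→32×48)."""

    density: int

    def __post_init__(self) -> None:
        if self.density not in GEOMETRIES:
            raise GeometryError(f"unsupported plate density {self.density!r}; "
                                f"choose one of {sorted(GEOMETRIES)}")

    @property
    def n_rows(self) -> int:
        return GEOMETRIES[self.density][0]

    @property
    def n_cols(self) -> int:
        return GEOMETRIES[self.density][1]

    @property
    def n_wells(self) -> int:
        return self.density

    def labels(self) -> list[str]:
        """All well labels in row-major order (A1, A2, ..)."""
        return [position_label(r, c, self)
                for r in range(self.n_rows) for c in range(self.n_cols)]

    def label_index(self, label: str) -> int:
        """Row-major index of a label within this geometry."""
        r, c = parse_label(label, self)
        return r * self.n_cols + c


def _row_letters(row: int) -> str:
    # A..Z then AA..AF, enough for 1536-density (32 rows)
    if row < 26:
        return chr(ord("A") + row)
    return "A" + chr(ord("A") + row - 26)


def position_label(row: int, col: int, geometry: PlateGeometry) -> str:
    """Label for 0-based (row, col), e.g. ``(0, 0) -> "A1"``, ``(15, 23) -> "P24"``."""
    if not (0 <= row < geometry.n_rows and 0 <= col < geometry.n_cols):
        raise GeometryError(f"position ({row}, {col}) outside {geometry.density}-well plate")
    return f"{_row_letters(row)}{col + 1}"


def parse_label(label: str, geometry: PlateGeometry) -> tuple[int, int]:
    """Inverse of :func:`position_label`: ``"H12" -> (7, 11)`` on a 96 plate."""
    i = 0
    while i < len(label) and label[i].isalpha():
        i += 1
    letters, digits = label[:i], label[i:]
    if not letters or not digits.isdigit():
        raise GeometryError(f"malformed well label {label!r}")
    if len(letters) == 1:
        row = ord(letters) - ord("A")
    elif len(letters) == 2 and letters[0] == "A":
        row = 26 + ord(letters[1]) - ord("A")
    else:
        raise GeometryError(f"malformed well label {label!r}")
    col = int(digits) - 1
    if not (0 <= row < geometry.n_rows and 0 <= col < geometry.n_cols):
        raise GeometryError(f"label {label!r} outside {geometry.density}-well plate")
    return row, col


@dataclass(frozen=True)
class WellPosition:
    """A well addressed both by 0-based indices and by its public label."""

    row_index: int
    col_index: int
    label: str

    @classmethod
    def from_indices(cls, row: int, col: int, geometry: PlateGeometry) -> "WellPosition":
        return cls(row, col, position_label(row, col, geometry))

    @classmethod
    def from_label(cls, label: str, geometry: PlateGeometry) -> "WellPosition":
        r, c = parse_label(label, geometry)
        return cls(r, c, position_label(r, c, geometry))


def quadrant_map(pos96: WellPosition, quadrant: int) -> WellPosition:
    """Map a 96-array position into one interleaved quadrant of a 384 array.

    Four 96 arrays are superimposed with a one-well offset, so
    ``row384 = 2*row96 + quadrant//2`` and ``col384 = 2*col96 + quadrant%2``;
    the four quadrant images tile the 384 grid exactly once.
    """
    if quadrant not in (0, 1, 2, 3):
        raise PlatePhenError(f"quadrant must be in 0..3, got {quadrant}")
    g384 = PlateGeometry(384)
    row = 2 * pos96.row_index + quadrant // 2
    col = 2 * pos96.col_index + quadrant % 2
    return WellPosition.from_indices(row, col, g384)


# ---------------------------------------------------------------------------
# Reading runs and the canonical run-file dialect
# ---------------------------------------------------------------------------

@dataclass
class ReadingRun:
    """One continuous reading session: timestamps × wells of OD600 absorbance.

    ``readings`` is a (timepoint × well) float matrix with wells in row-major
    label order; missing readings are NaN.  Times are seconds from
    ``start_time``, strictly increasing.
    """

    plate_id: str
    geometry: PlateGeometry
    program: str
    start_time: datetime
    times_s: np.ndarray
    readings: np.ndarray

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.readings = np.asarray(self.readings, dtype=float)
        if self.times_s.ndim != 1:
            raise OrderingError("times_s must be one-dimensional")
        if np.any(np.diff(self.times_s) <= 0):
            raise OrderingError("run timepoints must be strictly increasing")
        expected = (len(self.times_s), self.geometry.n_wells)
        if self.readings.shape != expected:
            raise GeometryError(
                f"readings shape {self.readings.shape} != (timepoints, wells) {expected}")
        if np.any(self.readings[np.isfinite(self.readings)] > SATURATION_CEILING):
            raise PlatePhenError(
                f"readings exceed the reader ceiling of {SATURATION_CEILING}")

    @property
    def run_id(self) -> str:
        return f"{self.plate_id}/{self.program}@{self.start_time.isoformat()}"

    @property
    def n_timepoints(self) -> int:
        return len(self.times_s)


def _fmt(value: float) -> str:
    """Shortest round-tripping decimal representation; NaN -> empty cell."""
    if isinstance(value, float) and math.isnan(value):
        return ""
    return repr(float(value))


def write_run_file(run: ReadingRun, stream=None) -> str:
    """Serialize a run in the canonical dialect; inverse of :func:`parse_run_file`."""
    out = io.StringIO()
    out.write(RUN_FILE_MAGIC + "\n")
    out.write(f"# plate_id: {run.plate_id}\n")
    out.write(f"# geometry: {run.geometry.density}\n")
    out.write(f"# program: {run.program}\n")
    out.write(f"# started: {run.start_time.isoformat()}\n")
    out.write("time_s," + ",".join(run.geometry.labels()) + "\n")
    for t, row in zip(run.times_s, run.readings):
        out.write(_fmt(t) + "," + ",".join(_fmt(v) for v in row) + "\n")
    text = out.getvalue()
    if stream is not None:
        stream.write(text)
    return text


def parse_run_file(stream) -> ReadingRun:
    """Parse the canonical run-file dialect into a :class:`ReadingRun`.

    Accepts a text string or a readable text stream.  Header must carry, in
    order: the magic line, plate_id, geometry, program and start timestamp;
    the CSV body must list every well label of the geometry in row-major
    order.  Empty cells become NaN (missing) readings.
    """
    if hasattr(stream, "read"):
        text = stream.read()
    else:
        text = stream
    lines = text.splitlines()
    header_keys = ["plate_id", "geometry", "program", "started"]
    if not lines or lines[0].strip() != RUN_FILE_MAGIC:
        raise FormatError(f"missing magic line {RUN_FILE_MAGIC!r} "
                          f"(got {lines[0]!r})" if lines else "empty stream")
    meta: dict[str, str] = {}
    idx = 1
    for key in header_keys:
        if idx >= len(lines):
            raise FormatError(f"truncated header: missing '# {key}:' line")
        line = lines[idx]
        prefix = f"# {key}:"
        if not line.startswith(prefix):
            raise FormatError(f"malformed header line {idx + 1}: {line!r} "
                              f"(expected {prefix!r})")
        meta[key] = line[len(prefix):].strip()
        idx += 1
    try:
        geometry = PlateGeometry(int(meta["geometry"]))
    except ValueError as exc:
        raise FormatError(f"bad geometry value {meta['geometry']!r}") from exc
    try:
        start_time = datetime.fromisoformat(meta["started"])
    except ValueError as exc:
        raise FormatError(f"bad start timestamp {meta['started']!r}") from exc

    # skip any additional comment lines before the CSV header
    while idx < len(lines) and lines[idx].startswith("#"):
        idx += 1
    if idx >= len(lines):
        raise FormatError("missing CSV header line")
    reader = csv.reader(lines[idx:])
    header = next(reader)
    if header[:1] != ["time_s"]:
        raise FormatError(f"CSV header must start with 'time_s', got {header[:1]}")
    expected = geometry.labels()
    if header[1:] != expected:
        raise GeometryError(
            f"well columns do not match the full {geometry.density}-well label set "
            f"in row-major order")
    times: list[float] = []
    rows: list[list[float]] = []
    for lineno, rec in enumerate(reader, start=idx + 2):
        if not rec:
            continue
        if len(rec) != len(expected) + 1:
            raise FormatError(f"line {lineno}: expected {len(expected) + 1} fields, "
                              f"got {len(rec)}")
        times.append(float(rec[0]))
        rows.append([float(v) if v != "" else math.nan for v in rec[1:]])
    times_arr = np.array(times, dtype=float)
    if np.any(np.diff(times_arr) <= 0):
        raise OrderingError("run timepoints are not strictly increasing")
    return ReadingRun(meta["plate_id"], geometry, meta["program"], start_time,
                      times_arr, np.array(rows, dtype=float))


# Parser registry: additional reader dialects can be registered by name, so
# exports from other instruments can be adapted without touching this module.
_PARSERS: dict[str, Callable[..., ReadingRun]] = {"canonical": parse_run_file}


def register_parser(name: str, parser: Callable[..., ReadingRun]) -> None:
    _PARSERS[name] = parser


def get_parser(name: str) -> Callable[..., ReadingRun]:
    try:
        return _PARSERS[name]
    except KeyError:
        raise FormatError(f"no parser registered under {name!r}; "
                          f"known: {sorted(_PARSERS)}") from None


# ---------------------------------------------------------------------------
# Array layouts
# ---------------------------------------------------------------------------

@dataclass
class ArrayLayout:
    """Maps well positions to strain / cross / tetrad / replicate annotations.

    Backed by a DataFrame indexed by well label (full label set of the
    geometry, row-major); unlisted positions carry an empty strain_id.
    """

    geometry: PlateGeometry
    table: pd.DataFrame  # index: label; columns: strain, cross, tetrad, replicate

    COLUMNS = ("strain", "cross", "tetrad", "replicate")

    @classmethod
    def empty(cls, geometry: PlateGeometry) -> "ArrayLayout":
        table = pd.DataFrame("", index=pd.Index(geometry.labels(), name="position"),
                             columns=list(cls.COLUMNS))
        return cls(geometry, table)

    def strain_at(self, label: str) -> str:
        return str(self.table.at[label, "strain"])

    def non_empty_labels(self) -> list[str]:
        return [lab for lab in self.table.index if self.table.at[lab, "strain"] != ""]

    def replicate_groups(self) -> dict[str, list[str]]:
        """Strain id -> list of well labels holding a replicate of it."""
        groups: dict[str, list[str]] = {}
        for lab in self.non_empty_labels():
            groups.setdefault(self.strain_at(lab), []).append(lab)
        return groups


def load_layout(stream, geometry: PlateGeometry) -> ArrayLayout:
    """Read a layout CSV (columns: position,strain[,cross,tetrad,replicate])."""
    if hasattr(stream, "read"):
        text = stream.read()
    else:
        text = stream
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    reader = csv.reader(lines)
    header = next(reader)
    if header[:2] != ["position", "strain"]:
        raise FormatError("layout header must start with 'position,strain'")
    extras = header[2:]
    unknown = set(extras) - set(ArrayLayout.COLUMNS)
    if unknown:
        raise FormatError(f"unknown layout columns: {sorted(unknown)}")
    layout = ArrayLayout.empty(geometry)
    seen: set[str] = set()
    for rec in reader:
        label = rec[0]
        parse_label(label, geometry)  # raises GeometryError on bad labels
        if label in seen:
            raise LayoutError(f"duplicate position {label!r} in layout")
        seen.add(label)
        layout.table.at[label, "strain"] = rec[1]
        for col, value in zip(extras, rec[2:]):
            layout.table.at[label, col] = value
    return layout


def write_layout(layout: ArrayLayout, stream=None) -> str:
    out = io.StringIO()
    out.write("position,strain,cross,tetrad,replicate\n")
    for lab in layout.non_empty_labels():
        row = layout.table.loc[lab]
        out.write(",".join([lab, row["strain"], row["cross"], row["tetrad"],
                            row["replicate"]]) + "\n")
    text = out.getvalue()
    if stream is not None:
        stream.write(text)
    return text


# ---------------------------------------------------------------------------
# Combining runs into an experiment series
# ---------------------------------------------------------------------------

@dataclass
class ExperimentSeries:
    """Time-aligned raw absorbance for one experimental plate.

    ``times_s`` is the merged timeline in seconds from the start of the
    earliest growth run; ``agar`` holds the per-well mean of the pre-print
    blank run; ``series`` carries raw (not yet agar-subtracted) absorbance.
    """

    plate_id: str
    geometry: PlateGeometry
    agar: np.ndarray            # (wells,)
    times_s: np.ndarray         # (timepoints,)
    series: np.ndarray          # (timepoints, wells)
    provenance: list[str]
    treatment: str = ""
    layout: ArrayLayout | None = None


def combine_runs(runs: Sequence[ReadingRun], agar_run: ReadingRun,
                 layout: ArrayLayout | None = None,
                 treatment: str = "") -> ExperimentSeries:
    """Merge reading sessions of one plate onto a single absolute timeline.

    All runs (and the agar blank) must share plate_id and geometry, and the
    blank must precede every growth run.  The merged timeline is the union of
    each run's timepoints offset by that run's start relative to the earliest
    growth run; identical absolute timestamps from different runs clash.
    The per-well agar reference is the mean over the blank run's passes.
    """
    if not runs:
        raise CombineError("no growth runs supplied")
    ordered = sorted(runs, key=lambda r: r.start_time)
    first = ordered[0]
    for run in list(ordered) + [agar_run]:
        if run.plate_id != first.plate_id or run.geometry != first.geometry:
            raise CombineError(
                f"run {run.run_id} does not match plate "
                f"{first.plate_id!r}/{first.geometry.density}")
    if agar_run.start_time > first.start_time:
        raise CombineError("agar blank run must precede all growth runs")
    if layout is not None and layout.geometry != first.geometry:
        raise GeometryError("layout geometry does not match the runs")

    agar = np.nanmean(agar_run.readings, axis=0)
    chunks_t, chunks_v = [], []
    for run in ordered:
        offset = (run.start_time - first.start_time).total_seconds()
        chunks_t.append(run.times_s + offset)
        chunks_v.append(run.readings)
    all_t = np.concatenate(chunks_t)
    all_v = np.vstack(chunks_v)
    order = np.argsort(all_t, kind="stable")
    all_t, all_v = all_t[order], all_v[order]
    if np.any(np.diff(all_t) == 0):
        raise CombineError("different runs contribute identical absolute timestamps")
    return ExperimentSeries(first.plate_id, first.geometry, agar, all_t, all_v,
                            [r.run_id for r in ordered], treatment, layout)
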