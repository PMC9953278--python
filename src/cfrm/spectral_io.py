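"""Data model and text I/O for Raman spectral maps.

A Raman map is an ``H x W`` spatial grid in which every pixel holds a full
vibrational spectrum sampled on a shared wavenumber axis (Raman shift,
cm^-1).  Two plain-text dialects are supported so that fixtures stay
inspectable and diffable:

``csv_long``
    CSV with columns ``(row, col, wavenumber, intensity)``, one line per
    (pixel, channel) entry.

``matrix_stack``
    Optional ``# key value`` metadata lines, then a header line ``H W m``,
    then one line with the ``m`` axis values, then ``H*W`` rows of ``m``
    intensities in row-major pixel order.

Pixel indices are 0-based ``(row, col)``; stage coordinates are micrometres
with the row axis increasing downward.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import AxisError, BoundsError, FormatError, RangeError

__all__ = [
    "WavenumberAxis",
    "Spectrum",
    "RamanMap",
    "StageLabel",
    "STAGE_NAMES",
    "default_axis",
    "nearest_channel",
    "read_map",
    "write_map",
    "crop_map",
    "read_labels",
    "write_labels",
]

#: Number of significant digits used when serializing floats (round-trip safe).
_FLOAT_FMT = "%.17g"


@dataclass(frozen=True)
class WavenumberAxis:
    """Strictly increasing Raman-shift axis in cm^-1."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size < 1:
            raise FormatError("axis must be a 1-D array with at least one channel")
        if not np.all(np.isfinite(v)):
            raise FormatError("axis contains non-finite values")
        if v.size > 1 and not np.all(np.diff(v) > 0):
            raise FormatError("axis values must be strictly increasing")
        object.__setattr__(self, "values", v)

    @property
    def m(self) -> int:
        return int(self.values.size)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WavenumberAxis):
            return NotImplemented
        return self.values.shape == other.values.shape and bool(
            np.array_equal(self.values, other.values)
        )

    def __hash__(self) -> int:
        return hash((self.values.size, float(self.values[0]), float(self.values[-1])))


def default_axis(m: int = 1600, lo: float = 439.0, hi: float = 3228.0) -> WavenumberAxis:
    """Uniform axis over the closed interval [lo, hi] with ``m`` channels."""
    return WavenumberAxis(np.linspace(lo, hi, m))


@dataclass(frozen=True)
class Spectrum:
    """One intensity vector bound to a wavenumber axis."""

    intensities: np.ndarray
    axis: WavenumberAxis

    def __post_init__(self) -> None:
        y = np.asarray(self.intensities, dtype=float)
        if y.ndim != 1:
            raise FormatError("spectrum intensities must be 1-D")
        if y.size != self.axis.m:
            raise AxisError(
                f"spectrum has {y.size} values but axis has {self.axis.m} channels"
            )
        if not np.all(np.isfinite(y)):
            raise FormatError("spectrum contains non-finite values")
        object.__setattr__(self, "intensities", y)

    def with_intensities(self, y: np.ndarray) -> "Spectrum":
        return Spectrum(np.asarray(y, dtype=float), self.axis)


@dataclass
class RamanMap:
    """H x W grid of spectra sharing one wavenumber axis.

    ``cube`` has shape ``(height, width, m)``.  ``origin`` is the stage
    coordinate (row_um, col_um) of pixel (0, 0).
    """

    cube: np.ndarray
    axis: WavenumberAxis
    pixel_size: float = 1.0
    origin: tuple[float, float] = (0.0, 0.0)
    label: str | None = None
    cell_id: str | None = None

    def __post_init__(self) -> None:
        c = np.asarray(self.cube, dtype=float)
        if c.ndim != 3:
            raise FormatError("cube must have shape (height, width, m)")
        if c.shape[2] != self.axis.m:
            raise AxisError(
                f"cube has {c.shape[2]} channels but axis has {self.axis.m}"
            )
        if c.shape[0] < 1 or c.shape[1] < 1:
            raise FormatError("map must be at least 1x1 pixels")
        if not np.all(np.isfinite(c)):
            raise FormatError("cube contains non-finite values")
        self.cube = c
        self.origin = (float(self.origin[0]), float(self.origin[1]))

    @property
    def height(self) -> int:
        return int(self.cube.shape[0])

    @property
    def width(self) -> int:
        return int(self.cube.shape[1])

    def spectrum_at(self, row: int, col: int) -> Spectrum:
        if not (0 <= row < self.height and 0 <= col < self.width):
            raise BoundsError(f"pixel ({row}, {col}) outside {self.height}x{self.width} map")
        return Spectrum(self.cube[row, col].copy(), self.axis)


class StageLabel(enum.IntEnum):
    """Cell-cycle stage in biological temporal order.

    Interphase is adjacent only to prophase; the five mitotic stages follow
    in temporal order, which is what makes the tridiagonal (one-miss)
    accuracy meaningful.
    """

    INTERPHASE = 0
    PROPHASE = 1
    PROMETAPHASE = 2
    METAPHASE = 3
    ANAPHASE = 4
    TELOPHASE = 5

    @classmethod
    def from_name(cls, name: str) -> "StageLabel":
        try:
            return cls[name.strip().upper()]
        except KeyError:
            raise FormatError(f"unknown stage label {name!r}") from None

    @property
    def display(self) -> str:
        return self.name.lower()


STAGE_NAMES: tuple[str, ...] = tuple(s.display for s in StageLabel)


def nearest_channel(axis: WavenumberAxis, wn: float) -> int:
    """Index of the channel closest to ``wn``; ties break toward the lower index."""
    v = axis.values
    if not (v[0] <= wn <= v[-1]):
        raise RangeError(f"wavenumber {wn} outside axis range [{v[0]}, {v[-1]}]")
    j = int(np.searchsorted(v, wn))
    if j == 0:
        return 0
    # candidate below and at/above; strict '<' keeps ties on the lower index
    below, at = j - 1, min(j, axis.m - 1)
    return at if abs(v[at] - wn) < abs(v[below] - wn) else below


# ---------------------------------------------------------------------------
# map serialization


def write_map(raman_map: RamanMap, path, dialect: str = "matrix_stack"):
    """Serialize a map; re-reading restores axis and intensities bit-identically."""
    if dialect == "matrix_stack":
        _write_matrix_stack(raman_map, path)
    elif dialect == "csv_long":
        _write_csv_long(raman_map, path)
    else:
        raise FormatError(f"unknown dialect {dialect!r}")
    return path


def read_map(path, dialect: str = "matrix_stack") -> RamanMap:
    if dialect == "matrix_stack":
        return _read_matrix_stack(path)
    if dialect == "csv_long":
        return _read_csv_long(path)
    raise FormatError(f"unknown dialect {dialect!r}")


def _write_matrix_stack(m: RamanMap, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# pixel_size {_FLOAT_FMT % m.pixel_size}\n")
        fh.write(f"# origin {_FLOAT_FMT % m.origin[0]} {_FLOAT_FMT % m.origin[1]}\n")
        if m.label is not None:
            fh.write(f"# label {m.label}\n")
        if m.cell_id is not None:
            fh.write(f"# cell_id {m.cell_id}\n")
        fh.write(f"{m.height} {m.width} {m.axis.m}\n")
        fh.write(" ".join(_FLOAT_FMT % x for x in m.axis.values) + "\n")
        flat = m.cube.reshape(m.height * m.width, m.axis.m)
        for row in flat:
            fh.write(" ".join(_FLOAT_FMT % x for x in row) + "\n")


def _read_matrix_stack(path) -> RamanMap:
    meta: dict[str, str] = {}
    with open(path) as fh:
        lines = fh.read().splitlines()
    ln = 0
    while ln < len(lines) and lines[ln].startswith("#"):
        parts = lines[ln][1:].strip().split(None, 1)
        if len(parts) == 2:
            meta[parts[0]] = parts[1]
        ln += 1
    if ln >= len(lines):
        raise FormatError(f"{path}: missing header line")
    header = lines[ln].split()
    if len(header) != 3:
        raise FormatError(f"{path}: line {ln + 1}: header must be 'H W m'")
    try:
        h, w, m = (int(x) for x in header)
    except ValueError:
        raise FormatError(f"{path}: line {ln + 1}: non-integer header field") from None
    if h < 1 or w < 1 or m < 1:
        raise FormatError(f"{path}: line {ln + 1}: non-positive dimension")
    ln += 1
    if ln >= len(lines):
        raise FormatError(f"{path}: line {ln + 1}: missing axis line")
    try:
        axis_vals = np.array([float(x) for x in lines[ln].split()])
    except ValueError:
        raise FormatError(f"{path}: line {ln + 1}: non-numeric axis value") from None
    if axis_vals.size != m:
        raise FormatError(f"{path}: line {ln + 1}: expected {m} axis values, got {axis_vals.size}")
    if axis_vals.size > 1 and not np.all(np.diff(axis_vals) > 0):
        raise FormatError(f"{path}: line {ln + 1}: axis not strictly increasing")
    ln += 1
    data_lines = [l for l in lines[ln:] if l.strip()]
    if len(data_lines) != h * w:
        raise FormatError(
            f"{path}: expected {h * w} data rows, found {len(data_lines)} (first data line {ln + 1})"
        )
    cube = np.empty((h * w, m), dtype=float)
    for i, line in enumerate(data_lines):
        try:
            row = np.array([float(x) for x in line.split()])
        except ValueError:
            raise FormatError(f"{path}: line {ln + i + 1}: non-numeric intensity") from None
        if row.size != m:
            raise FormatError(
                f"{path}: line {ln + i + 1}: expected {m} intensities, got {row.size}"
            )
        if not np.all(np.isfinite(row)):
            raise FormatError(f"{path}: line {ln + i + 1}: non-finite intensity")
        cube[i] = row
    origin = (0.0, 0.0)
    if "origin" in meta:
        oy, ox = meta["origin"].split()
        origin = (float(oy), float(ox))
    return RamanMap(
        cube.reshape(h, w, m),
        WavenumberAxis(axis_vals),
        pixel_size=float(meta.get("pixel_size", 1.0)),
        origin=origin,
        label=meta.get("label"),
        cell_id=meta.get("cell_id"),
    )


def _write_csv_long(m: RamanMap, path) -> None:
    h, w, nchan = m.cube.shape
    rows, cols = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    df = pd.DataFrame(
        {
            "row": np.repeat(rows.ravel(), nchan),
            "col": np.repeat(cols.ravel(), nchan),
            "wavenumber": np.tile(m.axis.values, h * w),
            "intensity": m.cube.ravel(),
        }
    )
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def _read_csv_long(path) -> RamanMap:
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:  # malformed CSV
        raise FormatError(f"{path}: cannot parse csv_long file: {exc}") from exc
    required = {"row", "col", "wavenumber", "intensity"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: csv_long needs columns {sorted(required)}")
    if not np.all(np.isfinite(df["intensity"].to_numpy())):
        bad = int(np.flatnonzero(~np.isfinite(df["intensity"].to_numpy()))[0]) + 2
        raise FormatError(f"{path}: line {bad}: non-finite intensity")
    h = int(df["row"].max()) + 1
    w = int(df["col"].max()) + 1
    axis_vals = np.sort(df["wavenumber"].unique())
    m = axis_vals.size
    if len(df) != h * w * m:
        raise FormatError(
            f"{path}: expected {h * w * m} rows for a {h}x{w}x{m} map, found {len(df)}"
        )
    if m > 1 and not np.all(np.diff(axis_vals) > 0):
        raise FormatError(f"{path}: wavenumbers not strictly increasing")
    df = df.sort_values(["row", "col", "wavenumber"], kind="mergesort")
    cube = df["intensity"].to_numpy().reshape(h, w, m)
    return RamanMap(cube, WavenumberAxis(axis_vals))


def crop_map(raman_map: RamanMap, top: int, left: int, height: int, width: int) -> RamanMap:
    """Rectangular spatial crop; origin shifts by (top, left) * pixel_size."""
    if top < 0 or left < 0 or height < 1 or width < 1:
        raise BoundsError("crop rectangle must be positive and inside the map")
    if top + height > raman_map.height or left + width > raman_map.width:
        raise BoundsError(
            f"crop ({top},{left})+({height}x{width}) exceeds map "
            f"{raman_map.height}x{raman_map.width}"
        )
    sub = raman_map.cube[top : top + height, left : left + width].copy()
    oy, ox = raman_map.origin
    return replace(
        raman_map,
        cube=sub,
        origin=(oy + top * raman_map.pixel_size, ox + left * raman_map.pixel_size),
    )


# ---------------------------------------------------------------------------
# stage-label tables


def write_labels(labels: dict[str, StageLabel], path) -> None:
    df = pd.DataFrame(
        {"cell_id": list(labels), "stage": [s.display for s in labels.values()]}
    )
    df.to_csv(path, index=False)


def read_labels(path) -> dict[str, StageLabel]:
    df = pd.read_csv(path)
    if not {"cell_id", "stage"}.issubset(df.columns):
        raise FormatError(f"{path}: labels CSV needs columns (cell_id, stage)")
    return {
        str(r.cell_id): StageLabel.from_name(str(r.stage)) for r in df.itertuples()
    }
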