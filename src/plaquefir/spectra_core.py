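"""Core data model for FTIR spectra and hyperspectral absorbance cubes.

The central objects are :class:`WavenumberAxis` (a strictly descending
spectral axis in cm^-1, as FTIR axes are conventionally stored),
:class:`Spectrum`, :class:`HyperCube` (rows x cols x channels absorbance
with a physical pixel size) and :class:`PixelMask`.  Readers and writers
cover the neutral container formats the pipeline touches: HDF5
(canonical), ENVI BSQ float32, and two-column CSV for single spectra.

Defaults match a focal-plane-array FTIR microscope operating in high
magnification mode: 3700 down to ~948 cm^-1 at 1.9 cm^-1 sampling and a
nominal pixel size of 1.1 um.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import h5py
import numpy as np

__all__ = [
    "PipelineError",
    "FormatError",
    "RangeError",
    "InputError",
    "WavenumberAxis",
    "Spectrum",
    "HyperCube",
    "PixelMask",
    "default_axis",
    "index_of",
    "extract_range",
    "read_cube",
    "write_cube",
    "write_spectrum_csv",
    "read_spectrum_csv",
]

DEFAULT_START_CM1 = 3700.0
DEFAULT_STEP_CM1 = 1.9
DEFAULT_SPAN_LOW_CM1 = 948.0
DEFAULT_PIXEL_SIZE_UM = 1.1


class PipelineError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(PipelineError):
    """A file is missing required metadata or is internally inconsistent."""


class RangeError(PipelineError, ValueError):
    """A wavenumber or pixel selection falls outside the available data."""


class InputError(PipelineError, ValueError):
    """Arguments violate an operation's preconditions."""


@dataclass(frozen=True)
class WavenumberAxis:
    """Strictly descending wavenumber axis (cm^-1).

    The channel values are stored explicitly so that non-uniform or
    non-default instruments can be represented; the constructor only
    requires strict monotonic decrease.
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=np.float64)
        if vals.ndim != 1 or vals.size < 2:
            raise InputError("axis needs at least two channels")
        if not np.all(np.diff(vals) < 0):
            raise InputError("wavenumber axis must be strictly decreasing")
        object.__setattr__(self, "values", vals)

    @classmethod
    def from_range(
        cls,
        start_cm1: float = DEFAULT_START_CM1,
        step_cm1: float = DEFAULT_STEP_CM1,
        n_channels: int | None = None,
        low_cm1: float = DEFAULT_SPAN_LOW_CM1,
    ) -> "WavenumberAxis":
        """Uniform descending axis ``start - k*step``; if ``n_channels``
        is omitted it is the largest count keeping the axis >= ``low_cm1``."""
        if n_channels is None:
            n_channels = int(np.floor((start_cm1 - low_cm1) / step_cm1)) + 1
        return cls(start_cm1 - step_cm1 * np.arange(n_channels))

    @property
    def n_channels(self) -> int:
        return int(self.values.size)

    @property
    def start_cm1(self) -> float:
        return float(self.values[0])

    @property
    def step_cm1(self) -> float:
        """Mean channel spacing (positive)."""
        return float(-np.mean(np.diff(self.values)))

    @property
    def span(self) -> tuple[float, float]:
        """(lowest, highest) wavenumber covered."""
        return float(self.values[-1]), float(self.values[0])

    def __len__(self) -> int:  # pragma: no cover - convenience
        return self.n_channels

    def __eq__(self, other: object) -> bool:
        return isinstance(other, WavenumberAxis) and np.array_equal(
            self.values, other.values
        )

    def __hash__(self) -> int:  # frozen dataclass with array field
        return hash((self.values.size, float(self.values[0]), float(self.values[-1])))


def default_axis() -> WavenumberAxis:
    """The package default axis: 3700 -> 948.8 cm^-1 at 1.9 cm^-1 (1449 channels)."""
    return WavenumberAxis.from_range()


def index_of(axis: WavenumberAxis, target_cm1: float) -> int:
    """Index of the channel nearest to ``target_cm1``.

    Ties are broken toward the lower index (the higher wavenumber).
    Raises :class:`RangeError` if the target lies outside the axis span.
    """
    lo, hi = axis.span
    if not (lo <= target_cm1 <= hi):
        raise RangeError(
            f"target {target_cm1} cm^-1 outside axis span [{lo}, {hi}]"
        )
    # argmin returns the first minimiser: on a descending axis that is the
    # lower index, i.e. the higher wavenumber, as required.
    return int(np.argmin(np.abs(axis.values - target_cm1)))


def channel_slice(axis: WavenumberAxis, lo_cm1: float, hi_cm1: float) -> slice:
    """Contiguous channel slice covering [lo, hi] cm^-1, bounded by the
    channels nearest to each endpoint (inclusive)."""
    if lo_cm1 >= hi_cm1:
        raise RangeError(f"empty wavenumber range [{lo_cm1}, {hi_cm1}]")
    span_lo, span_hi = axis.span
    if hi_cm1 < span_lo or lo_cm1 > span_hi:
        raise RangeError(
            f"range [{lo_cm1}, {hi_cm1}] outside axis span [{span_lo}, {span_hi}]"
        )
    i_first = index_of(axis, min(hi_cm1, span_hi))  # high wavenumber -> low index
    i_last = index_of(axis, max(lo_cm1, span_lo))
    return slice(i_first, i_last + 1)


@dataclass
class Spectrum:
    """A single absorbance spectrum on a wavenumber axis."""

    axis: WavenumberAxis
    absorbance: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.absorbance, dtype=np.float64)
        if arr.ndim != 1 or arr.size != self.axis.n_channels:
            raise InputError(
                f"absorbance length {arr.size} != axis channels {self.axis.n_channels}"
            )
        self.absorbance = arr

    def value_at(self, target_cm1: float) -> float:
        """Absorbance at the channel nearest ``target_cm1``."""
        return float(self.absorbance[index_of(self.axis, target_cm1)])

    def copy(self) -> "Spectrum":
        return Spectrum(self.axis, self.absorbance.copy())


def extract_range(spectrum: Spectrum, lo_cm1: float, hi_cm1: float) -> Spectrum:
    """Contiguous sub-spectrum covering [lo, hi] cm^-1 (nearest-boundary
    channels inclusive).  Idempotent for a fixed range."""
    sl = channel_slice(spectrum.axis, lo_cm1, hi_cm1)
    return Spectrum(
        WavenumberAxis(spectrum.axis.values[sl]), spectrum.absorbance[sl].copy()
    )


@dataclass
class HyperCube:
    """Absorbance cube (rows x cols x channels) with physical pixel size."""

    data: np.ndarray
    axis: WavenumberAxis
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.ndim != 3:
            raise InputError("cube data must be rows x cols x channels")
        if data.shape[2] != self.axis.n_channels:
            raise InputError(
                f"cube has {data.shape[2]} channels, axis {self.axis.n_channels}"
            )
        if not self.pixel_size_um > 0:
            raise InputError("pixel_size_um must be positive")
        self.data = data

    @property
    def rows(self) -> int:
        return self.data.shape[0]

    @property
    def cols(self) -> int:
        return self.data.shape[1]

    def spectrum_at(self, row: int, col: int) -> Spectrum:
        return Spectrum(self.axis, self.data[row, col].astype(np.float64))

    def flat(self) -> np.ndarray:
        """(rows*cols, channels) view of the data."""
        return self.data.reshape(-1, self.axis.n_channels)


@dataclass
class PixelMask:
    """Boolean membership per pixel of a cube or image."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.mask)
        if m.ndim != 2 or m.dtype != bool:
            m = np.asarray(m, dtype=bool)
            if m.ndim != 2:
                raise InputError("mask must be 2-D")
        self.mask = m

    @property
    def rows(self) -> int:
        return self.mask.shape[0]

    @property
    def cols(self) -> int:
        return self.mask.shape[1]

    @property
    def count(self) -> int:
        return int(self.mask.sum())


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_cube(cube: HyperCube, path: str, format: str | None = None) -> None:
    """Write a cube as HDF5 (datasets /cube float32, /wavenumbers float64,
    attribute pixel_size_um) or as ENVI BSQ float32 with the wavelength
    list carried in the text header."""
    fmt = _resolve_format(path, format)
    if fmt == "hdf5":
        with h5py.File(path, "w") as f:
            f.create_dataset("cube", data=cube.data.astype(np.float32))
            f.create_dataset("wavenumbers", data=cube.axis.values.astype(np.float64))
            f.attrs["pixel_size_um"] = float(cube.pixel_size_um)
    elif fmt == "envi":
        _write_envi(cube, path)
    else:  # pragma: no cover
        raise FormatError(f"unknown cube format {fmt!r}")


def read_cube(path: str, format: str | None = None) -> HyperCube:
    fmt = _resolve_format(path, format)
    if fmt == "hdf5":
        with h5py.File(path, "r") as f:
            if "wavenumbers" not in f:
                raise FormatError(f"{path}: missing /wavenumbers dataset")
            if "cube" not in f:
                raise FormatError(f"{path}: missing /cube dataset")
            data = f["cube"][()]
            wn = f["wavenumbers"][()]
            px = float(f.attrs.get("pixel_size_um", DEFAULT_PIXEL_SIZE_UM))
        if data.ndim != 3 or data.shape[2] != wn.size:
            raise FormatError(f"{path}: cube/axis shape mismatch")
        return HyperCube(data, WavenumberAxis(wn), px)
    if fmt == "envi":
        return _read_envi(path)
    raise FormatError(f"unknown cube format {fmt!r}")  # pragma: no cover


def _resolve_format(path: str, format: str | None) -> str:
    if format is not None:
        return format.lower()
    ext = os.path.splitext(path)[1].lower()
    if ext in (".h5", ".hdf5"):
        return "hdf5"
    if ext in (".hdr", ".img", ".envi"):
        return "envi"
    return "hdf5"


def _envi_paths(path: str) -> tuple[str, str]:
    base, ext = os.path.splitext(path)
    if ext.lower() == ".hdr":
        return path, base + ".img"
    if ext.lower() == ".img":
        return base + ".hdr", path
    return path + ".hdr", path + ".img"


def _write_envi(cube: HyperCube, path: str) -> None:
    hdr_path, img_path = _envi_paths(path)
    rows, cols, nb = cube.data.shape
    # BSQ: band-sequential, i.e. (bands, lines, samples) on disk
    bsq = np.ascontiguousarray(np.moveaxis(cube.data.astype(np.float32), 2, 0))
    bsq.tofile(img_path)
    wavelengths = ", ".join(f"{v:.6f}" for v in cube.axis.values)
    header = (
        "ENVI\n"
        "description = {FTIR absorbance cube}\n"
        f"samples = {cols}\n"
        f"lines = {rows}\n"
        f"bands = {nb}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        "data type = 4\n"
        "interleave = bsq\n"
        "byte order = 0\n"
        "wavelength units = cm-1\n"
        f"pixel size = {{{cube.pixel_size_um}, {cube.pixel_size_um}}}\n"
        f"wavelength = {{{wavelengths}}}\n"
    )
    with open(hdr_path, "w") as f:
        f.write(header)


def _parse_envi_header(hdr_path: str) -> dict:
    with open(hdr_path) as f:
        text = f.read()
    if not text.lstrip().startswith("ENVI"):
        raise FormatError(f"{hdr_path}: not an ENVI header")
    fields: dict[str, str] = {}
    key, buf, in_braces = None, [], False
    for line in text.splitlines()[1:]:
        if in_braces:
            buf.append(line)
            if "}" in line:
                fields[key] = " ".join(buf)
                in_braces = False
            continue
        if "=" not in line:
            continue
        key, _, val = line.partition("=")
        key, val = key.strip().lower(), val.strip()
        if "{" in val and "}" not in val:
            buf = [val]
            in_braces = True
        else:
            fields[key] = val
    return fields


def _read_envi(path: str) -> HyperCube:
    hdr_path, img_path = _envi_paths(path)
    fields = _parse_envi_header(hdr_path)
    try:
        rows = int(fields["lines"])
        cols = int(fields["samples"])
        nb = int(fields["bands"])
    except KeyError as exc:
        raise FormatError(f"{hdr_path}: missing dimension field {exc}") from exc
    if fields.get("data type") != "4":
        raise FormatError(f"{hdr_path}: only float32 (data type 4) is supported")
    if fields.get("interleave", "bsq").lower() != "bsq":
        raise FormatError(f"{hdr_path}: only BSQ interleave is supported")
    if "wavelength" not in fields:
        raise FormatError(f"{hdr_path}: missing wavelength list")
    wn = np.array(
        [float(t) for t in fields["wavelength"].strip("{} ").split(",") if t.strip()]
    )
    if wn.size != nb:
        raise FormatError(f"{hdr_path}: wavelength list length != bands")
    px = DEFAULT_PIXEL_SIZE_UM
    if "pixel size" in fields:
        px = float(fields["pixel size"].strip("{} ").split(",")[0])
    data = np.fromfile(img_path, dtype=np.float32)
    if data.size != rows * cols * nb:
        raise FormatError(f"{img_path}: data size does not match header dimensions")
    cube = np.moveaxis(data.reshape(nb, rows, cols), 0, 2)
    return HyperCube(cube.copy(), WavenumberAxis(wn), px)


def write_spectrum_csv(spectrum: Spectrum, path: str) -> None:
    """Two-column CSV export: wavenumber_cm1, absorbance."""
    arr = np.column_stack([spectrum.axis.values, spectrum.absorbance])
    np.savetxt(
        path, arr, delimiter=",", header="wavenumber_cm1,absorbance", comments=""
    )


def read_spectrum_csv(path: str) -> Spectrum:
    arr = np.loadtxt(path, delimiter=",", skiprows=1)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise FormatError(f"{path}: expected two columns")
    return Spectrum(WavenumberAxis(arr[:, 0]), arr[:, 1])
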