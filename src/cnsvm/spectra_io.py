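"""Reading, validating, cropping and writing hyperspectral signatures and cubes.

Signatures are per-pixel reflectance spectra (in percent) on an explicit,
evenly spaced wavelength grid in the visible/near-infrared range.  Labelled
signatures carry a binary class: basal cell carcinoma (BCC) = 1, healthy
skin (H) = 0.  Two on-disk forms are supported:

* delimited text tables (CSV/TSV) with numeric wavelength headers plus one
  label column — one row per pixel;
* ENVI header + flat binary pairs for full hyperspectral cubes, with an
  ``.npz`` dense dump as a package-native fallback.
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from cnsvm.errors import (
    ConfigError,
    FormatError,
    LabelError,
    MetadataError,
    ShapeError,
    WindowError,
)

#: Tolerance (nm) when reconstructing an even grid from file headers.
HEADER_TOLERANCE_NM = 0.01

#: The sensor grid of the study data: 398.08 nm start, 2.2 nm channel
#: separation, 260 channels.
DEFAULT_GRID_START_NM = 398.08
DEFAULT_GRID_SPACING_NM = 2.2
DEFAULT_GRID_CHANNELS = 260

#: The discriminative window where healthy and BCC spectra differ most.
DEFAULT_WINDOW_NM = (573.45, 779.88)


@dataclass(frozen=True)
class WavelengthGrid:
    """Evenly spaced wavelength grid: ``values[k] = start_nm + k * spacing_nm``."""

    start_nm: float
    spacing_nm: float
    n_channels: int

    def __post_init__(self) -> None:
        if self.n_channels < 1:
            raise ConfigError(f"n_channels must be >= 1, got {self.n_channels}")
        if self.spacing_nm <= 0:
            raise ConfigError(f"spacing_nm must be positive, got {self.spacing_nm}")

    @property
    def values(self) -> np.ndarray:
        """Wavelengths in nm, strictly increasing."""
        return self.start_nm + self.spacing_nm * np.arange(self.n_channels)

    @classmethod
    def from_values(
        cls, values: Sequence[float], tolerance_nm: float = HEADER_TOLERANCE_NM
    ) -> "WavelengthGrid":
        """Reconstruct an even grid from explicit wavelengths.

        The spacing is taken from the first two values; every value must then
        lie within ``tolerance_nm`` of ``start + k * spacing`` (headers of real
        files carry rounding jitter).
        """
        vals = np.asarray(values, dtype=float)
        if vals.ndim != 1 or vals.size < 1:
            raise MetadataError("wavelength list must be a non-empty 1-D sequence")
        if vals.size == 1:
            return cls(float(vals[0]), DEFAULT_GRID_SPACING_NM, 1)
        spacing = float(vals[1] - vals[0])
        if spacing <= 0:
            raise MetadataError("wavelengths must be strictly increasing")
        grid = cls(float(vals[0]), spacing, vals.size)
        if np.max(np.abs(grid.values - vals)) > tolerance_nm:
            raise MetadataError(
                "wavelengths are not evenly spaced within "
                f"{tolerance_nm} nm of start + k*spacing"
            )
        return grid

    @classmethod
    def default(cls) -> "WavelengthGrid":
        """The study sensor grid (398.08 nm + k * 2.2 nm, 260 channels)."""
        return cls(DEFAULT_GRID_START_NM, DEFAULT_GRID_SPACING_NM, DEFAULT_GRID_CHANNELS)


@dataclass(frozen=True)
class SpectralWindow:
    """Closed wavelength interval [low_nm, high_nm] used to crop spectra."""

    low_nm: float
    high_nm: float

    def __post_init__(self) -> None:
        if not self.low_nm < self.high_nm:
            raise ConfigError(
                f"window bounds must satisfy low < high, got [{self.low_nm}, {self.high_nm}]"
            )

    @classmethod
    def default(cls) -> "SpectralWindow":
        """The discriminative 573.45-779.88 nm window."""
        return cls(*DEFAULT_WINDOW_NM)


@dataclass(frozen=True)
class Signature:
    """One pixel's reflectance spectrum with an optional label and patient id."""

    reflectance: np.ndarray
    label: int | None = None
    patient_id: str | None = None


class SignatureSet:
    """Ordered collection of signatures sharing one wavelength grid.

    Reflectance is stored as an ``(n_signatures, n_channels)`` float array in
    percent; labels (if present) as an int array of 0/1.
    """

    def __init__(
        self,
        grid: WavelengthGrid,
        reflectance: np.ndarray,
        labels: np.ndarray | None = None,
        patient_ids: np.ndarray | None = None,
    ):
        reflectance = np.asarray(reflectance, dtype=float)
        if reflectance.ndim != 2:
            raise ShapeError("reflectance must be 2-D (signatures x channels)")
        if reflectance.shape[1] != grid.n_channels:
            raise ShapeError(
                f"reflectance has {reflectance.shape[1]} channels, grid has {grid.n_channels}"
            )
        if labels is not None:
            labels = np.asarray(labels)
            if labels.shape != (reflectance.shape[0],):
                raise ShapeError("labels must have one entry per signature")
            if not np.isin(labels, (0, 1)).all():
                raise LabelError("labels must be binary: BCC = 1, healthy = 0")
            labels = labels.astype(np.int64)
        if patient_ids is not None:
            patient_ids = np.asarray(patient_ids, dtype=object)
            if patient_ids.shape != (reflectance.shape[0],):
                raise ShapeError("patient_ids must have one entry per signature")
        self.grid = grid
        self.reflectance = reflectance
        self.labels = labels
        self.patient_ids = patient_ids

    def __len__(self) -> int:
        return self.reflectance.shape[0]

    def __getitem__(self, i: int) -> Signature:
        return Signature(
            reflectance=self.reflectance[i],
            label=None if self.labels is None else int(self.labels[i]),
            patient_id=None if self.patient_ids is None else self.patient_ids[i],
        )

    @property
    def is_labelled(self) -> bool:
        return self.labels is not None

    def label_counts(self) -> dict[int, int]:
        """Counts of each label value; empty dict when unlabelled."""
        if self.labels is None:
            return {}
        values, counts = np.unique(self.labels, return_counts=True)
        return {int(v): int(c) for v, c in zip(values, counts)}

    def subset(self, indices: np.ndarray) -> "SignatureSet":
        """New set with the selected rows, preserving order of ``indices``."""
        indices = np.asarray(indices)
        return SignatureSet(
            self.grid,
            self.reflectance[indices],
            None if self.labels is None else self.labels[indices],
            None if self.patient_ids is None else self.patient_ids[indices],
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SignatureSet):
            return NotImplemented
        same_labels = (self.labels is None) == (other.labels is None) and (
            self.labels is None or np.array_equal(self.labels, other.labels)
        )
        return (
            self.grid == other.grid
            and np.array_equal(self.reflectance, other.reflectance)
            and same_labels
        )


@dataclass
class HyperCube:
    """Dense reflectance tensor of shape (rows, cols, channels)."""

    grid: WavelengthGrid
    data: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ShapeError("cube data must be 3-D (rows, cols, channels)")
        rows, cols, channels = self.data.shape
        if rows < 1 or cols < 1:
            raise ShapeError("cube must have at least one row and column")
        if channels != self.grid.n_channels:
            raise ShapeError(
                f"cube has {channels} channels but grid has {self.grid.n_channels}"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


# ---------------------------------------------------------------------------
# Delimited signature tables
# ---------------------------------------------------------------------------

def read_signature_table(
    path: str | os.PathLike,
    label_column: str = "label",
    allow_unlabelled: bool = False,
    patient_column: str = "patient_id",
) -> SignatureSet:
    """Read a delimited text table of labelled signatures.

    Columns are numeric wavelength headers plus one binary label column (and
    optionally a patient-id column).  The delimiter (comma or tab) is
    autodetected.  Reading a table without the label column requires
    ``allow_unlabelled=True`` so unlabelled rows can never silently enter
    training.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    with open(path) as fh:
        first_line = fh.readline()
    if not first_line.strip():
        raise FormatError(f"{path}: empty file")
    sep = "\t" if "\t" in first_line else ","
    try:
        # round_trip parsing keeps written float64 values bit-exact
        frame = pd.read_csv(path, sep=sep, float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty file") from exc
    except pd.errors.ParserError as exc:
        raise FormatError(f"{path}: {exc}") from exc
    if frame.shape[0] == 0:
        raise FormatError(f"{path}: table has no data rows")

    labels = None
    if label_column in frame.columns:
        raw = frame.pop(label_column)
        labels = pd.to_numeric(raw, errors="coerce").to_numpy()
        if np.isnan(labels).any():
            bad = int(np.flatnonzero(np.isnan(labels))[0])
            raise FormatError(f"{path}: non-numeric label in row {bad}")
        if not np.isin(labels, (0, 1)).all():
            bad_values = sorted(set(labels) - {0, 1})
            raise LabelError(
                f"{path}: labels outside the binary domain {{0, 1}}: {bad_values}"
            )
        labels = labels.astype(np.int64)
    elif not allow_unlabelled:
        raise LabelError(
            f"{path}: label column {label_column!r} not found "
            "(pass allow_unlabelled=True to read unlabelled data)"
        )

    patient_ids = None
    if patient_column in frame.columns:
        patient_ids = frame.pop(patient_column).astype(str).to_numpy(dtype=object)

    try:
        wavelengths = [float(c) for c in frame.columns]
    except ValueError as exc:
        raise FormatError(
            f"{path}: non-numeric wavelength header among {list(frame.columns)[:5]}..."
        ) from exc
    grid = WavelengthGrid.from_values(wavelengths)

    values = frame.to_numpy()
    if values.dtype == object or not np.issubdtype(values.dtype, np.number):
        coerced = frame.apply(pd.to_numeric, errors="coerce").to_numpy()
        bad_rows = np.flatnonzero(np.isnan(coerced).any(axis=1))
        raise FormatError(f"{path}: non-numeric reflectance in row {int(bad_rows[0])}")
    if np.isnan(values).any():
        bad = int(np.flatnonzero(np.isnan(values).any(axis=1))[0])
        raise FormatError(f"{path}: missing reflectance value in row {bad}")

    return SignatureSet(grid, values, labels, patient_ids)


def write_signature_table(
    s: SignatureSet,
    path: str | os.PathLike,
    label_column: str = "label",
    patient_column: str = "patient_id",
    sep: str = ",",
) -> None:
    """Write a signature set as a delimited table readable by
    :func:`read_signature_table`.

    Wavelength headers use two decimals (matching the sensor's nm precision);
    reflectance values are written at full float64 precision so round-trips
    are exact.
    """
    columns = {f"{w:.2f}": s.reflectance[:, k] for k, w in enumerate(s.grid.values)}
    frame = pd.DataFrame(columns)
    if s.labels is not None:
        frame[label_column] = s.labels
    if s.patient_ids is not None:
        frame[patient_column] = s.patient_ids
    frame.to_csv(path, index=False, sep=sep, float_format="%.17g")


# ---------------------------------------------------------------------------
# Window cropping
# ---------------------------------------------------------------------------

def window_channel_mask(grid: WavelengthGrid, window: SpectralWindow) -> np.ndarray:
    """Boolean mask of channels with low_nm <= wavelength <= high_nm.

    Inclusion is closed on both ends; a 1e-9 nm guard absorbs float noise in
    the reconstructed grid.
    """
    values = grid.values
    return (values >= window.low_nm - 1e-9) & (values <= window.high_nm + 1e-9)


def _cropped_grid(grid: WavelengthGrid, mask: np.ndarray) -> WavelengthGrid:
    kept = np.flatnonzero(mask)
    return WavelengthGrid(
        start_nm=float(grid.values[kept[0]]),
        spacing_nm=grid.spacing_nm,
        n_channels=kept.size,
    )


def crop_to_window(s: SignatureSet, window: SpectralWindow) -> SignatureSet:
    """Retain exactly the channels inside the closed window, preserving order.

    On the study grid the default window keeps 94 channels, the network's
    input dimension.
    """
    mask = window_channel_mask(s.grid, window)
    if not mask.any():
        raise WindowError(
            f"window [{window.low_nm}, {window.high_nm}] nm does not intersect the grid"
        )
    return SignatureSet(
        _cropped_grid(s.grid, mask),
        s.reflectance[:, mask],
        s.labels,
        s.patient_ids,
    )


def crop_cube_to_window(c: HyperCube, window: SpectralWindow) -> HyperCube:
    """Channel-crop a cube the same way :func:`crop_to_window` crops a set."""
    mask = window_channel_mask(c.grid, window)
    if not mask.any():
        raise WindowError(
            f"window [{window.low_nm}, {window.high_nm}] nm does not intersect the grid"
        )
    return HyperCube(_cropped_grid(c.grid, mask), c.data[:, :, mask])


# ---------------------------------------------------------------------------
# ENVI cubes
# ---------------------------------------------------------------------------

_ENVI_DTYPES = {4: "<f4", 5: "<f8"}
_ENVI_DTYPE_CODES = {np.dtype("float32"): 4, np.dtype("float64"): 5}


def _header_path(data_path: str) -> str:
    return str(data_path) + ".hdr"


def _parse_envi_header(text: str) -> dict[str, str]:
    # Collapse { ... } blocks (possibly multi-line) before splitting key = value.
    text = re.sub(r"\{[^}]*\}", lambda m: m.group(0).replace("\n", " "), text)
    fields: dict[str, str] = {}
    for line in text.splitlines():
        if "=" not in line:
            continue
        key, _, value = line.partition("=")
        fields[key.strip().lower()] = value.strip()
    return fields


def write_cube(c: HyperCube, path: str | os.PathLike) -> None:
    """Write a cube as an ENVI header+binary pair, or as ``.npz`` if the path
    ends in ``.npz``.

    ENVI output uses band-interleaved-by-pixel (BIP) layout and float64
    samples, so read/write round-trips are bit-identical.
    """
    path = str(path)
    if path.endswith(".npz"):
        np.savez(path, data=c.data, wavelengths=c.grid.values)
        return
    rows, cols, channels = c.shape
    data = np.ascontiguousarray(c.data, dtype="<f8")
    wavelengths = ", ".join(f"{w:.6f}" for w in c.grid.values)
    header = (
        "ENVI\n"
        f"samples = {cols}\n"
        f"lines = {rows}\n"
        f"bands = {channels}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        f"data type = {_ENVI_DTYPE_CODES[np.dtype('float64')]}\n"
        "interleave = bip\n"
        "byte order = 0\n"
        "wavelength units = Nanometers\n"
        f"wavelength = {{ {wavelengths} }}\n"
    )
    with open(_header_path(path), "w") as fh:
        fh.write(header)
    data.tofile(path)


def read_cube(path: str | os.PathLike) -> HyperCube:
    """Read a cube written by :func:`write_cube` (ENVI pair or ``.npz``)."""
    path = str(path)
    if path.endswith(".npz"):
        with np.load(path) as bundle:
            if "wavelengths" not in bundle:
                raise MetadataError(f"{path}: missing wavelength metadata")
            grid = WavelengthGrid.from_values(bundle["wavelengths"])
            return HyperCube(grid, bundle["data"])

    header_path = _header_path(path)
    if not os.path.exists(header_path):
        raise MetadataError(f"{path}: ENVI header {header_path} not found")
    fields = _parse_envi_header(open(header_path).read())
    try:
        rows = int(fields["lines"])
        cols = int(fields["samples"])
        channels = int(fields["bands"])
        dtype_code = int(fields.get("data type", "5"))
    except (KeyError, ValueError) as exc:
        raise FormatError(f"{header_path}: malformed ENVI header") from exc
    if "wavelength" not in fields:
        raise MetadataError(f"{header_path}: missing wavelength metadata")
    wl_text = fields["wavelength"].strip().strip("{}")
    wavelengths = [float(tok) for tok in wl_text.replace(",", " ").split()]
    if len(wavelengths) != channels:
        raise MetadataError(
            f"{header_path}: {len(wavelengths)} wavelengths for {channels} bands"
        )
    if dtype_code not in _ENVI_DTYPES:
        raise FormatError(f"{header_path}: unsupported ENVI data type {dtype_code}")
    interleave = fields.get("interleave", "bip").lower()
    if interleave != "bip":
        raise FormatError(f"{header_path}: only BIP interleave is supported")

    raw = np.fromfile(path, dtype=_ENVI_DTYPES[dtype_code])
    expected = rows * cols * channels
    if raw.size != expected:
        raise FormatError(
            f"{path}: data has {raw.size} samples, header implies {expected}"
        )
    grid = WavelengthGrid.from_values(wavelengths)
    return HyperCube(grid, raw.reshape(rows, cols, channels))


# ---------------------------------------------------------------------------
# Cube <-> signature conversion
# ---------------------------------------------------------------------------

def cube_to_signatures(c: HyperCube) -> SignatureSet:
    """Flatten a cube into rows*cols unlabelled signatures in row-major order.

    Pixel ``(r, col)`` becomes signature index ``r * cols + col``; use
    :func:`signatures_to_image` to reassemble per-pixel predictions.
    """
    rows, cols, channels = c.shape
    return SignatureSet(c.grid, c.data.reshape(rows * cols, channels))


def signatures_to_image(values: np.ndarray, spatial_shape: tuple[int, int]) -> np.ndarray:
    """Inverse of :func:`cube_to_signatures` for per-pixel scalars."""
    values = np.asarray(values)
    rows, cols = spatial_shape
    if values.size != rows * cols:
        raise ShapeError(
            f"{values.size} per-pixel values cannot fill a {rows}x{cols} image"
        )
    return values.reshape(rows, cols)
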