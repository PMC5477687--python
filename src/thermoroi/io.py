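"""Reading and writing thermal frame sequences and ROI masks.

Temperatures are stored in degrees Celsius throughout; conversion to kelvin
happens only inside the radiometric quantification step. Two portable
interchange dialects are supported:

``tiff-stack``
    A multi-page 16-bit TIFF of raw counts plus a JSON sidecar
    (``<stem>.json``) holding the linear count-to-temperature scale and
    offset, the frame rate, and the sentinel count marking invalid pixels.
    Temperature is recovered as ``scale * count + offset``.

``csv-dir``
    A directory of per-frame comma-separated matrices (``frame_0000.csv``,
    ``frame_0001.csv``, ...) plus ``metadata.json``. Lossless; intended for
    debugging and tiny fixtures.

Invalid pixels (dead detector elements) are represented as NaN in memory and
are excluded from seeding, region growth, and all means downstream.
"""

from __future__ import annotations

import json
import math
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import imageio.v3 as iio
import numpy as np
import tifffile

from .exceptions import FormatError, ShapeError, TemperatureBandWarning

__all__ = [
    "ThermalFrame",
    "ThermalSequence",
    "RoiMask",
    "read_sequence",
    "write_sequence",
    "read_mask",
    "write_mask",
    "DEFAULT_PLAUSIBLE_BAND_C",
]

#: Default band of physiologically plausible skin temperatures (°C).
DEFAULT_PLAUSIBLE_BAND_C = (5.0, 45.0)

#: Raw-count sentinel for invalid (non-finite) pixels in the 16-bit dialect.
INVALID_COUNT = np.uint16(65535)

Dialect = Literal["tiff-stack", "csv-dir"]


@dataclass
class ThermalFrame:
    """One time point's grid of skin temperatures in °C.

    Non-finite entries mark invalid pixels; they are carried through I/O and
    ignored by every statistic computed downstream.
    """

    values: np.ndarray
    frame_index: int = 0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or self.values.size == 0:
            raise ShapeError(
                f"frame must be a non-empty 2-D grid, got shape {self.values.shape}"
            )
        if self.frame_index < 0:
            raise ValueError("frame_index must be non-negative")

    @property
    def height(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def valid_mask(self) -> np.ndarray:
        """Boolean grid of pixels carrying a finite temperature."""
        return np.isfinite(self.values)

    def out_of_band(
        self, band: tuple[float, float] = DEFAULT_PLAUSIBLE_BAND_C
    ) -> np.ndarray:
        """Flags of finite pixels outside the plausible temperature band."""
        lo, hi = band
        finite = self.valid_mask
        return finite & ((self.values < lo) | (self.values > hi))

    def validate_band(
        self, band: tuple[float, float] = DEFAULT_PLAUSIBLE_BAND_C
    ) -> np.ndarray:
        """Warn if any pixel leaves the plausible band; return the flag grid."""
        flags = self.out_of_band(band)
        n_bad = int(flags.sum())
        if n_bad:
            warnings.warn(
                f"frame {self.frame_index}: {n_bad} pixel(s) outside the "
                f"plausible band {band[0]}-{band[1]} °C",
                TemperatureBandWarning,
                stacklevel=2,
            )
        return flags


@dataclass
class ThermalSequence:
    """An ordered stack of equally-shaped thermal frames with timing metadata."""

    frames: list[ThermalFrame]
    frame_rate_hz: float = 30.0
    duration_s: float | None = None

    def __post_init__(self):
        if not self.frames:
            raise ValueError("a sequence must contain at least one frame")
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be positive")
        shape0 = self.frames[0].shape
        for f in self.frames:
            if f.shape != shape0:
                raise ShapeError(
                    f"all frames must share dimensions: {f.shape} != {shape0}"
                )
        if self.duration_s is not None:
            expected = round(self.frame_rate_hz * self.duration_s)
            if expected != len(self.frames):
                raise ValueError(
                    f"declared duration {self.duration_s} s at "
                    f"{self.frame_rate_hz} Hz implies {expected} frames, "
                    f"got {len(self.frames)}"
                )

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)

    def __getitem__(self, i: int) -> ThermalFrame:
        return self.frames[i]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames[0].shape

    def stack(self) -> np.ndarray:
        """All frame values as a (n_frames, height, width) array."""
        return np.stack([f.values for f in self.frames])


@dataclass
class RoiMask:
    """A boolean region-of-interest mask congruent with its source frame."""

    mask: np.ndarray
    frame_index: int = 0

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2 or self.mask.size == 0:
            raise ShapeError("mask must be a non-empty 2-D boolean grid")

    @property
    def pixel_count(self) -> int:
        return int(self.mask.sum())


# ---------------------------------------------------------------------------
# sequence I/O
# ---------------------------------------------------------------------------


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def _infer_dialect(path: Path) -> Dialect:
    if path.is_dir():
        return "csv-dir"
    if path.suffix.lower() in (".tif", ".tiff"):
        return "tiff-stack"
    raise FormatError(f"cannot infer dialect for {path}")


def write_sequence(
    seq: ThermalSequence,
    path: str | Path,
    dialect: Dialect = "tiff-stack",
    *,
    scale: float = 0.01,
    offset: float = 0.0,
) -> Path:
    """Write a sequence in the requested dialect; returns the primary path.

    The 16-bit TIFF dialect quantizes temperatures to ``scale`` °C steps
    (round-trip error at most ``scale / 2`` per pixel); the CSV dialect is
    lossless. Metadata (scale, offset, frame rate, duration) is stored in a
    JSON sidecar / metadata file and survives the round trip exactly.
    """
    path = Path(path)
    meta = {
        "format": "thermoroi-sequence",
        "version": 1,
        "scale": scale,
        "offset": offset,
        "frame_rate_hz": seq.frame_rate_hz,
        "duration_s": seq.duration_s,
        "n_frames": len(seq),
        "invalid_count": int(INVALID_COUNT),
    }
    if dialect == "tiff-stack":
        if scale <= 0:
            raise ValueError("scale must be positive")
        pages = []
        for frame in seq:
            counts = np.round((frame.values - offset) / scale)
            finite = np.isfinite(counts)
            lo, hi = 0, int(INVALID_COUNT) - 1
            if finite.any() and (
                counts[finite].min() < lo or counts[finite].max() > hi
            ):
                raise FormatError(
                    "temperatures do not fit the 16-bit count range for "
                    f"scale={scale}, offset={offset}"
                )
            page = np.where(finite, counts, float(INVALID_COUNT))
            pages.append(page.astype(np.uint16))
        path.parent.mkdir(parents=True, exist_ok=True)
        tifffile.imwrite(path, np.stack(pages), photometric="minisblack")
        _sidecar_path(path).write_text(json.dumps(meta, indent=1))
        return path
    elif dialect == "csv-dir":
        path.mkdir(parents=True, exist_ok=True)
        (path / "metadata.json").write_text(json.dumps(meta, indent=1))
        for i, frame in enumerate(seq):
            np.savetxt(path / f"frame_{i:04d}.csv", frame.values, delimiter=",")
        return path
    raise ValueError(f"unknown dialect {dialect!r}")


def read_sequence(path: str | Path, dialect: Dialect | None = None) -> ThermalSequence:
    """Read a temperature sequence written by :func:`write_sequence`.

    Counts in the TIFF dialect are mapped through ``scale * count + offset``;
    the invalid-pixel sentinel becomes NaN. Out-of-band temperatures trigger a
    :class:`TemperatureBandWarning` but do not fail the read.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect is None:
        dialect = _infer_dialect(path)

    if dialect == "tiff-stack":
        sidecar = _sidecar_path(path)
        if not sidecar.exists():
            raise FormatError(f"missing metadata sidecar {sidecar}")
        meta = json.loads(sidecar.read_text())
        for key in ("scale", "offset", "frame_rate_hz"):
            if key not in meta:
                raise FormatError(f"sidecar {sidecar} lacks required key {key!r}")
        counts = tifffile.imread(path)
        if counts.ndim == 2:
            counts = counts[None]
        invalid = counts == meta.get("invalid_count", int(INVALID_COUNT))
        values = meta["scale"] * counts.astype(np.float64) + meta["offset"]
        values[invalid] = np.nan
        frames = [ThermalFrame(v, i) for i, v in enumerate(values)]
    elif dialect == "csv-dir":
        meta_path = path / "metadata.json"
        if not meta_path.exists():
            raise FormatError(f"missing {meta_path}")
        meta = json.loads(meta_path.read_text())
        if "frame_rate_hz" not in meta:
            raise FormatError(f"{meta_path} lacks required key 'frame_rate_hz'")
        files = sorted(path.glob("frame_*.csv"), key=_frame_sort_key)
        if not files:
            raise FormatError(f"no frame_*.csv files in {path}")
        frames = []
        shape0 = None
        for i, f in enumerate(files):
            vals = np.loadtxt(f, delimiter=",", ndmin=2)
            if shape0 is None:
                shape0 = vals.shape
            elif vals.shape != shape0:
                raise ShapeError(
                    f"{f.name} has shape {vals.shape}, expected {shape0}"
                )
            frames.append(ThermalFrame(vals, i))
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    seq = ThermalSequence(
        frames,
        frame_rate_hz=float(meta["frame_rate_hz"]),
        duration_s=meta.get("duration_s"),
    )
    for frame in seq:
        frame.validate_band()
    return seq


def _frame_sort_key(p: Path) -> int:
    m = re.search(r"frame_(\d+)", p.stem)
    if m is None:
        raise FormatError(f"unrecognized frame file name {p.name}")
    return int(m.group(1))


# ---------------------------------------------------------------------------
# mask I/O
# ---------------------------------------------------------------------------


def write_mask(mask: RoiMask, path: str | Path) -> Path:
    """Serialize an ROI mask as an 8-bit PNG (0 = outside, 255 = member)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(path, (mask.mask.astype(np.uint8) * 255))
    return path


def read_mask(path: str | Path, frame_index: int = 0) -> RoiMask:
    arr = np.asarray(iio.imread(path))
    if arr.ndim == 3:  # collapse any color channels
        arr = arr[..., 0]
    return RoiMask(arr > 127, frame_index=frame_index)
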