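"""Reading plate-scan images and writing tabular outputs.

One stitched PNG per well is the input contract (the scanner writes a
lossless mosaic per well).  Images are normalized to floating point in
[0, 1] regardless of source bit depth so that all downstream math is
uniform; well identity and timepoint are parsed from the filename with a
configurable regular expression because scanner naming dialects vary.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np

from .errors import ContractError, ImageIOError, MetadataError

#: QC flags that can travel on a per-well count record.
QC_OVOID = "OVOID"
QC_NO_WELL_FOUND = "NO_WELL_FOUND"
QC_LOW_MASK_AREA = "LOW_MASK_AREA"
QC_FLAGS = frozenset({QC_OVOID, QC_NO_WELL_FOUND, QC_LOW_MASK_AREA})

#: Default filename dialect: ``[plate_]day<N>_<WELL>.png`` or
#: ``[anything_]<WELL>.png``.  Named groups: ``well`` (required), ``plate``
#: and ``day`` (optional).
DEFAULT_FILENAME_PATTERN = (
    r"^(?:(?P<plate>\w+?)_day(?P<day>\d+)_|.*?_)?"
    r"(?P<well>[A-Ha-h](?:0?[1-9]|1[0-2]))\.(?:png|PNG)$"
)

_CHANNEL_POLICIES = ("luminance", "red", "green", "blue", "max")
#: ITU-R BT.601 luma weights.
_LUMA = np.array([0.299, 0.587, 0.114])


def normalize_well_id(well: str) -> str:
    """Canonical well key: uppercase row letter + column without leading zeros."""
    m = re.fullmatch(r"([A-Ha-h])0*([1-9]\d?)", well.strip())
    if m is None:
        raise MetadataError(f"not a well id: {well!r}")
    return m.group(1).upper() + m.group(2)


def well_row_col(well_id: str) -> tuple[int, int]:
    """0-based (row, col) indices of a well id like ``'B7'``."""
    w = normalize_well_id(well_id)
    return ord(w[0]) - ord("A"), int(w[1:]) - 1


@dataclass(frozen=True)
class PlateLayout:
    """Geometry of the plate format (rows x columns, growth area per well)."""

    n_rows: int = 8
    n_cols: int = 12
    well_area_cm2: float = 0.32

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ContractError("plate layout must have positive dimensions")
        if self.well_area_cm2 <= 0:
            raise ContractError("well_area_cm2 must be > 0")

    @property
    def n_wells(self) -> int:
        return self.n_rows * self.n_cols

    def well_ids(self) -> list[str]:
        return [
            chr(ord("A") + r) + str(c + 1)
            for r in range(self.n_rows)
            for c in range(self.n_cols)
        ]


@dataclass
class TiledWellImage:
    """One stitched per-well mosaic plus its identity and tile geometry.

    ``pixels`` is a 2-D float array in [0, 1]; ``bit_depth`` records the
    source quantization (8 or 16 bits per channel).
    """

    pixels: np.ndarray
    bit_depth: int = 8
    plate_id: str = "plate1"
    well_id: str = "A1"
    timepoint: float = 0.0
    tile_rows: int = 3
    tile_cols: int = 4
    source_path: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2 or min(self.pixels.shape) < 2:
            raise ContractError("pixels must be 2-D with at least 2 rows and columns")
        if self.pixels.min() < 0 or self.pixels.max() > 1 + 1e-9:
            raise ContractError("pixel values must lie in [0, 1]")
        if self.tile_rows < 1 or self.tile_cols < 1:
            raise ContractError("tile_rows and tile_cols must be >= 1")
        self.well_id = normalize_well_id(self.well_id)
        if self.timepoint < 0:
            raise ContractError("timepoint must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def with_pixels(self, pixels: np.ndarray) -> "TiledWellImage":
        """Copy of this image with replaced pixel data (identity preserved)."""
        return replace(self, pixels=np.asarray(pixels, dtype=np.float64))


@dataclass(frozen=True)
class WellCountRecord:
    """Per-well, per-timepoint nucleus count with QC annotations."""

    plate_id: str
    well_id: str
    timepoint: float
    count: int
    qc_flags: frozenset = frozenset()
    mask_area_px: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "well_id", normalize_well_id(self.well_id))
        object.__setattr__(self, "timepoint", float(self.timepoint))
        object.__setattr__(self, "qc_flags", frozenset(self.qc_flags))
        if self.count < 0 or self.mask_area_px < 0:
            raise ContractError("count and mask_area_px must be non-negative")
        if not self.qc_flags <= QC_FLAGS:
            raise ContractError(f"unknown qc flags: {set(self.qc_flags) - QC_FLAGS}")


def parse_well_filename(
    name: str, pattern: str = DEFAULT_FILENAME_PATTERN
) -> tuple[str, str, float]:
    """Parse ``(plate_id, well_id, timepoint)`` from a scan filename.

    ``pattern`` must contain a named group ``well``; groups ``plate`` and
    ``day`` are optional and default to ``"plate1"`` and ``0``.
    """
    base = Path(name).name
    m = re.fullmatch(pattern, base)
    if m is None:
        raise MetadataError(
            f"filename {base!r} does not match well pattern {pattern!r}"
        )
    groups = m.groupdict()
    if "well" not in groups or groups["well"] is None:
        raise MetadataError(f"pattern {pattern!r} captured no 'well' group")
    well = normalize_well_id(groups["well"])
    plate = groups.get("plate") or "plate1"
    day = groups.get("day")
    timepoint = float(day) if day is not None else 0.0
    return plate, well, timepoint


def _collapse_channels(arr: np.ndarray, policy: str) -> np.ndarray:
    if policy not in _CHANNEL_POLICIES:
        raise ContractError(f"unknown channel policy {policy!r}")
    if arr.ndim == 2:
        return arr
    if arr.ndim != 3 or arr.shape[2] not in (3, 4):
        raise ImageIOError(f"unsupported image shape {arr.shape}")
    rgb = arr[:, :, :3].astype(np.float64)
    if policy == "luminance":
        return rgb @ _LUMA
    if policy == "max":
        return rgb.max(axis=2)
    return rgb[:, :, {"red": 0, "green": 1, "blue": 2}[policy]]


def read_well_image(
    path,
    channel_policy: str = "green",
    pattern: str = DEFAULT_FILENAME_PATTERN,
    tile_rows: int = 3,
    tile_cols: int = 4,
) -> TiledWellImage:
    """Read one per-well PNG into the normalized internal representation.

    The default channel policy keeps the green channel (nuclear GFP signal);
    grayscale sources are passed through unchanged.  Pixel values are
    divided by ``2**bit_depth - 1``.
    """
    path = Path(path)
    try:
        arr = iio.imread(path)
    except Exception as exc:  # imageio raises various concrete types
        raise ImageIOError(f"cannot read image {path}: {exc}") from exc
    if arr.dtype == np.uint8:
        bit_depth = 8
    elif arr.dtype == np.uint16:
        bit_depth = 16
    else:
        raise ImageIOError(f"{path}: unsupported dtype {arr.dtype}, expected 8/16-bit")
    plate, well, timepoint = parse_well_filename(path.name, pattern)
    gray = _collapse_channels(arr, channel_policy)
    pixels = gray.astype(np.float64) / float(2**bit_depth - 1)
    return TiledWellImage(
        pixels=pixels,
        bit_depth=bit_depth,
        plate_id=plate,
        well_id=well,
        timepoint=timepoint,
        tile_rows=tile_rows,
        tile_cols=tile_cols,
        source_path=str(path),
    )


def write_well_image(image: TiledWellImage, path, bit_depth: int = 8) -> Path:
    """Write pixels back to an 8- or 16-bit grayscale PNG."""
    path = Path(path)
    if bit_depth == 8:
        arr = np.round(np.clip(image.pixels, 0, 1) * 255).astype(np.uint8)
    elif bit_depth == 16:
        arr = np.round(np.clip(image.pixels, 0, 1) * 65535).astype(np.uint16)
    else:
        raise ContractError("bit_depth must be 8 or 16")
    try:
        iio.imwrite(path, arr)
    except Exception as exc:
        raise ImageIOError(f"cannot write image {path}: {exc}") from exc
    return path


_CSV_HEADER = ["plate_id", "well_id", "timepoint", "count", "mask_area_px", "qc_flags"]


def _record_sort_key(r: WellCountRecord):
    row, col = well_row_col(r.well_id)
    return (r.plate_id, r.timepoint, row, col)


def write_counts_csv(records: Sequence[WellCountRecord], path) -> Path:
    """Write count records as RFC-4180 CSV (UTF-8, LF), deterministically ordered.

    Rows are sorted by (plate, timepoint, well row, well column) so output is
    independent of input order.  ``qc_flags`` are ';'-joined in sorted order.
    """
    path = Path(path)
    rows = sorted(records, key=_record_sort_key)
    try:
        with open(path, "w", encoding="utf-8", newline="") as fh:
            w = csv.writer(fh, lineterminator="\n")
            w.writerow(_CSV_HEADER)
            for r in rows:
                w.writerow(
                    [
                        r.plate_id,
                        r.well_id,
                        f"{r.timepoint:g}",
                        r.count,
                        r.mask_area_px,
                        ";".join(sorted(r.qc_flags)),
                    ]
                )
    except OSError as exc:
        raise ImageIOError(f"cannot write counts CSV {path}: {exc}") from exc
    return path


def read_counts_csv(path) -> list[WellCountRecord]:
    """Inverse of :func:`write_counts_csv` (field-wise identical records)."""
    path = Path(path)
    out: list[WellCountRecord] = []
    try:
        with open(path, "r", encoding="utf-8", newline="") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames != _CSV_HEADER:
                raise ImageIOError(
                    f"{path}: unexpected header {reader.fieldnames}"
                )
            for row in reader:
                flags = frozenset(
                    f for f in (row["qc_flags"] or "").split(";") if f
                )
                out.append(
                    WellCountRecord(
                        plate_id=row["plate_id"],
                        well_id=row["well_id"],
                        timepoint=float(row["timepoint"]),
                        count=int(row["count"]),
                        qc_flags=flags,
                        mask_area_px=int(row["mask_area_px"]),
                    )
                )
    except OSError as exc:
        raise ImageIOError(f"cannot read counts CSV {path}: {exc}") from exc
    return out
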