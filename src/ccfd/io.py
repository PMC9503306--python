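"""Raster and report I/O.

Images are single-channel 8- or 16-bit TIFF/PNG.  Deficit masks are
serialized as 8-bit images with deficit = 0 (black) and flow = 255,
so a mask renders the way flow deficits are conventionally displayed.
Reports are RFC-4180 CSV with a header row and dot decimal separator;
an optional leading ``#`` comment line records the parameter set that
produced the numbers.
"""

from __future__ import annotations

import io as _stdio
from pathlib import Path
from typing import Iterable

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .geometry import BinaryMask, Channel, EnFaceImage, ScanGeometry, ValidationError
from .quant import FDReport

REPORT_COLUMNS = [
    "eye_id", "group", "radius_px",
    "fd_percent", "fd_count", "fd_mean_size_um2", "fd_total_area_mm2",
]


def read_enface(path: str | Path, geometry: ScanGeometry, channel: Channel) -> EnFaceImage:
    """Read a single-channel raster and attach scan geometry.

    Raises
    ------
    OSError
        If the file is missing or does not decode.
    ValidationError
        If the raster is multi-channel, has an unsupported dtype, or its
        dimensions disagree with ``geometry``.
    """
    path = Path(path)
    arr = iio.imread(path)
    if arr.ndim != 2:
        raise ValidationError(
            f"{path.name}: expected a single-channel image, got shape {arr.shape}"
        )
    if arr.dtype == np.uint8:
        bit_depth = 8
    elif arr.dtype == np.uint16:
        bit_depth = 16
    else:
        raise ValidationError(f"{path.name}: unsupported dtype {arr.dtype}")
    return EnFaceImage(arr, bit_depth, geometry, channel)


def write_enface(image: EnFaceImage, path: str | Path) -> None:
    """Write an image's raw pixel grid to TIFF or PNG (by suffix)."""
    iio.imwrite(Path(path), image.pixels)


def write_mask(mask: BinaryMask, path: str | Path) -> None:
    """Serialize a mask as 8-bit, deficit -> 0, flow -> 255."""
    raster = np.where(mask.pixels, 0, 255).astype(np.uint8)
    iio.imwrite(Path(path), raster)


def read_mask(path: str | Path, geometry: ScanGeometry, radius_px: int = 0) -> BinaryMask:
    """Read a mask written by :func:`write_mask` (0 = deficit)."""
    arr = iio.imread(Path(path))
    if arr.ndim != 2:
        raise ValidationError(f"{Path(path).name}: mask must be single-channel")
    return BinaryMask(arr == 0, geometry, radius_px)


def write_report(
    reports: Iterable[tuple[str, str, FDReport]],
    path: str | Path,
    header_comment: str | None = None,
) -> None:
    """Write per-eye FD reports as CSV, one row per eye per radius.

    ``reports`` yields ``(eye_id, group, FDReport)`` triples.
    ``header_comment`` (parameter provenance) is written as a leading
    ``#`` line; readers must pass ``comment='#'``.
    """
    rows = [
        {
            "eye_id": eye_id,
            "group": group,
            "radius_px": rep.radius_px,
            "fd_percent": rep.fd_percent,
            "fd_count": rep.fd_count,
            "fd_mean_size_um2": rep.fd_mean_size_um2,
            "fd_total_area_mm2": rep.fd_total_area_mm2,
        }
        for eye_id, group, rep in reports
    ]
    df = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    buf = _stdio.StringIO()
    if header_comment:
        for line in header_comment.splitlines():
            buf.write(f"# {line}\n")
    df.to_csv(buf, index=False, lineterminator="\n")
    Path(path).write_text(buf.getvalue())


def read_report(path: str | Path) -> pd.DataFrame:
    """Read a report CSV written by :func:`write_report`."""
    return pd.read_csv(path, comment="#")
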