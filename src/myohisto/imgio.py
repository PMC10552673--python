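"""Raster image and result-table I/O.

All images are held in floating point with intensities on [0, 1],
row-major, 0-based, (row, col) indexed with the origin at the top left.
Integer sample values read from disk are normalised by the maximum
representable value of their bit depth (255 for 8-bit, 65535 for 16-bit),
so an 8-bit pixel of 255 and a 16-bit pixel of 65535 both map to 1.0.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import tifffile
from PIL import Image

__all__ = [
    "MultichannelImage",
    "GrayImage",
    "BinaryMask",
    "UnsupportedImageError",
    "read_image",
    "write_image",
    "write_results_csv",
    "write_object_sizes_csv",
]

RGB = ("red", "green", "blue")


class UnsupportedImageError(ValueError):
    """Raised for files whose layout is not a 2-D single- or multi-channel raster."""


def _check_unit_interval(pixels: np.ndarray, what: str) -> None:
    if not np.isfinite(pixels).all():
        raise ValueError(f"{what}: non-finite intensity values")
    if pixels.size and (pixels.min() < 0.0 or pixels.max() > 1.0):
        raise ValueError(f"{what}: intensities must lie in [0, 1]")


@dataclass
class MultichannelImage:
    """A 2-D multichannel raster with named channels.

    pixels has shape (H, W, C); channel order is preserved exactly as read.
    """

    pixels: np.ndarray
    channel_names: tuple[str, ...]
    source_path: str | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        self.channel_names = tuple(self.channel_names)
        if self.pixels.ndim != 3:
            raise ValueError("MultichannelImage pixels must be H x W x C")
        h, w, c = self.pixels.shape
        if h < 1 or w < 1:
            raise ValueError("image must have at least one row and column")
        if c != len(self.channel_names):
            raise ValueError(
                f"channel count {c} does not match channel_names {self.channel_names}"
            )
        _check_unit_interval(self.pixels, "MultichannelImage")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.pixels.shape

    def channel(self, name: str) -> "GrayImage":
        if name not in self.channel_names:
            raise ValueError(f"no channel named {name!r}; have {self.channel_names}")
        idx = self.channel_names.index(name)
        return GrayImage(self.pixels[:, :, idx])


@dataclass
class GrayImage:
    """A single-channel raster, intensities on [0, 1]."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError("GrayImage pixels must be H x W")
        _check_unit_interval(self.pixels, "GrayImage")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class BinaryMask:
    """A {0, 1}-valued raster; 1 is foreground."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels)
        if arr.ndim != 2:
            raise ValueError("BinaryMask pixels must be H x W")
        vals = np.unique(arr)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError("BinaryMask may contain only 0 and 1")
        self.pixels = arr.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def _normalise_integer(arr: np.ndarray) -> np.ndarray:
    if arr.dtype == np.uint8:
        return arr.astype(np.float64) / 255.0
    if arr.dtype == np.uint16:
        return arr.astype(np.float64) / 65535.0
    if arr.dtype == bool:
        return arr.astype(np.float64)
    if np.issubdtype(arr.dtype, np.integer):
        info = np.iinfo(arr.dtype)
        return arr.astype(np.float64) / float(info.max)
    if np.issubdtype(arr.dtype, np.floating):
        out = arr.astype(np.float64)
        if out.size and (out.min() < 0.0 or out.max() > 1.0):
            raise UnsupportedImageError(
                "floating-point image with intensities outside [0, 1]"
            )
        return out
    raise UnsupportedImageError(f"unsupported sample dtype {arr.dtype}")


def read_image(path: str | Path) -> MultichannelImage:
    """Read a TIFF or PNG file into a MultichannelImage.

    Grayscale files yield a single channel named ``gray``; RGB files yield
    channels ``red``, ``green``, ``blue``. Alpha channels are dropped and
    palette PNGs are expanded to RGB. Files with more than two spatial
    dimensions (z-stacks, time series) are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"cannot read image: no such file {path}")
    suffix = path.suffix.lower()
    try:
        if suffix in (".tif", ".tiff"):
            arr = tifffile.imread(path)
        else:
            with Image.open(path) as im:
                if im.mode == "P":
                    im = im.convert("RGB")
                arr = np.asarray(im)
    except UnsupportedImageError:
        raise
    except Exception as exc:  # noqa: BLE001 - re-raise with the path named
        raise IOError(f"cannot read image {path}: {exc}") from exc

    if arr.ndim == 2:
        return MultichannelImage(
            _normalise_integer(arr)[:, :, None], ("gray",), str(path)
        )
    if arr.ndim == 3:
        c = arr.shape[2]
        if c == 2:  # gray + alpha
            return MultichannelImage(
                _normalise_integer(arr[:, :, 0])[:, :, None], ("gray",), str(path)
            )
        if c in (3, 4):
            return MultichannelImage(_normalise_integer(arr[:, :, :3]), RGB, str(path))
    raise UnsupportedImageError(
        f"{path}: images with more than 2 spatial dimensions are not supported "
        f"(got array of shape {arr.shape})"
    )


def _as_pixel_array(img: MultichannelImage | GrayImage | BinaryMask) -> np.ndarray:
    if isinstance(img, MultichannelImage):
        return img.pixels
    if isinstance(img, (GrayImage, BinaryMask)):
        return np.asarray(img.pixels, dtype=np.float64)
    raise TypeError(f"cannot write object of type {type(img).__name__}")


def write_image(img: MultichannelImage | GrayImage | BinaryMask, path: str | Path) -> None:
    """Write an image to TIFF (16-bit) or PNG (8-bit).

    TIFF output quantises to 16 bits, so a read-back reproduces intensities
    to within one part in 65535; PNG output is 8-bit.
    """
    path = Path(path)
    if not path.parent.exists():
        raise IOError(f"cannot write image: no such directory {path.parent}")
    arr = _as_pixel_array(img)
    suffix = path.suffix.lower()
    try:
        if suffix in (".tif", ".tiff"):
            tifffile.imwrite(path, np.round(arr * 65535.0).astype(np.uint16))
        elif suffix == ".png":
            data = np.round(arr * 255.0).astype(np.uint8)
            Image.fromarray(data.squeeze()).save(path)
        else:
            raise IOError(f"unsupported output format {suffix!r}; use .tif or .png")
    except IOError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise IOError(f"cannot write image {path}: {exc}") from exc


def _fmt(value: float | int) -> str:
    if isinstance(value, (int, np.integer)):
        return str(int(value))
    return format(float(value), ".10g")


def write_results_csv(results: Sequence, path: str | Path) -> None:
    """Write one CSV row per per-image assay result.

    All results must come from the same assay; the column schema is
    assay-specific (see :mod:`myohisto.pipelines`). An empty list writes
    the header row only — the schema then defaults to the damage-counting
    assay's columns.
    """
    from .pipelines import ASSAY_CSV_COLUMNS  # deferred: avoids an import cycle

    results = list(results)
    assays = {r.assay for r in results}
    if len(assays) > 1:
        raise ValueError(f"mixed assay types in one results file: {sorted(assays)}")
    assay = next(iter(assays)) if assays else "ebd"
    columns = ASSAY_CSV_COLUMNS[assay]
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(columns)
        for r in results:
            writer.writerow([_fmt(v) if isinstance(v, (int, float, np.integer, np.floating)) else v
                             for v in r.csv_row(columns)])


def write_object_sizes_csv(results: Sequence, path: str | Path) -> None:
    """Write the per-object companion file (image_id, label, area_px)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["image_id", "label", "area_px"])
        for r in results:
            for label, area in enumerate(r.sizes or (), start=1):
                writer.writerow([r.image_id, label, _fmt(area)])
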