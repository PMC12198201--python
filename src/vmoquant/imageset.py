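"""Micrograph batch handling: I/O, type classification, coloring, cropping.

Micrographs arrive as single-plane 8- or 16-bit grayscale TIFFs in
per-device directories.  Within a directory, image types (Vessels, Tumor,
Perfusion, or Ignore) follow the acquisition order cyclically over the
sorted file names, so classification assigns labels sequentially.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile

__all__ = [
    "TYPE_LABELS",
    "ImageRecord",
    "ImagePlane",
    "CropRect",
    "ClassificationError",
    "read_plane",
    "write_plane",
    "classify_images",
    "classify_directory",
    "colorize",
    "merge",
    "crop",
    "crop_batch",
]

TYPE_LABELS = ("Vessels", "Tumor", "Perfusion", "Ignore")

_COLOR_CHANNELS = {
    "red": (1, 0, 0), "green": (0, 1, 0), "blue": (0, 0, 1),
    "cyan": (0, 1, 1), "magenta": (1, 0, 1), "yellow": (1, 1, 0),
    "gray": (1, 1, 1),
}


class ClassificationError(ValueError):
    pass


@dataclass
class ImagePlane:
    """Single 2D grayscale plane with its nominal bit depth."""

    values: np.ndarray
    bit_depth: int = 8

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2 or 0 in self.values.shape:
            raise ValueError("image must be a non-empty 2D plane")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")
        if self.values.size and self.values.max() > 2 ** self.bit_depth - 1:
            raise ValueError("intensities exceed bit depth")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass(frozen=True)
class ImageRecord:
    path: Path
    type_label: str
    device_id: str
    series_index: int
    pixel_size_um: float | None = None

    def __post_init__(self) -> None:
        if self.type_label not in TYPE_LABELS:
            raise ClassificationError(f"unknown image type {self.type_label!r}")


@dataclass(frozen=True)
class CropRect:
    """Top-left (x, y) with 0-based origin at the image top-left, y down."""

    x: int
    y: int
    w: int
    h: int

    def __post_init__(self) -> None:
        if self.w <= 0 or self.h <= 0:
            raise ValueError("crop width and height must be positive")
        if self.x < 0 or self.y < 0:
            raise ValueError("crop origin must be non-negative")


def read_plane(path) -> ImagePlane:
    arr = np.squeeze(tifffile.imread(str(path)))
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected a single grayscale plane, got {arr.shape}")
    depth = 16 if arr.dtype.itemsize >= 2 else 8
    return ImagePlane(values=arr, bit_depth=depth)


def write_plane(path, values: np.ndarray) -> None:
    tifffile.imwrite(str(path), np.asarray(values))


def classify_images(file_list, type_order, device_id: str = "",
                    pixel_size_um: float | None = None) -> list[ImageRecord]:
    """Assign type labels cyclically over sorted file names.

    The file count must be a positive multiple of the number of types.
    Records labeled Ignore are returned too (for audit) but are meant to be
    excluded from downstream processing.
    """
    if not type_order:
        raise ClassificationError("type_order must be non-empty")
    for label in type_order:
        if label not in TYPE_LABELS:
            raise ClassificationError(
                f"unknown image type {label!r}; must be one of {TYPE_LABELS}")
    files = sorted(Path(p) for p in file_list)
    if not files or len(files) % len(type_order) != 0:
        where = files[0].parent if files else device_id or "<empty>"
        raise ClassificationError(
            f"{where}: {len(files)} images is not a positive multiple of "
            f"{len(type_order)} image types")
    counters = {label: 0 for label in type_order}
    records = []
    for i, path in enumerate(files):
        label = type_order[i % len(type_order)]
        records.append(ImageRecord(path=path, type_label=label,
                                   device_id=device_id or path.parent.name,
                                   series_index=counters[label],
                                   pixel_size_um=pixel_size_um))
        counters[label] += 1
    return records


def classify_directory(root, type_order, pattern: str = "*.tif*",
                       pixel_size_um: float | None = None,
                       ) -> dict[str, list[ImageRecord]]:
    """Classify every sub-directory of ``root`` (device grouping by folder).

    A directory whose image count does not divide evenly raises per that
    directory; callers may catch and continue with the others.
    """
    root = Path(root)
    out: dict[str, list[ImageRecord]] = {}
    subdirs = [d for d in sorted(root.iterdir()) if d.is_dir()]
    targets = subdirs or [root]
    for d in targets:
        files = sorted(d.glob(pattern))
        if not files:
            continue
        out[d.name] = classify_images(files, type_order, device_id=d.name,
                                      pixel_size_um=pixel_size_um)
    if not out:
        raise ClassificationError(f"{root}: no TIFF images found")
    return out


def _to_8bit(plane: ImagePlane) -> np.ndarray:
    """Linear min-max display mapping of 16-bit data to 8-bit."""
    v = plane.values.astype(np.float64)
    if plane.bit_depth == 8:
        return plane.values.astype(np.uint8)
    lo, hi = v.min(), v.max()
    if hi == lo:
        return np.zeros(plane.shape, np.uint8)
    return np.round((v - lo) / (hi - lo) * 255.0).astype(np.uint8)


def colorize(plane: ImagePlane, color: str) -> np.ndarray:
    """Place the (display-rescaled) intensities into the named RGB channels."""
    if color not in _COLOR_CHANNELS:
        raise ValueError(f"unknown color {color!r}; choose from {sorted(_COLOR_CHANNELS)}")
    mono = _to_8bit(plane)
    rgb = np.zeros(plane.shape + (3,), np.uint8)
    for ch, on in enumerate(_COLOR_CHANNELS[color]):
        if on:
            rgb[..., ch] = mono
    return rgb


def merge(images: list[np.ndarray]) -> np.ndarray:
    """Per-pixel, per-channel additive blend of RGB images, clipped to 255."""
    if len(images) < 2:
        raise ValueError("merge needs at least 2 images")
    shape = images[0].shape
    bad = [i for i, im in enumerate(images) if im.shape != shape]
    if bad:
        raise ValueError(f"dimension mismatch at input(s) {bad}; expected {shape}")
    acc = np.zeros(shape, np.uint16)
    for im in images:
        acc += im.astype(np.uint16)
    return np.clip(acc, 0, 255).astype(np.uint8)


def crop(values: np.ndarray, rect: CropRect) -> np.ndarray:
    h, w = values.shape[:2]
    if rect.x + rect.w > w or rect.y + rect.h > h:
        raise ValueError(f"crop rect {rect} exceeds {w}x{h} image bounds")
    return values[rect.y:rect.y + rect.h, rect.x:rect.x + rect.w].copy()


def crop_batch(records: list[ImageRecord], rect_mode: str, rects,
               out_dir) -> list[Path]:
    """Crop a batch of records into ``out_dir`` as TIFFs.

    ``rect_mode`` is one of batch (one rect for all), per_device (a mapping
    device_id -> rect) or per_image (one rect per record, in order).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for i, rec in enumerate(records):
        if rect_mode == "batch":
            rect = rects if isinstance(rects, CropRect) else rects[0]
        elif rect_mode == "per_device":
            rect = rects[rec.device_id]
        elif rect_mode == "per_image":
            rect = rects[i]
        else:
            raise ValueError(f"unknown rect_mode {rect_mode!r}")
        plane = read_plane(rec.path)
        target = out_dir / rec.path.name
        write_plane(target, crop(plane.values, rect))
        written.append(target)
    return written
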