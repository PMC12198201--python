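"""Tumor mask morphometry and gray-level statistics.

Shape descriptors follow the conventions of the standard image-analysis
environment: circularity = 4*pi*A/P^2 (capped at 1), roundness =
4*A/(pi*major_axis^2) with the major axis from the fitted ellipse of the
largest component, and solidity = A / convex-hull area.  Multi-component
masks (spheroids dispersing over time) aggregate area and perimeter over all
components.  Longitudinal series are normalized to their baseline timepoint.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage import measure, morphology

from .segmentation import BinaryMask

__all__ = [
    "TumorMetrics",
    "GrayStats",
    "NormalizedSeries",
    "measure_tumor",
    "measure_gray",
    "normalize_to_baseline",
]


@dataclass
class GrayStats:
    mean_gray: float
    modal_gray: float
    min_gray: float
    std_gray: float


@dataclass
class TumorMetrics:
    area_px: int
    mean_gray: float | None = None
    modal_gray: float | None = None
    min_gray: float | None = None
    std_gray: float | None = None
    integrated_density: float | None = None
    whole_image_mean_gray: float | None = None
    circularity: float | None = None
    roundness: float | None = None
    solidity: float | None = None
    perimeter_px: float | None = None
    major_axis_px: float | None = None
    area_um2: float | None = None
    n_components: int = 0

    def as_row(self) -> dict:
        return {k: getattr(self, k) for k in (
            "area_px", "area_um2", "mean_gray", "modal_gray", "min_gray",
            "std_gray", "integrated_density", "whole_image_mean_gray",
            "circularity", "roundness", "solidity", "perimeter_px",
            "major_axis_px", "n_components")}


@dataclass
class NormalizedSeries:
    metric: str
    values: list[float]
    baseline_index: int


def measure_gray(img: np.ndarray, mask: BinaryMask | None = None) -> GrayStats:
    """Mean / modal / minimum / population-SD of gray values.

    With a mask, statistics are restricted to foreground pixels; the modal
    value is the most frequent intensity, ties resolved to the smaller value.
    """
    arr = np.asarray(img)
    if mask is not None:
        if mask.values.shape != arr.shape:
            raise ValueError("mask and image dimensions differ")
        sel = arr[mask.values]
    else:
        sel = arr.ravel()
    if sel.size == 0:
        raise ValueError("no pixels selected for gray statistics")
    vals, counts = np.unique(sel, return_counts=True)
    modal = vals[np.argmax(counts)]  # np.unique sorts: first max is smallest
    return GrayStats(mean_gray=float(sel.mean()), modal_gray=float(modal),
                     min_gray=float(sel.min()), std_gray=float(sel.std(ddof=0)))


def measure_tumor(mask: BinaryMask, img: np.ndarray,
                  pixel_size_um: float | None = None) -> TumorMetrics:
    """Area, gray statistics and shape descriptors of a tumor mask.

    Empty masks return area 0 with shape fields absent.  For multi-component
    masks the area, perimeter and convex hull aggregate over the union while
    the ellipse axes come from the largest component.
    """
    arr = np.asarray(img)
    fg = mask.values
    if fg.shape != arr.shape:
        raise ValueError("mask and image dimensions differ")
    area = int(fg.sum())
    if area == 0:
        return TumorMetrics(area_px=0, n_components=0,
                            whole_image_mean_gray=float(arr.mean()))

    gray = measure_gray(arr, mask)
    lab, n = ndi.label(fg, structure=np.ones((3, 3)))
    perim = float(measure.perimeter(fg, neighborhood=4))
    hull = morphology.convex_hull_image(fg)
    solidity = min(1.0, area / float(hull.sum()))
    sizes = np.bincount(lab.ravel())[1:]
    largest = (lab == (1 + int(np.argmax(sizes))))
    props = measure.regionprops(largest.astype(np.uint8))[0]
    major = float(props.axis_major_length)
    circularity = min(1.0, 4.0 * math.pi * area / perim ** 2) if perim > 0 else None
    roundness = 4.0 * area / (math.pi * major ** 2) if major > 0 else None
    return TumorMetrics(
        area_px=area,
        area_um2=area * pixel_size_um ** 2 if pixel_size_um else None,
        mean_gray=gray.mean_gray, modal_gray=gray.modal_gray,
        min_gray=gray.min_gray, std_gray=gray.std_gray,
        integrated_density=gray.mean_gray * area,
        whole_image_mean_gray=float(arr.mean()),
        circularity=circularity, roundness=roundness, solidity=solidity,
        perimeter_px=perim, major_axis_px=major, n_components=int(n),
    )


def normalize_to_baseline(values, baseline_index: int = 0,
                          metric: str = "") -> NormalizedSeries:
    """Divide a longitudinal metric series by its baseline value."""
    vals = [float(v) for v in values]
    if not 0 <= baseline_index < len(vals):
        raise IndexError("baseline_index outside series")
    base = vals[baseline_index]
    if base == 0:
        raise ZeroDivisionError(
            f"series {metric or '<unnamed>'}: baseline value is zero")
    return NormalizedSeries(metric=metric, values=[v / base for v in vals],
                            baseline_index=baseline_index)
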