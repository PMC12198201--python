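"""Vascular permeability and perfusion quantification from time-lapse images.

Permeability follows the two-point extravasation model: for an extravascular
region of interest with initial mean intensity I_i, final intensity I_f and
a constant background I_b,

    PD = 1/(I_i - I_b) * (I_f - I_i)/dt * Vol/SA,     Vol/SA ~ d/4,

where d is the mean vessel diameter and dt the elapsed time between the
first and last frame.  PD carries units of length/time when d does (the
intensity ratio is dimensionless, so uniform offsets and gain cancel).

Perfusion is quantified by mask subtraction: regions present at a later
timepoint but absent in the reference mask are extravascular leak; the
composite score is final leak area over reference vascular area.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage import draw
from skimage.registration import phase_cross_correlation

from .segmentation import BinaryMask

__all__ = [
    "RoiSpec",
    "PermeabilityInputs",
    "PermeabilityResult",
    "PerfusionResult",
    "measure_roi_series",
    "permeability_coefficient",
    "estimate_permeability",
    "perfusion_subtract",
]


@dataclass(frozen=True)
class RoiSpec:
    """Circular region of interest: center (x, y) in pixels, radius, role."""

    center: tuple[int, int]
    radius: int = 25
    kind: str = "measurement"     # or "background"

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("ROI radius must be > 0")
        if self.kind not in ("measurement", "background"):
            raise ValueError(f"unknown ROI kind {self.kind!r}")

    def disk(self, shape) -> tuple[np.ndarray, np.ndarray]:
        x, y = self.center
        h, w = shape
        if not (self.radius <= x < w - self.radius and
                self.radius <= y < h - self.radius):
            raise ValueError(f"ROI at ({x}, {y}) r={self.radius} exceeds {w}x{h} image")
        return draw.disk((y, x), self.radius, shape=shape)


@dataclass
class PermeabilityInputs:
    i_initial: float
    i_final: float
    i_background: float
    delta_t: float                # seconds between first and last frame
    d: float                      # mean vessel diameter (length units)

    def __post_init__(self) -> None:
        if self.i_initial <= self.i_background:
            raise ZeroDivisionError(
                "initial intensity must exceed background (I_i > I_b)")
        if self.delta_t <= 0:
            raise ValueError("delta_t must be > 0")
        if self.d <= 0:
            raise ValueError("vessel diameter must be > 0")


@dataclass
class PermeabilityResult:
    pd_per_roi: list[float]
    mean_pd: float
    sd_pd: float
    rois: list[RoiSpec] = field(default_factory=list)


@dataclass
class PerfusionResult:
    leak_area_px: list[int]       # one per non-reference timepoint, in order
    leak_mean_intensity: list[float]
    composite_score: float | None
    reference_area_px: int
    reference_index: int
    # the composite-score definition (final leak area / reference vascular
    # area) is one reading of "composite score based on total perfusable
    # vascular area"; flagged here so downstream users see the convention
    composite_definition: str = "leak_area(final) / area(reference mask)"


def align_frames(frames: list[np.ndarray]) -> list[np.ndarray]:
    """Integer-pixel translation alignment of all frames to the first."""
    ref = np.asarray(frames[0], dtype=np.float64)
    out = [np.asarray(frames[0])]
    for f in frames[1:]:
        shift, _, _ = phase_cross_correlation(ref, np.asarray(f, dtype=np.float64),
                                              upsample_factor=1)
        dy, dx = (int(round(s)) for s in shift)
        out.append(np.roll(np.asarray(f), (dy, dx), axis=(0, 1)))
    return out


def measure_roi_series(frames: list[np.ndarray], rois: list[RoiSpec],
                       align: bool = False) -> dict[RoiSpec, np.ndarray]:
    """Mean intensity of every ROI disk in every frame.

    Frames must share dimensions; with ``align`` an integer-pixel
    translation (estimated by phase correlation against the first frame) is
    applied identically before sampling.
    """
    if len(frames) < 2:
        raise ValueError("need at least 2 frames")
    shape = np.asarray(frames[0]).shape
    for f in frames[1:]:
        if np.asarray(f).shape != shape:
            raise ValueError("all frames must share dimensions")
    if align:
        frames = align_frames(frames)
    out: dict[RoiSpec, np.ndarray] = {}
    for roi in rois:
        rr, cc = roi.disk(shape)
        out[roi] = np.array([float(np.asarray(f, dtype=np.float64)[rr, cc].mean())
                             for f in frames])
    return out


def permeability_coefficient(inputs: PermeabilityInputs) -> float:
    """Two-point permeability coefficient PD (length/time)."""
    return (1.0 / (inputs.i_initial - inputs.i_background)
            * (inputs.i_final - inputs.i_initial) / inputs.delta_t
            * inputs.d / 4.0)


def estimate_permeability(frames: list[np.ndarray], rois: list[RoiSpec],
                          dt_s: float, d: float,
                          align: bool = False) -> PermeabilityResult:
    """Per-ROI PD from a time series: first frame initial, last frame final.

    Exactly one background ROI supplies I_b (its first-frame mean, constant
    by assumption); every measurement ROI yields one PD.
    """
    bg = [r for r in rois if r.kind == "background"]
    meas = [r for r in rois if r.kind == "measurement"]
    if len(bg) != 1:
        raise ValueError(f"exactly one background ROI required, got {len(bg)}")
    if not meas:
        raise ValueError("at least one measurement ROI required")
    series = measure_roi_series(frames, rois, align=align)
    i_b = float(series[bg[0]][0])
    total_dt = dt_s * (len(frames) - 1)
    pds = []
    for roi in meas:
        s = series[roi]
        pds.append(permeability_coefficient(PermeabilityInputs(
            i_initial=float(s[0]), i_final=float(s[-1]), i_background=i_b,
            delta_t=total_dt, d=d)))
    arr = np.array(pds)
    return PermeabilityResult(pd_per_roi=pds, mean_pd=float(arr.mean()),
                              sd_pd=float(arr.std(ddof=1)) if len(pds) > 1 else 0.0,
                              rois=list(rois))


def perfusion_subtract(masks: list[BinaryMask], reference_index: int,
                       frames: list[np.ndarray] | None = None) -> PerfusionResult:
    """Leak regions by reference-mask subtraction.

    For each non-reference timepoint t, leak = mask_t AND NOT mask_ref;
    the leak area and (when frames are given) its mean intensity on frame_t
    are reported, plus the composite score leak_area(final)/area(reference).
    An empty reference mask leaves the composite undefined but still reports
    the leak areas.
    """
    if not 0 <= reference_index < len(masks):
        raise IndexError("reference_index outside series")
    ref = masks[reference_index].values
    shape = ref.shape
    for m in masks:
        if m.values.shape != shape:
            raise ValueError("all masks must share dimensions")
    ref_area = int(ref.sum())
    areas: list[int] = []
    intensities: list[float] = []
    last_leak = 0
    for t, m in enumerate(masks):
        if t == reference_index:
            continue
        leak = m.values & ~ref
        a = int(leak.sum())
        areas.append(a)
        last_leak = a
        if frames is not None and a > 0:
            intensities.append(float(np.asarray(frames[t], dtype=np.float64)[leak].mean()))
        else:
            intensities.append(float("nan"))
    composite = last_leak / ref_area if ref_area > 0 else None
    return PerfusionResult(leak_area_px=areas, leak_mean_intensity=intensities,
                           composite_score=composite, reference_area_px=ref_area,
                           reference_index=reference_index)
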