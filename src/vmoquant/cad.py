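"""Vessel contour tracing, Fourier-descriptor smoothing and DXF export.

Traced vessel outlines feed a downstream 2D flow model: each 8-connected
mask component contributes one outer contour plus one contour per interior
hole, optionally smoothed by truncating the high-frequency Fourier
descriptors of the closed curve, and written as closed LWPOLYLINE entities
in a minimal ASCII DXF file.  Internal coordinates use the image convention
(x right, y down); the y-axis is flipped to CAD convention only at export.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from skimage import measure

__all__ = [
    "Contour",
    "trace_contours",
    "fd_smooth",
    "write_dxf",
    "read_dxf",
    "rasterize_contours",
]

_UNIT_CODES = {"px": 0, "unitless": 0, "um": 13, "µm": 13, "mm": 4}


@dataclass
class Contour:
    """Closed polygon in (x, y) image coordinates; closure is implied.

    ``is_hole`` marks interior (background-enclosing) boundaries.  Outer
    contours are counterclockwise and holes clockwise in the CAD (y-up)
    frame.
    """

    vertices: np.ndarray          # (n, 2) float, columns (x, y)
    is_hole: bool = False

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise ValueError("vertices must be (n, 2)")
        if len(self.vertices) < 3:
            raise ValueError("a contour needs at least 3 vertices")

    @property
    def signed_area(self) -> float:
        """Shoelace area in the image (y-down) frame."""
        x, y = self.vertices[:, 0], self.vertices[:, 1]
        return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))

    @property
    def area(self) -> float:
        return abs(self.signed_area)

    @property
    def perimeter(self) -> float:
        d = np.diff(np.vstack([self.vertices, self.vertices[:1]]), axis=0)
        return float(np.hypot(d[:, 0], d[:, 1]).sum())

    @property
    def centroid(self) -> tuple[float, float]:
        return tuple(self.vertices.mean(axis=0))


def trace_contours(mask) -> list[Contour]:
    """Sub-pixel boundaries of a binary mask at the 0.5 iso-level.

    With ``positive_orientation='high'`` the traced curve runs
    counterclockwise (in the y-down frame this is a negative shoelace sign)
    around foreground, so boundaries that enclose background — holes — are
    identified by the opposite orientation.
    """
    values = mask.values if hasattr(mask, "values") else np.asarray(mask, bool)
    if not values.any():
        return []
    padded = np.pad(values.astype(np.float64), 1)
    out = []
    for rc in measure.find_contours(padded, 0.5, fully_connected="high",
                                    positive_orientation="high"):
        rc = rc[:-1] if np.allclose(rc[0], rc[-1]) else rc
        if len(rc) < 3:
            continue
        xy = np.column_stack([rc[:, 1] - 1.0, rc[:, 0] - 1.0])  # undo pad
        c = Contour(xy)
        # positive_orientation='high' winds CCW around foreground in the
        # y-up frame, so outer boundaries have negative shoelace under y-down
        c.is_hole = c.signed_area > 0
        out.append(c)
    return out


def _next_pow2(n: int) -> int:
    return 1 << max(6, (n - 1).bit_length())        # at least 64


def resample_closed(vertices: np.ndarray, n: int) -> np.ndarray:
    """Resample a closed polygon to n points equally spaced in arc length."""
    closed = np.vstack([vertices, vertices[:1]])
    seg = np.hypot(*np.diff(closed, axis=0).T)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    targets = np.linspace(0.0, total, n, endpoint=False)
    x = np.interp(targets, s, closed[:, 0])
    y = np.interp(targets, s, closed[:, 1])
    return np.column_stack([x, y])


def fd_smooth(contour: Contour, keep_percent: float) -> Contour:
    """Low-pass the contour in the Fourier-descriptor domain.

    The contour is resampled to N points (N the next power of two, at least
    64), treated as complex samples x + iy, and all but the
    ceil(keep_percent * N / 100) lowest frequencies — kept symmetrically
    around frequency 0 — are zeroed before inverting.  keep_percent = 100
    returns the resampled contour unchanged; the frequency-0 descriptor is
    always retained, so the centroid is preserved exactly.
    """
    if not 0 < keep_percent <= 100:
        raise ValueError("keep_percent must be in (0, 100]")
    if len(contour.vertices) < 4:
        raise ValueError("need at least 4 vertices to smooth")
    n = _next_pow2(len(contour.vertices))
    pts = resample_closed(contour.vertices, n)
    z = pts[:, 0] + 1j * pts[:, 1]
    zf = np.fft.fft(z)
    n_keep = math.ceil(keep_percent * n / 100.0)
    order = np.argsort(np.abs(np.fft.fftfreq(n)), kind="stable")
    kill = order[n_keep:]
    zf[kill] = 0.0
    zs = np.fft.ifft(zf)
    return Contour(np.column_stack([zs.real, zs.imag]), is_hole=contour.is_hole)


# ---------------------------------------------------------------------------
# DXF

def write_dxf(contours: list[Contour], path, units: str = "px",
              image_height: float | None = None) -> None:
    """Write closed LWPOLYLINE entities to a minimal ASCII DXF file.

    The image y-axis (downward) is converted to the CAD y-axis (upward) via
    y' = image_height - y when ``image_height`` is given; pass None to keep
    raw coordinates.  ``units`` sets the $INSUNITS header (px/unitless, um,
    mm).
    """
    code = _UNIT_CODES.get(units)
    if code is None:
        raise ValueError(f"unknown units {units!r}")
    lines = [
        "0", "SECTION", "2", "HEADER",
        "9", "$ACADVER", "1", "AC1015",
        "9", "$INSUNITS", "70", str(code),
        "0", "ENDSEC",
        "0", "SECTION", "2", "ENTITIES",
    ]
    for c in contours:
        v = c.vertices.copy()
        if image_height is not None:
            v[:, 1] = image_height - v[:, 1]
        lines += ["0", "LWPOLYLINE",
                  "8", "holes" if c.is_hole else "vessels",
                  "90", str(len(v)),
                  "70", "1"]            # closed polyline flag
        for x, y in v:
            lines += ["10", f"{x:.6f}", "20", f"{y:.6f}"]
    lines += ["0", "ENDSEC", "0", "EOF"]
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_dxf(path) -> list[Contour]:
    """Parse LWPOLYLINE entities from an ASCII DXF file.

    A generic group-code/value pair reader: it walks the tagged stream and
    collects 10/20 coordinate pairs inside each LWPOLYLINE entity, so it does
    not depend on the ordering quirks of any particular writer.
    """
    with open(path) as fh:
        raw = [line.rstrip("\n") for line in fh]
    pairs = [(raw[i].strip(), raw[i + 1].strip()) for i in range(0, len(raw) - 1, 2)]
    contours = []
    current: list[list[float]] | None = None
    layer = ""
    for code, value in pairs:
        if code == "0":
            if current is not None and len(current) >= 3:
                contours.append(Contour(np.array(current), is_hole=layer == "holes"))
            current = [] if value == "LWPOLYLINE" else None
            layer = ""
        elif current is not None:
            if code == "8":
                layer = value
            elif code == "10":
                current.append([float(value), 0.0])
            elif code == "20":
                current[-1][1] = float(value)
    if current is not None and len(current) >= 3:
        contours.append(Contour(np.array(current), is_hole=layer == "holes"))
    return contours


def rasterize_contours(contours: list[Contour], shape) -> np.ndarray:
    """Fill traced polygons back into a boolean mask (holes subtracted)."""
    from skimage.draw import polygon

    out = np.zeros(shape, bool)
    holes = np.zeros(shape, bool)
    for c in contours:
        rr, cc = polygon(c.vertices[:, 1], c.vertices[:, 0], shape=shape)
        (holes if c.is_hole else out)[rr, cc] = True
    out &= ~holes
    return out
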