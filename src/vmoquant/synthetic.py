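"""Seeded synthetic micrograph generators with machine-readable ground truth.

Three scene families emulate the data the analysis pipeline consumes:

* tube-like fluorescent vessel networks of known widths and topology,
* blob-like tumor spheroids (compact or dispersing),
* dextran perfusion time series with a linearly growing extravascular leak.

Every generator is deterministic in its seed, and each scene carries a
:class:`GroundTruth` describing exactly what was drawn, so recovery tests can
compare measured morphometry against the drawn graph rather than against
another image-analysis routine.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from .segmentation import BinaryMask

__all__ = [
    "Segment",
    "VesselSceneSpec",
    "GroundTruth",
    "generate_vessel_scene",
    "generate_tumor_scene",
    "generate_leak_movie",
    "y_spec",
    "plus_spec",
    "h_spec",
    "ladder_spec",
    "bar_spec",
    "random_tree_spec",
]

_TOL = 1e-6


@dataclass(frozen=True)
class Segment:
    """One straight tube: endpoints in (x, y) pixel coordinates and a width."""

    a: tuple[float, float]
    b: tuple[float, float]
    width: float
    dim: bool = False  # drawn at the dim intensity (for branch-filter tests)

    @property
    def length(self) -> float:
        return math.hypot(self.b[0] - self.a[0], self.b[1] - self.a[1])


@dataclass
class VesselSceneSpec:
    shape: tuple[int, int] = (256, 256)          # (rows, cols)
    segments: list[Segment] = field(default_factory=list)
    fg_intensity: float = 200.0
    dim_intensity: float = 35.0
    bg_intensity: float = 12.0
    noise_sigma: float = 4.0
    bit_depth: int = 8
    seed: int = 0

    def validate(self) -> None:
        h, w = self.shape
        for s in self.segments:
            for (x, y) in (s.a, s.b):
                if not (0 <= x < w and 0 <= y < h):
                    raise ValueError(f"segment endpoint ({x}, {y}) outside {w}x{h} image")
            if s.width < 1:
                raise ValueError("tube width must be >= 1 px")


@dataclass
class GroundTruth:
    """What was drawn, independent of any image measurement."""

    mask: np.ndarray | None = None
    segment_widths: list[float] = field(default_factory=list)
    segment_lengths: list[float] = field(default_factory=list)
    junctions: list[tuple[float, float]] = field(default_factory=list)
    endpoints: list[tuple[float, float]] = field(default_factory=list)
    n_branches: int = 0
    dim_segments: list[int] = field(default_factory=list)
    total_length: float = 0.0
    # tumor scenes
    area_px: int = 0
    # leak movies
    pd_true: float = 0.0
    d_um: float = 0.0
    dt_s: float = 0.0
    rois: list[tuple[int, int]] = field(default_factory=list)
    background_roi: tuple[int, int] | None = None
    roi_radius: int = 25

    @property
    def n_junctions(self) -> int:
        return len(self.junctions)

    @property
    def n_endpoints(self) -> int:
        return len(self.endpoints)


# ---------------------------------------------------------------------------
# geometry helpers

def _seg_point_dist(seg: Segment, px: np.ndarray, py: np.ndarray) -> np.ndarray:
    ax, ay = seg.a
    bx, by = seg.b
    dx, dy = bx - ax, by - ay
    L2 = dx * dx + dy * dy
    if L2 == 0:
        return np.hypot(px - ax, py - ay)
    t = np.clip(((px - ax) * dx + (py - ay) * dy) / L2, 0.0, 1.0)
    return np.hypot(px - (ax + t * dx), py - (ay + t * dy))


def _point_on_segment(p: tuple[float, float], seg: Segment, tol: float = 0.5):
    """Return ('end'|'interior'|None) for the incidence of p on seg."""
    d_a = math.hypot(p[0] - seg.a[0], p[1] - seg.a[1])
    d_b = math.hypot(p[0] - seg.b[0], p[1] - seg.b[1])
    if d_a <= tol or d_b <= tol:
        return "end"
    d = float(_seg_point_dist(seg, np.array([p[0]]), np.array([p[1]]))[0])
    if d <= tol:
        return "interior"
    return None


def _segment_intersections(s1: Segment, s2: Segment) -> list[tuple[float, float]]:
    ax, ay = s1.a
    bx, by = s1.b
    cx, cy = s2.a
    dx_, dy_ = s2.b
    r = (bx - ax, by - ay)
    s = (dx_ - cx, dy_ - cy)
    denom = r[0] * s[1] - r[1] * s[0]
    if abs(denom) < _TOL:
        return []
    t = ((cx - ax) * s[1] - (cy - ay) * s[0]) / denom
    u = ((cx - ax) * r[1] - (cy - ay) * r[0]) / denom
    if -_TOL <= t <= 1 + _TOL and -_TOL <= u <= 1 + _TOL:
        return [(ax + t * r[0], ay + t * r[1])]
    return []


def graph_truth(segments: list[Segment], tol: float = 0.75) -> GroundTruth:
    """Junction/endpoint/branch counts of the drawn network.

    A node's degree counts +1 for each segment ending there and +2 for each
    segment passing through it.  Junctions have degree >= 3, free endpoints
    degree 1.  Branches are the segment pieces between nodes; collinear
    chains joined at degree-2 nodes merge into one branch.
    """
    candidates: list[tuple[float, float]] = []

    def add(p):
        for q in candidates:
            if math.hypot(p[0] - q[0], p[1] - q[1]) <= tol:
                return
        candidates.append((float(p[0]), float(p[1])))

    for s in segments:
        add(s.a)
        add(s.b)
    for i, s1 in enumerate(segments):
        for s2 in segments[i + 1:]:
            for p in _segment_intersections(s1, s2):
                add(p)

    junctions, endpoints = [], []
    n_deg2_joins = 0
    interior_hits = [0] * len(segments)
    for p in candidates:
        deg = 0
        ends_here = 0
        through = []
        for k, s in enumerate(segments):
            kind = _point_on_segment(p, s, tol)
            if kind == "end":
                deg += 1
                ends_here += 1
            elif kind == "interior":
                deg += 2
                through.append(k)
        if deg >= 3:
            junctions.append(p)
            for k in through:
                interior_hits[k] += 1
        elif deg == 1:
            endpoints.append(p)
        elif deg == 2 and ends_here == 2:
            n_deg2_joins += 1

    n_branches = sum(1 + h for h in interior_hits) - n_deg2_joins
    return GroundTruth(
        segment_widths=[s.width for s in segments],
        segment_lengths=[s.length for s in segments],
        junctions=junctions,
        endpoints=endpoints,
        n_branches=n_branches,
        dim_segments=[i for i, s in enumerate(segments) if s.dim],
        total_length=sum(s.length for s in segments),
    )


# ---------------------------------------------------------------------------
# vessel scenes

def _rasterize(spec: VesselSceneSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Anti-aliased coverage images for bright and dim tubes, plus the mask.

    Coverage at a pixel is clip(width/2 + 0.5 - dist, 0, 1); the ground-truth
    mask binarizes at 0.5, i.e. dist <= width/2, so the drawn width is the
    mask's exact width for odd integer widths.
    """
    h, w = spec.shape
    yy, xx = np.mgrid[0:h, 0:w]
    xx = xx.astype(np.float64)
    yy = yy.astype(np.float64)
    cov_bright = np.zeros(spec.shape)
    cov_dim = np.zeros(spec.shape)
    mask = np.zeros(spec.shape, bool)
    for s in spec.segments:
        pad = s.width / 2 + 2
        x0 = max(0, int(min(s.a[0], s.b[0]) - pad))
        x1 = min(w, int(max(s.a[0], s.b[0]) + pad) + 1)
        y0 = max(0, int(min(s.a[1], s.b[1]) - pad))
        y1 = min(h, int(max(s.a[1], s.b[1]) + pad) + 1)
        d = _seg_point_dist(s, xx[y0:y1, x0:x1], yy[y0:y1, x0:x1])
        cov = np.clip(s.width / 2 + 0.5 - d, 0.0, 1.0)
        tgt = cov_dim if s.dim else cov_bright
        np.maximum(tgt[y0:y1, x0:x1], cov, out=tgt[y0:y1, x0:x1])
        mask[y0:y1, x0:x1] |= d <= s.width / 2
    return cov_bright, cov_dim, mask


def generate_vessel_scene(spec: VesselSceneSpec) -> tuple[np.ndarray, GroundTruth]:
    """Render a tube network to a noisy grayscale image with ground truth."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    cov_bright, cov_dim, mask = _rasterize(spec)
    img = np.full(spec.shape, spec.bg_intensity)
    img += (spec.fg_intensity - spec.bg_intensity) * cov_bright
    img += (spec.dim_intensity - spec.bg_intensity) * np.where(cov_bright > 0, 0, cov_dim)
    img += rng.normal(0.0, spec.noise_sigma, spec.shape)
    vmax = 2 ** spec.bit_depth - 1
    img = np.clip(np.round(img), 0, vmax)
    dtype = np.uint8 if spec.bit_depth == 8 else np.uint16
    truth = graph_truth(spec.segments)
    truth.mask = mask
    return img.astype(dtype), truth


# -- ready-made scene specs --------------------------------------------------

def _c(shape):
    return (shape[1] / 2, shape[0] / 2)


def bar_spec(width: float = 11, length: float = 160, angle_deg: float = 0.0,
             shape=(256, 256), seed: int = 0, **kw) -> VesselSceneSpec:
    cx, cy = _c(shape)
    th = math.radians(angle_deg)
    dx, dy = math.cos(th) * length / 2, math.sin(th) * length / 2
    seg = Segment((cx - dx, cy - dy), (cx + dx, cy + dy), width)
    return VesselSceneSpec(shape=shape, segments=[seg], seed=seed, **kw)


def y_spec(width: float = 9, arm: float = 80, shape=(256, 256), seed: int = 0,
           **kw) -> VesselSceneSpec:
    cx, cy = _c(shape)
    segs = []
    for ang in (90, 210, 330):
        th = math.radians(ang)
        segs.append(Segment((cx, cy), (cx + arm * math.cos(th), cy + arm * math.sin(th)), width))
    return VesselSceneSpec(shape=shape, segments=segs, seed=seed, **kw)


def plus_spec(width: float = 9, arm: float = 80, shape=(256, 256), seed: int = 0,
              **kw) -> VesselSceneSpec:
    cx, cy = _c(shape)
    segs = [Segment((cx - arm, cy), (cx + arm, cy), width),
            Segment((cx, cy - arm), (cx, cy + arm), width)]
    return VesselSceneSpec(shape=shape, segments=segs, seed=seed, **kw)


def h_spec(width: float = 9, shape=(256, 256), seed: int = 0, **kw) -> VesselSceneSpec:
    cx, cy = _c(shape)
    segs = [Segment((cx - 50, cy - 80), (cx - 50, cy + 80), width),
            Segment((cx + 50, cy - 80), (cx + 50, cy + 80), width),
            Segment((cx - 50, cy), (cx + 50, cy), width)]
    return VesselSceneSpec(shape=shape, segments=segs, seed=seed, **kw)


def ladder_spec(n_rungs: int = 6, width: float = 7, rail_len: float = 220,
                rail_gap: float = 90, shape=(300, 300), seed: int = 0,
                **kw) -> VesselSceneSpec:
    cx, cy = _c(shape)
    y0, y1 = cy - rail_len / 2, cy + rail_len / 2
    xl, xr = cx - rail_gap / 2, cx + rail_gap / 2
    segs = [Segment((xl, y0), (xl, y1), width), Segment((xr, y0), (xr, y1), width)]
    for i in range(n_rungs):
        y = y0 + (i + 1) * rail_len / (n_rungs + 1)
        segs.append(Segment((xl, y), (xr, y), width))
    return VesselSceneSpec(shape=shape, segments=segs, seed=seed, **kw)


def random_tree_spec(seed: int, n_branches: int = 9, shape=(512, 512),
                     widths=(7, 9, 11, 13, 15, 17, 19, 21, 23, 25),
                     arm_range=(55, 85), **kw) -> VesselSceneSpec:
    """Random trivalent tree with well-separated junctions.

    The root spawns three arms; leaves then bifurcate until ``n_branches``
    segments exist.  Child directions stay within +/-65 degrees of the parent
    with >= 55 degrees between siblings, arms are 55-85 px, and a new arm is
    rejected if its tube would touch an unrelated existing tube — together
    this keeps the skeleton topology identical to the drawn graph.  Widths
    start at 7 px: a 5-px tube at an oblique angle sits below the resolution
    of the default cleaning radius (see edm_prune) and may be erased.
    """
    rng = np.random.default_rng(seed)
    h, w = shape
    margin = 30
    cx, cy = w / 2, h / 2
    segs: list[Segment] = []

    def clear_of_others(a, b, width, parent_idx):
        px = np.linspace(a[0], b[0], 24)
        py = np.linspace(a[1], b[1], 24)
        for k, s in enumerate(segs):
            if k == parent_idx:
                continue
            d = _seg_point_dist(s, px, py)
            near_start = np.hypot(px - a[0], py - a[1]) < (width + s.width)
            if np.any((d < (width + s.width) / 2 + 12) & ~near_start):
                return False
        return True

    frontier: list[tuple[tuple[float, float], float, int]] = []  # (pos, heading, parent idx)
    base = rng.uniform(0, 2 * math.pi)
    for k in range(3):
        ang = base + k * 2 * math.pi / 3 + rng.uniform(-0.25, 0.25)
        L = rng.uniform(*arm_range)
        wdt = float(rng.choice(widths))
        b = (cx + L * math.cos(ang), cy + L * math.sin(ang))
        segs.append(Segment((cx, cy), b, wdt))
        frontier.append((b, ang, len(segs) - 1))

    while len(segs) < n_branches and frontier:
        pos, heading, pidx = frontier.pop(int(rng.integers(len(frontier))))
        placed = []
        sides = [-1, 1]
        rng.shuffle(sides)
        for side in sides:
            if len(segs) >= n_branches:
                break
            for _ in range(12):  # rejection sampling
                dth = math.radians(rng.uniform(32, 65)) * side
                ang = heading + dth
                L = rng.uniform(*arm_range)
                wdt = float(rng.choice(widths))
                b = (pos[0] + L * math.cos(ang), pos[1] + L * math.sin(ang))
                if not (margin < b[0] < w - margin and margin < b[1] < h - margin):
                    continue
                if placed and abs(ang - placed[0]) < math.radians(55):
                    continue
                if not clear_of_others(pos, b, wdt, pidx):
                    continue
                segs.append(Segment(pos, b, wdt))
                frontier.append((b, ang, len(segs) - 1))
                placed.append(ang)
                break
        # a node that placed exactly one child would be degree 2: undo
        if len(placed) == 1:
            segs.pop()
            frontier.pop()
    return VesselSceneSpec(shape=shape, segments=segs, seed=seed, **kw)


# ---------------------------------------------------------------------------
# tumor scenes

def generate_tumor_scene(n_blobs: int = 5, radii=(12, 20), dispersal: float = 0.0,
                         noise: float = 3.0, seed: int = 0, shape=(256, 256),
                         fg_intensity: float = 180.0, bg_intensity: float = 10.0,
                         ) -> tuple[np.ndarray, GroundTruth]:
    """Compact or dispersing spheroid scene.

    ``dispersal = 0`` stacks all blobs at the center into one compact mass;
    larger values scatter blob centers within that radius, which lowers the
    aggregate solidity while total area stays comparable — the signature of
    a spheroid dispersing over time.
    """
    rng = np.random.default_rng(seed)
    h, w = shape
    cy, cx = h / 2, w / 2
    yy, xx = np.mgrid[0:h, 0:w]
    mask = np.zeros(shape, bool)
    for i in range(n_blobs):
        r = rng.uniform(*radii) if np.ndim(radii) else float(radii)
        if r < 2:
            raise ValueError("blob radius must be >= 2 px")
        if dispersal > 0:
            ang = rng.uniform(0, 2 * math.pi)
            rad = rng.uniform(0, dispersal)
            by, bx = cy + rad * math.sin(ang), cx + rad * math.cos(ang)
        else:
            by, bx = cy, cx
        mask |= (yy - by) ** 2 + (xx - bx) ** 2 <= r * r
    img = np.where(mask, fg_intensity, bg_intensity).astype(np.float64)
    img += rng.normal(0, noise, shape)
    img = np.clip(np.round(img), 0, 255).astype(np.uint8)
    truth = GroundTruth(mask=mask, area_px=int(mask.sum()))
    return img, truth


# ---------------------------------------------------------------------------
# perfusion / leak movies

def generate_leak_movie(spec: VesselSceneSpec | None = None, pd_true: float = 0.05,
                        frames: int = 3, dt: float = 60.0, noise: float = 0.0,
                        seed: int = 0, d_um: float = 40.0, roi_radius: int = 25,
                        leak_halo: float = 85.0, i_initial: float = 60.0,
                        i_background: float = 20.0, i_vessel: float = 210.0,
                        ) -> tuple[list[np.ndarray], GroundTruth]:
    """Dextran time-lapse with a linearly accumulating extravascular leak.

    The extravascular halo (within ``leak_halo`` px of a vessel) starts at
    ``i_initial`` and grows so that the two-point permeability formula
    PD = (I_f - I_i) / ((I_i - I_b) * dt_total) * d/4 applied to noiseless
    ROI means returns ``pd_true`` exactly; background beyond the halo stays
    at ``i_background``.  Measurement ROI centers are chosen inside the halo
    with the full ROI disk clear of both vessels and background.
    """
    if pd_true < 0:
        raise ValueError("pd_true must be >= 0")
    if frames < 2:
        raise ValueError("need at least 2 frames")
    if spec is None:
        spec = ladder_spec(n_rungs=3, width=11, shape=(420, 420), seed=seed,
                           noise_sigma=0.0)
    spec.validate()
    rng = np.random.default_rng(seed)
    _, _, vessel_mask = _rasterize(spec)
    dist = ndi.distance_transform_edt(~vessel_mask)
    halo = (dist > 0) & (dist <= leak_halo)

    # slope per second chosen so Eq. 1 inverts to pd_true over the full series
    total_t = dt * (frames - 1)
    i_final = i_initial + pd_true * (i_initial - i_background) * total_t * 4.0 / d_um

    # ROI centers: disk of roi_radius fully inside the halo band
    ok = (dist > roi_radius + 2) & (dist + roi_radius + 2 <= leak_halo)
    ok[:roi_radius + 1, :] = ok[-roi_radius - 1:, :] = False
    ok[:, :roi_radius + 1] = ok[:, -roi_radius - 1:] = False
    rois: list[tuple[int, int]] = []
    cand = np.argwhere(ok)
    rng.shuffle(cand)
    for (ry, rx) in cand:
        if all((ry - y) ** 2 + (rx - x) ** 2 > (2.2 * roi_radius) ** 2 for (x, y) in rois):
            rois.append((int(rx), int(ry)))
        if len(rois) >= 4:
            break
    bg_ok = dist > leak_halo + roi_radius + 4
    bg_ok[:roi_radius + 1, :] = bg_ok[-roi_radius - 1:, :] = False
    bg_ok[:, :roi_radius + 1] = bg_ok[:, -roi_radius - 1:] = False
    bg_cand = np.argwhere(bg_ok)
    background_roi = None
    if len(bg_cand):
        by, bx = bg_cand[int(rng.integers(len(bg_cand)))]
        background_roi = (int(bx), int(by))

    movie = []
    for k in range(frames):
        frac = k / (frames - 1)
        halo_val = i_initial + frac * (i_final - i_initial)
        img = np.full(spec.shape, i_background)
        img[halo] = halo_val
        img[vessel_mask] = i_vessel
        if noise > 0:
            img = img + rng.normal(0, noise, spec.shape)
        # frames stay float: quantizing would perturb the exact Eq.-1 inversion
        movie.append(np.clip(img, 0.0, 255.0))

    truth = GroundTruth(mask=vessel_mask, pd_true=pd_true, d_um=d_um, dt_s=dt,
                        rois=rois, background_roi=background_roi,
                        roi_radius=roi_radius)
    return movie, truth
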