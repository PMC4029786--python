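"""Synthetic rosette images with exact polygon ground truth.

Rosettes are built from 2-12 leaves radiating from a common center, each a
teardrop (two circular arcs) or an ellipse on a short petiole. Per-leaf
areas, the union area and the overlap fraction are computed by exact polygon
geometry (shapely), never by pixel counting, so every downstream stage of
the area-estimation pipeline can be scored against an analytic truth.

Coordinate convention (used package-wide): images are (row, col), 0-based,
with pixel centers at integer coordinates. A pixel is foreground when its
center lies inside a leaf polygon. Leaf angles follow atan2(drow, dcol) in
degrees on [0, 360).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import shapely
from shapely.geometry import Polygon
from shapely.ops import unary_union

__all__ = [
    "LeafSpec",
    "RosetteSpec",
    "GroundTruth",
    "leaf_polygon",
    "render_rosette",
    "grow_series",
]


@dataclass(frozen=True)
class LeafSpec:
    """Geometry of one leaf: a blade on a short petiole, radiating from the
    plant center.

    ``length`` is the center-to-tip distance in pixels, petiole included
    (leaf length is measured from the petiole base, taken to be the plant
    center, to the outermost point of the blade). ``petiole_fraction`` is
    the fraction of that length occupied by the bare petiole.
    """

    angle: float  # degrees in [0, 360)
    length: float  # px, center to tip
    width: float  # px, max blade width
    shape: str = "teardrop"  # "teardrop" | "ellipse"
    petiole_fraction: float = 0.25

    def __post_init__(self) -> None:
        if not 0.0 <= self.angle < 360.0:
            raise ValueError(f"angle must be in [0, 360), got {self.angle}")
        if self.length <= 0:
            raise ValueError("length must be positive")
        if self.width <= 0:
            raise ValueError("width must be positive")
        if self.width >= 2 * self.length:
            raise ValueError("width must be < 2*length")
        if self.shape not in ("teardrop", "ellipse"):
            raise ValueError(f"unknown leaf shape {self.shape!r}")
        if not 0.0 <= self.petiole_fraction < 1.0:
            raise ValueError("petiole_fraction must be in [0, 1)")


@dataclass(frozen=True)
class RosetteSpec:
    """A full synthetic rosette: leaves, image geometry and noise model."""

    center: tuple[float, float]  # (row, col) px
    leaves: tuple[LeafSpec, ...]
    image_size: tuple[int, int] = (512, 512)  # (height, width)
    background_level: float = 200.0
    foreground_level: float = 3000.0
    #: intensity factor where two or more leaves overlap — mutual shading
    #: dims the fluorescence there, which is what lets edge detectors see
    #: leaf complexes in real images
    overlap_attenuation: float = 0.85
    noise_sd: float = 80.0  # ~2% of a 12-bit dynamic range
    seed: int = 0

    def __post_init__(self) -> None:
        h, w = self.image_size
        r, c = self.center
        if not (0 <= r < h and 0 <= c < w):
            raise ValueError("center must lie inside the image bounds")
        if len(self.leaves) < 1:
            raise ValueError("a rosette needs at least one leaf")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        object.__setattr__(self, "leaves", tuple(self.leaves))


@dataclass(frozen=True)
class GroundTruth:
    """Exact geometric truth for one rendered frame.

    ``union_area`` is the oracle for the observed top-view area a_t;
    ``per_leaf_polygon_areas`` are the oracles for the per-leaf areas a_l is
    built from; ``overlap_fraction`` = (sum of leaf areas - union) / sum.
    """

    center: tuple[float, float]
    tip_points: tuple[tuple[float, float], ...]
    per_leaf_polygon_areas: tuple[float, ...]
    union_area: float
    overlap_fraction: float
    leaf_polygons: tuple[Polygon, ...] = field(repr=False, default=())


def _ray(angle_deg: float) -> tuple[float, float]:
    a = math.radians(angle_deg)
    return math.sin(a), math.cos(a)  # (drow, dcol) unit vector


def _arc_points(p0, p1, sagitta, side, n=48):
    """Circular arc from p0 to p1 bulging by ``sagitta`` to the given side
    (+1/-1 of the left normal)."""
    p0 = np.asarray(p0, float)
    p1 = np.asarray(p1, float)
    chord = p1 - p0
    clen = float(np.hypot(*chord))
    if sagitta <= 0 or clen == 0:
        return np.linspace(p0, p1, n)
    radius = (clen**2 / 4 + sagitta**2) / (2 * sagitta)
    mid = (p0 + p1) / 2
    normal = np.array([-chord[1], chord[0]]) / clen * side
    centre = mid + normal * (radius - sagitta)
    a0 = math.atan2(*(p0 - centre))
    a1 = math.atan2(*(p1 - centre))
    # sweep the short way round (the arc subtends < pi for sagitta < clen/2)
    da = (a1 - a0 + math.pi) % (2 * math.pi) - math.pi
    angles = a0 + np.linspace(0.0, da, n)
    return centre + radius * np.stack([np.sin(angles), np.cos(angles)], axis=1)


def leaf_polygon(center: tuple[float, float], leaf: LeafSpec) -> Polygon:
    """Exact polygon of one leaf (blade plus petiole strip), in (row, col).

    Teardrop blades are two circular arcs from the petiole base to the tip;
    ellipse blades span from petiole_fraction*length to the tip along the
    leaf axis. The petiole is a thin strip from the center to the blade base
    so the rendered plant is connected.
    """
    c = np.asarray(center, float)
    u = np.asarray(_ray(leaf.angle))
    base = c + u * (leaf.petiole_fraction * leaf.length)
    tip = c + u * leaf.length

    if leaf.shape == "teardrop":
        chord = float(np.linalg.norm(tip - base))
        if leaf.width / 2 > chord:
            raise ValueError(
                "teardrop width/2 must not exceed the blade chord "
                f"({chord:.1f} px) — the arcs would self-intersect"
            )
        left = _arc_points(base, tip, leaf.width / 2, +1)
        right = _arc_points(tip, base, leaf.width / 2, +1)
        blade = Polygon(np.vstack([left, right[1:]]))
    else:  # ellipse
        semi_major = (leaf.length - leaf.petiole_fraction * leaf.length) / 2
        semi_minor = leaf.width / 2
        mid = (base + tip) / 2
        t = np.linspace(0, 2 * math.pi, 96, endpoint=False)
        pts = (
            mid
            + np.outer(semi_major * np.cos(t), u)
            + np.outer(semi_minor * np.sin(t), np.array([-u[1], u[0]]))
        )
        blade = Polygon(pts)

    petiole_w = max(1.5, 0.12 * leaf.width)
    n = np.array([-u[1], u[0]]) * (petiole_w / 2)
    # overshoot the blade base slightly so the union has proper overlap
    # rather than a single degenerate touching vertex
    reach = base + u * 0.1 * (leaf.length - leaf.petiole_fraction * leaf.length)
    petiole = Polygon([c + n, reach + n, reach - n, c - n])
    if not blade.is_valid:
        blade = blade.buffer(0)
    poly = blade.union(petiole)
    if poly.geom_type != "Polygon":  # pragma: no cover - safety net
        poly = poly.convex_hull
    return poly


def _ground_truth(spec: RosetteSpec) -> GroundTruth:
    polys = tuple(leaf_polygon(spec.center, lf) for lf in spec.leaves)
    areas = tuple(p.area for p in polys)
    union = unary_union(polys).area
    total = float(sum(areas))
    overlap = 0.0 if total == 0 else max(0.0, (total - union) / total)
    tips = tuple(
        (
            spec.center[0] + _ray(lf.angle)[0] * lf.length,
            spec.center[1] + _ray(lf.angle)[1] * lf.length,
        )
        for lf in spec.leaves
    )
    return GroundTruth(
        center=spec.center,
        tip_points=tips,
        per_leaf_polygon_areas=areas,
        union_area=float(union),
        overlap_fraction=float(overlap),
        leaf_polygons=polys,
    )


def rasterize(polys, image_size: tuple[int, int]) -> np.ndarray:
    """Boolean raster of the polygon union: pixel-center-in-polygon test."""
    h, w = image_size
    mask = np.zeros((h, w), dtype=bool)
    geom = unary_union(list(polys))
    minr = max(0, int(math.floor(geom.bounds[0])) - 1)
    minc = max(0, int(math.floor(geom.bounds[1])) - 1)
    maxr = min(h - 1, int(math.ceil(geom.bounds[2])) + 1)
    maxc = min(w - 1, int(math.ceil(geom.bounds[3])) + 1)
    if minr > maxr or minc > maxc:
        return mask
    rows = np.arange(minr, maxr + 1)
    cols = np.arange(minc, maxc + 1)
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    # shapely x/y are our row/col; only the consistent pairing matters
    inside = shapely.contains_xy(geom, rr.ravel(), cc.ravel())
    mask[minr : maxr + 1, minc : maxc + 1] = inside.reshape(rr.shape)
    return mask


def render_rosette(spec: RosetteSpec) -> tuple[np.ndarray, GroundTruth]:
    """Render a rosette to a grayscale image and its exact ground truth.

    Deterministic given ``spec.seed``. Raises ValueError naming the first
    leaf whose polygon extends outside the image.
    """
    truth = _ground_truth(spec)
    h, w = spec.image_size
    for i, poly in enumerate(truth.leaf_polygons):
        minr, minc, maxr, maxc = poly.bounds
        if minr < -0.5 or minc < -0.5 or maxr > h - 0.5 or maxc > w - 0.5:
            raise ValueError(
                f"leaf {i} (angle {spec.leaves[i].angle:g} deg, length "
                f"{spec.leaves[i].length:g} px) extends outside the "
                f"{h}x{w} image"
            )
    mask = rasterize(truth.leaf_polygons, spec.image_size)
    image = np.full((h, w), spec.background_level, dtype=float)
    image[mask] = spec.foreground_level
    if len(truth.leaf_polygons) > 1 and spec.overlap_attenuation != 1.0:
        coverage = np.zeros((h, w), dtype=np.uint8)
        for poly in truth.leaf_polygons:
            coverage += rasterize([poly], spec.image_size)
        image[coverage >= 2] = spec.foreground_level * spec.overlap_attenuation
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        image += rng.normal(0.0, spec.noise_sd, size=image.shape)
    hi = max(spec.foreground_level, spec.background_level) * 1.3
    np.clip(image, 0.0, hi, out=image)
    return image, truth


# ---------------------------------------------------------------------------
# growth series


def _logistic(t, a0, aa, gamma):
    return a0 * aa / (a0 + (aa - a0) * np.exp(-gamma * t))


def _solve_width(leaf: LeafSpec, length: float, target_area: float) -> float:
    """Width at which the exact leaf polygon area equals ``target_area``.

    Polygon area is monotone in width at fixed length but not exactly
    separable (arc sagitta, petiole strip), so solve by bisection.
    """
    from scipy.optimize import brentq

    def f(w):
        return leaf_polygon((0.0, 0.0), replace(leaf, length=length, width=w)).area - target_area

    # teardrop arcs are valid only while the sagitta (width/2) stays below
    # the half-chord; the ellipse blade has no such cap
    chord = (1.0 - leaf.petiole_fraction) * length
    hi = 0.98 * chord if leaf.shape == "teardrop" else 1.9 * length
    lo = 1e-3
    if f(hi) < 0:
        raise ValueError(
            f"target area {target_area:g} px^2 not reachable at length {length:g} px"
        )
    return float(brentq(f, lo, hi, xtol=1e-8, rtol=1e-12))


def grow_series(
    spec0: RosetteSpec,
    growth: list[tuple[float, float, float]],
    times,
    length_model=None,
    branch: str = "linear",
):
    """Generate a growth image series whose per-leaf areas follow the
    three-parameter logistic law A(t) = A0*Aa / (A0 + (Aa-A0)e^{-gamma t}).

    ``growth`` gives one (gamma, A0, Aa) triple per leaf of ``spec0``. For
    each frame the leaf length is set by inverting the configured
    length-to-area branch at the target area (so tips map back through the
    length-to-area model) and the width is solved so the exact polygon area
    equals the target. Returns a list of (image, GroundTruth), one per time.
    """
    from phenogrow.leaf_area import LengthAreaModel

    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or len(times) == 0:
        raise ValueError("times must be a non-empty 1-D sequence")
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    if len(growth) != len(spec0.leaves):
        raise ValueError("need one (gamma, A0, Aa) triple per leaf")
    model = length_model if length_model is not None else LengthAreaModel()

    frames = []
    for j, t in enumerate(times):
        leaves = []
        for leaf, (gamma, a0, aa) in zip(spec0.leaves, growth):
            if not (0 < a0 < aa) or gamma <= 0:
                raise ValueError("growth parameters must satisfy 0 < A0 < Aa, gamma > 0")
            target = float(_logistic(t, a0, aa, gamma))
            length = model.invert_length(target, branch=branch)
            width = _solve_width(leaf, length, target)
            leaves.append(replace(leaf, length=length, width=width))
        frame_spec = replace(
            spec0, leaves=tuple(leaves), seed=spec0.seed + j
        )
        frames.append(render_rosette(frame_spec))
    return frames
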