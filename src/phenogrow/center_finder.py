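"""Plant-center identification from leaf orientation lines.

Rosette leaves radiate from the growing point, so the axes of a few isolated
("simple") leaves nearly intersect at the plant center. The center is
estimated as the point minimizing the summed squared perpendicular distance
to the leaf orientation lines (closed-form normal equations); an optional
iteratively-reweighted mode minimizes the plain sum of distances instead.
Overlapping or fused leaves ("leaf complexes") are excluded by region-level
shape tests rather than segmented. Center of mass is the baseline and the
fallback when fewer than two simple leaves are found.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform
from skimage import measure
from skimage.feature import canny
from skimage.filters import gaussian, sobel, threshold_otsu
from skimage.morphology import dilation, disk, opening

from phenogrow.foreground_mask import ForegroundMask

__all__ = [
    "LeafRegion",
    "OrientationLine",
    "PlantCenter",
    "SimpleLeafParams",
    "detect_simple_leaves",
    "orientation_line",
    "estimate_center",
    "center_of_mass",
]


@dataclass(frozen=True)
class LeafRegion:
    """A connected foreground region judged to be a single isolated leaf."""

    coords: np.ndarray  # (n, 2) pixel coordinates (row, col)
    boundary: np.ndarray  # (m, 2) boundary points (row, col)
    solidity: float
    area: int


@dataclass(frozen=True)
class OrientationLine:
    """The longest chord across a leaf; the implied infinite line points at
    the plant center."""

    p0: tuple[float, float]
    p1: tuple[float, float]

    def __post_init__(self) -> None:
        if tuple(self.p0) == tuple(self.p1):
            raise ValueError("orientation line endpoints must be distinct")

    @property
    def direction(self) -> np.ndarray:
        d = np.asarray(self.p1, float) - np.asarray(self.p0, float)
        return d / np.linalg.norm(d)

    def distance_to(self, point) -> float:
        v = np.asarray(point, float) - np.asarray(self.p0, float)
        u = self.direction
        return float(np.abs(v[0] * u[1] - v[1] * u[0]))


@dataclass(frozen=True)
class PlantCenter:
    point: tuple[float, float]  # (row, col)
    method: str  # "orientation_lines" | "center_of_mass"
    n_leaves_used: int = 0


@dataclass(frozen=True)
class SimpleLeafParams:
    """Thresholds for the simple-leaf screen.

    ``sigma`` is the Gaussian pre-smoothing scale in pixels; ``s_min`` the
    minimum solidity (area over convex-hull area); ``a_min`` the minimum
    region area; ``a_max_fraction`` caps a region at that fraction of the
    whole-plant area (complexes are large); ``min_chord_ratio`` skips
    near-round regions whose longest chord is unstable as an axis.
    """

    sigma: float = 2.0
    s_min: float = 0.85
    a_min: float = 100.0
    a_max_fraction: float = 0.5
    min_chord_ratio: float = 1.2
    #: reject regions dimmer than this fraction of the brightest candidate:
    #: mutual shading attenuates the signal where leaves overlap, so a
    #: markedly dim region is overlap zone, not a single leaf
    min_intensity_ratio: float = 0.93


def detect_simple_leaves(
    image: np.ndarray,
    mask: ForegroundMask,
    params: SimpleLeafParams | None = None,
) -> tuple[list[LeafRegion], bool]:
    """Find isolated single-leaf regions usable for orientation lines.

    The image is Gaussian-smoothed and its connected foreground regions
    (8-connectivity) are screened: a simple leaf must have a single closed
    outer contour (no holes), solidity >= s_min and area within bounds.
    Regions failing any test are treated as leaf complexes and dropped.

    Returns ``(regions, insufficient)`` where ``insufficient`` is True when
    fewer than 2 simple leaves were found (caller should fall back to the
    center of mass).
    """
    params = params or SimpleLeafParams()
    m = mask.mask
    if m.sum() == 0:
        return [], True

    # A rosette is one connected blob, so leaves cannot be separated by
    # plain connected components. Edge detection on the smoothed image
    # outlines each blade; removing the edge band from the mask leaves one
    # interior region per isolated leaf, while overlapping blades (no
    # intensity edge between them) stay fused and fail the shape screen.
    image = np.asarray(image, float)
    smoothed = gaussian(image, sigma=params.sigma, preserve_range=True)
    grad = sobel(image)
    edges = grad > threshold_otsu(grad)
    edges |= canny(smoothed / max(float(smoothed.max()), 1e-9), sigma=0.0)
    interior = m & ~dilation(edges, disk(2))
    # mask holes (background-dark pixels enclosed by the plant) are not leaf
    # tissue; dropping them stops blades fusing through the filled rosette
    # center. Otsu over the whole image separates background from tissue.
    interior &= image > threshold_otsu(image)
    # petiole-junction spines a few px wide still bridge adjacent blades
    interior = opening(interior, disk(2))
    labels = measure.label(interior, connectivity=2)
    a_max = params.a_max_fraction * float(m.sum())

    regions: list[LeafRegion] = []
    for rp in measure.regionprops(labels):
        if rp.area < params.a_min or rp.area > a_max:
            continue
        if rp.solidity < params.s_min:
            continue
        if rp.euler_number != 1:  # holes: edge not a single closed contour
            continue
        sub = np.pad(rp.image, 1)
        contours = measure.find_contours(sub.astype(float), 0.5)
        if len(contours) != 1:
            continue
        offset = np.array(rp.bbox[:2]) - 1
        boundary = contours[0] + offset
        regions.append(
            LeafRegion(
                coords=rp.coords,
                boundary=boundary,
                solidity=float(rp.solidity),
                area=int(rp.area),
            )
        )
    if len(regions) > 1:
        medians = [float(np.median(image[r.coords[:, 0], r.coords[:, 1]])) for r in regions]
        brightest = max(medians)
        regions = [
            r for r, med in zip(regions, medians)
            if med >= params.min_intensity_ratio * brightest
        ]
    return regions, len(regions) < 2


def orientation_line(region: LeafRegion) -> OrientationLine:
    """Longest chord across the leaf boundary (the leaf orientation line).

    Endpoints are the boundary point pair at maximal Euclidean distance;
    ties are broken by the smallest (row, col) of the first endpoint. The
    search runs over convex-hull vertices (the diameter of a point set is
    attained on its hull).
    """
    pts = np.asarray(region.boundary, float)
    if len(pts) < 3:
        raise ValueError("region boundary needs at least 3 points")
    try:
        from scipy.spatial import ConvexHull

        hull = pts[ConvexHull(pts).vertices]
    except Exception as exc:  # collinear/degenerate region
        raise ValueError("degenerate region: boundary is collinear") from exc

    d = squareform(pdist(hull))
    best = float(d.max())
    if best <= 0:
        raise ValueError("degenerate region: zero-length chord")
    pairs = []
    for i, j in zip(*np.nonzero(d >= best - 1e-9)):
        if i < j:
            a, b = sorted([tuple(hull[i]), tuple(hull[j])])
            pairs.append((a, b))
    p0, p1 = min(pairs)  # ties: smallest (row, col) first endpoint
    return OrientationLine(p0=p0, p1=p1)


def chord_ratio(region: LeafRegion) -> float:
    """Max over min width of the boundary: elongation screen for axes."""
    pts = np.asarray(region.boundary, float)
    line = orientation_line(region)
    u = line.direction
    proj_major = pts @ u
    proj_minor = pts @ np.array([-u[1], u[0]])
    major = proj_major.max() - proj_major.min()
    minor = proj_minor.max() - proj_minor.min()
    return float(major / max(minor, 1e-9))


def estimate_center(
    lines: list[OrientationLine],
    method: str = "least_squares",
    max_iter: int = 100,
) -> PlantCenter:
    """Point minimizing the summed (squared) perpendicular distance to the
    leaf orientation lines.

    ``method="least_squares"`` (default) solves the normal equations of the
    squared-distance objective in closed form. ``method="l1"`` minimizes the
    plain sum of distances by iteratively reweighted least squares.

    Raises ValueError with fewer than 2 lines or when all lines are parallel
    (singular normal matrix; the objective has no unique minimizer).
    """
    if len(lines) < 2:
        raise ValueError("need at least 2 orientation lines")

    def solve(weights):
        m = np.zeros((2, 2))
        b = np.zeros(2)
        for wgt, ln in zip(weights, lines):
            u = ln.direction
            proj = np.eye(2) - np.outer(u, u)
            m_i = wgt * proj
            m += m_i
            b += m_i @ np.asarray(ln.p0, float)
        if np.linalg.cond(m) > 1e10:
            raise ValueError("all orientation lines are parallel; center undefined")
        return np.linalg.solve(m, b)

    w = np.ones(len(lines))
    c = solve(w)
    if method == "l1":
        for _ in range(max_iter):
            dists = np.array([ln.distance_to(c) for ln in lines])
            w_new = 1.0 / np.maximum(dists, 1e-6)
            c_new = solve(w_new)
            if np.linalg.norm(c_new - c) < 1e-8:
                c = c_new
                break
            c = c_new
    elif method != "least_squares":
        raise ValueError(f"unknown method {method!r}")
    return PlantCenter(point=(float(c[0]), float(c[1])), method="orientation_lines",
                       n_leaves_used=len(lines))


def center_of_mass(mask: ForegroundMask) -> PlantCenter:
    """Arithmetic mean of the foreground pixel coordinates (baseline)."""
    coords = np.argwhere(mask.mask)
    if len(coords) == 0:
        raise ValueError("empty mask has no center of mass")
    r, c = coords.mean(axis=0)
    return PlantCenter(point=(float(r), float(c)), method="center_of_mass")


def find_center(
    image: np.ndarray,
    mask: ForegroundMask,
    params: SimpleLeafParams | None = None,
) -> PlantCenter:
    """Full center stage: orientation lines from simple leaves, with center
    of mass as the fallback when fewer than two usable leaves exist."""
    params = params or SimpleLeafParams()
    regions, insufficient = detect_simple_leaves(image, mask, params)
    if not insufficient:
        usable = [r for r in regions if chord_ratio(r) >= params.min_chord_ratio]
        if len(usable) >= 2:
            try:
                return estimate_center([orientation_line(r) for r in usable])
            except ValueError:
                pass
    return center_of_mass(mask)
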