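"""Leaf-tip detection on a polar boundary profile.

From the plant center a radius profile r(phi) is built over 360 degrees: for
each angular bin, the distance to the outermost foreground pixel. A circular
moving average smooths the profile; leaf tips are the *raw* radii at the
local maxima of the smoothed profile (smoothing always underestimates tip
radius, so the raw value is kept), subject to a minimum-radius threshold T_r
that suppresses spurious maxima near the center. The curvature ratio
cr = (r - r_s)/r at a tip is a shape index: low for round leaves, high for
elongated ones; it selects the branch of the length-to-area model downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter1d

from phenogrow.center_finder import PlantCenter
from phenogrow.foreground_mask import ForegroundMask

__all__ = [
    "PolarProfile",
    "SmoothedProfile",
    "LeafTip",
    "polar_profile",
    "smooth_profile",
    "detect_tips",
]

DEFAULT_BIN_WIDTH = 1.0  # degrees
DEFAULT_WINDOW = 9  # bins
DEFAULT_RELATIVE_TR = 0.15  # fraction of max radius


@dataclass(frozen=True)
class PolarProfile:
    """Outermost-edge radius per angular bin about the plant center."""

    radii: np.ndarray  # px, one per bin
    center: tuple[float, float]
    bin_width: float  # degrees
    interpolated: np.ndarray = field(default=None, repr=False)  # bool per bin

    @property
    def angles(self) -> np.ndarray:
        return np.arange(len(self.radii)) * self.bin_width


@dataclass(frozen=True)
class SmoothedProfile:
    radii: np.ndarray
    window: int  # odd number of bins


@dataclass(frozen=True)
class LeafTip:
    """One detected leaf tip: angle, raw tip radius and curvature ratio."""

    angle: float  # degrees
    radius: float  # px, raw profile at the smoothed maximum
    curvature_ratio: float  # (r - r_s)/r


def polar_profile(
    mask: ForegroundMask,
    center: PlantCenter,
    bin_width: float = DEFAULT_BIN_WIDTH,
) -> PolarProfile:
    """Radius to the outermost foreground pixel in each angular bin.

    Angles follow atan2(drow, dcol) in degrees on [0, 360). Bins with no
    foreground pixel are filled by circular linear interpolation and flagged
    in ``interpolated``.
    """
    m = mask.mask
    if m.sum() == 0:
        raise ValueError("empty mask has no polar profile")
    cr, cc = center.point
    h, w = m.shape
    if not (0 <= cr < h and 0 <= cc < w):
        raise ValueError("center lies outside the image")
    n_bins = int(round(360.0 / bin_width))
    if n_bins < 4 or abs(n_bins * bin_width - 360.0) > 1e-9:
        raise ValueError("bin_width must divide 360 degrees")

    rows, cols = np.nonzero(m)
    # each pixel is a unit square: sample its corners as well as its center
    # so narrow angular wedges still see the outermost boundary
    offs = np.array([(0.0, 0.0), (-0.5, -0.5), (-0.5, 0.5), (0.5, -0.5), (0.5, 0.5)])
    dr = (rows[None, :] + offs[:, 0:1]) - cr
    dc = (cols[None, :] + offs[:, 1:2]) - cc
    dr, dc = dr.ravel(), dc.ravel()
    radius = np.hypot(dr, dc)
    angle = np.degrees(np.arctan2(dr, dc)) % 360.0
    bins = np.minimum((angle / bin_width).astype(int), n_bins - 1)

    radii = np.zeros(n_bins)
    np.maximum.at(radii, bins, radius)
    filled = np.zeros(n_bins, dtype=bool)
    filled[np.unique(bins)] = True

    interpolated = ~filled
    if interpolated.any() and filled.any():
        idx = np.arange(n_bins)
        good = idx[filled]
        # circular linear interpolation over empty bins
        radii[~filled] = np.interp(
            idx[~filled],
            np.concatenate([good - n_bins, good, good + n_bins]),
            np.tile(radii[filled], 3),
        )
    return PolarProfile(
        radii=radii,
        center=(float(cr), float(cc)),
        bin_width=float(bin_width),
        interpolated=interpolated,
    )


def smooth_profile(profile: PolarProfile, k: int = DEFAULT_WINDOW) -> SmoothedProfile:
    """Circular (wrap-around) unweighted moving average over k bins."""
    n = len(profile.radii)
    if k % 2 == 0 or not 1 <= k < n:
        raise ValueError("window k must be odd and in [1, n_bins)")
    if k == 1:
        return SmoothedProfile(radii=profile.radii.copy(), window=1)
    smoothed = uniform_filter1d(profile.radii, size=k, mode="wrap")
    return SmoothedProfile(radii=smoothed, window=k)


def _circular_local_maxima(values: np.ndarray) -> list[int]:
    """Indices of strict local maxima under circular topology.

    Plateaus count once and yield their central bin (the lower-index middle
    bin when the plateau length is even). A constant profile has no maxima.
    """
    n = len(values)
    if np.all(values == values[0]):
        return []
    # group circularly-contiguous runs of equal value
    change = np.nonzero(np.diff(values) != 0)[0] + 1
    starts = np.concatenate([[0], change])
    runs = []  # (start, length, value)
    for i, s in enumerate(starts):
        e = starts[i + 1] if i + 1 < len(starts) else n
        runs.append([s, e - s, values[s]])
    # merge wrap-around run
    if len(runs) > 1 and runs[0][2] == runs[-1][2]:
        runs[0][0] = runs[-1][0]
        runs[0][1] += runs[-1][1]
        runs.pop()

    maxima = []
    nr = len(runs)
    for i, (s, ln, v) in enumerate(runs):
        prev_v = runs[(i - 1) % nr][2]
        next_v = runs[(i + 1) % nr][2]
        if v > prev_v and v > next_v:
            centre = (s + (ln - 1) // 2) % n
            maxima.append(int(centre))
    return sorted(maxima)


def detect_tips(
    profile: PolarProfile,
    smoothed: SmoothedProfile,
    t_r: float | None = None,
) -> list[LeafTip]:
    """Leaf tips: raw radii at local maxima of the smoothed profile.

    ``t_r`` is the minimum raw radius (px) for a maximum to count as a tip;
    ``None`` uses 0.15 x max raw radius, which tracks plant size across
    ages. Returned sorted by angle.
    """
    r = profile.radii
    rs = smoothed.radii
    if len(r) != len(rs):
        raise ValueError("profile and smoothed profile are not aligned")
    if not np.any(r > 0):
        return []
    if t_r is None:
        t_r = DEFAULT_RELATIVE_TR * float(r.max())

    tips = []
    for idx in _circular_local_maxima(rs):
        raw = float(r[idx])
        if raw < t_r or raw <= 0:
            continue
        cr_val = (raw - float(rs[idx])) / raw
        tips.append(
            LeafTip(
                angle=float(idx * profile.bin_width),
                radius=raw,
                curvature_ratio=cr_val,
            )
        )
    return sorted(tips, key=lambda t: t.angle)
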