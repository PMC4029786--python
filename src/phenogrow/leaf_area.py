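"""Per-leaf area inference and overlap-corrected plant area.

A leaf's projected area is inferred from just two tip-local features: the
tip radius r (center-to-tip distance, petiole included) and the curvature
ratio cr. Round leaves (cr below a cutoff) follow a linear length-to-area
law, elongated leaves an exponential one:

    area = slope * r + intercept        if cr <  cutoff
    area = scale * exp(rate * r)        otherwise

The shipped coefficients (32.9, -769.9, 513.8, 0.0146; cutoff 0.07) were
calibrated on 87 wild-type Arabidopsis leaves at a specific magnification
and are imaging-setup specific; ``fit_length_area_model`` and ``fit_cutoff``
recalibrate them from a user's own training leaves.

The whole-plant area combines the summed per-leaf areas a_l with the
observed top-view area a_t. Their relative disagreement is the overlap
proxy p_overlap = |a_t - a_l| / max(a_t, a_l), and the corrected area is

    a = a_l * (1 + p_overlap)

which reduces to a = 2*a_l - a_t when a_l > a_t (tips seen, blades hidden)
and a = 2*a_l - a_l^2/a_t otherwise.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.stats import norm, t as t_dist
from sklearn.mixture import GaussianMixture

__all__ = [
    "LengthAreaModel",
    "PlantAreaRecord",
    "leaf_area_from_tip",
    "fit_cutoff",
    "fit_length_area_model",
    "plant_area",
]

#: 95% CIs of the shipped coefficients, calibration metadata only
#: (not re-derivable without the original training leaves).
SHIPPED_COEFFICIENT_CI = {
    "linear_slope": (29.9, 36.0),
    "linear_intercept": (-1012.0, -527.6),
    "exp_scale": (406.1, 621.6),
    "exp_rate": (0.0130, 0.0162),
}


@dataclass(frozen=True)
class LengthAreaModel:
    """Piecewise length-to-area model with a curvature-ratio branch switch."""

    linear_slope: float = 32.9  # px^2 / px
    linear_intercept: float = -769.9  # px^2
    exp_scale: float = 513.8  # px^2
    exp_rate: float = 0.0146  # 1/px
    cr_cutoff: float = 0.07
    r2_linear: float | None = None
    r2_exp: float | None = None
    coefficient_ci: dict = field(
        default_factory=lambda: dict(SHIPPED_COEFFICIENT_CI)
    )

    def __post_init__(self) -> None:
        if not 0 < self.cr_cutoff < 1:
            raise ValueError("cr_cutoff must be in (0, 1)")
        if self.exp_scale <= 0:
            raise ValueError("exp scale must be positive")

    def invert_length(self, area: float, branch: str = "linear") -> float:
        """Leaf length at which the given branch predicts ``area``."""
        if area <= 0:
            raise ValueError("area must be positive")
        if branch == "linear":
            length = (area - self.linear_intercept) / self.linear_slope
        elif branch == "exp":
            length = math.log(area / self.exp_scale) / self.exp_rate
        else:
            raise ValueError(f"unknown branch {branch!r}")
        if length <= 0:
            raise ValueError(f"area {area:g} is below the {branch} branch's range")
        return float(length)


@dataclass(frozen=True)
class PlantAreaRecord:
    """One frame's area bookkeeping: summed leaf areas a_l, observed
    top-view area a_t, overlap proxy and the corrected plant area a."""

    time: float
    summed_leaf_area: float  # a_l
    observed_area: float  # a_t
    p_overlap: float
    corrected_area: float  # a
    n_tips: int


def leaf_area_from_tip(r: float, cr: float, model: LengthAreaModel | None = None) -> float:
    """Leaf area from tip radius and curvature ratio.

    Linear branch when cr is strictly below the cutoff, exponential branch
    otherwise (boundary values take the exponential branch). Negative linear
    predictions (short leaves below the line's root) clamp to 0 with a
    warning.
    """
    if r <= 0:
        raise ValueError("tip radius must be positive")
    model = model or LengthAreaModel()
    if cr < model.cr_cutoff:
        area = model.linear_slope * r + model.linear_intercept
        if area < 0:
            warnings.warn(
                f"linear length-to-area prediction negative at r={r:g}; clamped to 0",
                stacklevel=2,
            )
            return 0.0
        return float(area)
    return float(model.exp_scale * math.exp(model.exp_rate * r))


def fit_cutoff(cr_values, seed: int = 0, default: float = 0.07) -> float:
    """Curvature-ratio cutoff between round and elongated leaves.

    Fits a two-component Gaussian mixture to the cr distribution and returns
    the equal-posterior point between the two component means. Degenerate
    fits (a vanishing component, or means closer than a quarter of the
    pooled sd) fall back to the shipped default with a warning.
    """
    x = np.asarray(cr_values, dtype=float).reshape(-1, 1)
    if len(x) < 20:
        raise ValueError("need at least 20 curvature ratios to fit a cutoff")
    if np.ptp(x) == 0:
        warnings.warn("constant curvature ratios; returning default cutoff", stacklevel=2)
        return default

    gm = GaussianMixture(n_components=2, n_init=10, random_state=seed)
    gm.fit(x)
    means = gm.means_.ravel()
    sds = np.sqrt(gm.covariances_.ravel())
    weights = gm.weights_.ravel()
    order = np.argsort(means)
    mu1, mu2 = means[order]
    sd1, sd2 = sds[order]
    w1, w2 = weights[order]

    pooled_sd = math.sqrt((sd1**2 + sd2**2) / 2)
    if min(w1, w2) < 0.05 or (mu2 - mu1) < pooled_sd / 4:
        warnings.warn("degenerate mixture fit; returning default cutoff", stacklevel=2)
        return default

    # equal-responsibility point between the means
    grid = np.linspace(mu1, mu2, 20001)
    diff = w1 * norm.pdf(grid, mu1, sd1) - w2 * norm.pdf(grid, mu2, sd2)
    sign_change = np.nonzero(np.diff(np.sign(diff)) != 0)[0]
    if len(sign_change) == 0:
        warnings.warn("no posterior crossing between means; returning default", stacklevel=2)
        return default
    i = sign_change[0]
    return float((grid[i] + grid[i + 1]) / 2)


def _r_squared(y, yhat) -> float:
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    return 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0


def _ols_ci(x, y, slope, intercept):
    n = len(x)
    resid = y - (slope * x + intercept)
    dof = max(n - 2, 1)
    s2 = float(resid @ resid) / dof
    sxx = float(np.sum((x - x.mean()) ** 2))
    se_slope = math.sqrt(s2 / sxx)
    se_int = math.sqrt(s2 * (1 / n + x.mean() ** 2 / sxx))
    tcrit = t_dist.ppf(0.975, dof)
    return (
        (slope - tcrit * se_slope, slope + tcrit * se_slope),
        (intercept - tcrit * se_int, intercept + tcrit * se_int),
    )


def fit_length_area_model(training, cutoff: float = 0.07) -> LengthAreaModel:
    """Recalibrate the length-to-area model from training leaves.

    ``training`` is an iterable of (r, cr, true_area). The linear branch is
    ordinary least squares of area on r; the exponential branch is fit by
    log-linearization refined with one nonlinear least-squares pass. R^2 is
    reported on the original area scale per branch, and 95% CIs for all four
    coefficients are stored in ``coefficient_ci``.
    """
    data = np.asarray(list(training), dtype=float)
    if data.ndim != 2 or data.shape[1] != 3:
        raise ValueError("training rows must be (r, cr, true_area)")
    r, cr, area = data.T
    lin = cr < cutoff
    if lin.sum() < 3:
        raise ValueError("need >= 3 training leaves in the linear (round) branch")
    if (~lin).sum() < 3:
        raise ValueError("need >= 3 training leaves in the exponential branch")

    # linear branch: OLS
    slope, intercept = np.polyfit(r[lin], area[lin], 1)
    r2_lin = _r_squared(area[lin], slope * r[lin] + intercept)
    ci_slope, ci_int = _ols_ci(r[lin], area[lin], slope, intercept)

    # exponential branch: log-linear init, nonlinear refinement
    re_, ae_ = r[~lin], area[~lin]
    if np.any(ae_ <= 0):
        raise ValueError("exponential-branch training areas must be positive")
    rate0, logscale0 = np.polyfit(re_, np.log(ae_), 1)
    p0 = (math.exp(logscale0), rate0)
    popt, pcov = optimize.curve_fit(
        lambda x, s, b: s * np.exp(b * x), re_, ae_, p0=p0, maxfev=10000
    )
    scale, rate = popt
    r2_exp = _r_squared(ae_, scale * np.exp(rate * re_))
    dof = max(len(re_) - 2, 1)
    tcrit = t_dist.ppf(0.975, dof)
    se = np.sqrt(np.diag(pcov))
    ci_scale = (scale - tcrit * se[0], scale + tcrit * se[0])
    ci_rate = (rate - tcrit * se[1], rate + tcrit * se[1])

    return LengthAreaModel(
        linear_slope=float(slope),
        linear_intercept=float(intercept),
        exp_scale=float(scale),
        exp_rate=float(rate),
        cr_cutoff=float(cutoff),
        r2_linear=float(r2_lin),
        r2_exp=float(r2_exp),
        coefficient_ci={
            "linear_slope": tuple(map(float, ci_slope)),
            "linear_intercept": tuple(map(float, ci_int)),
            "exp_scale": tuple(map(float, ci_scale)),
            "exp_rate": tuple(map(float, ci_rate)),
        },
    )


def plant_area(leaf_areas, a_t: float, time: float = 0.0) -> PlantAreaRecord:
    """Overlap-corrected plant area a = a_l * (1 + p_overlap).

    ``leaf_areas`` are the per-tip inferred areas (a_l is their sum), ``a_t``
    the observed top-view pixel area. p_overlap = |a_t - a_l| / max(a_t, a_l).
    """
    leaf_areas = list(leaf_areas)
    if not leaf_areas:
        raise ValueError("no leaf areas: no tips were detected")
    if a_t <= 0:
        raise ValueError("observed top-view area must be positive")
    a_l = float(np.sum(leaf_areas))
    p = abs(a_t - a_l) / max(a_t, a_l) if a_l > 0 else 1.0
    a = a_l * (1.0 + p)
    return PlantAreaRecord(
        time=float(time),
        summed_leaf_area=a_l,
        observed_area=float(a_t),
        p_overlap=float(p),
        corrected_area=float(a),
        n_tips=len(leaf_areas),
    )
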