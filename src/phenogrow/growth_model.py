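"""Three-parameter logistic growth modeling and functional analysis.

The plant-area series A(t) is fit with the three-parameter logistic model

    A(t) = A0 * Aa / (A0 + (Aa - A0) * exp(-gamma * t))

with initial area A0 (the lower asymptote), final area Aa (the upper
asymptote) and rate gamma. The model satisfies the logistic ODE
dA/dt = gamma * A * (1 - A/Aa), so its derivatives have closed forms:

    velocity      v = dA/dt  = gamma * A * (1 - A/Aa)
    acceleration  a = d2A/dt2 = gamma * v * (1 - 2*A/Aa)

Functional features follow: the inflection (max velocity gamma*Aa/4 at
A = Aa/2), the acceleration extrema +-gamma^2*Aa/(6*sqrt(3)) at
A/Aa = (3 -+ sqrt(3))/6 with velocity gamma*Aa/6 there, and the phase-plane
plot of acceleration against velocity, whose enclosed loop area
(integral of a dv over the full growth span, equal to the time integral of
a^2) is gamma^3 * Aa^2 / 30 for an exact logistic and serves as an
energy-transfer proxy. Replicates are screened with Welch's two-tailed
unequal-variance t-test and averaged pointwise.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

__all__ = [
    "ThreePLFit",
    "GrowthRates",
    "PhasePlaneFeatures",
    "logistic3",
    "logistic3_velocity",
    "logistic3_acceleration",
    "fit_3plm",
    "growth_rates",
    "curve_derivatives",
    "phase_plane_features",
    "genotype_phase_plane",
    "flag_outlier_replicates",
    "average_replicates",
]

DEFAULT_DT = 0.35  # days; finite-difference interval for AGR/RGR


@dataclass(frozen=True)
class ThreePLFit:
    """A fitted three-parameter logistic curve with 95% CIs."""

    gamma: float  # 1/time
    a0: float  # px^2, initial area (lower asymptote)
    aa: float  # px^2, final area (upper asymptote)
    ci_gamma: tuple[float, float] = (float("nan"), float("nan"))
    ci_a0: tuple[float, float] = (float("nan"), float("nan"))
    ci_aa: tuple[float, float] = (float("nan"), float("nan"))
    residual_sd: float = float("nan")
    n_obs: int = 0
    decreasing_flag: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.a0 < self.aa):
            raise ValueError("need 0 < A0 < Aa")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")

    def __call__(self, t):
        return logistic3(t, self.a0, self.aa, self.gamma)

    @property
    def inflection_time(self) -> float:
        """Time at which A = Aa/2 (maximum velocity)."""
        return math.log((self.aa - self.a0) / self.a0) / self.gamma


@dataclass(frozen=True)
class GrowthRates:
    """Finite-difference absolute and relative growth rates."""

    times: np.ndarray
    agr: np.ndarray  # px^2/time
    rgr: np.ndarray  # 1/time
    dt: float


@dataclass(frozen=True)
class PhasePlaneFeatures:
    """Landmarks of the acceleration-vs-velocity phase-plane trajectory.

    point_b: maximum acceleration (most active proliferation), point_c:
    maximum velocity with zero acceleration (the inflection), point_d:
    minimum (most negative) acceleration. Each is (velocity, acceleration,
    time). ``loop_area`` is the area enclosed by the trajectory.
    """

    point_b: tuple[float, float, float]
    point_c: tuple[float, float, float]
    point_d: tuple[float, float, float]
    loop_area: float
    degenerate: bool = False


# ---------------------------------------------------------------------------
# closed-form curve and derivatives


def logistic3(t, a0: float, aa: float, gamma: float):
    """Three-parameter logistic area A(t); A(0) = A0, A(inf) = Aa."""
    t = np.asarray(t, dtype=float)
    out = a0 * aa / (a0 + (aa - a0) * np.exp(-gamma * t))
    return float(out) if out.ndim == 0 else out


def logistic3_velocity(t, a0: float, aa: float, gamma: float):
    """dA/dt = gamma * A * (1 - A/Aa), the growth velocity."""
    a = logistic3(t, a0, aa, gamma)
    return gamma * a * (1.0 - a / aa)


def logistic3_acceleration(t, a0: float, aa: float, gamma: float):
    """d2A/dt2 = gamma * v * (1 - 2A/Aa), the growth acceleration."""
    a = logistic3(t, a0, aa, gamma)
    v = gamma * a * (1.0 - a / aa)
    return gamma * v * (1.0 - 2.0 * a / aa)


# ---------------------------------------------------------------------------
# fitting


def fit_3plm(times, areas) -> ThreePLFit:
    """Nonlinear least-squares fit of the three-parameter logistic model.

    Initialization: A0 = first positive observation, Aa = 1.2 x the maximum
    observation, gamma from the slope of logit((A - A0)/(Aa - A0)) against
    time. 95% CIs come from the Jacobian-based covariance at the optimum.
    Non-convergence and degenerate (constant or unidentifiable) series raise
    RuntimeError; a net-decreasing series is flagged, not rejected.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(areas, dtype=float)
    ok = np.isfinite(t) & np.isfinite(y)
    if not ok.all():
        raise ValueError("times and areas must be finite")
    if len(t) < 10:
        raise ValueError("need at least 10 observations to fit the growth model")
    if np.ptp(y) == 0:
        raise RuntimeError("constant area series: growth model unidentifiable")
    decreasing = y[-1] < y[0]
    if decreasing:
        warnings.warn("net-decreasing area series; fit flagged", stacklevel=2)

    a0_init = float(y[y > 0][0]) if np.any(y > 0) else 1.0
    aa_init = 1.2 * float(y.max())
    frac = np.clip((y - a0_init) / max(aa_init - a0_init, 1e-9), 1e-4, 1 - 1e-4)
    gamma_init = max(float(np.polyfit(t, np.log(frac / (1 - frac)), 1)[0]), 1e-4)

    def model(tt, a0, aa, gamma):
        return logistic3(tt, a0, aa, gamma)

    try:
        popt, pcov = optimize.curve_fit(
            model,
            t,
            y,
            p0=(a0_init, aa_init, gamma_init),
            bounds=([1e-9, 1e-9, 1e-9], [np.inf, np.inf, np.inf]),
            maxfev=20000,
        )
    except (RuntimeError, optimize.OptimizeWarning) as exc:
        raise RuntimeError(f"growth-model fit did not converge: {exc}") from exc
    a0, aa, gamma = map(float, popt)
    if not (0 < a0 < aa) or not np.all(np.isfinite(pcov)):
        raise RuntimeError("growth-model fit degenerate (check the input series)")

    resid = y - model(t, *popt)
    dof = max(len(t) - 3, 1)
    residual_sd = float(np.sqrt(resid @ resid / dof))
    tcrit = stats.t.ppf(0.975, dof)
    se = np.sqrt(np.diag(pcov))
    ci = [(p - tcrit * s, p + tcrit * s) for p, s in zip(popt, se)]
    return ThreePLFit(
        gamma=gamma,
        a0=a0,
        aa=aa,
        ci_gamma=tuple(map(float, ci[2])),
        ci_a0=tuple(map(float, ci[0])),
        ci_aa=tuple(map(float, ci[1])),
        residual_sd=residual_sd,
        n_obs=len(t),
        decreasing_flag=bool(decreasing),
    )


# ---------------------------------------------------------------------------
# functional analysis


def growth_rates(source, times, dt: float = DEFAULT_DT) -> GrowthRates:
    """Absolute and relative growth rates by backward finite differences.

    AGR(t) = (A(t) - A(t - dt)) / dt and RGR(t) = (ln A(t) - ln A(t-dt)) / dt
    evaluated at the given times. ``source`` is a ThreePLFit (or any callable
    mapping time to area).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    t = np.asarray(times, dtype=float)
    a_now = np.asarray(source(t), dtype=float)
    a_prev = np.asarray(source(t - dt), dtype=float)
    agr = (a_now - a_prev) / dt
    if np.any(a_now <= 0) or np.any(a_prev <= 0):
        raise ValueError("RGR requires positive areas")
    rgr = (np.log(a_now) - np.log(a_prev)) / dt
    return GrowthRates(times=t, agr=agr, rgr=rgr, dt=float(dt))


def curve_derivatives(fit: ThreePLFit, times) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form velocity and acceleration of the fitted curve."""
    t = np.asarray(times, dtype=float)
    v = logistic3_velocity(t, fit.a0, fit.aa, fit.gamma)
    a = logistic3_acceleration(t, fit.a0, fit.aa, fit.gamma)
    return v, a


def _default_grid(fit: ThreePLFit, n: int = 20001) -> np.ndarray:
    # cover A/Aa from ~0.1% to ~99.9%: the derivatives decay to 0 outside
    span = math.log(999.0) / fit.gamma
    t_mid = fit.inflection_time
    return np.linspace(t_mid - 1.5 * span, t_mid + 1.5 * span, n)


def phase_plane_features(
    fit: ThreePLFit | None = None,
    times=None,
    velocity=None,
    acceleration=None,
    n_grid: int = 20001,
) -> PhasePlaneFeatures:
    """Phase-plane landmarks and enclosed loop area of a growth trajectory.

    Either pass a fitted model (sampled densely over the full growth span by
    default) or explicit (times, velocity, acceleration) samples of any
    growth curve, e.g. a genotype-averaged one. The loop area is the
    integral of acceleration with respect to velocity along the trajectory
    (trapezoid rule), which for a closed loop is the enclosed area.
    """
    if fit is not None:
        t = _default_grid(fit, n_grid) if times is None else np.asarray(times, float)
        v, a = curve_derivatives(fit, t)
    else:
        if times is None or velocity is None or acceleration is None:
            raise ValueError("pass either a fit or (times, velocity, acceleration)")
        t = np.asarray(times, float)
        v = np.asarray(velocity, float)
        a = np.asarray(acceleration, float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    vmax = float(v.max()) if len(v) else 0.0
    if vmax <= 0 or np.ptp(v) == 0:
        return PhasePlaneFeatures(
            point_b=(math.nan,) * 3,
            point_c=(math.nan,) * 3,
            point_d=(math.nan,) * 3,
            loop_area=math.nan,
            degenerate=True,
        )
    dv = np.abs(np.diff(v))
    if dv.max() > 0.01 * vmax:
        raise ValueError(
            "sampling too sparse: max velocity step exceeds 1% of max velocity"
        )

    ib = int(np.argmax(a))
    ic = int(np.argmax(v))
    idx = int(np.argmin(a))
    loop = float(abs(np.trapezoid(a, v)))
    return PhasePlaneFeatures(
        point_b=(float(v[ib]), float(a[ib]), float(t[ib])),
        point_c=(float(v[ic]), float(a[ic]), float(t[ic])),
        point_d=(float(v[idx]), float(a[idx]), float(t[idx])),
        loop_area=loop,
    )


def genotype_phase_plane(
    fits: list[ThreePLFit], mode: str = "per_replicate"
) -> PhasePlaneFeatures:
    """Genotype-level phase-plane summary over retained replicates.

    ``mode="per_replicate"`` (default) computes each replicate's features
    and averages them component-wise. ``mode="curve_first"`` averages the
    replicate curves pointwise on a common time grid and extracts the
    features of that averaged curve.
    """
    if len(fits) < 2:
        raise ValueError("need at least 2 replicates")
    if mode == "per_replicate":
        feats = [phase_plane_features(f) for f in fits]
        if any(f.degenerate for f in feats):
            raise ValueError("a replicate produced a degenerate trajectory")

        def avg(getter):
            return tuple(float(np.mean([getter(f)[i] for f in feats])) for i in range(3))

        return PhasePlaneFeatures(
            point_b=avg(lambda f: f.point_b),
            point_c=avg(lambda f: f.point_c),
            point_d=avg(lambda f: f.point_d),
            loop_area=float(np.mean([f.loop_area for f in feats])),
        )
    if mode == "curve_first":
        lo = min(_default_grid(f)[0] for f in fits)
        hi = max(_default_grid(f)[-1] for f in fits)
        t = np.linspace(lo, hi, 40001)
        v = np.mean([curve_derivatives(f, t)[0] for f in fits], axis=0)
        a = np.mean([curve_derivatives(f, t)[1] for f in fits], axis=0)
        return phase_plane_features(times=t, velocity=v, acceleration=a)
    raise ValueError(f"unknown mode {mode!r}")


# ---------------------------------------------------------------------------
# replicates


def flag_outlier_replicates(replicate_series, alpha: float = 0.05):
    """Welch-test screen of replicate area series.

    ``replicate_series`` is a sequence of per-replicate area arrays sampled
    on a common time grid. Each replicate's areas are compared against the
    pooled areas of the remaining replicates with a two-tailed t-test with
    unequal variance; replicates with p < alpha are flagged.

    Returns a list of (flagged: bool, p_value: float), one per replicate.
    """
    series = [np.asarray(s, dtype=float) for s in replicate_series]
    if len(series) < 3:
        raise ValueError("need at least 3 replicates to screen for outliers")
    out = []
    for i, s in enumerate(series):
        rest = np.concatenate([x for j, x in enumerate(series) if j != i])
        if np.ptp(s) == 0 and np.ptp(rest) == 0 and s[0] == rest[0]:
            p = 1.0
        else:
            p = float(stats.ttest_ind(s, rest, equal_var=False).pvalue)
            if math.isnan(p):
                p = 1.0
        out.append((bool(p < alpha), p))
    return out


def average_replicates(fits: list[ThreePLFit], time_grid):
    """Pointwise mean and sd band of replicate growth curves.

    Returns (mean, sd) arrays evaluated on ``time_grid``. Functional
    features of the genotype can then be taken either from this averaged
    curve or as the mean of per-replicate features (see
    ``genotype_phase_plane``).
    """
    if len(fits) < 2:
        raise ValueError("need at least 2 retained replicates to average")
    t = np.asarray(time_grid, dtype=float)
    curves = np.stack([f(t) for f in fits])
    return curves.mean(axis=0), curves.std(axis=0, ddof=0)
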