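"""End-to-end orchestration: images in, area series and growth fits out.

The per-plant pipeline chains the four area-estimation stages — foreground
mask, plant center (computed once per plant and reused), polar tip detection
and overlap-corrected area — then fits the logistic growth model. An
evaluation harness scores predictions against ground truth with the field's
usual metrics: tip true-positive rate, relative area error rate and
center-to-center distance in pixels.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from phenogrow.center_finder import PlantCenter, SimpleLeafParams, find_center
from phenogrow.foreground_mask import ForegroundMask, build_foreground_mask
from phenogrow.growth_model import DEFAULT_DT, ThreePLFit, fit_3plm
from phenogrow.leaf_area import LengthAreaModel, PlantAreaRecord, leaf_area_from_tip, plant_area
from phenogrow.tip_finder import (
    DEFAULT_BIN_WIDTH,
    DEFAULT_RELATIVE_TR,
    DEFAULT_WINDOW,
    LeafTip,
    detect_tips,
    polar_profile,
    smooth_profile,
)

logger = logging.getLogger("phenogrow")

__all__ = ["RunConfig", "EvaluationReport", "PipelineResult", "run_pipeline", "evaluate"]


@dataclass(frozen=True)
class RunConfig:
    """Every tunable of the pipeline, with documented defaults.

    Mask stage: ``edge_threshold`` (None = Otsu on the gradient magnitude),
    ``dilation_radius`` px, ``erode_back``. Center stage: Gaussian ``sigma``
    px, solidity floor ``s_min``, region area band (``a_min`` px^2 and
    ``a_max_fraction`` of plant area), ``min_chord_ratio`` elongation screen.
    Tip stage: ``bin_width`` deg, smoothing window ``k`` bins, ``t_r_mode``
    ("relative": T_r = t_r_value x max radius; "absolute": T_r = t_r_value
    px). Area stage: the length-to-area coefficients and cr cutoff. Growth
    stage: AGR/RGR interval ``dt`` (time units), Welch screen level
    ``alpha``. ``time_unit`` names the unit of the input time column (gamma
    is reported in 1/time_unit).
    """

    edge_threshold: float | None = None
    dilation_radius: int = 2
    erode_back: bool = True
    sigma: float = 2.0
    s_min: float = 0.85
    a_min: float = 100.0
    a_max_fraction: float = 0.5
    min_chord_ratio: float = 1.2
    bin_width: float = DEFAULT_BIN_WIDTH
    k: int = DEFAULT_WINDOW
    t_r_mode: str = "relative"
    t_r_value: float = DEFAULT_RELATIVE_TR
    cr_cutoff: float = 0.07
    linear_slope: float = 32.9
    linear_intercept: float = -769.9
    exp_scale: float = 513.8
    exp_rate: float = 0.0146
    dt: float = DEFAULT_DT
    alpha: float = 0.05
    seed: int = 0
    time_unit: str = "days"
    center_frame: str = "median_area"  # or an integer frame index as str

    def leaf_params(self) -> SimpleLeafParams:
        return SimpleLeafParams(
            sigma=self.sigma,
            s_min=self.s_min,
            a_min=self.a_min,
            a_max_fraction=self.a_max_fraction,
            min_chord_ratio=self.min_chord_ratio,
        )

    def area_model(self) -> LengthAreaModel:
        return LengthAreaModel(
            linear_slope=self.linear_slope,
            linear_intercept=self.linear_intercept,
            exp_scale=self.exp_scale,
            exp_rate=self.exp_rate,
            cr_cutoff=self.cr_cutoff,
        )

    def t_r(self, max_radius: float) -> float:
        if self.t_r_mode == "relative":
            return self.t_r_value * max_radius
        if self.t_r_mode == "absolute":
            return self.t_r_value
        raise ValueError(f"unknown t_r_mode {self.t_r_mode!r}")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        data = json.loads(text)
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - names
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


@dataclass(frozen=True)
class EvaluationReport:
    """Scores against ground truth: tip true-positive rate (%), mean
    relative area error (%), and center distance (px)."""

    tip_tpr: float
    area_error_rate: float
    naive_area_error_rate: float
    center_distance: float
    n_frames: int


@dataclass
class PipelineResult:
    records: list[PlantAreaRecord]
    center: PlantCenter
    fit: ThreePLFit | None
    tips_per_frame: list[list[LeafTip]]
    masks: list[ForegroundMask] = field(repr=False, default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for rec in self.records:
            rows.append(
                {
                    "time": rec.time,
                    "n_tips": rec.n_tips,
                    "a_l": rec.summed_leaf_area,
                    "a_t": rec.observed_area,
                    "p_overlap": rec.p_overlap,
                    "a": rec.corrected_area,
                }
            )
        return pd.DataFrame(rows)


def run_pipeline(images, times, config: RunConfig | None = None) -> PipelineResult:
    """Run the full area-estimation and growth-modeling chain on one plant.

    ``images`` is a sequence of 2-D grayscale arrays (consistent shape) and
    ``times`` the acquisition times in config.time_unit. The plant center is
    computed once — on the frame of median observed area by default — and
    reused for every frame. Frames with an empty mask yield a null record
    and a warning; the growth fit proceeds on the remaining frames when at
    least 10 are usable.
    """
    config = config or RunConfig()
    images = list(images)
    times = list(times)
    if len(images) != len(times):
        raise ValueError("need one time per image")
    if not images:
        raise ValueError("need at least one image")

    masks: list[ForegroundMask | None] = []
    for i, img in enumerate(images):
        try:
            masks.append(
                build_foreground_mask(
                    img,
                    edge_threshold=config.edge_threshold,
                    dilation_radius=config.dilation_radius,
                    erode_back=config.erode_back,
                )
            )
        except ValueError as exc:
            logger.warning("frame %d: mask failed (%s); skipped", i, exc)
            masks.append(None)

    areas = [m.observed_area if m is not None else -1 for m in masks]
    usable = [i for i, a in enumerate(areas) if a > 0]
    if not usable:
        raise ValueError("no frame produced a non-empty mask")

    if config.center_frame == "median_area":
        order = sorted(usable, key=lambda i: areas[i])
        ref = order[len(order) // 2]
    else:
        ref = int(config.center_frame)
        if ref not in usable:
            raise ValueError(f"center frame {ref} has no usable mask")
    center = find_center(images[ref], masks[ref], config.leaf_params())
    logger.info(
        "center: %s at (%.1f, %.1f) using %d leaves (frame %d)",
        center.method, *center.point, center.n_leaves_used, ref,
    )

    model = config.area_model()
    records: list[PlantAreaRecord] = []
    tips_per_frame: list[list[LeafTip]] = []
    for i, (img, t_i) in enumerate(zip(images, times)):
        mask = masks[i]
        if mask is None or mask.observed_area == 0:
            logger.warning("frame %d: empty mask; null area record", i)
            tips_per_frame.append([])
            records.append(
                PlantAreaRecord(
                    time=float(t_i),
                    summed_leaf_area=math.nan,
                    observed_area=0.0,
                    p_overlap=math.nan,
                    corrected_area=math.nan,
                    n_tips=0,
                )
            )
            continue
        profile = polar_profile(mask, center, bin_width=config.bin_width)
        smoothed = smooth_profile(profile, k=config.k)
        tips = detect_tips(profile, smoothed, t_r=config.t_r(float(profile.radii.max())))
        tips_per_frame.append(tips)
        if not tips:
            logger.warning("frame %d: no tips above T_r; null area record", i)
            records.append(
                PlantAreaRecord(
                    time=float(t_i),
                    summed_leaf_area=math.nan,
                    observed_area=float(mask.observed_area),
                    p_overlap=math.nan,
                    corrected_area=math.nan,
                    n_tips=0,
                )
            )
            continue
        leaf_areas = [
            leaf_area_from_tip(tp.radius, tp.curvature_ratio, model) for tp in tips
        ]
        records.append(
            plant_area(leaf_areas, float(mask.observed_area), time=float(t_i))
        )

    good = [r for r in records if math.isfinite(r.corrected_area)]
    fit = None
    if len(good) >= 10:
        try:
            fit = fit_3plm([r.time for r in good], [r.corrected_area for r in good])
        except (RuntimeError, ValueError) as exc:
            logger.warning("growth fit failed: %s", exc)
    return PipelineResult(
        records=records,
        center=center,
        fit=fit,
        tips_per_frame=tips_per_frame,
        masks=[m for m in masks if m is not None],
    )


def _match_tips(pred: list[LeafTip], truth_tips, truth_center,
                angle_tol: float, radius_tol: float) -> int:
    """Greedy one-to-one matching of predicted to true tips."""
    truth = []
    for (r, c) in truth_tips:
        dr, dc = r - truth_center[0], c - truth_center[1]
        truth.append((math.degrees(math.atan2(dr, dc)) % 360.0, math.hypot(dr, dc)))
    used = [False] * len(pred)
    matched = 0
    for phi_t, rad_t in truth:
        best_j, best_d = None, None
        for j, tp in enumerate(pred):
            if used[j]:
                continue
            dphi = abs((tp.angle - phi_t + 180.0) % 360.0 - 180.0)
            if dphi <= angle_tol and abs(tp.radius - rad_t) <= radius_tol * rad_t:
                if best_d is None or dphi < best_d:
                    best_j, best_d = j, dphi
        if best_j is not None:
            used[best_j] = True
            matched += 1
    return matched


def evaluate(
    result: PipelineResult,
    truths,
    angle_tol: float = 5.0,
    radius_tol: float = 0.10,
) -> EvaluationReport:
    """Score a pipeline run against per-frame ground truth.

    Tip TPR counts a predicted tip as correct when it sits within
    ``angle_tol`` degrees and ``radius_tol`` (relative) of a true tip. The
    area error rate is mean |a - truth| / truth x 100 over frames, reported
    both for the corrected area and for the naive top-view area a_t.
    """
    truths = list(truths)
    if len(truths) != len(result.records):
        raise ValueError("one ground truth per frame required")

    n_true = n_matched = 0
    errs, naive_errs = [], []
    for rec, tips, truth in zip(result.records, result.tips_per_frame, truths):
        n_true += len(truth.tip_points)
        n_matched += _match_tips(tips, truth.tip_points, truth.center, angle_tol, radius_tol)
        if math.isfinite(rec.corrected_area) and truth.union_area > 0:
            true_total = float(sum(truth.per_leaf_polygon_areas))
            errs.append(abs(rec.corrected_area - true_total) / true_total)
            naive_errs.append(abs(rec.observed_area - true_total) / true_total)
    cd = math.hypot(
        result.center.point[0] - truths[0].center[0],
        result.center.point[1] - truths[0].center[1],
    )
    return EvaluationReport(
        tip_tpr=100.0 * n_matched / n_true if n_true else math.nan,
        area_error_rate=100.0 * float(np.mean(errs)) if errs else math.nan,
        naive_area_error_rate=100.0 * float(np.mean(naive_errs)) if naive_errs else math.nan,
        center_distance=float(cd),
        n_frames=len(truths),
    )
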