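"""Intra-diffusion (square-root-of-time) kinetics and composition trends.

When pore diffusion limits the degradation, ln(C/C0) is linear in sqrt(t):

    ln(C/C0) = -Kd * sqrt(t)          Kd: intra-diffusion rate constant, min^-0.5

Rewriting with a characteristic diffusion time tau,

    ln(C/C0) = -sqrt(t / tau),   tau = 1/Kd^2,   Kd = 1/sqrt(tau)

so a small tau means fast intra-particle transport.  Across the catalyst
composition x the characteristic time falls off exponentially,

    tau(x) = tau0 * exp(-theta (x - x0))      =>   Kd(x) = Kd0 * exp(+theta/2 (x - x0))

with Kd0 = 1/sqrt(tau0), in up to three composition domains with their own
(theta, x0).  This module fits the sqrt-t law per series, the exponential
tau(x) law per domain, and locates domain boundaries by exhaustive
piecewise-linear segmentation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy import stats

from .data import DegradationSeries, PhotokinError, PhotokinWarning, ValidationError

__all__ = [
    "IntraDiffusionFit",
    "TauSegment",
    "TauDomainModel",
    "Segmentation",
    "fit_intradiffusion",
    "tau_from_kd",
    "kd_from_tau",
    "fit_tau_exponential",
    "kd_x_predict",
    "segment_domains",
]


class ExtrapolationWarning(PhotokinWarning):
    """Prediction requested outside the range the model was fitted on."""


@dataclass(frozen=True)
class IntraDiffusionFit:
    """Kd (min^-0.5) and its characteristic time tau = 1/Kd^2 (min)."""

    kd: float
    tau: float
    correlation: float


def tau_from_kd(kd: float) -> float:
    """Characteristic time tau = 1/Kd^2 (min)."""
    if not kd > 0:
        raise ValidationError(f"kd must be positive, got {kd}")
    return 1.0 / (kd * kd)


def kd_from_tau(tau: float) -> float:
    """Intra-diffusion rate constant Kd = 1/sqrt(tau) (min^-0.5)."""
    if not tau > 0:
        raise ValidationError(f"tau must be positive, got {tau}")
    return 1.0 / math.sqrt(tau)


def fit_intradiffusion(series: DegradationSeries) -> IntraDiffusionFit:
    """Intercept-free slope of ln(C/C0) on sqrt(t).

    Kd is the negated closed-form slope sum(sqrt(t)*y)/sum(t); the reported
    correlation is the magnitude of Pearson's R on (sqrt(t), ln ratio).
    The zero-intercept form is kept by default so the fitted law passes
    through (0, 0) like the data; a boundary-layer intercept is a diagnostic
    concern outside this model.
    """
    t = series.times
    y = series.log_ratios()
    st = np.sqrt(t)
    denom = np.sum(t)
    if denom <= 0:
        raise PhotokinError("all sampling times are zero")
    kd = -float(np.sum(st * y) / denom)
    if np.ptp(st) == 0 or np.ptp(y) == 0:
        corr = float("nan")
    else:
        corr = float(abs(stats.pearsonr(st, y).statistic))
    return IntraDiffusionFit(kd=kd, tau=tau_from_kd(kd) if kd > 0 else float("inf"),
                             correlation=corr)


@dataclass(frozen=True)
class TauSegment:
    """One composition domain of the exponential tau(x) law."""

    x_lo: float
    x_hi: float  # closed-open [x_lo, x_hi); the last segment is closed
    theta: float
    x0: float
    correlation: float
    n_points: int

    @property
    def decaying(self) -> bool:
        return self.theta > 0


@dataclass(frozen=True)
class TauDomainModel:
    """Piecewise exponential tau(x) = tau0 exp(-theta (x - x0)) per domain."""

    tau0: float
    segments: tuple[TauSegment, ...]

    def segment_for(self, x: float) -> TauSegment:
        for seg in self.segments:
            if seg.x_lo <= x < seg.x_hi:
                return seg
        last = self.segments[-1]
        if x == last.x_hi:
            return last
        warnings.warn(
            f"x={x} outside fitted range [{self.segments[0].x_lo}, {last.x_hi}]; "
            "extrapolating with the nearest domain",
            ExtrapolationWarning,
            stacklevel=3,
        )
        return self.segments[0] if x < self.segments[0].x_lo else last

    def predict_tau(self, x: float) -> float:
        seg = self.segment_for(x)
        return self.tau0 * math.exp(-seg.theta * (x - seg.x0))


def fit_tau_exponential(
    points: Sequence[tuple[float, float]],
    tau0: float | None = None,
    boundaries: Sequence[float] = (0.2, 0.3),
) -> TauDomainModel:
    """Fit the exponential tau(x) law domain by domain.

    Within each domain a least-squares line on (x, ln(tau/tau0)) gives the
    decay slope theta (negated slope) and the offset x0 (the line's root).
    tau0 defaults to the tau observed at the smallest x, the initial maximum
    the decay starts from.  ``boundaries`` are the interior domain edges;
    every domain needs at least two points.  A point sitting exactly on an
    interior boundary is used by both adjacent domains when fitting —
    composition grids are coarse, and the shared endpoint is what makes a
    two-point middle domain fittable at all — while prediction assigns each
    x to exactly one domain (closed-open intervals, last domain closed).
    """
    pts = sorted((float(x), float(tau)) for x, tau in points)
    if len(pts) < 2:
        raise ValidationError("need at least two (x, tau) points")
    if any(tau <= 0 for _, tau in pts):
        raise ValidationError("tau values must be positive")
    if tau0 is None:
        tau0 = pts[0][1]
    if not tau0 > 0:
        raise ValidationError("tau0 must be positive")
    edges = [pts[0][0]] + sorted(boundaries) + [pts[-1][0]]
    segments = []
    for i, (lo, hi) in enumerate(zip(edges[:-1], edges[1:])):
        last = i == len(edges) - 2
        sel = [(x, tau) for x, tau in pts if lo <= x <= hi]
        if len(sel) < 2:
            raise ValidationError(
                f"domain [{lo}, {hi}{']' if last else ')'} has {len(sel)} point(s); need >= 2"
            )
        xs = np.array([x for x, _ in sel])
        z = np.log([tau / tau0 for _, tau in sel])
        slope, intercept = np.polyfit(xs, z, 1)
        theta = -float(slope)
        if theta <= 0:
            warnings.warn(
                f"domain [{lo}, {hi}): theta = {theta:.3g} <= 0, tau not decaying",
                PhotokinWarning,
                stacklevel=2,
            )
            x0 = float("nan")
        else:
            x0 = float(intercept) / theta
        if np.ptp(z) == 0:
            corr = float("nan")
        else:
            corr = float(abs(stats.pearsonr(xs, z).statistic))
        segments.append(
            TauSegment(x_lo=lo, x_hi=hi, theta=theta, x0=x0,
                       correlation=corr, n_points=len(sel))
        )
    return TauDomainModel(tau0=float(tau0), segments=tuple(segments))


def kd_x_predict(model: TauDomainModel, x: float) -> float:
    """Kd at composition x implied by the tau(x) law.

    Kd0 = 1/sqrt(tau0) and Kd(x) = Kd0 * exp(+theta/2 (x - x0)); the positive
    exponent is what the tau/Kd duality demands — tau falling with x means Kd
    rising.  The value equals kd_from_tau(predict_tau(x)) identically.
    """
    seg = model.segment_for(x)
    kd0 = kd_from_tau(model.tau0)
    if not seg.decaying:  # flat domain: x0 is undefined, Kd stays at Kd0
        return kd0
    return kd0 * math.exp(0.5 * seg.theta * (x - seg.x0))


@dataclass(frozen=True)
class SegmentLine:
    x_lo: float
    x_hi: float
    slope: float
    intercept: float
    sse: float
    n_points: int


@dataclass(frozen=True)
class Segmentation:
    breakpoints: tuple[float, ...]
    segments: tuple[SegmentLine, ...]
    total_sse: float


def _line_sse(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    return float(slope), float(intercept), float(np.dot(resid, resid))


def segment_domains(
    points: Sequence[tuple[float, float]],
    n_breakpoints: int = 2,
    min_points: int = 2,
) -> Segmentation:
    """Exhaustive piecewise-linear segmentation over observed-grid midpoints.

    Candidate breakpoints are the midpoints between consecutive observed x
    values; every admissible breakpoint combination (each resulting segment
    holding at least ``min_points`` points) is scored by the total residual
    sum of squares of its per-segment least-squares lines, and the minimizer
    wins.  Ties are broken deterministically in favour of the earliest
    breakpoints.  Intended for small composition grids, where an exhaustive
    search is cheap and reproducible.
    """
    pts = sorted((float(x), float(y)) for x, y in points)
    n = len(pts)
    if n < n_breakpoints + 2:
        raise ValidationError(
            f"need at least {n_breakpoints + 2} points for {n_breakpoints} breakpoints"
        )
    xs = np.array([p[0] for p in pts])
    ys = np.array([p[1] for p in pts])
    if np.any(np.diff(xs) <= 0):
        raise ValidationError("x values must be distinct")
    mids = (xs[:-1] + xs[1:]) / 2.0  # mids[i] splits after point index i
    best: Segmentation | None = None
    for cut_idx in combinations(range(n - 1), n_breakpoints):
        bounds = [0] + [i + 1 for i in cut_idx] + [n]
        sizes = np.diff(bounds)
        if np.any(sizes < min_points):
            continue
        segs = []
        total = 0.0
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            slope, intercept, sse = _line_sse(xs[lo:hi], ys[lo:hi])
            segs.append(
                SegmentLine(
                    x_lo=float(xs[lo]), x_hi=float(xs[hi - 1]),
                    slope=slope, intercept=intercept, sse=sse,
                    n_points=int(hi - lo),
                )
            )
            total += sse
        if best is None or total < best.total_sse:
            best = Segmentation(
                breakpoints=tuple(float(mids[i]) for i in cut_idx),
                segments=tuple(segs),
                total_sse=total,
            )
    if best is None:
        raise ValidationError(
            f"no admissible segmentation with >= {min_points} points per segment"
        )
    return best
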