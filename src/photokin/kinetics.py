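"""Reaction-order model family for photocatalytic decay curves.

Three nested descriptions of a normalized decay C/C0 over time t (minutes):

* pseudo-first-order            ln(C/C0) = -k1 t
* pseudo-n-order                C/C0 = [(n-1) kn t + 1]^(-1/(n-1)),  n > 1
* modified (quadratic-log)      ln(C/C0) = -a1 t + a2 t^2 = -a1 t (1 - alpha t)

The modified law extends the first-order one with a t^2 term; the increment
alpha = a2/a1 measures how far the process deviates from true first order
(alpha = 0 recovers the exponential).  The n-order law interpolates between
integer reaction orders and degenerates to first order as n -> 1.

Also provided: degradation percentage at the final sampling time and the
intrinsic (per square metre of catalyst) rate constant, which removes the
trend in specific surface area across compositions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import optimize, stats

from .data import (
    CatalystRecord,
    DegradationSeries,
    FitReport,
    PhotokinError,
    PhotokinWarning,
    ValidationError,
)

__all__ = [
    "FirstOrderFit",
    "PseudoNOrderFit",
    "ModifiedFit",
    "FIRST_ORDER_METHODS",
    "log_ratio_transform",
    "fit_first_order",
    "degradation_percent",
    "intrinsic_rate",
    "fit_pseudo_n_order",
    "fit_modified",
    "predict_ratio",
]

FIRST_ORDER_METHODS = ("through_origin", "ols_intercept", "nonlinear_ratio")


class NonDecayingWarning(PhotokinWarning):
    """Fit produced a non-positive rate constant (series does not decay)."""


def log_ratio_transform(series: DegradationSeries) -> np.ndarray:
    """Return the (t, ln C/C0) point cloud as an (n, 2) array."""
    return np.column_stack([series.times, series.log_ratios()])


def _pearson_magnitude(a: np.ndarray, b: np.ndarray) -> float:
    # magnitude-only Pearson R of the linearized point cloud, origin included
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return float("nan")
    return float(abs(stats.pearsonr(a, b).statistic))


@dataclass(frozen=True)
class FirstOrderFit:
    """Pseudo-first-order rate constant k1 (min^-1) with its estimator tag."""

    k1: float
    method: str
    correlation: float
    residuals: np.ndarray

    def report(self, label: str = "") -> FitReport:
        return FitReport(
            model_id="first_order",
            parameters={"k1_per_min": self.k1},
            correlation=self.correlation,
            residuals=self.residuals,
            provenance={"label": label, "method": self.method},
        )


def fit_first_order(
    series: DegradationSeries, method: str = "through_origin"
) -> FirstOrderFit:
    """Estimate k1 from a decay series.

    ``through_origin`` (default) regresses ln(C/C0) on t with no intercept,
    honouring the zero-intercept form of the integrated rate law; the slope
    has the closed form sum(t*y)/sum(t^2).  ``ols_intercept`` frees the
    intercept.  ``nonlinear_ratio`` least-squares fits exp(-k1 t) directly to
    the ratios.  The reported correlation is the magnitude of Pearson's R of
    (t, ln ratio) including the origin point, whichever estimator is used.
    """
    if method not in FIRST_ORDER_METHODS:
        raise ValidationError(f"unknown method {method!r}; valid: {FIRST_ORDER_METHODS}")
    t = series.times
    y = series.log_ratios()
    if t.size < 3:
        raise ValidationError("need at least 3 points")
    if method == "through_origin":
        k1 = -float(np.sum(t * y) / np.sum(t * t))
        resid = y + k1 * t
    elif method == "ols_intercept":
        slope, intercept = np.polyfit(t, y, 1)
        k1 = -float(slope)
        resid = y - (slope * t + intercept)
    else:  # nonlinear_ratio
        k0 = max(-np.sum(t * y) / np.sum(t * t), 1e-9)
        sol = optimize.least_squares(
            lambda p: np.exp(-p[0] * t) - series.ratios, x0=[k0],
            xtol=1e-14, ftol=1e-14, gtol=1e-14,
        )
        k1 = float(sol.x[0])
        resid = sol.fun
    if k1 <= 0:
        warnings.warn(
            f"series {series.label!r}: fitted k1 = {k1:.3g} <= 0 (no decay)",
            NonDecayingWarning,
            stacklevel=2,
        )
    return FirstOrderFit(
        k1=k1,
        method=method,
        correlation=_pearson_magnitude(t, y),
        residuals=np.asarray(resid, dtype=float),
    )


def degradation_percent(series: DegradationSeries) -> float:
    """Percent removal at the final sampling time: 100 * (1 - C/C0 at t_end)."""
    return 100.0 * (1.0 - float(series.ratios[-1]))


def intrinsic_rate(
    k1: float,
    record: CatalystRecord,
    catalyst_load: float = 1.0,
    volume: float = 0.030,
) -> float:
    """Rate constant per square metre of catalyst surface, min^-1 m^-2.

    Divides k1 by the total catalyst area in the reactor:
    surface_area (m^2/g) * catalyst_load (g/L) * volume (L).  The defaults
    are the study conditions (1.0 g/L in 30 mL).
    """
    if record.surface_area <= 0:
        raise ValidationError("surface area must be positive")
    if catalyst_load <= 0 or volume <= 0:
        raise ValidationError("catalyst load and volume must be positive")
    return k1 / (record.surface_area * catalyst_load * volume)


@dataclass(frozen=True)
class PseudoNOrderFit:
    """Shared pseudo order n with one rate constant kn per fitted series.

    ``kn`` maps the series label to its rate constant, in
    min^-1 (dimensionless ratio)^(1-n).  ``at_lower_bound`` flags n drifting
    to 1, where the model is singular and the exponential limit applies.
    """

    n: float
    kn: Mapping[str, float]
    converged: bool
    cost: float
    at_lower_bound: bool

    def kn_single(self) -> float:
        if len(self.kn) != 1:
            raise PhotokinError("kn_single() is only defined for a single-series fit")
        return next(iter(self.kn.values()))


N_ORDER_LOWER = 1.0 + 1e-6
N_ORDER_UPPER = 5.0


def _n_order_ratio(n: float, kn: float, t: np.ndarray) -> np.ndarray:
    # singular at n=1 (the exponential limit); for n<1 the base hits zero at
    # finite time, beyond which the law is undefined and we return 0
    base = (n - 1.0) * kn * t + 1.0
    with np.errstate(invalid="ignore"):
        return np.where(base > 0, base ** (-1.0 / (n - 1.0)), 0.0)


def fit_pseudo_n_order(
    series: DegradationSeries | Sequence[DegradationSeries],
    n_starts: Iterable[float] = (1.2, 1.65, 2.5),
) -> PseudoNOrderFit:
    """Joint nonlinear least-squares fit of the pseudo-n-order law.

    A single shared order n and a per-series rate constant kn are estimated
    by minimizing the summed squared ratio residuals over all provided
    series.  The solver is bounded (n in (1, 5], kn >= 0) and multi-started
    from several n values; the best converged solution wins.
    """
    many = [series] if isinstance(series, DegradationSeries) else list(series)
    if not many:
        raise ValidationError("no series supplied")
    for s in many:
        if s.n_points < 4:
            raise ValidationError(f"series {s.label!r}: need >= 4 points")
    labels = [s.label for s in many]

    def residuals(p: np.ndarray) -> np.ndarray:
        n = p[0]
        return np.concatenate(
            [_n_order_ratio(n, kn, s.times) - s.ratios for kn, s in zip(p[1:], many)]
        )

    k_starts = [max(fit_first_order(s).k1, 1e-9) for s in many]
    lower = [N_ORDER_LOWER] + [0.0] * len(many)
    upper = [N_ORDER_UPPER] + [np.inf] * len(many)
    best = None
    for n0 in n_starts:
        sol = optimize.least_squares(
            residuals, x0=[n0] + k_starts, bounds=(lower, upper),
            xtol=1e-14, ftol=1e-14, gtol=1e-14,
        )
        if best is None or (sol.success and sol.cost < best.cost):
            best = sol
    if best is None or not best.success:
        raise PhotokinError(
            f"pseudo-n-order fit did not converge; last iterate {best.x if best else None}"
        )
    n = float(best.x[0])
    return PseudoNOrderFit(
        n=n,
        kn=dict(zip(labels, (float(k) for k in best.x[1:]))),
        converged=bool(best.success),
        cost=float(best.cost),
        at_lower_bound=bool(n < N_ORDER_LOWER + 1e-3),
    )


@dataclass(frozen=True)
class ModifiedFit:
    """Quadratic-log fit ln(C/C0) = -a1 t + a2 t^2; alpha = a2/a1."""

    a1: float  # min^-1
    a2: float  # min^-2
    correlation: float

    @property
    def alpha(self) -> float:
        return self.a2 / self.a1

    def report(self, label: str = "") -> FitReport:
        return FitReport(
            model_id="modified",
            parameters={
                "a1_per_min": self.a1,
                "a2_per_min2": self.a2,
                "alpha_per_min": self.alpha,
            },
            correlation=self.correlation,
            residuals=np.empty(0),
            provenance={"label": label},
        )


def fit_modified(series: DegradationSeries) -> ModifiedFit:
    """Intercept-free quadratic least squares on (t, ln ratio).

    Solves the 2x2 normal equations of min sum (y + a1 t - a2 t^2)^2 in
    closed form.  Because the design contains no constant column the fitted
    curve passes through the origin exactly, matching the model's ratio(0)=1.
    """
    if series.n_points < 4:
        raise ValidationError("need >= 4 points for the quadratic-log fit")
    t = series.times
    y = series.log_ratios()
    s2, s3, s4 = np.sum(t**2), np.sum(t**3), np.sum(t**4)
    b1, b2 = -np.sum(t * y), np.sum(t**2 * y)
    det = s2 * s4 - s3 * s3
    if det <= 0 or not np.isfinite(det):
        raise PhotokinError("singular normal equations (degenerate time grid)")
    a1 = float((b1 * s4 + b2 * s3) / det)
    a2 = float((s2 * b2 + s3 * b1) / det)
    yhat = -a1 * t + a2 * t**2
    return ModifiedFit(a1=a1, a2=a2, correlation=_pearson_magnitude(y, yhat))


_MODEL_PARAMS = {
    "first_order": ("k1",),
    "n_order": ("n", "kn"),
    "modified": ("a1", "a2"),
    "intradiffusion": ("kd",),
}


def predict_ratio(
    model_id: str,
    parameters: Mapping[str, float],
    times,
    clip: bool = True,
) -> np.ndarray:
    """Forward-evaluate any of the decay laws at the given times (minutes).

    Every law satisfies ratio(0) = 1.  If the evaluated law leaves (0, 1]
    (possible e.g. for the modified law with a2 > 0 at large t) the values
    are clipped into the interval and a warning is emitted; pass
    ``clip=False`` to get the raw values.
    """
    if model_id not in _MODEL_PARAMS:
        raise ValidationError(
            f"unknown model {model_id!r}; valid: {sorted(_MODEL_PARAMS)}"
        )
    missing = [p for p in _MODEL_PARAMS[model_id] if p not in parameters]
    if missing:
        raise ValidationError(f"model {model_id!r} missing parameters {missing}")
    t = np.asarray(times, dtype=float)
    if model_id == "first_order":
        out = np.exp(-parameters["k1"] * t)
    elif model_id == "n_order":
        n = parameters["n"]
        if n == 1.0:
            raise ValidationError("n_order law is singular at n = 1 (use first_order)")
        out = _n_order_ratio(n, parameters["kn"], t)
    elif model_id == "modified":
        out = np.exp(-parameters["a1"] * t + parameters["a2"] * t * t)
    else:  # intradiffusion
        out = np.exp(-parameters["kd"] * np.sqrt(t))
    if clip and (np.any(out > 1.0) or np.any(out <= 0.0)):
        warnings.warn(
            f"{model_id} predictions left (0, 1]; clipping",
            PhotokinWarning,
            stacklevel=2,
        )
        out = np.clip(out, np.finfo(float).tiny, 1.0)
    return out
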