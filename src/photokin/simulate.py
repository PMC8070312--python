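"""Synthetic decay curves, reflectance edges and tau profiles with known truth.

Every fitting stage in this package gets a parameter-recovery test from this
module: a forward law evaluated on the study's sampling grid, optionally
perturbed by a seeded noise model, so the generating parameters are the
oracle.  Defaults mirror the study conditions: the eight-point time grid
{0, 10, 20, 30, 60, 90, 120, 180} min, multiplicative lognormal noise on
ratios (concentration readings are positive with roughly proportional
error), and reflectance plateaus near 13% in the strongly absorbing region.

Seeds are mandatory wherever noise is drawn; there is no hidden global
randomness, and the t=0 ratio is pinned at exactly 1 (never perturbed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import yaml

from .data import DegradationSeries, ReflectanceSpectrum, ValidationError
from .kinetics import predict_ratio
from .optics import EV_NM

__all__ = [
    "PAPER_TIME_GRID",
    "SimulationSpec",
    "simulate_series",
    "simulate_reflectance",
    "simulate_tau_profile",
]

#: the degradation study's sampling grid, minutes
PAPER_TIME_GRID = (0.0, 10.0, 20.0, 30.0, 60.0, 90.0, 120.0, 180.0)

NOISE_MODELS = ("none", "multiplicative_lognormal", "additive_gaussian_truncated")
LAWS = ("first_order", "n_order", "modified", "intradiffusion")


@dataclass(frozen=True)
class SimulationSpec:
    """Recipe for one synthetic degradation series."""

    law: str
    parameters: Mapping[str, float]
    seed: int
    times: Sequence[float] = PAPER_TIME_GRID
    noise_model: str = "none"
    noise_scale: float = 0.0
    x: float = 0.0
    label: str = ""

    def __post_init__(self) -> None:
        if self.law not in LAWS:
            raise ValidationError(f"unknown law {self.law!r}; valid: {LAWS}")
        if self.noise_model not in NOISE_MODELS:
            raise ValidationError(
                f"unknown noise model {self.noise_model!r}; valid: {NOISE_MODELS}"
            )
        if self.noise_scale < 0:
            raise ValidationError("noise_scale must be >= 0")
        if not isinstance(self.seed, (int, np.integer)):
            raise ValidationError("seed is mandatory and must be an integer")

    @classmethod
    def from_config(cls, path) -> "SimulationSpec":
        """Load a spec from a YAML or JSON mapping file."""
        with open(path) as fh:
            text = fh.read()
        try:
            payload = json.loads(text)
        except json.JSONDecodeError:
            payload = yaml.safe_load(text)
        if not isinstance(payload, dict):
            raise ValidationError(f"config {path!r} must hold a mapping")
        return cls(**payload)


def simulate_series(spec: SimulationSpec) -> DegradationSeries:
    """Evaluate the law on the grid and apply the seeded noise model.

    With ``noise_model='none'`` the output is the exact law.  Multiplicative
    lognormal noise scales each ratio by exp(sigma Z); truncated additive
    Gaussian noise adds sigma Z.  Either way the result is forced back into
    (0, 1] and the t=0 point stays exactly 1.  Identical seeds give identical
    series.
    """
    t = np.asarray(spec.times, dtype=float)
    clean = predict_ratio(spec.law, spec.parameters, t, clip=False)
    bad = (clean <= 0) | (clean > 1.0 + 1e-12)
    if np.any(bad):
        raise ValidationError(
            f"law {spec.law!r} leaves (0, 1] at t = {t[bad][0]:g} min "
            f"(ratio {clean[bad][0]:.4g}); adjust parameters"
        )
    ratios = clean.copy()
    if spec.noise_model != "none" and spec.noise_scale > 0:
        rng = np.random.default_rng(spec.seed)
        z = rng.standard_normal(t.size)
        if spec.noise_model == "multiplicative_lognormal":
            ratios = ratios * np.exp(spec.noise_scale * z)
        else:
            ratios = ratios + spec.noise_scale * z
        ratios = np.clip(ratios, np.finfo(float).tiny, 1.0)
    ratios[t == 0.0] = 1.0
    label = spec.label or f"sim-{spec.law}-seed{spec.seed}"
    return DegradationSeries(label=label, x=spec.x, times=t, ratios=ratios)


def simulate_reflectance(
    eg: float,
    edge_width: float = 0.05,
    baseline: float = 0.13,
    grid_nm: Sequence[float] | None = None,
    seed: int | None = None,
    noise_scale: float = 0.0,
) -> ReflectanceSpectrum:
    """Reflectance spectrum whose direct-allowed edge sits exactly at ``eg``.

    The construction runs the band-gap extraction backwards: the Tauc
    ordinate (F(R) hv)^2 is exactly A2 (hv - eg) for hv >= eg + edge_width,
    blends quadratically (C1-smooth) to zero across [eg - edge_width,
    eg + edge_width], and vanishes below the gap.  A2 is chosen so that the
    reflectance at the top of the energy span equals ``baseline`` — the deep-
    absorption plateau (about 13-15% in the reference instrument's traces) —
    and the curve relaxes towards transparency (R -> 1) below the gap.
    Inverting the Kubelka-Munk transform then yields R(hv).  Optional
    multiplicative noise (seeded) perturbs the reflectance.
    """
    if grid_nm is None:
        grid_nm = np.arange(200.0, 801.0, 3.0)
    wl = np.asarray(grid_nm, dtype=float)
    energy = EV_NM / wl
    e_lo, e_hi = float(energy.min()), float(energy.max())
    if not (e_lo < eg < e_hi):
        raise ValidationError(
            f"eg = {eg} eV outside the grid's energy span ({e_lo:.3f}, {e_hi:.3f})"
        )
    if not (0.0 < baseline < 1.0):
        raise ValidationError("baseline reflectance must lie in (0, 1)")
    if edge_width <= 0:
        raise ValidationError("edge_width must be positive")
    f_plateau = (1.0 - baseline) ** 2 / (2.0 * baseline)
    a2 = (f_plateau * e_hi) ** 2 / (e_hi - eg)
    w = edge_width
    u = energy - eg
    ordinate = np.where(
        u >= w, a2 * u, np.where(u > -w, a2 * (u + w) ** 2 / (4.0 * w), 0.0)
    )
    f = np.sqrt(ordinate) / energy
    reflectance = 1.0 + f - np.sqrt(f * (f + 2.0))
    if noise_scale > 0:
        if seed is None:
            raise ValidationError("a seed is required when noise_scale > 0")
        rng = np.random.default_rng(seed)
        reflectance = reflectance * np.exp(
            noise_scale * rng.standard_normal(reflectance.size)
        )
        reflectance = np.clip(reflectance, 1e-9, 1.0)
    return ReflectanceSpectrum(
        abscissa=wl, reflectance=reflectance, abscissa_kind="wavelength"
    )


def simulate_tau_profile(
    tau0: float,
    segments: Sequence[tuple[float, float, float, float]],
    xs: Sequence[float],
    noise_scale: float = 0.0,
    seed: int | None = None,
) -> list[tuple[float, float]]:
    """Characteristic times tau(x) = tau0 exp(-theta (x - x0)) per domain.

    ``segments`` is a sequence of (x_lo, x_hi, theta, x0) with the last
    segment closed on the right; every requested x must be covered.  With
    noise, each tau is scaled by a seeded lognormal factor.
    """
    if not tau0 > 0:
        raise ValidationError("tau0 must be positive")
    xs = [float(x) for x in xs]
    taus = []
    for x in xs:
        for i, (lo, hi, theta, x0) in enumerate(segments):
            last = i == len(segments) - 1
            if lo <= x < hi or (last and x == hi):
                taus.append(tau0 * np.exp(-theta * (x - x0)))
                break
        else:
            raise ValidationError(f"x = {x} not covered by any segment")
    taus = np.asarray(taus)
    if noise_scale > 0:
        if seed is None:
            raise ValidationError("a seed is required when noise_scale > 0")
        rng = np.random.default_rng(seed)
        taus = taus * np.exp(noise_scale * rng.standard_normal(taus.size))
    return list(zip(xs, (float(v) for v in taus)))
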