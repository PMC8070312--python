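"""Band-gap extraction from diffuse reflectance, and rate/band-gap trends.

The Kubelka-Munk transform F(R) = (1-R)^2 / (2R) converts diffuse
reflectance into an absorption/scattering proxy.  For a semiconductor with
optical gap Eg and transition exponent n, (F(R) * hv)^(1/n) is linear in the
photon energy hv just above the absorption edge:

    (F(R) * hv)^(1/n) = A2 (hv - Eg)

(n = 1/2 for a direct allowed transition, so the plotted ordinate is
(F hv)^2).  The straight portion of that plot, extended to ordinate zero,
intercepts the energy axis at Eg.  Since no instrument marks where "the
straight portion" begins, the extractor slides a window (at least five
points, starting no lower than the point of maximum slope) across the
transformed curve, keeps the window maximizing R^2, and reports the line's
abscissa intercept; explicit window bounds override the search.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .data import PhotokinError, PhotokinWarning, ReflectanceSpectrum, ValidationError

__all__ = [
    "EV_NM",
    "TRANSITION_EXPONENTS",
    "TaucFit",
    "RateBandgapCorrelation",
    "kubelka_munk",
    "to_photon_energy",
    "tauc_transform",
    "extract_bandgap",
    "correlate_rate_bandgap",
]

#: hc in eV*nm: E[eV] = EV_NM / wavelength[nm]
EV_NM = 1239.84193

#: transition exponent n: direct/indirect x allowed/forbidden
TRANSITION_EXPONENTS = (0.5, 1.5, 2.0, 3.0)


def kubelka_munk(reflectance) -> np.ndarray:
    """F(R) = (1-R)^2 / (2R), elementwise.

    R must be a fraction in (0, 1]; arrays that look like percent (any value
    above 1.5) are rescaled by 1/100 with a warning.  F(1) = 0 and F grows
    without bound as R -> 0+.
    """
    r = np.asarray(reflectance, dtype=float)
    if np.any(r <= 0):
        raise ValidationError("reflectance must be strictly positive")
    if np.any(r > 1.5):
        warnings.warn(
            "reflectance looks like percent (values > 1.5); rescaling by 1/100",
            PhotokinWarning,
            stacklevel=2,
        )
        r = r / 100.0
    if np.any(r > 1.0):
        raise ValidationError("reflectance fraction cannot exceed 1")
    return (1.0 - r) ** 2 / (2.0 * r)


def to_photon_energy(wavelengths_nm) -> np.ndarray:
    """Photon energy in eV from wavelength in nm (E = 1239.84193 / lambda)."""
    wl = np.asarray(wavelengths_nm, dtype=float)
    if np.any(wl <= 0):
        raise ValidationError("wavelengths must be positive")
    return EV_NM / wl


def tauc_transform(
    spectrum: ReflectanceSpectrum, transition_n: float = 0.5
) -> np.ndarray:
    """Return (hv, (F(R) hv)^(1/n)) pairs sorted by ascending photon energy."""
    if transition_n not in TRANSITION_EXPONENTS:
        raise ValidationError(
            f"unsupported transition exponent {transition_n}; "
            f"valid: {TRANSITION_EXPONENTS}"
        )
    if spectrum.abscissa_kind == "wavelength":
        energy = to_photon_energy(spectrum.abscissa)
    else:
        energy = np.asarray(spectrum.abscissa, dtype=float)
    f = kubelka_munk(spectrum.reflectance)
    ordinate = (f * energy) ** (1.0 / transition_n)
    order = np.argsort(energy, kind="stable")
    return np.column_stack([energy[order], ordinate[order]])


@dataclass(frozen=True)
class TaucFit:
    """Band gap Eg (eV) with the fitted linear window and its quality."""

    eg: float
    window: tuple[float, float]  # photon-energy bounds of the fitted region, eV
    slope_coeff: float  # proportionality constant A2 of the linear law
    window_r2: float
    n_points_window: int


def _window_stats(e: np.ndarray, y: np.ndarray):
    """Vectorized slope/intercept/R^2 for every contiguous index window.

    Returns arrays indexed by (start i, end j inclusive) built from prefix
    sums, so the O(n^2) window sweep costs O(n^2) arithmetic total.
    """
    n = e.size
    one = np.ones(n)
    cs = lambda v: np.concatenate([[0.0], np.cumsum(v)])
    Sx, Sy, Sxx, Sxy, Syy, Sn = map(cs, (e, y, e * e, e * y, y * y, one))
    i = np.arange(n)[:, None]
    j = np.arange(n)[None, :]
    cnt = Sn[j + 1] - Sn[i]
    sx = Sx[j + 1] - Sx[i]
    sy = Sy[j + 1] - Sy[i]
    sxx = Sxx[j + 1] - Sxx[i]
    sxy = Sxy[j + 1] - Sxy[i]
    syy = Syy[j + 1] - Syy[i]
    with np.errstate(divide="ignore", invalid="ignore"):
        vx = sxx - sx * sx / cnt
        vy = syy - sy * sy / cnt
        cov = sxy - sx * sy / cnt
        slope = cov / vx
        intercept = (sy - slope * sx) / cnt
        r2 = np.where(vy > 0, cov * cov / (vx * vy), 0.0)
    return slope, intercept, r2, cnt


def extract_bandgap(
    spectrum: ReflectanceSpectrum,
    transition_n: float = 0.5,
    window: tuple[float, float] | None = None,
    min_window: int = 5,
) -> TaucFit:
    """Locate the linear absorption edge and return its energy intercept.

    With ``window=(lo, hi)`` (photon-energy bounds, eV) the line is fitted to
    the points inside those bounds.  Otherwise all contiguous windows of at
    least ``min_window`` points starting at or above the edge onset are
    scored by R^2, and the widest window within 1e-3 of the best score wins;
    it must have positive slope, else there is no absorption edge to fit.

    The onset anchor is the first point where a lightly smoothed derivative
    of the transformed curve reaches half its maximum.  On noiseless data
    this coincides with the first maximum-slope point (the derivative is
    constant over the linear region); under noise it is far more stable than
    the raw argmax, whose position wanders anywhere in the linear region and
    can strand the search on a handful of high-energy points.  Preferring
    the widest near-optimal window counters the known bias of raw R^2
    maximization towards very short, accidentally well-fitting windows.
    """
    data = tauc_transform(spectrum, transition_n)
    e, y = data[:, 0], data[:, 1]
    if e.size < 10:
        raise ValidationError("need >= 10 spectral points spanning the edge")

    if window is not None:
        lo, hi = float(window[0]), float(window[1])
        sel = (e >= lo) & (e <= hi)
        if sel.sum() < 2:
            raise ValidationError(f"window ({lo}, {hi}) eV contains < 2 points")
        slope, intercept = np.polyfit(e[sel], y[sel], 1)
        if slope <= 0:
            raise PhotokinError("no absorption edge: window slope not positive")
        resid = y[sel] - (slope * e[sel] + intercept)
        tot = y[sel] - y[sel].mean()
        r2 = 1.0 - float(np.dot(resid, resid) / np.dot(tot, tot))
        return TaucFit(
            eg=float(-intercept / slope),
            window=(float(e[sel].min()), float(e[sel].max())),
            slope_coeff=float(slope),
            window_r2=r2,
            n_points_window=int(sel.sum()),
        )

    # edge onset: first half-max point of the smoothed derivative
    kernel = np.ones(min(5, e.size)) / min(5, e.size)
    y_smooth = np.convolve(y, kernel, mode="same")
    grad = np.gradient(y_smooth, e)
    i0 = int(np.argmax(grad >= 0.5 * grad.max()))
    i0 = min(i0, e.size - min_window)  # keep at least one admissible window

    slope, intercept, r2, cnt = _window_stats(e, y)
    ii = np.arange(e.size)[:, None]
    admissible = (ii >= i0) & (cnt >= min_window) & (slope > 0)
    if not admissible.any():
        raise PhotokinError("no absorption edge: no window with positive slope")
    score = np.where(admissible, r2, -np.inf)
    best_r2 = score.max()
    tied = admissible & (score >= best_r2 - 1e-3)
    width = np.where(tied, cnt, -1)
    flat = int(np.argmax(width))  # widest among ties; argmax takes the earliest
    bi, bj = divmod(flat, e.size)
    m, b = float(slope[bi, bj]), float(intercept[bi, bj])
    return TaucFit(
        eg=-b / m,
        window=(float(e[bi]), float(e[bj])),
        slope_coeff=m,
        window_r2=float(r2[bi, bj]),
        n_points_window=int(cnt[bi, bj]),
    )


@dataclass(frozen=True)
class RateBandgapCorrelation:
    """Spearman rank and Pearson (Eg, ln k1) correlation across catalysts."""

    spearman: float
    pearson_ln: float
    n: int
    degenerate: bool


def correlate_rate_bandgap(k1_values, eg_values) -> RateBandgapCorrelation:
    """Correlate first-order rate constants with band gaps across catalysts.

    Returns the Spearman rank correlation of (Eg, k1) — invariant to the log
    — and the Pearson correlation of (Eg, ln k1).  Constant inputs make rank
    correlation undefined; the result is then flagged degenerate with NaN
    statistics rather than raising.
    """
    k1 = np.asarray(k1_values, dtype=float)
    eg = np.asarray(eg_values, dtype=float)
    if k1.size != eg.size:
        raise ValidationError(f"length mismatch: {k1.size} rates vs {eg.size} gaps")
    if k1.size < 3:
        raise ValidationError("need at least 3 catalysts to correlate")
    if np.any(k1 <= 0):
        raise ValidationError("rate constants must be positive (ln is taken)")
    if np.ptp(eg) == 0 or np.ptp(k1) == 0:
        return RateBandgapCorrelation(
            spearman=float("nan"), pearson_ln=float("nan"),
            n=int(k1.size), degenerate=True,
        )
    rho = float(stats.spearmanr(eg, k1).statistic)
    pear = float(stats.pearsonr(eg, np.log(k1)).statistic)
    return RateBandgapCorrelation(spearman=rho, pearson_ln=pear,
                                  n=int(k1.size), degenerate=False)
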