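"""Domain types, tabular I/O and packaged reference tables.

The central object is :class:`DegradationSeries`: one catalyst's normalized
concentration trajectory C/C0 over irradiation time.  Ratios are stored as
measured after the dark-adsorption equilibrium (C0 already discounts dark
adsorption) and are never renormalized by this package.  Time is fixed to
minutes internally; readers accept seconds/hours and convert on ingest.

The reference tables packaged under ``fixtures/`` are the printed degradation
time courses, textural properties, kinetic transforms and band gaps of a
series of Cd-doped Mn-Zn spinel ferrites (composition label ``x``, the Cd
coordination, 0 <= x <= 0.5) degrading penicillin G under visible light.
They serve as verification inputs for every downstream fitting stage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Literal, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "PhotokinError",
    "ValidationError",
    "ParseError",
    "PhotokinWarning",
    "DegradationSeries",
    "CatalystRecord",
    "ReflectanceSpectrum",
    "FitReport",
    "KineticTable",
    "read_series",
    "write_series",
    "load_fixture",
    "FIXTURE_NAMES",
]


class PhotokinError(Exception):
    """Base class for errors raised by this package."""


class ValidationError(PhotokinError, ValueError):
    """A domain object violates one of its invariants."""


class ParseError(PhotokinError, ValueError):
    """Tabular input could not be parsed into a domain object."""


class PhotokinWarning(UserWarning):
    """Base class for warnings emitted by this package."""


#: factors converting a time unit to minutes
TIME_UNIT_TO_MIN = {"s": 1.0 / 60.0, "min": 1.0, "h": 60.0}


@dataclass(frozen=True)
class DegradationSeries:
    """One catalyst's (time, C/C0) degradation trajectory.

    Parameters
    ----------
    label : str
        Free-text identifier (e.g. ``"x=0.2"``).
    x : float
        Dopant coordination in [0, 0.5], dimensionless.
    times : array-like
        Sampling times in minutes, strictly increasing, first entry 0.
    ratios : array-like
        Concentration ratios C/C0 in (0, 1]; the t=0 entry must be exactly 1.
    """

    label: str
    x: float
    times: np.ndarray
    ratios: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        r = np.asarray(self.ratios, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "ratios", r)
        if t.ndim != 1 or r.ndim != 1 or t.size != r.size:
            raise ValidationError("times and ratios must be 1-D and equal length")
        if t.size < 3:
            raise ValidationError(
                f"series {self.label!r}: need at least 3 points, got {t.size}"
            )
        if not (np.isfinite(t).all() and np.isfinite(r).all()):
            raise ValidationError(f"series {self.label!r}: non-finite values")
        if np.any(np.diff(t) <= 0) or t[0] < 0:
            raise ValidationError(
                f"series {self.label!r}: times must be non-negative and strictly increasing"
            )
        if t[0] != 0.0:
            raise ValidationError(f"series {self.label!r}: first time must be 0")
        if r[0] != 1.0:
            raise ValidationError(f"series {self.label!r}: ratio at t=0 must be 1.0")
        if np.any(r <= 0.0) or np.any(r > 1.0):
            raise ValidationError(f"series {self.label!r}: ratios must lie in (0, 1]")
        if not (0.0 <= float(self.x) <= 0.5):
            raise ValidationError(f"series {self.label!r}: x={self.x} outside [0, 0.5]")

    @property
    def n_points(self) -> int:
        return int(self.times.size)

    def log_ratios(self) -> np.ndarray:
        """Natural log of C/C0, elementwise (always defined: ratios > 0)."""
        return np.log(self.ratios)


@dataclass(frozen=True)
class CatalystRecord:
    """Textural/optical descriptors of one catalyst composition."""

    x: float
    surface_area: float  # m^2/g
    pore_volume: float | None = None  # cm^3/g
    pore_diameter: float | None = None  # Angstrom
    band_gap: float | None = None  # eV

    def __post_init__(self) -> None:
        if not self.surface_area > 0:
            raise ValidationError(f"x={self.x}: surface_area must be > 0")
        if self.band_gap is not None and not (0.5 < self.band_gap < 6.5):
            raise ValidationError(
                f"x={self.x}: band gap {self.band_gap} eV outside the plausible "
                "semiconductor range (0.5, 6.5)"
            )


@dataclass(frozen=True)
class ReflectanceSpectrum:
    """A diffuse-reflectance spectrum R_inf over wavelength (nm) or energy (eV).

    Reflectance is stored as a fraction in (0, 1]; values supplied in percent
    (any entry > 1.5) are rescaled by 1/100 with a warning, since a true
    fraction cannot exceed 1.
    """

    abscissa: np.ndarray
    reflectance: np.ndarray
    abscissa_kind: Literal["wavelength", "energy"] = "wavelength"

    def __post_init__(self) -> None:
        a = np.asarray(self.abscissa, dtype=float)
        r = np.asarray(self.reflectance, dtype=float)
        if a.ndim != 1 or r.ndim != 1 or a.size != r.size:
            raise ValidationError("abscissa and reflectance must be 1-D, equal length")
        if self.abscissa_kind not in ("wavelength", "energy"):
            raise ValidationError(f"unknown abscissa_kind {self.abscissa_kind!r}")
        d = np.diff(a)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValidationError("abscissa must be strictly monotone")
        if np.any(r > 1.5):
            warnings.warn(
                "reflectance looks like percent (values > 1.5); rescaling by 1/100",
                PhotokinWarning,
                stacklevel=2,
            )
            r = r / 100.0
        if np.any(r <= 0):
            raise ValidationError("reflectance must be strictly positive")
        if np.any(r > 1.0):
            raise ValidationError("reflectance fraction cannot exceed 1")
        object.__setattr__(self, "abscissa", a)
        object.__setattr__(self, "reflectance", r)

    @property
    def n_points(self) -> int:
        return int(self.abscissa.size)


@dataclass(frozen=True)
class FitReport:
    """Uniform summary of any fit: parameters, linear correlation, residuals."""

    model_id: str
    parameters: Mapping[str, float]
    correlation: float
    residuals: np.ndarray = field(default_factory=lambda: np.empty(0))
    provenance: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, value in self.parameters.items():
            if not np.isfinite(value):
                raise ValidationError(f"parameter {name!r} is not finite: {value}")
        if np.isfinite(self.correlation) and abs(self.correlation) > 1 + 1e-12:
            raise ValidationError(f"|correlation| > 1: {self.correlation}")

    def to_json_dict(self) -> dict:
        return {
            "model_id": self.model_id,
            "parameters": {k: float(v) for k, v in self.parameters.items()},
            "correlation": float(self.correlation),
            "n_points": int(np.asarray(self.residuals).size),
        }


@dataclass(frozen=True)
class KineticTable:
    """The printed kinetic-transform table: sqrt-t and ln(C/C0) columns plus
    the reported first-order rate constants and correlation coefficients."""

    times: np.ndarray
    sqrt_times: np.ndarray
    ln_ratios: Mapping[float, np.ndarray]  # x -> column
    k1: Mapping[float, float]  # x -> printed k1, min^-1 (already descaled)
    correlation: Mapping[float, float]  # x -> printed R


def read_series(
    source,
    label: str = "",
    x: float = 0.0,
    time_unit: str = "min",
) -> DegradationSeries:
    """Read a two-column (time, ratio) table into a validated series.

    The reader accepts a path or file-like object holding CSV with a header
    row; the first column is time (in ``time_unit``), the second the ratio
    C/C0.  Rows are sorted by time; a missing t=0 row is prepended with ratio
    1.0 and a warning, since instruments frequently omit the trivial point.
    """
    if time_unit not in TIME_UNIT_TO_MIN:
        raise ValidationError(f"unknown time unit {time_unit!r}; use s, min or h")
    try:
        frame = pd.read_csv(source)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"could not parse {source!r}: {exc}") from exc
    if frame.shape[1] < 2:
        raise ParseError("need at least two columns (time, ratio)")
    frame = frame.iloc[:, :2]
    numeric = frame.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna().any(axis=1)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ParseError(f"non-numeric cell in data row {row}: {frame.iloc[row].tolist()}")
    t = numeric.iloc[:, 0].to_numpy(dtype=float) * TIME_UNIT_TO_MIN[time_unit]
    r = numeric.iloc[:, 1].to_numpy(dtype=float)
    order = np.argsort(t, kind="stable")
    t, r = t[order], r[order]
    if t.size == 0 or t[0] != 0.0:
        warnings.warn(
            f"series {label!r}: no t=0 row; prepending (0, 1.0)",
            PhotokinWarning,
            stacklevel=2,
        )
        t = np.concatenate([[0.0], t])
        r = np.concatenate([[1.0], r])
    return DegradationSeries(label=label, x=x, times=t, ratios=r)


def write_series(series: DegradationSeries, path) -> None:
    """Write a series as RFC-4180 CSV with header ``time_min,ratio``.

    Numbers are written with ``repr`` precision so a read/write round trip
    reproduces every stored value exactly.
    """
    lines = ["time_min,ratio"]
    lines += [f"{float(t)!r},{float(r)!r}" for t, r in zip(series.times, series.ratios)]
    text = "\n".join(lines) + "\n"
    if hasattr(path, "write"):
        path.write(text)
    else:
        with open(path, "w", encoding="ascii") as fh:
            fh.write(text)


FIXTURE_NAMES = ("table1", "table2", "table3", "bandgaps")


def _fixture_path(name: str):
    return resources.files("photokin.fixtures").joinpath(name)


def load_fixture(name: str):
    """Load one of the packaged reference tables.

    ``table1``  -> list[CatalystRecord] (textural properties per x)
    ``table2``  -> list[DegradationSeries] (six C/C0 time courses)
    ``table3``  -> KineticTable (sqrt-t, ln ratios, printed k1 and R)
    ``bandgaps``-> dict x -> band gap, eV
    """
    if name == "table1":
        df = pd.read_csv(_fixture_path("table1.csv"))
        return [
            CatalystRecord(
                x=row.x,
                surface_area=row.surface_area_m2_per_g,
                pore_volume=row.pore_volume_cm3_per_g,
                pore_diameter=row.pore_diameter_angstrom,
            )
            for row in df.itertuples()
        ]
    if name == "table2":
        df = pd.read_csv(_fixture_path("table2.csv"))
        t = df["time_min"].to_numpy(dtype=float)
        out = []
        for col in df.columns[1:]:
            x = float(col.removeprefix("x"))
            out.append(
                DegradationSeries(
                    label=f"x={x}", x=x, times=t, ratios=df[col].to_numpy(dtype=float)
                )
            )
        return out
    if name == "table3":
        ln = pd.read_csv(_fixture_path("table3_lnratios.csv"))
        cons = pd.read_csv(_fixture_path("table3_constants.csv"))
        return KineticTable(
            times=ln["time_min"].to_numpy(dtype=float),
            sqrt_times=ln["sqrt_t_min05"].to_numpy(dtype=float),
            ln_ratios={
                float(c.removeprefix("x")): ln[c].to_numpy(dtype=float)
                for c in ln.columns[2:]
            },
            k1={r.x: r.k1_e3_per_min * 1e-3 for r in cons.itertuples()},
            correlation={r.x: r.correlation_r for r in cons.itertuples()},
        )
    if name == "bandgaps":
        df = pd.read_csv(_fixture_path("bandgaps.csv"))
        return {float(r.x): float(r.band_gap_ev) for r in df.itertuples()}
    raise KeyError(f"unknown fixture {name!r}; valid names: {FIXTURE_NAMES}")
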