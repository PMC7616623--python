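"""Wavelength-domain types and colorimetric integration.

Spectra are sampled on a uniform wavelength grid (default 400-700 nm at
5 nm, 61 samples). Tristimulus integration uses the CIE 1931 2-degree
standard observer, bundled as an abridged 10 nm table and interpolated
onto the working grid on load. Tristimulus values are plain length-3
numpy arrays ``[X, Y, Z]``; whether they are absolute (Y in cd/m^2) or
relative (Y of the reference white = 100) is a property of the
normalization constant used, which callers track explicitly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Luminous efficacy of monochromatic 555 nm radiation, lm/W. Used as the
#: normalization constant turning spectral radiance integrated against
#: ybar into absolute luminance (cd/m^2).
KM = 683.0

SPECTRUM_ROLES = ("reflectance", "radiance", "irradiance")

#: Reflectances may slightly exceed 1 (measurement noise, near-fluorescent
#: samples); above this they are rejected as physically implausible.
REFLECTANCE_HARD_MAX = 1.5


@dataclass(frozen=True)
class WavelengthGrid:
    """Uniform wavelength sampling ``start, start+step, ..., stop`` (inclusive)."""

    start_nm: float = 400.0
    stop_nm: float = 700.0
    step_nm: float = 5.0

    def __post_init__(self) -> None:
        if not self.start_nm < self.stop_nm:
            raise ValueError("start_nm must be < stop_nm")
        if self.step_nm <= 0:
            raise ValueError("step_nm must be > 0")
        n = (self.stop_nm - self.start_nm) / self.step_nm
        if abs(n - round(n)) > 1e-9:
            raise ValueError("step_nm must divide the range evenly")

    @property
    def n(self) -> int:
        return int(round((self.stop_nm - self.start_nm) / self.step_nm)) + 1

    @property
    def wavelengths(self) -> np.ndarray:
        return self.start_nm + self.step_nm * np.arange(self.n)

    def covers(self, other: "WavelengthGrid") -> bool:
        return self.start_nm <= other.start_nm + 1e-9 and self.stop_nm >= other.stop_nm - 1e-9


DEFAULT_GRID = WavelengthGrid()


@dataclass
class Spectrum:
    """A nonnegative wavelength-sampled function.

    ``role`` is one of reflectance / radiance / irradiance and controls
    validation: reflectances must stay below ``REFLECTANCE_HARD_MAX``
    (values in (1, 1.5] are accepted with a warning).
    """

    grid: WavelengthGrid
    values: np.ndarray
    role: str = "radiance"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.role not in SPECTRUM_ROLES:
            raise ValueError(f"unknown spectrum role {self.role!r}")
        if self.values.shape != (self.grid.n,):
            raise ValueError(
                f"values shape {self.values.shape} does not match grid ({self.grid.n} points)"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("spectrum values must be finite")
        if np.any(self.values < 0):
            raise ValueError("spectrum values must be nonnegative")
        if self.role == "reflectance":
            vmax = float(self.values.max())
            if vmax > REFLECTANCE_HARD_MAX:
                raise ValueError(
                    f"reflectance exceeds {REFLECTANCE_HARD_MAX} (max {vmax:.3f})"
                )
            if vmax > 1.0:
                logger.warning("reflectance exceeds 1 (max %.3f); keeping it", vmax)


@dataclass
class CMFSet:
    """Color-matching functions (xbar, ybar, zbar) on a shared grid."""

    grid: WavelengthGrid
    xbar: np.ndarray
    ybar: np.ndarray
    zbar: np.ndarray

    def __post_init__(self) -> None:
        for name in ("xbar", "ybar", "zbar"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (self.grid.n,):
                raise ValueError(f"{name} does not match the grid")
            if np.any(arr < 0) or not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} must be finite and nonnegative")
            setattr(self, name, arr)
        peak = self.grid.wavelengths[int(np.argmax(self.ybar))]
        if not 540 <= peak <= 570:
            raise ValueError(f"ybar peak at {peak} nm; expected near 555 nm")

    @property
    def matrix(self) -> np.ndarray:
        """(n_wavelengths, 3) stack of xbar, ybar, zbar."""
        return np.stack([self.xbar, self.ybar, self.zbar], axis=1)


def _data_path(name: str):
    return resources.files("tiltmet.data").joinpath(name)


def load_cie1931(grid: WavelengthGrid = DEFAULT_GRID) -> CMFSet:
    """CIE 1931 2-degree observer interpolated onto ``grid``.

    The bundled table spans 400-700 nm at 10 nm; requesting a grid
    outside that range raises.
    """
    with _data_path("cie1931_2deg.csv").open() as fh:
        tab = pd.read_csv(fh)
    src = tab["wavelength_nm"].to_numpy(float)
    if grid.start_nm < src[0] - 1e-9 or grid.stop_nm > src[-1] + 1e-9:
        raise ValueError("requested grid extends beyond the bundled CMF range")
    wl = grid.wavelengths
    return CMFSet(
        grid=grid,
        xbar=np.interp(wl, src, tab["xbar"].to_numpy(float)),
        ybar=np.interp(wl, src, tab["ybar"].to_numpy(float)),
        zbar=np.interp(wl, src, tab["zbar"].to_numpy(float)),
    )


def resample_spectrum(s: Spectrum, target: WavelengthGrid) -> Spectrum:
    """Linear interpolation of ``s`` onto ``target``; extrapolation is an error."""
    if not s.grid.covers(target):
        raise ValueError(
            f"target grid [{target.start_nm}, {target.stop_nm}] not covered by "
            f"source [{s.grid.start_nm}, {s.grid.stop_nm}]"
        )
    vals = np.interp(target.wavelengths, s.grid.wavelengths, s.values)
    return Spectrum(grid=target, values=np.clip(vals, 0.0, None), role=s.role)


def spectrum_to_xyz(s: Spectrum, cmf: CMFSet, k: float) -> np.ndarray:
    """Riemann-sum tristimulus integration ``X = k * sum s * xbar * dlambda``.

    ``k = KM`` turns absolute spectral radiance (W sr^-1 m^-2 nm^-1) into
    XYZ with Y in cd/m^2; ``k = relative_normalization(white, cmf)`` gives
    relative colorimetry with Y(white) = 100.
    """
    if s.grid != cmf.grid:
        raise ValueError("spectrum and CMFs must share a grid")
    return k * s.grid.step_nm * (cmf.matrix.T @ s.values)


def spectra_to_xyz(values: np.ndarray, cmf: CMFSet, k: float) -> np.ndarray:
    """Vectorized form of :func:`spectrum_to_xyz` over a (..., n_wavelengths) array."""
    values = np.asarray(values, dtype=float)
    if values.shape[-1] != cmf.grid.n:
        raise ValueError("last axis must match the CMF grid")
    return k * cmf.grid.step_nm * (values @ cmf.matrix)


def relative_normalization(white: Spectrum, cmf: CMFSet) -> float:
    """k such that the reference white integrates to Y = 100."""
    if white.grid != cmf.grid:
        raise ValueError("white and CMFs must share a grid")
    denom = float(np.sum(white.values * cmf.ybar)) * cmf.grid.step_nm
    if denom <= 0:
        raise ValueError("reference white has zero luminance")
    return 100.0 / denom


def xyz_to_chromaticity(xyz: np.ndarray) -> np.ndarray:
    """CIE (x, y) chromaticity; raises when X+Y+Z vanishes."""
    xyz = np.asarray(xyz, dtype=float)
    total = xyz.sum(axis=-1)
    if np.any(total <= 0):
        raise ValueError("chromaticity undefined for zero-sum tristimulus")
    return xyz[..., :2] / total[..., None]


def pearson_correlation(s1: Spectrum, s2: Spectrum) -> float:
    """Sample Pearson correlation between two spectra on a shared grid."""
    if s1.grid != s2.grid:
        raise ValueError("spectra must share a grid")
    a, b = s1.values, s2.values
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("correlation undefined for a constant spectrum")
    a = a - a.mean()
    b = b - b.mean()
    return float(np.clip((a @ b) / np.sqrt((a @ a) * (b @ b)), -1.0, 1.0))
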