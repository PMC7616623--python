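"""Color appearance and dichromat simulation.

Implements the CIECAM02 forward model (CAT02 chromatic adaptation,
Hunt-Pointer-Estevez cone space, luminance-level compression), the
CAM02-UCS uniform coordinates whose Euclidean distance is the color
difference dE used throughout, and the Brettel-Vienot-Mollon half-plane
projection that maps trichromatic XYZ to the XYZ seen by a protan,
deutan or tritan dichromat.

All colorimetric quantities are numpy arrays with XYZ (or J'a'b') on the
last axis, so every function is vectorized over leading axes.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from functools import lru_cache

import numpy as np

from .spectral import CMFSet, DEFAULT_GRID, load_cie1931

__all__ = [
    "Observer",
    "ViewingConditions",
    "ciecam02_forward",
    "jmh_to_ucs",
    "xyz_to_ucs",
    "delta_e",
    "brettel_dichromat",
]


class Observer(str, Enum):
    """Color-vision phenotype: normal trichromat or one of the dichromacies."""

    TRICHROMAT = "trichromat"
    PROTAN = "protan"
    DEUTAN = "deutan"
    TRITAN = "tritan"

    @classmethod
    def from_name(cls, name: "str | Observer") -> "Observer":
        if isinstance(name, cls):
            return name
        try:
            return cls(name.lower())
        except ValueError:
            raise ValueError(f"unknown observer type {name!r}") from None


# CAT02 chromatic-adaptation matrix (XYZ -> sharpened RGB).
M_CAT02 = np.array(
    [
        [0.7328, 0.4296, -0.1624],
        [-0.7036, 1.6975, 0.0061],
        [0.0030, 0.0136, 0.9834],
    ]
)
M_CAT02_INV = np.linalg.inv(M_CAT02)

# Hunt-Pointer-Estevez matrix (XYZ -> LMS), equal-energy-white normalized.
M_HPE = np.array(
    [
        [0.38971, 0.68898, -0.07868],
        [-0.22981, 1.18340, 0.04641],
        [0.00000, 0.00000, 1.00000],
    ]
)
M_HPE_INV = np.linalg.inv(M_HPE)

#: Surround parameters (F, c, Nc). This pipeline always uses "average".
SURROUNDS = {
    "average": (1.0, 0.69, 1.0),
    "dim": (0.9, 0.59, 0.9),
    "dark": (0.8, 0.525, 0.8),
}


@dataclass
class ViewingConditions:
    """CIECAM02 viewing-condition parameters.

    white_point is relative XYZ with Y = 100; adapting_luminance (L_A) is
    absolute, in cd/m^2; background_factor (Y_b) is the background
    relative luminance in percent of the white.
    """

    white_point: np.ndarray
    adapting_luminance: float
    background_factor: float = 20.0
    surround: str = "average"

    def __post_init__(self) -> None:
        self.white_point = np.asarray(self.white_point, dtype=float)
        if self.white_point.shape != (3,):
            raise ValueError("white_point must be a length-3 XYZ vector")
        if np.any(self.white_point <= 0):
            raise ValueError("degenerate white point: all channels must be > 0")
        if self.adapting_luminance <= 0:
            raise ValueError("adapting_luminance must be > 0")
        if not 0 < self.background_factor <= 100:
            raise ValueError("background_factor must lie in (0, 100]")
        if self.surround not in SURROUNDS:
            raise ValueError(f"unknown surround {self.surround!r}")
        self._precompute()

    def _precompute(self) -> None:
        F, c, Nc = SURROUNDS[self.surround]
        la = self.adapting_luminance
        xyz_w = self.white_point
        yw = xyz_w[1]

        D = F * (1.0 - (1.0 / 3.6) * np.exp((-la - 42.0) / 92.0))
        D = float(np.clip(D, 0.0, 1.0))

        rgb_w = M_CAT02 @ xyz_w
        d_rgb = D * yw / rgb_w + 1.0 - D

        k = 1.0 / (5.0 * la + 1.0)
        fl = 0.2 * k**4 * (5.0 * la) + 0.1 * (1.0 - k**4) ** 2 * (5.0 * la) ** (1.0 / 3.0)

        n = self.background_factor / yw  # Y_b relative to Y_w = 100
        z = 1.48 + np.sqrt(n)
        nbb = 0.725 * (1.0 / n) ** 0.2

        rgbp_w = M_HPE @ (M_CAT02_INV @ (d_rgb * rgb_w))
        rgba_w = _compress(rgbp_w, fl)
        aw = (2.0 * rgba_w[0] + rgba_w[1] + rgba_w[2] / 20.0 - 0.305) * nbb

        self._F, self._c, self._Nc = F, c, Nc
        self._D, self._d_rgb, self._fl = D, d_rgb, fl
        self._n, self._z, self._nbb, self._ncb = n, z, nbb, nbb
        self._aw = aw


def _compress(rgb: np.ndarray, fl: float) -> np.ndarray:
    """Post-adaptation nonlinear response compression, sign-symmetric."""
    x = np.asarray(rgb, dtype=float)
    ax = (fl * np.abs(x) / 100.0) ** 0.42
    return np.sign(x) * 400.0 * ax / (27.13 + ax) + 0.1


def ciecam02_forward(xyz: np.ndarray, vc: ViewingConditions):
    """CIECAM02 lightness J, colorfulness M and hue angle h (degrees).

    ``xyz`` is relative colorimetry (Y of the adapted white = 100), any
    leading shape; returns three arrays of that leading shape.
    """
    xyz = np.asarray(xyz, dtype=float)
    rgb = xyz @ M_CAT02.T
    rgb_c = rgb * vc._d_rgb
    rgbp = rgb_c @ (M_HPE @ M_CAT02_INV).T
    rgba = _compress(rgbp, vc._fl)

    ra, ga, ba = rgba[..., 0], rgba[..., 1], rgba[..., 2]
    a = ra - 12.0 * ga / 11.0 + ba / 11.0
    b = (ra + ga - 2.0 * ba) / 9.0
    h = np.degrees(np.arctan2(b, a)) % 360.0

    et = 0.25 * (np.cos(np.radians(h) + 2.0) + 3.8)
    A = (2.0 * ra + ga + ba / 20.0 - 0.305) * vc._nbb
    J = 100.0 * np.clip(A / vc._aw, 0.0, None) ** (vc._c * vc._z)

    t_num = (50000.0 / 13.0) * vc._Nc * vc._ncb * et * np.hypot(a, b)
    t_den = ra + ga + 21.0 / 20.0 * ba
    t = np.where(t_den != 0, t_num / np.where(t_den != 0, t_den, 1.0), 0.0)
    t = np.clip(t, 0.0, None)
    C = t**0.9 * np.sqrt(J / 100.0) * (1.64 - 0.29**vc._n) ** 0.73
    M = C * vc._fl**0.25
    return J, M, h


def jmh_to_ucs(J: np.ndarray, M: np.ndarray, h: np.ndarray) -> np.ndarray:
    """CAM02-UCS coordinates (J', a', b') from lightness, colorfulness, hue.

    J' = 1.7 J / (1 + 0.007 J);  M' = ln(1 + 0.0228 M) / 0.0228;
    a' = M' cos h, b' = M' sin h.
    """
    J = np.asarray(J, dtype=float)
    M = np.asarray(M, dtype=float)
    h = np.asarray(h, dtype=float)
    if np.any(J < 0) or np.any(M < 0):
        raise ValueError("J and M must be nonnegative")
    jp = 1.7 * J / (1.0 + 0.007 * J)
    mp = np.log1p(0.0228 * M) / 0.0228
    hr = np.radians(h)
    return np.stack([jp, mp * np.cos(hr), mp * np.sin(hr)], axis=-1)


def xyz_to_ucs(xyz: np.ndarray, vc: ViewingConditions) -> np.ndarray:
    """Convenience composition: relative XYZ -> CAM02-UCS (J', a', b')."""
    return jmh_to_ucs(*ciecam02_forward(xyz, vc))


def delta_e(u1: np.ndarray, u2: np.ndarray) -> np.ndarray:
    """Euclidean color difference in CAM02-UCS."""
    u1 = np.asarray(u1, dtype=float)
    u2 = np.asarray(u2, dtype=float)
    return np.linalg.norm(u1 - u2, axis=-1)


# ---------------------------------------------------------------------------
# Brettel-Vienot-Mollon dichromat simulation
# ---------------------------------------------------------------------------

#: Monochromatic anchor wavelengths (nm) for the two projection half-planes.
#: Protan and deutan planes hinge on 575 nm (yellow) and 475 nm (blue);
#: tritan planes on 660 nm (red) and 485 nm (cyan).
_ANCHOR_NM = {
    Observer.PROTAN: (575.0, 475.0),
    Observer.DEUTAN: (575.0, 475.0),
    Observer.TRITAN: (660.0, 485.0),
}
_MISSING_AXIS = {Observer.PROTAN: 0, Observer.DEUTAN: 1, Observer.TRITAN: 2}


def _monochromatic_lms(cmf: CMFSet, nm: float) -> np.ndarray:
    idx = int(np.argmin(np.abs(cmf.grid.wavelengths - nm)))
    return M_HPE @ cmf.matrix[idx]


@lru_cache(maxsize=8)
def _brettel_planes(grid_key, observer: Observer):
    """Per-observer (white axis, plane normals, side rule) from the CMFs.

    The neutral hinge is the LMS of the equal-energy (flat) spectrum
    integrated over the working grid, so a flat-spectrum stimulus is an
    exact fixed point of the projection.
    """
    grid = DEFAULT_GRID if grid_key is None else grid_key
    cmf = load_cie1931(grid)
    white = M_HPE @ (cmf.matrix.sum(axis=0) * grid.step_nm)
    a1 = _monochromatic_lms(cmf, _ANCHOR_NM[observer][0])
    a2 = _monochromatic_lms(cmf, _ANCHOR_NM[observer][1])
    n1 = np.cross(white, a1)
    n2 = np.cross(white, a2)
    return white, n1, n2


def brettel_dichromat(
    xyz: np.ndarray,
    observer: Observer,
    grid=None,
) -> np.ndarray:
    """Project trichromatic XYZ onto a dichromat's reduced gamut.

    In HPE cone space the missing cone's signal is replaced so that the
    stimulus falls on one of two half-planes, each containing the
    equal-energy-white axis and one monochromatic anchor; the half-plane
    is chosen by which side of the neutral axis the stimulus lies on.
    Trichromat input is returned unchanged. Works on any leading shape;
    the projection is piecewise linear and scale-invariant.
    """
    observer = Observer.from_name(observer)
    xyz = np.asarray(xyz, dtype=float)
    if observer is Observer.TRICHROMAT:
        return xyz.copy()

    white, n1, n2 = _brettel_planes(grid, observer)
    lms = xyz @ M_HPE.T
    m = _MISSING_AXIS[observer]
    keep = [i for i in range(3) if i != m]

    # The two half-planes are separated by the plane spanned by the white
    # axis and the missing cone's axis: classification by that plane is
    # invariant under the projection (which moves stimuli parallel to the
    # missing axis), making the transform exactly idempotent.
    if observer is Observer.PROTAN:
        # yellow side (low S/M) -> 575 nm anchor plane
        side = lms[..., 2] * white[1] <= lms[..., 1] * white[2]
    elif observer is Observer.DEUTAN:
        # yellow side (low S/L) -> 575 nm anchor plane
        side = lms[..., 2] * white[0] <= lms[..., 0] * white[2]
    else:
        # red side (low M/L) -> 660 nm anchor plane
        side = lms[..., 1] * white[0] <= lms[..., 0] * white[1]

    out = lms.copy()
    for normal, mask in ((n1, side), (n2, ~side)):
        if normal[m] == 0:
            raise ValueError("degenerate projection plane")
        proj = -(
            normal[keep[0]] * lms[..., keep[0]] + normal[keep[1]] * lms[..., keep[1]]
        ) / normal[m]
        out[..., m] = np.where(mask, proj, out[..., m])
    return out @ M_HPE_INV.T
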