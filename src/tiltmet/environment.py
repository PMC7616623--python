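"""Hyperspectral environment maps and Lambertian surface rendering.

An environment map records incident spectral radiance as a function of
direction on an equirectangular grid: rows span inclination theta in
[0, pi] from the zenith (z-up), columns span azimuth phi in [0, 2*pi).
A matte planar surface with normal n receives the cosine-weighted
irradiance

    E(lambda) = sum_pixels L(omega, lambda) * max(0, n . omega) * d_omega

and re-emits radiance L_out = R * E / pi (Lambertian, no occluders or
interreflections), which replaces a full path-traced render exactly for
an unoccluded plane.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .appearance import Observer, ViewingConditions, brettel_dichromat
from .spectral import KM, Spectrum, WavelengthGrid, load_cie1931, spectra_to_xyz

__all__ = [
    "EnvironmentMap",
    "TiltGrid",
    "TiltSeries",
    "make_tilt_grid",
    "cosine_weighted_irradiance",
    "irradiance_matrix",
    "render_surface",
    "compute_viewing_conditions",
]

N_TILTS = 81
GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))


@dataclass
class EnvironmentMap:
    """Direction-indexed spectral radiance on an equirectangular grid.

    radiance has shape (rows, cols, n_wavelengths) in absolute units
    (W sr^-1 m^-2 nm^-1 up to the luminance calibration recorded in
    ``calibration_cd_per_m2``, the adapting luminance the map was scaled
    to). scene_label tags the map as outdoor or indoor.
    """

    grid: WavelengthGrid
    radiance: np.ndarray
    scene_label: str = "outdoor"
    name: str = "env"
    calibration_cd_per_m2: float | None = None

    def __post_init__(self) -> None:
        self.radiance = np.asarray(self.radiance, dtype=float)
        if self.radiance.ndim != 3 or self.radiance.shape[2] != self.grid.n:
            raise ValueError("radiance must be (rows, cols, n_wavelengths)")
        rows, cols = self.radiance.shape[:2]
        if rows < 8 or cols < 16:
            raise ValueError("directional resolution must be at least 8 x 16")
        if np.any(self.radiance < 0) or not np.all(np.isfinite(self.radiance)):
            raise ValueError("radiance must be finite and nonnegative")
        if self.scene_label not in ("outdoor", "indoor"):
            raise ValueError("scene_label must be 'outdoor' or 'indoor'")
        total = float(self.solid_angles.sum())
        if abs(total - 4.0 * np.pi) > 0.01 * 4.0 * np.pi:
            raise ValueError(f"solid angles sum to {total:.4f}, expected ~4*pi")

    @property
    def shape(self) -> tuple[int, int]:
        return self.radiance.shape[:2]

    @property
    def thetas(self) -> np.ndarray:
        """Pixel-center inclinations, midpoint rule over [0, pi]."""
        rows = self.shape[0]
        return (np.arange(rows) + 0.5) * np.pi / rows

    @property
    def phis(self) -> np.ndarray:
        cols = self.shape[1]
        return (np.arange(cols) + 0.5) * 2.0 * np.pi / cols

    @property
    def solid_angles(self) -> np.ndarray:
        """Per-pixel solid angle d_omega = sin(theta) dtheta dphi, shape (rows, cols)."""
        rows, cols = self.shape
        dtheta = np.pi / rows
        dphi = 2.0 * np.pi / cols
        return np.repeat(
            (np.sin(self.thetas) * dtheta * dphi)[:, None], cols, axis=1
        )

    @property
    def directions(self) -> np.ndarray:
        """Unit direction per pixel, shape (rows, cols, 3); z is up."""
        th = self.thetas[:, None]
        ph = self.phis[None, :]
        return np.stack(
            [
                np.sin(th) * np.cos(ph) * np.ones_like(ph),
                np.sin(th) * np.sin(ph) * np.ones_like(th),
                np.cos(th) * np.ones_like(ph),
            ],
            axis=-1,
        )


@dataclass
class TiltGrid:
    """The set of surface normals (tilts) at which a surface is rendered."""

    normals: np.ndarray
    mode: str = "fibonacci"

    def __post_init__(self) -> None:
        self.normals = np.asarray(self.normals, dtype=float)
        if self.normals.ndim != 2 or self.normals.shape[1] != 3:
            raise ValueError("normals must be (n, 3)")
        norms = np.linalg.norm(self.normals, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-9):
            raise ValueError("normals must be unit vectors")
        if np.any(self.normals[:, 2] < -1e-12):
            raise ValueError("normals must lie in the upper hemisphere")

    def __len__(self) -> int:
        return len(self.normals)


@dataclass
class TiltSeries:
    """Per-tilt CAM02-UCS coordinates of one surface for one observer."""

    surface_id: str
    observer: Observer
    ucs: np.ndarray
    spectra: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.ucs = np.asarray(self.ucs, dtype=float)
        if self.ucs.ndim != 2 or self.ucs.shape[1] != 3:
            raise ValueError("ucs must be (n_tilts, 3)")


def make_tilt_grid(mode: str = "fibonacci", n: int = N_TILTS) -> TiltGrid:
    """Deterministic set of ``n`` upper-hemisphere surface normals.

    fibonacci: quasi-uniform spiral from the zenith (included exactly) to
    the horizon. slant_azimuth: the zenith plus rings of constant slant
    at 11.25 degree increments, 10 azimuths per ring (n must be 81).
    """
    if mode == "fibonacci":
        i = np.arange(n)
        z = 1.0 - i / (n - 1)
        r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
        phi = i * GOLDEN_ANGLE
        normals = np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)
    elif mode == "slant_azimuth":
        if n != 81:
            raise ValueError("slant_azimuth mode defines exactly 81 tilts")
        slants = np.radians(11.25 * np.arange(1, 9))  # 8 nonzero slants
        azimuths = 2.0 * np.pi * np.arange(10) / 10.0
        normals = [np.array([0.0, 0.0, 1.0])]
        for s in slants:
            for a in azimuths:
                normals.append(
                    np.array([np.sin(s) * np.cos(a), np.sin(s) * np.sin(a), np.cos(s)])
                )
        normals = np.array(normals)
    else:
        raise ValueError(f"unknown tilt mode {mode!r}")
    normals /= np.linalg.norm(normals, axis=1, keepdims=True)
    return TiltGrid(normals=normals, mode=mode)


def _check_unit(normal: np.ndarray) -> np.ndarray:
    normal = np.asarray(normal, dtype=float)
    if abs(np.linalg.norm(normal) - 1.0) > 1e-6:
        raise ValueError("normal must be a unit vector")
    return normal


def irradiance_matrix(env: EnvironmentMap, normals: np.ndarray) -> np.ndarray:
    """Cosine-weighted irradiance spectra for many normals at once.

    The cosine-weighted quadrature weights of each normal are
    renormalized to sum to pi (their exact continuous value), so a
    direction-independent radiance field yields bit-identical irradiance
    at every tilt; for directional fields this corrects the sub-percent
    anisotropy of the equirectangular pixel grid. Returns shape
    (n_normals, n_wavelengths).
    """
    normals = np.atleast_2d(np.asarray(normals, dtype=float))
    dirs = env.directions.reshape(-1, 3)
    w = np.clip(normals @ dirs.T, 0.0, None) * env.solid_angles.reshape(-1)
    w *= np.pi / w.sum(axis=1, keepdims=True)
    return w @ env.radiance.reshape(-1, env.grid.n)


def cosine_weighted_irradiance(env: EnvironmentMap, normal: np.ndarray) -> Spectrum:
    """Spectral irradiance onto a plane with the given unit normal."""
    normal = _check_unit(normal)
    values = irradiance_matrix(env, normal[None, :])[0]
    return Spectrum(grid=env.grid, values=np.clip(values, 0.0, None), role="irradiance")


def render_surface(R: Spectrum, env: EnvironmentMap, tilts: TiltGrid) -> list[Spectrum]:
    """Reflected radiance L_out = R * E / pi at every tilt (matte surface)."""
    if R.role != "reflectance":
        raise ValueError("R must have reflectance role")
    if R.grid != env.grid:
        raise ValueError("reflectance and environment grids differ")
    E = irradiance_matrix(env, tilts.normals)
    out = R.values[None, :] * E / np.pi
    return [Spectrum(grid=env.grid, values=v, role="radiance") for v in out]


def render_corpus(values: np.ndarray, env: EnvironmentMap, tilts: TiltGrid) -> np.ndarray:
    """Reflected radiance for a whole corpus: (n_surfaces, n_tilts, n_wavelengths)."""
    E = irradiance_matrix(env, tilts.normals) / np.pi
    return np.einsum("nl,tl->ntl", np.asarray(values, dtype=float), E)


def compute_viewing_conditions(env: EnvironmentMap, tilts: TiltGrid) -> ViewingConditions:
    """Scene-derived CIECAM02 parameters.

    W_p: mean absolute XYZ over all tilts of a perfectly white (R = 1)
    rendering. L_A: solid-angle-weighted mean luminance of the map's
    pixels. Y_b: 100 * L_A / Y(W_p), clamped into (0, 100].
    """
    cmf = load_cie1931(env.grid)
    E = irradiance_matrix(env, tilts.normals) / np.pi  # white-surface radiance
    xyz_tilts = spectra_to_xyz(E, cmf, KM)
    wp_abs = xyz_tilts.mean(axis=0)
    if wp_abs[1] <= 0:
        raise ValueError("zero-luminance environment")
    omega = env.solid_angles
    y_pix = spectra_to_xyz(env.radiance, cmf, KM)[..., 1]
    la = float((y_pix * omega).sum() / omega.sum())
    yb = float(np.clip(100.0 * la / wp_abs[1], 1e-6, 100.0))
    # CIECAM02 works in relative colorimetry: rescale W_p to Y = 100.
    wp_rel = wp_abs * (100.0 / wp_abs[1])
    vc = ViewingConditions(
        white_point=wp_rel,
        adapting_luminance=la,
        background_factor=yb,
        surround="average",
    )
    vc.white_luminance = wp_abs[1]  # cd/m^2; used to normalize stimuli
    return vc


def dichromat_viewing_conditions(vc: ViewingConditions, observer: Observer) -> ViewingConditions:
    """Viewing conditions whose white point is what the dichromat adapts to.

    The trichromatic scene white is passed through the dichromat
    projection and renormalized to Y = 100; L_A and Y_b are luminance
    quantities and carry over unchanged.
    """
    observer = Observer.from_name(observer)
    if observer is Observer.TRICHROMAT:
        return vc
    wp = brettel_dichromat(vc.white_point, observer)
    out = ViewingConditions(
        white_point=wp * (100.0 / wp[1]),
        adapting_luminance=vc.adapting_luminance,
        background_factor=vc.background_factor,
        surround=vc.surround,
    )
    out.white_luminance = getattr(vc, "white_luminance", None)
    return out
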