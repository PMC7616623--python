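"""Synthetic reflectance corpora and lighting environments.

The analysis needs (a) a corpus of smooth natural-like surface
reflectances, including a controlled fraction of near-duplicates to
exercise deduplication, and (b) directional hyperspectral environments
with distinct sun-like and sky-like spectral zones (outdoor) or low
directional contrast (indoor). Everything here is generated from a
seeded RNG so any run is exactly reproducible.

Illuminant spectra come from the CIE daylight series (S0/S1/S2
reconstruction along the daylight locus, valid 4000-25000 K) for sun
and sky zones, and from Planck blackbody radiation (3000-4000 K,
incandescent-like) for indoor scenes.

Metameric pairs are constructed with the classical metameric-black
device: a perturbation drawn from the null space of the matrix that
maps reflectance to the observer's sensor responses under one tilt's
irradiance is added to a base reflectance, producing a second surface
with identical responses at that tilt but generically different
responses at others whenever the illumination is directional.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import null_space

from .appearance import M_HPE, Observer
from .environment import EnvironmentMap, cosine_weighted_irradiance
from .spectral import (
    DEFAULT_GRID,
    Spectrum,
    WavelengthGrid,
    _data_path,
    load_cie1931,
)

__all__ = [
    "CATEGORIES",
    "ReflectanceGeneratorConfig",
    "EnvironmentGeneratorConfig",
    "daylight_spectrum",
    "daylight_chromaticity",
    "planck_spectrum",
    "generate_reflectances",
    "generate_environment",
    "generate_metameric_pair",
    "make_fixture",
]

CATEGORIES = ("flower", "fruit", "skin", "leaf", "manmade")

# Per-category priors: base reflectance level range, number-of-bumps range,
# bump-center range (nm) and bump amplitude range. Loose caricatures of the
# corresponding natural/manufactured materials (leaves peak in the green and
# rise at the red edge, skin rises smoothly toward long wavelengths, ...).
_CATEGORY_PRIORS = {
    "flower": dict(base=(0.05, 0.45), bumps=(2, 4), center=(400, 700), amp=(0.1, 0.5)),
    "fruit": dict(base=(0.05, 0.35), bumps=(2, 4), center=(540, 700), amp=(0.1, 0.5)),
    "skin": dict(base=(0.15, 0.45), bumps=(1, 3), center=(580, 700), amp=(0.05, 0.3)),
    "leaf": dict(base=(0.02, 0.15), bumps=(2, 3), center=(530, 700), amp=(0.05, 0.35)),
    "manmade": dict(base=(0.02, 0.7), bumps=(1, 5), center=(400, 700), amp=(0.05, 0.6)),
}


@dataclass
class ReflectanceGeneratorConfig:
    """Parameters of the synthetic reflectance corpus."""

    n_samples: int = 200
    n_basis: int = 8
    smoothness: float = 60.0  # Gaussian bump width (nm)
    duplicate_fraction: float = 0.05
    category_mix: dict = field(
        default_factory=lambda: {
            # roughly the mix of the kinds of corpora this emulates:
            # man-made materials dominate, then skin/flowers/leaves/fruit
            "flower": 0.05,
            "fruit": 0.03,
            "skin": 0.15,
            "leaf": 0.03,
            "manmade": 0.74,
        }
    )
    seed: int = 0
    grid: WavelengthGrid = field(default_factory=lambda: DEFAULT_GRID)

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        if set(self.category_mix) - set(CATEGORIES):
            raise ValueError("unknown category in category_mix")
        total = sum(self.category_mix.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError("category_mix proportions must sum to 1")
        if not 0 <= self.duplicate_fraction < 1:
            raise ValueError("duplicate_fraction must lie in [0, 1)")


@dataclass
class EnvironmentGeneratorConfig:
    """Parameters of a synthetic lighting environment."""

    kind: str = "two_zone_outdoor"  # or low_contrast_indoor, uniform
    sun_cct: float = 5000.0
    sky_cct: float = 10000.0
    indoor_cct: float = 3500.0
    sun_direction: np.ndarray = field(
        default_factory=lambda: np.array([0.5, 0.5, np.sqrt(0.5)])
    )
    sun_angular_radius: float = 10.0  # deg; enlarged so the disc resolves at 32x64
    contrast: float = 30.0  # sun/sky radiance ratio (outdoor); max/min ratio (indoor)
    resolution: tuple[int, int] = (32, 64)
    calibration_cd_per_m2: float | None = None  # default set per kind
    seed: int = 0
    grid: WavelengthGrid = field(default_factory=lambda: DEFAULT_GRID)
    name: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("two_zone_outdoor", "low_contrast_indoor", "uniform"):
            raise ValueError(f"unknown environment kind {self.kind!r}")
        for cct in (self.sun_cct, self.sky_cct):
            if not 4000 <= cct <= 25000:
                raise ValueError("daylight CCT must lie in [4000, 25000] K")
        if not 2500 <= self.indoor_cct <= 5000:
            raise ValueError("indoor_cct must lie in [2500, 5000] K")
        if self.contrast < 1:
            raise ValueError("contrast must be >= 1")
        self.sun_direction = np.asarray(self.sun_direction, dtype=float)
        self.sun_direction = self.sun_direction / np.linalg.norm(self.sun_direction)
        if self.calibration_cd_per_m2 is None:
            # typical adapting luminances: bright daylight vs artificial interior
            self.calibration_cd_per_m2 = (
                300.0 if self.kind == "low_contrast_indoor" else 3000.0
            )


# ---------------------------------------------------------------------------
# Illuminant spectra
# ---------------------------------------------------------------------------


def daylight_chromaticity(cct: float) -> tuple[float, float]:
    """CIE daylight-locus chromaticity (x_D, y_D) for a CCT in [4000, 25000] K."""
    if not 4000 <= cct <= 25000:
        raise ValueError("daylight CCT must lie in [4000, 25000] K")
    t = 1e3 / cct
    if cct <= 7000:
        x = 0.244063 + 0.09911 * t + 2.9678 * t**2 - 4.6070 * t**3
    else:
        x = 0.237040 + 0.24748 * t + 1.9018 * t**2 - 2.0064 * t**3
    y = -3.000 * x**2 + 2.870 * x - 0.275
    return x, y


def _daylight_components(grid: WavelengthGrid) -> np.ndarray:
    with _data_path("cie_daylight_components.csv").open() as fh:
        tab = pd.read_csv(fh)
    src = tab["wavelength_nm"].to_numpy(float)
    if grid.start_nm < src[0] - 1e-9 or grid.stop_nm > src[-1] + 1e-9:
        raise ValueError("grid extends beyond the daylight component tables")
    wl = grid.wavelengths
    return np.stack(
        [np.interp(wl, src, tab[c].to_numpy(float)) for c in ("S0", "S1", "S2")]
    )


def daylight_spectrum(cct: float, grid: WavelengthGrid = DEFAULT_GRID) -> Spectrum:
    """CIE daylight-series relative spectral power at the given CCT.

    Reconstructed as S0 + M1*S1 + M2*S2 with the locus chromaticity;
    normalized to unit mean over the grid.
    """
    x, y = daylight_chromaticity(cct)
    den = 0.0241 + 0.2562 * x - 0.7341 * y
    m1 = (-1.3515 - 1.7703 * x + 5.9114 * y) / den
    m2 = (0.0300 - 31.4424 * x + 30.0717 * y) / den
    s0, s1, s2 = _daylight_components(grid)
    vals = np.clip(s0 + m1 * s1 + m2 * s2, 0.0, None)
    return Spectrum(grid=grid, values=vals / vals.mean(), role="radiance")


def planck_spectrum(temperature: float, grid: WavelengthGrid = DEFAULT_GRID) -> Spectrum:
    """Blackbody relative spectral radiance, normalized to unit mean."""
    if temperature <= 0:
        raise ValueError("temperature must be > 0")
    h, c, kb = 6.62607015e-34, 2.99792458e8, 1.380649e-23
    lam = grid.wavelengths * 1e-9
    vals = 1.0 / (lam**5 * np.expm1(h * c / (lam * kb * temperature)))
    return Spectrum(grid=grid, values=vals / vals.mean(), role="radiance")


# ---------------------------------------------------------------------------
# Reflectance corpus
# ---------------------------------------------------------------------------


def _gaussian_bumps(rng, wl: np.ndarray, priors: dict, n_basis: int, smoothness: float):
    lo, hi = priors["bumps"]
    k = int(rng.integers(lo, min(hi, n_basis) + 1))
    vals = np.full(wl.shape, rng.uniform(*priors["base"]))
    for _ in range(k):
        mu = rng.uniform(*priors["center"])
        sigma = smoothness * rng.uniform(0.6, 1.4) / 2.0
        amp = rng.uniform(*priors["amp"])
        vals = vals + amp * np.exp(-0.5 * ((wl - mu) / sigma) ** 2)
    return np.clip(vals, 0.0, 1.0)


def _near_duplicate(rng, wl: np.ndarray, parent: np.ndarray, r_target: float = 0.9995):
    """Parent plus low-amplitude smooth noise, correlation > r_target."""
    sigma = 40.0
    noise = sum(
        rng.normal() * np.exp(-0.5 * ((wl - rng.uniform(400, 700)) / sigma) ** 2)
        for _ in range(3)
    )
    noise = np.asarray(noise)
    noise -= noise.mean()
    scale = 0.01
    for _ in range(40):
        child = np.clip(parent + scale * noise, 0.0, 1.0)
        pc = np.corrcoef(parent, child)[0, 1]
        if np.ptp(child) > 0 and pc > r_target:
            return child
        scale *= 0.5
    return parent.copy()


def generate_reflectances(
    cfg: ReflectanceGeneratorConfig,
) -> tuple[list[Spectrum], list[str], list[int]]:
    """Seeded synthetic reflectance corpus.

    Returns (spectra, category labels, duplicate parent index per sample:
    -1 for originals). The first ``n_samples - n_duplicates`` samples are
    independent draws (redrawn on the rare event that one correlates
    above 0.999 with an earlier original, so a duplicate-free corpus
    survives deduplication intact); the remainder are near-duplicates of
    random parents with spectral correlation > 0.999.
    """
    rng = np.random.default_rng(cfg.seed)
    wl = cfg.grid.wavelengths
    n_dup = int(round(cfg.duplicate_fraction * cfg.n_samples))
    n_orig = cfg.n_samples - n_dup
    cats = list(cfg.category_mix)
    probs = np.array([cfg.category_mix[c] for c in cats])

    values: list[np.ndarray] = []
    labels: list[str] = []
    parents: list[int] = []
    unit_rows: list[np.ndarray] = []
    for _ in range(n_orig):
        for _attempt in range(50):
            cat = cats[int(rng.choice(len(cats), p=probs))]
            v = _gaussian_bumps(rng, wl, _CATEGORY_PRIORS[cat], cfg.n_basis, cfg.smoothness)
            if np.ptp(v) == 0:
                continue
            c = v - v.mean()
            u = c / np.linalg.norm(c)
            if unit_rows and np.max(np.array(unit_rows) @ u) > 0.999:
                continue  # accidental near-duplicate: redraw
            break
        values.append(v)
        labels.append(cat)
        parents.append(-1)
        unit_rows.append(u)

    for _ in range(n_dup):
        p = int(rng.integers(0, n_orig))
        values.append(_near_duplicate(rng, wl, values[p]))
        labels.append(labels[p])
        parents.append(p)

    spectra = [Spectrum(grid=cfg.grid, values=v, role="reflectance") for v in values]
    return spectra, labels, parents


# ---------------------------------------------------------------------------
# Environments
# ---------------------------------------------------------------------------


def generate_environment(cfg: EnvironmentGeneratorConfig) -> EnvironmentMap:
    """Synthetic hyperspectral environment map, calibrated to a target L_A.

    two_zone_outdoor: sky hemisphere at the sky-CCT daylight spectrum, a
    solar disc at the sun-CCT spectrum scaled by ``contrast``, ground
    hemisphere as a gray (0.2) reflection of the mean sky radiance.
    low_contrast_indoor: one Planck spectrum everywhere, with a smooth
    seeded directional intensity modulation of max/min ratio
    ``contrast``. uniform: the sky spectrum in every direction.
    """
    rows, cols = cfg.resolution
    grid = cfg.grid
    name = cfg.name or f"{cfg.kind}_{cfg.seed}"
    rng = np.random.default_rng(cfg.seed)

    # assemble directions without constructing the map twice
    th = (np.arange(rows) + 0.5) * np.pi / rows
    ph = (np.arange(cols) + 0.5) * 2.0 * np.pi / cols
    TH, PH = np.meshgrid(th, ph, indexing="ij")
    dirs = np.stack(
        [np.sin(TH) * np.cos(PH), np.sin(TH) * np.sin(PH), np.cos(TH)], axis=-1
    )

    if cfg.kind == "uniform":
        sky = daylight_spectrum(cfg.sky_cct, grid).values
        radiance = np.broadcast_to(sky, (rows, cols, grid.n)).copy()
        label = "outdoor"
    elif cfg.kind == "two_zone_outdoor":
        sky = daylight_spectrum(cfg.sky_cct, grid).values
        sun = daylight_spectrum(cfg.sun_cct, grid).values * cfg.contrast
        radiance = np.empty((rows, cols, grid.n))
        upper = dirs[..., 2] > 0
        radiance[upper] = sky
        radiance[~upper] = 0.2 * sky  # gray ground lit by the sky
        cosr = np.cos(np.radians(cfg.sun_angular_radius))
        in_sun = (dirs @ cfg.sun_direction) >= cosr
        radiance[in_sun] = sun
        label = "outdoor"
    else:  # low_contrast_indoor
        base = planck_spectrum(cfg.indoor_cct, grid).values
        lobes = rng.normal(size=(3, 3))
        lobes /= np.linalg.norm(lobes, axis=1, keepdims=True)
        g = sum(
            w * np.clip(dirs @ d, 0.0, None) ** 2
            for w, d in zip(rng.uniform(0.5, 1.0, 3), lobes)
        )
        g = (g - g.min()) / max(g.max() - g.min(), 1e-12)  # -> [0, 1]
        amp = (cfg.contrast - 1.0) / (cfg.contrast + 1.0)
        modulation = 1.0 + amp * (2.0 * g - 1.0)
        radiance = modulation[..., None] * base
        label = "indoor"

    env = EnvironmentMap(
        grid=grid,
        radiance=radiance,
        scene_label=label,
        name=name,
        calibration_cd_per_m2=cfg.calibration_cd_per_m2,
    )
    # scale so the solid-angle-weighted mean luminance hits the target
    from .spectral import KM, spectra_to_xyz

    cmf = load_cie1931(grid)
    y = spectra_to_xyz(env.radiance, cmf, KM)[..., 1]
    la = float((y * env.solid_angles).sum() / env.solid_angles.sum())
    if la <= 0:
        raise ValueError("generated environment has zero luminance")
    env.radiance = env.radiance * (cfg.calibration_cd_per_m2 / la)
    return env


# ---------------------------------------------------------------------------
# Metameric pairs
# ---------------------------------------------------------------------------


def generate_metameric_pair(
    base: Spectrum,
    env: EnvironmentMap,
    tilt: np.ndarray,
    observer: Observer | str = Observer.TRICHROMAT,
    rng: np.random.Generator | None = None,
    target_amplitude: float = 0.25,
) -> tuple[Spectrum, Spectrum]:
    """A reflectance pair with identical sensor responses at one tilt.

    The second member is ``base`` plus a metameric black: a smooth random
    perturbation projected onto the null space of the matrix mapping
    reflectance to tristimulus (trichromat) or to the two surviving cone
    responses (dichromat) under that tilt's irradiance, scaled as large
    as [0, 1] bounds allow up to ``target_amplitude``. Base values should
    sit in [0.1, 0.9] to leave headroom.
    """
    observer = Observer.from_name(observer)
    if base.role != "reflectance":
        raise ValueError("base must be a reflectance")
    if base.grid != env.grid:
        raise ValueError("base and environment grids differ")
    rng = np.random.default_rng(0) if rng is None else rng

    E = cosine_weighted_irradiance(env, np.asarray(tilt, dtype=float)).values
    cmf = load_cie1931(env.grid)
    A = (cmf.matrix * E[:, None]).T  # (3, n_wavelengths): reflectance -> XYZ
    if observer is not Observer.TRICHROMAT:
        lms_rows = M_HPE @ A
        missing = {"protan": 0, "deutan": 1, "tritan": 2}[observer.value]
        A = np.delete(lms_rows, missing, axis=0)  # (2, n): surviving cones

    N = null_space(A)
    if N.shape[1] == 0:
        raise ValueError("sensor matrix has no null space on this grid")

    wl = base.grid.wavelengths
    d = sum(
        rng.normal() * np.exp(-0.5 * ((wl - rng.uniform(420, 680)) / 50.0) ** 2)
        for _ in range(4)
    )
    b = N @ (N.T @ np.asarray(d))
    peak = np.abs(b).max()
    if peak < 1e-12:
        raise ValueError("no feasible nonzero metameric black for this draw")
    b = b / peak

    up = b > 1e-12
    dn = b < -1e-12
    amp = target_amplitude
    if up.any():
        amp = min(amp, float(((1.0 - base.values)[up] / b[up]).min()))
    if dn.any():
        amp = min(amp, float((base.values[dn] / -b[dn]).min()))
    if amp < 1e-3:
        raise ValueError("no feasible nonzero metameric black within [0, 1] bounds")
    partner = Spectrum(
        grid=base.grid, values=np.clip(base.values + amp * b, 0.0, 1.0), role="reflectance"
    )
    return base, partner


# ---------------------------------------------------------------------------
# Test fixture scene
# ---------------------------------------------------------------------------


def make_fixture(seed: int = 0):
    """A tiny end-to-end scene: 40 reflectances plus one outdoor and one
    indoor environment at 32x64, for tests and quick demos."""
    refl_cfg = ReflectanceGeneratorConfig(n_samples=40, seed=seed)
    spectra, labels, parents = generate_reflectances(refl_cfg)
    outdoor = generate_environment(
        EnvironmentGeneratorConfig(kind="two_zone_outdoor", seed=seed, name="fixture_outdoor")
    )
    indoor = generate_environment(
        EnvironmentGeneratorConfig(kind="low_contrast_indoor", seed=seed + 1, name="fixture_indoor")
    )
    return spectra, labels, parents, [outdoor, indoor]
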