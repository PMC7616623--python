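"""Tabular and container I/O.

Reflectance corpora travel as CSV: first column the wavelength in nm,
one column per sample with the sample id in the header, and an optional
second header row of category labels (first cell "category").
Environment maps travel as HDF5 (datasets ``radiance`` (rows x cols x
wavelengths, float32) and ``wavelengths_nm``; attributes ``scene_label``,
``calibration_cd_per_m2``, ``name``) with a CSV-per-band fallback for
portability.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .environment import EnvironmentMap
from .spectral import Spectrum, WavelengthGrid

__all__ = [
    "write_corpus_csv",
    "read_corpus_csv",
    "write_environment_h5",
    "read_environment_h5",
    "write_environment_csv",
    "read_environment_csv",
    "read_environment",
]


def _grid_from_wavelengths(wl: np.ndarray) -> WavelengthGrid:
    wl = np.asarray(wl, dtype=float)
    steps = np.diff(wl)
    if wl.size < 2 or np.ptp(steps) > 1e-6:
        raise ValueError("wavelengths must form a uniform grid")
    return WavelengthGrid(float(wl[0]), float(wl[-1]), float(steps[0]))


def write_corpus_csv(
    path, spectra: list[Spectrum], ids: list[str] | None = None,
    categories: list[str] | None = None,
) -> None:
    if not spectra:
        raise ValueError("empty corpus")
    grid = spectra[0].grid
    if any(s.grid != grid for s in spectra):
        raise ValueError("all spectra must share a grid")
    if ids is None:
        ids = [f"s{i:05d}" for i in range(len(spectra))]
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["wavelength"] + list(ids))
        if categories is not None:
            w.writerow(["category"] + list(categories))
        for k, wl in enumerate(grid.wavelengths):
            w.writerow([f"{wl:g}"] + [f"{s.values[k]:.8g}" for s in spectra])


def read_corpus_csv(path) -> tuple[list[Spectrum], list[str], list[str] | None]:
    """Returns (spectra, ids, categories-or-None)."""
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    if len(rows) < 3:
        raise ValueError("corpus CSV too short")
    ids = rows[0][1:]
    categories = None
    start = 1
    if rows[1] and rows[1][0].strip().lower() == "category":
        categories = rows[1][1:]
        start = 2
    data = np.array([[float(x) for x in r] for r in rows[start:]])
    grid = _grid_from_wavelengths(data[:, 0])
    spectra = [
        Spectrum(grid=grid, values=data[:, 1 + j], role="reflectance")
        for j in range(len(ids))
    ]
    return spectra, ids, categories


def write_environment_h5(path, env: EnvironmentMap) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("radiance", data=env.radiance.astype(np.float32))
        f.create_dataset("wavelengths_nm", data=env.grid.wavelengths)
        f.attrs["scene_label"] = env.scene_label
        f.attrs["name"] = env.name
        if env.calibration_cd_per_m2 is not None:
            f.attrs["calibration_cd_per_m2"] = float(env.calibration_cd_per_m2)


def read_environment_h5(path) -> EnvironmentMap:
    with h5py.File(path, "r") as f:
        grid = _grid_from_wavelengths(f["wavelengths_nm"][...])
        return EnvironmentMap(
            grid=grid,
            radiance=f["radiance"][...].astype(float),
            scene_label=str(f.attrs.get("scene_label", "outdoor")),
            name=str(f.attrs.get("name", Path(path).stem)),
            calibration_cd_per_m2=float(f.attrs["calibration_cd_per_m2"])
            if "calibration_cd_per_m2" in f.attrs
            else None,
        )


def write_environment_csv(directory, env: EnvironmentMap) -> None:
    """Plain-text fallback: one CSV of rows x cols per wavelength band."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    meta = {
        "wavelengths_nm": env.grid.wavelengths.tolist(),
        "scene_label": env.scene_label,
        "name": env.name,
        "calibration_cd_per_m2": env.calibration_cd_per_m2,
        "shape": list(env.shape),
    }
    (d / "meta.json").write_text(json.dumps(meta, indent=1))
    for k, wl in enumerate(env.grid.wavelengths):
        np.savetxt(d / f"band_{wl:07.2f}nm.csv", env.radiance[:, :, k], delimiter=",")


def read_environment_csv(directory) -> EnvironmentMap:
    d = Path(directory)
    meta = json.loads((d / "meta.json").read_text())
    wl = np.asarray(meta["wavelengths_nm"], dtype=float)
    grid = _grid_from_wavelengths(wl)
    bands = [
        np.loadtxt(d / f"band_{w:07.2f}nm.csv", delimiter=",", ndmin=2) for w in wl
    ]
    return EnvironmentMap(
        grid=grid,
        radiance=np.stack(bands, axis=-1),
        scene_label=meta["scene_label"],
        name=meta["name"],
        calibration_cd_per_m2=meta.get("calibration_cd_per_m2"),
    )


def read_environment(path) -> EnvironmentMap:
    """Dispatch on path type: HDF5 file or CSV-per-band directory."""
    p = Path(path)
    if p.is_dir():
        return read_environment_csv(p)
    return read_environment_h5(p)


def summaries_to_frame(summaries) -> pd.DataFrame:
    return pd.DataFrame([s.as_row() for s in summaries])
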