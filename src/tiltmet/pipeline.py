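"""End-to-end orchestration: corpus -> render -> appearance -> statistics.

run_pipeline executes the full analysis for a configured corpus, set of
environments, observer list and threshold list, and writes tidy CSV
results plus a JSON provenance record. Re-running with the same
configuration is bit-identical: all randomness flows through the
configured seeds and pair iteration order is canonical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .appearance import Observer, ViewingConditions, brettel_dichromat, xyz_to_ucs
from .environment import (
    EnvironmentMap,
    compute_viewing_conditions,
    dichromat_viewing_conditions,
    make_tilt_grid,
    render_corpus,
)
from .metamerism import (
    DEFAULT_THRESHOLDS,
    aggregate_scenes,
    deduplicate,
    mixed_anova_bonferroni,
    pair_stats,
    threshold_sweep,
)
from .spectral import KM, load_cie1931, spectra_to_xyz
from .synthetic import (
    EnvironmentGeneratorConfig,
    ReflectanceGeneratorConfig,
    generate_environment,
    generate_reflectances,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "observer_ucs"]

ALL_OBSERVERS = tuple(o.value for o in Observer)


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    corpus: "str | ReflectanceGeneratorConfig" = field(
        default_factory=ReflectanceGeneratorConfig
    )
    environments: list = field(
        default_factory=lambda: [
            EnvironmentGeneratorConfig(kind="two_zone_outdoor", seed=0),
            EnvironmentGeneratorConfig(kind="low_contrast_indoor", seed=1),
        ]
    )
    tilt_mode: str = "fibonacci"
    observers: tuple = ALL_OBSERVERS
    thresholds: tuple = DEFAULT_THRESHOLDS
    bin_width: float = 1.0
    out_dir: str = "results"
    seed: int = 0
    log_level: str = "INFO"
    dedup_threshold: float = 0.999
    #: "transformed": dichromat XYZ and a Brettel-transformed white point
    #: (the dichromat adapts to a color it can see); "trichromat_white":
    #: transform after white normalization, keep the trichromatic W_p.
    dichromat_white: str = "transformed"

    def __post_init__(self) -> None:
        if not self.observers:
            raise ValueError("need at least one observer")
        self.observers = tuple(Observer.from_name(o).value for o in self.observers)
        th = list(self.thresholds)
        if not th or th != sorted(th) or any(t <= 0 for t in th):
            raise ValueError("thresholds must be nonempty, positive and ascending")
        if self.dichromat_white not in ("transformed", "trichromat_white"):
            raise ValueError("dichromat_white must be 'transformed' or 'trichromat_white'")
        if self.tilt_mode not in ("fibonacci", "slant_azimuth"):
            raise ValueError(f"unknown tilt mode {self.tilt_mode!r}")


def observer_ucs(
    xyz_abs: np.ndarray,
    vc: ViewingConditions,
    observer: Observer | str,
    dichromat_white: str = "transformed",
) -> np.ndarray:
    """Absolute stimulus XYZ -> CAM02-UCS for one observer.

    ``vc`` is the trichromatic scene viewing conditions carrying
    ``white_luminance`` (cd/m^2). For dichromats, default order is
    Brettel projection of the absolute stimuli followed by
    normalization against the projected white.
    """
    observer = Observer.from_name(observer)
    yw = vc.white_luminance
    if observer is Observer.TRICHROMAT:
        return xyz_to_ucs(xyz_abs * (100.0 / yw), vc)
    if dichromat_white == "transformed":
        vcd = dichromat_viewing_conditions(vc, observer)
        xyz_d = brettel_dichromat(xyz_abs, observer)
        wp_d_y = brettel_dichromat(vc.white_point, observer)[1] * yw / 100.0
        return xyz_to_ucs(xyz_d * (100.0 / wp_d_y), vcd)
    xyz_rel = xyz_abs * (100.0 / yw)
    return xyz_to_ucs(brettel_dichromat(xyz_rel, observer), vc)


def _load_corpus(cfg: RunConfig):
    if isinstance(cfg.corpus, ReflectanceGeneratorConfig):
        spectra, labels, _ = generate_reflectances(cfg.corpus)
        ids = [f"s{i:05d}" for i in range(len(spectra))]
        return spectra, ids, labels
    from .io import read_corpus_csv

    spectra, ids, labels = read_corpus_csv(cfg.corpus)
    return spectra, ids, labels


def _load_environments(cfg: RunConfig) -> list[EnvironmentMap]:
    envs = []
    for e in cfg.environments:
        if isinstance(e, EnvironmentGeneratorConfig):
            envs.append(generate_environment(e))
        else:
            from .io import read_environment

            envs.append(read_environment(e))
    return envs


def _config_record(cfg: RunConfig) -> dict:
    def enc(obj):
        if isinstance(obj, (ReflectanceGeneratorConfig, EnvironmentGeneratorConfig)):
            d = dict(obj.__dict__)
            d["__type__"] = type(obj).__name__
            return {k: enc(v) for k, v in d.items()}
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (list, tuple)):
            return [enc(v) for v in obj]
        if isinstance(obj, dict):
            return {k: enc(v) for k, v in obj.items()}
        if hasattr(obj, "wavelengths"):  # WavelengthGrid
            return {
                "start_nm": obj.start_nm,
                "stop_nm": obj.stop_nm,
                "step_nm": obj.step_nm,
            }
        return obj

    return {k: enc(v) for k, v in cfg.__dict__.items()}


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute dedup -> render -> appearance -> pair stats -> summaries ->
    sweep -> aggregation -> ANOVA; write CSVs and provenance under
    ``cfg.out_dir``; return the in-memory result tables."""
    logging.basicConfig(level=cfg.log_level)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "histograms").mkdir(exist_ok=True)

    spectra, ids, _labels = _load_corpus(cfg)
    retained, removed = deduplicate(spectra, cfg.dedup_threshold)
    logger.info("dedup: %d -> %d surfaces (%d removed)", len(spectra), len(retained), len(removed))
    spectra = [spectra[i] for i in retained]
    ids = [ids[i] for i in retained]
    values = np.stack([s.values for s in spectra])

    envs = _load_environments(cfg)
    grid = envs[0].grid
    if any(e.grid != grid for e in envs) or spectra[0].grid != grid:
        raise ValueError("corpus and all environments must share one wavelength grid")
    cmf = load_cie1931(grid)
    tilts = make_tilt_grid(cfg.tilt_mode)

    all_summaries = []
    for env in envs:
        vc = compute_viewing_conditions(env, tilts)
        logger.info(
            "scene %s (%s): L_A=%.1f cd/m^2, Y_b=%.1f", env.name, env.scene_label,
            vc.adapting_luminance, vc.background_factor,
        )
        L = render_corpus(values, env, tilts)
        xyz_abs = spectra_to_xyz(L, cmf, KM)
        for obs in cfg.observers:
            ucs = observer_ucs(xyz_abs, vc, obs, cfg.dichromat_white)
            pairs = pair_stats(ucs, ids=ids, observer=obs)
            sums = threshold_sweep(
                pairs,
                cfg.thresholds,
                bin_width=cfg.bin_width,
                scene=env.name,
                scene_label=env.scene_label,
            )
            all_summaries.extend(sums)
            for s in sums:
                if s.threshold == cfg.thresholds[0]:
                    for kind, hist in (("abs", s.abs_hist), ("rel", s.rel_hist)):
                        lefts, counts = hist
                        pd.DataFrame(
                            {
                                "bin_left": lefts,
                                "bin_right": lefts + cfg.bin_width,
                                "count": counts,
                            }
                        ).to_csv(
                            out / "histograms" / f"{env.name}_{obs}_{kind}_increase.csv",
                            index=False,
                        )

    summary_df = pd.DataFrame([s.as_row() for s in all_summaries])
    summary_df.to_csv(out / "summaries.csv", index=False, float_format="%.10g")

    agg_frames = []
    for label in ("outdoor", "indoor"):
        if any(s.scene_label == label for s in all_summaries):
            agg_frames.append(aggregate_scenes(all_summaries, label))
    agg_df = pd.concat(agg_frames, ignore_index=True) if agg_frames else pd.DataFrame()
    if len(agg_df):
        agg_df.to_csv(out / "aggregates.csv", index=False, float_format="%.10g")

    results = {"summaries": summary_df, "aggregates": agg_df}

    theta0 = cfg.thresholds[0]
    anova_tbl = summary_df[summary_df["threshold"] == theta0].rename(
        columns={"proportion_solved": "value"}
    )[["scene", "scene_label", "observer", "value"]]
    anova_tbl.to_csv(out / "anova_table.csv", index=False, float_format="%.10g")
    n_out = anova_tbl[anova_tbl.scene_label == "outdoor"].scene.nunique()
    n_in = anova_tbl[anova_tbl.scene_label == "indoor"].scene.nunique()
    if (
        n_out >= 2
        and n_in >= 2
        and len(cfg.observers) >= 2
        and anova_tbl["value"].notna().all()
    ):
        aov, post = mixed_anova_bonferroni(anova_tbl)
        aov.to_csv(out / "anova.csv", index=False, float_format="%.10g")
        post.to_csv(out / "pairwise.csv", index=False, float_format="%.10g")
        results["anova"] = aov
        results["pairwise"] = post
    else:
        logger.info("ANOVA skipped: incomplete design (%d outdoor, %d indoor scenes)", n_out, n_in)

    provenance = {
        "package": "tiltmet",
        "version": __version__,
        "numpy": np.__version__,
        "config": _config_record(cfg),
        "n_surfaces_input": len(retained) + len(removed),
        "n_surfaces_retained": len(retained),
        "scenes": [e.name for e in envs],
    }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=1, sort_keys=True))
    results["out_dir"] = str(out)
    return results
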