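"""Metamerism-resolution statistics.

Given per-tilt CAM02-UCS coordinates for every surface, each unordered
surface pair is summarized by its minimum and maximum color difference
dE across tilts. A pair is a metamer *candidate* when its minimum dE
falls below the discriminability threshold theta (default 0.36, the
average just-noticeable-difference radius of MacAdam ellipses expressed
in CAM02-UCS); it is *solved* when some other tilt pushes dE to or
above theta, and *never distinguishable* when even the maximum stays
below. Discriminability gains are quantified by the absolute increase
max dE - min dE and the relative increase (max - min) / min * 100, and
summarized per scene by histogram modes.

The split-plot (mixed-design) ANOVA on the per-scene proportions —
scene type as the between factor, observer type as the within factor,
Bonferroni-corrected pairwise observer comparisons — is delegated to
pingouin.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .appearance import Observer
from .spectral import Spectrum

logger = logging.getLogger(__name__)

__all__ = [
    "SceneSummary",
    "deduplicate",
    "pair_stats",
    "summarize_scene",
    "histogram_mode",
    "aggregate_scenes",
    "threshold_sweep",
    "mixed_anova_bonferroni",
    "DEFAULT_THRESHOLD",
    "DEFAULT_THRESHOLDS",
]

#: Discriminability criterion: average MacAdam-ellipse JND radius in CAM02-UCS.
DEFAULT_THRESHOLD = 0.36
#: Robustness sweep thresholds.
DEFAULT_THRESHOLDS = (0.36, 0.5, 1.0, 2.0)


def deduplicate(
    reflectances: list[Spectrum],
    r_threshold: float = 0.999,
) -> tuple[list[int], list[tuple[int, int]]]:
    """Greedy near-duplicate removal by spectral Pearson correlation.

    A single deterministic pass in input order: a spectrum is dropped
    when it correlates above ``r_threshold`` with any already-retained
    spectrum. Returns (retained indices, removal log of
    (removed index, correlated retained index)). Constant spectra, for
    which the correlation is undefined, are retained and logged.
    """
    if not reflectances:
        raise ValueError("need at least one spectrum")
    if not 0 < r_threshold < 1:
        raise ValueError("r_threshold must lie in (0, 1)")
    values = np.stack([s.values for s in reflectances])
    centered = values - values.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    constant = norms == 0
    for i in np.nonzero(constant)[0]:
        logger.warning("spectrum %d is constant; correlation undefined, retained", i)
    unit = np.where(constant[:, None], 0.0, centered / np.where(norms == 0, 1.0, norms)[:, None])

    retained: list[int] = []
    removed: list[tuple[int, int]] = []
    kept_rows: list[np.ndarray] = []
    for i in range(len(reflectances)):
        if constant[i] or not kept_rows:
            retained.append(i)
            kept_rows.append(unit[i])
            continue
        r = np.array(kept_rows) @ unit[i]
        hit = np.nonzero(r > r_threshold)[0]
        if hit.size and not constant[retained[hit[0]]]:
            removed.append((i, retained[int(hit[0])]))
        else:
            retained.append(i)
            kept_rows.append(unit[i])
    return retained, removed


def n_pairs(n: int) -> int:
    """Number of unordered pairs n * (n - 1) / 2."""
    return n * (n - 1) // 2


def pair_stats(
    ucs: np.ndarray,
    ids: list[str] | None = None,
    observer: Observer | str = Observer.TRICHROMAT,
    block: int = 64,
) -> pd.DataFrame:
    """Min/max dE over tilts for every unordered surface pair.

    ``ucs`` has shape (n_surfaces, n_tilts, 3). Surfaces are ordered by
    id (canonical pair ordering id_a < id_b); computation is blocked
    over the pair index space so memory stays bounded. Returns a
    DataFrame with columns id_a, id_b, observer, min_de, max_de,
    argmin_tilt, argmax_tilt.
    """
    ucs = np.asarray(ucs, dtype=float)
    if ucs.ndim != 3 or ucs.shape[2] != 3:
        raise ValueError("ucs must be (n_surfaces, n_tilts, 3)")
    n = ucs.shape[0]
    if ids is None:
        ids = [f"s{i:05d}" for i in range(n)]
    if len(ids) != n:
        raise ValueError("ids length mismatch")
    order = np.argsort(np.asarray(ids, dtype=object))
    ucs = ucs[order]
    ids_sorted = [ids[i] for i in order]
    observer = Observer.from_name(observer)

    ia_parts, ib_parts = [], []
    mins, maxs, amins, amaxs = [], [], [], []
    for i0 in range(0, n, block):
        i1 = min(i0 + block, n)
        # all pairs (i, j) with i in [i0, i1), j > i
        diff = ucs[i0:i1, None, :, :] - ucs[None, i0:, :, :]
        de = np.sqrt((diff * diff).sum(axis=-1))  # (bi, nj, tilts)
        bi, nj = de.shape[:2]
        ii, jj = np.meshgrid(np.arange(i0, i1), np.arange(i0, n), indexing="ij")
        mask = jj > ii
        de = de[mask]
        ia_parts.append(ii[mask])
        ib_parts.append(jj[mask])
        mins.append(de.min(axis=1))
        maxs.append(de.max(axis=1))
        amins.append(de.argmin(axis=1))
        amaxs.append(de.argmax(axis=1))

    ia = np.concatenate(ia_parts) if ia_parts else np.array([], dtype=int)
    ib = np.concatenate(ib_parts) if ib_parts else np.array([], dtype=int)
    df = pd.DataFrame(
        {
            "id_a": [ids_sorted[i] for i in ia],
            "id_b": [ids_sorted[j] for j in ib],
            "observer": observer.value,
            "min_de": np.concatenate(mins) if mins else [],
            "max_de": np.concatenate(maxs) if maxs else [],
            "argmin_tilt": np.concatenate(amins).astype(int) if amins else [],
            "argmax_tilt": np.concatenate(amaxs).astype(int) if amaxs else [],
        }
    )
    return df


def histogram_mode(values: np.ndarray, bin_width: float = 1.0, origin: float = 0.0) -> float:
    """Center of the most populated histogram bin; ties go to the lowest bin.

    Bins are half-open ``[origin + k*w, origin + (k+1)*w)``.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("histogram_mode needs at least one value")
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    k = np.floor((values - origin) / bin_width).astype(np.int64)
    uniq, counts = np.unique(k, return_counts=True)  # sorted: tie -> lowest bin
    return origin + (uniq[int(np.argmax(counts))] + 0.5) * bin_width


def _histogram(values: np.ndarray, bin_width: float, origin: float):
    """Sparse histogram: (left bin edges of occupied bins, counts).

    Sparse because heavy-tailed metrics (relative increase near a zero
    minimum) can span astronomically many empty bins.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        return np.array([origin]), np.array([0])
    k = np.floor((values - origin) / bin_width).astype(np.int64)
    uniq, counts = np.unique(k, return_counts=True)
    return origin + bin_width * uniq.astype(float), counts


@dataclass
class SceneSummary:
    """Metamerism-resolution summary for one scene, observer and threshold."""

    scene: str
    scene_label: str
    observer: str
    threshold: float
    n_pairs: int
    n_candidates: int
    n_solved: int
    n_never: int
    proportion_solved: float | None
    n_rel_excluded: int
    abs_mode: float
    rel_mode: float | None
    abs_hist: tuple[np.ndarray, np.ndarray] = field(repr=False, default=None)
    rel_hist: tuple[np.ndarray, np.ndarray] = field(repr=False, default=None)

    def as_row(self) -> dict:
        return {
            "scene": self.scene,
            "scene_label": self.scene_label,
            "observer": self.observer,
            "threshold": self.threshold,
            "n_pairs": self.n_pairs,
            "n_candidates": self.n_candidates,
            "n_solved": self.n_solved,
            "n_never": self.n_never,
            "proportion_solved": self.proportion_solved,
            "n_rel_excluded": self.n_rel_excluded,
            "abs_mode": self.abs_mode,
            "rel_mode": self.rel_mode,
        }


def summarize_scene(
    pairs: pd.DataFrame,
    threshold: float = DEFAULT_THRESHOLD,
    bin_width: float = 1.0,
    origin: float = 0.0,
    scene: str = "scene",
    scene_label: str = "outdoor",
) -> SceneSummary:
    """Candidate / solved / never-distinguishable counts and increase metrics.

    candidate: min dE < theta (indistinguishable at some tilt);
    solved: candidate whose max dE >= theta; never: max dE < theta.
    The absolute increase max - min is histogrammed over *all* pairs;
    the relative increase (max - min)/min * 100 excludes (and counts)
    pairs with min dE = 0.
    """
    if len(pairs) == 0:
        raise ValueError("empty pair list")
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    mn = pairs["min_de"].to_numpy(float)
    mx = pairs["max_de"].to_numpy(float)
    cand = mn < threshold
    solved = cand & (mx >= threshold)
    never = mx < threshold
    n_cand = int(cand.sum())
    prop = 100.0 * solved.sum() / n_cand if n_cand else None

    abs_inc = mx - mn
    nz = mn > 0
    n_excluded = int((~nz).sum())
    if n_excluded:
        logger.info("relative increase: excluded %d pairs with min dE = 0", n_excluded)
    rel_inc = (mx[nz] - mn[nz]) / mn[nz] * 100.0

    observers = pairs["observer"].unique()
    obs = observers[0] if len(observers) == 1 else "mixed"
    return SceneSummary(
        scene=scene,
        scene_label=scene_label,
        observer=str(obs),
        threshold=float(threshold),
        n_pairs=len(pairs),
        n_candidates=n_cand,
        n_solved=int(solved.sum()),
        n_never=int(never.sum()),
        proportion_solved=prop,
        n_rel_excluded=n_excluded,
        abs_mode=histogram_mode(abs_inc, bin_width, origin),
        rel_mode=histogram_mode(rel_inc, bin_width, origin) if rel_inc.size else None,
        abs_hist=_histogram(abs_inc, bin_width, origin),
        rel_hist=_histogram(rel_inc, bin_width, origin),
    )


def threshold_sweep(
    pairs: pd.DataFrame,
    thresholds=DEFAULT_THRESHOLDS,
    **kwargs,
) -> list[SceneSummary]:
    """One :func:`summarize_scene` per threshold (ascending)."""
    thresholds = list(thresholds)
    if thresholds != sorted(thresholds):
        raise ValueError("thresholds must be ascending")
    return [summarize_scene(pairs, threshold=t, **kwargs) for t in thresholds]


def aggregate_scenes(summaries: list[SceneSummary], label: str) -> pd.DataFrame:
    """Across-scene mean and sample SD per observer and threshold.

    Aggregates proportion_solved and the per-scene histogram modes over
    all summaries carrying ``label``; scenes with no candidates are
    dropped from the proportion average (missing, not zero).
    """
    rows = [s.as_row() for s in summaries if s.scene_label == label]
    if not rows:
        raise ValueError(f"no summaries with label {label!r}")
    df = pd.DataFrame(rows)
    out = []
    for (obs, th), grp in df.groupby(["observer", "threshold"], sort=True):
        prop = grp["proportion_solved"].dropna()
        out.append(
            {
                "scene_label": label,
                "observer": obs,
                "threshold": th,
                "n_scenes": len(grp),
                "prop_solved_mean": prop.mean() if len(prop) else np.nan,
                "prop_solved_sd": prop.std(ddof=1) if len(prop) > 1 else np.nan,
                "abs_mode_mean": grp["abs_mode"].mean(),
                "abs_mode_sd": grp["abs_mode"].std(ddof=1),
                "rel_mode_mean": grp["rel_mode"].dropna().mean(),
                "rel_mode_sd": grp["rel_mode"].dropna().std(ddof=1),
            }
        )
    return pd.DataFrame(out)


def mixed_anova_bonferroni(
    table: pd.DataFrame,
    dv: str = "value",
    scene: str = "scene",
    scene_label: str = "scene_label",
    observer: str = "observer",
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split-plot ANOVA with Bonferroni-corrected observer comparisons.

    ``table`` is long-format with one row per scene x observer cell and
    must be complete. Scene type (outdoor/indoor) is the between-scene
    factor; observer type the within-scene factor. Returns the ANOVA
    table (with both partial and generalized eta-squared) and the
    pairwise observer comparisons.
    """
    import pingouin as pg

    counts = table.groupby([scene, observer], observed=True)[dv].count().unstack()
    if counts.isna().any().any() or (counts != 1).any().any():
        raise ValueError("design must be complete with one value per scene x observer cell")

    if table[dv].nunique() == 1:
        # degenerate flat table: every effect explains nothing
        obs_levels = sorted(table[observer].unique())
        k = table[scene_label].nunique()
        p = len(obs_levels)
        n = table[scene].nunique()
        aov = pd.DataFrame(
            {
                "Source": [scene_label, observer, "Interaction"],
                "DF1": [k - 1, p - 1, (k - 1) * (p - 1)],
                "DF2": [n - k, (n - k) * (p - 1), (n - k) * (p - 1)],
                "F": 0.0,
                "p_unc": 1.0,
                "np2": 0.0,
                "ng2": 0.0,
            }
        )
        post = pd.DataFrame(
            [
                {"A": a, "B": b, "p_unc": 1.0, "p_corr": 1.0, "significant": False}
                for i, a in enumerate(obs_levels)
                for b in obs_levels[i + 1:]
            ]
        )
        return aov, post

    aov = pg.mixed_anova(
        data=table, dv=dv, within=observer, subject=scene, between=scene_label,
        effsize="np2",
    )
    ng2 = pg.mixed_anova(
        data=table, dv=dv, within=observer, subject=scene, between=scene_label,
        effsize="ng2",
    )
    aov = aov.assign(ng2=ng2["ng2"])
    post = pg.pairwise_tests(
        data=table, dv=dv, within=observer, subject=scene,
        padjust="bonf", effsize="cohen",
    )
    post = post.assign(significant=post["p_corr"] < alpha)
    return aov, post
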