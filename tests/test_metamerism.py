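import numpy as np
import pandas as pd
import pytest

from tiltmet.metamerism import (
    aggregate_scenes,
    deduplicate,
    histogram_mode,
    mixed_anova_bonferroni,
    n_pairs,
    pair_stats,
    summarize_scene,
    threshold_sweep,
)
from tiltmet.spectral import Spectrum, WavelengthGrid


def _spectrum(grid, values):
    return Spectrum(grid=grid, values=np.asarray(values, float), role="reflectance")


@pytest.fixture(scope="module")
def coarse_grid():
    return WavelengthGrid(400, 700, 10)


class TestDeduplicate:
    def test_exact_duplicates_removed(self, coarse_grid):
        rng = np.random.default_rng(0)
        a = rng.uniform(0, 1, coarse_grid.n)
        b = rng.uniform(0, 1, coarse_grid.n)
        retained, removed = deduplicate([_spectrum(coarse_grid, v) for v in (a, a, b)])
        assert retained == [0, 2]
        assert removed == [(1, 0)]

    def test_uncorrelated_set_untouched(self, coarse_grid):
        rng = np.random.default_rng(1)
        spectra = [_spectrum(coarse_grid, rng.uniform(0, 1, coarse_grid.n)) for _ in range(20)]
        retained, removed = deduplicate(spectra)
        assert retained == list(range(20)) and removed == []

    def test_greedy_chain_keeps_endpoints(self, coarse_grid):
        """A ~ B and B ~ C but A !~ C: the greedy pass drops B (correlated
        with retained A) then keeps C (uncorrelated with A)."""
        wl = coarse_grid.wavelengths
        base = 0.5 + 0.3 * np.sin((wl - 400) / 60)
        bump = np.exp(-0.5 * ((wl - 550) / 60) ** 2)
        eps = 0.02
        a, b, c = base, base + eps * bump, base + 2 * eps * bump
        from tiltmet.spectral import pearson_correlation

        sab = pearson_correlation(_spectrum(coarse_grid, a), _spectrum(coarse_grid, b))
        sac = pearson_correlation(_spectrum(coarse_grid, a), _spectrum(coarse_grid, c))
        assert sab > 0.999 > sac  # construction sanity
        retained, removed = deduplicate(
            [_spectrum(coarse_grid, v) for v in (a, b, c)], r_threshold=0.999
        )
        assert retained == [0, 2]
        assert removed == [(1, 0)]

    def test_retained_set_has_no_close_pair(self, coarse_grid):
        from tiltmet.spectral import pearson_correlation

        rng = np.random.default_rng(2)
        wl = coarse_grid.wavelengths
        spectra = []
        for _ in range(30):
            mu = rng.uniform(450, 650)
            spectra.append(
                _spectrum(coarse_grid, 0.2 + 0.6 * np.exp(-0.5 * ((wl - mu) / 80) ** 2))
            )
        retained, _ = deduplicate(spectra, r_threshold=0.999)
        kept = [spectra[i] for i in retained]
        for i in range(len(kept)):
            for j in range(i + 1, len(kept)):
                assert pearson_correlation(kept[i], kept[j]) <= 0.999

    def test_constant_spectra_retained(self, coarse_grid):
        c = _spectrum(coarse_grid, np.full(coarse_grid.n, 0.5))
        s = _spectrum(coarse_grid, np.linspace(0.1, 0.9, coarse_grid.n))
        retained, removed = deduplicate([c, s, c])
        assert 0 in retained and 1 in retained


class TestPairStats:
    def test_pair_count_formula(self):
        assert n_pairs(3) == 3
        assert n_pairs(20132) == 202_638_646  # 2.03e8 to 3 significant figures
        assert round(n_pairs(20132) / 1e8, 2) == 2.03

    def test_three_surfaces_three_pairs(self):
        rng = np.random.default_rng(0)
        df = pair_stats(rng.normal(size=(3, 81, 3)))
        assert len(df) == 3
        assert (df.id_a < df.id_b).all()

    def test_identical_surfaces_zero_de(self):
        rng = np.random.default_rng(1)
        u = rng.normal(size=(81, 3))
        df = pair_stats(np.stack([u, u]))
        assert df.min_de.iloc[0] == 0 and df.max_de.iloc[0] == 0

    def test_min_max_and_argtilts(self):
        ucs = np.zeros((2, 4, 3))
        ucs[1, :, 0] = [5.0, 1.0, 3.0, 9.0]
        df = pair_stats(ucs)
        assert df.min_de.iloc[0] == 1.0 and df.max_de.iloc[0] == 9.0
        assert df.argmin_tilt.iloc[0] == 1 and df.argmax_tilt.iloc[0] == 3

    def test_blocking_does_not_change_results(self):
        rng = np.random.default_rng(2)
        ucs = rng.normal(size=(23, 11, 3))
        a = pair_stats(ucs, block=4)
        b = pair_stats(ucs, block=64)
        pd.testing.assert_frame_equal(a, b)


class TestSummarize:
    def _pairs(self, stats):
        return pd.DataFrame(
            {
                "min_de": [s[0] for s in stats],
                "max_de": [s[1] for s in stats],
                "observer": "trichromat",
            }
        )

    def test_candidate_solved_never_partition(self):
        s = summarize_scene(self._pairs([(0.1, 0.2), (0.1, 5.0), (1.0, 5.0)]), 0.36)
        assert s.n_candidates == 2 and s.n_solved == 1 and s.n_never == 1
        assert s.proportion_solved == pytest.approx(50.0)
        assert s.n_solved + s.n_never == s.n_candidates

    def test_no_candidates_reports_missing(self):
        s = summarize_scene(self._pairs([(1.0, 2.0), (0.5, 0.9)]), 0.36)
        assert s.n_candidates == 0
        assert s.proportion_solved is None

    def test_increase_metrics(self):
        s = summarize_scene(self._pairs([(2.0, 6.0)]), 0.36)
        assert s.abs_mode == pytest.approx(4.5)  # abs increase 4 -> bin [4,5)
        assert s.rel_mode == pytest.approx(200.5)  # 200% -> bin [200,201)

    def test_zero_min_pairs_excluded_from_relative(self):
        s = summarize_scene(self._pairs([(0.0, 1.0), (2.0, 6.0)]), 0.36)
        assert s.n_rel_excluded == 1
        assert s.rel_mode == pytest.approx(200.5)

    def test_empty_pairs_rejected(self):
        with pytest.raises(ValueError):
            summarize_scene(self._pairs([]), 0.36)


class TestHistogramMode:
    @pytest.mark.parametrize(
        "values, expected",
        [
            ([1.2, 1.3, 2.7], 1.5),
            ([7.01], 7.5),
            ([0.5, 1.5], 0.5),  # tie -> lowest bin
        ],
    )
    def test_modes(self, values, expected):
        assert histogram_mode(np.array(values), 1.0, 0.0) == pytest.approx(expected)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            histogram_mode(np.array([]))


class TestSweepAndAggregate:
    def test_candidate_count_monotone_in_threshold(self):
        rng = np.random.default_rng(3)
        mn = rng.uniform(0, 3, 500)
        mx = mn + rng.uniform(0, 5, 500)
        pairs = pd.DataFrame({"min_de": mn, "max_de": mx, "observer": "trichromat"})
        sums = threshold_sweep(pairs, [0.36, 0.5, 1.0, 2.0])
        cands = [s.n_candidates for s in sums]
        assert cands == sorted(cands)
        for s in sums:
            assert s.n_solved + s.n_never == s.n_candidates

    def test_extreme_thresholds(self):
        pairs = pd.DataFrame(
            {"min_de": [1.0, 2.0], "max_de": [3.0, 4.0], "observer": "trichromat"}
        )
        hi = summarize_scene(pairs, 10.0)
        assert hi.n_candidates == 2 and hi.n_solved == 0
        lo = summarize_scene(pairs, 0.5)
        assert lo.n_candidates == 0

    def test_unsorted_thresholds_rejected(self):
        pairs = pd.DataFrame({"min_de": [1.0], "max_de": [2.0], "observer": "trichromat"})
        with pytest.raises(ValueError):
            threshold_sweep(pairs, [1.0, 0.5])

    def test_aggregate_mean_and_sd(self):
        base = dict(threshold=0.36, n_pairs=10, n_candidates=5, n_never=0,
                    n_rel_excluded=0, abs_mode=3.5, rel_mode=60.5, abs_hist=None,
                    rel_hist=None, scene_label="outdoor", observer="trichromat")
        from tiltmet.metamerism import SceneSummary

        s1 = SceneSummary(scene="a", n_solved=4, proportion_solved=80.0, **base)
        s2 = SceneSummary(scene="b", n_solved=4, proportion_solved=90.0, **base)
        agg = aggregate_scenes([s1, s2], "outdoor")
        row = agg.iloc[0]
        assert row.prop_solved_mean == pytest.approx(85.0)
        assert row.prop_solved_sd == pytest.approx(np.sqrt(50.0))
        assert row.abs_mode_mean == pytest.approx(3.5)
        assert row.abs_mode_sd == pytest.approx(0.0)


def _splitplot_reference(df, dv="value", subject="scene", between="scene_label", within="observer"):
    """Textbook split-plot sums of squares (independent of pingouin)."""
    grand = df[dv].mean()
    y = df[dv]
    mb = df.groupby(between)[dv].transform("mean")
    mw = df.groupby(within)[dv].transform("mean")
    mc = df.groupby([between, within])[dv].transform("mean")
    ms = df.groupby(subject)[dv].transform("mean")
    ss_b = ((mb - grand) ** 2).sum()
    ss_w = ((mw - grand) ** 2).sum()
    ss_i = ((mc - grand) ** 2).sum() - ss_b - ss_w
    ss_sb = ((ms - grand) ** 2).sum() - ss_b
    ss_ew = ((y - grand) ** 2).sum() - ((mc - grand) ** 2).sum() - ss_sb
    k = df[between].nunique()
    p = df[within].nunique()
    N = df[subject].nunique()
    f_b = (ss_b / (k - 1)) / (ss_sb / (N - k))
    f_w = (ss_w / (p - 1)) / (ss_ew / ((N - k) * (p - 1)))
    f_i = (ss_i / ((k - 1) * (p - 1))) / (ss_ew / ((N - k) * (p - 1)))
    return f_b, f_w, f_i


def _random_table(seed, n_out=6, n_in=4):
    rng = np.random.default_rng(seed)
    rows = []
    for si in range(n_out + n_in):
        label = "outdoor" if si < n_out else "indoor"
        for obs in ("trichromat", "deutan", "protan", "tritan"):
            rows.append(
                {"scene": f"sc{si}", "scene_label": label, "observer": obs,
                 "value": rng.uniform(60, 99)}
            )
    return pd.DataFrame(rows)


class TestMixedAnova:
    def test_df_structure_on_10x4_design(self):
        aov, _ = mixed_anova_bonferroni(_random_table(0))
        by = aov.set_index("Source")
        assert (by.loc["scene_label", "DF1"], by.loc["scene_label", "DF2"]) == (1, 8)
        assert (by.loc["observer", "DF1"], by.loc["observer", "DF2"]) == (3, 24)
        assert (by.loc["Interaction", "DF1"], by.loc["Interaction", "DF2"]) == (3, 24)

    @pytest.mark.parametrize("seed", [0, 7])
    def test_f_values_match_independent_reference(self, seed):
        table = _random_table(seed)
        aov, _ = mixed_anova_bonferroni(table)
        f_b, f_w, f_i = _splitplot_reference(table)
        by = aov.set_index("Source")
        assert by.loc["scene_label", "F"] == pytest.approx(f_b, abs=1e-8)
        assert by.loc["observer", "F"] == pytest.approx(f_w, abs=1e-8)
        assert by.loc["Interaction", "F"] == pytest.approx(f_i, abs=1e-8)

    def test_all_equal_cells_give_zero_f(self):
        table = _random_table(0)
        table["value"] = 80.0
        aov, _ = mixed_anova_bonferroni(table)
        assert np.allclose(np.nan_to_num(aov["F"].to_numpy(float)), 0.0)

    def test_effect_sizes_reported_both_ways(self):
        aov, _ = mixed_anova_bonferroni(_random_table(1))
        assert {"np2", "ng2"} <= set(aov.columns)
        assert ((aov["np2"] >= 0) & (aov["np2"] <= 1)).all()

    def test_bonferroni_pairwise_count(self):
        _, post = mixed_anova_bonferroni(_random_table(2))
        assert len(post) == 6  # 4 choose 2 observer comparisons
        assert (post["p_corr"] >= post["p_unc"] - 1e-12).all()

    def test_incomplete_design_rejected(self):
        table = _random_table(3).iloc[:-1]
        with pytest.raises(ValueError):
            mixed_anova_bonferroni(table)
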