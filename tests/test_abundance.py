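"""Library-size scaling, NB GLM/GAM fitting, BH screening."""

import numpy as np
import pandas as pd
import pytest

from poseidonia import abundance, simulate
from poseidonia.abundance import AbundanceDataset, GLMFit


def make_dataset(counts, meta):
    return AbundanceDataset(counts=counts, metadata=meta)


class TestScaleByLibrarySize:
    def test_identical_columns_give_unit_factors(self):
        counts = pd.DataFrame({"S1": [10, 20, 5], "S2": [10, 20, 5]}, index=list("abc"))
        factors, scaled = abundance.scale_by_library_size(counts)
        np.testing.assert_allclose(factors, 1.0)
        pd.testing.assert_frame_equal(scaled, counts.astype(float))

    def test_doubled_column_has_double_factor_ratio(self):
        counts = pd.DataFrame({"S1": [10, 20, 5], "S2": [20, 40, 10]}, index=list("abc"))
        factors, scaled = abundance.scale_by_library_size(counts)
        assert factors["S2"] / factors["S1"] == pytest.approx(2.0)
        np.testing.assert_allclose(scaled["S1"], scaled["S2"])

    def test_hand_computed_median_of_ratios(self):
        # 4 clades x 3 samples; clade d has a zero and is excluded
        counts = pd.DataFrame(
            {"S1": [2, 4, 8, 0], "S2": [4, 8, 16, 5], "S3": [8, 16, 32, 5]},
            index=list("abcd"),
        )
        # geometric means rows a..c: 4, 8, 16 -> ratios identical per sample:
        # S1: 0.5, S2: 1, S3: 2; medians likewise
        factors, _ = abundance.scale_by_library_size(counts)
        np.testing.assert_allclose(factors, [0.5, 1.0, 2.0])

    def test_no_everywhere_nonzero_clade_raises(self):
        counts = pd.DataFrame({"S1": [0, 3], "S2": [3, 0]}, index=list("ab"))
        with pytest.raises(ValueError, match="pseudo-count"):
            abundance.scale_by_library_size(counts)

    def test_fixed_reference_gives_exact_scale_equivariance(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(
            rng.poisson(50, size=(6, 4)) + 1,
            index=list("abcdef"), columns=["S1", "S2", "S3", "S4"],
        )
        ref = pd.Series(np.exp(np.log(counts).mean(axis=1)), index=counts.index)
        f1, s1 = abundance.scale_by_library_size(counts, reference=ref)
        bumped = counts.copy()
        bumped["S2"] = bumped["S2"] * 3
        f2, s2 = abundance.scale_by_library_size(bumped, reference=ref)
        assert f2["S2"] / f1["S2"] == pytest.approx(3.0)
        np.testing.assert_allclose(s2["S2"], s1["S2"])

    def test_free_reference_equivariance_is_approximate(self):
        # without a fixed reference the factor shift is c^((m-1)/m)
        rng = np.random.default_rng(1)
        counts = pd.DataFrame(
            rng.poisson(50, size=(8, 10)) + 1,
            index=[f"c{i}" for i in range(8)],
            columns=[f"S{j}" for j in range(10)],
        )
        f1, _ = abundance.scale_by_library_size(counts)
        bumped = counts.copy()
        bumped["S0"] = bumped["S0"] * 2
        f2, _ = abundance.scale_by_library_size(bumped)
        assert f2["S0"] / f1["S0"] == pytest.approx(2.0, rel=0.08)


class TestExcludeSparseSamples:
    def test_equal_totals_keep_everything(self):
        counts = pd.DataFrame(np.full((3, 10), 7), columns=[f"S{i}" for i in range(10)])
        kept = abundance.exclude_sparse_samples(counts, 0.05)
        assert kept.shape[1] == 10

    def test_empty_sample_dropped(self):
        counts = pd.DataFrame({"S1": [5, 5], "S2": [0, 0], "S3": [5, 5]})
        kept = abundance.exclude_sparse_samples(counts, 0.05)
        assert list(kept.columns) == ["S1", "S3"]

    def test_constructed_cutoff_drops_exactly_the_sparse_six(self):
        totals = [1000] * 14 + [1] * 6  # share of the small ones ~ 7e-5 < 0.05/20
        counts = pd.DataFrame([totals], columns=[f"S{i}" for i in range(20)])
        kept = abundance.exclude_sparse_samples(counts, 0.05)
        assert kept.shape[1] == 14

    def test_all_dropped_raises(self):
        counts = pd.DataFrame({"S1": [0], "S2": [0]})
        with pytest.raises(ValueError):
            abundance.exclude_sparse_samples(counts, 0.05)


def simulate_single_clade(beta, alpha, n, seed, mu0=50.0):
    """One clade with a standard-normal covariate and a planted effect."""
    rng = np.random.default_rng(seed)
    x = rng.normal(0, 1, n)
    mu = mu0 * np.exp(beta * x)
    lam = rng.gamma(1.0 / alpha, alpha * mu) if alpha > 0 else mu
    y = rng.poisson(lam)
    counts = pd.DataFrame([y], index=["clade"], columns=[f"S{i}" for i in range(n)])
    meta = pd.DataFrame({"x": x}, index=counts.columns)
    return make_dataset(counts, meta)


class TestFitNbGlm:
    def test_intercept_only_equals_log_mean(self):
        counts = pd.DataFrame([[7] * 30], index=["clade"], columns=[f"S{i}" for i in range(30)])
        meta = pd.DataFrame(
            {"x": np.r_[np.zeros(15), np.ones(15)]}, index=counts.columns
        )
        ds = make_dataset(counts, meta)
        fit = abundance.fit_nb_glm(ds, "clade", "x")
        # constant counts: slope 0 and intercept log 7
        assert fit.params["Intercept"] == pytest.approx(np.log(7), abs=1e-6)
        assert fit.params["x"] == pytest.approx(0.0, abs=1e-6)

    def test_planted_effect_recovered(self):
        ds = simulate_single_clade(beta=0.5, alpha=0.5, n=500, seed=3)
        fit = abundance.fit_nb_glm(ds, "clade", "x")
        assert fit.params["x"] == pytest.approx(0.5, abs=0.1)
        assert 0.25 < fit.alpha < 0.75  # within ±50% of the planted 0.5

    def test_alpha_is_a_local_aic_minimum(self):
        ds = simulate_single_clade(beta=0.3, alpha=0.4, n=300, seed=5)
        fit = abundance.fit_nb_glm(ds, "clade", "x")
        X = np.column_stack(
            [np.ones(300), ds.metadata["x"].to_numpy()]
        )
        y = ds.counts.loc["clade"].to_numpy(dtype=float)

        def aic_at(alpha):
            res = abundance._nb_fit(y, X, alpha)
            return abundance._aic(res, X.shape[1])

        assert aic_at(fit.alpha) <= aic_at(fit.alpha * 2) + 1e-6
        assert aic_at(fit.alpha) <= aic_at(fit.alpha / 2) + 1e-6

    def test_missing_metadata_rows_dropped(self):
        ds = simulate_single_clade(beta=0.0, alpha=0.3, n=60, seed=6)
        ds.metadata.loc[ds.metadata.index[:10], "x"] = np.nan
        fit = abundance.fit_nb_glm(ds, "clade", "x")
        assert fit.converged

    def test_constant_variable_rejected(self):
        counts = pd.DataFrame([[5] * 10], index=["clade"], columns=[f"S{i}" for i in range(10)])
        meta = pd.DataFrame({"x": np.ones(10)}, index=counts.columns)
        with pytest.raises(ValueError, match="constant"):
            abundance.fit_nb_glm(make_dataset(counts, meta), "clade", "x")

    def test_treatment_coding_names_and_reference(self):
        rng = np.random.default_rng(7)
        groups = np.repeat(["deep", "mid", "surface"], 30)
        mu = {"deep": 20, "mid": 40, "surface": 80}
        y = rng.poisson([mu[g] for g in groups])
        counts = pd.DataFrame([y], index=["clade"], columns=[f"S{i}" for i in range(90)])
        meta = pd.DataFrame({"zone": groups}, index=counts.columns)
        fit = abundance.fit_nb_glm(make_dataset(counts, meta), "clade", "zone", reference="deep")
        assert fit.reference_level == "deep"
        assert set(fit.params.index) == {"Intercept", "zone[T.mid]", "zone[T.surface]"}
        assert fit.params["zone[T.surface]"] == pytest.approx(np.log(4), abs=0.3)

    def test_sum_coding_columns_sum_to_zero_effectively(self):
        rng = np.random.default_rng(8)
        groups = np.repeat(["a", "b", "c"], 20)
        y = rng.poisson(30, size=60)
        counts = pd.DataFrame([y], index=["clade"], columns=[f"S{i}" for i in range(60)])
        meta = pd.DataFrame({"g": groups}, index=counts.columns)
        fit = abundance.fit_nb_glm(
            make_dataset(counts, meta), "clade", "g", coding="sum_to_zero", reference="a"
        )
        assert set(fit.params.index) == {"Intercept", "g[S.b]", "g[S.c]"}
        # balanced null: intercept estimates the grand log-mean
        assert fit.params["Intercept"] == pytest.approx(np.log(y.mean()), abs=0.1)


class TestSelectReferenceLevel:
    def _dataset(self, seed=9):
        rng = np.random.default_rng(seed)
        groups = np.repeat(["a", "b", "c"], 25)
        mu = {"a": 10, "b": 40, "c": 42}
        y = rng.poisson([mu[g] for g in groups])
        counts = pd.DataFrame([y], index=["clade"], columns=[f"S{i}" for i in range(75)])
        meta = pd.DataFrame({"g": groups}, index=counts.columns)
        return make_dataset(counts, meta)

    def test_two_level_factor_returns_a_finite_fit(self):
        ds = self._dataset()
        ds.metadata["g"] = np.repeat(["a", "b"], [38, 37])
        level, fit = abundance.select_reference_level(ds, "clade", "g")
        assert level in {"a", "b"} and np.isfinite(fit.aic)

    def test_deterministic_across_reruns(self):
        ds = self._dataset()
        l1, _ = abundance.select_reference_level(ds, "clade", "g")
        l2, _ = abundance.select_reference_level(ds, "clade", "g")
        assert l1 == l2

    def test_returned_aic_not_beaten_by_any_candidate(self):
        ds = self._dataset()
        _, best = abundance.select_reference_level(ds, "clade", "g")
        for level in ["a", "b", "c"]:
            alt = abundance.fit_nb_glm(ds, "clade", "g", reference=level)
            assert best.aic <= alt.aic + 1e-6


def fake_fit(clade, variable, block_p, coef_p=None, estimate=1.0):
    coef_p = block_p if coef_p is None else coef_p
    name = f"{variable}[T.b]"
    return GLMFit(
        clade=clade, variable=variable, coding="treatment", reference_level="a",
        params=pd.Series({"Intercept": 0.0, name: estimate}),
        bse=pd.Series({"Intercept": 0.1, name: 0.1}),
        wald_p=pd.Series({name: coef_p}),
        block_p=block_p, alpha=0.5, aic=10.0,
    )


class TestSignificanceScreen:
    def test_hand_benjamini_hochberg_four_rejections(self):
        # p = {0.01..0.04, 0.2} at threshold 0.05: sorted p(i) <= i/5*0.05
        # holds for the first four
        ps = [0.01, 0.02, 0.03, 0.04, 0.2]
        fits = [fake_fit(f"c{i}", "temp", p) for i, p in enumerate(ps)]
        out = abundance.significance_screen(
            fits, variable_threshold=0.05, coefficient_threshold=0.05
        )
        assert sorted(out["clade"]) == ["c0", "c1", "c2", "c3"]

    def test_all_ones_rejects_nothing(self):
        fits = [fake_fit(f"c{i}", "temp", 1.0) for i in range(5)]
        out = abundance.significance_screen(fits)
        assert out.empty

    def test_single_test_bh_is_identity(self):
        out = abundance.significance_screen(
            [fake_fit("c0", "temp", 0.04)], variable_threshold=0.05
        )
        assert len(out) == 1
        assert out.loc[0, "p_adj"] == pytest.approx(0.04)

    def test_adjusted_never_below_raw(self):
        ps = [0.001, 0.01, 0.02, 0.04, 0.07, 0.3]
        fits = [fake_fit(f"c{i}", "temp", p) for i, p in enumerate(ps)]
        out = abundance.significance_screen(fits, variable_threshold=1.0,
                                            coefficient_threshold=1.01)
        assert (out["p_adj"] >= out["p"] - 1e-12).all()

    def test_sign_taken_from_coefficient(self):
        fits = [
            fake_fit("up", "temp", 0.001, estimate=2.0),
            fake_fit("down", "temp", 0.001, estimate=-2.0),
        ]
        out = abundance.significance_screen(fits).set_index("clade")
        assert out.loc["up", "sign"] == 1
        assert out.loc["down", "sign"] == -1

    def test_families_are_per_variable(self):
        # a significant temperature family must not be diluted by a large
        # null salinity family when adjusting per variable
        fits = [fake_fit(f"t{i}", "temp", 0.004) for i in range(3)]
        fits += [fake_fit(f"s{i}", "salinity", 0.9) for i in range(30)]
        out = abundance.significance_screen(fits, family="variable")
        assert set(out["variable"]) == {"temp"}
        assert len(out) == 3

    def test_empty_fit_list_rejected(self):
        with pytest.raises(ValueError):
            abundance.significance_screen([])


class TestFitNbGam:
    def test_constant_series_gives_flat_smooth_with_truth_in_band(self):
        y = pd.Series([20.0] * 15, name="clade")
        fit = abundance.fit_nb_gam(y, np.arange(15.0))
        assert np.ptp(fit.fitted) / fit.fitted.mean() < 0.05
        assert ((fit.lower <= 20.0) & (20.0 <= fit.upper)).all()
        assert not fit.significant_vs_baseline

    def test_annual_sinusoid_recovered(self):
        t = np.arange(15.0)
        mu = np.exp(3.0 + 1.0 * np.sin(2 * np.pi * t / 12.0))
        rng = np.random.default_rng(5)
        y = rng.poisson(rng.gamma(1 / 0.2, 0.2 * mu))
        fit = abundance.fit_nb_gam(pd.Series(y, name="clade"), t)
        assert np.corrcoef(fit.fitted, mu)[0, 1] > 0.9

    def test_df_monotone_with_wiggliness(self):
        # a 2-cycle sinusoid needs at least the df chosen for a linear trend
        t = np.arange(24.0)
        rng = np.random.default_rng(6)
        linear = rng.poisson(np.exp(2.0 + 0.05 * t))
        wiggly = rng.poisson(np.exp(3.0 + 1.2 * np.sin(2 * np.pi * t / 12.0)))
        df_linear = abundance.fit_nb_gam(pd.Series(linear, name="l"), t).spline_df
        df_wiggly = abundance.fit_nb_gam(pd.Series(wiggly, name="w"), t).spline_df
        assert df_linear <= df_wiggly

    def test_short_series_truncates_df_range(self, caplog):
        y = pd.Series(np.arange(10.0) + 5.0, name="clade")
        with caplog.at_level("WARNING", logger="poseidonia.abundance"):
            fit = abundance.fit_nb_gam(y, np.arange(10.0))
        assert fit.spline_df <= 8
        assert "truncated" in caplog.text

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            abundance.fit_nb_gam(pd.Series([1.0] * 5, name="c"), np.arange(5.0))


class TestBaselineContrast:
    def test_identical_groups_unflagged(self):
        stats_df = pd.DataFrame(
            {"estimate": [5.0, 5.0, 5.0], "se": [0.5, 0.5, 0.5]}, index=list("abc")
        )
        out = abundance.baseline_contrast(stats_df)
        assert not out["differs_from_baseline"].any()

    def test_shifted_group_flagged(self):
        stats_df = pd.DataFrame(
            {"estimate": [5.0, 5.0, 5.0, 7.5], "se": [0.5] * 4}, index=list("abcd")
        )
        out = abundance.baseline_contrast(stats_df)
        assert out.loc["d", "differs_from_baseline"]

    def test_invariant_under_relabelling(self):
        stats_df = pd.DataFrame(
            {"estimate": [5.0, 9.0, 5.2], "se": [0.4, 0.4, 0.4]}, index=list("abc")
        )
        out1 = abundance.baseline_contrast(stats_df)
        perm = ["c", "a", "b"]
        out2 = abundance.baseline_contrast(stats_df.loc[perm])
        assert (
            out1["differs_from_baseline"].sort_index()
            == out2["differs_from_baseline"].sort_index()
        ).all()

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            abundance.baseline_contrast(
                pd.DataFrame({"estimate": [1.0], "se": [0.1]}, index=["a"])
            )


class TestNormalizeBySingleCopy:
    def test_equal_counts_give_unit_ratio(self):
        assert abundance.normalize_by_single_copy(5, [5, 5, 5, 5, 5]) == 1.0

    def test_hand_arithmetic(self):
        assert abundance.normalize_by_single_copy(10, [4, 5, 6, 5, 5]) == 2.0

    def test_scale_invariance(self):
        a = abundance.normalize_by_single_copy(10, [4, 5, 6, 5, 5])
        b = abundance.normalize_by_single_copy(20, [8, 10, 12, 10, 10])
        assert a == b

    def test_named_ribosomal_genes(self):
        counts = {"S4": 4, "S15": 5, "S24e": 6, "S27ae": 5, "L21": 5}
        assert abundance.normalize_by_single_copy(10, counts) == 2.0

    def test_all_zero_is_nan_with_warning(self, caplog):
        with caplog.at_level("WARNING", logger="poseidonia.abundance"):
            out = abundance.normalize_by_single_copy(10, [0, 0, 0, 0, 0])
        assert np.isnan(out)

    def test_wrong_gene_count_rejected(self):
        with pytest.raises(ValueError):
            abundance.normalize_by_single_copy(1, [1, 2, 3])
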