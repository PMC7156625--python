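"""Agreement/reliability statistics against closed forms and independent
ANOVA oracles."""

import numpy as np
import pytest

from brainmorph.evalstats import (
    PairedSeries,
    age_trend,
    bland_altman,
    bonferroni_threshold,
    cicchetti_band,
    cohen_d_adjusted,
    icc_2_1,
    pearson_r,
    r_squared,
    relative_deviation,
    rescan_sd,
    rescan_summary,
)
from brainmorph.targets import build_registry


def icc_2_1_oracle(y, g):
    """Independent brute-force two-way ANOVA: explicit sums of squares over
    the n×2 table, then the Shrout–Fleiss single-measure absolute-agreement
    ratio."""
    table = np.column_stack([y, g]).astype(float)
    n, k = table.shape
    grand = table.mean()
    ss_total = ((table - grand) ** 2).sum()
    ss_rows = sum(k * (table[i].mean() - grand) ** 2 for i in range(n))
    ss_cols = sum(n * (table[:, j].mean() - grand) ** 2 for j in range(k))
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k / n * (msc - mse))


class TestRSquared:
    def test_perfect_fit(self):
        g = np.array([1.0, 2.0, 5.0, 3.0])
        assert r_squared(g, g) == pytest.approx(1.0)

    def test_mean_predictor_scores_zero(self):
        g = np.array([1.0, 2.0, 3.0, 6.0])
        y = np.full_like(g, g.mean())
        assert r_squared(y, g) == pytest.approx(0.0)

    def test_worked_example(self):
        assert r_squared(np.array([1.0, 2, 4]), np.array([1.0, 2, 3])) == pytest.approx(0.5)

    def test_constant_reference_undefined(self):
        assert np.isnan(r_squared(np.array([1.0, 2]), np.array([3.0, 3])))


class TestPearson:
    def test_scale_bias_blindness(self):
        g = np.array([1.0, 2.0, 4.0, 7.0])
        assert pearson_r(2 * g, g) == pytest.approx(1.0)
        assert pearson_r(g + 1, g) == pytest.approx(1.0)

    def test_anticorrelation(self):
        g = np.array([1.0, 2.0, 4.0])
        assert pearson_r(-g, g) == pytest.approx(-1.0)

    def test_constant_series_undefined(self):
        assert np.isnan(pearson_r(np.array([1.0, 1.0]), np.array([1.0, 2.0])))


class TestICC:
    def test_perfect_agreement(self):
        g = np.array([1.0, 2.0, 4.0, 7.0, 3.0])
        assert icc_2_1(g, g).value == pytest.approx(1.0)

    def test_fixed_bias_detected_where_pearson_blind(self):
        g = np.array([1.0, 2.0, 4.0, 7.0, 3.0])
        res = icc_2_1(g + 2.0, g)
        assert pearson_r(g + 2.0, g) == pytest.approx(1.0)
        assert res.value < 1.0

    def test_matches_anova_oracle_on_random_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            y = rng.normal(size=10)
            g = rng.normal(size=10)
            res = icc_2_1(y, g)
            assert res.value == pytest.approx(icc_2_1_oracle(y, g), abs=1e-10)

    def test_matches_pingouin_reference_implementation(self):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(1)
        for _ in range(25):
            g = rng.normal(size=12)
            y = g + rng.normal(scale=0.5, size=12)
            df = pd.DataFrame(
                {
                    "targets": np.repeat(np.arange(12), 2),
                    "raters": np.tile(["y", "g"], 12),
                    "scores": np.column_stack([y, g]).ravel(),
                }
            )
            ref = pingouin.intraclass_corr(
                data=df, targets="targets", raters="raters", ratings="scores"
            )
            # two-way absolute-agreement single-measure row (label varies
            # across pingouin versions: ICC2 / ICC(A,1))
            row = ref[ref["Type"].isin(["ICC2", "ICC(A,1)"])].iloc[0]
            ci_col = "CI95%" if "CI95%" in ref.columns else "CI95"
            res = icc_2_1(y, g)
            assert res.value == pytest.approx(row["ICC"], abs=1e-9)
            # pingouin rounds the interval to 2 decimals
            assert res.ci95[0] == pytest.approx(row[ci_col][0], abs=6e-3)
            assert res.ci95[1] == pytest.approx(row[ci_col][1], abs=6e-3)

    def test_affine_invariance_and_bias_sensitivity(self):
        rng = np.random.default_rng(2)
        g = rng.normal(size=20)
        y = g + rng.normal(scale=0.3, size=20)
        base = icc_2_1(y, g).value
        affine = icc_2_1(3.0 * y + 5.0, 3.0 * g + 5.0).value
        assert affine == pytest.approx(base, abs=1e-12)
        biased = icc_2_1(y + 1.0, g).value
        assert biased < base

    def test_icc_never_exceeds_one(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            y = rng.normal(size=8)
            g = rng.normal(size=8)
            assert icc_2_1(y, g).value <= 1.0 + 1e-12

    def test_zero_between_subject_variance_flagged(self):
        with pytest.warns(UserWarning, match="variability"):
            res = icc_2_1(np.array([1.0, 1.0, 1.0]), np.array([1.0, 1.0, 1.0]))
        assert np.isnan(res.value)
        assert res.band == "undefined"

    def test_ci_contains_point_estimate(self):
        rng = np.random.default_rng(4)
        g = rng.normal(size=15)
        y = g + rng.normal(scale=0.4, size=15)
        res = icc_2_1(y, g)
        assert res.ci95[0] <= res.value <= res.ci95[1]


class TestCicchettiBands:
    @pytest.mark.parametrize(
        "icc,band",
        [
            (0.39, "poor"),
            (0.40, "fair"),
            (0.59, "fair"),
            (0.60, "good"),
            (0.74, "good"),
            (0.75, "excellent"),
            (1.00, "excellent"),
            (-0.5, "poor"),
        ],
    )
    def test_boundaries(self, icc, band):
        assert cicchetti_band(icc) == band


class TestBlandAltman:
    def test_perfect_agreement_collapses_limits(self):
        g = np.array([1.0, 2.0, 3.0])
        ba = bland_altman(g, g)
        assert (ba.mean_diff, ba.sd_diff, ba.loa_low, ba.loa_high) == (0, 0, 0, 0)

    def test_pure_bias(self):
        g = np.array([1.0, 2.0, 3.0])
        ba = bland_altman(g + 5.0, g)
        assert ba.mean_diff == pytest.approx(5.0)
        assert ba.sd_diff == pytest.approx(0.0)

    def test_hand_computed_four_pairs(self):
        y = np.array([1.0, 2.0, 4.0, 5.0])
        g = np.array([1.0, 1.0, 5.0, 4.0])
        d = y - g  # 0, 1, -1, 1
        ba = bland_altman(y, g)
        assert ba.mean_diff == pytest.approx(d.mean())
        assert ba.sd_diff == pytest.approx(d.std(ddof=1))
        assert ba.loa_low == pytest.approx(d.mean() - 1.96 * d.std(ddof=1))
        assert ba.loa_high == pytest.approx(d.mean() + 1.96 * d.std(ddof=1))

    def test_limits_cover_nominal_mass_on_gaussian(self):
        rng = np.random.default_rng(5)
        g = rng.normal(size=5000)
        y = g + rng.normal(scale=0.5, size=5000)
        ba = bland_altman(y, g)
        d = y - g
        frac = ((d >= ba.loa_low) & (d <= ba.loa_high)).mean()
        assert frac >= 0.93


class TestRelativeDeviation:
    def test_identity_gives_zero(self, registry):
        ref = np.abs(np.random.default_rng(6).normal(size=(5, 165))) + 1.0
        out = relative_deviation(ref, ref, registry)
        for mean, sd in out.values():
            assert mean == pytest.approx(0.0)
            assert sd == pytest.approx(0.0)

    def test_uniform_five_percent_inflation(self, registry):
        ref = np.abs(np.random.default_rng(7).normal(size=(4, 165))) + 1.0
        out = relative_deviation(1.05 * ref, ref, registry)
        for mean, _ in out.values():
            assert mean == pytest.approx(5.0)

    def test_mixed_fixture_matches_hand_computation(self, registry):
        ref = np.ones((2, 165))
        pred = np.ones((2, 165))
        vol_idx = [d.index for d in registry if d.category == "volume"]
        pred[0, vol_idx[0]] = 1.10  # +10% on one of 29 volumes
        out = relative_deviation(pred, ref, registry)
        per_subject = np.array([10.0 / 29, 0.0])
        assert out["volume"][0] == pytest.approx(per_subject.mean())
        assert out["volume"][1] == pytest.approx(per_subject.std(ddof=1))


class TestCohenD:
    def test_identical_groups_give_zero(self):
        v = np.tile([1.0, 2.0, 3.0], 2)
        grp = ["control"] * 3 + ["patient"] * 3
        assert cohen_d_adjusted(v, grp).cohen_d == pytest.approx(0.0)

    def test_unit_effect_closed_form(self):
        v = np.array([1.0, 2.0, 3.0, 2.0, 3.0, 4.0])
        grp = ["control"] * 3 + ["patient"] * 3
        assert cohen_d_adjusted(v, grp).cohen_d == pytest.approx(1.0)

    def test_age_confound_removed_by_adjustment(self):
        rng = np.random.default_rng(8)
        n = 300
        # patients are systematically older; values driven purely by age
        age_c = rng.uniform(20, 50, n)
        age_p = rng.uniform(40, 70, n)
        ages = np.concatenate([age_c, age_p])
        values = 2.0 + 0.05 * ages + rng.normal(scale=0.05, size=2 * n)
        grp = ["control"] * n + ["patient"] * n
        raw = cohen_d_adjusted(values, grp)
        adj = cohen_d_adjusted(values, grp, age=ages)
        assert abs(raw.cohen_d) > 1.0
        assert abs(adj.cohen_d) < 0.15

    def test_constant_covariate_dropped_with_warning(self):
        v = np.array([1.0, 2.0, 3.0, 2.0, 3.0, 4.0])
        grp = ["control"] * 3 + ["patient"] * 3
        with pytest.warns(UserWarning, match="sex"):
            res = cohen_d_adjusted(v, grp, sex=["F"] * 6)
        assert res.cohen_d == pytest.approx(1.0)


class TestAgeTrend:
    def test_noiseless_linear_recovered_exactly(self):
        ages = np.linspace(10, 80, 30)
        values = 3.0 - 0.004 * ages
        trend = age_trend(values, ages, order=1)
        assert trend.slope == pytest.approx(-0.004, abs=1e-12)

    def test_noisy_slope_within_own_ci(self):
        rng = np.random.default_rng(9)
        ages = rng.uniform(6, 84, 200)
        values = 2.66 - 0.004 * ages + rng.normal(scale=0.05, size=200)
        trend = age_trend(values, ages, order=1)
        assert trend.slope_ci95[0] <= -0.004 <= trend.slope_ci95[1]

    def test_quadratic_peak_recovered(self):
        ages = np.linspace(10, 80, 50)
        values = 3.0 - 0.0005 * (ages - 45.0) ** 2
        trend = age_trend(values, ages, order=2)
        assert trend.peak_age == pytest.approx(45.0, abs=0.5)


class TestBonferroni:
    @pytest.mark.parametrize(
        "alpha,m,expected",
        [(0.05, 68, 0.05 / 68), (0.05, 1, 0.05), (0.01, 10, 0.001)],
    )
    def test_threshold(self, alpha, m, expected):
        assert bonferroni_threshold(alpha, m) == pytest.approx(expected)

    def test_68_parcellation_threshold_below_0007(self):
        assert bonferroni_threshold(0.05, 68) < 0.0007 + 5e-5


class TestRescan:
    def test_published_thalamus_rescan_example(self):
        vals = [7079, 7066, 7028, 7010, 7021, 7003]
        mean, sd = rescan_sd(vals)
        assert int(np.floor(mean + 0.5)) == 7035  # half-up, as printed
        assert int(np.floor(sd + 0.5)) == 31

    def test_identical_rescans_have_zero_sd(self):
        assert rescan_sd([5.0, 5.0, 5.0])[1] == 0.0

    def test_two_scan_closed_form(self):
        _, sd = rescan_sd([3.0, 5.0])
        assert sd == pytest.approx(np.sqrt(2.0))

    def test_summary_excludes_singletons_keeps_pooled(self):
        df = rescan_summary({"a": [1.0, 2.0], "b": [5.0]})
        assert set(df["subject_id"]) == {"a", "__all__"}
        pooled = df[df["subject_id"] == "__all__"].iloc[0]
        assert pooled["n_scans"] == 3
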