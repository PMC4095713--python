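"""Sampling, descriptive statistics, histograms, ANOVA and t-tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pulpmorph.stats import (
    CLASS_WIDTHS,
    anova_one_way,
    build_histogram,
    describe,
    gaussian_overlay,
    sample_records,
    significance_tier,
    t_test_two_sample,
)


def _db(n: int, seed: int = 0) -> pd.DataFrame:
    rng = np.random.default_rng(seed)
    area = rng.uniform(5, 60, n)
    ff = rng.uniform(0.05, 0.9, n)
    return pd.DataFrame(
        {
            "case_id": "caseX",
            "image_id": "img",
            "region_id": np.arange(1, n + 1),
            "area_um2": area,
            "perimeter_um": np.sqrt(4 * np.pi * area / ff),
            "form_factor": ff,
        }
    )


class TestSampleRecords:
    def test_exact_size_returns_full_database(self):
        db = _db(100)
        out = sample_records(db, 100, seed=5)
        assert sorted(out["region_id"]) == sorted(db["region_id"])

    def test_deterministic_given_seed(self):
        db = _db(600)
        s1 = sample_records(db, 100, seed=9)
        s2 = sample_records(db, 100, seed=9)
        pd.testing.assert_frame_equal(s1, s2)

    def test_without_replacement(self):
        out = sample_records(_db(600), 100, seed=1)
        assert out["region_id"].is_unique

    def test_rows_stay_aligned(self):
        out = sample_records(_db(600), 100, seed=2)
        assert out["form_factor"].to_numpy() == pytest.approx(
            4 * np.pi * out["area_um2"].to_numpy() / out["perimeter_um"].to_numpy() ** 2
        )

    def test_uniform_inclusion_frequency(self):
        """Each record's inclusion rate across many draws is ~ n/N."""
        db = _db(600)
        draws = 1500
        rng = np.random.default_rng(123)
        counts = np.zeros(601)
        for _ in range(draws):
            out = sample_records(db, 100, seed=rng)
            counts[out["region_id"].to_numpy()] += 1
        counts = counts[1:]
        p = 100 / 600
        se = np.sqrt(p * (1 - p) / draws)
        freq = counts / draws
        assert (np.abs(freq - p) < 5 * se).mean() > 0.995

    def test_insufficient_records_names_case(self):
        with pytest.raises(ValueError, match="caseX"):
            sample_records(_db(80), 100)


class TestDescribe:
    def test_constant_sample(self):
        st_ = describe([5, 5, 5])
        assert (st_.mean, st_.sd, st_.min, st_.max) == (5, 0, 5, 5)

    def test_sample_sd_uses_n_minus_one(self):
        st_ = describe([1, 2, 3])
        assert st_.mean == 2
        assert st_.sd == pytest.approx(1.0)

    def test_stage_records_recover_mean(self):
        from pulpmorph.synthetic import generate_stage_records, stage_defaults

        params = stage_defaults()["cap"]
        df = generate_stage_records(params, 500, np.random.default_rng(21))
        st_ = describe(df["area"])
        se = params.sd_area / np.sqrt(500)
        assert abs(st_.mean - 17.733) < 3 * se

    def test_rejects_empty(self):
        with pytest.raises(ValueError):
            describe([])


class TestHistogram:
    def test_empty_input_all_zero(self):
        hist = build_histogram([], "area")
        assert hist.counts.sum() == 0
        assert hist.counts.size == 20
        assert hist.out_of_range == 0

    def test_default_class_widths(self):
        assert build_histogram([1.0], "area").class_width == 3.5
        assert build_histogram([1.0], "perimeter").class_width == 7.0
        assert build_histogram([0.1], "form_factor").class_width == 0.05

    def test_interior_edge_goes_right(self):
        hist = build_histogram([3.5], "area")
        assert hist.counts[0] == 0
        assert hist.counts[1] == 1

    def test_out_of_range_counted_not_dropped(self):
        hist = build_histogram([1.0, 71.0], "area")  # 71 >= 20 * 3.5
        assert hist.counts.sum() == 1
        assert hist.out_of_range == 1
        assert hist.n == 2

    def test_count_conservation(self):
        values = np.random.default_rng(2).uniform(0, 90, 500)
        hist = build_histogram(values, "area")
        assert hist.counts.sum() == 500 - hist.out_of_range

    def test_unknown_parameter_needs_width(self):
        with pytest.raises(ValueError, match="class width"):
            build_histogram([1.0], "volume")
        assert build_histogram([1.0], "volume", class_width=2.0).class_width == 2.0


class TestGaussianOverlay:
    def _stats_hist(self, values, parameter="area"):
        hist = build_histogram(values, parameter)
        return describe(values), hist

    def test_peak_at_mean_bin(self):
        values = np.random.default_rng(3).normal(35, 5, 400).clip(0.1)
        stats, hist = self._stats_hist(values)
        curve = gaussian_overlay(stats, hist)
        peak_center = hist.centers[np.argmax(curve)]
        assert abs(peak_center - stats.mean) <= hist.class_width

    def test_integral_close_to_n(self):
        values = np.random.default_rng(4).normal(35, 4, 1000).clip(0.1)
        stats, hist = self._stats_hist(values)
        curve = gaussian_overlay(stats, hist)
        assert curve.sum() == pytest.approx(stats.n, rel=0.02)

    def test_doubling_width_doubles_heights(self):
        """At the same abscissa, the overlay height scales with class width."""
        values = np.random.default_rng(5).normal(30, 6, 300)
        stats = describe(values)
        from dataclasses import replace

        h1 = build_histogram(values, "area", class_width=3.5)
        h2 = replace(h1, class_width=7.0)  # same centres, doubled class width
        c1 = gaussian_overlay(stats, h1)
        c2 = gaussian_overlay(stats, h2)
        assert c2 == pytest.approx(2.0 * c1)

    def test_zero_sd_gives_no_curve(self):
        stats, hist = self._stats_hist(np.full(10, 7.0))
        assert gaussian_overlay(stats, hist) is None


class TestAnova:
    def test_identical_groups_degenerate(self):
        res = anova_one_way([np.full(5, 2.0), np.full(5, 2.0), np.full(5, 2.0)])
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_two_groups_f_equals_t_squared(self):
        rng = np.random.default_rng(6)
        x, y = rng.normal(0, 1, 30), rng.normal(0.5, 1, 25)
        f = anova_one_way([x, y])
        t = t_test_two_sample(x, y, equal_variance=True)
        assert f.statistic == pytest.approx(t.statistic**2, rel=1e-10)
        assert f.p_value == pytest.approx(t.p_value, rel=1e-10)

    def test_matches_sum_of_squares_oracle(self):
        rng = np.random.default_rng(7)
        groups = [rng.normal(m, 1.0, n) for m, n in ((0, 8), (1, 12), (0.5, 10))]
        res = anova_one_way(groups)
        grand = np.concatenate(groups).mean()
        ss_between = sum(g.size * (g.mean() - grand) ** 2 for g in groups)
        ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
        k, n = len(groups), sum(g.size for g in groups)
        f_oracle = (ss_between / (k - 1)) / (ss_within / (n - k))
        assert res.statistic == pytest.approx(f_oracle, rel=1e-10)
        assert res.df == (k - 1, n - k)

    def test_shift_invariance_and_scaling(self):
        rng = np.random.default_rng(8)
        groups = [rng.normal(m, 1.0, 15) for m in (0, 1, 2)]
        base = anova_one_way(groups).statistic
        shifted = anova_one_way([g + 100.0 for g in groups]).statistic
        scaled = anova_one_way([g * 3.0 for g in groups]).statistic
        assert shifted == pytest.approx(base, rel=1e-9)
        assert scaled == pytest.approx(base, rel=1e-9)

    def test_rejects_single_group(self):
        with pytest.raises(ValueError):
            anova_one_way([np.arange(5.0)])


class TestTTest:
    def test_equal_samples(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        res = t_test_two_sample(x, x)
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_antisymmetry(self):
        rng = np.random.default_rng(9)
        x, y = rng.normal(1, 1, 20), rng.normal(0, 1, 22)
        a = t_test_two_sample(x, y)
        b = t_test_two_sample(y, x)
        assert a.statistic == pytest.approx(-b.statistic)
        assert a.p_value == pytest.approx(b.p_value)

    def test_welch_matches_textbook_formula(self):
        x = np.array([4.1, 5.2, 6.3, 5.5, 4.8])
        y = np.array([6.9, 7.2, 8.1, 7.7])
        res = t_test_two_sample(x, y)
        vx, vy = x.var(ddof=1) / x.size, y.var(ddof=1) / y.size
        t_oracle = (x.mean() - y.mean()) / np.sqrt(vx + vy)
        df_oracle = (vx + vy) ** 2 / (vx**2 / (x.size - 1) + vy**2 / (y.size - 1))
        assert res.statistic == pytest.approx(t_oracle, rel=1e-12)
        assert res.df == pytest.approx(df_oracle, rel=1e-12)
        assert res.equal_variance is False

    def test_pooled_matches_textbook_formula(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.5, 3.5, 4.5])
        res = t_test_two_sample(x, y, equal_variance=True)
        sp2 = ((x.size - 1) * x.var(ddof=1) + (y.size - 1) * y.var(ddof=1)) / (
            x.size + y.size - 2
        )
        t_oracle = (x.mean() - y.mean()) / np.sqrt(sp2 * (1 / x.size + 1 / y.size))
        assert res.statistic == pytest.approx(t_oracle, rel=1e-12)

    def test_degenerate_equal_constants(self):
        res = t_test_two_sample([3.0, 3.0], [3.0, 3.0])
        assert res.p_value == 1.0

    def test_degenerate_different_constants_rejected(self):
        with pytest.raises(ValueError):
            t_test_two_sample([3.0, 3.0], [4.0, 4.0])

    @given(st.floats(min_value=1e-6, max_value=1.0))
    def test_tiers(self, p):
        tier = significance_tier(p)
        if p <= 0.001:
            assert tier == "p<=0.001"
        elif p <= 0.01:
            assert tier == "p<=0.01"
        elif p <= 0.05:
            assert tier == "p<=0.05"
        else:
            assert tier == "ns"
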