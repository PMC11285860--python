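"""Count scaling, seasonal budgets, sex ratios, roles and comparisons."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from passflow import bioflow as bf
from passflow.config import PipelineConfig


class TestScaling:
    @pytest.mark.parametrize("n1,expected", [(0, 0), (1, 8), (15, 120)])
    def test_bihourly(self, n1, expected):
        assert bf.scale_bihourly(n1) == expected

    @pytest.mark.parametrize("n2,expected", [(0, 0), (1, 225), (4, 900)])
    def test_video(self, n2, expected):
        assert bf.scale_video(n2) == expected

    @pytest.mark.parametrize("count,dur,width,expected", [
        (45, 15, 30, 0.1),
        (0, 1, 2, 0.0),
        (7366, 1, 2, 3683.0),  # the busiest recorded 1-min video count
    ])
    def test_mtr(self, count, dur, width, expected):
        assert bf.mtr(count, dur, width) == pytest.approx(expected)

    def test_mtr_rejects_bad_geometry(self):
        with pytest.raises(ValueError):
            bf.mtr(10, 0, 2)
        with pytest.raises(ValueError):
            bf.mtr(10, 1, -2)
        with pytest.raises(ValueError):
            bf.scale_video(-1)

    @given(st.integers(0, 10**6), st.integers(0, 10**6))
    @settings(deadline=None)
    def test_scaling_is_linear(self, a, b):
        assert bf.scale_video(a + b) == bf.scale_video(a) + bf.scale_video(b)
        assert (bf.scale_bihourly(a + b)
                == bf.scale_bihourly(a) + bf.scale_bihourly(b))

    @given(st.integers(1, 10**6), st.integers(1, 60), st.integers(1, 5))
    @settings(deadline=None)
    def test_mtr_scale_invariant(self, count, dur, k):
        assert bf.mtr(k * count, k * dur, 2) == pytest.approx(
            bf.mtr(count, dur, 2))


class TestCorrectMissed:
    @pytest.mark.parametrize("visible,frac,expected", [
        (43, 0.57, 100),
        (0, 0.57, 0),
        (1000, 0.0, 1000),
    ])
    def test_examples(self, visible, frac, expected):
        assert bf.correct_missed(visible, frac) == expected

    def test_rejects_full_missing(self):
        with pytest.raises(ValueError):
            bf.correct_missed(10, 1.0)

    def test_unbiased_under_thinning(self):
        """Thinning at rate 1-f then correcting recovers the true total."""
        rng = np.random.default_rng(0)
        true_total = 100_000
        f = 0.57
        reps = 200
        est = np.array([
            bf.correct_missed(rng.binomial(true_total, 1 - f), f)
            for _ in range(reps)], dtype=float)
        rel_bias = abs(est.mean() - true_total) / true_total
        assert rel_bias < 0.01


def _video(rows):
    return pd.DataFrame(rows, columns=["timestamp", "duration_min",
                                       "width_m", "count"])


def _visual(rows):
    return pd.DataFrame(rows, columns=["timestamp", "duration_min",
                                       "width_m", "taxon", "count"])


class TestSeasonTotals:
    def test_fold_variation_of_stated_extremes(self):
        """Seasons totalling 6.2M and 27.1M insects differ 4.4-fold."""
        # raw video counts that scale to the two seasonal totals
        f = PipelineConfig().missed_fraction
        raw = {2019: 6.2e6, 2020: 27.1e6}
        rows = [(f"{yr}-09-01 10:00", 1.0, 2.0,
                 round(total * (1 - f) / 225)) for yr, total in raw.items()]
        res = bf.season_totals(_video(rows), _visual([]))
        assert round(res.fold_variation, 1) == 4.4

    def test_single_season_fold_one(self):
        rows = [("2021-09-01 10:00", 1.0, 2.0, 50)]
        res = bf.season_totals(_video(rows), _visual([]))
        assert res.fold_variation == pytest.approx(1.0)

    def test_empty_season_excluded(self):
        rows = [("2020-09-01 10:00", 1.0, 2.0, 0),
                ("2021-09-01 10:00", 1.0, 2.0, 40)]
        res = bf.season_totals(_video(rows), _visual([]))
        assert list(res.per_season.index) == [2021]

    def test_row_order_invariant(self):
        rows = [("2020-09-01 10:00", 1.0, 2.0, 7),
                ("2020-09-02 10:00", 1.0, 2.0, 9),
                ("2021-09-01 10:00", 1.0, 2.0, 40)]
        a = bf.season_totals(_video(rows), _visual([]))
        b = bf.season_totals(_video(rows[::-1]), _visual([]))
        pd.testing.assert_frame_equal(a.per_season, b.per_season)

    def test_nutrient_fractions_of_biomass(self):
        """140 kg of biomass carries 14 kg N and 1.4 kg P."""
        cfg = PipelineConfig(mass_table={"_video_mean_mg": 10.0})
        # counts chosen so total biomass is ~140 kg at 10 mg each
        # (140 kg = 1.4e8 mg -> 1.4e7 individuals)
        n_raw = 1.4e7 * (1 - cfg.missed_fraction) / 225
        rows = [("2021-09-01 10:00", 1.0, 2.0, round(n_raw))]
        res = bf.season_totals(_video(rows), _visual([]), cfg)
        assert res.per_season["biomass_kg"].sum() == pytest.approx(140, rel=1e-3)
        assert res.per_season["nitrogen_kg"].sum() == pytest.approx(14, rel=1e-3)
        assert res.per_season["phosphorus_kg"].sum() == pytest.approx(
            1.4, rel=1e-3)


class TestIntegratedDailyTotals:
    def test_combines_streams_per_day(self):
        vid = _video([("2021-09-01 10:00", 1.0, 2.0, 43),
                      ("2021-09-01 12:00", 1.0, 2.0, 0),
                      ("2021-09-02 10:00", 1.0, 2.0, 1)])
        vis = _visual([("2021-09-01 10:00", 15.0, 30.0, "Pieridae", 4)])
        out = bf.integrated_daily_totals(vid, vis, PipelineConfig())
        day1 = out.loc[out["date"] == "2021-09-01", "total_count"].iloc[0]
        # 43*225/0.43 + 4*8 = 22500 + 32
        assert day1 == round(43 * 225 / 0.43) + 32
        day2 = out.loc[out["date"] == "2021-09-02", "total_count"].iloc[0]
        assert day2 == round(225 / 0.43)


class TestSexRatio:
    def test_female_majority(self):
        frac, n = bf.sex_ratio(537, 826)
        assert round(100 * frac) == 65 and n == 826

    def test_all_male(self):
        frac, n = bf.sex_ratio(0, 10)
        assert frac == 0.0

    def test_zero_individuals_flagged(self):
        frac, n = bf.sex_ratio(0, 0)
        assert frac is None and n == 0

    def test_binomial_sampling_within_two_se(self):
        rng = np.random.default_rng(5)
        p, n = 0.96, 929
        females = rng.binomial(n, p)
        frac, _ = bf.sex_ratio(int(females), n)
        se = np.sqrt(p * (1 - p) / n)
        assert abs(frac - p) <= 2 * se


class TestRolePercentages:
    def test_universal_role_is_100(self):
        counts = pd.Series({"A": 10, "B": 90})
        roles = {"A": {"nutrient-transfer"}, "B": {"nutrient-transfer"}}
        out = bf.role_percentages(counts, roles)
        assert out["nutrient-transfer"] == pytest.approx(100.0)

    def test_half_share(self):
        counts = pd.Series({"A": 50, "B": 50})
        roles = {"A": {"pollinator"}, "B": {"decomposer"}}
        out = bf.role_percentages(counts, roles)
        assert out["pollinator"] == pytest.approx(50.0)

    def test_constructed_share_recovered(self):
        counts = pd.Series({"A": 875, "B": 125})
        roles = {"A": {"pollinator", "nutrient-transfer"},
                 "B": {"nutrient-transfer"}}
        out = bf.role_percentages(counts, roles)
        assert out["pollinator"] == pytest.approx(87.5)

    def test_missing_taxon_listed(self):
        with pytest.raises(KeyError, match="Mystery"):
            bf.role_percentages(pd.Series({"Mystery": 1}), {})


class TestHistoricalComparison:
    def test_hoverfly_benchmark(self):
        """A scaled count of 6100 is just over 46% of 13228."""
        pct = bf.historical_comparison(6100, 13228)
        assert pct == pytest.approx(46.1, abs=0.05)

    def test_identity(self):
        assert bf.historical_comparison(777, 777) == pytest.approx(100.0)

    def test_minor_species_benchmark(self):
        pct = bf.historical_comparison(2798, 107602)
        assert pct == pytest.approx(2.6, abs=0.05)

    def test_zero_benchmark_rejected(self):
        with pytest.raises(ValueError):
            bf.historical_comparison(100, 0)
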