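import datetime as dt
import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ballastrisk.data_io import TankRecord
from ballastrisk.env_distance import fit_annual_norm, fit_monthly_norm
from ballastrisk.temporal_comparison import (
    DEFAULT_DIFF_THRESHOLDS,
    DiffThresholds,
    diff_category,
    diff_thresholds_from_data,
    effect_size_r,
    histogram_table,
    pair_distances,
    per_port_average_diff,
    regional_comparison,
    wilcoxon_paired,
)

from .conftest import make_profile, sinusoid_profile


def exact_wilcoxon_p(diffs):
    """Independent oracle: two-sided p by enumerating all sign assignments
    of the ranked absolute differences."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = d.size
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = np.array(
        [sum(r for r, s in zip(ranks, signs) if s) for signs in
         itertools.product([False, True], repeat=n)]
    )
    p_low = np.mean(ws <= w_obs)
    p_high = np.mean(ws >= w_obs)
    return min(1.0, 2.0 * min(p_low, p_high))


class TestWilcoxon:
    def test_all_positive_sextet_worked_case(self):
        res = wilcoxon_paired(diffs=[1, 2, 3, 4, 5, 6])
        assert res.p_value == pytest.approx(2 / 64)
        assert res.z_statistic > 0

    def test_exact_p_equals_enumeration_for_all_sign_patterns(self):
        magnitudes = np.array([0.7, 1.3, 2.1, 3.4, 4.2, 5.9, 6.1, 7.7])
        for signs in itertools.product([-1, 1], repeat=len(magnitudes)):
            d = magnitudes * signs
            res = wilcoxon_paired(diffs=d)
            assert res.p_value == pytest.approx(exact_wilcoxon_p(d), abs=1e-12)

    def test_exact_p_matches_enumeration_on_random_samples(self):
        rng = np.random.default_rng(8)
        for n in (3, 5, 7, 10):
            for _ in range(10):
                d = rng.normal(0.3, 1.0, n)
                res = wilcoxon_paired(diffs=d)
                assert res.p_value == pytest.approx(exact_wilcoxon_p(d), abs=1e-12)

    def test_antisymmetric_pair_sits_at_null_centre(self):
        res = wilcoxon_paired(diffs=[-1.5, 1.5])
        assert res.z_statistic == 0.0
        assert res.p_value == 1.0

    def test_all_zero_diffs_flagged_degenerate(self):
        res = wilcoxon_paired(diffs=[0.0, 0.0, 0.0])
        assert res.degenerate and res.n_nonzero == 0
        assert res.p_value == 1.0

    def test_zeros_dropped_before_ranking(self):
        res = wilcoxon_paired(diffs=[0.0, 1.0, 2.0, 3.0])
        assert res.n == 4 and res.n_nonzero == 3

    def test_power_approaches_one_with_growing_shift(self):
        rng = np.random.default_rng(9)
        rejections = []
        for shift in (0.0, 0.3, 1.0):
            rej = sum(
                wilcoxon_paired(diffs=rng.normal(shift, 1.0, 100)).p_value < 0.05
                for _ in range(50)
            )
            rejections.append(rej / 50)
        assert rejections[0] < 0.2
        assert rejections[1] > rejections[0]
        assert rejections[2] > 0.95

    def test_signed_z_tracks_direction(self):
        rng = np.random.default_rng(10)
        up = wilcoxon_paired(diffs=rng.normal(1.0, 1.0, 200))
        down = wilcoxon_paired(diffs=rng.normal(-1.0, 1.0, 200))
        assert up.z_statistic > 0 > down.z_statistic


class TestEffectSize:
    @pytest.mark.parametrize(
        "z,n,r,mag",
        [
            (2.82, 100, 0.282, "small"),
            (0.0, 50, 0.0, "small"),
            (4.0, 100, 0.4, "moderate"),
            (6.37, 100, 0.637, "large"),
            (5.0, 100, 0.5, "large"),
        ],
    )
    def test_r_and_magnitude(self, z, n, r, mag):
        got_r, got_mag = effect_size_r(z, n)
        assert got_r == pytest.approx(r, abs=1e-9)
        assert got_mag == mag

    def test_sign_of_z_is_irrelevant(self):
        assert effect_size_r(-3.0, 100) == effect_size_r(3.0, 100)


class TestDiffThresholds:
    def test_positive_percentiles_by_hand(self):
        diffs = list(range(1, 101)) + [-1.0]
        t = diff_thresholds_from_data(diffs)
        assert t.pos75 == pytest.approx(75.25)
        assert t.pos90 == pytest.approx(90.1)

    def test_symmetric_diffs_mirror_thresholds(self):
        rng = np.random.default_rng(12)
        pos = rng.uniform(0.1, 5.0, 500)
        t = diff_thresholds_from_data(np.concatenate([pos, -pos]))
        assert t.neg75 == pytest.approx(-t.pos75)
        assert t.neg90 == pytest.approx(-t.pos90)

    def test_one_sided_data_degrades_gracefully(self):
        t = diff_thresholds_from_data([1.0, 2.0, 3.0])
        assert t.neg75 is None and t.neg90 is None
        assert diff_category(-10.0, t) is None
        assert diff_category(10.0, t) == "much lower risk"

    def test_published_defaults(self):
        t = DEFAULT_DIFF_THRESHOLDS
        assert (t.pos75, t.pos90, t.neg75, t.neg90) == (0.835, 1.586, -1.720, -2.248)

    @pytest.mark.parametrize(
        "diff,expected",
        [
            (2.0, "much lower risk"),
            (1.586, "lower risk"),      # boundary joins the inner band
            (1.0, "lower risk"),
            (0.835, "lower risk"),
            (0.1, None),
            (-0.5, None),
            (-1.720, "higher risk"),
            (-2.0, "higher risk"),
            (-2.248, "higher risk"),
            (-3.0, "much higher risk"),
        ],
    )
    def test_category_bands(self, diff, expected):
        assert diff_category(diff) == expected

    def test_invalid_ordering_rejected(self):
        with pytest.raises(Exception):
            DiffThresholds(pos75=2.0, pos90=1.0)


def record(tank_id, src, dst, uptake, discharge):
    return TankRecord(tank_id, src, dst, dt.date.fromisoformat(uptake),
                      dt.date.fromisoformat(discharge))


class TestPairDistances:
    @pytest.fixture()
    def world(self):
        profiles = {
            "SRC": sinusoid_profile("SRC", base=12.0, amp=8.0, peak_month=7),
            "FLAT": make_profile("FLAT", T=np.full(12, 6.0), S=np.full(12, 32.0)),
            "DST": sinusoid_profile("DST", base=8.0, amp=4.0, peak_month=7, S=31.0),
        }
        plist = list(profiles.values())
        return profiles, fit_annual_norm(plist), fit_monthly_norm(plist)

    def test_conservation_one_pair_per_record(self, world):
        profiles, an, mn = world
        records = [record(f"t{i}", "SRC", "DST", "2019-03-01", "2019-03-20")
                   for i in range(7)]
        pairs, skipped = pair_distances(records, profiles, an, mn)
        assert len(pairs) == 7 and not skipped
        assert (pairs["diff"] == pairs["d_month"] - pairs["d_annual"]).all()

    def test_unprofiled_port_skipped_and_reported(self, world):
        profiles, an, mn = world
        records = [record("t0", "SRC", "DST", "2019-03-01", "2019-03-20"),
                   record("t1", "GHOST", "DST", "2019-03-01", "2019-03-20")]
        pairs, skipped = pair_distances(records, profiles, an, mn)
        assert len(pairs) == 1 and len(skipped) == 1
        assert "GHOST" in skipped[0]["reason"]

    def test_seasonal_source_diff_sign_flips_across_seasons(self, world):
        profiles, an, mn = world
        # same route sailed in winter and in summer
        winter = record("w", "SRC", "FLAT", "2019-01-05", "2019-01-25")
        summer = record("s", "SRC", "FLAT", "2019-07-05", "2019-07-25")
        pairs, _ = pair_distances([winter, summer], profiles, an, mn)
        d = pairs.set_index("tank_id")["diff"]
        assert np.sign(d["w"]) != np.sign(d["s"])


class TestAggregation:
    def make_pairs(self, rows):
        return pd.DataFrame(
            rows,
            columns=["tank_id", "source_port_id", "dest_port_id", "dest_coast",
                     "year", "d_month", "d_annual", "diff"],
        )

    def test_per_port_mean_then_categorise(self):
        pairs = self.make_pairs(
            [("t0", "S", "P", "Pacific", 2019, 1.0, 4.0, -3.0),
             ("t1", "S", "P", "Pacific", 2019, 3.0, 4.0, -1.0)]
        )
        out = per_port_average_diff(pairs)
        assert out.loc[0, "mean_diff"] == pytest.approx(-2.0)
        assert out.loc[0, "category"] == "higher risk"

    def test_single_tank_port_mean_is_that_diff(self):
        pairs = self.make_pairs([("t0", "S", "P", "Pacific", 2019, 1.0, 2.0, -1.0)])
        out = per_port_average_diff(pairs)
        assert out.loc[0, "mean_diff"] == -1.0 and out.loc[0, "category"] == ""

    def test_balanced_diffs_cancel(self):
        pairs = self.make_pairs(
            [("t0", "S", "P", "Pacific", 2019, 5.0, 2.0, 3.0),
             ("t1", "S", "P", "Pacific", 2019, -1.0, 2.0, -3.0)]
        )
        out = per_port_average_diff(pairs)
        assert out.loc[0, "mean_diff"] == 0.0 and out.loc[0, "category"] == ""

    def test_regional_grouping_produces_one_row_per_region_year(self):
        rng = np.random.default_rng(13)
        rows = []
        for region in ("Pacific", "Atlantic", "Arctic"):
            for year in (2019, 2020):
                for i in range(30):
                    d = rng.normal(-0.5, 1.0)
                    rows.append((f"{region}{year}{i}", "S", "P", region, year,
                                 3.0 + d, 3.0, d))
        res = regional_comparison(self.make_pairs(rows))
        assert len(res) == 6
        assert set(res["region"]) == {"Pacific", "Atlantic", "Arctic"}

    def test_duplicated_year_gives_identical_effect_size(self):
        rng = np.random.default_rng(14)
        d = rng.normal(-0.8, 1.0, 60)
        rows = [(f"a{i}", "S", "P", "Atlantic", year, 3 + d[i], 3.0, d[i])
                for year in (2019, 2020) for i in range(60)]
        res = regional_comparison(self.make_pairs(rows))
        assert res.loc[0, "r"] == res.loc[1, "r"]

    def test_injected_strong_shift_yields_large_magnitude(self):
        rng = np.random.default_rng(15)
        rows = []
        for i in range(200):
            strong = rng.normal(-2.0, 1.0)
            weak = rng.normal(0.0, 1.0)
            rows.append((f"s{i}", "S", "P", "Arctic", 2019, 3 + strong, 3.0, strong))
            rows.append((f"w{i}", "S", "P", "Pacific", 2019, 3 + weak, 3.0, weak))
        res = regional_comparison(self.make_pairs(rows)).set_index("region")
        assert res.loc["Arctic", "magnitude"] == "large"
        assert res.loc["Pacific", "magnitude"] == "small"

    def test_sign_coherence_mean_diff_matches_z_direction(self):
        rng = np.random.default_rng(16)
        d = rng.normal(-0.6, 0.5, 80)
        res = regional_comparison(
            self.make_pairs(
                [(f"t{i}", "S", "P", "Pacific", 2019, 3 + d[i], 3.0, d[i])
                 for i in range(80)]
            )
        )
        assert res.loc[0, "mean_diff"] < 0 and res.loc[0, "z_statistic"] < 0

    def test_histogram_table_counts_everything(self):
        rng = np.random.default_rng(17)
        vals = rng.normal(size=500)
        h = histogram_table(vals, bins=20)
        assert h["count"].sum() == 500
        assert (h["bin_right"] > h["bin_left"]).all()
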