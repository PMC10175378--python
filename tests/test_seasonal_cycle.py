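import datetime as dt

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ballastrisk.data_io import TankRecord
from ballastrisk.env_distance import fit_monthly_norm
from ballastrisk.errors import UsageError
from ballastrisk.seasonal_cycle import (
    arrival_month,
    cycle_monthly_distances,
    equal_interval_bins,
    flag_top_decile,
    high_intensity_high_variability,
    port_env_stdev,
    region_month_means,
    summarize_port_pairs,
    unique_port_pairs,
)

from .conftest import make_profile, sinusoid_profile


class TestPortEnvStdev:
    def test_constant_profile_has_zero_spread(self):
        s = port_env_stdev(make_profile())
        assert s.stdev_T == 0.0 and s.stdev_S == 0.0

    def test_linear_ramp_hand_value(self):
        s = port_env_stdev(make_profile(T=np.arange(1.0, 13.0)))
        assert s.stdev_T == pytest.approx(np.std(np.arange(1, 13), ddof=1))
        assert s.stdev_T == pytest.approx(3.6056, abs=1e-4)

    def test_sinusoid_amplitude_relation(self):
        # 12 equispaced samples of a pure sinusoid: population sd = A/sqrt(2)
        A = 6.0
        s = port_env_stdev(sinusoid_profile(amp=A, base=10.0))
        assert s.stdev_T == pytest.approx(A / np.sqrt(2) * np.sqrt(12 / 11), rel=1e-9)


class TestEqualIntervalBins:
    def test_even_span_edges(self):
        edges, idx = equal_interval_bins([0.0, 2.0, 4.0, 6.0, 8.0, 10.0], k=5)
        np.testing.assert_allclose(edges, [0, 2, 4, 6, 8, 10])
        assert list(idx) == [0, 1, 2, 3, 4, 4]

    def test_maximum_joins_top_bin(self):
        _, idx = equal_interval_bins([0.0, 10.0], k=4)
        assert idx[1] == 3

    def test_single_bin_for_degenerate_range(self):
        edges, idx = equal_interval_bins([3.0, 3.0, 3.0], k=4)
        assert set(idx) == {0}

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(
        st.lists(st.floats(-100, 100, allow_nan=False), min_size=2, max_size=30),
        st.integers(1, 10),
    )
    def test_indices_consistent_with_direct_width_computation(self, values, k):
        edges, idx = equal_interval_bins(values, k)
        lo, hi = min(values), max(values)
        assert ((idx >= 0) & (idx < k)).all()
        if hi > lo:
            width = (hi - lo) / k
            for v, i in zip(values, idx):
                expected = min(int((v - lo) / width), k - 1)
                assert i == expected


def record(tank_id, src, dst, uptake, days):
    up = dt.date.fromisoformat(uptake)
    return TankRecord(tank_id, src, dst, up, up + dt.timedelta(days=days))


class TestUniquePortPairs:
    def test_tau_is_mean_voyage_time(self):
        recs = [record(f"t{i}", "A", "B", "2019-01-01", days) for i, days in
                enumerate((10, 20, 30))]
        pairs = unique_port_pairs(recs)
        assert len(pairs) == 1
        assert pairs.loc[0, "n_tanks"] == 3 and pairs.loc[0, "tau"] == 20.0

    def test_replicate_tanks_collapse_to_one_route(self):
        recs = [record(f"t{i}", "ZHO", "VAN", "2019-03-01", 12) for i in range(854)]
        pairs = unique_port_pairs(recs)
        assert len(pairs) == 1 and pairs.loc[0, "n_tanks"] == 854

    def test_counts_conserved_across_routes(self):
        recs = [record("a", "A", "B", "2019-01-01", 5),
                record("b", "A", "B", "2019-02-01", 7),
                record("c", "A", "C", "2019-03-01", 9)]
        pairs = unique_port_pairs(recs)
        assert len(pairs) == 2 and pairs["n_tanks"].sum() == 3


class TestVoyageCycling:
    def test_zero_tau_arrives_in_start_month(self):
        assert [arrival_month(m, 0) for m in range(1, 13)] == list(range(1, 13))

    def test_december_departure_wraps_to_january(self):
        assert arrival_month(12, 45) == 1

    def test_negative_tau_rejected(self):
        with pytest.raises(UsageError):
            arrival_month(1, -1)

    def test_constant_pair_has_flat_cycle(self):
        profiles = [make_profile("A", T=np.full(12, 5.0)),
                    make_profile("B", T=np.full(12, 15.0), S=np.full(12, 33.0))]
        norm = fit_monthly_norm(profiles)
        d = cycle_monthly_distances(profiles[0], profiles[1], 20.0, norm)
        assert d.shape == (12,)
        assert np.ptp(d) == pytest.approx(0.0, abs=1e-12)

    def test_hemisphere_antiphase_shifts_curve_six_months(self):
        north = sinusoid_profile("N", base=12, amp=8, peak_month=7)
        south = sinusoid_profile("S", base=12, amp=8, peak_month=1)
        dest = make_profile("D", T=np.full(12, 4.0), S=np.full(12, 33.0))
        norm = fit_monthly_norm([north, south, dest])
        dn = cycle_monthly_distances(north, dest, 0.0, norm)
        ds = cycle_monthly_distances(south, dest, 0.0, norm)
        np.testing.assert_allclose(ds, np.roll(dn, 6), atol=1e-9)

    def test_amplitude_growth_never_reduces_cycle_spread(self):
        dest = make_profile("D", T=np.full(12, 30.0), S=np.full(12, 33.0))
        ref = [sinusoid_profile("R", base=10, amp=8), dest]
        norm = fit_monthly_norm(ref)  # fixed scaling across amplitudes
        spreads = []
        for amp in (0.0, 2.0, 4.0, 8.0):
            src = sinusoid_profile("S", base=10, amp=amp)
            d = cycle_monthly_distances(src, dest, 15.0, norm)
            spreads.append(np.std(d, ddof=1))
        assert all(b >= a - 1e-12 for a, b in zip(spreads, spreads[1:]))


class TestSummaries:
    def build_summaries(self):
        src_a = sinusoid_profile("A", base=10, amp=8)       # strongly seasonal
        src_b = make_profile("B", T=np.full(12, 12.0))      # flat
        dst = make_profile("D", T=np.full(12, 5.0), S=np.full(12, 33.0))
        profiles = {"A": src_a, "B": src_b, "D": dst}
        norm = fit_monthly_norm(list(profiles.values()))
        recs = [record(f"a{i}", "A", "D", "2019-01-01", 10) for i in range(300)]
        recs += [record("b0", "B", "D", "2019-01-01", 10)]
        return summarize_port_pairs(
            recs, profiles, norm, source_regions={"A": "Eastern Asia", "B": "Tropics"}
        )

    def test_one_row_per_route_with_counts_conserved(self):
        s = self.build_summaries()
        assert len(s) == 2 and s["n_tanks"].sum() == 301

    def test_seasonal_route_flagged_top_decile(self):
        s = self.build_summaries().set_index("source_port_id")
        assert s.loc["A", "stdev_cycle"] > s.loc["B", "stdev_cycle"]
        assert bool(s.loc["A", "top_decile"])

    def test_high_intensity_high_variability_join(self):
        s = self.build_summaries()
        hot = high_intensity_high_variability(s, min_tanks=250)
        assert list(hot["source_port_id"]) == ["A"]

    def test_exactly_one_of_ten_distinct_spreads_flagged(self):
        import pandas as pd

        df = pd.DataFrame({"stdev_cycle": np.linspace(0.1, 1.0, 10)})
        flagged = flag_top_decile(df)
        assert flagged["top_decile"].sum() == 1
        assert flagged.loc[9, "top_decile"]

    def test_all_equal_spreads_all_flagged(self):
        import pandas as pd

        df = pd.DataFrame({"stdev_cycle": np.ones(10)})
        assert flag_top_decile(df)["top_decile"].all()

    def test_region_month_means_single_pair_identity(self):
        s = self.build_summaries()
        means = region_month_means(s)
        asia = means[means["source_region"] == "Eastern Asia"]
        row_a = s[s["source_port_id"] == "A"].iloc[0]
        for m in range(1, 13):
            got = asia.loc[asia["start_month"] == m, "mean_distance"].iloc[0]
            assert got == pytest.approx(row_a[f"d{m:02d}"])

    def test_duplicate_pairs_leave_means_unchanged(self):
        import pandas as pd

        s = self.build_summaries()
        doubled = pd.concat([s, s], ignore_index=True)
        a = region_month_means(s)
        b = region_month_means(doubled)
        np.testing.assert_allclose(a["mean_distance"], b["mean_distance"])
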