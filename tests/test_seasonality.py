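"""Quartile baseline construction and the season decision table."""

import numpy as np
import pytest

from shellprov import (
    assign_season,
    build_baseline,
    edge_trend,
    edge_value,
    season_table,
    SeasonClassifier,
)
from shellprov.seasonality import BaselineError, ReconciliationError, SeasonalBaseline
from conftest import make_profile

import pandas as pd


def baseline_from_range(lo, hi, site="siteX"):
    return SeasonalBaseline(
        site=site,
        d18o_min=lo,
        d18o_max=hi,
        boundaries=tuple(lo + k * (hi - lo) / 4 for k in (1, 2, 3)),
        source_shells=("b1",),
    )


class TestBuildBaseline:
    def test_equal_width_boundaries(self):
        p = make_profile([-0.5, 0.2, 1.5, 0.8], role="baseline")
        b = build_baseline([p])
        assert b.boundaries == pytest.approx((0.0, 0.5, 1.0))
        widths = np.diff((b.d18o_min,) + b.boundaries + (b.d18o_max,))
        assert widths == pytest.approx([0.5] * 4)

    def test_pooling_across_shells(self):
        p1 = make_profile([0.0, 0.5, 1.0, 0.3], shell_id="a", role="baseline")
        p2 = make_profile([0.5, 1.2, 2.0, 1.8], shell_id="b", role="baseline")
        b = build_baseline([p1, p2])
        assert (b.d18o_min, b.d18o_max) == (0.0, 2.0)
        assert b.boundaries == pytest.approx((0.5, 1.0, 1.5))
        assert b.source_shells == ("a", "b")

    def test_open_coast_only_with_no_open_coast_errors(self):
        p = make_profile([0.0, 1.0, 0.5, 0.2], shell_id="a", role="baseline")
        with pytest.raises(BaselineError):
            build_baseline(
                [p], filter="open_coast_only", provenance={"a": "upper_estuary"}
            )

    def test_seasonality_shells_excluded_from_baseline(self):
        b_shell = make_profile([0.0, 1.0, 0.5, 0.2], shell_id="a", role="baseline")
        s_shell = make_profile([5.0, 6.0, 5.5, 5.2], shell_id="b", role="seasonality")
        b = build_baseline([b_shell, s_shell])
        assert b.d18o_max == 1.0  # the short shell's extremes play no part

    def test_distribution_mode_uses_quantiles(self):
        vals = [0.0, 0.2, 0.4, 0.9, 1.1, 1.6, 1.8, 2.0]
        p = make_profile(vals, role="baseline")
        b = build_baseline([p], mode="distribution")
        assert b.boundaries == pytest.approx(tuple(np.quantile(vals, [0.25, 0.5, 0.75])))


class TestEdgeValue:
    def test_last_sample_default(self):
        p = make_profile([0.5, 0.8, 1.2])
        assert edge_value(p) == pytest.approx(1.2)

    def test_window_mean(self):
        p = make_profile([9.9, 1.0, 1.1, 1.3])
        assert edge_value(p, edge_window=3) == pytest.approx((1.0 + 1.1 + 1.3) / 3)

    @pytest.mark.parametrize("w", [0, 5])
    def test_bad_window(self, w):
        with pytest.raises(ValueError):
            edge_value(make_profile([0.1, 0.2, 0.3]), edge_window=w)


class TestEdgeTrend:
    def test_strictly_increasing_is_rising(self):
        p = make_profile([0.1 * i for i in range(10)])
        trend, slope = edge_trend(p)
        assert trend == "rising" and slope > 0

    def test_constant_is_flat(self):
        trend, slope = edge_trend(make_profile([0.7] * 10))
        assert trend == "flat" and slope == pytest.approx(0.0, abs=1e-12)

    def test_matches_normal_equations_oracle(self):
        y = [0.0, 0.3, 0.1, 0.4, 0.2, 0.5, 0.3, 0.6, 0.4, 0.7]
        x = list(range(10))
        n = len(y)
        # closed-form OLS slope: (n Σxy − Σx Σy) / (n Σx² − (Σx)²)
        sxy = sum(a * b for a, b in zip(x, y))
        expected = (n * sxy - sum(x) * sum(y)) / (n * sum(v * v for v in x) - sum(x) ** 2)
        trend, slope = edge_trend(make_profile(y))
        assert slope == pytest.approx(expected, abs=1e-12)
        assert trend == "rising"

    def test_window_clipped_to_profile(self):
        # only the last 3 of 20 samples fall in the window
        vals = [1.0] * 17 + [0.5, 0.3, 0.1]
        trend, _ = edge_trend(make_profile(vals), trend_window=3)
        assert trend == "falling"


@pytest.fixture(scope="module")
def baseline():
    return baseline_from_range(0.0, 2.0)  # bands at 0.5, 1.0, 1.5


class TestAssignSeason:
    @pytest.mark.parametrize(
        "edge,trend,season,confirmed",
        [
            (2.0, "rising", "winter", True),  # baseline max: coldest water
            (2.0, "falling", "winter", False),  # contradictory approach
            (0.0, "falling", "summer", True),  # baseline min: warmest
            (0.0, "rising", "summer", False),
            (1.3, "rising", "autumn", True),  # Q3 midpoint, cooling limb
            (1.3, "falling", "spring", True),
            (0.7, "falling", "spring", True),  # Q2, warming limb
            (0.7, "rising", "autumn", True),
            (0.7, "flat", "spring", False),  # flat tie: midpoint side
            (1.3, "flat", "autumn", False),
        ],
    )
    def test_decision_table(self, baseline, edge, trend, season, confirmed):
        a = assign_season(edge, trend, baseline)
        assert (a.season, a.confirmed) == (season, confirmed)

    @pytest.mark.parametrize(
        "edge,band,season",
        [(-0.5, "Q1", "summer"), (2.5, "Q4", "winter")],
    )
    def test_out_of_range_clamps_and_flags(self, baseline, edge, band, season):
        a = assign_season(edge, "flat", baseline)
        assert a.out_of_range
        assert a.band == band and a.season == season

    def test_band_partition_is_exhaustive(self, baseline):
        for edge in np.linspace(0.0, 2.0, 101):
            band, out = baseline.band(float(edge))
            assert band in ("Q1", "Q2", "Q3", "Q4") and not out


class TestSeasonTable:
    def test_proportions_mirror_counts(self):
        seasons = pd.DataFrame(
            {
                "shell_id": [f"s{i}" for i in range(8)],
                "site": ["P"] * 8,
                "season": ["winter"] * 5 + ["autumn"] * 3,
            }
        )
        provenance = pd.DataFrame(
            {"shell_id": [f"s{i}" for i in range(8)], "habitat": ["open_coast"] * 8}
        )
        tab = season_table(seasons, provenance)
        by_season = dict(zip(tab.season, tab.proportion))
        assert by_season["winter"] == pytest.approx(0.625)
        assert by_season["autumn"] == pytest.approx(0.375)

    def test_single_shell(self):
        seasons = pd.DataFrame(
            {"shell_id": ["s1"], "site": ["P"], "season": ["spring"]}
        )
        provenance = pd.DataFrame({"shell_id": ["s1"], "habitat": ["open_coast"]})
        tab = season_table(seasons, provenance)
        assert tab.proportion.iloc[0] == 1.0

    def test_mismatched_ids_raise(self):
        seasons = pd.DataFrame({"shell_id": ["a"], "site": ["P"], "season": ["winter"]})
        provenance = pd.DataFrame({"shell_id": ["b"], "habitat": ["open_coast"]})
        with pytest.raises(ReconciliationError, match="a"):
            season_table(seasons, provenance)


class TestSeasonClassifierEstimator:
    def _profiles(self):
        rng = np.random.default_rng(7)
        base = make_profile(
            list(np.linspace(-0.5, 1.5, 30)), shell_id="base", role="baseline"
        )
        short = make_profile(
            list(np.linspace(1.4, 1.5, 10)), shell_id="edge_winter", role="seasonality"
        )
        return [base, short]

    def test_fit_predict(self):
        profiles = self._profiles()
        clf = SeasonClassifier().fit(profiles)
        assert set(clf.baselines_) == {"siteX"}
        seasons = clf.predict(profiles[1:])
        assert seasons[0] == "winter"  # high, rising edge δ18O = cold water

    def test_assign_table_schema(self):
        profiles = self._profiles()
        tab = SeasonClassifier().fit(profiles).assign_table(profiles)
        assert list(tab.columns) == [
            "shell_id", "site", "unit", "edge_d18o", "band", "trend_slope",
            "trend", "season", "confirmed", "out_of_range", "baseline_filter",
        ]
        assert len(tab) == 2

    def test_sklearn_clone(self):
        from sklearn.base import clone

        clf = SeasonClassifier(trend_window=5, baseline_filter="open_coast_only")
        assert clone(clf).get_params()["trend_window"] == 5
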