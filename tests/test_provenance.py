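"""Fisher-z intervals and the habitat decision surface."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from shellprov import (
    HabitatClassifier,
    build_calibration,
    classify_assemblage,
    classify_shell,
    fisher_interval,
    pearson_r,
    simulate_shell,
)
from shellprov.provenance import (
    CalibrationOverlapWarning,
    DegenerateSeriesError,
)
from shellprov.synthetic import DEFAULT_HABITATS, EnvironmentParams
from conftest import make_profile


class TestPearsonR:
    def test_perfect_anticorrelation(self):
        o = [0.1 * i for i in range(10)]
        p = make_profile(o, d13c=[-v for v in o])
        assert pearson_r(p) == pytest.approx(-1.0)

    def test_matches_covariance_oracle(self):
        # brute-force covariance / (sigma_x sigma_y) on fixed values
        o = [0.0, 1.0, 2.0, 3.0, 4.0]
        c = [0.2, 0.1, 0.4, 0.3, 0.6]
        mo, mc = sum(o) / 5, sum(c) / 5
        cov = sum((a - mc) * (b - mo) for a, b in zip(c, o)) / 5
        so = math.sqrt(sum((b - mo) ** 2 for b in o) / 5)
        sc = math.sqrt(sum((a - mc) ** 2 for a in c) / 5)
        expected = cov / (so * sc)
        assert pearson_r(make_profile(o, d13c=c)) == pytest.approx(expected, abs=1e-12)

    def test_constant_series_degenerate(self):
        p = make_profile([0.1, 0.2, 0.3, 0.4], d13c=[1.0] * 4)
        with pytest.raises(DegenerateSeriesError):
            pearson_r(p)

    def test_too_short(self):
        with pytest.raises(ValueError, match="4 samples"):
            pearson_r(make_profile([0.1, 0.2, 0.3]))


class TestFisherInterval:
    @pytest.mark.parametrize(
        "r,n,lo,hi",
        [
            (-0.27, 159, -0.41, -0.12),  # fully marine reference
            (0.13, 88, -0.08, 0.33),  # lower estuary
            (0.56, 88, 0.40, 0.69),  # upper estuary
        ],
    )
    def test_reference_bounds_at_two_decimals(self, r, n, lo, hi):
        a, b = fisher_interval(r, n, 0.95)
        assert round(a, 2) == lo
        assert round(b, 2) == hi

    def test_symmetric_about_zero(self):
        lo, hi = fisher_interval(0.0, 103, 0.95)
        assert lo == pytest.approx(-hi, abs=1e-15)

    @pytest.mark.parametrize("r,n", [(0.5, 3), (1.0, 100), (-1.0, 100)])
    def test_domain_errors(self, r, n):
        with pytest.raises(ValueError):
            fisher_interval(r, n)

    @given(
        r=st.floats(-0.95, 0.95),
        n=st.integers(5, 500),
        level=st.floats(0.5, 0.99),
    )
    def test_interval_brackets_r_and_stays_in_unit_disc(self, r, n, level):
        lo, hi = fisher_interval(r, n, level)
        assert -1 < lo < r < hi < 1

    @given(r=st.floats(-0.9, 0.9), n=st.integers(5, 400))
    def test_width_decreases_with_n(self, r, n):
        lo1, hi1 = fisher_interval(r, n)
        lo2, hi2 = fisher_interval(r, n + 50)
        assert (hi2 - lo2) < (hi1 - lo1)

    def test_agrees_with_bootstrap_on_bivariate_normal(self, rng):
        # independent oracle: percentile bootstrap of r, n=500, 2000 resamples
        n, true_r = 500, 0.5
        cov = [[1, true_r], [true_r, 1]]
        x, y = rng.multivariate_normal([0, 0], cov, size=n).T
        r_hat = float(np.corrcoef(x, y)[0, 1])
        idx = rng.integers(0, n, size=(2000, n))
        xs, ys = x[idx], y[idx]
        xs = xs - xs.mean(axis=1, keepdims=True)
        ys = ys - ys.mean(axis=1, keepdims=True)
        boots = (xs * ys).sum(axis=1) / np.sqrt(
            (xs**2).sum(axis=1) * (ys**2).sum(axis=1)
        )
        b_lo, b_hi = np.percentile(boots, [2.5, 97.5])
        f_lo, f_hi = fisher_interval(r_hat, n, 0.95)
        assert f_lo == pytest.approx(b_lo, abs=0.03)
        assert f_hi == pytest.approx(b_hi, abs=0.03)


class TestBuildCalibration:
    def test_default_ordering(self):
        cals = build_calibration()
        assert [c.habitat for c in cals] == [
            "open_coast",
            "lower_estuary",
            "upper_estuary",
        ]
        for c in cals:
            assert c.ci_low < c.r_ref < c.ci_high

    def test_single_habitat(self):
        cals = build_calibration([("only", 0.2, 50)])
        assert len(cals) == 1

    def test_identical_r_tie_breaks_by_label_and_warns(self):
        with pytest.warns(CalibrationOverlapWarning):
            cals = build_calibration([("b_hab", 0.2, 50), ("a_hab", 0.2, 50)])
        assert [c.habitat for c in cals] == ["a_hab", "b_hab"]

    def test_duplicate_habitats_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            build_calibration([("x", 0.1, 50), ("x", 0.3, 50)])


@pytest.fixture(scope="module")
def cals():
    return build_calibration()


class TestClassifyShell:
    @pytest.mark.parametrize(
        "r_obs,habitat,rule",
        [
            (-0.11, "unknown", "gap_unknown"),  # the unplaceable-gap case
            (-0.55, "open_coast", "below_marine_extension"),
            (0.75, "upper_estuary", "above_estuary_extension"),
            (0.13, "lower_estuary", "within_ci"),
            (-0.27, "open_coast", "within_ci"),
            (0.56, "upper_estuary", "within_ci"),
            (0.36, "unknown", "gap_unknown"),  # between lower and upper CIs
        ],
    )
    def test_decision_surface(self, cals, r_obs, habitat, rule):
        a = classify_shell(r_obs, cals)
        assert (a.habitat, a.rule) == (habitat, rule)

    def test_every_boundary_epsilon(self, cals):
        eps = 1e-9
        for c in cals:
            for bound in (c.ci_low, c.ci_high):
                inside = classify_shell(bound, cals)
                assert inside.habitat == c.habitat  # closed interval
                assert inside.rule == "within_ci"
            just_below = classify_shell(c.ci_low - eps, cals)
            just_above = classify_shell(c.ci_high + eps, cals)
            assert just_below.habitat != c.habitat or just_below.rule != "within_ci"
            assert just_above.habitat != c.habitat or just_above.rule != "within_ci"

    @given(r=st.floats(-1, 1))
    def test_total_deterministic_partition(self, r):
        cals = build_calibration()
        a = classify_shell(r, cals)
        b = classify_shell(r, cals)
        assert (a.habitat, a.rule) == (b.habitat, b.rule)
        assert a.rule in {
            "within_ci",
            "below_marine_extension",
            "above_estuary_extension",
            "gap_unknown",
        }

    def test_overlapping_cis_give_ambiguous(self):
        with pytest.warns(CalibrationOverlapWarning):
            cals = build_calibration([("a", 0.10, 30), ("b", 0.20, 30)])
        assert classify_shell(0.15, cals).rule == "ambiguous_overlap"


class TestClassifyAssemblage:
    def test_proportions(self):
        profiles = []
        for i in range(8):  # strongly negative r -> open coast
            o = [0.1 * j for j in range(10)]
            profiles.append(
                make_profile(o, d13c=[-v for v in o], shell_id=f"oc{i}", site="P")
            )
        for i in range(2):  # strongly positive r -> upper estuary
            o = [0.1 * j for j in range(10)]
            profiles.append(
                make_profile(o, d13c=o, shell_id=f"ue{i}", site="P")
            )
        assignments, props = classify_assemblage(profiles)
        assert len(assignments) == 10
        oc = props[(props.site == "P") & (props.habitat == "open_coast")]
        assert oc["proportion"].iloc[0] == pytest.approx(0.80)
        assert props.groupby("site")["proportion"].sum().iloc[0] == pytest.approx(1.0)

    def test_empty_input(self):
        assignments, props = classify_assemblage([])
        assert assignments.empty and props.empty

    def test_degenerate_shell_counted_as_unknown(self):
        p = make_profile([0.1, 0.2, 0.3, 0.4], d13c=[1.0] * 4)
        assignments, _ = classify_assemblage([p])
        assert assignments.iloc[0].habitat == "unknown"
        assert assignments.iloc[0].rule == "degenerate"

    def test_simulated_noisefree_shells_recover_habitat(self):
        env = EnvironmentParams()
        profiles = []
        for i, (name, hp) in enumerate(DEFAULT_HABITATS.items()):
            prof, _ = simulate_shell(
                env, hp, capture_doy=100, n_samples=200, span_days=365,
                seed=i, shell_id=name, site="sim",
            )
            profiles.append(prof)
        assignments, _ = classify_assemblage(profiles)
        assert dict(zip(assignments.shell_id, assignments.habitat)) == {
            h: h for h in DEFAULT_HABITATS
        }


class TestHabitatClassifierEstimator:
    def test_sklearn_contract(self):
        from sklearn.base import clone

        clf = HabitatClassifier(ci_level=0.9)
        cloned = clone(clf)
        assert cloned.get_params()["ci_level"] == 0.9
        clf.set_params(ci_level=0.95).fit()
        assert hasattr(clf, "calibrations_")
        labels = clf.predict([-0.55, -0.11, 0.13, 0.75])
        assert list(labels) == [
            "open_coast",
            "unknown",
            "lower_estuary",
            "upper_estuary",
        ]

    def test_unfitted_raises(self):
        with pytest.raises(RuntimeError, match="fit"):
            HabitatClassifier().predict([0.1])
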