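"""ICC, adjusted multiplier, overlap rule and its calibration."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mcidkit.comparison import (
    LITERATURE_THRESHOLDS,
    LiteratureThreshold,
    adjusted_multiplier,
    build_adjusted,
    calibrate_overlap_rule,
    compare_literature,
    icc_baseline_followup,
    overlap_matrix,
)
from mcidkit.util import display1, round_half_away


def anova_icc1_oracle(baseline, followup):
    """Brute-force one-way ANOVA variance-components ICC(1,1)."""
    x = [[b, f] for b, f in zip(baseline, followup)]
    n, k = len(x), 2
    grand = sum(sum(row) for row in x) / (n * k)
    ss_between = sum(k * (sum(row) / k - grand) ** 2 for row in x)
    ss_within = sum((v - sum(row) / k) ** 2 for row in x for v in row)
    ms_between = ss_between / (n - 1)
    ms_within = ss_within / (n * (k - 1))
    return (ms_between - ms_within) / (ms_between + (k - 1) * ms_within)


class TestICC:
    def test_identical_scores_give_one(self):
        b = np.array([10.0, 20.0, 30.0, 15.0])
        assert icc_baseline_followup(b, b) == pytest.approx(1.0)

    def test_independent_scores_give_about_zero(self):
        rng = np.random.default_rng(0)
        b, f = rng.normal(size=2000), rng.normal(size=2000)
        assert abs(icc_baseline_followup(b, f, "icc3")) < 0.06

    def test_matches_anova_oracle_on_small_worked_sets(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            n = rng.integers(3, 11)
            b = rng.normal(20, 7, size=n)
            f = 0.6 * b + rng.normal(2, 4, size=n)
            assert icc_baseline_followup(b, f, "icc1") == pytest.approx(
                max(0.0, anova_icc1_oracle(b, f)), abs=1e-12)

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(5)
        b = rng.normal(20, 7, 30)
        f = 0.6 * b + rng.normal(5, 4, 30)
        df = pd.DataFrame({
            "targets": np.repeat(np.arange(30), 2),
            "raters": np.tile(["a", "b"], 30),
            "scores": np.column_stack([b, f]).ravel(),
        })
        ref = pg.intraclass_corr(df, targets="targets", raters="raters",
                                 ratings="scores").set_index("Type")["ICC"]
        assert icc_baseline_followup(b, f, "icc1") == pytest.approx(
            ref["ICC(1,1)"], abs=1e-9)
        assert icc_baseline_followup(b, f, "icc3") == pytest.approx(
            ref["ICC(C,1)"], abs=1e-9)

    def test_negative_estimate_truncated_with_warning(self):
        b = np.array([0.0, 10.0, 0.0, 10.0])
        f = np.array([10.0, 0.0, 10.0, 0.0])
        with pytest.warns(UserWarning, match="truncated"):
            assert icc_baseline_followup(b, f) == 0.0

    def test_requires_three_pairs(self):
        with pytest.raises(ValueError):
            icc_baseline_followup([1, 2], [1, 2])


class TestAdjustedMultiplier:
    def test_half_dependency_gives_098(self):
        assert round_half_away(adjusted_multiplier(0.5), 2) == 0.98

    def test_independence_limit(self):
        assert adjusted_multiplier(0.0) == pytest.approx(1.386, abs=5e-4)

    def test_perfect_dependency_limit(self):
        assert adjusted_multiplier(1.0) == 0.0

    def test_lookup_mode_reproduces_published_mapping(self):
        assert adjusted_multiplier(0.7, mode="lookup") == 0.62
        for rho in (0.5, 0.6):
            assert adjusted_multiplier(rho, mode="lookup") == 0.98

    @given(st.integers(0, 1000), st.integers(0, 1000))
    @settings(max_examples=100, deadline=None)
    def test_strictly_decreasing_in_rho(self, i, j):
        if i == j:
            return
        lo, hi = sorted((i / 1000, j / 1000))
        assert adjusted_multiplier(lo) > adjusted_multiplier(hi)

    def test_continuous_on_unit_interval(self):
        # modulus of continuity of sqrt: |z(a)-z(b)| <= z95*sqrt(2h)/2
        rho = np.linspace(0, 1, 2001)
        z = np.array([adjusted_multiplier(r) for r in rho])
        h = rho[1] - rho[0]
        bound = 1.96 * np.sqrt(2 * h) / 2
        assert np.max(np.abs(np.diff(z))) <= bound + 1e-12

    def test_rejects_rho_outside_unit_interval(self):
        with pytest.raises(ValueError):
            adjusted_multiplier(-0.1)
        with pytest.raises(ValueError):
            adjusted_multiplier(1.1)


class TestBuildAdjusted:
    @pytest.mark.parametrize(
        "inst, mean, sd, n, icc, lo, hi",
        [
            ("CAT", -2.3, 6.1, 80, 0.6, "-3.0", "-1.6"),
            ("CCQ", -0.4, 1.0, 107, 0.6, "-0.5", "-0.3"),
            ("SGRQ", -10.3, 12.9, 80, 0.7, "-11.2", "-9.4"),
        ],
    )
    def test_reproduces_published_adjusted_cells(self, inst, mean, sd, n,
                                                 icc, lo, hi):
        c = build_adjusted(mean, sd, n, icc, instrument=inst, mode="lookup")
        assert (display1(c.ci_adj[0]), display1(c.ci_adj[1])) == (lo, hi)

    def test_se_is_sd_over_sqrt_n(self):
        c = build_adjusted(-3.1, 5.3, 196, 0.7)
        assert c.se == pytest.approx(5.3 / np.sqrt(196))
        assert display1(c.se) == "0.4"

    def test_zero_multiplier_degenerates_to_point(self):
        c = build_adjusted(-2.0, 5.0, 50, 1.0)
        assert c.ci_adj == (pytest.approx(-2.0), pytest.approx(-2.0))

    def test_width_is_exactly_twice_zstar_se(self):
        c = build_adjusted(-2.0, 5.0, 50, 0.3)
        assert c.ci_adj[1] - c.ci_adj[0] == pytest.approx(2 * c.z_star * c.se)

    def test_adjusted_ci_nested_in_unadjusted(self):
        c = build_adjusted(-2.0, 5.0, 50, 0.4)
        assert c.z_star < 1.96
        lo95 = -2.0 - 1.96 * c.se
        hi95 = -2.0 + 1.96 * c.se
        assert lo95 < c.ci_adj[0] and c.ci_adj[1] < hi95

    def test_rejects_tiny_n(self):
        with pytest.raises(ValueError):
            build_adjusted(-2.0, 5.0, 1, 0.5)


def _interval(inst, lo, hi, period="T1", scheme="grc15", scale="native"):
    mean, half = (lo + hi) / 2, (hi - lo) / 2
    n, sd = 100, 5.0
    se = sd / np.sqrt(n)
    c = build_adjusted(mean, sd, n, 0.5, instrument=inst, period=period,
                       scheme=scheme, scale=scale)
    # overwrite the interval to the stated endpoints for verdict tests
    c.ci_adj = (lo, hi)
    return c


class TestOverlap:
    def test_published_overlapping_pair_not_significant(self):
        res = overlap_matrix([
            _interval("CAT", -3.4, -2.9, "T1"),
            _interval("CAT", -3.4, -2.1, "T2"),
        ])
        assert res.verdicts[0].overlap and not res.verdicts[0].significant

    def test_published_disjoint_pair_significant(self):
        res = overlap_matrix([
            _interval("CAT", -2.0, -0.8, "T5", scheme="grc5"),
            _interval("CAT", -3.5, -2.1, "T5"),
        ])
        assert res.verdicts[0].significant

    def test_touching_intervals_count_as_overlap(self):
        res = overlap_matrix([
            _interval("CAT", -3.0, -2.0, "T1"),
            _interval("CAT", -2.0, -1.0, "T2"),
        ])
        assert res.verdicts[0].overlap

    def test_identical_intervals_overlap(self):
        res = overlap_matrix([
            _interval("CAT", -3.0, -2.0, "T1"),
            _interval("CAT", -3.0, -2.0, "T2"),
        ])
        assert res.verdicts[0].overlap

    def test_matrix_symmetric_and_order_invariant(self):
        a = _interval("CAT", -3.0, -2.5, "T1")
        b = _interval("CAT", -2.0, -1.0, "T2")
        c = _interval("CAT", -2.6, -1.8, "T3")
        res1 = overlap_matrix([a, b, c])
        res2 = overlap_matrix([c, a, b])
        assert (res1.significant.values == res1.significant.values.T).all()
        for v in res1.verdicts:
            match = [w for w in res2.verdicts
                     if {w.a, w.b} == {v.a, v.b}][0]
            assert match.overlap == v.overlap

    def test_mixed_scales_rejected(self):
        with pytest.raises(ValueError, match="scale"):
            overlap_matrix([
                _interval("CAT", -3.0, -2.0, "T1"),
                _interval("CAT", -8.0, -6.0, "T2", scale="standardized"),
            ])

    def test_different_instruments_need_standardized_scale(self):
        with pytest.raises(ValueError, match="instrument"):
            overlap_matrix([
                _interval("CAT", -3.0, -2.0),
                _interval("CCQ", -0.5, -0.3, "T2"),
            ])
        # standardized scale across instruments is fine
        res = overlap_matrix([
            _interval("CAT", -8.0, -6.0, scale="standardized"),
            _interval("CCQ", -9.0, -7.0, "T2", scale="standardized"),
        ])
        assert res.forest.shape[0] == 2


class TestLiterature:
    def test_sgrq_interval_excludes_four_points(self):
        c = build_adjusted(-8.4, 11.8, 196, 0.7, instrument="SGRQ",
                           mode="lookup")
        verdict = compare_literature(c, LITERATURE_THRESHOLDS["SGRQ"])
        assert not verdict.inside and verdict.significant

    def test_ccq_interval_includes_04(self):
        c = build_adjusted(-0.5, 1.0, 88, 0.5, instrument="CCQ",
                           mode="lookup")
        verdict = compare_literature(c, LITERATURE_THRESHOLDS["CCQ"])
        assert verdict.inside

    def test_boundary_threshold_counts_as_inside(self):
        c = _interval("CAT", -2.0, -1.0)
        verdict = compare_literature(c, LiteratureThreshold("CAT", 2.0))
        assert verdict.inside

    def test_instrument_mismatch_rejected(self):
        c = _interval("CAT", -3.0, -2.0)
        with pytest.raises(ValueError):
            compare_literature(c, LITERATURE_THRESHOLDS["SGRQ"])


class TestCalibration:
    def test_formula_mode_holds_alpha(self):
        res = calibrate_overlap_rule(0.5, n=100, reps=2000, seed=9)
        assert 0.03 <= res.rate <= 0.07

    def test_naive_unadjusted_rule_is_conservative(self):
        res = calibrate_overlap_rule(0.5, n=100, reps=2000, seed=9,
                                     z_star=1.96)
        assert res.rate < 0.01

    def test_rejects_too_few_reps(self):
        with pytest.raises(ValueError):
            calibrate_overlap_rule(0.5, reps=50)
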