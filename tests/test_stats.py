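"""Agreement and outcome statistics against explicit sums-of-squares oracles.

Every oracle here is computed from the raw numbers with textbook
formulas (difference-vector t, ANOVA sums of squares, two-way variance
components) independently of the implementation, and comparisons are at
10 significant digits.  pingouin's ICC serves as an additional
independent cross-check.
"""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from cermetrics import (
    DegenerateVarianceError,
    MeasurementSeries,
    ValidationError,
    bland_altman,
    classify_severity,
    cohort_report,
    icc_agreement,
    improvement_rate,
    one_way_anova,
    paired_t,
    two_way_anova,
)
from cermetrics.stats import AGREEMENT_COLUMNS, SEVERITY_COLUMNS, SUMMARY_COLUMNS

SIG10 = dict(rel=1e-10, abs=1e-12)

TOY_A = np.array([60.0, 65.0, 70.0, 75.0, 80.0, 85.0])
TOY_B = np.array([62.0, 64.0, 72.0, 74.0, 83.0, 84.0])


def oracle_mean_squares(a, b):
    """Two-way crossed mean squares by explicit double loops."""
    data = np.column_stack([a, b])
    n, k = data.shape
    gm = sum(sum(row) for row in data) / (n * k)
    row_means = [sum(row) / k for row in data]
    col_means = [sum(data[:, j]) / n for j in range(k)]
    ssr = k * sum((m - gm) ** 2 for m in row_means)
    ssc = n * sum((m - gm) ** 2 for m in col_means)
    sst = sum((x - gm) ** 2 for row in data for x in row)
    sse = sst - ssr - ssc
    return ssr / (n - 1), ssc / (k - 1), sse / ((n - 1) * (k - 1))


class TestPairedT:
    def test_identical_series_gives_zero_t_unit_p(self):
        assert paired_t([4.0, 5.0, 6.0], [4.0, 5.0, 6.0]) == (0.0, 1.0)

    def test_constant_nonzero_difference_is_degenerate(self):
        with pytest.raises(DegenerateVarianceError):
            paired_t([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])

    def test_matches_difference_vector_oracle(self):
        pre = np.array([50.0, 55.0, 60.0, 65.0])
        post = np.array([70.0, 72.0, 80.0, 85.0])
        d = pre - post
        mean = sum(d) / len(d)
        sd = math.sqrt(sum((x - mean) ** 2 for x in d) / (len(d) - 1))
        t_expected = mean / (sd / math.sqrt(len(d)))
        t, p = paired_t(pre, post)
        assert t == pytest.approx(t_expected, **SIG10)
        assert 0 < p < 0.001

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            paired_t([1.0, 2.0], [1.0, 2.0, 3.0])
        with pytest.raises(ValidationError):
            paired_t([1.0], [2.0])


class TestICC:
    def test_identical_series_is_exactly_one(self):
        for form in ("absolute_agreement", "consistency"):
            res = icc_agreement(TOY_A, TOY_A, form=form)
            assert res.icc == 1.0
            assert res.degenerate
            assert (res.ci_low, res.ci_high) == (1.0, 1.0)

    def test_constant_offset_separates_the_two_forms(self):
        res_c = icc_agreement(TOY_A, TOY_A + 5.0, form="consistency")
        res_a = icc_agreement(TOY_A, TOY_A + 5.0, form="absolute_agreement")
        assert res_c.icc == pytest.approx(1.0, **SIG10)
        assert res_a.icc < 1.0

    def test_matches_variance_component_oracle(self):
        msr, msc, mse = oracle_mean_squares(TOY_A, TOY_B)
        n, k = len(TOY_A), 2
        expected_a = (msr - mse) / (msr + (k - 1) * mse + (k / n) * (msc - mse))
        expected_c = (msr - mse) / (msr + (k - 1) * mse)
        assert icc_agreement(TOY_A, TOY_B).icc == pytest.approx(expected_a, **SIG10)
        assert icc_agreement(TOY_A, TOY_B, form="consistency").icc == pytest.approx(
            expected_c, **SIG10
        )

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        df = pd.DataFrame(
            {
                "targets": list(range(6)) * 2,
                "raters": ["a"] * 6 + ["b"] * 6,
                "scores": np.concatenate([TOY_A, TOY_B]),
            }
        )
        table = pg.intraclass_corr(df, targets="targets", raters="raters", ratings="scores")
        table = table.set_index("Type")
        res_a = icc_agreement(TOY_A, TOY_B)
        res_c = icc_agreement(TOY_A, TOY_B, form="consistency")
        assert res_a.icc == pytest.approx(table.loc["ICC(A,1)", "ICC"], **SIG10)
        assert res_c.icc == pytest.approx(table.loc["ICC(C,1)", "ICC"], **SIG10)
        lo, hi = table.loc["ICC(A,1)", "CI95"]
        assert round(res_a.ci_low, 2) == lo and round(res_a.ci_high, 2) == hi

    def test_band_labels(self):
        assert icc_agreement(TOY_A, TOY_B).band == "excellent"
        rng = np.random.default_rng(0)
        noisy = np.clip(TOY_A + rng.normal(0, 25, 6), 0, 100)
        res = icc_agreement(TOY_A, noisy)
        assert res.band in ("poor", "moderate", "substantial")

    def test_eye_id_permutation_invariance(self):
        perm = np.array([3, 0, 5, 1, 4, 2])
        base = icc_agreement(TOY_A, TOY_B).icc
        assert icc_agreement(TOY_A[perm], TOY_B[perm]).icc == pytest.approx(base, **SIG10)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValidationError):
            icc_agreement([1.0, 2.0], [1.0, 2.0])

    def test_unknown_form_rejected(self):
        with pytest.raises(ValidationError):
            icc_agreement(TOY_A, TOY_B, form="one_way")


class TestBlandAltman:
    def test_identical_series_collapse_to_zero(self):
        res = bland_altman(TOY_A, TOY_A)
        assert (res.bias, res.loa_low, res.loa_high) == (0.0, 0.0, 0.0)

    def test_alternating_unit_differences(self):
        a = np.array([10.0, 10.0, 10.0, 10.0])
        b = a - np.array([1.0, -1.0, 1.0, -1.0])
        res = bland_altman(a, b)
        sd = math.sqrt(4.0 / 3.0)
        assert res.bias == pytest.approx(0.0, abs=1e-12)
        assert res.loa_high == pytest.approx(1.96 * sd, **SIG10)
        assert res.loa_low == pytest.approx(-1.96 * sd, **SIG10)

    def test_swapping_series_negates_bias_and_reflects_loas(self):
        fwd = bland_altman(TOY_A, TOY_B)
        rev = bland_altman(TOY_B, TOY_A)
        assert rev.bias == pytest.approx(-fwd.bias, **SIG10)
        assert rev.loa_low == pytest.approx(-fwd.loa_high, **SIG10)
        assert rev.loa_high == pytest.approx(-fwd.loa_low, **SIG10)

    def test_single_pair_rejected(self):
        with pytest.raises(ValidationError):
            bland_altman([1.0], [2.0])

    @settings(derandomize=True, max_examples=50)
    @given(
        a=arrays(float, 8, elements=st.floats(0, 100, allow_nan=False)),
        b=arrays(float, 8, elements=st.floats(0, 100, allow_nan=False)),
    )
    def test_limits_always_bracket_the_bias(self, a, b):
        res = bland_altman(a, b)
        assert res.loa_low <= res.bias <= res.loa_high
        rev = bland_altman(b, a)
        assert rev.bias == pytest.approx(-res.bias, abs=1e-9)


class TestOneWayAnova:
    def test_identical_groups_give_zero_f(self):
        f, p = one_way_anova([TOY_A, TOY_A.copy(), TOY_A.copy()])
        assert f == 0.0
        assert p == pytest.approx(1.0)

    def test_matches_sums_of_squares_oracle(self):
        g1, g2 = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
        gm = sum(g1 + g2) / 6
        ssb = 3 * ((2.0 - gm) ** 2 + (5.0 - gm) ** 2)
        ssw = sum((x - 2.0) ** 2 for x in g1) + sum((x - 5.0) ** 2 for x in g2)
        f_expected = (ssb / 1) / (ssw / 4)
        f, _ = one_way_anova([g1, g2])
        assert f == pytest.approx(f_expected, **SIG10)

    def test_grand_mean_shift_invariance(self):
        f0, _ = one_way_anova([TOY_A, TOY_B])
        f1, _ = one_way_anova([TOY_A + 17.0, TOY_B + 17.0])
        assert f1 == pytest.approx(f0, **SIG10)

    def test_degenerate_groups_rejected(self):
        with pytest.raises(ValidationError):
            one_way_anova([TOY_A])
        with pytest.raises(ValidationError):
            one_way_anova([[1.0], [2.0]])
        with pytest.raises(DegenerateVarianceError):
            one_way_anova([[3.0, 3.0], [3.0, 3.0]])


class TestImprovementAndSeverity:
    @pytest.mark.parametrize(
        "pre,post,expected",
        [(63.59, 75.93, 19.41), (47.67, 75.74, 58.88), (40.0, 40.0, 0.0)],
        ids=["mild", "moderate_severe", "no_change"],
    )
    def test_improvement_rate(self, pre, post, expected):
        assert improvement_rate(pre, post) == expected

    def test_nonpositive_pre_mean_rejected(self):
        with pytest.raises(ValidationError):
            improvement_rate(0.0, 10.0)

    @pytest.mark.parametrize(
        "droop,label",
        [(2.0, "mild"), (2.1, "moderate_to_severe"), (0.0, "mild"), (8.0, "moderate_to_severe")],
    )
    def test_severity_threshold(self, droop, label):
        assert classify_severity(droop).label == label

    def test_negative_droop_rejected(self):
        with pytest.raises(ValidationError):
            classify_severity(-0.1)

    @settings(derandomize=True, max_examples=50)
    @given(
        pre=st.floats(1.0, 100.0, allow_nan=False),
        delta=st.floats(0.0, 100.0, allow_nan=False),
    )
    def test_improvement_rate_sign_tracks_change(self, pre, delta):
        assert improvement_rate(pre, pre + delta) >= 0.0
        assert improvement_rate(pre + delta if pre + delta > 0 else pre, pre) <= 0.0


class TestMeasurementSeries:
    def test_out_of_range_values_rejected(self):
        with pytest.raises(ValidationError):
            MeasurementSeries(values=np.array([50.0, 120.0]))

    def test_missing_values_rejected(self):
        with pytest.raises(ValidationError):
            MeasurementSeries(values=np.array([50.0, np.nan]))


def make_long(n=24, shift=20.0, sigma=2.0, seed=0, methods=("ai", "manual")):
    rng = np.random.default_rng(seed)
    droop = rng.uniform(0, 8, n)
    pre = np.clip(95 - 8 * droop + rng.normal(0, sigma, n), 0, 100)
    post = np.clip(pre + shift + rng.normal(0, sigma, n), 0, 100)
    rows = []
    for i in range(n):
        for m in methods:
            jitter = 0.0 if m == methods[0] else rng.normal(0, 0.5)
            rows.append(("e%02d" % i, "pre", m, np.clip(pre[i] + jitter, 0, 100), droop[i]))
            rows.append(("e%02d" % i, "post", m, np.clip(post[i] + jitter, 0, 100), droop[i]))
    return pd.DataFrame(rows, columns=["eye_id", "timepoint", "method", "cer", "droop_mm"])


class TestCohortReport:
    def test_identical_methods_agree_perfectly(self):
        df = make_long()
        dup = df[df["method"] == "ai"].copy()
        dup["method"] = "manual"
        rep = cohort_report(pd.concat([df[df["method"] == "ai"], dup]))
        assert (rep.agreement["icc"] == 1.0).all()
        assert (rep.agreement["bias"] == 0.0).all()

    def test_injected_shift_is_recovered(self):
        # +20-point postoperative shift on a mean preoperative CER of ~63:
        # expected improvement rate ≈ 100 * 20 / pre_mean
        df = make_long(n=60, shift=20.0, sigma=1.0, seed=4)
        rep = cohort_report(df)
        row = rep.summary[rep.summary["method"] == "ai"].iloc[0]
        measured_shift = row["post_mean"] - row["pre_mean"]
        assert measured_shift == pytest.approx(20.0, abs=3 * 1.0 * math.sqrt(2 / 60) * 3)
        assert not rep.severity.empty
        assert rep.anova_two_way is not None

    def test_report_schemas(self):
        rep = cohort_report(make_long())
        assert tuple(rep.summary.columns) == SUMMARY_COLUMNS
        assert tuple(rep.agreement.columns) == AGREEMENT_COLUMNS
        assert tuple(rep.severity.columns) == SEVERITY_COLUMNS

    def test_missing_timepoint_is_excluded_and_listed(self):
        df = make_long(n=10)
        df = df[~((df["eye_id"] == "e03") & (df["timepoint"] == "post"))]
        rep = cohort_report(df)
        assert set(rep.exclusions["eye_id"]) == {"e03"}
        assert (rep.summary["n"] == 9).all()

    def test_malformed_table_rejected(self):
        with pytest.raises(ValidationError, match="timepoint"):
            cohort_report(
                pd.DataFrame(
                    {"eye_id": ["a"], "timepoint": ["mid"], "method": ["m"], "cer": [50.0]}
                )
            )
        with pytest.raises(ValidationError, match="missing column"):
            cohort_report(pd.DataFrame({"eye_id": ["a"]}))


def test_two_way_anova_detects_timepoint_effect():
    df = make_long(n=40, shift=20.0, sigma=1.0, seed=2)
    df["severity"] = [classify_severity(d).label for d in df["droop_mm"]]
    table = two_way_anova(df[df["method"] == "ai"])
    assert table.loc["C(timepoint)", "PR(>F)"] < 0.001
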