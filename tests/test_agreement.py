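"""Paired agreement battery: CCC, Bland-Altman, MSE, paired t, normality."""

import json

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from ventrivol import (
    AgreementResults,
    DegenerateDataError,
    MethodComparison,
    agreement_report,
    bland_altman,
    lins_ccc,
    loa_from_summary,
    mse_paired,
    normality_check,
    paired_t,
    t_from_confidence_interval,
)


def vector_with_moments(mean, sd, n, seed=0):
    """Vector with exactly the requested sample mean and SD (ddof=1)."""
    base = np.random.default_rng(seed).normal(size=n)
    base = (base - base.mean()) / base.std(ddof=1)
    return mean + sd * base


paired_vectors = st.integers(3, 25).flatmap(
    lambda n: st.tuples(
        st.lists(st.floats(-100, 100), min_size=n, max_size=n),
        st.lists(st.floats(-100, 100), min_size=n, max_size=n),
    )
)


class TestLinsCCC:
    def test_perfect_agreement(self):
        x = np.array([3.0, 1.0, 4.0, 1.5, 9.0])
        ccc, ci = lins_ccc(x, x)
        assert ccc == pytest.approx(1.0, abs=1e-12)
        assert ci[1] == pytest.approx(1.0)

    def test_constant_offset_hand_value(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        ccc, _ = lins_ccc(x, x + 10.0)
        # 2 s^2 / (2 s^2 + delta^2) with n-denominator s^2 = 2.0
        assert ccc == pytest.approx(2 * 2.0 / (2 * 2.0 + 100.0), abs=1e-12)
        assert ccc == pytest.approx(0.0385, abs=5e-5)

    def test_perfect_reversed_agreement(self):
        x = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
        ccc, _ = lins_ccc(x, -x)
        assert ccc == pytest.approx(-1.0, abs=1e-12)

    def test_both_constant_is_an_error(self):
        with pytest.raises(DegenerateDataError):
            lins_ccc(np.ones(5), np.ones(5))

    def test_estimate_inside_its_ci(self):
        rng = np.random.default_rng(8)
        x = rng.normal(100, 20, 30)
        y = x + rng.normal(2, 5, 30)
        ccc, (lo, hi) = lins_ccc(x, y)
        assert lo <= ccc <= hi
        assert -1.0 <= lo and hi <= 1.0

    def test_ccc_never_exceeds_pearson_in_magnitude(self):
        rng = np.random.default_rng(77)
        for _ in range(50):
            x = rng.normal(0, rng.uniform(0.5, 10), 15)
            y = rng.uniform(0.2, 3) * x + rng.normal(0, 2, 15) + rng.uniform(-5, 5)
            ccc, _ = lins_ccc(x, y)
            r = stats.pearsonr(x, y).statistic
            assert abs(ccc) <= abs(r) + 1e-12

    def test_invariant_under_joint_location_scale_change(self):
        rng = np.random.default_rng(4)
        x = rng.normal(50, 7, 20)
        y = x + rng.normal(0, 3, 20)
        ccc, _ = lins_ccc(x, y)
        for c, s in ((10.0, 2.5), (-30.0, 0.1)):
            ccc2, _ = lins_ccc(s * x + c, s * y + c)
            assert ccc2 == pytest.approx(ccc, rel=1e-9)
        # but not under a change applied to one vector only
        ccc3, _ = lins_ccc(x, 2.0 * y)
        assert ccc3 != pytest.approx(ccc, rel=1e-3)


class TestBlandAltman:
    def test_identical_vectors(self):
        x = np.array([1.0, 2.0, 3.0])
        ba = bland_altman(x, x)
        assert ba.mean_diff == 0.0 and ba.sd_diff == 0.0 and ba.loa == (0.0, 0.0)

    def test_published_summary_arithmetic(self):
        # limits recomputed from a printed mean 4.19 and SD 6.04 match the
        # printed interval (-7.65, 16.05) to within input rounding
        lo, hi = loa_from_summary(4.19, 6.04)
        assert hi == pytest.approx(16.05, abs=0.03)
        assert lo == pytest.approx(-7.65, abs=0.03)

    @given(paired_vectors)
    def test_antisymmetry_under_method_swap(self, xy):
        x, y = np.array(xy[0]), np.array(xy[1])
        ba = bland_altman(x, y)
        ba_sw = bland_altman(y, x)
        assert ba_sw.mean_diff == pytest.approx(-ba.mean_diff, abs=1e-9)
        assert ba_sw.loa[0] == pytest.approx(-ba.loa[1], abs=1e-9)
        assert ba_sw.loa[1] == pytest.approx(-ba.loa[0], abs=1e-9)

    def test_loa_bracket_mean(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=20), rng.normal(size=20)
        ba = bland_altman(x, y)
        assert ba.loa[0] <= ba.mean_diff <= ba.loa[1]
        assert len(ba.means) == len(ba.diffs) == 20


class TestMSE:
    def test_identical_vectors(self):
        x = np.arange(5.0)
        assert mse_paired(x, x) == 0.0

    def test_simple_arithmetic(self):
        assert mse_paired(np.array([3.0, -3.0]), np.zeros(2)) == pytest.approx(9.0)

    def test_closed_form_from_printed_summaries(self):
        d = vector_with_moments(4.19, 6.04, 20)
        assert mse_paired(d, np.zeros(20)) == pytest.approx(
            4.19**2 + 6.04**2 * 19 / 20, rel=1e-12
        )
        assert mse_paired(d, np.zeros(20)) == pytest.approx(52.21, abs=0.01)

    @given(paired_vectors)
    def test_moment_identity(self, xy):
        x, y = np.array(xy[0]), np.array(xy[1])
        d = x - y
        n = len(d)
        expected = d.mean() ** 2 + d.std(ddof=1) ** 2 * (n - 1) / n
        assert mse_paired(x, y) == pytest.approx(expected, rel=1e-9, abs=1e-9)

    def test_unbiased_variant(self):
        x, y = np.array([1.0, 2.0, 4.0]), np.zeros(3)
        assert mse_paired(x, y, unbiased=True) == pytest.approx(21.0 / 2.0)


class TestPairedT:
    def test_symmetric_differences_give_zero_t(self):
        t, df, p, _ = paired_t(np.array([1.0, -1.0]), np.zeros(2))
        assert t == 0.0 and df == 1 and p == pytest.approx(1.0)

    def test_matches_scipy(self):
        rng = np.random.default_rng(12)
        x, y = rng.normal(10, 2, 20), rng.normal(9, 2, 20)
        t, df, p, ci = paired_t(x, y)
        ref = stats.ttest_rel(x, y)
        assert t == pytest.approx(ref.statistic, rel=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-12)
        lo, hi = ref.confidence_interval()
        assert ci == pytest.approx((lo, hi), rel=1e-12)

    def test_recovers_published_t_from_mean_and_ci(self):
        assert t_from_confidence_interval(-18.18, (-24.63, -11.73), 20) == pytest.approx(
            -5.9, abs=0.02
        )

    def test_zero_variance_nonzero_mean_is_degenerate(self):
        with pytest.raises(DegenerateDataError):
            paired_t(np.full(5, 2.0), np.zeros(5))

    def test_all_zero_differences_flagged(self):
        with pytest.warns(UserWarning, match="identically zero"):
            t, _, p, _ = paired_t(np.ones(5), np.ones(5))
        assert t == 0.0 and p == 1.0

    def test_invalid_ci_rejected(self):
        with pytest.raises(ValueError, match="positive width"):
            t_from_confidence_interval(1.0, (2.0, 2.0), 10)


class TestNormality:
    def test_null_calibration(self):
        """Under normal differences, Shapiro-Wilk rejects at roughly alpha."""
        rng = np.random.default_rng(6)
        rejections = sum(
            normality_check(rng.normal(size=20))[1] < 0.05 for _ in range(2000)
        )
        assert 0.03 < rejections / 2000 < 0.07

    def test_power_against_bimodal(self):
        rng = np.random.default_rng(13)
        hits = 0
        for _ in range(200):
            signs = rng.choice([-3.0, 3.0], size=50)
            d = signs + rng.normal(0, 0.5, 50)
            hits += normality_check(d)[1] < 0.05
        assert hits / 200 > 0.8

    def test_constant_vector_is_degenerate(self):
        with pytest.raises(DegenerateDataError):
            normality_check(np.ones(10))

    def test_sample_size_bounds(self):
        with pytest.raises(ValueError, match="3 <= n <= 5000"):
            normality_check(np.array([1.0, 2.0]))


class TestAgreementResults:
    def test_identity_report(self):
        x = np.array([80.0, 120.0, 160.0, 200.0])
        with pytest.warns(UserWarning):
            res = agreement_report(x, x.copy(), labels=("A", "B"))
        assert res.ccc == pytest.approx(1.0)
        assert res.mean_diff == 0.0 and res.mse == 0.0 and res.loa == (0.0, 0.0)

    def test_bias_recovery(self):
        """Injected bias b is recovered within 2 sigma / sqrt(n)."""
        rng = np.random.default_rng(21)
        truth = rng.normal(140, 30, 40)
        b, sigma = 5.0, 4.0
        x = truth + b + rng.normal(0, sigma, 40)
        res = agreement_report(x, truth, labels=("meas", "truth"))
        assert res.mean_diff == pytest.approx(b, abs=2 * sigma / np.sqrt(40))

    def test_json_roundtrip_is_lossless(self):
        rng = np.random.default_rng(3)
        x = rng.normal(150, 30, 20)
        y = x + rng.normal(2, 5, 20)
        res = MethodComparison(x, y, labels=("pdp", "vrps")).fit()
        back = AgreementResults.from_dict(json.loads(res.to_json()))
        assert back == res

    def test_invariants(self):
        rng = np.random.default_rng(9)
        x = rng.normal(150, 30, 25)
        y = 0.9 * x + rng.normal(5, 8, 25)
        res = MethodComparison(x, y).fit()
        assert res.loa[0] <= res.mean_diff <= res.loa[1]
        assert res.ccc_ci[0] <= res.ccc <= res.ccc_ci[1]
        assert abs(res.ccc) <= 1.0
        assert res.mse == pytest.approx(
            res.mean_diff**2 + res.sd_diff**2 * (res.n - 1) / res.n, rel=1e-12
        )

    def test_summary_is_printable(self):
        rng = np.random.default_rng(14)
        x = rng.normal(150, 30, 20)
        res = MethodComparison(x, x + rng.normal(0, 5, 20), labels=("pdp", "vrps")).fit()
        text = res.summary()
        assert "Lin's CCC" in text and "limits of agreement" in text and "pdp" in text

    def test_needs_at_least_three_pairs(self):
        with pytest.raises(ValueError, match="n >= 3"):
            MethodComparison(np.array([1.0, 2.0]), np.array([1.0, 2.0])).fit()
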