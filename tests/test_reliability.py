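import numpy as np
import pytest

from frtkin import (
    RatingsMatrix,
    classify_icc,
    icc,
    ks_normality,
    paired_compare,
    reliability_table,
)
from frtkin.errors import (
    DegenerateMatrix,
    InsufficientData,
    LengthMismatch,
    MissingVariable,
)
from frtkin.reliability import comparison_table, format_reliability_table

#: Published Lilliefors critical value at alpha=.05 for n=100.
LILLIEFORS_CRIT_100 = 0.0886

TOY_6x2 = np.array([[9, 10], [8, 8], [7, 9], [10, 11], [6, 7], [8, 9]], float)


def brute_force_icc(Y, form="icc2"):
    """Variance-components ICC assembled from explicit double loops."""
    n, k = Y.shape
    grand = sum(Y[i][j] for i in range(n) for j in range(k)) / (n * k)
    row = [sum(Y[i][j] for j in range(k)) / k for i in range(n)]
    col = [sum(Y[i][j] for i in range(n)) / n for j in range(k)]
    ssr = k * sum((r - grand) ** 2 for r in row)
    ssc = n * sum((c - grand) ** 2 for c in col)
    sst = sum((Y[i][j] - grand) ** 2 for i in range(n) for j in range(k))
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = (sst - ssr - ssc) / ((n - 1) * (k - 1))
    if form == "icc3":
        return (msr - mse) / (msr + (k - 1) * mse)
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


class TestKsNormality:
    def test_too_small_sample_rejected(self):
        with pytest.raises(InsufficientData):
            ks_normality([1.0, 2.0, 3.0])

    def test_uniform_statistic_against_published_critical_value(self):
        # decisions must agree with the published n=100 critical value
        for seed in range(20):
            x = np.random.default_rng(seed).uniform(0, 1, 100)
            stat, p = ks_normality(x)
            assert (p <= 0.05) == (stat >= LILLIEFORS_CRIT_100)

    def test_normal_sample_rarely_rejected(self):
        x = np.random.default_rng(7).normal(10, 2, 200)
        _, p = ks_normality(x)
        assert p > 0.05

    def test_null_calibration_of_rejection_rate(self):
        # 200 standard-normal samples of n=50: rejections ~ Binomial(200, .05)
        rejections = 0
        for seed in range(200):
            x = np.random.default_rng(1000 + seed).normal(0, 1, 50)
            _, p = ks_normality(x)
            rejections += p <= 0.05
        # 99% binomial bounds for Binomial(200, 0.05): [2, 18]
        assert 2 <= rejections <= 18


class TestPairedCompare:
    def test_identical_pairs_not_significant(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        res = paired_compare(x, x)
        assert res.mean_difference == 0.0
        assert not res.significant

    def test_t_statistic_matches_hand_computation(self):
        # hand-picked differences (1.0, 2.1, 1.4, 2.0, 0.9) pass the
        # normality gate; t must equal d-bar / (s_d / sqrt(n))
        d = np.array([1.0, 2.1, 1.4, 2.0, 0.9])
        y = np.array([1.0, 2.0, 2.0, 3.0, 3.0])
        res = paired_compare(y + d, y)
        assert res.method == "student_t"
        t_hand = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        assert res.statistic == pytest.approx(t_hand, abs=1e-10)

    def test_two_point_differences_fail_gate_and_go_to_wilcoxon(self):
        # differences (1, 2, 1, 2, 1) are two-valued: the Lilliefors gate
        # rejects normality, so the signed-rank branch is taken
        x = [2.0, 4.0, 3.0, 5.0, 4.0]
        y = [1.0, 2.0, 2.0, 3.0, 3.0]
        res = paired_compare(x, y)
        _, p_norm = ks_normality(np.array(x) - np.array(y))
        assert p_norm <= 0.05
        assert res.method == "wilcoxon"

    def test_method_consistent_with_normality_gate(self):
        # heavy-tailed differences that fail the normality gate go to Wilcoxon
        rng = np.random.default_rng(3)
        found_wilcoxon = False
        for _ in range(20):
            d = rng.standard_cauchy(40)
            x = d + 10.0
            y = np.full(40, 10.0)
            res = paired_compare(x, y)
            _, p_norm = ks_normality(d)
            assert res.method == ("student_t" if p_norm > 0.05 else "wilcoxon")
            found_wilcoxon = found_wilcoxon or res.method == "wilcoxon"
        assert found_wilcoxon

    def test_length_mismatch(self):
        with pytest.raises(LengthMismatch):
            paired_compare([1, 2, 3, 4], [1, 2, 3])

    def test_insufficient_data(self):
        with pytest.raises(InsufficientData):
            paired_compare([1, 2, 3], [4, 5, 6])

    def test_obvious_shift_detected(self, rng):
        x = rng.normal(10, 1, 30)
        res = paired_compare(x + 5.0, x)
        assert res.significant
        assert res.mean_difference == pytest.approx(5.0)


class TestIcc:
    def test_perfect_agreement(self):
        m = RatingsMatrix(np.array([[1, 1], [2, 2], [3, 3.0]]))
        res = icc(m)
        assert res.icc == 1.0
        assert res.ci_high == 1.0

    def test_no_between_subject_variance_gives_nonpositive_icc(self):
        m = RatingsMatrix(np.array([[1, 2.0], [1, 2], [1, 2], [1, 2]]))
        assert icc(m).icc <= 0.0

    def test_degenerate_matrix(self):
        with pytest.raises(DegenerateMatrix):
            icc(RatingsMatrix(np.full((4, 3), 7.0)))

    def test_toy_matrix_matches_brute_force(self):
        res = icc(RatingsMatrix(TOY_6x2))
        assert res.icc == pytest.approx(brute_force_icc(TOY_6x2), abs=1e-12)

    def test_toy_matrix_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        n, k = TOY_6x2.shape
        df = pd.DataFrame({
            "s": np.repeat(np.arange(n), k),
            "r": np.tile(np.arange(k), n),
            "y": TOY_6x2.ravel(),
        })
        ref = pg.intraclass_corr(df, targets="s", raters="r", ratings="y")
        ref = ref.set_index("Type")
        res2 = icc(RatingsMatrix(TOY_6x2), form="icc2")
        res3 = icc(RatingsMatrix(TOY_6x2), form="icc3")
        assert res2.icc == pytest.approx(ref.loc["ICC(A,1)", "ICC"], abs=1e-10)
        assert res3.icc == pytest.approx(ref.loc["ICC(C,1)", "ICC"], abs=1e-10)
        lo, hi = ref.loc["ICC(A,1)", "CI95"]
        assert res2.ci_low == pytest.approx(lo, abs=5e-3)
        assert res2.ci_high == pytest.approx(hi, abs=5e-3)

    @pytest.mark.parametrize("seed", range(10))
    def test_random_matrices_match_brute_force(self, seed):
        r = np.random.default_rng(seed)
        Y = r.normal(10, 3, (r.integers(4, 12), r.integers(2, 5)))
        for form in ("icc2", "icc3"):
            assert icc(RatingsMatrix(Y), form=form).icc == pytest.approx(
                brute_force_icc(Y, form), abs=1e-10
            )

    def test_invariance_under_shift_and_scale(self, rng):
        Y = rng.normal(0, 1, (8, 3))
        base = icc(RatingsMatrix(Y)).icc
        assert icc(RatingsMatrix(Y + 100.0)).icc == pytest.approx(base, abs=1e-9)
        assert icc(RatingsMatrix(Y * 37.0)).icc == pytest.approx(base, abs=1e-9)

    def test_consistency_form_forgives_rater_bias(self, rng):
        Y = rng.normal(0, 1, (10, 3)) + rng.normal(0, 1, (10, 1)) * 2
        Y_biased = Y + np.array([0.0, 2.0, 4.0])  # constant rater offsets
        r2 = icc(RatingsMatrix(Y_biased), form="icc2")
        r3 = icc(RatingsMatrix(Y_biased), form="icc3")
        assert r3.icc >= r2.icc

    def test_ci_brackets_estimate(self, rng):
        for _ in range(10):
            Y = rng.normal(0, 1, (6, 3)) + rng.normal(0, 2, (6, 1))
            res = icc(RatingsMatrix(Y))
            assert res.ci_low <= res.icc <= res.ci_high

    def test_matrix_invariants_enforced(self):
        with pytest.raises(ValueError):
            RatingsMatrix(np.zeros((1, 3)))
        with pytest.raises(ValueError):
            RatingsMatrix(np.array([[1.0, np.nan], [2, 3]]))


class TestClassifyIcc:
    @pytest.mark.parametrize("value,band", [
        (0.989, "very_high"),
        (0.978, "very_high"),
        (0.872, "high"),
        (0.70, "high"),
        (0.90, "very_high"),
        (0.50, "moderate"),
        (0.30, "low"),
        (0.29, "very_low"),
        (0.0, "very_low"),
        (-0.4, "very_low"),
    ])
    def test_bands(self, value, band):
        assert classify_icc(value) == band

    def test_above_one_rejected(self):
        with pytest.raises(ValueError):
            classify_icc(1.2)


class TestReliabilityTable:
    def _dataset(self, rng, variables=("Time_A_B",)):
        return {
            v: {
                "intraobserver": RatingsMatrix(
                    rng.normal(0, 1, (7, 3)) + rng.normal(0, 2, (7, 1)),
                    "intraobserver",
                ),
                "interobserver": RatingsMatrix(
                    rng.normal(0, 1, (7, 2)) + rng.normal(0, 2, (7, 1)),
                    "interobserver",
                ),
            }
            for v in variables
        }

    def test_single_variable_gives_one_row_with_four_numbers(self, rng):
        table = reliability_table(self._dataset(rng))
        assert len(table) == 1
        row = table.iloc[0]
        for col in ("intraobserver_icc", "intraobserver_ci_low",
                    "interobserver_icc", "interobserver_ci_low"):
            assert np.isfinite(row[col])

    def test_table_equals_direct_icc_calls(self, rng):
        ds = self._dataset(rng, variables=("Time_A_B", "Displacement_A_B"))
        table = reliability_table(ds).set_index("variable")
        for v, matrices in ds.items():
            assert table.loc[v, "intraobserver_icc"] == pytest.approx(
                icc(matrices["intraobserver"]).icc
            )
            assert table.loc[v, "interobserver_icc"] == pytest.approx(
                icc(matrices["interobserver"]).icc
            )

    def test_missing_matrix_named(self, rng):
        ds = self._dataset(rng)
        del ds["Time_A_B"]["interobserver"]
        with pytest.raises(MissingVariable, match="Time_A_B"):
            reliability_table(ds)

    def test_formatted_table_style(self, rng):
        formatted = format_reliability_table(reliability_table(self._dataset(rng)))
        cell = formatted.iloc[0]["intraobserver_icc"]
        assert cell.startswith(".") or cell.startswith("-.") or cell.startswith("1")
        assert "-" in formatted.iloc[0]["intraobserver_ci"]


class TestComparisonTable:
    def test_p_label_style(self):
        rng = np.random.default_rng(0)
        x = rng.normal(10, 1, 20)
        results = [paired_compare(x + 3, x, variable="shift"),
                   paired_compare(x, x + rng.normal(0, 0.01, 20), variable="null")]
        table = comparison_table(results).set_index("variable")
        assert table.loc["shift", "p_label"].startswith("P")
        assert table.loc["shift", "significant"]
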