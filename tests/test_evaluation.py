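import numpy as np
import pytest
from hypothesis import given, strategies as st

from embryosel import evaluation as ev


def brute_force_auc(scores, labels):
    """Oracle: concordant + half-tied positive/negative pairs."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_separation(self):
        r = ev.roc_auc([1, 2, 3, 4], [0, 0, 1, 1])
        assert r.auc == 1.0

    def test_all_ties_half(self):
        r = ev.roc_auc([5.0] * 6, [0, 1, 0, 1, 0, 1])
        assert r.auc == 0.5

    def test_one_inversion_matches_pair_count(self):
        scores = [1, 2, 3, 4, 5, 6]
        labels = [0, 0, 1, 0, 1, 1]
        r = ev.roc_auc(scores, labels)
        assert r.auc == pytest.approx(brute_force_auc(scores, labels))

    def test_matches_brute_force_random(self, rng):
        for _ in range(50):
            n = int(rng.integers(4, 50))
            scores = rng.integers(0, 10, n).astype(float)  # many ties
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                continue
            r = ev.roc_auc(scores, labels)
            assert r.auc == pytest.approx(brute_force_auc(scores, labels), abs=1e-12)

    def test_curve_endpoints_and_monotonicity(self, rng):
        scores = rng.standard_normal(40)
        labels = rng.integers(0, 2, 40)
        labels[:2] = [0, 1]
        r = ev.roc_auc(scores, labels)
        assert r.sensitivity[0] == 0.0 and r.one_minus_specificity[0] == 0.0
        assert r.sensitivity[-1] == 1.0 and r.one_minus_specificity[-1] == 1.0
        assert np.all(np.diff(r.sensitivity) >= 0)
        assert np.all(np.diff(r.one_minus_specificity) >= 0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            ev.roc_auc([1, 2, 3], [1, 1, 1])

    def test_complement_symmetry(self, rng):
        scores = rng.standard_normal(60)
        labels = rng.integers(0, 2, 60)
        labels[:2] = [0, 1]
        a = ev.roc_auc(scores, labels).auc
        b = ev.roc_auc(-scores, labels).auc
        assert a + b == pytest.approx(1.0)

    def test_monotone_transform_invariance(self, rng):
        scores = rng.standard_normal(50)
        labels = rng.integers(0, 2, 50)
        labels[:2] = [0, 1]
        a = ev.roc_auc(scores, labels).auc
        b = ev.roc_auc(np.exp(scores), labels).auc
        assert a == pytest.approx(b, abs=1e-12)


class TestGradeAuc:
    @pytest.mark.parametrize(
        "auc,grade",
        [
            (0.69, "poor"),
            (0.95, "excellent"),
            (0.5, "fail"),
            (0.9, "excellent"),
            (0.8, "good"),
            (0.7, "fair"),
            (0.6, "poor"),
            (0.55, "fail"),
            (1.0, "excellent"),
        ],
    )
    def test_bands(self, auc, grade):
        assert ev.grade_auc(auc) == grade

    @pytest.mark.parametrize("bad", [-0.1, 1.1])
    def test_domain(self, bad):
        with pytest.raises(ValueError):
            ev.grade_auc(bad)

    @given(st.floats(0.0, 1.0))
    def test_total_on_domain(self, auc):
        assert ev.grade_auc(auc) in {"excellent", "good", "fair", "poor", "fail"}


class TestCompareAuc:
    def test_identical_paired(self, rng):
        scores = rng.standard_normal(50)
        labels = rng.integers(0, 2, 50)
        labels[:2] = [0, 1]
        a, b, p = ev.compare_auc(scores, labels, scores, labels, paired=True)
        assert a == b
        assert p == 1.0

    def test_paired_mismatch_rejected(self, rng):
        s = rng.standard_normal(20)
        y = np.r_[np.zeros(10), np.ones(10)].astype(int)
        y2 = y[::-1]
        with pytest.raises(ValueError):
            ev.compare_auc(s, y, s, y2, paired=True)

    def test_null_type_i_error(self, rng):
        # paired DeLong on two independent noise scores: ~5% rejections
        reps = 600
        rejections = 0
        y = np.r_[np.zeros(100), np.ones(100)].astype(int)
        for _ in range(reps):
            s1 = rng.standard_normal(200)
            s2 = rng.standard_normal(200)
            _, _, p = ev.compare_auc(s1, y, s2, y, paired=True)
            rejections += p < 0.05
        assert 0.02 <= rejections / reps <= 0.08

    def test_unpaired_null_p_uniform(self, rng):
        # two independent cohorts scored by the same model: p ~ U(0,1)
        from scipy import stats

        reps = 400
        pvals = []
        for _ in range(reps):
            y1 = np.r_[np.zeros(120), np.ones(120)].astype(int)
            s1 = y1 * 0.8 + rng.standard_normal(240)
            y2 = np.r_[np.zeros(120), np.ones(120)].astype(int)
            s2 = y2 * 0.8 + rng.standard_normal(240)
            _, _, p = ev.compare_auc(s1, y1, s2, y2, paired=False)
            pvals.append(p)
        ks_p = stats.kstest(pvals, "uniform").pvalue
        assert ks_p > 0.001

    def test_delong_auc_equals_trapezoid(self, rng):
        scores = rng.integers(0, 5, 80).astype(float)
        labels = rng.integers(0, 2, 80)
        labels[:2] = [0, 1]
        a, _, _ = ev.compare_auc(scores, labels, scores, labels, paired=True)
        assert a == pytest.approx(ev.roc_auc(scores, labels).auc, abs=1e-12)


class TestIcc:
    def test_duplicate_columns(self, rng):
        x = rng.standard_normal(30)
        res = ev.icc(np.c_[x, x])
        assert res.value == pytest.approx(1.0)
        assert res.grade == "excellent"

    def test_printed_band_good(self):
        assert ev.grade_agreement(0.747) == "good"

    def test_matches_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        n = 40
        x = rng.standard_normal(n)
        ratings = np.c_[x, x + 0.3 * rng.standard_normal(n)]
        res = ev.icc(ratings)
        df = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(n), 2),
                "rater": np.tile([0, 1], n),
                "score": ratings.ravel(),
            }
        )
        ref = pingouin.intraclass_corr(
            df, targets="subject", raters="rater", ratings="score"
        )
        icc2 = ref.loc[ref["Type"] == "ICC(A,1)", "ICC"].iloc[0]
        assert res.value == pytest.approx(icc2, abs=1e-6)

    def test_independent_permutation_near_zero(self, rng):
        vals = []
        for _ in range(30):
            x = rng.standard_normal(100)
            ratings = np.c_[x, rng.permutation(x)]
            vals.append(ev.icc(ratings).value)
        assert abs(np.mean(vals)) < 0.15

    def test_too_few_subjects(self):
        with pytest.raises(ValueError):
            ev.icc(np.ones((2, 2)))

    def test_no_between_subject_variance(self):
        with pytest.raises(ZeroDivisionError):
            ev.icc(np.ones((5, 2)))


class TestCohenKappa:
    def test_identical_ratings(self):
        res = ev.cohen_kappa([0, 1, 2, 0, 1], [0, 1, 2, 0, 1])
        assert res.value == 1.0
        assert res.grade == "excellent"

    def test_constructed_table(self):
        # observed agreement 0.8, chance 0.5 -> kappa 0.6
        r1 = [0] * 5 + [1] * 5
        r2 = [0, 0, 0, 0, 1, 1, 1, 1, 1, 0]
        res = ev.cohen_kappa(r1, r2)
        assert res.value == pytest.approx(0.6)
        assert res.grade == "good"

    def test_matches_sklearn(self, rng):
        sklearn = pytest.importorskip("sklearn.metrics")
        r1 = rng.integers(0, 4, 200)
        r2 = rng.integers(0, 4, 200)
        res = ev.cohen_kappa(r1, r2)
        assert res.value == pytest.approx(
            sklearn.cohen_kappa_score(r1, r2), abs=1e-10
        )

    def test_independent_near_zero(self, rng):
        r1 = rng.integers(0, 3, 10_000)
        r2 = rng.integers(0, 3, 10_000)
        assert abs(ev.cohen_kappa(r1, r2).value) < 0.03

    def test_kappa_not_above_observed_agreement(self, rng):
        r1 = rng.integers(0, 3, 100)
        r2 = rng.integers(0, 3, 100)
        p_o = np.mean(r1 == r2)
        assert ev.cohen_kappa(r1, r2).value <= p_o + 1e-12

    def test_both_constant_identical_undefined(self):
        with pytest.raises(ZeroDivisionError):
            ev.cohen_kappa([1, 1, 1], [1, 1, 1])


class TestAgreementBands:
    @pytest.mark.parametrize(
        "value,grade",
        [
            (0.8, "excellent"),
            (0.79, "good"),
            (0.6, "good"),
            (0.59, "moderate"),
            (0.4, "moderate"),
            (0.2, "poor"),
            (0.19, "very poor"),
            (-0.3, "very poor"),
        ],
    )
    def test_bands(self, value, grade):
        assert ev.grade_agreement(value) == grade


class TestCollinearity:
    def test_orthogonal_columns(self, rng):
        n = 200
        X = np.c_[np.ones(n), rng.standard_normal((n, 3))]
        rep = ev.collinearity_diagnostics(X)
        assert np.all(rep.vif[1:] < 1.2)
        assert rep.condition_indices.max() < 5
        assert all(f == "weak" for f in rep.flags)

    def test_band_flags(self):
        # 30 <= ci <= 100 flagged moderate to strong (the printed 92 case)
        n = 500
        rng = np.random.default_rng(5)
        x = rng.standard_normal(n)
        found = None
        for eps in [0.3, 0.1, 0.05, 0.03, 0.02, 0.015, 0.01, 0.005]:
            X = np.c_[np.ones(n), x, x + eps * rng.standard_normal(n)]
            rep = ev.collinearity_diagnostics(X)
            ci = rep.condition_indices.max()
            if 30 <= ci <= 100:
                found = rep
                break
        assert found is not None
        assert found.flags[np.argmax(found.condition_indices)] == "moderate to strong"

    def test_vif_diverges_as_duplicate(self, rng):
        n = 300
        x = rng.standard_normal(n)
        vifs = []
        for eps in [0.5, 0.1, 0.02]:
            X = np.c_[np.ones(n), x, x + eps * rng.standard_normal(n)]
            rep = ev.collinearity_diagnostics(X)
            vifs.append(rep.vif[1])
        assert vifs[0] < vifs[1] < vifs[2]

    def test_vif_closed_form(self, rng):
        # two standardized columns with correlation r: VIF = 1/(1-r^2)
        n = 5000
        x = rng.standard_normal(n)
        z = 0.6 * x + 0.8 * rng.standard_normal(n)
        X = np.c_[x, z]
        rep = ev.collinearity_diagnostics(np.c_[np.ones(n), X])
        r = np.corrcoef(x, z)[0, 1]
        # intercept makes the regression equivalent to centered correlation
        assert rep.vif[1] == pytest.approx(1 / (1 - r**2), rel=0.05)

    def test_exact_singular_flagged_not_crash(self, rng):
        x = rng.standard_normal(100)
        X = np.c_[np.ones(100), x, x]
        rep = ev.collinearity_diagnostics(X)
        assert np.isinf(rep.vif[1]) and np.isinf(rep.vif[2])

    def test_vdp_columns_sum_to_one(self, rng):
        X = np.c_[np.ones(80), rng.standard_normal((80, 4))]
        rep = ev.collinearity_diagnostics(X)
        np.testing.assert_allclose(
            rep.variance_decomposition.sum(axis=0), 1.0, atol=1e-9
        )


class TestMutualInformation:
    def test_feature_equals_outcome(self):
        y = np.r_[np.zeros(500), np.ones(500)].astype(int)
        assert ev.mutual_information(y.astype(float), y) == pytest.approx(1.0)

    def test_constant_feature_zero(self):
        assert ev.mutual_information(np.ones(50), np.r_[np.zeros(25), np.ones(25)].astype(int)) == 0.0

    def test_independent_below_permutation_null(self, rng):
        n = 10_000
        x = rng.standard_normal(n)
        y = rng.integers(0, 2, n)
        mi = ev.mutual_information(x, y)
        null = [
            ev.mutual_information(x, rng.permutation(y)) for _ in range(100)
        ]
        assert mi <= np.quantile(null, 0.99) * 2 + 1e-3

    def test_half_deterministic_closed_form(self, rng):
        # outcome equals the binary feature for half the rows, coin flip else
        n = 200_000
        x = rng.integers(0, 2, n)
        coin = rng.integers(0, 2, n)
        det = rng.random(n) < 0.5
        y = np.where(det, x, coin)
        # joint: P(x=a, y=a) = 0.375, P(x=a, y=1-a) = 0.125 each
        expected = sum(
            p * np.log2(p / 0.25) for p in (0.375, 0.375, 0.125, 0.125)
        )
        mi = ev.mutual_information(x.astype(float), y)
        assert mi == pytest.approx(expected, abs=0.01)
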