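"""Statistical battery against independent oracles and printed values."""

import numpy as np
import pandas as pd
import pytest

from physometry import (
    CompletenessError,
    UndefinedKappaError,
    ValidationError,
    cohen_kappa,
    cohort_summary,
    kappa_from_counts,
    ks_normality,
    mann_whitney_u,
    multiple_regression,
    pearson_r_ci,
)
from physometry.stats import average_over_observers
from physometry.morphometry import SubjectMorphometry


def solve_normal_equations(X, y):
    """Independent OLS solve: form X'X b = X'y and eliminate by hand."""
    Xd = np.column_stack([np.ones(len(y)), X])
    A = Xd.T @ Xd
    b = Xd.T @ y
    n = A.shape[0]
    M = np.hstack([A.astype(float), b.reshape(-1, 1).astype(float)])
    for col in range(n):
        piv = max(range(col, n), key=lambda r: abs(M[r, col]))
        M[[col, piv]] = M[[piv, col]]
        M[col] = M[col] / M[col, col]
        for r in range(n):
            if r != col:
                M[r] -= M[r, col] * M[col]
    return M[:, -1]


class TestPearson:
    def test_perfect_lines(self):
        assert pearson_r_ci([1, 2, 3], [2, 4, 6]).r == pytest.approx(1.0)
        assert pearson_r_ci([1, 2, 3], [6, 4, 2]).r == pytest.approx(-1.0)

    def test_hand_evaluated_example(self):
        # r = 3 / sqrt(2 * 14/3) for x=(1,2,3), y=(1,2,4)
        res = pearson_r_ci([1, 2, 3], [1, 2, 4])
        assert res.r == pytest.approx(3 / np.sqrt(2 * 14 / 3), abs=1e-4)
        assert res.r == pytest.approx(0.9820, abs=1e-4)

    def test_ci_brackets_r(self, rng):
        x = rng.normal(size=30)
        y = x + rng.normal(size=30)
        res = pearson_r_ci(x, y)
        assert res.ci_low <= res.r <= res.ci_high
        assert -1 <= res.ci_low and res.ci_high <= 1

    def test_zero_variance_rejected(self):
        with pytest.raises(ValidationError):
            pearson_r_ci([1, 1, 1], [1, 2, 3])


class TestKappa:
    def test_printed_contingency_table(self):
        # p_o = 0.8, p_e = 0.5 -> kappa = 0.6
        res = kappa_from_counts(40, 10, 10, 40)
        assert res.kappa == pytest.approx(0.6)

    def test_identical_masks(self, rng):
        mask = rng.random((20, 20)) > 0.5
        assert cohen_kappa(mask, mask).kappa == 1.0

    def test_label_swap_invariant(self, rng):
        a = rng.random((20, 20)) > 0.5
        b = rng.random((20, 20)) > 0.5
        k1 = cohen_kappa(a, b).kappa
        k2 = cohen_kappa(~a, ~b).kappa
        assert k1 == pytest.approx(k2)

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import cohen_kappa_score

        a = rng.random((30, 30)) > 0.4
        b = a ^ (rng.random((30, 30)) > 0.9)
        ours = cohen_kappa(a, b).kappa
        theirs = cohen_kappa_score(a.ravel(), b.ravel())
        assert ours == pytest.approx(theirs, abs=1e-12)

    def test_domain_restriction(self, rng):
        a = rng.random((20, 20)) > 0.5
        b = rng.random((20, 20)) > 0.5
        domain = np.zeros((20, 20), dtype=bool)
        domain[:10] = True
        restricted = cohen_kappa(a, b, domain=domain)
        assert restricted.n == 200

    def test_undefined_kappa_signalled(self):
        ones = np.ones((5, 5), dtype=bool)
        with pytest.raises(UndefinedKappaError):
            cohen_kappa(ones, ones)


def brute_force_u(a, b):
    """All-pairs count: U for the first sample, ties as 1/2."""
    u = 0.0
    for x in a:
        for y in b:
            if x > y:
                u += 1.0
            elif x == y:
                u += 0.5
    return u


class TestMannWhitney:
    def test_extreme_separation(self):
        u, _ = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert u == 0.0

    def test_identical_groups(self):
        u, p = mann_whitney_u([1, 2, 3], [1, 2, 3])
        assert u == 3 * 3 / 2
        assert p == pytest.approx(1.0, abs=0.05)

    def test_matches_all_pairs_oracle(self, rng):
        for _ in range(10):
            a = rng.integers(0, 40, size=rng.integers(2, 15))
            b = rng.integers(0, 40, size=rng.integers(2, 15))
            u, _ = mann_whitney_u(a, b)
            assert u == brute_force_u(a, b)

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationError):
            mann_whitney_u([], [1.0])


class TestNormality:
    def test_normal_sample_passes(self):
        x = np.random.default_rng(0).normal(size=500)
        _, p = ks_normality(x)
        assert p > 0.05

    def test_uniform_sample_fails(self, rng):
        x = rng.uniform(0, 1, size=200)
        _, p = ks_normality(x)
        assert p < 0.05

    def test_degenerate_rejected(self):
        with pytest.raises(ValidationError):
            ks_normality([3.0, 3.0, 3.0, 3.0])


class TestRegression:
    def test_exact_linear_fit(self):
        rng = np.random.default_rng(0)
        age = rng.uniform(10, 26, size=30)
        y = 1.5 * age - 3.0
        X = pd.DataFrame({"age": age, "noise": rng.normal(size=30)})
        res = multiple_regression(y, X)
        assert res.r_squared == pytest.approx(1.0)
        assert res.table.loc["age", "p"] < 1e-10

    def test_row_permutation_invariant(self, rng):
        X = pd.DataFrame(rng.normal(size=(25, 3)), columns=list("abc"))
        y = rng.normal(size=25)
        r1 = multiple_regression(y, X)
        perm = rng.permutation(25)
        r2 = multiple_regression(y[perm], X.iloc[perm].reset_index(drop=True))
        pd.testing.assert_frame_equal(r1.table, r2.table, atol=1e-10)

    def test_matches_normal_equations_oracle(self, rng):
        X = rng.normal(size=(20, 3))
        y = rng.normal(size=20)
        res = multiple_regression(y, pd.DataFrame(X, columns=list("xyz")))
        beta = solve_normal_equations(X, y)
        assert np.allclose(res.table["coef"].to_numpy(), beta, atol=1e-8)

    def test_partial_r_bounds(self, rng):
        X = pd.DataFrame(rng.normal(size=(30, 4)), columns=list("abcd"))
        y = rng.normal(size=30)
        res = multiple_regression(y, X)
        pr = res.table.loc[list("abcd"), "partial_r"]
        assert ((pr >= -1) & (pr <= 1)).all()

    def test_collinear_columns_named(self, rng):
        x = rng.normal(size=25)
        X = pd.DataFrame({"a": x, "b": 2 * x, "c": rng.normal(size=25)})
        with pytest.raises(ValidationError, match="collinear") as err:
            multiple_regression(rng.normal(size=25), X)
        assert "a" in str(err.value) and "b" in str(err.value)


class TestCohortSummary:
    def test_field_strength_row(self):
        """Descriptives of the 50-scanner field-strength vector (11 x 3 T,
        30 x 1.5 T, 9 x 1 T)."""
        values = [3.0] * 11 + [1.5] * 30 + [1.0] * 9
        row = cohort_summary(values, "B0")
        assert row.mean == pytest.approx(1.740, abs=5e-4)
        assert row.sd == pytest.approx(0.702, abs=5e-4)
        assert row.median == 1.5
        assert row.min == 1.0 and row.max == 3.0
        assert row.ci_low == pytest.approx(1.541, abs=1e-3)
        assert row.ci_high == pytest.approx(1.939, abs=1e-3)

    def test_trivial_row(self):
        row = cohort_summary([1.0, 2.0, 3.0], "x")
        assert row.mean == 2.0 and row.median == 2.0
        assert row.min == 1.0 and row.max == 3.0

    def test_n1_rejected(self):
        with pytest.raises(ValidationError):
            cohort_summary([1.0], "x")


def _morph(subject, observer, ari):
    return SubjectMorphometry(
        subject_id=subject, observer_id=observer, per_slice=[],
        af=ari, ae=1.0, ari=ari, ts=4.0, ns=7, vf=0.0, ve=0.0, vri=ari,
    )


class TestAverageOverObservers:
    def test_mean_of_three(self):
        morphs = [_morph("s1", o, v) for o, v in [("a", 9.0), ("b", 10.0), ("c", 11.0)]]
        assert average_over_observers(morphs) == {"s1": 10.0}

    def test_single_observer_identity(self):
        assert average_over_observers([_morph("s1", "a", 7.5)]) == {"s1": 7.5}

    def test_missing_observer_rejected(self):
        morphs = [
            _morph("s1", "a", 1.0),
            _morph("s1", "b", 2.0),
            _morph("s2", "a", 3.0),
        ]
        with pytest.raises(CompletenessError):
            average_over_observers(morphs)
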