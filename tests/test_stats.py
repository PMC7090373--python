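"""Statistical kernels vs independent brute-force oracles and library checks."""

import math
from itertools import combinations

import numpy as np
import pytest
from scipy import stats as sps

from ocor.errors import OcorError
from ocor.stats import (
    mann_whitney,
    normality_check,
    paired_t,
    rm_anova,
    tukey_quartiles,
)


class TestPairedT:
    def test_worked_example(self):
        # diffs (1, 2, 3): t = 2 / (1/sqrt(3)) = 3.464, p = 0.0742
        res = paired_t([1.0, 2.0, 3.0])
        assert res.t == pytest.approx(2 / (1 / math.sqrt(3)), rel=1e-9)
        assert res.p == pytest.approx(0.0742, abs=5e-4)

    def test_matches_scipy_on_random_pairs(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            x = rng.normal(size=9)
            y = x + rng.normal(0.3, 1.0, size=9)
            res = paired_t(y - x)
            ref = sps.ttest_rel(y, x)
            assert res.t == pytest.approx(ref.statistic, rel=1e-12)
            assert res.p == pytest.approx(ref.pvalue, rel=1e-12)

    def test_constant_nonzero_diffs_degenerate(self):
        res = paired_t([1.0, 1.0, 1.0])
        assert res.degenerate_variance
        assert res.p == 0.0 and math.isinf(res.t)

    def test_all_zero_diffs(self):
        res = paired_t([0.0, 0.0, 0.0])
        assert res.degenerate_variance
        assert res.p == 1.0 and res.t == 0.0


def brute_force_rm_anova(x):
    """Direct sums-of-squares by explicit loops (independent oracle)."""
    n, k = x.shape
    grand = x.sum() / (n * k)
    ss_sub = sum(k * (x[i].mean() - grand) ** 2 for i in range(n))
    ss_time = sum(n * (x[:, j].mean() - grand) ** 2 for j in range(k))
    ss_tot = sum((x[i, j] - grand) ** 2 for i in range(n) for j in range(k))
    ss_err = ss_tot - ss_sub - ss_time
    f = (ss_time / (k - 1)) / (ss_err / ((n - 1) * (k - 1)))
    return f


class TestRMAnova:
    def test_matches_brute_force_3x3(self):
        x = np.array([[1.0, 2.0, 1.5], [2.0, 2.5, 2.2], [0.5, 1.8, 1.1]])
        res = rm_anova(x)
        assert res.f == pytest.approx(brute_force_rm_anova(x), rel=1e-9)

    def test_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(3)
        x = rng.normal(600, 30, size=(8, 4))
        res = rm_anova(x)
        long = pd.DataFrame(
            {
                "y": x.ravel(),
                "subject": np.repeat(np.arange(8), 4),
                "time": np.tile(np.arange(4), 8),
            }
        )
        ref = pingouin.rm_anova(data=long, dv="y", within="time", subject="subject")
        assert res.f == pytest.approx(float(ref["F"].iloc[0]), rel=1e-9)
        assert res.p == pytest.approx(float(ref["p_unc"].iloc[0]), rel=1e-6)

    def test_no_time_effect_gives_f_zero(self):
        # rows shifted subject-by-subject, columns identical within subject
        x = np.array([[5.0, 5.0, 5.0], [7.0, 7.0, 7.0], [6.0, 6.0, 6.0]])
        res = rm_anova(x)
        assert res.f == 0.0 and res.p == 1.0

    def test_subject_shifts_do_not_create_time_effect(self):
        base = np.array([1.0, 2.0, 3.0])
        x = np.vstack([base + s for s in (0.0, 10.0, -5.0)])
        res = rm_anova(x)
        # pure time effect with zero error -> infinite F
        assert math.isinf(res.f) and res.p == 0.0
        # now remove the time effect, keep subject shifts
        y = np.vstack([np.full(3, s) for s in (0.0, 10.0, -5.0)])
        assert rm_anova(y).f == 0.0

    def test_f_equals_t_squared_on_two_timepoints(self):
        rng = np.random.default_rng(5)
        x = rng.normal(650, 20, size=(13, 2))
        res_f = rm_anova(x)
        res_t = paired_t(x[:, 1] - x[:, 0])
        assert res_f.f == pytest.approx(res_t.t**2, rel=1e-9)
        assert res_f.p == pytest.approx(res_t.p, rel=1e-9)


def brute_force_mw_exact_p(a, b):
    """Enumerate all assignments of the pooled sample (independent oracle)."""
    pooled = list(a) + list(b)
    n = len(a)
    def u_stat(xs, ys):
        return sum(
            1.0 if x > y else 0.5 if x == y else 0.0 for x in xs for y in ys
        )
    u_obs = u_stat(a, b)
    us = []
    for idx in combinations(range(len(pooled)), n):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(len(pooled)) if i not in idx]
        us.append(u_stat(xs, ys))
    le = sum(u <= u_obs + 1e-12 for u in us)
    ge = sum(u >= u_obs - 1e-12 for u in us)
    return min(1.0, 2.0 * min(le, ge) / len(us))


class TestMannWhitney:
    def test_separated_groups_exact(self):
        u, p = mann_whitney([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1, rel=1e-12)

    def test_exact_matches_brute_force(self):
        rng = np.random.default_rng(9)
        for _ in range(5):
            a = list(rng.integers(0, 10, size=4).astype(float))
            b = list(rng.integers(0, 10, size=5).astype(float))
            _, p = mann_whitney(a, b)
            assert p == pytest.approx(brute_force_mw_exact_p(a, b), rel=1e-12)

    def test_identical_groups(self):
        _, p_exact = mann_whitney([2.0] * 4, [2.0] * 4)
        assert p_exact >= 0.99
        _, p_approx = mann_whitney([2.0] * 12, [2.0] * 12)
        assert p_approx == pytest.approx(1.0)

    def test_u_sum_invariance(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=6)
        b = rng.normal(size=7)
        ua, _ = mann_whitney(a, b)
        ub, _ = mann_whitney(b, a)
        assert ua + ub == pytest.approx(len(a) * len(b))

    def test_approx_close_to_scipy(self):
        rng = np.random.default_rng(21)
        a = rng.normal(0, 1, size=15)
        b = rng.normal(0.8, 1, size=14)
        u, p = mann_whitney(a, b)
        ref = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        assert u == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue, rel=0.05)

    def test_empty_group_raises(self):
        with pytest.raises(OcorError):
            mann_whitney([], [1.0])


class TestNormalityCheck:
    def test_normal_samples_rarely_rejected(self):
        rng = np.random.default_rng(7)
        ps = [normality_check(rng.normal(size=20))[1] for _ in range(100)]
        assert np.mean(np.asarray(ps) > 0.05) >= 0.90

    def test_skewed_samples_usually_rejected(self):
        rng = np.random.default_rng(8)
        ps = [normality_check(rng.exponential(size=30))[1] for _ in range(100)]
        assert np.mean(np.asarray(ps) < 0.05) >= 0.90

    def test_constant_vector_raises(self):
        with pytest.raises(OcorError):
            normality_check([3.0] * 10)

    def test_n_out_of_range_raises(self):
        with pytest.raises(OcorError):
            normality_check([1.0, 2.0])


class TestTukeyQuartiles:
    def test_published_hb_column_convention(self):
        hb = [98, 104, 105, 117, 113, 93, 132, 101, 144, 184, 100, 118, 121]
        q1, med, q3 = tukey_quartiles(hb)
        assert med == 113.0
        assert q1 == 100.5
        assert q3 == 126.5

    def test_repeated_value(self):
        q1, med, q3 = tukey_quartiles([5.0] * 7)
        assert q1 == med == q3 == 5.0

    def test_even_n(self):
        q1, med, q3 = tukey_quartiles([1, 2, 3, 4])
        assert med == 2.5
        assert q1 == 1.5 and q3 == 3.5
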