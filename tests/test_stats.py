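import math
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sstats

from sicdscreen.stats import (
    PatientRecord,
    ci_halfwidth,
    compare_groups,
    load_patient_counts,
    mann_whitney_u,
    summarize_table,
    welch_t,
)

NORMAL_PRIMARY = [3, 2613, 17, 1, 0, 2, 1]
HF_PRIMARY = [8, 1024, 1280, 0, 2305, 0, 1104, 3555, 389, 5562, 13, 808, 0, 2]


def brute_force_mw_p(x, y):
    """Permutation p by re-deriving U from pairwise win counts (independent
    of the implementation's rank-sum route)."""

    def u_min(a, b):
        wins = sum(1.0 if xi > yi else 0.5 if xi == yi else 0.0 for xi in a for yi in b)
        return min(wins, len(a) * len(b) - wins)

    pooled = list(x) + list(y)
    n1 = len(x)
    obs = u_min(x, y)
    hits = total = 0
    for idx in combinations(range(len(pooled)), n1):
        a = [pooled[i] for i in idx]
        b = [pooled[i] for i in range(len(pooled)) if i not in idx]
        total += 1
        if u_min(a, b) <= obs + 1e-12:
            hits += 1
    return hits / total


class TestWelch:
    def test_identical_samples(self):
        t, df, p = welch_t([1, 2, 3], [1, 2, 3])
        assert t == 0.0
        assert p == pytest.approx(1.0)

    def test_matches_closed_form(self):
        x, y = [2.0, 4.0, 6.0, 8.0], [1.0, 2.0, 3.0]
        t, df, p = welch_t(x, y)
        # hand evaluation of the Welch formula
        sx2 = np.var(x, ddof=1) / len(x)
        sy2 = np.var(y, ddof=1) / len(y)
        t_hand = (np.mean(x) - np.mean(y)) / math.sqrt(sx2 + sy2)
        df_hand = (sx2 + sy2) ** 2 / (sx2**2 / 3 + sy2**2 / 2)
        assert t == pytest.approx(t_hand, abs=1e-12)
        assert df == pytest.approx(df_hand, abs=1e-12)
        # independent route: scipy's Welch test
        res = sstats.ttest_ind(x, y, equal_var=False)
        assert t == pytest.approx(res.statistic, abs=1e-12)
        assert p == pytest.approx(res.pvalue, abs=1e-12)

    def test_reduces_to_student_t_for_equal_groups(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 10)
        y = rng.normal(0.5, 1, 10)
        # force exactly equal sample variances by construction
        y = (y - y.mean()) / y.std(ddof=1) * x.std(ddof=1) + y.mean()
        t, df, p = welch_t(x, y)
        student = sstats.ttest_ind(x, y, equal_var=True)
        assert t == pytest.approx(student.statistic, abs=1e-12)
        assert df == pytest.approx(18.0, abs=1e-9)

    def test_sign_flips_on_swap(self):
        x, y = [2.0, 4.0, 6.0], [1.0, 2.0, 3.0]
        t1, _, p1 = welch_t(x, y)
        t2, _, p2 = welch_t(y, x)
        assert t1 == -t2
        assert p1 == p2

    def test_zero_variance_both_errors(self):
        with pytest.raises(ValueError):
            welch_t([1.0, 1.0], [2.0, 2.0])

    def test_too_small_errors(self):
        with pytest.raises(ValueError):
            welch_t([1.0], [1.0, 2.0])


class TestMannWhitney:
    def test_complete_separation(self):
        u, _ = mann_whitney_u([1, 2], [3, 4])
        assert u == 0

    def test_interleaved(self):
        u, _ = mann_whitney_u([1, 3], [2, 4])
        assert u == 1

    def test_u_complement_identity(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            x = rng.normal(size=rng.integers(2, 8))
            y = rng.normal(size=rng.integers(2, 8))
            from sicdscreen.stats import _u_statistics

            u1, u2 = _u_statistics(x, y)
            assert u1 + u2 == pytest.approx(len(x) * len(y))

    @pytest.mark.parametrize("n1,n2", [(2, 2), (3, 3), (4, 3), (5, 5), (2, 6), (4, 6)])
    def test_exact_p_equals_brute_force(self, n1, n2):
        rng = np.random.default_rng(n1 * 10 + n2)
        for _ in range(3):
            x = rng.normal(size=n1)
            y = rng.normal(size=n2)
            _, p = mann_whitney_u(x, y)
            assert p == pytest.approx(brute_force_mw_p(x, y), abs=1e-12)

    def test_exact_p_matches_scipy(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=4)
        y = rng.normal(size=5)
        _, p = mann_whitney_u(x, y)
        ref = sstats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_large_sample_normal_approximation(self):
        rng = np.random.default_rng(6)
        x = rng.normal(0, 1, 40)
        y = rng.normal(0.8, 1, 35)
        _, p = mann_whitney_u(x, y)
        ref = sstats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        assert p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])


class TestCiHalfwidth:
    def test_published_normal_primary(self):
        assert round(ci_halfwidth(NORMAL_PRIMARY)) == 731

    def test_published_hf_primary(self):
        assert round(ci_halfwidth(HF_PRIMARY)) == 862

    def test_constant_list(self):
        assert ci_halfwidth([5.0, 5.0, 5.0]) == 0.0

    def test_n_below_two_errors(self):
        with pytest.raises(ValueError):
            ci_halfwidth([1.0])


class TestSummarizeTable:
    def test_reproduces_all_printed_values(self):
        """Full-row regression against the published per-patient counts."""
        df = summarize_table(load_patient_counts()).set_index(["group", "vector"])
        printed = {
            ("Normal", "primary"): (7, 377, 731),
            ("Normal", "alternate"): (7, 230, 301),
            ("Normal", "secondary"): (7, 45, 76),
            ("HF", "primary"): (14, 1146, 862),
            ("HF", "alternate"): (14, 841, 640),
            ("HF", "secondary"): (8, 934, 1105),  # NA-excluded n = 8
        }
        for key, (n, mean, ci) in printed.items():
            row = df.loc[key]
            assert row["n"] == n
            assert row["mean_count_display"] == mean
            assert row["ci_halfwidth_display"] == ci

    def test_mean_percentages(self):
        df = summarize_table(load_patient_counts()).set_index(["group", "vector"])
        assert df.loc[("HF", "primary"), "mean_percent"] == pytest.approx(13.3, abs=0.05)
        assert df.loc[("HF", "alternate"), "mean_percent"] == pytest.approx(9.7, abs=0.05)
        assert df.loc[("HF", "secondary"), "mean_percent"] == pytest.approx(10.8, abs=0.05)

    def test_all_zero_column(self):
        recs = [
            PatientRecord(i, "Normal", {"primary": 0, "alternate": 0, "secondary": 0})
            for i in range(3)
        ]
        df = summarize_table(recs).set_index(["group", "vector"])
        assert df.loc[("Normal", "primary"), "mean_count"] == 0.0
        assert df.loc[("Normal", "primary"), "ci_halfwidth"] == 0.0

    def test_count_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            PatientRecord(1, "Normal", {"primary": 9000})

    def test_packaged_fixture_shape(self):
        records = load_patient_counts()
        assert len(records) == 21
        assert sum(1 for r in records if r.group == "HF") == 14
        na_secondary = [r for r in records if r.counts["secondary"] is None]
        assert len(na_secondary) == 6  # patients 8-13


class TestCompareGroups:
    def make_frame(self, hf_mean, nm_mean, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for i in range(14):
            rows.append(("HF", rng.normal(hf_mean, 0.04), rng.normal(0.09, 0.02)))
        for i in range(7):
            rows.append(("Normal", rng.normal(nm_mean, 0.03), rng.normal(0.067, 0.018)))
        return pd.DataFrame(rows, columns=["group", "mean_tr", "sd_tr"])

    def test_separated_groups_significant(self):
        out = compare_groups(self.make_frame(0.18, 0.10))
        assert out["mean_tr"].welch_p < 0.001
        assert out["mean_tr"].mean_hf > out["mean_tr"].mean_normal

    def test_swapped_labels_flip_sign(self):
        df = self.make_frame(0.18, 0.10)
        swapped = df.assign(group=df["group"].map({"HF": "Normal", "Normal": "HF"}))
        a = compare_groups(df)["mean_tr"]
        b = compare_groups(swapped)["mean_tr"]
        assert a.welch_t == pytest.approx(-b.welch_t)
        assert a.welch_p == pytest.approx(b.welch_p)

    def test_identical_groups_nonsignificant(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(0.15, 0.05, 7)
        df = pd.DataFrame(
            {
                "group": ["HF"] * 7 + ["Normal"] * 7,
                "mean_tr": np.concatenate([vals, vals]),
                "sd_tr": np.concatenate([vals, vals]),
            }
        )
        out = compare_groups(df)
        assert out["mean_tr"].welch_t == 0.0
        assert out["mean_tr"].welch_p == pytest.approx(1.0)
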