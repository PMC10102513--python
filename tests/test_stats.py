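import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from gazenet import (
    compare_tasks,
    friedman_kendall,
    kendall_w_from_chi2,
    pairwise_wilcoxon,
    rank_regression,
)
from gazenet.stats import _friedman_chi2, interpret_w


def permutation_friedman_p(blocks):
    """Independent oracle: exact null over within-block rank permutations."""
    blocks = np.asarray(blocks, float)
    n, k = blocks.shape
    obs = _friedman_chi2(blocks)
    ranks = np.apply_along_axis(sps.rankdata, 1, blocks)
    den = np.sum(ranks**2) - n * k * (k + 1) ** 2 / 4.0
    count = total = 0
    for combo in itertools.product(itertools.permutations(range(k)), repeat=n):
        col = sum(ranks[b, list(pi)] for b, pi in enumerate(combo))
        stat = (k - 1) * np.sum((col - n * (k + 1) / 2.0) ** 2) / den
        total += 1
        if stat >= obs - 1e-12:
            count += 1
    return count / total


class TestFriedmanKendall:
    def test_statistic_matches_scipy(self):
        rng = np.random.default_rng(3)
        blocks = rng.normal(size=(12, 4))
        res = friedman_kendall(blocks, p_method="chi2")
        ref = sps.friedmanchisquare(*blocks.T)
        assert res.chi2 == pytest.approx(ref.statistic)
        assert res.p == pytest.approx(ref.pvalue)
        assert res.df == 3

    def test_w_relation_holds(self):
        rng = np.random.default_rng(9)
        blocks = rng.normal(size=(10, 4))
        res = friedman_kendall(blocks)
        assert res.W == pytest.approx(res.chi2 / (10 * 3))

    def test_perfect_concordance(self):
        blocks = np.array([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]])
        res = friedman_kendall(blocks)
        assert res.W == pytest.approx(1.0)
        assert res.chi2 == pytest.approx(2 * (3 - 1))  # N(k-1)

    def test_exact_p_equals_permutation_oracle(self):
        rng = np.random.default_rng(0)
        blocks = rng.normal(size=(4, 3))
        res = friedman_kendall(blocks, p_method="exact")
        assert res.p == pytest.approx(permutation_friedman_p(blocks))

    def test_auto_uses_exact_for_tiny_and_chi2_for_large(self):
        rng = np.random.default_rng(1)
        assert friedman_kendall(rng.normal(size=(4, 3))).p_method == "exact"
        assert friedman_kendall(rng.normal(size=(40, 4))).p_method == "chi2"

    def test_constant_rows_allowed(self):
        blocks = np.array([[1.0, 1.0, 1.0], [2.0, 2.0, 2.0], [1, 2, 3]])
        res = friedman_kendall(blocks)
        assert np.isfinite(res.chi2)

    def test_incomplete_blocks_rejected(self):
        blocks = np.array([[1.0, 2.0], [np.nan, 1.0]])
        with pytest.raises(ValueError, match="incomplete"):
            friedman_kendall(blocks)

    @pytest.mark.parametrize(
        "w,label",
        [(0.05, "negligible"), (0.15, "small"), (0.35, "medium"), (0.9, "large")],
    )
    def test_effect_size_labels(self, w, label):
        assert interpret_w(w) == label


def wilcoxon_sign_enumeration_p(d):
    """Oracle: exact two-sided p over all 2^n sign assignments."""
    d = np.asarray(d, float)
    d = d[d != 0]
    n = len(d)
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    mu = n * (n + 1) / 4
    count = 0
    for signs in itertools.product([0, 1], repeat=n):
        w = ranks[np.array(signs, bool)].sum()
        if abs(w - mu) >= abs(w_obs - mu) - 1e-12:
            count += 1
    return count / 2**n


class TestPairwiseWilcoxon:
    @staticmethod
    def cohort_from(wide: dict) -> pd.DataFrame:
        rows = []
        for task, vals in wide.items():
            for i, v in enumerate(vals):
                rows.append({"subject_id": f"S{i}", "task": task, "y": v})
        return pd.DataFrame(rows)

    def test_identical_samples_give_p_one(self):
        c = self.cohort_from({"A": [1, 2, 3, 4], "B": [1, 2, 3, 4]})
        (res,) = pairwise_wilcoxon(c, "y", tasks=("A", "B"))
        assert res.p_adj == 1.0
        assert res.n_pairs == 0

    def test_six_positive_differences_exact_p(self):
        # all six differences positive: the most extreme of the 2^6 sign
        # patterns, one-tailed p = 1/64, two-sided 1/32
        c = self.cohort_from({"A": [2, 3.5, 5, 6.5, 8, 9.5], "B": [1, 2, 3, 4, 5, 6]})
        (res,) = pairwise_wilcoxon(c, "y", tasks=("A", "B"))
        assert res.p_raw == pytest.approx(1 / 32)  # 2 * (1/64)

    def test_bonferroni_factor_is_pair_count(self):
        rng = np.random.default_rng(2)
        c = self.cohort_from({t: rng.normal(size=10) for t in "ABCD"})
        results = pairwise_wilcoxon(c, "y")
        assert len(results) == 6
        for r in results:
            assert r.p_adj == pytest.approx(min(1.0, 6 * r.p_raw))

    def test_exact_p_matches_sign_enumeration(self):
        rng = np.random.default_rng(8)
        for _ in range(5):
            a = rng.normal(size=9)
            b = a + rng.normal(size=9)
            c = self.cohort_from({"A": a, "B": b})
            (res,) = pairwise_wilcoxon(c, "y", tasks=("A", "B"))
            assert res.p_raw == pytest.approx(wilcoxon_sign_enumeration_p(a - b))

    def test_statistic_is_positive_rank_sum(self):
        c = self.cohort_from({"A": [2, 3, 4], "B": [1, 2, 3]})
        (res,) = pairwise_wilcoxon(c, "y", tasks=("A", "B"))
        assert res.statistic == 6.0  # all three positive, ranks 1+2+3


class TestRankRegression:
    def test_noiseless_linear_fit(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 10, 20)
        y = 2 * x + 1
        res = rank_regression(y, x)
        assert res.coef[0] == pytest.approx(2.0, abs=1e-6)
        assert res.intercept == pytest.approx(1.0, abs=1e-6)
        assert res.R2 == pytest.approx(1.0, abs=1e-6)

    def test_robust_to_gross_outliers(self):
        rng = np.random.default_rng(4)
        x = np.linspace(0, 10, 40)
        y = x + rng.normal(0, 0.3, 40)
        y[3] += 40.0
        y[17] -= 35.0
        res = rank_regression(y, x)
        # closed-form least squares on the same data
        xc = x - x.mean()
        b_ols = (xc * (y - y.mean())).sum() / (xc**2).sum()
        assert abs(res.coef[0] - 1.0) < abs(b_ols - 1.0)

    def test_null_relation_gives_small_r2(self):
        r2 = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            y = rng.normal(size=200)
            X = rng.normal(size=(200, 2))
            r2.append(rank_regression(y, X).R2)
        assert np.mean(r2) < 0.1
        assert np.max(r2) < 0.2

    def test_scale_equivariance(self):
        rng = np.random.default_rng(6)
        x = rng.uniform(0, 5, 30)
        y = 3 * x + rng.normal(0, 0.5, 30)
        a = rank_regression(y, x)
        b = rank_regression(10 * y + 7, x)
        assert b.coef[0] == pytest.approx(10 * a.coef[0], rel=1e-4)
        assert b.R2 == pytest.approx(a.R2, abs=1e-6)

    def test_collinear_error_names_columns(self):
        rng = np.random.default_rng(1)
        x1 = rng.normal(size=25)
        X = np.column_stack([x1, x1 - 1.0, rng.normal(size=25)])
        with pytest.raises(ValueError, match="collinear") as err:
            rank_regression(rng.normal(size=25), X, predictors=["a", "alias", "b"])
        assert "alias" in str(err.value) or "a" in str(err.value)

    def test_collinear_drop_mode_records_column(self):
        rng = np.random.default_rng(1)
        x1 = rng.normal(size=25)
        X = np.column_stack([x1, x1 - 1.0])
        res = rank_regression(2 * x1, X, predictors=["a", "alias"], on_collinear="drop")
        assert len(res.dropped) == 1
        assert len(res.predictors) == 1

    def test_too_few_observations(self):
        with pytest.raises(ValueError, match="n >"):
            rank_regression([1.0, 2.0], np.array([[1.0], [2.0]]))


class TestCompareTasks:
    @staticmethod
    def synthetic_cohort(n=12, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for i in range(n):
            base = rng.normal()
            for j, task in enumerate(("N-num", "N-cha", "N-obj", "N-col")):
                t_total = 15 + 5 * j + rng.normal(0, 2)
                rows.append(
                    {
                        "subject_id": f"S{i}",
                        "task": task,
                        "avg_degree": 1.5 * t_total + rng.normal(0, 0.1),
                        "modularity": 0.8 + 0.02 * base + rng.normal(0, 0.01),
                        "total_time": t_total,
                        "avg_fix_duration": 300 + rng.normal(0, 20),
                        "fixation_counts": 55 + rng.integers(0, 10),
                        "avg_saccade_amplitude": 150 + rng.normal(0, 10),
                        "saccade_counts": 54 + rng.integers(0, 10),
                        "regression_counts": int(rng.integers(0, 6)),
                    }
                )
        return pd.DataFrame(rows)

    def test_report_structure(self):
        report = compare_tasks(self.synthetic_cohort(), parameters=("avg_degree", "modularity"))
        assert set(report.friedman) == {"avg_degree", "modularity"}
        assert len(report.pairwise["avg_degree"]) == 6
        assert ("avg_degree", "N-num") in report.regressions
        assert report.friedman["avg_degree"].W > 0.8  # strong task ordering built in

    def test_incomplete_blocks_reported(self):
        cohort = self.synthetic_cohort().iloc[:-1]  # drop one task of last subject
        with pytest.raises(ValueError, match="incomplete blocks"):
            compare_tasks(cohort, parameters=("avg_degree",))

    def test_duplicate_keys_rejected(self):
        cohort = self.synthetic_cohort()
        dup = pd.concat([cohort, cohort.iloc[[0]]])
        with pytest.raises(ValueError, match="duplicated"):
            compare_tasks(dup, parameters=("avg_degree",))

    def test_json_roundtrip_deterministic(self, tmp_path):
        report = compare_tasks(self.synthetic_cohort(), parameters=("avg_degree",))
        a = report.to_json(tmp_path / "a.json")
        b = compare_tasks(self.synthetic_cohort(), parameters=("avg_degree",)).to_json()
        assert a == b

    def test_type_i_error_controlled_under_null(self):
        # two identically generated tasks: adjusted p not systematically small
        rejections = 0
        n_rep = 100
        for rep in range(n_rep):
            rng = np.random.default_rng(rep)
            rows = []
            for i in range(12):
                for task in ("A", "B"):
                    rows.append({"subject_id": f"S{i}", "task": task, "y": rng.normal()})
            c = pd.DataFrame(rows)
            (res,) = pairwise_wilcoxon(c, "y", tasks=("A", "B"), correction="none")
            rejections += res.p_raw < 0.05
        assert rejections / n_rep <= 0.08
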