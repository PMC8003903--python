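import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

from chondroquant.longstats import (
    StatsConfig,
    cohort_matrix,
    effect_size,
    friedman,
    paired_t,
    rm_anova,
    run_severity_analysis,
    shapiro_wilk,
    wilcoxon_signed_rank,
)
from chondroquant.phantom import ProgressionModel, simulate_measure_table


class TestShapiroWilk:
    def test_symmetric_tiny_sample(self):
        w, p = shapiro_wilk([-1.0, 0.0, 1.0])
        assert w > 0.99  # reference implementations give W = 1 here

    def test_skewed_sample_rejected(self, rng):
        x = rng.exponential(size=50)
        _, p = shapiro_wilk(x)
        assert p < 0.01

    def test_normal_rejection_rate(self, rng):
        rejections = sum(shapiro_wilk(rng.normal(size=50))[1] < 0.05 for _ in range(500))
        # binomial 99.9% interval around 5% of 500
        assert 10 <= rejections <= 44

    def test_constant_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            shapiro_wilk([2.0, 2.0, 2.0, 2.0])


class TestFriedman:
    def test_hand_computed_example(self):
        res = friedman(np.array([[1, 2, 3]] * 3, dtype=float))
        assert res.statistic == pytest.approx(6.0)
        assert res.df == 2
        # the extreme statistic needs all 3 rows concordant in one of the
        # 6 shared orderings: 6 of the 6^3 equally likely assignments
        assert res.pvalue == pytest.approx(6 / 6**3)

    def test_identical_columns(self):
        res = friedman(np.tile(np.arange(4.0)[:, None], (1, 3)))
        assert res.statistic == 0.0
        assert res.pvalue == 1.0

    def test_exact_matches_permutation_oracle(self, rng):
        for _ in range(3):
            m = rng.normal(size=(10, 3))
            res = friedman(m, method="exact")
            ranks = np.vstack([rankdata(r) for r in m])
            s_obs = float((ranks.sum(axis=0) ** 2).sum())
            perms = np.array(list(itertools.permutations([1.0, 2.0, 3.0])))
            n_mc = 100_000
            choice = rng.integers(0, 6, size=(n_mc, 10))
            colsums = perms[choice].sum(axis=1)
            p_mc = float(((colsums**2).sum(axis=1) >= s_obs - 1e-9).mean())
            mc_err = 4 * np.sqrt(p_mc * (1 - p_mc) / n_mc) + 1e-3
            assert abs(res.pvalue - p_mc) < mc_err

    def test_monotone_transform_invariance(self, rng):
        m = rng.normal(size=(8, 3))
        res1 = friedman(m)
        res2 = friedman(np.exp(m))  # strictly monotone per row
        assert res1.statistic == res2.statistic
        assert res1.pvalue == res2.pvalue

    def test_ties_handled(self):
        m = np.array([[1.0, 1.0, 2.0], [3.0, 2.0, 2.0], [1.0, 2.0, 3.0]])
        res = friedman(m)
        assert 0 <= res.pvalue <= 1

    def test_missing_cells_rejected(self):
        m = np.array([[1.0, 2.0, np.nan], [1.0, 2.0, 3.0]])
        with pytest.raises(ValueError, match="complete"):
            friedman(m)

    def test_chisq_fallback_for_large_n(self, rng):
        m = rng.normal(size=(50, 3))
        res = friedman(m)
        assert res.method == "chisq"


class TestWilcoxon:
    def test_worked_example(self):
        res = wilcoxon_signed_rank(np.array([1.0, -2.0, 3.0, 4.0, 5.0]))
        assert res.statistic == 2.0
        assert res.pvalue == pytest.approx(6 / 32)
        assert res.method == "exact"

    def test_all_zero_degenerate(self):
        res = wilcoxon_signed_rank(np.zeros(6), np.zeros(6))
        assert res.degenerate

    def test_exact_matches_enumeration(self, rng):
        for n in (6, 9, 12):
            d = rng.normal(0.4, 1.0, n)
            res = wilcoxon_signed_rank(d)
            ranks = rankdata(np.abs(d))
            total = ranks.sum()
            w_all = np.array(
                [sum(r for r, s in zip(ranks, bits) if s)
                 for bits in itertools.product([0, 1], repeat=n)]
            )
            w = min(res.statistic, total - res.statistic)
            p_oracle = min(1.0, ((w_all <= w).sum() + (w_all >= total - w).sum()) / 2**n)
            assert abs(res.pvalue - p_oracle) < 1e-12

    def test_approx_mode_reasonable(self, rng):
        x = rng.normal(0.8, 1.0, 60)
        res = wilcoxon_signed_rank(x, mode="approx")
        assert res.method == "approx"
        assert res.pvalue < 0.001

    def test_pratt_zero_method_runs(self):
        d = np.array([0.0, 1.0, -2.0, 3.0, 4.0, 0.0, 5.0, -1.5])
        res = wilcoxon_signed_rank(d, zero_method="pratt")
        assert 0 <= res.pvalue <= 1


class TestRMAnova:
    def test_identical_columns(self):
        m = np.tile(np.random.default_rng(0).normal(size=(5, 1)), (1, 3))
        res = rm_anova(m)
        assert res.f == 0.0 and res.pvalue == 1.0

    def test_ss_decomposition_oracle(self, rng):
        m = rng.normal(size=(4, 3))
        res = rm_anova(m)
        gm = m.mean()
        ss_time = 4 * ((m.mean(axis=0) - gm) ** 2).sum()
        ss_subj = 3 * ((m.mean(axis=1) - gm) ** 2).sum()
        ss_err = ((m - gm) ** 2).sum() - ss_time - ss_subj
        f_oracle = (ss_time / 2) / (ss_err / 6)
        assert res.f == pytest.approx(f_oracle, rel=1e-12)
        assert res.df1 == 2 and res.df2 == 6

    def test_null_type_i_error(self, rng):
        hits = 0
        reps = 1000
        for _ in range(reps):
            m = rng.normal(size=(10, 3))
            if rm_anova(m).pvalue < 0.05:
                hits += 1
        # binomial 99.9% interval around 0.05 * 1000
        assert 28 <= hits <= 75

    def test_gg_correction_reduces_df(self, rng):
        m = rng.normal(size=(8, 4))
        m[:, 0] += m[:, 1]  # induce non-sphericity
        res = rm_anova(m, gg_correction=True)
        assert res.epsilon < 1.0
        assert res.df1 < 3

    def test_missing_cells_rejected(self):
        with pytest.raises(ValueError, match="complete"):
            rm_anova(np.array([[1.0, np.nan], [2.0, 3.0]]))


class TestPairedTAndEffectSize:
    def test_constant_differences_degenerate(self):
        x = np.arange(5.0)
        res = paired_t(x + 1.0, x)
        assert res.degenerate

    def test_x_equals_y(self):
        x = np.random.default_rng(0).normal(size=10)
        assert np.isnan(effect_size(x, x, "parametric"))  # sd of d is 0
        res = wilcoxon_signed_rank(x, x)
        assert res.degenerate

    def test_effect_size_simulation(self, rng):
        d = rng.normal(0.8, 1.0, 10_000)
        es = effect_size(d, np.zeros_like(d), "parametric")
        assert abs(es - 0.8) < 0.03

    def test_nonparametric_effect_size_bounded(self, rng):
        x = rng.normal(1.0, 0.1, 30)
        es = effect_size(x, np.zeros_like(x), "nonparametric")
        # all-positive differences: |Z|/sqrt(n) at its maximum for n=30
        assert es == pytest.approx(np.sqrt(3 * 30 * (30 + 1) / (2 * (2 * 30 + 1))) / np.sqrt(30))

    def test_paired_t_matches_scipy(self, rng):
        from scipy.stats import ttest_rel

        x, y = rng.normal(size=20), rng.normal(size=20)
        res = paired_t(x, y)
        ref = ttest_rel(x, y)
        assert res.t == pytest.approx(ref.statistic)
        assert res.pvalue == pytest.approx(ref.pvalue)


def _table_from_matrix(m, measure="Mc_T2"):
    rows = []
    for knee, row in enumerate(m):
        for tp, v in zip(("KL1", "KL2", "KL3"), row):
            rows.append({"knee": knee, "timepoint": tp, "measure": measure, "value": v})
    return pd.DataFrame(rows)


class TestRunSeverityAnalysis:
    def test_all_identical_no_significance(self, rng):
        base = rng.normal(40, 5, size=8)
        m = np.tile(base[:, None], (1, 3))
        table = pd.concat(
            [_table_from_matrix(m, "Mc_T2"), _table_from_matrix(m * 0.05, "Mc_thickness")]
        )
        res = run_severity_analysis(table)
        assert not res["significant"].any()
        assert (res["comparison"] == "omnibus").all()  # gate: no post-hoc run

    def test_gatekeeping_no_pairwise_without_omnibus(self, rng):
        model = ProgressionModel()  # null
        for seed in range(5):
            table = simulate_measure_table(10, model, seed=seed)
            res = run_severity_analysis(table)
            omnibus = res[res.comparison == "omnibus"].set_index("measure")
            for measure, grp in res[res.comparison != "omnibus"].groupby("measure"):
                assert omnibus.loc[measure, "significant"]

    def test_family_gate_choices(self, rng):
        model = ProgressionModel(t2_multipliers={"KL2": {"all": 1.3}},
                                 thickness_multipliers={"KL2": {"all": 1.3}})
        table = simulate_measure_table(10, model, seed=1)
        res = run_severity_analysis(table)
        t2_tests = res[res.measure.str.endswith("_T2") & (res.comparison == "omnibus")]
        th_tests = res[res.measure.str.endswith("_thickness") & (res.comparison == "omnibus")]
        assert (t2_tests.test == "friedman").all()
        assert (th_tests.test == "rm_anova").all()

    def test_effect_recovery(self):
        model = ProgressionModel(t2_multipliers={"KL2": {"M": 1.2}, "KL3": {"M": 1.2}})
        table = simulate_measure_table(19, model, seed=4)
        res = run_severity_analysis(table)
        row = res[(res.measure == "Mc_T2") & (res.comparison == "KL1-KL2")]
        assert len(row) == 1 and bool(row.significant.iloc[0])
        assert row.effect_size.iloc[0] > 0.5
        lc = res[(res.measure == "Lc_T2") & (res.comparison == "omnibus")]
        assert not bool(lc.significant.iloc[0])

    def test_bonferroni_threshold_is_strict_printed_value(self, rng):
        cfg = StatsConfig()
        assert cfg.bonferroni_alpha == 0.017

    def test_incomplete_knees_dropped(self):
        m = np.random.default_rng(0).normal(size=(6, 3))
        table = _table_from_matrix(m)
        table = table[~((table.knee == 5) & (table.timepoint == "KL3"))]
        mat, dropped = cohort_matrix(table, "Mc_T2")
        assert mat.shape == (5, 3) and dropped == 1

    def test_shapiro_gate_mode(self, rng):
        model = ProgressionModel()
        table = simulate_measure_table(10, model, seed=2)
        res = run_severity_analysis(table, StatsConfig(gate="shapiro"))
        assert set(res.test) <= {"friedman", "rm_anova"}
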