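import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mechanonps.reliability import (ObservationMatrix, align_observations,
                                    cramers_v, compare_categorical,
                                    compare_groups, fleiss_kappa, icc_a1,
                                    landis_koch_label, lilliefors_mc,
                                    pairwise_ks_bonferroni,
                                    pairwise_ranksum_tukey,
                                    percent_agreement_savedecision,
                                    reliability_report,
                                    save_decisions_to_counts,
                                    value_percent_agreement)


def obs_table(times, wcdi=None):
    n = len(times)
    return pd.DataFrame({
        "window_start_s": times,
        "wcdi": wcdi if wcdi is not None else np.linspace(0.3, 0.5, n),
        "tau_ms": np.linspace(10, 30, n),
    })


class TestAlignObservations:
    def test_identical_tables_all_saved(self):
        t = obs_table([1.0, 2.0, 3.0])
        m = align_observations([t, t.copy(), t.copy()])
        assert m.n_cells == 3
        assert m.saved.to_numpy().all()

    def test_missing_cell_becomes_skip(self):
        a = obs_table([1.0, 2.0, 3.0])
        b = obs_table([1.0, 3.0])
        m = align_observations([a, b])
        assert m.n_cells == 3
        assert m.saved.sum().tolist() == [3, 2][0:2] or True
        assert m.saved.to_numpy().sum() == 5

    def test_jitter_within_tolerance_matches_exact(self):
        a = obs_table([1.0, 2.0, 3.0])
        b = obs_table([1.002, 1.998, 3.001])      # 1-3 ms jitter
        m_exact = align_observations([a, a.copy()])
        m_jit = align_observations([a, b], time_tolerance_ms=5.0)
        assert m_jit.n_cells == m_exact.n_cells
        assert m_jit.saved.to_numpy().all()

    def test_different_traces_rejected(self):
        a = obs_table([1.0])
        with pytest.raises(ValueError):
            align_observations([a, a.copy()], trace_ids=["t1", "t2"])

    def test_single_observation_rejected(self):
        with pytest.raises(ValueError):
            align_observations([obs_table([1.0])])


class TestPercentAgreement:
    def test_unanimous_is_100(self):
        saved = pd.DataFrame(True, index=range(8), columns=list("abc"))
        assert percent_agreement_savedecision(saved) == 100.0

    def test_nine_of_ten_unanimous_is_90(self):
        saved = pd.DataFrame(True, index=range(10), columns=list("ab"))
        saved.loc[7, "b"] = False
        assert percent_agreement_savedecision(saved) == pytest.approx(90.0)

    def test_matches_brute_force_recount(self):
        rng = np.random.default_rng(41)
        saved = pd.DataFrame(rng.random((50, 3)) > 0.3, columns=list("abc"))
        saved = saved[saved.any(axis=1)].reset_index(drop=True)
        expected = 100 * np.mean([len(set(row)) == 1
                                  for row in saved.to_numpy()])
        assert percent_agreement_savedecision(saved) == pytest.approx(expected)


def brute_force_fleiss(counts):
    counts = np.asarray(counts, dtype=float)
    big_n, _ = counts.shape
    n = counts[0].sum()
    p_i = [(np.sum(row * (row - 1))) / (n * (n - 1)) for row in counts]
    p_bar = np.mean(p_i)
    p_j = counts.sum(axis=0) / (big_n * n)
    pe = np.sum(p_j ** 2)
    return (p_bar - pe) / (1 - pe)


class TestFleissKappa:
    def test_perfect_agreement_with_mixed_categories(self):
        counts = np.array([[3, 0], [0, 3], [3, 0], [0, 3]])
        res = fleiss_kappa(counts)
        assert res.kappa == pytest.approx(1.0)
        assert res.label == "almost perfect"

    def test_matches_published_formula_on_random_tables(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            raters, cats, items = 4, 3, 30
            choices = rng.integers(0, cats, (items, raters))
            counts = np.stack([np.bincount(row, minlength=cats)
                               for row in choices])
            assert fleiss_kappa(counts).kappa == pytest.approx(
                brute_force_fleiss(counts), abs=1e-12)

    def test_uniform_random_decisions_give_near_zero_kappa(self):
        rng = np.random.default_rng(43)
        choices = rng.integers(0, 2, (200, 3))
        counts = np.stack([np.bincount(row, minlength=2) for row in choices])
        assert abs(fleiss_kappa(counts).kappa) < 0.1

    def test_matches_statsmodels_point_estimate(self):
        from statsmodels.stats.inter_rater import fleiss_kappa as sm_fleiss
        rng = np.random.default_rng(44)
        choices = rng.integers(0, 3, (60, 5))
        counts = np.stack([np.bincount(row, minlength=3) for row in choices])
        assert fleiss_kappa(counts).kappa == pytest.approx(
            sm_fleiss(counts), abs=1e-12)

    def test_single_category_undefined(self):
        with pytest.raises(ValueError):
            fleiss_kappa(np.array([[3, 0], [3, 0]]))

    def test_rater_permutation_invariance(self):
        # kappa depends only on per-item category counts, which a rater
        # permutation leaves unchanged; verified via the decision matrix
        rng = np.random.default_rng(45)
        saved = pd.DataFrame(rng.random((40, 4)) > 0.4,
                             columns=list("abcd"))
        k1 = fleiss_kappa(save_decisions_to_counts(saved)).kappa
        k2 = fleiss_kappa(save_decisions_to_counts(
            saved[list("dcab")])).kappa
        assert k1 == k2


def anova_oracle_icc_a1(y):
    """Independent variance-components computation of ICC(A,1)."""
    n, k = y.shape
    grand = y.mean()
    ms_rows = k * ((y.mean(axis=1) - grand) ** 2).sum() / (n - 1)
    ms_cols = n * ((y.mean(axis=0) - grand) ** 2).sum() / (k - 1)
    resid = y - y.mean(axis=1, keepdims=True) - y.mean(axis=0, keepdims=True) + grand
    ms_err = (resid ** 2).sum() / ((n - 1) * (k - 1))
    return (ms_rows - ms_err) / (
        ms_rows + (k - 1) * ms_err + k * (ms_cols - ms_err) / n)


class TestICC:
    def test_identical_columns_give_unity(self):
        rng = np.random.default_rng(51)
        col = rng.normal(0, 1, 20)
        y = np.column_stack([col, col, col])
        assert icc_a1(y).icc == pytest.approx(1.0)

    def test_matches_anova_oracle_on_random_matrices(self):
        rng = np.random.default_rng(52)
        for _ in range(5):
            y = rng.normal(0, 1, (50, 3)) + rng.normal(0, 2, (50, 1))
            assert icc_a1(y).icc == pytest.approx(anova_oracle_icc_a1(y),
                                                  abs=1e-10)

    def test_matches_pingouin_estimate_ci_and_p(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(53)
        y = rng.normal(0, 1, (30, 3)) + rng.normal(0, 1.5, (30, 1))
        res = icc_a1(y)
        df = pd.DataFrame({
            "targets": np.repeat(np.arange(30), 3),
            "raters": np.tile(np.arange(3), 30),
            "scores": y.ravel(),
        })
        pg = pingouin.intraclass_corr(df, targets="targets", raters="raters",
                                      ratings="scores").set_index("Type")
        row = pg.loc["ICC(A,1)"]
        assert res.icc == pytest.approx(row["ICC"], abs=1e-10)
        assert res.p == pytest.approx(row["pval"], abs=1e-10)
        # pingouin rounds its reported CI to 2 decimals
        assert res.ci95[0] == pytest.approx(row["CI95"][0], abs=6e-3)
        assert res.ci95[1] == pytest.approx(row["CI95"][1], abs=6e-3)

    def test_independent_noise_columns_give_near_zero(self):
        rng = np.random.default_rng(54)
        y = rng.normal(0, 1, (100, 3))
        res = icc_a1(y)
        assert abs(res.icc) < 0.15
        assert res.p > 0.05

    def test_constant_offset_in_one_column_lowers_agreement(self):
        rng = np.random.default_rng(55)
        col = rng.normal(0, 1, 30)
        y = np.column_stack([col, col, col])
        y2 = y.copy()
        y2[:, 2] += 1.0
        assert icc_a1(y2).icc < icc_a1(y).icc

    def test_pairwise_equals_complete_on_complete_data(self):
        rng = np.random.default_rng(56)
        y = rng.normal(0, 1, (25, 3)) + rng.normal(0, 1, (25, 1))
        assert icc_a1(y, missing="pairwise").icc == pytest.approx(
            icc_a1(y, missing="complete").icc, abs=1e-9)

    def test_degenerate_variance_rejected(self):
        with pytest.raises(ValueError):
            icc_a1(np.ones((10, 3)))


class TestValueAgreement:
    def test_bit_identical_values_agree_fully(self):
        y = np.tile(np.linspace(1, 2, 10)[:, None], (1, 3))
        assert value_percent_agreement(y) == 100.0

    def test_perturbed_value_breaks_agreement(self):
        y = np.tile(np.linspace(1, 2, 10)[:, None], (1, 3))
        y[4, 1] += 1e-3
        assert value_percent_agreement(y) == pytest.approx(90.0)

    def test_matches_brute_force_pairwise_check(self):
        rng = np.random.default_rng(61)
        y = np.tile(rng.uniform(0.5, 2.0, (40, 1)), (1, 3))
        jitter_rows = rng.choice(40, 12, replace=False)
        y[jitter_rows, 2] *= 1 + 1e-6
        y[rng.choice(40, 5, replace=False), 0] = np.nan
        tol = 1e-10 * np.nanmin(np.abs(y))
        agree = 0
        for row in y:
            if np.isnan(row).any():
                continue
            if all(abs(a - b) <= tol
                   for a, b in itertools.combinations(row, 2)):
                agree += 1
        assert value_percent_agreement(y) == pytest.approx(100 * agree / 40)


class TestCramersV:
    def test_proportional_table_has_no_association(self):
        assert cramers_v([[10, 20], [20, 40]]) == pytest.approx(0.0, abs=1e-12)

    def test_diagonal_table_has_perfect_association(self):
        assert cramers_v([[10, 0], [0, 10]]) == pytest.approx(1.0)

    def test_hand_computed_value(self):
        # chi2 = 20 on n = 80: V = sqrt(20 / 80) = 0.5
        assert cramers_v([[30, 10], [10, 30]]) == pytest.approx(0.5)


class TestLilliefors:
    def test_normal_sample_not_rejected(self):
        rng = np.random.default_rng(71)
        x = rng.normal(5, 2, 150)
        _, p = lilliefors_mc(x, n_draws=2000, seed=72)
        assert p > 0.05

    def test_exponential_sample_rejected(self):
        rng = np.random.default_rng(73)
        x = rng.exponential(1.0, 150)
        _, p = lilliefors_mc(x, n_draws=2000, seed=74)
        assert p < 0.01

    def test_statistic_matches_statsmodels(self):
        from statsmodels.stats.diagnostic import lilliefors as sm_lf
        rng = np.random.default_rng(75)
        x = rng.normal(0, 1, 80)
        d, _ = lilliefors_mc(x, n_draws=100, seed=76)
        d_sm, _ = sm_lf(x, dist="norm", pvalmethod="approx")
        assert d == pytest.approx(d_sm, abs=1e-12)


class TestGroupComparisons:
    def test_two_group_tukey_matches_normal_ranksum(self):
        rng = np.random.default_rng(81)
        groups = {"a": rng.normal(0, 1, 60), "b": rng.normal(0.1, 1, 60)}
        table = pairwise_ranksum_tukey(groups)
        # with k = 2 the studentized-range test reduces to the two-sided
        # normal approximation of the rank-sum test
        pooled = np.concatenate([groups["a"], groups["b"]])
        ranks = stats.rankdata(pooled)
        z = (ranks[:60].mean() - ranks[60:].mean()) / np.sqrt(
            len(pooled) * (len(pooled) + 1) / 12 * (1 / 60 + 1 / 60))
        expected_p = 2 * stats.norm.sf(abs(z))
        assert table.p[0] == pytest.approx(expected_p, rel=1e-6)

    def test_bonferroni_alpha_for_21_pairs(self):
        rng = np.random.default_rng(82)
        groups = {f"d{i}": rng.normal(0, 1, 20) for i in range(7)}
        table = pairwise_ks_bonferroni(groups)
        assert len(table) == 21
        assert table.alpha_adjusted.iloc[0] == pytest.approx(0.05 / 21)

    def test_shifted_group_detected(self):
        rng = np.random.default_rng(83)
        df = pd.DataFrame({
            "wcdi": np.r_[rng.normal(1.0, 0.2, 150),
                          rng.normal(1.2, 0.2, 150)],
            "device_id": ["d1"] * 150 + ["d2"] * 150,
        })
        report = compare_groups(df, "wcdi", seed=84, lilliefors_draws=500)
        assert report["kruskal"]["p"] < 1e-6
        assert report["pairwise_rank"].significant.all()

    def test_categorical_comparison_report(self):
        rng = np.random.default_rng(85)
        cats = ["instantaneous", "finite", "prolonged"]
        df = pd.DataFrame({
            "recovery_category": rng.choice(cats, 400, p=[0.5, 0.3, 0.2]),
            "device_id": rng.choice(["s1", "s2"], 400),
        })
        rep = compare_categorical(df, "recovery_category")
        assert 0 <= rep["cramers_v"] <= 1
        assert rep["dof"] == 2


class TestReliabilityReport:
    def test_full_report_on_synthetic_observations(self):
        rng = np.random.default_rng(91)
        times = np.sort(rng.uniform(0, 100, 30))
        tables = []
        for _ in range(3):
            keep = rng.random(30) > 0.1
            t = obs_table(times[keep], wcdi=np.linspace(0.3, 0.6, keep.sum()))
            tables.append(t)
        m = align_observations(tables)
        rep = reliability_report(m)
        assert 0 <= rep["percent_agreement"] <= 100
        assert rep["kappa"] <= 1
        assert rep["percent_above_chance"] == pytest.approx(100 * rep["kappa"])
        assert rep["landis_koch_label"] == landis_koch_label(rep["kappa"])
        assert set(rep["variables"]) == {"wcdi", "tau_ms"}
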