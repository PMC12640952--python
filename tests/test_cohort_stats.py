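"""CAD-RADS grading, threshold derivation, group tests, classification."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ccperf import (CohortConfig, DegenerateInputError, InputError,
                    TerritoryAssessment, bootstrap_youden_threshold,
                    cadrads_from_stenosis, classify_cohort, classify_patient,
                    cohort_summary, is_obstructive, report_from_means,
                    simulate_cohort, spearman_rho, unpaired_ttest,
                    youden_threshold)


class TestCadRads:
    @pytest.mark.parametrize("pct,grade", [
        (0, 0), (1, 1), (24, 1), (25, 2), (49, 2), (50, 3), (69, 3),
        (69.5, 3), (70, 4), (99, 4), (100, 5)])
    def test_bin_boundaries(self, pct, grade):
        assert cadrads_from_stenosis(pct) == grade

    def test_out_of_range_rejected(self):
        with pytest.raises(InputError):
            cadrads_from_stenosis(-1)
        with pytest.raises(InputError):
            cadrads_from_stenosis(101)

    @pytest.mark.parametrize("grade,flag", [
        (0, False), (2, False), (3, True), (4, True), (5, True)])
    def test_obstructive_from_grade_3(self, grade, flag):
        assert is_obstructive(grade) is flag


class TestYouden:
    def _brute_force(self, mbf, pos):
        """Independent exhaustive ROC enumeration over all midpoints."""
        u = np.unique(mbf)
        best_j, best_t = -np.inf, None
        for t in 0.5 * (u[:-1] + u[1:]):
            sens = np.mean(mbf[pos] < t)
            spec = np.mean(mbf[~pos] >= t)
            j = sens + spec - 1
            if j > best_j + 1e-12:
                best_j, best_t = j, t
        return best_t

    def test_hand_table_matches_brute_force(self):
        mbf = np.array([120.0, 150.0, 170.0, 190.0, 230.0, 260.0, 300.0, 320.0])
        pos = np.array([1, 1, 1, 0, 1, 0, 0, 0], dtype=bool)
        assert youden_threshold(mbf, pos) == self._brute_force(mbf, pos)

    def test_random_tables_match_brute_force(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            n = rng.integers(6, 50)
            mbf = rng.uniform(80, 350, n)
            pos = rng.random(n) < 0.5
            if pos.all() or not pos.any():
                continue
            assert youden_threshold(mbf, pos) == self._brute_force(mbf, pos)

    def test_perfect_separation_threshold_in_gap(self):
        rows = [dict(patient_id=i, cadrads=4, territory_mbf=100.0 + i)
                for i in range(10)]
        rows += [dict(patient_id=100 + i, cadrads=0, territory_mbf=300.0 + i)
                 for i in range(10)]
        res = bootstrap_youden_threshold(pd.DataFrame(rows), n_boot=200, seed=0)
        assert 109.0 < res.ci_low <= res.threshold <= res.ci_high < 300.0

    def test_single_class_rejected(self):
        rows = [dict(patient_id=i, cadrads=4, territory_mbf=150.0 + i)
                for i in range(5)]
        with pytest.raises(DegenerateInputError):
            bootstrap_youden_threshold(pd.DataFrame(rows), n_boot=10, seed=0)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(2)
        rows = [dict(patient_id=i, cadrads=g, territory_mbf=m)
                for i, (g, m) in enumerate(zip(
                    rng.choice([0, 4], 60), rng.uniform(100, 350, 60)))]
        t = pd.DataFrame(rows)
        a = bootstrap_youden_threshold(t, n_boot=50, seed=7)
        b = bootstrap_youden_threshold(t, n_boot=50, seed=7)
        assert a.threshold == b.threshold
        assert a.ci_low == b.ci_low and a.ci_high == b.ci_high


class TestSpearmanAndTTest:
    def test_monotone_decreasing_is_minus_one(self):
        x = np.arange(10.0)
        rho, _ = spearman_rho(x, -2 * x + 3)
        assert rho == pytest.approx(-1.0)

    def test_ties_match_rank_then_pearson_oracle(self):
        rng = np.random.default_rng(8)
        x = rng.integers(0, 5, 40).astype(float)     # heavy ties
        y = rng.integers(0, 6, 40).astype(float)
        rho, _ = spearman_rho(x, y)
        oracle = stats.pearsonr(stats.rankdata(x), stats.rankdata(y))[0]
        assert rho == pytest.approx(oracle, abs=1e-12)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(9)
        x, y = rng.normal(size=30), rng.normal(size=30)
        rho1, _ = spearman_rho(x, y)
        perm = rng.permutation(30)
        rho2, _ = spearman_rho(x[perm], y[perm])
        assert rho1 == pytest.approx(rho2, abs=1e-12)

    def test_constant_input_rejected(self):
        with pytest.raises(DegenerateInputError):
            spearman_rho(np.ones(5), np.arange(5.0))

    def test_identical_groups_t_zero_p_one(self):
        t, p = unpaired_ttest([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_textbook_example_matches_hand_formula(self):
        a = np.array([6.0, 8.0, 10.0, 12.0])
        b = np.array([5.0, 7.0, 9.0])
        t, p = unpaired_ttest(a, b)
        sp2 = (3 * a.var(ddof=1) + 2 * b.var(ddof=1)) / 5
        t_hand = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / 4 + 1 / 3))
        assert t == pytest.approx(t_hand, rel=1e-12)
        assert p == pytest.approx(2 * stats.t.sf(abs(t_hand), 5), rel=1e-12)

    def test_swapping_groups_negates_t(self):
        a, b = [1.0, 2.0, 4.0], [3.0, 5.0, 6.0]
        assert unpaired_ttest(a, b)[0] == pytest.approx(-unpaired_ttest(b, a)[0])

    def test_degenerate_variance_equal_means(self):
        assert unpaired_ttest([2.0, 2.0], [2.0, 2.0]) == (0.0, 1.0)


class TestClassification:
    def _terr(self, lad, rca, lcx, g_lad=0, g_rca=0, g_lcx=0):
        return [TerritoryAssessment("LAD", lad, g_lad),
                TerritoryAssessment("RCA", rca, g_rca),
                TerritoryAssessment("LCX", lcx, g_lcx)]

    def test_obstructive_lad_with_low_flow_is_flow_limiting(self):
        """CAD-RADS 4 LAD with territory MBF 178, others preserved."""
        c = classify_patient(self._terr(178.0, 280.0, 290.0, g_lad=4), 200.0)
        assert c.label == "flow_limiting"

    def test_all_normal(self):
        c = classify_patient(self._terr(280.0, 300.0, 260.0), 200.0)
        assert c.label == "normal"

    def test_diffuse_mvd_with_report(self):
        """Grades 0 everywhere, 10/16 segments at 120, global mean 130."""
        means = {s: 120.0 if s <= 10 else 146.7 for s in range(1, 17)}
        report = report_from_means(means)
        assert report.global_mean_mbf == pytest.approx(130.0, abs=0.1)
        c = classify_patient(self._terr(120.0, 120.0, 130.0), 200.0,
                             aha_report=report)
        assert c.label == "mvd_diffuse"

    def test_focal_mvd_without_diffuse_pattern(self):
        c = classify_patient(self._terr(150.0, 290.0, 300.0), 200.0)
        assert c.label == "mvd_focal"

    def test_obstructive_preserved_is_discordant(self):
        c = classify_patient(self._terr(280.0, 290.0, 300.0, g_lad=4), 200.0)
        assert c.label == "discordant_preserved"

    def test_no_evaluable_territory_rejected(self):
        with pytest.raises(DegenerateInputError):
            classify_patient([TerritoryAssessment("LAD", np.nan, 0)], 200.0)

    def test_every_patient_gets_exactly_one_label(self):
        table = simulate_cohort(CohortConfig(n_patients=150, seed=4))
        patients = classify_cohort(table, 200.0)
        assert len(patients) == 150
        assert patients.label.isin(
            ["normal", "flow_limiting", "mvd_focal", "mvd_diffuse",
             "discordant_preserved"]).all()

    def test_raising_threshold_never_reduces_ischemic_count(self):
        table = simulate_cohort(CohortConfig(n_patients=100, seed=6))
        counts = [int((table.territory_mbf < thr).sum())
                  for thr in (150.0, 200.0, 250.0)]
        assert counts == sorted(counts)


@pytest.fixture(scope="module")
def summary():
    table = simulate_cohort(CohortConfig(n_patients=400, seed=3))
    return cohort_summary(table, 200.0), table


class TestCohortSummary:
    def test_counts_conserve_cohort_size(self, summary):
        summ, table = summary
        assert summ["labels_total"] == table.patient_id.nunique()

    def test_mvd_truth_recovery(self, summary):
        summ, _ = summary
        rec = summ["mvd_recovery"]
        assert rec["sensitivity"] >= 0.9
        assert rec["specificity"] >= 0.9

    def test_obstructed_mean_below_non_obstructed(self, summary):
        summ, table = summary
        nd = table.loc[~table.diabetes]
        obst = nd.loc[nd.cadrads >= 3, "territory_mbf"]
        non = nd.loc[nd.cadrads < 3, "territory_mbf"]
        se = np.sqrt(obst.var(ddof=1) / len(obst) + non.var(ddof=1) / len(non))
        assert non.mean() - obst.mean() > 3 * se

    def test_negative_rank_correlation(self, summary):
        summ, _ = summary
        rho, p = summ["spearman_mbf_vs_cadrads"]
        assert rho < 0 and p < 0.05


# ---------------------------------------------------------------------------
# property tests
# ---------------------------------------------------------------------------

from hypothesis import given, settings, strategies as st  # noqa: E402


@settings(derandomize=True, max_examples=200, deadline=None)
@given(st.floats(min_value=0.0, max_value=100.0, allow_nan=False))
def test_cadrads_monotone_in_stenosis(pct):
    """Grades never decrease as stenosis grows (bins are ordered)."""
    g = cadrads_from_stenosis(pct)
    assert 0 <= g <= 5
    if pct <= 99.0:
        assert cadrads_from_stenosis(min(pct + 1.0, 100.0)) >= g


@settings(derandomize=True, max_examples=100, deadline=None)
@given(st.lists(st.floats(min_value=50.0, max_value=400.0,
                          allow_nan=False), min_size=4, max_size=30),
       st.integers(min_value=0, max_value=2 ** 31 - 1))
def test_youden_threshold_maximizes_j(mbf, seed):
    """The returned threshold attains the maximal Youden J among all
    candidate midpoints, and is the lowest such threshold."""
    mbf = np.asarray(mbf)
    rng = np.random.default_rng(seed)
    pos = rng.random(mbf.size) < 0.5
    if pos.all() or not pos.any() or np.unique(mbf).size < 2:
        return
    t = youden_threshold(mbf, pos)

    def j(c):
        return np.mean(mbf[pos] < c) + np.mean(mbf[~pos] >= c) - 1

    u = np.unique(mbf)
    cands = 0.5 * (u[:-1] + u[1:])
    js = np.array([j(c) for c in cands])
    assert j(t) >= js.max() - 1e-12
    assert t <= cands[js >= js.max() - 1e-12].min() + 1e-12


@settings(derandomize=True, max_examples=50, deadline=None)
@given(st.lists(st.floats(min_value=10.0, max_value=500.0,
                          allow_nan=False), min_size=16, max_size=16))
def test_territory_value_never_exceeds_any_pair_mean(means_list):
    """The representative territory MBF is a lower bound over its pairs."""
    from ccperf import ADJACENCY
    means = {s: means_list[s - 1] for s in range(1, 17)}
    report = report_from_means(means)
    for terr, pairs in ADJACENCY.items():
        from ccperf import territory_mbf
        got = territory_mbf(report, terr)
        for a, b in pairs:
            assert got.value <= 0.5 * (means[a] + means[b]) + 1e-9
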