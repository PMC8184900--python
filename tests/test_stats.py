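import itertools

import numpy as np
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

from topospeech.core import Cell, GridSpec
from topospeech.design import ResponseRecord, SessionLog, WordPool, generate_plan
from topospeech.encoder import TrialSpec, WordToken
from topospeech.io import load_fixture
from topospeech.observer import ObserverModel, simulate_cohort
from topospeech.stats import (
    DegenerateDataError,
    bonferroni_adjust,
    binned_error_rate,
    build_report,
    cell_heatmap,
    cumulative_success,
    equivalence_tost,
    exclude_outliers,
    friedman_test,
    group_summary,
    kruskal_wallis,
    mann_whitney_z,
    median_diff_ci,
    spatial_bias_screen,
    summarize_success,
    wilcoxon_signed_rank,
)

CHANCE = 100.0 / 9.0


def _log(outcomes, subject_id="s01", cells=None):
    """Build a SessionLog from a list of correct/incorrect flags."""
    log = SessionLog(subject_id=subject_id, condition="forward", phase="test")
    for i, ok in enumerate(outcomes):
        cell = cells[i] if cells else Cell(i % 3, (i // 3) % 3)
        resp = cell if ok else Cell((cell.row + 1) % 3, cell.col)
        log.records.append(ResponseRecord(
            trial_index=i,
            spec=TrialSpec(word=WordToken(token_id=f"w{i}"), cell=cell),
            response=resp, n_presentations=1, correct=ok,
        ))
    return log


def _sim_logs(n_subjects=6, seed=0, **model_kw):
    pool = WordPool("test", tuple(WordToken(token_id=f"w{i}") for i in range(30)))
    plans = [generate_plan("test", pool, seed=seed + i) for i in range(n_subjects)]
    return simulate_cohort(ObserverModel(**model_kw), plans, seed=seed)


class TestGroupSummaries:
    def test_forward_fixture_reproduces_printed_group_stats(self):
        g = group_summary(load_fixture("forward").success)
        assert round(g["mean"], 2) == 80.24
        assert round(g["sd"], 2) == 9.08
        assert round(g["median"], 2) == 80.56

    def test_backward_fixture_reproduces_printed_group_stats(self):
        g = group_summary(load_fixture("backward").success)
        assert round(g["mean"], 2) == 79.60
        assert round(g["sd"], 2) == 8.65
        assert round(g["median"], 2) == 79.44

    def test_all_correct_logs_are_100_percent_everywhere(self):
        table = summarize_success([_log([True] * 90)])
        assert table.group["mean"] == 100.0
        assert (table.per_subject[["overall", "row", "col"]] == 100.0).all().all()

    def test_per_cell_table_matches_direct_recount(self):
        logs = _sim_logs(4, seed=21)
        table = summarize_success(logs)
        for log in logs:
            hits = np.zeros((3, 3))
            seen = np.zeros((3, 3))
            for r in log.records:
                seen[r.spec.cell.row, r.spec.cell.col] += 1
                hits[r.spec.cell.row, r.spec.cell.col] += r.correct
            np.testing.assert_allclose(table.per_cell[log.subject_id], 100 * hits / seen)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            summarize_success([])


class TestOutlierRule:
    def test_low_performer_excluded(self):
        rates = [80.0] * 14 + [40.0]  # mean 77.33, SD 10.33, cutoff 56.67
        kept, excluded = exclude_outliers(rates)
        assert list(excluded) == [14]
        assert len(kept) == 14

    def test_equal_values_keep_everyone(self):
        kept, excluded = exclude_outliers([75.0] * 10)
        assert excluded.size == 0

    def test_tight_cluster_keeps_everyone(self):
        kept, excluded = exclude_outliers([80.0, 81.0, 82.0])
        assert excluded.size == 0

    def test_high_performers_never_excluded(self):
        kept, excluded = exclude_outliers([50.0] * 10 + [99.0])
        assert 10 in kept

    def test_too_few_subjects(self):
        with pytest.raises(ValueError):
            exclude_outliers([80.0, 90.0])


class TestWilcoxonSignedRank:
    def test_fixture_vs_chance_reproduces_z(self):
        for condition in ("forward", "backward"):
            rates = np.array(load_fixture(condition).success)
            res = wilcoxon_signed_rank(rates, mu=CHANCE, alternative="greater")
            assert round(abs(res.z), 2) == 3.27
            assert res.p < 0.0006

    def test_symmetric_pair_gives_zero_z(self):
        res = wilcoxon_signed_rank([9.0, 11.0], mu=10.0)
        assert res.statistic == 1.5  # W equals its null mean n(n+1)/4
        assert res.z == 0.0

    def test_all_zero_differences_degenerate(self):
        with pytest.raises(DegenerateDataError):
            wilcoxon_signed_rank([5.0, 5.0, 5.0], mu=5.0)

    def test_normal_approx_close_to_enumeration_at_n6(self):
        rng = np.random.default_rng(2024)
        for _ in range(20):
            d = rng.normal(0.3, 1.0, size=6)
            d = d[d != 0]
            ranks = scipy.stats.rankdata(np.abs(d))
            # independent oracle: enumerate all 2**n sign patterns
            ws = [
                sum(r for r, s in zip(ranks, signs) if s)
                for signs in itertools.product([False, True], repeat=len(d))
            ]
            w_obs = ranks[d > 0].sum()
            exact_p = np.mean([w >= w_obs for w in ws])
            approx = wilcoxon_signed_rank(d, alternative="greater", method="approx")
            assert abs(approx.p - exact_p) < 0.05
            exact = wilcoxon_signed_rank(d, alternative="greater", method="exact")
            assert exact.p == pytest.approx(exact_p, abs=1e-12)

    def test_matches_scipy_approx_with_ties(self):
        rng = np.random.default_rng(7)
        x = np.round(rng.normal(0.5, 1.0, size=25), 1)
        x = x[x != 0]
        ours = wilcoxon_signed_rank(x, alternative="two-sided", method="approx")
        ref = scipy.stats.wilcoxon(x, correction=True, alternative="two-sided",
                                   method="approx")
        assert ours.p == pytest.approx(ref.pvalue, rel=1e-9)

    @given(st.integers(0, 1000))
    @settings(max_examples=25, derandomize=True, deadline=None)
    def test_one_sided_p_values_sum_near_one(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(0, 1, size=15)
        hi = wilcoxon_signed_rank(x, alternative="greater").p
        lo = wilcoxon_signed_rank(x, alternative="less").p
        # overlap comes only from the continuity correction
        assert 0.9 <= hi + lo <= 1.1


class TestMannWhitney:
    def test_identical_samples_give_zero_z(self):
        res = mann_whitney_z([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert round(abs(res.z), 2) == 0.0

    def test_tiny_case_exact_p(self):
        # all mass below: p = 1 / C(4,2) choices... enumeration gives 1/6
        res = mann_whitney_z([1.0, 2.0], [3.0, 4.0], alternative="less", method="exact")
        assert res.p == pytest.approx(1 / 6)

    def test_matches_scipy_asymptotic_with_ties(self):
        rng = np.random.default_rng(3)
        x = np.round(rng.normal(0, 1, 18), 1)
        y = np.round(rng.normal(0.4, 1, 15), 1)
        ours = mann_whitney_z(x, y, alternative="two-sided")
        ref = scipy.stats.mannwhitneyu(x, y, alternative="two-sided",
                                       method="asymptotic", use_continuity=True)
        assert ours.p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_tied_data_against_permutation_oracle(self):
        rng = np.random.default_rng(5)
        x = rng.integers(0, 4, size=8).astype(float)
        y = rng.integers(1, 5, size=7).astype(float)
        pooled = np.concatenate([x, y])
        ranks = scipy.stats.rankdata(pooled)
        w_obs = ranks[:8].sum()
        perm = []
        for _ in range(10_000):
            rng.shuffle(ranks)
            perm.append(ranks[:8].sum())
        p_perm = np.mean([w >= w_obs for w in perm])
        ours = mann_whitney_z(x, y, alternative="greater")
        assert abs(ours.p - p_perm) < 0.02

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_z([], [1.0])


class TestKruskalWallis:
    def test_equal_groups_h_zero(self):
        res = kruskal_wallis([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)

    def test_closed_form_small_case(self):
        # H = 12/(N(N+1)) * sum R^2/n - 3(N+1) = 2.4 for {1,2} vs {3,4}
        res = kruskal_wallis([[1.0, 2.0], [3.0, 4.0]])
        assert res.statistic == pytest.approx(2.4)
        assert res.df == 1

    def test_matches_scipy_with_ties(self):
        rng = np.random.default_rng(11)
        groups = [np.round(rng.normal(loc, 1, 12), 0) for loc in (0, 0.5, 1.0)]
        ours = kruskal_wallis(groups)
        ref = scipy.stats.kruskal(*groups)
        assert ours.statistic == pytest.approx(ref.statistic, rel=1e-9)
        assert ours.p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_constant_data_degenerate(self):
        with pytest.raises(DegenerateDataError):
            kruskal_wallis([[2.0, 2.0], [2.0, 2.0]])


class TestFriedman:
    def test_identical_columns_chi2_zero(self):
        m = np.tile(np.arange(5.0)[:, None], (1, 3))
        with pytest.raises(DegenerateDataError):
            friedman_test(m)  # constant rows: no within-subject ranking

    def test_matches_scipy(self):
        rng = np.random.default_rng(13)
        m = rng.normal(size=(10, 4)) + np.array([0.0, 0.2, 0.4, 0.6])
        ours = friedman_test(m)
        ref = scipy.stats.friedmanchisquare(*m.T)
        assert ours.statistic == pytest.approx(ref.statistic, rel=1e-9)
        assert ours.p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_two_condition_case_equals_sign_test_statistic(self):
        # with k=2 and no ties, chi2 = (n_plus - n_minus)**2 / n
        rng = np.random.default_rng(17)
        m = rng.normal(size=(12, 2))
        signs = np.sign(m[:, 1] - m[:, 0])
        expected = (signs.sum()) ** 2 / 12
        assert friedman_test(m).statistic == pytest.approx(expected)

    def test_small_matrix_rejected(self):
        with pytest.raises(ValueError):
            friedman_test(np.array([[1.0, 2.0]]))


class TestBonferroni:
    def test_adjustment_and_cap(self):
        adj = bonferroni_adjust([0.01, 0.5, 0.002, 0.3, 0.04])
        np.testing.assert_allclose(adj, [0.05, 1.0, 0.01, 1.0, 0.2])

    def test_single_test_identity(self):
        assert bonferroni_adjust([0.3])[0] == 0.3

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bonferroni_adjust([1.2])


class TestEquivalence:
    def test_fixture_bounds_and_delta_median(self):
        fwd = load_fixture("forward").success
        bwd = load_fixture("backward").success
        eq = equivalence_tost(fwd, bwd)
        assert round(eq.bound_upper, 3) == 0.024
        assert eq.bound_lower == -eq.bound_upper
        assert eq.delta_median == pytest.approx(0.0055, abs=1e-4)

    def test_matched_groups_with_small_noise_are_equivalent(self):
        rng = np.random.default_rng(23)
        fwd = 80.0 + rng.normal(0, 3.0, 14)
        bwd = fwd + rng.normal(0, 0.15, 14)  # noise far below the ~2.4pt bound
        eq = equivalence_tost(fwd, bwd)
        assert abs(eq.delta_median) < 0.005
        assert eq.equivalent

    def test_shifted_groups_are_not_equivalent(self):
        rng = np.random.default_rng(29)
        bwd = 75.0 + rng.normal(0, 3.0, 14)
        eq = equivalence_tost(bwd + 10.0, bwd)
        assert not eq.equivalent
        assert eq.ci95[0] > eq.bound_upper  # CI sits entirely above the band

    def test_verdict_coheres_with_ci(self):
        rng = np.random.default_rng(31)
        for _ in range(25):
            fwd = 80 + rng.normal(0, 4, 14)
            bwd = fwd + rng.normal(0, rng.uniform(0.1, 8.0), 14)
            try:
                eq = equivalence_tost(fwd, bwd)
            except DegenerateDataError:
                continue
            inside = eq.bound_lower <= eq.ci95[0] and eq.ci95[1] <= eq.bound_upper
            assert eq.equivalent == inside

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError, match="pair"):
            equivalence_tost([80.0] * 14, [80.0] * 13)


class TestMedianDiffCI:
    def test_against_r_wilcox_test_exact_ci(self):
        # frozen from R: wilcox.test(d, conf.int=TRUE, exact=TRUE)
        d5 = [0.10, -0.20, 0.30, 0.50, 0.40]
        assert median_diff_ci(d5, 0.95) == pytest.approx((-0.20, 0.50))
        d7 = [-0.3, 0.15, 0.2, 0.4, -0.1, 0.25, 0.05]
        assert median_diff_ci(d7, 0.95) == pytest.approx((-0.125, 0.30))

    def test_nestedness(self):
        rng = np.random.default_rng(37)
        d = rng.normal(0.1, 1.0, 14)
        lo95, hi95 = median_diff_ci(d, 0.95)
        lo90, hi90 = median_diff_ci(d, 0.90)
        assert lo95 <= lo90 and hi90 <= hi95

    def test_symmetric_data_ci_centred_on_pseudomedian(self):
        d = np.array([-0.4, -0.2, -0.1, 0.0, 0.1, 0.2, 0.4])
        lo, hi = median_diff_ci(d, 0.90)
        assert lo == pytest.approx(-hi, abs=1e-12)

    def test_bootstrap_agrees_roughly_with_walsh(self):
        rng = np.random.default_rng(41)
        d = rng.normal(0.3, 1.0, 20)
        walsh = median_diff_ci(d, 0.95)
        boot = median_diff_ci(d, 0.95, method="bootstrap", seed=1)
        assert walsh[0] == pytest.approx(boot[0], abs=0.5)
        assert walsh[1] == pytest.approx(boot[1], abs=0.5)

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            median_diff_ci([0.1, 0.2], 0.95)


class TestCurvesAndMaps:
    def test_cumulative_success_arithmetic(self):
        series = cumulative_success(_log([True, False, True]))
        np.testing.assert_allclose(series, [1.0, 0.5, 2 / 3])

    def test_final_cumulative_point_equals_overall_rate(self):
        for log in _sim_logs(3, seed=43):
            series = cumulative_success(log)
            table = summarize_success([log])
            assert 100 * series[-1] == pytest.approx(table.group["mean"])

    def test_90_trial_logs_give_nine_bins(self):
        logs = _sim_logs(5, seed=47)
        bins = binned_error_rate(logs, bin_size=10)
        assert bins.shape == (9,)

    def test_all_correct_logs_have_zero_error_bins(self):
        assert np.all(binned_error_rate([_log([True] * 90)]) == 0.0)

    def test_bins_match_direct_recount(self):
        logs = _sim_logs(5, seed=53)
        bins = binned_error_rate(logs, bin_size=10)
        manual = np.mean([
            [100 * np.mean([not r.correct for r in log.records[i : i + 10]])
             for i in range(0, 90, 10)]
            for log in logs
        ], axis=0)
        np.testing.assert_allclose(bins, manual)

    def test_partial_bin_rejected(self):
        with pytest.raises(ValueError, match="partial bin"):
            binned_error_rate([_log([True] * 85)])

    def test_heatmap_all_correct(self):
        logs = _sim_logs(3, seed=59,
                         p_row_init=1, p_row_asym=1, p_col_init=1, p_col_asym=1)
        np.testing.assert_allclose(cell_heatmap(logs), np.ones((3, 3)))

    def test_heatmap_shape_matches_grid(self):
        assert cell_heatmap(_sim_logs(2, seed=61)).shape == (3, 3)

    def test_uniform_guessing_heatmap_within_binomial_bounds(self):
        logs = _sim_logs(100, seed=67, p_row_init=1 / 3, p_row_asym=1 / 3,
                         p_col_init=1 / 3, p_col_asym=1 / 3, adj_weight=1.0)
        hm = cell_heatmap(logs)  # each cell: 100 subjects x 10 presentations
        lo, hi = scipy.stats.binom.ppf([0.0005, 0.9995], 1000, 1 / 9) / 1000
        assert np.all((hm >= lo) & (hm <= hi))

    def test_missing_cell_rejected(self):
        log = _log([True] * 10, cells=[Cell(0, 0)] * 10)
        with pytest.raises(ValueError, match="never presented"):
            cell_heatmap([log])


class TestSpatialBiasScreen:
    def test_strong_positive_ratings_flagged_high(self):
        out = spatial_bias_screen({"hat": [0.8] * 11})
        assert out["hat"]["bias_flag"] == "high"
        assert out["hat"]["p"] == pytest.approx(2 * 2**-11, rel=1e-9)

    def test_symmetric_ratings_not_flagged(self):
        out = spatial_bias_screen({"ruler": [-0.5, -0.3, -0.1, 0.1, 0.3, 0.5]})
        assert out["ruler"]["bias_flag"] == "none"

    def test_constant_zero_ratings_degenerate(self):
        out = spatial_bias_screen({"cup": [0.0] * 5})
        assert out["cup"]["bias_flag"] == "none"
        assert out["cup"]["p"] == 1.0

    def test_weak_mixed_ratings_match_enumeration(self):
        ratings = [0.2, -0.1, 0.3, -0.4, 0.1, 0.5, -0.2, 0.6]
        out = spatial_bias_screen({"w": ratings})
        d = np.array(ratings)
        ranks = scipy.stats.rankdata(np.abs(d))
        ws = [sum(r for r, s in zip(ranks, signs) if s)
              for signs in itertools.product([False, True], repeat=len(d))]
        w_obs = ranks[d > 0].sum()
        p_exact = min(1.0, 2 * min(np.mean([w >= w_obs for w in ws]),
                                   np.mean([w <= w_obs for w in ws])))
        assert out["w"]["p"] == pytest.approx(p_exact, abs=1e-12)


class TestReport:
    def test_report_is_json_serializable_and_complete(self):
        import json

        fwd = _sim_logs(7, seed=71)
        bwd = _sim_logs(7, seed=81)
        report = build_report(fwd, bwd)
        text = json.dumps(report)
        assert '"equivalence"' in text
        for cond in ("forward", "backward"):
            block = report["conditions"][cond]
            assert len(block["binned_error_pct"]) == 9
            assert len(block["mean_cumulative_success"]) == 90
            assert block["vs_chance"]["p"] < 0.05
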