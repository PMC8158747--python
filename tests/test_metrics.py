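import numpy as np
import pytest

from conftest import make_instance
from pcleval import (
    VolumeGroups,
    compare_counts,
    cumulative_curves,
    mcnemar_test,
    overall_metrics,
    regional_rate_test,
    stratified_metrics,
    summarize_gt,
)
from pcleval.errors import ValidationError
from pcleval.instances import MatchResult

GRID = (50, 20, 20)


def inst(inst_id, n_voxels, source="gt", offset=0):
    start = offset
    ids = range(start, start + n_voxels)
    return make_instance(ids, GRID, inst_id=inst_id, voxel_volume=1.0, source=source)


def simple_match(gt_vols, detected, fp_vols):
    """Build instances + MatchResult where detected[i] says GT i is matched."""
    gt, pred, pairs, fn = [], [], [], []
    offset = 0
    for i, (v, det) in enumerate(zip(gt_vols, detected), start=1):
        gt.append(inst(i, int(v), offset=offset))
        offset += int(v) + 5
        if det:
            pred.append(inst(len(pred) + 1, int(v), source="pred", offset=offset - int(v) - 5))
            pairs.append((i, len(pred), 1.0))
        else:
            fn.append(i)
    fp = []
    for v in fp_vols:
        pred.append(inst(len(pred) + 1, int(v), source="pred", offset=offset))
        fp.append(len(pred))
        offset += int(v) + 5
    m = MatchResult(pairs, fn, fp, [], [], 0.30)
    return m, gt, pred


class TestVolumeGroups:
    def test_group_membership(self):
        vg = VolumeGroups()
        assert [vg.group_of(v) for v in (10, 50, 51, 200, 201, 600, 601, 39973.5)] == [
            0, 0, 1, 1, 2, 2, 3, 3,
        ]

    def test_below_floor_rejected(self):
        with pytest.raises(ValidationError):
            VolumeGroups().group_of(9.9)

    def test_boundaries_must_increase(self):
        with pytest.raises(ValidationError):
            VolumeGroups(boundaries=(10.0, 10.0, 200.0, 600.0))


class TestStratifiedMetrics:
    def test_formula_evaluation(self):
        """tp=9, fn=1, fp=2 over 4 cases: sens 0.9, fp/case 0.5, f1 18/21."""
        m, gt, pred = simple_match([20] * 10, [True] * 9 + [False], [30, 30])
        table = stratified_metrics(m, gt, pred, VolumeGroups(), n_cases=4)
        row = table[table.stratum == "10-50"].iloc[0]
        assert row.sensitivity == pytest.approx(0.9)
        assert row.fp_per_case == pytest.approx(0.5)
        assert row.f1 == pytest.approx(18 / 21)

    def test_perfect_detection(self):
        m, gt, pred = simple_match([20, 100, 400, 700], [True] * 4, [])
        table = stratified_metrics(m, gt, pred, VolumeGroups(), n_cases=2)
        assert (table.sensitivity == 1.0).all()
        assert (table.fp_per_case == 0.0).all()
        assert (table.f1 == 1.0).all()

    def test_empty_stratum_flagged_undefined(self):
        m, gt, pred = simple_match([20], [True], [])
        table = stratified_metrics(m, gt, pred, VolumeGroups(), n_cases=1)
        empty = table[table.stratum == ">600"].iloc[0]
        assert np.isnan(empty.sensitivity)
        assert empty.fp_per_case == 0.0

    def test_fp_stratified_by_predicted_volume(self):
        m, gt, pred = simple_match([20], [True], [700])
        table = stratified_metrics(m, gt, pred, VolumeGroups(), n_cases=1)
        assert table[table.stratum == ">600"].fp.iloc[0] == 1
        assert table[table.stratum == "10-50"].fp.iloc[0] == 0

    def test_per_stratum_counts_sum_to_overall(self):
        m, gt, pred = simple_match(
            [15, 60, 60, 300, 900, 900], [True, False, True, True, False, True], [25, 250]
        )
        table = stratified_metrics(m, gt, pred, VolumeGroups(), n_cases=3)
        overall = overall_metrics(m, gt, pred, n_cases=3)
        assert table.tp.sum() == overall["tp"]
        assert table.fn.sum() == overall["fn"]
        assert table.fp.sum() == overall["fp"]


class TestCumulativeCurves:
    def test_floor_threshold_equals_overall(self):
        m, gt, pred = simple_match([20, 300, 700], [False, True, True], [40])
        curves = cumulative_curves(m, gt, pred, [10.0], n_cases=2)
        overall = overall_metrics(m, gt, pred, n_cases=2)
        assert curves.sensitivity.iloc[0] == pytest.approx(overall["sensitivity"])
        assert curves.fp_per_case.iloc[0] == pytest.approx(overall["fp_per_case"])

    def test_enumerated_thresholds(self):
        """GT {20, 300, 700}, all detected except the 20 mm³ one."""
        m, gt, pred = simple_match([20, 300, 700], [False, True, True], [])
        curves = cumulative_curves(m, gt, pred, [10.0, 220.0], n_cases=1)
        assert curves.sensitivity.iloc[0] == pytest.approx(2 / 3)
        assert curves.sensitivity.iloc[1] == pytest.approx(1.0)

    def test_threshold_above_largest_gt(self):
        m, gt, pred = simple_match([20, 300], [True, True], [5000])
        curves = cumulative_curves(m, gt, pred, [4000.0], n_cases=1)
        assert np.isnan(curves.sensitivity.iloc[0])
        assert curves.fp_per_case.iloc[0] == 1.0


class TestCompareCounts:
    def test_identical_lists_degenerate(self):
        res = compare_counts([2, 3, 2], [2, 3, 2])
        assert res.degenerate and res.mean_gt == res.mean_pred

    def test_constant_difference_degenerate_with_mean(self):
        res = compare_counts([2, 3, 2, 3], [1, 2, 1, 2])
        assert res.degenerate
        assert res.mean_difference == pytest.approx(1.0)

    def test_hand_computed_paired_t(self):
        """Pairs (3,1),(2,2),(4,1): differences {2,0,3} → t = 5/√7."""
        res = compare_counts([3, 2, 4], [1, 2, 1])
        assert res.mean_gt == pytest.approx(3.0)
        assert res.mean_pred == pytest.approx(4 / 3)
        assert res.t_statistic == pytest.approx(5 / np.sqrt(7), abs=1e-9)

    def test_cross_check_against_scipy(self):
        from scipy import stats

        rng = np.random.default_rng(1)
        a = rng.poisson(2.5, size=30).astype(float)
        b = rng.poisson(1.8, size=30).astype(float)
        res = compare_counts(a, b)
        t, p = stats.ttest_rel(a, b)
        assert res.t_statistic == pytest.approx(t)
        assert res.p_value == pytest.approx(p)


class TestRegionalRateTest:
    def test_equal_rates_give_zero_chi2(self):
        res = regional_rate_test([50, 50, 50], [100, 100, 100])
        assert res.chi2 == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_hand_computed_table(self):
        """Detected/missed (90,10),(50,50),(10,90): chi² = 128 at df 2."""
        res = regional_rate_test([90, 50, 10], [100, 100, 100])
        assert res.chi2 == pytest.approx(128.0, abs=1e-9)
        assert res.df == 2

    def test_empty_region_rejected(self):
        with pytest.raises(ValidationError):
            regional_rate_test([1, 1, 0], [2, 2, 0])

    def test_small_expected_cell_warns(self):
        res = regional_rate_test([1, 1, 1], [1, 1, 2])
        assert res.small_sample_warning


class TestMcNemar:
    def test_symmetric_counts_p_one(self):
        res = mcnemar_test(4, 4)
        assert res.p_value == pytest.approx(1.0)
        assert res.exact

    def test_corrected_chi_square_statistic(self):
        """b=15, c=5: statistic (|10|−1)²/20 = 4.05."""
        res = mcnemar_test(15, 5)
        assert res.statistic == pytest.approx(4.05, abs=1e-12)

    def test_exact_binomial_small_counts(self):
        """b=2, c=0: exact two-sided binomial p = 2·(1/2)² = 0.5."""
        res = mcnemar_test(2, 0)
        assert res.exact and res.p_value == pytest.approx(0.5, abs=1e-12)

    def test_large_counts_use_chi_square(self):
        from scipy import stats

        res = mcnemar_test(30, 12)
        assert not res.exact
        expected = (abs(30 - 12) - 1) ** 2 / 42
        assert res.statistic == pytest.approx(expected)
        assert res.p_value == pytest.approx(stats.chi2.sf(expected, 1))

    def test_cross_check_against_statsmodels(self):
        from statsmodels.stats.contingency_tables import mcnemar as sm_mcnemar

        ours = mcnemar_test(3, 9)
        theirs = sm_mcnemar([[0, 3], [9, 0]], exact=True)
        assert ours.p_value == pytest.approx(float(theirs.pvalue))

    def test_degenerate_when_no_discordant_pairs(self):
        assert mcnemar_test(0, 0).degenerate


class TestSummarizeGT:
    def test_study_scale_mean_per_case(self):
        """543 lesions over 221 cases report a mean of 2.5 per case."""
        counts = [543 // 221 + (1 if i < 543 % 221 else 0) for i in range(221)]
        per_case = {f"c{i}": [100.0] * c for i, c in enumerate(counts)}
        summary = summarize_gt(per_case)
        assert summary.n_cysts == 543 and summary.n_cases == 221
        assert summary.report()["mean_per_case"] == 2.5

    def test_single_case_single_cyst(self):
        s = summarize_gt({"c": [500.0]})
        assert (s.n_cysts, s.n_cases) == (1, 1)
        assert s.mean_per_case == 1.0 and s.sd_per_case == 0.0
        assert s.volume_min == s.volume_max == s.volume_mean == 500.0

    def test_matches_phantom_catalogue_exactly(self, four_group_phantom):
        _, _, truth = four_group_phantom
        vols = truth.catalogue.volume_mm3.tolist()
        s = summarize_gt({"phantom": vols})
        assert s.volume_min == pytest.approx(min(vols))
        assert s.volume_max == pytest.approx(max(vols))
        assert s.volume_mean == pytest.approx(np.mean(vols))
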