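import numpy as np
import pytest
from statsmodels.stats.contingency_tables import mcnemar as sm_mcnemar

from ssvepclean import (
    EvalConfig,
    accuracy,
    group_paired_test,
    loso_splits,
    mcnemar_test,
    run_full_evaluation,
    snr_at_frequency,
    snr_report,
    wolpaw_itr,
)
from ssvepclean.evaluation_metrics import EvalReport
from ssvepclean.reference_results import svm_accuracy_table


class TestLosoSplits:
    def test_twelve_subjects(self):
        ids = [f"S{i:02d}" for i in range(12) for _ in range(3)]
        splits = loso_splits(ids)
        assert len(splits) == 12
        assert all(len(s.train_subjects) == 11 for s in splits)

    def test_partition_property(self):
        splits = loso_splits(["a", "b", "c"])
        tests = [s.test_subject for s in splits]
        assert sorted(tests) == ["a", "b", "c"]
        for s in splits:
            assert s.test_subject not in s.train_subjects

    def test_two_subjects_minimum(self):
        assert len(loso_splits(["a", "b"])) == 2
        with pytest.raises(ValueError):
            loso_splits(["only"])


class TestAccuracy:
    def test_values(self):
        assert accuracy([1, 1], [1, 1]) == 100.0
        truth = np.repeat([7, 8, 9], 60)
        assert round(accuracy(np.full(180, 7), truth), 1) == 33.3
        pred = truth.copy()
        pred[:37] = -1  # 143 of 180 correct
        assert round(accuracy(pred, truth), 1) == 79.4

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            accuracy([1], [1, 2])


def synth_mcnemar_inputs(b, c, n_both=30):
    """Predictions realizing exactly b and c discordant windows."""
    truth = np.zeros(n_both + b + c)
    pred_a = truth.copy()
    pred_b = truth.copy()
    pred_a[n_both : n_both + c] = 1  # A wrong where only B correct
    pred_b[n_both + c :] = 1  # B wrong where only A correct
    return pred_a, pred_b, truth


class TestMcnemar:
    def test_exact_binomial_closed_form(self):
        b, c, p = mcnemar_test(*synth_mcnemar_inputs(10, 0))
        assert (b, c) == (10, 0)
        assert p == pytest.approx(2 * 0.5**10)

    def test_symmetric_discordance(self):
        _, _, p = mcnemar_test(*synth_mcnemar_inputs(7, 7))
        assert p == pytest.approx(1.0)

    def test_chi_square_with_correction(self):
        b, c, p = mcnemar_test(*synth_mcnemar_inputs(40, 20))
        stat = (abs(40 - 20) - 1) ** 2 / 60
        assert stat == pytest.approx(6.016, abs=1e-3)
        assert p == pytest.approx(0.0142, abs=5e-4)

    def test_degenerate_no_discordance(self):
        _, _, p = mcnemar_test(*synth_mcnemar_inputs(0, 0))
        assert p == 1.0

    @pytest.mark.parametrize("b,c", [(3, 1), (10, 5), (12, 13), (2, 0)])
    def test_exact_matches_statsmodels(self, b, c):
        _, _, p = mcnemar_test(*synth_mcnemar_inputs(b, c))
        table = [[0, b], [c, 0]]
        expected = sm_mcnemar(table, exact=True).pvalue
        assert p == pytest.approx(expected, abs=1e-10)

    def test_switchover_consistency(self):
        # at b + c = 25 the exact and corrected-chi2 p agree within 0.02
        for b, c in [(18, 7), (20, 5), (16, 9)]:
            _, _, p_exact = mcnemar_test(*synth_mcnemar_inputs(b, c))
            stat = (abs(b - c) - 1) ** 2 / (b + c)
            from scipy.stats import chi2

            assert abs(p_exact - chi2.sf(stat, 1)) <= 0.02


class TestGroupPairedTest:
    def test_constant_shift_is_certain(self):
        base = np.array([50.0, 60, 70, 80, 90, 55, 65, 75, 85, 95, 62, 72])
        ps = group_paired_test(base, base + 5.0)
        assert ps["t"] < 1e-10

    def test_symmetric_differences_not_significant(self):
        a = np.array([50.0, 60, 70, 80, 90, 55])
        b = a + np.array([2.0, -2, 1, -1, 3, -3])
        ps = group_paired_test(a, b)
        assert ps["t"] > 0.9
        assert ps["wilcoxon"] > 0.9

    def test_published_svm_improvement_is_significant(self):
        table = svm_accuracy_table()
        ps = group_paired_test(table.o_only.to_numpy(), table.o_clean.to_numpy())
        assert ps["t"] < 0.001
        assert ps["wilcoxon"] < 0.001

    def test_all_zero_differences_degenerate(self):
        a = np.array([50.0, 60, 70, 80, 90])
        ps = group_paired_test(a, a)
        assert ps["t"] == 1.0
        assert np.isnan(ps["wilcoxon"])


class TestWolpawItr:
    def test_published_operating_point(self):
        assert round(wolpaw_itr(0.707, 3, 1.0), 1) == 25.2

    def test_analytic_anchors(self):
        assert wolpaw_itr(1.0, 3, 1.0) == pytest.approx(60 * np.log2(3), abs=1e-9)
        assert round(wolpaw_itr(1.0, 3, 1.0), 1) == 95.1
        assert wolpaw_itr(1 / 3, 3, 1.0) == 0.0

    def test_strictly_increasing_above_chance(self):
        grid = np.linspace(0.34, 1.0, 50)
        vals = [wolpaw_itr(p, 3, 1.0) for p in grid]
        assert np.all(np.diff(vals) > 0)

    def test_clamp_vs_raw(self):
        assert wolpaw_itr(0.2, 3, 1.0) == 0.0
        assert wolpaw_itr(0.2, 3, 1.0, clamp=False) > 0.0  # raw formula rises again

    def test_window_scaling(self):
        assert wolpaw_itr(0.9, 3, 0.5) == pytest.approx(2 * wolpaw_itr(0.9, 3, 1.0))

    def test_domain_checks(self):
        with pytest.raises(ValueError):
            wolpaw_itr(1.2, 3, 1.0)
        with pytest.raises(ValueError):
            wolpaw_itr(0.5, 1, 1.0)


class TestSnrAtFrequency:
    def test_flat_spectrum_zero_db(self):
        assert snr_at_frequency(np.ones(30), 9.0) == pytest.approx(0.0)

    def test_ten_times_neighbours(self):
        power = np.ones(30)
        power[9] = 10.0
        assert snr_at_frequency(power, 9.0) == pytest.approx(10.0)

    def test_hand_arithmetic(self):
        power = np.ones(30)
        power[9] = 2.0
        power[12] = 4.0  # neighbours {1,1,1,1,1,4}: mean 1.5
        assert snr_at_frequency(power, 9.0) == pytest.approx(
            10 * np.log10(2 / 1.5), abs=1e-9
        )
        assert round(snr_at_frequency(power, 9.0), 2) == 1.25

    def test_gain_invariant_to_rescaling(self, rng):
        power = rng.uniform(0.5, 2.0, size=40)
        assert snr_at_frequency(7.0 * power, 9.0) == pytest.approx(
            snr_at_frequency(power, 9.0)
        )

    def test_empty_neighbourhood_flagged(self):
        power = np.zeros(30)
        power[9] = 1.0
        assert np.isinf(snr_at_frequency(power, 9.0))


class TestSnrReport:
    def test_identical_inputs_zero_gain(self, small_dataset):
        dataset, _ = small_dataset
        raw = dataset.select_channels(["O1", "O2", "Oz"])
        df = snr_report(raw, raw)
        np.testing.assert_allclose(df.gain_db, 0.0)
        assert sorted(df.frequency.unique()) == [7.0, 8.0, 9.0]

    def test_artifact_removal_gains_snr(self, small_dataset):
        from ssvepclean import clean_epochs

        dataset, _ = small_dataset
        raw = dataset.select_channels(["O1", "O2", "Oz"])
        clean = clean_epochs(dataset).cleaned
        df = snr_report(raw, clean)
        by_freq = df.groupby("frequency").gain_db.mean()
        assert (by_freq > 0).all()


class TestRunFullEvaluation:
    def test_report_shape_contract(self, small_dataset):
        dataset, _ = small_dataset
        report = run_full_evaluation(
            dataset, EvalConfig(methods=("svm", "cca"), seed=1)
        )
        assert len(report.accuracies) == 3 * 2 * 2  # subjects x variants x methods
        assert report.accuracies.accuracy.between(0, 100).all()
        assert report.mcnemar.p.between(0, 1).all()
        assert len(report.itr) == 4
        # JSON round trip preserves the tables
        back = EvalReport.from_json(report.to_json())
        assert back.accuracies.accuracy.tolist() == report.accuracies.accuracy.tolist()

    def test_artifact_free_variants_agree(self, quiet_dataset):
        report = run_full_evaluation(
            quiet_dataset, EvalConfig(methods=("cca",), compute_snr=False)
        )
        diff = report.mean_accuracy("cca", "O-clean") - report.mean_accuracy(
            "cca", "O-only"
        )
        assert abs(diff) <= 2.0
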