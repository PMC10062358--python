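"""Agreement statistics: formula oracles, category conventions, Fisher
enumeration vs the independent implementation, per-patient summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from afpulse.agreement import (
    accuracy_within_tolerance,
    bland_altman,
    categorize_rate,
    compare_groups_fisher,
    confusion_matrix,
    ConfusionMatrix,
    fisher_exact_2x2,
    is_le40,
    per_patient_summary,
    rmse,
    stratified_report,
    summarize_agreement,
)
from afpulse.fixtures import TABLE2_DAY, TABLE2_NIGHT
from afpulse.synth import simulate_segment_table


class TestRmse:
    def test_identical_zero(self):
        assert rmse([70, 80], [70, 80]) == 0.0

    def test_hand_value(self):
        # diffs (4, -3, 0) -> sqrt(25/3)
        assert rmse([70, 80, 90], [74, 77, 90]) == pytest.approx(np.sqrt(25 / 3))

    def test_constant_offset(self):
        a = np.array([60.0, 75.0, 90.0])
        assert rmse(a, a + 5) == pytest.approx(5.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            rmse([], [])

    @given(
        st.lists(st.floats(30, 200), min_size=2, max_size=30),
        st.floats(-20, 20),
    )
    @settings(max_examples=50, deadline=None)
    def test_rmse_at_least_abs_bias(self, base, offset):
        a = np.array(base)
        b = a + offset + np.sin(a)  # any perturbation
        res = bland_altman(a, b)
        assert rmse(a, b) >= abs(res.bias) - 1e-9


class TestBlandAltman:
    def test_constant_offset_degenerate(self):
        a = np.array([60.0, 70.0, 80.0])
        res = bland_altman(a, a + 5)
        assert res.bias == pytest.approx(5.0)
        assert res.lower_limit == pytest.approx(5.0)
        assert res.upper_limit == pytest.approx(5.0)

    def test_two_point_hand_value(self):
        # diffs (-1, +1): bias 0, sample SD sqrt(2), limits -+1.96*sqrt(2)
        res = bland_altman([70.0, 80.0], [69.0, 81.0])
        assert res.bias == pytest.approx(0.0)
        assert res.upper_limit == pytest.approx(1.96 * np.sqrt(2.0))
        assert res.lower_limit == pytest.approx(-1.96 * np.sqrt(2.0))

    def test_population_sd_option(self):
        res = bland_altman([70.0, 80.0], [69.0, 81.0], ddof=0)
        assert res.upper_limit == pytest.approx(1.96)

    def test_limits_symmetric_about_bias(self):
        rng = np.random.default_rng(0)
        a = rng.uniform(50, 120, 100)
        b = a + rng.normal(1, 3, 100)
        res = bland_altman(a, b)
        assert res.upper_limit - res.bias == pytest.approx(res.bias - res.lower_limit)

    def test_too_few_pairs(self):
        with pytest.raises(ValueError):
            bland_altman([70.0], [71.0])


class TestAccuracy:
    def test_strict_boundary(self):
        # 9% deviation counts, exactly 10% does not
        assert accuracy_within_tolerance([100.0], [109.0]) == 100.0
        assert accuracy_within_tolerance([80.0], [88.0]) == 0.0

    def test_all_equal(self):
        assert accuracy_within_tolerance([70, 80], [70, 80]) == 100.0

    @given(st.floats(0.1, 10.0))
    @settings(max_examples=30, deadline=None)
    def test_scale_invariance(self, c):
        a = np.array([60.0, 80.0, 100.0, 120.0])
        b = np.array([65.0, 81.0, 95.0, 140.0])
        assert accuracy_within_tolerance(a, b) == accuracy_within_tolerance(c * a, c * b)


class TestCategories:
    @pytest.mark.parametrize(
        "hr, cat",
        [(80.0, "<=80"), (110.0, "80-110"), (110.5, ">110"), (38.0, "<=80"), (80.1, "80-110")],
    )
    def test_boundaries(self, hr, cat):
        assert categorize_rate(hr) == cat

    def test_le40_subband(self):
        assert is_le40(38.0) and not is_le40(41.0)

    def test_invalid_hr(self):
        with pytest.raises(ValueError):
            categorize_rate(0.0)


class TestConfusionMatrix:
    def test_perfect_agreement_diagonal(self):
        hr = np.array([60.0, 75, 90, 100, 120, 130])
        cm = confusion_matrix(hr, hr)
        assert np.trace(cm.counts) == 6
        assert cm.rough_accuracy() == 100.0

    def test_printed_day_table_row_percentages(self):
        cm = ConfusionMatrix.from_counts(TABLE2_DAY)
        pct = cm.row_percentages()
        assert pct[0, 0] == pytest.approx(93.5, abs=0.05)
        assert pct[0, 1] == pytest.approx(6.3, abs=0.05)
        assert pct[2, 2] == pytest.approx(61.8, abs=0.05)

    def test_printed_night_rough_accuracy(self):
        cm = ConfusionMatrix.from_counts(TABLE2_NIGHT)
        assert round(cm.rough_accuracy()) == 98
        assert np.trace(cm.counts) == 15956

    def test_row_sums_stable_under_column_permutation(self):
        rng = np.random.default_rng(1)
        a = rng.uniform(50, 130, 300)
        b = a + rng.normal(0, 8, 300)
        cm = confusion_matrix(a, b)
        # permuting the PPG assignments of the same segments preserves
        # the ECG row totals
        cm2 = confusion_matrix(a, rng.permutation(b))
        assert np.array_equal(cm.counts.sum(axis=1), cm2.counts.sum(axis=1))


class TestFisher:
    def test_chf_table_reproduction(self):
        assert fisher_exact_2x2([[7, 8], [6, 29]]) == pytest.approx(0.040, abs=5e-4)

    def test_identical_proportions_p1(self):
        assert fisher_exact_2x2([[10, 20], [10, 20]]) == 1.0

    def test_degenerate_margins(self):
        assert fisher_exact_2x2([[0, 0], [5, 7]]) == 1.0
        assert fisher_exact_2x2([[3, 0], [4, 0]]) == 1.0

    @pytest.mark.parametrize("table", [[[2, 3], [3, 2]], [[1, 9], [11, 3]], [[5, 0], [1, 4]]])
    def test_matches_scipy_oracle(self, table):
        ours = fisher_exact_2x2(table)
        ref = stats.fisher_exact(table).pvalue
        assert ours == pytest.approx(ref, rel=1e-9)

    @given(st.integers(0, 12), st.integers(0, 12), st.integers(0, 12), st.integers(0, 12))
    @settings(max_examples=200, deadline=None)
    def test_matches_scipy_property(self, a, b, c, d):
        ours = fisher_exact_2x2([[a, b], [c, d]])
        ref = stats.fisher_exact([[a, b], [c, d]]).pvalue
        assert ours == pytest.approx(ref, rel=1e-7, abs=1e-12)

    def test_compare_groups_wrapper(self):
        flags = np.array([True] * 15 + [False] * 35)
        chf = np.array([True] * 7 + [False] * 8 + [True] * 6 + [False] * 29)
        table, p = compare_groups_fisher(flags, chf)
        assert np.array_equal(table, [[7, 8], [6, 29]])
        assert p == pytest.approx(0.040, abs=5e-4)


class TestPatientSummaries:
    def _table(self, hr_ppg_fn, n=120):
        hr = np.linspace(60, 90, n)
        return pd.DataFrame(
            {
                "patient_id": "P000",
                "minute_start": np.arange(n) * 60.0,
                "hr_ecg": hr,
                "hr_ppg": hr_ppg_fn(hr),
                "included": True,
            }
        )

    def test_constant_patient(self):
        df = self._table(lambda hr: hr * 0 + 72.0)
        df["hr_ecg"] = 72.0
        s = per_patient_summary(df)[0]
        assert s.mean_ecg == s.min_ecg == s.max_ecg == 72.0
        assert s.agreement_rate == 100.0
        assert not s.low_agreement_flag

    def test_low_agreement_flag_threshold(self):
        def ppg(hr):
            out = hr.copy()
            out[: int(0.06 * len(hr))] *= 1.25  # 6% of minutes off by 25%
            return out

        s = per_patient_summary(self._table(ppg))[0]
        assert s.agreement_rate < 95.0
        assert s.low_agreement_flag

    def test_mean_rmse_not_above_segment_rmse_when_bias_free(self):
        """Averaging within patients can only shrink bias-free error."""
        tab = simulate_segment_table("unbiased", n_patients=12, minutes_per_patient=150, seed=4)
        summaries = per_patient_summary(tab)
        seg_rmse = rmse(tab["hr_ecg"], tab["hr_ppg"])
        mean_rmse = rmse(
            [s.mean_ecg for s in summaries], [s.mean_ppg for s in summaries]
        )
        assert mean_rmse <= seg_rmse


class TestStratifiedReport:
    def test_identical_strata_identical_summaries(self):
        rng = np.random.default_rng(2)
        hr = rng.uniform(55, 115, 200)
        ppg = hr + rng.normal(0, 3, 200)
        half = pd.DataFrame(
            {
                "patient_id": ["P%d" % (i % 4) for i in range(200)],
                "minute_start": np.arange(200) * 60.0,
                "hr_ecg": hr,
                "hr_ppg": ppg,
                "included": True,
                "daynight": "day",
                "motion_quartile": "G1",
            }
        )
        other = half.copy()
        other["daynight"] = "night"
        other["motion_quartile"] = "G4"
        rep = stratified_report(pd.concat([half, other], ignore_index=True))
        day, night = rep["strata"]["day"], rep["strata"]["night"]
        assert day.rmse == pytest.approx(night.rmse)
        assert day.pct_within_10 == pytest.approx(night.pct_within_10)
        assert rep["comparisons"]["day_vs_night"]["fisher_p"] == 1.0

    def test_summary_invariant_rmse_vs_bias(self):
        rng = np.random.default_rng(3)
        a = rng.uniform(50, 120, 500)
        b = a + rng.normal(2, 4, 500)
        s = summarize_agreement(a, b)
        assert s.rmse >= abs(s.bland_altman.bias)
        assert 0.0 <= s.pct_within_10 <= 100.0
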