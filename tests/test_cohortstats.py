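"""Culture/condition aggregation, Dunnett statistics and PI concordance."""

import numpy as np
import pytest
from scipy import stats as sps

from phasetox.cohortstats import (
    concordance, dose_response, dunnett_vs_control, round_half_up, stars,
    summarize_condition, summarize_culture, unpaired_t,
)


class TestSummaries:
    def test_culture_percentages(self):
        s = summarize_culture(["BP"] * 5 + ["RD"] * 10 + ["ID"] * 5)
        assert (s.pct_BP, s.pct_RD, s.pct_ID) == (25.0, 50.0, 25.0)

    def test_all_id_culture(self):
        s = summarize_culture(["ID"] * 20)
        assert (s.pct_BP, s.pct_RD, s.pct_ID) == (0.0, 0.0, 100.0)

    def test_none_and_unclassified_excluded_from_denominator(self):
        s = summarize_culture(["ID"] * 3 + ["RD"] * 1 + ["NONE"] * 4 + ["UNCLASSIFIED"])
        assert s.pct_ID == pytest.approx(75.0)
        assert (s.n_none, s.n_unclassified, s.n_cells) == (4, 1, 9)

    def test_empty_culture_raises(self):
        with pytest.raises(ValueError):
            summarize_culture([])

    def test_percentages_sum_to_100(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            labels = rng.choice(["BP", "RD", "ID", "NONE"], size=30)
            if not set(labels) & {"BP", "RD", "ID"}:
                continue
            s = summarize_culture(labels)
            assert s.pct_BP + s.pct_RD + s.pct_ID == pytest.approx(100.0)

    def test_condition_mean_and_sem_closed_form(self):
        cultures = [summarize_culture(["ID"] * 6 + ["RD"] * 4),   # 60% ID
                    summarize_culture(["ID"] * 7 + ["RD"] * 3)]   # 70% ID
        s = summarize_condition(cultures)
        assert s.mean_pct_ID == pytest.approx(65.0)
        assert s.sem_pct_ID == pytest.approx(5.0)

    def test_single_culture_sem_is_flagged_nan(self):
        s = summarize_condition([summarize_culture(["ID"] * 5)])
        assert np.isnan(s.sem_pct_ID)

    def test_simulated_control_cultures_recover_generating_rate(self):
        """16 binomial cultures at p_ID = 0.66, 29 cells each: the mean ID
        percentage lands within 3 SEM of 66 (binomial oracle, no traces)."""
        rng = np.random.default_rng(123)
        cultures = []
        for _ in range(16):
            n_id = rng.binomial(29, 0.66)
            cultures.append(summarize_culture(["ID"] * n_id + ["RD"] * (29 - n_id)))
        s = summarize_condition(cultures)
        assert abs(s.mean_pct_ID - 66.0) < 3 * s.sem_pct_ID

    def test_sem_shrinks_like_inverse_sqrt_n(self):
        rng = np.random.default_rng(5)
        sems = []
        for n_cult in (8, 32, 128):
            reps = []
            for _ in range(200):
                cultures = []
                for _ in range(n_cult):
                    k = rng.binomial(29, 0.5)
                    k = min(max(k, 1), 28)
                    cultures.append(summarize_culture(["ID"] * k + ["RD"] * (29 - k)))
                reps.append(summarize_condition(cultures).sem_pct_ID)
            sems.append(np.mean(reps))
        assert sems[0] / sems[1] == pytest.approx(2.0, rel=0.1)
        assert sems[1] / sems[2] == pytest.approx(2.0, rel=0.1)


class TestDunnett:
    def test_single_treatment_reduces_to_pooled_t(self):
        """With one treatment group Dunnett's adjusted p equals the two-sided
        pooled-variance two-sample t-test p."""
        rng = np.random.default_rng(11)
        a, b = rng.normal(50, 10, 8), rng.normal(42, 10, 9)
        res = dunnett_vs_control(a, {"t": b}, rng=0)
        expected = sps.ttest_ind(b, a, equal_var=True).pvalue
        assert res.adjusted_p["t"] == pytest.approx(expected, abs=1e-3)

    def test_adjusted_p_never_below_unadjusted(self):
        rng = np.random.default_rng(2)
        control = rng.normal(60, 8, 10)
        treats = {f"t{i}": rng.normal(55, 8, 10) for i in range(3)}
        res = dunnett_vs_control(control, treats, rng=0)
        for name, vals in treats.items():
            raw = sps.ttest_ind(vals, control, equal_var=True).pvalue
            assert res.adjusted_p[name] >= raw - 1e-6

    def test_constant_groups_raise(self):
        with pytest.raises(ValueError, match="variance"):
            dunnett_vs_control([5.0, 5.0, 5.0], {"t": [5.0, 5.0, 5.0]})

    def test_too_few_replicates_raise(self):
        with pytest.raises(ValueError, match="replicate"):
            dunnett_vs_control([1.0], {"t": [2.0, 3.0]})

    def test_stars_follow_report_convention(self):
        assert stars(0.04) == "*"
        assert stars(0.009) == "**"
        assert stars(0.004) == "***"
        assert stars(0.2) == "ns"


class TestUnpairedT:
    def test_identical_groups_give_p_one(self):
        p = unpaired_t([1.0, 2.0, 3.0], [3.0, 2.0, 1.0])
        assert p == pytest.approx(1.0)

    def test_matches_hand_computed_t(self):
        """Textbook case checked against the pooled-variance formula."""
        a, b = np.array([1.0, 2.0, 3.0, 4.0]), np.array([3.0, 4.0, 5.0, 6.0])
        sp2 = (a.var(ddof=1) * 3 + b.var(ddof=1) * 3) / 6
        t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / 4 + 1 / 4))
        expected = 2 * sps.t.sf(abs(t), df=6)
        assert unpaired_t(a, b) == pytest.approx(expected, abs=1e-12)

    def test_shifted_groups_at_large_n_reject(self):
        rng = np.random.default_rng(3)
        assert unpaired_t(rng.normal(0, 1, 500), rng.normal(1, 1, 500)) < 1e-10


class TestConcordance:
    def test_reproduces_printed_id_percentage(self):
        """57 of 66 ID cells PI-positive -> 86% after half-up rounding."""
        labels = ["ID"] * 66
        pi = [True] * 57 + [False] * 9
        table = concordance(labels, pi)
        assert table.pct_rounded("ID") == 86

    def test_reproduces_printed_protected_percentage(self):
        """17 of 54 cells PI-positive -> 31%."""
        labels = ["RD"] * 54
        pi = [True] * 17 + [False] * 37
        assert concordance(labels, pi).pct_rounded("RD") == 31

    def test_empty_class_is_flagged(self):
        table = concordance(["RD", "RD"], [True, False])
        with pytest.raises(ValueError, match="no cells"):
            table.pct_rounded("ID")
        assert "ID" not in table.counts.index

    def test_mismatched_lengths_raise(self):
        with pytest.raises(ValueError):
            concordance(["ID"], [True, False])

    def test_counts_partition_the_input(self):
        labels = ["ID"] * 4 + ["RD"] * 3 + ["BP"] * 2
        pi = [True, True, False, False, True, False, False, False, True]
        table = concordance(labels, pi)
        assert int(table.counts.to_numpy().sum()) == len(labels)

    def test_rounding_is_half_up(self):
        assert round_half_up(85.5) == 86
        assert round_half_up(30.49) == 30
        assert round_half_up(0.5) == 1


class TestDoseResponse:
    def _binomial_cultures(self, rng, p, n_cult=12, cells=29):
        out = []
        for _ in range(n_cult):
            k = rng.binomial(cells, p)
            out.append(100.0 * k / cells)
        return out

    def test_identical_doses_show_no_significance(self):
        rng = np.random.default_rng(8)
        per_dose = {d: self._binomial_cultures(rng, 0.66) for d in (0.0, 1.0, 5.0, 10.0)}
        res = dose_response(per_dose, rng=0)
        assert res.lowest_significant_dose is None

    def test_single_dose_reduces_to_t_test(self):
        rng = np.random.default_rng(9)
        per_dose = {0.0: self._binomial_cultures(rng, 0.66),
                    10.0: self._binomial_cultures(rng, 0.32)}
        res = dose_response(per_dose, rng=0)
        expected = sps.ttest_ind(per_dose[10.0], per_dose[0.0], equal_var=True).pvalue
        assert res.adjusted_p[10.0] == pytest.approx(expected, abs=1e-3)

    def test_missing_control_dose_raises(self):
        with pytest.raises(ValueError, match="control dose"):
            dose_response({1.0: [50.0, 60.0], 5.0: [40.0, 45.0]})
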