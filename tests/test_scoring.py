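"""EMT score arithmetic, eligibility rules and quartile stratification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from emtime.scoring import (CohortIneligibleError, MarkerPanel,
                            EMTScoreTable, check_cohort_eligibility,
                            compute_emt_score, stratify_by_emt,
                            summarize_distribution, GROUP_HIGH,
                            GROUP_INTERMEDIATE, GROUP_LOW)
from conftest import make_expression


def _panel_matrix(values, samples, panel):
    """Full 16-gene matrix in panel order (epithelial first)."""
    genes = list(panel.epithelial) + list(panel.mesenchymal)
    return make_expression(values, genes, samples)


class TestMarkerPanel:
    def test_default_panel_is_the_canonical_16(self, panel):
        assert panel.epithelial == ("CDH1", "DSP", "TJP1")
        assert len(panel.mesenchymal) == 13
        assert len(set(panel.all_genes)) == 16

    def test_overlapping_lists_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            MarkerPanel(epithelial=("VIM",), mesenchymal=("VIM", "FN1"))


class TestComputeScore:
    def test_all_zero_sample_scores_zero(self, panel):
        m = _panel_matrix(np.zeros((16, 2)), ["a", "b"], panel)
        s = compute_emt_score(m, panel)
        assert s.score.tolist() == [0.0, 0.0]
        assert (s.n_epi_used, s.n_mes_used) == (3, 13)

    def test_unit_mesenchymal_zero_epithelial_scores_one(self, panel):
        vals = np.vstack([np.zeros((3, 1)), np.ones((13, 1))])
        s = compute_emt_score(_panel_matrix(vals, ["a"], panel), panel)
        assert s.score.iloc[0] == pytest.approx(1.0)

    def test_random_matrix_matches_column_mean_oracle(self, panel, rng):
        vals = rng.normal(size=(16, 5))
        s = compute_emt_score(
            _panel_matrix(vals, [f"s{i}" for i in range(5)], panel), panel)
        # independent spreadsheet-style oracle: per column, mean of rows
        # 3..15 minus mean of rows 0..2
        expected = vals[3:, :].mean(axis=0) - vals[:3, :].mean(axis=0)
        np.testing.assert_allclose(s.score.to_numpy(), expected, rtol=1e-12)

    def test_missing_panel_genes_use_available_ones(self, panel):
        m = make_expression([[1.0], [0.2]], ["VIM", "CDH1"], ["a"])
        s = compute_emt_score(m, panel)
        assert s.score.iloc[0] == pytest.approx(0.8)
        assert (s.n_epi_used, s.n_mes_used) == (1, 1)

    def test_no_usable_side_is_ineligible_error(self, panel):
        m = make_expression([[1.0]], ["VIM"], ["a"])
        with pytest.raises(CohortIneligibleError, match="epithelial"):
            compute_emt_score(m, panel)

    def test_sample_with_all_missing_side_gets_nan_score(self, panel):
        vals = np.array([[np.nan, 0.5], [1.0, 1.0]])
        s = compute_emt_score(make_expression(vals, ["CDH1", "VIM"],
                                              ["a", "b"]), panel)
        assert np.isnan(s.score.loc["a"])
        assert s.score.loc["b"] == pytest.approx(0.5)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(c=st.floats(-5, 5, allow_nan=False),
           seed=st.integers(0, 10_000))
    def test_translation_equivariance(self, c, seed):
        """+c on every mesenchymal z raises each score by exactly c; +c on
        epithelial genes lowers it by c."""
        panel = MarkerPanel()
        rng = np.random.default_rng(seed)
        vals = rng.normal(size=(16, 6))
        samples = [f"s{i}" for i in range(6)]
        base = compute_emt_score(_panel_matrix(vals, samples, panel), panel)
        shifted = vals.copy()
        shifted[3:, :] += c
        up = compute_emt_score(_panel_matrix(shifted, samples, panel), panel)
        np.testing.assert_allclose(up.score, base.score + c, atol=1e-9)
        shifted = vals.copy()
        shifted[:3, :] += c
        down = compute_emt_score(_panel_matrix(shifted, samples, panel), panel)
        np.testing.assert_allclose(down.score, base.score - c, atol=1e-9)

    def test_permutation_invariance(self, panel, rng):
        vals = rng.normal(size=(16, 7))
        samples = [f"s{i}" for i in range(7)]
        genes = list(panel.epithelial) + list(panel.mesenchymal)
        base = compute_emt_score(make_expression(vals, genes, samples), panel)
        gp = rng.permutation(16)
        sp = rng.permutation(7)
        shuffled = make_expression(vals[np.ix_(gp, sp)],
                                   [genes[i] for i in gp],
                                   [samples[i] for i in sp])
        perm = compute_emt_score(shuffled, panel)
        np.testing.assert_allclose(perm.score.loc[samples], base.score,
                                   rtol=1e-12)


class TestEligibility:
    def _cohort(self, n, panel, drop=()):
        genes = [g for g in panel.all_genes if g not in drop]
        return make_expression(np.zeros((len(genes), n)), genes,
                               [f"s{i}" for i in range(n)])

    def test_large_complete_cohort_eligible(self, panel):
        v = check_cohort_eligibility(self._cohort(150, panel), panel)
        assert v.eligible and v.reasons == ()

    def test_missing_cdh1_is_ineligible(self, panel):
        v = check_cohort_eligibility(self._cohort(150, panel, drop=("CDH1",)),
                                     panel)
        assert not v.eligible
        assert any("required epithelial marker absent: CDH1" in r
                   for r in v.reasons)

    def test_small_cohort_is_ineligible(self, panel):
        v = check_cohort_eligibility(self._cohort(80, panel), panel)
        assert not v.eligible
        assert any("n <= 100" in r for r in v.reasons)

    def test_boundary_n_exactly_100_is_ineligible(self, panel):
        # eligibility requires n > 100, not n >= 100
        assert not check_cohort_eligibility(self._cohort(100, panel),
                                            panel).eligible
        assert check_cohort_eligibility(self._cohort(101, panel),
                                        panel).eligible

    def test_required_genes_configurable(self, panel):
        v = check_cohort_eligibility(self._cohort(150, panel, drop=("CDH1",)),
                                     panel, required_genes=("DSP",))
        assert v.eligible


def _scores(values, cohort="X"):
    return EMTScoreTable(cohort, pd.Series(
        np.asarray(values, dtype=float),
        index=[f"s{i}" for i in range(len(values))]), 3, 13)


def brute_force_stratify(values):
    """Independent rank-and-cut enumeration: sort indices by (score, input
    position), cut the sorted list at floor(n/4) and ceil(3n/4)."""
    n = len(values)
    order = sorted(range(n), key=lambda i: (values[i], i))
    low = set(order[: n // 4])
    high = set(order[int(np.ceil(0.75 * n)):])
    return ["low" if i in low else "high" if i in high else "intermediate"
            for i in range(n)]


class TestStratify:
    def test_scores_1_to_8_give_2_4_2(self):
        g = stratify_by_emt(_scores(range(1, 9)))
        assert g.counts() == {"high": 2, "intermediate": 4, "low": 2}
        assert set(g.members(GROUP_HIGH)) == {"s6", "s7"}   # scores 7, 8
        assert set(g.members(GROUP_LOW)) == {"s0", "s1"}    # scores 1, 2

    def test_1000_distinct_scores_give_exactly_250_high(self, rng):
        vals = rng.permutation(1000).astype(float)
        g = stratify_by_emt(_scores(vals))
        assert g.counts() == {"high": 250, "intermediate": 500, "low": 250}

    def test_boundary_tie_matches_brute_force_rank_oracle(self):
        # 12 scores with a 4-way tie spanning the upper quartile boundary
        vals = [0, 1, 2, 3, 4, 5, 7, 7, 7, 7, 9, 10]
        g = stratify_by_emt(_scores(vals))
        assert g.group.tolist() == brute_force_stratify(vals)
        assert g.counts() == {"high": 3, "intermediate": 6, "low": 3}

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.lists(st.integers(-5, 5), min_size=8, max_size=40))
    def test_rank_rule_matches_oracle_and_is_monotone(self, vals):
        g = stratify_by_emt(_scores(vals))
        assert g.group.tolist() == brute_force_stratify(vals)
        high = [vals[int(s[1:])] for s in g.members(GROUP_HIGH)]
        low = [vals[int(s[1:])] for s in g.members(GROUP_LOW)]
        assert min(high) >= max(low)  # no low sample above any high sample

    def test_fewer_than_8_samples_rejected(self):
        with pytest.raises(ValueError, match=">= 8"):
            stratify_by_emt(_scores(range(7)))

    def test_nan_scores_excluded_before_cutting(self):
        vals = list(range(1, 9)) + [np.nan]
        g = stratify_by_emt(_scores(vals))
        assert "s8" not in g.samples
        assert g.counts() == {"high": 2, "intermediate": 4, "low": 2}

    def test_boundaries_are_type7_quartiles(self):
        g = stratify_by_emt(_scores(range(1, 9)))
        assert g.boundaries == pytest.approx((2.75, 6.25))


class TestSummarize:
    def test_symmetric_scores_have_median_zero(self):
        assert summarize_distribution(_scores([-1, 0, 1])).median == 0.0

    def test_iqr_of_0123_under_type7_quantiles(self):
        # hand enumeration: q1 = 0 + 0.75*(1-0) = 0.75, q3 = 2 + 0.25 = 2.25
        s = summarize_distribution(_scores([0, 1, 2, 3]))
        assert s.quartile1 == pytest.approx(0.75)
        assert s.quartile3 == pytest.approx(2.25)
        assert s.iqr == pytest.approx(1.5)

    def test_constant_scores_have_zero_iqr(self):
        assert summarize_distribution(_scores([2, 2, 2, 2])).iqr == 0.0

    def test_single_score_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            summarize_distribution(_scores([1.0]))
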