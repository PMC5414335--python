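import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from regact import (
    roc_auc,
    stratify_by_modes,
    stratify_tertiles,
    stratum_response_table,
    subgroup_report,
)
from regact.containers import ClinicalTable
from regact.response import ActivityStrata

from conftest import all_pairs_concordance, fisher_two_sided_exhaustive


def _clinical(responses, index=None, **extra):
    idx = index if index is not None else [f"s{i}" for i in range(len(responses))]
    df = pd.DataFrame({"response": responses, **extra}, index=pd.Index(idx, name="sample_id"))
    return ClinicalTable(df)


def _strata(labels, index=None, t_low=-1.0, t_high=1.0):
    idx = index if index is not None else [f"s{i}" for i in range(len(labels))]
    return ActivityStrata("fixed", t_low, t_high, pd.Series(labels, index=idx))


class TestStratifyByModes:
    def test_bimodal_mixture_thresholds_near_modes(self):
        rng = np.random.default_rng(4)
        scores = np.r_[rng.normal(-2, 0.5, 300), rng.normal(2, 0.5, 300)]
        strata = stratify_by_modes(pd.Series(scores))
        # KDE modes should land near the component means.
        assert strata.t_low == pytest.approx(-2.0, abs=0.3)
        assert strata.t_high == pytest.approx(2.0, abs=0.3)
        assert (strata.labels[scores < strata.t_low] == "low").all()
        assert (strata.labels[scores > strata.t_high] == "high").all()

    def test_unimodal_scores_raise(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError, match="tertiles"):
            stratify_by_modes(pd.Series(rng.normal(0, 1, 200)))

    def test_minimum_cohort_size(self):
        with pytest.raises(ValueError, match="20"):
            stratify_by_modes(pd.Series(np.arange(10.0)))


class TestStratifyTertiles:
    def test_nine_distinct_split_evenly(self):
        strata = stratify_tertiles(pd.Series(np.arange(9.0)))
        assert strata.counts() == {"low": 3, "intermediate": 3, "high": 3}

    def test_ten_scores_low_gets_remainder(self):
        strata = stratify_tertiles(pd.Series(np.arange(10.0)))
        assert strata.counts() == {"low": 4, "intermediate": 3, "high": 3}

    def test_all_identical_all_low(self):
        strata = stratify_tertiles(pd.Series(np.ones(7)))
        assert strata.counts()["low"] == 7

    def test_boundary_ties_fall_to_lower_stratum(self):
        strata = stratify_tertiles(pd.Series([1.0, 1.0, 1.0, 1.0, 2.0, 3.0]))
        # The value 1.0 straddles the low boundary: all 1.0 samples are low,
        # emptying the intermediate stratum.
        assert strata.counts() == {"low": 4, "intermediate": 0, "high": 2}

    def test_labels_consistent_with_thresholds(self):
        s = pd.Series([5.0, 1.0, 3.0, 2.0, 4.0, 0.0])
        strata = stratify_tertiles(s)
        assert (s[strata.labels == "low"] <= strata.t_low).all()
        assert (s[strata.labels == "high"] >= strata.t_high).all()


class TestStratumResponseTable:
    def test_extreme_gradient(self):
        labels = ["low"] * 10 + ["intermediate"] * 10 + ["high"] * 10
        resp = ["RD"] * 20 + ["pCR"] * 10
        tab = stratum_response_table(_strata(labels), _clinical(resp))
        assert list(tab.table["pcr_rate"]) == [0.0, 0.0, 1.0]
        assert tab.chi2_p < 0.001

    def test_identical_rates_null(self):
        labels = ["low"] * 10 + ["intermediate"] * 10 + ["high"] * 10
        resp = (["pCR"] * 5 + ["RD"] * 5) * 3
        tab = stratum_response_table(_strata(labels), _clinical(resp))
        assert tab.chi2 == pytest.approx(0.0, abs=1e-12)
        assert tab.chi2_p == pytest.approx(1.0)

    def test_fisher_matches_exhaustive_hypergeometric(self):
        # Collapsed 2x2 = [[1, 9], [11, 3]]
        labels = ["low"] * 10 + ["high"] * 14
        resp = ["pCR"] * 1 + ["RD"] * 9 + ["pCR"] * 11 + ["RD"] * 3
        tab = stratum_response_table(_strata(labels), _clinical(resp))
        assert tab.fisher_p == pytest.approx(fisher_two_sided_exhaustive(1, 9, 11, 3), rel=1e-9)

    def test_missing_responses_excluded_and_counted(self):
        labels = ["low", "low", "high", "high"]
        resp = ["pCR", np.nan, "RD", "pCR"]
        tab = stratum_response_table(_strata(labels), _clinical(resp))
        assert tab.n_missing_response == 1
        assert tab.table["n"].sum() == 3

    def test_count_conservation(self):
        rng = np.random.default_rng(3)
        labels = rng.choice(["low", "intermediate", "high"], 60)
        resp = rng.choice(["pCR", "RD"], 60)
        tab = stratum_response_table(_strata(list(labels)), _clinical(list(resp)))
        assert tab.table["n_pcr"].sum() == (resp == "pCR").sum()

    def test_empty_stratum_skips_chi2_keeps_rates(self):
        labels = ["low"] * 5 + ["high"] * 5
        resp = ["pCR"] * 5 + ["RD"] * 5
        tab = stratum_response_table(_strata(labels), _clinical(resp))
        assert tab.chi2 is None
        assert tab.table.loc["low", "pcr_rate"] == 1.0


class TestRocAuc:
    def test_perfect_separation(self):
        roc = roc_auc([1.0, 2.0, 3.0, 4.0], ["RD", "RD", "pCR", "pCR"])
        assert roc.auc == 1.0
        assert roc.fpr[0] == roc.tpr[0] == 0.0
        assert roc.fpr[-1] == roc.tpr[-1] == 1.0

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            roc_auc([1.0, 2.0], ["pCR", "pCR"])

    def test_curve_monotone_nondecreasing(self):
        rng = np.random.default_rng(7)
        roc = roc_auc(rng.normal(size=80), rng.random(80) < 0.3)
        assert (np.diff(roc.fpr) >= 0).all()
        assert (np.diff(roc.tpr) >= 0).all()

    def test_null_expectation_large_n(self):
        rng = np.random.default_rng(11)
        scores = rng.normal(size=4000)
        labels = rng.random(4000) < 0.5
        assert roc_auc(scores, labels).auc == pytest.approx(0.5, abs=0.05)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(st.integers(4, 40), st.integers(0, 2**31 - 1), st.booleans())
    def test_matches_all_pairs_concordance(self, n, seed, with_ties):
        """Primary oracle: sweep AUC == Mann-Whitney concordance (ties 1/2)."""
        rng = np.random.default_rng(seed)
        scores = rng.integers(0, 6, n).astype(float) if with_ties else rng.normal(size=n)
        labels = np.zeros(n, dtype=bool)
        labels[rng.choice(n, rng.integers(1, n), replace=False)] = True
        if labels.all() or not labels.any():
            labels[0] = ~labels[0]
        assert roc_auc(scores, labels).auc == pytest.approx(
            all_pairs_concordance(scores, labels), abs=1e-12
        )

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(5, 30), st.integers(0, 2**31 - 1))
    def test_antisymmetry_and_monotone_invariance(self, n, seed):
        rng = np.random.default_rng(seed)
        scores = rng.normal(size=n)
        labels = rng.random(n) < 0.4
        if labels.all() or not labels.any():
            labels[0] = ~labels[0]
        auc = roc_auc(scores, labels).auc
        assert roc_auc(-scores, labels).auc == pytest.approx(1.0 - auc, abs=1e-12)
        assert roc_auc(np.exp(scores), labels).auc == pytest.approx(auc, abs=1e-12)


class TestSubgroupReport:
    def test_partition_by_er(self):
        labels = ["low"] * 6 + ["high"] * 6
        er = ["positive", "negative"] * 6
        resp = ["pCR", "RD"] * 6
        clin = _clinical(resp, er=er)
        tables = subgroup_report(_strata(labels), clin, by="er")
        assert set(tables) == {"positive", "negative"}
        assert sum(t.table["n"].sum() for t in tables.values()) == 12

    def test_single_stratum_level_skips_test(self):
        labels = ["low"] * 4 + ["high"] * 4
        grp = ["a"] * 4 + ["b"] * 4
        resp = ["pCR", "RD"] * 4
        tables = subgroup_report(_strata(labels), _clinical(resp, subtype=grp), by="subtype")
        assert tables["a"].chi2_p is None

    def test_gradient_within_er_subgroups(self, default_cohort, default_iras):
        strata = stratify_by_modes(default_iras.as_series())
        tables = subgroup_report(strata, default_cohort.clinical, by="er")
        for tab in tables.values():
            rates = tab.table["pcr_rate"].to_numpy()
            assert rates[0] <= rates[1] <= rates[2]
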