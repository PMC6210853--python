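"""Contingency tests, survival curves, log-rank and ROC threshold selection."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from hccmolrisk.stats import (
    association_scan,
    clinical_dichotomies,
    fisher_exact_test,
    km_estimate,
    logrank_test,
    pearson_chi_square,
    roc_best_threshold,
)


def chi2_2x2_oracle(a, b, c, d):
    """Closed-form 2x2 chi-square and p, written independently of scipy's table code."""
    n = a + b + c + d
    stat = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
    p = math.erfc(math.sqrt(stat / 2.0))  # upper tail of chi2(1)
    return stat, p


def fisher_2x2_oracle(a, b, c, d):
    """Two-sided Fisher p by exhaustive hypergeometric enumeration."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def prob(x):
        return (math.comb(r1, x) * math.comb(r2, c1 - x)) / math.comb(n, c1)

    p_obs = prob(a)
    return sum(prob(x) for x in range(max(0, c1 - r2), min(r1, c1) + 1)
               if prob(x) <= p_obs * (1 + 1e-9))


def km_oracle(times, events):
    """Hand-rolled product-limit estimator over the distinct observed times."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    out = {}
    s = 1.0
    for t in np.unique(times):
        at_risk = (times >= t).sum()
        d = ((times == t) & (events == 1)).sum()
        if at_risk > 0:
            s *= 1.0 - d / at_risk
        out[t] = s
    return out


def logrank_oracle(ta, ea, tb, eb):
    """Hand-computed two-group log-rank chi-square (O-E and hypergeometric variance)."""
    ta, tb = np.asarray(ta, float), np.asarray(tb, float)
    ea, eb = np.asarray(ea, int), np.asarray(eb, int)
    all_t = np.unique(np.concatenate([ta[ea == 1], tb[eb == 1]]))
    o_minus_e = 0.0
    var = 0.0
    for t in all_t:
        n1 = (ta >= t).sum()
        n2 = (tb >= t).sum()
        d1 = ((ta == t) & (ea == 1)).sum()
        d2 = ((tb == t) & (eb == 1)).sum()
        n, d = n1 + n2, d1 + d2
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e ** 2 / var


class TestChiSquare:
    def test_reference_table_p_value(self):
        res = pearson_chi_square([[28, 62], [3, 32]])
        assert round(res.p_value, 4) == 0.0088
        assert res.df == 1

    def test_equal_proportions_statistic_zero(self):
        res = pearson_chi_square([[10, 10], [20, 20]])
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    @given(st.lists(st.integers(1, 80), min_size=4, max_size=4))
    def test_random_2x2_matches_closed_form_oracle(self, cells):
        a, b, c, d = cells
        res = pearson_chi_square([[a, b], [c, d]])
        stat, p = chi2_2x2_oracle(a, b, c, d)
        assert res.statistic == pytest.approx(stat, abs=1e-10)
        assert res.p_value == pytest.approx(p, abs=1e-10)

    def test_invariant_to_transposition_and_permutation(self):
        t = np.array([[5, 9, 2], [7, 1, 6]])
        base = pearson_chi_square(t).statistic
        assert pearson_chi_square(t.T).statistic == pytest.approx(base)
        assert pearson_chi_square(t[:, [2, 0, 1]]).statistic == pytest.approx(base)

    def test_zero_margin_errors(self):
        with pytest.raises(ValueError, match="margin"):
            pearson_chi_square([[0, 0], [3, 4]])


class TestFisher:
    def test_matches_enumeration_oracle(self):
        res = fisher_exact_test([[1, 9], [9, 1]])
        assert res.p_value == pytest.approx(fisher_2x2_oracle(1, 9, 9, 1), abs=1e-10)

    @given(st.lists(st.integers(1, 15), min_size=4, max_size=4))
    def test_random_tables_match_oracle(self, cells):
        a, b, c, d = cells
        res = fisher_exact_test([[a, b], [c, d]])
        assert res.p_value == pytest.approx(fisher_2x2_oracle(a, b, c, d), abs=1e-8)

    def test_symmetric_table_p_one(self):
        assert fisher_exact_test([[5, 5], [5, 5]]).p_value == pytest.approx(1.0)

    def test_zero_margin_and_shape_errors(self):
        with pytest.raises(ValueError):
            fisher_exact_test([[0, 0], [3, 4]])
        with pytest.raises(ValueError, match="2x2"):
            fisher_exact_test([[1, 2, 3], [4, 5, 6]])


class TestKaplanMeier:
    def test_censored_only_is_flat_one(self):
        curve = km_estimate(np.arange(1, 11), np.zeros(10))
        assert (curve.survival_probabilities == 1.0).all()

    def test_single_event_quarter_drop(self):
        curve = km_estimate([2, 3, 4, 5], [1, 0, 0, 0])
        assert curve.at(2) == pytest.approx(0.75)
        assert curve.at(1.9) == pytest.approx(1.0)

    def test_matches_hand_oracle_on_random_data(self, rng):
        times = rng.integers(1, 30, size=50).astype(float)
        events = rng.integers(0, 2, size=50)
        curve = km_estimate(times, events)
        oracle = km_oracle(times, events)
        for t, s in oracle.items():
            assert curve.at(t) == pytest.approx(s, abs=1e-10)

    def test_monotone_nonincreasing_and_bounded(self, rng):
        curve = km_estimate(rng.exponential(10, 40), rng.integers(0, 2, 40))
        s = curve.survival_probabilities
        assert (np.diff(s) <= 1e-12).all()
        assert ((0 <= s) & (s <= 1)).all()

    def test_merged_identical_groups_equal_each_group(self, rng):
        times = rng.exponential(10, 30)
        events = rng.integers(0, 2, 30)
        single = km_estimate(times, events)
        merged = km_estimate(np.concatenate([times, times]),
                             np.concatenate([events, events]))
        for t in np.unique(times):
            assert merged.at(t) == pytest.approx(single.at(t), abs=1e-10)

    def test_negative_time_errors(self):
        with pytest.raises(ValueError):
            km_estimate([-1, 2], [1, 0])


class TestLogrank:
    def test_identical_groups_p_one(self):
        t = [1, 2, 3, 4, 5]
        e = [1, 0, 1, 0, 1]
        res = logrank_test(t, e, t, e)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_matches_hand_oracle(self, rng):
        ta = rng.exponential(10, 40)
        ea = rng.integers(0, 2, 40)
        tb = rng.exponential(20, 35)
        eb = rng.integers(0, 2, 35)
        res = logrank_test(ta, ea, tb, eb)
        assert res.statistic == pytest.approx(logrank_oracle(ta, ea, tb, eb), abs=1e-8)

    def test_no_events_errors(self):
        with pytest.raises(ValueError, match="undefined"):
            logrank_test([1, 2], [0, 0], [3, 4], [0, 0])

    def test_empty_group_errors(self):
        with pytest.raises(ValueError):
            logrank_test([], [], [1], [1])


class TestRocThreshold:
    def test_separable_scores_midpoint(self):
        cut = roc_best_threshold([-3, -2, 2, 3], [True, True, False, False],
                                 positive_is_low=True)
        assert cut == pytest.approx(0.0)

    @given(st.data())
    def test_matches_exhaustive_search(self, data):
        n = 10
        scores = np.array(data.draw(st.lists(
            st.floats(-5, 5, allow_nan=False), min_size=n, max_size=n)))
        labels = np.array(data.draw(st.lists(st.booleans(), min_size=n, max_size=n)))
        if labels.all() or not labels.any() or len(np.unique(scores)) < 2:
            return
        cut = roc_best_threshold(scores, labels, positive_is_low=True)

        def j_at(c):
            pred = scores < c
            return ((pred & labels).sum() / labels.sum()
                    + (~pred & ~labels).sum() / (~labels).sum() - 1)

        uniq = np.unique(scores)
        best_j = max(j_at(c) for c in (uniq[:-1] + uniq[1:]) / 2)
        assert j_at(cut) == pytest.approx(best_j, abs=1e-12)

    def test_direction_flag(self):
        cut = roc_best_threshold([1, 2, 8, 9], [False, False, True, True])
        assert 2 < cut < 8

    def test_degenerate_inputs_error(self):
        with pytest.raises(ValueError, match="identical"):
            roc_best_threshold([1, 1, 1], [True, False, True])
        with pytest.raises(ValueError, match="classes"):
            roc_best_threshold([1, 2, 3], [True, True, True])


def cohort_from_2x2(feature_counts):
    """Per-sample frames reproducing a printed feature x covariate table."""
    rows = []
    for (feat, cov), count in feature_counts.items():
        rows += [{"feat": feat, "cov": cov}] * count
    df = pd.DataFrame(rows, index=[f"p{i:03d}" for i in range(len(rows))])
    return df


class TestAssociationScan:
    def _clinical(self, sexes):
        n = len(sexes)
        return pd.DataFrame({
            "sex": sexes,
            "age_years": [50.0] * n,
            "hbsag": ["negative"] * n,
            "hcvab": ["negative"] * n,
            "afp_ng_ml": [10.0] * n,
            "tumor_size_cm": [3.0] * n,
            "vascular_invasion": ["missing"] * n,
            "tumor_number": ["missing"] * n,
            "differentiation": ["missing"] * n,
        }, index=[f"p{i:03d}" for i in range(n)])

    def test_reproduces_printed_mutation_by_sex_table(self):
        # 28 mutant males, 62 wild-type males, 3 mutant females, 32 wild-type females
        sexes = ["male"] * 90 + ["female"] * 35
        flags = [True] * 28 + [False] * 62 + [True] * 3 + [False] * 32
        clinical = self._clinical(sexes)
        features = pd.DataFrame({"ctnnb1_mut": flags}, index=clinical.index)
        results = association_scan(clinical, features, covariates=["sex"])
        assert len(results) == 1
        assert round(results[0].test.p_value, 4) == 0.0088
        # feature levels in rows, covariate levels in columns
        assert results[0].table.to_numpy().tolist() == [[28, 3], [62, 32]]

    def test_all_missing_covariate_skipped(self, caplog):
        clinical = self._clinical(["male"] * 6 + ["female"] * 2)
        features = pd.DataFrame({"f": [True, False] * 4}, index=clinical.index)
        with caplog.at_level("WARNING"):
            results = association_scan(clinical, features,
                                       covariates=["vascular_invasion"])
        assert results == []

    def test_subclass_by_covariate_2x4(self):
        # subclass x HCV counts from the published 4-group table
        pos = {"A1": 10, "A2": 15, "B1": 25, "B2": 27}
        neg = {"A1": 17, "A2": 6, "B1": 16, "B2": 9}
        rows = []
        for sub in ("A1", "A2", "B1", "B2"):
            rows += [{"subclass": sub, "hcv": "positive"}] * pos[sub]
            rows += [{"subclass": sub, "hcv": "negative"}] * neg[sub]
        df = pd.DataFrame(rows, index=[f"p{i:03d}" for i in range(len(rows))])
        clinical = self._clinical(["male"] * len(df))
        clinical["hcvab"] = df["hcv"].to_numpy()
        features = pd.DataFrame({"subclass": df["subclass"].to_numpy()},
                                index=clinical.index)
        results = association_scan(clinical, features, covariates=["hcv"])
        assert round(results[0].test.p_value, 4) == 0.0149
        assert results[0].test.df == 3

    def test_dichotomies_missing_propagates(self):
        clinical = self._clinical(["male"] * 4)
        dich = clinical_dichotomies(clinical)
        assert dich["vascular_invasion"].isna().all()
        assert (dich["afp_high"] == "<cut").all()
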