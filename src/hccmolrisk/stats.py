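"""Contingency-table tests, survival estimation and ROC threshold selection.

Pearson chi-square (never continuity-corrected), Fisher's exact test,
Kaplan-Meier product-limit curves and the two-group log-rank test wrap
scipy and lifelines behind a uniform result type; all p-values are
two-sided.  ``association_scan`` reproduces the feature-by-covariate
association tables, dropping missing clinical values pairwise per test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats as sps

logger = logging.getLogger(__name__)


@dataclass
class TestResult:
    statistic: float
    df: int
    p_value: float
    method: str


@dataclass
class SurvivalCurve:
    """Product-limit estimate: stepwise survival over the observed event times."""

    event_times: np.ndarray
    survival_probabilities: np.ndarray
    numbers_at_risk: np.ndarray

    def at(self, t: float) -> float:
        """S(t): survival probability at time t (right-continuous step function)."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival_probabilities[idx])


def _as_counts(table) -> np.ndarray:
    counts = np.asarray(table, dtype=float)
    if counts.ndim != 2 or counts.shape[0] < 2 or counts.shape[1] < 2:
        raise ValueError(f"need an r x c table with r,c >= 2, got shape {counts.shape}")
    if (counts < 0).any():
        raise ValueError("negative cell count")
    if counts.sum() <= 0:
        raise ValueError("empty table")
    return counts


def pearson_chi_square(table) -> TestResult:
    """Pearson chi-square test of independence, without continuity correction.

    Raises on a zero row/column margin; logs a warning when any expected
    count is below 5 (Fisher's exact test is the usual fallback for 2x2).
    """
    counts = _as_counts(table)
    if (counts.sum(axis=1) == 0).any() or (counts.sum(axis=0) == 0).any():
        raise ValueError("zero row/column margin: chi-square undefined")
    stat, p, df, expected = sps.chi2_contingency(counts, correction=False)
    if (expected < 5).any():
        logger.warning("expected count < 5 in chi-square table; consider Fisher's exact test")
    return TestResult(float(stat), int(df), float(p), "pearson_chi_square")


def fisher_exact_test(table) -> TestResult:
    """Two-sided Fisher's exact test on a 2x2 table."""
    counts = _as_counts(table)
    if counts.shape != (2, 2):
        raise ValueError(f"Fisher's exact test requires a 2x2 table, got {counts.shape}")
    if (counts.sum(axis=1) == 0).any() or (counts.sum(axis=0) == 0).any():
        raise ValueError("zero row/column margin: Fisher's exact test undefined")
    _, p = sps.fisher_exact(counts.astype(int), alternative="two-sided")
    return TestResult(float("nan"), 1, float(p), "fisher_exact")


def km_estimate(times, events) -> SurvivalCurve:
    """Kaplan-Meier product-limit estimate of the survival function."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if (times < 0).any():
        raise ValueError("negative follow-up time")
    if not np.isin(events, (0, 1)).all():
        raise ValueError("events must be 0/1")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    event_table = kmf.event_table
    # keep only rows where the estimator can change (observed events), plus t=0
    surv = kmf.survival_function_["KM_estimate"]
    return SurvivalCurve(
        event_times=surv.index.to_numpy(dtype=float),
        survival_probabilities=surv.to_numpy(dtype=float),
        numbers_at_risk=event_table["at_risk"].reindex(surv.index).to_numpy(dtype=float),
    )


def logrank_test(times_a, events_a, times_b, events_b) -> TestResult:
    """Two-group log-rank test (1 degree of freedom)."""
    times_a = np.asarray(times_a, dtype=float)
    times_b = np.asarray(times_b, dtype=float)
    events_a = np.asarray(events_a, dtype=int)
    events_b = np.asarray(events_b, dtype=int)
    if len(times_a) == 0 or len(times_b) == 0:
        raise ValueError("both groups must be non-empty")
    if events_a.sum() + events_b.sum() == 0:
        raise ValueError("log-rank test undefined: no events in either group")
    res = _ll_logrank(times_a, times_b, event_observed_A=events_a, event_observed_B=events_b)
    return TestResult(float(res.test_statistic), 1, float(res.p_value), "logrank")


def roc_best_threshold(scores, labels, positive_is_low: bool = False) -> float:
    """ROC-optimal decision threshold by Youden's J.

    Candidate cuts are the midpoints between adjacent sorted unique scores;
    the returned cut maximizes J = sensitivity + specificity - 1, with ties
    broken toward the cut with higher sensitivity (then toward the lower
    cut).  ``positive_is_low=True`` means positives score strictly BELOW
    the cut (the global-hypomethylation convention); otherwise positives
    score strictly above it.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape:
        raise ValueError("scores/labels length mismatch")
    if labels.all() or not labels.any():
        raise ValueError("both label classes must be present")
    uniq = np.unique(scores)
    if len(uniq) < 2:
        raise ValueError("all scores identical: no threshold discriminates")
    cuts = (uniq[:-1] + uniq[1:]) / 2.0
    n_pos = labels.sum()
    n_neg = (~labels).sum()
    best = None
    for cut in cuts:
        pred = scores < cut if positive_is_low else scores > cut
        sens = (pred & labels).sum() / n_pos
        spec = (~pred & ~labels).sum() / n_neg
        j = sens + spec - 1.0
        key = (j, sens, -cut)
        if best is None or key > best[0]:
            best = (key, cut)
    return float(best[1])


# ---------------------------------------------------------------------------
# Association scan over clinical covariates
# ---------------------------------------------------------------------------

# covariate -> (level shown first in the table, second level); mirrors the
# published dichotomizations
_DICHOTOMY_ORDER = {
    "sex": ("male", "female"),
    "age_gt60": (">60", "<=60"),
    "hbv": ("positive", "negative"),
    "hcv": ("positive", "negative"),
    "nbnc": ("yes", "no"),
    "afp_high": (">=cut", "<cut"),
    "tumor_size_ge3": (">=3.0", "<3.0"),
    "vascular_invasion": ("presence", "absence"),
    "tumor_number": ("solitary", "multiple"),
    "differentiation": ("well", "moderately_poorly"),
}


def clinical_dichotomies(clinical: pd.DataFrame, afp_cut: float = 200.0,
                         size_cut: float = 3.0) -> pd.DataFrame:
    """Dichotomized clinical covariates; missing levels become NaN (dropped pairwise)."""
    out = pd.DataFrame(index=clinical.index)
    out["sex"] = clinical["sex"]
    out["age_gt60"] = np.where(clinical["age_years"] > 60, ">60", "<=60")
    out["hbv"] = clinical["hbsag"]
    out["hcv"] = clinical["hcvab"]
    nbnc = (clinical["hbsag"] == "negative") & (clinical["hcvab"] == "negative")
    out["nbnc"] = np.where(nbnc, "yes", "no")
    out["afp_high"] = np.where(clinical["afp_ng_ml"] >= afp_cut, ">=cut", "<cut")
    out["tumor_size_ge3"] = np.where(clinical["tumor_size_cm"] >= size_cut, ">=3.0", "<3.0")
    for col in ("vascular_invasion", "tumor_number", "differentiation"):
        out[col] = clinical[col].where(clinical[col] != "missing")
    return out


@dataclass
class AssociationResult:
    feature: str
    covariate: str
    table: pd.DataFrame
    test: TestResult


def association_scan(clinical: pd.DataFrame, features: pd.DataFrame,
                     covariates: list[str] | None = None,
                     afp_cut: float = 200.0, size_cut: float = 3.0,
                     ) -> list[AssociationResult]:
    """Chi-square association of each molecular feature with each covariate.

    ``features`` holds boolean columns (the molecular events) and/or a
    categorical ``subclass`` column; rows of the 2 x c (or k x c) table are
    feature levels, columns the covariate levels, missing clinical values
    dropped pairwise.  Degenerate pairs (all-missing covariate, zero
    margin) are skipped with a warning.
    """
    dich = clinical_dichotomies(clinical, afp_cut=afp_cut, size_cut=size_cut)
    if covariates is None:
        covariates = list(_DICHOTOMY_ORDER)
    results: list[AssociationResult] = []
    for feat in features.columns:
        fcol = features[feat]
        if fcol.dtype == bool or set(fcol.dropna().unique()) <= {0, 1, True, False}:
            fcat = pd.Categorical(
                np.where(fcol.astype(bool), "present", "absent"),
                categories=["present", "absent"],
            )
        else:
            fcat = pd.Categorical(fcol)
        fser = pd.Series(fcat, index=features.index, name=feat)
        for cov in covariates:
            levels = _DICHOTOMY_ORDER.get(cov)
            cser = dich[cov].reindex(features.index)
            if levels is not None:
                cser = pd.Series(pd.Categorical(cser, categories=list(levels)),
                                 index=features.index)
            keep = cser.notna() & fser.notna()
            if keep.sum() == 0:
                logger.warning("skipping %s x %s: no complete pairs", feat, cov)
                continue
            table = pd.crosstab(fser[keep], cser[keep], dropna=False)
            try:
                test = pearson_chi_square(table)
            except ValueError as exc:
                logger.warning("skipping %s x %s: %s", feat, cov, exc)
                continue
            results.append(AssociationResult(feat, cov, table, test))
    return results
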