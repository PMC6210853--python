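"""Calling the six binary molecular features per tumor.

Three features come straight from mutation calls (CTNNB1, TP53, TERT
promoter).  The remaining three are derived here:

* ``tsg_hyper`` — promoter hypermethylation of the eight-gene tumor
  suppressor panel, called by Ward hierarchical clustering of the
  8-dimensional methylation vectors cut at two clusters; the cluster with
  the higher grand-mean methylation is the hypermethylated one.
* ``global_hypo`` — global hypomethylation estimated from Alu/LINE-1/SAT2
  methylation, either by the same clustering (positive = lower grand mean)
  or, for samples outside the training cohort, by a z-score rule: pool all
  repeat-element values of the training cohort into one mean and standard
  deviation, z-score each marker, and call a sample hypomethylated when the
  sum of its three z-scores falls strictly below a ROC-optimal threshold.
* ``fal_high`` — fractional allelic loss (percent of informative
  microsatellite loci with allelic imbalance) at or above the cohort
  median (21% in the reference cohort).

A copy-number route replaces FAL when only array data exist: the percent of
genes with altered copy number, dichotomized at 39%.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.base import BaseEstimator, ClusterMixin

from .cohort import (
    Cohort,
    GeneCopyNumberMatrix,
    PROMOTER_MARKERS,
    REPEAT_MARKERS,
    FEATURE_FLAGS,
)
from .stats import roc_best_threshold

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Fractional allelic loss
# ---------------------------------------------------------------------------

def compute_fal(informative, imbalance, min_informative: int = 10) -> float:
    """Fractional allelic loss: 100 x (#imbalanced) / (#informative loci).

    Non-informative loci are excluded from both numerator and denominator.
    Returns NaN (undefined) when fewer than ``min_informative`` loci are
    informative; such samples must be excluded from the cohort median and
    flagged un-scorable.
    """
    informative = np.asarray(informative, dtype=bool)
    imbalance = np.asarray(imbalance, dtype=bool)
    if imbalance[~informative].any():
        raise ValueError("imbalance called on a non-informative locus")
    n_inf = int(informative.sum())
    if n_inf < min_informative:
        return float("nan")
    return 100.0 * int(imbalance[informative].sum()) / n_inf


def fal_by_sample(microsatellites: pd.DataFrame, min_informative: int = 10) -> pd.Series:
    """Per-sample FAL from the long-form microsatellite table (NaN if undefined)."""
    def _one(group: pd.DataFrame) -> float:
        return compute_fal(group["informative"], group["imbalance"], min_informative)

    out = microsatellites.groupby("sample_id", sort=True).apply(_one, include_groups=False)
    n_undef = int(out.isna().sum())
    if n_undef:
        logger.warning("FAL undefined for %d sample(s) (<%d informative loci)",
                       n_undef, min_informative)
    return out.rename("fal_percent")


def fal_threshold_from_cohort(fal_values) -> float:
    """Cohort median FAL, the dichotomization threshold (21% in the reference cohort)."""
    values = np.asarray(pd.Series(fal_values).dropna(), dtype=float)
    if len(values) < 2:
        raise ValueError("need at least 2 defined FAL values to take a cohort median")
    return float(np.median(values))


# ---------------------------------------------------------------------------
# Cluster-based methylation callers
# ---------------------------------------------------------------------------

@dataclass
class MethylationCallResult:
    """Per-sample boolean calls plus the clustering evidence behind them."""

    calls: pd.Series
    linkage: np.ndarray
    cluster_means: tuple[float, float]  # (negative cluster, positive cluster)


class MethylationClusterCaller(ClusterMixin, BaseEstimator):
    """Two-group Ward clustering of methylation vectors.

    ``direction="hyper"`` labels the cluster with the higher grand-mean
    methylation positive (TSG promoter hypermethylation); ``"hypo"`` labels
    the lower-mean cluster positive (global hypomethylation).  Samples are
    sorted by identifier before the distance computation so the call is
    invariant to input order; if the two clusters have equal grand means
    the larger cluster is the negative call.

    Parameters
    ----------
    direction : {"hyper", "hypo"}
    method : linkage method passed to scipy (default "ward")
    metric : distance metric (default "euclidean")
    impute_missing : mean-impute missing marker values per column (logged)
    """

    def __init__(self, direction: str = "hyper", method: str = "ward",
                 metric: str = "euclidean", impute_missing: bool = True):
        self.direction = direction
        self.method = method
        self.metric = metric
        self.impute_missing = impute_missing

    def fit(self, X, y=None):
        if self.direction not in ("hyper", "hypo"):
            raise ValueError(f"direction must be 'hyper' or 'hypo', got {self.direction!r}")
        X = pd.DataFrame(X).copy()
        if len(X) < 4:
            raise ValueError("need at least 4 samples to cluster")
        if X.isna().any().any():
            if not self.impute_missing:
                raise ValueError("missing methylation values and impute_missing=False")
            n = int(X.isna().sum().sum())
            logger.warning("mean-imputing %d missing methylation value(s)", n)
            X = X.fillna(X.mean())
        order = np.argsort(X.index.astype(str), kind="stable")
        Xs = X.iloc[order]
        arr = Xs.to_numpy(dtype=float)
        if np.allclose(arr, arr[0]):
            raise ValueError("degenerate clustering input: all samples identical")
        Z = linkage(arr, method=self.method, metric=self.metric)
        raw = fcluster(Z, t=2, criterion="maxclust")
        means = {c: float(arr[raw == c].mean()) for c in (1, 2)}
        sizes = {c: int((raw == c).sum()) for c in (1, 2)}
        if means[1] == means[2]:
            # equal-mean tie: larger cluster is the negative call
            positive = min((1, 2), key=lambda c: sizes[c])
        elif self.direction == "hyper":
            positive = max((1, 2), key=lambda c: means[c])
        else:
            positive = min((1, 2), key=lambda c: means[c])
        negative = 3 - positive
        calls_sorted = pd.Series(raw == positive, index=Xs.index, name="call")
        self.calls_ = calls_sorted.reindex(X.index)
        self.labels_ = self.calls_.to_numpy()
        self.linkage_ = Z
        self.cluster_means_ = (means[negative], means[positive])
        self.n_features_in_ = X.shape[1]
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_

    def result(self) -> MethylationCallResult:
        return MethylationCallResult(self.calls_, self.linkage_, self.cluster_means_)


def call_tsg_hypermethylation(promoter_meth: pd.DataFrame, **kwargs) -> MethylationCallResult:
    """TSG-promoter hypermethylation calls from the samples x 8 promoter matrix."""
    return MethylationClusterCaller(direction="hyper", **kwargs).fit(promoter_meth).result()


def call_global_hypomethylation_cluster(repeat_meth: pd.DataFrame, **kwargs) -> MethylationCallResult:
    """Global-hypomethylation calls from the samples x 3 repeat-element matrix."""
    return MethylationClusterCaller(direction="hypo", **kwargs).fit(repeat_meth).result()


# ---------------------------------------------------------------------------
# Z-score route for global hypomethylation
# ---------------------------------------------------------------------------

@dataclass
class ZScoreCalibration:
    """Pooled mean/sd of repeat-element methylation plus the z-sum threshold.

    The reference cohort's published values are mean 0.36, sd 0.25 and
    threshold -0.01217; a sample is hypomethylated when its z-score sum is
    strictly below the threshold.
    """

    mean: float
    sd: float
    threshold: float

    def __post_init__(self) -> None:
        if not self.sd > 0:
            raise ValueError(f"sd must be > 0, got {self.sd}")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(
            {"mean": float(self.mean), "sd": float(self.sd),
             "threshold": float(self.threshold)}, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ZScoreCalibration":
        d = yaml.safe_load(Path(path).read_text())
        return cls(mean=float(d["mean"]), sd=float(d["sd"]), threshold=float(d["threshold"]))


# Published calibration of the 125-tumor resection cohort.
REFERENCE_CALIBRATION = ZScoreCalibration(mean=0.36, sd=0.25, threshold=-0.01217)


def zscore_sum(repeat_values, calib: ZScoreCalibration):
    """Sum over Alu/LINE-1/SAT2 of (value - mean)/sd; strictly increasing in each marker.

    Accepts a length-3 vector, a mapping keyed by marker name, or a
    samples x 3 DataFrame (returns a Series).
    """
    if isinstance(repeat_values, pd.DataFrame):
        missing = [m for m in REPEAT_MARKERS if m not in repeat_values.columns]
        if missing:
            raise ValueError(f"missing repeat markers: {missing}")
        vals = repeat_values[list(REPEAT_MARKERS)]
        if vals.isna().any().any():
            raise ValueError("missing repeat-element methylation value")
        return ((vals - calib.mean) / calib.sd).sum(axis=1)
    if isinstance(repeat_values, dict):
        missing = [m for m in REPEAT_MARKERS if m not in repeat_values]
        if missing:
            raise ValueError(f"missing repeat markers: {missing}")
        repeat_values = [repeat_values[m] for m in REPEAT_MARKERS]
    arr = np.asarray(repeat_values, dtype=float)
    if arr.shape != (3,):
        raise ValueError(f"expected 3 repeat-element values, got shape {arr.shape}")
    if np.isnan(arr).any():
        raise ValueError("missing repeat-element methylation value")
    return float(((arr - calib.mean) / calib.sd).sum())


class ZScoreHypomethylationCaller(BaseEstimator):
    """Calibrate the z-sum hypomethylation rule on a labeled training cohort.

    ``fit`` pools all Alu/LINE-1/SAT2 values of the training samples into a
    single mean and standard deviation, scores every training sample by its
    z-score sum, and picks the threshold that best discriminates the
    cluster-derived hypomethylation labels on a ROC curve (Youden's J).
    ``predict`` then applies ``z-sum < threshold`` to new samples — this is
    how the rule trained on one cohort transfers to another (e.g. from
    resection to transplantation tumors).
    """

    def fit(self, X: pd.DataFrame, y):
        X = pd.DataFrame(X)
        y = np.asarray(y, dtype=bool)
        if len(y) != len(X):
            raise ValueError("label length mismatch")
        if y.all() or not y.any():
            raise ValueError("constant labels: ROC threshold undefined")
        vals = X[list(REPEAT_MARKERS)].to_numpy(dtype=float).ravel()
        mean = float(vals.mean())
        sd = float(vals.std(ddof=1))
        if not sd > 0:
            raise ValueError("sd must be > 0: training methylation values are constant")
        partial = ZScoreCalibration(mean=mean, sd=sd, threshold=0.0)
        scores = zscore_sum(X, partial).to_numpy()
        threshold = roc_best_threshold(scores, y, positive_is_low=True)
        self.calibration_ = ZScoreCalibration(mean=mean, sd=sd, threshold=float(threshold))
        self.classes_ = np.array([False, True])
        return self

    def decision_function(self, X):
        return zscore_sum(pd.DataFrame(X), self.calibration_)

    def predict(self, X):
        scores = self.decision_function(X)
        out = scores < self.calibration_.threshold
        return out if np.isscalar(scores) else np.asarray(out)


def fit_zscore_calibration(repeat_meth: pd.DataFrame, labels) -> ZScoreCalibration:
    """Pooled mean/sd and ROC-optimal z-sum threshold from a labeled training cohort."""
    return ZScoreHypomethylationCaller().fit(repeat_meth, labels).calibration_


def call_global_hypomethylation_zscore(repeat_values, calib: ZScoreCalibration):
    """True iff the z-score sum is strictly below the calibrated threshold."""
    s = zscore_sum(repeat_values, calib)
    if isinstance(s, pd.Series):
        return s < calib.threshold
    return bool(s < calib.threshold)


# ---------------------------------------------------------------------------
# Copy-number surrogate for FAL
# ---------------------------------------------------------------------------

def cn_alteration_fraction(matrix: GeneCopyNumberMatrix, sample_id: str,
                           log_ratio_cut: float = 0.2) -> float:
    """Percent of genes with altered copy number in one sample.

    Thresholded input: altered means state != 0.  Continuous input: altered
    means \\|log-ratio\\| >= ``log_ratio_cut``.
    """
    if sample_id not in matrix.values.columns:
        raise KeyError(f"unknown sample {sample_id!r}")
    col = matrix.values[sample_id].to_numpy(dtype=float)
    if matrix.value_kind == "thresholded":
        altered = col != 0
    else:
        altered = np.abs(col) >= log_ratio_cut
    return 100.0 * int(altered.sum()) / len(col)


def binarize_cn_fraction(percent: float, threshold: float = 39.0) -> bool:
    """High-FAL surrogate: copy-number-alteration fraction >= 39% by default."""
    if not 0.0 <= percent <= 100.0:
        raise ValueError(f"percent must be in [0, 100], got {percent}")
    return bool(percent >= threshold)


# ---------------------------------------------------------------------------
# Whole-cohort feature calling
# ---------------------------------------------------------------------------

def call_features(
    cohort: Cohort,
    mode: str = "cluster",
    calibration: ZScoreCalibration | None = None,
    fal_threshold: float | str = "median",
    min_informative: int = 10,
    **cluster_kwargs,
) -> pd.DataFrame:
    """Call all six binary features plus FAL percent for every sample.

    ``mode="cluster"`` calls global hypomethylation by within-cohort
    clustering; ``mode="zscore"`` applies a :class:`ZScoreCalibration`
    trained elsewhere.  ``fal_threshold`` is either ``"median"`` (cohort
    median of defined FAL values) or a fixed percent.  Returns a DataFrame
    indexed by sample with the six flags, ``fal_percent`` and the applied
    ``fal_threshold`` recorded in ``DataFrame.attrs``.
    """
    features = pd.DataFrame(index=cohort.clinical.index)
    for flag in ("ctnnb1_mut", "tp53_mut", "tertp_mut"):
        features[flag] = cohort.mutations[flag].reindex(features.index)

    hyper = call_tsg_hypermethylation(cohort.promoter_matrix(), **cluster_kwargs)
    features["tsg_hyper"] = hyper.calls.reindex(features.index)

    repeats = cohort.repeat_matrix()
    if mode == "cluster":
        hypo = call_global_hypomethylation_cluster(repeats, **cluster_kwargs)
        features["global_hypo"] = hypo.calls.reindex(features.index)
    elif mode == "zscore":
        if calibration is None:
            raise ValueError("mode='zscore' requires a calibration")
        features["global_hypo"] = call_global_hypomethylation_zscore(
            repeats, calibration).reindex(features.index)
    else:
        raise ValueError(f"unknown mode {mode!r}")

    fal = fal_by_sample(cohort.microsatellites, min_informative=min_informative)
    features["fal_percent"] = fal.reindex(features.index)
    if fal_threshold == "median":
        threshold = fal_threshold_from_cohort(features["fal_percent"])
    else:
        threshold = float(fal_threshold)
    features["fal_high"] = features["fal_percent"] >= threshold
    features.attrs["fal_threshold"] = threshold

    undefined = features.index[features["fal_percent"].isna()]
    if len(undefined):
        logger.warning("%d sample(s) have undefined FAL and are un-scorable: %s",
                       len(undefined), list(undefined))
    features = features[list(FEATURE_FLAGS) + ["fal_percent"]]
    return features
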