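"""Molecular subclassification by correspondence analysis + clustering.

The six binary events per tumor are coded as a complete disjunctive
(indicator) table — each event contributes a "present" and an "absent"
column, so every row sums to six.  Correspondence analysis of that table
embeds the tumors in two dimensions; Ward clustering of the 2-D sample
coordinates, cut at four clusters, yields the molecular subclasses.
Clusters are labeled deterministically from their feature profiles:
clusters rich in TSG-promoter hypermethylation form group B, the rest
group A; within each pair the chromosomally unstable cluster (higher
prevalence of high FAL) takes subscript 1.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.base import BaseEstimator, ClusterMixin, TransformerMixin

from .cohort import FEATURE_FLAGS

logger = logging.getLogger(__name__)

SUBCLASS_LABELS = ("A1", "A2", "B1", "B2")


def build_indicator_matrix(features: pd.DataFrame) -> pd.DataFrame:
    """Complete disjunctive coding of the six binary events.

    Returns a samples x 12 0/1 DataFrame with columns
    ``<flag>=present`` / ``<flag>=absent``; every row sums to 6.
    """
    cols: dict[str, np.ndarray] = {}
    for flag in FEATURE_FLAGS:
        if flag not in features.columns:
            raise ValueError(f"feature table lacks {flag!r}")
        col = features[flag]
        if col.isna().any():
            bad = features.index[col.isna()][0]
            raise ValueError(f"undefined {flag!r} for sample {bad!r}")
        present = col.astype(bool).to_numpy()
        cols[f"{flag}=present"] = present.astype(int)
        cols[f"{flag}=absent"] = (~present).astype(int)
    return pd.DataFrame(cols, index=features.index)


class CorrespondenceAnalysis(TransformerMixin, BaseEstimator):
    """Correspondence analysis of a nonnegative table.

    Standard CA: with correspondence matrix P = N / n, row/column masses r
    and c, the standardized residuals S = D_r^{-1/2} (P - r c^T) D_c^{-1/2}
    are decomposed by SVD; row principal coordinates are D_r^{-1/2} U S.
    Total inertia equals the Pearson chi-square statistic of the table
    divided by its grand total.  Constant columns are dropped (logged)
    before the analysis.  Axis signs, arbitrary in any SVD, are anchored so
    the ``anchor_column`` ("tp53_mut=present" by default) has a nonnegative
    coordinate on axis 1; remaining axes put the largest-magnitude column
    coordinate positive.

    Fitted attributes: ``row_coords_`` (samples x 2), ``col_coords_``,
    ``singular_values_``, ``total_inertia_``, ``dropped_columns_``.
    """

    def __init__(self, n_components: int = 2, anchor_column: str = "tp53_mut=present"):
        self.n_components = n_components
        self.anchor_column = anchor_column

    def fit(self, X, y=None):
        X = pd.DataFrame(X)
        arr = X.to_numpy(dtype=float)
        if (arr < 0).any():
            raise ValueError("correspondence analysis requires a nonnegative table")
        if (arr.sum(axis=1) == 0).any():
            bad = X.index[arr.sum(axis=1) == 0][0]
            raise ValueError(f"all-zero row for sample {bad!r}")
        constant = X.columns[(arr == arr[0]).all(axis=0)]
        if len(constant):
            logger.warning("dropping %d constant column(s): %s",
                           len(constant), list(constant))
        X = X.drop(columns=constant)
        self.dropped_columns_ = list(constant)
        arr = X.to_numpy(dtype=float)
        if arr.shape[1] < 2:
            raise ValueError("cannot embed in 2-D: fewer than 2 varying columns")

        total = arr.sum()
        P = arr / total
        r = P.sum(axis=1)
        c = P.sum(axis=0)
        S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
        U, sv, Vt = np.linalg.svd(S, full_matrices=False)
        tol = max(S.shape) * np.finfo(float).eps * (sv[0] if len(sv) else 0.0)
        keep = sv > max(tol, 1e-12)
        U, sv, Vt = U[:, keep], sv[keep], Vt[keep]
        if keep.sum() < self.n_components:
            raise ValueError("cannot embed in 2-D: table rank below 2 after dropping constants")

        row_std = U / np.sqrt(r)[:, None]            # standard row coordinates
        col_std = Vt.T / np.sqrt(c)[:, None]         # standard column coordinates
        # anchor axis signs for reproducibility
        col_index = list(X.columns)
        for k in range(len(sv)):
            flip = False
            if k == 0 and self.anchor_column in col_index:
                a = col_std[col_index.index(self.anchor_column), k]
                if a != 0:
                    flip = a < 0
                else:
                    flip = col_std[np.argmax(np.abs(col_std[:, k])), k] < 0
            else:
                flip = col_std[np.argmax(np.abs(col_std[:, k])), k] < 0
            if flip:
                col_std[:, k] *= -1
                row_std[:, k] *= -1

        nc = self.n_components
        self.columns_ = col_index
        self.row_masses_ = r
        self.col_masses_ = c
        self.singular_values_ = sv
        self.total_inertia_ = float((sv ** 2).sum())
        self._col_std_full_ = col_std
        self.row_coords_ = pd.DataFrame(
            (row_std * sv)[:, :nc], index=X.index,
            columns=[f"axis{i + 1}" for i in range(nc)])
        self.col_coords_ = pd.DataFrame(
            (col_std * sv)[:, :nc], index=col_index,
            columns=[f"axis{i + 1}" for i in range(nc)])
        return self

    def transform(self, X):
        """Principal coordinates of (possibly supplementary) rows via the transition formula."""
        X = pd.DataFrame(X)
        cols = [c for c in X.columns if c not in self.dropped_columns_]
        X = X[cols]
        if list(X.columns) != self.columns_:
            raise ValueError("column mismatch with the fitted table")
        arr = X.to_numpy(dtype=float)
        profiles = arr / arr.sum(axis=1, keepdims=True)
        coords = profiles @ (self._col_std_full_[:, : self.n_components])
        return pd.DataFrame(coords, index=X.index,
                            columns=[f"axis{i + 1}" for i in range(self.n_components)])

    def fit_transform(self, X, y=None):
        self.fit(X)
        return self.row_coords_


def correspondence_analysis(table: pd.DataFrame, n_components: int = 2,
                            **kwargs) -> CorrespondenceAnalysis:
    """Fit CA on an indicator (or any nonnegative) table; returns the fitted estimator."""
    return CorrespondenceAnalysis(n_components=n_components, **kwargs).fit(table)


def cluster_subclasses(row_coords: pd.DataFrame, k: int = 4,
                       method: str = "ward", metric: str = "euclidean") -> pd.Series:
    """Ward agglomeration of the 2-D sample coordinates, cut at ``k`` clusters.

    Samples are sorted by identifier before the distance computation and
    cluster ids renumbered by ascending cluster centroid (axis 1, then
    axis 2), so the result is invariant to input order.
    """
    coords = pd.DataFrame(row_coords)
    if len(coords) < k:
        raise ValueError(f"need at least k={k} samples, got {len(coords)}")
    n_distinct = len(np.unique(coords.to_numpy(dtype=float), axis=0))
    if n_distinct < k:
        raise ValueError(
            f"only {n_distinct} distinct coordinate points for k={k}; lower k"
        )
    order = np.argsort(coords.index.astype(str), kind="stable")
    cs = coords.iloc[order]
    Z = linkage(cs.to_numpy(dtype=float), method=method, metric=metric)
    raw = fcluster(Z, t=k, criterion="maxclust")
    # renumber deterministically by centroid
    centroids = {c: tuple(cs.to_numpy()[raw == c].mean(axis=0)) for c in np.unique(raw)}
    rank = {c: i + 1 for i, c in enumerate(sorted(centroids, key=centroids.get))}
    renumbered = pd.Series([rank[c] for c in raw], index=cs.index, name="raw_cluster")
    return renumbered.reindex(coords.index)


def label_subclasses(raw_clusters: pd.Series, features: pd.DataFrame,
                     ) -> tuple[pd.Series, dict[int, str], pd.DataFrame]:
    """Map raw clusters onto A1/A2/B1/B2 from their feature profiles.

    Clusters whose TSG-hypermethylation prevalence is >= 50% form group B
    (in the reference cohort B clusters sit at 94-95% and A clusters at
    10-22%); if that split is not 2+2 the four clusters are ranked by
    hypermethylation prevalence and the top two become B, with a warning.
    Within each group the cluster with the higher prevalence of high FAL
    takes subscript 1.  Returns (labels per sample, cluster->label map,
    per-cluster feature-prevalence profile).
    """
    raw_clusters = pd.Series(raw_clusters)
    profile = features[list(FEATURE_FLAGS)].astype(bool).groupby(raw_clusters).mean()
    if len(profile) != 4:
        raise ValueError(f"expected 4 clusters, got {len(profile)}")
    hyper = profile["tsg_hyper"]
    b_ids = list(hyper.index[hyper >= 0.5])
    if len(b_ids) != 2:
        logger.warning(
            "hypermethylation prevalences %s do not split 2+2 at 50%%; "
            "taking the top two clusters as group B",
            dict(hyper.round(2)))
        b_ids = list(hyper.sort_values(ascending=False, kind="stable").index[:2])
    a_ids = [c for c in profile.index if c not in b_ids]
    mapping: dict[int, str] = {}
    for group, ids in (("A", a_ids), ("B", b_ids)):
        fal = profile.loc[ids, "fal_high"]
        unstable = fal.sort_values(ascending=False, kind="stable").index[0]
        for cid in ids:
            mapping[cid] = f"{group}{1 if cid == unstable else 2}"
    labels = raw_clusters.map(mapping).rename("subclass")
    return labels, mapping, profile


class MolecularSubclassifier(ClusterMixin, BaseEstimator):
    """End-to-end subclassification: indicator coding -> CA -> Ward -> labels.

    ``fit`` expects the per-sample feature table (six boolean flags).
    Fitted attributes: ``ca_`` (the fitted :class:`CorrespondenceAnalysis`),
    ``assignments_`` (sample_id, axis1, axis2, raw_cluster, subclass),
    ``labels_``, ``cluster_map_`` and ``profile_`` (per-cluster feature
    prevalences).
    """

    def __init__(self, n_clusters: int = 4, method: str = "ward",
                 metric: str = "euclidean", anchor_column: str = "tp53_mut=present"):
        self.n_clusters = n_clusters
        self.method = method
        self.metric = metric
        self.anchor_column = anchor_column

    def fit(self, X, y=None):
        features = pd.DataFrame(X)
        indicator = build_indicator_matrix(features)
        self.ca_ = CorrespondenceAnalysis(anchor_column=self.anchor_column).fit(indicator)
        coords = self.ca_.row_coords_
        raw = cluster_subclasses(coords, k=self.n_clusters,
                                 method=self.method, metric=self.metric)
        if self.n_clusters == 4:
            subclass, mapping, profile = label_subclasses(raw, features)
        else:
            subclass = raw.map(lambda c: f"C{c}").rename("subclass")
            mapping = {c: f"C{c}" for c in raw.unique()}
            profile = features[list(FEATURE_FLAGS)].astype(bool).groupby(raw).mean()
        self.cluster_map_ = mapping
        self.profile_ = profile
        self.assignments_ = pd.DataFrame({
            "axis1": coords["axis1"],
            "axis2": coords["axis2"],
            "raw_cluster": raw,
            "subclass": subclass,
        })
        self.labels_ = subclass.to_numpy()
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_
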