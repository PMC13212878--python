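"""Kinetic clustering of mean protein trajectories.

Longitudinally shared differentially abundant proteins are summarised by
their per-timepoint mean abundance across patients and grouped by trajectory
shape: the pairwise Pearson correlation matrix between trajectories is
computed, each protein's row of correlations serves as its feature vector,
and complete-linkage agglomerative clustering with Euclidean distance on
those vectors is cut into ``n_clusters`` groups.  Cluster quality is scored
by the silhouette in the same feature space.  An alternative metric
(distance = 1 - r) is available behind a flag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import silhouette_score

from .preprocess import AbundanceMatrix

ARCHETYPES = ("increasing", "decreasing", "nonmonotone")


def mean_trajectories(matrix: AbundanceMatrix, protein_set=None) -> pd.DataFrame:
    """Per-timepoint mean abundance across available patients (protein × timepoint)."""
    proteins = list(protein_set) if protein_set is not None else list(matrix.proteins)
    if not proteins:
        raise ValueError("empty protein set")
    missing = [p for p in proteins if p not in matrix.proteins]
    if missing:
        raise KeyError(f"proteins not in matrix: {', '.join(map(str, missing[:5]))}")
    cols = {}
    for t in matrix.timepoints:
        sel = matrix.samples_at(t)
        if len(sel):
            cols[t] = matrix.values.loc[proteins, sel].mean(axis=1)
    return pd.DataFrame(cols)


@dataclass
class ClusterResult:
    labels: pd.Series            # protein -> cluster id (1..n_clusters)
    linkage_matrix: np.ndarray
    silhouette: float
    features: pd.DataFrame       # correlation rows used as feature vectors
    excluded: list               # constant-trajectory proteins left out


def correlation_cluster(
    profiles: pd.DataFrame,
    n_clusters: int = 3,
    zscore_trajectories: bool = True,
    one_minus_r: bool = False,
) -> ClusterResult:
    """Cluster trajectory shapes via their correlation structure.

    ``profiles`` is protein × timepoint (as from :func:`mean_trajectories`).
    With ``zscore_trajectories`` each trajectory is standardised first so
    shape, not level, drives the correlations.  ``one_minus_r`` switches the
    pairwise distance to 1 - r instead of Euclidean distance between
    correlation-matrix rows.
    """
    if profiles.shape[1] < 3:
        raise ValueError("need at least 3 timepoints to cluster trajectories")
    arr = profiles.to_numpy(dtype=float)
    sd = arr.std(axis=1)
    constant = sd == 0
    excluded = list(profiles.index[constant])
    if excluded:
        warnings.warn(
            f"excluding {len(excluded)} constant trajectory(ies): correlation undefined",
            stacklevel=2,
        )
        arr = arr[~constant]
    index = profiles.index[~constant]
    if arr.shape[0] < n_clusters:
        raise ValueError("fewer usable profiles than requested clusters")
    if zscore_trajectories:
        arr = (arr - arr.mean(axis=1, keepdims=True)) / arr.std(axis=1, keepdims=True)
    corr = np.corrcoef(arr)
    if one_minus_r:
        dist = squareform(1.0 - corr, checks=False)
        features = pd.DataFrame(corr, index=index, columns=index)
        Z = linkage(dist, method="complete")
        labels = fcluster(Z, t=n_clusters, criterion="maxclust")
        sil = silhouette_score(squareform(dist), labels, metric="precomputed")
    else:
        features = pd.DataFrame(corr, index=index, columns=index)
        Z = linkage(pdist(corr, metric="euclidean"), method="complete")
        labels = fcluster(Z, t=n_clusters, criterion="maxclust")
        sil = silhouette_score(corr, labels, metric="euclidean")
    return ClusterResult(
        labels=pd.Series(labels, index=index, name="cluster"),
        linkage_matrix=Z,
        silhouette=float(sil),
        features=features,
        excluded=excluded,
    )


def classify_archetype(means, tol: float | None = None) -> str:
    """Label a trajectory increasing / decreasing / nonmonotone.

    Monotonicity is judged up to a slack ``tol`` (default 5% of the
    trajectory's range): increasing means every successive difference is
    >= -tol with a positive net change; decreasing is symmetric.
    """
    y = np.asarray(means, dtype=float)
    if y.size < 3:
        raise ValueError("need at least 3 timepoints")
    if tol is None:
        tol = 0.05 * (y.max() - y.min())
    d = np.diff(y)
    net = y[-1] - y[0]
    if (d >= -tol).all() and net > 0:
        return "increasing"
    if (d <= tol).all() and net < 0:
        return "decreasing"
    return "nonmonotone"


def cluster_archetypes(profiles: pd.DataFrame, labels: pd.Series,
                       tol: float | None = None) -> dict[int, str]:
    """Archetype of each cluster's mean trajectory."""
    out = {}
    for c in sorted(labels.unique()):
        curve = profiles.loc[labels.index[labels == c]].mean(axis=0)
        out[int(c)] = classify_archetype(curve.to_numpy(), tol=tol)
    return out
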