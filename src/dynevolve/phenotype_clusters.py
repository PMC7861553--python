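"""Phenotype-space analyses of clone fitness profiles.

Each isolated clone is a five-dimensional vector of per-cycle fitness
values (one per remeasurement condition: glycerol/ethanol, fluconazole,
mix, 1:1 and 1:3 switching). Four analyses characterize phenotypes:

* experiment-level relatedness via per-condition Kolmogorov-Smirnov
  distances, combined in quadrature and hierarchically clustered;
* PCA projection of clone profiles to two components;
* removal of a neutral ellipse (2 SD of the known-neutral clones along
  PC1/PC2) before clustering;
* hierarchical clustering of the non-neutral clones at a Euclidean
  distance threshold, and per-cluster percentile-rank characteristics
  (the spider-plot statistic).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from sklearn.decomposition import PCA

__all__ = [
    "CONDITIONS",
    "NeutralEllipse",
    "ExperimentDistanceMatrix",
    "ks_distance_matrix",
    "pca_project",
    "remove_neutral_ellipse",
    "cluster_clones",
    "cluster_characteristics",
    "cluster_usage",
]

#: The five fitness-remeasurement conditions.
CONDITIONS = ("Gly/Eth", "Fluconazole", "Mix", "1:1", "1:3")


@dataclass
class NeutralEllipse:
    """Neutral region in PC space: centroid and 2-SD semi-axes."""

    center: np.ndarray
    semi_axes: np.ndarray

    def contains(self, coords) -> np.ndarray:
        xy = np.atleast_2d(np.asarray(coords, float))
        z = (xy - self.center) / self.semi_axes
        return (z**2).sum(axis=1) <= 1.0


@dataclass
class ExperimentDistanceMatrix:
    """Pairwise experiment distances with per-condition components."""

    experiments: list
    distances: np.ndarray
    components: dict
    cluster_labels: np.ndarray | None = None

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.distances, index=self.experiments, columns=self.experiments)


def ks_distance_matrix(
    profiles: pd.DataFrame,
    conditions=CONDITIONS,
    origin_col: str = "origin",
    max_clusters: int = 4,
    linkage_method: str = "median",
    min_clones: int = 2,
) -> ExperimentDistanceMatrix:
    """Kolmogorov-Smirnov distance matrix between experiments.

    For experiments k, l the per-condition component is the two-sample KS
    statistic (sup-norm ECDF distance) between their clone fitness
    distributions; the combined distance is the quadrature sum
    ``sqrt(sum_j D_j^2)``. The matrix is hierarchically clustered (median
    linkage, ``max_clusters`` flat clusters). Experiments with fewer than
    ``min_clones`` finite values in any condition are excluded.
    """
    groups = {}
    for name, sub in profiles.groupby(origin_col):
        vals = {c: sub[c].dropna().to_numpy() for c in conditions}
        if all(v.size >= min_clones for v in vals.values()):
            groups[name] = vals
        else:
            import warnings

            warnings.warn(
                f"experiment {name!r} excluded: fewer than {min_clones} "
                "reliable clones in some condition"
            )
    names = sorted(groups)
    k = len(names)
    dist = np.zeros((k, k))
    comps = {c: np.zeros((k, k)) for c in conditions}
    for i in range(k):
        for j in range(i + 1, k):
            total = 0.0
            for c in conditions:
                d = float(
                    stats.ks_2samp(groups[names[i]][c], groups[names[j]][c]).statistic
                )
                comps[c][i, j] = comps[c][j, i] = d
                total += d * d
            dist[i, j] = dist[j, i] = np.sqrt(total)
    labels = None
    if k >= 2:
        link = hierarchy.linkage(squareform(dist, checks=False), method=linkage_method)
        labels = hierarchy.fcluster(link, t=max_clusters, criterion="maxclust")
    return ExperimentDistanceMatrix(names, dist, comps, labels)


def pca_project(profiles: pd.DataFrame, conditions=CONDITIONS, n_components: int = 2):
    """Centered PCA of complete clone profiles onto two components.

    Rows with any missing condition are dropped (not imputed). The sign of
    each component is fixed so its largest-magnitude loading is positive.
    Returns ``(coords DataFrame indexed like the kept rows,
    explained-variance ratios, fitted PCA)``.
    """
    x = profiles[list(conditions)]
    keep = x.notna().all(axis=1)
    if keep.sum() < 3:
        raise ValueError("need >= 3 clones with complete fitness profiles")
    xv = x[keep].to_numpy(float)
    n_comp = min(n_components, np.linalg.matrix_rank(xv - xv.mean(0)))
    pca = PCA(n_components=n_comp)
    coords = pca.fit_transform(xv)
    for j in range(n_comp):
        load = pca.components_[j]
        if load[np.argmax(np.abs(load))] < 0:
            pca.components_[j] = -load
            coords[:, j] = -coords[:, j]
    cols = [f"PC{j + 1}" for j in range(n_comp)]
    out = pd.DataFrame(coords, index=x.index[keep], columns=cols)
    return out, pca.explained_variance_ratio_.copy(), pca


def remove_neutral_ellipse(
    coords: pd.DataFrame, known_neutral_flags, n_sd: float = 2.0, min_neutrals: int = 5
):
    """Drop clones inside the known-neutral ellipse in PC space.

    The ellipse is centred on the known-neutral centroid with semi-axes
    ``n_sd`` standard deviations of the known neutrals along PC1 and PC2.
    Returns ``(non-neutral coords, neutral-labelled mask, ellipse)``.
    """
    flags = np.asarray(known_neutral_flags, bool)
    if flags.sum() < min_neutrals:
        raise ValueError(f"need >= {min_neutrals} known neutral clones")
    xy = coords.to_numpy(float)[:, :2]
    neut = xy[flags]
    ellipse = NeutralEllipse(
        center=neut.mean(axis=0),
        semi_axes=np.maximum(n_sd * neut.std(axis=0, ddof=0), 1e-12),
    )
    inside = ellipse.contains(xy)
    return coords.loc[~inside], inside, ellipse


def cluster_clones(
    coords: pd.DataFrame,
    distance_threshold: float = 2.5,
    linkage_method: str = "average",
    reassign_singletons: bool = True,
    sensitivity_thresholds=(1.0, 1.5, 2.0, 2.5, 3.0),
):
    """Hierarchically cluster clone coordinates at a distance threshold.

    All pairwise Euclidean distances are clustered and the dendrogram cut
    where merges exceed ``distance_threshold``. Singleton clusters are
    reassigned to the cluster of their nearest non-singleton neighbor.
    Returns ``(labels Series, sensitivity DataFrame)`` where the
    sensitivity report gives the cluster count at alternative thresholds.
    """
    xy = coords.to_numpy(float)
    if xy.shape[0] < 2:
        raise ValueError("need >= 2 clones to cluster")
    d = pdist(xy)
    link = hierarchy.linkage(d, method=linkage_method)
    labels = hierarchy.fcluster(link, t=distance_threshold, criterion="distance")
    if reassign_singletons:
        labels = _reassign_singletons(labels, squareform(d))
    labels = _relabel_by_size(labels)
    sens = pd.DataFrame(
        {
            "threshold": list(sensitivity_thresholds),
            "n_clusters": [
                len(
                    np.unique(
                        _reassign_singletons(
                            hierarchy.fcluster(link, t=t, criterion="distance"),
                            squareform(d),
                        )
                        if reassign_singletons
                        else hierarchy.fcluster(link, t=t, criterion="distance")
                    )
                )
                for t in sensitivity_thresholds
            ],
        }
    )
    return pd.Series(labels, index=coords.index, name="cluster"), sens


def _reassign_singletons(labels: np.ndarray, dmat: np.ndarray) -> np.ndarray:
    labels = labels.copy()
    ids, counts = np.unique(labels, return_counts=True)
    single = set(ids[counts == 1])
    if len(single) == len(ids):
        return labels
    for i in np.flatnonzero(np.isin(labels, list(single))):
        order = np.argsort(dmat[i])
        for j in order:
            if j != i and labels[j] not in single:
                labels[i] = labels[j]
                break
    return labels


def _relabel_by_size(labels: np.ndarray) -> np.ndarray:
    ids, counts = np.unique(labels, return_counts=True)
    rank = {old: new + 1 for new, old in enumerate(ids[np.argsort(-counts)])}
    return np.array([rank[v] for v in labels])


def cluster_clones_5d(
    profiles: pd.DataFrame,
    conditions=CONDITIONS,
    distance_threshold: float = 1.5,
    linkage_method: str = "average",
):
    """Unprojected clustering in standardized 5-condition fitness space."""
    x = profiles[list(conditions)].dropna()
    z = (x - x.mean()) / x.std(ddof=0)
    return cluster_clones(z, distance_threshold, linkage_method)


def cluster_characteristics(
    assignments: pd.Series, profiles: pd.DataFrame, conditions=CONDITIONS
) -> pd.DataFrame:
    """Percentile rank of each cluster's median fitness, per condition.

    For cluster k and condition j: the percentile (fraction of the pooled
    all-cluster distribution at or below) of
    ``median(fitness of cluster-k clones in j)`` — the spider-plot
    statistic; ~50 = typical, 100 = the cluster holding the most fit clone.
    """
    prof = profiles.loc[assignments.index]
    rows = {}
    for k, members in assignments.groupby(assignments):
        if members.empty:
            raise ValueError(f"cluster {k} is empty")
        rows[k] = {
            c: stats.percentileofscore(
                prof[c].dropna(), prof.loc[members.index, c].median(), kind="weak"
            )
            for c in conditions
        }
    out = pd.DataFrame(rows).T[list(conditions)]
    out.index.name = "cluster"
    return out


def cluster_usage(
    assignments: pd.Series, origins: pd.Series
) -> pd.DataFrame:
    """Fraction of each evolution experiment's clones falling in each cluster."""
    df = pd.DataFrame({"cluster": assignments, "origin": origins.loc[assignments.index]})
    tab = pd.crosstab(df["origin"], df["cluster"])
    return tab.div(tab.sum(axis=1), axis=0)
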