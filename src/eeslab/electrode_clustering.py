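"""Clustering of electrode recruitment patterns.

Single-trial rAUC responses are arranged into a feature table with one row
per (electrode, repeat) and one column per (muscle, amplitude) block for
each stimulation frequency, horizontally concatenated.  Columns are
normalized with the Yeo–Johnson power transform and standardized, embedded
in 2D, and partitioned with spectral clustering; the cluster count is picked
by the mean silhouette coefficient over a candidate range, and electrodes
receive the majority label of their repeats.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import SpectralClustering
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score
from sklearn.preprocessing import PowerTransformer

__all__ = [
    "ClusterSolution",
    "build_feature_table",
    "power_normalize",
    "embed_2d",
    "select_k_spectral",
    "majority_vote",
    "cluster_electrodes",
]


@dataclass
class ClusterSolution:
    embedding: np.ndarray  # (n_points, 2)
    point_labels: np.ndarray  # (n_points,)
    electrode_labels: dict[str, int]
    k: int
    silhouette_by_k: dict[int, float]
    point_electrodes: tuple[str, ...]


def build_feature_table(rauc: pd.DataFrame, value_col: str = "rauc_raw") -> pd.DataFrame:
    """Pivot a long rAUC table into the (electrode, repeat) x feature matrix.

    Columns are a MultiIndex (frequency, muscle, amplitude): the recruitment
    block for each frequency, concatenated horizontally.
    """
    wide = rauc.pivot_table(
        index=["electrode", "repeat"],
        columns=["frequency_hz", "muscle", "amplitude_ua"],
        values=value_col,
    )
    if wide.isna().any().any():
        raise ValueError("incomplete factorial design: missing feature cells")
    return wide.sort_index(axis=1)


def power_normalize(features: pd.DataFrame | np.ndarray):
    """Per-column Yeo–Johnson (maximum-likelihood lambda) + standardization.

    The transform is monotone per column, so rank order within a column is
    preserved.  Constant columns cannot be standardized and raise.
    """
    X = features.to_numpy(dtype=float) if isinstance(features, pd.DataFrame) else np.asarray(features, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("features must be finite")
    if np.any(X.std(axis=0) == 0):
        raise ValueError("constant feature column cannot be power-normalized")
    out = PowerTransformer(method="yeo-johnson", standardize=True).fit_transform(X)
    if isinstance(features, pd.DataFrame):
        return pd.DataFrame(out, index=features.index, columns=features.columns)
    return out


def embed_2d(features, method: str = "umap", seed: int = 0, n_neighbors: int = 15) -> np.ndarray:
    """Two-dimensional embedding of the normalized feature rows.

    ``method="umap"`` (default) uses a seeded neighbour embedding;
    ``method="pca"`` projects onto the principal plane — exact, fast and
    fully deterministic, useful for tests and closed-form checks.
    """
    X = features.to_numpy(dtype=float) if isinstance(features, pd.DataFrame) else np.asarray(features, dtype=float)
    if X.shape[0] < 3:
        raise ValueError("at least 3 rows required for a 2D embedding")
    if method == "pca":
        return PCA(n_components=2, random_state=seed).fit_transform(X)
    if method == "umap":
        import umap  # deferred: numba-backed import is slow

        reducer = umap.UMAP(
            n_components=2,
            n_neighbors=min(n_neighbors, X.shape[0] - 1),
            random_state=seed,
            n_jobs=1,
        )
        return np.asarray(reducer.fit_transform(X), dtype=float)
    raise ValueError(f"unknown embedding method {method!r}")


def select_k_spectral(
    embedding: np.ndarray,
    point_electrodes,
    k_range=range(2, 17),
    seed: int = 0,
    n_neighbors: int = 10,
) -> ClusterSolution:
    """Spectral clustering over candidate k; keep the best-silhouette solution.

    Affinity is a symmetrized k-nearest-neighbour graph; the embedded points
    are clustered for every candidate k and the mean silhouette coefficient
    selects the returned partition.  k = 1 has no silhouette and is outside
    the candidate range by construction.
    """
    X = np.asarray(embedding, dtype=float)
    ks = sorted(set(int(k) for k in k_range))
    if not ks or ks[0] < 2:
        raise ValueError("candidate k values must be >= 2")
    if ks[-1] > X.shape[0] - 1:
        raise ValueError("k exceeds number of points")
    scores: dict[int, float] = {}
    labels_by_k: dict[int, np.ndarray] = {}
    for k in ks:
        model = SpectralClustering(
            n_clusters=k,
            affinity="nearest_neighbors",
            n_neighbors=min(n_neighbors, X.shape[0] - 1),
            assign_labels="kmeans",
            random_state=seed,
        )
        labels = model.fit_predict(X)
        labels_by_k[k] = labels
        scores[k] = float(silhouette_score(X, labels)) if np.unique(labels).size > 1 else -1.0
    best_k = max(ks, key=lambda k: scores[k])
    point_labels = labels_by_k[best_k]
    electrodes = tuple(point_electrodes)
    return ClusterSolution(
        embedding=X,
        point_labels=point_labels,
        electrode_labels=majority_vote(electrodes, point_labels),
        k=best_k,
        silhouette_by_k=scores,
        point_electrodes=electrodes,
    )


def majority_vote(point_electrodes, point_labels) -> dict[str, int]:
    """Assign each electrode the modal label of its points.

    Ties break deterministically to the lowest label id.
    """
    labels = np.asarray(point_labels)
    out: dict[str, int] = {}
    electrodes = np.asarray(point_electrodes)
    for e in dict.fromkeys(electrodes.tolist()):
        sub = labels[electrodes == e]
        vals, counts = np.unique(sub, return_counts=True)
        out[e] = int(vals[np.argmax(counts)])  # np.unique sorts: lowest id wins ties
    return out


def cluster_electrodes(
    rauc: pd.DataFrame,
    value_col: str = "rauc_raw",
    method: str = "umap",
    k_range=range(2, 17),
    seed: int = 0,
    cluster_on: str = "embedding",
) -> ClusterSolution:
    """Full pipeline: feature table -> power normalize -> embed -> cluster.

    ``cluster_on="features"`` clusters the normalized features directly and
    keeps the 2D embedding for display only.
    """
    table = build_feature_table(rauc, value_col)
    norm = power_normalize(table)
    emb = embed_2d(norm, method=method, seed=seed)
    electrodes = tuple(str(e) for e, _ in table.index)
    if cluster_on == "features":
        sol = select_k_spectral(norm.to_numpy(), electrodes, k_range, seed)
        return ClusterSolution(
            embedding=emb,
            point_labels=sol.point_labels,
            electrode_labels=sol.electrode_labels,
            k=sol.k,
            silhouette_by_k=sol.silhouette_by_k,
            point_electrodes=electrodes,
        )
    return select_k_spectral(emb, electrodes, k_range, seed)
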