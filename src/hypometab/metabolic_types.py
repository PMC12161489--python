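"""Metabolic typing: clustering samples on the deregulation matrix.

Samples are clustered into k (default 3) types on their pathway
deregulation profiles and relabeled M1..Mk in ascending order of
cluster-mean deregulation, so M1 is always the least and M3 the most
deregulated type regardless of the clusterer's internal indices.
Labels transfer to new panels (e.g. cell lines) by nearest centroid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import AgglomerativeClustering, KMeans

from .associations import GroupComparison, compare_groups
from .deregulation import DeregulationMatrix
from .signatures import ScoreTable


@dataclass
class ClusterAssignment:
    """Sample -> ordered metabolic type, with per-sample mean deregulation
    and the per-type centroids (pathways x types) used for transfer."""

    table: pd.DataFrame        # index sample_id; columns label, mean_dereg[, margin]
    centroids: pd.DataFrame | None = None

    @property
    def labels(self) -> pd.Series:
        return self.table["label"]

    def type_means(self) -> pd.Series:
        """Cluster-mean deregulation per label, ascending by construction."""
        return self.table.groupby("label")["mean_dereg"].mean()


def _ordered_labels(raw: np.ndarray, mean_dereg: np.ndarray, k: int) -> np.ndarray:
    """Relabel raw cluster indices as M1..Mk by ascending mean deregulation."""
    order = np.argsort(
        [mean_dereg[raw == c].mean() for c in range(k)], kind="stable"
    )
    name = {c: f"M{rank + 1}" for rank, c in enumerate(order)}
    return np.array([name[c] for c in raw])


def cluster_types(
    dereg: DeregulationMatrix,
    k: int = 3,
    method: str = "kmeans",
    seed: int = 17,
    n_restarts: int = 20,
) -> ClusterAssignment:
    """Cluster samples (columns of the deregulation matrix) into k types.

    ``kmeans`` (default) restarts ``n_restarts`` times from the given
    seed; ``ward`` is the deterministic hierarchical alternative.
    """
    x = dereg.scores.T.to_numpy()          # samples x pathways
    n = x.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds the {n} available samples")
    if method == "kmeans":
        model = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
        raw = model.fit_predict(x)
    elif method == "ward":
        raw = AgglomerativeClustering(n_clusters=k, linkage="ward").fit_predict(x)
    else:
        raise ValueError(f"unknown clustering method {method!r}")

    mean_dereg = dereg.mean_per_sample().to_numpy()
    labels = _ordered_labels(raw, mean_dereg, k)
    table = pd.DataFrame(
        {"label": labels, "mean_dereg": mean_dereg},
        index=pd.Index(dereg.sample_ids, name="sample_id"),
    )
    centroids = (
        dereg.scores.T.groupby(labels).mean().T.sort_index(axis=1)
    )
    return ClusterAssignment(table, centroids)


def predict_labels(
    dereg_new: DeregulationMatrix,
    reference: ClusterAssignment,
    reference_dereg: DeregulationMatrix | None = None,
) -> ClusterAssignment:
    """Assign reference type labels to a new panel by nearest centroid.

    Distances are Euclidean over the pathways shared between the
    reference and the new matrix; the margin (distance to the runner-up
    centroid minus distance to the winner) flags ambiguous assignments.
    """
    centroids = reference.centroids
    if centroids is None:
        if reference_dereg is None:
            raise ValueError("reference carries no centroids and no "
                             "reference deregulation matrix was given")
        labels = reference.labels.reindex(reference_dereg.sample_ids)
        if labels.isna().any():
            raise ValueError("reference assignment does not cover every "
                             "sample of the reference deregulation matrix")
        centroids = (
            reference_dereg.scores.T
            .groupby(labels.to_numpy()).mean().T.sort_index(axis=1)
        )
    shared = dereg_new.scores.index.intersection(centroids.index)
    if shared.empty:
        raise ValueError("no shared pathways between panel and reference")
    x = dereg_new.scores.loc[shared].T.to_numpy()      # samples x shared
    c = centroids.loc[shared].to_numpy()               # shared x types
    d = np.linalg.norm(x[:, :, None] - c[None, :, :], axis=1)  # samples x types
    order = np.argsort(d, axis=1)
    win = order[:, 0]
    margin = d[np.arange(len(x)), order[:, 1]] - d[np.arange(len(x)), win]
    table = pd.DataFrame(
        {
            "label": centroids.columns.to_numpy()[win],
            "mean_dereg": dereg_new.scores.loc[shared].mean(axis=0).to_numpy(),
            "margin": margin,
        },
        index=pd.Index(dereg_new.sample_ids, name="sample_id"),
    )
    return ClusterAssignment(table, centroids)


def summarize_hs_by_type(
    scores: ScoreTable, assign: ClusterAssignment, min_per_type: int = 3
) -> tuple[pd.DataFrame, GroupComparison]:
    """Mean ± SEM of the hypoxia score per metabolic type, with a
    Kruskal–Wallis test across types and Dunn's post hoc pairs."""
    shared = scores.table.index.intersection(assign.table.index)
    if shared.empty:
        raise ValueError("no shared samples between scores and assignment")
    hs = scores.table.loc[shared, "hs"].astype(float)
    labels = assign.table.loc[shared, "label"]
    groups = {lab: hs[labels == lab].to_numpy() for lab in sorted(labels.unique())}
    for lab, vals in groups.items():
        if len(vals) < min_per_type:
            raise ValueError(
                f"type {lab} has {len(vals)} samples, {min_per_type} required"
            )
    summary = pd.DataFrame(
        {
            "n": {lab: len(v) for lab, v in groups.items()},
            "mean_hs": {lab: float(np.mean(v)) for lab, v in groups.items()},
            "sem_hs": {
                lab: float(np.std(v, ddof=1) / np.sqrt(len(v)))
                for lab, v in groups.items()
            },
        }
    )
    summary.index.name = "label"
    comparison = compare_groups(groups)
    return summary, comparison
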