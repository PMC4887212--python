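"""Sample clustering on DMR methylation-frequency matrices.

Complete-linkage hierarchical clustering (euclidean distance) with ordinary
bootstrap support per internal node from resampling the DMR columns, plus
PCA scores on the column-centered matrix. Bootstrap support here replaces
multiscale-bootstrap AU p-values: it is the fraction of column-resampled
trees in which the exact same sample cluster reappears.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy as sch
from scipy.spatial.distance import pdist
from sklearn.decomposition import PCA


@dataclass
class ClusterResult:
    labels: list[str]
    linkage: np.ndarray  # scipy linkage matrix (complete)
    support: np.ndarray  # bootstrap support per internal node
    clusters: list[frozenset]  # sample membership per internal node
    n_boot: int
    seed: int | None
    newick: str = field(default="")

    def cut(self, n_clusters: int) -> dict[str, int]:
        assign = sch.fcluster(self.linkage, t=n_clusters, criterion="maxclust")
        return dict(zip(self.labels, (int(a) for a in assign)))

    def cophenetic_matrix(self) -> pd.DataFrame:
        from scipy.spatial.distance import squareform

        d = squareform(sch.cophenet(self.linkage))
        return pd.DataFrame(d, index=self.labels, columns=self.labels)


def _cluster_sets(Z: np.ndarray, labels: list[str]) -> list[frozenset]:
    n = len(labels)
    members: dict[int, frozenset] = {i: frozenset([labels[i]]) for i in range(n)}
    sets = []
    for i, (a, b, _, _) in enumerate(Z):
        merged = members[int(a)] | members[int(b)]
        members[n + i] = merged
        sets.append(merged)
    return sets


def cluster_samples(
    matrix: pd.DataFrame,
    method: str = "complete",
    metric: str = "euclidean",
    n_boot: int = 1000,
    seed: int | None = None,
) -> ClusterResult:
    """Cluster samples (rows) on feature columns with bootstrap support.

    ``matrix`` is samples x DMRs. Deterministic given ``seed``; requires at
    least 3 samples and a finite matrix.
    """
    if matrix.shape[0] < 3:
        raise ValueError("need at least 3 samples to cluster")
    X = matrix.to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("matrix contains non-finite values; filter DMRs first")
    labels = [str(i) for i in matrix.index]
    Z = sch.linkage(pdist(X, metric=metric), method=method)
    clusters = _cluster_sets(Z, labels)
    support = np.zeros(len(clusters))
    rng = np.random.default_rng(seed)
    n_cols = X.shape[1]
    for _ in range(n_boot):
        cols = rng.integers(0, n_cols, size=n_cols)
        Zb = sch.linkage(pdist(X[:, cols], metric=metric), method=method)
        boot_sets = set(_cluster_sets(Zb, labels))
        for i, s in enumerate(clusters):
            if s in boot_sets:
                support[i] += 1
    if n_boot > 0:
        support /= n_boot
    newick = linkage_to_newick(Z, labels)
    return ClusterResult(
        labels=labels,
        linkage=Z,
        support=support,
        clusters=clusters,
        n_boot=n_boot,
        seed=seed,
        newick=newick,
    )


def linkage_to_newick(Z: np.ndarray, labels: list[str]) -> str:
    """Render a scipy linkage matrix as a Newick string with branch lengths."""
    n = len(labels)
    heights = {i: 0.0 for i in range(n)}
    reps = {i: labels[i] for i in range(n)}
    for i, (a, b, h, _) in enumerate(Z):
        a, b = int(a), int(b)
        la = f"{reps[a]}:{h - heights[a]:.6g}"
        lb = f"{reps[b]}:{h - heights[b]:.6g}"
        reps[n + i] = f"({la},{lb})"
        heights[n + i] = h
    return reps[n + len(Z) - 1] + ";"


def pca_scores(matrix: pd.DataFrame, n_components: int = 2) -> pd.DataFrame:
    """PCA component scores per sample on the column-centered matrix."""
    n_components = min(n_components, matrix.shape[0] - 1, matrix.shape[1])
    X = matrix.to_numpy(dtype=float)
    X = X - X.mean(axis=0, keepdims=True)
    model = PCA(n_components=n_components, svd_solver="full")
    scores = model.fit_transform(X)
    return pd.DataFrame(
        scores,
        index=matrix.index,
        columns=[f"PC{i + 1}" for i in range(scores.shape[1])],
    )
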