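"""Pathway clustering with bootstrap-stability selection of k.

The pairwise similarity matrix is transformed to a distance matrix
(D = 1 - S) and clustered by agglomerative hierarchical clustering on the
precomputed distances (average linkage by default; Ward is deliberately
not offered because 1 - similarity is not Euclidean).  The number of
clusters is chosen from a candidate range by bootstrap stability: for each
candidate k, individuals are resampled with replacement, the induced
distance submatrix is reclustered, and the adjusted Rand index (ARI)
between the resample partition and the full-data partition (restricted to
the unique resampled individuals) is averaged over resamples.  The k with
the highest mean stability wins; ties go to the smaller k.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from skbio.tree import TreeNode
from sklearn.metrics import adjusted_rand_score

__all__ = [
    "ClusterSolution",
    "similarity_to_distance",
    "agglomerative_cluster",
    "adjusted_rand_index",
    "bootstrap_stability",
    "select_num_clusters",
    "dendrogram_newick",
]

logger = logging.getLogger(__name__)

LINKAGE_METHODS = ("average", "single", "complete")


def similarity_to_distance(S: pd.DataFrame) -> pd.DataFrame:
    """D = 1 - S for a symmetric unit-diagonal similarity matrix in (0, 1]."""
    A = np.asarray(S, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("similarity matrix must be square")
    if np.abs(A - A.T).max(initial=0.0) > 1e-9:
        raise ValueError("similarity matrix asymmetric beyond 1e-9")
    if not np.allclose(np.diag(A), 1.0):
        raise ValueError("similarity matrix diagonal must be 1")
    if (A <= 0).any() or (A > 1 + 1e-12).any():
        raise ValueError("similarity entries must lie in (0, 1]")
    D = 1.0 - A
    np.fill_diagonal(D, 0.0)
    if isinstance(S, pd.DataFrame):
        return pd.DataFrame(D, index=S.index, columns=S.columns)
    return pd.DataFrame(D)


def _as_array(D) -> np.ndarray:
    A = np.asarray(D, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("distance matrix must be square")
    return A


def _linkage(D: np.ndarray, method: str) -> np.ndarray:
    if method not in LINKAGE_METHODS:
        raise ValueError(f"linkage must be one of {LINKAGE_METHODS}")
    return linkage(squareform(D, checks=False), method=method)


def _canonical_labels(raw: np.ndarray) -> np.ndarray:
    """Relabel clusters 1..k ordered by decreasing size, then smallest member."""
    order = sorted(
        np.unique(raw),
        key=lambda c: (-(raw == c).sum(), int(np.argmax(raw == c))),
    )
    mapping = {c: i + 1 for i, c in enumerate(order)}
    return np.array([mapping[c] for c in raw], dtype=int)


def agglomerative_cluster(D, k: int, linkage_method: str = "average") -> np.ndarray:
    """Cut the hierarchical tree at k clusters; labels are canonicalized.

    Returns an integer label per row of ``D`` (1..k, ordered by decreasing
    cluster size then smallest member position), deterministic given inputs.
    """
    A = _as_array(D)
    n = A.shape[0]
    if not 2 <= k <= n - 1:
        raise ValueError(f"k={k} outside valid range [2, {n - 1}]")
    Z = _linkage(A, linkage_method)
    raw = fcluster(Z, t=k, criterion="maxclust")
    return _canonical_labels(raw)


def adjusted_rand_index(labelsA, labelsB) -> float:
    """Chance-corrected partition agreement in [-1, 1]; 1 iff identical.

    Accepts two mappings id -> cluster (same id set) or two equal-length
    label arrays.
    """
    if isinstance(labelsA, dict) or isinstance(labelsB, dict):
        if set(labelsA) != set(labelsB):
            raise ValueError("label mappings cover different id sets")
        ids = sorted(labelsA)
        a = [labelsA[i] for i in ids]
        b = [labelsB[i] for i in ids]
    else:
        a, b = list(labelsA), list(labelsB)
        if len(a) != len(b):
            raise ValueError("label arrays differ in length")
    return float(adjusted_rand_score(a, b))


def bootstrap_stability(
    D,
    k: int,
    B: int = 100,
    seed: int | np.random.SeedSequence = 0,
    linkage_method: str = "average",
) -> float:
    """Mean bootstrap ARI between resample partitions and the full partition.

    Each of the B resamples draws n individuals with replacement, reclusters
    the induced submatrix at k, and scores the ARI against the full-data
    labels over the unique resampled individuals.  Resamples with fewer than
    k unique individuals are redrawn (logged).
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    A = _as_array(D)
    n = A.shape[0]
    full = agglomerative_cluster(A, k, linkage_method)
    rng = np.random.default_rng(seed)

    scores = []
    for _ in range(B):
        while True:
            idx = rng.integers(0, n, size=n)
            uniq, first_pos = np.unique(idx, return_index=True)
            if len(uniq) >= k:
                break
            logger.info("bootstrap resample had <%d unique individuals; redrawn", k)
        sub = A[np.ix_(idx, idx)]
        sub_labels = agglomerative_cluster(sub, k, linkage_method)
        scores.append(
            adjusted_rand_score(sub_labels[first_pos], full[uniq])
        )
    return float(np.mean(scores))


@dataclass
class ClusterSolution:
    """A chosen clustering: k, per-individual labels, and provenance."""

    k: int
    labels: dict[str, int]
    linkage_method: str
    stability: dict[int, float]
    linkage_matrix: np.ndarray = field(repr=False)
    newick: str = field(repr=False, default="")

    def labels_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"individual_id": list(self.labels), "cluster": list(self.labels.values())}
        )

    def stability_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"k": list(self.stability), "mean_stability": list(self.stability.values())}
        )


def dendrogram_newick(Z: np.ndarray, ids: list[str]) -> str:
    """Serialize a linkage matrix as Newick (leaf names = individual ids,
    branch lengths = merge-height differences)."""
    tree = TreeNode.from_linkage_matrix(Z, ids)
    return str(tree).strip()


def select_num_clusters(
    D,
    k_min: int = 2,
    k_max: int = 12,
    B: int = 100,
    seed: int = 0,
    linkage_method: str = "average",
) -> ClusterSolution:
    """Evaluate bootstrap stability over k_min..k_max and keep the argmax.

    Ties are broken toward the smaller k (parsimony).  Deterministic given
    the seed: each candidate k gets an independent child seed derived from
    ``seed``.
    """
    A = _as_array(D)
    ids = (
        [str(i) for i in D.index]
        if isinstance(D, pd.DataFrame)
        else [str(i) for i in range(len(A))]
    )
    n = A.shape[0]
    if not 2 <= k_min <= k_max <= n - 1:
        raise ValueError(f"need 2 <= k_min <= k_max <= n-1 (n={n})")

    candidates = list(range(k_min, k_max + 1))
    children = np.random.SeedSequence(seed).spawn(len(candidates))
    stability = {
        k: bootstrap_stability(A, k, B=B, seed=ss, linkage_method=linkage_method)
        for k, ss in zip(candidates, children)
    }
    best_k = max(candidates, key=lambda k: (stability[k], -k))
    labels = agglomerative_cluster(A, best_k, linkage_method)
    Z = _linkage(A, linkage_method)
    return ClusterSolution(
        k=best_k,
        labels=dict(zip(ids, (int(c) for c in labels))),
        linkage_method=linkage_method,
        stability=stability,
        linkage_matrix=Z,
        newick=dendrogram_newick(Z, ids),
    )


def write_solution(solution: ClusterSolution, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    solution.labels_frame().to_csv(out / "clusters.csv", index=False)
    solution.stability_frame().to_csv(out / "stability.csv", index=False)
    (out / "dendrogram.nwk").write_text(solution.newick + "\n")
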