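"""Community-structure comparison: distances, hierarchical clustering, PCA.

Samples are the entities throughout: Euclidean distances between their
standardized T-RF profiles, complete-linkage agglomeration on that
distance matrix, and a PCA of the profiles with fragment bins as
variables (mean-centered, not variance-scaled).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from skbio.tree import TreeNode

from .trflp import BinnedMatrix

__all__ = [
    "DistanceMatrix",
    "LinkageTree",
    "PcaResult",
    "euclidean_distances",
    "complete_linkage",
    "pca",
]


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise sample distances with a zero diagonal."""

    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1] or v.shape[0] != len(self.sample_ids):
            raise ValueError("distance matrix shape must match sample ids")
        if not np.allclose(v, v.T) or np.any(np.diag(v) != 0) or np.any(v < 0):
            raise ValueError("distances must be symmetric, non-negative, zero-diagonal")
        object.__setattr__(self, "values", v)

    @property
    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)


@dataclass(frozen=True)
class LinkageTree:
    """Agglomerative merge sequence in scipy linkage-matrix form.

    Row i of ``merges`` is (node_a, node_b, merge_height, cluster_size);
    leaves 0..n-1 map onto ``leaf_ids`` in order.
    """

    leaf_ids: list[str]
    merges: np.ndarray

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2]

    def to_newick(self) -> str:
        """Serialize as Newick; branch length = parent height - child height."""
        tree = TreeNode.from_linkage_matrix(self.merges, self.leaf_ids)
        return str(tree).strip()


@dataclass(frozen=True)
class PcaResult:
    """PCA scores and variance decomposition of sample profiles."""

    sample_ids: list[str]
    scores: np.ndarray  # samples x components
    component_variance: np.ndarray
    variance_explained_percent: np.ndarray

    def scores_frame(self) -> pd.DataFrame:
        cols = [f"PC{i + 1}" for i in range(self.scores.shape[1])]
        frame = pd.DataFrame(self.scores, columns=cols)
        frame.insert(0, "sample_id", self.sample_ids)
        return frame


def _profile_matrix(matrix: BinnedMatrix) -> np.ndarray:
    """Samples x bins array from a standardized BinnedMatrix."""
    if not matrix.standardized:
        raise ValueError("ordination requires a standardized matrix")
    return matrix.values.T


def euclidean_distances(matrix: BinnedMatrix) -> DistanceMatrix:
    """Pairwise Euclidean distances between standardized sample profiles."""
    profiles = _profile_matrix(matrix)
    if profiles.shape[0] < 2:
        raise ValueError("need at least 2 samples for a distance matrix")
    return DistanceMatrix(list(matrix.sample_ids), squareform(pdist(profiles, "euclidean")))


def complete_linkage(d: DistanceMatrix) -> LinkageTree:
    """Complete-linkage (farthest-neighbour) hierarchical clustering.

    Clusters merging at the smallest maximum inter-cluster distance are
    joined first; merge heights are therefore non-decreasing.
    """
    if len(d.sample_ids) < 2:
        raise ValueError("need at least 2 samples to cluster")
    merges = hierarchy.linkage(d.condensed, method="complete")
    return LinkageTree(list(d.sample_ids), merges)


def pca(matrix: BinnedMatrix, n_components: int | None = None) -> PcaResult:
    """PCA of sample profiles: bins as variables, mean-centered, unscaled.

    Component variances are the eigenvalues of the sample covariance
    (divisor n-1); ``variance_explained_percent`` sums to 100 over all
    components.  Each component's sign is fixed so its largest-magnitude
    loading is positive, making the output deterministic.
    """
    profiles = _profile_matrix(matrix)
    n, _ = profiles.shape
    if n < 2:
        raise ValueError("need at least 2 samples for PCA")
    centered = profiles - profiles.mean(axis=0, keepdims=True)
    total_var = float((centered**2).sum()) / (n - 1)
    if total_var == 0:
        raise ValueError("zero total variance: all sample profiles identical")

    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    # deterministic sign: largest-|loading| entry of each axis made positive
    for k in range(vt.shape[0]):
        pivot = np.argmax(np.abs(vt[k]))
        if vt[k, pivot] < 0:
            vt[k] *= -1
            u[:, k] *= -1

    variances = s**2 / (n - 1)
    keep = min(n - 1, vt.shape[0]) if n_components is None else n_components
    scores = (u * s)[:, :keep]
    variances = variances[:keep]
    explained = 100.0 * variances / total_var
    return PcaResult(list(matrix.sample_ids), scores, variances, explained)
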