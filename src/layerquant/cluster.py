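"""Pearson similarity and average-linkage clustering of standardized profiles.

Standardized profiles all live on the same -50..+50 grid, so a whole
collection can be compared directly: pairwise Pearson correlation is the
similarity measure, distance d = 1 - r feeds an unweighted average-linkage
(UPGMA) agglomeration, and cutting the tree at a similarity threshold
(default 0.6) yields groups of co-expressed spatial patterns.  The leaf
order of the dendrogram also orders the heatmap display.

Correlations are computed on the grid excluding the duplicated +50 endpoint
(which repeats the -50 aboral sample and would otherwise be double-weighted).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
from scipy.cluster.hierarchy import dendrogram, fcluster, leaves_list, linkage
from scipy.spatial.distance import squareform

from .errors import ZeroVarianceError
from .profile_ops import StandardProfile

__all__ = ["SimilarityMatrix", "ClusterTree", "similarity_matrix", "cluster_profiles",
           "plot_heatmap"]


@dataclass
class SimilarityMatrix:
    labels: List[str]
    values: np.ndarray  # n x n Pearson correlations

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("similarity matrix shape must match label count")


@dataclass
class ClusterTree:
    """UPGMA tree: scipy linkage matrix + leaf order + groups after cutting."""

    linkage_matrix: np.ndarray  # (n-1, 4) scipy format, heights = 1 - similarity
    labels: List[str]
    leaf_order: np.ndarray
    groups: np.ndarray  # group id per input profile, numbered in leaf order
    cut_similarity: float

    @property
    def n_groups(self) -> int:
        return int(self.groups.max())


def _profile_matrix(profiles: Sequence[StandardProfile], drop_last: bool = True) -> np.ndarray:
    lengths = {len(p) for p in profiles}
    if len(lengths) != 1:
        raise ValueError("profiles have different grid lengths")
    X = np.vstack([p.values for p in profiles])
    if drop_last and X.shape[1] > 1:
        X = X[:, :-1]  # -50 and +50 are the same physical point
    return X


def similarity_matrix(profiles: Sequence[StandardProfile]) -> SimilarityMatrix:
    """Pairwise Pearson correlation matrix of standardized profiles.

    Raises
    ------
    ZeroVarianceError
        If any profile is constant (its correlation is undefined); the
        error lists the offending labels.
    """
    profiles = list(profiles)
    if len(profiles) < 2:
        raise ValueError("need at least 2 profiles")
    X = _profile_matrix(profiles)
    sd = X.std(axis=1)
    if np.any(sd == 0):
        raise ZeroVarianceError([p.label for p, s in zip(profiles, sd) if s == 0])
    R = np.corrcoef(X)
    np.fill_diagonal(R, 1.0)
    return SimilarityMatrix(labels=[p.label for p in profiles], values=R)


def cluster_profiles(matrix: SimilarityMatrix, cut_similarity: float = 0.6) -> ClusterTree:
    """Average-linkage (UPGMA) tree on d = 1 - r, cut at the given similarity.

    Groups are numbered 1..k in order of first appearance along the
    dendrogram leaf order, so group 1 is at the top of the heatmap.
    """
    R = matrix.values
    D = 1.0 - R
    np.fill_diagonal(D, 0.0)
    D = np.clip((D + D.T) / 2.0, 0.0, None)  # enforce exact symmetry
    Z = linkage(squareform(D, checks=False), method="average")
    order = leaves_list(Z)
    raw = fcluster(Z, t=1.0 - cut_similarity, criterion="distance")
    # renumber groups by first appearance in leaf order
    remap = {}
    for leaf in order:
        remap.setdefault(raw[leaf], len(remap) + 1)
    groups = np.array([remap[g] for g in raw])
    return ClusterTree(
        linkage_matrix=Z,
        labels=list(matrix.labels),
        leaf_order=order,
        groups=groups,
        cut_similarity=float(cut_similarity),
    )


def plot_heatmap(
    profiles: Sequence[StandardProfile],
    tree: ClusterTree,
    path=None,
    show_dendrogram: bool = True,
):
    """Heatmap of profiles in dendrogram leaf order, black (0) to bright green.

    Returns the matplotlib figure; saves to ``path`` when given.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import LinearSegmentedColormap

    cmap = LinearSegmentedColormap.from_list("blackgreen", ["black", "#00ff00"])
    X = np.vstack([p.values for p in profiles])[tree.leaf_order]
    labels = [tree.labels[i] for i in tree.leaf_order]

    if show_dendrogram:
        fig, (ax_d, ax_h) = plt.subplots(
            1, 2, figsize=(9, 0.3 * len(labels) + 1.5),
            gridspec_kw={"width_ratios": [1, 3]},
        )
        dendrogram(tree.linkage_matrix, orientation="left", no_labels=True, ax=ax_d,
                   color_threshold=1.0 - tree.cut_similarity)
        ax_d.invert_yaxis()
        ax_d.set_xlabel("1 - r")
    else:
        fig, ax_h = plt.subplots(figsize=(7, 0.3 * len(labels) + 1.5))
    im = ax_h.imshow(X, aspect="auto", cmap=cmap, vmin=0, vmax=100,
                     extent=[-50, 50, len(labels), 0])
    ax_h.set_yticks(np.arange(len(labels)) + 0.5)
    ax_h.set_yticklabels(labels, fontsize=7)
    ax_h.yaxis.tick_right()
    ax_h.set_xlabel("normalized cell layer position")
    fig.colorbar(im, ax=ax_h, label="expression (0-100)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
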