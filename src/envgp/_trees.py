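"""Dendrogram helpers shared by the genomics and enviromics modules."""

from __future__ import annotations

import numpy as np
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.spatial.distance import squareform

__all__ = ["Dendrogram", "average_linkage_tree"]


class Dendrogram:
    """Hierarchical clustering result with Newick export.

    Wraps a scipy linkage matrix together with leaf labels and keeps the
    cophenetic distance matrix for later tree comparison.
    """

    def __init__(self, linkage_matrix: np.ndarray, labels: list):
        self.linkage = linkage_matrix
        self.labels = list(labels)
        self._coph = squareform(cophenet(linkage_matrix))

    @property
    def cophenetic(self) -> np.ndarray:
        return self._coph

    def to_newick(self) -> str:
        from skbio.tree import TreeNode

        tree = TreeNode.from_linkage_matrix(
            self.linkage, [str(lab) for lab in self.labels]
        )
        return str(tree).strip()

    def write_newick(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick() + "\n")


def average_linkage_tree(dist_values: np.ndarray, labels: list) -> Dendrogram:
    """Average-linkage (UPGMA) tree from a square distance matrix."""
    condensed = squareform(np.asarray(dist_values, dtype=float), checks=False)
    return Dendrogram(linkage(condensed, method="average"), labels)
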