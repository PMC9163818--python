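"""Binary enzyme-profile clustering of bins: Jaccard distances + Ward tree.

Bins are compared by which linkage targets their encoded CAZymes attack,
ignoring how many enzymes they devote to each: the bin-by-target count
matrix is binarised (present iff count > 0, optionally restricted to the
significantly changed targets), pairwise Jaccard distances are computed,
and the bins are agglomerated into a dendrogram under the Ward
(minimum-variance) update.  The tree exports to Newick with per-leaf
annotation tables (phylum, per-group abundance, per-target presence) laid
out for ring-style tree viewers.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "binary_matrix",
    "jaccard_distance",
    "DendrogramTree",
    "ward_tree",
    "export_newick",
    "leaf_annotations",
]


def binary_matrix(
    counts: pd.DataFrame, restrict_to: Optional[Sequence[str]] = None
) -> pd.DataFrame:
    """Presence/absence observation matrix from a bin-by-feature count matrix.

    ``restrict_to`` limits the columns to a given (e.g. significantly
    changed) target list; unknown names raise an error listing them.
    Binarising an already-binary matrix is the identity.
    """
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be non-negative")
    if restrict_to is not None:
        unknown = [t for t in restrict_to if t not in counts.columns]
        if unknown:
            raise ValueError(f"unknown feature(s) in restriction list: {unknown}")
        counts = counts[list(restrict_to)]
    return counts > 0


def jaccard_distance(matrix: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Jaccard distances between the rows of a binary matrix.

    ``d(a, b) = |a XOR b| / |a OR b|``; two all-absent rows are identical
    by convention (distance 0).
    """
    if matrix.shape[0] < 2:
        raise ValueError("need >= 2 rows")
    x = matrix.to_numpy(dtype=bool)
    dist = squareform(pdist(x, metric="jaccard"))
    return pd.DataFrame(dist, index=matrix.index, columns=matrix.index)


@dataclass(frozen=True)
class DendrogramTree:
    """Agglomerative tree over labelled leaves.

    ``linkage`` is a scipy linkage matrix; ``leaves`` the row labels of the
    clustered matrix in input order.
    """

    linkage: np.ndarray
    leaves: tuple[str, ...]

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def cut(self, k: int) -> pd.Series:
        """Leaf → cluster-id labels for a cut into *k* clusters."""
        labels = hierarchy.fcluster(self.linkage, t=k, criterion="maxclust")
        return pd.Series(labels, index=list(self.leaves), name="cluster")

    def leaf_order(self) -> list[str]:
        """Leaves in dendrogram display order."""
        order = hierarchy.leaves_list(self.linkage)
        return [self.leaves[i] for i in order]


def ward_tree(distances: pd.DataFrame) -> DendrogramTree:
    """Ward (minimum-variance) agglomeration of a precomputed distance matrix.

    The Lance–Williams Ward update is applied directly to the given
    dissimilarities — e.g. Jaccard distances — even though Ward's variance
    interpretation strictly assumes Euclidean input; agglomeration is
    deterministic, with tied merges resolved toward the lowest pair index.
    """
    d = np.asarray(distances, dtype=float)
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T):
        raise ValueError("distance matrix must be square and symmetric")
    if (d < 0).any():
        raise ValueError("distances must be non-negative")
    condensed = squareform(d, checks=False)
    linkage = hierarchy.linkage(condensed, method="ward")
    return DendrogramTree(linkage, tuple(map(str, distances.index)))


_NEWICK_UNQUOTED = re.compile(r"^[^\s()\[\]{}:;,']+$")


def _quote(label: str) -> str:
    if _NEWICK_UNQUOTED.match(label):
        return label
    return "'" + label.replace("'", "''") + "'"


def export_newick(
    tree: DendrogramTree, path: Optional[Union[str, Path]] = None
) -> str:
    """Serialise a tree to Newick; branch lengths are merge-height differences.

    Leaf labels containing Newick-reserved characters are quoted per the
    standard.  If *path* is given, the string is also written there.
    """
    n = tree.n_leaves
    linkage = tree.linkage
    height = {i: 0.0 for i in range(n)}
    for idx, row in enumerate(linkage):
        height[n + idx] = float(row[2])

    def render(node: int, parent_height: float) -> str:
        length = parent_height - height[node]
        if node < n:
            return f"{_quote(tree.leaves[node])}:{length:.12g}"
        left, right = int(linkage[node - n, 0]), int(linkage[node - n, 1])
        inner = ",".join(render(c, height[node]) for c in (left, right))
        return f"({inner}):{length:.12g}"

    root = n + len(linkage) - 1
    if n == 1:  # degenerate single-leaf tree
        text = f"{_quote(tree.leaves[0])}:0;"
    else:
        left, right = int(linkage[-1, 0]), int(linkage[-1, 1])
        inner = ",".join(render(c, height[root]) for c in (left, right))
        text = f"({inner});"
    if path is not None:
        Path(path).write_text(text + "\n", encoding="utf-8")
    return text


def leaf_annotations(
    tree: DendrogramTree,
    binary: pd.DataFrame,
    phylum: Mapping[str, str],
    abundance_ref: Mapping[str, float],
    abundance_con: Mapping[str, float],
) -> pd.DataFrame:
    """Per-leaf annotation table for ring-style tree rendering.

    One row per leaf in dendrogram display order: phylum colour class,
    group-mean relative abundances (reference and contrast), then one 0/1
    column per target of the binary matrix.
    """
    order = tree.leaf_order()
    rows = pd.DataFrame(
        {
            "phylum": [phylum.get(b, "Unknown phylum") for b in order],
            "abundance_ref": [float(abundance_ref.get(b, 0.0)) for b in order],
            "abundance_con": [float(abundance_con.get(b, 0.0)) for b in order],
        },
        index=pd.Index(order, name="bin_id"),
    )
    presence = binary.loc[order].astype(int)
    return pd.concat([rows, presence], axis=1)
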