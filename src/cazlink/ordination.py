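"""Correlation-distance ordination of samples and the cluster separation score.

Samples (animals) are placed in a plane by classical metric MDS (principal
coordinates) of the pairwise correlation distance ``1 - corr`` between
their feature profiles.  The contrast between two labelled groups of
points is then quantified by the separation score: the distance between
the two cluster centroids divided by the accumulated (or averaged)
member-to-centroid distances of the two clusters.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "correlation_distance",
    "Embedding2D",
    "embed_2d",
    "PointCluster",
    "separation_score",
]


def correlation_distance(
    profile: pd.DataFrame, method: str = "spearman"
) -> pd.DataFrame:
    """Sample-by-sample distance matrix ``d(s, t) = 1 - corr(col_s, col_t)``.

    *profile* is feature-by-sample; *method* is ``"spearman"`` (rank
    correlation, default) or ``"pearson"``.  Constant sample columns have
    no defined correlation and raise an error naming the sample.
    """
    if method not in ("spearman", "pearson"):
        raise ValueError(f"method must be 'spearman' or 'pearson', got {method!r}")
    if profile.shape[1] < 2:
        raise ValueError("need >= 2 samples")
    x = profile.to_numpy(dtype=float)
    constant = np.ptp(x, axis=0) == 0
    if constant.any():
        bad = profile.columns[constant][0]
        raise ValueError(f"sample {bad!r} has a constant profile; "
                         "correlation distance is undefined")
    if method == "spearman":
        x = sps.rankdata(x, axis=0)
    corr = np.corrcoef(x.T)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2.0  # enforce exact symmetry
    return pd.DataFrame(dist, index=profile.columns, columns=profile.columns)


@dataclass(frozen=True)
class Embedding2D:
    """2-D sample embedding with an explained-variance diagnostic."""

    coordinates: pd.DataFrame  # sample -> (x, y)
    eigenvalues: np.ndarray  # all eigenvalues of the centred Gram matrix
    explained: tuple[float, float]  # fraction of positive inertia on each axis

    def points(self, samples: Sequence[str]) -> np.ndarray:
        return self.coordinates.loc[list(samples)].to_numpy()


def embed_2d(distances: pd.DataFrame) -> Embedding2D:
    """Classical (metric) MDS of a distance matrix, top two coordinates.

    Double-centres the squared distances, eigendecomposes the Gram matrix
    and keeps the two leading axes.  Negative eigenvalues (non-Euclidean
    input) are clipped to zero for the coordinates.  Axis orientation is
    fixed deterministically: each axis is flipped so its largest-magnitude
    coordinate is positive.
    """
    d = np.asarray(distances, dtype=float)
    n = d.shape[0]
    if n < 3:
        raise ValueError("need >= 3 samples to embed")
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T):
        raise ValueError("distance matrix must be square and symmetric")
    if not np.allclose(np.diag(d), 0.0):
        raise ValueError("distance matrix must have a zero diagonal")
    j = np.eye(n) - np.ones((n, n)) / n
    gram = -0.5 * j @ (d ** 2) @ j
    eigval, eigvec = np.linalg.eigh(gram)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    lam = np.clip(eigval[:2], 0.0, None)
    coords = eigvec[:, :2] * np.sqrt(lam)
    for axis in range(2):
        col = coords[:, axis]
        if col[np.argmax(np.abs(col))] < 0:
            coords[:, axis] = -col
    positive = np.clip(eigval, 0.0, None).sum()
    explained = tuple(
        float(v / positive) if positive > 0 else 0.0 for v in lam
    )
    frame = pd.DataFrame(coords, index=distances.index, columns=["x", "y"])
    frame.index.name = "sample"
    return Embedding2D(frame, eigval, explained)


@dataclass(frozen=True)
class PointCluster:
    """A labelled set of points sharing one coordinate dimension."""

    label: str
    points: np.ndarray

    def __init__(self, label: str, points: Iterable[Sequence[float]]):
        pts = np.atleast_2d(np.asarray(list(points), dtype=float))
        if pts.size == 0:
            raise ValueError("a cluster needs at least one point")
        object.__setattr__(self, "label", label)
        object.__setattr__(self, "points", pts)

    @property
    def centroid(self) -> np.ndarray:
        return self.points.mean(axis=0)

    @property
    def member_distances(self) -> np.ndarray:
        """Euclidean distance of every member to the cluster centroid."""
        return np.linalg.norm(self.points - self.centroid, axis=1)


def separation_score(
    cluster_m: PointCluster, cluster_n: PointCluster, variant: str = "sum"
) -> float:
    """Separation between two labelled clusters.

    ``variant="sum"`` (default) divides the inter-centroid distance
    ``|c_m - c_n|`` by the *sum* of all member-to-centroid distances of
    both clusters; ``variant="mean"`` divides by the sum of the two
    clusters' *mean* member-to-centroid distances.  The score is
    dimensionless: invariant under rotation, translation and uniform
    scaling, zero iff the centroids coincide.
    """
    if variant not in ("sum", "mean"):
        raise ValueError(f"variant must be 'sum' or 'mean', got {variant!r}")
    if cluster_m.points.shape[1] != cluster_n.points.shape[1]:
        raise ValueError("clusters must share one coordinate dimension")
    between = float(np.linalg.norm(cluster_m.centroid - cluster_n.centroid))
    dm = cluster_m.member_distances
    dn = cluster_n.member_distances
    if variant == "sum":
        denom = float(dm.sum() + dn.sum())
    else:
        denom = float(dm.mean() + dn.mean())
    if denom == 0.0:
        raise ValueError("degenerate clusters: zero member spread in both groups")
    return between / denom
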