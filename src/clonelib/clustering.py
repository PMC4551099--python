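"""OTU clustering of pre-aligned marker-gene sequences.

Sequences are grouped into operational taxonomic units at a fixed distance
threshold (3% by convention, the common proxy for prokaryote species).
Distances are uncorrected p-distances with pairwise gap deletion; at the
3% divergence relevant to OTU calling, model-corrected distances differ
from p-distance by far less than the threshold.

`OtuClusterer` follows the scikit-learn clustering API (fit / fit_predict /
labels_) on a precomputed distance matrix. Agglomeration is average-linkage
with a documented lexicographic tie-break, making partitions
bit-reproducible across runs and platforms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skbio import DistanceMatrix
from sklearn.base import BaseEstimator, ClusterMixin

__all__ = [
    "OtuAssignment",
    "pairwise_p_distance",
    "OtuClusterer",
    "cluster_otus",
]


@dataclass(frozen=True)
class OtuAssignment:
    """A partition of sequence ids into OTUs at a given distance threshold.

    OTU ids are "OTU_1", "OTU_2", ... assigned by decreasing abundance,
    ties broken by the lexicographically smallest member id.
    """

    threshold: float
    clusters: dict[str, frozenset[str]]

    @property
    def n_otus(self) -> int:
        return len(self.clusters)

    @property
    def abundances(self) -> list[int]:
        """Clones per OTU, in OTU-id order (decreasing)."""
        return [len(self.clusters[k]) for k in sorted(
            self.clusters, key=lambda k: int(k.split("_")[1]))]

    def otu_of(self) -> dict[str, str]:
        """Map sequence id -> OTU id."""
        return {sid: otu for otu, members in self.clusters.items() for sid in members}


def pairwise_p_distance(aligned) -> DistanceMatrix:
    """Uncorrected p-distance matrix for equal-length aligned sequences.

    For each pair, columns gapped in either sequence are excluded
    (pairwise deletion); distance = mismatches / compared columns.
    A pair with zero comparable columns is an error.
    """
    if len(aligned) < 2:
        raise ValueError("need at least 2 sequences")
    lengths = {len(r.residues) for r in aligned}
    if len(lengths) != 1:
        raise ValueError(f"aligned sequences have unequal lengths: {sorted(lengths)}")
    ids = [r.id for r in aligned]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sequence ids")
    arr = np.frombuffer(
        "".join(r.residues.upper() for r in aligned).encode(), dtype="S1"
    ).reshape(len(aligned), -1)
    gap = arr == b"-"
    n = len(aligned)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~(gap[i] | gap[j])
            ncols = int(ok.sum())
            if ncols == 0:
                raise ValueError(
                    f"pair ({ids[i]}, {ids[j]}) has no comparable columns"
                )
            d[i, j] = d[j, i] = np.count_nonzero(arr[i, ok] != arr[j, ok]) / ncols
    return DistanceMatrix(d, ids)


class OtuClusterer(BaseEstimator, ClusterMixin):
    """Average-linkage agglomerative clustering at a distance threshold.

    Parameters
    ----------
    threshold : float, default 0.03
        Merging stops when the smallest inter-cluster average distance
        exceeds this value (0.03 = the 97%-identity OTU convention).
    linkage : {"average", "complete"}, default "average"
        Inter-cluster distance: unweighted mean over all original pairwise
        distances, or the maximum (furthest neighbor).

    Attributes
    ----------
    labels_ : ndarray of int
        Cluster index per input sequence (0-based, ordered as OTU ids).
    ids_ : list of str
        Sequence ids, input order.
    assignment_ : OtuAssignment
        The partition with named OTU ids.
    """

    def __init__(self, threshold: float = 0.03, linkage: str = "average"):
        self.threshold = threshold
        self.linkage = linkage

    def fit(self, X, y=None):
        if not 0.0 <= self.threshold <= 1.0:
            raise ValueError(f"threshold must be in [0, 1], got {self.threshold}")
        if self.linkage not in ("average", "complete"):
            raise ValueError(f"unknown linkage {self.linkage!r}")
        if isinstance(X, DistanceMatrix):
            dm = X
        else:
            X = np.asarray(X, dtype=float)
            dm = DistanceMatrix(X, [str(i) for i in range(len(X))])
        ids = list(dm.ids)
        d = dm.data
        if not np.all(np.isfinite(d)):
            raise ValueError("distance matrix contains non-finite entries")

        clusters = self._agglomerate(d, ids)

        # OTU ids by decreasing abundance, then lexicographic representative
        ordered = sorted(
            clusters, key=lambda c: (-len(c), min(ids[i] for i in c))
        )
        named = {
            f"OTU_{k + 1}": frozenset(ids[i] for i in members)
            for k, members in enumerate(ordered)
        }
        labels = np.empty(len(ids), dtype=int)
        for k, members in enumerate(ordered):
            for i in members:
                labels[i] = k
        self.ids_ = ids
        self.labels_ = labels
        self.assignment_ = OtuAssignment(self.threshold, named)
        self.n_clusters_ = len(ordered)
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_

    def _agglomerate(self, d: np.ndarray, ids: list[str]) -> list[frozenset[int]]:
        n = len(ids)
        clusters: list[set[int]] = [{i} for i in range(n)]
        # sum of original pairwise distances between clusters; average = sum/(na*nb)
        while len(clusters) > 1:
            best = None  # (distance, tie_key, a, b)
            for a in range(len(clusters)):
                for b in range(a + 1, len(clusters)):
                    pairs = d[np.ix_(sorted(clusters[a]), sorted(clusters[b]))]
                    dist = pairs.mean() if self.linkage == "average" else pairs.max()
                    key = tuple(sorted((
                        min(ids[i] for i in clusters[a]),
                        min(ids[i] for i in clusters[b]),
                    )))
                    if best is None or (dist, key) < (best[0], best[1]):
                        best = (dist, key, a, b)
            dist, _, a, b = best
            if dist > self.threshold:
                break
            clusters[a] = clusters[a] | clusters[b]
            del clusters[b]
        return [frozenset(c) for c in clusters]


def cluster_otus(dm: DistanceMatrix, threshold: float = 0.03,
                 linkage: str = "average") -> OtuAssignment:
    """Group sequences into OTUs at `threshold`; see :class:`OtuClusterer`."""
    return OtuClusterer(threshold=threshold, linkage=linkage).fit(dm).assignment_
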