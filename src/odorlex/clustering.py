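"""UPGMA clustering of descriptors, K-cluster cuts, OR-rule cluster labels.

The dendrogram is grown by unweighted-average (UPGMA) linkage: the closest
pair of clusters merges, and the distance from the merged cluster A∪B to
any C is the size-weighted mean (|A| d(A,C) + |B| d(B,C)) / (|A|+|B|).
Ties are broken by the lowest lexicographic pair of cluster indices, each
cluster indexed by its smallest original leaf, so the merge sequence is
fully deterministic.

Cutting at K clusters undoes the last K-1 merges.  A chemical is then
labeled with a cluster iff it carries at least one of the cluster's member
descriptors (the OR rule), turning the sparse descriptor catalog into a
denser chemicals x K binary target matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .catalog import SensoryCatalog
from .semantics import DistanceMatrix


class ClusteringError(ValueError):
    """Raised for invalid clustering inputs."""


#: merge distances closer than this are treated as exact ties, so the
#: lexicographic tie-break is robust to float round-off in the linkage update
TIE_TOL = 1e-9


@dataclass
class Dendrogram:
    """UPGMA merge tree over descriptor leaves.

    ``merges`` lists (node_a, node_b, height, new_size) in merge order;
    node ids < n are leaves, id n+i is the cluster created by merge i.
    """

    leaves: list[str]
    merges: list[tuple[int, int, float, int]]

    def __post_init__(self) -> None:
        n = len(self.leaves)
        if len(self.merges) != max(n - 1, 0):
            raise ClusteringError(f"{n} leaves require {n - 1} merges")

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    def to_linkage(self) -> np.ndarray:
        """Merge list as a scipy-style (n-1) x 4 linkage array."""
        return np.array(self.merges, dtype=float).reshape(-1, 4)

    def to_newick(self) -> str:
        """Newick string with branch lengths derived from merge heights."""
        n = self.n_leaves
        height = {i: 0.0 for i in range(n)}
        node: dict[int, str] = {i: _escape(self.leaves[i]) for i in range(n)}
        for i, (a, b, h, _) in enumerate(self.merges):
            half = h / 2.0
            la, lb = half - height[a], half - height[b]
            node[n + i] = f"({node[a]}:{la:g},{node[b]}:{lb:g})"
            height[n + i] = half
        root = n + len(self.merges) - 1 if self.merges else 0
        return node[root] + ";"


def _escape(name: str) -> str:
    return name.replace(" ", "_").replace("(", "").replace(")", "").replace(",", "")


@dataclass
class ClusterAssignment:
    """Flat partition of descriptors into K clusters."""

    K: int
    member_map: dict[str, int]

    def __post_init__(self) -> None:
        used = set(self.member_map.values())
        if used != set(range(self.K)):
            raise ClusteringError(
                f"expected cluster indices 0..{self.K - 1}, got {sorted(used)}"
            )

    def members(self, k: int) -> list[str]:
        return [d for d, c in self.member_map.items() if c == k]


@dataclass
class ClusterLabelMatrix:
    """Chemicals x clusters binary matrix produced by the OR rule."""

    chemical_ids: list[str]
    K: int
    matrix: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix)
        if self.matrix.shape != (len(self.chemical_ids), self.K):
            raise ClusteringError("label matrix shape mismatch")
        if not np.isin(self.matrix, (0, 1)).all():
            raise ClusteringError("label entries must be 0/1")
        self.matrix = self.matrix.astype(np.int8)


def upgma(dm: DistanceMatrix) -> Dendrogram:
    """UPGMA agglomeration with deterministic lexicographic tie-breaking.

    Active clusters are keyed by their smallest original leaf index; at
    each step the pair with minimal linkage distance merges, equal
    distances resolved toward the smallest (i, j) key pair.
    """
    n = dm.n
    if n < 2:
        raise ClusteringError("need at least 2 leaves")
    if np.isnan(dm.values).any():
        raise ClusteringError("NaN in distance matrix")

    # dist[i][j] between active clusters keyed by smallest-leaf index
    dist = {i: {j: float(dm.values[i, j]) for j in range(n) if j != i} for i in range(n)}
    size = {i: 1 for i in range(n)}
    node_id = {i: i for i in range(n)}  # active key -> dendrogram node id
    merges: list[tuple[int, int, float, int]] = []
    next_id = n

    active = sorted(dist)
    while len(active) > 1:
        # distances within TIE_TOL count as tied; among ties the
        # lexicographically smallest key pair wins (scan order is sorted)
        d_min = min(dist[i][j] for idx, i in enumerate(active) for j in active[idx + 1 :])
        best = None
        for idx, i in enumerate(active):
            for j in active[idx + 1 :]:
                if dist[i][j] <= d_min + TIE_TOL:
                    best = (dist[i][j], i, j)
                    break
            if best is not None:
                break
        d, i, j = best
        merges.append((node_id[i], node_id[j], d, size[i] + size[j]))
        # unweighted-average update: merged cluster keeps key i (= min leaf)
        for k in active:
            if k in (i, j):
                continue
            dk = (size[i] * dist[i][k] + size[j] * dist[j][k]) / (size[i] + size[j])
            dist[i][k] = dist[k][i] = dk
            del dist[k][j]
        del dist[j]
        dist[i].pop(j, None)
        size[i] += size[j]
        del size[j]
        node_id[i] = next_id
        next_id += 1
        active.remove(j)

    return Dendrogram(list(dm.labels), merges)


def cut_to_k(dend: Dendrogram, K: int) -> ClusterAssignment:
    """Cut the tree into exactly K clusters by undoing the last K-1 merges.

    Cluster indices are assigned in order of each cluster's
    first-appearing leaf, for stable output.
    """
    n = dend.n_leaves
    if not 1 <= K <= n:
        raise ClusteringError(f"K={K} out of range [1, {n}]")
    parent = list(range(2 * n - 1))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, (a, b, _, _) in enumerate(dend.merges[: n - K]):
        new = n + i
        parent[find(a)] = new
        parent[find(b)] = new

    roots: dict[int, int] = {}
    member_map: dict[str, int] = {}
    for leaf in range(n):
        r = find(leaf)
        if r not in roots:
            roots[r] = len(roots)
        member_map[dend.leaves[leaf]] = roots[r]
    return ClusterAssignment(K, member_map)


def cut_at_height(dend: Dendrogram, height: float) -> ClusterAssignment:
    """Alternative cut: keep every merge at height <= the threshold."""
    n_kept = sum(1 for m in dend.merges if m[2] <= height)
    return cut_to_k(dend, dend.n_leaves - n_kept)


def build_cluster_labels(cat: SensoryCatalog, asg: ClusterAssignment) -> ClusterLabelMatrix:
    """OR rule: chemical i carries cluster c iff any member descriptor is 1."""
    if set(asg.member_map) != set(cat.descriptor_names):
        raise ClusteringError("cluster assignment does not cover the catalog descriptors")
    out = np.zeros((cat.n_chemicals, asg.K), dtype=np.int8)
    for j, d in enumerate(cat.descriptor_names):
        c = asg.member_map[d]
        out[:, c] |= cat.matrix[:, j]
    return ClusterLabelMatrix(list(cat.chemical_ids), asg.K, out)


def cluster_size_distribution(labels: ClusterLabelMatrix) -> np.ndarray:
    """Positive-sample count per cluster (column sums).

    A single dominant count flags the degenerate regime where most
    descriptors collapse into one huge cluster and high accuracy carries
    little information.
    """
    return labels.matrix.sum(axis=0).astype(int)


def write_assignment_csv(asg: ClusterAssignment, path) -> None:
    with open(path, "w") as fh:
        fh.write("descriptor,cluster_id\n")
        for d, c in sorted(asg.member_map.items(), key=lambda t: (t[1], t[0])):
            fh.write(f"{d},{c}\n")
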