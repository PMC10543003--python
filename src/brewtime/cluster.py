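"""Trajectory clustering and cluster annotation.

Proteins whose row-mean-normalised profile changes at least two-fold (|log2
ratio| >= 1) at some time point are clustered with average-linkage
agglomeration on correlation distance (1 - Pearson r).  Clusters are
extracted by *node depth*: descending a fixed number of levels from the
dendrogram root, every node reached at that depth (or leaf reached earlier)
is one cluster, and oversized clusters are re-cut at a deeper level.
Clusters are annotated with a generic hypergeometric over-representation
test over user-supplied term sets (GO terms, pathways, complexes, ...).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

from .containers import AbundanceMatrix, ValidationError
from .diffexp import bh_adjust
from .qc import protein_correlation


def twofold_filter(matrix: AbundanceMatrix, min_abs_log2: float = 1.0) -> AbundanceMatrix:
    """Keep proteins changing at least two-fold relative to their mean.

    Input must be row-mean-normalised; a row survives when the largest
    |log2 ratio| over time points is >= ``min_abs_log2`` (inclusive: an
    exactly two-fold change is retained).
    """
    if matrix.state != "row_mean_normalized":
        raise ValidationError(
            f"two-fold filter expects row_mean_normalized input, got {matrix.state!r}"
        )
    peak = matrix.data.abs().max(axis=1, skipna=True)
    return AbundanceMatrix(matrix.data.loc[peak >= min_abs_log2], state=matrix.state)


@dataclass
class DendrogramModel:
    """Agglomerative tree over proteins: a SciPy linkage matrix plus the
    leaf order (leaf i of the linkage is ``leaves[i]``)."""

    linkage: np.ndarray
    leaves: list[str]

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)


@dataclass
class ClusterAssignment:
    labels: pd.Series  # protein -> cluster label
    node_depth: dict[str, int] = field(default_factory=dict)  # label -> cut depth

    def sizes(self) -> pd.Series:
        return self.labels.value_counts()


def _correlation_distance(matrix: AbundanceMatrix) -> tuple[np.ndarray, list[str]]:
    """Condensed 1 - Pearson distance over rows, pairwise-complete.

    Pairs with undefined correlation (insufficient overlap) are assigned the
    maximal distance 2 so the tree stays well defined.
    """
    cm = protein_correlation(matrix)
    r = cm.values.to_numpy(copy=True)
    np.fill_diagonal(r, 1.0)
    d = 1.0 - r
    d[~np.isfinite(d)] = 2.0
    iu = np.triu_indices(d.shape[0], k=1)
    return d[iu], list(cm.values.index)


def hcluster(
    matrix: AbundanceMatrix, metric: str = "correlation", method: str = "average"
) -> DendrogramModel:
    """Average-linkage hierarchical clustering of protein trajectories.

    ``metric`` is ``correlation`` (1 - Pearson, the default for expression
    rows) or ``euclidean``.  Zero-variance rows are undefined under
    correlation distance and are excluded with a warning.
    """
    data = matrix.data
    if data.shape[0] < 2:
        raise ValidationError("clustering needs at least two rows")
    if metric == "correlation":
        flat = data.std(axis=1, skipna=True).fillna(0) == 0
        if flat.any():
            warnings.warn(f"excluding {int(flat.sum())} zero-variance rows from clustering")
            data = data.loc[~flat]
        sub = AbundanceMatrix(data, state=matrix.state)
        dist, leaves = _correlation_distance(sub)
    elif metric == "euclidean":
        if data.isna().any().any():
            raise ValidationError("euclidean clustering does not accept missing values")
        from scipy.spatial.distance import pdist

        dist = pdist(data.to_numpy(), metric="euclidean")
        leaves = list(data.index)
    else:
        raise ValidationError(f"unknown metric {metric!r}")
    Z = hierarchy.linkage(dist, method=method)
    return DendrogramModel(linkage=Z, leaves=leaves)


def _children(Z: np.ndarray, node: int, n: int) -> tuple[int, int] | None:
    if node < n:
        return None
    row = Z[node - n]
    return int(row[0]), int(row[1])


def _subtree_leaves(Z: np.ndarray, node: int, n: int) -> list[int]:
    stack, out = [node], []
    while stack:
        cur = stack.pop()
        kids = _children(Z, cur, n)
        if kids is None:
            out.append(cur)
        else:
            stack.extend(kids)
    return sorted(out)


def _nodes_at_depth(Z: np.ndarray, root: int, n: int, depth: int) -> list[int]:
    """Nodes reached exactly ``depth`` levels below ``root``, with leaves
    encountered earlier closing as their own node.  Left-to-right order."""
    frontier = [root]
    for _ in range(depth):
        nxt: list[int] = []
        for node in frontier:
            kids = _children(Z, node, n)
            if kids is None:
                nxt.append(node)  # leaf closes early
            else:
                nxt.extend(kids)
        frontier = nxt
    return frontier


def cut_by_node_depth(
    tree: DendrogramModel,
    depth: int,
    subset_threshold: int | None = 500,
    subset_depth: int = 5,
) -> ClusterAssignment:
    """Extract clusters at a fixed node depth below the dendrogram root.

    The root is depth 0; at depth d a balanced binary tree yields 2**d
    clusters, fewer when leaves close early.  Clusters larger than
    ``subset_threshold`` are re-cut at ``subset_depth`` (counted from the
    root) and their sub-clusters labelled ``<i>a``, ``<i>b``, ...
    """
    if depth < 0:
        raise ValidationError("depth must be >= 0")
    Z, leaves = tree.linkage, tree.leaves
    n = len(leaves)
    root = 2 * n - 2 if n > 1 else 0
    assignment: dict[str, str] = {}
    node_depth: dict[str, int] = {}
    for i, node in enumerate(_nodes_at_depth(Z, root, n, depth), start=1):
        label = str(i)
        members = _subtree_leaves(Z, node, n)
        if (
            subset_threshold is not None
            and len(members) > subset_threshold
            and subset_depth > depth
        ):
            subnodes = _nodes_at_depth(Z, node, n, subset_depth - depth)
            for k, sub in enumerate(subnodes):
                sub_label = f"{label}{_letter(k)}"
                for leaf in _subtree_leaves(Z, sub, n):
                    assignment[leaves[leaf]] = sub_label
                node_depth[sub_label] = subset_depth
        else:
            for leaf in members:
                assignment[leaves[leaf]] = label
            node_depth[label] = depth
    labels = pd.Series(assignment).reindex(leaves)
    return ClusterAssignment(labels=labels, node_depth=node_depth)


def _letter(k: int) -> str:
    out = ""
    k += 1
    while k:
        k, rem = divmod(k - 1, 26)
        out = chr(ord("a") + rem) + out
    return out


def cut_to_n_clusters(
    tree: DendrogramModel, n_clusters: int, max_depth: int = 32
) -> ClusterAssignment:
    """Smallest node depth whose cut yields at least ``n_clusters`` clusters."""
    for depth in range(max_depth + 1):
        assignment = cut_by_node_depth(tree, depth, subset_threshold=None)
        if assignment.labels.nunique() >= n_clusters:
            return assignment
    raise ValidationError(f"no depth <= {max_depth} yields {n_clusters} clusters")


def cut_by_height(tree: DendrogramModel, n_clusters: int) -> ClusterAssignment:
    """Height-threshold cut producing exactly ``n_clusters`` clusters.

    The alternative interpretation of a dendrogram cut: remove the
    ``n_clusters - 1`` highest merges instead of descending a fixed number
    of levels.  Unlike the depth cut it is insensitive to tree imbalance —
    an archetype far from every other class does not get split internally
    before nearer classes separate.
    """
    flat = hierarchy.fcluster(tree.linkage, t=n_clusters, criterion="maxclust")
    labels = pd.Series([str(c) for c in flat], index=tree.leaves)
    return ClusterAssignment(labels=labels, node_depth={})


# ---------------------------------------------------------------------------
# Term enrichment
# ---------------------------------------------------------------------------

def enrich_terms(
    cluster: set[str],
    annotations: dict[str, set[str]],
    universe: set[str],
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric over-representation of term sets in a cluster.

    Terms are intersected with the universe (all detected proteins by
    default); the one-sided upper-tail p-value asks whether the overlap k of
    a term of size K with a cluster of size n drawn from a universe of size
    N is surprisingly large.  BH adjustment is applied across terms and the
    ``significant`` flag marks q < ``fdr``.
    """
    if not universe:
        raise ValidationError("empty universe")
    if not cluster <= universe:
        raise ValidationError("cluster must be a subset of the universe")
    N, n = len(universe), len(cluster)
    rows = []
    for term, members in annotations.items():
        term_set = members & universe
        K = len(term_set)
        if K == 0:
            continue
        k = len(term_set & cluster)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append({"term": term, "k": k, "n": n, "K": K, "N": N, "p": p})
    result = pd.DataFrame(rows, columns=["term", "k", "n", "K", "N", "p"])
    if len(result):
        result["q"] = bh_adjust(result["p"].to_numpy())
        result["significant"] = result["q"] < fdr
        result = result.sort_values(["p", "term"], kind="stable").reset_index(drop=True)
    else:
        result["q"] = []
        result["significant"] = []
    return result


def annotate_clusters(
    assignment: ClusterAssignment,
    annotations: dict[str, set[str]],
    universe: set[str],
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Run term enrichment for every cluster; long-format result table."""
    frames = []
    for label in sorted(assignment.labels.dropna().unique()):
        members = set(assignment.labels.index[assignment.labels == label])
        table = enrich_terms(members, annotations, universe, fdr=fdr)
        table.insert(0, "cluster", label)
        frames.append(table)
    if not frames:
        return pd.DataFrame(
            columns=["cluster", "term", "k", "n", "K", "N", "p", "q", "significant"]
        )
    return pd.concat(frames, ignore_index=True)
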