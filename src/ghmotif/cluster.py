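"""Structure-similarity clustering with leave-one-out node reliability.

The analysis takes a symmetric matrix of pairwise structural-similarity
Z-scores (Dali-style: self-scores on the diagonal), converts it to a
distance metric, builds a UPGMA tree, and flags each internal node as
reliable only if the clade reappears in every leave-one-taxon-out replicate
tree (Lanyon jackknife).

The default similarity→distance transform is

    D_ij = 100 * (1 - 2 * S_ij / (S_ii + S_jj))

which is zero for identical structures, 100 for unrelated ones (S_ij = 0),
and strictly decreasing in S_ij at fixed self-scores. Alternative
transforms can be registered by name or passed as callables.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

from .errors import GHMotifError, MatrixFormatError

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# matrices
# ---------------------------------------------------------------------------

@dataclass
class SimilarityMatrix:
    """Labelled symmetric matrix of structure-pair similarity scores."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise MatrixFormatError(
                f"matrix shape {self.values.shape} does not match {n} labels"
            )
        if len(set(self.labels)) != n:
            raise MatrixFormatError("duplicate labels")
        if n and not np.allclose(self.values, self.values.T, atol=1e-6):
            raise MatrixFormatError("similarity matrix not symmetric within 1e-6")

    @property
    def n(self) -> int:
        return len(self.labels)

    @property
    def self_scores(self) -> np.ndarray:
        return np.diag(self.values)

    def drop(self, label: str) -> "SimilarityMatrix":
        """Submatrix with one taxon removed (for jackknife replicates)."""
        idx = [i for i, l in enumerate(self.labels) if l != label]
        if len(idx) == self.n:
            raise KeyError(label)
        return SimilarityMatrix(
            labels=[self.labels[i] for i in idx],
            values=self.values[np.ix_(idx, idx)],
        )


@dataclass
class DistanceMatrix:
    """Labelled symmetric non-negative distances with a zero diagonal."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise MatrixFormatError(
                f"matrix shape {self.values.shape} does not match {n} labels"
            )
        if n:
            if np.any(np.isnan(self.values)):
                raise MatrixFormatError("NaN in distance matrix")
            if not np.allclose(self.values, self.values.T, atol=1e-9):
                raise MatrixFormatError("distance matrix not symmetric")
            if np.any(np.diag(self.values) != 0):
                raise MatrixFormatError("distance diagonal must be exactly zero")
            if np.any(self.values < 0):
                raise MatrixFormatError("negative distances")

    @property
    def n(self) -> int:
        return len(self.labels)

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.labels.index(a), self.labels.index(b)])


# ---------------------------------------------------------------------------
# similarity -> distance
# ---------------------------------------------------------------------------

def _zscore_ratio(sij: float, sii: float, sjj: float) -> float:
    return 100.0 * (1.0 - 2.0 * sij / (sii + sjj))


#: named transforms usable in configs; signature (S_ij, S_ii, S_jj) -> D_ij
TRANSFORMS: dict[str, Callable[[float, float, float], float]] = {
    "zscore-ratio": _zscore_ratio,
}


def similarity_to_distance(
    sim: SimilarityMatrix,
    transform: str | Callable[[float, float, float], float] = "zscore-ratio",
) -> DistanceMatrix:
    """Convert a similarity matrix into a distance matrix.

    Negative distances produced by the transform (``S_ij`` exceeding the
    self-score average, which violates the Dali-score domain assumption)
    are clamped to 0 and logged.
    """
    fn = TRANSFORMS[transform] if isinstance(transform, str) else transform
    n = sim.n
    diag = sim.self_scores
    D = np.zeros((n, n), dtype=float)
    for i in range(n):
        for j in range(i + 1, n):
            sij = sim.values[i, j]
            if sij > min(diag[i], diag[j]):
                logger.warning(
                    "S(%s,%s)=%.3g exceeds a self-score; domain assumption violated",
                    sim.labels[i], sim.labels[j], sij,
                )
            d = fn(sij, diag[i], diag[j])
            if d < 0:
                logger.warning(
                    "negative distance %.3g for (%s,%s); clamping to 0",
                    d, sim.labels[i], sim.labels[j],
                )
                d = 0.0
            D[i, j] = D[j, i] = d
    return DistanceMatrix(labels=list(sim.labels), values=D)


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClusterNode:
    height: float
    children: tuple["ClusterNode", ...]
    label: str | None
    clade: frozenset[str]
    reliability: bool | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class ClusterTree:
    """Rooted ultrametric tree from agglomerative clustering."""

    root: ClusterNode

    @property
    def leaf_labels(self) -> list[str]:
        out: list[str] = []

        def walk(node: ClusterNode) -> None:
            if node.is_leaf:
                out.append(node.label)
            for c in node.children:
                walk(c)

        walk(self.root)
        return out

    def internal_nodes(self) -> list[ClusterNode]:
        out: list[ClusterNode] = []

        def walk(node: ClusterNode) -> None:
            if not node.is_leaf:
                out.append(node)
                for c in node.children:
                    walk(c)

        walk(self.root)
        return out

    def clades(self) -> set[frozenset[str]]:
        """Leaf sets of all internal nodes (including the root)."""
        return {node.clade for node in self.internal_nodes()}

    def cophenetic(self) -> DistanceMatrix:
        """Pairwise tree distances: 2 × height of the lowest common ancestor."""
        labels = sorted(self.leaf_labels)
        index = {l: i for i, l in enumerate(labels)}
        n = len(labels)
        D = np.zeros((n, n))

        def walk(node: ClusterNode) -> list[str]:
            if node.is_leaf:
                return [node.label]
            groups = [walk(c) for c in node.children]
            for gi in range(len(groups)):
                for gj in range(gi + 1, len(groups)):
                    for a in groups[gi]:
                        for b in groups[gj]:
                            D[index[a], index[b]] = D[index[b], index[a]] = (
                                2.0 * node.height
                            )
            return [l for g in groups for l in g]

        walk(self.root)
        return DistanceMatrix(labels=labels, values=D)

    def with_reliability(self, reliable: Mapping[frozenset[str], bool]) -> "ClusterTree":
        """Copy of the tree with reliability flags set per internal clade."""

        def walk(node: ClusterNode) -> ClusterNode:
            if node.is_leaf:
                return node
            children = tuple(walk(c) for c in node.children)
            return replace(node, children=children,
                           reliability=reliable.get(node.clade, node.reliability))

        return ClusterTree(root=walk(self.root))


def upgma(dist: DistanceMatrix) -> ClusterTree:
    """Unweighted pair-group (arithmetic average) agglomerative clustering.

    Repeatedly joins the closest pair of clusters; the distance from the
    merged cluster to any other is the size-weighted arithmetic mean. Node
    heights are half the merge distance, so the tree is ultrametric. Ties
    are broken by the lexicographically smallest (min-leaf-label) pair, for
    determinism.
    """
    if dist.n < 2:
        raise GHMotifError("UPGMA requires at least two taxa")
    if np.any(np.isnan(dist.values)):
        raise MatrixFormatError("NaN in distance matrix")

    # cluster id -> (node, size, smallest leaf label)
    clusters: dict[int, tuple[ClusterNode, int, str]] = {}
    for i, label in enumerate(dist.labels):
        clusters[i] = (
            ClusterNode(height=0.0, children=(), label=label,
                        clade=frozenset([label])),
            1,
            label,
        )
    d: dict[frozenset[int], float] = {}
    ids = list(clusters)
    for ai in range(len(ids)):
        for bi in range(ai + 1, len(ids)):
            d[frozenset((ids[ai], ids[bi]))] = float(dist.values[ids[ai], ids[bi]])

    next_id = dist.n
    while len(clusters) > 1:
        best: tuple[float, str, str, int, int] | None = None
        for pair, val in d.items():
            a, b = sorted(pair)
            la, lb = sorted((clusters[a][2], clusters[b][2]))
            key = (val, la, lb, a, b)
            if best is None or key < best:
                best = key
        _, _, _, a, b = best
        dist_ab = d[frozenset((a, b))]
        node_a, size_a, min_a = clusters[a]
        node_b, size_b, min_b = clusters[b]
        merged = ClusterNode(
            height=dist_ab / 2.0,
            children=(node_a, node_b) if min_a <= min_b else (node_b, node_a),
            label=None,
            clade=node_a.clade | node_b.clade,
        )
        for other in list(clusters):
            if other in (a, b):
                continue
            dao = d.pop(frozenset((a, other)))
            dbo = d.pop(frozenset((b, other)))
            d[frozenset((next_id, other))] = (
                size_a * dao + size_b * dbo
            ) / (size_a + size_b)
        del d[frozenset((a, b))]
        del clusters[a]
        del clusters[b]
        clusters[next_id] = (merged, size_a + size_b, min(min_a, min_b))
        next_id += 1

    (root, _, _), = clusters.values()
    return ClusterTree(root=root)


# ---------------------------------------------------------------------------
# jackknife reliability
# ---------------------------------------------------------------------------

@dataclass
class JackknifeReport:
    """Per-clade reliability from leave-one-out replicates.

    ``absent_in`` maps each internal clade of the full tree to the deleted
    taxa whose replicate tree lacked the (restricted) clade; a clade is
    reliable iff that list is empty.
    """

    absent_in: dict[frozenset[str], list[str]]

    def reliable(self, clade: frozenset[str]) -> bool:
        return not self.absent_in[clade]

    @property
    def n_reliable(self) -> int:
        return sum(1 for v in self.absent_in.values() if not v)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "clade": ",".join(sorted(c)),
                "size": len(c),
                "reliable": int(not absent),
                "absent_in": ",".join(absent),
            }
            for c, absent in sorted(
                self.absent_in.items(), key=lambda kv: (len(kv[0]), sorted(kv[0]))
            )
        ]
        return pd.DataFrame(rows, columns=["clade", "size", "reliable", "absent_in"])


def jackknife_reliability(
    sim: SimilarityMatrix,
    transform: str | Callable[[float, float, float], float] = "zscore-ratio",
) -> tuple[ClusterTree, JackknifeReport]:
    """UPGMA tree plus leave-one-taxon-out node reliability.

    For each of the n replicates one structure is removed, the tree is
    rebuilt from the remaining similarities, and each internal clade of the
    full tree — restricted to the surviving taxa — is looked up among the
    replicate's clades. Restricted clades of size < 2 (or covering all
    surviving taxa) are vacuously present. A node is reliable only if it is
    found in all replicates.
    """
    if sim.n < 4:
        raise GHMotifError(
            "jackknife reliability needs n >= 4 taxa (no testable internal node)"
        )
    full_tree = upgma(similarity_to_distance(sim, transform))
    full_clades = full_tree.clades()
    absent_in: dict[frozenset[str], list[str]] = {c: [] for c in full_clades}
    for leaf in sim.labels:
        replicate = upgma(similarity_to_distance(sim.drop(leaf), transform))
        rep_clades = replicate.clades()
        remaining = frozenset(replicate.leaf_labels)
        for clade in full_clades:
            restricted = clade - {leaf}
            if len(restricted) < 2 or restricted == remaining:
                continue  # vacuously present
            if restricted not in rep_clades:
                absent_in[clade].append(leaf)
    report = JackknifeReport(absent_in=absent_in)
    tree = full_tree.with_reliability(
        {c: not absent for c, absent in absent_in.items()}
    )
    return tree, report


# ---------------------------------------------------------------------------
# family distance summaries
# ---------------------------------------------------------------------------

def family_distances(
    dist: DistanceMatrix, assignment: Mapping[str, str]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Within- and between-family mean structural distances.

    Returns ``(within, between)``: ``within`` has one row per family with
    member count and the mean over unordered member pairs (NaN for
    singletons, rendered as "–" in the tables); ``between`` is a square
    family-by-family frame of means over all cross pairs.
    """
    missing = [l for l in dist.labels if l not in assignment]
    if missing:
        raise GHMotifError(f"labels without family assignment: {missing}")
    families: dict[str, list[int]] = {}
    for i, label in enumerate(dist.labels):
        families.setdefault(assignment[label], []).append(i)
    names = sorted(families)

    within_rows = []
    for fam in names:
        idx = families[fam]
        if len(idx) < 2:
            mean = math.nan
        else:
            vals = [dist.values[a, b] for k, a in enumerate(idx) for b in idx[k + 1:]]
            mean = float(np.mean(vals))
        within_rows.append({"family": fam, "n_members": len(idx), "mean_within": mean})
    within = pd.DataFrame(within_rows).set_index("family")

    between = pd.DataFrame(np.nan, index=names, columns=names)
    for i, fa in enumerate(names):
        between.loc[fa, fa] = 0.0
        for fb in names[i + 1:]:
            vals = dist.values[np.ix_(families[fa], families[fb])]
            between.loc[fa, fb] = between.loc[fb, fa] = float(np.mean(vals))
    return within, between
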