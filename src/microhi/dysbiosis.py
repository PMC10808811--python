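"""Dysbiosis detection from dendrogram position.

Gut samples are clustered by Bray-Curtis dissimilarity with average linkage
(UPGMA). Working from the anchor assumption that most individuals of a
species carry a normal gut microbiota, each species' "normal branch" is the
subtree where its conspecifics concentrate; samples falling outside every
normal branch of their species are called disordered (unhealthy).

Two operationalisations are provided:

* ``branch`` (default): candidate branches for species *s* are subtrees
  with at least ``min_conspecifics`` members of *s* and *s*-purity at least
  ``purity_min``; the normal branch maximises net support times
  persistence, where net support is members of *s* minus intruders and
  persistence is how long the subtree survives before being absorbed into
  a larger merge (its parent's height minus its own). A definite species
  branch is strongly separated from the rest of the forest and persists
  long, whereas subclades inside a mixed disordered region are absorbed
  almost immediately; weighting support by persistence therefore anchors
  the call on the coherent conspecific clade even when, by sampling
  accident, disordered conspecifics outnumber normal ones. No cut height
  is needed.
* ``cut``: the tree is cut into flat clusters at the ``cut_q``-th percentile
  of merge heights and the cluster holding the plurality of conspecifics is
  the normal branch.

Species with fewer than ``min_conspecifics`` samples cannot anchor a branch
of their own and are judged against ecotype-similar neighbours instead: such
a sample is healthy when its nearest sizeable ancestor branch is dominated
by gut samples sharing its ecotype.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster
from scipy.spatial.distance import pdist, squareform

from .io_config import AbundanceTable, SampleMetadata, ValidationError, metadata_frame

logger = logging.getLogger("microhi")

SYMMETRY_TOL = 1e-12


@dataclass
class DistanceMatrix:
    """Symmetric Bray-Curtis dissimilarity matrix over named samples."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1] or v.shape[0] != len(self.ids):
            raise ValidationError("distance matrix shape does not match ids")
        if np.abs(v - v.T).max(initial=0.0) > SYMMETRY_TOL:
            raise ValidationError("distance matrix is not symmetric")
        if np.abs(np.diag(v)).max(initial=0.0) > SYMMETRY_TOL:
            raise ValidationError("distance matrix diagonal is not zero")
        if (v < -SYMMETRY_TOL).any() or (v > 1 + 1e-9).any():
            raise ValidationError("Bray-Curtis dissimilarities must lie in [0, 1]")
        self.values = v


@dataclass
class Dendrogram:
    """Binary merge tree in scipy linkage format over named leaves.

    ``linkage[k] = [i, j, height, size]`` merges clusters ``i`` and ``j``
    (ids below ``n`` are leaves, id ``n + k`` is the cluster made at step
    ``k``). Average-linkage heights are non-decreasing from leaves to root.
    """

    ids: list[str]
    linkage: np.ndarray

    @property
    def merge_heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def to_newick(self) -> str:
        from skbio.tree import TreeNode  # deliberate lazy import: heavy

        tree = TreeNode.from_linkage_matrix(self.linkage, self.ids)
        return str(tree)


def bray_curtis_matrix(
    table: AbundanceTable, subset: Sequence[str] | None = None
) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarity between sample columns.

    For proportion vectors a, b: BC(a, b) = 1 - sum_t min(a_t, b_t) / 1,
    equivalently sum|a - b| / sum(a + b).
    """
    if subset is not None:
        table = table.subset(subset)
    if len(table.samples) < 2:
        raise ValidationError("need at least two samples for a distance matrix")
    condensed = pdist(table.values.T, metric="braycurtis")
    matrix = squareform(condensed)
    return DistanceMatrix(table.samples, matrix)


_LINKAGE_UPDATES = {
    "average": lambda di, dj, ni, nj: (ni * di + nj * dj) / (ni + nj),
    "single": lambda di, dj, ni, nj: np.minimum(di, dj),
    "complete": lambda di, dj, ni, nj: np.maximum(di, dj),
}


def average_linkage_tree(dm: DistanceMatrix, method: str = "average") -> Dendrogram:
    """Agglomerative clustering with deterministic lexicographic tie-breaks.

    At every step the closest pair of clusters is merged; among equally
    close pairs the one with the lexicographically smallest (older, older)
    cluster ids wins, so the tree is a pure function of the input matrix.
    """
    if method not in _LINKAGE_UPDATES:
        raise ValidationError(f"unknown linkage method {method!r}")
    update = _LINKAGE_UPDATES[method]
    n = len(dm.ids)
    D = dm.values.astype(float).copy()
    np.fill_diagonal(D, np.inf)
    cluster_ids = list(range(n))  # kept ascending; new clusters append
    sizes = [1] * n
    Z = np.zeros((n - 1, 4))
    for step in range(n - 1):
        m = D.shape[0]
        iu, ju = np.triu_indices(m, 1)
        k = int(np.argmin(D[iu, ju]))  # row-major: smallest (i, j) on ties
        i, j = int(iu[k]), int(ju[k])
        height = D[i, j]
        ni, nj = sizes[i], sizes[j]
        Z[step] = (cluster_ids[i], cluster_ids[j], height, ni + nj)
        merged = update(np.delete(D[i], [i, j]), np.delete(D[j], [i, j]), ni, nj)
        keep = [c for c in range(m) if c not in (i, j)]
        D = D[np.ix_(keep, keep)]
        D = np.pad(D, ((0, 1), (0, 1)), constant_values=np.inf)
        D[-1, :-1] = merged
        D[:-1, -1] = merged
        cluster_ids = [cluster_ids[c] for c in keep] + [n + step]
        sizes = [sizes[c] for c in keep] + [ni + nj]
    return Dendrogram(list(dm.ids), Z)


# ---------------------------------------------------------------------------
# Health labels
# ---------------------------------------------------------------------------


@dataclass
class HealthLabel:
    sample_id: str
    status: str  # "healthy" | "unhealthy"
    branch_id: int
    branch_purity: float
    rule_trace: str


def _node_members(Z: np.ndarray, n: int) -> list[np.ndarray]:
    """Leaf index sets for every node id (0..2n-2)."""
    members: list[list[int]] = [[i] for i in range(n)]
    for step in range(n - 1):
        left, right = int(Z[step, 0]), int(Z[step, 1])
        members.append(members[left] + members[right])
    return [np.asarray(m) for m in members]


def classify_disordered(
    tree: Dendrogram,
    meta: Sequence[SampleMetadata] | pd.DataFrame,
    min_conspecifics: int = 3,
    purity_min: float = 0.6,
    strategy: str = "branch",
    cut_q: float = 75.0,
) -> list[HealthLabel]:
    """Label every gut leaf of the dendrogram healthy or unhealthy.

    All leaves must be gut samples carrying species and ecotype. See the
    module docstring for the two strategies.
    """
    frame = meta if isinstance(meta, pd.DataFrame) else metadata_frame(meta)
    missing = [s for s in tree.ids if s not in frame.index]
    if missing:
        raise ValidationError(f"leaves without metadata: {missing}")
    sub = frame.loc[list(tree.ids)]
    if (sub["source"] != "gut").any():
        bad = sub.index[sub["source"] != "gut"].tolist()
        raise ValidationError(f"non-gut leaves in the dendrogram: {bad}")
    species = sub["species"].to_numpy()
    ecotype = sub["ecotype"].to_numpy()

    if strategy == "branch":
        return _classify_branch(tree, species, ecotype, min_conspecifics, purity_min)
    if strategy == "cut":
        return _classify_cut(tree, species, ecotype, min_conspecifics, purity_min, cut_q)
    raise ValidationError(f"unknown disorder-rule strategy {strategy!r}")


def _classify_branch(
    tree: Dendrogram,
    species: np.ndarray,
    ecotype: np.ndarray,
    min_conspecifics: int,
    purity_min: float,
) -> list[HealthLabel]:
    n = len(tree.ids)
    members = _node_members(tree.linkage, n)
    labels: dict[int, HealthLabel] = {}
    Z = tree.linkage
    heights = np.zeros(2 * n - 1)
    top = float(Z[:, 2].max()) if n > 1 else 0.0
    parent_height = np.full(2 * n - 1, top + max(top, 1.0) * 0.05)
    for step in range(n - 1):
        heights[n + step] = Z[step, 2]
        parent_height[int(Z[step, 0])] = Z[step, 2]
        parent_height[int(Z[step, 1])] = Z[step, 2]

    def ecotype_fallback(leaf: int, why: str) -> HealthLabel:
        # nearest ancestor with enough members, judged by ecotype purity
        node = _smallest_ancestor(tree.linkage, n, leaf, min_conspecifics)
        if node is None:
            return HealthLabel(tree.ids[leaf], "unhealthy", -1, 0.0, f"{why}; no branch")
        group = members[node]
        others = group[group != leaf]
        purity = float((ecotype[others] == ecotype[leaf]).mean()) if others.size else 0.0
        status = "healthy" if purity >= purity_min else "unhealthy"
        return HealthLabel(
            tree.ids[leaf],
            status,
            node,
            purity,
            f"{why}; ecotype branch purity {purity:.2f} at node {node}",
        )

    for s in sorted(set(species)):
        leaves = np.flatnonzero(species == s)
        if leaves.size < min_conspecifics:
            logger.warning(
                "species %s has %d sample(s) (< %d): judged by ecotype branches",
                s,
                leaves.size,
                min_conspecifics,
            )
            for leaf in leaves:
                labels[leaf] = ecotype_fallback(
                    leaf, f"rare species {s} (n={leaves.size})"
                )
            continue
        best = None  # (support * persistence, margin, count, -size, -node_id)
        for node_id, group in enumerate(members):
            count = int((species[group] == s).sum())
            if count < min_conspecifics:
                continue
            purity = count / group.size
            if purity < purity_min:
                continue
            # net support: conspecifics minus intruders; persistence: how
            # long the subtree survives before being absorbed upward
            margin = 2 * count - group.size
            persistence = float(parent_height[node_id] - heights[node_id])
            key = (margin * persistence, margin, count, -group.size, -node_id)
            if best is None or key > best[0]:
                best = (key, node_id, purity)
        if best is None:
            logger.warning("species %s anchors no pure branch; using ecotype rule", s)
            for leaf in leaves:
                labels[leaf] = ecotype_fallback(leaf, f"no pure branch for {s}")
            continue
        _, node_id, purity = best
        inside = set(members[node_id].tolist())
        for leaf in leaves:
            if leaf in inside:
                labels[leaf] = HealthLabel(
                    tree.ids[leaf],
                    "healthy",
                    node_id,
                    purity,
                    f"inside normal branch {node_id} of {s}",
                )
            else:
                labels[leaf] = HealthLabel(
                    tree.ids[leaf],
                    "unhealthy",
                    node_id,
                    purity,
                    f"outside normal branch {node_id} of {s}",
                )
    return [labels[i] for i in range(n)]


def _smallest_ancestor(
    Z: np.ndarray, n: int, leaf: int, min_size: int
) -> int | None:
    parent = np.full(2 * n - 1, -1)
    sizes = np.ones(2 * n - 1, dtype=int)
    for step in range(n - 1):
        left, right = int(Z[step, 0]), int(Z[step, 1])
        parent[left] = parent[right] = n + step
        sizes[n + step] = sizes[left] + sizes[right]
    node = leaf
    while node != -1:
        if sizes[node] >= min_size and node != leaf:
            return node
        node = parent[node]
    return None


def _classify_cut(
    tree: Dendrogram,
    species: np.ndarray,
    ecotype: np.ndarray,
    min_conspecifics: int,
    purity_min: float,
    cut_q: float,
) -> list[HealthLabel]:
    n = len(tree.ids)
    height = float(np.percentile(tree.merge_heights, cut_q))
    flat = fcluster(tree.linkage, t=height, criterion="distance")
    labels: dict[int, HealthLabel] = {}
    for s in sorted(set(species)):
        leaves = np.flatnonzero(species == s)
        if leaves.size < min_conspecifics:
            for leaf in leaves:
                cluster = flat[leaf]
                group = np.flatnonzero(flat == cluster)
                others = group[group != leaf]
                purity = (
                    float((ecotype[others] == ecotype[leaf]).mean())
                    if others.size
                    else 0.0
                )
                ok = purity >= purity_min and group.size >= min_conspecifics
                labels[leaf] = HealthLabel(
                    tree.ids[leaf],
                    "healthy" if ok else "unhealthy",
                    int(cluster),
                    purity,
                    f"rare species {s}; ecotype purity {purity:.2f} in cluster {cluster}",
                )
            continue
        clusters, counts = np.unique(flat[leaves], return_counts=True)
        order = np.lexsort((clusters, -counts))  # plurality, ties -> smaller id
        normal = int(clusters[order[0]])
        count = int(counts[order[0]])
        size = int((flat == normal).sum())
        purity = count / size
        for leaf in leaves:
            inside = flat[leaf] == normal
            ok = inside and count >= min_conspecifics
            labels[leaf] = HealthLabel(
                tree.ids[leaf],
                "healthy" if ok else "unhealthy",
                normal,
                purity,
                f"{'inside' if inside else 'outside'} plurality cluster {normal} of {s}",
            )
    return [labels[i] for i in range(n)]


# ---------------------------------------------------------------------------
# Multi-level consensus
# ---------------------------------------------------------------------------


def labels_to_series(labels: Sequence[HealthLabel]) -> pd.Series:
    return pd.Series(
        {l.sample_id: l.status for l in labels}, name="status"
    ).sort_index()


def classify_multilevel(
    tables: Mapping[str, AbundanceTable],
    meta: Sequence[SampleMetadata] | pd.DataFrame,
    subset: Sequence[str] | None = None,
    min_conspecifics: int = 3,
    purity_min: float = 0.6,
    strategy: str = "branch",
    cut_q: float = 75.0,
    linkage: str = "average",
) -> pd.DataFrame:
    """Classify at each taxonomic level and take the majority consensus.

    ``tables`` maps level name (species/genus/family/...) to the abundance
    table at that level over the same samples. Returns one row per sample
    with a status column per level and a ``consensus`` column; ties resolve
    to healthy, following the anchor assumption that normality is the norm.
    """
    if not tables:
        raise ValidationError("no abundance tables supplied")
    per_level = {}
    for level, table in sorted(tables.items()):
        dm = bray_curtis_matrix(table, subset=subset)
        tree = average_linkage_tree(dm, method=linkage)
        labels = classify_disordered(
            tree,
            meta,
            min_conspecifics=min_conspecifics,
            purity_min=purity_min,
            strategy=strategy,
            cut_q=cut_q,
        )
        per_level[level] = labels_to_series(labels)
    frame = pd.DataFrame(per_level)
    votes = (frame == "unhealthy").sum(axis=1)
    frame["consensus"] = np.where(
        votes * 2 > len(per_level), "unhealthy", "healthy"
    )
    frame.index.name = "sample_id"
    return frame
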