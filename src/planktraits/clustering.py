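"""Gower dissimilarity, Ward clustering and functional-group extraction.

Functional groups are obtained by agglomerative Ward clustering of the
species x trait one-hot matrix under Gower dissimilarity, with the number
of groups chosen by the elbow (maximum-curvature) criterion on the
within-cluster dispersion curve.

Two equivalent Gower modes are provided: ``binary_columns`` averages
absolute differences over the 17 binary modality columns, while
``categorical_traits`` counts the number of the four traits whose
modalities differ.  For one-hot inputs a mismatching trait flips exactly
two binary columns, so ``d_bin = (8/17) * d_cat`` and the two modes yield
identical tree topologies (Ward is invariant to uniform rescaling).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .datamodel import TRAITS, TRAIT_BLOCKS, TraitMatrix, ValidationError

__all__ = [
    "DissimilarityMatrix",
    "Dendrogram",
    "FunctionalGroupAssignment",
    "ElbowCurve",
    "gower",
    "ward_cluster",
    "cut_tree",
    "elbow_select",
    "argmax_curvature",
    "export_dendrogram",
    "import_dendrogram",
]


@dataclass
class DissimilarityMatrix:
    """Symmetric pairwise dissimilarity in [0, 1] with zero diagonal."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValidationError(
                f"dissimilarity matrix shape {self.values.shape} does not match "
                f"{n} labels"
            )
        if not np.allclose(self.values, self.values.T, rtol=0, atol=1e-12):
            raise ValidationError("dissimilarity matrix is not symmetric")
        if np.any(np.diag(self.values) != 0):
            raise ValidationError("dissimilarity matrix diagonal must be exactly 0")
        if np.any(self.values < 0) or np.any(self.values > 1):
            raise ValidationError("dissimilarity values must lie in [0, 1]")

    @property
    def n(self) -> int:
        return len(self.labels)


@dataclass
class Dendrogram:
    """Full merge tree from agglomerative clustering.

    ``merges`` holds ``n - 1`` tuples ``(left, right, height, size)`` using
    the usual node numbering: leaves are ``0 .. n-1`` in ``leaf_labels``
    order and the merge at step ``t`` creates node ``n + t``.
    """

    leaf_labels: list[str]
    merges: list[tuple[int, int, float, int]]

    def __post_init__(self) -> None:
        n = len(self.leaf_labels)
        if len(self.merges) != n - 1:
            raise ValidationError(
                f"dendrogram must contain {n - 1} merges, got {len(self.merges)}"
            )
        heights = [m[2] for m in self.merges]
        if any(h2 < h1 - 1e-9 for h1, h2 in zip(heights, heights[1:])):
            raise ValidationError("merge heights must be non-decreasing")
        if self.merges and self.merges[-1][3] != n:
            raise ValidationError("final merge must contain all leaves")

    @property
    def n(self) -> int:
        return len(self.leaf_labels)

    def leaf_sets(self) -> list[frozenset[int]]:
        """Leaf membership of every node (leaves first, then merge nodes)."""
        n = self.n
        members: list[frozenset[int]] = [frozenset([i]) for i in range(n)]
        for left, right, _h, _s in self.merges:
            members.append(members[left] | members[right])
        return members


@dataclass
class FunctionalGroupAssignment:
    """Species -> functional-group labels for one cut of the dendrogram.

    Group ids are contiguous ``1 .. k``.  Cuts produced by
    :func:`cut_tree` number groups by decreasing size, breaking ties by
    the first species (leaf order) each group contains.
    """

    species: list[str]
    group_ids: np.ndarray
    k: int

    def __post_init__(self) -> None:
        self.group_ids = np.asarray(self.group_ids, dtype=int)
        if self.group_ids.shape != (len(self.species),):
            raise ValidationError("one group id per species required")
        present = set(self.group_ids.tolist())
        if present != set(range(1, self.k + 1)):
            raise ValidationError(
                f"group ids must be contiguous 1..{self.k}, got {sorted(present)}"
            )

    def as_dict(self) -> dict[str, int]:
        return dict(zip(self.species, self.group_ids.tolist()))

    def members(self, group_id: int) -> list[str]:
        return [s for s, g in zip(self.species, self.group_ids) if g == group_id]

    def sizes(self) -> dict[int, int]:
        ids, counts = np.unique(self.group_ids, return_counts=True)
        return dict(zip(ids.tolist(), counts.tolist()))


@dataclass
class ElbowCurve:
    """Within-cluster dispersion versus number of groups, with selected k."""

    k_values: list[int]
    wss: list[float]
    selected_k: int


def gower(matrix: TraitMatrix, mode: str = "categorical_traits") -> DissimilarityMatrix:
    """Pairwise Gower dissimilarity between species trait profiles.

    ``binary_columns``: mean absolute difference over the 17 one-hot
    columns.  ``categorical_traits``: fraction of the 4 traits whose
    modalities differ.
    """
    X = matrix.values  # validated one-hot upstream by TraitMatrix
    n = X.shape[0]
    if mode == "binary_columns":
        diff = np.abs(X[:, None, :] - X[None, :, :]).sum(axis=2)
        values = diff / X.shape[1]
    elif mode == "categorical_traits":
        mismatch = np.zeros((n, n))
        for block in TRAIT_BLOCKS.values():
            codes = np.argmax(X[:, block], axis=1)
            mismatch += codes[:, None] != codes[None, :]
        values = mismatch / len(TRAITS)
    else:
        raise ValueError(f"unknown gower mode {mode!r}")
    np.fill_diagonal(values, 0.0)
    return DissimilarityMatrix(labels=list(matrix.species), values=values)


def ward_cluster(d: DissimilarityMatrix, squared: bool = True) -> Dendrogram:
    """Agglomerative Ward clustering via the Lance-Williams recurrence.

    With ``squared=True`` (the default, the Ward.D2 convention) the
    recurrence runs on squared dissimilarities and merge heights are the
    square roots of the updated values, matching the common default of
    hierarchical-clustering toolkits; ``squared=False`` runs classic
    Ward.D directly on the dissimilarities.  Ties in the merge cost are
    broken toward the smallest (row, column) node-id pair, which makes
    the merge sequence fully deterministic.
    """
    n = d.n
    if n < 2:
        raise ValidationError("clustering requires at least 2 items")
    total = 2 * n - 1
    M = np.full((total, total), np.inf)
    M[:n, :n] = d.values**2 if squared else d.values
    np.fill_diagonal(M, np.inf)
    sizes = np.zeros(total, dtype=int)
    sizes[:n] = 1
    active: list[int] = list(range(n))
    merges: list[tuple[int, int, float, int]] = []
    for step in range(n - 1):
        ids = np.array(active)
        sub = M[np.ix_(ids, ids)]
        iu = np.triu_indices(len(ids), k=1)
        flat = sub[iu]
        # Costs within a relative tolerance of the minimum are treated as
        # exact ties so the tie-break (smallest (row, col) pair, row-major
        # order) is stable under uniform rescaling of the input.
        m = float(np.min(flat))
        best = int(np.nonzero(flat <= m + 1e-9 * max(m, 1e-300))[0][0])
        i = int(ids[iu[0][best]])
        j = int(ids[iu[1][best]])
        cost = float(flat[best])
        height = math.sqrt(max(cost, 0.0)) if squared else cost
        new = n + step
        si, sj = sizes[i], sizes[j]
        others = np.array([a for a in active if a not in (i, j)], dtype=int)
        if others.size:
            sk = sizes[others]
            upd = ((si + sk) * M[i, others] + (sj + sk) * M[j, others] - sk * cost) / (
                si + sj + sk
            )
            M[new, others] = upd
            M[others, new] = upd
        sizes[new] = si + sj
        active = [a for a in active if a not in (i, j)] + [new]
        merges.append((i, j, height, int(si + sj)))
    return Dendrogram(leaf_labels=list(d.labels), merges=merges)


def _relabel(species: Sequence[str], raw_groups: list[set[int]]) -> FunctionalGroupAssignment:
    # Number groups by decreasing size; ties go to the group whose first
    # species appears earliest in leaf order.
    order = sorted(range(len(raw_groups)), key=lambda g: (-len(raw_groups[g]), min(raw_groups[g])))
    ids = np.zeros(len(species), dtype=int)
    for new_id, g in enumerate(order, start=1):
        for leaf in raw_groups[g]:
            ids[leaf] = new_id
    return FunctionalGroupAssignment(species=list(species), group_ids=ids, k=len(raw_groups))


def cut_tree(dendrogram: Dendrogram, k: int) -> FunctionalGroupAssignment:
    """Partition species into ``k`` groups by undoing the last ``k-1`` merges."""
    n = dendrogram.n
    if not 1 <= k <= n:
        raise ValidationError(f"k must lie in [1, {n}], got {k}")
    members: list[set[int] | None] = [set([i]) for i in range(n)]
    for left, right, _h, _s in dendrogram.merges[: n - k]:
        merged = members[left] | members[right]  # type: ignore[operator]
        members[left] = None
        members[right] = None
        members.append(merged)
    raw = [m for m in members if m is not None]
    assert len(raw) == k
    return _relabel(dendrogram.leaf_labels, raw)


def _within_dispersion(d2: np.ndarray, assignment: FunctionalGroupAssignment) -> float:
    """Total within-cluster dispersion: sum over clusters of
    (1 / (2 |C|)) * sum over ordered member pairs of d^2."""
    total = 0.0
    for g in range(1, assignment.k + 1):
        idx = np.nonzero(assignment.group_ids == g)[0]
        if idx.size > 1:
            total += d2[np.ix_(idx, idx)].sum() / (2 * idx.size)
    return total


def argmax_curvature(k_values: Sequence[int], wss: Sequence[float]) -> int:
    """Elbow rule: k maximizing the second difference of the wss curve.

    Only interior points (those with both neighbours on the curve) are
    eligible; ties go to the smallest k.
    """
    if len(k_values) < 3:
        raise ValidationError("elbow selection needs at least 3 points on the curve")
    best_k, best_c = None, -np.inf
    for t in range(1, len(k_values) - 1):
        c = wss[t - 1] - 2 * wss[t] + wss[t + 1]
        if c > best_c + 1e-12:
            best_c, best_k = c, k_values[t]
    assert best_k is not None
    return int(best_k)


def elbow_select(
    d: DissimilarityMatrix, dendrogram: Dendrogram, k_max: int | None = None
) -> ElbowCurve:
    """Within-cluster dispersion for k = 2..k_max and the elbow choice of k.

    The default ``k_max`` is ``min(n - 1, 15)``.  The full curve is always
    returned so the automatic choice can be overridden by inspection.
    """
    n = d.n
    if k_max is None:
        k_max = min(n - 1, 15)
    if not 2 <= k_max <= n - 1:
        raise ValidationError(f"k_max must lie in [2, {n - 1}], got {k_max}")
    if k_max < 4:
        raise ValidationError("k_max must be at least 4 to locate a curvature maximum")
    d2 = d.values**2
    k_values = list(range(2, k_max + 1))
    wss = [_within_dispersion(d2, cut_tree(dendrogram, k)) for k in k_values]
    return ElbowCurve(k_values=k_values, wss=wss, selected_k=argmax_curvature(k_values, wss))


# ---------------------------------------------------------------------------
# Dendrogram export / import


def _node_heights(dendrogram: Dendrogram) -> list[float]:
    heights = [0.0] * dendrogram.n
    for _l, _r, h, _s in dendrogram.merges:
        heights.append(h)
    return heights


def export_dendrogram(dendrogram: Dendrogram, format: str = "newick") -> str:
    """Serialize a dendrogram as newick or as a JSON merge list.

    Newick internal nodes are labelled ``n<step>`` with their merge step so
    that the merge order (including ties at equal heights) survives a round
    trip; branch lengths are differences of merge heights.
    """
    if format == "merge_json":
        return json.dumps(
            {
                "leaves": dendrogram.leaf_labels,
                "merges": [[l, r, h, s] for l, r, h, s in dendrogram.merges],
            }
        )
    if format != "newick":
        raise ValueError(f"unknown dendrogram format {format!r}")
    n = dendrogram.n
    heights = _node_heights(dendrogram)

    def render(node: int, parent_height: float) -> str:
        length = parent_height - heights[node]
        if node < n:
            return f"{dendrogram.leaf_labels[node]}:{length:.10g}"
        left, right, _h, _s = dendrogram.merges[node - n]
        inner = f"({render(left, heights[node])},{render(right, heights[node])})"
        return f"{inner}n{node - n}:{length:.10g}"

    root = 2 * n - 2
    left, right, _h, _s = dendrogram.merges[-1]
    body = f"({render(left, heights[root])},{render(right, heights[root])})n{n - 2}"
    return body + ";"


def import_dendrogram(text: str, format: str = "newick") -> Dendrogram:
    """Rebuild a dendrogram from :func:`export_dendrogram` output."""
    if format == "merge_json":
        payload = json.loads(text)
        merges = [(int(l), int(r), float(h), int(s)) for l, r, h, s in payload["merges"]]
        return Dendrogram(leaf_labels=list(payload["leaves"]), merges=merges)
    if format != "newick":
        raise ValueError(f"unknown dendrogram format {format!r}")
    import dendropy

    tree = dendropy.Tree.get(
        data=text,
        schema="newick",
        suppress_internal_node_taxa=True,
        preserve_underscores=True,
    )
    leaves = [lf.taxon.label for lf in tree.leaf_node_iter()]
    leaf_index = {label: i for i, label in enumerate(leaves)}
    n = len(leaves)

    node_height: dict[int, float] = {}
    node_id: dict[int, int] = {}
    step_children: dict[int, tuple[int, int]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            node_id[id(node)] = leaf_index[node.taxon.label]
            node_height[id(node)] = 0.0
        else:
            step = int(str(node.label)[1:])
            children = node.child_nodes()
            if len(children) != 2:
                raise ValidationError("dendrogram newick must be strictly binary")
            h = max(
                node_height[id(c)] + (c.edge.length or 0.0) for c in children
            )
            node_height[id(node)] = h
            node_id[id(node)] = n + step
            step_children[step] = (node_id[id(children[0])], node_id[id(children[1])])

    members: dict[int, int] = {i: 1 for i in range(n)}
    heights_by_step = {
        node_id[id(node)] - n: node_height[id(node)]
        for node in tree.postorder_internal_node_iter()
    }
    merges: list[tuple[int, int, float, int]] = []
    for step in range(n - 1):
        left, right = step_children[step]
        left, right = min(left, right), max(left, right)
        size = members[left] + members[right]
        members[n + step] = size
        merges.append((left, right, float(heights_by_step[step]), size))
    return Dendrogram(leaf_labels=leaves, merges=merges)
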