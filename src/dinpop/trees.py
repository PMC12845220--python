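"""Neighbor-Joining trees with column-resampling bootstrap support.

The agglomeration is Saitou-Nei with the Studier-Keppler Q criterion; ties in
Q are broken deterministically by the smallest pair of leaf labels, so a
fixed input always yields the same topology.  Bootstrap support is mapped by
bipartition (split) identity, not node identity: a replicate tree supports a
split of the original tree iff it contains the same leaf partition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .datamodel import DistanceMatrix, ValidationError


@dataclass
class Tree:
    """Unrooted tree as an adjacency map with branch lengths."""

    adjacency: dict[str, dict[str, float]]
    leaves: list[str]

    def neighbors(self, node: str) -> dict[str, float]:
        return self.adjacency[node]

    # -- bipartitions -------------------------------------------------------

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial splits, each canonicalised as the side that excludes
        the lexicographically smallest leaf."""
        ref = min(self.leaves)
        out: set[frozenset[str]] = set()
        seen_edges = set()
        for u in self.adjacency:
            for v in self.adjacency[u]:
                edge = frozenset((u, v))
                if edge in seen_edges:
                    continue
                seen_edges.add(edge)
                side = self._leaves_beyond(u, v)
                if ref in side:
                    side = frozenset(set(self.leaves) - side)
                if 2 <= len(side) <= len(self.leaves) - 2:
                    out.add(side)
        return out

    def _leaves_beyond(self, u: str, v: str) -> frozenset[str]:
        """Leaves on the v-side of the edge (u, v)."""
        stack, visited, found = [v], {u, v}, []
        while stack:
            node = stack.pop()
            if node in self.leaf_set:
                found.append(node)
            for nxt in self.adjacency[node]:
                if nxt not in visited:
                    visited.add(nxt)
                    stack.append(nxt)
        return frozenset(found)

    @property
    def leaf_set(self) -> set[str]:
        return set(self.leaves)

    def path_length(self, a: str, b: str) -> float:
        """Sum of branch lengths along the unique a-b path."""
        prev: dict[str, str] = {a: a}
        stack = [a]
        while stack:
            node = stack.pop()
            if node == b:
                break
            for nxt in self.adjacency[node]:
                if nxt not in prev:
                    prev[nxt] = node
                    stack.append(nxt)
        if b not in prev:
            raise KeyError(f"no path {a} .. {b}")
        total, node = 0.0, b
        while node != a:
            total += self.adjacency[node][prev[node]]
            node = prev[node]
        return total

    # -- Newick -------------------------------------------------------------

    def to_newick(self, support: dict[frozenset[str], float] | None = None,
                  min_support: float = 50.0) -> str:
        """Serialise rooted at an internal node (or the first leaf for n<=2).

        Internal nodes whose subtree defines a supported bipartition are
        labelled with the rounded support percentage when >= ``min_support``.
        """
        internal = [n for n in self.adjacency if n not in self.leaf_set]
        root = internal[0] if internal else self.leaves[0]
        ref = min(self.leaves)

        def render(node: str, parent: str | None) -> str:
            children = [c for c in self.adjacency[node] if c != parent]
            if not children:
                return node
            parts = []
            for c in children:
                sub = render(c, node)
                parts.append(f"{sub}:{self.adjacency[node][c]:.10g}")
            label = ""
            if support is not None and parent is not None:
                side = self._leaves_beyond(parent, node)
                key = side if ref not in side else frozenset(self.leaf_set - side)
                val = support.get(key)
                if val is not None and val >= min_support:
                    label = format(val, ".6g")
            return f"({','.join(parts)}){label}"

        return render(root, None) + ";"


def nj_tree(dm: DistanceMatrix) -> Tree:
    """Neighbor-Joining on a distance matrix (n >= 2 taxa, no NAs).

    Q(i, j) = (r - 2) d(i, j) - R_i - R_j; the minimising pair joins with
    limb lengths d(i,j)/2 +- (R_i - R_j) / (2 (r - 2)).  The final three
    nodes join at a central node by the three-point formulas.  Negative limb
    lengths are clamped to zero.
    """
    n = dm.n
    if n < 2:
        raise ValidationError("NJ needs >=2 taxa")
    nan_pairs = [
        (dm.labels[i], dm.labels[j])
        for i, j in zip(*np.where(~np.isfinite(dm.values)))
        if i < j
    ]
    if nan_pairs:
        raise ValidationError(f"distance matrix has NA entries for pairs: {nan_pairs}")

    adjacency: dict[str, dict[str, float]] = {l: {} for l in dm.labels}
    if n == 2:
        a, b = dm.labels
        d = float(dm.values[0, 1])
        adjacency[a][b] = adjacency[b][a] = d
        return Tree(adjacency, list(dm.labels))

    active = list(dm.labels)
    # smallest leaf label under each active node, for deterministic ties
    rep = {l: l for l in dm.labels}
    D = {a: {b: float(dm.values[i, j]) for j, b in enumerate(dm.labels)}
         for i, a in enumerate(dm.labels)}
    counter = 0

    def add_edge(u: str, v: str, length: float) -> None:
        length = max(length, 0.0)
        adjacency.setdefault(u, {})[v] = length
        adjacency.setdefault(v, {})[u] = length

    while len(active) > 3:
        r = len(active)
        R = {a: sum(D[a][b] for b in active if b != a) for a in active}
        best = None
        best_key = None
        for i, a in enumerate(active):
            for b in active[i + 1:]:
                q = (r - 2) * D[a][b] - R[a] - R[b]
                key = (q, *sorted((rep[a], rep[b])))
                if best_key is None or key < best_key:
                    best_key = key
                    best = (a, b)
        a, b = best
        counter += 1
        new = f"_nj{counter}"
        la = D[a][b] / 2 + (R[a] - R[b]) / (2 * (r - 2))
        lb = D[a][b] - la
        add_edge(new, a, la)
        add_edge(new, b, lb)
        D[new] = {}
        for c in active:
            if c in (a, b):
                continue
            d = (D[a][c] + D[b][c] - D[a][b]) / 2
            D[new][c] = D[c][new] = d
        active = [c for c in active if c not in (a, b)] + [new]
        rep[new] = min(rep[a], rep[b])

    a, b, c = sorted(active, key=lambda x: rep[x])
    counter += 1
    center = f"_nj{counter}"
    add_edge(center, a, (D[a][b] + D[a][c] - D[b][c]) / 2)
    add_edge(center, b, (D[a][b] + D[b][c] - D[a][c]) / 2)
    add_edge(center, c, (D[a][c] + D[b][c] - D[a][b]) / 2)
    return Tree(adjacency, list(dm.labels))


def bootstrap_support(
    data: np.ndarray,
    labels: list[str],
    distance_fn: Callable[[np.ndarray, list[str]], DistanceMatrix],
    reps: int = 2000,
    seed: int | np.random.Generator | None = None,
) -> dict[frozenset[str], float]:
    """Column-resampling bootstrap support for the NJ tree of ``data``.

    ``distance_fn(data, labels)`` must return a DistanceMatrix; each
    pseudoreplicate resamples columns of ``data`` with replacement.  Returns
    support (percent of replicate trees containing the split) for every
    non-trivial bipartition of the original tree.
    """
    rng = np.random.default_rng(seed)
    original = nj_tree(distance_fn(data, labels))
    targets = original.bipartitions()
    counts = {split: 0 for split in targets}
    m = data.shape[1]
    for _ in range(reps):
        cols = rng.integers(0, m, size=m)
        rep_tree = nj_tree(distance_fn(data[:, cols], labels))
        rep_splits = rep_tree.bipartitions()
        for split in targets:
            if split in rep_splits:
                counts[split] += 1
    return {split: 100.0 * c / reps for split, c in counts.items()}
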